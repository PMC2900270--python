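"""Shared fixtures: small simulated chromosomes for every stage.

Fingerprint fixtures use a 1/4000 bp restriction-site rate (~25-50 bands
per 100-200 kb clone) and a matching tolerance of 1 migration unit: with
noise-free band values the tolerance only needs to absorb rounding, and a
tight tolerance keeps chance band collisions — which crowd the small end
of the exponential fragment-size distribution — from eroding the score's
discrimination.
"""

import itertools

import pytest

from fpmap.assembly import AssemblyParams
from fpmap.simulate import Clone, digest_clones, simulate_genome

GRADIENT_PROFILE = (
    ((0, 1_500_000), 2.19),
    ((1_500_000, 3_000_000), 1.42),
    ((3_000_000, 6_000_000), 0.09),
)


@pytest.fixture(scope="session")
def gradient_genome():
    """6 Mb chromosome with the distal-high / proximal-low CE gradient."""
    return simulate_genome(6_000_000, 60, 1 / 4000, GRADIENT_PROFILE, seed=101)


@pytest.fixture(scope="session")
def uniform_genome():
    """1.2 Mb uniform-rate chromosome for assembly fixtures."""
    return simulate_genome(1_200_000, 0, 1 / 4000, (((0, 1_200_000), 1.0),), seed=7)


@pytest.fixture(scope="session")
def tiling_clones():
    """50-clone tiling path: 120 kb clones staggered by 20 kb."""
    return [Clone(f"C{i:03d}", i * 20_000, i * 20_000 + 120_000) for i in range(50)]


@pytest.fixture(scope="session")
def tiling_fingerprints(uniform_genome, tiling_clones):
    return digest_clones(uniform_genome, tiling_clones, 0.0, seed=0)


@pytest.fixture
def default_params():
    """Noise-free-fingerprint assembly settings (tolerance 1 unit)."""
    return AssemblyParams(tolerance=1)


def true_overlap_components(clones, min_overlap_bp):
    """Oracle: connected components of the physical-overlap graph."""
    parent = {c.id: c.id for c in clones}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in itertools.combinations(clones, 2):
        if min(a.end, b.end) - max(a.start, b.start) >= min_overlap_bp:
            ra, rb = find(a.id), find(b.id)
            if ra != rb:
                parent[ra] = rb
    comps = {}
    for c in clones:
        comps.setdefault(find(c.id), set()).add(c.id)
    return {frozenset(v) for v in comps.values()}
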