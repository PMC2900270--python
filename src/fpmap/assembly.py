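"""FPC-style contig assembly from restriction-fingerprint band lists.

Clone overlap is judged by the Sulston coincidence score: the probability
that two fingerprints share at least the observed number of bands by
chance.  Clone pairs scoring at or below a stringency cutoff are joined,
and contigs are the connected components of the resulting overlap graph.
Contig physical size is summarised in consensus-band (CB) units — the
number of distinct band classes across the contig's fingerprints — and
converted to kb with the library's average kb-per-CB factor.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from scipy.stats import binom

__all__ = [
    "Fingerprint",
    "AssemblyParams",
    "Contig",
    "match_bands",
    "sulston_score",
    "assemble_contigs",
    "consensus_band_count",
    "reassemble_targeted",
]


@dataclass(frozen=True)
class Fingerprint:
    """One clone's fingerprint: a sorted multiset of integer band sizes
    (gel migration units)."""

    clone_id: str
    bands: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError(f"fingerprint {self.clone_id}: at least one band required")
        if any(b <= 0 for b in self.bands):
            raise ValueError(f"fingerprint {self.clone_id}: band sizes must be positive")
        object.__setattr__(self, "bands", tuple(sorted(self.bands)))

    def __len__(self) -> int:
        return len(self.bands)


@dataclass(frozen=True)
class AssemblyParams:
    """Sulston-score assembly parameters.

    tolerance
        Band-matching tolerance t in migration units.
    gel_length
        Number G of distinguishable migration positions on the gel.
    cutoff
        Score threshold: pairs with score <= cutoff are joined.
    min_shared_bands
        Additional requirement on the matched-band count of a joined pair.
    kb_per_cb
        Average physical size of one consensus band, used for contig kb.
    """

    tolerance: int = 3
    gel_length: int = 3000
    cutoff: float = 1e-12
    min_shared_bands: int = 1
    kb_per_cb: float = 1.9

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if self.gel_length <= 2 * self.tolerance:
            raise ValueError("gel_length must exceed 2 * tolerance")
        if not 0 < self.cutoff < 1:
            raise ValueError("cutoff must lie in (0, 1)")
        if self.min_shared_bands < 0:
            raise ValueError("min_shared_bands must be >= 0")


@dataclass(frozen=True)
class Contig:
    """An assembled clone group with its consensus-band size."""

    id: str
    clone_ids: frozenset[str]
    cb_count: int
    size_kb: float

    def __post_init__(self) -> None:
        if not self.clone_ids:
            raise ValueError(f"contig {self.id}: clone set must be non-empty")

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    def __contains__(self, clone_id: str) -> bool:
        return clone_id in self.clone_ids


def match_bands(f1: Fingerprint, f2: Fingerprint, tolerance: int) -> int:
    """Count the maximum one-to-one band matching within ``tolerance``.

    Bands b1, b2 may pair iff |b1 - b2| <= tolerance.  On sorted band lists
    a two-pointer greedy sweep attains the maximum matching (ties resolve
    toward the smaller partner band); the count is symmetric in arguments.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    a, b = f1.bands, f2.bands
    i = j = matched = 0
    while i < len(a) and j < len(b):
        if abs(a[i] - b[j]) <= tolerance:
            matched += 1
            i += 1
            j += 1
        elif a[i] < b[j]:
            i += 1
        else:
            j += 1
    return matched


def sulston_score(f1: Fingerprint, f2: Fingerprint, params: AssemblyParams) -> float:
    """Probability that two fingerprints share >= the observed bands by chance.

    With band counts nL <= nH and m matched bands, each low-clone band is
    modelled as matching some high-clone band with probability
    p = 1 - (1 - 2t/G)**nH, independently; the score is the upper binomial
    tail P(X >= m), X ~ Binomial(nL, p).  Lower scores mean stronger
    evidence of true overlap; m = 0 gives 1.0.
    """
    n_low, n_high = sorted((len(f1), len(f2)))
    m = match_bands(f1, f2, params.tolerance)
    p = 1.0 - (1.0 - 2.0 * params.tolerance / params.gel_length) ** n_high
    # binom.sf(m-1) is the tail P(X >= m); clamp into (0, 1] for log-safety.
    score = float(binom.sf(m - 1, n_low, p))
    return min(1.0, max(score, 5e-324))


def consensus_band_count(fingerprints: list[Fingerprint], tolerance: int) -> int:
    """Number of consensus-band (CB) classes across a contig's fingerprints.

    Bands from all clones are pooled and merged by single linkage: sorted
    values chain into one class while consecutive values differ by at most
    ``tolerance``.  The class count is the contig's size in CB units.
    """
    if not fingerprints:
        raise ValueError("consensus_band_count requires at least one fingerprint")
    values = sorted(itertools.chain.from_iterable(f.bands for f in fingerprints))
    classes = 1
    for prev, cur in zip(values, values[1:]):
        if cur - prev > tolerance:
            classes += 1
    return classes


def _score_edges(fingerprints, params):
    """All clone pairs passing the cutoff and shared-band requirements,
    sorted by ascending score for reproducible merge order."""
    edges = []
    for fa, fb in itertools.combinations(fingerprints, 2):
        m = match_bands(fa, fb, params.tolerance)
        if m < params.min_shared_bands:
            continue
        s = sulston_score(fa, fb, params)
        if s <= params.cutoff:
            edges.append((s, fa.clone_id, fb.clone_id))
    edges.sort(key=lambda e: (e[0], e[1], e[2]))
    return edges


def assemble_contigs(
    fingerprints: list[Fingerprint],
    params: AssemblyParams | None = None,
) -> list[Contig]:
    """Assemble clones into contigs by Sulston-score overlap clustering.

    Clone pairs with score <= ``params.cutoff`` and at least
    ``params.min_shared_bands`` matched bands are joined; contigs are the
    connected components (merged in ascending-score edge order, which fixes
    the clustering trace without changing the partition).  Unjoined clones
    become singleton contigs.  Contig ids are assigned by descending clone
    count, then by the lexicographically smallest member clone id.
    """
    if params is None:
        params = AssemblyParams()
    if not fingerprints:
        raise ValueError("assemble_contigs requires at least one fingerprint")
    ids = [f.clone_id for f in fingerprints]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate clone ids: {', '.join(dupes)}")

    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for _, a, b in _score_edges(fingerprints, params):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    groups: dict[str, list[Fingerprint]] = {}
    for f in fingerprints:
        groups.setdefault(find(f.clone_id), []).append(f)

    members = sorted(groups.values(), key=lambda g: (-len(g), min(f.clone_id for f in g)))
    contigs = []
    for idx, group in enumerate(members, start=1):
        cb = consensus_band_count(group, params.tolerance)
        contigs.append(
            Contig(
                id=f"ctg{idx}",
                clone_ids=frozenset(f.clone_id for f in group),
                cb_count=cb,
                size_kb=cb * params.kb_per_cb,
            )
        )
    return contigs


def reassemble_targeted(
    initial_contigs: list[Contig],
    positive_clone_ids: set[str],
    fingerprints: list[Fingerprint],
    params: AssemblyParams | None = None,
) -> list[Contig]:
    """Re-assemble only the clones connected to marker-positive clones.

    The subset is the union of all clones of any initial contig containing
    at least one positive clone, plus positive singletons not covered by an
    initial contig; this restricted set is then assembled from scratch.
    Re-assembling a targeted subset avoids false joins induced by the
    genome-wide fingerprint network.  An empty positive set yields an empty
    result.
    """
    if params is None:
        params = AssemblyParams()
    by_id = {f.clone_id: f for f in fingerprints}
    unknown = sorted(set(positive_clone_ids) - set(by_id))
    if unknown:
        raise ValueError(f"unknown positive clone id(s): {', '.join(unknown)}")
    if not positive_clone_ids:
        return []

    subset: set[str] = set()
    in_contig: set[str] = set()
    for contig in initial_contigs:
        in_contig |= contig.clone_ids
        if contig.clone_ids & positive_clone_ids:
            subset |= contig.clone_ids
    subset |= {cid for cid in positive_clone_ids if cid not in in_contig}  # positive singletons
    if not subset:
        return []
    return assemble_contigs([by_id[cid] for cid in sorted(subset)], params)
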