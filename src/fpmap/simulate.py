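"""Synthetic chromosome, BAC library, fingerprint and mapping-population simulators.

Everything downstream of this module (contig assembly, map anchoring,
recombination profiling, synteny analysis) is exercised against chromosomes
generated here, so each simulator carries explicit ground truth: clone
intervals, true restriction-fragment sets, true marker positions and the
piecewise recombination-rate profile.

Coordinate conventions: 0-based, half-open intervals on a single
chromosome; strands are encoded as +1/-1. All randomness flows through a
``numpy.random.Generator`` seeded explicitly per call; there is no global
RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembly import Fingerprint

__all__ = [
    "GenomeModel",
    "Clone",
    "GeneticMap",
    "MarkerLocus",
    "RearrangementScenario",
    "simulate_genome",
    "simulate_bac_library",
    "digest_clones",
    "simulate_marker_screen",
    "simulate_genetic_map",
    "derive_reference_orders",
    "apply_reversal",
    "bp_to_migration_units",
]

#: bp per migration unit of the simulated fingerprinting gel.
BP_PER_MIGRATION_UNIT = 10


def bp_to_migration_units(fragment_bp: float) -> int:
    """Convert a fragment length in bp to integer gel migration units."""
    return max(1, int(round(fragment_bp / BP_PER_MIGRATION_UNIT)))


@dataclass(frozen=True)
class Clone:
    """A simulated BAC clone: a genomic interval with a library tag."""

    id: str
    start: int
    end: int
    library: str = "BB"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"clone {self.id}: invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MarkerLocus:
    """A marker with its clone-screen result and optional map position.

    ``marker_class`` distinguishes expressed-gene probes ("EST-unigene",
    the only class counted as a gene by island detection) from genomic
    markers ("genomic/ISBP").  ``cM`` must be given together with
    ``map_source``; ``genotype_source`` names the accession whose DNA the
    screen and map share, which the anchoring rule requires to match the
    BAC-library genotype.
    """

    id: str
    marker_class: str = "EST-unigene"
    positive_clone_ids: frozenset[str] = frozenset()
    genotype_source: str = "AL8/78"
    cM: float | None = None
    map_source: str | None = None
    bin: str | None = None

    def __post_init__(self) -> None:
        if (self.cM is None) != (self.map_source is None):
            raise ValueError(f"marker {self.id}: cM and map_source must be given together")


@dataclass(frozen=True)
class GeneticMap:
    """An ordered genetic map: (marker_id, cM) with non-decreasing cM."""

    name: str
    entries: tuple[tuple[str, float], ...]
    genotype: str = "AL8/78"

    def __post_init__(self) -> None:
        positions = [cm for _, cm in self.entries]
        if any(b < a for a, b in zip(positions, positions[1:])):
            raise ValueError(f"map {self.name}: cM positions must be non-decreasing")

    def position(self, marker_id: str) -> float:
        hits = [cm for m, cm in self.entries if m == marker_id]
        if not hits:
            raise KeyError(f"marker {marker_id!r} not on map {self.name}")
        if len(set(hits)) > 1:
            raise ValueError(f"marker {marker_id!r} mapped at two positions on {self.name}")
        return hits[0]

    def __contains__(self, marker_id: str) -> bool:
        return any(m == marker_id for m, _ in self.entries)


@dataclass(frozen=True)
class GenomeModel:
    """A simulated chromosome with gene loci, restriction sites and a
    piecewise-constant recombination-rate (coefficient of exchange) profile.

    ``ce_profile`` is a tuple of ((start_bp, end_bp), rate_cM_per_Mb)
    entries that must tile [0, length) without overlap; the chromosome's
    total genetic length is exactly sum(rate_i * span_i_in_Mb).
    """

    length: int
    gene_loci: tuple[tuple[str, int, int], ...]  # (id, position bp, strand ±1)
    site_positions: tuple[int, ...]
    ce_profile: tuple[tuple[tuple[int, int], float], ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("genome length must be positive")
        validate_ce_profile(self.ce_profile, self.length)
        for gid, pos, strand in self.gene_loci:
            if not 0 <= pos < self.length:
                raise ValueError(f"gene {gid} position {pos} outside [0, {self.length})")
            if strand not in (-1, 1):
                raise ValueError(f"gene {gid}: strand must be ±1")
        for p in self.site_positions:
            if not 0 <= p < self.length:
                raise ValueError(f"restriction site {p} outside [0, {self.length})")

    @property
    def genetic_length_cM(self) -> float:
        return sum(rate * (e - s) / 1e6 for (s, e), rate in self.ce_profile)

    def genetic_position_cM(self, bp: float) -> float:
        """Integrate the CE profile from 0 to ``bp`` (cM)."""
        if not 0 <= bp <= self.length:
            raise ValueError(f"position {bp} outside [0, {self.length}]")
        total = 0.0
        for (s, e), rate in self.ce_profile:
            if bp <= s:
                break
            total += rate * (min(bp, e) - s) / 1e6
        return total


def validate_ce_profile(profile, length: int) -> None:
    """Require a non-overlapping, gap-free tiling of [0, length) with rates >= 0."""
    if not profile:
        raise ValueError("ce_profile must not be empty")
    intervals = sorted(profile, key=lambda iv: iv[0][0])
    cursor = 0
    for (s, e), rate in intervals:
        if rate < 0:
            raise ValueError(f"ce rate must be >= 0, got {rate}")
        if s != cursor:
            kind = "overlap" if s < cursor else "gap"
            raise ValueError(f"ce_profile {kind} at {min(s, cursor)}..{max(s, cursor)} bp")
        if e <= s:
            raise ValueError(f"empty ce interval [{s}, {e})")
        cursor = e
    if cursor != length:
        raise ValueError(f"ce_profile covers [0, {cursor}) but genome length is {length}")


def simulate_genome(
    length_bp: int,
    n_genes: int,
    site_rate_per_bp: float,
    ce_profile,
    seed: int,
    n_islands: int | None = None,
    island_span_bp: int = 150_000,
) -> GenomeModel:
    """Simulate a chromosome: clustered gene loci, Poisson restriction sites.

    Genes are placed uniformly within ``n_islands`` island windows (default:
    one island per ~3 genes) whose centres are uniform on the chromosome,
    emulating the gene-island organisation of Triticeae genomes; restriction
    sites are a homogeneous Poisson process at ``site_rate_per_bp``.
    """
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if site_rate_per_bp < 0:
        raise ValueError("site_rate_per_bp must be >= 0")
    profile = tuple(((int(s), int(e)), float(r)) for (s, e), r in ce_profile)
    validate_ce_profile(profile, length_bp)

    rng = np.random.default_rng(seed)
    # Restriction sites: Poisson count, then uniform order statistics.
    n_sites = rng.poisson(length_bp * site_rate_per_bp)
    sites = np.sort(rng.integers(0, length_bp, size=n_sites))

    # Gene islands: uniform centres, genes uniform inside their island window.
    loci: list[tuple[str, int, int]] = []
    if n_genes > 0:
        k = n_islands if n_islands is not None else max(1, n_genes // 3)
        centres = np.sort(rng.integers(0, length_bp, size=k))
        assignment = rng.integers(0, k, size=n_genes)
        width = min(island_span_bp, length_bp)
        digits = len(str(n_genes))
        positions = []
        for i in range(n_genes):
            c = int(centres[assignment[i]])
            lo = max(0, c - width // 2)
            hi = min(length_bp, c + width // 2)
            positions.append(int(rng.integers(lo, max(lo + 1, hi))))
        order = np.argsort(positions, kind="stable")
        strands = rng.choice([-1, 1], size=n_genes)
        loci = [
            (f"G{di + 1:0{digits}d}", int(positions[oi]), int(strands[oi]))
            for di, oi in enumerate(order)
        ]

    return GenomeModel(
        length=length_bp,
        gene_loci=tuple(loci),
        site_positions=tuple(int(p) for p in sites),
        ce_profile=profile,
        seed=seed,
    )


def simulate_bac_library(
    genome: GenomeModel,
    n_clones: int,
    insert_range_bp: tuple[int, int],
    seed: int,
    library: str = "BB",
) -> list[Clone]:
    """Draw a BAC library: uniform starts, uniform insert lengths.

    Clones running off the chromosome end are discarded and redrawn, so the
    returned list always has exactly ``n_clones`` fully contained clones.
    """
    if n_clones < 0:
        raise ValueError("n_clones must be >= 0")
    lo, hi = insert_range_bp
    if not 0 < lo <= hi <= genome.length:
        raise ValueError(f"insert range ({lo}, {hi}) must lie within (0, {genome.length}]")
    rng = np.random.default_rng(seed)
    clones: list[Clone] = []
    digits = max(4, len(str(n_clones)))
    while len(clones) < n_clones:
        start = int(rng.integers(0, genome.length))
        length = int(rng.integers(lo, hi + 1))
        if start + length > genome.length:
            continue  # clipped: discard and redraw
        clones.append(Clone(f"{library}{len(clones) + 1:0{digits}d}", start, start + length, library))
    return clones


def true_fragments_bp(genome: GenomeModel, clone: Clone) -> list[int]:
    """Exact restriction-fragment lengths of a clone insert (end fragments kept)."""
    sites = np.asarray(genome.site_positions)
    inside = sites[(sites > clone.start) & (sites < clone.end)]
    cuts = [clone.start, *inside.tolist(), clone.end]
    return [int(b - a) for a, b in zip(cuts, cuts[1:]) if b > a]


def digest_clones(
    genome: GenomeModel,
    clones: list[Clone],
    noise_sd_migration_units: float = 0.0,
    seed: int = 0,
) -> list[Fingerprint]:
    """Fingerprint clones: restriction fragments sized in noisy migration units.

    Fragments are the spans between consecutive restriction sites inside the
    clone plus the two end fragments, so a site-free clone yields a single
    band and, at zero noise, fragment lengths sum exactly to the clone
    length.  Sizes are converted to integer migration units (bp / 10,
    rounded) before Gaussian noise of the stated SD is added.
    """
    if noise_sd_migration_units < 0:
        raise ValueError("noise SD must be >= 0")
    rng = np.random.default_rng(seed)
    fingerprints = []
    for clone in clones:
        if clone.start < 0 or clone.end > genome.length:
            raise ValueError(f"clone {clone.id} outside the genome")
        bands = []
        for frag in true_fragments_bp(genome, clone):
            mu = bp_to_migration_units(frag)
            if noise_sd_migration_units > 0:
                mu = max(1, int(round(mu + rng.normal(0.0, noise_sd_migration_units))))
            bands.append(mu)
        fingerprints.append(Fingerprint(clone.id, tuple(sorted(bands))))
    return fingerprints


def simulate_marker_screen(
    genome: GenomeModel,
    clones: list[Clone],
    marker_positions: dict[str, int],
    false_pos_rate: float = 0.0,
    false_neg_rate: float = 0.0,
    seed: int = 0,
    marker_class: str = "EST-unigene",
    genotype_source: str = "AL8/78",
) -> list[MarkerLocus]:
    """Screen the clone library with markers (hybridization/PCR stand-in).

    A clone is truly positive iff its interval contains the marker position;
    each truth value is then flipped independently at the stated false-
    positive / false-negative rates.
    """
    for rate in (false_pos_rate, false_neg_rate):
        if not 0 <= rate <= 1:
            raise ValueError("error rates must lie in [0, 1]")
    for mid, pos in marker_positions.items():
        if not 0 <= pos < genome.length:
            raise ValueError(f"marker {mid} at {pos} outside the genome")
    rng = np.random.default_rng(seed)
    loci = []
    for mid in sorted(marker_positions):
        pos = marker_positions[mid]
        positives = set()
        for clone in clones:
            truth = clone.start <= pos < clone.end
            flip_p = false_neg_rate if truth else false_pos_rate
            observed = truth != (flip_p > 0 and rng.random() < flip_p)
            if observed:
                positives.add(clone.id)
        loci.append(
            MarkerLocus(
                id=mid,
                marker_class=marker_class,
                positive_clone_ids=frozenset(positives),
                genotype_source=genotype_source,
            )
        )
    return loci


def simulate_genetic_map(
    genome: GenomeModel,
    marker_positions: dict[str, int],
    mode: str = "expected",
    n_individuals: int = 0,
    seed: int = 0,
    name: str = "simulated",
    genotype: str = "AL8/78",
) -> GeneticMap:
    """Build a genetic map of the given markers from the CE profile.

    ``expected`` mode integrates the profile between adjacent markers, giving
    the deterministic expected map.  ``f2`` mode emulates an F2 mapping
    population: for each adjacent interval the expected distance d cM is
    converted to a recombinant fraction r = d/100 (identity mapping
    function; intervals are assumed small), recombinant counts are drawn
    Binomial(n_individuals, r) and the estimated distance is 100 * count/n.
    """
    if mode not in ("expected", "f2"):
        raise ValueError(f"mode must be 'expected' or 'f2', got {mode!r}")
    if mode == "f2" and n_individuals <= 0:
        raise ValueError("f2 mode requires n_individuals > 0")
    for mid, pos in marker_positions.items():
        if not 0 <= pos <= genome.length:
            raise ValueError(f"unmapped marker {mid!r}: position {pos} outside the genome")

    ordered = sorted(marker_positions.items(), key=lambda kv: (kv[1], kv[0]))
    expected_cm = [genome.genetic_position_cM(pos) for _, pos in ordered]

    if mode == "expected":
        base = expected_cm[0] if expected_cm else 0.0
        entries = tuple((mid, cm - base) for (mid, _), cm in zip(ordered, expected_cm))
        return GeneticMap(name=name, entries=entries, genotype=genotype)

    rng = np.random.default_rng(seed)
    entries = []
    cursor = 0.0
    for i, (mid, _) in enumerate(ordered):
        if i > 0:
            d = expected_cm[i] - expected_cm[i - 1]
            r = min(d / 100.0, 0.5)
            count = rng.binomial(n_individuals, r)
            cursor += 100.0 * count / n_individuals
        entries.append((mid, cursor))
    return GeneticMap(name=name, entries=tuple(entries), genotype=genotype)


# ---------------------------------------------------------------------------
# Rearrangement scenarios: signed segment orders under lineage-specific
# reversals relative to a common ancestor.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RearrangementScenario:
    """Lineage-specific reversal histories applied to an ancestral order.

    ``ancestor`` is a signed permutation of 1..k (segment identifiers);
    ``lineage_ops`` maps each lineage name to an ordered list of reversals,
    each an inclusive 1-based (start, end) position interval.  A reversal
    flips both the order and the sign of the elements inside its interval.
    """

    ancestor: tuple[int, ...]
    lineage_ops: dict[str, tuple[tuple[int, int], ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = len(self.ancestor)
        if sorted(abs(x) for x in self.ancestor) != list(range(1, k + 1)):
            raise ValueError("ancestor must be a signed permutation of 1..k")
        for lineage, ops in self.lineage_ops.items():
            for s, e in ops:
                if not 1 <= s <= e <= k:
                    raise ValueError(
                        f"{lineage}: reversal ({s}, {e}) out of bounds for {k} segments"
                    )


def apply_reversal(order: tuple[int, ...], start: int, end: int) -> tuple[int, ...]:
    """Reverse the inclusive 1-based position interval [start, end], negating signs."""
    if not 1 <= start <= end <= len(order):
        raise ValueError(f"reversal ({start}, {end}) out of bounds for length {len(order)}")
    i, j = start - 1, end
    return order[:i] + tuple(-x for x in reversed(order[i:j])) + order[j:]


def derive_reference_orders(
    gene_order: tuple[int, ...] | RearrangementScenario,
    scenario: RearrangementScenario | None = None,
) -> dict[str, tuple[int, ...]]:
    """Apply each lineage's reversal list to the ancestral order.

    Accepts either (ancestor_order, scenario) or just a scenario whose own
    ``ancestor`` field supplies the order.
    """
    if scenario is None:
        scenario = gene_order  # type: ignore[assignment]
        ancestor = scenario.ancestor
    else:
        ancestor = tuple(gene_order)
        if sorted(abs(x) for x in ancestor) != sorted(abs(x) for x in scenario.ancestor):
            raise ValueError("gene_order and scenario segment sets differ")
    out = {}
    for lineage, ops in scenario.lineage_ops.items():
        order = tuple(ancestor)
        for s, e in ops:
            order = apply_reversal(order, s, e)
        out[lineage] = order
    return out
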