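"""Synteny-block detection, inversion calls and reversal-scenario analysis.

Markers of the ordered physical map are projected onto a reference genome
through best-hit ortholog tables; maximal monotone runs of reference
positions form collinear (+) or inverted (-) synteny blocks, and each
inverted block yields an inversion call with its map span and reference
interval.  At the segment scale, lineage histories are modelled as signed
permutations under reversals: an exact breadth-first search gives minimum
reversal distances, and candidate scenarios (per-lineage reversal lists
relative to a common ancestor) are checked for consistency against
observed pairwise segment orientations.
"""

from __future__ import annotations

import itertools
import math
from collections import deque
from dataclasses import dataclass, field

from .simulate import RearrangementScenario, derive_reference_orders

__all__ = [
    "OrthologHit",
    "SyntenyBlock",
    "Projection",
    "InversionCall",
    "ScenarioReport",
    "filter_ortholog_hits",
    "project_markers",
    "detect_blocks",
    "call_inversions",
    "inversion_distance",
    "scenario_consistent",
    "search_scenarios",
]


@dataclass(frozen=True)
class OrthologHit:
    """A marker's sequence-similarity hit on a reference genome."""

    marker_id: str
    species: str
    reference_gene_id: str
    reference_position_kb: float
    strand: int = 1
    evalue: float = 1e-30

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError("evalue must be > 0")
        if self.strand not in (-1, 1):
            raise ValueError("strand must be ±1")


@dataclass(frozen=True)
class SyntenyBlock:
    """A maximal monotone run of projected markers on one reference."""

    species: str
    marker_ids: tuple[str, ...]
    orientation: int  # +1 collinear, -1 inverted
    reference_start_kb: float
    reference_end_kb: float

    def __len__(self) -> int:
        return len(self.marker_ids)


@dataclass(frozen=True)
class Projection:
    """Physical-map markers with reference positions, in map order."""

    species: str
    entries: tuple[tuple[str, float, int], ...]  # (marker, ref position kb, strand)
    unmatched_count: int = 0


@dataclass(frozen=True)
class InversionCall:
    species: str
    map_span: tuple[str, str]  # first and last marker of the inverted run
    reference_interval_kb: tuple[float, float]
    marker_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class ScenarioReport:
    consistent: bool
    details: tuple[tuple[str, str, str, str, str], ...] = ()
    # rows: (segment, species_pair, predicted, observed, verdict)


def filter_ortholog_hits(
    hits: list[OrthologHit],
    thresholds_by_species: dict[str, float],
) -> list[OrthologHit]:
    """Apply per-species E-value cutoffs and keep one best hit per
    (marker, species).

    A hit survives iff its E-value is <= its species' threshold (the
    boundary is inclusive); among survivors the lowest E-value wins, ties
    broken by lexicographic reference gene id.  Species without a stated
    threshold are dropped entirely.
    """
    for sp, thr in thresholds_by_species.items():
        if thr <= 0:
            raise ValueError(f"threshold for {sp!r} must be > 0")
    best: dict[tuple[str, str], OrthologHit] = {}
    for hit in hits:
        thr = thresholds_by_species.get(hit.species)
        if thr is None or hit.evalue > thr:
            continue
        key = (hit.marker_id, hit.species)
        cur = best.get(key)
        if cur is None or (hit.evalue, hit.reference_gene_id) < (cur.evalue, cur.reference_gene_id):
            best[key] = hit
    return sorted(best.values(), key=lambda h: (h.species, h.marker_id))


def project_markers(
    ordered_map: list[str],
    ortholog_table: list[OrthologHit],
    species: str,
) -> Projection:
    """Project the ordered map's markers onto one reference genome.

    ``ordered_map`` lists marker ids in physical-map order; markers without
    a hit for ``species`` are skipped and counted in ``unmatched_count``.
    A species entirely absent from the table is rejected.
    """
    if not any(h.species == species for h in ortholog_table):
        raise ValueError(f"species {species!r} absent from the ortholog table")
    by_marker = {h.marker_id: h for h in ortholog_table if h.species == species}
    entries = []
    unmatched = 0
    for marker in ordered_map:
        hit = by_marker.get(marker)
        if hit is None:
            unmatched += 1
        else:
            entries.append((marker, hit.reference_position_kb, hit.strand))
    return Projection(species=species, entries=tuple(entries), unmatched_count=unmatched)


def _cut_points(positions: list[float], max_gap_kb: float) -> set[int]:
    """Step indices after which a new block starts.

    A cut is placed where the reference gap exceeds ``max_gap_kb`` and
    wherever the monotone direction flips.  At a direction conflict the
    boundary markers attach to the side with the smaller reference gap
    (ties to the left side), so a reversal embedded in a collinear
    background is recovered with its exact extent.
    """
    n = len(positions)
    gaps = [positions[i + 1] - positions[i] for i in range(n - 1)]
    cuts: set[int] = {i for i, g in enumerate(gaps) if abs(g) > max_gap_kb}
    signed = [(i, 1 if g > 0 else -1) for i, g in enumerate(gaps) if g != 0]
    for (a, sa), (b, sb) in zip(signed, signed[1:]):
        if sa == sb:
            continue
        # conflict: markers a+1..b sit between opposite-direction steps
        if abs(gaps[a]) > abs(gaps[b]):
            cuts.add(a)  # boundary markers join the right-hand block
        else:
            cuts.add(b)  # boundary markers join the left-hand block
    return cuts


def detect_blocks(
    projection: Projection,
    max_gap_kb: float = math.inf,
    min_len: int = 2,
) -> tuple[list[SyntenyBlock], list[str]]:
    """Partition a projection into monotone synteny blocks.

    Returns (blocks, unassigned_marker_ids): maximal runs with monotone
    reference positions (ties order-preserving), ascending runs oriented
    +1 and descending runs -1; runs shorter than ``min_len`` go to the
    unassigned list.  Adjacent markers further than ``max_gap_kb`` apart on
    the reference never share a block.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    entries = list(projection.entries)
    if not entries:
        return [], []
    positions = [p for _, p, _ in entries]
    cuts = _cut_points(positions, max_gap_kb)

    blocks: list[SyntenyBlock] = []
    unassigned: list[str] = []
    start = 0
    for end in range(len(entries)):
        if end == len(entries) - 1 or end in cuts:
            run = entries[start : end + 1]
            refs = [p for _, p, _ in run]
            orient = 1
            for a, b in zip(refs, refs[1:]):
                if a != b:
                    orient = 1 if b > a else -1
                    break
            if len(run) >= min_len:
                blocks.append(
                    SyntenyBlock(
                        species=projection.species,
                        marker_ids=tuple(m for m, _, _ in run),
                        orientation=orient,
                        reference_start_kb=min(refs),
                        reference_end_kb=max(refs),
                    )
                )
            else:
                unassigned.extend(m for m, _, _ in run)
            start = end + 1
    return blocks, unassigned


def call_inversions(
    blocks: list[SyntenyBlock],
    reference_orientation: int = 1,
) -> list[InversionCall]:
    """Call one inversion per block running against the reference orientation."""
    calls = []
    for block in blocks:
        if block.orientation == reference_orientation:
            continue
        calls.append(
            InversionCall(
                species=block.species,
                map_span=(block.marker_ids[0], block.marker_ids[-1]),
                reference_interval_kb=(block.reference_start_kb, block.reference_end_kb),
                marker_ids=block.marker_ids,
            )
        )
    return calls


def _all_reversals(order: tuple[int, ...]):
    n = len(order)
    for i in range(n):
        for j in range(i, n):
            yield order[:i] + tuple(-x for x in reversed(order[i : j + 1])) + order[j + 1 :]


def inversion_distance(signed_permutation, max_n: int = 8) -> int:
    """Exact minimum number of reversals sorting a signed permutation.

    Breadth-first search from the identity over all reversal moves; exact
    but exponential, hence guarded by ``max_n`` (the segment counts of
    chromosome-scale scenarios are small).
    """
    perm = tuple(signed_permutation)
    n = len(perm)
    if sorted(abs(x) for x in perm) != list(range(1, n + 1)):
        raise ValueError("input must be a signed permutation of 1..n")
    if n > max_n:
        raise ValueError(f"n = {n} exceeds max_n = {max_n}")
    identity = tuple(range(1, n + 1))
    if perm == identity:
        return 0
    seen = {identity: 0}
    queue = deque([identity])
    while queue:
        cur = queue.popleft()
        d = seen[cur] + 1
        for nxt in _all_reversals(cur):
            if nxt in seen:
                continue
            if nxt == perm:
                return d
            seen[nxt] = d
            queue.append(nxt)
    raise AssertionError("reversal graph is connected; unreachable")


def _segment_signs(order: tuple[int, ...]) -> dict[int, int]:
    return {abs(x): (1 if x > 0 else -1) for x in order}


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def scenario_consistent(
    scenario: RearrangementScenario,
    observed: dict[tuple[str, tuple[str, str]], str],
    ancestor_lineages: tuple[str, ...] = (),
) -> ScenarioReport:
    """Check a reversal scenario against observed pairwise segment
    orientations.

    ``observed`` maps (segment_label, (species_a, species_b)) to
    "collinear", "inverted" or "unknown"; segment labels are the string
    forms of the scenario's segment ids.  Lineages named in
    ``ancestor_lineages`` (e.g. outgroups retaining the ancestral order)
    are assigned the unrearranged ancestor.  A prediction disagreeing with
    any non-"unknown" observation makes the scenario inconsistent;
    "unknown" is always consistent.
    """
    orders = derive_reference_orders(scenario)
    for lineage in ancestor_lineages:
        orders.setdefault(lineage, scenario.ancestor)
    signs = {lin: _segment_signs(order) for lin, order in orders.items()}
    valid_segments = {str(abs(x)) for x in scenario.ancestor}

    details = []
    consistent = True
    for (segment, pair), obs in sorted(observed.items()):
        if segment not in valid_segments:
            raise ValueError(f"unknown segment label {segment!r}")
        a, b = pair
        for lin in (a, b):
            if lin not in signs:
                raise ValueError(f"lineage {lin!r} not covered by the scenario")
        seg = int(segment)
        predicted = "collinear" if signs[a][seg] == signs[b][seg] else "inverted"
        if obs == "unknown":
            verdict = "unknown"
        elif obs == predicted:
            verdict = "match"
        else:
            verdict = "conflict"
            consistent = False
        details.append((segment, f"{a}~{b}", predicted, obs, verdict))
    return ScenarioReport(consistent=consistent, details=tuple(details))


def search_scenarios(
    observed: dict[tuple[str, tuple[str, str]], str],
    n_segments: int,
    lineages: tuple[str, ...],
    ancestor_lineages: tuple[str, ...] = (),
    max_ops_per_lineage: int = 2,
) -> list[RearrangementScenario]:
    """Enumerate scenarios with at most ``max_ops_per_lineage`` reversals
    per lineage that are consistent with the observed orientation table.

    Exhaustive over all reversal-interval choices, so restricted to small
    segment counts (n <= 6).
    """
    if n_segments > 6:
        raise ValueError("scenario search is limited to n_segments <= 6")
    intervals = [(i, j) for i in range(1, n_segments + 1) for j in range(i, n_segments + 1)]
    op_lists = [()]
    for k in range(1, max_ops_per_lineage + 1):
        op_lists.extend(itertools.product(intervals, repeat=k))
    ancestor = tuple(range(1, n_segments + 1))
    found = []
    for combo in itertools.product(op_lists, repeat=len(lineages)):
        scenario = RearrangementScenario(
            ancestor=ancestor,
            lineage_ops={lin: ops for lin, ops in zip(lineages, combo)},
        )
        report = scenario_consistent(scenario, observed, ancestor_lineages)
        if report.consistent:
            found.append(scenario)
    return found
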