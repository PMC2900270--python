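"""Recombination-rate (coefficient of exchange) metrics.

The coefficient of exchange CE = genetic distance / physical distance, in
cM/Mb, profiles meiotic recombination along a chromosome arm.  Physical
distances come from contig consensus-band counts via the library's average
kb-per-CB factor; marker intervals spanning several contigs can only sum
contig sizes while neglecting inter-contig gaps, so such composite
distances are lower bounds and their CE values overestimates.  Comparing
the observed average CE with an externally known reference rate inverts
the relation to estimate the true physical extent of the mapped region and
hence the total gap fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple

from .mapping import round_half_up
from .simulate import GeneticMap

__all__ = [
    "CEInterval",
    "SizeInference",
    "CompositeInterval",
    "cb_to_kb",
    "coefficient_of_exchange",
    "interval_ce",
    "composite_interval_kb",
    "estimate_true_size",
    "fold_increase",
]


@dataclass(frozen=True)
class CEInterval:
    """A marker interval with genetic (cM), physical (kb) distance and CE.

    ``composite`` marks intervals whose kb distance sums several contigs
    neglecting the gaps: the distance is a lower bound and the CE an
    overestimate.
    """

    left_marker: str
    right_marker: str
    genetic_distance_cM: float
    physical_distance_kb: float
    ce: float
    composite: bool = False

    @property
    def ce_rounded(self) -> float:
        return round_half_up(self.ce, 2)


@dataclass(frozen=True)
class SizeInference:
    """Region size inferred from genetic length at a reference CE."""

    genetic_length_cM: float
    reference_ce: float
    estimated_size_Mb: float
    observed_size_Mb: float
    gap_fraction: float


class CompositeInterval(NamedTuple):
    kb: float
    lower_bound: bool = True


def cb_to_kb(cb: float, kb_per_cb: float = 1.9, rounded: bool = False) -> float:
    """Convert consensus-band units to kb at the library's kb/CB average.

    With ``rounded`` the result is reported to the nearest integer kb
    (half-up), the convention of the printed tables.
    """
    if cb < 0:
        raise ValueError("cb must be >= 0")
    kb = cb * kb_per_cb
    return round_half_up(kb, 0) if rounded else kb


def coefficient_of_exchange(cM: float, kb: float) -> float:
    """CE in cM/Mb from a genetic distance (cM) and physical distance (kb)."""
    if cM < 0:
        raise ValueError("cM must be >= 0")
    if kb <= 0:
        raise ValueError("kb must be > 0")
    return cM / (kb / 1000.0)


def interval_ce(
    genetic_map: GeneticMap,
    physical_sizes: Mapping[str, float] | float,
    left_marker: str,
    right_marker: str,
    composite: bool = False,
) -> CEInterval:
    """Assemble a CE interval between two mapped markers.

    ``physical_sizes`` is either a marker -> kb physical-position mapping
    (the kb distance is the absolute difference) or the kb distance itself
    when the caller has already resolved it, e.g. from a within-contig CB
    span or a composite contig sum.  An identical marker pair gives 0 cM
    and CE 0 regardless of the physical distance.
    """
    cm = abs(genetic_map.position(right_marker) - genetic_map.position(left_marker))
    if isinstance(physical_sizes, Mapping):
        for m in (left_marker, right_marker):
            if m not in physical_sizes:
                raise ValueError(f"no physical position for marker {m!r}")
        kb = abs(physical_sizes[right_marker] - physical_sizes[left_marker])
    else:
        kb = float(physical_sizes)
    if left_marker == right_marker:
        return CEInterval(left_marker, right_marker, 0.0, kb, 0.0, composite)
    if kb <= 0:
        raise ValueError(
            f"markers {left_marker!r} and {right_marker!r} span no resolvable physical distance"
        )
    return CEInterval(left_marker, right_marker, cm, kb, coefficient_of_exchange(cm, kb), composite)


def composite_interval_kb(contig_sizes_kb: list[float]) -> CompositeInterval:
    """Sum contig sizes across a run, neglecting the gaps between them.

    The result is flagged as a lower bound on the true physical distance.
    """
    if not contig_sizes_kb:
        raise ValueError("composite interval requires at least one contig size")
    if any(s <= 0 for s in contig_sizes_kb):
        raise ValueError("contig sizes must be > 0")
    return CompositeInterval(kb=float(sum(contig_sizes_kb)), lower_bound=True)


def estimate_true_size(
    genetic_length_cM: float,
    reference_ce: float,
    observed_kb: float = 0.0,
) -> SizeInference:
    """Estimate the true physical size of a region from its genetic length.

    Dividing the region's genetic length by an externally known reference
    CE gives the physical size the region would have at that recombination
    rate; the shortfall of the observed (assembled) size against this
    estimate is the gap fraction of the physical map.
    """
    if reference_ce <= 0:
        raise ValueError("reference_ce must be > 0")
    if genetic_length_cM < 0 or observed_kb < 0:
        raise ValueError("genetic length and observed size must be >= 0")
    estimated = genetic_length_cM / reference_ce
    observed = observed_kb / 1000.0
    gap = 1.0 - observed / estimated if estimated > observed else 0.0
    return SizeInference(genetic_length_cM, reference_ce, estimated, observed, gap)


def fold_increase(size_a: float, size_b: float) -> tuple[int, float]:
    """Size ratio a/b as (nearest integer half-up, unrounded ratio)."""
    if size_b <= 0:
        raise ValueError("size_b must be > 0")
    ratio = size_a / size_b
    return int(round_half_up(ratio, 0)), ratio
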