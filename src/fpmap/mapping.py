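"""Genetic-map anchoring, multi-evidence contig ordering, gene islands and
physical-map summary tables.

A contig is anchored to a map position only when one of its clones is
positive for a mapped marker whose genotype source matches the genotype of
the BAC library — the same-genotype rule that makes hybridisation
phenotypes comparable between the screen and the mapping population.
Contigs missing from the primary map are placed by a configurable priority
hierarchy of secondary evidence sources (reference physical map, related-
species genetic maps, model-genome gene order).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .assembly import Contig
from .simulate import GeneticMap, MarkerLocus

__all__ = [
    "AnchorRecord",
    "OrderedContig",
    "GeneIsland",
    "MapSummary",
    "anchor_contigs",
    "order_contigs",
    "find_gene_islands",
    "summarize_map",
    "round_half_up",
    "truncate",
]

GENE_CLASS = "EST-unigene"


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at ``ndigits`` (print convention)."""
    scale = 10.0**ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def truncate(x: float, ndigits: int = 0) -> float:
    """Truncate (round toward zero) at ``ndigits``."""
    scale = 10.0**ndigits
    return math.trunc(x * scale) / scale


@dataclass(frozen=True)
class AnchorRecord:
    contig_id: str
    cM: float
    marker_id: str
    map_name: str


@dataclass(frozen=True)
class OrderedContig:
    """One row of the ordered physical map: position, evidence provenance
    and an id shared by contigs left in an unresolved tie."""

    contig_id: str
    position: float | None
    evidence: str
    tie_group: int | None = None


@dataclass(frozen=True)
class GeneIsland:
    contig_id: str
    gene_ids: frozenset[str]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class MapSummary:
    """Totals and per-contig average / min / max for the map's metrics,
    following the print conventions of physical-map summary tables: clone
    and kb averages rounded half-up to integers, the CB average to one
    decimal, and the loci average truncated to one decimal."""

    n_contigs: int
    stats: dict[str, dict[str, float]] = field(default_factory=dict)

    def __getitem__(self, metric: str) -> dict[str, float]:
        return self.stats[metric]


def anchor_contigs(
    contigs: list[Contig],
    markers: list[MarkerLocus],
    genetic_map: GeneticMap,
    library_genotype: str = "AL8/78",
) -> list[AnchorRecord]:
    """Anchor contigs to the map via the same-genotype positive-clone rule.

    A contig acquires one anchor record per mapped marker that (a) has a
    positive clone inside the contig, (b) is on ``genetic_map``, and (c)
    was genotyped on the same accession as the BAC library.  A marker
    mapped at two distinct positions is rejected.
    """
    records = []
    for marker in markers:
        if marker.id not in genetic_map:
            continue
        if marker.genotype_source != library_genotype:
            continue
        cm = genetic_map.position(marker.id)  # raises on duplicate positions
        for contig in contigs:
            if marker.positive_clone_ids & contig.clone_ids:
                records.append(AnchorRecord(contig.id, cm, marker.id, genetic_map.name))
    records.sort(key=lambda r: (r.cM, r.contig_id, r.marker_id))
    return records


def order_contigs(
    contigs: list[Contig],
    anchor_sets_by_source: dict[str, list[AnchorRecord]],
    priority: list[str],
) -> list[OrderedContig]:
    """Place every contig by its highest-priority available evidence source.

    Contigs are sorted by position within their evidence placement; contigs
    that coincide on their placing source are interleaved using the next
    available lower-priority source, and if none resolves them they remain
    an explicit tie group (never silently broken).  Contigs with no
    evidence anywhere are emitted last with the label "unplaced".
    """
    positions: dict[str, dict[str, float]] = {src: {} for src in priority}
    for src, records in anchor_sets_by_source.items():
        if src not in positions:
            raise ValueError(f"evidence source {src!r} missing from priority list")
        for rec in records:
            cur = positions[src].get(rec.contig_id)
            positions[src][rec.contig_id] = rec.cM if cur is None else min(cur, rec.cM)

    placed: list[tuple[str, float, str]] = []  # (contig_id, position, source)
    unplaced: list[str] = []
    for contig in contigs:
        for src in priority:
            if contig.id in positions[src]:
                placed.append((contig.id, positions[src][contig.id], src))
                break
        else:
            unplaced.append(contig.id)

    # Group by (source, position); resolve ties with lower-priority evidence.
    placed.sort(key=lambda it: (it[1], it[0]))
    out: list[OrderedContig] = []
    tie_counter = 0
    i = 0
    while i < len(placed):
        j = i
        while (
            j + 1 < len(placed)
            and placed[j + 1][1] == placed[i][1]
            and placed[j + 1][2] == placed[i][2]
        ):
            j += 1
        group = placed[i : j + 1]
        if len(group) == 1:
            cid, pos, src = group[0]
            out.append(OrderedContig(cid, pos, src))
        else:
            src = group[0][2]
            lower = priority[priority.index(src) + 1 :]
            resolver = next(
                (s for s in lower if all(cid in positions[s] for cid, _, _ in group)),
                None,
            )
            if resolver is not None:
                group = sorted(group, key=lambda it: (positions[resolver][it[0]], it[0]))
                for cid, pos, _ in group:
                    out.append(OrderedContig(cid, pos, f"{src}+{resolver}"))
            else:
                tie_counter += 1
                for cid, pos, _ in sorted(group):
                    out.append(OrderedContig(cid, pos, src, tie_group=tie_counter))
        i = j + 1

    for cid in sorted(unplaced):
        out.append(OrderedContig(cid, None, "unplaced"))
    return out


def find_gene_islands(
    contigs: list[Contig],
    markers: list[MarkerLocus],
) -> list[GeneIsland]:
    """Detect gene islands: within each contig, connected components of the
    gene-clone bipartite graph restricted to gene-class markers.

    Two genes join one island iff they share at least one positive clone
    (directly or through a chain of co-positive genes); a gene detected on
    clones of several islands' clone sets still forms a single component.
    """
    islands: list[GeneIsland] = []
    genes = [m for m in markers if m.marker_class == GENE_CLASS and m.positive_clone_ids]
    for contig in contigs:
        local = {g.id: g.positive_clone_ids & contig.clone_ids for g in genes}
        local = {gid: cl for gid, cl in local.items() if cl}
        # Union-find over genes keyed by shared clones.
        parent = {gid: gid for gid in local}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        by_clone: dict[str, str] = {}
        for gid in sorted(local):
            for cid in local[gid]:
                if cid in by_clone:
                    ra, rb = find(by_clone[cid]), find(gid)
                    if ra != rb:
                        parent[max(ra, rb)] = min(ra, rb)
                else:
                    by_clone[cid] = gid
        components: dict[str, set[str]] = {}
        for gid in local:
            components.setdefault(find(gid), set()).add(gid)
        for root in sorted(components):
            islands.append(GeneIsland(contig.id, frozenset(components[root])))
    return islands


def summarize_map(contigs: list[Contig], markers: list[MarkerLocus]) -> MapSummary:
    """Build the physical-map characteristics table (Table-1 style).

    Metrics: clones, loci (markers with >= 1 positive clone in the contig),
    CB units and kb per contig; each reported as total, per-contig average,
    minimum and maximum under the documented rounding conventions.
    """
    if not contigs:
        raise ValueError("summarize_map requires at least one contig")
    n = len(contigs)
    loci_per_contig = [
        sum(1 for m in markers if m.positive_clone_ids & c.clone_ids) for c in contigs
    ]
    metrics = {
        "clones": [c.n_clones for c in contigs],
        "loci": loci_per_contig,
        "cb": [c.cb_count for c in contigs],
        "kb": [c.size_kb for c in contigs],
    }
    rounders = {
        "clones": lambda x: round_half_up(x, 0),
        "loci": lambda x: truncate(x, 1),
        "cb": lambda x: round_half_up(x, 1),
        "kb": lambda x: round_half_up(x, 0),
    }
    stats = {}
    for name, values in metrics.items():
        total = sum(values)
        stats[name] = {
            "total": total,
            "average": rounders[name](total / n),
            "min": min(values),
            "max": max(values),
        }
    return MapSummary(n_contigs=n, stats=stats)
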