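"""End-to-end pipeline: simulate -> fingerprint -> assemble -> anchor ->
order -> recombination profile -> synteny, with a reproducibility manifest.

The default configuration emulates the mapped chromosome region the
package models: a single chromosome with a steep distal-to-proximal
recombination gradient (~2.2 cM/Mb distal, ~1.4 intermediate, ~0.1
proximal), BAC clones of 100-200 kb at moderate coverage, an F2-style
genetic map, and three reference lineages derived from a shared ancestral
gene order by lineage-specific inversions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import yaml

from . import io as fio
from .assembly import AssemblyParams, assemble_contigs, reassemble_targeted
from .mapping import anchor_contigs, find_gene_islands, order_contigs, summarize_map
from .recombination import composite_interval_kb, estimate_true_size
from .simulate import (
    RearrangementScenario,
    derive_reference_orders,
    digest_clones,
    simulate_bac_library,
    simulate_genetic_map,
    simulate_genome,
    simulate_marker_screen,
)
from .synteny import OrthologHit, call_inversions, detect_blocks, filter_ortholog_hits, project_markers, scenario_consistent

log = logging.getLogger("fpmap")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """All pipeline knobs; see the methods note for units and rationale."""

    seed: int = 0
    # genome
    length_bp: int = 6_000_000
    n_genes: int = 60
    site_rate_per_bp: float = 1 / 4000
    ce_profile: list = field(
        default_factory=lambda: [
            [[0, 1_500_000], 2.19],
            [[1_500_000, 3_000_000], 1.42],
            [[3_000_000, 6_000_000], 0.09],
        ]
    )
    # library & fingerprints
    n_clones: int = 240
    insert_range_bp: tuple = (100_000, 200_000)
    noise_sd_migration_units: float = 0.0
    # marker screen / genetic map
    n_markers: int = 30
    false_pos_rate: float = 0.0
    false_neg_rate: float = 0.0
    map_mode: str = "expected"
    n_individuals: int = 2000
    library_genotype: str = "AL8/78"
    # assembly; tolerance 1 suits the default noise-free band values
    tolerance: int = 1
    gel_length: int = 3000
    cutoff: float = 1e-12
    min_shared_bands: int = 1
    # the synthetic library's own kb-per-CB follows its restriction-site
    # spacing (~4 kb); published library averages belong in user configs
    kb_per_cb: float = 4.0
    # ordering & recombination
    priority: list = field(default_factory=lambda: ["own-map", "reference-physical", "barley", "rice"])
    reference_ce: float = 0.87
    # synteny
    evalue_thresholds: dict = field(
        default_factory=lambda: {"rice": 1e-10, "brachypodium": 1e-10, "barley": 1e-20}
    )
    scenario: dict = field(
        default_factory=lambda: {
            "ancestor": [1, 2, 3, 4, 5],
            "lineages": {"Aegilops": [[5, 5], [1, 2]], "Hordeum": [[5, 5], [2, 3]]},
        }
    )

    def assembly_params(self) -> AssemblyParams:
        return AssemblyParams(
            tolerance=self.tolerance,
            gel_length=self.gel_length,
            cutoff=self.cutoff,
            min_shared_bands=self.min_shared_bands,
            kb_per_cb=self.kb_per_cb,
        )

    def scenario_obj(self) -> RearrangementScenario:
        return RearrangementScenario(
            ancestor=tuple(self.scenario["ancestor"]),
            lineage_ops={
                lin: tuple((int(a), int(b)) for a, b in ops)
                for lin, ops in self.scenario.get("lineages", {}).items()
            },
        )


def load_config(path: str | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config file (any subset of fields) plus keyword overrides."""
    data = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
    data.update(overrides)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(unknown)}")
    cfg = PipelineConfig(**data)
    if "insert_range_bp" in data:
        cfg.insert_range_bp = tuple(cfg.insert_range_bp)
    return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _segment_ortholog_hits(genome, scenario, markers_by_gene, gene_kb_step=10.0):
    """Build per-lineage ortholog tables from the scenario ground truth.

    Genes are partitioned into equal segments matching the scenario's
    ancestral order; each lineage's reference positions are the gene's rank
    in that lineage's rearranged gene order, scaled to kb.
    """
    genes = [gid for gid, _, _ in genome.gene_loci]
    k = len(scenario.ancestor)
    seg_size = max(1, len(genes) // k)
    segments = {}
    for i, gid in enumerate(genes):
        segments[gid] = min(i // seg_size + 1, k)
    lineage_orders = derive_reference_orders(scenario)
    hits = []
    for lineage, seg_order in lineage_orders.items():
        ordered_genes = []
        for seg in seg_order:
            block = [g for g in genes if segments[g] == abs(seg)]
            if seg < 0:
                block = list(reversed(block))
            ordered_genes.extend((g, -1 if seg < 0 else 1) for g in block)
        for rank, (gid, strand) in enumerate(ordered_genes):
            marker = markers_by_gene.get(gid)
            if marker is None:
                continue
            hits.append(
                OrthologHit(
                    marker_id=marker,
                    species=lineage,
                    reference_gene_id=f"{lineage[:2].upper()}_{gid}",
                    reference_position_kb=(rank + 1) * gene_kb_step,
                    strand=strand,
                    evalue=1e-30,
                )
            )
    return hits, segments


def run_pipeline(config: PipelineConfig, outdir: str) -> dict:
    """Run every stage and write all artifacts plus a run manifest.

    Returns the manifest dict; identical (config, seed) produce
    byte-identical text outputs.
    """
    os.makedirs(outdir, exist_ok=True)
    p = lambda name: os.path.join(outdir, name)
    seed = config.seed

    log.info("[simulate] genome %.1f Mb, %d genes", config.length_bp / 1e6, config.n_genes)
    genome = simulate_genome(
        config.length_bp,
        config.n_genes,
        config.site_rate_per_bp,
        [((s, e), r) for (s, e), r in ((tuple(iv), r) for iv, r in config.ce_profile)],
        seed=seed,
    )
    clones = simulate_bac_library(genome, config.n_clones, tuple(config.insert_range_bp), seed=seed + 1)
    fio.write_bed(p("clones_truth.bed"), clones)

    log.info("[fingerprint] digesting %d clones", len(clones))
    fingerprints = digest_clones(genome, clones, config.noise_sd_migration_units, seed=seed + 2)
    fio.write_band_file(p("fingerprints.bands"), fingerprints)

    # markers at evenly spaced gene loci, named after their gene
    step = max(1, len(genome.gene_loci) // max(1, config.n_markers))
    marker_genes = genome.gene_loci[::step][: config.n_markers]
    marker_positions = {f"M_{gid}": pos for gid, pos, _ in marker_genes}
    markers_by_gene = {gid: f"M_{gid}" for gid, _, _ in marker_genes}

    log.info("[screen] %d markers against the library", len(marker_positions))
    markers = simulate_marker_screen(
        genome, clones, marker_positions,
        config.false_pos_rate, config.false_neg_rate,
        seed=seed + 3, genotype_source=config.library_genotype,
    )
    positive_ids = set().union(*[m.positive_clone_ids for m in markers]) if markers else set()

    log.info("[assemble] global assembly then targeted re-assembly")
    params = config.assembly_params()
    initial = assemble_contigs(fingerprints, params)
    contigs = (
        reassemble_targeted(initial, positive_ids, fingerprints, params) if positive_ids else initial
    )
    fio.write_contig_membership(p("contig_membership.tsv"), contigs)
    fio.write_contig_summary(p("contig_summary.tsv"), contigs)

    gmap = simulate_genetic_map(
        genome, marker_positions, mode=config.map_mode,
        n_individuals=config.n_individuals, seed=seed + 4,
        name="own-map", genotype=config.library_genotype,
    )
    mapped = [
        dataclasses.replace(m, cM=gmap.position(m.id), map_source=gmap.name) for m in markers
    ]
    fio.write_marker_table(p("markers.tsv"), mapped)
    fio.write_genetic_map(p("genetic_map.tsv"), gmap)

    log.info("[anchor/order] anchoring contigs on %s", gmap.name)
    anchors = anchor_contigs(contigs, mapped, gmap, config.library_genotype)
    ordered = order_contigs(contigs, {"own-map": anchors}, list(config.priority))
    fio.write_ordered_map(p("ordered_map.tsv"), ordered)

    islands = find_gene_islands(contigs, mapped)
    summary = summarize_map(contigs, mapped)

    log.info("[ce] recombination profile and size inference")
    ce_rows = []
    anchored_sorted = sorted(
        {a.contig_id: a for a in anchors}.items(),
        key=lambda kv: kv[1].cM,
    )
    by_id = {c.id: c for c in contigs}
    marker_cm = dict(gmap.entries)
    # per-profile-region CE from the flanking markers of each region
    for (s, e), rate in genome.ce_profile:
        inside = sorted(
            (pos, mid) for mid, pos in marker_positions.items() if s <= pos < e
        )
        if len(inside) < 2:
            continue
        (lp, lm), (rp, rm) = inside[0], inside[-1]
        ce_rows.append(
            {
                "region": f"{s}-{e}",
                "left": lm,
                "right": rm,
                "cM": abs(marker_cm[rm] - marker_cm[lm]),
                "kb": (rp - lp) / 1000.0,
                "true_rate": rate,
            }
        )
    with open(p("ce_profile.tsv"), "w", encoding="utf-8", newline="\n") as fh:
        fh.write("region\tleft\tright\tcM\tkb\tce\ttrue_rate\n")
        for row in ce_rows:
            ce = row["cM"] / (row["kb"] / 1000.0) if row["kb"] > 0 else 0.0
            fh.write(
                f"{row['region']}\t{row['left']}\t{row['right']}\t{row['cM']:.4f}"
                f"\t{row['kb']:.1f}\t{ce:.2f}\t{row['true_rate']:.2f}\n"
            )

    observed_kb = composite_interval_kb([c.size_kb for c in contigs]).kb if contigs else 0.0
    inference = estimate_true_size(gmap.entries[-1][1] if gmap.entries else 0.0, config.reference_ce, observed_kb)

    log.info("[synteny] projecting onto %d lineages", len(config.scenario.get("lineages", {})))
    scenario = config.scenario_obj()
    hits, segments = _segment_ortholog_hits(genome, scenario, markers_by_gene)
    hits = filter_ortholog_hits(hits, {lin: 1e-10 for lin in scenario.lineage_ops})
    fio.write_ortholog_table(p("orthologs.tsv"), hits)

    physical_order = [f"M_{gid}" for gid, _, _ in genome.gene_loci if gid in markers_by_gene]
    synteny_out = {}
    for lineage in scenario.lineage_ops:
        projection = project_markers(physical_order, hits, lineage)
        blocks, unassigned = detect_blocks(projection)
        calls = call_inversions(blocks)
        synteny_out[lineage] = {
            "blocks": [
                {
                    "markers": list(b.marker_ids),
                    "orientation": "+" if b.orientation > 0 else "-",
                    "reference_kb": [b.reference_start_kb, b.reference_end_kb],
                }
                for b in blocks
            ],
            "unassigned": unassigned,
            "inversions": [
                {"map_span": list(c.map_span), "reference_kb": list(c.reference_interval_kb)}
                for c in calls
            ],
        }

    # scenario self-consistency on the derived orders
    lineages = sorted(scenario.lineage_ops)
    signs = {
        lin: {abs(x): (1 if x > 0 else -1) for x in order}
        for lin, order in derive_reference_orders(scenario).items()
    }
    signs["ancestor"] = {abs(x): 1 for x in scenario.ancestor}
    observed = {}
    for seg in sorted(abs(x) for x in scenario.ancestor):
        for a, b in [(x, y) for i, x in enumerate(lineages + ["ancestor"]) for y in (lineages + ["ancestor"])[i + 1:]]:
            observed[(str(seg), (a, b))] = (
                "collinear" if signs[a][seg] == signs[b][seg] else "inverted"
            )
    report = scenario_consistent(scenario, observed, ancestor_lineages=("ancestor",))
    fio.write_scenario(p("scenario.yaml"), scenario)
    with open(p("synteny_report.yaml"), "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(
            {
                "lineages": synteny_out,
                "scenario_consistent": bool(report.consistent),
            },
            fh,
            sort_keys=True,
        )

    artifacts = sorted(
        f for f in os.listdir(outdir) if f != "manifest.json" and os.path.isfile(p(f))
    )
    cfg_dict = dataclasses.asdict(config)
    manifest = {
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=list).encode()
        ).hexdigest(),
        "n_contigs": len(contigs),
        "n_anchored": len({a.contig_id for a in anchors}),
        "n_gene_islands": len(islands),
        "summary": {k: summary[k] for k in ("clones", "loci", "cb", "kb")},
        "estimated_size_Mb": inference.estimated_size_Mb,
        "observed_size_Mb": inference.observed_size_Mb,
        "gap_fraction": inference.gap_fraction,
        "scenario_consistent": bool(report.consistent),
        "files": {f: _sha256(p(f)) for f in artifacts},
    }
    with open(p("manifest.json"), "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("[done] %d contigs, %d anchored, manifest written", len(contigs), manifest["n_anchored"])
    return manifest
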