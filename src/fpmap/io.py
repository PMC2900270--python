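"""Readers and writers for the pipeline's plain-text formats.

All tabular data is tab-separated UTF-8 with LF line endings and '#'
comment lines; BED intervals are 0-based half-open; band files follow the
fingerprint convention of a header line per clone followed by one
migration value per line, records separated by blank lines.  Every writer
output is re-parseable by the corresponding reader (round-trip identity).
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
import yaml

from .assembly import Contig, Fingerprint
from .mapping import OrderedContig
from .simulate import Clone, GeneticMap, MarkerLocus, RearrangementScenario
from .synteny import OrthologHit

__all__ = [
    "write_band_file",
    "read_band_file",
    "write_bed",
    "read_bed",
    "write_marker_table",
    "read_marker_table",
    "write_genetic_map",
    "read_genetic_map",
    "write_contig_membership",
    "read_contig_membership",
    "write_contig_summary",
    "read_contig_summary",
    "write_ordered_map",
    "read_ordered_map",
    "write_ortholog_table",
    "read_ortholog_table",
    "write_scenario",
    "read_scenario",
]


class FormatError(ValueError):
    """A malformed record, reported with its file and line number."""


def _fail(path: str, lineno: int, message: str) -> None:
    raise FormatError(f"{os.path.basename(path)}:{lineno}: {message}")


# -- band files -------------------------------------------------------------


def write_band_file(path: str, fingerprints: Iterable[Fingerprint]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for fp in fingerprints:
            fh.write(f"{fp.clone_id}\t{len(fp.bands)}\n")
            for band in fp.bands:
                fh.write(f"{band}\n")
            fh.write("\n")


def read_band_file(path: str) -> list[Fingerprint]:
    fingerprints: list[Fingerprint] = []
    clone_id: str | None = None
    expected = 0
    bands: list[int] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("#"):
                continue
            if not line.strip():
                if clone_id is not None:
                    if len(bands) != expected:
                        _fail(path, lineno, f"clone {clone_id}: expected {expected} bands, got {len(bands)}")
                    fingerprints.append(Fingerprint(clone_id, tuple(bands)))
                    clone_id, bands = None, []
                continue
            if clone_id is None:
                parts = line.split("\t")
                if len(parts) != 2:
                    _fail(path, lineno, "expected 'clone_id<TAB>band_count' header")
                clone_id = parts[0]
                try:
                    expected = int(parts[1])
                except ValueError:
                    _fail(path, lineno, f"band count {parts[1]!r} is not an integer")
            else:
                try:
                    bands.append(int(line.strip()))
                except ValueError:
                    _fail(path, lineno, f"band value {line.strip()!r} is not an integer")
    if clone_id is not None:
        if len(bands) != expected:
            _fail(path, lineno, f"clone {clone_id}: expected {expected} bands, got {len(bands)}")
        fingerprints.append(Fingerprint(clone_id, tuple(bands)))
    return fingerprints


# -- BED --------------------------------------------------------------------


def write_bed(path: str, clones: Iterable[Clone], chrom: str = "chr1") -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for c in clones:
            fh.write(f"{chrom}\t{c.start}\t{c.end}\t{c.id}\t0\t+\n")


def read_bed(path: str) -> list[Clone]:
    clones = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                _fail(path, lineno, "BED line needs >= 4 columns (chrom, start, end, name)")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                _fail(path, lineno, "start/end must be integers")
            library = parts[6] if len(parts) > 6 else "BB"
            clones.append(Clone(parts[3], start, end, library))
    return clones


# -- generic TSV helpers ----------------------------------------------------


def _read_tsv(path: str, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{os.path.basename(path)}: missing column {col!r}")
    unknown = [c for c in df.columns if c not in required]
    if unknown:
        raise FormatError(f"{os.path.basename(path)}: unknown column {unknown[0]!r}")
    return df


def _write_tsv(path: str, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# -- marker tables ----------------------------------------------------------

_MARKER_COLS = ["marker_id", "class", "positive_clones", "genotype_source", "cM", "map_source", "bin"]


def write_marker_table(path: str, markers: Iterable[MarkerLocus]) -> None:
    rows = [
        {
            "marker_id": m.id,
            "class": m.marker_class,
            "positive_clones": ",".join(sorted(m.positive_clone_ids)),
            "genotype_source": m.genotype_source,
            "cM": "" if m.cM is None else f"{m.cM:.2f}",
            "map_source": m.map_source or "",
            "bin": m.bin or "",
        }
        for m in markers
    ]
    _write_tsv(path, pd.DataFrame(rows, columns=_MARKER_COLS))


def read_marker_table(path: str) -> list[MarkerLocus]:
    df = _read_tsv(path, _MARKER_COLS)
    markers = []
    for _, row in df.iterrows():
        positives = frozenset(p for p in row["positive_clones"].split(",") if p)
        markers.append(
            MarkerLocus(
                id=row["marker_id"],
                marker_class=row["class"],
                positive_clone_ids=positives,
                genotype_source=row["genotype_source"],
                cM=float(row["cM"]) if row["cM"] else None,
                map_source=row["map_source"] or None,
                bin=row["bin"] or None,
            )
        )
    return markers


# -- genetic maps -----------------------------------------------------------


def write_genetic_map(path: str, gmap: GeneticMap) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# map={gmap.name}\tgenotype={gmap.genotype}\n")
        fh.write("marker_id\tcM\n")
        for marker, cm in gmap.entries:
            fh.write(f"{marker}\t{cm:.6g}\n")


def read_genetic_map(path: str) -> GeneticMap:
    name, genotype = "map", "AL8/78"
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("# map="):
        fields = dict(part.split("=", 1) for part in first[2:].strip().split("\t"))
        name = fields.get("map", name)
        genotype = fields.get("genotype", genotype)
    df = _read_tsv(path, ["marker_id", "cM"])
    entries = tuple((row["marker_id"], float(row["cM"])) for _, row in df.iterrows())
    return GeneticMap(name=name, entries=entries, genotype=genotype)


# -- contigs ----------------------------------------------------------------


def write_contig_membership(path: str, contigs: Iterable[Contig]) -> None:
    rows = [
        {"contig_id": c.id, "clone_id": clone}
        for c in contigs
        for clone in sorted(c.clone_ids)
    ]
    _write_tsv(path, pd.DataFrame(rows, columns=["contig_id", "clone_id"]))


def read_contig_membership(path: str) -> dict[str, frozenset[str]]:
    df = _read_tsv(path, ["contig_id", "clone_id"])
    groups: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        groups.setdefault(row["contig_id"], set()).add(row["clone_id"])
    return {cid: frozenset(cl) for cid, cl in groups.items()}


def write_contig_summary(path: str, contigs: Iterable[Contig]) -> None:
    rows = [
        {"contig_id": c.id, "n_clones": c.n_clones, "cb": c.cb_count, "kb": f"{c.size_kb:.6g}"}
        for c in contigs
    ]
    _write_tsv(path, pd.DataFrame(rows, columns=["contig_id", "n_clones", "cb", "kb"]))


def read_contig_summary(path: str) -> pd.DataFrame:
    df = _read_tsv(path, ["contig_id", "n_clones", "cb", "kb"])
    return df.astype({"n_clones": int, "cb": int, "kb": float})


def write_contigs(path_membership: str, path_summary: str, contigs: list[Contig]) -> None:
    write_contig_membership(path_membership, contigs)
    write_contig_summary(path_summary, contigs)


def read_contigs(path_membership: str, path_summary: str) -> list[Contig]:
    members = read_contig_membership(path_membership)
    df = read_contig_summary(path_summary)
    contigs = []
    for _, row in df.iterrows():
        cid = row["contig_id"]
        if cid not in members:
            raise FormatError(f"contig {cid!r} in summary but not in membership table")
        contigs.append(Contig(cid, members[cid], int(row["cb"]), float(row["kb"])))
    return contigs


# -- ordered map ------------------------------------------------------------

_ORDER_COLS = ["position", "contig_id", "evidence", "tie_group"]


def write_ordered_map(path: str, ordered: Iterable[OrderedContig]) -> None:
    rows = [
        {
            "position": "" if o.position is None else f"{o.position:.6g}",
            "contig_id": o.contig_id,
            "evidence": o.evidence,
            "tie_group": "" if o.tie_group is None else str(o.tie_group),
        }
        for o in ordered
    ]
    _write_tsv(path, pd.DataFrame(rows, columns=_ORDER_COLS))


def read_ordered_map(path: str) -> list[OrderedContig]:
    df = _read_tsv(path, _ORDER_COLS)
    return [
        OrderedContig(
            contig_id=row["contig_id"],
            position=float(row["position"]) if row["position"] else None,
            evidence=row["evidence"],
            tie_group=int(row["tie_group"]) if row["tie_group"] else None,
        )
        for _, row in df.iterrows()
    ]


# -- ortholog tables --------------------------------------------------------

_ORTHO_COLS = ["marker_id", "species", "reference_gene_id", "position_kb", "strand", "evalue"]


def write_ortholog_table(path: str, hits: Iterable[OrthologHit]) -> None:
    rows = [
        {
            "marker_id": h.marker_id,
            "species": h.species,
            "reference_gene_id": h.reference_gene_id,
            "position_kb": f"{h.reference_position_kb:.6g}",
            "strand": "+" if h.strand > 0 else "-",
            "evalue": f"{h.evalue:.3g}",
        }
        for h in hits
    ]
    _write_tsv(path, pd.DataFrame(rows, columns=_ORTHO_COLS))


def read_ortholog_table(path: str) -> list[OrthologHit]:
    df = _read_tsv(path, _ORTHO_COLS)
    return [
        OrthologHit(
            marker_id=row["marker_id"],
            species=row["species"],
            reference_gene_id=row["reference_gene_id"],
            reference_position_kb=float(row["position_kb"]),
            strand=1 if row["strand"] == "+" else -1,
            evalue=float(row["evalue"]),
        )
        for _, row in df.iterrows()
    ]


# -- scenarios --------------------------------------------------------------


def write_scenario(path: str, scenario: RearrangementScenario) -> None:
    doc = {
        "ancestor": list(scenario.ancestor),
        "lineages": {
            lin: [list(op) for op in ops] for lin, ops in scenario.lineage_ops.items()
        },
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_scenario(path: str) -> RearrangementScenario:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "ancestor" not in doc:
        raise FormatError(f"{os.path.basename(path)}: scenario file needs an 'ancestor' key")
    return RearrangementScenario(
        ancestor=tuple(int(x) for x in doc["ancestor"]),
        lineage_ops={
            lin: tuple((int(a), int(b)) for a, b in ops)
            for lin, ops in (doc.get("lineages") or {}).items()
        },
    )
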