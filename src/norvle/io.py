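"""Readers and writers for the package's text interfaces.

Coordinates are 0-based half-open internally; custom tab-separated
outputs use 1-based inclusive coordinates, while bedGraph-like files
keep the standard 0-based half-open convention of that format.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .assembly import ArrayAssembly, Join, LandmarkMap, UnitAnnotation
from .errors import ParameterError
from .model import (
    GeneUnitToken,
    ReferenceGeneModel,
    Region,
    TokenRead,
    VleCall,
    VleCatalog,
    VleVariant,
)

__all__ = [
    "read_reads",
    "write_fastq",
    "write_fasta",
    "write_catalog",
    "read_catalog",
    "write_gene_model",
    "read_gene_model",
    "write_tokens",
    "read_tokens",
    "write_landmark_map",
    "write_assembly",
    "read_assembly",
    "write_bedgraph",
    "write_match_matrix",
    "write_vcf",
    "write_methylation",
    "read_methylation",
    "write_ground_truth",
]


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_reads(path) -> list[tuple[str, str]]:
    """Read FASTA/FASTQ (optionally .gz) into (id, sequence) pairs."""
    path = Path(path)
    stem = path.name[:-3] if path.name.endswith(".gz") else path.name
    fmt = "fastq" if stem.endswith((".fq", ".fastq")) else "fasta"
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, fmt)]


def write_fastq(reads, path, quality: int = 20) -> None:
    qchar = chr(33 + quality)
    with _open_text(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qchar * len(seq)}\n")


def write_fasta(records, path, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# catalog


def write_catalog(catalog: VleCatalog, fasta_path, registry_path=None) -> None:
    """FASTA with ``>region|variant`` headers plus a registry sidecar."""
    records = []
    for region_id, variants in catalog.variants.items():
        for v in variants:
            header = f"{region_id}|{v.variant_id}"
            if v.diagnostic_snps:
                snps = ",".join(f"{pos}:{base}" for pos, base in v.diagnostic_snps)
                header += f" snps={snps}"
            records.append((header, v.sequence))
    write_fasta(records, fasta_path)
    if registry_path is not None:
        with open(registry_path, "w") as fh:
            for perm, sid in sorted(catalog.subtype_registry.items(),
                                    key=lambda x: x[1]):
                pairs = ",".join(f"{r}={v}"
                                 for r, v in zip(catalog.region_ids, perm))
                fh.write(f"{sid}\t{pairs}\n")


def read_catalog(fasta_path, registry_path=None) -> VleCatalog:
    variants: dict[str, list[VleVariant]] = {}
    with _open_text(fasta_path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if "|" not in rec.id:
                raise ParameterError(f"catalog header without '|': {rec.id}")
            region_id, variant_id = rec.id.split("|", 1)
            snps = ()
            for token in rec.description.split():
                if token.startswith("snps="):
                    snps = tuple(
                        (int(p.split(":")[0]), p.split(":")[1])
                        for p in token[5:].split(","))
            variants.setdefault(region_id, []).append(
                VleVariant(region_id, variant_id, str(rec.seq).upper(), snps))
    registry: dict[tuple[str, ...], int] = {}
    if registry_path is not None and Path(registry_path).exists():
        region_ids = list(variants)
        for line in Path(registry_path).read_text().splitlines():
            if not line.strip():
                continue
            sid_s, pairs = line.split("\t")
            by_region = dict(p.split("=", 1) for p in pairs.split(","))
            registry[tuple(by_region[r] for r in region_ids)] = int(sid_s)
    return VleCatalog(variants=variants, subtype_registry=registry)


# ---------------------------------------------------------------------------
# gene model


def write_gene_model(model: ReferenceGeneModel, fasta_path, regions_path) -> None:
    """One-record FASTA plus a BED-like region table with a k=v header."""
    write_fasta([("45S_unit", model.ref_sequence)], fasta_path)
    with open(regions_path, "w") as fh:
        fh.write(f"#anchor_start={model.anchor_start}\n")
        fh.write(f"#anchor_length={model.anchor_length}\n")
        fh.write(f"#ippoi_site={model.ippoi_site}\n")
        for r in model.regions:
            var = "variable" if r.variable else "conserved"
            fh.write(f"45S_unit\t{r.start}\t{r.end}\t{r.region_id}\t{var}\n")


def read_gene_model(fasta_path, regions_path) -> ReferenceGeneModel:
    with _open_text(fasta_path) as fh:
        rec = next(SeqIO.parse(fh, "fasta"))
    meta = {"anchor_start": 0, "anchor_length": 500, "ippoi_site": 60}
    regions = []
    for line in Path(regions_path).read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            key, _, val = line[1:].partition("=")
            if key in meta:
                meta[key] = int(val)
            continue
        _chrom, start, end, region_id, kind = line.split("\t")
        regions.append(Region(region_id, int(start), int(end),
                              variable=(kind == "variable")))
    return ReferenceGeneModel(ref_sequence=str(rec.seq).upper(),
                              regions=tuple(regions), **meta)


# ---------------------------------------------------------------------------
# token strings


def write_tokens(token_reads: list[TokenRead], path) -> None:
    """One line per unit: read, unit index, strand, 1-based inclusive
    interval, subtype and the per-region variant calls."""
    with open(path, "w") as fh:
        fh.write("#read_id\tunit_index\tstrand\tstart\tend\tsubtype_id\tcalls\n")
        for tr in token_reads:
            for i, u in enumerate(tr.units):
                calls = ";".join(
                    f"{c.region_id}={c.variant_id}" +
                    ("*" if c.ambiguous else "")
                    for c in u.calls if c is not None)
                sid = u.subtype_id if u.subtype_id is not None else "."
                fh.write(f"{tr.read_id}\t{i}\t{u.strand}\t"
                         f"{u.interval[0] + 1}\t{u.interval[1]}\t{sid}\t"
                         f"{calls if calls else '.'}\n")


def read_tokens(path, catalog: VleCatalog) -> list[TokenRead]:
    by_read: dict[str, list] = {}
    lengths: dict[str, int] = {}
    order = list(catalog.region_ids)
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        rid, _idx, strand, start, end, sid, calls_s = line.split("\t")
        calls_map = {}
        if calls_s != ".":
            for part in calls_s.split(";"):
                region, variant = part.split("=")
                ambiguous = variant.endswith("*")
                calls_map[region] = (variant.rstrip("*"), ambiguous)
        calls = tuple(
            VleCall(r, calls_map[r][0], 0, calls_map[r][1])
            if r in calls_map else None
            for r in order)
        partial = any(c is None for c in calls)
        unit = GeneUnitToken(
            calls=calls,
            subtype_id=None if sid == "." else int(sid),
            partial=partial, strand=strand,
            interval=(int(start) - 1, int(end)))
        by_read.setdefault(rid, []).append(unit)
        lengths[rid] = max(lengths.get(rid, 0), int(end))
    return [TokenRead(rid, tuple(units), lengths[rid])
            for rid, units in by_read.items()]


# ---------------------------------------------------------------------------
# landmark maps and assemblies


def write_landmark_map(lmap: LandmarkMap, path) -> None:
    from .assembly import _pattern_str
    with open(path, "w") as fh:
        fh.write("#landmark_id\tpattern\tposition_units\tgap_to_next\n")
        for i, (lm, pos) in enumerate(zip(lmap.landmarks, lmap.positions)):
            gap = lmap.gaps[i] if i < len(lmap.gaps) else "."
            fh.write(f"L{i + 1}\t{_pattern_str(lm.pattern)}\t{pos}\t{gap}\n")


def write_assembly(assembly: ArrayAssembly, out_dir, name="nor_assembly") -> None:
    """FASTA consensus plus a per-unit annotation table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta([(name, assembly.sequence)], out_dir / f"{name}.fasta")
    join_positions = {j.position for j in assembly.joins}
    with open(out_dir / f"{name}.units.tsv", "w") as fh:
        fh.write("#unit_index\tstart\tend\tsubtype_id\tdepth\tflags\n")
        for u in assembly.units:
            flags = []
            if u.is_join:
                flags.append("join_fill")
            if u.index in join_positions:
                flags.append("join")
            sid = u.subtype_id if u.subtype_id is not None else \
                ",".join(str(v) for v in u.token)
            fh.write(f"{u.index}\t{u.interval[0] + 1}\t{u.interval[1]}\t"
                     f"{sid}\t{u.depth}\t{';'.join(flags) or '.'}\n")


def read_assembly(out_dir, name="nor_assembly") -> ArrayAssembly:
    out_dir = Path(out_dir)
    with open(out_dir / f"{name}.fasta") as fh:
        rec = next(SeqIO.parse(fh, "fasta"))
    units = []
    joins = []
    for line in (out_dir / f"{name}.units.tsv").read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        idx, start, end, sid, depth, flags = line.split("\t")
        try:
            token = int(sid)
        except ValueError:
            token = tuple(sid.split(","))
        is_join = "join_fill" in flags
        units.append(UnitAnnotation(
            index=int(idx), token=token,
            subtype_id=token if isinstance(token, int) else None,
            interval=(int(start) - 1, int(end)),
            depth=int(depth), is_join=is_join))
        if "join" in flags.split(";"):
            joins.append(Join(position=int(idx), subtype_id=token, n_inserted=0))
    return ArrayAssembly(sequence=str(rec.seq).upper(), units=units, joins=joins)


# ---------------------------------------------------------------------------
# tracks, matrices, variant/methylation tables


def write_bedgraph(path, chrom: str, intervals, values) -> None:
    """bedGraph-like output (0-based half-open, per that format)."""
    with open(path, "w") as fh:
        for (start, end), v in zip(intervals, values):
            fh.write(f"{chrom}\t{start}\t{end}\t{v}\n")


def write_match_matrix(matrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#shape\t{matrix.shape[0]}\t{matrix.shape[1]}"
                 f"\twindow\t{matrix.window}\n")
        for i, j in sorted(matrix.pairs):
            fh.write(f"{i}\t{j}\n")


def write_vcf(sites: pd.DataFrame, path, chrom: str = "45S") -> None:
    """Minimal VCF: CHROM POS ID REF ALT QUAL FILTER INFO(AF=)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, row in sites.iterrows():
            fh.write(f"{chrom}\t{int(row['pos'])}\t.\t{row['ref']}\t"
                     f"{row['alt']}\t.\tPASS\tAF={row['frequency']:.6f}\n")


def write_methylation(sites: pd.DataFrame, path) -> None:
    sites.to_csv(path, sep="\t", index=False)


def read_methylation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ground_truth(truth, path) -> None:
    payload = {
        "tokens": list(truth.tokens),
        "unit_intervals": [list(iv) for iv in truth.unit_intervals],
        "anomalies": [[u, kind, list(iv)] for u, kind, iv in truth.anomalies],
        "planted_landmarks": [[p, list(pat)]
                              for p, pat in truth.planted_landmarks],
        "expressed_block": list(truth.expressed_block),
        "silenced_subtypes": list(truth.silenced_subtypes),
    }
    Path(path).write_text(json.dumps(payload, indent=1))
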