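"""Read tokenization: raw DNA reads -> ordered strings of VLE calls.

The tokenizer segments a read at approximate matches of the conserved 25S
anchor, locates each variable region between its conserved flanks, calls
the closest catalog variant per region by edit distance, and classifies
each complete unit's permutation of calls as a gene subtype.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from ._align import (
    BASE_CODE,
    best_infix,
    edit_distance,
    find_occurrences,
    global_alignment,
    revcomp,
    seq_codes,
)
from .errors import OrientationConflictError, ParameterError
from .model import (
    GeneUnitToken,
    ReferenceGeneModel,
    TokenRead,
    VleCall,
    VleCatalog,
    VleVariant,
)

__all__ = [
    "UnitSegment",
    "segment_read",
    "extract_regions",
    "call_vle",
    "classify_subtype",
    "tokenize_read",
    "tokenize_reads",
    "bootstrap_catalog",
]


@dataclass(frozen=True)
class UnitSegment:
    """One anchor-delimited segment of a read, on the transcribed strand.

    ``start``/``end`` are half-open coordinates on the source read;
    ``flank`` marks the leading (pre-first-anchor) and trailing
    (post-last-anchor) segments, which may be truncated units.
    """

    seq: str
    start: int
    end: int
    strand: str
    flank: bool


def segment_read(seq: str,
                 model: ReferenceGeneModel,
                 max_anchor_divergence: float = 0.15) -> list[UnitSegment]:
    """Split a read into oriented gene-unit segments at 25S anchor hits.

    Successive approximate anchor matches (edit distance <=
    ``max_anchor_divergence`` x anchor length) delimit the segments; all
    segments are reported on the transcribed strand.  Reads with anchor
    hits on both strands raise :class:`OrientationConflictError`; reads
    with no anchor yield an empty list.
    """
    if not seq:
        return []
    if not 0 <= max_anchor_divergence < 0.5:
        raise ParameterError("max_anchor_divergence must be in [0, 0.5)")
    anchor = model.anchor
    k = int(max_anchor_divergence * len(anchor))
    min_sep = 2 * len(anchor)
    fwd = find_occurrences(anchor, seq, k, min_separation=min_sep)
    rev = find_occurrences(revcomp(anchor), seq, k, min_separation=min_sep)
    if fwd and rev:
        raise OrientationConflictError(
            f"anchors on both strands ({len(fwd)} forward, {len(rev)} reverse)")
    if not fwd and not rev:
        return []
    if fwd:
        strand, work = "+", seq
        starts = [s for s, _e, _d in fwd]
    else:
        strand, work = "-", revcomp(seq)
        n = len(seq)
        starts = sorted(n - e for _s, e, _d in rev)

    def src_interval(a: int, b: int) -> tuple[int, int]:
        if strand == "+":
            return a, b
        n = len(seq)
        return n - b, n - a

    segments: list[UnitSegment] = []
    if starts[0] > 0:
        a, b = 0, starts[0]
        segments.append(UnitSegment(work[a:b], *src_interval(a, b), strand, True))
    for a, b in zip(starts, starts[1:]):
        segments.append(UnitSegment(work[a:b], *src_interval(a, b), strand, False))
    a, b = starts[-1], len(work)
    if b > a:
        segments.append(UnitSegment(work[a:b], *src_interval(a, b), strand, True))
    return segments


def extract_regions(unit_seq: str,
                    model: ReferenceGeneModel,
                    flank: int = 200,
                    max_flank_divergence: float = 0.25) -> dict[str, str | None]:
    """Locate each variable region of a unit between its conserved flanks.

    Flanks are the ``flank`` bp of reference sequence immediately outside
    the region, found in the unit by approximate matching, scanning left
    to right so region order is preserved.  Regions whose flanks cannot
    be located (truncated or heavily diverged units) map to None.
    """
    ref = model.ref_sequence
    out: dict[str, str | None] = {}
    lo = 0
    for region in model.variable_regions:
        lf = ref[max(0, region.start - flank):region.start]
        rf = ref[region.end:region.end + flank]
        seg = None
        left_end = None
        if lf:
            d, locs = best_infix(lf, unit_seq[lo:],
                                 k=int(max_flank_divergence * len(lf)))
            if d is not None:
                left_end = lo + locs[0][1]
        else:
            left_end = 0
        if left_end is not None and rf:
            d, locs = best_infix(rf, unit_seq[left_end:],
                                 k=int(max_flank_divergence * len(rf)))
            if d is not None:
                right_start = left_end + locs[0][0]
                seg = unit_seq[left_end:right_start]
                # advance only past the region itself: the right flank may
                # overlap the next region's left flank in a short spacer
                lo = right_start
        elif left_end is not None and not rf:
            seg = unit_seq[left_end:]
            lo = len(unit_seq)
        out[region.region_id] = seg
    return out


def call_vle(region_seq: str | None,
             variants: list[VleVariant],
             max_score: int | None = None) -> VleCall | None:
    """Call the catalog variant with minimum edit distance to region_seq.

    Ties are broken toward the earliest variant in catalog order and
    flagged ambiguous.  A None region (absent flanks) yields no call, as
    does a best score above ``max_score`` when one is given.
    """
    if region_seq is None:
        return None
    if not variants:
        raise ParameterError("variants must be non-empty")
    region_id = variants[0].region_id
    if any(v.region_id != region_id for v in variants):
        raise ParameterError("all variants must belong to one region")
    best: VleVariant | None = None
    best_d: int | None = None
    tied = False
    for v in variants:
        k = -1 if best_d is None else best_d
        d = edit_distance(region_seq, v.sequence, k=k)
        if d < 0:
            continue
        if best_d is None or d < best_d:
            best, best_d, tied = v, d, False
        elif d == best_d:
            tied = True
    assert best is not None and best_d is not None
    if max_score is not None and best_d > max_score:
        return None
    return VleCall(region_id, best.variant_id, best_d, ambiguous=tied)


def classify_subtype(unit: GeneUnitToken,
                     catalog: VleCatalog,
                     register_new: bool = False) -> int | None:
    """Exact permutation lookup in the subtype registry.

    Partial units return None.  With ``register_new`` a novel complete
    permutation is issued a fresh id (max existing + 1) and recorded;
    otherwise the catalog is never mutated.
    """
    if unit.partial:
        return None
    key = unit.key
    if None in key:
        return None
    sid = catalog.lookup_subtype(key)
    if sid is None and register_new:
        sid = catalog.register_subtype(key)
    return sid


def tokenize_read(read,
                  catalog: VleCatalog,
                  model: ReferenceGeneModel,
                  max_anchor_divergence: float = 0.15,
                  max_score: int | None = None,
                  register_new: bool = False) -> TokenRead:
    """Convert one read into its ordered VLE token string.

    Composition of :func:`segment_read`, :func:`extract_regions`,
    :func:`call_vle` per region and :func:`classify_subtype` per unit.
    Deterministic for fixed inputs; propagates orientation conflicts.
    """
    read_id, seq = _as_pair(read)
    if tuple(catalog.region_ids) != model.variable_region_ids:
        raise ParameterError("catalog and gene model disagree on region ids")
    segments = segment_read(seq, model, max_anchor_divergence)
    units = []
    for seg in segments:
        regions = extract_regions(seg.seq, model)
        calls = tuple(
            call_vle(regions[r], catalog.variants_for(r), max_score=max_score)
            for r in catalog.region_ids
        )
        if all(c is None for c in calls):
            continue
        partial = any(c is None for c in calls)
        unit = GeneUnitToken(calls=calls, subtype_id=None, partial=partial,
                             strand=seg.strand, interval=(seg.start, seg.end))
        sid = classify_subtype(unit, catalog, register_new=register_new)
        if sid is not None:
            unit = GeneUnitToken(calls=calls, subtype_id=sid, partial=partial,
                                 strand=seg.strand, interval=(seg.start, seg.end))
        units.append(unit)
    return TokenRead(read_id=read_id, units=tuple(units), source_length=len(seq))


def tokenize_reads(reads, catalog, model, skip_conflicts: bool = True,
                   **kwargs) -> list[TokenRead]:
    """Tokenize many reads, optionally dropping orientation-conflicted ones."""
    out = []
    for read in reads:
        try:
            tr = tokenize_read(read, catalog, model, **kwargs)
        except OrientationConflictError:
            if skip_conflicts:
                continue
            raise
        if tr.n_units:
            out.append(tr)
    return out


def _as_pair(read) -> tuple[str, str]:
    if isinstance(read, tuple):
        return read[0], str(read[1])
    return read.id, str(read.seq)


# ---------------------------------------------------------------------------
# catalog bootstrapping from raw unit subsequences


def bootstrap_catalog(units: list[dict[str, str | None]],
                      min_cluster_size: int = 5,
                      length_tolerance: int = 20,
                      snp_min_fraction: float = 0.2) -> VleCatalog:
    """Derive a VLE catalog from per-unit region subsequences.

    Per region, subsequences are grouped into length bins (single-linkage
    with gap > ``length_tolerance``); each bin's column-wise majority
    consensus (in the coordinates of a median-length template) becomes a
    candidate variant, and bins are split recursively at columns where a
    minority base exceeds ``snp_min_fraction`` (diagnostic SNPs).
    Clusters below ``min_cluster_size`` are discarded; variant ids are
    assigned in descending cluster-size order.  The registry starts
    empty; subtypes are registered during tokenization.
    """
    if len(units) < min_cluster_size:
        return VleCatalog()
    regions: dict[str, list[str]] = {}
    for u in units:
        for rid, seq in u.items():
            if seq:
                regions.setdefault(rid, []).append(seq)
    variants: dict[str, list[VleVariant]] = {}
    for rid, seqs in regions.items():
        if len(seqs) < min_cluster_size:
            continue
        clusters: list[tuple[str, int, tuple]] = []
        for bin_seqs in _length_bins(seqs, length_tolerance):
            if len(bin_seqs) < min_cluster_size:
                continue
            clusters.extend(
                _consensus_clusters(bin_seqs, min_cluster_size, snp_min_fraction))
        clusters.sort(key=lambda c: (-c[1], c[0]))
        variants[rid] = [
            VleVariant(rid, f"v{i + 1}", cons, diagnostic_snps=snps)
            for i, (cons, _n, snps) in enumerate(clusters)
        ]
    variants = {rid: vs for rid, vs in variants.items() if vs}
    return VleCatalog(variants=variants)


def _length_bins(seqs: list[str], tol: int) -> list[list[str]]:
    ordered = sorted(seqs, key=len)
    bins: list[list[str]] = [[ordered[0]]]
    for s in ordered[1:]:
        if len(s) - len(bins[-1][-1]) > tol:
            bins.append([s])
        else:
            bins[-1].append(s)
    return bins


def _alignment_matrix(seqs: list[str], template: str) -> np.ndarray:
    """Per-sequence aligned base codes in template columns (4 = gap)."""
    mat = np.full((len(seqs), len(template)), 4, dtype=np.uint8)
    for i, s in enumerate(seqs):
        if s == template:
            mat[i] = seq_codes(template)
            continue
        _d, ops = global_alignment(s, template)
        codes = seq_codes(s)
        qp = tp = 0
        for n, op in ops:
            if op in "=XM":
                mat[i, tp:tp + n] = codes[qp:qp + n]
                qp += n
                tp += n
            elif op == "D":  # template-only: gap in this sequence
                tp += n
            else:  # I: sequence-only insertion, dropped in template coords
                qp += n
    return mat


def _consensus_clusters(seqs: list[str], min_size: int, snp_min_fraction: float,
                        _depth: int = 0):
    """Recursively split one length bin at diagnostic-SNP columns.

    A median-length member seeds the template, which is polished by
    plurality vote so its own read errors (including indels) do not
    survive into the consensus; members are then re-aligned to the
    polished template to detect diagnostic columns.
    """
    from .assembly import _polish

    ordered = sorted(seqs, key=lambda s: (len(s), s))
    template = ordered[len(ordered) // 2]
    for _ in range(2):
        template = _polish(template, seqs)
    mat = _alignment_matrix(seqs, template)
    counts = np.stack([(mat == b).sum(axis=0) for b in range(5)])
    base_counts = counts[:4]
    totals = base_counts.sum(axis=0)
    order = np.sort(base_counts, axis=0)
    runner_up = order[-2]
    with np.errstate(divide="ignore", invalid="ignore"):
        minority = np.where(totals > 0, runner_up / np.maximum(totals, 1), 0.0)
    diagnostic = np.flatnonzero(
        (minority >= snp_min_fraction) & (totals >= max(min_size, 2)))
    if diagnostic.size and _depth < 8:
        col = int(diagnostic[0])
        groups: dict[int, list[str]] = {}
        for i, s in enumerate(seqs):
            groups.setdefault(int(mat[i, col]), []).append(s)
        real = [g for code, g in sorted(groups.items())
                if code < 4 and len(g) >= min_size]
        if len(real) >= 2:
            out = []
            for g in real:
                for cons, n, snps in _consensus_clusters(
                        g, min_size, snp_min_fraction, _depth + 1):
                    out.append((cons, n, snps))
            # annotate the split column as a diagnostic SNP on each product
            annotated = []
            for cons, n, snps in out:
                offset = min(col, len(cons) - 1)
                annotated.append(
                    (cons, n, tuple(sorted(set(snps) | {(offset, cons[offset])}))))
            return annotated
    keep = counts.argmax(axis=0)
    cons = "".join("ACGT"[c] for c in keep if c < 4)
    if len(cons) < 1 or len(seqs) < min_size:
        return []
    return [(cons, len(seqs), ())]
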