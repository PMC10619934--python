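"""Positional analyses of an assembled rRNA gene array.

Gene counting and I-PpoI unit lengths, subtype composition, local
homogeneity (concerted-evolution signal), VLE similarity matrices,
structural anomaly scans, discriminating sgRNA design and Cas9 fragment
prediction for CHEF-gel validation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._align import find_occurrences, global_alignment, revcomp
from .errors import ParameterError
from .model import ReferenceGeneModel, VleVariant

__all__ = [
    "HomogeneityTrack",
    "MatchMatrix",
    "AnomalyCall",
    "count_and_measure_units",
    "subtype_composition",
    "homogeneity_track",
    "vle_similarity_matrix",
    "structural_anomaly_scan",
    "design_discriminating_guides",
    "predict_cas9_fragments",
]


@dataclass(frozen=True)
class HomogeneityTrack:
    """Per-window homogeneity scores along the array (unit coordinates)."""

    scores: tuple[int, ...]
    window: int
    mode: str = "modal"

    def __post_init__(self):
        if any(not 1 <= s <= self.window for s in self.scores):
            raise ParameterError("scores must lie in [1, window]")


@dataclass(frozen=True)
class MatchMatrix:
    """Sparse set of (i, j) unit pairs whose VLE windows match exactly."""

    pairs: frozenset[tuple[int, int]]
    shape: tuple[int, int]
    window: int

    def transpose(self) -> "MatchMatrix":
        return MatchMatrix(frozenset((j, i) for i, j in self.pairs),
                           (self.shape[1], self.shape[0]), self.window)


@dataclass(frozen=True)
class AnomalyCall:
    """A structural anomaly of one unit relative to the reference."""

    unit_index: int
    kind: str
    interval: tuple[int, int]
    size: int


def _as_sequence(assembly) -> str:
    return assembly if isinstance(assembly, str) else assembly.sequence


def count_and_measure_units(assembly, model: ReferenceGeneModel,
                            max_anchor_divergence: float = 0.1):
    """Gene count and I-PpoI-to-I-PpoI unit lengths of an assembly.

    The gene count is the number of 25S anchor occurrences on the
    transcribed strand (the strand carrying the majority of anchor hits);
    unit lengths are the distances between successive I-PpoI cut
    positions, which occur once per gene within the 25S.
    """
    seq = _as_sequence(assembly)
    anchor = model.anchor
    k = int(max_anchor_divergence * len(anchor))
    min_sep = 2 * len(anchor)
    fwd = find_occurrences(anchor, seq, k, min_separation=min_sep)
    rev = find_occurrences(revcomp(anchor), seq, k, min_separation=min_sep)
    if len(rev) > len(fwd):
        seq = revcomp(seq)
        n = len(seq)
        hits = sorted(n - e for _s, e, _d in rev)
    else:
        hits = [s for s, _e, _d in fwd]
    count = len(hits)
    ippoi_delta = model.ippoi_site - model.anchor_start
    cut_positions = [h + ippoi_delta for h in hits]
    lengths = [b - a for a, b in zip(cut_positions, cut_positions[1:])]
    return count, lengths


def subtype_composition(assembly, class_labels: dict | None = None) -> pd.DataFrame:
    """Unit counts and fractions per subtype, descending by count.

    Fractions are reported to 4 decimal places and sum to 1 over the
    unrounded values; ``class_labels`` optionally maps subtype ids to
    class names (e.g. VAR1.1).
    """
    tokens = assembly if isinstance(assembly, (list, tuple)) \
        else assembly.token_sequence
    counts = Counter(tokens)
    total = sum(counts.values())
    rows = []
    for subtype, c in sorted(counts.items(), key=lambda x: (-x[1], str(x[0]))):
        row = {"subtype": subtype, "count": c,
               "fraction": round(c / total, 4)}
        if class_labels is not None:
            row["class"] = class_labels.get(subtype)
        rows.append(row)
    return pd.DataFrame(rows)


def homogeneity_track(subtypes, window: int = 9,
                      mode: str = "modal") -> HomogeneityTrack:
    """Sliding-window homogeneity of the subtype sequence.

    ``modal`` scores each window by the multiplicity of its modal
    subtype (the count of identical gene subtypes within the window);
    ``center`` scores by the number of window members identical to the
    center unit.
    """
    subtypes = tuple(subtypes)
    if window < 1:
        raise ParameterError("window must be >= 1")
    if window > len(subtypes):
        raise ParameterError("window exceeds array length")
    if mode not in ("modal", "center"):
        raise ParameterError("mode must be 'modal' or 'center'")
    scores = []
    for i in range(len(subtypes) - window + 1):
        win = subtypes[i:i + window]
        if mode == "modal":
            scores.append(max(Counter(win).values()))
        else:
            scores.append(sum(1 for s in win if s == win[window // 2]))
    return HomogeneityTrack(scores=tuple(scores), window=window, mode=mode)


def vle_similarity_matrix(tokens_a, tokens_b, window: int = 3) -> MatchMatrix:
    """Dot-plot of VLE content: (i, j) where window-length tuples match."""
    tokens_a, tokens_b = tuple(tokens_a), tuple(tokens_b)
    if len(tokens_a) < window or len(tokens_b) < window:
        raise ParameterError("both token sequences must be >= window")
    index: dict[tuple, list[int]] = {}
    for j in range(len(tokens_b) - window + 1):
        index.setdefault(tokens_b[j:j + window], []).append(j)
    pairs = set()
    for i in range(len(tokens_a) - window + 1):
        for j in index.get(tokens_a[i:i + window], ()):
            pairs.add((i, j))
    shape = (len(tokens_a) - window + 1, len(tokens_b) - window + 1)
    return MatchMatrix(pairs=frozenset(pairs), shape=shape, window=window)


def structural_anomaly_scan(assembly, model: ReferenceGeneModel,
                            min_deletion: int = 500,
                            merge_gap: int = 20) -> list[AnomalyCall]:
    """Scan each unit for large deletions/insertions vs the reference.

    Every unit is globally aligned to the reference unit; contiguous
    reference spans of at least ``min_deletion`` bp absent from the unit
    are reported as deletions labeled with the overlapped region, and
    unit insertions of the same size as insertion anomalies.  Alignments
    of large indels are not unique, so gap runs separated by fewer than
    ``merge_gap`` aligned bases (coincidental matches inside the event)
    are coalesced before thresholding.
    """
    if min_deletion < 50:
        raise ParameterError("min_deletion must be >= 50")
    seq = _as_sequence(assembly)
    units = ([(0, len(seq))] if isinstance(assembly, str)
             else [u.interval for u in assembly.units])
    ref = model.ref_sequence
    calls: list[AnomalyCall] = []
    for idx, (a, b) in enumerate(units):
        unit_seq = seq[a:b]
        _d, ops = global_alignment(unit_seq, ref)
        qp = tp = 0
        dels: list[list[int]] = []   # [ref_start, ref_end, unit_pos]
        inss: list[list[int]] = []   # [unit_start, unit_end, ref_pos]
        for n, op in ops:
            if op in "=XM":
                qp += n
                tp += n
            elif op == "D":  # reference span missing from the unit
                dels.append([tp, tp + n, qp, n])
                tp += n
            else:  # I: extra unit sequence
                inss.append([qp, qp + n, tp, n])
                qp += n
        for start, end, upos, size in _merge_runs(dels, merge_gap):
            if size >= min_deletion:
                region = _dominant_region(model, start, end)
                upos = min(upos, max(len(unit_seq) - 1, 0))
                calls.append(AnomalyCall(
                    unit_index=idx, kind=f"{region}_deletion",
                    interval=(upos, upos + 1), size=size))
        for start, end, _rpos, size in _merge_runs(inss, merge_gap):
            if size >= min_deletion:
                calls.append(AnomalyCall(
                    unit_index=idx, kind="insertion",
                    interval=(start, end), size=size))
    return calls


def _merge_runs(runs: list[list[int]], merge_gap: int) -> list[list[int]]:
    """Coalesce gap runs separated by <= merge_gap aligned bases; the
    merged size is the summed gap length (matches inside a smeared
    alignment of one event do not count)."""
    merged: list[list[int]] = []
    for start, end, pos, size in runs:
        if merged and start - merged[-1][1] <= merge_gap:
            merged[-1][1] = end
            merged[-1][3] += size
        else:
            merged.append([start, end, pos, size])
    return merged


def _dominant_region(model: ReferenceGeneModel, start: int, end: int) -> str:
    best, best_ov = None, -1
    for r in model.regions:
        ov = min(end, r.end) - max(start, r.start)
        if ov > best_ov:
            best, best_ov = r.region_id, ov
    return best


def _pam_adjacent_protospacers(seq: str, guide_len: int = 20):
    """All (protospacer, position, strand) with an NGG PAM, both strands."""
    out = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for i in range(len(s) - guide_len - 2):
            if s[i + guide_len + 1:i + guide_len + 3] == "GG":
                out.append((s[i:i + guide_len], i, strand))
    return out


def design_discriminating_guides(variants: list[VleVariant],
                                 guide_len: int = 20) -> pd.DataFrame:
    """sgRNA targets separating the variants of one region.

    Returns every ``guide_len``-mer immediately 5' of an NGG PAM that is
    present (at 0 mismatches, PAM-adjacent, either strand) in at least
    one variant and absent from at least one other, annotated with the
    hit/miss variant sets.
    """
    if len(variants) < 2:
        raise ParameterError("need at least two variants")
    presence: dict[str, set[str]] = {}
    first_site: dict[str, tuple] = {}
    for v in variants:
        for proto, pos, strand in _pam_adjacent_protospacers(v.sequence, guide_len):
            presence.setdefault(proto, set()).add(v.variant_id)
            first_site.setdefault(proto, (v.variant_id, pos, strand))
    all_ids = [v.variant_id for v in variants]
    rows = []
    for proto in sorted(presence):
        hits = presence[proto]
        if 0 < len(hits) < len(all_ids):
            vid, pos, strand = first_site[proto]
            rows.append({
                "protospacer": proto,
                "example_variant": vid,
                "position": pos,
                "strand": strand,
                "hit_variants": ",".join(sorted(hits)),
                "miss_variants": ",".join(sorted(set(all_ids) - hits)),
            })
    return pd.DataFrame(rows, columns=["protospacer", "example_variant",
                                       "position", "strand", "hit_variants",
                                       "miss_variants"])


def predict_cas9_fragments(assembly, guides: list[str],
                           guide_len: int = 20) -> list[int]:
    """Fragment lengths from Cas9 cutting at all exact guide matches.

    Guides are protospacers (an appended PAM is stripped; the NGG PAM is
    required next to each match).  Cuts are blunt, 3 bp 5' of the PAM
    (between protospacer positions 17 and 18), on both strands.  Returns
    sorted fragment lengths; with no matches the single fragment is the
    assembly length.
    """
    if not guides:
        raise ParameterError("guides must be non-empty")
    seq = _as_sequence(assembly)
    L = len(seq)
    cuts: set[int] = set()
    for guide in guides:
        proto = guide[:guide_len]
        for i in range(L - guide_len - 2):
            if seq[i:i + guide_len] == proto and \
                    seq[i + guide_len + 1:i + guide_len + 3] == "GG":
                cuts.add(i + guide_len - 3)
        rc = revcomp(proto)
        for j in range(3, L - guide_len):
            if seq[j:j + guide_len] == rc and seq[j - 3:j - 1] == "CC":
                cuts.add(j + 3)
    boundaries = [0] + sorted(c for c in cuts if 0 < c < L) + [L]
    return sorted(b - a for a, b in zip(boundaries, boundaries[1:]))
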