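"""Landmark discovery, locus mapping and tag-registered consensus.

Single-copy VLE token patterns ("landmarks") anchor and order reads:
patterns whose read-set frequency is about one genome copy are selected,
spanning reads vote on the distances between them, and each read's units
are then assigned absolute array positions through its landmark offsets.
The consensus is polished per unit by plurality vote of all covering
read segments aligned to a subtype-derived draft — the per-unit
positional register that the original pipeline enforced by inserting a
unique sequence tag at every 25S anchor.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._align import (
    CODE_BASE,
    best_infix,
    edit_distance,
    global_alignment,
    revcomp,
    seq_codes,
)
from .errors import (
    AdjacencyConflictError,
    AmbiguousAdjacencyError,
    CoverageGapError,
    NoJoinError,
    ParameterError,
)
from .model import ReferenceGeneModel, TokenRead, VleCatalog

__all__ = [
    "PatternCount",
    "Landmark",
    "LandmarkMap",
    "UnitAnnotation",
    "Join",
    "ArrayAssembly",
    "filter_nor_reads",
    "estimate_coverage",
    "count_patterns",
    "find_landmarks",
    "build_landmark_map",
    "build_landmark_maps",
    "tagged_consensus",
    "join_contigs",
    "validate_assembly",
]


@dataclass(frozen=True)
class PatternCount:
    """A token k-gram, its read-set count and estimated genome copies."""

    pattern: tuple
    count: int
    copy_estimate: float


@dataclass(frozen=True)
class Landmark:
    """A single-copy token pattern with its supporting read offsets."""

    pattern: tuple
    supporting_reads: tuple[tuple[str, int], ...]
    merged_patterns: tuple[tuple[tuple, int], ...] = ()
    """Overlapping patterns absorbed into this landmark, as
    (pattern, offset relative to this landmark's start)."""

    @property
    def k(self) -> int:
        return len(self.pattern)


@dataclass
class LandmarkMap:
    """Ordered landmarks with inter-landmark distances in gene units.

    ``positions`` are landmark start positions on the contig (unit
    coordinates, 0 = leftmost landmark start); ``gaps`` are
    start-to-start distances between consecutive landmarks.  ``joins``
    records positions merged by abundance accounting rather than
    spanning reads.
    """

    landmarks: list[Landmark]
    positions: list[int]
    gaps: list[int]
    telomeric_end: bool = True
    centromeric_end: bool = True
    joins: list = field(default_factory=list)

    def __post_init__(self):
        if any(g < 0 for g in self.gaps):
            raise ParameterError("gaps must be >= 0")


@dataclass(frozen=True)
class UnitAnnotation:
    """Per-unit annotation of an assembled array."""

    index: int
    token: object
    subtype_id: int | None
    interval: tuple[int, int]
    depth: int
    is_join: bool = False


@dataclass(frozen=True)
class Join:
    position: int
    subtype_id: object
    n_inserted: int


@dataclass
class ArrayAssembly:
    """Polished DNA consensus with per-unit annotations."""

    sequence: str
    units: list[UnitAnnotation]
    joins: list[Join] = field(default_factory=list)

    def __post_init__(self):
        pos = 0
        for u in self.units:
            if u.interval[0] != pos:
                raise ParameterError("unit intervals must tile the sequence")
            pos = u.interval[1]
        if pos != len(self.sequence):
            raise ParameterError("unit intervals must cover the sequence")

    @property
    def token_sequence(self) -> tuple:
        return tuple(u.token for u in self.units)

    @property
    def subtype_sequence(self) -> tuple:
        return tuple(u.subtype_id for u in self.units)

    @property
    def n_units(self) -> int:
        return len(self.units)


# ---------------------------------------------------------------------------
# read filtering


def filter_nor_reads(reads,
                     model: ReferenceGeneModel,
                     min_len: int = 85_000,
                     keep_whole_above: int = 275_000,
                     split_gap: int = 12_000,
                     kmer_size: int = 16,
                     max_anchor_divergence: float = 0.15):
    """Select and split the NOR assembly read set.

    Reads containing the 25S anchor are retained; reads longer than
    ``keep_whole_above`` pass unfiltered; the rest are split wherever a
    stretch of at least ``split_gap`` bp contains no k-mer of the
    reference unit, then length-filtered at ``min_len``.
    """
    if not min_len < keep_whole_above:
        raise ParameterError("min_len must be < keep_whole_above")
    ref2 = model.ref_sequence + model.ref_sequence[:kmer_size - 1]
    kmers = set()
    for s in (ref2, revcomp(ref2)):
        for i in range(len(s) - kmer_size + 1):
            kmers.add(s[i:i + kmer_size])
    anchor = model.anchor
    k = int(max_anchor_divergence * len(anchor))
    out = []
    for read in reads:
        rid, seq = _as_pair(read)
        d, _ = best_infix(anchor, seq, k=k)
        if d is None:
            d, _ = best_infix(revcomp(anchor), seq, k=k)
        if d is None:
            continue
        if len(seq) > keep_whole_above:
            out.append((rid, seq))
            continue
        pieces = _split_at_kmer_gaps(seq, kmers, kmer_size, split_gap)
        for j, (a, b) in enumerate(pieces):
            if b - a >= min_len:
                piece_id = rid if len(pieces) == 1 else f"{rid}/{j + 1}"
                out.append((piece_id, seq[a:b]))
    return out


def _split_at_kmer_gaps(seq, kmers, k, split_gap):
    hits = [i for i in range(len(seq) - k + 1) if seq[i:i + k] in kmers]
    if not hits:
        return []
    pieces = []
    start = hits[0]
    prev = hits[0]
    for h in hits[1:]:
        if h - prev >= split_gap:
            pieces.append((start, prev + k))
            start = h
        prev = h
    pieces.append((start, prev + k))
    return pieces


# ---------------------------------------------------------------------------
# landmarks


def estimate_coverage(token_reads: list[TokenRead], expected_genes: int) -> float:
    """Read-set coverage = total tokenized units / expected gene count."""
    if expected_genes <= 0:
        raise ParameterError("expected_genes must be positive")
    total = sum(tr.n_units for tr in token_reads)
    return total / expected_genes


def count_patterns(token_reads: list[TokenRead], k: int,
                   coverage: float) -> list[PatternCount]:
    """All token k-grams of the read set with copy estimates."""
    counts: Counter = Counter()
    for tr in token_reads:
        toks = tr.tokens
        for i in range(len(toks) - k + 1):
            pat = toks[i:i + k]
            if None not in pat:
                counts[pat] += 1
    return [PatternCount(p, c, c / coverage)
            for p, c in sorted(counts.items(), key=lambda x: (-x[1], str(x[0])))]


def find_landmarks(token_reads: list[TokenRead],
                   coverage: float,
                   k_min: int = 2,
                   k_max: int = 12,
                   copy_tolerance: float = 0.4,
                   min_support: int = 5,
                   context_purity: float = 0.7) -> list[Landmark]:
    """Select minimal-k single-copy token patterns as landmarks.

    For k from ``k_min`` upward, patterns whose copy estimate
    (count / coverage) lies within ``1 +- copy_tolerance`` and whose
    count reaches ``min_support`` are selected, skipping any pattern
    that contains an already-selected shorter pattern.  The coverage is
    span-corrected per k: a read can only witness a k-gram occurrence if
    it spans k consecutive complete units, so the effective coverage of
    k-gram positions is ``coverage x sum(n_r - k + 1) / sum(n_r)`` over
    read unit counts ``n_r``.

    Candidates must also be context-pure: across reads, the token
    immediately left (and right) of the pattern must agree at
    ``context_purity`` majority.  A single-copy pattern has one fixed
    neighbourhood; split contexts betray a multi-copy pattern that
    sampling noise pushed into the copy-estimate band.
    """
    if coverage <= 0:
        raise ParameterError("coverage must be > 0")
    token_lists = [tr.tokens for tr in token_reads]
    total_units = sum(len(t) for t in token_lists)
    selected: list[tuple] = []
    selected_set: set = set()
    lo, hi = 1 - copy_tolerance, 1 + copy_tolerance
    for k in range(k_min, k_max + 1):
        counts: Counter = Counter()
        spanning = 0
        for toks in token_lists:
            spanning += max(0, len(toks) - k + 1)
            for i in range(len(toks) - k + 1):
                pat = toks[i:i + k]
                if None not in pat:
                    counts[pat] += 1
        coverage_k = coverage * spanning / max(total_units, 1)
        if coverage_k <= 0:
            break
        for pat, c in counts.items():
            if c < min_support or not lo <= c / coverage_k <= hi:
                continue
            if _contains_selected(pat, selected_set, k_min, k):
                continue
            if not _context_pure(pat, token_lists, context_purity):
                continue
            selected.append(pat)
            selected_set.add(pat)
    landmarks = []
    for pat in sorted(selected, key=lambda p: (len(p), str(p))):
        support = []
        for tr, toks in zip(token_reads, token_lists):
            for off in _occurrences(toks, pat):
                support.append((tr.read_id, off))
        landmarks.append(Landmark(pattern=pat, supporting_reads=tuple(support)))
    return landmarks


def _context_pure(pat, token_lists, purity: float, min_votes: int = 4) -> bool:
    k = len(pat)
    left: Counter = Counter()
    right: Counter = Counter()
    for toks in token_lists:
        for i in _occurrences(toks, pat):
            if i > 0 and toks[i - 1] is not None:
                left[toks[i - 1]] += 1
            if i + k < len(toks) and toks[i + k] is not None:
                right[toks[i + k]] += 1
    for ctx in (left, right):
        votes = sum(ctx.values())
        if votes >= min_votes and ctx.most_common(1)[0][1] / votes < purity:
            return False
    return True


def _contains_selected(pat, selected_set, k_min, k):
    for j in range(k_min, k):
        for i in range(k - j + 1):
            if pat[i:i + j] in selected_set:
                return True
    return False


def _occurrences(tokens: tuple, pattern: tuple):
    k = len(pattern)
    return [i for i in range(len(tokens) - k + 1) if tokens[i:i + k] == pattern]


# ---------------------------------------------------------------------------
# landmark map


def build_landmark_maps(token_reads: list[TokenRead],
                        landmarks: list[Landmark],
                        min_agreement: float = 0.8,
                        min_pair_support: int = 3) -> list[LandmarkMap]:
    """Link landmarks into ordered contig maps via spanning-read votes.

    Reads containing two landmarks vote on their offset difference; the
    modal vote fixes the distance, votes below ``min_agreement``
    agreement raise :class:`AdjacencyConflictError`, and a landmark with
    two distinct nearest right-neighbours at comparable support raises
    :class:`AmbiguousAdjacencyError`.  Overlapping landmarks are merged
    (the earlier landmark absorbs the later).  One map is returned per
    connected component, ordered left to right.
    """
    if not landmarks:
        raise ParameterError("need at least one landmark")
    occs = []
    for tr in token_reads:
        toks = tr.tokens
        row = []
        for li, lm in enumerate(landmarks):
            for off in _occurrences(toks, lm.pattern):
                row.append((li, off))
        if len(row) >= 1:
            occs.append(row)

    votes: dict[tuple[int, int], Counter] = defaultdict(Counter)
    for row in occs:
        for a in range(len(row)):
            for b in range(a + 1, len(row)):
                (li, oi), (lj, oj) = row[a], row[b]
                if li == lj:
                    continue
                i, j = (li, lj) if li < lj else (lj, li)
                delta = (oj - oi) if li < lj else (oi - oj)
                votes[(i, j)][delta] += 1

    edges: dict[tuple[int, int], int] = {}
    for (i, j), ctr in votes.items():
        support = sum(ctr.values())
        if support < min_pair_support:
            continue
        delta, modal = ctr.most_common(1)[0]
        if modal / support < min_agreement:
            raise AdjacencyConflictError(
                f"landmarks {landmarks[i].pattern!r} / {landmarks[j].pattern!r}: "
                f"only {modal}/{support} spanning reads agree on the gap")
        edges[(i, j)] = delta

    _check_right_neighbour_ambiguity(landmarks, votes, edges)

    adj: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for (i, j), d in edges.items():
        adj[i].append((j, d))
        adj[j].append((i, -d))
    pos: dict[int, int] = {}
    comps: list[list[int]] = []
    support_of = {i: len(lm.supporting_reads) for i, lm in enumerate(landmarks)}
    for root in sorted(range(len(landmarks)),
                       key=lambda i: (-support_of[i], i)):
        if root in pos:
            continue
        pos[root] = 0
        comp = [root]
        stack = [root]
        while stack:
            u = stack.pop()
            for v, d in adj[u]:
                p = pos[u] + d
                if v in pos:
                    if pos[v] != p:
                        raise AdjacencyConflictError(
                            f"inconsistent placement of landmark "
                            f"{landmarks[v].pattern!r}: {pos[v]} vs {p}")
                    continue
                pos[v] = p
                comp.append(v)
                stack.append(v)
        comps.append(comp)

    maps = []
    for comp in comps:
        ordered = sorted(comp, key=lambda i: (pos[i], i))
        base = pos[ordered[0]]
        kept: list[Landmark] = []
        kept_pos: list[int] = []
        for i in ordered:
            p = pos[i] - base
            lm = landmarks[i]
            if kept and p < kept_pos[-1] + kept[-1].k:
                prev = kept[-1]
                kept[-1] = replace(prev, merged_patterns=prev.merged_patterns
                                   + ((lm.pattern, p - kept_pos[-1]),))
                continue
            kept.append(lm)
            kept_pos.append(p)
        gaps = [b - a for a, b in zip(kept_pos, kept_pos[1:])]
        maps.append(LandmarkMap(landmarks=kept, positions=kept_pos, gaps=gaps))
    maps.sort(key=lambda m: -sum(len(l.supporting_reads) for l in m.landmarks))
    if len(maps) > 1:
        for m in maps:
            m.telomeric_end = m is maps[0]
            m.centromeric_end = m is maps[-1]
    return maps


def build_landmark_map(token_reads, landmarks, **kwargs) -> LandmarkMap:
    """Like :func:`build_landmark_maps` but expects one connected contig."""
    maps = build_landmark_maps(token_reads, landmarks, **kwargs)
    if len(maps) > 1:
        raise AdjacencyConflictError(
            f"landmarks split into {len(maps)} unconnected contigs; "
            "use build_landmark_maps")
    return maps[0]


def _check_right_neighbour_ambiguity(landmarks, votes, edges):
    rights: dict[int, list[tuple[int, int, int]]] = defaultdict(list)
    for (i, j), ctr in votes.items():
        if (i, j) not in edges:
            continue
        delta = edges[(i, j)]
        support = sum(ctr.values())
        if delta > 0:
            rights[i].append((delta, j, support))
        elif delta < 0:
            rights[j].append((-delta, i, support))
    for i, cands in rights.items():
        cands.sort()
        nearest = [c for c in cands if c[0] == cands[0][0]]
        if len(nearest) > 1:
            top = max(s for _d, _j, s in nearest)
            contenders = [landmarks[j].pattern for _d, j, s in nearest
                          if s >= 0.5 * top]
            patterns = {landmarks[j].pattern for _d, j, _s in nearest}
            if len(contenders) > 1 and len(patterns) > 1:
                raise AmbiguousAdjacencyError(landmarks[i].pattern, contenders)


# ---------------------------------------------------------------------------
# consensus


def _as_pair(read):
    if isinstance(read, tuple):
        return read[0], str(read[1])
    return read.id, str(read.seq)


def _unit_draft(token, catalog: VleCatalog, model: ReferenceGeneModel) -> str:
    """Synthesize a draft unit sequence from a unit token."""
    if isinstance(token, int):
        perm = catalog.subtype_permutation(token)
    else:
        perm = token
    by_region = dict(zip(catalog.region_ids, perm))
    parts = []
    for region in model.regions:
        if region.variable:
            parts.append(catalog.get_variant(region.region_id,
                                             by_region[region.region_id]).sequence)
        else:
            parts.append(model.region_sequence(region.region_id))
    return "".join(parts)


def _polish(draft: str, segments: list[str]) -> str:
    """One round of plurality-vote polishing of covering segments.

    Each segment is globally aligned to the draft; per draft column the
    plurality base wins (ties resolved toward the draft base), a
    plurality of gaps deletes the column, and an inserted sequence seen
    in a strict majority of segments is inserted.
    """
    L = len(draft)
    depth = len(segments)
    counts = np.zeros((L, 5), dtype=np.int32)
    inserts: dict[int, Counter] = defaultdict(Counter)
    dcodes = seq_codes(draft)
    for seg in segments:
        codes = seq_codes(seg)
        _d, ops = global_alignment(seg, draft)
        qp = tp = 0
        for n, op in ops:
            if op in "=XM":
                np.add.at(counts, (np.arange(tp, tp + n), codes[qp:qp + n]), 1)
                qp += n
                tp += n
            elif op == "D":
                counts[tp:tp + n, 4] += 1
                tp += n
            else:  # I
                inserts[tp][seg[qp:qp + n]] += 1
                qp += n
    best = counts.max(axis=1)
    draft_best = counts[np.arange(L), dcodes] == best
    winner = np.where(draft_best, dcodes, counts.argmax(axis=1))
    out = []
    for col in range(L):
        ins = inserts.get(col)
        if ins:
            seq, c = ins.most_common(1)[0]
            if c * 2 > depth:
                out.append(seq)
        w = winner[col]
        if w < 4:
            out.append(chr(CODE_BASE[w]))
    ins = inserts.get(L)
    if ins:
        seq, c = ins.most_common(1)[0]
        if c * 2 > depth:
            out.append(seq)
    return "".join(out)


def tagged_consensus(reads,
                     token_reads: list[TokenRead],
                     lmap: LandmarkMap,
                     model: ReferenceGeneModel,
                     catalog: VleCatalog,
                     rounds: int = 2,
                     max_depth: int = 40,
                     min_place_agreement: float = 0.8) -> ArrayAssembly:
    """Assemble a polished array consensus from landmark-placed reads.

    Each read's units get absolute array positions from its landmark
    offsets (modal vote over all landmark occurrences; reads whose votes
    agree below ``min_place_agreement`` are dropped as likely chimeras).
    Per array position the plurality unit token is taken, a draft unit is
    synthesized from the catalog, and ``rounds`` rounds of plurality-vote
    polishing against up to ``max_depth`` covering read segments produce
    the consensus.  Positions covered by zero complete read units and not
    declared joins raise :class:`CoverageGapError`.
    """
    if rounds < 1:
        raise ParameterError("rounds must be >= 1")
    seq_by_id = dict(_as_pair(r) for r in reads)

    patterns: list[tuple[tuple, int]] = []
    for lm, p in zip(lmap.landmarks, lmap.positions):
        patterns.append((lm.pattern, p))
        for pat, rel in lm.merged_patterns:
            patterns.append((pat, p + rel))

    placed: dict[str, int] = {}
    for tr in token_reads:
        toks = tr.tokens
        ballot: Counter = Counter()
        for pat, p in patterns:
            for off in _occurrences(toks, pat):
                ballot[p - off] += 1
        if not ballot:
            continue
        base, c = ballot.most_common(1)[0]
        if c / sum(ballot.values()) < min_place_agreement:
            continue
        placed[tr.read_id] = base

    if not placed:
        raise CoverageGapError("no read could be placed on the landmark map")
    tr_by_id = {tr.read_id: tr for tr in token_reads}
    lo = min(placed[rid] for rid in placed)
    hi = max(placed[rid] + tr_by_id[rid].n_units for rid in placed)
    n_units = hi - lo

    token_votes: list[Counter] = [Counter() for _ in range(n_units)]
    segments: list[list[tuple[str, str]]] = [[] for _ in range(n_units)]
    for rid, base in placed.items():
        tr = tr_by_id[rid]
        src = seq_by_id.get(rid)
        for u_idx, unit in enumerate(tr.units):
            pos = base - lo + u_idx
            if unit.partial or unit.token is None:
                continue
            token_votes[pos][unit.token] += 1
            if src is not None:
                a, b = unit.interval
                seg = src[a:b]
                if unit.strand == "-":
                    seg = revcomp(seg)
                segments[pos].append((rid, seg))

    join_positions = set()
    for j in lmap.joins:
        join_positions.update(range(j.position, j.position + j.n_inserted))
    units: list[UnitAnnotation] = []
    drafts: list[str] = []
    for pos in range(n_units):
        if not token_votes[pos]:
            if pos in join_positions:
                continue
            raise CoverageGapError(
                f"array position {pos} is covered by no complete read unit")
        token = _modal_token(token_votes[pos])
        segs = [s for _rid, s in sorted(segments[pos])][:max_depth]
        draft = _unit_draft(token, catalog, model)
        for _ in range(rounds):
            if segs:
                draft = _polish(draft, segs)
        drafts.append(draft)
        units.append(UnitAnnotation(
            index=pos, token=token,
            subtype_id=token if isinstance(token, int) else None,
            interval=(0, 1), depth=len(segs)))

    sequence = "".join(drafts)
    final_units = []
    cursor = 0
    for u, d in zip(units, drafts):
        final_units.append(replace(u, index=len(final_units),
                                   interval=(cursor, cursor + len(d))))
        cursor += len(d)
    return ArrayAssembly(sequence=sequence, units=final_units,
                         joins=list(lmap.joins))


def _modal_token(ctr: Counter):
    top = max(ctr.values())
    winners = sorted((t for t, c in ctr.items() if c == top), key=str)
    return winners[0]


# ---------------------------------------------------------------------------
# joining and validation


def join_contigs(contigs: list[ArrayAssembly],
                 token_reads: list[TokenRead],
                 total_copy_estimates: dict) -> ArrayAssembly:
    """Merge contigs whose facing ends share one homogeneous subtype.

    The number of units inserted at each join reconciles the joining
    subtype's total copy estimate (read abundance / coverage) with the
    copies already placed across all contigs; joins are recorded, never
    silently interpolated.  Facing ends with different subtypes raise
    :class:`NoJoinError`.
    """
    if len(contigs) < 2:
        raise ParameterError("need at least two contigs to join")
    placed: Counter = Counter()
    for c in contigs:
        placed.update(t for t in c.token_sequence)

    join_subtypes = []
    for left, right in zip(contigs, contigs[1:]):
        s_left = left.token_sequence[-1]
        s_right = right.token_sequence[0]
        if s_left != s_right:
            raise NoJoinError(
                f"facing contig ends have subtypes {s_left!r} vs {s_right!r}")
        join_subtypes.append(s_left)

    per_subtype_joins = Counter(join_subtypes)
    to_insert: dict = {}
    for s, n_joins in per_subtype_joins.items():
        est = total_copy_estimates.get(s)
        if est is None:
            raise ParameterError(f"no copy estimate for joining subtype {s!r}")
        missing = max(0, round(est) - placed[s])
        share = missing // n_joins
        to_insert[s] = [share] * n_joins
        to_insert[s][0] += missing - share * n_joins

    merged_seq = [contigs[0].sequence]
    merged_units = list(contigs[0].units)
    joins = list(contigs[0].joins)
    used: Counter = Counter()
    offset = len(contigs[0].sequence)
    for s, right in zip(join_subtypes, contigs[1:]):
        n_ins = to_insert[s][used[s]]
        used[s] += 1
        a, b = merged_units[-1].interval
        tpl_seq = "".join(merged_seq)[a:b]
        join_pos = len(merged_units)
        joins.append(Join(position=join_pos, subtype_id=s, n_inserted=n_ins))
        for _ in range(n_ins):
            merged_units.append(UnitAnnotation(
                index=len(merged_units), token=s,
                subtype_id=s if isinstance(s, int) else None,
                interval=(offset, offset + len(tpl_seq)), depth=0, is_join=True))
            merged_seq.append(tpl_seq)
            offset += len(tpl_seq)
        for u in right.units:
            a, b = u.interval
            merged_units.append(replace(
                u, index=len(merged_units), interval=(offset, offset + (b - a))))
            offset += b - a
        merged_seq.append(right.sequence)
        joins.extend(right.joins)
    return ArrayAssembly(sequence="".join(merged_seq), units=merged_units,
                         joins=joins)


def validate_assembly(token_reads: list[TokenRead],
                      assembly: ArrayAssembly,
                      k: int = 3) -> tuple[pd.DataFrame, float]:
    """Compare per-pattern frequencies in reads vs counts in the assembly.

    Read k-gram counts are normalized by the read-set coverage implied by
    the assembly's unit count; the returned R^2 is for the least-squares
    fit through the origin, and the residual table is the
    "unaccounted copies" diagnostic (positive residual = copies present
    in reads but missing from the assembly).
    """
    asm_tokens = assembly.token_sequence
    asm_counts: Counter = Counter(
        asm_tokens[i:i + k] for i in range(len(asm_tokens) - k + 1))
    read_counts: Counter = Counter()
    total_units = 0
    for tr in token_reads:
        toks = tr.tokens
        total_units += len(toks)
        for i in range(len(toks) - k + 1):
            pat = toks[i:i + k]
            if None not in pat:
                read_counts[pat] += 1
    coverage = total_units / max(assembly.n_units, 1)
    patterns = sorted(set(asm_counts) | set(read_counts), key=str)
    x = np.array([asm_counts.get(p, 0) for p in patterns], dtype=float)
    y = np.array([read_counts.get(p, 0) / coverage for p in patterns])
    sxx = float((x * x).sum())
    slope = float((x * y).sum()) / sxx if sxx else 0.0
    resid = y - slope * x
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot else 1.0
    table = pd.DataFrame({
        "pattern": [_pattern_str(p) for p in patterns],
        "assembly_count": x.astype(int),
        "read_count": [read_counts.get(p, 0) for p in patterns],
        "read_copy_estimate": y,
        "residual": resid,
    })
    table = table.sort_values("residual", ascending=False,
                              ignore_index=True)
    return table, r2


def _pattern_str(pattern: tuple) -> str:
    def tok(t):
        if isinstance(t, tuple):
            return "(" + ",".join(str(v) for v in t) + ")"
        return str(t)
    return "+".join(tok(t) for t in pattern)
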