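"""Thin edit-distance / alignment layer over edlib.

All scoring in the package is plain Levenshtein (unit costs).  edlib's HW
("infix") mode only reports the *best*-scoring locations, so exhaustive
occurrence search is done by iteratively masking the best hit and
re-searching until the remaining best exceeds the threshold.
"""

from __future__ import annotations

import re

import edlib
import numpy as np

_COMP = str.maketrans("ACGTRYKMBVDHNacgtrykmbvdhn", "TGCAYRMKVBHDNtgcayrmkvbhdn")

# base codes used throughout: A=0 C=1 G=2 T=3, gap/other=4
BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    BASE_CODE[_b] = _i
    BASE_CODE[_b + 32] = _i
CODE_BASE = np.frombuffer(b"ACGT-", dtype=np.uint8)

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware)."""
    return seq.translate(_COMP)[::-1]


def seq_codes(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0 C=1 G=2 T=3, other=4)."""
    return BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def edit_distance(a: str, b: str, k: int = -1) -> int:
    """Levenshtein distance between two strings (-1 if above `k`)."""
    return edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"]


def cigar_ops(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def global_alignment(query: str, target: str) -> tuple[int, list[tuple[int, str]]]:
    """Global (NW) alignment of query against target.

    Returns ``(edit_distance, ops)`` where ops consume the query on
    ``= X I`` and the target on ``= X D``.
    """
    res = edlib.align(query, target, mode="NW", task="path")
    return res["editDistance"], cigar_ops(res["cigar"])


def best_infix(pattern, text, k: int = -1):
    """Best approximate occurrence(s) of pattern within text.

    Returns ``(distance, [(start, end), ...])`` with half-open intervals,
    or ``(None, [])`` when no occurrence scores <= k.
    """
    if len(text) == 0:
        return None, []
    res = edlib.align(pattern, text, mode="HW", task="locations", k=k)
    d = res["editDistance"]
    if d < 0 or (k >= 0 and d > k):  # edlib ignores k for degenerate targets
        return None, []
    locs = [(0 if s is None else s, e + 1) for s, e in res["locations"]]
    locs.sort()
    return d, locs


def find_occurrences(pattern: str, text: str, max_edits: int,
                     min_separation: int | None = None):
    """All approximate occurrences of pattern in text within max_edits.

    Found greedily best-first with masking; occurrences whose starts lie
    within ``min_separation`` of an already-accepted start are dropped
    (edlib reports a fringe of equivalent locations per occurrence).

    Returns a list of ``(start, end, distance)`` sorted by start.
    """
    if min_separation is None:
        min_separation = max(1, len(pattern) // 2)
    buf = bytearray(text.encode())
    mask = b"#"
    hits: list[tuple[int, int, int]] = []
    while True:
        d, locs = best_infix(pattern, bytes(buf), k=max_edits)
        if d is None:
            break
        accepted = []
        last = None
        for s, e in locs:
            if last is not None and s - last < min_separation:
                continue
            accepted.append((s, e))
            last = s
        for s, e in accepted:
            hits.append((s, e, d))
            buf[s:e] = mask * (e - s)
    hits.sort()
    deduped: list[tuple[int, int, int]] = []
    for s, e, d in hits:
        if deduped and s - deduped[-1][0] < min_separation:
            # keep the better-scoring of two colliding hits
            if d < deduped[-1][2]:
                deduped[-1] = (s, e, d)
            continue
        deduped.append((s, e, d))
    return deduped
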