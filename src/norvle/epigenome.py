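"""Nucleolar enrichment of VLEs and sliding-window methylation binning.

Fluorescence-sorted nucleolar vs total-nuclei DNA, tokenized into VLE
calls, measures which gene variants associate with the nucleolus (a
proxy for transcriptional activity).  Per-cytosine 5mC calls are binned
in sliding windows by sequence context (CG / CHG / CHH).
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from .errors import ParameterError
from .model import TokenRead

__all__ = ["vle_enrichment", "bin_methylation"]

CONTEXTS = ("CG", "CHG", "CHH")


def vle_enrichment(nucleolus_tokens: list[TokenRead],
                   nuclei_tokens: list[TokenRead],
                   pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-VLE nucleolar enrichment from sorted-fraction token sets.

    For every (region, variant), each fraction's call counts are
    pseudocounted, converted to fractions among that region's calls, and
    compared as log2(nucleolus fraction / nuclei fraction).  Identical
    fraction sets give 0 everywhere; swapping the sets negates every
    value exactly.
    """
    if not nucleolus_tokens or not nuclei_tokens:
        raise ParameterError("both token sets must be non-empty")
    no_counts = _vle_counts(nucleolus_tokens)
    nu_counts = _vle_counts(nuclei_tokens)
    regions = sorted({r for r, _v in no_counts} | {r for r, _v in nu_counts})
    rows = []
    for region in regions:
        variants = sorted({v for r, v in no_counts if r == region} |
                          {v for r, v in nu_counts if r == region})
        no_tot = sum(no_counts.get((region, v), 0) + pseudocount
                     for v in variants)
        nu_tot = sum(nu_counts.get((region, v), 0) + pseudocount
                     for v in variants)
        for v in variants:
            no_c = no_counts.get((region, v), 0)
            nu_c = nu_counts.get((region, v), 0)
            no_f = (no_c + pseudocount) / no_tot
            nu_f = (nu_c + pseudocount) / nu_tot
            rows.append({
                "region": region,
                "variant": v,
                "nucleolus_count": no_c,
                "nuclei_count": nu_c,
                "nucleolus_fraction": no_f,
                "nuclei_fraction": nu_f,
                "log2_enrichment": float(np.log2(no_f / nu_f)),
            })
    return pd.DataFrame(rows)


def _vle_counts(token_reads: list[TokenRead]) -> Counter:
    counts: Counter = Counter()
    for tr in token_reads:
        for unit in tr.units:
            for call in unit.calls:
                if call is not None:
                    counts[(call.region_id, call.variant_id)] += 1
    return counts


def bin_methylation(sites: pd.DataFrame,
                    window: int = 500,
                    step: int = 250,
                    min_sites: int = 5,
                    min_coverage: int = 3,
                    span: int | None = None,
                    coverage_weighted: bool = False) -> pd.DataFrame:
    """Sliding-window percent methylation per context.

    ``sites`` columns: position (1-based), strand, context, methylated_count,
    total_count.  Per context and window the mean methylated fraction
    (site-weighted by default, coverage-weighted on request) over sites
    with coverage >= ``min_coverage`` is reported as a percentage;
    windows with fewer than ``min_sites`` qualifying sites are emitted
    with a missing (NaN) percentage, mirroring regions with a paucity of
    uniquely mapped reads.
    """
    if window < step:
        raise ParameterError("window must be >= step")
    df = sites.copy()
    df = df[df["total_count"] >= min_coverage]
    if span is None:
        span = int(sites["position"].max()) if len(sites) else window
    starts = np.arange(0, max(span - window, 0) + 1, step, dtype=int)
    if len(starts) == 0:
        starts = np.array([0])
    rows = []
    for context in CONTEXTS:
        sub = df[df["context"] == context]
        pos = sub["position"].to_numpy() - 1  # to 0-based
        meth = sub["methylated_count"].to_numpy(dtype=float)
        tot = sub["total_count"].to_numpy(dtype=float)
        order = np.argsort(pos)
        pos, meth, tot = pos[order], meth[order], tot[order]
        frac = np.divide(meth, tot, out=np.zeros_like(meth), where=tot > 0)
        for w0 in starts:
            lo = int(np.searchsorted(pos, w0, "left"))
            hi = int(np.searchsorted(pos, w0 + window, "left"))
            n = hi - lo
            if n < min_sites:
                pct = np.nan
            elif coverage_weighted:
                pct = 100.0 * meth[lo:hi].sum() / tot[lo:hi].sum()
            else:
                pct = 100.0 * frac[lo:hi].mean()
            rows.append({"context": context, "start": int(w0),
                         "end": int(w0 + window), "n_sites": n,
                         "percent_methylation": pct})
    return pd.DataFrame(rows)
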