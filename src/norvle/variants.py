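"""Per-unit variant calling and RNA expression mapping onto the array.

Short-read DNA/RNA sequencing against a single 45S reference collapses
all gene copies onto one coordinate system; mapping the resulting allele
frequencies back through a per-unit variant matrix assigns expression to
specific array positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from os import PathLike
from pathlib import Path

import numpy as np
import pandas as pd

from ._align import global_alignment
from .errors import ParameterError, VcfParseError
from .model import ReferenceGeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "VariantSite",
    "UnitVariantMatrix",
    "ExpressionTrack",
    "load_variant_sites",
    "per_unit_variant_calls",
    "normalize_expression",
]

MISSING = "."


@dataclass(frozen=True)
class VariantSite:
    """One SNV on the 45S reference: 1-based position, ref/alt, frequency."""

    position: int
    ref_base: str
    alt_base: str
    frequency: float

    def __post_init__(self):
        # zero is allowed so unexpressed RNA alleles can carry value 0
        if not 0 <= self.frequency <= 1:
            raise ParameterError("frequency must lie in [0, 1]")
        if self.ref_base == self.alt_base:
            raise ParameterError("ref and alt base must differ")


@dataclass
class UnitVariantMatrix:
    """Observed base per (unit, variant site).

    ``calls`` is a DataFrame with one row per unit in array order and
    one column per site position (1-based); cells hold the unit base
    aligned to that reference position, or '.' where a deletion covers
    the site.
    """

    calls: pd.DataFrame
    sites: list[VariantSite]

    @property
    def n_units(self) -> int:
        return len(self.calls)

    def carriers(self, site: VariantSite) -> list[int]:
        """Unit indices whose aligned base equals the site's alt allele."""
        col = self.calls[site.position]
        return [int(i) for i in np.flatnonzero(col.values == site.alt_base)]


@dataclass
class ExpressionTrack:
    """Normalized expression per (site, carrier unit position).

    ``values`` has columns (position, unit, value); ``orphans`` lists
    RNA sites whose alt allele is absent from the assembly.
    """

    values: pd.DataFrame
    orphans: list[VariantSite]
    mode: str = "copy_count"


def load_variant_sites(source, min_frequency: float = 0.001) -> list[VariantSite]:
    """Read SNV sites from a minimal VCF (CHROM POS ID REF ALT ... INFO AF=).

    Records with frequency <= ``min_frequency`` are dropped, as are
    non-SNV (indel / multi-base) records, with the dropped counts logged.
    Malformed records raise :class:`VcfParseError` naming the line.
    """
    if isinstance(source, (str, PathLike)):
        lines = Path(source).read_text().splitlines()
    else:
        lines = [str(l).rstrip("\n") for l in source]
    sites: list[VariantSite] = []
    n_low = n_non_snv = 0
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise VcfParseError(lineno, line, "fewer than 5 columns")
        _chrom, pos_s, *rest = fields
        if len(fields) >= 8:
            ref, alt, info = fields[3], fields[4], fields[7]
        else:
            ref, alt, info = fields[2], fields[3], fields[4]
        try:
            pos = int(pos_s)
        except ValueError:
            raise VcfParseError(lineno, line, "POS is not an integer") from None
        freq = _parse_af(info)
        if freq is None:
            raise VcfParseError(lineno, line, "no AF= in INFO")
        if len(ref) != 1 or len(alt) != 1 or ref == alt:
            n_non_snv += 1
            continue
        if freq <= min_frequency:
            n_low += 1
            continue
        sites.append(VariantSite(pos, ref, alt, freq))
    if n_low or n_non_snv:
        logger.info("load_variant_sites: dropped %d low-frequency and %d "
                    "non-SNV records; kept %d", n_low, n_non_snv, len(sites))
    return sites


def _parse_af(info: str):
    for token in info.split(";"):
        if token.startswith("AF="):
            try:
                return float(token[3:])
            except ValueError:
                return None
    return None


def per_unit_variant_calls(assembly, model: ReferenceGeneModel,
                           sites: list[VariantSite]) -> UnitVariantMatrix:
    """Record each unit's base at every variant site of the reference.

    Units are globally aligned to the reference unit; the unit base
    aligned to each site position is recorded, with deletions covering
    the site recorded as missing ('.').
    """
    seq = assembly if isinstance(assembly, str) else assembly.sequence
    units = ([(0, len(seq))] if isinstance(assembly, str)
             else [u.interval for u in assembly.units])
    positions = sorted({s.position for s in sites})
    pos_arr = np.array(positions, dtype=int)
    rows = np.full((len(units), len(positions)), MISSING, dtype=object)
    ref = model.ref_sequence
    for u_idx, (a, b) in enumerate(units):
        unit_seq = seq[a:b]
        _d, ops = global_alignment(unit_seq, ref)
        qp = tp = 0
        for n, op in ops:
            if op in "=XM":
                lo = int(np.searchsorted(pos_arr, tp + 1, "left"))
                hi = int(np.searchsorted(pos_arr, tp + n, "right"))
                for i in range(lo, hi):  # positions are 1-based
                    p = positions[i]
                    rows[u_idx, i] = unit_seq[qp + (p - 1 - tp)]
                qp += n
                tp += n
            elif op == "D":
                tp += n
            else:
                qp += n
    calls = pd.DataFrame(rows, columns=positions)
    return UnitVariantMatrix(calls=calls, sites=list(sites))


def normalize_expression(rna_sites: list[VariantSite],
                         matrix: UnitVariantMatrix,
                         mode: str = "copy_count") -> ExpressionTrack:
    """Distribute RNA alt-allele frequencies over carrier unit positions.

    For each RNA site the normalized value is the site's alt frequency
    divided by the number of assembly units carrying the alt allele
    (``copy_count`` mode) or by the carrier *fraction* of units
    (``carrier_fraction`` mode); the value is assigned at every carrier
    position.  Sites with zero assembly carriers are reported as orphans
    and receive no track values.
    """
    if mode not in ("copy_count", "carrier_fraction"):
        raise ParameterError("mode must be 'copy_count' or 'carrier_fraction'")
    known = {s.position for s in matrix.sites}
    rows = []
    orphans: list[VariantSite] = []
    for site in rna_sites:
        if site.position not in known or site.position not in matrix.calls.columns:
            orphans.append(site)
            continue
        carriers = matrix.carriers(site)
        if not carriers:
            orphans.append(site)
            continue
        denom = (len(carriers) if mode == "copy_count"
                 else len(carriers) / matrix.n_units)
        value = site.frequency / denom
        for u in carriers:
            rows.append({"position": site.position, "unit": u, "value": value})
    values = pd.DataFrame(rows, columns=["position", "unit", "value"])
    return ExpressionTrack(values=values, orphans=orphans, mode=mode)
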