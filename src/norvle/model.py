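"""Domain model for 45S rRNA gene units and their variable-length elements.

A 45S gene unit is ~10 kbp of promoter, transcribed rRNAs/spacers and the
intergenic spacer (IGS).  Unit coordinates in this package are phased so
that position 0 is the start of the conserved 25S anchor: tandem arrays
are phase-symmetric, and the anchor is where reads are segmented, so the
anchor-first rotation makes segment boundaries coincide with unit
boundaries.  Several regions are variable-length elements (VLEs): the
3'ETS repeat block, the Sal-repeat array, the spacer-promoter cluster and
the 5'ETS C-repeats.  A gene *subtype* is one specific permutation of VLE
variants across all variable regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import ParameterError

__all__ = [
    "Region",
    "ReferenceGeneModel",
    "VleVariant",
    "VleCatalog",
    "VleCall",
    "GeneUnitToken",
    "TokenRead",
]


@dataclass(frozen=True)
class Region:
    """One annotated interval of the gene unit (0-based, half-open)."""

    region_id: str
    start: int
    end: int
    variable: bool = False

    def __post_init__(self):
        if self.end <= self.start:
            raise ParameterError(f"region {self.region_id}: end <= start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ReferenceGeneModel:
    """Consensus sequence and annotation of one complete 45S gene unit.

    Parameters
    ----------
    ref_sequence
        DNA of one full consensus unit, anchor-first phase.
    regions
        Ordered, non-overlapping regions tiling the unit.
    anchor_start, anchor_length
        Conserved 25S subsequence used to segment reads into units.
    ippoi_site
        Offset of the I-PpoI cut position; must fall in the anchor's
        (25S) region.  I-PpoI cuts once per gene, so successive cut
        positions measure unit lengths.
    """

    ref_sequence: str
    regions: tuple[Region, ...]
    anchor_start: int = 0
    anchor_length: int = 500
    ippoi_site: int = 60

    def __post_init__(self):
        pos = 0
        for r in self.regions:
            if r.start != pos:
                raise ParameterError(
                    f"regions must tile the unit; gap/overlap at {r.region_id}")
            pos = r.end
        if pos != len(self.ref_sequence):
            raise ParameterError("regions do not cover the full unit")
        anchor = self.anchor
        if self.ref_sequence.count(anchor) != 1:
            raise ParameterError("anchor must occur exactly once in ref_sequence")
        host = self.region_at(self.anchor_start)
        if not (host.start <= self.ippoi_site < host.end):
            raise ParameterError("ippoi_site must fall inside the anchor's region")

    @property
    def anchor(self) -> str:
        return self.ref_sequence[self.anchor_start:
                                 self.anchor_start + self.anchor_length]

    @property
    def unit_length(self) -> int:
        return len(self.ref_sequence)

    @property
    def variable_regions(self) -> tuple[Region, ...]:
        return tuple(r for r in self.regions if r.variable)

    @property
    def variable_region_ids(self) -> tuple[str, ...]:
        return tuple(r.region_id for r in self.variable_regions)

    def region(self, region_id: str) -> Region:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(region_id)

    def region_at(self, position: int) -> Region:
        for r in self.regions:
            if r.start <= position < r.end:
                return r
        raise KeyError(position)

    def region_sequence(self, region_id: str) -> str:
        r = self.region(region_id)
        return self.ref_sequence[r.start:r.end]


@dataclass(frozen=True)
class VleVariant:
    """One sequence variant of a variable-length element.

    diagnostic_snps lists ``(offset, base)`` pairs distinguishing this
    variant from same-length variants of the same region.
    """

    region_id: str
    variant_id: str
    sequence: str
    diagnostic_snps: tuple[tuple[int, str], ...] = ()

    def __post_init__(self):
        if not self.sequence:
            raise ParameterError(
                f"variant {self.region_id}|{self.variant_id}: empty sequence")


@dataclass
class VleCatalog:
    """Library of VLE variants per region plus the subtype registry.

    The registry maps a full permutation of variant calls, one per
    variable region in catalog order, to an integer subtype id.
    """

    variants: dict[str, list[VleVariant]] = field(default_factory=dict)
    subtype_registry: dict[tuple[str, ...], int] = field(default_factory=dict)

    def __post_init__(self):
        seen = set()
        for region_id, vs in self.variants.items():
            for v in vs:
                if v.region_id != region_id:
                    raise ParameterError(
                        f"variant {v.variant_id} filed under wrong region")
                key = (region_id, v.variant_id)
                if key in seen:
                    raise ParameterError(f"duplicate variant {key}")
                seen.add(key)
        ids = list(self.subtype_registry.values())
        if len(ids) != len(set(ids)):
            raise ParameterError("subtype ids must be unique")
        for perm in self.subtype_registry:
            self._check_permutation(perm)

    def _check_permutation(self, perm):
        if len(perm) != len(self.variants):
            raise ParameterError(f"permutation {perm!r} has wrong arity")
        for region_id, variant_id in zip(self.variants, perm):
            if variant_id not in {v.variant_id for v in self.variants[region_id]}:
                raise ParameterError(
                    f"permutation references unknown variant "
                    f"{region_id}|{variant_id}")

    @property
    def region_ids(self) -> tuple[str, ...]:
        return tuple(self.variants)

    def variants_for(self, region_id: str) -> list[VleVariant]:
        return self.variants[region_id]

    def get_variant(self, region_id: str, variant_id: str) -> VleVariant:
        for v in self.variants[region_id]:
            if v.variant_id == variant_id:
                return v
        raise KeyError((region_id, variant_id))

    def lookup_subtype(self, perm: tuple[str, ...]):
        return self.subtype_registry.get(perm)

    def register_subtype(self, perm: tuple[str, ...]) -> int:
        self._check_permutation(perm)
        existing = self.subtype_registry.get(perm)
        if existing is not None:
            return existing
        new_id = max(self.subtype_registry.values(), default=0) + 1
        self.subtype_registry[perm] = new_id
        return new_id

    def subtype_permutation(self, subtype_id: int) -> tuple[str, ...]:
        for perm, sid in self.subtype_registry.items():
            if sid == subtype_id:
                return perm
        raise KeyError(subtype_id)

    @property
    def n_subtypes(self) -> int:
        return len(self.subtype_registry)

    def copy(self) -> "VleCatalog":
        return VleCatalog(
            variants={r: list(vs) for r, vs in self.variants.items()},
            subtype_registry=dict(self.subtype_registry),
        )


@dataclass(frozen=True)
class VleCall:
    """The variant chosen for one VLE of one unit (minimum edit distance)."""

    region_id: str
    variant_id: str
    score: int
    ambiguous: bool = False

    def __post_init__(self):
        if self.score < 0:
            raise ParameterError("score must be >= 0")


@dataclass(frozen=True)
class GeneUnitToken:
    """One gene unit of a read reduced to its per-region VLE calls.

    ``calls`` holds one VleCall (or None) per variable region, in gene
    model order.  ``interval`` is half-open on the *source* read;
    ``strand`` is the unit's orientation relative to the transcribed
    strand.  Units truncated at read ends are ``partial``.
    """

    calls: tuple
    subtype_id: int | None
    partial: bool
    strand: str
    interval: tuple[int, int]

    def __post_init__(self):
        if self.interval[1] <= self.interval[0]:
            raise ParameterError("interval end must exceed start")
        if self.strand not in "+-":
            raise ParameterError("strand must be '+' or '-'")
        if not self.partial and any(c is None for c in self.calls):
            raise ParameterError("non-partial unit must have a call per region")

    @property
    def key(self) -> tuple:
        """Permutation key: variant ids in region order (None where uncalled)."""
        return tuple(c.variant_id if c is not None else None for c in self.calls)

    @property
    def token(self):
        """Hashable unit token: subtype id, else the permutation key, else
        None for units missing any call."""
        if self.subtype_id is not None:
            return self.subtype_id
        key = self.key
        return None if None in key else key


@dataclass(frozen=True)
class TokenRead:
    """A read reduced to its ordered string of gene-unit tokens."""

    read_id: str
    units: tuple[GeneUnitToken, ...]
    source_length: int

    def __post_init__(self):
        mids = self.units[1:-1]
        if any(u.partial for u in mids):
            raise ParameterError("only terminal units may be partial")

    @property
    def tokens(self) -> tuple:
        return tuple(u.token for u in self.units)

    @property
    def n_units(self) -> int:
        return len(self.units)

    def with_units(self, units) -> "TokenRead":
        return replace(self, units=tuple(units))
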