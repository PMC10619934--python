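"""Synthetic NOR generator: catalogs, arrays, ultralong reads, observables.

Emulates the data shapes the pipeline consumes: a tandem array of ~10-kbp
gene units drawn from a subtype catalog (with homogeneous regions and
optional structural anomalies), a log-normal ultralong-read length model
with independent per-base substitution/insertion/deletion errors,
nucleolus/nuclei sorted-fraction token sets with subtype-specific
depletion, RNA allele-frequency tables confined to an expressed block,
and per-cytosine methylation tables with a hypomethylated active region.

All outputs are byte-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from ._align import global_alignment, revcomp
from .errors import ConfigError
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
    "RegionSpec",
    "HomogeneousRegion",
    "ReadModel",
    "ExpressionSpec",
    "SilencingSpec",
    "MethylationSpec",
    "SimConfig",
    "GroundTruth",
    "Observables",
    "simulate_gene_model",
    "simulate_catalog",
    "simulate_array",
    "simulate_reads",
    "simulate_observables",
    "simulate_locus",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 0, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass(frozen=True)
class RegionSpec:
    """Layout of one gene-unit region in the synthetic gene model.

    Variable regions are built as head + motif*copies + tail (emulating
    the short-repeat structure of real VLE zones), with per-variant
    marker SNPs planted in the conserved head/tail context.
    """

    region_id: str
    length: int = 0
    variable: bool = False
    n_variants: int = 0
    motif_length: int = 60
    min_copies: int = 2
    max_copies: int = 10
    flank_length: int = 80
    marker_snps: int = 6


def _default_regions() -> tuple[RegionSpec, ...]:
    return (
        RegionSpec("25S", length=2800),
        RegionSpec("ETS3_R", variable=True, n_variants=6, motif_length=45,
                   min_copies=4, max_copies=12),
        RegionSpec("SP1", length=250),
        RegionSpec("IGS_SAL", variable=True, n_variants=8, motif_length=72,
                   min_copies=5, max_copies=14),
        RegionSpec("SP2", length=250),
        RegionSpec("IGS_SPP", variable=True, n_variants=4, motif_length=90,
                   min_copies=1, max_copies=5),
        RegionSpec("PROM", length=450),
        RegionSpec("ETS5_C", variable=True, n_variants=5, motif_length=55,
                   min_copies=3, max_copies=10),
        RegionSpec("18S", length=1800),
        RegionSpec("ITS1", length=250),
        RegionSpec("5.8S", length=160),
        RegionSpec("ITS2", length=230),
    )


@dataclass(frozen=True)
class HomogeneousRegion:
    """A run of near-identical subtypes: (start, length, subtype, purity)."""

    start: int
    length: int
    subtype_id: int
    purity: float = 1.0


@dataclass(frozen=True)
class ReadModel:
    """Ultralong-read model: log-normal lengths, iid per-base errors."""

    coverage: float = 100.0
    mean_length: int = 60_000
    sigma_log: float = 0.55
    min_length: int = 5_000
    max_length: int = 300_000
    error_rate: float = 0.03
    sub_fraction: float = 0.4
    ins_fraction: float = 0.3
    del_fraction: float = 0.3


@dataclass(frozen=True)
class ExpressionSpec:
    """Which units are transcribed: a contiguous block, per-copy rate."""

    block: tuple[int, int] = (45, 75)
    per_copy_frequency: float = 0.01


@dataclass(frozen=True)
class SilencingSpec:
    """Subtypes depleted from the nucleolus-associated fraction."""

    silenced_subtypes: tuple[int, ...] = (2,)
    depletion: float = 8.0
    reads_per_fraction: int = 3000


@dataclass(frozen=True)
class MethylationSpec:
    """Per-context 5mC means outside/inside the hypomethylated block."""

    context_means: dict = field(default_factory=lambda: {
        "CG": (0.90, 0.10),
        "CHG": (0.70, 0.08),
        "CHH": (0.12, 0.04),
    })
    site_fraction: float = 0.05
    coverage_mean: float = 30.0
    sd: float = 0.05


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic NOR.

    Defaults describe the round-trip benchmark locus: a 120-unit array of
    30 subtypes with two 10-unit homogeneous regions and 8 planted unique
    landmark trigrams, read at 100x coverage with 60-kbp mean reads and
    3% total error.
    """

    seed: int = 1
    regions: tuple[RegionSpec, ...] = field(default_factory=_default_regions)
    n_subtypes: int = 30
    n_units: int = 120
    homogeneous_regions: tuple[HomogeneousRegion, ...] = (
        HomogeneousRegion(20, 8, 1),
        HomogeneousRegion(80, 8, 2),
    )
    composition: dict | None = None
    background_decay: float = 0.85
    planted_landmarks: int = 8
    anomalies: dict = field(default_factory=dict)
    read_model: ReadModel = field(default_factory=ReadModel)
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    silencing: SilencingSpec = field(default_factory=SilencingSpec)
    methylation: MethylationSpec = field(default_factory=MethylationSpec)

    @classmethod
    def small(cls, seed: int = 1, **overrides) -> "SimConfig":
        """Reduced locus for fast unit tests (40 units, 30x coverage)."""
        kw = dict(
            seed=seed,
            n_units=40,
            n_subtypes=18,
            homogeneous_regions=(HomogeneousRegion(8, 4, 1),
                                 HomogeneousRegion(26, 4, 2)),
            planted_landmarks=4,
            read_model=ReadModel(coverage=30.0, mean_length=50_000,
                                 sigma_log=0.6, min_length=12_000,
                                 max_length=250_000),
            expression=ExpressionSpec(block=(14, 26)),
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def paper_like(cls, seed: int = 1, **overrides) -> "SimConfig":
        """Full-scale preset: 894 units, 74 subtypes, 100x coverage."""
        kw = dict(
            seed=seed,
            n_units=894,
            n_subtypes=74,
            homogeneous_regions=(HomogeneousRegion(120, 40, 1),
                                 HomogeneousRegion(600, 40, 2)),
            planted_landmarks=16,
            read_model=ReadModel(coverage=100.0, mean_length=45_000),
            expression=ExpressionSpec(block=(300, 600)),
        )
        kw.update(overrides)
        return cls(**kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        """Rebuild a config from a (possibly partial) nested mapping."""
        kw = dict(data)
        if "regions" in kw:
            kw["regions"] = tuple(RegionSpec(**r) for r in kw["regions"])
        if "homogeneous_regions" in kw:
            kw["homogeneous_regions"] = tuple(
                HomogeneousRegion(**h) if isinstance(h, dict)
                else HomogeneousRegion(*h)
                for h in kw["homogeneous_regions"])
        for key, klass in (("read_model", ReadModel),
                           ("expression", ExpressionSpec),
                           ("silencing", SilencingSpec),
                           ("methylation", MethylationSpec)):
            if key in kw and isinstance(kw[key], dict):
                sub = dict(kw[key])
                for tkey in ("block", "silenced_subtypes"):
                    if tkey in sub and isinstance(sub[tkey], list):
                        sub[tkey] = tuple(sub[tkey])
                kw[key] = klass(**sub)
        return cls(**kw)


@dataclass
class GroundTruth:
    """Everything the simulator knows about the emitted locus."""

    tokens: tuple[int, ...]
    dna: str
    unit_intervals: tuple[tuple[int, int], ...]
    unit_subtypes: tuple[int, ...]
    anomalies: tuple[tuple[int, str, tuple[int, int]], ...]
    planted_landmarks: tuple[tuple[int, tuple], ...]
    expressed_block: tuple[int, int]
    silenced_subtypes: tuple[int, ...]

    @property
    def n_units(self) -> int:
        return len(self.tokens)

    def unique_kgrams(self, k: int) -> dict[tuple, int]:
        """Map of k-grams occurring exactly once -> their start position."""
        counts: dict[tuple, list[int]] = {}
        for i in range(len(self.tokens) - k + 1):
            counts.setdefault(tuple(self.tokens[i:i + k]), []).append(i)
        return {p: pos[0] for p, pos in counts.items() if len(pos) == 1}


@dataclass
class Observables:
    """Sorted-fraction token sets, variant tables and methylation table."""

    nucleolus_tokens: list[TokenRead]
    nuclei_tokens: list[TokenRead]
    dna_sites: pd.DataFrame
    rna_sites: pd.DataFrame
    methylation: pd.DataFrame
    site_carriers: dict[int, tuple[int, ...]]


# ---------------------------------------------------------------------------
# blueprint: conserved sequences + variant sequences, shared by model/catalog


def _random_dna(rng, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _blueprint(cfg: SimConfig, seed: int | None = None):
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    conserved: dict[str, str] = {}
    variants: dict[str, list[VleVariant]] = {}
    for spec in cfg.regions:
        if not spec.variable:
            conserved[spec.region_id] = _random_dna(rng, spec.length)
            continue
        if spec.n_variants < 1:
            raise ConfigError(f"{spec.region_id}: need >= 1 variant")
        head = _random_dna(rng, spec.flank_length)
        tail = _random_dna(rng, spec.flank_length)
        motif = _random_dna(rng, spec.motif_length)
        span = spec.max_copies - spec.min_copies + 1
        copies = [spec.min_copies + (i % span) for i in range(spec.n_variants)]
        if spec.n_variants >= 2:
            copies[1] = copies[0]  # one same-length pair, SNP-discriminated
        region_variants = []
        for vi in range(spec.n_variants):
            body = head + motif * copies[vi] + tail
            chars = list(body)
            ctx = len(head) + len(tail)
            offsets = rng.choice(ctx, size=min(spec.marker_snps, ctx),
                                 replace=False)
            snps = []
            for off in sorted(int(o) for o in offsets):
                pos = off if off < len(head) else len(body) - ctx + off
                old = chars[pos]
                new = "ACGT"[("ACGT".index(old) + int(rng.integers(1, 4))) % 4]
                chars[pos] = new
                snps.append((pos, new))
            region_variants.append(
                VleVariant(spec.region_id, f"v{vi + 1}", "".join(chars),
                           diagnostic_snps=tuple(snps)))
        variants[spec.region_id] = region_variants

    parts = []
    regions = []
    pos = 0
    for spec in cfg.regions:
        seq = (variants[spec.region_id][0].sequence if spec.variable
               else conserved[spec.region_id])
        regions.append(Region(spec.region_id, pos, pos + len(seq), spec.variable))
        parts.append(seq)
        pos += len(seq)
    model = ReferenceGeneModel(ref_sequence="".join(parts),
                               regions=tuple(regions))

    registry: dict[tuple[str, ...], int] = {}
    var_region_ids = [s.region_id for s in cfg.regions if s.variable]
    reference_perm = tuple("v1" for _ in var_region_ids)
    registry[reference_perm] = 1
    # subtype 2 carries each region's last variant, which no other
    # subtype uses: locus-private VLEs, as real NORs have (silenced
    # subtypes are distinguishable by their private elements)
    if cfg.n_subtypes >= 2:
        private_perm = tuple(f"v{len(variants[r])}" for r in var_region_ids)
        registry[private_perm] = 2
    while len(registry) < cfg.n_subtypes:
        perm = tuple(
            f"v{int(rng.integers(1, max(len(variants[r]), 2)))}"
            for r in var_region_ids
        )
        if perm not in registry:
            registry[perm] = len(registry) + 1
    catalog = VleCatalog(variants=variants, subtype_registry=registry)
    return model, catalog


def simulate_gene_model(cfg: SimConfig, seed: int | None = None) -> ReferenceGeneModel:
    """Synthetic 45S reference gene model (anchor-first phase)."""
    return _blueprint(cfg, seed)[0]


def simulate_catalog(cfg: SimConfig, seed: int | None = None) -> VleCatalog:
    """Synthetic VLE catalog with registered subtype permutations."""
    return _blueprint(cfg, seed)[1]


# ---------------------------------------------------------------------------
# array


def _subtype_sequence(catalog: VleCatalog, model: ReferenceGeneModel,
                      subtype_id: int) -> str:
    perm = dict(zip(catalog.region_ids, catalog.subtype_permutation(subtype_id)))
    parts = []
    for region in model.regions:
        if region.variable:
            parts.append(catalog.get_variant(region.region_id,
                                             perm[region.region_id]).sequence)
        else:
            parts.append(model.region_sequence(region.region_id))
    return "".join(parts)


def simulate_array(catalog: VleCatalog, cfg: SimConfig,
                   seed: int | None = None) -> tuple[str, GroundTruth]:
    """Draw a unit-subtype sequence and emit the array DNA plus truth.

    Homogeneous regions are filled with their designated subtype at the
    given purity; all other positions are sampled from the remaining
    subtypes with geometrically decaying weights (or ``cfg.composition``
    when given).  ``cfg.planted_landmarks`` evenly spaced background
    trigrams are re-drawn until globally unique, and any configured
    structural anomalies are applied to randomly chosen units.
    """
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 0x5A)
    model = simulate_gene_model(cfg)
    n = cfg.n_units
    all_subtypes = sorted(catalog.subtype_registry.values())
    hom_subtypes = {h.subtype_id for h in cfg.homogeneous_regions}
    for h in cfg.homogeneous_regions:
        if not (0 <= h.start and h.start + h.length <= n):
            raise ConfigError("homogeneous region outside array bounds")
        if h.subtype_id not in all_subtypes:
            raise ConfigError(f"unknown subtype {h.subtype_id}")

    background = [s for s in all_subtypes if s not in hom_subtypes]
    if cfg.composition is not None:
        total = sum(cfg.composition.values())
        if total > 1 + 1e-9:
            raise ConfigError("composition fractions must sum to <= 1")
        background = sorted(cfg.composition)
        weights = np.array([cfg.composition[s] for s in background], float)
    else:
        weights = cfg.background_decay ** np.arange(len(background))
    if not background:
        raise ConfigError("no background subtypes available")
    weights = weights / weights.sum()

    subtypes = rng.choice(np.array(background), size=n, p=weights)
    hom_mask = np.zeros(n, dtype=bool)
    for h in cfg.homogeneous_regions:
        for i in range(h.start, h.start + h.length):
            if rng.random() < h.purity:
                subtypes[i] = h.subtype_id
            hom_mask[i] = True

    # plant unique landmark trigrams in the background
    planted: list[tuple[int, tuple]] = []
    if cfg.planted_landmarks:
        free = np.flatnonzero(~hom_mask)
        # the whole trigram must stay in background, off the array edges
        free = free[(free >= 1) & (free < n - 3)]
        free = np.array([p for p in free if not hom_mask[p:p + 3].any()])
        step = max(1, len(free) // max(cfg.planted_landmarks, 1))
        positions = [int(free[min(i * step, len(free) - 1)])
                     for i in range(cfg.planted_landmarks)]
        # keep planted trigrams disjoint
        spaced = []
        for p in sorted(set(positions)):
            if not spaced or p - spaced[-1] >= 3:
                spaced.append(p)
        positions = spaced
        for p in positions:
            for _attempt in range(200):
                tri = tuple(int(s) for s in
                            rng.choice(np.array(background), size=3, p=weights))
                subtypes[p:p + 3] = tri
                occ = sum(
                    1 for i in range(n - 2)
                    if tuple(subtypes[i:i + 3]) == tri
                )
                if occ == 1:
                    planted.append((p, tri))
                    break
            else:  # pragma: no cover
                raise ConfigError("could not plant a unique landmark trigram")

    subtype_seq = {s: _subtype_sequence(catalog, model, s)
                   for s in sorted(set(int(s) for s in subtypes))}

    # structural anomalies
    anomalies: list[tuple[int, str, tuple[int, int]]] = []
    unit_seqs = [subtype_seq[int(s)] for s in subtypes]
    n_anom = sum(cfg.anomalies.values())
    if n_anom:
        pool = [i for i in range(n) if not hom_mask[i]]
        chosen = rng.choice(np.array(pool), size=n_anom, replace=False)
        idx = 0
        for kind, count in sorted(cfg.anomalies.items()):
            for _ in range(count):
                u = int(chosen[idx])
                idx += 1
                unit_seqs[u], interval = _apply_anomaly(
                    unit_seqs[u], kind, model, rng)
                anomalies.append((u, kind, interval))

    intervals = []
    pos = 0
    for s in unit_seqs:
        intervals.append((pos, pos + len(s)))
        pos += len(s)
    tokens = tuple(int(s) for s in subtypes)
    truth = GroundTruth(
        tokens=tokens,
        dna="".join(unit_seqs),
        unit_intervals=tuple(intervals),
        unit_subtypes=tokens,
        anomalies=tuple(anomalies),
        planted_landmarks=tuple(planted),
        expressed_block=cfg.expression.block,
        silenced_subtypes=cfg.silencing.silenced_subtypes,
    )
    return truth.dna, truth


def _apply_anomaly(unit_seq: str, kind: str, model: ReferenceGeneModel, rng):
    if kind.endswith("_deletion"):
        rid = {"18S_deletion": "18S", "25S_deletion": "25S",
               "promoter_deletion": "PROM"}[kind]
        region = model.region(rid)
        lo = region.start
        if rid == "25S":  # keep the anchor and I-PpoI site intact
            lo = max(lo, model.anchor_start + model.anchor_length + 50)
        span = region.end - lo
        size = int(rng.integers(max(500, span // 4), max(501, span - 50)))
        size = min(size, span - 20)
        start = lo + int(rng.integers(0, span - size))
        return unit_seq[:start] + unit_seq[start + size:], (start, start + size)
    if kind == "insertion":
        region = model.region("IGS_SAL")
        start = region.start + int(rng.integers(0, region.length))
        size = int(rng.integers(2000, 4000))
        ins = _random_dna(rng, size)
        return unit_seq[:start] + ins + unit_seq[start:], (start, start + size)
    raise ConfigError(f"unknown anomaly kind {kind!r}")


# ---------------------------------------------------------------------------
# reads


def _apply_errors(seq: str, rng, p_sub: float, p_ins: float, p_del: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = arr.size
    r = rng.random(n)
    del_mask = r < p_del
    sub_mask = (r >= p_del) & (r < p_del + p_sub)
    ins_mask = (r >= p_del + p_sub) & (r < p_del + p_sub + p_ins)
    counts = np.ones(n, dtype=np.int64)
    counts[del_mask] = 0
    counts[ins_mask] = 2
    starts = np.cumsum(counts) - counts
    out = np.empty(int(counts.sum()), dtype=np.uint8)
    keep = ~del_mask
    out[starts[keep]] = arr[keep]
    n_sub = int(sub_mask.sum())
    if n_sub:
        idx = _CODE[arr[sub_mask]]
        out[starts[sub_mask]] = _BASES[(idx + rng.integers(1, 4, n_sub)) % 4]
    n_ins = int(ins_mask.sum())
    if n_ins:
        out[starts[ins_mask] + 1] = _BASES[rng.integers(0, 4, n_ins)]
    return out.tobytes().decode()


def simulate_reads(dna: str, cfg: SimConfig,
                   seed: int | None = None) -> tuple[list[tuple[str, str]], dict]:
    """Sample ultralong reads from the array until coverage is reached.

    Start positions are uniform (reads may be clipped at either array
    end), lengths log-normal truncated to [min, max], strands uniform,
    and per-base substitution/insertion/deletion errors independent.
    Returns ``(reads, report)`` where reads are (read_id, sequence) pairs
    and the report records realized coverage and per-read ground truth.
    """
    rm = cfg.read_model
    rate = rm.error_rate
    for frac in (rm.sub_fraction, rm.ins_fraction, rm.del_fraction):
        if not 0 <= frac * rate < 1:
            raise ConfigError("error rates must lie in [0, 1)")
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 0x51)
    L = len(dna)
    target = rm.coverage * L
    mu = np.log(rm.mean_length) - rm.sigma_log ** 2 / 2
    reads: list[tuple[str, str]] = []
    read_truth: dict[str, tuple[int, int, str]] = {}
    total = 0
    i = 0
    while total < target:
        length = int(np.clip(rng.lognormal(mu, rm.sigma_log),
                             rm.min_length, rm.max_length))
        start = int(rng.integers(-length + 1, L))
        s, e = max(0, start), min(L, start + length)
        strand = "+" if rng.random() < 0.5 else "-"
        if e - s < 200:
            continue
        sub = dna[s:e]
        if strand == "-":
            sub = revcomp(sub)
        mutated = _apply_errors(sub, rng, rm.sub_fraction * rate,
                                rm.ins_fraction * rate, rm.del_fraction * rate)
        rid = f"sim{i:06d}"
        reads.append((rid, mutated))
        read_truth[rid] = (s, e, strand)
        total += e - s
        i += 1
    report = {
        "n_reads": len(reads),
        "target_coverage": rm.coverage,
        "realized_coverage": total / L,
        "reads": read_truth,
    }
    return reads, report


# ---------------------------------------------------------------------------
# observables (sorted fractions, RNA, methylation)


def _token_read(read_id: str, catalog: VleCatalog, subtype_id: int,
                unit_length: int) -> TokenRead:
    perm = catalog.subtype_permutation(subtype_id)
    calls = tuple(VleCall(r, v, 0) for r, v in zip(catalog.region_ids, perm))
    unit = GeneUnitToken(calls=calls, subtype_id=subtype_id, partial=False,
                         strand="+", interval=(0, unit_length))
    return TokenRead(read_id=read_id, units=(unit,), source_length=unit_length)


def _snv_sites(truth: GroundTruth, catalog: VleCatalog,
               model: ReferenceGeneModel) -> dict[int, dict]:
    """Point mismatches of each subtype's unit vs the reference.

    Only short mismatch runs (<= 3 bp) count as SNVs; longer runs come
    from motif-copy-number length differences and are not point alleles.
    """
    ref = model.ref_sequence
    sites: dict[tuple[int, str, str], set[int]] = {}
    for subtype in sorted(set(truth.unit_subtypes)):
        unit = _subtype_sequence(catalog, model, subtype)
        _d, ops = global_alignment(unit, ref)
        qp = tp = 0
        for n, op in ops:
            if op in "=M":
                qp += n
                tp += n
            elif op == "X":
                if n <= 3:
                    for j in range(n):
                        key = (tp + j, ref[tp + j], unit[qp + j])
                        sites.setdefault(key, set()).add(subtype)
                qp += n
                tp += n
            elif op == "D":
                tp += n
            else:
                qp += n
    out: dict[int, dict] = {}
    for (pos, rb, ab), subs in sorted(sites.items()):
        if pos in out:  # one alt allele per position keeps tables minimal
            continue
        out[pos] = {"ref": rb, "alt": ab, "subtypes": frozenset(subs)}
    return out


def simulate_observables(truth: GroundTruth, cfg: SimConfig,
                         seed: int | None = None,
                         catalog: VleCatalog | None = None,
                         model: ReferenceGeneModel | None = None) -> Observables:
    """Emit sorted-fraction token sets, DNA/RNA variant tables, methylation.

    Nuclei token reads sample units uniformly; nucleolus reads retain
    silenced subtypes with probability 1/depletion.  RNA allele
    frequencies are per-copy-rate x (carriers inside the expressed
    block), so :func:`norvle.variants.normalize_expression` recovers the
    block.  Methylation sites are real cytosines of the array with
    context-specific means, hypomethylated inside the expressed block.
    """
    if catalog is None:
        catalog = simulate_catalog(cfg)
    if model is None:
        model = simulate_gene_model(cfg)
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 0x0B)
    n = truth.n_units
    unit_len = {s: len(_subtype_sequence(catalog, model, s))
                for s in sorted(set(truth.unit_subtypes))}
    silenced = set(cfg.silencing.silenced_subtypes)
    depletion = cfg.silencing.depletion

    def sample_fraction(name: str, depleted: bool) -> list[TokenRead]:
        out: list[TokenRead] = []
        while len(out) < cfg.silencing.reads_per_fraction:
            u = int(rng.integers(0, n))
            s = truth.unit_subtypes[u]
            if depleted and s in silenced and rng.random() > 1.0 / depletion:
                continue
            out.append(_token_read(f"{name}{len(out):05d}", catalog, s,
                                   unit_len[s]))
        return out

    nucleolus = sample_fraction("no", depleted=True)
    nuclei = sample_fraction("nu", depleted=False)

    sites = _snv_sites(truth, catalog, model)
    b0, b1 = truth.expressed_block
    block = truth.unit_subtypes[b0:b1]
    dna_rows, rna_rows = [], []
    site_carriers: dict[int, tuple[int, ...]] = {}
    for pos, info in sites.items():
        carriers = tuple(i for i, s in enumerate(truth.unit_subtypes)
                         if s in info["subtypes"])
        if not carriers:
            continue
        site_carriers[pos + 1] = carriers
        dna_rows.append({
            "pos": pos + 1, "ref": info["ref"], "alt": info["alt"],
            "frequency": len(carriers) / n,
        })
        in_block = sum(1 for s in block if s in info["subtypes"])
        if in_block:
            rna_rows.append({
                "pos": pos + 1, "ref": info["ref"], "alt": info["alt"],
                "frequency": cfg.expression.per_copy_frequency * in_block,
            })
    dna_sites = pd.DataFrame(dna_rows, columns=["pos", "ref", "alt", "frequency"])
    rna_sites = pd.DataFrame(rna_rows, columns=["pos", "ref", "alt", "frequency"])

    meth = _simulate_methylation(truth, cfg, rng)
    return Observables(nucleolus_tokens=nucleolus, nuclei_tokens=nuclei,
                       dna_sites=dna_sites, rna_sites=rna_sites,
                       methylation=meth, site_carriers=site_carriers)


def _simulate_methylation(truth: GroundTruth, cfg: SimConfig, rng) -> pd.DataFrame:
    ms = cfg.methylation
    dna = np.frombuffer(truth.dna.encode(), dtype=np.uint8)
    c_pos = np.flatnonzero(dna[:-2] == ord("C"))
    if ms.site_fraction < 1.0:
        keep = rng.random(c_pos.size) < ms.site_fraction
        c_pos = c_pos[keep]
    nxt1 = dna[c_pos + 1]
    nxt2 = dna[c_pos + 2]
    context = np.where(nxt1 == ord("G"), "CG",
                       np.where(nxt2 == ord("G"), "CHG", "CHH"))
    b0, b1 = truth.expressed_block
    lo = truth.unit_intervals[b0][0]
    hi = truth.unit_intervals[b1 - 1][1]
    inside = (c_pos >= lo) & (c_pos < hi)
    means = np.empty(c_pos.size)
    for ctx, (out_mean, in_mean) in ms.context_means.items():
        mask = context == ctx
        means[mask] = np.where(inside[mask], in_mean, out_mean)
    frac = np.clip(means + rng.normal(0, ms.sd, c_pos.size), 0, 1)
    cov = rng.poisson(ms.coverage_mean, c_pos.size)
    meth_count = rng.binomial(np.maximum(cov, 0), frac)
    return pd.DataFrame({
        "position": c_pos + 1,
        "strand": "+",
        "context": context,
        "methylated_count": meth_count,
        "total_count": cov,
    })


def simulate_token_reads(truth: GroundTruth, catalog: VleCatalog,
                         cfg: SimConfig, seed: int | None = None,
                         miscall_rate: float = 0.01,
                         mean_unit_length: int = 8500) -> list[TokenRead]:
    """Sample reads directly at the token level (no DNA round trip).

    Uses the configured read-length model translated into gene units;
    each unit's subtype is miscalled (replaced by a random registered
    subtype) at ``miscall_rate``, emulating tokenization errors without
    paying for base-level simulation.  Useful for statistics that only
    need token strings, e.g. read-vs-assembly pattern concordance at
    full locus scale.
    """
    rm = cfg.read_model
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 0x7E)
    n = truth.n_units
    target_units = rm.coverage * n
    mu = np.log(rm.mean_length) - rm.sigma_log ** 2 / 2
    subtype_ids = np.array(sorted(catalog.subtype_registry.values()))
    reads: list[TokenRead] = []
    total = 0
    i = 0
    while total < target_units:
        length_bp = float(np.clip(rng.lognormal(mu, rm.sigma_log),
                                  rm.min_length, rm.max_length))
        n_units = max(1, int(round(length_bp / mean_unit_length)))
        start = int(rng.integers(-n_units + 1, n))
        s, e = max(0, start), min(n, start + n_units)
        if e - s < 1:
            continue
        tokens = list(truth.tokens[s:e])
        miscalls = rng.random(len(tokens)) < miscall_rate
        for j in np.flatnonzero(miscalls):
            tokens[j] = int(rng.choice(subtype_ids))
        reads.append(_token_window(f"tok{i:06d}", tokens, catalog))
        total += e - s
        i += 1
    return reads


def _token_window(read_id: str, tokens: list[int],
                  catalog: VleCatalog) -> TokenRead:
    units = []
    for j, t in enumerate(tokens):
        perm = catalog.subtype_permutation(t)
        calls = tuple(VleCall(r, v, 0)
                      for r, v in zip(catalog.region_ids, perm))
        units.append(GeneUnitToken(calls=calls, subtype_id=t, partial=False,
                                   strand="+",
                                   interval=(j * 10, (j + 1) * 10)))
    return TokenRead(read_id=read_id, units=tuple(units),
                     source_length=10 * len(tokens))


def simulate_locus(cfg: SimConfig):
    """Convenience: (model, catalog, dna, truth, reads, report) in one call."""
    model, catalog = _blueprint(cfg)
    dna, truth = simulate_array(catalog, cfg)
    reads, report = simulate_reads(dna, cfg)
    return model, catalog, dna, truth, reads, report
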