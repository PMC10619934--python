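"""Landmark discovery, mapping, consensus, joining and validation."""

import numpy as np
import pytest

from norvle import (
    SimConfig,
    build_landmark_map,
    estimate_coverage,
    filter_nor_reads,
    find_landmarks,
    join_contigs,
    simulate_array,
    simulate_catalog,
    tagged_consensus,
    validate_assembly,
)
from norvle._align import edit_distance, revcomp
from norvle.assembly import (
    ArrayAssembly,
    Landmark,
    UnitAnnotation,
    build_landmark_maps,
    count_patterns,
)
from norvle.errors import (
    AmbiguousAdjacencyError,
    NoJoinError,
    ParameterError,
)
from norvle.model import GeneUnitToken, TokenRead, VleCall


def _token_read(read_id, tokens, catalog):
    units = []
    for i, t in enumerate(tokens):
        perm = catalog.subtype_permutation(t)
        calls = tuple(VleCall(r, v, 0)
                      for r, v in zip(catalog.region_ids, perm))
        units.append(GeneUnitToken(calls=calls, subtype_id=t, partial=False,
                                   strand="+", interval=(i * 10, (i + 1) * 10)))
    return TokenRead(read_id, tuple(units), 10 * len(tokens))


# ---------------------------------------------------------------------------
# read filtering


def test_filter_drops_short_reads_and_keeps_ultralong(locus):
    model, _c, dna, _t, _r, _rep = locus
    short = ("short", dna[:50_000])
    ultralong = ("ultra", (dna * 2)[:280_000])
    out = filter_nor_reads([short, ultralong], model)
    assert [rid for rid, _ in out] == ["ultra"]


def test_filter_rejects_reads_without_anchor(locus):
    model = locus[0]
    rng = np.random.default_rng(0)
    foreign = "".join("ACGT"[b] for b in rng.integers(0, 4, 100_000))
    assert filter_nor_reads([("bg", foreign)], model) == []


def test_filter_splits_at_foreign_insert_and_length_filters(locus):
    model, _c, dna, _t, _r, _rep = locus
    rng = np.random.default_rng(1)
    insert = "".join("ACGT"[b] for b in rng.integers(0, 4, 20_000))
    read = dna[:60_000] + insert + dna[60_000:120_000]
    out = filter_nor_reads([("chimera", read)], model,
                           min_len=50_000, keep_whole_above=275_000)
    assert len(out) == 2
    (id1, piece1), (id2, piece2) = out
    assert id1 == "chimera/1" and id2 == "chimera/2"
    assert abs(len(piece1) - 60_000) < 100
    assert abs(len(piece2) - 60_000) < 100
    # at the published defaults both ~60 kbp pieces fall below 85 kbp
    assert filter_nor_reads([("chimera", read)], model) == []


# ---------------------------------------------------------------------------
# landmark discovery


def test_copy_estimate_arithmetic(catalog):
    reads = [_token_read(f"r{i}", (1, 2, 3, 4), catalog) for i in range(30)] \
        + [_token_read(f"d{i}", (5, 6, 5, 6), catalog) for i in range(30)]
    counts = {pc.pattern: pc for pc in count_patterns(reads, 2, coverage=30)}
    assert counts[(1, 2)].copy_estimate == pytest.approx(1.0)
    assert counts[(5, 6)].copy_estimate == pytest.approx(2.0)
    landmarks = find_landmarks(reads, coverage=30, k_min=2, k_max=3)
    patterns = {lm.pattern for lm in landmarks}
    assert (1, 2) in patterns          # single copy: selected
    assert (5, 6) not in patterns      # two copies: rejected
    with pytest.raises(ParameterError):
        find_landmarks(reads, coverage=0)


def test_planted_landmark_trigrams_recovered(token_reads, truth, small_cfg):
    coverage = estimate_coverage(token_reads, small_cfg.n_units)
    landmarks = find_landmarks(token_reads, coverage=coverage)
    selected = set()
    for lm in landmarks:
        for off in range(len(lm.pattern) - 2):
            selected.add(lm.pattern[off:off + 3])
        for i in range(len(lm.pattern) - 1):
            selected.add(lm.pattern[i:i + 2])
    # every planted unique trigram is covered by some selected landmark
    for _pos, tri in truth.planted_landmarks:
        assert tri in selected or any(
            tri[j:j + 2] in {lm.pattern for lm in landmarks} for j in (0, 1))


def test_no_false_unique_landmarks(token_reads, truth, small_cfg):
    coverage = estimate_coverage(token_reads, small_cfg.n_units)
    for lm in find_landmarks(token_reads, coverage=coverage):
        k = len(lm.pattern)
        occurrences = sum(
            1 for i in range(truth.n_units - k + 1)
            if truth.tokens[i:i + k] == lm.pattern)
        assert occurrences == 1, lm.pattern


def test_landmark_supporting_reads_contain_pattern(token_reads, landmark_map):
    by_id = {tr.read_id: tr.tokens for tr in token_reads}
    for lm in landmark_map.landmarks:
        assert lm.supporting_reads
        for rid, off in lm.supporting_reads:
            toks = by_id[rid]
            assert toks[off:off + lm.k] == lm.pattern


# ---------------------------------------------------------------------------
# landmark map


def test_unanimous_gap_votes(catalog):
    reads = [_token_read(f"r{i}", (1, 2, 9, 9, 9, 9, 9, 3, 4), catalog)
             for i in range(40)]
    landmarks = [Landmark((1, 2), ()), Landmark((3, 4), ())]
    lmap = build_landmark_map(reads, landmarks)
    assert lmap.positions == [0, 7]
    assert lmap.gaps == [7]


def test_map_recovers_true_order_and_gaps(landmark_map, truth):
    positions = []
    for lm, pos in zip(landmark_map.landmarks, landmark_map.positions):
        k = len(lm.pattern)
        true_pos = [i for i in range(truth.n_units - k + 1)
                    if truth.tokens[i:i + k] == lm.pattern]
        assert len(true_pos) == 1
        positions.append((pos, true_pos[0]))
    offsets = {true - mapped for mapped, true in positions}
    assert len(offsets) == 1  # one rigid shift: order and gaps all exact


def test_equal_support_branching_raises_ambiguity(catalog):
    reads = [_token_read(f"a{i}", (1, 2, 9, 3, 4), catalog) for i in range(10)] \
        + [_token_read(f"b{i}", (1, 2, 9, 5, 6), catalog) for i in range(10)]
    landmarks = [Landmark((1, 2), ()), Landmark((3, 4), ()),
                 Landmark((5, 6), ())]
    with pytest.raises(AmbiguousAdjacencyError) as exc:
        build_landmark_maps(reads, landmarks)
    assert exc.value.landmark_pattern == (1, 2)


# ---------------------------------------------------------------------------
# consensus

def test_error_free_consensus_reproduces_truth_exactly():
    cfg = SimConfig.small(seed=13)
    cfg = SimConfig.from_dict({
        **cfg.to_dict(),
        "read_model": {**cfg.to_dict()["read_model"],
                       "error_rate": 0.0, "coverage": 20.0}})
    from norvle import simulate_locus, tokenize_reads
    model, catalog, dna, truth, reads, _rep = simulate_locus(cfg)
    trs = tokenize_reads(reads, catalog, model)
    lmap = build_landmark_map(
        trs, find_landmarks(trs, coverage=estimate_coverage(trs, cfg.n_units)))
    asm = tagged_consensus(reads, trs, lmap, model, catalog, rounds=1)
    assert asm.subtype_sequence == truth.tokens
    assert asm.sequence == dna


def test_noisy_consensus_identity_and_length(locus, assembly):
    """3% read error, ~30x: identity >= 99.9%, length error <= 0.2%."""
    dna, truth = locus[2], locus[3]
    assert assembly.subtype_sequence == truth.tokens
    d = edit_distance(assembly.sequence, dna)
    assert 1 - d / len(dna) >= 0.999
    assert abs(len(assembly.sequence) - len(dna)) / len(dna) <= 0.002
    assert all(u.depth >= 1 for u in assembly.units)


# ---------------------------------------------------------------------------
# joining


def _mini_assembly(tokens, unit_len=100):
    seq = ""
    units = []
    rng = np.random.default_rng(0)
    for i, t in enumerate(tokens):
        u = "".join("ACGT"[b] for b in rng.integers(0, 4, unit_len))
        units.append(UnitAnnotation(index=i, token=t, subtype_id=t,
                                    interval=(i * unit_len, (i + 1) * unit_len),
                                    depth=5))
        seq += u
    return ArrayAssembly(sequence=seq, units=units)


def test_join_inserts_missing_copies_of_shared_subtype():
    left = _mini_assembly([1, 2, 6, 6, 6] + [6] * 25)
    right = _mini_assembly([6] * 25 + [3, 4])
    placed = (left.token_sequence + right.token_sequence).count(6)
    assert placed == 53
    merged = join_contigs([left, right], [], {6: 60})
    inserted = sum(j.n_inserted for j in merged.joins)
    # conservation: placed + inserted = round(copy estimate)
    assert inserted == 60 - placed
    assert merged.token_sequence.count(6) == 60
    assert sum(1 for u in merged.units if u.is_join) == inserted


def test_join_inserts_nothing_when_estimate_matches():
    left = _mini_assembly([1, 6, 6])
    right = _mini_assembly([6, 6, 2])
    merged = join_contigs([left, right], [], {6: 4})
    assert sum(j.n_inserted for j in merged.joins) == 0
    assert merged.token_sequence == (1, 6, 6, 6, 6, 2)


def test_join_refuses_mismatched_subtypes():
    left = _mini_assembly([1, 6])
    right = _mini_assembly([32, 2])
    with pytest.raises(NoJoinError):
        join_contigs([left, right], [], {6: 4, 32: 4})


# ---------------------------------------------------------------------------
# validation


def test_self_validation_is_perfect(catalog):
    # error-free reads spanning the whole array witness every pattern in
    # exact proportion to its assembly count
    truth_tokens = tuple([1, 2, 3, 4, 5, 6, 7, 8, 9, 10] * 2)
    asm = _mini_assembly(truth_tokens)
    reads = [_token_read(f"r{i}", truth_tokens, catalog) for i in range(10)]
    _table, r2 = validate_assembly(reads, asm, k=3)
    assert r2 == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
def test_full_scale_read_vs_assembly_concordance(seed):
    """At full locus scale (894 units) the read/assembly VLE pattern
    frequencies agree with R^2 >= 0.98, as for the real NOR read sets."""
    from norvle.simulate import simulate_token_reads

    cfg = SimConfig.paper_like(seed=seed)
    catalog = simulate_catalog(cfg)
    _dna, truth = simulate_array(catalog, cfg)
    reads = simulate_token_reads(truth, catalog, cfg)
    units = [UnitAnnotation(index=i, token=t, subtype_id=t,
                            interval=(i * 10, (i + 1) * 10), depth=1)
             for i, t in enumerate(truth.tokens)]
    asm = ArrayAssembly(sequence="A" * (10 * truth.n_units), units=units)
    _table, r2 = validate_assembly(reads, asm, k=3)
    assert r2 >= 0.98


def test_deleted_units_show_largest_positive_residual(token_reads, assembly,
                                                      truth):
    # delete all units of the modal subtype from the assembly
    from collections import Counter
    modal = Counter(truth.tokens).most_common(1)[0][0]
    kept = [u for u in assembly.units if u.token != modal]
    seq = "".join(assembly.sequence[a:b] for a, b in
                  (u.interval for u in kept))
    pos = 0
    reindexed = []
    for i, u in enumerate(kept):
        ln = u.interval[1] - u.interval[0]
        reindexed.append(UnitAnnotation(index=i, token=u.token,
                                        subtype_id=u.subtype_id,
                                        interval=(pos, pos + ln),
                                        depth=u.depth))
        pos += ln
    damaged = ArrayAssembly(sequence=seq, units=reindexed)
    table, r2_damaged = validate_assembly(token_reads, damaged, k=1)
    _t2, r2_true = validate_assembly(token_reads, assembly, k=1)
    assert table.iloc[0]["pattern"] == str(modal)
    assert table.iloc[0]["residual"] > 0
    assert r2_damaged < r2_true
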