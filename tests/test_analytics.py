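"""Array analytics: counting, composition, homogeneity, dot plots, guides."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from norvle import (
    count_and_measure_units,
    design_discriminating_guides,
    homogeneity_track,
    predict_cas9_fragments,
    structural_anomaly_scan,
    subtype_composition,
    vle_similarity_matrix,
)
from norvle._align import revcomp
from norvle.errors import ParameterError
from norvle.model import VleVariant


# ---------------------------------------------------------------------------
# counting and unit lengths


def test_count_and_lengths_on_true_array(locus):
    model, _c, dna, truth, _r, _rep = locus
    count, lengths = count_and_measure_units(dna, model)
    assert count == truth.n_units
    true_lengths = [b - a for (a, _), (b, _2) in
                    zip(truth.unit_intervals, truth.unit_intervals[1:])]
    assert lengths == true_lengths


def test_count_is_strand_agnostic(locus):
    model, _c, dna, truth, _r, _rep = locus
    count, _ = count_and_measure_units(revcomp(dna), model)
    assert count == truth.n_units


# ---------------------------------------------------------------------------
# composition


def test_composition_fractions_and_order():
    tokens = [1] * 100 + [2] * 60 + [3] * 40
    table = subtype_composition(tokens)
    assert list(table["subtype"]) == [1, 2, 3]
    assert list(table["fraction"]) == [0.5, 0.3, 0.2]
    assert table["count"].sum() == 200
    assert table["fraction"].sum() == pytest.approx(1.0, abs=1e-9)


def test_composition_single_subtype():
    table = subtype_composition([7] * 25)
    assert len(table) == 1
    assert table.iloc[0]["fraction"] == 1.0


def test_composition_invariant_under_reversal(truth):
    fwd = subtype_composition(list(truth.tokens))
    rev = subtype_composition(list(reversed(truth.tokens)))
    assert fwd.set_index("subtype")["count"].to_dict() == \
        rev.set_index("subtype")["count"].to_dict()


# ---------------------------------------------------------------------------
# homogeneity


@pytest.mark.parametrize("subtypes,expected", [
    ("AAAAAAAAA", (9,)),
    ("ABCDEFGHI", (1,)),
    ("AABABABAA", (6,)),
])
def test_homogeneity_examples(subtypes, expected):
    assert homogeneity_track(tuple(subtypes), window=9).scores == expected


def test_homogeneity_window_guardrails():
    with pytest.raises(ParameterError):
        homogeneity_track((1, 2, 3), window=9)
    with pytest.raises(ParameterError):
        homogeneity_track((1, 2, 3), window=0)


def test_homogeneity_center_mode_counts_matches_to_center():
    track = homogeneity_track(tuple("ABABA"), window=5, mode="center")
    assert track.scores == (3,)  # center 'A' matches positions 0, 2, 4


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 5), min_size=9, max_size=40),
       st.integers(1, 9))
def test_homogeneity_matches_bruteforce_modal_count(subtypes, window):
    track = homogeneity_track(tuple(subtypes), window=window)
    for i, score in enumerate(track.scores):
        win = subtypes[i:i + window]
        assert score == max(Counter(win).values())


# ---------------------------------------------------------------------------
# similarity matrix


def test_self_similarity_contains_full_diagonal(truth):
    m = vle_similarity_matrix(truth.tokens, truth.tokens, window=3)
    assert all((i, i) in m.pairs for i in range(m.shape[0]))


def test_similarity_enumeration_example():
    a = tuple("XYZXYZ")
    b = tuple("XYZ")
    m = vle_similarity_matrix(a, b, window=3)
    assert m.pairs == frozenset({(0, 0), (3, 0)})


def test_similarity_disjoint_alphabets_is_empty():
    m = vle_similarity_matrix(tuple("AAAA"), tuple("BBBB"), window=3)
    assert m.pairs == frozenset()


def test_similarity_transpose_symmetry(truth):
    a = truth.tokens[:30]
    b = truth.tokens[10:]
    ab = vle_similarity_matrix(a, b, window=3)
    ba = vle_similarity_matrix(b, a, window=3)
    assert ab.transpose().pairs == ba.pairs
    assert ab.shape == ba.shape[::-1]


# ---------------------------------------------------------------------------
# structural anomalies


def test_reference_unit_has_no_anomalies(model):
    assert structural_anomaly_scan(model.ref_sequence, model) == []


def test_planted_deletion_and_insertion_detected(model):
    ref = model.ref_sequence
    r18 = model.region("18S")
    deleted = ref[:r18.start + 100] + ref[r18.start + 2100:]
    calls = structural_anomaly_scan(deleted, model)
    assert len(calls) == 1
    assert calls[0].kind == "18S_deletion"
    assert calls[0].size == 2000

    sal = model.region("IGS_SAL")
    rng = np.random.default_rng(5)
    ins = "".join("ACGT"[b] for b in rng.integers(0, 4, 4000))
    mid = (sal.start + sal.end) // 2
    inserted = ref[:mid] + ins + ref[mid:]
    calls = structural_anomaly_scan(inserted, model)
    assert len(calls) == 1
    assert calls[0].kind == "insertion"
    assert calls[0].size == pytest.approx(4000, abs=50)


# ---------------------------------------------------------------------------
# guide design and Cas9 fragments


def test_identical_variants_have_no_discriminating_guide():
    seq = "ACGTAC" * 20
    variants = [VleVariant("R", "v1", seq), VleVariant("R", "v2", seq)]
    assert len(design_discriminating_guides(variants)) == 0


def test_guides_inside_an_insertion_discriminate():
    rng = np.random.default_rng(6)
    base = "".join("ACGT"[b] for b in rng.integers(0, 4, 400))
    ins = "".join("ACGT"[b] for b in rng.integers(0, 4, 300))
    v1 = VleVariant("R", "v1", base)
    v2 = VleVariant("R", "v2", base[:200] + ins + base[200:])
    guides = design_discriminating_guides([v1, v2])
    assert len(guides) > 0
    only_v2 = guides[guides["hit_variants"] == "v2"]
    assert len(only_v2) > 0
    # exhaustive check of the hit/miss annotation for every guide
    for _, row in guides.iterrows():
        proto = row["protospacer"]
        for v in (v1, v2):
            present = _pam_adjacent(v.sequence, proto)
            if v.variant_id in row["hit_variants"].split(","):
                assert present
            else:
                assert not present


def _pam_adjacent(seq, proto):
    for s in (seq, revcomp(seq)):
        start = 0
        while True:
            i = s.find(proto, start)
            if i < 0:
                break
            if s[i + 21:i + 23] == "GG":
                return True
            start = i + 1
    return False


def test_cas9_no_match_returns_whole_assembly():
    seq = "AT" * 5000
    assert predict_cas9_fragments(seq, ["G" * 20]) == [len(seq)]


def test_cas9_single_cut_arithmetic():
    rng = np.random.default_rng(7)
    seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 10_000))
    target = seq[4000:4020]
    site = seq[4000:4023]
    if site[21:23] != "GG":
        seq = seq[:4021] + "GG" + seq[4023:]
        target = seq[4000:4020]
    frags = predict_cas9_fragments(seq, [target])
    # blunt cut 3 bp 5' of the PAM: position 4017
    assert sorted(frags) == sorted([4017, len(seq) - 4017])


def test_cas9_fragment_lengths_sum_to_assembly_length(locus):
    model, catalog, dna, _t, _r, _rep = locus
    variants = catalog.variants_for("ETS3_R")
    guides = design_discriminating_guides(variants)
    protos = list(guides["protospacer"].head(10))
    frags = predict_cas9_fragments(dna, protos)
    assert sum(frags) == len(dna)
    assert len(frags) > 1


def test_cas9_periodic_target_gives_unit_scale_fragments(model, catalog):
    from norvle.simulate import _subtype_sequence
    # array alternating: target-bearing subtype every 3rd unit
    unit_a = _subtype_sequence(catalog, model, 3)
    unit_b = _subtype_sequence(catalog, model, 4)
    rng = np.random.default_rng(8)
    proto = "".join("ACGT"[b] for b in rng.integers(0, 4, 20))
    site = proto + "TGG"
    sal = model.region("IGS_SAL")
    unit_target = unit_a[:sal.start] + site + unit_a[sal.start:]
    array = (unit_target + unit_b + unit_b) * 6
    frags = predict_cas9_fragments(array, [proto])
    period = len(unit_target) + 2 * len(unit_b)
    # 6 cuts -> 5 interior fragments of one period; the 2 edge fragments
    # together make up the remaining period
    assert sum(1 for f in frags if abs(f - period) < 5) >= 5
    assert sum(frags) == len(array)
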