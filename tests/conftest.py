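"""Shared fixtures: one small simulated locus reused across the suite."""

import pytest

from norvle import (
    SimConfig,
    estimate_coverage,
    find_landmarks,
    build_landmark_map,
    simulate_locus,
    simulate_observables,
    tagged_consensus,
    tokenize_reads,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig.small(seed=3)


@pytest.fixture(scope="session")
def locus(small_cfg):
    """(model, catalog, dna, truth, reads, report) for the small locus."""
    return simulate_locus(small_cfg)


@pytest.fixture(scope="session")
def model(locus):
    return locus[0]


@pytest.fixture(scope="session")
def catalog(locus):
    return locus[1]


@pytest.fixture(scope="session")
def truth(locus):
    return locus[3]


@pytest.fixture(scope="session")
def token_reads(locus, small_cfg):
    model, catalog, _dna, _truth, reads, _report = locus
    return tokenize_reads(reads, catalog, model)


@pytest.fixture(scope="session")
def landmark_map(token_reads, small_cfg):
    coverage = estimate_coverage(token_reads, small_cfg.n_units)
    landmarks = find_landmarks(token_reads, coverage=coverage)
    return build_landmark_map(token_reads, landmarks)


@pytest.fixture(scope="session")
def assembly(locus, token_reads, landmark_map):
    model, catalog, _dna, _truth, reads, _report = locus
    return tagged_consensus(reads, token_reads, landmark_map, model, catalog,
                            rounds=2)


@pytest.fixture(scope="session")
def observables(small_cfg, locus):
    model, catalog, _dna, truth, _reads, _report = locus
    return simulate_observables(truth, small_cfg, catalog=catalog, model=model)


def expected_vle_enrichment(truth, catalog, depletion):
    """Arithmetic oracle for nucleolar VLE enrichment.

    Nuclei sample units uniformly; the nucleolus retains silenced-subtype
    units at 1/depletion.  The expected log2 enrichment of each
    (region, variant) follows from the truth composition alone.
    """
    import numpy as np

    silenced = set(truth.silenced_subtypes)
    weights = [1.0 / depletion if s in silenced else 1.0
               for s in truth.unit_subtypes]
    perms = {s: catalog.subtype_permutation(s)
             for s in set(truth.unit_subtypes)}
    expected = {}
    for idx, region in enumerate(catalog.region_ids):
        nuc, nol = {}, {}
        for s, w in zip(truth.unit_subtypes, weights):
            v = perms[s][idx]
            nuc[v] = nuc.get(v, 0.0) + 1.0
            nol[v] = nol.get(v, 0.0) + w
        for v in nuc:
            no_f = nol[v] / sum(nol.values())
            nu_f = nuc[v] / sum(nuc.values())
            expected[(region, v)] = (float(np.log2(no_f / nu_f)),
                                     nu_f)  # (log2, nuclei fraction)
    return expected
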