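"""Coancestry estimators, relationship classification, estimator selection."""

import itertools

import numpy as np
import pytest

from vitipanel import (
    KinshipMatrix,
    SimulationConfig,
    classify_pairs,
    classify_relationship,
    inject_relatives,
    kinship_ais,
    kinship_bno,
    kinship_loiselle,
    kinship_mle,
    kinship_wais,
    select_estimator_by_interchrom_ld,
    simulate_panel,
)
from vitipanel.diversity import allele_frequencies
from vitipanel.kinship import _ibd_tables, _locus_freq_arrays

from conftest import make_snp_matrix, make_ssr_matrix


def _brute_force_ais(gm):
    """Direct double loop over alleles: the independent AIS oracle."""
    ap = gm.allele_pairs()
    n = gm.n_individuals
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            vals = []
            for l in range(gm.n_loci):
                a, b = ap[i, l]
                c, d = ap[j, l]
                if a < 0 or c < 0:
                    continue
                vals.append((int(a == c) + int(a == d)
                             + int(b == c) + int(b == d)) / 4.0)
            out[i, j] = np.mean(vals)
    return out


def test_ais_two_allele_exhaustive_table():
    # rows: AA, AB, BB as dosages 0, 0.5, 1
    gm = make_snp_matrix([[0.0], [0.5], [1.0]])
    K = kinship_ais(gm).values
    assert K[0, 0] == pytest.approx(1.0)       # AA vs AA
    assert K[1, 1] == pytest.approx(0.5)       # AB vs AB (self)
    assert K[0, 1] == pytest.approx(0.5)       # AA vs AB
    assert K[0, 2] == pytest.approx(0.0)       # AA vs BB
    assert K[1, 2] == pytest.approx(0.5)       # AB vs BB


def test_ais_brute_force_oracle(rng):
    d = rng.choice([0.0, 0.5, 1.0, np.nan], size=(10, 12), p=[0.3, 0.3, 0.3, 0.1])
    calls = rng.integers(0, 5, size=(10, 8, 2))
    from vitipanel import combine

    gm = combine(make_snp_matrix(d), make_ssr_matrix(calls))
    np.testing.assert_allclose(kinship_ais(gm).values, _brute_force_ais(gm),
                               atol=1e-12)


def test_ais_self_identity(small_panel):
    """AIS(i, i) = 1 - Ho(i)/2 exactly."""
    _, gm, _, _ = small_panel
    K = kinship_ais(gm).values
    ap = gm.allele_pairs()
    for i in range(0, gm.n_individuals, 7):
        ok = ap[i, :, 0] >= 0
        ho = np.mean(ap[i, ok, 0] != ap[i, ok, 1])
        assert K[i, i] == pytest.approx(1.0 - ho / 2.0, abs=1e-12)


def test_symmetry_and_locus_order_invariance(rng):
    d = rng.choice([0.0, 0.5, 1.0], size=(12, 20))
    subs = ["A"] * 6 + ["B"] * 6
    gm = make_snp_matrix(d, subgroups=subs)
    perm = rng.permutation(20)
    gm_perm = make_snp_matrix(d[:, perm], subgroups=subs)
    for est in (kinship_ais, kinship_wais, kinship_bno, kinship_loiselle):
        K1 = est(gm).values
        K2 = est(gm_perm).values
        np.testing.assert_allclose(K1, K1.T, atol=1e-12)
        np.testing.assert_allclose(K1, K2, atol=1e-12)


def test_wais_cross_group_centering(small_panel):
    """Mean corrected value over cross-group pairs is 0 by construction."""
    _, gm, _, _ = small_panel
    KW = kinship_wais(gm)
    assert KW.estimator == "WAIS4"
    from vitipanel import group_indices

    gidx = group_indices(gm)
    cross = np.concatenate([
        KW.values[np.ix_(gidx[g1], gidx[g2])].ravel()
        for g1, g2 in itertools.combinations(sorted(gidx), 2)
    ])
    assert abs(cross.mean()) < 1e-10


def test_bno_centering_and_hand_computed_value(rng):
    d = rng.choice([0.0, 0.5, 1.0], size=(20, 30))
    subs = ["A"] * 10 + ["B"] * 10
    gm = make_snp_matrix(d, subgroups=subs)
    KB = kinship_bno(gm).values
    cross = KB[np.ix_(range(10), range(10, 20))]
    assert abs(cross.mean()) < 1e-10
    # hand-computed (AIS - s)/(1 - s) from the raw AIS matrix
    KA = kinship_ais(gm).values
    ais_cross = KA[np.ix_(range(10), range(10, 20))]
    s = ais_cross.mean()
    np.testing.assert_allclose(KB, (KA - s) / (1 - s), atol=1e-10)


def test_bno_equals_wais_single_locus(rng):
    """With one locus there is a single s_l, so the corrections collapse."""
    d = rng.choice([0.0, 0.5, 1.0], size=(16, 1))
    subs = ["A"] * 8 + ["B"] * 8
    gm = make_snp_matrix(d, subgroups=subs)
    np.testing.assert_allclose(kinship_wais(gm).values, kinship_bno(gm).values,
                               atol=1e-12)


def test_wais_twin_in_other_group_maximal_in_row():
    rng = np.random.default_rng(77)
    d = rng.choice([0.0, 0.5, 1.0], size=(20, 60))
    d[10] = d[0]  # identical twin across the group boundary
    subs = ["A"] * 10 + ["B"] * 10
    gm = make_snp_matrix(d, subgroups=subs)
    KW = kinship_wais(gm).values
    row = KW[0].copy()
    row[0] = -np.inf  # exclude self
    assert np.argmax(row) == 10
    assert KW[0, 10] < 1.0


def test_loiselle_unrelated_mean_near_zero():
    cfg = SimulationConfig(seed=13, group_sizes={"A": 60}, fst_targets={"A": 0.0},
                           regions=(), n_distributed_snps=500, n_ssr=0)
    gm, _, _ = simulate_panel(cfg)
    K = kinship_loiselle(gm).values
    off = K[np.triu_indices(60, 1)]
    assert abs(off.mean()) < 0.01


def test_loiselle_duplicate_and_relabelling(rng):
    d = rng.choice([0.0, 0.5, 1.0], size=(15, 80))
    d[7] = d[0]
    gm = make_snp_matrix(d)
    K = kinship_loiselle(gm).values
    row = K[0].copy()
    row[0] = -np.inf
    assert np.argmax(row) == 7
    assert K[0, 7] == pytest.approx(K[7, 7], rel=1e-9)
    # allele relabelling (swap ref/alt at every locus) leaves LOI unchanged
    K2 = kinship_loiselle(make_snp_matrix(1.0 - d)).values
    np.testing.assert_allclose(K, K2, atol=1e-10)


@pytest.fixture(scope="module")
def mle_panel():
    cfg = SimulationConfig(seed=17, group_sizes={"A": 40}, fst_targets={"A": 0.02},
                           regions=(), n_distributed_snps=500, n_ssr=0,
                           related_pairs={"A": {"PO": 5}})
    gm, _, truth = simulate_panel(cfg)
    gm, truth = inject_relatives(gm, truth, cfg)
    KM, ktab = kinship_mle(gm, return_k=True)
    return gm, truth, KM, ktab


def test_mle_po_recovery(mle_panel):
    gm, truth, KM, _ = mle_panel
    pos = {iid: i for i, iid in enumerate(gm.ind_ids)}
    po = [(pos[a], pos[b]) for a, b, r in truth.registry if r == "PO"]
    vals = [KM.values[i, j] for i, j in po]
    assert np.mean(vals) == pytest.approx(0.25, abs=0.05)


def test_mle_unrelated_near_zero(mle_panel):
    gm, truth, KM, _ = mle_panel
    pos = {iid: i for i, iid in enumerate(gm.ind_ids)}
    related = {i for a, b, _ in truth.registry for i in (pos[a], pos[b])}
    vals = [KM.values[i, j]
            for i in range(gm.n_individuals) for j in range(i + 1, gm.n_individuals)
            if i not in related and j not in related]
    assert np.mean(vals) < 0.05


def test_mle_likelihood_optimality(mle_panel):
    """Mixture likelihood at the EM iterate >= likelihood at the fixed
    vertices (1,0,0) and (0,1,0), up to the EM stopping tolerance."""
    gm_full, truth, _, _ = mle_panel
    gm = gm_full.subset(ind_idx=range(16))
    _, ktab = kinship_mle(gm, return_k=True, max_iter=3000, tol=1e-9)
    pos = {iid: i for i, iid in enumerate(gm.ind_ids)}
    sample = ktab
    pairs = np.array([[pos[a], pos[b]]
                      for a, b in zip(sample.ind_a, sample.ind_b)])
    plist = _locus_freq_arrays(gm, allele_frequencies(gm))
    ap = gm.allele_pairs()
    P, valid = _ibd_tables(ap[pairs[:, 0]], ap[pairs[:, 1]], plist)

    def loglik(kmat):
        mix = np.einsum("plm,pm->pl", P, np.asarray(kmat))
        mix = np.maximum(mix, 1e-300)
        return np.where(valid, np.log(mix), 0.0).sum(axis=1)

    k_fit = sample[["k0", "k1", "k2"]].to_numpy()
    ll_fit = loglik(k_fit)
    ll_u = loglik(np.tile([1.0, 0.0, 0.0], (len(pairs), 1)))
    ll_po = loglik(np.tile([0.0, 1.0, 0.0], (len(pairs), 1)))
    assert np.all(ll_fit >= ll_u - 1e-3)
    assert np.all(ll_fit >= ll_po - 1e-3)


def test_classifier_mendelian_exclusion():
    """A pair with an opposite-homozygote locus is never classified PO."""
    d = np.array([
        [0.0, 0.5, 0.5, 0.0, 1.0] * 8,
        [1.0, 0.5, 0.0, 0.0, 1.0] * 8,  # locus 1 is opposite-homozygote
        [0.5, 0.0, 1.0, 0.5, 0.5] * 8,
    ])
    gm = make_snp_matrix(d)
    call = classify_relationship(gm, "I001", "I002")
    assert call.loglik["PO"] == -np.inf
    assert call.best != "PO"


def test_classifier_recovers_injected_pairs():
    """PO/FS pairs are flagged first-degree >= 90 %, unrelated <= 10 %,
    at the study's distributed marker count."""
    fd_related, fd_unrelated = [], []
    for seed in (41, 42):
        cfg = SimulationConfig(
            seed=seed, group_sizes={"A": 120}, fst_targets={"A": 0.02},
            regions=(), n_distributed_snps=129, n_ssr=20,
            related_pairs={"A": {"PO": 15, "FS": 10}})
        gm, _, truth = simulate_panel(cfg)
        gm, truth = inject_relatives(gm, truth, cfg)
        pos = {iid: i for i, iid in enumerate(gm.ind_ids)}
        rel_idx = np.array([[pos[a], pos[b]] for a, b, _ in truth.registry])
        calls = classify_pairs(gm, rel_idx)
        fd_related += list(calls.first_degree)
        related = {i for ij in rel_idx for i in ij}
        unrel = [i for i in range(gm.n_individuals) if i not in related]
        un_idx = np.array(list(zip(unrel[:50], unrel[50:100])))
        fd_unrelated += list(classify_pairs(gm, un_idx).first_degree)
    assert np.mean(fd_related) >= 0.9
    assert np.mean(fd_unrelated) <= 0.1


def test_estimator_selection_argmin_and_tiebreak(small_panel):
    _, gm, _, _ = small_panel
    sub = gm.select_loci([l.locus_id for l in gm.loci
                          if l.locus_type == "snp"][:60])
    KA = kinship_ais(gm)
    ident = KinshipMatrix(gm.ind_ids, np.eye(gm.n_individuals), "MLE")
    tag, report = select_estimator_by_interchrom_ld(sub, [KA, ident])
    winner_mean = report.set_index("estimator").loc[tag].iloc[0]
    assert winner_mean <= report["mean_interchrom_r2_V"].min() + 1e-15
    # exact ties break by canonical tag order
    dup_a = KinshipMatrix(gm.ind_ids, np.eye(gm.n_individuals), "BNO")
    dup_b = KinshipMatrix(gm.ind_ids, np.eye(gm.n_individuals), "WAIS2")
    tag2, _ = select_estimator_by_interchrom_ld(sub, [dup_a, dup_b])
    assert tag2 == "WAIS2"


def test_estimator_selection_single_chromosome_error(rng):
    d = rng.choice([0.0, 0.5, 1.0], size=(10, 6))
    gm = make_snp_matrix(d)  # all loci on chr1
    with pytest.raises(ValueError, match="2 chromosomes"):
        select_estimator_by_interchrom_ld(gm, [kinship_ais(gm)])
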