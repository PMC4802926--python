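"""Dissimilarity, maximin subsampling, panel design, representativeness."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vitipanel import (
    SimulationConfig,
    StructureMatrix,
    assess_representativeness,
    classify_pairs,
    design_panel,
    inject_relatives,
    maximin_subsample,
    simple_matching_dissimilarity,
    simulate_panel,
)

from conftest import make_snp_matrix, make_ssr_matrix


def test_simple_matching_identical_and_opposite():
    gm = make_snp_matrix([[0.0] * 5, [0.0] * 5, [1.0] * 5])
    D = simple_matching_dissimilarity(gm).to_numpy()
    assert D[0, 1] == pytest.approx(0.0)  # identical individuals
    assert D[0, 2] == pytest.approx(1.0)  # AA vs BB everywhere
    assert np.allclose(D, D.T)
    assert np.all(np.diag(D) == 0)


def test_simple_matching_brute_force_oracle(rng):
    calls = rng.integers(0, 4, size=(5, 10, 2))
    gm = make_ssr_matrix(calls)
    D = simple_matching_dissimilarity(gm).to_numpy()
    for i, j in itertools.combinations(range(5), 2):
        shares = []
        for l in range(10):
            gi = sorted(calls[i, l])
            gj = sorted(calls[j, l])
            if gi == gj:
                shares.append(1.0)
            elif set(gi) & set(gj):
                shares.append(0.5)
            else:
                shares.append(0.0)
        assert D[i, j] == pytest.approx(1.0 - np.mean(shares))


def test_maximin_full_set_and_farthest_pair():
    pts = np.array([0.0, 1.0, 10.0])
    D = pd.DataFrame(np.abs(pts[:, None] - pts[None, :]),
                     index=["a", "b", "c"], columns=["a", "b", "c"])
    assert set(maximin_subsample(D, 3)) == {"a", "b", "c"}
    assert set(maximin_subsample(D, 2)) == {"a", "c"}  # {0, 10}


def test_maximin_beats_random_subsets(rng):
    n, m = 100, 12
    X = rng.normal(size=(n, 3))
    Dm = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
    ids = [f"c{i:03d}" for i in range(n)]
    D = pd.DataFrame(Dm, index=ids, columns=ids)
    sel = maximin_subsample(D, m)
    idx = [ids.index(s) for s in sel]
    sel_min = Dm[np.ix_(idx, idx)][np.triu_indices(m, 1)].min()
    for _ in range(1000):
        r = rng.choice(n, m, replace=False)
        rand_min = Dm[np.ix_(r, r)][np.triu_indices(m, 1)].min()
        assert sel_min >= rand_min


def test_maximin_input_order_invariance(rng):
    n = 30
    X = rng.normal(size=(n, 2))
    Dm = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
    ids = [f"c{i:02d}" for i in range(n)]
    D = pd.DataFrame(Dm, index=ids, columns=ids)
    perm = rng.permutation(n)
    Dp = D.iloc[perm, perm]
    assert maximin_subsample(D, 8) == maximin_subsample(Dp, 8)


def test_maximin_mandatory_and_errors(rng):
    ids = list("abcd")
    D = pd.DataFrame(rng.random((4, 4)), index=ids, columns=ids)
    D = (D + D.T) / 2
    np.fill_diagonal(D.values, 0)
    sel = maximin_subsample(D, 3, mandatory=["d"])
    assert sel[0] == "d"
    with pytest.raises(ValueError, match="exceeds"):
        maximin_subsample(D, 5)
    with pytest.raises(ValueError, match="mandatory"):
        maximin_subsample(D, 2, mandatory=["z"])


def _collection(seed, with_relatives=True):
    cfg = SimulationConfig(
        seed=seed,
        group_sizes={"WE": 55, "WW": 55, "TE": 55},
        fst_targets={"WE": 0.02, "WW": 0.04, "TE": 0.06},
        regions=(), n_distributed_snps=100, n_ssr=15,
        related_pairs={"WE": {"PO": 3, "FS": 2}, "WW": {"PO": 2}}
        if with_relatives else {},
    )
    gm, q, truth = simulate_panel(cfg)
    if with_relatives:
        gm, truth = inject_relatives(gm, truth, cfg)
    return gm, q, truth


def test_design_panel_no_relatives_single_iteration():
    gm, q, _ = _collection(3, with_relatives=False)
    founders = [gm.ind_ids[0], gm.ind_ids[60]]
    sel = design_panel(gm, q, founders=founders, subgroup_size=20)
    assert all(len(ids) == 20 for ids in sel.selected.values())
    assert set(founders) <= set(sel.all_ids)
    prunes = [e for e in sel.log if e.get("event") == "pruned"]
    assert prunes == []  # clean on the first pass


def test_design_panel_removes_planted_pair():
    gm, q, truth = _collection(4)
    sel = design_panel(gm, q, subgroup_size=30)
    assert all(len(ids) == 30 for ids in sel.selected.values())
    # final selection is classifier-clean within every subgroup
    pos = {iid: i for i, iid in enumerate(gm.ind_ids)}
    for ids in sel.selected.values():
        idx = np.array([[pos[a], pos[b]]
                        for a, b in itertools.combinations(ids, 2)])
        assert not classify_pairs(gm, idx).first_degree.any()


def test_design_panel_shortfall_error():
    gm, q, _ = _collection(5, with_relatives=False)
    with pytest.raises(ValueError, match="candidates"):
        design_panel(gm, q, subgroup_size=56)


def test_representativeness_identity():
    gm, _, _ = _collection(6, with_relatives=False)
    pheno = pd.DataFrame({"trait": np.random.default_rng(1).normal(size=gm.n_individuals)},
                         index=gm.ind_ids)
    rep = assess_representativeness(gm.ind_ids, gm, phenotypes=pheno)
    assert rep.allele_retention == pytest.approx(1.0)
    assert rep.freq_correlation_r2 == pytest.approx(1.0)
    assert rep.trait_tests.variance_captured.iloc[0] == pytest.approx(1.0)


def test_retention_counts_only_non_rare_alleles(rng):
    """A panel missing exactly the rare alleles has retention 1."""
    # collection: allele 9 is rare (one copy in one individual)
    calls = rng.integers(0, 3, size=(40, 1, 2))
    calls[0, 0, 0] = 9
    gm = make_ssr_matrix(calls)
    panel_ids = gm.ind_ids[1:]  # drop the rare-allele carrier
    rep = assess_representativeness(panel_ids, gm, rare_maf=0.05)
    assert rep.allele_retention == pytest.approx(1.0)


def test_ranksum_permutation_oracle(rng):
    """Normal-approximation rank-sum p-value matches exact permutation on
    an 8 + 8 fixture within 0.01."""
    x = rng.normal(size=8)
    y = rng.normal(loc=0.8, size=8)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    obs = ranks[:8].sum()
    count = 0
    total = 0
    for comb in itertools.combinations(range(16), 8):
        s = ranks[list(comb)].sum()
        if abs(s - 8 * 17 / 2) >= abs(obs - 8 * 17 / 2) - 1e-9:
            count += 1
        total += 1
    exact_p = count / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert res.pvalue == pytest.approx(exact_p, abs=0.01)
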