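"""Generator properties: determinism, differentiation, LD decay, relatives,
phenotype model."""

import numpy as np
import pytest
from scipy import stats

from vitipanel import (
    ConfigError,
    SimulationConfig,
    inject_relatives,
    kinship_ais,
    pairwise_fst,
    pairwise_ld,
    diversity_stats,
    simulate_panel,
    simulate_phenotype,
)


def test_same_seed_identical():
    cfg = SimulationConfig(seed=3, group_sizes={"A": 20, "B": 20},
                           regions=(("chr1", 1000, 100_000, 30),),
                           n_distributed_snps=20, n_ssr=5)
    gm1, q1, _ = simulate_panel(cfg)
    gm2, q2, _ = simulate_panel(cfg)
    np.testing.assert_array_equal(gm1.snp_dosage, gm2.snp_dosage)
    np.testing.assert_array_equal(gm1.ssr_calls, gm2.ssr_calls)
    np.testing.assert_array_equal(q1.Q, q2.Q)


def test_fst_target_zero_null_case():
    cfg = SimulationConfig(seed=4, group_sizes={"A": 40, "B": 40},
                           fst_targets={"A": 0.0, "B": 0.0},
                           regions=(), n_distributed_snps=500, n_ssr=0)
    gm, _, _ = simulate_panel(cfg)
    assert abs(pairwise_fst(gm).values[0, 1]) < 0.01


def test_fst_targets_recovered():
    """Distributed (pool-free) SNPs realize the Balding-Nichols target."""
    cfg = SimulationConfig(seed=5, group_sizes={"A": 45, "B": 45},
                           fst_targets={"A": 0.05, "B": 0.05},
                           regions=(), n_distributed_snps=500, n_ssr=0)
    gm, _, _ = simulate_panel(cfg)
    assert pairwise_fst(gm).values[0, 1] == pytest.approx(0.05, abs=0.02)


def test_region_ld_monotone_decay():
    """Mean r2 decreases across distance bins within a region."""
    cfg = SimulationConfig(seed=6, group_sizes={"A": 90},
                           fst_targets={"A": 0.03},
                           regions=(("chr1", 1_000_000, 2_000_000, 100),),
                           n_distributed_snps=0, n_ssr=0)
    gm, _, _ = simulate_panel(cfg)
    ld = pairwise_ld(gm, min_maf=0.05)
    edges = [0, 5e4, 1e5, 2e5, 5e5, 1e6, 2e6]
    means = [
        ld[(ld.distance_bp > lo) & (ld.distance_bp <= hi)].r2.mean()
        for lo, hi in zip(edges[:-1], edges[1:])
    ]
    ranks = stats.spearmanr(np.arange(len(means)), means)
    assert ranks.statistic < -0.8  # strongly decreasing in the bin index


def test_switch_rate_infinite_limit_background():
    """With at least one expected switch per bp, far-apart loci are unlinked:
    their mean r2 sits at the 1/n sampling floor, below the 1/pool-size
    ceiling."""
    n = 80
    cfg = SimulationConfig(seed=8, group_sizes={"A": n}, fst_targets={"A": 0.03},
                           regions=(("chr1", 1_000_000, 2_000_000, 80),),
                           n_distributed_snps=0, n_ssr=0,
                           haplotype_pool_size={"A": 10}, switch_rate=1.0)
    gm, _, _ = simulate_panel(cfg)
    ld = pairwise_ld(gm, min_maf=0.05)
    far = ld[ld.distance_bp >= 10_000].r2.mean()
    assert far <= 1.0 / 10  # pool-size background ceiling
    assert far == pytest.approx(1.0 / n, abs=3.0 / n)  # sampling floor


def test_po_pair_shares_allele_everywhere(small_panel):
    """Mendelian necessity: a PO pair is never opposite-homozygous."""
    _, gm, _, truth = small_panel
    pos = {iid: i for i, iid in enumerate(gm.ind_ids)}
    ap = gm.allele_pairs()
    po = [(a, b) for a, b, rel in truth.registry if rel == "PO"]
    assert po
    for a, b in po:
        ga, gb = ap[pos[a]], ap[pos[b]]
        ok = (ga[:, 0] >= 0) & (gb[:, 0] >= 0)
        share = ((ga[:, 0] == gb[:, 0]) | (ga[:, 0] == gb[:, 1])
                 | (ga[:, 1] == gb[:, 0]) | (ga[:, 1] == gb[:, 1]))
        assert share[ok].all()


def test_fs_pairs_ais_above_background():
    """Injected full sibs have mean AIS above the unrelated background
    (aggregated over replicates)."""
    fs_vals, bg_vals = [], []
    for seed in range(20):
        cfg = SimulationConfig(seed=seed, group_sizes={"A": 24},
                               fst_targets={"A": 0.03},
                               regions=(), n_distributed_snps=80, n_ssr=10,
                               related_pairs={"A": {"FS": 3}})
        gm, _, truth = simulate_panel(cfg)
        gm, truth = inject_relatives(gm, truth, cfg)
        K = kinship_ais(gm).values
        pos = {iid: i for i, iid in enumerate(gm.ind_ids)}
        fs_idx = {(pos[a], pos[b]) for a, b, r in truth.registry if r == "FS"}
        related_members = {i for ij in fs_idx for i in ij}
        for i, j in fs_idx:
            fs_vals.append(K[i, j])
        for i in range(gm.n_individuals):
            for j in range(i + 1, gm.n_individuals):
                if (i, j) not in fs_idx and (j, i) not in fs_idx \
                        and i not in related_members and j not in related_members:
                    bg_vals.append(K[i, j])
    assert np.mean(fs_vals) > np.mean(bg_vals)


def test_zero_requested_pairs_identity(small_panel):
    cfg, gm, _, truth = small_panel
    cfg0 = SimulationConfig(seed=cfg.seed, group_sizes=cfg.group_sizes,
                            regions=cfg.regions,
                            n_distributed_snps=cfg.n_distributed_snps,
                            n_ssr=cfg.n_ssr, related_pairs={})
    gm0, _, truth0 = simulate_panel(cfg0)
    gm_same, truth_same = inject_relatives(gm0, truth0, cfg0)
    np.testing.assert_array_equal(gm_same.snp_dosage, gm0.snp_dosage)
    assert truth_same.registry == []


def test_too_many_pairs_config_error():
    cfg = SimulationConfig(seed=1, group_sizes={"A": 6}, fst_targets={"A": 0.02},
                           regions=(), n_distributed_snps=20, n_ssr=0,
                           related_pairs={"A": {"PO": 4}})
    gm, _, truth = simulate_panel(cfg)
    with pytest.raises(ConfigError, match="slots"):
        inject_relatives(gm, truth, cfg)


def test_wild_less_diverse_than_cultivated():
    """Half-sized wild founder pool yields lower wild Nei diversity."""
    cfg = SimulationConfig(seed=10, group_sizes={"WE": 60, "wild": 60},
                           fst_targets={"WE": 0.03, "wild": 0.03},
                           regions=(("chr1", 1_000_000, 2_000_000, 150),),
                           n_distributed_snps=0, n_ssr=0,
                           haplotype_pool_size={"WE": 8, "wild": 4})
    gm, _, _ = simulate_panel(cfg)
    st = diversity_stats(gm)
    means = st[st.locus_id == "<mean>"].set_index("group")["Nei"]
    assert means["wild"] < means["WE"]


def test_phenotype_limits_and_calibration(small_panel):
    _, gm, _, _ = small_panel
    maf = gm.locus_maf()
    causal = next(l.locus_id for k, l in enumerate(gm.loci)
                  if l.locus_type == "snp" and maf[k] > 0.2)
    K = np.eye(gm.n_individuals)
    # h2 = 0: pure noise with unit variance
    y0 = simulate_phenotype(gm, K, h2=0.0, q_effect=0.5, causal=causal, seed=1)
    assert np.var(y0) == pytest.approx(1.0, rel=0.3)
    # h2 = 1, q = 1: exactly mu + beta x
    y1, beta = simulate_phenotype(gm, K, h2=1.0, q_effect=1.0, causal=causal,
                                  seed=2, return_effect=True)
    snp_ids = [l.locus_id for l in gm.snp_loci]
    x = gm.snp_dosage[:, snp_ids.index(causal)]
    np.testing.assert_allclose(y1, beta * x, atol=1e-12)
    # determinism
    y2 = simulate_phenotype(gm, K, h2=0.5, q_effect=0.2, causal=causal, seed=3)
    y3 = simulate_phenotype(gm, K, h2=0.5, q_effect=0.2, causal=causal, seed=3)
    np.testing.assert_array_equal(y2, y3)


def test_phenotype_effect_recovered_by_regression(small_panel):
    """OLS of Y on the causal dosage recovers beta within 2 SE (replicated)."""
    _, gm, _, _ = small_panel
    maf = gm.locus_maf()
    causal = next(l.locus_id for k, l in enumerate(gm.loci)
                  if l.locus_type == "snp" and maf[k] > 0.2)
    snp_ids = [l.locus_id for l in gm.snp_loci]
    x = gm.snp_dosage[:, snp_ids.index(causal)]
    K = np.eye(gm.n_individuals)
    betas = []
    for seed in range(500):
        y, beta = simulate_phenotype(gm, K, h2=0.5, q_effect=0.25, causal=causal,
                                     seed=seed, return_effect=True)
        betas.append(stats.linregress(x, y).slope)
    se = np.std(betas) / np.sqrt(len(betas))
    assert np.mean(betas) == pytest.approx(beta, abs=2 * se + 1e-9)


def test_monomorphic_causal_rejected():
    cfg = SimulationConfig(seed=2, group_sizes={"A": 10}, fst_targets={"A": 0.0},
                           regions=(), n_distributed_snps=5, n_ssr=0)
    gm, _, _ = simulate_panel(cfg)
    gm.snp_dosage[:, 0] = 1.0
    with pytest.raises(ValueError, match="monomorphic"):
        simulate_phenotype(gm, np.eye(10), 0.5, 0.1,
                           gm.snp_loci[0].locus_id, seed=0)


def test_config_validation():
    with pytest.raises(ConfigError):
        SimulationConfig(regions=(("chr1", 1, 10, 100),))  # SNPs > length
    with pytest.raises(ConfigError):
        SimulationConfig(switch_rate=0.0)
    with pytest.raises(ConfigError):
        SimulationConfig(fst_targets={"WE": 0.7})
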