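# vitipanel

Characterization of germplasm diversity panels for genome-wide association
studies: diversity statistics, marker-based kinship, kinship- and
structure-corrected linkage disequilibrium (LD), Hill–Weir LD-decay
modelling, analytic mixed-model power, and structure-aware panel design —
motivated by grapevine (*Vitis vinifera*) collections structured into wine
East / wine West / table East cultivated pools plus a wild group, and
exercised end to end on synthetic panels with controlled differentiation,
relatedness and distance-dependent LD.

## Who it is for

Anyone assembling an association panel from a large clonal germplasm
collection and asking the standard pre-GWAS questions: how much diversity
does the panel capture, how related are its members, how far does LD
extend, how many markers are needed, and what locus effects are detectable
at a given heritability.

## What it computes

**Diversity** — per-locus and per-group Na, Ne = 1/Σp², He = 1 − Σp²
(Nei's diversity), Ho, MAF, and pairwise Weir & Cockerham (1984) θ with
ratio-of-sums averaging.

**Kinship** — five coancestry estimators: AIS (raw identity-by-state
sharing), WAIS (per-locus correction by the mean cross-group AIS s_l:
(AIS_l − s_l)/(1 − s_l), tagged WAIS2/WAIS4 by the number of assumed
unrelated groups), BNO (one global correction factor), Loiselle's
bias-corrected frequency correlation, and a pairwise maximum-likelihood
estimator of the IBD coefficients (k0, k1, k2) by EM with coancestry
k1/4 + k2/2. A likelihood classifier labels pairs U / HS / FS / PO for
first-degree pruning, and the estimator whose correction leaves the least
inter-chromosomal LD can be selected automatically.

**Corrected LD** — classical r², kinship-corrected r²_V, and
kinship+structure-corrected r²_VS via whitening by the inverse Cholesky
factor of the kinship matrix and residualization on the whitened intercept
(plus structure covariates), with pairwise-LD tables and sliding-window
summaries.

**LD decay** — the Hill–Weir expectation
E[r²] = [(10+C)/((2+C)(11+C))]·[1 + ((3+C)(12+12C+C²))/(n(2+C)(11+C))]
with C = ρ·d, least-squares fitting of ρ, LD extent (the distance where
the fitted curve crosses a threshold, 0.2 by convention), and the
equally-spaced marker count needed to keep every genome position within
that distance of a marker.

**GWAS power** — the Li & Ji eigenvalue-based effective number of tests
Meff, the analytic power of the mixed-model Wald test
(Y = 1μ + x_lβ_l + U + E, U ~ N(0, Kσ²_g)) from a 1-df noncentral
chi-square, power at linked markers (power at the causal locus × r²_VS),
and a Monte-Carlo validation of the analytic power.

**Panel design** — simple-matching dissimilarity, greedy maximin
subsampling, the full design loop (structure-membership filter at 0.8 →
founder seeding → maximin fill → iterative first-degree pruning with
refill), and representativeness reports (allele retention, frequency
correlation, rank-sum and Brown–Forsythe trait tests, variance captured).

**Synthetic panels** — Balding–Nichols subgroup frequencies around
ancestral frequencies, within-region LD from a founder-haplotype copying
model, genome-distributed SNPs and multiallelic SSRs, injected
parent-offspring and full-sib pairs with ground truth, and phenotypes under
the mixed model above.

## Worked example

```python
from vitipanel import (SimulationConfig, simulate_panel, inject_relatives,
                       kinship_wais, pairwise_ld, fit_hill_weir, ld_extent,
                       meff_li_ji)

cfg = SimulationConfig(seed=42, related_pairs={"WE": {"PO": 4, "FS": 3}})
gm, structure, truth = simulate_panel(cfg)
gm, truth = inject_relatives(gm, truth, cfg)

kin_ids = [l.locus_id for l in gm.loci
           if l.region_label == "distributed" or l.locus_type == "ssr"]
K = kinship_wais(gm.select_loci(kin_ids))

chr8 = [l.locus_id for l in gm.snp_loci if l.region_label == "chr8"]
ld = pairwise_ld(gm, loci=chr8, K=K.values, S=structure.Q, min_maf=0.05)

region_ids = [l.locus_id for l in gm.snp_loci
              if l.region_label != "distributed"]
print(gm.n_individuals, len(gm.snp_loci), K.estimator,
      len(ld), meff_li_ji(gm, region_ids))
```

prints `334 501 WAIS4 3240 226.0`: a 334-individual panel typed at 501
SNPs (four ~2 Mb regions plus 129 distributed) and 20 SSRs, a WAIS
kinship assuming four unrelated groups, 3240 kinship/structure-corrected
LD pairs in the chr8 region, and 226 effective tests among the 372 region
SNPs — so a 5 % family-wise error rate corresponds to a per-test
threshold of 0.05/226.

Fitting the decay curve on a single-subgroup region simulated with a
3-founder pool and a 6e-6 per-bp switch rate:

```python
from vitipanel import fit_hill_weir, ld_extent, markers_required

cfg = SimulationConfig(seed=42, group_sizes={"WE": 90}, fst_targets={"WE": 0.03},
                       regions=(("chr1", 1_000_000, 2_000_000, 120),),
                       n_distributed_snps=0, n_ssr=0,
                       haplotype_pool_size={"WE": 3}, switch_rate=6e-6)
gm, _, _ = simulate_panel(cfg)
ld = pairwise_ld(gm, min_maf=0.05)
fit = fit_hill_weir(ld, n=90)
print(round(ld_extent(fit, 0.2) / 1000, 1),
      markers_required(fit, 487_000_000, 0.45))
```

prints `64.8 181884`: expected r² falls to 0.2 at ~65 Kb, and about
182,000 equally spaced markers would keep every position of a 487 Mb
genome within the distance where expected r² is still 0.45.

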