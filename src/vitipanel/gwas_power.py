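"""Analytic mixed-model GWAS power and effective-test multiple-testing
correction.

Locus effects are tested with the Wald statistic in the mixed model
Y = 1*mu + x_l*beta_l + U + E, U ~ N(0, K sigma2_gl), E ~ N(0, I sigma2_e),
with variance components treated as known. On a unit-total-variance scale
with trait heritability h2 and a locus explaining a fraction q of the
genetic variance: sigma2_e = 1 - h2, sigma2_gl = (1 - q) h2, and beta_l is
calibrated so beta_l^2 Var(x_l) = q h2. The Wald statistic then follows a
1-df noncentral chi-square with noncentrality beta_l^2 / var(beta_hat),
var(beta_hat) the x_l entry of (X' V^-1 X)^-1, V = sigma2_gl K + sigma2_e I.

The per-test threshold is the family-wise error rate divided by the Li-Ji
effective number of independent tests (the eigenvalue-based count on the
locus-locus correlation matrix).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corrected_ld import prepare_kinship
from .genotypes_io import GenotypeMatrix


@dataclass
class PowerSpec:
    """Trait/locus/testing configuration for one power evaluation."""

    h2: float
    q_effect: float
    fwer: float = 0.05
    meff: float = 1.0
    kinship_tag: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.h2 <= 1 or not 0 <= self.q_effect <= 1:
            raise ValueError("h2 and q_effect must lie in [0, 1]")
        if not 0 < self.fwer < 1 or self.meff < 1:
            raise ValueError("need 0 < fwer < 1 and meff >= 1")

    @property
    def alpha(self) -> float:
        return self.fwer / self.meff


def meff_li_ji(gm: GenotypeMatrix, loci: Sequence[str] | None = None) -> float:
    """Li-Ji effective number of independent tests among SNP loci.

    Meff = sum_i [ I(|lambda_i| >= 1) + (|lambda_i| - floor(|lambda_i|)) ]
    over the eigenvalues of the locus-locus Pearson correlation matrix
    (pairwise-complete; undefined correlations are set to 0 with a warning;
    zero-variance loci are dropped with a warning).
    """
    snp_ids = [l.locus_id for l in gm.snp_loci]
    if loci is not None:
        wanted = set(loci)
        keep = [j for j, lid in enumerate(snp_ids) if lid in wanted]
    else:
        keep = list(range(len(snp_ids)))
    D = gm.snp_dosage[:, keep]
    var = np.nanvar(D, axis=0)
    if np.any(var == 0):
        warnings.warn(f"{int((var == 0).sum())} zero-variance loci dropped "
                      "before eigen-decomposition", stacklevel=2)
        D = D[:, var > 0]
    if D.shape[1] < 2:
        return float(D.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        C = pd.DataFrame(D).corr(min_periods=2).to_numpy()
    if np.isnan(C).any():
        warnings.warn("undefined pairwise correlations set to 0", stacklevel=2)
        C = np.nan_to_num(C, nan=0.0)
        np.fill_diagonal(C, 1.0)
    lam = np.abs(np.linalg.eigvalsh(C))
    return float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))


def _wald_variance(x: np.ndarray, Vinv: np.ndarray) -> float:
    X = np.column_stack([np.ones_like(x), x])
    XtVX = X.T @ Vinv @ X
    return float(np.linalg.inv(XtVX)[1, 1])


def power_at_locus(
    x_l: np.ndarray, K: np.ndarray, spec: PowerSpec
) -> float:
    """Analytic power of the mixed-model Wald test at one locus.

    Missing dosages are mean-imputed; a monomorphic locus yields NaN with a
    warning. At q_effect = 0 the power equals the per-test alpha exactly.
    """
    x = np.asarray(x_l, dtype=float).copy()
    if np.isnan(x).any():
        x[np.isnan(x)] = np.nanmean(x)
    v = float(np.var(x))
    if v == 0:
        warnings.warn("monomorphic locus: power undefined", stacklevel=2)
        return np.nan
    n = len(x)
    sig_e2 = 1.0 - spec.h2
    sig_g2 = (1.0 - spec.q_effect) * spec.h2
    V = sig_g2 * prepare_kinship(K) + sig_e2 * np.eye(n)
    Vinv = np.linalg.inv(V)
    beta = np.sqrt(spec.q_effect * spec.h2 / v)
    var_beta = _wald_variance(x, Vinv)
    lam = beta ** 2 / var_beta
    crit = stats.chi2.ppf(1.0 - spec.alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=lam))


def power_at_marker(power_causal: float, r2_vs: float) -> float:
    """Power at a marker in LD r2 with the causal locus (product rule)."""
    if not 0 <= power_causal <= 1 or not 0 <= r2_vs <= 1:
        raise ValueError("arguments must lie in [0, 1]")
    return power_causal * r2_vs


def power_grid(
    gm: GenotypeMatrix,
    K: np.ndarray,
    loci: Sequence[str] | None = None,
    h2_list: Sequence[float] = (0.3, 0.5, 0.7, 0.9),
    q_list: Sequence[float] = (0.05, 0.1, 0.25),
    fwer: float = 0.05,
    maf_min: float = 0.0,
    meff: float | None = None,
    kinship_tag: str = "",
) -> pd.DataFrame:
    """Full factorial per-locus analytic power over h2 x locus-effect.

    Meff is computed (Li-Ji) on the same locus selection unless supplied.
    Returns a long table with locus metadata, MAF, h2, q_effect and power.
    """
    snp_ids = [l.locus_id for l in gm.snp_loci]
    snp_info = {l.locus_id: l for l in gm.snp_loci}
    if loci is None:
        loci = snp_ids
    maf = gm.locus_maf()
    maf_by_id = {l.locus_id: maf[k] for k, l in enumerate(gm.loci)}
    if maf_min > 0:
        loci = [lid for lid in loci if maf_by_id[lid] >= maf_min]
    if meff is None:
        meff = meff_li_ji(gm, loci)
    Kp = prepare_kinship(K)
    n = gm.n_individuals
    col = {lid: j for j, lid in enumerate(snp_ids)}
    rows = []
    for h2 in h2_list:
        for q in q_list:
            spec = PowerSpec(h2=h2, q_effect=q, fwer=fwer, meff=meff,
                             kinship_tag=kinship_tag)
            sig_e2 = 1.0 - h2
            sig_g2 = (1.0 - q) * h2
            Vinv = np.linalg.inv(sig_g2 * Kp + sig_e2 * np.eye(n))
            crit = stats.chi2.ppf(1.0 - spec.alpha, df=1)
            for lid in loci:
                x = gm.snp_dosage[:, col[lid]].copy()
                if np.isnan(x).any():
                    x[np.isnan(x)] = np.nanmean(x)
                v = float(np.var(x))
                if v == 0:
                    rows.append((lid, snp_info[lid].region_label,
                                 maf_by_id[lid], h2, q, np.nan))
                    continue
                beta = np.sqrt(q * h2 / v)
                lam = beta ** 2 / _wald_variance(x, Vinv)
                pw = float(stats.ncx2.sf(crit, df=1, nc=lam))
                rows.append((lid, snp_info[lid].region_label,
                             maf_by_id[lid], h2, q, pw))
    df = pd.DataFrame(rows, columns=["locus_id", "region", "MAF", "h2",
                                     "q_effect", "power"])
    df.attrs["meff"] = meff
    df.attrs["fwer"] = fwer
    df.attrs["kinship_tag"] = kinship_tag
    return df


def empirical_power(
    gm: GenotypeMatrix,
    K: np.ndarray,
    causal: str,
    spec: PowerSpec,
    n_reps: int = 2000,
    seed: int = 0,
) -> float:
    """Monte-Carlo Wald rejection rate under the generating mixed model.

    Phenotypes are simulated with the same kinship and variance components
    used by the analytic power (components treated as known, so the Wald
    statistic is referred to the central chi-square(1) critical value at
    the spec's per-test alpha).
    """
    snp_ids = [l.locus_id for l in gm.snp_loci]
    x = gm.snp_dosage[:, snp_ids.index(causal)].copy()
    if np.isnan(x).any():
        x[np.isnan(x)] = np.nanmean(x)
    n = len(x)
    Kp = prepare_kinship(K)
    sig_e2 = 1.0 - spec.h2
    sig_g2 = (1.0 - spec.q_effect) * spec.h2
    Vinv = np.linalg.inv(sig_g2 * Kp + sig_e2 * np.eye(n))
    X = np.column_stack([np.ones(n), x])
    XtVX_inv = np.linalg.inv(X.T @ Vinv @ X)
    A = XtVX_inv @ X.T @ Vinv  # GLS estimator matrix
    var_beta = XtVX_inv[1, 1]
    crit = stats.chi2.ppf(1.0 - spec.alpha, df=1)
    rng = np.random.default_rng(seed)
    # same generating model as simulate_phenotype, with the PSD square root
    # of K factored once instead of per replicate
    v = float(np.var(x))
    beta = np.sqrt(spec.q_effect * spec.h2 / v) if v > 0 else 0.0
    w, U = np.linalg.eigh(Kp)
    Lu = U * np.sqrt(np.clip(w, 0.0, None) * sig_g2)
    hits = 0
    for _ in range(n_reps):
        y = x * beta + Lu @ rng.standard_normal(n) \
            + rng.standard_normal(n) * np.sqrt(sig_e2)
        beta_hat = (A @ y)[1]
        if beta_hat ** 2 / var_beta > crit:
            hits += 1
    return hits / n_reps
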