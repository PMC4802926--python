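"""Classical and kinship/structure-corrected linkage disequilibrium.

Three squared-correlation LD estimators on genotype dosages:

* ``r2`` — classical squared Pearson correlation;
* ``r2_V`` — correlation corrected for relatedness: both dosage vectors and
  the intercept are whitened by the inverse lower Cholesky factor of the
  kinship matrix V, the whitened dosages are residualized on the whitened
  intercept, and the squared correlation of residuals is returned;
* ``r2_VS`` — as ``r2_V`` with the structure membership columns (one dropped
  for identifiability) added to the whitened covariates.

Whitening turns the generalized-least-squares correlation under a
relatedness covariance into an ordinary one, so ``r2_V`` with V = identity
collapses exactly to the classical ``r2``.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes_io import GenotypeMatrix, StructureMatrix


class LDNumericalError(RuntimeError):
    """Cholesky or conditioning failure in the corrected-LD computation."""


def prepare_kinship(K: np.ndarray, truncate: bool = True) -> np.ndarray:
    """Symmetrize, optionally truncate negatives at 0, and ridge to a
    Cholesky-factorizable matrix.

    Conditioning policy: if the Cholesky factorization fails, add
    ``1e-6 * mean(diag)`` to the diagonal and retry; if the matrix is still
    indefinite (group-corrected estimators subtract rank-one terms and can
    be genuinely indefinite, not merely ill-conditioned), shift the whole
    spectrum by ``|lambda_min| + 1e-6 * mean(diag)``, which preserves the
    eigenstructure while making the matrix positive definite. A failure
    after shifting raises :class:`LDNumericalError`.
    """
    K = np.asarray(K, dtype=float)
    K = (K + K.T) / 2.0
    if truncate:
        K = np.clip(K, 0.0, None)
        K = (K + K.T) / 2.0
    try:
        np.linalg.cholesky(K)
        return K
    except np.linalg.LinAlgError:
        pass
    eps = 1e-6 * float(np.mean(np.diag(K)))
    if eps <= 0:
        eps = 1e-6
    K2 = K + eps * np.eye(K.shape[0])
    try:
        np.linalg.cholesky(K2)
        return K2
    except np.linalg.LinAlgError:
        pass
    w_min = float(np.linalg.eigvalsh(K).min())
    K3 = K + (abs(w_min) + eps) * np.eye(K.shape[0])
    try:
        np.linalg.cholesky(K3)
        return K3
    except np.linalg.LinAlgError as exc:
        raise LDNumericalError(
            "kinship matrix is not positive definite after ridge and "
            "spectrum shift"
        ) from exc


def _covariates(n: int, S: np.ndarray | None) -> np.ndarray:
    """Intercept plus structure columns with the last dropped."""
    cols = [np.ones((n, 1))]
    if S is not None:
        S = np.asarray(S, dtype=float)
        if S.shape[0] != n:
            raise ValueError("structure matrix does not align with individuals")
        if S.shape[1] > 1:
            cols.append(S[:, :-1])
    return np.hstack(cols)


def whitened_residuals(
    X: np.ndarray, K: np.ndarray | None, S: np.ndarray | None = None
) -> np.ndarray:
    """Whiten columns of X by chol(K)^-1 and project out the whitened
    covariates; identity whitening when K is None."""
    from scipy.linalg import solve_triangular

    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    C = _covariates(n, S)
    if K is not None:
        L = np.linalg.cholesky(prepare_kinship(K))
        X = solve_triangular(L, X, lower=True)
        C = solve_triangular(L, C, lower=True)
    beta, *_ = np.linalg.lstsq(C, X, rcond=None)
    return X - C @ beta


def _sq_corr(u: np.ndarray, v: np.ndarray) -> float:
    """Squared uncentered correlation of two residual vectors."""
    uu = float(u @ u)
    vv = float(v @ v)
    if uu == 0 or vv == 0:
        warnings.warn("zero-variance residual; LD undefined", stacklevel=3)
        return np.nan
    return float((u @ v) ** 2 / (uu * vv))


def r2_corrected(
    x: np.ndarray,
    y: np.ndarray,
    K: np.ndarray | None = None,
    S: np.ndarray | None = None,
) -> float:
    """LD between two dosage vectors: classical r2 (no K), r2_V (K only) or
    r2_VS (K and S). Pairwise-complete individuals only; needs >= 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 pairwise-complete individuals")
    x, y = x[ok], y[ok]
    if K is None:
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn("zero-variance locus; LD undefined", stacklevel=2)
            return np.nan
        return float(np.corrcoef(x, y)[0, 1] ** 2)
    K = np.asarray(K, dtype=float)
    if K.shape[0] == len(ok):  # subset to pairwise-complete individuals
        sub = np.flatnonzero(ok)
        K = K[np.ix_(sub, sub)]
    Ssub = None
    if S is not None:
        S = S.Q if isinstance(S, StructureMatrix) else np.asarray(S, dtype=float)
        Ssub = S[ok] if S.shape[0] == len(ok) else S
    R = whitened_residuals(np.column_stack([x, y]), K, Ssub)
    return _sq_corr(R[:, 0], R[:, 1])


def _snp_selection(gm: GenotypeMatrix, loci: Sequence[str] | None,
                   min_maf: float) -> list[int]:
    snp_idx = [k for k, l in enumerate(gm.loci) if l.locus_type == "snp"]
    if loci is not None:
        wanted = set(loci)
        snp_idx = [k for k in snp_idx if gm.loci[k].locus_id in wanted]
    if min_maf > 0:
        maf = gm.locus_maf()
        snp_idx = [k for k in snp_idx if not np.isnan(maf[k]) and maf[k] >= min_maf]
    return snp_idx


def pairwise_ld(
    gm: GenotypeMatrix,
    loci: Sequence[str] | None = None,
    K: np.ndarray | None = None,
    S: np.ndarray | StructureMatrix | None = None,
    min_maf: float = 0.0,
) -> pd.DataFrame:
    """All unordered SNP-pair LD records within a locus selection.

    Returns a long table with locus ids, chromosome/position metadata,
    inter-locus distance in bp (NaN when chromosomes differ), the classical
    ``r2``, ``r2_V`` (when K is given), ``r2_VS`` (when K and S are given)
    and ``n_used`` pairwise-complete individuals.
    """
    idx = _snp_selection(gm, loci, min_maf)
    if len(idx) < 2:
        raise ValueError("fewer than 2 loci after the MAF filter")
    snp_cols = {k: j for j, k in enumerate(
        i for i, l in enumerate(gm.loci) if l.locus_type == "snp")}
    cols = [snp_cols[k] for k in idx]
    D = gm.snp_dosage[:, cols]
    locs = [gm.loci[k] for k in idx]
    m = len(idx)
    if isinstance(S, StructureMatrix):
        S = S.Q

    complete = not np.isnan(D).any()
    r2_mat = r2v_mat = r2vs_mat = None
    if complete:
        # fast path: one whitening of the full dosage block
        def corr2(R: np.ndarray) -> np.ndarray:
            norms = np.linalg.norm(R, axis=0)
            norms[norms == 0] = np.nan
            C = (R.T @ R) / np.outer(norms, norms)
            return C ** 2

        r2_mat = corr2(whitened_residuals(D, None))
        if K is not None:
            r2v_mat = corr2(whitened_residuals(D, K))
            if S is not None:
                r2vs_mat = corr2(whitened_residuals(D, K, S))

    rows = []
    for a in range(m):
        for b in range(a + 1, m):
            la, lb = locs[a], locs[b]
            dist = abs(la.pos_bp - lb.pos_bp) if la.chrom == lb.chrom else np.nan
            if complete:
                n_used = D.shape[0]
                r2 = r2_mat[a, b]
                r2v = r2v_mat[a, b] if r2v_mat is not None else np.nan
                r2vs = r2vs_mat[a, b] if r2vs_mat is not None else np.nan
            else:
                x, y = D[:, a], D[:, b]
                ok = ~np.isnan(x) & ~np.isnan(y)
                n_used = int(ok.sum())
                r2 = r2_corrected(x, y)
                r2v = r2_corrected(x, y, K=K) if K is not None else np.nan
                r2vs = (r2_corrected(x, y, K=K, S=S)
                        if K is not None and S is not None else np.nan)
            rows.append((la.locus_id, lb.locus_id, la.chrom, lb.chrom,
                         la.pos_bp, lb.pos_bp, dist, r2, r2v, r2vs, n_used))
    return pd.DataFrame(
        rows,
        columns=["locus_a", "locus_b", "chrom_a", "chrom_b", "pos_a", "pos_b",
                 "distance_bp", "r2", "r2_V", "r2_VS", "n_used"],
    )


def sliding_window_ld(
    ld: pd.DataFrame,
    window_bp: int,
    step_bp: int,
    min_pairs: int = 10,
    ld_column: str = "r2_V",
) -> pd.DataFrame:
    """Windowed mean LD along one chromosome.

    A pair belongs to a window iff BOTH loci lie inside it; windows are
    anchored at their start coordinate and step by ``step_bp`` across the
    span of the table. Windows with fewer than ``min_pairs`` pairs get NaN.
    """
    if window_bp <= 0 or step_bp <= 0:
        raise ValueError("window_bp and step_bp must be positive")
    chroms = set(ld["chrom_a"]) | set(ld["chrom_b"])
    if len(chroms) > 1:
        raise ValueError("sliding window requires a single chromosome")
    lo = int(min(ld["pos_a"].min(), ld["pos_b"].min()))
    hi = int(max(ld["pos_a"].max(), ld["pos_b"].max()))
    pos_a = ld["pos_a"].to_numpy()
    pos_b = ld["pos_b"].to_numpy()
    vals = ld[ld_column].to_numpy(dtype=float)
    rows = []
    start = lo
    while start <= hi:
        end = start + window_bp
        inside = (pos_a >= start) & (pos_a < end) & (pos_b >= start) & (pos_b < end)
        inside &= ~np.isnan(vals)
        n = int(inside.sum())
        mean = float(vals[inside].mean()) if n >= min_pairs else np.nan
        rows.append((start, end, n, mean))
        start += step_bp
    return pd.DataFrame(rows, columns=["window_start", "window_end", "n_pairs",
                                       f"mean_{ld_column}"])


def mean_interchromosomal_ld(
    gm: GenotypeMatrix,
    K: np.ndarray | None = None,
    S: np.ndarray | StructureMatrix | None = None,
    min_maf: float = 0.05,
    ld_column: str | None = None,
) -> float:
    """Mean LD over all SNP pairs on different chromosomes.

    True LD between unlinked loci is null, so this mean measures the bias a
    given kinship/structure correction leaves behind.
    """
    tab = pairwise_ld(gm, K=K, S=S, min_maf=min_maf)
    inter = tab[np.isnan(tab["distance_bp"])]
    if ld_column is None:
        ld_column = "r2_VS" if (K is not None and S is not None) else (
            "r2_V" if K is not None else "r2")
    return float(inter[ld_column].mean())
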