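"""Marker-based coancestry estimation and relationship classification.

Five estimators of the coancestry (kinship) coefficient between pairs of
individuals:

* **AIS** — alikeness in state: the probability that two alleles drawn at a
  random locus, one from each individual, are identical by state.
* **WAIS2 / WAIS4** — AIS corrected per locus for chance IBS: with a
  partition into putatively unrelated groups, the per-locus mean AIS over
  all cross-group pairs ``s_l`` estimates the IBS-not-IBD background, and
  the corrected value is the mean over loci of ``(AIS_l - s_l)/(1 - s_l)``
  (tagged by the number of unrelated groups used).
* **BNO** — the same correction with a single global factor ``s`` (mean AIS
  over all loci and cross-group pairs).
* **LOI** — Loiselle's bias-corrected correlation of individual allele
  frequencies.
* **MLE** — maximum-likelihood estimation of the IBD coefficients
  (k0, k1, k2) per pair by EM over the mixture of the three IBD-state
  genotype-pair likelihoods; coancestry = k1/4 + k2/2.

A likelihood classifier evaluates each pair at the canonical IBD vectors
for unrelated (1,0,0), half-sib (0.5,0.5,0), full-sib (0.25,0.5,0.25) and
parent-offspring (0,1,0) relationships, for first-degree-relative pruning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes_io import MISSING_ALLELE, GenotypeMatrix, group_indices

ESTIMATOR_ORDER = ("AIS", "WAIS2", "WAIS4", "BNO", "LOI", "MLE")

_RELATIONSHIP_K = {
    "U": (1.0, 0.0, 0.0),
    "HS": (0.5, 0.5, 0.0),
    "FS": (0.25, 0.5, 0.25),
    "PO": (0.0, 1.0, 0.0),
}


@dataclass
class KinshipMatrix:
    """Symmetric N x N coancestry estimate tagged with its estimator."""

    ind_ids: list[str]
    values: np.ndarray
    estimator: str
    unrelated_groups: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ind_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match ids")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ind_ids, columns=self.ind_ids)


@dataclass
class RelationshipCall:
    """Per-category pair log-likelihoods and the best-supported category."""

    pair: tuple[str, str]
    loglik: dict[str, float]
    best: str = field(init=False)
    first_degree: bool = field(init=False)

    def __post_init__(self) -> None:
        order = ("U", "HS", "FS", "PO")  # tie-break: U preferred, then HS
        vals = np.array([self.loglik[c] for c in order])
        self.best = order[int(np.argmax(vals))]
        self.first_degree = self.best in ("PO", "FS")


# ---------------------------------------------------------------------------
# AIS and its corrected variants
# ---------------------------------------------------------------------------


def _pairwise_ais_accumulate(
    pairs: np.ndarray,
    scale: np.ndarray | None = None,
    offset: np.ndarray | None = None,
    locus_mask: np.ndarray | None = None,
    block: int = 64,
) -> np.ndarray:
    """Mean over pairwise-complete loci of ``offset_l + scale_l * AIS_l``.

    ``pairs`` is the (N, L, 2) allele-pair view. Per-locus AIS between
    genotypes (a,b) and (c,d) is [I(a=c)+I(a=d)+I(b=c)+I(b=d)] / 4.
    """
    n, L, _ = pairs.shape
    scale = np.ones(L) if scale is None else scale
    offset = np.zeros(L) if offset is None else offset
    usable = np.ones(L, dtype=bool) if locus_mask is None else locus_mask
    a = pairs[:, :, 0]
    b = pairs[:, :, 1]
    valid = (a != MISSING_ALLELE) & usable
    out = np.full((n, n), np.nan)
    for i0 in range(0, n, block):
        i1 = min(i0 + block, n)
        ai = a[i0:i1, None, :]
        bi = b[i0:i1, None, :]
        aj = a[None, :, :]
        bj = b[None, :, :]
        ais = ((ai == aj).astype(np.float32) + (ai == bj)
               + (bi == aj) + (bi == bj)) / 4.0
        v = valid[i0:i1, None, :] & valid[None, :, :]
        contrib = np.where(v, offset + scale * ais, 0.0)
        cnt = v.sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[i0:i1] = contrib.sum(axis=2) / cnt
    if np.isnan(out).any():
        warnings.warn("some pairs share no typed loci", stacklevel=3)
    return out


def kinship_ais(gm: GenotypeMatrix) -> KinshipMatrix:
    """Raw alikeness-in-state coancestry (SNPs and SSRs together)."""
    values = _pairwise_ais_accumulate(gm.allele_pairs())
    return KinshipMatrix(gm.ind_ids, values, "AIS")


def _cross_group_ais_per_locus(
    pairs: np.ndarray, gidx: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus mean AIS over cross-group pairs, and pair-count weights.

    Uses the closed form: the average of AIS over all (i in g, j in g')
    pairs equals sum_a c_ga * c_g'a / (4 n_g n_g') with c the group allele
    counts at the locus (over non-missing individuals).
    """
    L = pairs.shape[1]
    labels = sorted(gidx)
    num = np.zeros(L)
    den = np.zeros(L)
    counts = {}
    ns = {}
    all_alleles = int(pairs.max()) + 1
    for g in labels:
        sub = pairs[gidx[g]]
        ok = sub[:, :, 0] != MISSING_ALLELE
        ns[g] = ok.sum(axis=0).astype(float)
        c = np.zeros((all_alleles, L))
        for slot in (0, 1):
            v = sub[:, :, slot]
            for l in range(L):
                vals = v[ok[:, l], l]
                if vals.size:
                    c[:, l] += np.bincount(vals, minlength=all_alleles)
        counts[g] = c
    for i, g in enumerate(labels):
        for g2 in labels[i + 1:]:
            num += (counts[g] * counts[g2]).sum(axis=0) / 4.0
            den += ns[g] * ns[g2]
    with np.errstate(invalid="ignore", divide="ignore"):
        s_l = num / den
    weights = den
    return s_l, weights


def kinship_wais(
    gm: GenotypeMatrix, unrelated_groups: dict[str, Sequence[str]] | None = None
) -> KinshipMatrix:
    """AIS corrected per locus by the cross-group mean ``s_l``.

    The partition of putatively unrelated groups defaults to the
    individuals' subgroup labels; the estimator tag is WAIS2 or WAIS4 for
    two or four groups (WAIS<k> otherwise).
    """
    gidx = group_indices(gm, unrelated_groups)
    if len(gidx) < 2:
        raise ValueError("WAIS needs a partition with >= 2 groups")
    pairs = gm.allele_pairs()
    s_l, _ = _cross_group_ais_per_locus(pairs, gidx)
    usable = ~np.isnan(s_l) & (s_l < 1.0 - 1e-12)
    if not usable.all():
        warnings.warn(
            f"{int((~usable).sum())} loci skipped in WAIS correction (s_l = 1 "
            "or undefined)", stacklevel=2)
    scale = np.where(usable, 1.0 / (1.0 - np.where(usable, s_l, 0.0)), 0.0)
    offset = np.where(usable, -np.where(usable, s_l, 0.0) * scale, 0.0)
    values = _pairwise_ais_accumulate(pairs, scale, offset, locus_mask=usable)
    tag = f"WAIS{len(gidx)}"
    groups_out = {g: [gm.ind_ids[i] for i in idx] for g, idx in gidx.items()}
    return KinshipMatrix(gm.ind_ids, values, tag, groups_out)


def kinship_bno(
    gm: GenotypeMatrix, unrelated_groups: dict[str, Sequence[str]] | None = None
) -> KinshipMatrix:
    """AIS corrected by a single global cross-group factor ``s``."""
    gidx = group_indices(gm, unrelated_groups)
    if len(gidx) < 2:
        raise ValueError("BNO needs a partition with >= 2 groups")
    pairs = gm.allele_pairs()
    s_l, w = _cross_group_ais_per_locus(pairs, gidx)
    ok = ~np.isnan(s_l) & (w > 0)
    s = float(np.sum(s_l[ok] * w[ok]) / np.sum(w[ok]))
    if s >= 1.0 - 1e-12:
        raise ValueError("degenerate data: global cross-group AIS is 1")
    ais = _pairwise_ais_accumulate(pairs)
    values = (ais - s) / (1.0 - s)
    groups_out = {g: [gm.ind_ids[i] for i in idx] for g, idx in gidx.items()}
    return KinshipMatrix(gm.ind_ids, values, "BNO", groups_out)


# ---------------------------------------------------------------------------
# Loiselle estimator
# ---------------------------------------------------------------------------


def kinship_loiselle(gm: GenotypeMatrix) -> KinshipMatrix:
    """Loiselle's bias-corrected kinship from individual allele frequencies.

    f_ij = [ sum_l sum_a (x_ila - p_la)(x_jla - p_la)
             + sum_l sum_a p_la (1 - p_la) / (n_l - 1) ]
           / sum_l sum_a p_la (1 - p_la),

    with x the individual allele frequency (0, 0.5, 1), p the sample
    frequency and n_l the number of non-missing individuals at locus l.
    Missing genotypes contribute zero to the cross-products.
    """
    if gm.n_individuals < 2:
        raise ValueError("need >= 2 individuals")
    pairs = gm.allele_pairs()
    n, L, _ = pairs.shape
    cols = []
    bias = 0.0
    denom = 0.0
    for l in range(L):
        g = pairs[:, l, :]
        ok = g[:, 0] != MISSING_ALLELE
        n_l = int(ok.sum())
        if n_l < 2:
            continue
        alleles = np.unique(g[ok].ravel())
        for a in alleles:
            x = 0.5 * ((g[:, 0] == a).astype(float) + (g[:, 1] == a))
            p = x[ok].mean()
            xc = np.where(ok, x - p, 0.0)
            cols.append(xc)
            bias += p * (1 - p) / (n_l - 1)
            denom += p * (1 - p)
    if denom == 0:
        raise ValueError("all loci monomorphic: Loiselle denominator undefined")
    X = np.column_stack(cols)
    values = (X @ X.T + bias) / denom
    return KinshipMatrix(gm.ind_ids, values, "LOI")


# ---------------------------------------------------------------------------
# IBD-state likelihoods (shared by the MLE and the classifier)
# ---------------------------------------------------------------------------


def _locus_freq_arrays(gm: GenotypeMatrix,
                       freqs: pd.DataFrame | None = None) -> list[np.ndarray]:
    """Per-locus allele frequency lookup arrays indexed by allele label."""
    if freqs is None:
        from .diversity import allele_frequencies

        freqs = allele_frequencies(gm)
    out = []
    by_locus = {k: v for k, v in freqs.groupby("locus_id")}
    for loc in gm.loci:
        tab = by_locus.get(loc.locus_id)
        if tab is None or len(tab) == 0:
            out.append(np.array([]))
            continue
        size = int(tab["allele"].max()) + 1
        p = np.zeros(size)
        p[tab["allele"].to_numpy(dtype=int)] = tab["freq"].to_numpy()
        out.append(p)
    return out


def _ibd_tables(
    gi: np.ndarray, gj: np.ndarray, plist: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """P(G_i, G_j | m alleles IBD) for m = 0, 1, 2, per pair and locus.

    ``gi``/``gj`` are (B, L, 2) allele-pair blocks for the two pair members.
    Returns (P, valid) with P of shape (B, L, 3); loci missing in either
    member get P = 1 (log-neutral) and valid = False.
    """
    B, L, _ = gi.shape
    P = np.ones((B, L, 3))
    valid = (gi[:, :, 0] != MISSING_ALLELE) & (gj[:, :, 0] != MISSING_ALLELE)
    for l in range(L):
        p = plist[l]
        if p.size == 0:
            valid[:, l] = False
            continue
        a, b = gi[:, l, 0], gi[:, l, 1]
        c, d = gj[:, l, 0], gj[:, l, 1]
        ok = valid[:, l]
        aa = np.where(ok, a, 0)
        bb = np.where(ok, b, 0)
        cc = np.where(ok, c, 0)
        dd = np.where(ok, d, 0)
        pa, pb, pc, pd_ = p[aa], p[bb], p[cc], p[dd]
        p_gi = pa * pb * np.where(aa != bb, 2.0, 1.0)
        p_gj = pc * pd_ * np.where(cc != dd, 2.0, 1.0)

        def trans(x):  # P({c,d} | IBD allele x, other drawn from population)
            hom = (cc == dd)
            return np.where(
                hom,
                (x == cc) * pc,
                (x == cc) * pd_ + (x == dd) * pc,
            )

        t = (trans(aa) + trans(bb)) / 2.0
        same = ((aa == cc) & (bb == dd)) | ((aa == dd) & (bb == cc))
        P[ok, l, 0] = (p_gi * p_gj)[ok]
        P[ok, l, 1] = (p_gi * t)[ok]
        P[ok, l, 2] = (p_gi * same)[ok]
    return P, valid


def _pair_blocks(n: int) -> np.ndarray:
    iu = np.triu_indices(n, k=1)
    return np.column_stack(iu)


def kinship_mle(
    gm: GenotypeMatrix,
    freqs: pd.DataFrame | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    block: int = 4000,
    return_k: bool = False,
) -> KinshipMatrix | tuple[KinshipMatrix, pd.DataFrame]:
    """Pairwise maximum-likelihood IBD coefficients by EM.

    For each pair, (k0, k1, k2) maximize the product over loci of
    sum_m k_m P(G_i, G_j | m IBD alleles); EM starts at (1/3, 1/3, 1/3),
    runs at most ``max_iter`` iterations to a log-likelihood tolerance of
    ``tol``. Coancestry = k1/4 + k2/2; the diagonal is the self-coancestry
    1/2 (no inbreeding assumed). Non-converged pairs keep the last iterate
    (a warning is emitted). With ``return_k`` the per-pair fitted
    (k0, k1, k2) come back as a second, long-format table.
    """
    pairs_view = gm.allele_pairs()
    plist = _locus_freq_arrays(gm, freqs)
    n = gm.n_individuals
    ij = _pair_blocks(n)
    values = np.full((n, n), 0.5)
    k_all = np.zeros((len(ij), 3))
    n_unconverged = 0
    for b0 in range(0, len(ij), block):
        blk = ij[b0:b0 + block]
        P, valid = _ibd_tables(pairs_view[blk[:, 0]], pairs_view[blk[:, 1]], plist)
        k = np.full((len(blk), 3), 1.0 / 3.0)
        P = np.where(valid[:, :, None], P, 1.0)
        prev_ll = np.full(len(blk), -np.inf)
        converged = np.zeros(len(blk), dtype=bool)
        active = np.arange(len(blk))
        Pa, va, cnta = P, valid, np.maximum(valid.sum(axis=1), 1)[:, None]
        for _ in range(max_iter):
            mix = np.einsum("plm,pm->pl", Pa, k[active])
            mix = np.maximum(mix, 1e-300)
            ll = np.where(va, np.log(mix), 0.0).sum(axis=1)
            gamma = Pa * k[active][:, None, :] / mix[:, :, None]
            gamma = np.where(va[:, :, None], gamma, 0.0)
            k_new = gamma.sum(axis=1) / cnta
            k_new /= k_new.sum(axis=1, keepdims=True)
            done = np.abs(ll - prev_ll[active]) < tol
            prev_ll[active] = ll
            k[active] = k_new
            converged[active] = done
            if done.all():
                break
            # shrink the active set to unconverged pairs
            if done.any():
                keep = ~done
                active = active[keep]
                Pa, va, cnta = Pa[keep], va[keep], cnta[keep]
        n_unconverged += int((~converged).sum())
        coa = k[:, 1] / 4.0 + k[:, 2] / 2.0
        values[blk[:, 0], blk[:, 1]] = coa
        values[blk[:, 1], blk[:, 0]] = coa
        k_all[b0:b0 + len(blk)] = k
    if n_unconverged:
        warnings.warn(f"MLE kinship: {n_unconverged} pairs not converged "
                      f"after {max_iter} EM iterations", stacklevel=2)
    km = KinshipMatrix(gm.ind_ids, values, "MLE")
    if return_k:
        ids = np.array(gm.ind_ids)
        ktab = pd.DataFrame({
            "ind_a": ids[ij[:, 0]], "ind_b": ids[ij[:, 1]],
            "k0": k_all[:, 0], "k1": k_all[:, 1], "k2": k_all[:, 2],
        })
        return km, ktab
    return km


def pair_loglikelihoods(
    gm: GenotypeMatrix,
    pair_idx: np.ndarray,
    freqs: pd.DataFrame | None = None,
) -> dict[str, np.ndarray]:
    """Log-likelihood of each canonical relationship for a set of pairs."""
    pairs_view = gm.allele_pairs()
    plist = _locus_freq_arrays(gm, freqs)
    P, valid = _ibd_tables(pairs_view[pair_idx[:, 0]], pairs_view[pair_idx[:, 1]],
                           plist)
    out = {}
    for name, kvec in _RELATIONSHIP_K.items():
        mix = np.einsum("plm,m->pl", P, np.array(kvec))
        with np.errstate(divide="ignore"):
            lg = np.where(valid, np.log(np.maximum(mix, 0.0)), 0.0)
            lg = np.where(valid & (mix <= 0.0), -np.inf, lg)
        out[name] = lg.sum(axis=1)
    return out


def classify_relationship(
    gm: GenotypeMatrix,
    ind_a: str,
    ind_b: str,
    freqs: pd.DataFrame | None = None,
) -> RelationshipCall:
    """Best-supported relationship category for one pair.

    Loci with an opposite-homozygote genotype drive the parent-offspring
    log-likelihood to -inf (Mendelian exclusion). With fewer than 20
    informative loci a soft warning is raised.
    """
    pos = {iid: i for i, iid in enumerate(gm.ind_ids)}
    idx = np.array([[pos[ind_a], pos[ind_b]]])
    n_informative = int(np.sum(
        (gm.allele_pairs()[idx[0, 0], :, 0] != MISSING_ALLELE)
        & (gm.allele_pairs()[idx[0, 1], :, 0] != MISSING_ALLELE)))
    if n_informative < 20:
        warnings.warn(f"only {n_informative} informative loci for pair "
                      f"({ind_a}, {ind_b})", stacklevel=2)
    lls = pair_loglikelihoods(gm, idx, freqs)
    return RelationshipCall((ind_a, ind_b), {k: float(v[0]) for k, v in lls.items()})


def classify_pairs(
    gm: GenotypeMatrix,
    pair_idx: np.ndarray,
    freqs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Vectorized relationship classification for many pairs at once."""
    lls = pair_loglikelihoods(gm, pair_idx, freqs)
    order = ("U", "HS", "FS", "PO")
    M = np.column_stack([lls[c] for c in order])
    best = np.array(order)[np.argmax(M, axis=1)]
    ids = np.array(gm.ind_ids)
    return pd.DataFrame({
        "ind_a": ids[pair_idx[:, 0]],
        "ind_b": ids[pair_idx[:, 1]],
        **{f"ll_{c}": lls[c] for c in order},
        "best": best,
        "first_degree": np.isin(best, ("PO", "FS")),
    })


# ---------------------------------------------------------------------------
# Estimator selection
# ---------------------------------------------------------------------------


def select_estimator_by_interchrom_ld(
    gm: GenotypeMatrix,
    candidates: Sequence[KinshipMatrix],
    min_maf: float = 0.05,
) -> tuple[str, pd.DataFrame]:
    """Pick the estimator whose kinship correction leaves the least
    inter-chromosomal LD.

    For each candidate kinship matrix the mean r2_V over all SNP pairs on
    different chromosomes (MAF >= ``min_maf``) is computed; true LD between
    unlinked loci is null, so the smallest mean indicates the least-biased
    correction. Ties break by the canonical tag order
    AIS < WAIS2 < WAIS4 < BNO < LOI < MLE (unknown tags last).
    """
    from .corrected_ld import mean_interchromosomal_ld

    chroms = {l.chrom for l in gm.snp_loci}
    if len(chroms) < 2:
        raise ValueError("need SNPs on >= 2 chromosomes")
    rows = []
    for cand in candidates:
        mean_ld = mean_interchromosomal_ld(gm, K=cand.values, min_maf=min_maf,
                                           ld_column="r2_V")
        rows.append((cand.estimator, mean_ld))
    report = pd.DataFrame(rows, columns=["estimator", "mean_interchrom_r2_V"])

    def rank(tag: str) -> int:
        return ESTIMATOR_ORDER.index(tag) if tag in ESTIMATOR_ORDER else 99

    best = min(rows, key=lambda r: (r[1], rank(r[0])))
    return best[0], report
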