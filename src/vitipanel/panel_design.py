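"""Structure-aware association-panel design and representativeness checks.

The design workflow, per subgroup of a structured collection: keep the non-
or low-admixed candidates (maximum structure membership above a threshold,
0.8 by default), seed the selection with the mandatory founder accessions,
fill up to the target size by a greedy maximin rule on the simple-matching
dissimilarity (each step adds the candidate farthest, in min-dissimilarity
terms, from the current selection), then classify all within-panel pairs
with the likelihood relationship classifier and iteratively remove / refill
until no first-degree pair remains (founders are never removed).

Representativeness of the resulting panel against the full collection is
assessed by allele retention above a rarity threshold, squared correlation
of allele frequencies, rank-sum mean-equality and Brown-Forsythe
variance-equality tests per phenotype, and the captured variance fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import allele_frequencies
from .genotypes_io import (
    MISSING_ALLELE,
    GenotypeMatrix,
    StructureMatrix,
    filter_individuals,
)
from .kinship import classify_pairs, kinship_ais


@dataclass
class PanelSelection:
    """Selected accessions per subgroup, with the pruning iteration log."""

    selected: dict[str, list[str]]
    mandatory: set[str]
    target_size: int
    log: list[dict] = field(default_factory=list)

    @property
    def all_ids(self) -> list[str]:
        return [i for ids in self.selected.values() for i in ids]

    def to_frame(self) -> pd.DataFrame:
        rows = [(i, g) for g, ids in self.selected.items() for i in ids]
        return pd.DataFrame(rows, columns=["ind_id", "subgroup"])


@dataclass
class RepresentativenessReport:
    """Panel-vs-collection genetic and phenotypic representativeness."""

    allele_retention: float
    freq_correlation_r2: float
    trait_tests: pd.DataFrame  # per trait: rank-sum & variance tests, captured var
    n_panel: int
    n_collection: int


def simple_matching_dissimilarity(gm: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise simple-matching dissimilarity over all loci.

    Per locus a pair contributes the fraction of shared alleles between the
    two unordered genotypes (1 identical, 0.5 one allele shared, 0 none);
    the dissimilarity is one minus the average over loci non-missing in
    both. Symmetric with a zero diagonal.
    """
    if gm.n_individuals < 2:
        raise ValueError("need >= 2 individuals")
    pairs = gm.allele_pairs()
    a = pairs[:, :, 0]
    b = pairs[:, :, 1]
    valid = a != MISSING_ALLELE
    n = gm.n_individuals
    out = np.zeros((n, n))
    for i in range(n):
        ai, bi = a[i], b[i]
        # shared-allele fraction between the unordered genotypes {ai,bi}
        # and {a,b}: 1 if both alleles pair up, 0.5 if exactly one does
        eq_aa = ai == a
        eq_ab = ai == b
        eq_ba = bi == a
        eq_bb = bi == b
        full = (eq_aa & eq_bb) | (eq_ab & eq_ba)
        one_shared = (~full) & (eq_aa | eq_ab | eq_ba | eq_bb)
        share = np.where(full, 1.0, np.where(one_shared, 0.5, 0.0))
        v = valid[i][None, :] & valid
        cnt = v.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[i] = 1.0 - np.where(v, share, 0.0).sum(axis=1) / cnt
    if np.isnan(out).any():
        warnings.warn("pairs with no shared typed loci have missing "
                      "dissimilarity", stacklevel=2)
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=gm.ind_ids, columns=gm.ind_ids)


def maximin_subsample(
    D: pd.DataFrame, m: int, mandatory: Sequence[str] = ()
) -> list[str]:
    """Greedy diversity-maximizing subsample of size ``m``.

    Starts from the mandatory set (or, if empty, the globally most distant
    pair) and repeatedly adds the candidate with the largest minimum
    dissimilarity to the current selection; ties break to the
    lexicographically smallest id. Deterministic and invariant to candidate
    input order.
    """
    ids = sorted(D.index)
    mandatory = sorted(set(mandatory))
    if not set(mandatory) <= set(ids):
        raise ValueError("mandatory ids missing from the dissimilarity matrix")
    if m < len(mandatory):
        raise ValueError("target size smaller than the mandatory set")
    if m > len(ids):
        raise ValueError(f"target size {m} exceeds {len(ids)} candidates")
    Dm = D.loc[ids, ids].to_numpy(dtype=float)
    pos = {x: i for i, x in enumerate(ids)}
    selected: list[str] = list(mandatory)
    if not selected and m > 0:
        iu = np.triu_indices(len(ids), k=1)
        best = np.argmax(Dm[iu])
        i, j = iu[0][best], iu[1][best]
        pair = sorted([ids[i], ids[j]])
        selected = pair[: min(2, m)]
    chosen = np.zeros(len(ids), dtype=bool)
    for s in selected:
        chosen[pos[s]] = True
    mind = np.full(len(ids), np.inf)
    for s in selected:
        mind = np.minimum(mind, Dm[pos[s]])
    while len(selected) < m:
        mind_masked = np.where(chosen, -np.inf, mind)
        best_val = np.nanmax(mind_masked)
        # ids are sorted, so argmax picks the lexicographically smallest tie
        k = int(np.argmax(mind_masked == best_val))
        selected.append(ids[k])
        chosen[k] = True
        mind = np.minimum(mind, Dm[k])
    return selected


def design_panel(
    gm: GenotypeMatrix,
    q: StructureMatrix,
    founders: Sequence[str] = (),
    subgroup_size: int = 93,
    freqs: pd.DataFrame | None = None,
    min_membership: float = 0.8,
    max_iter: int = 50,
) -> PanelSelection:
    """Run the full panel-design workflow on a collection.

    Wild-type groups are included only if candidates are assigned to them
    by the structure matrix; each structure group with enough candidates is
    filled to ``subgroup_size``. Pruning removes, from each first-degree
    pair, the non-founder member with the larger mean kinship to the rest
    of the subgroup selection, then refills by maximin; founders are never
    removed (a founder-founder first-degree pair is flagged and kept).
    """
    founders = set(founders)
    filtered = filter_individuals(gm, min_membership=min_membership, q=q)
    if freqs is None:
        freqs = allele_frequencies(gm)
    D_all = simple_matching_dissimilarity(filtered)
    K_all = kinship_ais(filtered)
    kin = K_all.as_frame()
    pos = {iid: i for i, iid in enumerate(filtered.ind_ids)}
    by_group: dict[str, list[str]] = {}
    for ind in filtered.individuals:
        by_group.setdefault(ind.subgroup, []).append(ind.ind_id)

    selected: dict[str, list[str]] = {}
    log: list[dict] = []
    for g, cand in sorted(by_group.items()):
        if len(cand) < subgroup_size:
            raise ValueError(
                f"subgroup {g}: {len(cand)} candidates < target {subgroup_size}")
        g_found = sorted(founders & set(cand))
        Dg = D_all.loc[cand, cand]
        pool = set(cand)
        sel = maximin_subsample(Dg, subgroup_size, g_found)
        for it in range(max_iter):
            idx = np.array([[pos[a], pos[b]]
                            for i, a in enumerate(sel)
                            for b in sel[i + 1:]])
            calls = classify_pairs(filtered, idx, freqs)
            fd = calls[calls["first_degree"]]
            fd_nonprotected = []
            for _, row in fd.iterrows():
                a, b = row["ind_a"], row["ind_b"]
                if a in founders and b in founders:
                    log.append({"iteration": it, "event": "founder_pair_kept",
                                "pair": (a, b)})
                    continue
                fd_nonprotected.append((a, b))
            if not fd_nonprotected:
                log.append({"iteration": it, "event": "clean", "group": g,
                            "n_first_degree": int(len(fd))})
                break
            removed = []
            for a, b in fd_nonprotected:
                if a not in sel or b not in sel:
                    continue  # already removed via another pair
                if a in founders:
                    victim = b
                elif b in founders:
                    victim = a
                else:
                    rest = [x for x in sel if x not in (a, b)]
                    ka = kin.loc[a, rest].mean()
                    kb = kin.loc[b, rest].mean()
                    victim = a if ka >= kb else b
                sel.remove(victim)
                pool.discard(victim)
                removed.append(victim)
            log.append({"iteration": it, "event": "pruned", "group": g,
                        "removed": removed})
            if len(pool) < subgroup_size:
                raise ValueError(
                    f"subgroup {g}: candidates exhausted "
                    f"({len(pool)} left, {subgroup_size} needed)")
            sel = maximin_subsample(D_all.loc[sorted(pool), sorted(pool)],
                                    subgroup_size, sorted(set(sel) | set(g_found)))
        selected[g] = sel
    return PanelSelection(selected=selected, mandatory=founders,
                          target_size=subgroup_size, log=log)


def _rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Wilcoxon rank-sum with normal approximation and tie correction."""
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def assess_representativeness(
    panel_ids: Sequence[str],
    collection: GenotypeMatrix,
    phenotypes: pd.DataFrame | None = None,
    rare_maf: float = 0.05,
) -> RepresentativenessReport:
    """Compare a panel against its source collection.

    Allele retention counts, among collection alleles with frequency above
    ``rare_maf``, the fraction present in the panel; the frequency
    correlation is the squared Pearson correlation of the allele frequency
    vectors. Phenotype columns (indexed by ind_id) are compared by the
    rank-sum mean-equality test, the Brown-Forsythe (median-centred Levene)
    variance-equality test, and the captured variance ratio.
    """
    panel_ids = list(panel_ids)
    if not set(panel_ids) <= set(collection.ind_ids):
        raise ValueError("panel ids must be a subset of the collection")
    pos = {iid: i for i, iid in enumerate(collection.ind_ids)}
    panel = collection.subset(ind_idx=[pos[i] for i in panel_ids])

    f_coll = allele_frequencies(collection).set_index(["locus_id", "allele"])
    f_pan = allele_frequencies(panel).set_index(["locus_id", "allele"])
    joined = f_coll.join(f_pan, how="left", lsuffix="_coll", rsuffix="_panel")
    joined["freq_panel"] = joined["freq_panel"].fillna(0.0)
    non_rare = joined[joined["freq_coll"] > rare_maf]
    retention = float((non_rare["freq_panel"] > 0).mean()) if len(non_rare) else np.nan
    if len(joined) > 1:
        r = np.corrcoef(joined["freq_coll"], joined["freq_panel"])[0, 1]
        freq_r2 = float(r ** 2)
    else:
        freq_r2 = np.nan

    rows = []
    if phenotypes is not None:
        for trait in phenotypes.columns:
            y_coll = phenotypes[trait].dropna()
            y_pan = y_coll[y_coll.index.isin(panel_ids)]
            if len(y_pan) < 3:
                warnings.warn(f"trait {trait!r}: fewer than 3 panel values; "
                              "skipped", stacklevel=2)
                continue
            u, p_mean = _rank_sum_test(y_pan.to_numpy(), y_coll.to_numpy())
            w, p_var = stats.levene(y_pan.to_numpy(), y_coll.to_numpy(),
                                    center="median")
            cap = float(np.var(y_pan, ddof=1) / np.var(y_coll, ddof=1))
            rows.append((trait, u, p_mean, float(w), float(p_var), cap))
    trait_tests = pd.DataFrame(
        rows, columns=["trait", "ranksum_stat", "ranksum_p",
                       "levene_stat", "levene_p", "variance_captured"])
    return RepresentativenessReport(
        allele_retention=retention,
        freq_correlation_r2=freq_r2,
        trait_tests=trait_tests,
        n_panel=len(panel_ids),
        n_collection=collection.n_individuals,
    )
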