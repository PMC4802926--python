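"""Per-locus diversity statistics and pairwise group differentiation.

Statistics follow the standard population-genetics definitions on allele
frequencies p_i estimated from non-missing calls: expected heterozygosity
He = 1 - sum(p_i^2) (= Nei's gene diversity), effective allele number
Ne = 1 / sum(p_i^2), observed heterozygosity Ho, allele count Na and minor
allele frequency. Differentiation uses the Weir & Cockerham (1984) theta
estimator with ratio-of-sums averaging over loci and alleles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes_io import MISSING_ALLELE, GenotypeMatrix, group_indices


@dataclass
class FstMatrix:
    """Pairwise Weir & Cockerham theta between groups (diagonal 0)."""

    group_labels: list[str]
    values: np.ndarray
    per_locus: pd.DataFrame | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.group_labels,
                            columns=self.group_labels)


def _locus_spectra(gm: GenotypeMatrix, idx: np.ndarray) -> list[dict[int, float]]:
    """Allele frequency spectrum per locus from the allele-pair view."""
    pairs = gm.allele_pairs()[idx]
    out = []
    for k in range(gm.n_loci):
        calls = pairs[:, k, :].ravel()
        calls = calls[calls != MISSING_ALLELE]
        if calls.size == 0:
            out.append({})
            continue
        alleles, counts = np.unique(calls, return_counts=True)
        tot = counts.sum()
        out.append({int(a): c / tot for a, c in zip(alleles, counts)})
    return out


def allele_frequencies(
    gm: GenotypeMatrix, group: str | None = None,
    groups: dict[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Long-format allele frequency table (locus_id, allele, freq).

    Frequencies come from non-missing calls only and sum to 1 per locus;
    for SNPs allele 1 is the alt allele (so its row is the alt frequency).
    A locus with all calls missing yields no rows.
    """
    if group is None:
        idx = np.arange(gm.n_individuals)
    else:
        gidx = group_indices(gm, groups)
        if group not in gidx or len(gidx[group]) < 2:
            raise ValueError(f"group {group!r} absent or has < 2 individuals")
        idx = gidx[group]
    spectra = _locus_spectra(gm, idx)
    rows = []
    for loc, spec in zip(gm.loci, spectra):
        for a in sorted(spec):
            rows.append((loc.locus_id, a, spec[a]))
    return pd.DataFrame(rows, columns=["locus_id", "allele", "freq"])


def _ho(gm: GenotypeMatrix, idx: np.ndarray) -> np.ndarray:
    pairs = gm.allele_pairs()[idx]
    ok = pairs[:, :, 0] != MISSING_ALLELE
    het = (pairs[:, :, 0] != pairs[:, :, 1]) & ok
    with np.errstate(invalid="ignore"):
        return np.where(ok.sum(0) > 0, het.sum(0) / np.maximum(ok.sum(0), 1), np.nan)


def diversity_stats(
    gm: GenotypeMatrix, groups: dict[str, Sequence[str]] | None = None,
    by_group: bool = True,
) -> pd.DataFrame:
    """Per-locus (and per-group) Na, Ne, He, Ho, MAF and Nei's diversity.

    A monomorphic locus has He = 0 and Ne = 1. Group means over loci are
    appended as rows with locus_id '<mean>'. With ``by_group`` False (or no
    subgroup labels) a single pooled 'all' group is used.
    """
    gidx = group_indices(gm, groups) if by_group else {}
    if not gidx:
        gidx = {"all": np.arange(gm.n_individuals)}
    rows = []
    for glab, idx in sorted(gidx.items()):
        spectra = _locus_spectra(gm, idx)
        ho = _ho(gm, idx)
        for k, loc in enumerate(gm.loci):
            spec = spectra[k]
            if not spec:
                rows.append((glab, loc.locus_id, *([np.nan] * 6)))
                continue
            p = np.array(list(spec.values()))
            sum_p2 = float(np.sum(p ** 2))
            he = 1.0 - sum_p2
            ne = 1.0 / sum_p2
            maf = 1.0 - p.max() if len(p) > 1 else 0.0
            if loc.locus_type == "snp":
                maf = min(spec.get(1, 0.0), 1.0 - spec.get(1, 0.0))
            rows.append((glab, loc.locus_id, len(p), ne, he, ho[k], maf, he))
    df = pd.DataFrame(
        rows, columns=["group", "locus_id", "Na", "Ne", "He", "Ho", "MAF", "Nei"]
    )
    means = (
        df.groupby("group")[["Na", "Ne", "He", "Ho", "MAF", "Nei"]]
        .mean()
        .reset_index()
    )
    means.insert(1, "locus_id", "<mean>")
    return pd.concat([df, means], ignore_index=True)


def snp_density(n_snps: int, total_bp: int, per_bp: int = 100) -> float:
    """Discovered-SNP density: SNPs per ``per_bp`` bases of aligned sequence."""
    if total_bp <= 0:
        raise ValueError("total_bp must be positive")
    return n_snps / total_bp * per_bp


def _wc_components(
    spectra_by_group: list[list[dict[int, float]]],
    het_by_group: list[list[dict[int, float]]],
    n_by_group: list[np.ndarray],
    n_loci: int,
) -> tuple[float, float]:
    """Summed Weir-Cockerham a and a+b+c over loci and alleles for r groups."""
    num = den = 0.0
    r = len(spectra_by_group)
    for k in range(n_loci):
        ns = np.array([n_by_group[g][k] for g in range(r)], dtype=float)
        if np.any(ns < 2):
            continue
        alleles = sorted({a for g in range(r) for a in spectra_by_group[g][k]})
        if len(alleles) < 2:
            continue
        nbar = ns.mean()
        nc = (r * nbar - np.sum(ns ** 2) / (r * nbar)) / (r - 1)
        for a in alleles:
            p = np.array([spectra_by_group[g][k].get(a, 0.0) for g in range(r)])
            # hbar needs the per-allele heterozygote frequency, not the
            # genotype-level het fraction
            h = np.array([het_by_group[g][k].get(a, 0.0) for g in range(r)])
            pbar = np.sum(ns * p) / (r * nbar)
            s2 = np.sum(ns * (p - pbar) ** 2) / ((r - 1) * nbar)
            hbar = np.sum(ns * h) / (r * nbar)
            av = (nbar / nc) * (
                s2
                - (1.0 / (nbar - 1))
                * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
            )
            bv = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            cv = hbar / 2.0
            num += av
            den += av + bv + cv
    return num, den


def _group_summaries(gm: GenotypeMatrix, idx: np.ndarray):
    """Per-locus spectra, per-allele heterozygote frequencies, sample sizes."""
    pairs = gm.allele_pairs()[idx]
    spectra = []
    het_freqs = []
    ns = np.zeros(gm.n_loci, dtype=int)
    for k in range(gm.n_loci):
        g = pairs[:, k, :]
        ok = g[:, 0] != MISSING_ALLELE
        ns[k] = int(ok.sum())
        g = g[ok]
        calls = g.ravel()
        if calls.size == 0:
            spectra.append({})
            het_freqs.append({})
            continue
        alleles, counts = np.unique(calls, return_counts=True)
        tot = counts.sum()
        spectra.append({int(a): c / tot for a, c in zip(alleles, counts)})
        het = g[g[:, 0] != g[:, 1]]
        hf: dict[int, float] = {}
        for a in alleles:
            hf[int(a)] = np.sum((het[:, 0] == a) | (het[:, 1] == a)) / len(g)
        het_freqs.append(hf)
    return spectra, het_freqs, ns


def pairwise_fst(
    gm: GenotypeMatrix, groups: dict[str, Sequence[str]] | None = None
) -> FstMatrix:
    """Pairwise Weir & Cockerham (1984) theta between groups.

    Theta is the ratio of summed among-group variance components to summed
    total components over all loci and alleles (ratio-of-sums averaging).
    Negative estimates are reported as computed. Groups of size < 2 are
    excluded with a warning. The estimator is invariant to allele
    relabelling by construction (it sums symmetric per-allele components).
    """
    gidx = group_indices(gm, groups)
    labels = sorted(gidx)
    keep = []
    for g in labels:
        if len(gidx[g]) < 2:
            warnings.warn(f"pairwise_fst: group {g!r} has < 2 individuals; excluded",
                          stacklevel=2)
        else:
            keep.append(g)
    labels = keep
    summ = {g: _group_summaries(gm, gidx[g]) for g in labels}
    m = len(labels)
    vals = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            gi, gj = labels[i], labels[j]
            num, den = _wc_components(
                [summ[gi][0], summ[gj][0]],
                [summ[gi][1], summ[gj][1]],
                [summ[gi][2], summ[gj][2]],
                gm.n_loci,
            )
            theta = num / den if den > 0 else np.nan
            vals[i, j] = vals[j, i] = theta
    return FstMatrix(labels, vals)
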