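"""Genotype containers, readers/writers, and filtering.

The shared data model of the package: diploid individuals typed at biallelic
SNPs (dosage-coded 0 / 0.5 / 1 for hom-ref / het / hom-alt) and/or multiallelic
SSR-like loci (two integer allele labels per locus). Coordinates are 1-based;
physical distance between loci is ``|pos_i - pos_j|`` in bp; genotypes are
unphased throughout.

Supported on-disk formats:

* VCF (read via :mod:`cyvcf2`, written as plain VCFv4.2 text; GT-only,
  biallelic records only);
* tab-delimited dosage table: ``ind_id`` plus one column per SNP;
* tab-delimited SSR table: ``ind_id`` plus two columns ``<locus>_a1`` /
  ``<locus>_a2`` per locus, blank or NA = missing;
* locus map: tab-delimited ``locus_id  chrom  pos_bp  locus_type
  region_label`` (1-based positions);
* individual metadata: ``ind_id  subgroup  founder  q1..qK``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING_ALLELE = -1

_DOSAGE_ALPHABET = (0.0, 0.5, 1.0)


class GenotypeError(ValueError):
    """Malformed or inconsistent genotype input."""


@dataclass
class LocusInfo:
    """One marker locus: identifier, 1-based physical position, type."""

    locus_id: str
    chrom: str
    pos_bp: int
    locus_type: str = "snp"  # 'snp' | 'ssr'
    region_label: str | None = None

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise GenotypeError(f"locus {self.locus_id}: pos_bp must be >= 1")
        if self.locus_type not in ("snp", "ssr"):
            raise GenotypeError(f"locus {self.locus_id}: bad type {self.locus_type!r}")


@dataclass
class IndividualInfo:
    """One accession: identifier, optional subgroup, founder flag, Q row."""

    ind_id: str
    subgroup: str | None = None
    founder: bool = False
    membership: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.membership is not None:
            m = np.asarray(self.membership, dtype=float)
            if m.ndim != 1 or np.any(m < -1e-8) or np.any(m > 1 + 1e-8):
                raise GenotypeError(f"{self.ind_id}: membership outside [0,1]")
            if abs(m.sum() - 1.0) > 1e-8:
                raise GenotypeError(f"{self.ind_id}: membership does not sum to 1")
            self.membership = m


@dataclass
class StructureMatrix:
    """N x K matrix of structure membership coefficients (rows sum to 1)."""

    Q: np.ndarray
    group_labels: list[str]

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        if self.Q.ndim != 2 or self.Q.shape[1] != len(self.group_labels):
            raise GenotypeError("Q shape does not match group labels")
        if np.any(self.Q < -1e-8) or np.any(self.Q > 1 + 1e-8):
            raise GenotypeError("Q entries outside [0,1]")
        if np.any(np.abs(self.Q.sum(axis=1) - 1.0) > 1e-8):
            raise GenotypeError("Q rows must sum to 1")

    @property
    def n_individuals(self) -> int:
        return self.Q.shape[0]


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid genotype matrix.

    ``loci`` lists SNP and SSR loci in display order; SNP loci map, in order,
    to columns of ``snp_dosage`` (values in {0, 0.5, 1}, NaN = missing) and
    SSR loci to slabs of ``ssr_calls`` (shape N x L_ssr x 2 of integer allele
    labels, -1 = missing).
    """

    individuals: list[IndividualInfo]
    loci: list[LocusInfo]
    snp_dosage: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    ssr_calls: np.ndarray = field(default_factory=lambda: np.empty((0, 0, 2), dtype=int))

    def __post_init__(self) -> None:
        n = len(self.individuals)
        self.snp_dosage = np.asarray(self.snp_dosage, dtype=float)
        self.ssr_calls = np.asarray(self.ssr_calls, dtype=int)
        if self.snp_dosage.size == 0:
            self.snp_dosage = self.snp_dosage.reshape(n, 0)
        if self.ssr_calls.size == 0:
            self.ssr_calls = self.ssr_calls.reshape(n, 0, 2)
        n_snp = sum(1 for l in self.loci if l.locus_type == "snp")
        n_ssr = sum(1 for l in self.loci if l.locus_type == "ssr")
        if self.snp_dosage.shape != (n, n_snp):
            raise GenotypeError(
                f"snp_dosage shape {self.snp_dosage.shape} != ({n}, {n_snp})"
            )
        if self.ssr_calls.shape != (n, n_ssr, 2):
            raise GenotypeError(
                f"ssr_calls shape {self.ssr_calls.shape} != ({n}, {n_ssr}, 2)"
            )
        finite = self.snp_dosage[~np.isnan(self.snp_dosage)]
        if finite.size and not np.all(np.isin(finite, _DOSAGE_ALPHABET)):
            bad = finite[~np.isin(finite, _DOSAGE_ALPHABET)]
            raise GenotypeError(f"dosage values outside {{0, 0.5, 1}}: {bad[:5]}")
        ids = [i.ind_id for i in self.individuals]
        if len(set(ids)) != len(ids):
            raise GenotypeError("duplicated ind_id")
        lids = [l.locus_id for l in self.loci]
        if len(set(lids)) != len(lids):
            raise GenotypeError("duplicated locus_id")

    # -- basic accessors -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def ind_ids(self) -> list[str]:
        return [i.ind_id for i in self.individuals]

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    @property
    def snp_loci(self) -> list[LocusInfo]:
        return [l for l in self.loci if l.locus_type == "snp"]

    @property
    def ssr_loci(self) -> list[LocusInfo]:
        return [l for l in self.loci if l.locus_type == "ssr"]

    def locus_missingness(self) -> np.ndarray:
        """Per-locus missing-call fraction, in ``loci`` order."""
        out = np.empty(self.n_loci)
        i_snp = i_ssr = 0
        for k, loc in enumerate(self.loci):
            if loc.locus_type == "snp":
                out[k] = np.mean(np.isnan(self.snp_dosage[:, i_snp]))
                i_snp += 1
            else:
                out[k] = np.mean(self.ssr_calls[:, i_ssr, 0] == MISSING_ALLELE)
                i_ssr += 1
        return out

    def individual_missingness(self) -> np.ndarray:
        miss = np.zeros(self.n_individuals)
        total = self.n_loci
        if total == 0:
            return miss
        cnt = np.sum(np.isnan(self.snp_dosage), axis=1).astype(float)
        cnt += np.sum(self.ssr_calls[:, :, 0] == MISSING_ALLELE, axis=1)
        return cnt / total

    def locus_maf(self) -> np.ndarray:
        """Per-locus minor allele frequency.

        SNPs: min(p, 1-p) of the alt-allele frequency. Multiallelic SSRs:
        1 - max allele frequency (the frequency mass carried by non-major
        alleles), so the same threshold semantics apply to both types.
        """
        out = np.full(self.n_loci, np.nan)
        i_snp = i_ssr = 0
        for k, loc in enumerate(self.loci):
            if loc.locus_type == "snp":
                col = self.snp_dosage[:, i_snp]
                ok = ~np.isnan(col)
                if ok.any():
                    p = col[ok].mean()
                    out[k] = min(p, 1.0 - p)
                i_snp += 1
            else:
                calls = self.ssr_calls[:, i_ssr, :].ravel()
                calls = calls[calls != MISSING_ALLELE]
                if calls.size:
                    _, counts = np.unique(calls, return_counts=True)
                    out[k] = 1.0 - counts.max() / counts.sum()
                i_ssr += 1
        return out

    def allele_pairs(self) -> np.ndarray:
        """Unified (N, L, 2) integer allele-pair view over all loci.

        SNP dosages are expanded to ref/alt label pairs (0-ref, 1-alt);
        missing calls are (-1, -1). SSR slabs are passed through.
        """
        n, L = self.n_individuals, self.n_loci
        out = np.full((n, L, 2), MISSING_ALLELE, dtype=int)
        i_snp = i_ssr = 0
        for k, loc in enumerate(self.loci):
            if loc.locus_type == "snp":
                d = self.snp_dosage[:, i_snp]
                ok = ~np.isnan(d)
                out[ok, k, 0] = (d[ok] >= 0.75).astype(int)
                out[ok, k, 1] = (d[ok] >= 0.25).astype(int)
                i_snp += 1
            else:
                out[:, k, :] = self.ssr_calls[:, i_ssr, :]
                i_ssr += 1
        return out

    def subset(
        self,
        ind_idx: Sequence[int] | None = None,
        locus_idx: Sequence[int] | None = None,
    ) -> "GenotypeMatrix":
        """Sub-matrix by positional individual / locus indices (order kept)."""
        ind_idx = np.arange(self.n_individuals) if ind_idx is None else np.asarray(ind_idx)
        locus_idx = np.arange(self.n_loci) if locus_idx is None else np.asarray(locus_idx)
        snp_pos = {k: j for j, k in enumerate(
            i for i, l in enumerate(self.loci) if l.locus_type == "snp")}
        ssr_pos = {k: j for j, k in enumerate(
            i for i, l in enumerate(self.loci) if l.locus_type == "ssr")}
        keep_snp = [snp_pos[k] for k in locus_idx if k in snp_pos]
        keep_ssr = [ssr_pos[k] for k in locus_idx if k in ssr_pos]
        return GenotypeMatrix(
            individuals=[self.individuals[i] for i in ind_idx],
            loci=[self.loci[k] for k in locus_idx],
            snp_dosage=self.snp_dosage[np.ix_(ind_idx, keep_snp)]
            if keep_snp else np.empty((len(ind_idx), 0)),
            ssr_calls=self.ssr_calls[np.ix_(ind_idx, keep_ssr)]
            if keep_ssr else np.empty((len(ind_idx), 0, 2), dtype=int),
        )

    def select_loci(self, locus_ids: Iterable[str]) -> "GenotypeMatrix":
        index = {l.locus_id: k for k, l in enumerate(self.loci)}
        return self.subset(locus_idx=[index[x] for x in locus_ids])


def combine(gm_a: GenotypeMatrix, gm_b: GenotypeMatrix) -> GenotypeMatrix:
    """Join two matrices over the same individuals, concatenating loci."""
    if gm_a.ind_ids != gm_b.ind_ids:
        raise GenotypeError("cannot combine: individual lists differ")
    return GenotypeMatrix(
        individuals=gm_a.individuals,
        loci=gm_a.loci + gm_b.loci,
        snp_dosage=np.hstack([gm_a.snp_dosage, gm_b.snp_dosage]),
        ssr_calls=np.concatenate([gm_a.ssr_calls, gm_b.ssr_calls], axis=1),
    )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_GT_TO_DOSAGE = {0: 0.0, 1: 0.5, 2: 0.5, 3: 1.0}


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    inds = [IndividualInfo(s) for s in vcf.samples]
    loci: list[LocusInfo] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise GenotypeError(
                f"{path}: multiallelic record at {var.CHROM}:{var.POS} not supported"
            )
        lid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        loci.append(LocusInfo(lid, var.CHROM, var.POS, "snp"))
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = var.gt_types
        col = np.array([_GT_TO_DOSAGE[int(g)] for g in gt])
        col[gt == 2] = np.nan
        cols.append(col)
    dosage = np.column_stack(cols) if cols else np.empty((len(inds), 0))
    return GenotypeMatrix(inds, loci, dosage)


def write_vcf(gm: GenotypeMatrix, path: Path | str) -> None:
    """Write the SNP loci of ``gm`` as a minimal GT-only VCFv4.2 text file."""
    path = Path(path)
    if gm.ssr_loci:
        raise GenotypeError("VCF output supports SNP loci only")
    code = {0.0: "0/0", 0.5: "0/1", 1.0: "1/1"}
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = sorted({l.chrom for l in gm.loci})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.ind_ids) + "\n")
        for k, loc in enumerate(gm.loci):
            gts = [
                "./." if np.isnan(d) else code[float(d)]
                for d in gm.snp_dosage[:, k]
            ]
            fh.write(
                f"{loc.chrom}\t{loc.pos_bp}\t{loc.locus_id}\tA\tG\t.\t.\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


def _read_dosage_table(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "ind_id":
        raise GenotypeError(f"{path}: first column must be 'ind_id'")
    inds = [IndividualInfo(str(s)) for s in df["ind_id"]]
    loci = [LocusInfo(c, "0", 1, "snp") for c in df.columns[1:]]
    dosage = df.iloc[:, 1:].to_numpy(dtype=float)
    return GenotypeMatrix(inds, loci, dosage)


def write_dosage_table(gm: GenotypeMatrix, path: Path | str) -> None:
    if gm.ssr_loci:
        raise GenotypeError("dosage table output supports SNP loci only")
    df = pd.DataFrame(gm.snp_dosage, columns=[l.locus_id for l in gm.loci])
    df.insert(0, "ind_id", gm.ind_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def _read_ssr_table(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "ind_id":
        raise GenotypeError(f"{path}: first column must be 'ind_id'")
    cols = list(df.columns[1:])
    names: list[str] = []
    for c in cols:
        if not (c.endswith("_a1") or c.endswith("_a2")):
            raise GenotypeError(f"{path}: SSR column {c!r} must end in _a1/_a2")
        base = c[:-3]
        if base not in names:
            names.append(base)
    for base in names:
        if f"{base}_a1" not in cols or f"{base}_a2" not in cols:
            raise GenotypeError(f"{path}: locus {base} lacks paired _a1/_a2 columns")
    inds = [IndividualInfo(str(s)) for s in df["ind_id"]]
    n = len(inds)
    calls = np.full((n, len(names), 2), MISSING_ALLELE, dtype=int)
    for j, base in enumerate(names):
        for a, col in enumerate((f"{base}_a1", f"{base}_a2")):
            v = pd.to_numeric(df[col], errors="coerce")
            ok = v.notna().to_numpy()
            calls[ok, j, a] = v[ok].astype(int)
    bad = (calls[:, :, 0] == MISSING_ALLELE) != (calls[:, :, 1] == MISSING_ALLELE)
    if bad.any():
        raise GenotypeError(f"{path}: half-missing SSR genotype")
    loci = [LocusInfo(b, "0", 1, "ssr") for b in names]
    return GenotypeMatrix(inds, loci, np.empty((n, 0)), calls)


def write_ssr_table(gm: GenotypeMatrix, path: Path | str) -> None:
    if gm.snp_loci:
        raise GenotypeError("SSR table output supports SSR loci only")
    data: dict[str, object] = {"ind_id": gm.ind_ids}
    for j, loc in enumerate(gm.loci):
        for a in (0, 1):
            col = gm.ssr_calls[:, j, a].astype(float)
            col[col == MISSING_ALLELE] = np.nan
            data[f"{loc.locus_id}_a{a + 1}"] = col
    pd.DataFrame(data).to_csv(
        path, sep="\t", index=False, na_rep="", float_format="%.0f"
    )


def read_genotypes(path: Path | str, fmt: str) -> GenotypeMatrix:
    """Read a genotype matrix in one of the supported dialects.

    ``fmt`` is one of ``vcf``, ``dosage_table`` or ``ssr_table``; see the
    module docstring for dialect details. Locus positions for the delimited
    formats default to placeholders until a locus map is attached with
    :func:`attach_locus_map`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "dosage_table":
        return _read_dosage_table(path)
    if fmt == "ssr_table":
        return _read_ssr_table(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_genotypes(gm: GenotypeMatrix, path: Path | str, fmt: str) -> None:
    if fmt == "vcf":
        write_vcf(gm, path)
    elif fmt == "dosage_table":
        write_dosage_table(gm, path)
    elif fmt == "ssr_table":
        write_ssr_table(gm, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_locus_map(path: Path | str) -> list[LocusInfo]:
    """Locus map: tab-delimited locus_id, chrom, pos_bp (1-based), locus_type,
    region_label (optional, '.' or blank = none)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        region = row.get("region_label")
        if pd.isna(region) or region in (".", ""):
            region = None
        out.append(
            LocusInfo(row["locus_id"], row["chrom"], int(row["pos_bp"]),
                      row.get("locus_type", "snp"), region)
        )
    return out


def write_locus_map(loci: Sequence[LocusInfo], path: Path | str) -> None:
    pd.DataFrame(
        {
            "locus_id": [l.locus_id for l in loci],
            "chrom": [l.chrom for l in loci],
            "pos_bp": [l.pos_bp for l in loci],
            "locus_type": [l.locus_type for l in loci],
            "region_label": [l.region_label or "." for l in loci],
        }
    ).to_csv(path, sep="\t", index=False)


def attach_locus_map(gm: GenotypeMatrix, loci: Sequence[LocusInfo]) -> GenotypeMatrix:
    """Replace placeholder locus metadata by the entries of a locus map."""
    index = {l.locus_id: l for l in loci}
    missing = [l.locus_id for l in gm.loci if l.locus_id not in index]
    if missing:
        raise GenotypeError(f"locus map lacks entries for {missing[:5]}")
    new = [replace(index[l.locus_id]) for l in gm.loci]
    for old, upd in zip(gm.loci, new):
        if upd.locus_type != old.locus_type:
            raise GenotypeError(f"locus {old.locus_id}: type mismatch with map")
    return GenotypeMatrix(gm.individuals, new, gm.snp_dosage, gm.ssr_calls)


def read_individuals(path: Path | str) -> tuple[list[IndividualInfo], StructureMatrix | None]:
    """Metadata table with columns ind_id, subgroup, founder, q1..qK."""
    df = pd.read_csv(path, sep="\t", dtype={"ind_id": str})
    qcols = [c for c in df.columns if c.startswith("q") and c[1:].isdigit()]
    inds = []
    for _, row in df.iterrows():
        sub = row.get("subgroup")
        sub = None if pd.isna(sub) else str(sub)
        q = row[qcols].to_numpy(dtype=float) if qcols else None
        inds.append(
            IndividualInfo(row["ind_id"], sub, bool(row.get("founder", False)), q)
        )
    structure = None
    if qcols:
        structure = StructureMatrix(
            df[qcols].to_numpy(dtype=float), [c for c in qcols]
        )
    return inds, structure


def write_individuals(inds: Sequence[IndividualInfo], path: Path | str) -> None:
    k = max((len(i.membership) for i in inds if i.membership is not None), default=0)
    data: dict[str, object] = {
        "ind_id": [i.ind_id for i in inds],
        "subgroup": [i.subgroup or "" for i in inds],
        "founder": [int(i.founder) for i in inds],
    }
    for j in range(k):
        data[f"q{j + 1}"] = [
            float(i.membership[j]) if i.membership is not None else np.nan
            for i in inds
        ]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def filter_loci(
    gm: GenotypeMatrix, max_missing: float = 1.0, min_maf: float = 0.0
) -> GenotypeMatrix:
    """Keep loci with missing fraction <= max_missing and MAF >= min_maf.

    Survivor order is preserved; individuals are untouched. Loci whose MAF is
    undefined (all calls missing) fail any min_maf > 0.
    """
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0,1]")
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    miss = gm.locus_missingness()
    maf = gm.locus_maf()
    keep = miss <= max_missing
    if min_maf > 0:
        keep &= ~np.isnan(maf) & (maf >= min_maf)
    if not keep.any():
        warnings.warn("filter_loci: no loci survive", stacklevel=2)
    return gm.subset(locus_idx=np.flatnonzero(keep))


def filter_individuals(
    gm: GenotypeMatrix,
    max_missing: float = 1.0,
    min_membership: float = 0.0,
    q: StructureMatrix | None = None,
) -> GenotypeMatrix:
    """Keep individuals with missing fraction <= max_missing and maximum
    structure membership >= min_membership; survivors get subgroup = the
    argmax membership group label."""
    if q is not None and q.Q.shape[0] != gm.n_individuals:
        raise GenotypeError("structure matrix does not align with individuals")
    keep = gm.individual_missingness() <= max_missing
    new_inds = list(gm.individuals)
    if q is not None:
        maxmem = q.Q.max(axis=1)
        best = q.Q.argmax(axis=1)
        keep &= maxmem >= min_membership
        new_inds = [
            replace(ind, subgroup=q.group_labels[best[i]], membership=q.Q[i].copy())
            for i, ind in enumerate(gm.individuals)
        ]
    elif min_membership > 0:
        raise GenotypeError("min_membership filter requires a structure matrix")
    out = GenotypeMatrix(new_inds, gm.loci, gm.snp_dosage, gm.ssr_calls)
    return out.subset(ind_idx=np.flatnonzero(keep))


def group_indices(gm: GenotypeMatrix, groups: dict[str, Sequence[str]] | None = None
                  ) -> dict[str, np.ndarray]:
    """Resolve a group partition to positional indices.

    ``groups`` maps label -> ind_ids; when omitted, the individuals'
    ``subgroup`` fields define the partition (unlabelled individuals are
    left out).
    """
    pos = {iid: i for i, iid in enumerate(gm.ind_ids)}
    if groups is not None:
        return {g: np.array([pos[i] for i in ids], dtype=int) for g, ids in groups.items()}
    out: dict[str, list[int]] = {}
    for i, ind in enumerate(gm.individuals):
        if ind.subgroup is not None:
            out.setdefault(ind.subgroup, []).append(i)
    return {g: np.array(v, dtype=int) for g, v in out.items()}
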