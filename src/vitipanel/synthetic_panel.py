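"""Synthetic structured germplasm panels with controlled Fst, relatedness
and distance-dependent LD.

The generator emulates the statistical structure of a clonally maintained
germplasm collection split into three cultivated subgroups plus a wild
group: subgroup allele frequencies follow the Balding-Nichols model around
ancestral frequencies; within-region LD arises from a haplotype-pool
copying model (each gamete copies along the region from a random founder
haplotype, switching to a new one with a per-bp probability, so that pairs
of close loci tend to be copied from the same founder and decay of r2 with
distance is monotone and tunable); loci distributed across chromosomes and
SSR loci are drawn independently (no LD). First-degree relative pairs
(parent-offspring, full-sib) can be injected with haplotype-level truth
retained, and phenotypes are simulated under the mixed model
Y = 1*mu + x*beta + U + E with U ~ N(0, K * sigma2_g).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotypes_io import (
    MISSING_ALLELE,
    GenotypeMatrix,
    IndividualInfo,
    LocusInfo,
    StructureMatrix,
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# Region layout mirrors a four-region candidate-gene design: four ~2 Mb
# windows with 86-109 genotyped SNPs each, plus genome-distributed SNPs.
_DEFAULT_REGIONS = (
    ("chr8", 14_529_243, 2_000_000, 86),
    ("chr9", 3_040_957, 2_000_000, 97),
    ("chr12", 18_728_014, 2_000_000, 80),
    ("chr17", 5_195_037, 2_000_000, 109),
)


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic panel.

    Defaults reproduce the reference study conditions: subgroups WE/WW/TE
    of 90/92/90 cultivars plus 62 wild accessions; subgroup differentiation
    in the 0.01-0.09 Fst range; four 2 Mb regions with 86-109 SNPs; 129
    genome-distributed SNPs; 20 SSR loci with 8-15 alleles. ``switch_rate``
    (per bp) sets the LD decay scale: the chance that two loci d bp apart
    are copied from the same founder haplotype is exp(-switch_rate * d).
    """

    seed: int = 0
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"WE": 90, "WW": 92, "TE": 90, "wild": 62}
    )
    fst_targets: dict[str, float] = field(
        default_factory=lambda: {"WE": 0.02, "WW": 0.04, "TE": 0.06, "wild": 0.09}
    )
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    regions: tuple[tuple[str, int, int, int], ...] = _DEFAULT_REGIONS
    n_distributed_snps: int = 129
    n_ssr: int = 20
    ssr_allele_range: tuple[int, int] = (8, 15)
    haplotype_pool_size: dict[str, int] = field(
        default_factory=lambda: {"WE": 8, "WW": 8, "TE": 8, "wild": 4}
    )
    switch_rate: float = 1e-5
    related_pairs: dict[str, dict[str, int]] = field(default_factory=dict)
    q_blur: float = 0.0  # Dirichlet concentration on the true group; 0 = indicator

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.group_sizes.values()):
            raise ConfigError("group sizes must be >= 0")
        if any(not 0 <= f < 0.5 for f in self.fst_targets.values()):
            raise ConfigError("fst targets must lie in [0, 0.5)")
        if self.switch_rate <= 0:
            raise ConfigError("switch_rate must be > 0")
        for chrom, start, length, n in self.regions:
            if n > length:
                raise ConfigError(f"{chrom}: {n} SNPs exceed region length {length}")
        for g, kinds in self.related_pairs.items():
            if any(v < 0 for v in kinds.values()):
                raise ConfigError("related pair counts must be >= 0")

    @property
    def groups(self) -> list[str]:
        return list(self.group_sizes)


@dataclass
class SimTruth:
    """Generating quantities retained for recovery tests.

    ``region_haplotypes`` is (N, 2, total region SNPs) with loci in panel
    order; ``subgroup_freqs`` maps group -> dict with 'region', 'distributed'
    (alt-allele frequency arrays) and 'ssr' (list of spectra). The registry
    lists injected pairs as (ind_id_a, ind_id_b, 'PO'|'FS').
    """

    ancestral_freqs: dict[str, object]
    subgroup_freqs: dict[str, dict[str, object]]
    region_haplotypes: np.ndarray
    registry: list[tuple[str, str, str]] = field(default_factory=list)
    causal_locus: str | None = None
    causal_beta: float | None = None


def _copying_gametes(
    rng: np.random.Generator,
    pool: np.ndarray,
    positions: np.ndarray,
    n_gametes: int,
    switch_rate: float,
) -> np.ndarray:
    """Sample gametes by copying along a region from a haplotype pool.

    Between consecutive loci separated by g bp the copied founder haplotype
    is replaced, with probability 1 - exp(-switch_rate * g), by a uniformly
    chosen pool member (possibly the same one).
    """
    H, m = pool.shape
    gaps = np.diff(positions).astype(float)
    p_switch = 1.0 - np.exp(-switch_rate * gaps)
    switch = np.ones((n_gametes, m), dtype=bool)
    if m > 1:
        switch[:, 1:] = rng.random((n_gametes, m - 1)) < p_switch
    choices = rng.integers(0, H, size=(n_gametes, m))
    cols = np.arange(m)
    last_switch = np.maximum.accumulate(np.where(switch, cols, 0), axis=1)
    hap_idx = np.take_along_axis(choices, last_switch, axis=1)
    return pool[hap_idx, cols]


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    if f <= 0:
        return p.copy()
    a = p * (1 - f) / f
    b = (1 - p) * (1 - f) / f
    out = rng.beta(a, b)
    return np.clip(out, 1e-6, 1 - 1e-6)


def _bn_dirichlet(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Multiallelic Balding-Nichols analogue: Dirichlet(p * (1-f)/f)."""
    if f <= 0:
        return p.copy()
    out = rng.dirichlet(p * (1 - f) / f)
    out = np.clip(out, 1e-9, None)
    return out / out.sum()


def simulate_panel(
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, StructureMatrix, SimTruth]:
    """Generate the structured panel defined by ``cfg`` (deterministic
    under ``cfg.seed``)."""
    rng = np.random.default_rng(cfg.seed)
    groups = cfg.groups
    lo, hi = cfg.ancestral_maf_range

    # -- locus maps -------------------------------------------------------
    region_loci: list[LocusInfo] = []
    region_positions: list[np.ndarray] = []
    for chrom, start, length, n in cfg.regions:
        pos = np.sort(rng.choice(length, size=n, replace=False)) + start
        region_positions.append(pos)
        region_loci += [
            LocusInfo(f"{chrom}_{p}", chrom, int(p), "snp", chrom) for p in pos
        ]
    dist_loci = []
    for j in range(cfg.n_distributed_snps):
        chrom = f"chr{(j % 19) + 1}"
        pos = int(rng.integers(1, 25_000_000))
        dist_loci.append(LocusInfo(f"D{j + 1:03d}_{chrom}", chrom, pos, "snp",
                                   "distributed"))
    ssr_loci = [
        LocusInfo(f"SSR{j + 1:02d}", "0", 1, "ssr", None) for j in range(cfg.n_ssr)
    ]

    # -- generating frequencies ------------------------------------------
    n_region = len(region_loci)
    anc_region = rng.uniform(lo, hi, n_region)
    anc_dist = rng.uniform(lo, hi, cfg.n_distributed_snps)
    k_lo, k_hi = cfg.ssr_allele_range
    ssr_k = rng.integers(k_lo, k_hi + 1, cfg.n_ssr)
    anc_ssr = [rng.dirichlet(np.ones(k) * 2.0) for k in ssr_k]

    subgroup_freqs: dict[str, dict[str, object]] = {}
    for g in groups:
        f = cfg.fst_targets.get(g, 0.0)
        subgroup_freqs[g] = {
            "region": _balding_nichols(rng, anc_region, f),
            "distributed": _balding_nichols(rng, anc_dist, f),
            "ssr": [_bn_dirichlet(rng, p, f) for p in anc_ssr],
        }

    # -- individuals ------------------------------------------------------
    individuals: list[IndividualInfo] = []
    group_of: list[str] = []
    for g in groups:
        for i in range(cfg.group_sizes[g]):
            individuals.append(IndividualInfo(f"{g}_{i + 1:03d}", subgroup=g))
            group_of.append(g)
    n_total = len(individuals)

    # -- region genotypes via the copying model ---------------------------
    hap = np.zeros((n_total, 2, n_region), dtype=np.int8)
    offset = 0
    for r, (chrom, start, length, n) in enumerate(cfg.regions):
        pos = region_positions[r]
        sl = slice(offset, offset + n)
        for g in groups:
            p = subgroup_freqs[g]["region"][sl]
            H = cfg.haplotype_pool_size.get(g, 8)
            pool = (rng.random((H, n)) < p).astype(np.int8)
            idx = np.flatnonzero(np.array(group_of) == g)
            gam = _copying_gametes(rng, pool, pos, 2 * len(idx), cfg.switch_rate)
            hap[idx, 0, sl] = gam[: len(idx)]
            hap[idx, 1, sl] = gam[len(idx):]
        offset += n

    # -- distributed SNPs (independent HWE draws) -------------------------
    dist_dosage = np.zeros((n_total, cfg.n_distributed_snps))
    for g in groups:
        idx = np.flatnonzero(np.array(group_of) == g)
        p = subgroup_freqs[g]["distributed"]
        a1 = rng.random((len(idx), cfg.n_distributed_snps)) < p
        a2 = rng.random((len(idx), cfg.n_distributed_snps)) < p
        dist_dosage[idx] = (a1.astype(float) + a2) / 2.0

    # -- SSRs -------------------------------------------------------------
    ssr_calls = np.full((n_total, cfg.n_ssr, 2), MISSING_ALLELE, dtype=int)
    for g in groups:
        idx = np.flatnonzero(np.array(group_of) == g)
        for j in range(cfg.n_ssr):
            p = subgroup_freqs[g]["ssr"][j]
            ssr_calls[idx, j, 0] = rng.choice(len(p), size=len(idx), p=p)
            ssr_calls[idx, j, 1] = rng.choice(len(p), size=len(idx), p=p)

    snp_dosage = np.hstack([hap.sum(axis=1) / 2.0, dist_dosage])
    loci = region_loci + dist_loci + ssr_loci
    gm = GenotypeMatrix(individuals, loci, snp_dosage, ssr_calls)

    # -- structure matrix -------------------------------------------------
    K = len(groups)
    Q = np.zeros((n_total, K))
    gpos = {g: j for j, g in enumerate(groups)}
    if cfg.q_blur > 0:
        for i, g in enumerate(group_of):
            alpha = np.ones(K)
            alpha[gpos[g]] = cfg.q_blur
            Q[i] = rng.dirichlet(alpha)
    else:
        for i, g in enumerate(group_of):
            Q[i, gpos[g]] = 1.0
    for ind, qrow in zip(individuals, Q):
        ind.membership = qrow.copy()
    structure = StructureMatrix(Q, groups)

    truth = SimTruth(
        ancestral_freqs={"region": anc_region, "distributed": anc_dist, "ssr": anc_ssr},
        subgroup_freqs=subgroup_freqs,
        region_haplotypes=hap,
    )
    return gm, structure, truth


def _fresh_gamete_set(
    rng: np.random.Generator, cfg: SimulationConfig, group: str,
    freqs: dict[str, object],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One full gamete for an individual of ``group``: region haplotype,
    distributed alleles, SSR alleles."""
    n_region = int(sum(r[3] for r in cfg.regions))
    region_gam = np.zeros(n_region, dtype=np.int8)
    offset = 0
    for chrom, start, length, n in cfg.regions:
        p = freqs["region"][offset:offset + n]
        H = cfg.haplotype_pool_size.get(group, 8)
        pool = (rng.random((H, n)) < p).astype(np.int8)
        region_gam[offset:offset + n] = _copying_gametes(
            rng, pool, np.linspace(start, start + length, n), 1, cfg.switch_rate
        )[0]
        offset += n
    dist = (rng.random(len(freqs["distributed"])) < freqs["distributed"]).astype(float)
    ssr = np.array([rng.choice(len(p), p=p) for p in freqs["ssr"]], dtype=int)
    return region_gam, dist, ssr


def inject_relatives(
    gm: GenotypeMatrix, truth: SimTruth, cfg: SimulationConfig
) -> tuple[GenotypeMatrix, SimTruth]:
    """Overwrite chosen panel slots with injected PO / FS pairs.

    A PO child receives one recombination-free copy of a parental gamete
    per region plus one fresh pool gamete; FS sibs are two children of the
    same two pool-drawn parents. Returns new objects; truth's registry and
    haplotypes are updated. Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    if not cfg.related_pairs:
        return gm, truth

    n_region = int(sum(r[3] for r in cfg.regions))
    n_dist = cfg.n_distributed_snps
    dosage = gm.snp_dosage.copy()
    ssr_calls = gm.ssr_calls.copy()
    hap = truth.region_haplotypes.copy()
    registry = list(truth.registry)
    group_of = np.array([ind.subgroup for ind in gm.individuals])

    def ind_alleles(i: int) -> tuple[np.ndarray, np.ndarray]:
        """(2, n_dist) distributed allele pairs, (n_ssr, 2) ssr pairs for i."""
        d = dosage[i, n_region:]
        a = np.zeros((2, n_dist))
        a[0] = (d >= 0.75).astype(float)
        a[1] = (d >= 0.25).astype(float)
        return a, ssr_calls[i]

    def gamete_from(i: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """One recombination-free gamete sampled from individual ``i``."""
        region = np.zeros(n_region, dtype=np.int8)
        offset = 0
        for chrom, start, length, n in cfg.regions:
            which = rng.integers(0, 2)
            region[offset:offset + n] = hap[i, which, offset:offset + n]
            offset += n
        dist_pairs, ssr_pairs = ind_alleles(i)
        pick_d = rng.integers(0, 2, n_dist)
        dist = dist_pairs[pick_d, np.arange(n_dist)]
        pick_s = rng.integers(0, 2, cfg.n_ssr)
        ssr = ssr_pairs[np.arange(cfg.n_ssr), pick_s]
        return region, dist, ssr

    def set_individual(i: int, gam_a, gam_b) -> None:
        hap[i, 0] = gam_a[0]
        hap[i, 1] = gam_b[0]
        dosage[i, :n_region] = (gam_a[0].astype(float) + gam_b[0]) / 2.0
        dosage[i, n_region:] = (gam_a[1] + gam_b[1]) / 2.0
        ssr_calls[i, :, 0] = gam_a[2]
        ssr_calls[i, :, 1] = gam_b[2]

    for g, kinds in cfg.related_pairs.items():
        n_po = int(kinds.get("PO", 0))
        n_fs = int(kinds.get("FS", 0))
        idx = np.flatnonzero(group_of == g)
        needed = 2 * (n_po + n_fs)
        if needed > len(idx):
            raise ConfigError(f"group {g}: {needed} slots requested, {len(idx)} present")
        slots = rng.choice(idx, size=needed, replace=False)
        freqs = truth.subgroup_freqs[g]
        cursor = 0
        for _ in range(n_po):
            parent, child = slots[cursor], slots[cursor + 1]
            cursor += 2
            set_individual(child, gamete_from(parent),
                           _fresh_gamete_set(rng, cfg, g, freqs))
            registry.append((gm.ind_ids[parent], gm.ind_ids[child], "PO"))
        for _ in range(n_fs):
            s1, s2 = slots[cursor], slots[cursor + 1]
            cursor += 2
            # two pool parents, materialized only through their gametes
            pa = (_fresh_gamete_set(rng, cfg, g, freqs),
                  _fresh_gamete_set(rng, cfg, g, freqs))
            pb = (_fresh_gamete_set(rng, cfg, g, freqs),
                  _fresh_gamete_set(rng, cfg, g, freqs))

            def child_gamete(par):
                region = np.zeros(n_region, dtype=np.int8)
                offset = 0
                for chrom, start, length, n in cfg.regions:
                    which = rng.integers(0, 2)
                    region[offset:offset + n] = par[which][0][offset:offset + n]
                    offset += n
                pick = rng.integers(0, 2, n_dist)
                dist = np.where(pick == 0, par[0][1], par[1][1])
                pick_s = rng.integers(0, 2, cfg.n_ssr)
                ssr = np.where(pick_s == 0, par[0][2], par[1][2])
                return region, dist, ssr

            set_individual(s1, child_gamete(pa), child_gamete(pb))
            set_individual(s2, child_gamete(pa), child_gamete(pb))
            registry.append((gm.ind_ids[s1], gm.ind_ids[s2], "FS"))

    new_gm = GenotypeMatrix(gm.individuals, gm.loci, dosage, ssr_calls)
    new_truth = SimTruth(
        ancestral_freqs=truth.ancestral_freqs,
        subgroup_freqs=truth.subgroup_freqs,
        region_haplotypes=hap,
        registry=registry,
    )
    return new_gm, new_truth


def simulate_phenotype(
    gm: GenotypeMatrix,
    K: np.ndarray,
    h2: float,
    q_effect: float,
    causal: str,
    seed: int,
    return_effect: bool = False,
) -> np.ndarray | tuple[np.ndarray, float]:
    """Phenotypes under Y = mu + x*beta + U + E on a unit-total-variance scale.

    sigma2_e = 1 - h2; the causal effect is calibrated so that
    beta^2 * Var_emp(x) = q_effect * h2; the polygenic term U is multivariate
    normal with covariance K * (1 - q_effect) * h2. Missing causal dosages
    are mean-imputed before calibration.
    """
    if not 0 <= h2 <= 1 or not 0 <= q_effect <= 1:
        raise ValueError("h2 and q_effect must lie in [0, 1]")
    snp_ids = [l.locus_id for l in gm.snp_loci]
    if causal not in snp_ids:
        raise ValueError(f"causal locus {causal!r} not found among SNPs")
    x = gm.snp_dosage[:, snp_ids.index(causal)].copy()
    if np.isnan(x).any():
        x[np.isnan(x)] = np.nanmean(x)
    v = float(np.var(x))
    if v == 0:
        raise ValueError(f"causal locus {causal!r} is monomorphic")
    beta = float(np.sqrt(q_effect * h2 / v))
    rng = np.random.default_rng(seed)
    n = gm.n_individuals
    K = np.asarray(K, dtype=float)
    if K.shape != (n, n):
        raise ValueError("kinship matrix does not match panel size")
    sig_u2 = (1.0 - q_effect) * h2
    sig_e2 = 1.0 - h2
    u = np.zeros(n)
    if sig_u2 > 0:
        w, V = np.linalg.eigh((K + K.T) / 2.0)
        w = np.clip(w, 0.0, None)
        u = V @ (np.sqrt(w * sig_u2) * rng.standard_normal(n))
    e = rng.standard_normal(n) * np.sqrt(sig_e2)
    y = x * beta + u + e
    return (y, beta) if return_effect else y
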