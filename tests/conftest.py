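import numpy as np
import pytest

from vitipanel import (
    GenotypeMatrix,
    IndividualInfo,
    LocusInfo,
    SimulationConfig,
    inject_relatives,
    simulate_panel,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_snp_matrix(dosage, chrom="chr1", positions=None, ind_ids=None,
                    subgroups=None):
    """Small SNP-only GenotypeMatrix from a dosage array."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    positions = positions if positions is not None else 1000 * (np.arange(m) + 1)
    inds = [
        IndividualInfo(
            ind_ids[i] if ind_ids else f"I{i + 1:03d}",
            subgroup=subgroups[i] if subgroups else None,
        )
        for i in range(n)
    ]
    loci = [LocusInfo(f"L{j + 1:03d}", chrom, int(positions[j]), "snp")
            for j in range(m)]
    return GenotypeMatrix(inds, loci, dosage)


def make_ssr_matrix(calls, ind_ids=None, subgroups=None):
    """Small SSR-only GenotypeMatrix from an (N, L, 2) allele-label array."""
    calls = np.asarray(calls, dtype=int)
    n, m, _ = calls.shape
    inds = [
        IndividualInfo(
            ind_ids[i] if ind_ids else f"I{i + 1:03d}",
            subgroup=subgroups[i] if subgroups else None,
        )
        for i in range(n)
    ]
    loci = [LocusInfo(f"S{j + 1:02d}", "0", 1, "ssr") for j in range(m)]
    return GenotypeMatrix(inds, loci, np.empty((n, 0)), calls)


@pytest.fixture(scope="session")
def small_panel():
    """A small structured panel with relatives, reused across tests."""
    cfg = SimulationConfig(
        seed=2024,
        group_sizes={"WE": 40, "WW": 40, "TE": 40, "wild": 25},
        regions=(
            ("chr8", 14_529_243, 2_000_000, 40),
            ("chr17", 5_195_037, 2_000_000, 40),
        ),
        n_distributed_snps=60,
        n_ssr=10,
        related_pairs={"WE": {"PO": 3, "FS": 3}, "WW": {"PO": 3}},
    )
    gm, structure, truth = simulate_panel(cfg)
    gm, truth = inject_relatives(gm, truth, cfg)
    return cfg, gm, structure, truth
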