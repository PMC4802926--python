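"""Hill-Weir expected-r2 decay model, LD extent and marker-density needs.

The expected squared correlation between two loci separated by a scaled
recombination distance C = rho * d (rho per bp, d in bp) in a sample of n
individuals is

    E[r2] = (10 + C) / ((2 + C)(11 + C))
            * (1 + (3 + C)(12 + 12 C + C^2) / (n (2 + C)(11 + C))),

a monotone non-increasing function of C that tends to 10/22 * (1 + 36/(22 n))
at C = 0 and to 0 as C grows. Fitting rho to an observed distance/LD table
by least squares gives the decay scale; the "LD extent" at a threshold
(0.2 by convention) is the distance where the fitted curve crosses it.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar


@dataclass
class DecayFit:
    """Fitted decay parameter rho (per bp) with the sample size used."""

    rho: float
    n: int
    n_pairs: int
    residual_ss: float
    ld_column: str = "r2"

    def expected(self, d: np.ndarray | float) -> np.ndarray | float:
        return hill_weir_expectation(self.rho * np.asarray(d, dtype=float), self.n)


def hill_weir_expectation(C: np.ndarray | float, n: int) -> np.ndarray | float:
    """Expected r2 at scaled distance C >= 0 for sample size n >= 2."""
    if n < 2:
        raise ValueError("n must be >= 2")
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("C must be >= 0")
    base = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    corr = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C ** 2)) / (
        n * (2.0 + C) * (11.0 + C)
    )
    out = base * corr
    return float(out) if out.ndim == 0 else out


def fit_hill_weir(
    ld: pd.DataFrame,
    n: int,
    ld_column: str = "r2",
    n_starts: int = 8,
    rho_bounds: tuple[float, float] = (1e-12, 1.0),
) -> DecayFit:
    """Least-squares fit of rho to observed (distance, LD) pairs.

    Uses a bounded log-spaced multi-start local search (deterministic);
    pairs with missing distance or LD value are dropped; at least 10 such
    pairs are required.
    """
    d = ld["distance_bp"].to_numpy(dtype=float)
    y = ld[ld_column].to_numpy(dtype=float)
    ok = np.isfinite(d) & np.isfinite(y)
    d, y = d[ok], y[ok]
    if len(d) < 10:
        raise ValueError(f"only {len(d)} usable pairs; need >= 10")
    if np.all(d == 0):
        raise ValueError("all distances are zero")

    def sse(log_rho: float) -> float:
        rho = np.exp(log_rho)
        return float(np.sum((y - hill_weir_expectation(rho * d, n)) ** 2))

    lo, hi = np.log(rho_bounds[0]), np.log(rho_bounds[1])
    best = None
    starts = np.linspace(lo, hi, n_starts)
    for i in range(len(starts) - 1):
        res = minimize_scalar(sse, bounds=(starts[i], starts[i + 1]),
                              method="bounded",
                              options={"xatol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("Hill-Weir fit did not converge")
    rho = float(np.exp(best.x))
    return DecayFit(rho=rho, n=n, n_pairs=len(d), residual_ss=float(best.fun),
                    ld_column=ld_column)


def ld_extent(fit: DecayFit, threshold: float = 0.2,
              d_max: float = 1e12) -> float:
    """Distance (bp) where the fitted expected-r2 curve crosses ``threshold``.

    The curve is strictly decreasing from its value at d = 0, so the root is
    unique; it is found by bisection to relative tolerance 1e-6.
    """
    at_zero = hill_weir_expectation(0.0, fit.n)
    if threshold >= at_zero:
        raise ValueError(
            f"threshold {threshold} >= curve value at 0 ({at_zero:.4f}); "
            "curve never attains threshold from above")
    if threshold <= 0:
        raise ValueError("threshold must be positive")

    def f(d: float) -> float:
        return fit.expected(d) - threshold

    hi = 1.0 / max(fit.rho, 1e-300)
    while f(hi) > 0 and hi < d_max:
        hi *= 10.0
    return float(brentq(f, 0.0, hi, rtol=1e-6))


def markers_required(fit: DecayFit, genome_size_bp: int,
                     target_r2: float) -> int:
    """Number of equally spaced markers guaranteeing a marker within the
    distance at which expected r2 falls to ``target_r2``.

    With spacing 2 d*, every position lies within d* of a marker, so the
    count is ceil(genome_size / (2 d*)).
    """
    d_star = ld_extent(fit, target_r2)
    return int(ceil(genome_size_bp / (2.0 * d_star)))


def decay_report(
    fits: dict[tuple[str, str], DecayFit], threshold: float = 0.2
) -> pd.DataFrame:
    """Tabulate fitted rho and LD extent per (region, group) combination."""
    rows = []
    for (region, group), fit in fits.items():
        rows.append((region, group, fit.ld_column, fit.rho, fit.n, fit.n_pairs,
                     ld_extent(fit, threshold)))
    return pd.DataFrame(rows, columns=[
        "region", "group", "ld_column", "rho", "n", "n_pairs",
        f"extent_at_{threshold}"])
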