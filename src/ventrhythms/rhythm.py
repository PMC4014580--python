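"""Whittaker-Robinson periodogram with missing-value support.

The Whittaker-Robinson (WR) periodogram scans candidate integer periods
T. For each T the series is folded into a Buys-Ballot table — column j
collects the observations at slots i with i mod T == j — and the WR
amplitude statistic B(T) is the standard deviation of the column means.
A periodic component of period T concentrates variance in the column
means and inflates B(T); so do integer multiples (harmonics) of T.

Missing values are handled natively: they simply never enter a column
mean, and columns with no observation are excluded from the statistic.

Significance is assessed by a one-sided permutation test: the observed
values are shuffled over the observed slots (the missing pattern stays
fixed, preserving the information-loss structure) and B(T) is
recomputed for each shuffle. The p-value uses the add-one convention
p = (1 + #{B_perm >= B_obs}) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _iter_permutations

import numpy as np
import pandas as pd

from .series_prep import HourlySeries

__all__ = [
    "BuysBallotTable",
    "PeriodogramResult",
    "fold",
    "wr_statistic",
    "wr_periodogram",
    "harmonics",
]


@dataclass
class BuysBallotTable:
    """A series folded at candidate period T.

    ``columns[j]`` holds the observed values at slots congruent to j
    modulo T; ``column_means[j]`` is their mean, NaN when the column
    has no observation.
    """

    period_T: int
    columns: list
    column_means: np.ndarray

    @property
    def n_defined(self) -> int:
        return int(np.sum(~np.isnan(self.column_means)))


@dataclass
class PeriodogramResult:
    """WR periodogram over integer periods 2..T_max."""

    periods: np.ndarray
    amplitude: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    alpha: float
    n: int
    n_perm: int
    detrended: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "period": self.periods,
                "amplitude": self.amplitude,
                "p_value": self.p_value,
                "significant": self.significant,
            }
        )

    def significant_periods(self) -> np.ndarray:
        return self.periods[self.significant]


def fold(s: HourlySeries, T: int) -> BuysBallotTable:
    """Fold a series into a Buys-Ballot table with period ``T``.

    Valid periods run from 2 to n/2. Slot i goes to column i mod T;
    the column mean ignores missing members and is NaN for an
    all-missing column.
    """
    n = s.n
    if not 2 <= T <= n / 2:
        raise ValueError(f"period T={T} outside valid range [2, n/2={n / 2}]")
    values = s.values
    cols = [values[j::T] for j in range(T)]
    cols = [c[~np.isnan(c)] for c in cols]
    means = np.array([c.mean() if c.size else np.nan for c in cols])
    return BuysBallotTable(period_T=int(T), columns=cols, column_means=means)


def wr_statistic(table: BuysBallotTable, ddof: int = 1) -> float:
    """WR amplitude: standard deviation of the defined column means.

    The sample (n−1) standard deviation is the default; ``ddof=0``
    gives the population form for cross-checks against other
    implementations.
    """
    means = table.column_means[~np.isnan(table.column_means)]
    if means.size < 2:
        raise ValueError("need at least 2 defined column means")
    return float(np.std(means, ddof=ddof))


def _amplitudes_for_period(values2d: np.ndarray, missing: np.ndarray, T: int,
                           ddof: int = 1) -> np.ndarray:
    """B(T) for each row of ``values2d`` (rows share the missing mask).

    ``values2d`` has missing slots set to 0; ``missing`` is the shared
    boolean mask. Because permutations shuffle observed values over
    observed slots only, the per-column observation counts are
    identical across rows, which lets the whole permutation stack be
    folded with one reshape.
    """
    k, n = values2d.shape
    n_rows = -(-n // T)  # ceil
    pad = n_rows * T - n
    if pad:
        values2d = np.concatenate([values2d, np.zeros((k, pad))], axis=1)
        missing = np.concatenate([missing, np.ones(pad, dtype=bool)])
    counts = (~missing).reshape(n_rows, T).sum(axis=0)
    sums = values2d.reshape(k, n_rows, T).sum(axis=1)
    defined = counts > 0
    if defined.sum() < 2:
        return np.full(k, np.nan)
    means = sums[:, defined] / counts[defined]
    return np.std(means, axis=1, ddof=ddof)


def wr_periodogram(
    s: HourlySeries,
    T_max: int | None = None,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
    ddof: int = 1,
    method: str = "sampling",
) -> PeriodogramResult:
    """WR periodogram over integer periods 2..T_max with permutation test.

    Parameters
    ----------
    s : HourlySeries
        The (already stationary or detrended) series.
    T_max : int, optional
        Largest candidate period; defaults to floor(n/2).
    n_perm : int
        Number of random permutations (>= 99). Ignored for
        ``method="exact"``.
    alpha : float
        Per-period significance level (no multiple-testing correction,
        each period is flagged at its own p < alpha).
    seed : int or numpy Generator
        Randomness source for the permutations.
    method : {"sampling", "exact"}
        ``"exact"`` enumerates every permutation of the observed
        values (feasible only for tiny series) and returns the exact
        permutation p-value #{B_perm >= B_obs} / n!.
    """
    n = s.n
    if n < 4:
        raise ValueError("series too short for a periodogram (n < 4)")
    if T_max is None:
        T_max = n // 2
    T_max = int(min(T_max, n // 2))
    if method == "sampling" and n_perm < 99:
        raise ValueError("n_perm must be >= 99")

    missing = s.missing_mask
    obs_idx = np.flatnonzero(~missing)
    obs_vals = s.values[obs_idx]
    base = np.where(missing, 0.0, s.values)

    if method == "exact":
        if len(obs_vals) > 9:
            raise ValueError("exact enumeration is only feasible for <= 9 observed values")
        all_perms = np.array(list(_iter_permutations(obs_vals)))
        stack = np.zeros((all_perms.shape[0], n))
        stack[:, obs_idx] = all_perms
        n_eff = all_perms.shape[0]
    elif method == "sampling":
        rng = np.random.default_rng(seed)
        stack = np.zeros((n_perm, n))
        stack[:, obs_idx] = rng.permuted(
            np.tile(obs_vals, (n_perm, 1)), axis=1
        )
        n_eff = n_perm
    else:
        raise ValueError(f"unknown method {method!r}")

    periods = np.arange(2, T_max + 1)
    amplitude = np.empty(periods.size)
    p_value = np.empty(periods.size)
    obs_row = base[None, :]
    for i, T in enumerate(periods):
        amp = _amplitudes_for_period(obs_row, missing, T, ddof=ddof)[0]
        perm_amp = _amplitudes_for_period(stack, missing, T, ddof=ddof)
        amplitude[i] = amp
        exceed = int(np.sum(perm_amp >= amp))
        if method == "exact":
            p_value[i] = exceed / n_eff
        else:
            p_value[i] = (1 + exceed) / (n_eff + 1)

    significant = p_value < alpha
    return PeriodogramResult(
        periods=periods,
        amplitude=amplitude,
        p_value=p_value,
        significant=significant,
        alpha=alpha,
        n=n,
        n_perm=n_eff,
    )


def harmonics(T_base: int, T_max: int) -> list[int]:
    """Integer multiples of ``T_base`` up to ``T_max`` (inclusive).

    The WR statistic flags harmonics of a genuine period as
    significant too; this helper annotates them for interpretation.
    """
    if T_base < 2:
        raise ValueError("T_base must be >= 2")
    return list(range(T_base, T_max + 1, T_base))
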