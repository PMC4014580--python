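"""Permutation correlation tests with Holm correction.

Associations between taxa and between taxa and environmental sensors
are screened with two-tailed Pearson correlations whose significance
comes from a permutation test rather than normal theory — the
densities are counts and need no distributional assumption. Within a
family of tests (all pairs examined at one sampling frequency) the
p-values receive a step-down Holm correction.

Series are paired on mutually observed slots only; the number of
complete pairs n_used is always reported and nothing is imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations, permutations as _iter_permutations

import numpy as np
from statsmodels.stats.multitest import multipletests

from .series_prep import HourlySeries, subsample

logger = logging.getLogger(__name__)

__all__ = ["CorrelationResult", "perm_cor", "holm", "correlation_matrix"]


@dataclass
class CorrelationResult:
    pair: tuple
    r: float
    p_raw: float
    p_holm: float
    n_used: int
    frequency: int = 1


def perm_cor(
    x: HourlySeries | np.ndarray,
    y: HourlySeries | np.ndarray,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    method: str = "sampling",
) -> dict:
    """Two-tailed permutation test of the Pearson correlation.

    r is computed over complete (both-observed) pairs; the null
    distribution permutes y over those pairs. p = (1 + #{|r*| >=
    |r|}) / (n_perm + 1). ``method="exact"`` enumerates all
    permutations (tiny n only) and returns #{|r*| >= |r|} / n!.

    Returns ``{"r", "p_raw", "n_used"}``; a zero-variance input gives
    r = NaN with p = 1 and a flag.
    """
    xv = x.values if isinstance(x, HourlySeries) else np.asarray(x, dtype=float)
    yv = y.values if isinstance(y, HourlySeries) else np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise ValueError("series must share the same grid")
    ok = ~np.isnan(xv) & ~np.isnan(yv)
    xv, yv = xv[ok], yv[ok]
    n_used = int(ok.sum())
    if n_used < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(xv) == 0 or np.std(yv) == 0:
        logger.warning("zero variance in one series; correlation undefined")
        return {"r": np.nan, "p_raw": 1.0, "n_used": n_used, "degenerate": True}

    xs = (xv - xv.mean()) / xv.std()
    ys = (yv - yv.mean()) / yv.std()
    r_obs = float(np.mean(xs * ys))

    if method == "exact":
        if n_used > 9:
            raise ValueError("exact enumeration is only feasible for <= 9 pairs")
        perms = np.array(list(_iter_permutations(ys)))
        r_null = perms @ xs / n_used
        p = float(np.mean(np.abs(r_null) >= abs(r_obs) - 1e-12))
    elif method == "sampling":
        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.tile(ys, (n_perm, 1)), axis=1)
        r_null = perms @ xs / n_used
        p = (1 + int(np.sum(np.abs(r_null) >= abs(r_obs) - 1e-12))) / (n_perm + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"r": r_obs, "p_raw": p, "n_used": n_used, "degenerate": False}


def holm(p_values) -> np.ndarray:
    """Step-down Holm adjustment, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="holm")[1]


def correlation_matrix(
    density_table: dict,
    env_table: dict | None = None,
    frequencies=(1,),
    n_perm: int = 999,
    seed: int | None = None,
    pairs: list | None = None,
) -> list[CorrelationResult]:
    """Permutation correlations for many pairs at several frequencies.

    ``density_table`` and ``env_table`` map names to
    :class:`HourlySeries` on a shared hourly grid. By default the
    tested family is every within-density pair plus every
    density × environment pair; an explicit ``pairs`` list overrides
    it. At each frequency the series are subsampled (anchor 0) before
    testing, and Holm is applied within that frequency's family.
    """
    env_table = env_table or {}
    overlap = set(density_table) & set(env_table)
    if overlap:
        raise ValueError(f"names shared between density and env tables: {sorted(overlap)}")
    table = {**density_table, **env_table}
    if pairs is None:
        pairs = list(combinations(sorted(density_table), 2))
        pairs += [(d, e) for d in sorted(density_table) for e in sorted(env_table)]
    root = np.random.default_rng(seed)
    results: list[CorrelationResult] = []
    for freq in frequencies:
        fam: list[CorrelationResult] = []
        for a, b in pairs:
            xa = subsample(table[a], freq) if freq > 1 else table[a]
            xb = subsample(table[b], freq) if freq > 1 else table[b]
            try:
                res = perm_cor(xa, xb, n_perm=n_perm, seed=root.spawn(1)[0])
            except ValueError as err:
                logger.warning("pair (%s, %s) at %dh skipped: %s", a, b, freq, err)
                continue
            fam.append(
                CorrelationResult(
                    pair=(a, b), r=res["r"], p_raw=res["p_raw"],
                    p_holm=np.nan, n_used=res["n_used"], frequency=freq,
                )
            )
        if fam:
            adj = holm([c.p_raw for c in fam])
            for c, pa in zip(fam, adj):
                c.p_holm = float(pa)
        results.extend(fam)
    return results
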