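"""Temporal eigenfunctions and variation partitioning.

The multi-taxon density matrix Y is partitioned between two predictor
sets: W, temporal eigenfunctions capturing periodic/multi-scale
structure of the sampling times, and X, environmental sensors
(temperature probes). Temporal eigenfunctions are built as dbMEM
(distance-based Moran eigenvector maps) on the one-dimensional time
axis: the pairwise time-distance matrix is truncated (distances beyond
the largest gap t between adjacent retained slots are replaced by 4t),
the truncated matrix is double-centred and eigendecomposed, and the
positive-eigenvalue axes become orthogonal predictors. On a complete
regular grid they are discrete sinusoids ordered from low to high
frequency.

Explained variation uses the canonical R² (trace of fitted sums of
squares over total) with the Ezekiel adjustment
1 − (1−R²)(n−1)/(n−m−1), which is unbiased under the null. The
partition reports

    [a] unique to X, [c] unique to W, [b] joint, [d] = 1 − [a+b+c],

from the identities a = [a+b+c] − [b+c], c = [a+b+c] − [a+b],
b = [a+b] + [b+c] − [a+b+c]. Adjusted fractions can come out slightly
negative; they are reported as computed. [b] is not an R² of any
fitted model and carries no test; the testable fractions get
permutation p-values (rows of Y for marginal fractions, residuals of
the conditioning model for the unique ones).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "EigenfunctionBasis",
    "VarpartResult",
    "dbmem",
    "adjusted_r2",
    "forward_select",
    "variation_partition",
    "partition_from_printed",
]


@dataclass
class EigenfunctionBasis:
    """Positive-eigenvalue dbMEM axes for a set of time points."""

    vectors: np.ndarray  # (n_slots, n_eigenfunctions), unit-norm columns
    eigenvalues: np.ndarray
    truncation_distance: float

    @property
    def n_eigenfunctions(self) -> int:
        return self.vectors.shape[1]

    def labels(self) -> list[str]:
        return [f"MEM{i + 1}" for i in range(self.n_eigenfunctions)]


@dataclass
class VarpartResult:
    fraction_ab: float   # adjusted R² of Y ~ X
    fraction_bc: float   # adjusted R² of Y ~ W
    fraction_abc: float  # adjusted R² of Y ~ X + W
    a: float
    b: float
    c: float
    d: float
    p_values: dict = field(default_factory=dict)
    selected_X: list = field(default_factory=list)
    selected_W: list = field(default_factory=list)
    n: int = 0


def dbmem(timestamps, truncation: float | None = None) -> EigenfunctionBasis:
    """Temporal dbMEM basis for (possibly irregular) retained slots.

    ``timestamps`` may be hour offsets or datetimes; internally they
    become hours from the first slot. The truncation threshold t
    defaults to the largest gap between adjacent retained slots (the
    minimum keeping the series connected); larger distances are
    replaced by 4t before double-centring and eigendecomposition.
    Eigenvectors are returned unit-norm, ordered by decreasing
    eigenvalue; only positive-eigenvalue axes are kept.
    """
    t = np.asarray(timestamps)
    if np.issubdtype(t.dtype, np.datetime64) or t.dtype == object:
        import pandas as pd

        idx = pd.DatetimeIndex(t)
        t = (idx.asi8 - idx.asi8[0]) / 3.6e12
    t = np.sort(np.asarray(t, dtype=float))
    n = len(t)
    if n < 3:
        raise ValueError("dbMEM needs at least 3 time points")
    if np.unique(t).size < n:
        raise ValueError("time points must be distinct")
    gaps = np.diff(t)
    thresh = float(gaps.max()) if truncation is None else float(truncation)
    if thresh <= 0:
        raise ValueError("truncation distance must be positive")

    D = np.abs(t[:, None] - t[None, :])
    D = np.where(D > thresh, 4.0 * thresh, D)
    # Gower double-centring of -D²/2, the principal-coordinate kernel
    A = -0.5 * D**2
    A -= A.mean(axis=0, keepdims=True)
    A -= A.mean(axis=1, keepdims=True)
    eigval, eigvec = np.linalg.eigh(A)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-10, 1e-10 * abs(eigval[0]))
    keep = eigval > tol
    return EigenfunctionBasis(
        vectors=eigvec[:, keep],
        eigenvalues=eigval[keep],
        truncation_distance=thresh,
    )


def _design_q(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the centred design column space (SVD).

    SVD (not plain QR) so that rank-deficient designs — e.g. the union
    of two predictor sets sharing a column — yield a clean basis
    independent of column order.
    """
    Xc = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        return u[:, :0]
    keep = s > 1e-10 * s[0]
    return u[:, keep]


def _r2(Y: np.ndarray, X: np.ndarray, Q: np.ndarray | None = None) -> float:
    """Canonical R²: trace of fitted SS over total SS (centred)."""
    Yc = Y - Y.mean(axis=0)
    total = float((Yc**2).sum())
    if total == 0:
        raise ValueError("response matrix has zero variance")
    if Q is None:
        Q = _design_q(X)
    proj = Q.T @ Yc
    return float((proj**2).sum()) / total


def adjusted_r2(Y: np.ndarray, X: np.ndarray) -> float:
    """Ezekiel-adjusted canonical R² of Y on X.

    Y is (n, q) with q >= 1 response columns; X is (n, m). Requires
    m < n − 1 and a full-rank (centred) design.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    n, m = X.shape
    if Y.shape[0] != n:
        raise ValueError("Y and X must have aligned rows")
    if m >= n - 1:
        raise ValueError("need fewer predictors than n - 1")
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if rank < m:
        raise ValueError(
            f"singular design: rank {rank} < {m} predictors (collinear columns)"
        )
    r2 = _r2(Y, X)
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def forward_select(
    Y: np.ndarray,
    candidates: np.ndarray,
    labels: list | None = None,
    alpha: float = 0.05,
    r2a_cap: float | None = None,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> list:
    """Greedy forward selection with the double stopping criterion.

    Selection only starts if a global permutation test of the
    all-candidates model is significant at ``alpha`` (guarding the
    family-wise inclusion rate). Then, at each step, the candidate
    with the largest additional explained variance enters, subject to
    (i) its permutation p-value (residuals of the current model
    permuted) being < ``alpha`` and (ii) the cumulative adjusted R²
    staying at or below ``r2a_cap`` — by default the adjusted R² of
    the model with all candidates. Returns the selected labels
    (column indices when no labels given).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    C = np.asarray(candidates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    n, p = C.shape
    if labels is None:
        labels = list(range(p))
    if len(labels) != p:
        raise ValueError("one label per candidate column required")
    rng = np.random.default_rng(seed)
    if p < n - 1 and np.linalg.matrix_rank(C - C.mean(axis=0)) == p:
        global_r2a = adjusted_r2(Y, C)
        if r2a_cap is None:
            r2a_cap = global_r2a
        # global pre-test: without it, testing only the best candidate at
        # each step inflates the family-wise inclusion rate under the null
        n_obs = Y.shape[0]
        Q = _design_q(C)
        obs = _r2(Y, C, Q=Q)
        count = 0
        for _ in range(n_perm):
            count += _r2(Y[rng.permutation(n_obs)], C, Q=Q) >= obs - 1e-12
        if (1 + count) / (n_perm + 1) >= alpha:
            return []
    elif r2a_cap is None:
        r2a_cap = np.inf  # saturated or rank-deficient candidate set

    Yc = Y - Y.mean(axis=0)
    total = float((Yc**2).sum())
    Cc = C - C.mean(axis=0)
    selected: list[int] = []
    Yres = Yc.copy()
    Cres = Cc.copy()
    while len(selected) < min(p, n - 2):
        norms = (Cres**2).sum(axis=0)
        avail = [j for j in range(p) if j not in selected and norms[j] > 1e-12 * n]
        if not avail:
            break
        # additional explained SS of each candidate on current residuals
        gains = np.array([
            ((Cres[:, j] @ Yres) ** 2).sum() / norms[j] for j in avail
        ])
        best = avail[int(np.argmax(gains))]
        gain_obs = float(gains.max())

        # permutation test: shuffle residual rows of Y against the candidate
        u = Cres[:, best] / np.sqrt(norms[best])
        perm_rows = rng.permuted(
            np.tile(np.arange(n), (n_perm, 1)), axis=1
        )
        null_gains = ((Yres[perm_rows].transpose(0, 2, 1) @ u) ** 2).sum(axis=1)
        pval = (1 + int(np.sum(null_gains >= gain_obs - 1e-12))) / (n_perm + 1)
        if pval >= alpha:
            break
        selected.append(best)
        # residualize Y and the remaining candidates on the accepted column
        u = Cres[:, best] / np.sqrt(norms[best])
        Yres = Yres - np.outer(u, u @ Yres)
        Cres = Cres - np.outer(u, u @ Cres)
        # second stopping rule: once the cumulative adjusted R² crosses
        # the all-candidates cap, the crossing variable is kept and the
        # search ends
        if adjusted_r2(Y, C[:, selected]) > r2a_cap + 1e-12:
            break
    return [labels[j] for j in selected]


def _adjusted_r2_rank(Y: np.ndarray, X: np.ndarray) -> float:
    """Ezekiel adjustment with m = effective rank of the design.

    The union X ∪ W in a partition may legitimately carry redundant
    columns (predictors shared between the sets); the fit projects
    onto the column space and the adjustment charges its dimension.
    """
    Q = _design_q(X)
    n, m = X.shape[0], Q.shape[1]
    if m >= n - 1:
        raise ValueError("need effective rank below n - 1")
    r2 = _r2(Y, X, Q=Q)
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def _partition_fractions(r2a_x: float, r2a_w: float, r2a_xw: float) -> tuple:
    a = r2a_xw - r2a_w
    c = r2a_xw - r2a_x
    b = r2a_x + r2a_w - r2a_xw
    d = 1.0 - r2a_xw
    return a, b, c, d


def variation_partition(
    Y: np.ndarray,
    X: np.ndarray | None,
    W: np.ndarray | None,
    n_perm: int = 999,
    seed: int | None = None,
    selected_X: list | None = None,
    selected_W: list | None = None,
) -> VarpartResult:
    """Partition the variation of Y between predictor sets X and W.

    Either set may be None/empty, giving the degenerate partition
    where the corresponding fractions are zero. Permutation p-values
    are attached to the testable fractions: [a+b], [b+c] and [a+b+c]
    by permuting rows of Y; [a] and [c] by permuting residuals of the
    conditioning model (W for [a], X for [c]). [b] and [d] have no
    test.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    n = Y.shape[0]

    def _mat(M):
        if M is None:
            return np.empty((n, 0))
        M = np.asarray(M, dtype=float)
        if M.ndim == 1:
            M = M[:, None]
        return M

    X, W = _mat(X), _mat(W)
    if X.shape[1] == 0 and W.shape[1] == 0:
        raise ValueError("at least one predictor set must be non-empty")
    rng = np.random.default_rng(seed)

    def _r2a(M):
        return _adjusted_r2_rank(Y, M) if M.shape[1] else 0.0

    r2a_x = _r2a(X)
    r2a_w = _r2a(W)
    XW = np.hstack([X, W])
    if X.shape[1] and W.shape[1]:
        r2a_xw = _r2a(XW)
    else:
        r2a_xw = r2a_x if X.shape[1] else r2a_w
    a, b, c, d = _partition_fractions(r2a_x, r2a_w, r2a_xw)
    if min(a, b, c) < 0:
        logger.warning(
            "negative adjusted fraction(s) a=%.4f b=%.4f c=%.4f reported unclipped",
            a, b, c,
        )

    p_values = {}
    if n_perm and n_perm > 0:
        if X.shape[1]:
            p_values["ab"] = _perm_p_marginal(Y, X, rng, n_perm)
        if W.shape[1]:
            p_values["bc"] = _perm_p_marginal(Y, W, rng, n_perm)
        if X.shape[1] and W.shape[1]:
            p_values["abc"] = _perm_p_marginal(Y, XW, rng, n_perm)
            p_values["a"] = _perm_p_partial(Y, X, W, rng, n_perm)
            p_values["c"] = _perm_p_partial(Y, W, X, rng, n_perm)

    return VarpartResult(
        fraction_ab=r2a_x, fraction_bc=r2a_w, fraction_abc=r2a_xw,
        a=a, b=b, c=c, d=d, p_values=p_values,
        selected_X=selected_X or [], selected_W=selected_W or [],
        n=n,
    )


def _perm_p_marginal(Y, M, rng, n_perm) -> float:
    """Permutation p for the marginal fraction explained by M."""
    Q = _design_q(M)
    obs = _r2(Y, M, Q=Q)
    n = Y.shape[0]
    count = 0
    for _ in range(n_perm):
        count += _r2(Y[rng.permutation(n)], M, Q=Q) >= obs - 1e-12
    return (1 + count) / (n_perm + 1)


def _perm_p_partial(Y, M, Z, rng, n_perm) -> float:
    """Permutation p for the fraction of M after controlling Z.

    Residuals of Y on the conditioning set Z are permuted and
    re-attached to the fitted part (residual-permutation scheme).
    """
    Yc = Y - Y.mean(axis=0)
    Qz = _design_q(Z)
    fitted = Qz @ (Qz.T @ Yc)
    resid = Yc - fitted
    Qmz = _design_q(np.hstack([M, Z]))

    def stat(Ymat):
        return _r2(Ymat, None, Q=Qmz) - _r2(Ymat, None, Q=Qz)

    obs = stat(Yc)
    n = Y.shape[0]
    count = 0
    for _ in range(n_perm):
        Yp = fitted + resid[rng.permutation(n)]
        count += stat(Yp) >= obs - 1e-12
    return (1 + count) / (n_perm + 1)


def partition_from_printed(r2_x_percent: float, r2_w_percent: float,
                           joint_percent: float) -> dict:
    """Derive all Venn fractions from printed [a+b], [b+c] and [b] (%).

    Convenience for reading published partitions: given the variation
    explained by each set alone and jointly, the identities give
    [a+b+c] = [a+b] + [b+c] − [b], [a] = [a+b] − [b],
    [c] = [b+c] − [b], [d] = 100 − [a+b+c].
    """
    abc = r2_x_percent + r2_w_percent - joint_percent
    a, b, c, d = _partition_fractions(
        r2_x_percent / 100.0, r2_w_percent / 100.0, abc / 100.0
    )
    return {"a": 100 * a, "b": 100 * b, "c": 100 * c, "d": 100 * d,
            "abc": abc}
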