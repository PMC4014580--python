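"""Heat-map binning and nearest-neighbour segregation of point patterns.

Per-frame point annotations (taxon, x, y in pixels) support two
analyses: (i) heat maps — counts of observations per spatial bin per
taxon, accumulated over all frames — and (ii) Dixon's
nearest-neighbour contingency analysis of spatial segregation among
mobile taxa.

For the segregation analysis, each individual contributes its single
Euclidean nearest neighbour; N_AB counts individuals of taxon A whose
nearest neighbour belongs to taxon B. Under random labelling of a
fixed set of N locations the expectations are

    E_AA = n_A (n_A − 1) / (N − 1),      E_AB = n_A n_B / (N − 1),

and the segregation index compares observed to expected odds:

    S_AA = ln[ (N_AA / (n_A − N_AA)) / ((n_A − 1) / (N − n_A)) ]
    S_AB = ln[ (N_AB / (n_A − N_AB)) / (n_B / (N − 1 − n_B)) ]   (A ≠ B).

S_AA > 0 means the taxon clumps with conspecifics (segregation);
S_AB < 0 means B is under-represented among A's neighbours.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LabelledPointSet",
    "HeatMapGrid",
    "NNSegregationResult",
    "bin_points",
    "nn_contingency",
    "expected_counts",
    "segregation_index",
    "pooled_segregation",
]


@dataclass
class LabelledPointSet:
    """Per-frame labelled point annotations in pixel coordinates.

    ``points`` columns: frame_id, taxon, x, y. ``pixel_area_cm2`` is
    the physical area imaged by one pixel and calibrates heat-map bin
    sizes.
    """

    points: pd.DataFrame
    frame_width: int
    frame_height: int
    pixel_area_cm2: float = 1.0

    def __post_init__(self) -> None:
        required = {"frame_id", "taxon", "x", "y"}
        if not required.issubset(self.points.columns):
            raise ValueError(f"points table needs columns {sorted(required)}")
        if len(self.points):
            x = self.points["x"].to_numpy()
            y = self.points["y"].to_numpy()
            if (x < 0).any() or (x >= self.frame_width).any() \
                    or (y < 0).any() or (y >= self.frame_height).any():
                raise ValueError("points must lie inside the frame")

    @property
    def taxa(self) -> list:
        return sorted(self.points["taxon"].unique())

    def frame(self, frame_id) -> pd.DataFrame:
        return self.points[self.points["frame_id"] == frame_id]

    def frame_ids(self) -> list:
        return sorted(self.points["frame_id"].unique())


@dataclass
class HeatMapGrid:
    """Per-taxon grids of observation counts in square spatial bins."""

    counts: dict  # taxon -> 2-D array (rows=y bins, cols=x bins)
    bin_side_pixels: int
    bin_area_cm2: float

    def total(self, taxon) -> int:
        return int(self.counts[taxon].sum())


@dataclass
class NNSegregationResult:
    """Pooled nearest-neighbour contingency analysis.

    All matrices are indexed by ``taxa`` order: ``observed[i, j]`` is
    the number of individuals of taxon i whose nearest neighbour was
    of taxon j, summed over frames; ``expected`` likewise under random
    labelling. ``S[i, j]`` is the log odds-ratio segregation index;
    entries with degenerate (zero or infinite) odds are NaN with
    ``degenerate[i, j]`` set.
    """

    taxa: list
    observed: np.ndarray
    expected: np.ndarray
    S: np.ndarray
    degenerate: np.ndarray
    abundances: np.ndarray
    n_total: int
    n_frames: int = 1

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.taxa):
            for j, b in enumerate(self.taxa):
                rows.append((a, b, self.observed[i, j], self.expected[i, j], self.S[i, j]))
        return pd.DataFrame(rows, columns=["From", "To", "Obs. Count", "Exp. Count", "S"])


def bin_points(points: LabelledPointSet, bin_area_cm2: float = 1.125) -> HeatMapGrid:
    """Accumulate point annotations into square heat-map bins.

    The bin side is ceil(sqrt(bin_area / pixel_area)) pixels; bins tile
    the frame from the top-left origin and are left-closed/top-closed,
    so a point on a shared edge belongs to the bin of smaller index.
    Counts are conserved: each point lands in exactly one bin.
    """
    if points.pixel_area_cm2 <= 0:
        raise ValueError("pixel_area_cm2 must be positive")
    if bin_area_cm2 <= 0:
        raise ValueError("bin_area_cm2 must be positive")
    side = int(np.ceil(np.sqrt(bin_area_cm2 / points.pixel_area_cm2)))
    nx = -(-points.frame_width // side)
    ny = -(-points.frame_height // side)
    taxa = points.taxa
    counts = {t: np.zeros((ny, nx), dtype=int) for t in taxa}
    for taxon, sub in points.points.groupby("taxon"):
        ix = (sub["x"].to_numpy() // side).astype(int)
        iy = (sub["y"].to_numpy() // side).astype(int)
        np.add.at(counts[taxon], (iy, ix), 1)
    return HeatMapGrid(counts=counts, bin_side_pixels=side, bin_area_cm2=bin_area_cm2)


def nn_contingency(frame: pd.DataFrame, taxa: list | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-neighbour contingency counts for one frame.

    Returns ``(observed, abundances)`` over ``taxa`` order. Every
    individual contributes exactly one nearest neighbour (Euclidean;
    ties broken by the lowest record index), so each row of the
    observed matrix sums to that taxon's abundance. Duplicate
    coordinates are legal — distance zero is a valid nearest
    neighbour.
    """
    if taxa is None:
        taxa = sorted(frame["taxon"].unique())
    xy = frame[["x", "y"]].to_numpy(dtype=float)
    m = len(xy)
    if m < 2:
        raise ValueError("nearest-neighbour analysis needs at least 2 points")
    labels = pd.Categorical(frame["taxon"], categories=taxa).codes
    if (labels < 0).any():
        raise ValueError("frame contains taxa outside the declared set")
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nn = d2.argmin(axis=1)  # argmin returns the lowest index on ties
    k = len(taxa)
    observed = np.zeros((k, k), dtype=int)
    np.add.at(observed, (labels, labels[nn]), 1)
    abundances = np.bincount(labels, minlength=k)
    return observed, abundances


def expected_counts(abundances: np.ndarray) -> np.ndarray:
    """Random-labelling expectations for the NN contingency table."""
    n = np.asarray(abundances, dtype=float)
    N = n.sum()
    if N < 2:
        raise ValueError("need at least 2 individuals in total")
    E = np.outer(n, n) / (N - 1)
    np.fill_diagonal(E, n * (n - 1) / (N - 1))
    return E


def segregation_index(observed: np.ndarray, abundances: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Dixon's log odds-ratio segregation index S per taxon pair.

    Returns ``(S, degenerate)``; degenerate entries (zero or infinite
    observed odds, or undefined expected odds) are NaN in S with the
    flag set.
    """
    observed = np.asarray(observed, dtype=float)
    n = np.asarray(abundances, dtype=float)
    if not np.allclose(observed.sum(axis=1), n):
        raise ValueError("row sums of observed counts must equal abundances")
    N = n.sum()
    k = len(n)
    S = np.full((k, k), np.nan)
    degenerate = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(k):
            num_obs = observed[i, j]
            den_obs = n[i] - observed[i, j]
            if i == j:
                num_exp, den_exp = n[i] - 1.0, N - n[i]
            else:
                num_exp, den_exp = n[j], N - 1.0 - n[j]
            if num_obs <= 0 or den_obs <= 0 or num_exp <= 0 or den_exp <= 0:
                degenerate[i, j] = True
                continue
            S[i, j] = np.log((num_obs / den_obs) / (num_exp / den_exp))
    return S, degenerate


def _pooled_S(observed: np.ndarray, expected: np.ndarray,
              abundances: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """S from pooled observed and pooled expected odds.

    The expected odds E/(n−E) reduce to Dixon's closed forms on a
    single frame, so pooling by summing counts and expectations
    generalizes the single-frame index exactly.
    """
    n = np.asarray(abundances, dtype=float)
    k = len(n)
    S = np.full((k, k), np.nan)
    degenerate = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(k):
            num_obs, den_obs = observed[i, j], n[i] - observed[i, j]
            num_exp, den_exp = expected[i, j], n[i] - expected[i, j]
            if min(num_obs, den_obs, num_exp, den_exp) <= 0:
                degenerate[i, j] = True
                continue
            S[i, j] = np.log((num_obs / den_obs) / (num_exp / den_exp))
    return S, degenerate


def pooled_segregation(points: LabelledPointSet) -> NNSegregationResult:
    """NN segregation pooled over all frames of a point set.

    Observed and expected contingency tables are computed per frame
    (each frame has its own random-labelling null) and summed; S is
    then formed from the pooled odds. Frames with fewer than 2 points
    are skipped with a warning.
    """
    taxa = points.taxa
    k = len(taxa)
    observed = np.zeros((k, k), dtype=float)
    expected = np.zeros((k, k), dtype=float)
    abundances = np.zeros(k, dtype=float)
    n_used = 0
    for fid, frame in points.points.groupby("frame_id"):
        if len(frame) < 2:
            logger.warning("frame %r has <2 points; skipped", fid)
            continue
        obs_f, ab_f = nn_contingency(frame, taxa=taxa)
        observed += obs_f
        expected += expected_counts(ab_f)
        abundances += ab_f
        n_used += 1
    if n_used == 0:
        raise ValueError("no frame with at least 2 points")
    S, degenerate = _pooled_S(observed, expected, abundances)
    return NNSegregationResult(
        taxa=taxa,
        observed=observed,
        expected=expected,
        S=S,
        degenerate=degenerate,
        abundances=abundances,
        n_total=int(abundances.sum()),
        n_frames=n_used,
    )
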