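"""Synthetic inputs emulating the vent-observatory sampling design.

The study design this package targets is a 23-day continuous imagery
window: 559 hourly slots (2011-10-07 08:00 → 2011-10-30 14:00 UTC) of
which 23 are unusable, tidal forcing at the semi-diurnal (12.42 h) and
diurnal (24.84 h) constituents, slow linear trends, autocorrelated
sensor noise, Poisson-like faunal counts, and per-frame point
annotations for three mobile taxa with clustered, mutually segregated
distributions.

Everything downstream of the generator treats these series exactly
like real observatory exports, so the whole pipeline is testable
without any deposited data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series_prep import HourlySeries, build_grid
from .spatial import LabelledPointSet

__all__ = [
    "SeriesSpec",
    "PatternSpec",
    "LabelledPointSet",
    "generate_series",
    "generate_point_pattern",
    "STUDY_START",
    "STUDY_END",
    "STUDY_N_SLOTS",
    "STUDY_N_MISSING",
    "SEMIDIURNAL_H",
    "DIURNAL_H",
    "study_bundle",
]

# the continuous-recording window of the emulated deployment
STUDY_START = pd.Timestamp("2011-10-07 08:00", tz="UTC")
STUDY_END = pd.Timestamp("2011-10-30 14:00", tz="UTC")
STUDY_N_SLOTS = 559
STUDY_N_MISSING = 23

# principal lunar semi-diurnal (M2) and diurnal tidal periods, hours
SEMIDIURNAL_H = 12.42
DIURNAL_H = 24.84


@dataclass
class SeriesSpec:
    """Recipe for one synthetic hourly series.

    values = base_level + trend_slope·t + Σ amplitude·sin(2πt/period + φ)
             + AR(1) noise,
    sampled per ``family``; exactly ``n_missing`` slots are then
    knocked out uniformly at random.

    ``periods`` is a list of ``(period_hours, amplitude)`` pairs; each
    component gets an independent uniform [0, 2π) phase unless
    ``phases`` pins them. ``family="poisson-count"`` clamps the latent
    mean at zero and draws Poisson counts (densities are nonnegative).
    """

    n_slots: int = STUDY_N_SLOTS
    start_time: pd.Timestamp = STUDY_START
    n_missing: int = STUDY_N_MISSING
    trend_slope: float = 0.0
    periods: list = field(default_factory=list)
    noise_sd: float = 0.0
    ar1_coef: float = 0.0
    base_level: float = 0.0
    family: str = "gaussian"
    seed: int | None = None
    phases: list | None = None
    name: str = ""
    units: str = ""

    def validate(self) -> None:
        if self.n_slots < 1:
            raise ValueError("n_slots must be >= 1")
        if not 0 <= self.n_missing < self.n_slots:
            raise ValueError("need 0 <= n_missing < n_slots")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must lie in [0, 1)")
        for period, amp in self.periods:
            if period <= 0 or amp < 0:
                raise ValueError("periods need positive period and nonnegative amplitude")
        if self.family not in ("gaussian", "poisson-count"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.phases is not None and len(self.phases) != len(self.periods):
            raise ValueError("phases must match periods one-to-one")


@dataclass
class PatternSpec:
    """Recipe for clustered per-frame point annotations.

    Each taxon gets ``n_points`` individuals scattered isotropically
    (sd ``cluster_sd_pixels``) around ``n_clusters`` parent locations
    drawn uniformly in the frame; points are clipped to the frame.
    """

    frame_width: int
    frame_height: int
    taxa: list  # (name, n_points, n_clusters, cluster_sd_pixels)
    n_frames: int = 1
    seed: int | None = None
    centers: dict | None = None  # optional pinned parents: name -> [(x, y), ...]

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.centers is not None:
            declared = {name for name, *_ in self.taxa}
            if not set(self.centers) <= declared:
                raise ValueError("centers refer to undeclared taxa")
        if self.frame_width <= 0 or self.frame_height <= 0:
            raise ValueError("frame dimensions must be positive")
        for name, n_points, n_clusters, sd in self.taxa:
            if n_points < 0 or n_clusters < 1 or sd < 0:
                raise ValueError(f"invalid pattern parameters for taxon {name!r}")


def generate_series(spec: SeriesSpec) -> HourlySeries:
    """Draw one synthetic hourly series from a :class:`SeriesSpec`."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_slots
    t = np.arange(n, dtype=float)

    signal = spec.base_level + spec.trend_slope * t
    if spec.phases is not None:
        phases = list(spec.phases)
    else:
        phases = [rng.uniform(0, 2 * np.pi) for _ in spec.periods]
    for (period, amp), phi in zip(spec.periods, phases):
        signal = signal + amp * np.sin(2 * np.pi * t / period + phi)

    noise = np.zeros(n)
    if spec.noise_sd > 0:
        eps = rng.normal(0.0, spec.noise_sd, size=n)
        if spec.ar1_coef > 0:
            rho = spec.ar1_coef
            noise[0] = rng.normal(0.0, spec.noise_sd / np.sqrt(1 - rho**2))
            for i in range(1, n):
                noise[i] = rho * noise[i - 1] + eps[i]
        else:
            noise = eps

    latent = signal + noise
    if spec.family == "poisson-count":
        values = rng.poisson(np.clip(latent, 0.0, None)).astype(float)
    else:
        values = latent

    if spec.n_missing > 0:
        gaps = rng.choice(n, size=spec.n_missing, replace=False)
        values[gaps] = np.nan

    end = spec.start_time + pd.Timedelta(hours=n - 1)
    grid = build_grid(spec.start_time, end)
    return HourlySeries(grid, values, units=spec.units, name=spec.name)


def generate_point_pattern(spec: PatternSpec) -> LabelledPointSet:
    """Draw clustered point annotations over one or more frames.

    Cluster parents are uniform in the central region of the frame (a
    10 % margin keeps clusters from being clipped at the border) and
    stay fixed across frames — each taxon has a persistent home range,
    the spatial structure the pooled segregation analysis probes.
    Offspring are isotropic Gaussian around their parent, assigned
    round-robin, and clipped into the frame; counts per taxon are
    exact in every frame.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    w, h = spec.frame_width, spec.frame_height
    parents = {}
    for name, n_points, n_clusters, sd in spec.taxa:
        if spec.centers is not None and name in spec.centers:
            cxy = np.asarray(spec.centers[name], dtype=float)
            parents[name] = (cxy[:, 0], cxy[:, 1])
        else:
            parents[name] = (
                rng.uniform(0.1 * w, 0.9 * w, size=n_clusters),
                rng.uniform(0.1 * h, 0.9 * h, size=n_clusters),
            )
    rows = []
    for fid in range(spec.n_frames):
        for name, n_points, n_clusters, sd in spec.taxa:
            if n_points == 0:
                continue
            cx, cy = parents[name]
            parent = np.arange(n_points) % len(cx)
            x = cx[parent] + (rng.normal(0, sd, size=n_points) if sd > 0 else 0.0)
            y = cy[parent] + (rng.normal(0, sd, size=n_points) if sd > 0 else 0.0)
            x = np.clip(x, 0, np.nextafter(float(w), 0.0))
            y = np.clip(y, 0, np.nextafter(float(h), 0.0))
            for xi, yi in zip(x, y):
                rows.append((fid, name, float(xi), float(yi)))
    df = pd.DataFrame(rows, columns=["frame_id", "taxon", "x", "y"])
    return LabelledPointSet(df, frame_width=w, frame_height=h)


def study_bundle(seed: int | None = None, n_frames_points: int = 100) -> dict:
    """A full synthetic twin of the 23-day deployment.

    Returns ``{"counts": {...}, "sensors": {...}, "points": ...}``:
    hourly Poisson-like count series for six taxa (tubeworms,
    polynoids, pycnogonids, buccinids, a sparse zoarcid visitor and
    microbial cover on a coarser rhythm of its own), five temperature
    probes with probe-specific tidal amplitude and slow trends, and a
    clustered/segregated point pattern for the three mobile taxa.

    Counts are per frame (convert with the filmed area, ~0.0355 m²,
    to ind/m²). Tidal forcing uses the semi-diurnal (12.42 h) and
    diurnal (24.84 h) constituents. ``n_frames_points`` controls the
    number of annotated frames in the point pattern (full design: one
    per usable still).
    """
    root = np.random.default_rng(seed)

    def sub():
        return int(root.integers(0, 2**31 - 1))

    counts = {}
    fauna = {
        # name: (base count/frame, semi-diurnal amp, diurnal amp, trend/h)
        "Siboglinidae": (12.0, 3.0, 1.0, 0.004),
        "Polynoidae": (6.0, 1.5, 0.8, 0.0),
        "Pycnogonida": (9.0, 1.0, 2.0, -0.003),
        "Buccinidae": (3.0, 0.8, 0.4, 0.0),
    }
    for name, (base, amp12, amp24, slope) in fauna.items():
        spec = SeriesSpec(
            base_level=base, trend_slope=slope,
            periods=[(SEMIDIURNAL_H, amp12), (DIURNAL_H, amp24)],
            noise_sd=1.0, ar1_coef=0.3, family="poisson-count",
            seed=sub(), name=name, units="count",
        )
        counts[name] = generate_series(spec)
    # sparse visitor: present in a handful of frames only
    zo = generate_series(SeriesSpec(
        base_level=0.04, noise_sd=0.0, family="poisson-count",
        seed=sub(), name="Zoarcidae", units="count",
    ))
    counts["Zoarcidae"] = zo

    sensors = {}
    probes = {
        # probe-specific tidal amplitude and trend (°C)
        "T601": (3.1, 0.35, 0.25, 0.0008),
        "T602": (3.6, 0.40, 0.30, 0.0010),
        "T603": (4.1, 0.45, 0.30, 0.0),
        "T604": (10.9, 0.05, 0.05, 0.0025),
        "T605": (2.5, 0.15, 0.20, -0.0006),
    }
    for probe, (base, amp12, amp24, slope) in probes.items():
        spec = SeriesSpec(
            base_level=base, trend_slope=slope,
            periods=[(SEMIDIURNAL_H, amp12), (DIURNAL_H, amp24)],
            noise_sd=0.15, ar1_coef=0.5, n_missing=0,
            seed=sub(), name=probe, units="degC",
        )
        sensors[probe] = generate_series(spec)

    points = generate_point_pattern(PatternSpec(
        frame_width=720, frame_height=576,
        taxa=[
            ("Polynoidae", 6, 3, 60.0),
            ("Pycnogonida", 9, 2, 25.0),
            ("Buccinidae", 3, 1, 20.0),
        ],
        n_frames=n_frames_points,
        seed=sub(),
    ))
    return {"counts": counts, "sensors": sensors, "points": points}
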