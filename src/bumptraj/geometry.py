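"""State-space trajectories and their periodic geometry.

A single loading matrix is fit on the UTND matrix pooling all conditions
(``Y = P (X - mean)``); every trial is then projected with that same
transform so trajectories are comparable across trials, tempos and tasks.
Geometry is quantified per inter-tap segment: radius and variability on
the oscillatory component plane, linear speed on the leading three
components, plus sinusoid fits, percentile splits, anchor-point distances
and cross-trajectory distance profiles.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .binning import BinnedPopulation

__all__ = [
    "CoeffMatrix",
    "Trajectory",
    "SegmentGeometry",
    "SinusoidFit",
    "AnchorDistances",
    "fit_coefficients",
    "project",
    "segment_radius",
    "linear_speed",
    "geometry_table",
    "radius_variability",
    "percentile_split",
    "fit_sinusoid",
    "anchor_distances",
    "anchor_distance_analysis",
    "distance_profile",
    "condition_mean_trajectory",
]

DEFAULT_RADIUS_COMPONENTS = (1, 2)  # the oscillatory pair (0-based PC2, PC3)
DEFAULT_SPEED_COMPONENTS = (0, 1, 2)


@dataclass
class CoeffMatrix:
    """Component loadings fit on the pooled UTND training matrix."""

    P: np.ndarray  # components x neurons, orthonormal rows
    mean: np.ndarray  # per-neuron centering offsets
    explained_variance_ratio: np.ndarray
    neuron_ids: np.ndarray
    n_retained: int

    def __post_init__(self) -> None:
        if self.P.shape[1] != len(self.neuron_ids):
            raise ValueError("P columns must match neuron_ids")

    @property
    def n_components(self) -> int:
        return self.P.shape[0]


@dataclass
class Trajectory:
    """Projected state path: bins x components plus per-bin metadata."""

    Y: np.ndarray
    bins: pd.DataFrame
    n_components: int
    smoothed: bool = False
    smooth_span: float = 0.0

    def __post_init__(self) -> None:
        if self.Y.shape[0] != len(self.bins):
            raise ValueError("Y rows must match bin metadata")

    def segment_keys(self) -> pd.DataFrame:
        return (
            self.bins[["trial_id", "repetition", "target_interval_ms", "condition", "segment"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )

    def segment_indices(self, trial_id: int, segment: int) -> np.ndarray:
        mask = (self.bins["trial_id"] == trial_id) & (self.bins["segment"] == segment)
        return np.flatnonzero(mask.to_numpy())

    def segment(self, trial_id: int, segment: int, components: Sequence[int]) -> np.ndarray:
        idx = self.segment_indices(trial_id, segment)
        return self.Y[np.ix_(idx, list(components))]


@dataclass
class SegmentGeometry:
    """Radius and point spread of one inter-tap trajectory segment."""

    trial_id: int
    segment: int
    target_interval_ms: float
    condition: str
    repetition: int
    centroid: np.ndarray
    radius: float
    distances: np.ndarray
    speed: float | None = None

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be nonnegative")


@dataclass
class SinusoidFit:
    """Parameters of ``a * sin(2*pi*t + c) + d`` on a unit-time segment."""

    amplitude: float
    phase: float
    offset: float
    mse: float
    converged: bool = True

    def __post_init__(self) -> None:
        # canonical form: nonnegative amplitude, phase in [0, 2*pi)
        if self.amplitude < 0:
            self.amplitude = -self.amplitude
            self.phase += np.pi
        self.phase = float(np.mod(self.phase, 2 * np.pi))


@dataclass
class AnchorDistances:
    """Distances from a common anchor to tap and half-interval states."""

    anchor: np.ndarray
    table: pd.DataFrame  # target_interval_ms, segment, d_tap, d_half
    d_tap_regression: object = field(default=None, repr=False)
    d_half_regression: object = field(default=None, repr=False)


def fit_coefficients(X_utnd: BinnedPopulation, n_retained: int = 8) -> CoeffMatrix:
    """Fit the shared loading matrix on the UTND training matrix.

    Rows of ``P`` are orthonormal and ordered by explained variance.  The
    per-neuron means are stored so later projections reuse the training
    centering.
    """
    from sklearn.decomposition import PCA

    if X_utnd.n_bins < 2:
        raise ValueError("need at least 2 bins to fit coefficients")
    data = X_utnd.X.T  # bins x neurons
    if not np.any(np.std(data, axis=0) > 0):
        raise ValueError("training matrix has zero variance everywhere")
    pca = PCA(svd_solver="full")
    pca.fit(data)
    return CoeffMatrix(
        P=pca.components_,
        mean=pca.mean_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        neuron_ids=X_utnd.neuron_ids.copy(),
        n_retained=min(n_retained, pca.components_.shape[0]),
    )


def _lowess_smooth(y: np.ndarray, span_points: int) -> np.ndarray:
    from statsmodels.nonparametric.smoothers_lowess import lowess

    n = len(y)
    frac = min(max(span_points, 3) / n, 1.0)
    x = np.arange(n, dtype=float)
    return lowess(y, x, frac=frac, return_sorted=False)


def project(
    coeffs: CoeffMatrix,
    X: BinnedPopulation,
    smooth: bool = False,
    smooth_span: float = 0.1,
    n_components: int | None = None,
) -> Trajectory:
    """Project binned rates through the shared transform.

    Optional locally-weighted smoothing is applied per component within
    each trial; the window is ``smooth_span`` of the segment length (at
    least 3 bins).
    """
    if list(X.neuron_ids) != list(coeffs.neuron_ids):
        missing = set(map(str, coeffs.neuron_ids)) - set(map(str, X.neuron_ids))
        raise ValueError(
            "neuron set/order mismatch with fitted coefficients"
            + (f"; missing: {sorted(missing)[:10]}" if missing else "")
        )
    k = coeffs.n_retained if n_components is None else n_components
    k = min(k, coeffs.n_components)
    Y = (coeffs.P[:k] @ (X.X - coeffs.mean[:, None])).T
    if smooth:
        bins_per_segment = (
            X.bins.groupby(["trial_id", "segment"], sort=False).size().median()
        )
        span_points = max(int(round(smooth_span * bins_per_segment)), 3)
        for trial_id in X.bins["trial_id"].unique():
            idx = np.flatnonzero((X.bins["trial_id"] == trial_id).to_numpy())
            for c in range(k):
                Y[idx, c] = _lowess_smooth(Y[idx, c], span_points)
    return Trajectory(
        Y=Y,
        bins=X.bins.copy(),
        n_components=k,
        smoothed=smooth,
        smooth_span=smooth_span if smooth else 0.0,
    )


def segment_radius(
    traj: Trajectory,
    trial_id: int,
    segment: int,
    components: Sequence[int] = DEFAULT_RADIUS_COMPONENTS,
) -> SegmentGeometry:
    """Centroid-distance radius of one segment on the chosen plane."""
    idx = traj.segment_indices(trial_id, segment)
    if len(idx) < 3:
        raise ValueError("segment must have at least 3 bins")
    pts = traj.Y[np.ix_(idx, list(components))]
    centroid = pts.mean(axis=0)
    distances = np.linalg.norm(pts - centroid, axis=1)
    radius = float(distances.mean())
    if radius == 0:
        warnings.warn(f"degenerate segment (trial {trial_id}, segment {segment})")
    meta = traj.bins.iloc[idx[0]]
    return SegmentGeometry(
        trial_id=trial_id,
        segment=segment,
        target_interval_ms=float(meta["target_interval_ms"]),
        condition=str(meta["condition"]),
        repetition=int(meta["repetition"]),
        centroid=centroid,
        radius=radius,
        distances=distances,
    )


def linear_speed(
    traj: Trajectory,
    trial_id: int,
    segment: int,
    components: Sequence[int] = DEFAULT_SPEED_COMPONENTS,
) -> float:
    """Mean bin-to-bin speed (state units per ms of real time)."""
    idx = traj.segment_indices(trial_id, segment)
    if len(idx) < 2:
        raise ValueError("speed needs at least 2 bins")
    pts = traj.Y[np.ix_(idx, list(components))]
    dt = np.diff(traj.bins["time_ms"].to_numpy()[idx])
    if np.any(dt <= 0):
        raise ValueError("bin times must be increasing within a segment")
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return float(np.mean(steps / dt))


def geometry_table(
    traj: Trajectory,
    radius_components: Sequence[int] = DEFAULT_RADIUS_COMPONENTS,
    speed_components: Sequence[int] = DEFAULT_SPEED_COMPONENTS,
) -> tuple[list[SegmentGeometry], pd.DataFrame]:
    """Radius and speed for every segment of the trajectory."""
    geoms = []
    rows = []
    for _, key in traj.segment_keys().iterrows():
        tid, seg = int(key["trial_id"]), int(key["segment"])
        g = segment_radius(traj, tid, seg, radius_components)
        g.speed = linear_speed(traj, tid, seg, speed_components)
        geoms.append(g)
        rows.append(
            {
                "trial_id": tid,
                "repetition": g.repetition,
                "condition": g.condition,
                "target_interval_ms": g.target_interval_ms,
                "segment": seg,
                "radius": g.radius,
                "speed": g.speed,
                "n_bins": len(g.distances),
            }
        )
    return geoms, pd.DataFrame(rows)


def radius_variability(
    geometries: Sequence[SegmentGeometry],
    method: str = "pooled",
    expected_segments: int = 6,
) -> float:
    """Trajectory variability across serial-order segments.

    ``pooled`` (default): SD of the point-to-centroid distances pooled over
    segments.  ``radii``: SD of the per-segment radii.  Fewer than
    ``expected_segments`` segments is flagged but still computed.
    """
    if not geometries:
        raise ValueError("no segments supplied")
    if len(geometries) < expected_segments:
        warnings.warn(
            f"variability computed over {len(geometries)} segments "
            f"(< {expected_segments})"
        )
    if method == "pooled":
        pooled = np.concatenate([g.distances for g in geometries])
        return float(pooled.std())
    if method == "radii":
        return float(np.std([g.radius for g in geometries]))
    raise ValueError(f"unknown method {method!r}")


def percentile_split(
    radii: np.ndarray,
    produced_intervals_ms: np.ndarray,
    targets: np.ndarray,
    low: float = 20.0,
    high: float = 80.0,
) -> pd.DataFrame:
    """Mean radius of short- vs long-produced segments within each target.

    Segments are grouped by the within-target percentile of their produced
    interval: below ``low`` -> 'short', above ``high`` -> 'long'.
    """
    radii = np.asarray(radii, dtype=float)
    produced = np.asarray(produced_intervals_ms, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if not (radii.shape == produced.shape == targets.shape):
        raise ValueError("inputs must have identical shapes")
    rows = []
    for t in np.unique(targets):
        mask = targets == t
        if mask.sum() < 10:
            raise ValueError(f"need >= 10 observations per target (target {t})")
        p_lo = np.percentile(produced[mask], low)
        p_hi = np.percentile(produced[mask], high)
        short = mask & (produced < p_lo)
        long_ = mask & (produced > p_hi)
        rows.append(
            {
                "target_interval_ms": t,
                "short_mean_radius": float(radii[short].mean()) if short.any() else np.nan,
                "long_mean_radius": float(radii[long_].mean()) if long_.any() else np.nan,
                "n_short": int(short.sum()),
                "n_long": int(long_.sum()),
            }
        )
    return pd.DataFrame(rows)


def _resample_1d(y: np.ndarray, n: int) -> np.ndarray:
    old = np.arange(len(y), dtype=float)
    new = np.linspace(0, len(y) - 1, n)
    return np.interp(new, old, y)


def fit_sinusoid(
    segment_values: np.ndarray, n_bins: int = 30, detrend: bool = True
) -> SinusoidFit:
    """Least-squares sinusoid on a segment resampled to unit time.

    The segment is resampled to ``n_bins`` samples on t in [0, 1); a linear
    trend is removed first (set ``detrend=False`` to fit the raw values),
    then ``a*sin(2*pi*t + c) + d`` is fit with multiple phase starts.
    """
    y = _resample_1d(np.asarray(segment_values, dtype=float), n_bins)
    t = np.arange(n_bins) / n_bins
    if detrend:
        slope, intercept = np.polyfit(t, y, 1)
        y = y - (slope * t + intercept)

    def model(tt, a, c, d):
        return a * np.sin(2 * np.pi * tt + c) + d

    best = None
    converged = True
    a0 = max(np.std(y) * np.sqrt(2.0), 1e-6)
    for c0 in (0.0, np.pi / 2, np.pi, 3 * np.pi / 2):
        try:
            popt, _ = optimize.curve_fit(
                model, t, y, p0=[a0, c0, float(np.mean(y))], maxfev=5000
            )
        except RuntimeError:
            continue
        mse = float(np.mean((model(t, *popt) - y) ** 2))
        if best is None or mse < best[1]:
            best = (popt, mse)
    if best is None:
        # fall back to the linear-in-(sin, cos) solution, flagged
        A = np.column_stack([np.sin(2 * np.pi * t), np.cos(2 * np.pi * t), np.ones(n_bins)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        a = float(np.hypot(coef[0], coef[1]))
        c = float(np.arctan2(coef[1], coef[0]))
        mse = float(np.mean((A @ coef - y) ** 2))
        best = ((a, c, coef[2]), mse)
        converged = False
    (a, c, d), mse = best
    return SinusoidFit(amplitude=float(a), phase=float(c), offset=float(d), mse=mse, converged=converged)


def anchor_distances(
    tap_points: np.ndarray,
    half_points: np.ndarray,
    anchor: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distances from an anchor to tap states and half-interval states.

    The default anchor is the centroid of the tap states.  Returns
    ``(anchor, d_tap, d_half)``.
    """
    tap_points = np.atleast_2d(np.asarray(tap_points, dtype=float))
    half_points = np.atleast_2d(np.asarray(half_points, dtype=float))
    if anchor is None:
        anchor = tap_points.mean(axis=0)
    anchor = np.asarray(anchor, dtype=float)
    d_tap = np.linalg.norm(tap_points - anchor, axis=1)
    d_half = np.linalg.norm(half_points - anchor, axis=1)
    return anchor, d_tap, d_half


def _optimize_anchor(tap_points: np.ndarray) -> np.ndarray:
    """Anchor minimizing the variance of anchor-to-tap distances."""

    def cost(a):
        d = np.linalg.norm(tap_points - a, axis=1)
        return np.var(d)

    res = optimize.minimize(cost, tap_points.mean(axis=0), method="Nelder-Mead")
    return res.x


def anchor_distance_analysis(
    traj: Trajectory,
    components: Sequence[int] = DEFAULT_RADIUS_COMPONENTS,
    anchor_rule: str = "tap-centroid",
) -> AnchorDistances:
    """Anchor-point analysis over all segments of a (multi-tempo) trajectory.

    For each segment the state at the starting tap and at the half-interval
    bin are collected; distances to a single shared anchor are regressed on
    target interval.
    """
    tap_pts, half_pts, meta = [], [], []
    for _, key in traj.segment_keys().iterrows():
        idx = traj.segment_indices(int(key["trial_id"]), int(key["segment"]))
        pts = traj.Y[np.ix_(idx, list(components))]
        tap_pts.append(pts[0])
        half_pts.append(pts[len(idx) // 2])
        meta.append((float(key["target_interval_ms"]), int(key["segment"])))
    tap_pts = np.asarray(tap_pts)
    half_pts = np.asarray(half_pts)
    if anchor_rule == "tap-centroid":
        anchor = tap_pts.mean(axis=0)
    elif anchor_rule == "optimize":
        anchor = _optimize_anchor(tap_pts)
    else:
        raise ValueError(f"unknown anchor rule {anchor_rule!r}")
    anchor, d_tap, d_half = anchor_distances(tap_pts, half_pts, anchor)
    table = pd.DataFrame(
        {
            "target_interval_ms": [m[0] for m in meta],
            "segment": [m[1] for m in meta],
            "d_tap": d_tap,
            "d_half": d_half,
        }
    )
    if table["target_interval_ms"].nunique() >= 2:
        reg_t = stats.linregress(table["target_interval_ms"], table["d_tap"])
        reg_h = stats.linregress(table["target_interval_ms"], table["d_half"])
    else:
        reg_t = reg_h = None
    return AnchorDistances(
        anchor=anchor, table=table, d_tap_regression=reg_t, d_half_regression=reg_h
    )


def _segment_stack(
    traj: Trajectory, components: Sequence[int], n_bins: int
) -> np.ndarray:
    """(n_segments, n_bins, n_components) array of resampled segments."""
    out = []
    for _, key in traj.segment_keys().iterrows():
        idx = traj.segment_indices(int(key["trial_id"]), int(key["segment"]))
        pts = traj.Y[np.ix_(idx, list(components))]
        out.append(np.column_stack([_resample_1d(pts[:, c], n_bins) for c in range(pts.shape[1])]))
    return np.asarray(out)


def distance_profile(
    ref_traj: Trajectory,
    other_traj: Trajectory,
    components: Sequence[int] = DEFAULT_SPEED_COMPONENTS,
    n_bins: int = 30,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Bin-by-bin Euclidean distance between two trajectories.

    Both are resampled to ``n_bins`` per segment and must have the same
    number of segments; returns the full distance series plus per-segment
    mean and SD.
    """
    ref = _segment_stack(ref_traj, components, n_bins)
    oth = _segment_stack(other_traj, components, n_bins)
    if ref.shape[0] != oth.shape[0]:
        raise ValueError(
            f"segment count mismatch: {ref.shape[0]} vs {oth.shape[0]}"
        )
    dist = np.linalg.norm(ref - oth, axis=2)  # segments x bins
    summary = pd.DataFrame(
        {
            "segment": np.arange(dist.shape[0]),
            "mean_distance": dist.mean(axis=1),
            "sd_distance": dist.std(axis=1),
        }
    )
    return dist.ravel(), summary


def condition_mean_trajectory(traj: Trajectory, target_interval_ms: float, n_bins: int = 30) -> Trajectory:
    """Average a condition's segments (across trials) on a common time base.

    Produces a single-trial trajectory whose segments are the serial-order
    averages, resampled to ``n_bins``; used as the reference for
    cross-tempo distance profiles.
    """
    mask = traj.bins["target_interval_ms"] == target_interval_ms
    sub_bins = traj.bins.loc[mask]
    segments = sorted(sub_bins["segment"].unique())
    rows, meta_rows = [], []
    for seg in segments:
        stacks = []
        for tid in sub_bins["trial_id"].unique():
            idx = np.flatnonzero(
                ((traj.bins["trial_id"] == tid) & (traj.bins["segment"] == seg) & mask).to_numpy()
            )
            if idx.size == 0:
                continue
            pts = traj.Y[idx]
            stacks.append(
                np.column_stack([_resample_1d(pts[:, c], n_bins) for c in range(pts.shape[1])])
            )
        avg = np.mean(stacks, axis=0)
        rows.append(avg)
        for j in range(n_bins):
            meta_rows.append(
                (
                    -1,
                    str(sub_bins["condition"].iloc[0]),
                    target_interval_ms,
                    -1,
                    seg,
                    j,
                    seg + (j + 0.5) / n_bins,
                    seg * target_interval_ms + (j + 0.5) / n_bins * target_interval_ms,
                    target_interval_ms / n_bins,
                )
            )
    from .binning import BIN_META_COLUMNS

    return Trajectory(
        Y=np.vstack(rows),
        bins=pd.DataFrame(meta_rows, columns=BIN_META_COLUMNS),
        n_components=traj.n_components,
    )
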