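"""Decoding tempo from trajectory-segment shape and taps from component 1.

Interval decoding: each inter-tap segment of a chosen component is
resampled to 30 bins, a second-layer decomposition reduces segments to 3
coordinates, and a linear maximum-margin classifier is scored with
repeated stratified cross-validation.  Population ablation removes the
largest-loading neurons in 10% steps and re-runs the whole chain.

Tap decoding: a small time-delay network (20 delays, 10 sigmoid hidden
units, sigmoid output) is trained to emit 1 at tap bins; output peaks
above 0.12 are decoded taps, counted correct within a 60-ms window.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .binning import BinnedPopulation
from .geometry import CoeffMatrix, Trajectory, project

__all__ = [
    "SegmentCloud",
    "AblationSchedule",
    "TapDecoder",
    "build_segment_cloud",
    "classify_interval",
    "best_component",
    "ablation_schedule",
    "ablate_and_classify",
    "train_tap_decoder",
    "decode_taps",
    "match_taps",
]

SEGMENT_RESAMPLE_BINS = 30
SECOND_LAYER_COMPONENTS = 3
DEFAULT_OUTPUT_THRESHOLD = 0.12
DEFAULT_CORRECT_WINDOW_MS = 60.0
N_DELAYS = 20
N_HIDDEN = 10


@dataclass
class SegmentCloud:
    """One 3-coordinate point per trajectory segment."""

    points: np.ndarray  # segments x 3
    targets: np.ndarray  # target interval label per segment
    segments: np.ndarray  # serial-order index
    repetitions: np.ndarray
    component: int

    def __post_init__(self) -> None:
        if self.points.shape[0] != len(self.targets):
            raise ValueError("points and labels must align")


@dataclass
class AblationSchedule:
    """Neuron ranking by loading magnitude plus retained fractions."""

    ordered_neurons: np.ndarray  # descending |loading| on the best component
    fractions: tuple[float, ...] = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1, 0.01)
    best_component: int = 0

    def __post_init__(self) -> None:
        if any(f2 >= f1 for f1, f2 in zip(self.fractions, self.fractions[1:])):
            raise ValueError("fractions must be strictly decreasing")
        if min(self.fractions) <= 0:
            raise ValueError("fractions must be positive")

    def retained(self, fraction: float) -> np.ndarray:
        """Neurons kept at a step: drop the top (1-f) largest loadings."""
        n = len(self.ordered_neurons)
        keep = max(int(round(fraction * n)), 1)
        return self.ordered_neurons[n - keep :]


def _resample_1d(y: np.ndarray, n: int) -> np.ndarray:
    old = np.arange(len(y), dtype=float)
    return np.interp(np.linspace(0, len(y) - 1, n), old, y)


def build_segment_cloud(
    traj: Trajectory,
    component: int = 0,
    n_bins: int = SEGMENT_RESAMPLE_BINS,
    n_out: int = SECOND_LAYER_COMPONENTS,
) -> SegmentCloud:
    """Second-layer decomposition of one component's segments.

    Segments shorter than 3 bins are excluded with a warning.
    """
    import warnings

    from sklearn.decomposition import PCA

    rows, targets, segs, reps = [], [], [], []
    for _, key in traj.segment_keys().iterrows():
        idx = traj.segment_indices(int(key["trial_id"]), int(key["segment"]))
        if len(idx) < 3:
            warnings.warn(
                f"segment (trial {key['trial_id']}, {key['segment']}) too short; excluded"
            )
            continue
        rows.append(_resample_1d(traj.Y[idx, component], n_bins))
        targets.append(float(key["target_interval_ms"]))
        segs.append(int(key["segment"]))
        reps.append(int(key["repetition"]))
    M = np.asarray(rows)
    if M.shape[0] < 2:
        raise ValueError("need at least 2 segments")
    k = min(n_out, M.shape[0], M.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    pts = pca.fit_transform(M)
    if k < n_out:  # degenerate tiny inputs: pad for a stable interface
        pts = np.column_stack([pts, np.zeros((pts.shape[0], n_out - k))])
    return SegmentCloud(
        points=pts,
        targets=np.asarray(targets),
        segments=np.asarray(segs),
        repetitions=np.asarray(reps),
        component=component,
    )


def classify_interval(
    cloud: SegmentCloud,
    repeats: int = 10,
    folds: int = 5,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Linear SVM accuracy under repeated stratified cross-validation.

    Returns (mean, SD, per-split accuracies).
    """
    from sklearn.model_selection import RepeatedStratifiedKFold, cross_val_score
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    labels = cloud.targets
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"every class needs >= {folds} segments (smallest has {counts.min()})"
        )
    clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    scores = cross_val_score(clf, cloud.points, labels, cv=cv)
    return float(scores.mean()), float(scores.std()), scores


def best_component(
    traj: Trajectory,
    candidates: Sequence[int] = (0, 1, 2),
    repeats: int = 3,
    folds: int = 5,
    seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """Component whose segment cloud classifies target interval best."""
    accs = {}
    for c in candidates:
        cloud = build_segment_cloud(traj, component=c)
        accs[c] = classify_interval(cloud, repeats=repeats, folds=folds, seed=seed)[0]
    best = max(accs, key=accs.get)
    return best, accs


def ablation_schedule(
    coeffs: CoeffMatrix,
    best_comp: int,
    fractions: tuple[float, ...] | None = None,
) -> AblationSchedule:
    """Rank neurons by |loading| on the best component (descending)."""
    weights = np.abs(coeffs.P[best_comp])
    order = np.argsort(weights)[::-1]
    sched = AblationSchedule(ordered_neurons=coeffs.neuron_ids[order], best_component=best_comp)
    if fractions is not None:
        sched.fractions = fractions
        sched.__post_init__()
    return sched


def ablate_and_classify(
    binned: BinnedPopulation,
    coeffs: CoeffMatrix,
    schedule: AblationSchedule,
    component: int | None = None,
    repeats: int = 10,
    folds: int = 5,
    seed: int = 0,
    refit: bool = False,
) -> pd.DataFrame:
    """Classification accuracy as the largest-loading neurons are removed.

    At each retained fraction the trajectories are re-projected (with the
    original loadings restricted to the surviving neurons, or refit when
    ``refit=True``), the second-layer cloud rebuilt and the classifier
    rescored.
    """
    from .geometry import fit_coefficients

    component = schedule.best_component if component is None else component
    rows = []
    for frac in schedule.fractions:
        keep = schedule.retained(frac)
        keep_sorted = [n for n in binned.neuron_ids if n in set(keep.tolist())]
        sub = binned.select_neurons(keep_sorted)
        if refit:
            sub_coeffs = fit_coefficients(sub)
        else:
            index = {n: i for i, n in enumerate(coeffs.neuron_ids)}
            rows_idx = [index[n] for n in keep_sorted]
            sub_coeffs = CoeffMatrix(
                P=coeffs.P[:, rows_idx],
                mean=coeffs.mean[rows_idx],
                explained_variance_ratio=coeffs.explained_variance_ratio,
                neuron_ids=np.asarray(keep_sorted),
                n_retained=coeffs.n_retained,
            )
        traj = project(sub_coeffs, sub)
        cloud = build_segment_cloud(traj, component=component)
        mean, sd, _ = classify_interval(cloud, repeats=repeats, folds=folds, seed=seed)
        rows.append(
            {
                "retained_fraction": frac,
                "n_neurons": len(keep_sorted),
                "accuracy_mean": mean,
                "accuracy_sd": sd,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# time-delay tap decoder


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -35, 35)))


def _delay_matrix(series: np.ndarray, n_delays: int) -> np.ndarray:
    """Rows are the ``n_delays`` most recent samples (left-padded)."""
    padded = np.concatenate([np.full(n_delays - 1, series[0]), series])
    return np.lib.stride_tricks.sliding_window_view(padded, n_delays)


@dataclass
class TapDecoder:
    """Trained time-delay network plus its evaluation conventions."""

    n_delays: int = N_DELAYS
    n_hidden: int = N_HIDDEN
    threshold: float = DEFAULT_OUTPUT_THRESHOLD
    window_ms: float = DEFAULT_CORRECT_WINDOW_MS
    bin_ms: float = 20.0
    W1: np.ndarray | None = None  # hidden x (delays + 1)
    w2: np.ndarray | None = None  # hidden + 1
    ridge: float = 1e-3
    fold_assignments: np.ndarray | None = None
    fold_outputs: list = field(default_factory=list)

    def output(self, series: np.ndarray) -> np.ndarray:
        if self.W1 is None:
            raise RuntimeError("decoder is untrained")
        X = _delay_matrix(np.asarray(series, dtype=float), self.n_delays)
        H = _sigmoid(X @ self.W1[:, :-1].T + self.W1[:, -1])
        return _sigmoid(H @ self.w2[:-1] + self.w2[-1])


def _pack(W1: np.ndarray, w2: np.ndarray) -> np.ndarray:
    return np.concatenate([W1.ravel(), w2])


def _unpack(theta: np.ndarray, n_hidden: int, n_delays: int):
    n1 = n_hidden * (n_delays + 1)
    return theta[:n1].reshape(n_hidden, n_delays + 1), theta[n1:]


def _loss_grad(theta, X, t, n_hidden, n_delays, ridge):
    W1, w2 = _unpack(theta, n_hidden, n_delays)
    Z = X @ W1[:, :-1].T + W1[:, -1]
    H = _sigmoid(Z)
    u = H @ w2[:-1] + w2[-1]
    y = _sigmoid(u)
    err = y - t
    n = len(t)
    loss = float(np.mean(err**2)) + ridge * float(theta @ theta)
    dy = 2.0 * err * y * (1 - y) / n
    gw2 = np.concatenate([H.T @ dy, [dy.sum()]])
    dH = np.outer(dy, w2[:-1]) * H * (1 - H)
    gW1 = np.column_stack([dH.T @ X, dH.sum(axis=0)])
    grad = _pack(gW1, gw2) + 2.0 * ridge * theta
    return loss, grad


def _fit_network(
    X: np.ndarray,
    t: np.ndarray,
    rng: np.random.Generator,
    n_hidden: int,
    n_delays: int,
    ridge: float,
    restarts: int = 4,
) -> tuple[np.ndarray, np.ndarray, bool]:
    best = None
    converged = False
    for _ in range(restarts):
        theta0 = rng.normal(0.0, 0.5, n_hidden * (n_delays + 1) + n_hidden + 1)
        res = optimize.minimize(
            _loss_grad,
            theta0,
            args=(X, t, n_hidden, n_delays, ridge),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 1000},
        )
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)
    W1, w2 = _unpack(best.x, n_hidden, n_delays)
    return W1, w2, converged


def _tap_targets(n_bins: int, tap_times_ms: np.ndarray, bin_ms: float) -> np.ndarray:
    t = np.zeros(n_bins)
    for tap in tap_times_ms:
        j = int(tap // bin_ms)  # the bin containing the tap
        if 0 <= j < n_bins:
            t[j] = 1.0
    return t


def train_tap_decoder(
    series_list: Sequence[np.ndarray],
    tap_times_list: Sequence[np.ndarray],
    folds: int = 5,
    bin_ms: float = 20.0,
    seed: int = 0,
    ridge_grid: tuple[float, ...] = (1e-4, 1e-3, 1e-2),
    threshold: float = DEFAULT_OUTPUT_THRESHOLD,
    window_ms: float = DEFAULT_CORRECT_WINDOW_MS,
    require_full_context: bool = True,
) -> tuple[TapDecoder, pd.DataFrame]:
    """K-fold training of the tap decoder over trials.

    ``series_list`` holds per-trial component-1 series (20-ms bins) and
    ``tap_times_list`` the matching tap times in ms from the series start.
    The ridge penalty is chosen on an inner split of the training trials.
    Returns the decoder (trained on all trials with the selected penalty)
    and a per-fold report of held-out tap hits.

    With ``require_full_context`` (default) taps occurring before one full
    delay window of data exist are not scored: the network has no causal
    history there, only left padding.
    """
    if len(series_list) != len(tap_times_list):
        raise ValueError("series and tap lists must align")
    if len(series_list) < folds:
        raise ValueError("need at least one trial per fold")
    rng = np.random.default_rng(seed)
    n_trials = len(series_list)
    assign = np.arange(n_trials) % folds
    rng.shuffle(assign)

    def build(idx):
        Xs, ts = [], []
        for i in idx:
            s = np.asarray(series_list[i], dtype=float)
            Xs.append(_delay_matrix(s, N_DELAYS))
            ts.append(_tap_targets(len(s), np.asarray(tap_times_list[i]), bin_ms))
        return np.vstack(Xs), np.concatenate(ts)

    # inner ridge selection on a single split of the trials
    inner_train = np.arange(n_trials)[: max(n_trials * 4 // 5, 1)]
    inner_val = np.arange(n_trials)[max(n_trials * 4 // 5, 1) :]
    if len(inner_val) == 0:
        inner_val = inner_train[-1:]
    Xtr, ttr = build(inner_train)
    Xva, tva = build(inner_val)
    best_ridge, best_err = ridge_grid[0], np.inf
    for ridge in ridge_grid:
        W1, w2, _ = _fit_network(Xtr, ttr, rng, N_HIDDEN, N_DELAYS, ridge, restarts=1)
        H = _sigmoid(Xva @ W1[:, :-1].T + W1[:, -1])
        y = _sigmoid(H @ w2[:-1] + w2[-1])
        err = float(np.mean((y - tva) ** 2))
        if err < best_err:
            best_ridge, best_err = ridge, err

    report_rows = []
    for fold in range(folds):
        train_idx = np.flatnonzero(assign != fold)
        test_idx = np.flatnonzero(assign == fold)
        Xtr, ttr = build(train_idx)
        W1, w2, _ = _fit_network(Xtr, ttr, rng, N_HIDDEN, N_DELAYS, best_ridge)
        fold_dec = TapDecoder(bin_ms=bin_ms, W1=W1, w2=w2, ridge=best_ridge,
                              threshold=threshold, window_ms=window_ms)
        for i in test_idx:
            true_taps = np.asarray(tap_times_list[i], dtype=float)
            if require_full_context:
                true_taps = true_taps[true_taps >= N_DELAYS * bin_ms]
            decoded, errors, n_correct, n_true = decode_taps(
                fold_dec, series_list[i], true_taps
            )
            report_rows.append(
                {
                    "fold": fold,
                    "trial": i,
                    "n_true_taps": n_true,
                    "n_decoded": len(decoded),
                    "n_correct": n_correct,
                    "mean_error_ms": float(np.mean(errors)) if len(errors) else np.nan,
                }
            )

    Xall, tall = build(np.arange(n_trials))
    W1, w2, converged = _fit_network(Xall, tall, rng, N_HIDDEN, N_DELAYS, best_ridge)
    decoder = TapDecoder(
        bin_ms=bin_ms, W1=W1, w2=w2, ridge=best_ridge, fold_assignments=assign,
        threshold=threshold, window_ms=window_ms,
    )
    if not converged:
        import warnings

        warnings.warn("tap decoder optimizer did not report convergence; best restart kept")
    return decoder, pd.DataFrame(report_rows)


def match_taps(
    decoded_ms: np.ndarray, true_ms: np.ndarray, window_ms: float
) -> tuple[int, np.ndarray]:
    """Greedy nearest matching; each side is consumable once.

    Candidate (decoded, true) pairs are taken closest-first, so a spurious
    extra peak cannot steal a true tap from a nearer peak.  Returns the
    number of matched pairs within the window and their signed errors
    (decoded - true).
    """
    decoded = np.asarray(decoded_ms, dtype=float)
    true = np.asarray(true_ms, dtype=float)
    if decoded.size == 0 or true.size == 0:
        return 0, np.empty(0)
    cand = sorted(
        ((abs(d - t), i, j) for i, d in enumerate(decoded) for j, t in enumerate(true)),
        key=lambda c: c[0],
    )
    used_d: set[int] = set()
    used_t: set[int] = set()
    errors = []
    for _, i, j in cand:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        errors.append(decoded[i] - true[j])
    errors = np.asarray(errors)
    n_correct = int(np.sum(np.abs(errors) < window_ms))
    return n_correct, errors


def decode_taps(
    decoder: TapDecoder,
    series: np.ndarray,
    true_tap_times_ms: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Taps from output peaks above threshold.

    Returns (decoded tap times, signed errors vs matched true taps,
    number correct within the window, number of true taps).  With no true
    taps supplied the last three are empty/zero.
    """
    y = decoder.output(series)
    peaks, _ = signal.find_peaks(y, height=decoder.threshold)
    decoded = (peaks + 0.5) * decoder.bin_ms  # bin centers
    if true_tap_times_ms is None or len(true_tap_times_ms) == 0:
        return decoded, np.empty(0), 0, 0
    n_correct, errors = match_taps(decoded, true_tap_times_ms, decoder.window_ms)
    return decoded, errors, n_correct, len(true_tap_times_ms)
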