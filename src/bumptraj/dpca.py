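"""Demixed decomposition of condition-averaged population rates.

The data matrix is split into parameter-specific averages (a
condition-independent time course and a target-interval-dependent part)
plus a residual, and a separate reduced-rank encoder/decoder pair is fit
per marginalization by minimizing

    sum_phi || X_phi - F_phi D_phi X ||^2

via ridge-regularized reduced-rank regression in closed form.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .binning import BinnedPopulation, resample_segments

__all__ = ["Marginalization", "DpcaModel", "marginalize", "fit_dpca", "condition_average"]


@dataclass
class Marginalization:
    """Parameter-specific averages, shaped neurons x conditions x bins."""

    grand_mean: np.ndarray  # neurons
    parts: dict  # name -> neurons x conditions x bins
    residual: np.ndarray  # neurons x conditions x bins
    condition_labels: np.ndarray
    n_bins: int

    def reconstruct(self) -> np.ndarray:
        total = self.grand_mean[:, None, None] + self.residual
        for part in self.parts.values():
            total = total + part
        return total


@dataclass
class DpcaModel:
    """Per-parameter encoder/decoder pairs and component bookkeeping."""

    marginalization: Marginalization
    encoders: dict  # name -> neurons x components (F)
    decoders: dict  # name -> components x neurons (D)
    scores: dict  # name -> components x (conditions * bins)
    explained_variance: dict  # name -> per-component fraction of marginalized var
    regularization: float

    def loss(self) -> float:
        """Value of the summed reduced-rank loss at the fitted matrices."""
        Xc = _flatten(self.marginalization, centered=True)
        total = 0.0
        for name, part in self.marginalization.parts.items():
            approx = self.encoders[name] @ (self.decoders[name] @ Xc)
            total += float(np.sum((part.reshape(part.shape[0], -1) - approx) ** 2))
        return total

    def project(self, name: str, X: np.ndarray) -> np.ndarray:
        """Project (possibly single-trial) data with a fitted decoder."""
        return self.decoders[name] @ (X - self.marginalization.grand_mean[:, None])


def condition_average(binned: BinnedPopulation, n_bins: int = 30) -> Marginalization:
    """Resample to a common bin count and average trials per condition.

    Conditions are target intervals; the result feeds :func:`marginalize`.
    """
    res = resample_segments(binned, n_bins)
    targets = np.sort(res.bins["target_interval_ms"].unique())
    stack = []
    for t in targets:
        cols = []
        for j in range(n_bins):
            mask = (res.bins["target_interval_ms"] == t) & (res.bins["bin_in_segment"] == j)
            cols.append(res.X[:, mask.to_numpy()].mean(axis=1))
        stack.append(np.column_stack(cols))
    data = np.stack(stack, axis=1)  # neurons x conditions x bins
    return marginalize(data, targets)


def marginalize(data: np.ndarray, condition_labels: np.ndarray) -> Marginalization:
    """Split neurons x conditions x bins data into marginalized averages.

    ``time``: condition-independent time course (mean over conditions,
    grand mean removed).  ``interval``: what remains after removing the
    time course — the interval-dependent signal including its interaction
    with time.  The parts plus grand mean reconstruct the input exactly.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("expected neurons x conditions x bins")
    if data.shape[1] != len(condition_labels):
        raise ValueError("condition_labels must match axis 1")
    grand = data.mean(axis=(1, 2))
    centered = data - grand[:, None, None]
    time_part = centered.mean(axis=1, keepdims=True) * np.ones((1, data.shape[1], 1))
    interval_part = centered - time_part
    residual = np.zeros_like(data)
    return Marginalization(
        grand_mean=grand,
        parts={"time": time_part, "interval": interval_part},
        residual=residual,
        condition_labels=np.asarray(condition_labels),
        n_bins=data.shape[2],
    )


def _flatten(marg: Marginalization, centered: bool = True) -> np.ndarray:
    total = marg.reconstruct()
    flat = total.reshape(total.shape[0], -1)
    if centered:
        flat = flat - marg.grand_mean[:, None]
    return flat


def fit_dpca(
    marg: Marginalization, n_components: int = 5, regularization: float | None = None
) -> DpcaModel:
    """Closed-form reduced-rank solution per marginalization.

    For each parameter the unconstrained ridge solution
    ``A = X_phi X' (X X' + lam I)^-1`` is rank-reduced by projecting onto
    the leading left singular vectors of ``A X``; components are ordered by
    explained marginalized variance.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    Xc = _flatten(marg, centered=True)
    n_neurons = Xc.shape[0]
    cov = Xc @ Xc.T
    if regularization is None:
        mean_diag = float(np.trace(cov)) / max(n_neurons, 1)
        regularization = 1e-6 * mean_diag
    if regularization <= 0 and np.linalg.matrix_rank(cov) < n_neurons:
        warnings.warn("rank-deficient covariance; falling back to ridge")
        regularization = 1e-6 * float(np.trace(cov)) / max(n_neurons, 1)
    G = np.linalg.solve(cov + regularization * np.eye(n_neurons), Xc)  # = (XX'+lI)^-1 X

    encoders, decoders, scores, evar = {}, {}, {}, {}
    for name, part in marg.parts.items():
        flat = part.reshape(n_neurons, -1)
        A = flat @ G.T  # X_phi X' (XX' + lI)^-1
        r = min(n_components, n_neurons)
        U, _, _ = np.linalg.svd(A @ Xc, full_matrices=False)
        U = U[:, :r]
        D = U.T @ A
        S = D @ Xc
        # order components by captured marginalized variance
        total_var = float(np.sum(flat**2))
        comp_var = np.array(
            [float(np.sum((np.outer(U[:, i], S[i])) ** 2)) for i in range(r)]
        )
        order = np.argsort(comp_var)[::-1]
        U, D, S, comp_var = U[:, order], D[order], S[order], comp_var[order]
        encoders[name] = U
        decoders[name] = D
        scores[name] = S
        evar[name] = comp_var / total_var if total_var > 0 else comp_var
    return DpcaModel(
        marginalization=marg,
        encoders=encoders,
        decoders=decoders,
        scores=scores,
        explained_variance=evar,
        regularization=regularization,
    )
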