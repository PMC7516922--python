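"""Optimal transformations by alternating conditional expectations (ACE).

The pair of transforms ``h1(X)``, ``h2(Y)`` that best linearize an arbitrary
bivariate relationship ``h2(Y) = h1(X) + error`` is estimated by a simplified
alternating iteration: starting from the standardized response,

    h1(X) <- E[h2(Y) | X]          (a scatterplot smoother)
    h2(Y) <- E[h1(X) | Y] / ||.||  (smoothed, centered, unit norm)

until the sum of squared errors ``SSE = sum_i (h2_i - h1_i)^2`` stops
decreasing.  ``h2`` is constrained to sample mean zero and unit Euclidean
norm throughout, so SSE is directly the unexplained fraction of ``h2``.

The conditional expectations are estimated with a rank-space k-nearest-
neighbor smoother (local mean or local linear fit over a centered window of
k points in sort order, ties pooled).  The window fraction ``span`` is the
main stiffness knob: small spans track curvature closely but inflate the
apparent association of independent data; large spans do the opposite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike

from .measures import DegenerateInputError, PairedSample

__all__ = [
    "SmootherSpec",
    "TransformState",
    "smooth_conditional_mean",
    "center_and_normalize",
    "ace_fit",
]


@dataclass(frozen=True)
class SmootherSpec:
    """Configuration of the conditional-expectation smoother.

    Parameters
    ----------
    method:
        ``"local_linear"`` fits a least-squares line within each window and
        evaluates it at the query point (no first-order bias, exact for
        affine targets); ``"knn_local_mean"`` averages the window.
    span:
        Window size as a fraction of n, in (0, 1].
    min_neighbors:
        Lower bound on the window size, >= 2.
    """

    method: str = "local_linear"
    span: float = 0.40
    min_neighbors: int = 5

    def __post_init__(self) -> None:
        if self.method not in ("local_linear", "knn_local_mean"):
            raise ValueError(f"unknown smoother method {self.method!r}")
        if not 0.0 < self.span <= 1.0:
            raise ValueError("span must be in (0, 1]")
        if self.min_neighbors < 2:
            raise ValueError("min_neighbors must be >= 2")

    def effective_k(self, n: int) -> int:
        """Window size actually used for a sample of size n."""
        return min(n, max(self.min_neighbors, int(round(self.span * n))))


@dataclass(frozen=True)
class TransformState:
    """Fitted transform values and the optimization trace."""

    h1: np.ndarray
    h2: np.ndarray
    sse_trace: list
    n_iter: int
    converged: bool


def _window_bounds(starts: np.ndarray, ends: np.ndarray, n: int, k: int):
    """Per tie-group half-open window [a, b) of >= k sorted positions.

    The nominal window of k positions is centered on the group's mean rank
    and clipped at the edges of the sample; both ends are then extended
    outward to tie-group boundaries so that equal conditioner values always
    share one pooled neighborhood.
    """
    r = (starts + ends - 1) / 2.0
    a0 = np.floor(r - (k - 1) / 2.0 + 0.5).astype(int)
    a0 = np.clip(a0, 0, n - k)
    b0 = a0 + k
    a = starts[np.searchsorted(starts, a0, side="right") - 1]
    b = ends[np.searchsorted(starts, b0 - 1, side="right") - 1]
    return a, b


def smooth_conditional_mean(
    target: ArrayLike, conditioner: ArrayLike, spec: SmootherSpec | None = None
) -> np.ndarray:
    """Estimate E[target | conditioner] at every sample point.

    Sorts by the conditioner and, for each point, pools the k nearest
    neighbors in rank space (k from ``spec.effective_k``; tied conditioner
    values share one neighborhood).  ``knn_local_mean`` returns the window
    average; ``local_linear`` the windowed least-squares line evaluated at
    the point, falling back to the average when the window is constant.
    Deterministic in its inputs.
    """
    if spec is None:
        spec = SmootherSpec()
    t = np.asarray(target, dtype=float).ravel()
    c = np.asarray(conditioner, dtype=float).ravel()
    if t.shape != c.shape:
        raise ValueError("target and conditioner must have equal length")
    n = t.size
    if n < spec.min_neighbors:
        raise ValueError(
            f"need at least min_neighbors={spec.min_neighbors} points, got {n}"
        )
    k = spec.effective_k(n)

    order = np.argsort(c, kind="stable")
    cs, ts = c[order], t[order]
    _, starts = np.unique(cs, return_index=True)
    ends = np.append(starts[1:], n)
    a, b = _window_bounds(starts, ends, n, k)
    m = (b - a).astype(float)

    ct = np.concatenate([[0.0], np.cumsum(ts)])
    mean_t = (ct[b] - ct[a]) / m

    if spec.method == "knn_local_mean":
        fitted = mean_t
    else:
        cc = np.concatenate([[0.0], np.cumsum(cs)])
        ccc = np.concatenate([[0.0], np.cumsum(cs * cs)])
        cct = np.concatenate([[0.0], np.cumsum(cs * ts)])
        sum_c = cc[b] - cc[a]
        mean_c = sum_c / m
        var_c = (ccc[b] - ccc[a]) - sum_c * mean_c
        cov_ct = (cct[b] - cct[a]) - sum_c * mean_t
        scale = np.maximum((ccc[b] - ccc[a]), 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.where(var_c > 1e-12 * scale, cov_ct / var_c, 0.0)
        fitted = mean_t + slope * (cs[starts] - mean_c)

    out_sorted = np.repeat(fitted, ends - starts)
    out = np.empty(n)
    out[order] = out_sorted
    return out


def center_and_normalize(v: ArrayLike, unit_norm: bool = True) -> np.ndarray:
    """Subtract the mean; optionally scale to unit Euclidean norm.

    Raises
    ------
    DegenerateInputError
        If ``unit_norm`` is requested and the centered vector has
        (numerically) zero norm.
    """
    v = np.asarray(v, dtype=float).ravel()
    c = v - v.mean()
    if not unit_norm:
        return c
    norm = float(np.linalg.norm(c))
    if norm <= 1e-300 or norm <= 1e-14 * max(1.0, float(np.abs(v).max())):
        raise DegenerateInputError("zero norm after centering")
    return c / norm


def ace_fit(
    sample: PairedSample,
    spec: SmootherSpec | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
    patience: int = 2,
) -> TransformState:
    """Fit the optimal transform pair (h1, h2) by alternating smoothing.

    Starts from ``h2 = (y - mean(y)) / ||y - mean(y)||`` and alternates the
    two conditional-expectation updates, recording ``SSE = sum (h2-h1)^2``
    each iteration.  Terminates once SSE has failed to improve on the best
    value by more than ``tol`` for ``patience + 1`` consecutive iterations
    (the first iterations of hard cases such as circular data can plateau
    briefly before the main descent) or at ``max_iter``; the lowest-SSE
    iterate is returned.  The signs of h1 and h2 are flipped jointly so
    that corr(h2, y) >= 0 when that correlation is defined.

    Returns
    -------
    TransformState
        h1 mean-zero; h2 mean-zero, unit-norm; the SSE trace; the number of
        iterations run; and a convergence flag (False only when the loop
        exhausted ``max_iter`` while still improving).
    """
    if spec is None:
        spec = SmootherSpec()
    x, y = sample.x, sample.y
    if sample.n < 2 * spec.min_neighbors:
        raise ValueError(
            f"need n >= 2*min_neighbors = {2 * spec.min_neighbors}, got {sample.n}"
        )
    h2 = center_and_normalize(y, unit_norm=True)
    best_h1 = best_h2 = None
    best_sse = np.inf
    trace: list[float] = []
    stalled = 0
    converged = True
    for _ in range(max_iter):
        h1 = smooth_conditional_mean(h2, x, spec)
        h1 = h1 - h1.mean()
        h2 = center_and_normalize(smooth_conditional_mean(h1, y, spec), unit_norm=True)
        sse = float(np.sum((h2 - h1) ** 2))
        trace.append(sse)
        if sse < best_sse - tol:
            best_sse = sse
            best_h1, best_h2 = h1.copy(), h2.copy()
            stalled = 0
        else:
            stalled += 1
            if stalled > patience:
                break
    else:
        converged = False

    yc = y - y.mean()
    sign_ref = float(best_h2 @ yc)
    if sign_ref < 0.0:
        best_h1, best_h2 = -best_h1, -best_h2
    return TransformState(
        h1=best_h1,
        h2=best_h2,
        sse_trace=trace,
        n_iter=len(trace),
        converged=converged,
    )
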