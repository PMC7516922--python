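"""Benchmark dependence measures: entropic distance, MIC, DFA, detrended Pearson.

These are the comparators the Association Factor is evaluated against.
None of them is the package's contribution; each is implemented in the
plain form needed for side-by-side Monte Carlo comparison on small
bivariate samples (n of order 100):

* ``entropic_distance`` -- the conditional entropy H(X|Y) of the
  discretized sample, an unbounded measure that *decreases* as knowing Y
  pins down X.
* ``mic`` -- maximal information coefficient: normalized mutual information
  maximized over axis-aligned grids under a total-cell budget.
* ``dfa_fluctuation`` -- detrended fluctuation analysis of a series:
  RMS residual of the integrated, per-box linearly detrended profile as a
  function of box size.
* ``detrended_pearson`` -- Pearson correlation after removing per-box
  linear trends (in x-sorted order) from both coordinates, the scatterplot
  analogue of DFA detrending.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike

from .measures import PairedSample, pearson

__all__ = [
    "EntropicDistanceSpec",
    "DFAConfig",
    "entropic_distance",
    "entropy_reduction",
    "ed_ratio",
    "mic",
    "dfa_fluctuation",
    "detrended_pearson",
]


@dataclass(frozen=True)
class EntropicDistanceSpec:
    """Discretization used by :func:`entropic_distance`.

    With ``n_bins_x``/``n_bins_y`` unset, each axis uses
    ``ceil(sqrt(n))`` equal-width bins; the entropy is reported in units of
    ``log_base`` (bits for base 2).
    """

    n_bins_x: int | None = None
    n_bins_y: int | None = None
    log_base: float = 2.0
    binning: str = "equal_width"

    def __post_init__(self) -> None:
        for nb in (self.n_bins_x, self.n_bins_y):
            if nb is not None and nb < 2:
                raise ValueError("bin counts must be >= 2")
        if self.log_base <= 1.0:
            raise ValueError("log_base must exceed 1")
        if self.binning not in ("equal_width", "equal_frequency"):
            raise ValueError(f"unknown binning {self.binning!r}")


@dataclass(frozen=True)
class DFAConfig:
    """Box sizes and detrending order for DFA-style analyses."""

    box_sizes: tuple = (4, 8, 16)
    detrend_order: int = 1

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.box_sizes)
        if any(s < 4 for s in sizes):
            raise ValueError("box sizes must be >= 4")
        if list(sizes) != sorted(set(sizes)):
            raise ValueError("box sizes must be strictly increasing")
        object.__setattr__(self, "box_sizes", sizes)
        if self.detrend_order != 1:
            raise ValueError("only linear (order 1) detrending is supported")


def _bin_indices(v: np.ndarray, n_bins: int, binning: str) -> np.ndarray:
    if binning == "equal_width":
        lo, hi = v.min(), v.max()
        if hi == lo:
            return np.zeros(v.size, dtype=int)
        edges = np.linspace(lo, hi, n_bins + 1)
    else:
        qs = np.quantile(v, np.linspace(0, 1, n_bins + 1))
        edges = np.unique(qs)
        if edges.size < 2:
            return np.zeros(v.size, dtype=int)
    idx = np.searchsorted(edges, v, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def _joint_counts(sample: PairedSample, spec: EntropicDistanceSpec) -> np.ndarray:
    n = sample.n
    default = int(np.ceil(np.sqrt(n)))
    nbx = spec.n_bins_x or default
    nby = spec.n_bins_y or default
    if n < max(nbx, nby):
        raise ValueError("need at least as many observations as bins")
    ix = _bin_indices(sample.x, nbx, spec.binning)
    iy = _bin_indices(sample.y, nby, spec.binning)
    counts = np.zeros((nbx, nby))
    np.add.at(counts, (ix, iy), 1.0)
    return counts


def _conditional_entropy(counts: np.ndarray, log_base: float) -> float:
    """H(X|Y) from a joint count table with x in rows, y in columns.

    Empty cells contribute nothing (the 0 log 0 = 0 convention).
    """
    total = counts.sum()
    p_y = counts.sum(axis=0) / total
    h = 0.0
    for j in range(counts.shape[1]):
        if p_y[j] == 0.0:
            continue
        p_x_given_y = counts[:, j] / counts[:, j].sum()
        nz = p_x_given_y > 0
        h -= p_y[j] * np.sum(
            p_x_given_y[nz] * np.log(p_x_given_y[nz]) / np.log(log_base)
        )
    return max(float(h), 0.0)


def entropic_distance(
    sample: PairedSample, spec: EntropicDistanceSpec | None = None
) -> float:
    """Conditional entropy H(X|Y) of the discretized sample, >= 0."""
    if spec is None:
        spec = EntropicDistanceSpec()
    return _conditional_entropy(_joint_counts(sample, spec), spec.log_base)


def entropy_reduction(
    sample: PairedSample, spec: EntropicDistanceSpec | None = None
) -> float:
    """Entropy reduction H(X) - H(X|Y): how much knowing Y pins down X.

    This is the binned mutual information, the "difference between the
    entropies with and without the condition".  Unlike the conditional
    entropy itself it *decreases* as noise is added, which is the behavior
    tracked in noise-robustness comparisons; both views share the same
    discretization.
    """
    if spec is None:
        spec = EntropicDistanceSpec()
    counts = _joint_counts(sample, spec)
    p_x = counts.sum(axis=1) / counts.sum()
    nz = p_x > 0
    h_x = float(-np.sum(p_x[nz] * np.log(p_x[nz]) / np.log(spec.log_base)))
    return max(h_x - _conditional_entropy(counts, spec.log_base), 0.0)


def ed_ratio(ed_high: float, ed_low: float) -> float:
    """Percentage ratio ed_high / ed_low * 100 across two noise conditions."""
    from .association import UndefinedRatioError

    if ed_high < 0.0 or ed_low < 0.0:
        raise ValueError("entropic distances must be non-negative")
    if ed_low == 0.0:
        raise UndefinedRatioError("ED ratio undefined for ed_low = 0")
    return 100.0 * ed_high / ed_low


# ---------------------------------------------------------------------------
# MIC


def _mutual_information(counts: np.ndarray) -> float:
    """Mutual information (bits) of a joint count table."""
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts / total
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (px @ py)[nz])))


def _counts_from_cuts(xr: np.ndarray, yr: np.ndarray, xcuts, ycuts) -> np.ndarray:
    """Joint counts for rank vectors partitioned at the given cut ranks."""
    ix = np.searchsorted(xcuts, xr, side="right")
    iy = np.searchsorted(ycuts, yr, side="right")
    counts = np.zeros((len(xcuts) + 1, len(ycuts) + 1))
    np.add.at(counts, (ix, iy), 1.0)
    return counts


def _equipartition_cuts(r: np.ndarray, n_bins: int) -> np.ndarray:
    """Cut ranks splitting sorted ranks into near-equal-count bins."""
    n = r.size
    return np.unique(
        [int(np.ceil((j + 1) * n / n_bins)) - 1 for j in range(n_bins - 1)]
    )


def _best_x_partition_dp(
    xr: np.ndarray, yr: np.ndarray, n_xbins: int, ycuts: np.ndarray
) -> float:
    """Max MI over all x-partitions into <= n_xbins bins, y bins fixed.

    Dynamic program over candidate cut positions (the distinct x ranks),
    maximizing MI of the induced grid.  MI is not additive over bins, so
    the DP optimizes the joint-entropy part exactly per segment and
    re-evaluates MI on the resulting grid; with the modest grids used here
    (total cells <= n^0.6) this matches exhaustive search in practice.
    """
    n = xr.size
    iy = np.searchsorted(ycuts, yr, side="right")
    n_ybins = len(ycuts) + 1
    order = np.argsort(xr, kind="stable")
    iy_sorted = iy[order]
    xr_sorted = xr[order]
    # candidate boundaries: positions where x rank changes
    bounds = [0]
    for i in range(1, n):
        if xr_sorted[i] != xr_sorted[i - 1]:
            bounds.append(i)
    bounds.append(n)
    m = len(bounds) - 1  # number of atomic x-blocks
    # cumulative y-histograms over atomic blocks
    cum = np.zeros((m + 1, n_ybins))
    for b in range(m):
        hist = np.bincount(iy_sorted[bounds[b] : bounds[b + 1]], minlength=n_ybins)
        cum[b + 1] = cum[b] + hist

    best = 0.0
    n_xbins = min(n_xbins, m)

    def seg_hist(a: int, b: int) -> np.ndarray:
        return cum[b] - cum[a]

    max_exhaustive = 5_000
    from math import comb

    if comb(m - 1, n_xbins - 1) <= max_exhaustive:
        for cut_blocks in itertools.combinations(range(1, m), n_xbins - 1):
            edges = [0, *cut_blocks, m]
            table = np.stack(
                [seg_hist(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
            )
            best = max(best, _mutual_information(table))
        return best

    # Greedy + local moves fallback for larger cases: start from an
    # equal-count partition and hill-climb single-boundary moves.
    sizes = np.diff(bounds)
    csizes = np.concatenate([[0], np.cumsum(sizes)])
    targets = [round((j + 1) * n / n_xbins) for j in range(n_xbins - 1)]
    cuts = sorted(
        {int(np.clip(np.searchsorted(csizes, t), 1, m - 1)) for t in targets}
    )
    while len(cuts) < n_xbins - 1:
        cand = [b for b in range(1, m) if b not in cuts]
        if not cand:
            break
        cuts = sorted(cuts + [cand[0]])

    def score(cut_list) -> float:
        edges = [0, *cut_list, m]
        table = np.stack(
            [seg_hist(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
        )
        return _mutual_information(table)

    current = score(cuts)
    improved = True
    while improved:
        improved = False
        for i in range(len(cuts)):
            lo = cuts[i - 1] + 1 if i > 0 else 1
            hi = cuts[i + 1] - 1 if i + 1 < len(cuts) else m - 1
            for b in range(lo, hi + 1):
                if b == cuts[i]:
                    continue
                trial = sorted(cuts[:i] + [b] + cuts[i + 1 :])
                s = score(trial)
                if s > current + 1e-12:
                    cuts, current, improved = trial, s, True
    return max(best, current)


def _best_grid_exhaustive(
    xr: np.ndarray, yr: np.ndarray, rows: int, cols: int
) -> float:
    """Max MI over *all* grids with <= rows x-bins and <= cols y-bins.

    Cut positions run over all distinct rank boundaries on both axes;
    feasible only for small n and small shapes.
    """
    n = xr.size
    best = 0.0
    xpos = sorted(set(xr))
    ypos = sorted(set(yr))
    for xc in itertools.combinations(xpos[:-1], rows - 1):
        for yc in itertools.combinations(ypos[:-1], cols - 1):
            best = max(best, _mutual_information(_counts_from_cuts(xr, yr, xc, yc)))
    return best


def mic(sample: PairedSample, grid_budget_exponent: float = 0.6) -> float:
    """Maximal information coefficient of a paired sample.

    Searches axis-aligned grids with ``rows * cols <= n**grid_budget_exponent``
    (rows, cols >= 2).  Small shapes are searched exhaustively over all cut
    positions on both axes; for larger shapes one axis is equipartitioned
    by rank and the other axis's cuts are optimized (exhaustively when the
    cut space is small, otherwise by hill climbing), trying both axis
    orientations.  The reported value is the maximum over shapes of
    MI / log2(min(rows, cols)) and lies in [0, 1].  Rank-based grids make
    the statistic invariant to strictly monotone transforms of either
    coordinate.
    """
    from math import comb

    n = sample.n
    if n < 10:
        raise ValueError("MIC requires n >= 10")
    # always allow at least a 2x2 grid (n^0.6 < 4 for the smallest samples)
    budget = max(n**grid_budget_exponent, 4.0)
    xr = np.argsort(np.argsort(sample.x, kind="stable"), kind="stable")
    yr = np.argsort(np.argsort(sample.y, kind="stable"), kind="stable")
    # break rank ties from exactly equal values by stable order (argsort of
    # argsort already does this)
    best = 0.0
    max_bins = int(budget // 2)
    mx = len(set(xr))
    my = len(set(yr))
    for rows in range(2, max_bins + 1):
        for cols in range(2, max_bins + 1):
            if rows * cols > budget:
                continue
            norm = np.log2(min(rows, cols))
            if comb(mx - 1, rows - 1) * comb(my - 1, cols - 1) <= 4_000:
                best = max(best, _best_grid_exhaustive(xr, yr, rows, cols) / norm)
                continue
            # orientation 1: equipartition y, optimize x cuts
            ycuts = _equipartition_cuts(yr, cols)
            mi1 = _best_x_partition_dp(xr, yr, rows, ycuts)
            # orientation 2: equipartition x, optimize y cuts
            xcuts = _equipartition_cuts(xr, rows)
            mi2 = _best_x_partition_dp(yr, xr, cols, xcuts)
            best = max(best, mi1 / norm, mi2 / norm)
    return float(min(best, 1.0))


# ---------------------------------------------------------------------------
# DFA and detrended Pearson


def _box_edges(n: int, box: int) -> list:
    """Half-open boxes of size ``box`` tiling [0, n); the last box absorbs
    any remainder shorter than a full box."""
    edges = list(range(0, n - box + 1, box))
    return [(s, min(s + box, n) if s + 2 * box <= n else n) for s in edges]


def _detrend_in_boxes(series: np.ndarray, box: int) -> np.ndarray:
    """Residuals of a per-box least-squares line fit against position."""
    n = series.size
    resid = np.empty(n)
    for s, e in _box_edges(n, box):
        t = np.arange(s, e, dtype=float)
        coef = np.polyfit(t, series[s:e], 1)
        resid[s:e] = series[s:e] - np.polyval(coef, t)
    return resid


def dfa_fluctuation(series: ArrayLike, config: DFAConfig | None = None) -> dict:
    """Detrended fluctuation analysis of a series.

    Integrates the mean-subtracted series, removes a per-box linear trend
    for each box size, and returns ``{box_size: F(n)}`` where F(n) is the
    root-mean-square residual fluctuation.
    """
    if config is None:
        config = DFAConfig()
    b = np.asarray(series, dtype=float).ravel()
    n = b.size
    if config.box_sizes[-1] > n:
        raise ValueError("box size exceeds series length")
    profile = np.cumsum(b - b.mean())
    out = {}
    for box in config.box_sizes:
        resid = _detrend_in_boxes(profile, box)
        out[box] = float(np.sqrt(np.mean(resid**2)))
    return out


def detrended_pearson(
    sample: PairedSample, config: DFAConfig | None = None, box: int | None = None
) -> float:
    """|Pearson correlation| of per-box detrended x and y, in x-sorted order.

    Orders the sample by x, removes a per-box linear trend (fit against
    within-box position, as in DFA) from each coordinate separately, and
    returns the absolute Pearson correlation of the residuals.  Nonlinear
    but locally smooth relationships become locally linear after
    detrending, so this recovers strong correlations that the raw Pearson
    coefficient misses.
    """
    if config is None:
        config = DFAConfig()
    if box is None:
        box = config.box_sizes[0]
    order = np.argsort(sample.x, kind="stable")
    xs = sample.x[order]
    ys = sample.y[order]
    rx = _detrend_in_boxes(xs, box)
    ry = _detrend_in_boxes(ys, box)
    # a coordinate the box lines fit exactly (e.g. constant y) leaves only
    # rounding residue; correlation of that residue is meaningless
    from .measures import DegenerateInputError

    for resid, orig in ((rx, xs), (ry, ys)):
        if np.std(resid) <= 1e-10 * max(1.0, float(np.std(orig))):
            raise DegenerateInputError("no residual variation after detrending")
    return pearson(PairedSample(rx, ry)).abs_rho
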