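"""Pearson correlation and empirical distance covariance/correlation.

Distance correlation is computed from first principles via double-centered
pairwise-distance matrices: for paired univariate samples ``(x_k, y_k)`` the
entries ``a_kl = |x_k - x_l|`` are centered by row mean, column mean and grand
mean, and the squared distance covariance is the average of the elementwise
product of the two centered matrices.  All quantities here are the *squared*
V-statistics; the single square root that yields the distance correlation R
is taken in :func:`distance_correlation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike

__all__ = [
    "PairedSample",
    "PearsonResult",
    "CenteredDistanceMatrix",
    "DcorResult",
    "DegenerateInputError",
    "pearson",
    "pairwise_distances",
    "double_center",
    "distance_covariance",
    "distance_correlation",
]

#: Product of squared distance variances below which the distance
#: correlation is defined to be zero (the degenerate branch of its ratio
#: definition).
_DVAR_PRODUCT_TOL = 1e-24


class DegenerateInputError(ValueError):
    """Raised when a statistic is undefined for the given input.

    Typical cause: a constant vector, for which the Pearson correlation
    (zero standard deviation) or a unit-norm transform is undefined.
    """


@dataclass(frozen=True)
class PairedSample:
    """Two equal-length finite real vectors, the universal bivariate input."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float).ravel()
        y = np.asarray(self.y, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValueError(
                f"x and y must have equal length, got {x.size} and {y.size}"
            )
        if x.size < 4:
            raise ValueError(f"need at least 4 paired observations, got {x.size}")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("all entries of x and y must be finite")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.x.size

    def swapped(self) -> "PairedSample":
        """The same sample with the roles of x and y exchanged."""
        return PairedSample(self.y, self.x)


@dataclass(frozen=True)
class PearsonResult:
    rho: float
    abs_rho: float


@dataclass(frozen=True)
class CenteredDistanceMatrix:
    """A double-centered pairwise-distance matrix (all row/col means zero)."""

    values: np.ndarray
    side: str = "x"

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class DcorResult:
    """Squared distance covariance/variances and the distance correlation."""

    dcov: float
    dvar_x: float
    dvar_y: float
    dcor: float


def pearson(sample: PairedSample) -> PearsonResult:
    """Pearson product-moment correlation of a paired sample.

    Computed as the sample covariance divided by the product of the sample
    standard deviations, with the same divisor in numerator and denominator
    (the ratio is divisor-convention independent).

    Raises
    ------
    DegenerateInputError
        If either vector is constant (zero standard deviation).
    """
    x, y = sample.x, sample.y
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.mean(xc**2))
    sy = np.sqrt(np.mean(yc**2))
    if sx == 0.0 or sy == 0.0:
        raise DegenerateInputError(
            "Pearson correlation is undefined for a constant vector"
        )
    rho = float(np.mean(xc * yc) / (sx * sy))
    rho = float(np.clip(rho, -1.0, 1.0))
    return PearsonResult(rho=rho, abs_rho=abs(rho))


def pairwise_distances(v: ArrayLike) -> np.ndarray:
    """The n-by-n matrix of absolute pairwise differences |v_k - v_l|."""
    v = np.asarray(v, dtype=float).ravel()
    if not np.all(np.isfinite(v)):
        raise ValueError("entries must be finite")
    return np.abs(v[:, None] - v[None, :])


def double_center(d: np.ndarray, side: str = "x") -> CenteredDistanceMatrix:
    """Subtract row means, column means and add the grand mean.

    The result has every row mean and column mean equal to zero; symmetry
    of the input is preserved.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("expected a square matrix")
    row = d.mean(axis=1, keepdims=True)
    col = d.mean(axis=0, keepdims=True)
    grand = d.mean()
    return CenteredDistanceMatrix(values=d - row - col + grand, side=side)


def distance_covariance(
    a: CenteredDistanceMatrix, b: CenteredDistanceMatrix
) -> float:
    """Squared empirical distance covariance of two centered matrices.

    Returns ``(1/n^2) * sum_{k,l} A_kl * B_kl``.  With ``a is b`` this is the
    squared distance variance.  The caller takes square roots as needed.
    """
    if a.n != b.n:
        raise ValueError(f"dimension mismatch: {a.n} vs {b.n}")
    return float(np.mean(a.values * b.values))


def distance_correlation(sample: PairedSample) -> DcorResult:
    """Empirical distance correlation of a paired univariate sample.

    R = sqrt( nu2(X,Y) / sqrt(nu2(X) * nu2(Y)) ) when the denominator is
    positive, and 0 when either squared distance variance vanishes (e.g. a
    constant vector).  R always lies in [0, 1].
    """
    A = double_center(pairwise_distances(sample.x), side="x")
    B = double_center(pairwise_distances(sample.y), side="y")
    dcov2 = distance_covariance(A, B)
    dvar_x = distance_covariance(A, A)
    dvar_y = distance_covariance(B, B)
    prod = dvar_x * dvar_y
    if prod <= _DVAR_PRODUCT_TOL:
        dcor = 0.0
    else:
        # dcov2 is a V-statistic and can only dip below 0 via rounding.
        ratio = max(dcov2, 0.0) / np.sqrt(prod)
        dcor = float(np.sqrt(min(ratio, 1.0)))
    return DcorResult(dcov=dcov2, dvar_x=dvar_x, dvar_y=dvar_y, dcor=dcor)
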