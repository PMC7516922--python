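"""The Association Factor (AF) and derived quantities.

AF is the empirical distance correlation of the optimally transformed
variables: fit (h1, h2) by alternating conditional expectations, then
compute the distance correlation of the fitted transform values.  For any
noiseless functional relationship -- and, empirically, for circular data --
the transforms linearize the relationship and AF approaches 1, whereas the
raw distance correlation depends strongly on the relationship's shape.
AF is non-negative, near zero for independent data, and empirically
symmetric in the two variables, though the fit itself is directional
(one variable plays the response whose transform is standardized).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .measures import (
    DcorResult,
    DegenerateInputError,
    PairedSample,
    distance_correlation,
)
from .transform import SmootherSpec, TransformState, ace_fit

__all__ = [
    "AFResult",
    "UndefinedRatioError",
    "association_factor",
    "symmetry_gap",
    "af_ratio",
    "triangle_inequality_gap",
]


class UndefinedRatioError(ZeroDivisionError):
    """Raised when a ratio of measures has a zero denominator."""


@dataclass(frozen=True)
class AFResult:
    """Association Factor with the transform fit it came from.

    ``degenerate`` is set (and af = 0) when the transform fit collapsed,
    e.g. on a constant response; this mirrors the zero branch of the
    distance-correlation definition.
    """

    af: float
    direction: str
    transform: TransformState | None
    dcor_detail: DcorResult | None
    degenerate: bool = False


def association_factor(
    sample: PairedSample,
    direction: str = "x_to_y",
    spec: SmootherSpec | None = None,
) -> AFResult:
    """Association Factor of a paired sample.

    Parameters
    ----------
    sample:
        The paired observations.
    direction:
        ``"x_to_y"`` treats y as the response (h2 standardized on y);
        ``"y_to_x"`` swaps the roles.  The measure is empirically symmetric
        but the fit is directional.
    spec:
        Smoother configuration; defaults to :class:`SmootherSpec`.
    """
    if direction not in ("x_to_y", "y_to_x"):
        raise ValueError(f"unknown direction {direction!r}")
    fit_sample = sample if direction == "x_to_y" else sample.swapped()
    try:
        state = ace_fit(fit_sample, spec=spec)
    except DegenerateInputError as err:
        warnings.warn(
            f"degenerate transform ({err}); reporting AF = 0", stacklevel=2
        )
        return AFResult(
            af=0.0,
            direction=direction,
            transform=None,
            dcor_detail=None,
            degenerate=True,
        )
    detail = distance_correlation(PairedSample(state.h1, state.h2))
    return AFResult(
        af=detail.dcor,
        direction=direction,
        transform=state,
        dcor_detail=detail,
    )


def symmetry_gap(sample: PairedSample, spec: SmootherSpec | None = None) -> float:
    """|AF(X,Y) - AF(Y,X)|, the directional asymmetry of the fit."""
    a_xy = association_factor(sample, "x_to_y", spec).af
    a_yx = association_factor(sample, "y_to_x", spec).af
    return abs(a_xy - a_yx)


def af_ratio(af_high: float, af_low: float) -> float:
    """Percentage ratio of squared AF values across two noise conditions.

    Returns ``100 * af_high^2 / af_low^2``; below 100 the association
    weakened going from the low- to the high-noise condition, 100 means no
    change, above 100 it strengthened.
    """
    for v in (af_high, af_low):
        if not 0.0 <= v <= 1.0:
            raise ValueError("AF values must lie in [0, 1]")
    if af_low == 0.0:
        raise UndefinedRatioError("AF ratio undefined for af_low = 0")
    return 100.0 * af_high**2 / af_low**2


def triangle_inequality_gap(
    xy: PairedSample,
    xz: PairedSample,
    zy: PairedSample,
    spec: SmootherSpec | None = None,
) -> float:
    """Diagnostic: AF(X,Y) - (AF(X,Z) + AF(Z,Y)).

    A positive value is a violation of the triangle-style inequality
    AF(X,Y) <= AF(X,Z) + AF(Z,Y).  The inequality does not hold for
    arbitrary triples (take Y = X with Z independent of both), so this is
    exposed as a diagnostic rather than enforced as an invariant.
    """
    a_xy = association_factor(xy, spec=spec).af
    a_xz = association_factor(xz, spec=spec).af
    a_zy = association_factor(zy, spec=spec).af
    return a_xy - (a_xz + a_zy)
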