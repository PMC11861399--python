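"""Cubic-parabola model of the anterior dental arch.

The anterior arch (canine-to-canine through the incisal point) is modelled as
a third-degree parabola in a 2-D occlusal-plane coordinate system: the x-axis
runs through the distal canine contact points, the y-axis lies on the raphe
median plane, and the incisal point sits at (0, -L).  For a sagittal depth L
(mm) and half arch width W = aaw/2 (mm) the right half of the arch is

    f(x) = (L / W^3) * x^3 - L,   0 <= x <= W,

with f(0) = -L (incisal point) and f(W) = 0 (distal canine contact).  The
leading coefficient a = L / W^3 is the openness factor: the smaller a, the
wider the arch.  Arch length follows by line integration of
sqrt(1 + f'(x)^2); the symmetric left half doubles the one-sided integral.

A planned treatment displaces the incisal point sagittally by delta_s (mm,
protrusion positive) and may change the arch width by delta_aaw (mm); the
post-treatment length is the same integral evaluated on the updated geometry
(L + delta_s, (aaw + delta_aaw)/2).

All lengths are millimetres throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy.integrate import quad

__all__ = [
    "ArchGeometry",
    "ArchChange",
    "InvalidGeometryError",
    "InvalidPlanError",
    "QuadratureError",
    "openness_coefficient",
    "arch_profile",
    "half_arch_length",
    "anterior_arch_length",
    "predicted_arch_length",
    "delta_arch_length",
    "adapted_openness",
    "combine_sides",
]

#: Absolute and relative quadrature tolerances (mm).  The integrand is smooth
#: on [0, W]; 1e-9 far exceeds the 0.1 mm clinical relevance threshold.
QUAD_EPSABS = 1e-9
QUAD_EPSREL = 1e-9


class InvalidGeometryError(ValueError):
    """Raised for geometrically impossible arch parameters (W <= 0, L < 0)."""


class InvalidPlanError(ValueError):
    """Raised when a treatment plan produces an impossible post-treatment arch."""


class QuadratureError(ArithmeticError):
    """Raised when the arc-length quadrature fails to converge."""


Side = Literal["left", "right", "combined"]
Jaw = Literal["upper", "lower"]
Timepoint = Literal["T0", "T1"]


@dataclass(frozen=True)
class ArchGeometry:
    """One anterior arch half-profile: sagittal depth ``L`` and half-width ``W``.

    ``W`` is half the anterior arch width (aaw/2), the distance from the raphe
    median plane to the distal canine contact.  ``L`` is the perpendicular
    distance from the incisal point to the inter-canine line.  ``L = 0`` is
    the degenerate straight arch and is permitted.  ``side``, ``jaw`` and
    ``timepoint`` are bookkeeping labels only.
    """

    L: float
    W: float
    side: Optional[Side] = None
    jaw: Optional[Jaw] = None
    timepoint: Optional[Timepoint] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.L) or not np.isfinite(self.W):
            raise InvalidGeometryError("L and W must be finite")
        if self.W <= 0:
            raise InvalidGeometryError(f"half arch width W must be positive, got W={self.W}")
        if self.L < 0:
            raise InvalidGeometryError(f"sagittal depth L must be non-negative, got L={self.L}")

    @property
    def aaw(self) -> float:
        """Anterior arch width between the distal canine contacts: aaw = 2 W."""
        return 2.0 * self.W


@dataclass(frozen=True)
class ArchChange:
    """Planned change: sagittal incisal-point displacement and arch-width change.

    ``delta_s_total`` is the total sagittal displacement of the incisal point
    in mm, protrusion (anterior movement) positive.  ``delta_aaw`` is the
    change in anterior arch width in mm.
    """

    delta_s_total: float
    delta_aaw: float = 0.0


def openness_coefficient(arch: ArchGeometry) -> float:
    """Leading coefficient a = L / W**3 of the arch parabola, in mm^-2.

    Smaller values describe wider, flatter arches; a = 0 is the straight arch.
    """
    return arch.L / arch.W**3


def arch_profile(x, arch: ArchGeometry, *, allow_extrapolation: bool = False):
    """Evaluate the arch curve f(x) = (L/W^3) x^3 - L at ``x`` (mm).

    ``x`` may be a scalar or array.  Evaluation outside [0, W] is analytic
    but geometrically meaningless for the arch; it is refused unless
    ``allow_extrapolation`` is set (useful for plotting).
    """
    x = np.asarray(x, dtype=float)
    if not allow_extrapolation and (np.any(x < 0) or np.any(x > arch.W)):
        raise ValueError(
            f"x outside the arch domain [0, {arch.W}]; "
            "pass allow_extrapolation=True to evaluate anyway"
        )
    y = openness_coefficient(arch) * x**3 - arch.L
    return float(y) if y.ndim == 0 else y


def _arc_integrand_factory(L: float, W: float):
    c = 9.0 * L * L / W**6
    return lambda x: np.sqrt(1.0 + c * x**4)


def half_arch_length(arch: ArchGeometry) -> float:
    """One-sided arch length: integral of sqrt(1 + 9 L^2/W^6 x^4) over [0, W].

    Computed with adaptive Gauss-Kronrod quadrature at 1e-9 absolute and
    relative tolerance.  The result lies between the straight chord
    sqrt(W^2 + L^2) and the taxicab bound W + L.
    """
    L, W = arch.L, arch.W
    if L == 0.0:
        return W  # integrand is identically 1
    value, abserr = quad(
        _arc_integrand_factory(L, W), 0.0, W, epsabs=QUAD_EPSABS, epsrel=QUAD_EPSREL
    )
    if abserr > max(QUAD_EPSABS, abs(value) * 1e-6):
        raise QuadratureError(
            f"arc-length quadrature did not converge: value={value}, "
            f"estimated error={abserr}, L={L}, W={W}"
        )
    return value


def anterior_arch_length(L: float, aaw: float) -> float:
    """Full anterior arch length AL (mm) for sagittal depth ``L`` and width ``aaw``.

    The model arch is symmetric about the raphe median plane, so AL is exactly
    twice the one-sided integral with W = aaw/2.
    """
    return 2.0 * half_arch_length(ArchGeometry(L=L, W=aaw / 2.0))


def _post_treatment_geometry(arch_T0: ArchGeometry, change: ArchChange) -> ArchGeometry:
    L1 = arch_T0.L + change.delta_s_total
    aaw1 = arch_T0.aaw + change.delta_aaw
    if L1 < 0:
        raise InvalidPlanError(
            f"post-treatment sagittal depth L_T1 = {arch_T0.L} + ({change.delta_s_total}) "
            f"= {L1} mm is negative"
        )
    if aaw1 <= 0:
        raise InvalidPlanError(
            f"post-treatment arch width aaw_T1 = {arch_T0.aaw} + ({change.delta_aaw}) "
            f"= {aaw1} mm is not positive"
        )
    return ArchGeometry(L=L1, W=aaw1 / 2.0, jaw=arch_T0.jaw, side=arch_T0.side, timepoint="T1")


def predicted_arch_length(arch_T0: ArchGeometry, change: ArchChange) -> float:
    """Post-treatment arch length AL_T1 (mm).

    ``arch_T0`` is a full-arch geometry (W = aaw/2); the integral is evaluated
    on L_T0 + delta_s_total and (aaw_T0 + delta_aaw)/2.  A zero change
    reproduces AL_T0 through the same code path.
    """
    geo = _post_treatment_geometry(arch_T0, change)
    return 2.0 * half_arch_length(geo)


def delta_arch_length(arch_T0: ArchGeometry, change: ArchChange) -> float:
    """Therapeutic change in arch length: AL_T1 - AL_T0 (mm)."""
    return predicted_arch_length(arch_T0, change) - 2.0 * half_arch_length(arch_T0)


def adapted_openness(arch_T0: ArchGeometry, change: ArchChange) -> float:
    """Post-treatment openness factor a' = (L + delta_s) / ((aaw + delta_aaw)/2)^3."""
    return openness_coefficient(_post_treatment_geometry(arch_T0, change))


def combine_sides(left: ArchGeometry, right: ArchGeometry) -> ArchGeometry:
    """Total-arch geometry from per-side measurements.

    The total arch uses the mean of the left and right sagittal depths,
    L_total = (L_left + L_right) / 2, and the summed width
    W_total = aaw = W_left + W_right (which is the full-arch half-width
    convention: the combined geometry's W is aaw/2 of the full arch).
    """
    if left.jaw != right.jaw or left.timepoint != right.timepoint:
        raise ValueError("left and right sides must share jaw and timepoint")
    L_total = (left.L + right.L) / 2.0
    aaw = left.W + right.W
    return ArchGeometry(
        L=L_total, W=aaw / 2.0, side="combined", jaw=left.jaw, timepoint=left.timepoint
    )
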