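"""Cephalometric trigonometry: incisor movements to incisal-point displacements.

A planned orthodontic movement of a central incisor is described on a lateral
cephalogram by a change of the incisor axis angle (tipping about the centre
of rotation) plus a bodily sagittal translation.  Given the distance ``c``
from the centre of rotation to the incisal edge, the pre-treatment incisor
angle, and the occlusal-plane angle (both measured against the jaw's
reference plane: the nasal line NL for the upper jaw, the mandibular line ML
for the lower jaw), the incisal point's sagittal displacement delta_s and
vertical displacement delta_v follow from plane trigonometry:

upper jaw:
    delta_s(tipping) = c * (cos(1/NL - OcP/NL - (-d1/NL)) - cos(1/NL - OcP/NL))
    delta_v          = -c * (sin(1/NL - OcP/NL - (-d1/NL)) - sin(1/NL - OcP/NL))
lower jaw:
    delta_s(tipping) = c * (cos(180 - OcP/ML - 1/ML - d1/ML) - cos(180 - OcP/ML - 1/ML))
    delta_v          = -c * (sin(1/ML + OcP/ML + d1/ML) - sin(1/ML + OcP/ML))

where d1/NL, d1/ML are the planned inclination changes (T1 - T0, degrees).
delta_s(total) = delta_s(tipping) + delta_s(translation); delta_v(total) is
the sum over both jaws (bite opening/deepening).

Sign conventions: delta_s is positive for anterior movement (protrusion);
delta_v is positive for movement away from the occlusal plane (intrusion).
``delta_inclination`` is defined as (angle at T1) - (angle at T0).  The
formulas above are applied literally -- note that with the upper jaw's
double negative, a positive d1/NL (increasing 1/NL) yields a *negative*
delta_s at typical angle configurations.  No silent sign flip is applied;
callers who interpret positive d1/NL as proclination should check the sign
of the result against their convention.

Angles are accepted in degrees and converted to radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Literal, Optional, Sequence

from .arch_geometry import ArchChange, ArchGeometry, predicted_arch_length

__all__ = [
    "CephalometricState",
    "TreatmentAngles",
    "AuxiliaryAngles",
    "MissingReferenceError",
    "InconsistentAnglesError",
    "delta_s_tipping",
    "delta_s_total",
    "delta_v",
    "delta_v_total",
    "convert_incisor_angle",
    "ocp_sensitivity",
]


class MissingReferenceError(ValueError):
    """An angle conversion lacks the reference angles needed to determine the target."""


class InconsistentAnglesError(ValueError):
    """Over-determined auxiliary angles disagree beyond tolerance."""


@dataclass(frozen=True)
class CephalometricState:
    """Pre-treatment cephalometric configuration of one jaw.

    ``angle_incisor_ref`` is the incisor axis angle against the jaw's
    reference plane (1/NL upper, 1/ML lower) at T0, degrees.
    ``angle_ocp_ref`` is the occlusal-plane angle against the same reference
    plane (OcP/NL upper, OcP/ML lower) at T0, degrees.  ``c`` is the linear
    distance centre-of-rotation to incisal edge, mm.
    """

    jaw: Literal["upper", "lower"]
    angle_incisor_ref: float
    angle_ocp_ref: float
    c: float

    def __post_init__(self) -> None:
        if self.jaw not in ("upper", "lower"):
            raise ValueError(f"jaw must be 'upper' or 'lower', got {self.jaw!r}")
        if self.c <= 0:
            raise ValueError(f"rotation radius c must be positive, got {self.c}")
        for name, angle in (
            ("angle_incisor_ref", self.angle_incisor_ref),
            ("angle_ocp_ref", self.angle_ocp_ref),
        ):
            if not 0.0 < angle < 180.0:
                raise ValueError(f"{name} must lie in (0, 180) degrees, got {angle}")


@dataclass(frozen=True)
class TreatmentAngles:
    """Planned incisor movement: inclination change (degrees, T1 - T0) and
    bodily sagittal translation (mm, protrusion positive)."""

    delta_inclination: float = 0.0
    s_translation: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.delta_inclination) >= 90.0:
            raise ValueError(
                f"|delta_inclination| must be below 90 degrees, got {self.delta_inclination}"
            )


def delta_s_tipping(state: CephalometricState, plan: TreatmentAngles) -> float:
    """Sagittal incisal-point displacement (mm) from pure tipping."""
    d = math.radians(plan.delta_inclination)
    if plan.delta_inclination == 0.0:
        return 0.0
    if state.jaw == "upper":
        theta = math.radians(state.angle_incisor_ref - state.angle_ocp_ref)
        # literal "- (-d1/NL)" double negative: the argument gains +d
        return state.c * (math.cos(theta + d) - math.cos(theta))
    theta = math.radians(180.0 - state.angle_ocp_ref - state.angle_incisor_ref)
    return state.c * (math.cos(theta - d) - math.cos(theta))


def delta_s_total(state: CephalometricState, plan: TreatmentAngles) -> float:
    """Total sagittal displacement: tipping plus bodily translation (mm)."""
    return delta_s_tipping(state, plan) + plan.s_translation


def delta_v(state: CephalometricState, plan: TreatmentAngles) -> float:
    """Vertical incisal-point displacement (mm), perpendicular to the occlusal
    plane; positive = away from OcP (intrusion)."""
    d = math.radians(plan.delta_inclination)
    if plan.delta_inclination == 0.0:
        return 0.0
    if state.jaw == "upper":
        theta = math.radians(state.angle_incisor_ref - state.angle_ocp_ref)
        return -state.c * (math.sin(theta + d) - math.sin(theta))
    phi = math.radians(state.angle_incisor_ref + state.angle_ocp_ref)
    return -state.c * (math.sin(phi + d) - math.sin(phi))


def delta_v_total(dv_upper: float, dv_lower: float) -> float:
    """Total bite opening (positive) or deepening (negative): sum over jaws."""
    return dv_upper + dv_lower


# ---------------------------------------------------------------------------
# Incisor-angle conversions
#
# Incisor inclination can be reported against several reference lines
# (NL, ML, NSL, NA, NB).  With all angles opening to the same side, the
# standard additive identities relate them:
#
#     1/NSL = 1/NL - NL/NSL          (upper incisor)
#     1/NA  = 1/NSL - SNA            (upper incisor)
#     1/NB  = 1/ML + ML/NSL + SNB - 180   (lower incisor)
#
# ``opening_direction=-1`` flips the sign of the plane-to-plane offsets for
# configurations where NL/NSL (resp. ML/NSL) opens to the opposite side.
# ---------------------------------------------------------------------------

#: target names accepted by :func:`convert_incisor_angle`
INCISOR_ANGLE_NAMES = ("1/NL", "1/ML", "1/NSL", "1/NA", "1/NB")

#: tolerance (degrees) for consistency of over-determined inputs
CONSISTENCY_TOL = 0.5


@dataclass(frozen=True)
class AuxiliaryAngles:
    """Optional auxiliary incisor and reference angles (degrees) for conversions.

    Any subset may be supplied; conversions require enough of them to chain to
    the target through the additive plane identities.
    """

    angle_1_NL: Optional[float] = None
    angle_1_ML: Optional[float] = None
    angle_1_NSL: Optional[float] = None
    angle_1_NA: Optional[float] = None
    angle_1_NB: Optional[float] = None
    angle_NL_NSL: Optional[float] = None
    angle_ML_NSL: Optional[float] = None
    SNA: Optional[float] = None
    SNB: Optional[float] = None
    opening_direction: int = field(default=1)

    def supplied(self) -> Dict[str, float]:
        out = {}
        for attr, name in (
            ("angle_1_NL", "1/NL"),
            ("angle_1_ML", "1/ML"),
            ("angle_1_NSL", "1/NSL"),
            ("angle_1_NA", "1/NA"),
            ("angle_1_NB", "1/NB"),
        ):
            v = getattr(self, attr)
            if v is not None:
                out[name] = float(v)
        return out


def _derive_all(aux: AuxiliaryAngles) -> Dict[str, list]:
    """All derivable values for each incisor angle (for consistency checking)."""
    s = aux.opening_direction
    known: Dict[str, list] = {k: [v] for k, v in aux.supplied().items()}

    def add(name: str, value: float) -> None:
        known.setdefault(name, []).append(value)

    # propagate along the identity graph until closure (graph is tiny: 2 passes)
    for _ in range(3):
        vals = {k: v[0] for k, v in known.items()}
        if "1/NL" in vals and aux.angle_NL_NSL is not None and "1/NSL" not in vals:
            add("1/NSL", vals["1/NL"] - s * aux.angle_NL_NSL)
        if "1/NSL" in vals and aux.angle_NL_NSL is not None and "1/NL" not in vals:
            add("1/NL", vals["1/NSL"] + s * aux.angle_NL_NSL)
        if "1/NSL" in vals and aux.SNA is not None and "1/NA" not in vals:
            add("1/NA", vals["1/NSL"] - aux.SNA)
        if "1/NA" in vals and aux.SNA is not None and "1/NSL" not in vals:
            add("1/NSL", vals["1/NA"] + aux.SNA)
        if (
            "1/ML" in vals
            and aux.angle_ML_NSL is not None
            and aux.SNB is not None
            and "1/NB" not in vals
        ):
            add("1/NB", vals["1/ML"] + s * aux.angle_ML_NSL + aux.SNB - 180.0)
        if (
            "1/NB" in vals
            and aux.angle_ML_NSL is not None
            and aux.SNB is not None
            and "1/ML" not in vals
        ):
            add("1/ML", vals["1/NB"] - s * aux.angle_ML_NSL - aux.SNB + 180.0)

    # consistency: recompute every derivable quantity from each supplied source
    vals = {k: v[0] for k, v in known.items()}
    checks: Dict[str, list] = {k: list(v) for k, v in known.items()}
    supplied = aux.supplied()
    if "1/NL" in supplied and aux.angle_NL_NSL is not None:
        checks.setdefault("1/NSL", []).append(supplied["1/NL"] - s * aux.angle_NL_NSL)
    if "1/NSL" in supplied and aux.SNA is not None:
        checks.setdefault("1/NA", []).append(supplied["1/NSL"] - aux.SNA)
    if "1/NA" in supplied and aux.SNA is not None:
        checks.setdefault("1/NSL", []).append(supplied["1/NA"] + aux.SNA)
    if "1/ML" in supplied and aux.angle_ML_NSL is not None and aux.SNB is not None:
        checks.setdefault("1/NB", []).append(
            supplied["1/ML"] + s * aux.angle_ML_NSL + aux.SNB - 180.0
        )
    return checks


def convert_incisor_angle(aux: AuxiliaryAngles, target: str) -> float:
    """Convert among incisor inclination angles via additive plane identities.

    ``target`` is one of ``'1/NL', '1/ML', '1/NSL', '1/NA', '1/NB'``.  A
    directly supplied target is returned unchanged.  Raises
    :class:`MissingReferenceError` when the supplied angles cannot determine
    the target, and :class:`InconsistentAnglesError` when over-determined
    inputs disagree by more than 0.5 degrees.
    """
    if target not in INCISOR_ANGLE_NAMES:
        raise ValueError(f"unknown angle name {target!r}; expected one of {INCISOR_ANGLE_NAMES}")

    checks = _derive_all(aux)
    for name, values in checks.items():
        if max(values) - min(values) > CONSISTENCY_TOL:
            raise InconsistentAnglesError(
                f"supplied angles determine {name} inconsistently: {sorted(values)} "
                f"(spread > {CONSISTENCY_TOL} degrees)"
            )
    if target not in checks:
        needed = {
            "1/NSL": "1/NL with NL/NSL, or 1/NA with SNA",
            "1/NL": "1/NSL (or 1/NA with SNA) plus NL/NSL",
            "1/NA": "1/NSL (or 1/NL with NL/NSL) plus SNA",
            "1/NB": "1/ML plus ML/NSL and SNB",
            "1/ML": "1/NB plus ML/NSL and SNB",
        }[target]
        raise MissingReferenceError(
            f"cannot determine {target} from the supplied angles; needs {needed}"
        )
    return checks[target][0]


def ocp_sensitivity(
    state: CephalometricState,
    plan: TreatmentAngles,
    arch_T0: ArchGeometry,
    ocp_values: Sequence[float],
) -> float:
    """Spread of predicted AL_T1 under occlusal-plane misidentification.

    Substitutes each candidate occlusal-plane angle (degrees) for the state's
    ``angle_ocp_ref``, everything else fixed, computes delta_s(total) and the
    resulting post-treatment arch length, and returns the maximum pairwise
    absolute difference (mm) over the candidates.  ``arch_T0`` must be a
    full-arch geometry (W = aaw/2).
    """
    if len(ocp_values) == 0:
        raise ValueError("ocp_values must be non-empty")
    lengths = []
    for ocp in ocp_values:
        s = CephalometricState(
            jaw=state.jaw, angle_incisor_ref=state.angle_incisor_ref, angle_ocp_ref=ocp, c=state.c
        )
        ds = delta_s_total(s, plan)
        lengths.append(predicted_arch_length(arch_T0, ArchChange(delta_s_total=ds)))
    return max(lengths) - min(lengths)
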