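"""Method-agreement statistics for measured vs calculated arch lengths.

The arch-length model is validated by comparing, per stratum (jaw x side x
timepoint), the polyline-measured AL against the AL calculated from the
measured width and depth.  Agreement is quantified with Lin's concordance
correlation coefficient (CCC), the intraclass correlation coefficient (ICC,
two-way absolute-agreement single-measure by default), Bland-Altman limits
of agreement, and descriptive summaries of the absolute differences.

Differences are always oriented measured - calculated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Literal, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .arch_geometry import ArchGeometry, half_arch_length
from .measurement import SyntheticCohort

__all__ = [
    "PairedMeasurements",
    "DescriptiveSummary",
    "BlandAltmanResult",
    "StratumAgreement",
    "AgreementReport",
    "descriptive_summary",
    "lin_ccc",
    "lin_ccc_ci",
    "icc",
    "bland_altman",
    "bland_altman_plot",
    "absolute_difference_summary",
    "validate_cohort",
]

#: normal 95% factor for Bland-Altman limits of agreement (not t-adjusted)
LOA_FACTOR = 1.96

#: interpretation scales for correlation-type coefficients (labels only)
FLEISS_ICC_CUTOFFS = ((0.75, "excellent"), (0.4, "fair to good"), (-1.0, "poor"))
KOCH_SPOERL_CCC_CUTOFFS = (
    (0.9, "substantial"),
    (0.7, "good"),
    (0.5, "acceptable"),
    (-1.0, "poor"),
)


class InsufficientDataError(ValueError):
    """Fewer observations than the statistic requires."""


@dataclass(frozen=True)
class PairedMeasurements:
    """Two equal-length series of paired measurements (mm), e.g. measured and
    calculated arch length.  No missing values allowed."""

    x: np.ndarray
    y: np.ndarray
    label_x: str = "measured"
    label_y: str = "calculated"

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
            raise ValueError("paired series must be 1-D and of equal length")
        if len(x) < 2:
            raise InsufficientDataError("need at least 2 pairs")
        if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
            raise ValueError("paired series must not contain NaN/inf; filter explicitly first")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class DescriptiveSummary:
    mean: float
    sd: float
    min: float
    max: float
    ci_low: float
    ci_high: float
    n: int


def descriptive_summary(series: Sequence[float], confidence: float = 0.95) -> DescriptiveSummary:
    """Mean, sample SD (n-1), min, max and t-based confidence interval."""
    a = np.asarray(series, dtype=float)
    if a.ndim != 1 or len(a) < 2:
        raise InsufficientDataError("descriptive summary needs at least 2 values")
    n = len(a)
    mean = float(a.mean())
    sd = float(a.std(ddof=1))
    half = sps.t.ppf(0.5 + confidence / 2.0, n - 1) * sd / math.sqrt(n)
    return DescriptiveSummary(
        mean=mean, sd=sd, min=float(a.min()), max=float(a.max()),
        ci_low=mean - half, ci_high=mean + half, n=n,
    )


def lin_ccc(pairs: PairedMeasurements) -> float:
    """Lin's concordance correlation coefficient.

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (x_bar - y_bar)^2), with population
    (n-denominator) moments per Lin's original definition.  Equals 1 iff
    y = x elementwise; symmetric in the two series.
    """
    x, y = pairs.x, pairs.y
    sx2 = float(x.var())  # ddof=0
    sy2 = float(y.var())
    denom = sx2 + sy2 + (float(x.mean()) - float(y.mean())) ** 2
    if denom == 0.0:
        raise ValueError("CCC undefined: both series constant with equal means")
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    return 2.0 * sxy / denom


def lin_ccc_ci(
    pairs: PairedMeasurements, confidence: float = 0.95
) -> Tuple[float, float, float]:
    """CCC with a Fisher-z (inverse hyperbolic tangent) confidence interval.

    Returns (ccc, ci_low, ci_high).  The z-transform standard error uses the
    asymptotic approximation se = sqrt(1 / (n - 2)) on the transformed scale,
    adequate for the moderate sample sizes of agreement studies.
    """
    ccc = lin_ccc(pairs)
    n = pairs.n
    if n < 4 or abs(ccc) >= 1.0:
        return ccc, float("nan"), float("nan")
    z = math.atanh(ccc)
    se = 1.0 / math.sqrt(n - 2)
    zq = sps.norm.ppf(0.5 + confidence / 2.0)
    return ccc, math.tanh(z - zq * se), math.tanh(z + zq * se)


def icc(
    ratings: np.ndarray,
    variant: Literal["two-way-absolute-single", "two-way-consistency-single"] =
    "two-way-absolute-single",
) -> float:
    """Intraclass correlation from a complete subjects x raters/repeats matrix.

    The default is the two-way, absolute-agreement, single-measure ICC
    (ICC(A,1)), the appropriate form for repeated measurements by one rater:

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE))

    where MSR, MSC, MSE are the row (subject), column (repeat) and residual
    mean squares of the two-way ANOVA decomposition.  The consistency form
    ICC(C,1) = (MSR - MSE) / (MSR + (k-1) MSE) is also available.  Degenerate
    matrices (no between-subject variance) may yield values <= 0; they are
    reported as computed, not clamped.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x repeats matrix")
    n, k = m.shape
    if n < 2 or k < 2:
        raise InsufficientDataError("ICC needs >= 2 subjects and >= 2 repeats")
    if np.any(~np.isfinite(m)):
        raise ValueError("ratings matrix is incomplete (NaN/inf present)")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    msr = k * float(((row_means - grand) ** 2).sum()) / (n - 1)
    msc = n * float(((col_means - grand) ** 2).sum()) / (k - 1)
    mse = float(
        ((m - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    ) / ((n - 1) * (k - 1))
    if variant == "two-way-absolute-single":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    elif variant == "two-way-consistency-single":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unknown ICC variant {variant!r}")
    if denom == 0.0:
        raise ValueError("ICC undefined: zero total variance")
    return (msr - mse) / denom


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray  # per-pair (x + y)/2, for plotting
    diffs: np.ndarray  # per-pair x - y (measured - calculated)


def bland_altman(pairs: PairedMeasurements) -> BlandAltmanResult:
    """Bland-Altman analysis: mean difference, SD of differences, and 95%
    limits of agreement mean +/- 1.96 SD (differences as measured - calculated)."""
    diffs = pairs.x - pairs.y
    means = (pairs.x + pairs.y) / 2.0
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - LOA_FACTOR * sd_diff,
        loa_high=mean_diff + LOA_FACTOR * sd_diff,
        means=means,
        diffs=diffs,
    )


def bland_altman_plot(pairs: PairedMeasurements, path, title: str = "") -> None:
    """Write a Bland-Altman difference-vs-mean plot to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ba = bland_altman(pairs)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(ba.means, ba.diffs, s=18, alpha=0.7)
    for yv, style, lab in (
        (ba.mean_diff, "-", f"mean {ba.mean_diff:.3f}"),
        (ba.loa_low, "--", f"-1.96 SD {ba.loa_low:.3f}"),
        (ba.loa_high, "--", f"+1.96 SD {ba.loa_high:.3f}"),
    ):
        ax.axhline(yv, linestyle=style, color="grey")
        ax.annotate(lab, (ba.means.max(), yv), fontsize=8, va="bottom", ha="right")
    ax.set_xlabel(f"mean of {pairs.label_x} and {pairs.label_y} (mm)")
    ax.set_ylabel(f"{pairs.label_x} - {pairs.label_y} (mm)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def absolute_difference_summary(pairs: PairedMeasurements) -> DescriptiveSummary:
    """Descriptive summary of the absolute paired differences |x - y| (mm)."""
    return descriptive_summary(np.abs(pairs.x - pairs.y))


def ccc_label(value: float) -> str:
    """Koch & Spoerl interpretation label for a CCC value."""
    for cut, label in KOCH_SPOERL_CCC_CUTOFFS:
        if value >= cut:
            return label
    return "poor"


def icc_label(value: float) -> str:
    """Fleiss interpretation label for an ICC value."""
    for cut, label in FLEISS_ICC_CUTOFFS:
        if value >= cut:
            return label
    return "poor"


@dataclass(frozen=True)
class StratumAgreement:
    """Full agreement summary for one stratum (side or total of one jaw)."""

    stratum: str
    ccc: float
    ccc_ci: Tuple[float, float]
    ccc_interpretation: str
    bland_altman: BlandAltmanResult
    abs_diff: DescriptiveSummary
    measured: DescriptiveSummary
    calculated: DescriptiveSummary
    n: int


@dataclass(frozen=True)
class AgreementReport:
    """Agreement between measured and calculated AL, per stratum plus the
    mean CCC across strata.  Differences oriented measured - calculated."""

    jaw: str
    timepoint: str
    strata: Dict[str, StratumAgreement]
    mean_ccc: float

    def to_frame(self) -> pd.DataFrame:
        """Long-format (stratum, statistic, value) table."""
        rows = []
        for name, s in self.strata.items():
            rows += [
                (name, "n", s.n),
                (name, "ccc", s.ccc),
                (name, "ccc_ci_low", s.ccc_ci[0]),
                (name, "ccc_ci_high", s.ccc_ci[1]),
                (name, "mean_diff", s.bland_altman.mean_diff),
                (name, "sd_diff", s.bland_altman.sd_diff),
                (name, "loa_low", s.bland_altman.loa_low),
                (name, "loa_high", s.bland_altman.loa_high),
                (name, "abs_diff_mean", s.abs_diff.mean),
                (name, "abs_diff_sd", s.abs_diff.sd),
                (name, "abs_diff_max", s.abs_diff.max),
                (name, "measured_mean", s.measured.mean),
                (name, "calculated_mean", s.calculated.mean),
            ]
        rows.append(("all", "mean_ccc", self.mean_ccc))
        return pd.DataFrame(rows, columns=["stratum", "statistic", "value"])


class EmptyStratumError(ValueError):
    """The requested cohort stratum contains no rows."""


def _stratum_agreement(name: str, measured: np.ndarray, calculated: np.ndarray) -> StratumAgreement:
    pairs = PairedMeasurements(measured, calculated)
    ccc, lo, hi = lin_ccc_ci(pairs)
    return StratumAgreement(
        stratum=name,
        ccc=ccc,
        ccc_ci=(lo, hi),
        ccc_interpretation=ccc_label(ccc),
        bland_altman=bland_altman(pairs),
        abs_diff=absolute_difference_summary(pairs),
        measured=descriptive_summary(measured),
        calculated=descriptive_summary(calculated),
        n=pairs.n,
    )


def validate_cohort(
    cohort: SyntheticCohort | pd.DataFrame,
    timepoint: str,
    jaw: str,
) -> AgreementReport:
    """Compare measured with calculated AL in one cohort stratum.

    For each patient, the per-side calculated AL is the one-sided arc-length
    integral evaluated at that side's *measured* L and W; the total uses the
    mean depth L_total = (L_left + L_right)/2 and the summed width
    W_left + W_right.  The reference measured total AL is the sum of the two
    per-side measured ALs.  Agreement statistics are reported per side and
    for the total.
    """
    df = cohort.table if isinstance(cohort, SyntheticCohort) else cohort
    sub = df[(df["timepoint"] == timepoint) & (df["jaw"] == jaw)]
    if sub.empty:
        raise EmptyStratumError(f"cohort has no rows for jaw={jaw!r}, timepoint={timepoint!r}")

    wide = sub.pivot(index="patient_id", columns="side",
                     values=["L_meas", "W_meas", "AL_meas"])
    if wide.isna().any().any():
        raise EmptyStratumError("stratum is missing one side for some patients")

    def calc_side(side: str) -> np.ndarray:
        return np.array([
            half_arch_length(ArchGeometry(L=max(L, 0.0), W=W))
            for L, W in zip(wide[("L_meas", side)], wide[("W_meas", side)])
        ])

    L_tot = (wide[("L_meas", "left")].to_numpy() + wide[("L_meas", "right")].to_numpy()) / 2.0
    W_tot = wide[("W_meas", "left")].to_numpy() + wide[("W_meas", "right")].to_numpy()
    calc_total = np.array([
        2.0 * half_arch_length(ArchGeometry(L=max(L, 0.0), W=w / 2.0))
        for L, w in zip(L_tot, W_tot)
    ])
    meas_total = (
        wide[("AL_meas", "left")].to_numpy() + wide[("AL_meas", "right")].to_numpy()
    )

    strata = {
        "left": _stratum_agreement("left", wide[("AL_meas", "left")].to_numpy(), calc_side("left")),
        "right": _stratum_agreement(
            "right", wide[("AL_meas", "right")].to_numpy(), calc_side("right")
        ),
        "total": _stratum_agreement("total", meas_total, calc_total),
    }
    mean_ccc = float(np.mean([s.ccc for s in strata.values()]))
    return AgreementReport(jaw=jaw, timepoint=timepoint, strata=strata, mean_ccc=mean_ccc)
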