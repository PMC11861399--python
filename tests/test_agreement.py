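"""Agreement statistics: descriptives, Lin's CCC, ICC, Bland-Altman,
absolute differences, and cohort validation."""

import numpy as np
import pytest

from archlen import (
    CohortSpec,
    PairedMeasurements,
    absolute_difference_summary,
    bland_altman,
    descriptive_summary,
    generate_cohort,
    icc,
    lin_ccc,
    lin_ccc_ci,
    validate_cohort,
)
from archlen.agreement import EmptyStratumError, InsufficientDataError


class TestDescriptiveSummary:
    def test_small_sample(self):
        s = descriptive_summary([1.0, 2.0, 3.0])
        assert s.mean == 2.0
        assert s.sd == pytest.approx(1.0)
        assert (s.min, s.max) == (1.0, 3.0)
        # t(0.975, 2) = 4.3027
        assert s.ci_low == pytest.approx(-0.4841, abs=2e-4)
        assert s.ci_high == pytest.approx(4.4841, abs=2e-4)

    def test_constant_series(self):
        s = descriptive_summary([5.0, 5.0, 5.0, 5.0])
        assert s.sd == 0.0
        assert s.ci_low == s.ci_high == 5.0

    def test_single_value_rejected(self):
        with pytest.raises(InsufficientDataError):
            descriptive_summary([5.0])


class TestLinCCC:
    def test_perfect_concordance(self):
        p = PairedMeasurements([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert lin_ccc(p) == pytest.approx(1.0)

    def test_constant_offset(self):
        p = PairedMeasurements([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert lin_ccc(p) == pytest.approx(4.0 / 7.0)

    def test_perfect_discordance(self):
        x = np.array([-1.0, 0.0, 1.0])
        assert lin_ccc(PairedMeasurements(x, -x)) == pytest.approx(-1.0)

    def test_undefined_for_equal_constants(self):
        with pytest.raises(ValueError, match="undefined"):
            lin_ccc(PairedMeasurements([2.0, 2.0], [2.0, 2.0]))

    def test_symmetry_and_pearson_bound(self):
        rng = np.random.default_rng(0)
        x = rng.normal(50, 4, 40)
        y = x + rng.normal(0.5, 1.0, 40)
        p = PairedMeasurements(x, y)
        q = PairedMeasurements(y, x)
        assert lin_ccc(p) == pytest.approx(lin_ccc(q), rel=1e-12)
        assert abs(lin_ccc(p)) <= abs(np.corrcoef(x, y)[0, 1]) + 1e-12

    def test_fisher_ci_brackets_estimate(self):
        rng = np.random.default_rng(1)
        x = rng.normal(50, 4, 60)
        y = x + rng.normal(0, 1.0, 60)
        ccc, lo, hi = lin_ccc_ci(PairedMeasurements(x, y))
        assert lo < ccc < hi
        assert -1 < lo and hi < 1


class TestICC:
    def test_identical_columns(self):
        m = np.array([[10.0, 10.0], [20.0, 20.0], [30.0, 30.0]])
        assert icc(m) == pytest.approx(1.0)

    def test_constant_shift_column(self):
        """Second repeat = first + 1: high but sub-unity absolute agreement,
        matching the two-way ANOVA table worked by hand."""
        m = np.array([[10.0, 11.0], [20.0, 21.0], [30.0, 31.0]])
        # MSR=200, MSC=1.5, MSE=0 -> (200-0)/(200+0+(2/3)(1.5-0))
        assert icc(m) == pytest.approx(200.0 / 201.0)
        assert 0.9 < icc(m) < 1.0

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        m = rng.normal(20, 3, size=(15, 3))
        assert icc(m + 7.5) == pytest.approx(icc(m), rel=1e-9)

    def test_independent_noise_near_zero(self):
        """Columns of pure noise around one mean carry no subject signal."""
        rng = np.random.default_rng(3)
        m = rng.normal(0.0, 1.0, size=(200, 2))
        assert abs(icc(m)) < 0.2

    def test_consistency_variant_ignores_offset(self):
        m = np.array([[10.0, 11.0], [20.0, 21.0], [30.0, 31.0]])
        assert icc(m, variant="two-way-consistency-single") == pytest.approx(1.0)

    def test_incomplete_matrix_rejected(self):
        m = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="incomplete"):
            icc(m)

    def test_cross_check_against_pingouin(self):
        """Independent oracle: pingouin's ICC2 (two-way absolute, single)."""
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(4)
        subj = rng.normal(20, 3, 25)
        m = subj[:, None] + rng.normal(0, 0.5, size=(25, 3))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(25), 3),
                "rater": np.tile(np.arange(3), 25),
                "score": m.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        mask = ref["Type"].isin(["ICC2", "ICC(A,1)"])  # label differs across versions
        ref_icc2 = float(ref.loc[mask, "ICC"].iloc[0])
        assert icc(m) == pytest.approx(ref_icc2, abs=1e-9)


class TestBlandAltman:
    def test_constant_offset(self):
        x = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(PairedMeasurements(x, x + 1.0))
        assert ba.mean_diff == pytest.approx(-1.0)
        assert ba.sd_diff == 0.0
        assert ba.loa_low == ba.loa_high == pytest.approx(-1.0)

    def test_identity(self):
        x = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(PairedMeasurements(x, x))
        assert ba.mean_diff == 0.0 and ba.sd_diff == 0.0
        np.testing.assert_array_equal(ba.diffs, 0.0)

    def test_hand_example(self):
        ba = bland_altman(PairedMeasurements([10.0, 12.0], [11.0, 11.0]))
        assert ba.mean_diff == 0.0
        assert ba.sd_diff == pytest.approx(np.sqrt(2.0))
        assert ba.loa_low == pytest.approx(-2.772, abs=1e-3)
        assert ba.loa_high == pytest.approx(2.772, abs=1e-3)

    def test_loa_reconstruction(self):
        rng = np.random.default_rng(5)
        x = rng.normal(50, 4, 30)
        y = x + rng.normal(0.3, 0.8, 30)
        ba = bland_altman(PairedMeasurements(x, y))
        assert ba.loa_high - ba.loa_low == pytest.approx(2 * 1.96 * ba.sd_diff, rel=1e-12)

    def test_plot_written(self, tmp_path):
        from archlen import bland_altman_plot

        rng = np.random.default_rng(6)
        x = rng.normal(50, 4, 20)
        out = tmp_path / "ba.png"
        bland_altman_plot(PairedMeasurements(x, x + rng.normal(0, 0.5, 20)), out)
        assert out.stat().st_size > 0


class TestAbsoluteDifferenceSummary:
    def test_identity_all_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        s = absolute_difference_summary(PairedMeasurements(x, x))
        assert s.mean == 0.0 and s.sd == 0.0 and s.max == 0.0

    def test_sign_removed(self):
        s = absolute_difference_summary(PairedMeasurements([10.0, 12.0], [11.0, 11.0]))
        assert s.mean == 1.0 and s.sd == 0.0

    def test_hand_example_and_symmetry(self):
        x, y = [1.0, 2.0, 3.0], [1.5, 2.0, 2.5]
        s = absolute_difference_summary(PairedMeasurements(x, y))
        assert s.mean == pytest.approx(1.0 / 3.0)
        assert s.sd == pytest.approx(0.2887, abs=1e-4)
        t = absolute_difference_summary(PairedMeasurements(y, x))
        assert (s.mean, s.sd, s.min, s.max) == (t.mean, t.sd, t.min, t.max)


class TestValidateCohort:
    def test_noise_free_cohort_perfect_agreement(self):
        """The model validated against its own noise-free emulated measurements:
        CCC 1 and negligible absolute differences (polyline discretisation only)."""
        spec = CohortSpec(n=12, noise_sd=0.0, n_polyline_points=200, seed=20,
                          timepoints=("T0",))
        report = validate_cohort(generate_cohort(spec), "T0", "upper")
        for name in ("left", "right"):
            s = report.strata[name]
            assert s.ccc > 0.9999
            assert s.abs_diff.max < 0.05 / 100 * s.measured.mean
        # the total stratum compares the symmetric-model length (mean depth,
        # summed width) against the sum of two asymmetric sides, so a small
        # bookkeeping discrepancy survives even without noise
        total = report.strata["total"]
        assert total.ccc > 0.999
        assert total.abs_diff.max < 1.0 / 100 * total.measured.mean

    def test_default_noise_high_concordance(self):
        spec = CohortSpec(n=50, seed=21, timepoints=("T0",))
        report = validate_cohort(generate_cohort(spec), "T0", "upper")
        assert report.mean_ccc > 0.95
        assert set(report.strata) == {"left", "right", "total"}

    def test_ccc_improves_as_noise_vanishes(self):
        """Mean CCC increases monotonically as measurement noise shrinks
        (common seed across noise levels)."""
        cccs = []
        for sd in (0.4, 0.2, 0.1, 0.0):
            spec = CohortSpec(n=40, noise_sd=sd, seed=22, timepoints=("T0",),
                              jaws=("upper",))
            cccs.append(validate_cohort(generate_cohort(spec), "T0", "upper").mean_ccc)
        assert all(a < b for a, b in zip(cccs, cccs[1:]))

    def test_missing_stratum_rejected(self):
        cohort = generate_cohort(CohortSpec(n=3, seed=23, timepoints=("T0",)))
        with pytest.raises(EmptyStratumError):
            validate_cohort(cohort, "T1", "upper")

    def test_report_frame_layout(self):
        cohort = generate_cohort(CohortSpec(n=5, seed=24, timepoints=("T0",)))
        frame = validate_cohort(cohort, "T0", "lower").to_frame()
        assert list(frame.columns) == ["stratum", "statistic", "value"]
        assert ("all", "mean_ccc") in set(zip(frame.stratum, frame.statistic))
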