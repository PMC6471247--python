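"""Unit and property tests for the fractional-conversion kinetics module."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fermkin import (
    KineticFit,
    TimeCourse,
    build_rate_table,
    degradation_extent,
    fit_fractional_conversion,
    fractional_conversion,
    subtract_background,
)
from fermkin.kinetics import (
    AlignmentError,
    InsufficientDataError,
    NonIdentifiableError,
    PairingError,
)

from conftest import GRID, make_curve


class TestFractionalConversion:
    @pytest.mark.parametrize(
        "C0,Cinf,K,t,expected",
        [
            (10, 10, 0.5, 7, 10.0),            # constant curve when C0 == Cinf
            (0, 60, 0.131, 0, 0.0),            # t=0 returns C0
            (0, 60, 0.131, np.log(2) / 0.131, 30.0),  # half-conversion at ln2/K
        ],
    )
    def test_known_values(self, C0, Cinf, K, t, expected):
        assert fractional_conversion(C0, Cinf, K, t) == pytest.approx(expected)

    @pytest.mark.parametrize("K,t", [(-0.1, 1.0), (0.1, -1.0)])
    def test_negative_domain_rejected(self, K, t):
        with pytest.raises(ValueError):
            fractional_conversion(0, 60, K, t)

    @given(
        C0=st.floats(0, 100),
        Cinf=st.floats(0, 100),
        K=st.floats(0.001, 5),
    )
    def test_monotone_between_endpoints(self, C0, Cinf, K):
        """C(t) runs monotonically from C0 toward Cinf."""
        c = fractional_conversion(C0, Cinf, K, GRID)
        assert c[0] == pytest.approx(C0)
        diffs = np.diff(c)
        assert np.all(diffs >= -1e-12) or np.all(diffs <= 1e-12)
        lo, hi = min(C0, Cinf), max(C0, Cinf)
        assert np.all((c >= lo - 1e-9) & (c <= hi + 1e-9))

    @given(K=st.floats(0.01, 2), t=st.floats(0, 48))
    def test_exponential_approach_identity(self, K, t):
        """|C(t) - Cinf| equals |C0 - Cinf|·exp(-K·t) exactly."""
        C0, Cinf = 3.0, 40.0
        c = fractional_conversion(C0, Cinf, K, t)
        assert abs(c - Cinf) == pytest.approx(abs(C0 - Cinf) * np.exp(-K * t))


class TestFit:
    @pytest.mark.parametrize(
        "C0,Cinf,K",
        [(0.0, 60.0, 0.131), (0.8, 0.1, 0.211)],
        ids=["scfa-production", "procyanidin-degradation"],
    )
    def test_recovers_printed_rates_to_three_decimals(self, C0, Cinf, K):
        """Noiseless curves at study-reported rate constants refit exactly."""
        fit = fit_fractional_conversion(make_curve(C0, Cinf, K))
        assert round(fit.K_hat, 3) == K
        assert fit.converged

    @settings(max_examples=50, deadline=None)
    @given(
        K=st.floats(0.01, 0.5),
        C0=st.floats(0, 5),
        delta=st.floats(1, 60),
        up=st.booleans(),
    )
    def test_noiseless_recovery_property(self, K, C0, delta, up):
        """Any noiseless curve on the 9-point grid refits to 1e-4 relative."""
        Cinf = C0 + delta if up else max(C0 - delta, 0.0)
        if abs(Cinf - C0) < 0.5:
            Cinf = C0 + 0.5
        fit = fit_fractional_conversion(make_curve(C0, Cinf, K))
        assert fit.K_hat == pytest.approx(K, rel=1e-4)
        assert fit.C0_hat == pytest.approx(C0, rel=1e-4, abs=1e-5)
        assert fit.Cinf_hat == pytest.approx(Cinf, rel=1e-4, abs=1e-5)

    def test_flat_series_not_identifiable(self):
        with pytest.raises(NonIdentifiableError):
            fit_fractional_conversion(make_curve(5, 5, 2))

    def test_too_few_points(self):
        tc = TimeCourse("O1", "Mnc", 1, "acetate",
                        [0, 2, 4], [0, 1, 2], corrected=True)
        with pytest.raises(InsufficientDataError):
            fit_fractional_conversion(tc)

    def test_duplicate_times_averaged_with_warning(self):
        t = np.array([0, 0, 2, 4, 6, 8.0])
        base = fractional_conversion(0, 10, 0.3, np.array([0, 2, 4, 6, 8.0]))
        conc = np.array([base[0] + 0.2, base[0] - 0.2, *base[1:]])
        tc = TimeCourse("O1", "Mnc", 1, "x", t, conc, corrected=True)
        with pytest.warns(UserWarning, match="duplicate"):
            fit = fit_fractional_conversion(tc)
        assert fit.n_points == 5

    def test_direction_follows_asymptote(self):
        up = fit_fractional_conversion(make_curve(0, 60, 0.1))
        down = fit_fractional_conversion(make_curve(1, 0.1, 0.2))
        assert up.direction == "production"
        assert down.direction == "degradation"


class TestBackgroundSubtraction:
    def test_self_subtraction_is_zero(self):
        x = make_curve(0.1, 0.5, 0.2, matrix="control", corrected=False)
        tc = make_curve(0.1, 0.5, 0.2, corrected=False)
        out = subtract_background(tc, x)
        assert np.allclose(out.conc, 0.0)
        assert out.corrected

    def test_zero_control_is_identity(self):
        tc = make_curve(0, 10, 0.2, corrected=False)
        ctrl = TimeCourse("O1", "control", 1, "acetate", GRID,
                          np.zeros_like(GRID))
        out = subtract_background(tc, ctrl)
        assert np.allclose(out.conc, tc.conc)
        assert out.corrected and not out.clipped_points

    def test_clipping_records_indices(self):
        t = np.array([0.0, 2.0])
        tc = TimeCourse("O1", "Mnc", 1, "x", t, [0.05, 0.10])
        ctrl = TimeCourse("O1", "control", 1, "x", t, [0.08, 0.02])
        out = subtract_background(tc, ctrl)
        assert np.allclose(out.conc, [0.0, 0.08])
        assert out.clipped_points == [0]

    def test_unclipped_subtraction_roundtrips(self):
        tc = make_curve(0.0, 1.0, 0.1, corrected=False)
        ctrl = TimeCourse("O1", "control", 1, "acetate", GRID,
                          np.linspace(0.2, 0.05, len(GRID)))
        out = subtract_background(tc, ctrl, clip_at_zero=False)
        assert np.allclose(out.conc + ctrl.conc, tc.conc)

    def test_pairing_errors(self):
        tc = make_curve(0, 1, 0.1)
        wrong_donor = TimeCourse("O2", "control", 1, "acetate", GRID,
                                 np.zeros_like(GRID))
        not_control = make_curve(0, 1, 0.1, matrix="Mno")
        with pytest.raises(PairingError):
            subtract_background(tc, wrong_donor)
        with pytest.raises(PairingError):
            subtract_background(tc, not_control)

    def test_grid_mismatch_requires_interpolation(self):
        tc = make_curve(0, 1, 0.1)
        coarse = TimeCourse("O1", "control", 1, "acetate",
                            [0.0, 24.0, 48.0], [0.1, 0.1, 0.1])
        with pytest.raises(AlignmentError):
            subtract_background(tc, coarse)
        out = subtract_background(tc, coarse, interpolate_control=True)
        assert np.allclose(out.conc, np.maximum(tc.conc - 0.1, 0))


class TestDegradationExtent:
    @pytest.mark.parametrize(
        "c0,c48,expected", [(10, 0, 100.0), (10, 10, 0.0), (10, 1.6, 84.0)]
    )
    def test_extent_arithmetic(self, c0, c48, expected):
        conc = np.linspace(c0, c48, len(GRID))
        tc = TimeCourse("O1", "Mno", 1, "PCA", GRID, conc, corrected=True)
        assert degradation_extent(tc) == pytest.approx(expected)

    @given(scale=st.floats(0.01, 100))
    def test_scale_invariance(self, scale):
        conc = np.linspace(2.0, 0.5, len(GRID))
        a = TimeCourse("O1", "Mno", 1, "PCA", GRID, conc, corrected=True)
        b = TimeCourse("O1", "Mno", 1, "PCA", GRID, conc * scale, corrected=True)
        assert degradation_extent(a) == pytest.approx(degradation_extent(b))

    def test_zero_start_undefined(self):
        tc = TimeCourse("O1", "Mno", 1, "PCA", GRID,
                        np.zeros_like(GRID), corrected=True)
        with pytest.raises(ValueError, match="undefined"):
            degradation_extent(tc)

    def test_missing_endpoint(self):
        tc = TimeCourse("O1", "Mno", 1, "PCA", [0, 2, 4.0], [1, 0.8, 0.6],
                        corrected=True)
        with pytest.raises(ValueError, match="t=0 and t=48"):
            degradation_extent(tc)


class TestRateTable:
    @staticmethod
    def _fit():
        return KineticFit(C0_hat=0, Cinf_hat=1, K_hat=0.1, rss=0,
                          n_points=9, converged=True)

    def test_empty(self):
        assert len(build_rate_table({})) == 0

    @pytest.mark.parametrize(
        "n_donors,n_matrices,n_analytes",
        [(2, 1, 1), (4, 3, 4)],
        ids=["two-rows", "full-study-48-rows"],
    )
    def test_cardinality(self, n_donors, n_matrices, n_analytes):
        fits = {
            (f"O{d}", f"M{m}", f"a{a}"): self._fit()
            for d in range(n_donors)
            for m in range(n_matrices)
            for a in range(n_analytes)
        }
        assert len(build_rate_table(fits)) == n_donors * n_matrices * n_analytes

    def test_duplicate_key_rejected(self):
        pairs = [(("O1", "Mnc", "acetate"), self._fit()),
                 (("O1", "Mnc", "acetate"), self._fit())]
        with pytest.raises(ValueError, match="duplicate"):
            build_rate_table(pairs)

    def test_non_converged_flagged_not_dropped(self):
        bad = KineticFit(C0_hat=0, Cinf_hat=1, K_hat=0.1, rss=0,
                         n_points=9, converged=False)
        table = build_rate_table({("O1", "Mnc", "acetate"): bad})
        assert len(table) == 1
        assert not table.data["converged"].iloc[0]


class TestTimeCourseInvariants:
    def test_rejects_decreasing_times(self):
        with pytest.raises(ValueError, match="decreasing"):
            TimeCourse("O1", "Mnc", 1, "x", [0, 4, 2], [0, 1, 2])

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            TimeCourse("O1", "Mnc", 1, "x", [0, 2], [0.0])

    def test_rejects_negative_uncorrected(self):
        with pytest.raises(ValueError, match=">= 0"):
            TimeCourse("O1", "Mnc", 1, "x", [0, 2], [0.1, -0.1])
        # corrected series may be negative (unclipped subtraction)
        TimeCourse("O1", "Mnc", 1, "x", [0, 2], [0.1, -0.1], corrected=True)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="finite"):
            TimeCourse("O1", "Mnc", 1, "x", [0, 2], [0.1, np.nan])
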