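"""4PL model, fitting, ROUT, AICc comparison and IFN quantification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivtkit.dose_response import (
    DoseResponseDataset,
    StandardCurve,
    aicc,
    akaike_probability,
    blank_subtract,
    compare_shared_kd,
    eval_4pl,
    fit_4pl,
    quantify_ifn,
    rout_outliers,
)
from ivtkit.exceptions import (
    FitError,
    InsufficientDataError,
    ParameterError,
)
from ivtkit.synthdata import gen_dose_response


class TestEval4pl:
    def test_midpoint_identity(self):
        assert eval_4pl(10.0, 0.0, 2.0, 10.0, 1.0) == pytest.approx(1.0)
        assert eval_4pl(5.0, 0.5, 2.5, 5.0, 2.0) == pytest.approx(1.5)

    def test_asymptote(self):
        assert eval_4pl(1e12, 0.0, 2.0, 10.0, 1.0) == pytest.approx(2.0, rel=1e-9)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ParameterError):
            eval_4pl(0.0, 0.0, 1.0, 1.0, 1.0)

    @given(
        kd=st.floats(0.1, 100.0),
        top=st.floats(0.2, 5.0),
        slope=st.floats(0.3, 5.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_increasing_for_positive_slope(self, kd, top, slope):
        c = np.logspace(-2, 4, 40)
        od = eval_4pl(c, 0.0, top, kd, slope)
        # non-decreasing everywhere (float saturation near the asymptote)
        assert np.all(np.diff(od) >= 0)
        # strictly increasing through the transition region around Kd
        mid = (c > kd / 10) & (c < kd * 10)
        assert np.all(np.diff(od[mid]) > 0)
        assert od[0] < od[-1]


class TestBlankSubtract:
    def _ds(self, od, blanks):
        return DoseResponseDataset("g", np.ones(len(od)), np.array(od),
                                   blanks=np.array(blanks))

    def test_mean_blank_subtracted(self):
        out = blank_subtract(self._ds([0.8], [0.1, 0.1]))
        assert out.od[0] == pytest.approx(0.7)
        assert out.blank_corrected

    def test_negatives_retained(self):
        out = blank_subtract(self._ds([0.05], [0.1]))
        assert out.od[0] == pytest.approx(-0.05)

    def test_zero_blank_unchanged(self):
        out = blank_subtract(self._ds([0.4], [0.0]))
        assert out.od[0] == pytest.approx(0.4)

    def test_no_blanks_rejected(self):
        with pytest.raises(ParameterError):
            blank_subtract(self._ds([0.4], []))


class TestFit4pl:
    @pytest.mark.parametrize("kd,top,slope", [
        (5.0, 1.0, 1.0), (0.5, 2.0, 0.7), (80.0, 0.6, 2.5),
    ])
    def test_noiseless_recovery(self, concentrations, kd, top, slope):
        ds, _ = gen_dose_response(kd, top, slope, concentrations,
                                  noise_sd=0.0, n_replicates=2, seed=1)
        fit = fit_4pl(ds.concentration, ds.od)
        assert fit.kd == pytest.approx(kd, rel=1e-6)
        assert fit.top == pytest.approx(top, rel=1e-6)
        assert fit.slope == pytest.approx(slope, rel=1e-6)
        assert fit.bottom == 0.0 and fit.k_params == 3

    def test_free_bottom_recovery(self, concentrations):
        od = eval_4pl(np.tile(concentrations, 2), 0.3, 1.5, 8.0, 1.2)
        fit = fit_4pl(np.tile(concentrations, 2), od, constrain_bottom=False)
        assert fit.bottom == pytest.approx(0.3, abs=1e-5)
        assert fit.kd == pytest.approx(8.0, rel=1e-4)
        assert fit.k_params == 4

    def test_constant_od_unidentifiable(self, concentrations):
        with pytest.raises(FitError):
            fit_4pl(concentrations, np.full(8, 0.5))

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_4pl([1.0, 10.0, 100.0], [0.1, 0.5, 0.9])

    def test_narrow_span_warns(self):
        conc = np.linspace(5, 20, 8)
        od = eval_4pl(conc, 0.0, 1.0, 10.0, 1.0)
        with pytest.warns(UserWarning, match="log units"):
            fit_4pl(conc, od)

    def test_kd_recovery_under_noise(self, concentrations):
        """Median |Kd_hat/Kd - 1| <= 15% at noise SD 0.05, 8 conc x 4 reps."""
        errs = []
        for seed in range(100):
            ds, _ = gen_dose_response(10.0, 1.0, 1.0, concentrations,
                                      noise_sd=0.05, n_replicates=4,
                                      seed=5000 + seed)
            fit = fit_4pl(ds.concentration, ds.od)
            errs.append(abs(fit.kd / 10.0 - 1.0))
        assert np.median(errs) <= 0.15


class TestRout:
    def test_clean_noiseless_data_unflagged(self, concentrations):
        ds, _ = gen_dose_response(10, 1, 1, concentrations, noise_sd=0.0,
                                  n_replicates=2, seed=3)
        res = rout_outliers(ds.concentration, ds.od, q=0.01)
        assert res.flags.sum() == 0

    def test_single_gross_outlier_flagged(self, concentrations):
        ds, _ = gen_dose_response(10, 1, 1, concentrations, noise_sd=0.01,
                                  n_replicates=2, seed=4)
        od = ds.od.copy()
        od[5] += 50 * 0.01
        res = rout_outliers(ds.concentration, od, q=0.01)
        assert res.flags[5]
        assert res.flags.sum() == 1
        assert res.fit.outlier_mask[5]

    def test_refuses_mass_exclusion(self, concentrations):
        # 10 of 40 points grossly displaced: above the 20% ceiling, but
        # within the robust fit's breakdown point so they are all flagged
        ds, _ = gen_dose_response(10, 1, 1, concentrations, noise_sd=0.01,
                                  n_replicates=5, seed=5)
        od = ds.od.copy()
        od[::4] += np.where(np.arange(10) % 2 == 0, 0.5, -0.5)
        with pytest.warns(UserWarning, match="refusing"):
            res = rout_outliers(ds.concentration, od, q=0.01,
                                max_outlier_fraction=0.2)
        assert not res.excluded
        assert res.flags.sum() >= 8

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            rout_outliers(np.logspace(0, 2, 8), np.linspace(0, 1, 8))

    def test_operating_characteristics(self, concentrations):
        """10% injected gross outliers at 10x noise: >= 90% flagged,
        <= 2% of clean points flagged (median over 100 sims)."""
        sens, fpr = [], []
        for seed in range(100):
            ds, truth = gen_dose_response(
                10, 1.0, 1.0, concentrations, noise_sd=0.05,
                outlier_fraction=0.1, outlier_scale=10.0,
                n_replicates=5, seed=6000 + seed,
            )
            res = rout_outliers(ds.concentration, ds.od, q=0.01)
            injected = np.zeros(len(ds), dtype=bool)
            injected[truth.params["outlier_indices"]] = True
            sens.append((res.flags & injected).sum() / injected.sum())
            fpr.append((res.flags & ~injected).sum() / (~injected).sum())
        assert np.median(sens) >= 0.9
        assert np.median(fpr) <= 0.02


class TestAicc:
    def test_closed_form_hand_value(self):
        # N=20, K=3: 20 ln(0.05/20) + 6 + 24/16
        expected = 20 * np.log(0.05 / 20) + 6 + 2 * 3 * 4 / 16
        assert aicc(0.05, 20, 3) == pytest.approx(expected, rel=1e-12)

    def test_halving_ss_drops_n_ln2(self):
        assert aicc(0.05, 20, 3) - aicc(0.025, 20, 3) == pytest.approx(
            20 * np.log(2)
        )

    def test_domain_errors(self):
        with pytest.raises(ParameterError):
            aicc(1.0, 4, 3)
        with pytest.raises(ParameterError):
            aicc(0.0, 20, 3)

    def test_monotone_in_ss(self):
        values = [aicc(ss, 20, 3) for ss in (0.01, 0.02, 0.05, 0.5)]
        assert np.all(np.diff(values) > 0)


class TestAkaikeProbability:
    def test_fixed_points(self):
        assert akaike_probability(0.0) == pytest.approx(0.5, abs=1e-15)
        assert akaike_probability(2 * np.log(3)) == pytest.approx(0.75, abs=1e-12)

    def test_limits_and_monotonicity(self):
        x = np.linspace(-60, 60, 1001)
        y = np.array([akaike_probability(v) for v in x])
        assert np.all(np.diff(y) >= 0)
        assert y[0] < 1e-12 and y[-1] > 1 - 1e-12
        assert np.all((y >= 0) & (y <= 1))


class TestCompareSharedKd:
    def test_identical_kd_moderate_probability(self, concentrations):
        a, _ = gen_dose_response(10, 1.0, 1.0, concentrations, noise_sd=0.05,
                                 n_replicates=4, seed=10, group="A")
        b, _ = gen_dose_response(10, 1.1, 1.0, concentrations, noise_sd=0.05,
                                 n_replicates=4, seed=11, group="B")
        cmp = compare_shared_kd(a, b)
        assert 0 < cmp.akaike_probability < 1
        assert cmp.kd_ratio >= 1.0
        assert cmp.k_separate == 6 and cmp.k_shared == 5

    def test_hundredfold_kd_detected(self, concentrations):
        a, _ = gen_dose_response(1.0, 1.0, 1.0, concentrations, noise_sd=0.05,
                                 n_replicates=4, seed=12, group="A")
        b, _ = gen_dose_response(100.0, 1.0, 1.0, concentrations,
                                 noise_sd=0.05, n_replicates=4, seed=13,
                                 group="B")
        cmp = compare_shared_kd(a, b)
        assert cmp.prefers_separate
        assert cmp.akaike_probability > 0.99
        assert cmp.kd_ratio == pytest.approx(100.0, rel=0.35)

    def test_share_must_include_kd(self, concentrations):
        a, _ = gen_dose_response(10, 1, 1, concentrations, seed=14, group="A")
        b, _ = gen_dose_response(10, 1, 1, concentrations, seed=15, group="B")
        with pytest.raises(ParameterError):
            compare_shared_kd(a, b, share=("top",))

    def test_too_few_concentrations(self):
        conc = np.logspace(0, 2, 4)
        a, _ = gen_dose_response(10, 1, 1, conc, seed=16, group="A")
        b, _ = gen_dose_response(10, 1, 1, conc, seed=17, group="B")
        with pytest.raises(InsufficientDataError):
            compare_shared_kd(a, b)


class TestQuantifyIfn:
    @pytest.fixture()
    def curve(self):
        conc = np.array([1000.0, 250.0, 62.5, 15.6, 3.9, 0.98])
        od = eval_4pl(conc, 0.05, 1.8, 40.0, 1.1)
        return StandardCurve.from_standards(conc, od)

    def test_inverse_at_interior_standard(self, curve):
        od = eval_4pl(62.5, 0.05, 1.8, 40.0, 1.1)
        values, flags = quantify_ifn(curve, [od], dilution_factor=1.0)
        assert flags == ["ok"]
        assert values[0] == pytest.approx(62.5, rel=1e-6)

    def test_dilution_factor_multiplies(self, curve):
        od = eval_4pl(62.5, 0.05, 1.8, 40.0, 1.1)
        v1, _ = quantify_ifn(curve, [od], dilution_factor=1.0)
        v7, _ = quantify_ifn(curve, [od], dilution_factor=7.0)
        assert v7[0] == pytest.approx(7 * v1[0], rel=1e-9)

    def test_censoring_below_and_above(self, curve):
        values, flags = quantify_ifn(curve, [0.0, 10.0])
        assert flags == ["left", "right"]
        assert values[0] == pytest.approx(curve.lloq)
        assert values[1] == pytest.approx(curve.uloq)

    def test_nonfinite_od_rejected(self, curve):
        with pytest.raises(ParameterError):
            quantify_ifn(curve, [np.nan])
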