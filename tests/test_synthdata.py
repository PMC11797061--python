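"""Generator correctness: determinism, documented distributions, truth."""

import numpy as np
import pytest

from ivtkit.dose_response import eval_4pl
from ivtkit.exceptions import FormatError, ParameterError
from ivtkit.synthdata import (
    gen_cell_image,
    gen_dilution_assay,
    gen_dose_response,
    gen_dotblot,
    gen_shape_counts,
    gen_structured_reactivity,
    random_hairpin_structure,
)


class TestStructuredReactivity:
    def test_unpaired_exceeds_paired(self):
        profile, _ = gen_structured_reactivity("((((....))))" * 5, seed=1)
        paired = np.tile([1, 1, 1, 1, 0, 0, 0, 0, 1, 1, 1, 1], 5).astype(bool)
        assert profile[~paired].mean() > profile[paired].mean()
        assert np.all(profile >= 0)

    def test_all_dot_draws_from_unpaired_distribution(self):
        profile, _ = gen_structured_reactivity("." * 200, seed=2)
        # unpaired Gamma(4, 0.2): mean 0.8
        assert profile.mean() == pytest.approx(0.8, rel=0.15)

    @pytest.mark.parametrize("bad", ["((((....))", "....))....", "((((xx))))...."])
    def test_unbalanced_or_invalid_brackets_rejected(self, bad):
        with pytest.raises(FormatError):
            gen_structured_reactivity(bad, seed=0)

    def test_short_string_rejected(self):
        with pytest.raises(FormatError):
            gen_structured_reactivity("(...)", seed=0)

    def test_deterministic(self):
        a, _ = gen_structured_reactivity("((..........))", seed=7)
        b, _ = gen_structured_reactivity("((..........))", seed=7)
        np.testing.assert_array_equal(a, b)


class TestRandomHairpin:
    @pytest.mark.parametrize("length", [10, 57, 100, 1000])
    def test_valid_and_right_length(self, length):
        s = random_hairpin_structure(length, 5)
        assert len(s) == length
        gen_structured_reactivity(s, 0)  # parses


class TestShapeCounts:
    def test_zero_sensitivity_means_matched_rates(self):
        profile = np.full(200, 1.0)
        pairs, _ = gen_shape_counts(
            profile, coverage_mean=50_000, sensitivity=0.0, seed=3
        )
        nai, dmso = pairs[0]
        diff = nai.mutations / nai.coverage - dmso.mutations / dmso.coverage
        assert abs(diff.mean()) < 5e-5

    def test_replicate_count_and_lengths(self):
        profile = np.linspace(0, 1, 60)
        pairs, _ = gen_shape_counts(profile, n_replicates=3, seed=4)
        assert len(pairs) == 3
        assert all(len(n) == len(d) == 60 for n, d in pairs)
        channels = {(n.channel, d.channel) for n, d in pairs}
        assert channels == {("NAI", "DMSO")}

    def test_rate_above_one_rejected(self):
        with pytest.raises(ParameterError):
            gen_shape_counts(np.array([100.0] * 20), sensitivity=0.02, seed=0)

    def test_rate_difference_tracks_truth(self, hairpin_100):
        """NAI-DMSO rate difference correlates > 0.9 with truth at deep
        coverage, across 20 seeds."""
        for seed in range(20):
            profile, _ = gen_structured_reactivity(hairpin_100, 300 + seed)
            pairs, _ = gen_shape_counts(
                profile, coverage_mean=50_000, seed=400 + seed, n_replicates=1
            )
            nai, dmso = pairs[0]
            diff = nai.mutations / nai.coverage - dmso.mutations / dmso.coverage
            r = np.corrcoef(diff, profile)[0, 1]
            assert r > 0.9

    def test_deterministic(self):
        profile = np.linspace(0, 1, 30)
        a, _ = gen_shape_counts(profile, seed=9)
        b, _ = gen_shape_counts(profile, seed=9)
        for (na, da), (nb, db) in zip(a, b):
            np.testing.assert_array_equal(na.mutations, nb.mutations)
            np.testing.assert_array_equal(da.coverage, db.coverage)


class TestDoseResponse:
    def test_noiseless_points_on_curve(self, concentrations):
        ds, _ = gen_dose_response(
            5.0, 2.0, 1.3, concentrations, noise_sd=0.0, n_replicates=2, seed=1
        )
        expected = eval_4pl(ds.concentration, 0.0, 2.0, 5.0, 1.3)
        np.testing.assert_allclose(ds.od, expected, rtol=1e-12)

    def test_midpoint_identity(self):
        ds, _ = gen_dose_response(
            10.0, 2.0, 1.0, [10.0], noise_sd=0.0, n_replicates=1, seed=0
        )
        assert ds.od[0] == pytest.approx(1.0, abs=1e-12)

    def test_outlier_count_exact(self, concentrations):
        ds, truth = gen_dose_response(
            10, 1, 1, concentrations, noise_sd=0.05,
            outlier_fraction=0.1, n_replicates=5, seed=2,
        )
        assert len(ds) == 40
        assert truth.params["outlier_indices"].size == 4

    @pytest.mark.parametrize("kwargs", [
        {"kd": -1.0}, {"kd": 0.0},
    ])
    def test_bad_kd_rejected(self, kwargs, concentrations):
        with pytest.raises(ParameterError):
            gen_dose_response(top=1, slope=1, concentrations=concentrations,
                              seed=0, **kwargs)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ParameterError):
            gen_dose_response(1.0, 1.0, 1.0, [0.0, 1.0], seed=0)


class TestDilutionAssay:
    def test_titer_far_above_infects_everything(self):
        assay, _ = gen_dilution_assay(20.0, np.arange(1, 9), 8, seed=1)
        assert np.all(assay.wells_infected == 8)

    def test_titer_far_below_infects_nothing(self):
        assay, _ = gen_dilution_assay(-10.0, np.arange(1, 9), 8, seed=1)
        assert np.all(assay.wells_infected == 0)

    def test_half_infection_probability_at_titer(self):
        _, truth = gen_dilution_assay(4.0, np.arange(1, 9), 8, seed=0)
        p = truth.params["infection_probabilities"]
        assert p[3] == pytest.approx(0.5, abs=1e-12)  # exponent 4 == titer

    def test_uneven_spacing_rejected(self):
        with pytest.raises(ParameterError):
            gen_dilution_assay(5.0, [1.0, 2.0, 4.0], 8, seed=0)


class TestDotblot:
    def test_noiseless_monotone_and_default_series(self):
        table, _ = gen_dotblot(noise_sd=0.0, seed=1)
        amounts = table["standard_amounts"]
        np.testing.assert_array_equal(
            amounts, [500.0, 250.0, 125.0, 63.0, 31.0, 16.0]
        )
        order = np.argsort(amounts)
        assert np.all(np.diff(table["standard_intensities"][order]) > 0)

    def test_unknowns_follow_same_curve(self):
        table, truth = gen_dotblot(
            noise_sd=0.0, unknown_amounts=[100.0], seed=2
        )
        a, b = truth.params["intercept"], truth.params["slope"]
        assert table["unknown_intensities"][0] == pytest.approx(
            a + b * np.log10(100.0), rel=1e-12
        )

    def test_nonpositive_amount_rejected(self):
        with pytest.raises(ParameterError):
            gen_dotblot(standard_amounts=[10.0, -1.0, 1.0, 0.5], seed=0)


class TestCellImage:
    def test_blank_image(self):
        img, truth = gen_cell_image(0, seed=1, background_noise_sd=5.0)
        assert truth.params["n_pass"] == 0
        assert img.std() < 10

    def test_truth_count_is_n_pass(self):
        _, truth = gen_cell_image(5, n_fail_small=1, n_fail_dim=1, seed=2)
        assert truth.params["n_pass"] == 5

    def test_deterministic_bytes(self):
        a, _ = gen_cell_image(4, 1, 1, seed=5, background_noise_sd=3.0)
        b, _ = gen_cell_image(4, 1, 1, seed=5, background_noise_sd=3.0)
        assert a.tobytes() == b.tobytes()
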