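"""Rectangle + half-Gaussian unit model, profile simulator, and TFL pipeline."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sarcophen.tfl import (
    SQRT_2LN2,
    IntensityProfile,
    SarcomereUnitFit,
    aggregate_tfl,
    detect_units,
    extract_tfl_sl,
    fit_profile,
    fit_unit,
    generate_profile,
    model_unit,
    plateau_width,
    read_profile,
    results_to_frame,
    write_profile,
)


class TestModelUnit:
    def test_plateau_center(self):
        assert model_unit(1.3, c=1.3, b=5.0, A=10.0, w=1.6, sigma=0.2) == pytest.approx(15.0)

    def test_half_maximum_definition(self):
        c, b, A, w, sigma = 0.0, 2.0, 8.0, 1.6, 0.2
        x = c + w / 2 + sigma * SQRT_2LN2
        assert model_unit(x, c, b, A, w, sigma) == pytest.approx(b + A / 2)

    def test_closed_form_value(self):
        # b=0, A=1, w=1.6, σ=0.2 at x−c=1.0: exp(−0.2²/(2·0.04)) = exp(−1/2)
        val = model_unit(1.0, c=0.0, b=0.0, A=1.0, w=1.6, sigma=0.2)
        assert val == pytest.approx(math.exp(-0.5), rel=1e-12)

    def test_hard_edge_sigma_zero(self):
        assert model_unit(0.79, 0.0, 1.0, 2.0, 1.6, 0.0) == pytest.approx(3.0)
        assert model_unit(0.81, 0.0, 1.0, 2.0, 1.6, 0.0) == pytest.approx(1.0)

    @settings(deadline=None)
    @given(d=st.floats(0, 5), sigma=st.floats(0.01, 1.0))
    def test_symmetry(self, d, sigma):
        c = 1.7
        left = model_unit(c - d, c, 1.0, 3.0, 1.2, sigma)
        right = model_unit(c + d, c, 1.0, 3.0, 1.2, sigma)
        assert left == pytest.approx(right, rel=1e-12)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            model_unit(0.0, 0.0, 0.0, 1.0, -1.0, 0.1)
        with pytest.raises(ValueError):
            model_unit(0.0, 0.0, 0.0, 1.0, 1.0, -0.1)
        with pytest.raises(ValueError):
            model_unit(0.0, 0.0, 0.0, 0.0, 1.0, 0.1)


class TestGenerator:
    def test_plateau_width_closed_form(self):
        # w = 2·(1.06 − 0.15·√(2 ln 2)) = 1.7668 μm
        assert plateau_width(1.06, 0.15) == pytest.approx(1.7668, abs=5e-5)

    def test_impossible_width_rejected(self):
        with pytest.raises(ValueError, match="plateau"):
            generate_profile(true_tfl=0.1, sigma=0.15)

    def test_noiseless_bumpless_equals_model_sum(self):
        profile = generate_profile(bump_rel_amp=0.0, noise_sd=0.0, seed=3)
        truth = profile.truth
        expected = np.full_like(profile.positions, truth["baseline"])
        for c in truth["centers"]:
            expected += model_unit(
                profile.positions, c, 0.0, truth["amplitude"], truth["w"], truth["sigma"]
            )
        np.testing.assert_allclose(profile.intensities, expected, rtol=0, atol=1e-12)

    def test_determinism(self):
        a = generate_profile(noise_sd=20.0, seed=5)
        b = generate_profile(noise_sd=20.0, seed=5)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_profile_validation(self):
        with pytest.raises(ValueError, match="uniform"):
            IntensityProfile(np.cumsum([0.1, 0.1, 0.2] * 20), np.zeros(60), 0.1)
        with pytest.raises(ValueError, match="short"):
            IntensityProfile(np.arange(10) * 0.1, np.zeros(10), 0.1)


class TestDetect:
    def test_recovers_known_centers(self):
        profile = generate_profile(n_sarcomeres=5, bump_rel_amp=0.0, noise_sd=0.0)
        candidates = detect_units(profile)
        assert len(candidates) == 5
        for cand, true_c in zip(candidates, profile.truth["centers"]):
            assert abs(cand.center - true_c) <= profile.pixel_size

    def test_flat_profile_empty(self):
        flat = IntensityProfile(np.arange(64) * 0.05, np.full(64, 7.0), 0.05)
        assert detect_units(flat) == []

    def test_single_unit(self):
        profile = generate_profile(n_sarcomeres=1, bump_rel_amp=0.0)
        assert len(detect_units(profile)) == 1


class TestFitUnit:
    def test_noiseless_recovery(self):
        # a single isolated unit: the window contains no neighbouring tails
        profile = generate_profile(bump_rel_amp=0.0, noise_sd=0.0, n_sarcomeres=1)
        truth = profile.truth
        cand = detect_units(profile)[0]
        fit = fit_unit(profile, cand)
        assert fit.converged
        assert fit.c == pytest.approx(truth["centers"][0], rel=1e-4)
        assert fit.w == pytest.approx(truth["w"], rel=1e-4)
        assert fit.sigma == pytest.approx(truth["sigma"], rel=1e-4)
        assert fit.A == pytest.approx(truth["amplitude"], rel=1e-4)
        assert fit.b == pytest.approx(truth["baseline"], abs=1e-4 * truth["amplitude"])

    def test_bump_with_masking_within_10nm(self):
        profile = generate_profile(bump_rel_amp=0.15, noise_sd=0.0, n_sarcomeres=3, seed=1)
        cand = detect_units(profile)[1]
        fit = fit_unit(profile, cand, mask_fraction=0.5)
        assert abs(fit.tfl - profile.truth["true_tfl"]) <= 0.01

    def test_masking_reduces_bump_bias(self):
        profile = generate_profile(bump_rel_amp=0.15, noise_sd=0.0, n_sarcomeres=3, seed=2)
        w_true = profile.truth["w"]
        cand = detect_units(profile)[1]
        masked = fit_unit(profile, cand, mask_fraction=0.5)
        unmasked = fit_unit(profile, cand, mask_fraction=0.0)
        assert abs(masked.w - w_true) < abs(unmasked.w - w_true)

    def test_invalid_mask_fraction(self):
        profile = generate_profile(n_sarcomeres=1)
        cand = detect_units(profile)[0]
        with pytest.raises(ValueError):
            fit_unit(profile, cand, mask_fraction=1.0)


class TestExtract:
    def test_tfl_closed_form(self):
        fits = [
            SarcomereUnitFit(c=0.0, b=0, A=1, w=1.7668, sigma=0.15),
            SarcomereUnitFit(c=2.6, b=0, A=1, w=1.7668, sigma=0.15),
        ]
        results = extract_tfl_sl(fits)
        assert len(results) == 1
        assert results[0].tfl == pytest.approx(1.06, abs=5e-5)
        assert results[0].sl == pytest.approx(2.6)
        assert results[0].kept

    def test_hard_edge_limit(self):
        fit = SarcomereUnitFit(c=0.0, b=0, A=1, w=2.0, sigma=0.0)
        assert fit.tfl == pytest.approx(1.0)

    def test_window_membership(self):
        fits = [
            SarcomereUnitFit(c=x, b=0, A=1, w=1.8, sigma=0.1) for x in (0.0, 2.6, 5.2, 7.5)
        ]
        results = extract_tfl_sl(fits)
        assert [r.kept for r in results] == [True, True, False]  # last SL is 2.3

    def test_fewer_than_two_fits_empty(self):
        assert extract_tfl_sl([SarcomereUnitFit(c=0, b=0, A=1, w=1, sigma=0.1)]) == []
        bad = SarcomereUnitFit(c=1, b=0, A=1, w=1, sigma=0.1, converged=False)
        good = SarcomereUnitFit(c=0, b=0, A=1, w=1, sigma=0.1)
        assert extract_tfl_sl([good, bad]) == []

    def test_tfl_monotone_in_w_and_sigma(self):
        base = SarcomereUnitFit(c=0, b=0, A=1, w=1.6, sigma=0.15).tfl
        assert SarcomereUnitFit(c=0, b=0, A=1, w=1.7, sigma=0.15).tfl > base
        assert SarcomereUnitFit(c=0, b=0, A=1, w=1.6, sigma=0.20).tfl > base


class TestPipeline:
    def test_noiseless_round_trip_within_1nm(self):
        """Full detect→fit→extract recovers TFL and SL to 1e-3 μm (no bump)."""
        profile = generate_profile(
            true_tfl=1.06, sl=2.6, sigma=0.15, bump_rel_amp=0.0, noise_sd=0.0
        )
        results = extract_tfl_sl(fit_profile(profile))
        assert len(results) == 7
        for r in results:
            assert abs(r.tfl - 1.06) < 1e-3
            assert abs(r.sl - 2.6) < 1e-3
            assert r.kept

    def test_windowed_output_respects_sl_window(self):
        profile = generate_profile(sl=2.3, noise_sd=0.0)  # below the window
        results = extract_tfl_sl(fit_profile(profile))
        assert results and all(not r.kept for r in results)

    def test_noisy_recovery_unbiased(self):
        """5% noise + 15% bump: mean TFL over replicates within 0.02 μm."""
        tfls = []
        for rep in range(50):
            profile = generate_profile(
                true_tfl=1.06, noise_sd=50.0, bump_rel_amp=0.15,
                n_sarcomeres=4, seed=100 + rep,
            )
            tfls.extend(r.tfl for r in extract_tfl_sl(fit_profile(profile)) if r.kept)
        assert abs(np.mean(tfls) - 1.06) < 0.02


class TestAggregate:
    @staticmethod
    def frame(rows):
        return pd.DataFrame(
            rows, columns=["tfl", "sl", "kept", "animal", "bundle", "genotype"]
        )

    def test_hierarchical_mean(self):
        rows = [
            (1.0, 2.6, True, "a1", "b1", "WT"),
            (1.0, 2.6, True, "a1", "b1", "WT"),
            (1.2, 2.6, True, "a1", "b2", "WT"),
            (1.2, 2.6, True, "a1", "b2", "WT"),
        ]
        out = aggregate_tfl(self.frame(rows))
        assert out["per_animal"]["mean"].iloc[0] == pytest.approx(1.1)
        assert out["per_genotype"]["mean"].iloc[0] == pytest.approx(1.1)

    def test_empty_after_window_filter_rejected(self):
        rows = [(1.0, 2.0, False, "a1", "b1", "WT")]
        with pytest.raises(ValueError, match="SL-window"):
            aggregate_tfl(self.frame(rows))

    def test_two_group_t_test_reported(self):
        rows = []
        for animal, genotype, tfl_val in [
            ("a1", "WT", 1.06), ("a2", "WT", 1.05), ("a3", "WT", 1.07),
            ("a4", "HOM", 0.96), ("a5", "HOM", 0.95), ("a6", "HOM", 0.97),
        ]:
            rows += [(tfl_val, 2.6, True, animal, "b1", genotype)]
        out = aggregate_tfl(self.frame(rows))
        assert out["t_test"]["p"] < 0.01


def test_profile_csv_round_trip(tmp_path):
    profile = generate_profile(noise_sd=10.0, seed=9, source={"animal": "a1"})
    path = tmp_path / "profile.csv"
    write_profile(profile, path)
    back = read_profile(path)
    np.testing.assert_allclose(back.positions, profile.positions, atol=0)
    np.testing.assert_allclose(back.intensities, profile.intensities, atol=0)
    assert back.pixel_size == profile.pixel_size
    assert back.source["animal"] == "a1"


def test_results_frame_carries_hierarchy():
    profile = generate_profile(n_sarcomeres=3, noise_sd=0.0)
    results = extract_tfl_sl(
        fit_profile(profile), source={"animal": "a1", "bundle": "b1", "genotype": "WT"}
    )
    frame = results_to_frame(results)
    assert set(frame.columns) >= {"tfl", "sl", "kept", "animal", "bundle", "genotype"}
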