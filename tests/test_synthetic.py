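"""Generator properties: smoothness, attenuation law, determinism,
contaminant recoverability and clip-plan coverage."""

import math

import numpy as np
import pytest

import affectconsensus as ac
from affectconsensus.errors import InvalidClipError, InvalidParameterError
from affectconsensus.qc import run_qc
from affectconsensus.synthetic import FILM_DURATIONS_S
from affectconsensus.types import pearson_r


def lag1_autocorr(x):
    return float(np.corrcoef(x[:-1], x[1:])[0, 1])


class TestLatent:
    def test_standardized(self):
        lat = ac.generate_latent(600, 5.0, seed=1)
        assert abs(lat.values.mean()) < 1e-9
        assert abs(lat.values.std() - 1.0) < 1e-9

    def test_lag1_autocorrelation_matches_gaussian_kernel_closed_form(self):
        # Gaussian-smoothed white noise: rho(1) = exp(-1/(4 sd^2)) ~ 0.990 at sd 5.
        expected = math.exp(-1.0 / (4 * 5.0**2))
        rhos = [
            lag1_autocorr(ac.generate_latent(3000, 5.0, seed=s).values)
            for s in range(10)
        ]
        assert np.mean(rhos) == pytest.approx(expected, abs=0.005)
        assert min(rhos) > 0.9

    def test_deterministic_under_seed(self):
        a = ac.generate_latent(300, 5.0, seed=7)
        b = ac.generate_latent(300, 5.0, seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    @pytest.mark.parametrize("duration,smoothing", [(10, 5.0), (600, 0.0), (600, -1.0)])
    def test_invalid_parameters(self, duration, smoothing):
        with pytest.raises(InvalidParameterError):
            ac.generate_latent(duration, smoothing, seed=0)


class TestRaterSeries:
    def test_noiseless_rater_reproduces_latent_up_to_clipping(self):
        lat = ac.generate_latent(600, 5.0, seed=3)
        s = ac.simulate_rater_series(lat, ac.RaterModel("r1", gain=10.0), seed=0)
        inner = (s.values > 0) & (s.values < 100)
        assert pearson_r(s.values[inner], lat.values[inner]) == pytest.approx(1.0, abs=1e-9)

    def test_attenuation_law_pairwise_r_half(self):
        # sigma_n chosen so signal fraction = 0.5 => expected pairwise r = 0.5.
        rng = np.random.default_rng(0)
        noise = ac.choose_noise_for_agreement(0.5)
        rs = []
        for _ in range(200):
            lat = ac.generate_latent(300, 5.0, seed=rng)
            a = ac.simulate_rater_series(lat, ac.RaterModel("a", noise_sd=noise), seed=rng)
            b = ac.simulate_rater_series(lat, ac.RaterModel("b", noise_sd=noise), seed=rng)
            rs.append(pearson_r(a.values, b.values))
        assert np.mean(rs) == pytest.approx(0.5, abs=0.03)

    def test_constant_contamination_is_flat_and_caught_downstream(self):
        lat = ac.generate_latent(120, 5.0, seed=2)
        s = ac.simulate_rater_series(
            lat, ac.RaterModel("r1", contamination="constant"), seed=0
        )
        assert np.ptp(s.values) == 0.0
        _, verdicts = run_qc([s])
        assert any("constant" in v.flags for v in verdicts)

    def test_outlier_contamination_exceeds_screen_threshold(self):
        rng = np.random.default_rng(4)
        noise = ac.choose_noise_for_agreement(0.5)
        for _ in range(20):
            lat = ac.generate_latent(600, 5.0, seed=rng)
            s = ac.simulate_rater_series(
                lat, ac.RaterModel("r1", noise_sd=noise, contamination="outlier"), seed=rng
            )
            _, verdicts = run_qc([s])
            assert any("outlier" in v.flags for v in verdicts)

    def test_same_seed_identical(self):
        lat = ac.generate_latent(120, 5.0, seed=2)
        r = ac.RaterModel("r1", noise_sd=1.0)
        a = ac.simulate_rater_series(lat, r, seed=9)
        b = ac.simulate_rater_series(lat, r, seed=9)
        np.testing.assert_array_equal(a.values, b.values)


class TestChooseNoise:
    def test_algebra(self):
        assert ac.choose_noise_for_agreement(0.5) == pytest.approx(1.0)
        assert ac.choose_noise_for_agreement(0.999) < 0.04

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_domain(self, bad):
        with pytest.raises(InvalidParameterError):
            ac.choose_noise_for_agreement(bad)

    def test_monte_carlo_at_grand_mean_agreement(self):
        # 100 combos at the study's grand-mean agreement of 0.39.
        rng = np.random.default_rng(1)
        noise = ac.choose_noise_for_agreement(0.39)
        rs = []
        for _ in range(100):
            lat = ac.generate_latent(600, 5.0, seed=rng)
            a = ac.simulate_rater_series(lat, ac.RaterModel("a", noise_sd=noise), seed=rng)
            b = ac.simulate_rater_series(lat, ac.RaterModel("b", noise_sd=noise), seed=rng)
            rs.append(pearson_r(a.values, b.values))
        assert np.mean(rs) == pytest.approx(0.39, abs=0.03)


class TestClipPlan:
    def test_default_plan_coverage_matches_study_range(self):
        for seed in range(10):
            plan = ac.generate_clip_plan(600, seed=seed)
            coverage = sum(off - on for on, off in plan) / 600
            assert 0.14 <= coverage <= 0.27
            # sorted, non-overlapping, in bounds
            flat = [b for clip in plan for b in clip]
            assert flat == sorted(flat)
            assert flat[0] >= 0 and flat[-1] <= 600

    def test_single_whole_film_clip_rating_is_affine_latent_mean(self):
        lat = ac.generate_latent(300, 5.0, seed=5)
        crs = ac.simulate_clip_ratings(lat, clip_plan=[(0.0, 300.0)], noise_sd=0.0, seed=0)
        expected = np.clip(50.0 + 10.0 * lat.values.mean(), 0, 100)
        assert crs.clips[0][2] == pytest.approx(expected, abs=1e-9)

    def test_out_of_bounds_clip_rejected(self):
        lat = ac.generate_latent(300, 5.0, seed=5)
        with pytest.raises(InvalidClipError):
            ac.simulate_clip_ratings(lat, clip_plan=[(290.0, 310.0)], seed=0)

    def test_deterministic(self):
        lat = ac.generate_latent(300, 5.0, seed=5)
        a = ac.simulate_clip_ratings(lat, noise_sd=1.0, seed=4)
        b = ac.simulate_clip_ratings(lat, noise_sd=1.0, seed=4)
        assert a.clips == b.clips


class TestPhysioSimulator:
    def test_fixed_period_cardiac_event_spacing(self):
        _, events = ac.simulate_physio_trace("cardiac", 60, period_s=1.0, seed=0)
        np.testing.assert_allclose(np.diff(events), 1.0)

    def test_respiration_dominant_frequency(self):
        trace, _ = ac.simulate_physio_trace("respiration", 120, rate_hz=100, period_s=4.0, seed=0)
        freqs = np.fft.rfftfreq(trace.values.size, d=1 / 100)
        power = np.abs(np.fft.rfft(trace.values - trace.values.mean())) ** 2
        assert freqs[np.argmax(power)] == pytest.approx(0.25, abs=0.02)

    def test_deterministic(self):
        a, ea = ac.simulate_physio_trace("cardiac", 30, jitter_sd_s=0.1, seed=3)
        b, eb = ac.simulate_physio_trace("cardiac", 30, jitter_sd_s=0.1, seed=3)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(ea, eb)

    def test_unknown_kind_rejected(self):
        with pytest.raises(InvalidParameterError):
            ac.simulate_physio_trace("eda", 30, seed=0)


class TestDatasetSimulator:
    def test_film_catalogue_durations(self):
        # Spot-check the bundled credit-free durations (e.g. 8:16 -> 496 s).
        assert FILM_DURATIONS_S["AfterTheRain"] == 496
        assert len(FILM_DURATIONS_S) == 14

    def test_dataset_shape_and_truth_keys(self):
        cfg = ac.SimulationConfig(
            films={"f1": 120, "f2": 120}, items=("i1", "i2"),
            contamination_rates={"deviant": 0.3}, seed=5,
        )
        ds = ac.simulate_annotation_dataset(cfg)
        assert len(ds.series) == 2 * 2 * 4
        for (rater, film, item), mode in ds.contamination.items():
            assert mode == "deviant"
            assert any(s.key == (rater, film, item) for s in ds.series)

    def test_at_most_one_contaminated_rater_per_item_group(self):
        cfg = ac.SimulationConfig(
            films={"f1": 120}, items=tuple(f"i{k}" for k in range(30)),
            contamination_rates={"deviant": 0.5, "constant": 0.3}, seed=2,
        )
        ds = ac.simulate_annotation_dataset(cfg)
        per_item = {}
        for (rater, film, item) in ds.contamination:
            per_item[item] = per_item.get(item, 0) + 1
        assert per_item and max(per_item.values()) == 1
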