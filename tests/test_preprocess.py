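"""Preprocessing: errant-breath screening, interpolation, averaging, smoothing."""

import numpy as np
import pytest

from vo2kinetics import (
    BreathSeries,
    GeneratorConfig,
    UniformSeries,
    ensemble_average,
    exclude_errant,
    generate_breaths,
    generate_uniform,
    interpolate_1s,
    smooth,
    vo2peak_last30,
)
from vo2kinetics.preprocess import InsufficientDataError

from conftest import seeds_from


class TestExcludeErrant:
    def test_constant_series_untouched(self):
        b = BreathSeries(np.arange(30.0), np.full(30, 40.0))
        assert exclude_errant(b, window=5, k=3).excluded.sum() == 0

    def test_single_spike_flagged_exactly(self):
        v = np.full(30, 40.0)
        v[14] = 400.0
        b = BreathSeries(np.arange(30.0), v)
        out = exclude_errant(b, window=5, k=3)
        np.testing.assert_array_equal(np.flatnonzero(out.excluded), [14])
        assert out.reasons[14] == "errant"

    def test_infinite_threshold_is_identity(self):
        v = np.full(30, 40.0)
        v[14] = 400.0
        b = BreathSeries(np.arange(30.0), v)
        assert exclude_errant(b, k=np.inf).excluded.sum() == 0

    def test_values_never_mutated_and_flag_only(self, severe_off):
        spec, truth = severe_off
        b = generate_breaths(
            GeneratorConfig(spec=spec, truth=truth, noise_sd=2.0, errant_rate=0.05, seed=3)
        )
        out = exclude_errant(b)
        np.testing.assert_array_equal(out.t, b.t)
        np.testing.assert_array_equal(out.vo2, b.vo2)

    def test_idempotent(self, severe_off):
        spec, truth = severe_off
        b = generate_breaths(
            GeneratorConfig(spec=spec, truth=truth, noise_sd=2.0, errant_rate=0.05, seed=11)
        )
        once = exclude_errant(b)
        twice = exclude_errant(once)
        np.testing.assert_array_equal(once.excluded, twice.excluded)

    def test_short_series_warns_and_noop(self):
        b = BreathSeries(np.arange(3.0), np.full(3, 40.0))
        with pytest.warns(UserWarning):
            out = exclude_errant(b, window=5)
        assert out.excluded.sum() == 0

    def test_parameter_validation(self):
        b = BreathSeries(np.arange(10.0), np.full(10, 40.0))
        with pytest.raises(ValueError):
            exclude_errant(b, window=4)
        with pytest.raises(ValueError):
            exclude_errant(b, k=0.0)
        with pytest.raises(ValueError):
            exclude_errant(b, method="nope")

    def test_classic_mean_sd_variant_flags_spike(self):
        v = np.full(30, 40.0)
        v[14] = 400.0
        b = BreathSeries(np.arange(30.0), v)
        out = exclude_errant(b, window=5, k=3, method="mean_sd")
        np.testing.assert_array_equal(np.flatnonzero(out.excluded), [14])


class TestInterpolate:
    def test_hand_example(self):
        b = BreathSeries([0.0, 2.0, 5.0], [10.0, 12.0, 18.0])
        u = interpolate_1s(b)
        assert u.t0 == 0.0 and u.dt == 1.0
        np.testing.assert_allclose(u.vo2, [10, 11, 12, 14, 16, 18])

    def test_integer_breaths_preserved(self):
        t = np.arange(0.0, 10.0)
        v = np.linspace(20, 30, 10) ** 1.5
        u = interpolate_1s(BreathSeries(t, v))
        np.testing.assert_allclose(u.vo2, v)

    def test_excluded_breaths_contribute_nothing(self):
        b = BreathSeries([0.0, 2.0, 4.0], [10.0, 500.0, 14.0], excluded=[False, True, False])
        u = interpolate_1s(b)
        np.testing.assert_allclose(u.vo2, [10, 11, 12, 13, 14])

    def test_no_extrapolation_outside_span(self):
        u = interpolate_1s(BreathSeries([0.4, 3.6], [10.0, 20.0]))
        assert u.t0 == 1.0
        assert u.t[-1] == 3.0

    def test_too_few_breaths(self):
        with pytest.raises(InsufficientDataError):
            interpolate_1s(BreathSeries([1.0], [10.0]))
        with pytest.raises(InsufficientDataError):
            interpolate_1s(
                BreathSeries([0.0, 2.0, 4.0], [1.0, 2.0, 3.0], excluded=[False, True, True])
            )


class TestEnsembleAverage:
    def test_mean_of_identical_is_identity(self):
        u = UniformSeries(0.0, 1.0, np.arange(10.0))
        out = ensemble_average([u, u])
        np.testing.assert_allclose(out.vo2, u.vo2)

    def test_offset_series_give_midline(self):
        u = UniformSeries(0.0, 1.0, np.arange(10.0))
        v = u.with_values(u.vo2 + 4.0, "shift")
        np.testing.assert_allclose(ensemble_average([u, v]).vo2, u.vo2 + 2.0)

    def test_three_values_mean(self):
        series = [UniformSeries(5.0, 1.0, np.array([x])) for x in (1.0, 2.0, 6.0)]
        out = ensemble_average(series)
        assert out.vo2[0] == pytest.approx(3.0)

    def test_intersection_span(self):
        a = UniformSeries(0.0, 1.0, np.arange(10.0))
        b = UniformSeries(4.0, 1.0, np.arange(10.0) + 100)
        out = ensemble_average([a, b])
        assert out.t0 == 4.0 and len(out) == 6

    def test_errors(self):
        with pytest.raises(ValueError):
            ensemble_average([])
        a = UniformSeries(0.0, 1.0, np.arange(5.0))
        b = UniformSeries(100.0, 1.0, np.arange(5.0))
        with pytest.raises(ValueError):
            ensemble_average([a, b])

    def test_rmse_shrinks_like_root_n(self, severe_off):
        """Averaging n noisy transitions cuts pointwise RMSE ~ 1/sqrt(n)."""
        spec, truth = severe_off
        clean = generate_uniform(GeneratorConfig(spec=spec, truth=truth, noise_sd=0.0))
        rmse = {}
        seeds = iter(seeds_from(2024, 21))
        for n in (1, 4, 16):
            reps = [
                generate_uniform(
                    GeneratorConfig(spec=spec, truth=truth, noise_sd=2.0, seed=next(seeds))
                )
                for _ in range(n)
            ]
            avg = ensemble_average(reps)
            rmse[n] = float(np.sqrt(np.mean((avg.vo2 - clean.vo2) ** 2)))
        assert rmse[1] / rmse[4] == pytest.approx(2.0, rel=0.20)
        assert rmse[4] / rmse[16] == pytest.approx(2.0, rel=0.20)


class TestSmooth:
    def test_constant_fixed_point(self):
        u = UniformSeries(0.0, 1.0, np.full(50, 33.0))
        for method in ("moving_average", "median", "breath_average"):
            np.testing.assert_allclose(smooth(u, method, 5).vo2, u.vo2)

    def test_median_kills_spike(self):
        u = UniformSeries(0.0, 1.0, np.array([0.0, 0.0, 9.0, 0.0, 0.0]))
        np.testing.assert_allclose(smooth(u, "median", 3).vo2, np.zeros(5))

    def test_width_one_moving_average_is_identity(self):
        u = UniformSeries(0.0, 1.0, np.random.default_rng(0).random(20))
        np.testing.assert_allclose(smooth(u, "moving_average", 1).vo2, u.vo2)

    def test_unknown_filter_lists_supported(self):
        u = UniformSeries(0.0, 1.0, np.arange(5.0))
        with pytest.raises(ValueError, match="moving_average"):
            smooth(u, "boxcar", 3)

    def test_grid_and_provenance(self):
        u = UniformSeries(0.0, 1.0, np.arange(20.0))
        out = smooth(u, "moving_average", 5)
        assert out.t0 == u.t0 and len(out) == len(u)
        assert any("smooth" in p for p in out.provenance)


class TestVo2Peak:
    def test_constant(self):
        u = UniformSeries(0.0, 1.0, np.full(181, 50.0))
        assert vo2peak_last30(u) == pytest.approx(50.0)

    def test_linear_tail(self):
        v = np.concatenate([np.full(150, 40.0), np.linspace(40, 43, 31)])
        u = UniformSeries(0.0, 1.0, v)
        assert vo2peak_last30(u) == pytest.approx(41.5)

    def test_exact_span_boundary(self):
        u = UniformSeries(0.0, 1.0, np.linspace(10, 20, 31))
        assert vo2peak_last30(u) == pytest.approx(15.0)

    def test_short_series_error_mentions_span(self):
        u = UniformSeries(0.0, 1.0, np.arange(10.0))
        with pytest.raises(InsufficientDataError, match="9"):
            vo2peak_last30(u)


def test_screen_then_interpolate_recovers_clean_curve(severe_off):
    """Spiked breaths, once screened, leave the interpolated series close to truth."""
    from vo2kinetics.models import eval_raw

    spec, truth = severe_off
    b = generate_breaths(
        GeneratorConfig(
            spec=spec, truth=truth, noise_sd=2.0, errant_rate=0.05,
            errant_magnitude=10.0, seed=77,
        )
    )
    u_dirty = interpolate_1s(b)
    u_clean = interpolate_1s(exclude_errant(b))
    curve_dirty = eval_raw(spec, truth, u_dirty.t)
    curve_clean = eval_raw(spec, truth, u_clean.t)
    rmse_dirty = np.sqrt(np.mean((u_dirty.vo2 - curve_dirty) ** 2))
    rmse_clean = np.sqrt(np.mean((u_clean.vo2 - curve_clean) ** 2))
    assert rmse_clean < rmse_dirty / 1.5
    assert rmse_clean < 2.5  # within the interpolated-noise envelope
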