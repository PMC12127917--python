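"""Nonlinear fitting, nested-model testing, selection and CV."""

import numpy as np
import pytest

from vo2kinetics import (
    Direction,
    FitError,
    GeneratorConfig,
    ModelForm,
    ModelSpec,
    UniformSeries,
    cv_of_estimates,
    default_init,
    f_test,
    fit,
    generate_uniform,
    select_best,
)

from conftest import all_specs_with_truth, seeds_from


@pytest.mark.parametrize(
    "spec,truth", all_specs_with_truth(), ids=lambda v: v.name if hasattr(v, "name") else ""
)
def test_exact_recovery_noise_free(spec, truth):
    """Noise-free self-generated data is recovered exactly (SER ~ 0) by every form."""
    u = generate_uniform(GeneratorConfig(spec=spec, truth=truth, noise_sd=0.0, duration=300.0))
    fr = fit(u, spec, seed=1)
    assert fr.converged
    assert fr.ser <= 1e-6
    full = spec.complete(truth)
    for name in spec.free_params:
        assert fr.estimates.get(name) == pytest.approx(full.get(name), rel=1e-4, abs=1e-4)


def test_constant_series_degenerates_to_plateau():
    u = UniformSeries(0.0, 1.0, np.full(120, 42.0))
    fr = fit(u, ModelSpec(Direction.OFF, ModelForm.MONO_NO_TD), seed=0)
    assert fr.estimates.EEVO2 == pytest.approx(42.0, abs=1e-6)
    assert abs(fr.estimates.Ap) <= 1e-6


def test_fit_determinism(noisy_severe_series, severe_off):
    spec, _ = severe_off
    a = fit(noisy_severe_series, spec, seed=7)
    b = fit(noisy_severe_series, spec, seed=7)
    assert a.rss == b.rss
    np.testing.assert_array_equal(a.residuals, b.residuals)
    for name in spec.free_params:
        assert a.estimates.get(name) == b.estimates.get(name)


def test_ser_rss_consistency(noisy_severe_series, severe_off):
    spec, _ = severe_off
    fr = fit(noisy_severe_series, spec, seed=0)
    assert fr.ser**2 * (fr.n - fr.p) == pytest.approx(fr.rss, rel=1e-10)
    # residuals stored as data - fitted
    np.testing.assert_allclose(
        fr.fitted_curve(noisy_severe_series) + fr.residuals,
        noisy_severe_series.vo2,
        atol=1e-10,
    )


def test_n_must_exceed_p():
    u = UniformSeries(0.0, 1.0, np.arange(3.0) + 10)
    with pytest.raises(FitError):
        fit(u, ModelSpec(Direction.OFF, ModelForm.MONO_NO_TD))


class TestDefaultInit:
    def test_tau_guess_within_factor_three(self, severe_off):
        spec, truth = severe_off
        u = generate_uniform(GeneratorConfig(spec=spec, truth=truth, noise_sd=0.0))
        init = default_init(u, spec)
        assert 37.0 / 3 <= init.taup <= 37.0 * 3

    def test_constant_series_guard(self):
        u = UniformSeries(0.0, 1.0, np.full(100, 30.0))
        init = default_init(u, ModelSpec(Direction.OFF, ModelForm.MONO_NO_TD))
        assert init.Ap == 0.0 and np.isfinite(init.taup)

    def test_wrong_direction_still_finite(self, severe_off):
        # rising data initialised for a decay spec: finite init, flagged fit quality
        spec_on = ModelSpec(Direction.ON, ModelForm.MONO_TD)
        truth_on = ModelSpec(Direction.ON, ModelForm.MONO_TD)
        u = generate_uniform(
            GeneratorConfig(
                spec=spec_on,
                truth=__import__("vo2kinetics").ParameterSet(
                    VO2base=10.0, Ap=30.0, TDp=15.0, taup=20.0
                ),
                noise_sd=0.0,
            )
        )
        init = default_init(u, ModelSpec(Direction.OFF, ModelForm.MONO_NO_TD))
        assert all(
            np.isfinite(v) for v in init.to_dict().values()
        )


class TestFTest:
    def test_hand_arithmetic(self):
        """F = ((10-8)/2) / (8/95) = 11.875 for n=100, p1=3, p2=5."""
        simple = _stub_fit(ModelForm.MONO_NO_TD, rss=10.0, n=100, p=3)
        complex_ = _stub_fit(ModelForm.BIEXP_NO_TDP, rss=8.0, n=100, p=5)
        cmp = f_test(simple, complex_)
        assert cmp.F == pytest.approx(11.875)
        assert cmp.df1 == 2 and cmp.df2 == 95
        # brute force from the definition
        from scipy.stats import f as fdist

        assert cmp.p_value == pytest.approx(float(fdist.sf(11.875, 2, 95)), rel=1e-12)

    def test_equal_rss_gives_zero_F(self):
        cmp = f_test(
            _stub_fit(ModelForm.MONO_NO_TD, 5.0, 100, 3),
            _stub_fit(ModelForm.MONO_TD, 5.0, 100, 4),
        )
        assert cmp.F == 0.0 and cmp.p_value == 1.0

    def test_perfect_complex_fit(self):
        cmp = f_test(
            _stub_fit(ModelForm.MONO_NO_TD, 5.0, 100, 3),
            _stub_fit(ModelForm.BIEXP_TD, 0.0, 100, 7),
        )
        assert np.isinf(cmp.F) and cmp.p_value == 0.0

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError):
            f_test(
                _stub_fit(ModelForm.MONO_TD, 5.0, 100, 4),
                _stub_fit(ModelForm.BIEXP_NO_TDP, 4.0, 100, 6),
            )

    def test_different_data_rejected(self):
        with pytest.raises(ValueError):
            f_test(
                _stub_fit(ModelForm.MONO_NO_TD, 5.0, 100, 3),
                _stub_fit(ModelForm.MONO_TD, 4.0, 90, 4),
            )


def _stub_fit(form, rss, n, p):
    from vo2kinetics.fitting import FitResult
    from vo2kinetics import ParameterSet

    spec = ModelSpec(Direction.OFF, form)
    return FitResult(
        spec, ParameterSet(), rss, float(np.sqrt(rss / (n - p))) if n > p else np.inf,
        n, p, np.zeros(n), converged=True, n_restarts_used=1,
    )


class TestSelection:
    def test_noise_free_mono_resolved_by_parsimony(self, severe_off):
        spec, truth = severe_off
        u = generate_uniform(GeneratorConfig(spec=spec, truth=truth, noise_sd=0.0))
        rep = select_best(u, "off", seed=0)
        assert rep.best.spec.form == ModelForm.MONO_NO_TD
        assert rep.best.ser <= 1e-6

    def test_noise_free_biexp_selected(self):
        from vo2kinetics import ParameterSet

        spec = ModelSpec(Direction.OFF, ModelForm.BIEXP_TD)
        truth = ParameterSet(
            EEVO2=51.0, Ap=40.3, taup=37.0, TDp=13.7, Asc=8.0, TDsc=95.3, tausc=60.0
        )
        u = generate_uniform(
            GeneratorConfig(spec=spec, truth=truth, noise_sd=0.0, duration=300.0)
        )
        rep = select_best(u, "off", seed=0)
        assert rep.best.spec.form.has_slow
        assert rep.best.ser <= 1e-6

    def test_report_covers_all_models(self, noisy_severe_series):
        rep = select_best(noisy_severe_series, "off", seed=0)
        table = rep.table()
        assert len(table) + len(rep.failed) >= 4
        assert sum(row["selected"] for row in table) == 1

    def test_mostly_picks_generating_mono_under_noise(self, severe_off):
        """A quick 20-seed slice of the selection-consistency experiment."""
        spec, truth = severe_off
        wins = 0
        for s in seeds_from(888, 20):
            u = generate_uniform(
                GeneratorConfig(spec=spec, truth=truth, noise_sd=1.0, seed=s)
            )
            rep = select_best(u, "off", seed=s)
            wins += rep.best.spec.form == ModelForm.MONO_NO_TD
        assert wins >= 16


class TestCV:
    def test_definition(self):
        assert cv_of_estimates([8.0, 10.0, 12.0]) == pytest.approx(20.0)

    def test_identical_replicates(self):
        assert cv_of_estimates([5.0, 5.0, 5.0]) == 0.0

    def test_zero_mean_undefined(self):
        with pytest.raises(ZeroDivisionError):
            cv_of_estimates([-1.0, 1.0])

    def test_needs_two(self):
        with pytest.raises(ValueError):
            cv_of_estimates([1.0])
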