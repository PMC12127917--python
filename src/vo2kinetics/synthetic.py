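"""Synthetic validation data: exact model curves, Gaussian-noise series and realistic
breath-by-breath series with errant breaths.

The generator reproduces the validation protocol for the fitting engine — exact
model-generated curves on a uniform grid (noise-free and with additive homoskedastic
Gaussian noise) — plus irregular breath timing with occasional errant breaths so the
preprocessing chain can be exercised end to end without any recorded data.  Truth
parameter presets carry realistic magnitudes for the four swimming intensity domains
(group means from an incremental 5x200 m protocol).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .models import Direction, ModelForm, ModelSpec, ParameterSet, eval_raw, validate_params
from .preprocess import BreathSeries, UniformSeries

#: recovery-phase truth presets per intensity domain (level, amplitude, tau in
#: mL·kg⁻¹·min⁻¹ / s); magnitudes follow trained-swimmer group means.
OFF_PRESETS: dict[str, ParameterSet] = {
    "low": ParameterSet(EEVO2=38.8, Ap=30.1, taup=30.8, TDp=0.0),
    "moderate": ParameterSet(EEVO2=38.9, Ap=29.9, taup=29.7, TDp=0.0),
    "heavy": ParameterSet(EEVO2=46.3, Ap=36.0, taup=28.7, TDp=0.0),
    "severe": ParameterSet(EEVO2=51.0, Ap=40.3, taup=37.0, TDp=0.0),
}

#: exercise-onset truth presets; baseline = peak minus amplitude.
ON_PRESETS: dict[str, ParameterSet] = {
    "low": ParameterSet(VO2base=39.0 - 31.6, Ap=31.6, taup=15.8, TDp=22.4),
    "moderate": ParameterSet(VO2base=42.2 - 33.2, Ap=33.2, taup=11.3, TDp=19.8),
    "heavy": ParameterSet(VO2base=48.0 - 38.4, Ap=38.4, taup=13.9, TDp=20.5),
    "severe": ParameterSet(VO2base=51.4 - 40.3, Ap=40.3, taup=10.3, TDp=19.6),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything needed to generate one synthetic transition reproducibly."""

    spec: ModelSpec
    truth: ParameterSet
    duration: float = 180.0          # s
    rate: float = 1.0                # Hz, uniform-grid sampling
    breath_interval_mean: float = 3.0  # s, breath process
    breath_interval_sd: float = 0.75   # s
    noise_sd: float = 2.0            # mL·kg⁻¹·min⁻¹
    errant_rate: float = 0.0         # fraction of breaths displaced
    errant_magnitude: float = 10.0   # displacement in multiples of noise_sd
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.errant_rate < 0.2:
            raise ValueError("errant_rate must be in [0, 0.2)")
        if self.breath_interval_mean <= 0:
            raise ValueError("breath interval mean must be > 0")
        validate_params(self.spec, self.truth)

    def truth_record(self) -> dict:
        return {
            "model": self.spec.to_json_dict(),
            "truth": self.spec.complete(self.truth).to_dict(),
            "duration": self.duration,
            "noise_sd": self.noise_sd,
            "errant_rate": self.errant_rate,
            "errant_magnitude": self.errant_magnitude,
            "seed": self.seed,
        }

    def truth_json(self) -> str:
        return json.dumps(self.truth_record(), indent=2, sort_keys=True)


def generate_uniform(cfg: GeneratorConfig, with_truth: bool = False):
    """Model curve on a uniform grid plus i.i.d. Gaussian noise (exact when sd=0).

    Returns the series, or ``(series, truth_record)`` when ``with_truth`` is set.
    """
    dt = 1.0 / cfg.rate
    n = int(round(cfg.duration * cfg.rate)) + 1
    t = dt * np.arange(n)
    y = eval_raw(cfg.spec, cfg.truth, t)
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        y = y + rng.normal(0.0, cfg.noise_sd, size=n)
    y = np.maximum(y, 0.0)
    note = f"generate_uniform({cfg.spec.name}, noise_sd={cfg.noise_sd:g}, seed={cfg.seed})"
    u = UniformSeries(0.0, dt, y, (note,))
    return (u, cfg.truth_record()) if with_truth else u


def generate_breaths(cfg: GeneratorConfig, with_truth: bool = False):
    """Irregular breath series: truncated-normal breath intervals, Gaussian noise on
    the model value, and a fraction ``errant_rate`` of breaths displaced by
    ``errant_magnitude * noise_sd`` (random sign) to emulate coughs/swallows.

    Returns the series, or ``(series, truth_record)`` when ``with_truth`` is set; the
    truth record carries the indices of the displaced breaths.
    """
    rng = np.random.default_rng(cfg.seed)
    mu, sd = cfg.breath_interval_mean, cfg.breath_interval_sd
    times = []
    t = 0.0
    lo = 0.25 * mu  # physiological floor on the breath interval
    while t <= cfg.duration:
        times.append(t)
        if sd > 0:
            a = (lo - mu) / sd
            step = truncnorm.rvs(a, np.inf, loc=mu, scale=sd, random_state=rng)
        else:
            step = mu
        t += float(step)
    t_arr = np.asarray(times)
    y = eval_raw(cfg.spec, cfg.truth, t_arr)
    if cfg.noise_sd > 0:
        y = y + rng.normal(0.0, cfg.noise_sd, size=len(t_arr))
    errant = np.zeros(len(t_arr), dtype=bool)
    if cfg.errant_rate > 0 and cfg.noise_sd > 0:
        errant = rng.random(len(t_arr)) < cfg.errant_rate
        signs = rng.choice([-1.0, 1.0], size=len(t_arr))
        y = y + errant * signs * cfg.errant_magnitude * cfg.noise_sd
    y = np.maximum(y, 0.0)
    b = BreathSeries(t_arr, y)
    if not with_truth:
        return b
    record = cfg.truth_record()
    record["errant_indices"] = np.flatnonzero(errant).tolist()
    return b, record


def preset_spec(direction: Direction | str, domain: str, form: ModelForm = ModelForm.MONO_NO_TD) -> tuple[ModelSpec, ParameterSet]:
    """Convenience: (spec, truth) for a named intensity domain.

    On-transient presets carry a time delay, so the mono form with TD is substituted
    automatically when ``MONO_NO_TD`` is requested for direction "on".
    """
    direction = Direction(direction)
    presets = OFF_PRESETS if direction == Direction.OFF else ON_PRESETS
    if domain not in presets:
        raise KeyError(f"unknown domain {domain!r}; choose from {sorted(presets)}")
    truth = presets[domain]
    if direction == Direction.ON and form == ModelForm.MONO_NO_TD:
        form = ModelForm.MONO_TD
    spec = ModelSpec(direction, form)
    if form.has_slow:
        truth = truth.with_values(Asc=0.1 * truth.Ap, TDsc=90.0, tausc=60.0)
    if form.tdp_fixed_zero:
        truth = truth.with_values(TDp=0.0)
    return spec, spec.complete(truth)
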