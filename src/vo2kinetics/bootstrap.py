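"""Residual-bootstrap uncertainty for a single transition.

A single exercise transition yields one fitted curve; resampling its residuals with
replacement and refitting (warm-started at the base estimates) gives replicate
parameter estimates from which per-parameter SD, CV and percentile confidence
intervals are summarised.  Residual (not case) resampling preserves the time grid,
which carries the kinetic information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import FitResult, refit
from .preprocess import UniformSeries

#: above this fraction of failed replicate refits the result is flagged unreliable
MAX_FAILURE_FRACTION = 0.20


def percentile_ci(replicates, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed empirical percentile interval with linear interpolation."""
    r = np.asarray(replicates, dtype=float)
    if r.size == 0:
        raise ValueError("no replicates")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    lo = (1.0 - level) / 2.0
    return (
        float(np.quantile(r, lo, method="linear")),
        float(np.quantile(r, 1.0 - lo, method="linear")),
    )


@dataclass(frozen=True)
class BootstrapResult:
    spec_name: str
    n_samples: int
    n_converged: int
    replicates: dict[str, np.ndarray]   # per free parameter
    sd: dict[str, float]
    cv: dict[str, float]                # percent; NaN where the mean is ~0
    ci: dict[str, tuple[float, float]]
    level: float
    seed: int
    reliable: bool

    def to_json_dict(self) -> dict:
        return {
            "model": self.spec_name,
            "n_samples": self.n_samples,
            "n_converged": self.n_converged,
            "method": "residual bootstrap, percentile CI",
            "level": self.level,
            "seed": self.seed,
            "reliable": self.reliable,
            "sd": self.sd,
            "cv_percent": self.cv,
            "ci": {k: list(v) for k, v in self.ci.items()},
        }


def residual_bootstrap(
    u: UniformSeries,
    base: FitResult,
    n_samples: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> BootstrapResult:
    """Residual bootstrap of ``base`` (which must have converged on ``u``).

    Each replicate adds residuals resampled with replacement to the fitted curve and
    refits the same model from the base estimates.  Deterministic for a given seed.
    """
    if not base.converged:
        raise ValueError("base fit did not converge; bootstrap would be meaningless")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    fitted = base.fitted_curve(u)
    residuals = base.residuals
    n = len(fitted)
    names = base.spec.free_params
    reps: dict[str, list[float]] = {name: [] for name in names}
    n_converged = 0
    for _ in range(n_samples):
        y = fitted + rng.choice(residuals, size=n, replace=True)
        fr = refit(u, base, y)
        if fr is None:
            continue
        n_converged += 1
        est = fr.estimates
        for name in names:
            reps[name].append(float(est.get(name)))
    if n_converged < 2:
        raise RuntimeError(f"only {n_converged} bootstrap replicates converged")
    arrays = {k: np.asarray(v) for k, v in reps.items()}
    sd = {k: float(np.std(v, ddof=1)) for k, v in arrays.items()}
    cv = {}
    for k, v in arrays.items():
        m = float(np.mean(v))
        cv[k] = float("nan") if abs(m) < 1e-12 else 100.0 * sd[k] / m
    ci = {k: percentile_ci(v, level) for k, v in arrays.items()}
    return BootstrapResult(
        spec_name=base.spec.name,
        n_samples=n_samples,
        n_converged=n_converged,
        replicates=arrays,
        sd=sd,
        cv=cv,
        ci=ci,
        level=level,
        seed=seed,
        reliable=(n_samples - n_converged) <= MAX_FAILURE_FRACTION * n_samples,
    )
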