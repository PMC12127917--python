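"""Nonlinear least-squares estimation of transient models.

Fits are unconstrained by default (optional box bounds), driven by
:func:`scipy.optimize.least_squares` with a small deterministic multistart to escape
the local minima the time-delay gates induce: the Heaviside factor makes the objective
piecewise-smooth in TDp/TDsc, with kinks where a delay crosses a grid point, so a
single gradient descent can stall on the wrong side of a kink.  Model comparison uses
the extra-sum-of-squares F-test; selection prefers the lowest standard error of
regression (SER = sqrt(RSS/(n-p))), resolving statistically indistinguishable nested
pairs to the simpler form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .models import (
    Direction,
    ModelSpec,
    ParameterSet,
    eval_raw,
    is_nested,
    list_models,
)
from .preprocess import UniformSeries
from .symmetry import hochberg_adjust

#: two fits whose SER both fall below this are treated as exact ties (noise-free data);
#: the F statistic on accumulated rounding error is meaningless there.
SER_EXACT_TOL = 1e-7


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class FitResult:
    """One model fitted to one series."""

    spec: ModelSpec
    estimates: ParameterSet
    rss: float
    ser: float
    n: int
    p: int
    residuals: np.ndarray
    converged: bool
    n_restarts_used: int
    message: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residuals", np.asarray(self.residuals, dtype=float))

    def fitted_curve(self, u: UniformSeries) -> np.ndarray:
        """Fitted values on the grid of the series the fit was made on."""
        return eval_raw(self.spec, self.estimates, u.t - u.t0)

    def to_json_dict(self) -> dict:
        return {
            "model": self.spec.to_json_dict(),
            "estimates": self.estimates.to_dict(),
            "rss": self.rss,
            "ser": self.ser,
            "n": self.n,
            "p": self.p,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
            "message": self.message,
        }


@dataclass(frozen=True)
class ModelComparison:
    """Extra-sum-of-squares F-test between two nested fits on the same data."""

    simple: FitResult
    complex: FitResult
    F: float
    df1: int
    df2: int
    p_value: float


def default_init(u: UniformSeries, spec: ModelSpec) -> ParameterSet:
    """Data-driven starting values: plateau levels from 30-s end means, amplitude from
    the observed range, tau from the time-to-63%-of-range crossing; TDp=10 s, TDsc=90 s
    and Asc = 0.1*Ap where those parameters are free."""
    if len(u) < 4:
        raise FitError("need at least 4 points for initialisation")
    t, v = u.t - u.t0, u.vo2
    edge = min(30.0, u.span / 3.0)
    first = float(np.mean(v[t <= t[0] + edge]))
    last = float(np.mean(v[t >= t[-1] - edge]))
    amp = abs(first - last)
    off = spec.direction == Direction.OFF
    level = first if off else first  # EEVO2 = start of recovery; VO2base = start of onset
    if amp < 1e-9:  # degenerate (flat) data: guard values
        amp_init, tau_init = 0.0, 30.0
    else:
        amp_init = amp
        frac = 0.632 * amp
        target = first - frac if off else first + frac
        crossed = v <= target if off else v >= target
        idx = np.flatnonzero(crossed)
        tau_init = float(t[idx[0]]) if len(idx) else u.span / 3.0
        if "TDp" in spec.free_params:
            tau_init -= 10.0
        tau_init = max(tau_init, 1.0)
    vals: dict[str, float] = {spec.level_param: level, "Ap": amp_init, "taup": tau_init}
    if "TDp" in spec.free_params:
        vals["TDp"] = 10.0
    if spec.form.has_slow:
        vals.update(Asc=0.1 * amp_init, TDsc=min(90.0, 0.5 * u.span), tausc=60.0)
    init = ParameterSet(**vals)
    return spec.complete(init)


def _perturb(x0: np.ndarray, names: tuple[str, ...], rng: np.random.Generator) -> np.ndarray:
    x = x0.copy()
    for i, name in enumerate(names):
        if name.startswith("TD"):
            x[i] = max(0.0, x[i] + rng.normal(0.0, 10.0))
        elif name.startswith("tau"):
            x[i] = max(0.5, x[i] * (1.0 + 0.4 * rng.normal()))
        else:
            x[i] = x[i] * (1.0 + 0.2 * rng.normal()) + 0.5 * rng.normal()
    return x


def fit(
    u: UniformSeries,
    spec: ModelSpec,
    init: ParameterSet | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    max_nfev: int | None = None,
) -> FitResult:
    """Least-squares fit of ``spec`` to ``u``; deterministic given (data, init, seed).

    The first start uses ``init`` (or :func:`default_init`); ``n_restarts - 1`` further
    starts perturb it with a seeded generator, and the lowest-RSS converged solution
    wins.  Unconstrained unless ``bounds`` maps parameter names to (lo, hi).
    """
    n = len(u)
    p = spec.n_free
    if n <= p:
        raise FitError(f"n={n} <= p={p} free parameters")
    tau0 = (init or default_init(u, spec)).taup or 30.0
    if u.span < 4.0 * tau0:
        warnings.warn(
            f"series span {u.span:g}s < 4x initial tau guess {tau0:g}s; estimates may be unstable"
        )
    t = u.t - u.t0
    y = u.vo2
    x0 = spec.pack(spec.complete(init) if init is not None else default_init(u, spec))

    lo = np.full(p, -np.inf)
    hi = np.full(p, np.inf)
    if bounds:
        for name, (a, b) in bounds.items():
            if name in spec.free_params:
                i = spec.free_params.index(name)
                lo[i], hi[i] = a, b

    def residual(x: np.ndarray) -> np.ndarray:
        return eval_raw(spec, spec.unpack(x), t) - y

    rng = np.random.default_rng(seed)
    best = None
    used = 0
    for r in range(max(1, n_restarts)):
        xr = x0 if r == 0 else np.clip(_perturb(x0, spec.free_params, rng), lo, hi)
        try:
            sol = optimize.least_squares(
                residual, np.clip(xr, lo, hi), bounds=(lo, hi),
                method="trf", x_scale="jac", max_nfev=max_nfev,
            )
        except Exception:
            continue
        used = r + 1
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
        # an early essentially-perfect fit needs no further restarts
        if best is not None and best.cost < 1e-16:
            break

    if best is None:
        return FitResult(
            spec, spec.unpack(x0), float(np.sum(residual(x0) ** 2)), np.inf,
            n, p, -residual(x0), converged=False, n_restarts_used=used,
            message="no restart converged",
        )
    res = -residual(best.x)  # stored as data - fitted
    rss = float(np.sum(res**2))
    ser = float(np.sqrt(rss / (n - p)))
    return FitResult(
        spec, spec.unpack(best.x), rss, ser, n, p, res,
        converged=True, n_restarts_used=used, message=best.message,
    )


def refit(u: UniformSeries, base: FitResult, y: np.ndarray) -> FitResult | None:
    """Single warm-started refit of ``base.spec`` against replacement values ``y``.

    Used by the residual bootstrap; returns None when the solver fails.
    """
    spec = base.spec
    t = u.t - u.t0
    x0 = spec.pack(base.estimates)

    def residual(x: np.ndarray) -> np.ndarray:
        return eval_raw(spec, spec.unpack(x), t) - y

    try:
        sol = optimize.least_squares(residual, x0, method="trf", x_scale="jac")
    except Exception:
        return None
    if not sol.success:
        return None
    res = -residual(sol.x)
    rss = float(np.sum(res**2))
    n, p = len(y), spec.n_free
    return FitResult(
        spec, spec.unpack(sol.x), rss, float(np.sqrt(rss / (n - p))), n, p, res,
        converged=True, n_restarts_used=1, message=sol.message,
    )


def f_test(simple: FitResult, complex_: FitResult) -> ModelComparison:
    """Extra-sum-of-squares ANOVA F-test for nested fits on identical data.

    F = ((RSS1-RSS2)/(p2-p1)) / (RSS2/(n-p2)); conventions: equal RSS -> F=0, p=1;
    a perfect complex fit against an imperfect simple one -> F=inf, p=0.
    """
    if simple.n != complex_.n:
        raise ValueError("fits are on different data (n differs)")
    if not (
        simple.spec.direction == complex_.spec.direction
        and is_nested(simple.spec.form, complex_.spec.form)
    ):
        raise ValueError(f"{simple.spec.name} is not nested in {complex_.spec.name}")
    df1 = complex_.p - simple.p
    df2 = complex_.n - complex_.p
    if df1 <= 0 or df2 <= 0:
        raise ValueError("degenerate degrees of freedom")
    rss1, rss2 = simple.rss, complex_.rss
    if rss1 <= rss2:
        F, p_value = 0.0, 1.0
    elif rss2 == 0.0:
        F, p_value = np.inf, 0.0
    else:
        F = ((rss1 - rss2) / df1) / (rss2 / df2)
        p_value = float(stats.f.sf(F, df1, df2))
    return ModelComparison(simple, complex_, float(F), df1, df2, p_value)


def interpretability_violations(fr: FitResult, span: float, dt: float) -> tuple[str, ...]:
    """Reasons an unconstrained fit is not physiologically interpretable.

    Fits are unconstrained, so on noisy data a surplus component can converge onto a
    noise feature with meaningless estimates.  A fit competes in model selection only
    when: amplitudes are positive; time constants are positive and resolvable on the
    grid (tau >= dt); delays lie inside the record with TDsc >= TDp; and a slow
    component's realised amplitude within the record exceeds twice the residual noise
    level (below that it is indistinguishable from noise).
    """
    e = fr.estimates
    out: list[str] = []
    if not e.Ap > 0:
        out.append(f"Ap={e.Ap:.3g} not > 0")
    if not e.taup >= dt:
        out.append(f"taup={e.taup:.3g} below grid resolution {dt:g}")
    if not 0.0 <= e.TDp <= span:
        out.append(f"TDp={e.TDp:.3g} outside record [0, {span:g}]")
    if fr.spec.form.has_slow:
        if not e.Asc > 0:
            out.append(f"Asc={e.Asc:.3g} not > 0")
        if not e.tausc >= dt:
            out.append(f"tausc={e.tausc:.3g} below grid resolution {dt:g}")
        if not e.TDp <= e.TDsc <= span:
            out.append(f"TDsc={e.TDsc:.3g} outside [TDp, {span:g}]")
        if not out:
            realised = e.Asc * (1.0 - np.exp(-(span - e.TDsc) / e.tausc))
            if realised <= 2.0 * fr.ser:
                out.append(
                    f"slow component realised amplitude {realised:.3g} "
                    f"<= 2*SER={2 * fr.ser:.3g} (not distinguishable from noise)"
                )
    return tuple(out)


@dataclass(frozen=True)
class SelectionReport:
    """All candidate fits plus the chosen one, with the tie-break trail.

    ``fits`` holds every converged fit (including those whose estimates failed the
    interpretability screen and therefore did not compete); ``failed`` records
    non-converging models, ``screened_out`` the model names excluded by the screen.
    """

    best: FitResult
    fits: tuple[FitResult, ...]
    failed: tuple[str, ...]
    alpha: float
    notes: tuple[str, ...] = field(default_factory=tuple)
    screened_out: tuple[str, ...] = field(default_factory=tuple)

    def table(self) -> list[dict]:
        return [
            {
                "model": f.spec.name,
                "p": f.p,
                "rss": f.rss,
                "ser": f.ser,
                "converged": f.converged,
                "competed": f.spec.name not in self.screened_out,
                "selected": f.spec == self.best.spec,
            }
            for f in self.fits
        ]


def select_best(
    u: UniformSeries,
    direction: Direction | str,
    alpha: float = 0.05,
    n_restarts: int = 5,
    seed: int = 0,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> SelectionReport:
    """Fit all four forms for ``direction`` and pick the best by SER with parsimony.

    Among converged, physiologically interpretable fits (see
    :func:`interpretability_violations`) the lowest-SER model is the starting
    candidate; any nested simpler model whose F-test against the candidate is
    non-significant at ``alpha`` (or which ties it with SER below the exact-fit
    tolerance) replaces it, repeating until stable — so noise fitted by surplus
    parameters never wins.
    """
    all_fits: list[FitResult] = []
    failed: list[str] = []
    notes: list[str] = []
    for spec in list_models(direction):
        try:
            fr = fit(u, spec, n_restarts=n_restarts, seed=seed, bounds=bounds)
        except FitError as e:
            failed.append(f"{spec.name}: {e}")
            continue
        if fr.converged:
            all_fits.append(fr)
        else:
            failed.append(f"{fr.spec.name}: {fr.message}")
    if not all_fits:
        raise FitError("no model converged; attempts: " + "; ".join(failed))

    fits = []
    screened_out: list[str] = []
    for fr in all_fits:
        bad = interpretability_violations(fr, u.span, u.dt)
        if bad:
            screened_out.append(fr.spec.name)
            notes.append(f"{fr.spec.name} screened out ({'; '.join(bad)})")
        else:
            fits.append(fr)
    if not fits:  # everything screened out: fall back to the raw converged fits
        notes.append("no fit passed the interpretability screen; selecting among raw fits")
        fits = all_fits

    best = min(fits, key=lambda f: f.ser)
    while True:
        simpler = [
            f
            for f in fits
            if f.p < best.p and is_nested(f.spec.form, best.spec.form)
        ]
        simpler.sort(key=lambda f: (f.p, f.ser))
        chosen = None
        for cand in simpler:
            if cand.ser <= SER_EXACT_TOL and best.ser <= SER_EXACT_TOL:
                notes.append(f"{cand.spec.name} ties {best.spec.name} at ~zero SER; parsimony")
                chosen = cand
                break
            # the candidate is retained unless some nested complex alternative beats
            # it significantly; the comparisons form one family (Hochberg step-up),
            # since three complex forms each get a shot at the same data
            family = [
                c for c in fits
                if c.p > cand.p and is_nested(cand.spec.form, c.spec.form)
            ]
            pvals = [f_test(cand, c).p_value for c in family]
            rejected, _ = hochberg_adjust(pvals, alpha=alpha)
            if not rejected.any():
                notes.append(
                    f"no nested complex model significantly improves on {cand.spec.name} "
                    f"(Hochberg-corrected F-tests, alpha={alpha:g}); parsimony"
                )
                chosen = cand
                break
        if chosen is None:
            break
        best = chosen
    return SelectionReport(
        best, tuple(all_fits), tuple(failed), alpha, tuple(notes), tuple(screened_out)
    )


def cv_of_estimates(values) -> float:
    """Coefficient of variation, percent: 100 * sample SD / mean."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need >= 2 values")
    mean = float(np.mean(v))
    if mean == 0.0:
        raise ZeroDivisionError("CV undefined for zero mean")
    return 100.0 * float(np.std(v, ddof=1)) / mean
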