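"""On/off symmetry statistics.

Paired comparisons of kinetic parameters between the exercise (on) and recovery (off)
phases within each intensity domain, effect sizes, Hochberg step-up multiplicity
correction for consecutive-domain contrasts, and correlation/regression between
paired quantities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class PairedTest:
    t: float
    df: int
    p_value: float


def paired_t(x, y) -> PairedTest:
    """Student's paired t-test, two-sided: t = mean(d) / (SD(d)/sqrt(n)), d = x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-d vectors with n >= 2")
    d = x - y
    if np.std(d, ddof=1) == 0.0:
        raise ValueError("zero difference SD: paired t-test degenerate")
    res = stats.ttest_rel(x, y)
    return PairedTest(float(res.statistic), len(x) - 1, float(res.pvalue))


@dataclass(frozen=True)
class EffectSize:
    d: float
    ci: tuple[float, float]
    level: float
    method: str = "paired Cohen's d (difference-SD standardiser), noncentral-t CI"


def cohens_d_paired(x, y, level: float = 0.95) -> EffectSize:
    """Cohen's d for paired data, standardised by the SD of the differences.

    The confidence interval inverts the noncentral-t distribution of
    t = d*sqrt(n): the bounds are the noncentrality parameters for which the observed
    t sits at the (1±level)/2 tails, divided by sqrt(n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-d vectors with n >= 2")
    d = x - y
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise ValueError("zero difference SD: effect size degenerate")
    n = len(d)
    d_val = float(np.mean(d)) / sd
    t_obs = d_val * np.sqrt(n)
    df = n - 1
    alpha = 1.0 - level

    def tail(nc: float, q: float) -> float:
        return stats.nct.cdf(t_obs, df, nc) - q

    span = 10.0 + 4.0 * abs(t_obs)
    try:
        nc_lo = optimize.brentq(tail, t_obs - span, t_obs + span, args=(1.0 - alpha / 2.0,))
        nc_hi = optimize.brentq(tail, t_obs - span, t_obs + span, args=(alpha / 2.0,))
    except ValueError:  # extreme t: fall back to a normal approximation
        se = np.sqrt(1.0 / n + d_val**2 / (2.0 * n))
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        nc_lo, nc_hi = (d_val - z * se) * np.sqrt(n), (d_val + z * se) * np.sqrt(n)
    return EffectSize(d_val, (nc_lo / np.sqrt(n), nc_hi / np.sqrt(n)), level)


def hochberg_adjust(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Hochberg step-up correction: (rejected flags, adjusted p-values).

    With ordered p(1) <= ... <= p(m), all hypotheses up to the largest k with
    p(k) <= alpha/(m-k+1) are rejected; adjusted p-values follow the same step-up
    path, capped at 1 and monotone in rank.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-d vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, adjusted, _, _ = multipletests(p, alpha=alpha, method="simes-hochberg")
    return rejected, adjusted


@dataclass(frozen=True)
class Correlation:
    r: float
    r2: float
    p_value: float
    slope: float
    intercept: float


def pearson(x, y) -> Correlation:
    """Pearson product-moment correlation with the ordinary least-squares line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-d vectors with n >= 3")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("zero variance: correlation undefined")
    reg = stats.linregress(x, y)
    return Correlation(
        r=float(reg.rvalue),
        r2=float(reg.rvalue**2),
        p_value=float(reg.pvalue),
        slope=float(reg.slope),
        intercept=float(reg.intercept),
    )


def _safe_pair(x: np.ndarray, y: np.ndarray, label: str):
    """Paired test + effect size, degrading gracefully on zero difference SD."""
    try:
        test = paired_t(x, y)
        es = cohens_d_paired(x, y)
        return test.p_value, es
    except ValueError as e:
        warnings.warn(f"degenerate paired comparison for {label}: {e}")
        return float("nan"), EffectSize(0.0, (float("nan"), float("nan")), 0.95)


def _adjust_with_nan(raw: list[float], alpha: float) -> np.ndarray:
    out = np.full(len(raw), np.nan)
    valid = [i for i, p in enumerate(raw) if np.isfinite(p)]
    if valid:
        _, adj = hochberg_adjust([raw[i] for i in valid], alpha=alpha)
        out[valid] = adj
    return out


def build_symmetry_table(
    on: dict[str, pd.DataFrame],
    off: dict[str, pd.DataFrame],
    domain_order: tuple[str, ...] = ("low", "moderate", "heavy", "severe"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-parameter on/off comparisons by domain plus consecutive-domain contrasts.

    ``on`` / ``off`` map domain -> DataFrame (rows = subjects, columns = parameters);
    subjects must be paired (identical index) within each domain.  For every parameter
    present in both phases a within-domain paired test and effect size are computed;
    consecutive-domain contrasts (3 per parameter and phase) are Hochberg-corrected as
    one family, mirroring a step-incremental design with four intensity domains.
    """
    rows: list[dict] = []
    domains = [d for d in domain_order if d in on and d in off]
    if not domains:
        raise ValueError("no common intensity domains between on and off inputs")
    for d in domains:
        if not on[d].index.equals(off[d].index):
            raise ValueError(f"unpaired subjects in domain {d!r}")
    params = sorted(
        set.intersection(*(set(on[d].columns) & set(off[d].columns) for d in domains))
    )
    for param in params:
        for d in domains:
            x = on[d][param].to_numpy(dtype=float)
            y = off[d][param].to_numpy(dtype=float)
            p_val, es = _safe_pair(x, y, f"{param}@{d}")
            rows.append(
                {
                    "parameter": param,
                    "kind": "on_vs_off",
                    "domain": d,
                    "on_mean": float(np.mean(x)),
                    "on_sd": float(np.std(x, ddof=1)),
                    "off_mean": float(np.mean(y)),
                    "off_sd": float(np.std(y, ddof=1)),
                    "p": p_val,
                    "d": es.d,
                    "d_ci_low": es.ci[0],
                    "d_ci_high": es.ci[1],
                }
            )
        for phase, data in (("on", on), ("off", off)):
            contrasts = list(zip(domains[:-1], domains[1:]))
            if not contrasts:
                continue
            raw, extras = [], []
            for d1, d2 in contrasts:
                x = data[d1][param].to_numpy(dtype=float)
                y = data[d2][param].to_numpy(dtype=float)
                p_val, es = _safe_pair(x, y, f"{param} {phase} {d1} vs {d2}")
                raw.append(p_val)
                extras.append((d1, d2, es))
            adjusted = _adjust_with_nan(raw, alpha)
            for (d1, d2, es), p_raw, p_adj in zip(extras, raw, adjusted):
                rows.append(
                    {
                        "parameter": param,
                        "kind": f"{phase}_contrast",
                        "domain": f"{d1}_vs_{d2}",
                        "p": p_raw,
                        "p_adjusted": float(p_adj),
                        "d": es.d,
                        "d_ci_low": es.ci[0],
                        "d_ci_high": es.ci[1],
                    }
                )
    return pd.DataFrame(rows)
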