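"""Breath-by-breath preprocessing: errant-breath exclusion, 1-s interpolation,
ensemble averaging, smoothing and summary values.

Raw breath values are never mutated; exclusion is flag-only so every decision remains
auditable.  The fitting substrate is a :class:`UniformSeries` on a 1-s grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from statsmodels.robust.scale import qn_scale


class InsufficientDataError(ValueError):
    """Raised when a series is too short for the requested operation."""


@dataclass(frozen=True)
class BreathSeries:
    """Irregular breath samples straight off the analyser.

    ``excluded`` flags breaths removed from downstream analysis; ``reasons`` carries a
    code per flagged breath ("" when kept, "manual" or "errant" otherwise).
    """

    t: np.ndarray           # breath timestamps, s, strictly increasing
    vo2: np.ndarray         # VO2 per breath, mL·kg⁻¹·min⁻¹
    excluded: np.ndarray = None  # type: ignore[assignment]
    reasons: np.ndarray = None   # type: ignore[assignment]

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        vo2 = np.asarray(self.vo2, dtype=float)
        excluded = (
            np.zeros(t.shape, dtype=bool)
            if self.excluded is None
            else np.asarray(self.excluded, dtype=bool)
        )
        reasons = (
            np.full(t.shape, "", dtype=object)
            if self.reasons is None
            else np.asarray(self.reasons, dtype=object)
        )
        if not (len(t) == len(vo2) == len(excluded) == len(reasons)):
            raise ValueError("t, vo2, excluded and reasons must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("breath timestamps must be strictly increasing")
        if np.any(vo2 < 0):
            raise ValueError("VO2 must be non-negative")
        for name, arr in (("t", t), ("vo2", vo2), ("excluded", excluded), ("reasons", reasons)):
            object.__setattr__(self, name, arr)
            arr.setflags(write=False)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def kept(self) -> "BreathSeries":
        """View restricted to non-excluded breaths (new object, flags reset)."""
        m = ~self.excluded
        return BreathSeries(self.t[m].copy(), self.vo2[m].copy())


@dataclass(frozen=True)
class UniformSeries:
    """VO2 on a uniform time grid (default 1 s) — the fitting substrate."""

    t0: float
    dt: float
    vo2: np.ndarray
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        vo2 = np.asarray(self.vo2, dtype=float)
        if vo2.ndim != 1 or len(vo2) == 0:
            raise ValueError("vo2 must be a non-empty 1-d array")
        if np.any(~np.isfinite(vo2)):
            raise ValueError("grid must have no missing values")
        object.__setattr__(self, "vo2", vo2)
        vo2.setflags(write=False)
        object.__setattr__(self, "provenance", tuple(self.provenance))

    def __len__(self) -> int:
        return len(self.vo2)

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.vo2))

    @property
    def span(self) -> float:
        return self.dt * (len(self.vo2) - 1)

    def with_values(self, vo2: np.ndarray, note: str) -> "UniformSeries":
        return UniformSeries(self.t0, self.dt, vo2, self.provenance + (note,))


def _neighbour_windows(n: int, half: int, keep: np.ndarray):
    """Indices of the ``2*half`` nearest kept neighbours of every kept breath.

    Centered in the interior; at the record edges the short side is compensated by
    borrowing further neighbours from the long side, so edge breaths are screened
    with as much evidence as interior ones.
    """
    kept_idx = np.flatnonzero(keep)
    m = len(kept_idx)
    for i, j in enumerate(kept_idx):
        lo, hi = i - half, i + half + 1
        if lo < 0:
            hi += -lo
            lo = 0
        if hi > m:
            lo = max(0, lo - (hi - m))
            hi = m
        neigh = np.concatenate([kept_idx[lo:i], kept_idx[i + 1 : hi]])
        yield j, neigh


def _screen_deviations(
    t: np.ndarray, vo2: np.ndarray, keep: np.ndarray, half: int
) -> dict[int, float]:
    """Standardized deviation of each kept breath from its local robust trend.

    A Theil-Sen line through the ``4*half`` nearest kept neighbours (self excluded;
    windows shifted one-sidedly at the record edges) predicts each breath; the
    deviation is studentized by the least-squares prediction leverage so interior and
    edge breaths share one ~N(0, sigma^2) null scale.  The robust line tolerates a
    couple of errant neighbours inside the window and removes the slope bias a plain
    median reference would suffer on a fast transient.
    """
    kept_idx = np.flatnonzero(keep)
    n_kept = len(kept_idx)
    out = {}
    w = 4 * half
    for i, j in enumerate(kept_idx):
        lo, hi = i - w // 2, i + w // 2 + 1
        if lo < 0:
            hi += -lo
            lo = 0
        if hi > n_kept:
            lo = max(0, lo - (hi - n_kept))
            hi = n_kept
        neigh = np.concatenate([kept_idx[lo:i], kept_idx[i + 1 : hi]])
        m = len(neigh)
        if m < 2:
            continue
        x = t[neigh] - t[j]
        X = np.column_stack([np.ones(m), x])
        XtX = X.T @ X
        if abs(np.linalg.det(XtX)) < 1e-12:
            out[j] = float((vo2[j] - np.mean(vo2[neigh])) / np.sqrt(1.0 + 1.0 / m))
            continue
        dx = x[:, None] - x[None, :]
        dv = vo2[neigh][:, None] - vo2[neigh][None, :]
        iu = np.triu_indices(m, 1)
        slope = float(np.median(dv[iu] / dx[iu]))
        pred = float(np.median(vo2[neigh] - slope * x))
        leverage = float(np.linalg.solve(XtX, np.array([1.0, 0.0]))[0])
        out[j] = float((vo2[j] - pred) / np.sqrt(1.0 + leverage))
    return out


def exclude_errant(
    b: BreathSeries,
    window: int = 5,
    k: float = 4.5,
    method: str = "robust",
    max_passes: int = 10,
) -> BreathSeries:
    """Flag errant breaths (coughs, swallows, valve artifacts) for exclusion.

    A breath with zero VO2 is an artifact by definition and is always flagged.
    With ``method="robust"`` (default), each non-excluded breath is compared with a
    robust local trend (Theil-Sen line through its nearest non-excluded neighbours,
    studentized by prediction leverage — see :func:`_screen_deviations`) and flagged
    when the deviation exceeds ``k`` times a series-level robust SD (Qn estimator of
    all deviations); flagging repeats on the surviving breaths until a fixed point,
    and a reinstatement step clears breaths that only looked deviant because an
    errant neighbour contaminated their window.  ``method="mean_sd"`` applies the
    classic rule instead: deviation from the mean of the ``window - 1`` centered
    neighbours (self excluded) beyond ``k`` neighbour SDs.  A second call with the
    same settings leaves the flags unchanged.

    Values are never modified — only ``excluded``/``reasons`` flags are set.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if k <= 0:
        raise ValueError("k must be > 0")
    if method not in ("robust", "mean_sd"):
        raise ValueError("method must be 'robust' or 'mean_sd'")
    if len(b) < window:
        warnings.warn(f"series of {len(b)} breaths shorter than window={window}; no exclusion applied")
        return b

    excluded = b.excluded.copy()
    reasons = b.reasons.copy()
    zero = (b.vo2 <= 0.0) & ~excluded
    excluded[zero] = True
    reasons[zero] = "errant"
    half = (window - 1) // 2

    if method == "robust" and np.isfinite(k):
        dev_flagged: dict[int, float] = {}  # index -> |deviation| when flagged
        for _ in range(max_passes):
            before = excluded.copy()
            keep = ~excluded
            if keep.sum() < window:
                break
            devs = _screen_deviations(b.t, b.vo2, keep, half)
            scale = float(qn_scale(np.asarray(list(devs.values()))))
            # absolute floor guards against float-noise cascades on near-exact data
            thresh = max(k * scale, 1e-8 * (1.0 + float(np.max(np.abs(b.vo2)))))
            for _ in range(max_passes):
                new = [j for j, d in devs.items() if abs(d) > thresh and not excluded[j]]
                if not new:
                    break
                excluded[new] = True
                for j in new:
                    dev_flagged[j] = abs(devs[j])
                devs = _screen_deviations(b.t, b.vo2, ~excluded, half)
            # re-examine every deviation-flagged breath, least deviant first, so
            # contamination victims are reinstated before their errant neighbour is
            # reassessed against a window that contains them again
            for j in sorted((j for j in dev_flagged if excluded[j]),
                            key=lambda j: dev_flagged[j]):
                keep_j = ~excluded
                keep_j[j] = True
                d = _screen_deviations(b.t, b.vo2, keep_j, half).get(j)
                if d is not None and abs(d) <= thresh:
                    excluded[j] = False
                else:
                    reasons[j] = "errant"
            if np.array_equal(before, excluded):  # fixed point: rerun reproduces it
                break
    else:
        for _ in range(max_passes):
            keep = ~excluded
            if keep.sum() < window:
                break
            new_flags = []
            for j, neigh in _neighbour_windows(len(b), half, keep):
                if len(neigh) < 2:
                    continue
                mu = float(np.mean(b.vo2[neigh]))
                sd = float(np.std(b.vo2[neigh], ddof=1))
                if abs(b.vo2[j] - mu) > k * sd:
                    new_flags.append(j)
            if not new_flags:
                break
            excluded[new_flags] = True
            for j in new_flags:
                reasons[j] = "errant"
    return BreathSeries(b.t.copy(), b.vo2.copy(), excluded, reasons)


def interpolate_1s(b: BreathSeries, dt: float = 1.0) -> UniformSeries:
    """Linearly interpolate non-excluded breaths onto an integer-second grid.

    The grid spans [ceil(t_first), floor(t_last)] of the kept breaths — no
    extrapolation outside the observed span.
    """
    m = ~b.excluded
    t, v = b.t[m], b.vo2[m]
    if len(t) < 2:
        raise InsufficientDataError(f"need >= 2 non-excluded breaths, have {len(t)}")
    t_start = float(np.ceil(t[0] / dt) * dt)
    t_end = float(np.floor(t[-1] / dt) * dt)
    if t_end < t_start:
        raise InsufficientDataError("breath span shorter than one grid step")
    grid = t_start + dt * np.arange(int(round((t_end - t_start) / dt)) + 1)
    vo2 = np.interp(grid, t, v)
    note = f"interpolate_1s(dt={dt:g}, breaths={len(t)}, excluded={int(b.excluded.sum())})"
    return UniformSeries(t_start, dt, vo2, (note,))


def ensemble_average(series: list[UniformSeries]) -> UniformSeries:
    """Pointwise mean of time-aligned transitions over their common time span."""
    if not series:
        raise ValueError("need at least one series")
    dt = series[0].dt
    if any(abs(s.dt - dt) > 1e-12 for s in series):
        raise ValueError("all series must share the same grid step")
    t_start = max(s.t0 for s in series)
    t_end = min(s.t0 + s.dt * (len(s) - 1) for s in series)
    if t_end < t_start:
        raise ValueError("series have no overlapping time span")
    n_pts = int(round((t_end - t_start) / dt)) + 1
    stack = np.empty((len(series), n_pts))
    for i, s in enumerate(series):
        i0 = int(round((t_start - s.t0) / dt))
        stack[i] = s.vo2[i0 : i0 + n_pts]
    note = f"ensemble_average(n={len(series)})"
    return UniformSeries(t_start, dt, stack.mean(axis=0), (note,))


_FILTERS = ("moving_average", "median", "breath_average")


def smooth(u: UniformSeries, method: str = "moving_average", width: float = 5) -> UniformSeries:
    """Centered rolling filter; edges handled by window truncation, grid unchanged.

    ``moving_average`` takes ``width`` in seconds, ``median`` and ``breath_average``
    take ``width`` in samples (on a 1-s grid the distinction vanishes).
    """
    if method not in _FILTERS:
        raise ValueError(f"unknown filter {method!r}; supported: {', '.join(_FILTERS)}")
    if width < 1:
        raise ValueError("width must be >= 1")
    n_window = int(round(width / u.dt)) if method == "moving_average" else int(width)
    n_window = max(1, n_window)
    import pandas as pd

    s = pd.Series(u.vo2)
    roll = s.rolling(n_window, center=True, min_periods=1)
    out = roll.median() if method == "median" else roll.mean()
    return u.with_values(out.to_numpy(), f"smooth({method}, width={width:g})")


def vo2peak_last30(u: UniformSeries, window: float = 30.0) -> float:
    """Peak VO2 as the mean of the final ``window`` seconds of the exercise phase."""
    if u.span < window:
        raise InsufficientDataError(
            f"need >= {window:g} s of data, have {u.span:g} s"
        )
    t = u.t
    mask = t >= t[-1] - window
    return float(np.mean(u.vo2[mask]))
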