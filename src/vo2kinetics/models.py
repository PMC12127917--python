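"""Closed-form oxygen-uptake transient models.

The pulmonary VO2 response to a step change in exercise intensity is described by
exponential components gated by a Heaviside step: a fast (primary) component with
amplitude ``Ap``, time delay ``TDp`` and time constant ``taup``, optionally followed by
a delayed slow component (``Asc``, ``TDsc``, ``tausc``).  Off-transient (recovery)
curves decay from the end-exercise level ``EEVO2``; on-transient curves rise from the
pre-exercise baseline ``VO2base``.  Four nested forms are supported per direction:

========================  =============================================
``MONO_NO_TD``            mono-exponential, ``TDp`` fixed at 0
``MONO_TD``               mono-exponential with free ``TDp``
``BIEXP_NO_TDP``          bi-exponential, ``TDp`` fixed at 0, free ``TDsc``
``BIEXP_TD``              bi-exponential with free ``TDp`` and ``TDsc``
========================  =============================================

All VO2 quantities are body-mass normalised (mL·kg⁻¹·min⁻¹); times are in seconds with
t = 0 at the transition (exercise onset for "on", cessation for "off").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterator, Mapping

import numpy as np


class Direction(str, Enum):
    ON = "on"
    OFF = "off"


class ModelForm(str, Enum):
    MONO_NO_TD = "mono_no_td"
    MONO_TD = "mono_td"
    BIEXP_NO_TDP = "biexp_no_tdp"
    BIEXP_TD = "biexp_td"

    @property
    def has_slow(self) -> bool:
        return self in (ModelForm.BIEXP_NO_TDP, ModelForm.BIEXP_TD)

    @property
    def tdp_fixed_zero(self) -> bool:
        return self in (ModelForm.MONO_NO_TD, ModelForm.BIEXP_NO_TDP)


#: simple form -> complex forms it is nested in (its free parameters are a subset,
#: with the extra ones recovering the simple form at TD=0 / Asc=0)
NESTING: dict[ModelForm, tuple[ModelForm, ...]] = {
    ModelForm.MONO_NO_TD: (ModelForm.MONO_TD, ModelForm.BIEXP_NO_TDP, ModelForm.BIEXP_TD),
    ModelForm.MONO_TD: (ModelForm.BIEXP_TD,),
    ModelForm.BIEXP_NO_TDP: (ModelForm.BIEXP_TD,),
    ModelForm.BIEXP_TD: (),
}


def is_nested(simple: ModelForm, complex_: ModelForm) -> bool:
    """True when ``simple`` is a restriction of ``complex_`` (proper nesting)."""
    return complex_ in NESTING[simple]


@dataclass(frozen=True)
class ParameterSet:
    """Kinetic parameters; fields not referenced by a form stay ``None``.

    Units: levels and amplitudes in mL·kg⁻¹·min⁻¹, delays and time constants in s.
    """

    EEVO2: float | None = None
    VO2base: float | None = None
    Ap: float | None = None
    Asc: float | None = None
    TDp: float | None = None
    TDsc: float | None = None
    taup: float | None = None
    tausc: float | None = None

    def get(self, name: str) -> float | None:
        return getattr(self, name)

    def to_dict(self, drop_none: bool = True) -> dict[str, float]:
        d = {f: getattr(self, f) for f in PARAM_ORDER}
        return {k: v for k, v in d.items() if v is not None} if drop_none else d

    def with_values(self, **kwargs: float) -> "ParameterSet":
        return replace(self, **kwargs)


PARAM_ORDER = ("EEVO2", "VO2base", "Ap", "TDp", "taup", "Asc", "TDsc", "tausc")

_FORM_PARAMS: dict[ModelForm, tuple[str, ...]] = {
    ModelForm.MONO_NO_TD: ("Ap", "TDp", "taup"),
    ModelForm.MONO_TD: ("Ap", "TDp", "taup"),
    ModelForm.BIEXP_NO_TDP: ("Ap", "TDp", "taup", "Asc", "TDsc", "tausc"),
    ModelForm.BIEXP_TD: ("Ap", "TDp", "taup", "Asc", "TDsc", "tausc"),
}


@dataclass(frozen=True)
class ModelSpec:
    """One concrete model form: direction, functional form and fixed parameters.

    ``fixed_params`` maps parameter names to frozen values; by construction the no-TD
    forms carry ``TDp=0``.  Further parameters (e.g. a measured ``VO2base``) may be
    fixed by the caller.  ``free_params`` is the ordered complement.
    """

    direction: Direction
    form: ModelForm
    extra_fixed: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        items = tuple(sorted(dict(self.extra_fixed).items()))
        bad = {k for k, _ in items} - set(self.referenced_params)
        if bad:
            raise ValueError(f"fixed parameters {sorted(bad)} not referenced by {self.form.value}")
        object.__setattr__(self, "extra_fixed", items)  # hashable

    @property
    def level_param(self) -> str:
        """The asymptotic-level parameter: EEVO2 (off) or VO2base (on)."""
        return "EEVO2" if self.direction == Direction.OFF else "VO2base"

    @property
    def referenced_params(self) -> tuple[str, ...]:
        return (self.level_param,) + _FORM_PARAMS[self.form]

    @property
    def fixed_params(self) -> dict[str, float]:
        fixed = {"TDp": 0.0} if self.form.tdp_fixed_zero else {}
        fixed.update(self.extra_fixed)
        return fixed

    @property
    def free_params(self) -> tuple[str, ...]:
        fixed = self.fixed_params
        return tuple(p for p in self.referenced_params if p not in fixed)

    @property
    def n_free(self) -> int:
        return len(self.free_params)

    @property
    def name(self) -> str:
        return f"{self.direction.value}-{self.form.value.replace('_', '-')}"

    # -- (de)serialization ---------------------------------------------------
    def to_json_dict(self) -> dict:
        return {
            "direction": self.direction.value,
            "form": self.form.value,
            "fixed": dict(self.fixed_params),
        }

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "ModelSpec":
        form = ModelForm(d["form"])
        fixed = dict(d.get("fixed", {}))
        if form.tdp_fixed_zero:
            fixed.pop("TDp", None)
        return cls(Direction(d["direction"]), form, fixed)

    # -- parameter plumbing --------------------------------------------------
    def complete(self, params: ParameterSet) -> ParameterSet:
        """Merge fixed values into ``params`` (fixed values win)."""
        return params.with_values(**self.fixed_params)

    def pack(self, params: ParameterSet) -> np.ndarray:
        """Free parameters as a vector in ``free_params`` order."""
        vals = [params.get(p) for p in self.free_params]
        if any(v is None for v in vals):
            missing = [p for p, v in zip(self.free_params, vals) if v is None]
            raise ValueError(f"missing free parameters {missing} for {self.name}")
        return np.asarray(vals, dtype=float)

    def unpack(self, x: np.ndarray) -> ParameterSet:
        """Vector of free values -> complete ParameterSet (fixed values merged)."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_free,):
            raise ValueError(f"expected {self.n_free} free values, got shape {x.shape}")
        ps = ParameterSet(**dict(zip(self.free_params, x.tolist())))
        return self.complete(ps)


def heaviside(x):
    """Right-continuous Heaviside step: 0 for x < 0, 1 for x >= 0."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("heaviside requires finite input")
    out = np.where(x < 0.0, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def _component(t: np.ndarray, A: float, TD: float, tau: float) -> np.ndarray:
    """Gated exponential component H(t-TD)*A*(1-exp(-(t-TD)/tau)), overflow-safe."""
    gate = t >= TD
    with np.errstate(over="ignore", invalid="ignore"):
        # upper clip keeps squared residuals finite for absurd optimiser excursions
        arg = np.clip(-(t - TD) / tau, -700.0, 100.0)
        val = A * (1.0 - np.exp(arg))
    return np.where(gate, val, 0.0)


def eval_raw(spec: ModelSpec, params: ParameterSet, t) -> np.ndarray:
    """Evaluate without invariant checks (used inside the optimiser loop)."""
    t = np.asarray(t, dtype=float)
    p = spec.complete(params)
    level = p.get(spec.level_param)
    y = np.full_like(t, float(level))
    sign = -1.0 if spec.direction == Direction.OFF else 1.0
    y = y + sign * _component(t, p.Ap, p.TDp, p.taup)
    if spec.form.has_slow:
        y = y + sign * _component(t, p.Asc, p.TDsc, p.tausc)
    return y


def validate_params(spec: ModelSpec, params: ParameterSet) -> ParameterSet:
    """Check form invariants; returns the completed parameter set."""
    p = spec.complete(params)
    for name in spec.referenced_params:
        v = p.get(name)
        if v is None or not np.isfinite(v):
            raise ValueError(f"parameter {name} missing or non-finite for {spec.name}")
    if p.Ap <= 0:
        raise ValueError("Ap must be > 0")
    if p.taup <= 0:
        raise ValueError("taup must be > 0")
    if p.TDp < 0:
        raise ValueError("TDp must be >= 0")
    if spec.form.has_slow:
        if p.Asc < 0:
            raise ValueError("Asc must be >= 0")
        if p.tausc <= 0:
            raise ValueError("tausc must be > 0")
        if p.TDsc < p.TDp:
            raise ValueError("TDsc must be >= TDp")
    return p


def evaluate(spec: ModelSpec, params: ParameterSet, t) -> np.ndarray:
    """Evaluate the model at time(s) ``t`` (s since the transition), validated."""
    validate_params(spec, params)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0 (t=0 at the transition)")
    out = eval_raw(spec, params, t_arr)
    return float(out) if np.ndim(t) == 0 else out


def eval_off(spec: ModelSpec, params: ParameterSet, t):
    """Off-transient (recovery) evaluation; ``spec`` must have direction 'off'."""
    if spec.direction != Direction.OFF:
        raise ValueError("eval_off requires an off-direction spec")
    return evaluate(spec, params, t)


def eval_on(spec: ModelSpec, params: ParameterSet, t):
    """On-transient (exercise onset) evaluation; ``spec`` must have direction 'on'."""
    if spec.direction != Direction.ON:
        raise ValueError("eval_on requires an on-direction spec")
    return evaluate(spec, params, t)


def list_models(direction: Direction | str) -> tuple[ModelSpec, ...]:
    """The four supported forms for one direction, simplest first (nesting order)."""
    direction = Direction(direction)
    return tuple(
        ModelSpec(direction, form)
        for form in (
            ModelForm.MONO_NO_TD,
            ModelForm.MONO_TD,
            ModelForm.BIEXP_NO_TDP,
            ModelForm.BIEXP_TD,
        )
    )


def iter_all_models() -> Iterator[ModelSpec]:
    for direction in (Direction.OFF, Direction.ON):
        yield from list_models(direction)
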