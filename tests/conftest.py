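import warnings

import numpy as np
import pytest

from vo2kinetics import GeneratorConfig, ModelForm, ModelSpec, ParameterSet, preset_spec
from vo2kinetics.models import Direction


@pytest.fixture(autouse=True)
def _quiet_span_warnings():
    # short validation records legitimately trip the span-vs-tau advisory
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="series span")
        yield


@pytest.fixture(scope="session")
def severe_off():
    """Recovery truth for the severe intensity domain (mono-exponential, no TD)."""
    return preset_spec("off", "severe")


def all_specs_with_truth():
    """(spec, truth) for all 8 forms, with TD truths away from the default inits."""
    out = []
    for direction in (Direction.OFF, Direction.ON):
        for form in ModelForm:
            spec = ModelSpec(direction, form)
            p = {
                "Ap": 40.3,
                "taup": 37.0 if direction == Direction.OFF else 12.0,
                "TDp": 0.0 if form.tdp_fixed_zero else 13.7,
            }
            if direction == Direction.OFF:
                p["EEVO2"] = 51.0
            else:
                p["VO2base"] = 11.1
            if form.has_slow:
                p.update(Asc=8.0, TDsc=95.3, tausc=60.0)
            out.append((spec, ParameterSet(**p)))
    return out


@pytest.fixture(scope="session")
def noisy_severe_series(severe_off):
    spec, truth = severe_off
    from vo2kinetics import generate_uniform

    return generate_uniform(
        GeneratorConfig(spec=spec, truth=truth, noise_sd=2.0, seed=12345)
    )


def seeds_from(base: int, n: int) -> list[int]:
    """Deterministic seed family below 2**31."""
    return [int(s) % (2**31) for s in np.random.SeedSequence(base).generate_state(n)]
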