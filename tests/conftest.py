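import numpy as np
import pytest

from cvccost import (
    ComplicationProbabilities,
    ModelParameters,
    PopulationAssumptions,
    Range,
    TaskDuration,
    WageRate,
    default_parameters,
)
from cvccost.parameters import ROLES, TASKS


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    """The packaged central estimates and sensitivity ranges."""
    return default_parameters()


def make_params(
    wages=None, times=None, p_mal=0.068, p_ptx=0.011, population=None
) -> ModelParameters:
    """Build a parameter set from plain dicts of central values.

    Ranges collapse to the central value unless a (low, central, high)
    triple is given.
    """
    base_wages = {
        "bedside-physician": 1.72,
        "radiologist": 1.89,
        "registered-nurse": 0.64,
        "radiology-technician": 0.51,
    }
    base_times = {
        "mdTimeA": 3.0,
        "mdTimeB": 5.6,
        "radiologistRead": 3.0,
        "rnTimeB": 5.6,
        "techTimeA": 15.0,
    }
    base_wages.update(wages or {})
    base_times.update(times or {})

    def rng(v):
        if isinstance(v, tuple):
            lo, c, hi = v
            return {"low": lo, "central": c, "high": hi}
        return {"low": v, "central": v, "high": v}

    return ModelParameters(
        wages={r: WageRate(role=r, **rng(base_wages[r])) for r in ROLES},
        times={t: TaskDuration(task=t, **rng(base_times[t])) for t in TASKS},
        probabilities=ComplicationProbabilities(
            pMalposition=Range(**rng(p_mal)), pPneumothorax=Range(**rng(p_ptx))
        ),
        population=PopulationAssumptions(
            **(
                population
                or dict(
                    hospitalCvcTotal=3069,
                    hospitalCxrConfirmed=2045,
                    nationalCvcTotal=5_000_000,
                    supradiaphragmaticFraction=0.66,
                    nationalEligible=3_300_000,
                )
            )
        ),
    )


def random_parameters(rng: np.random.Generator) -> ModelParameters:
    """A random valid parameter set for property tests."""
    wages = {r: float(rng.uniform(0.1, 5.0)) for r in ROLES}
    times = {t: float(rng.uniform(0.5, 30.0)) for t in TASKS}
    p_mal = float(rng.uniform(0.0, 0.6))
    p_ptx = float(rng.uniform(0.0, min(0.4, 1.0 - p_mal)))
    return make_params(wages=wages, times=times, p_mal=p_mal, p_ptx=p_ptx)
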