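"""Published alternative inputs, packaged as named scenarios.

Three sources report the rate at which radiograph interpretation finds
a malposition or pneumothorax after catheter insertion: the Smit 2018
meta-analysis (the model's central values), the Ablordeppey 2017
meta-analysis, and 2019 internal institutional data.  Each scenario
carries those probabilities as overrides to overlay on a base
configuration, plus the sources' reported workflow time intervals
(radiograph order-to-performed, order-to-read, ultrasound
start-to-complete) as annotation only — the cost equations use the
model's own task times, never these intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

from .parameters import ComplicationProbabilities, ModelParameters, Range

#: Default sensitivity span for the probabilities: the range across the
#: three published sources.
_P_MAL_SPAN = (0.026, 0.176)
_P_PTX_SPAN = (0.011, 0.032)


@dataclass(frozen=True)
class TimeInterval:
    """A reported workflow interval in minutes (annotation only)."""

    start: str
    end: str
    minutes: float
    #: reported uncertainty, e.g. "95% CI 32.6-36.7" or "SD 57.1"
    spread: Optional[str] = None


@dataclass(frozen=True)
class Scenario:
    name: str
    description: str
    probabilities: ComplicationProbabilities
    time_intervals: Tuple[TimeInterval, ...]


def _probs(p_mal: float, p_ptx: float, source: str) -> ComplicationProbabilities:
    return ComplicationProbabilities(
        pMalposition=Range(
            central=p_mal, low=min(p_mal, _P_MAL_SPAN[0]), high=max(p_mal, _P_MAL_SPAN[1])
        ),
        pPneumothorax=Range(
            central=p_ptx, low=min(p_ptx, _P_PTX_SPAN[0]), high=max(p_ptx, _P_PTX_SPAN[1])
        ),
        source=source,
    )


SCENARIOS: Dict[str, Scenario] = {
    "smit2018": Scenario(
        name="smit2018",
        description="Smit 2018 meta-analysis (model central values)",
        probabilities=_probs(0.068, 0.011, "smit2018"),
        time_intervals=(
            TimeInterval("CXR ordered", "CXR performed", 34.7, "95% CI 32.6-36.7"),
            TimeInterval("CXR ordered", "radiology read complete", 46.3, "95% CI 44.4-48.2"),
            TimeInterval("POCUS confirmation initiated", "POCUS confirmation complete", 2.83, "95% CI 2.77-2.89"),
        ),
    ),
    "ablordeppey2017": Scenario(
        name="ablordeppey2017",
        description="Ablordeppey 2017 meta-analysis",
        probabilities=_probs(0.176, 0.011, "ablordeppey2017"),
        time_intervals=(
            TimeInterval("CXR ordered", "CXR performed", 63.9, "SD 57.1"),
            TimeInterval("CXR ordered", "radiology read complete", 143.4, "SD 123.7"),
            TimeInterval("POCUS confirmation initiated", "POCUS confirmation complete", 5.6, "SD 2.5"),
        ),
    ),
    "internal2019": Scenario(
        name="internal2019",
        description="Internal institutional data, 2019",
        probabilities=_probs(0.026, 0.032, "internal2019"),
        time_intervals=(
            TimeInterval("CXR ordered", "CXR performed", 29.0, "range 1-269"),
            TimeInterval("POCUS confirmation initiated", "POCUS confirmation complete", 9.0, "range 8.5-9.5"),
        ),
    ),
}


def load_scenario(name: str) -> Scenario:
    """Look up a named scenario's probability overrides and annotations."""
    try:
        return SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; valid names: {sorted(SCENARIOS)}"
        ) from None


def apply_scenario(params: ModelParameters, name: str) -> ModelParameters:
    """A new parameter set with the scenario's probabilities overlaid."""
    scenario = load_scenario(name)
    data = params.model_dump()
    data["probabilities"] = scenario.probabilities.model_dump()
    return ModelParameters.model_validate(data)
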