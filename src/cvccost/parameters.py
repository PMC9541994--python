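"""Parameter data model for the CVC-confirmation labor-cost model.

All quantities that enter the cost equations live here: per-role wage
rates ($/minute), per-task durations (minutes), complication
probabilities (malposition, pneumothorax), and the population counts
used for scaling.  Every wage, time and probability carries a central
estimate plus the [low, high] range used by the deterministic
sensitivity analysis.  ``ModelParameters`` is the single source of
truth consumed by every evaluation routine.
"""

from __future__ import annotations

from typing import Mapping

from pydantic import BaseModel, ConfigDict, Field, model_validator

#: The four personnel roles, keyed as they appear in parameter files.
ROLES = (
    "bedside-physician",
    "radiologist",
    "registered-nurse",
    "radiology-technician",
)

#: The five task durations that enter the cost equations.
#:   mdTimeA         bedside physician time reviewing the radiograph (protocol A)
#:   mdTimeB         bedside physician time performing the three-step ultrasound (protocol B)
#:   radiologistRead radiologist time interpreting the radiograph (protocol A)
#:   rnTimeB         registered-nurse assist time during the ultrasound (protocol B)
#:   techTimeA       radiology-technician time acquiring the portable radiograph (protocol A)
TASKS = ("mdTimeA", "mdTimeB", "radiologistRead", "rnTimeB", "techTimeA")


class Range(BaseModel):
    """A central estimate with the bounds used in sensitivity analysis."""

    model_config = ConfigDict(frozen=True)

    central: float
    low: float
    high: float

    @model_validator(mode="after")
    def _ordered(self) -> "Range":
        if not (self.low <= self.central <= self.high):
            raise ValueError(
                f"range must satisfy low <= central <= high, got "
                f"low={self.low}, central={self.central}, high={self.high}"
            )
        return self

    @classmethod
    def point(cls, value: float) -> "Range":
        """A degenerate range (no sensitivity span)."""
        return cls(central=value, low=value, high=value)


class WageRate(Range):
    """Wage rate in dollars per minute for one personnel role."""

    role: str

    @model_validator(mode="after")
    def _positive(self) -> "WageRate":
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.low <= 0:
            raise ValueError(f"wage for {self.role!r} must be positive, got low={self.low}")
        return self


class TaskDuration(Range):
    """Duration in minutes of one task in a confirmation protocol."""

    task: str

    @model_validator(mode="after")
    def _valid_task(self) -> "TaskDuration":
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if self.central <= 0:
            raise ValueError(f"duration for {self.task!r} must be positive")
        return self


class ComplicationProbabilities(BaseModel):
    """Probabilities that the bedside ultrasound suspects a complication.

    A suspected malposition or pneumothorax diverts the patient to the
    full radiograph pathway.  Ranges default to the span of the
    published incidence sources.
    """

    model_config = ConfigDict(frozen=True)

    pMalposition: Range
    pPneumothorax: Range
    source: str = "smit2018"

    @model_validator(mode="after")
    def _valid(self) -> "ComplicationProbabilities":
        for name, rng in (("pMalposition", self.pMalposition), ("pPneumothorax", self.pPneumothorax)):
            if not (0.0 <= rng.low and rng.high <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got [{rng.low}, {rng.high}]")
        if self.pMalposition.central + self.pPneumothorax.central > 1.0:
            raise ValueError(
                "pMalposition + pPneumothorax exceeds 1 under the additive convention"
            )
        return self


class PopulationAssumptions(BaseModel):
    """Annual catheter volumes used to scale per-patient costs."""

    model_config = ConfigDict(frozen=True)

    hospitalCvcTotal: int = Field(gt=0)
    hospitalCxrConfirmed: int = Field(ge=0)
    nationalCvcTotal: int = Field(gt=0)
    supradiaphragmaticFraction: float = Field(gt=0.0, le=1.0)
    nationalEligible: int = Field(gt=0)

    @model_validator(mode="after")
    def _consistent(self) -> "PopulationAssumptions":
        if self.hospitalCxrConfirmed > self.hospitalCvcTotal:
            raise ValueError("hospitalCxrConfirmed cannot exceed hospitalCvcTotal")
        implied = round(self.nationalCvcTotal * self.supradiaphragmaticFraction)
        if abs(self.nationalEligible - implied) > 0.01 * implied:
            raise ValueError(
                f"nationalEligible={self.nationalEligible} differs from "
                f"nationalCvcTotal x supradiaphragmaticFraction = {implied} by more than 1%"
            )
        return self


class ModelParameters(BaseModel):
    """Complete parameter set: wages, task times, probabilities, population."""

    model_config = ConfigDict(frozen=True)

    wages: Mapping[str, WageRate]
    times: Mapping[str, TaskDuration]
    probabilities: ComplicationProbabilities
    population: PopulationAssumptions

    @model_validator(mode="after")
    def _complete(self) -> "ModelParameters":
        if set(self.wages) != set(ROLES):
            missing = set(ROLES) - set(self.wages)
            extra = set(self.wages) - set(ROLES)
            raise ValueError(f"wages must cover exactly {ROLES}; missing={sorted(missing)}, extra={sorted(extra)}")
        if set(self.times) != set(TASKS):
            missing = set(TASKS) - set(self.times)
            extra = set(self.times) - set(TASKS)
            raise ValueError(f"times must cover exactly {TASKS}; missing={sorted(missing)}, extra={sorted(extra)}")
        for role, w in self.wages.items():
            if w.role != role:
                raise ValueError(f"wages[{role!r}] holds role {w.role!r}")
        for task, t in self.times.items():
            if t.task != task:
                raise ValueError(f"times[{task!r}] holds task {t.task!r}")
        return self

    def wage(self, role: str) -> WageRate:
        try:
            return self.wages[role]
        except KeyError:
            raise KeyError(f"no wage for role {role!r}; valid roles: {ROLES}") from None

    def time(self, task: str) -> TaskDuration:
        try:
            return self.times[task]
        except KeyError:
            raise KeyError(f"no duration for task {task!r}; valid tasks: {TASKS}") from None


def default_parameters() -> ModelParameters:
    """The packaged central estimates and sensitivity ranges.

    Wages are 2021-era US academic-medical-center figures ($/minute,
    ranges spanning the 25th-75th salary percentiles); times are local
    task-time estimates; probabilities are the meta-analytic malposition
    and pneumothorax detection rates, with ranges spanning the published
    sources; population counts are one hospital-year and the national
    supradiaphragmatic catheter volume.
    """
    from .config import load_default_parameters

    return load_default_parameters()
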