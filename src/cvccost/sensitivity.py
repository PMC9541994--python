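"""Deterministic sensitivity analysis on the incremental cost A - B.

One-way analysis re-evaluates the full model at one parameter's low and
high bound with everything else at central values; the tornado orders
the resulting swings; two-way analysis evaluates a grid over two
parameters; break-even solves for the parameter value at which the two
protocols cost the same.

Every cost in the model is affine in each single parameter (products of
at most one varying factor), so one-way differences are exact linear
interpolants and break-even roots have a closed form.  Varying a
protocol-A quantity moves protocol B as well, through the diversion
terms — the analysis always re-evaluates both arms from the perturbed
parameter set.

By default the tornado omits the four wage parameters: wages apply to
both protocols and rescale rather than reorder them, so their ranges
are exposed (``include_wages=True``) but not varied by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import DiversionConvention, incremental_result
from .parameters import ModelParameters, Range

#: Labels accepted by one_way/two_way/break_even, in registry order:
#: five task times, two diversion probabilities, four wages.
TIME_LABELS = ("mdTimeA", "mdTimeB", "radiologistRead", "rnTimeB", "techTimeA")
PROBABILITY_LABELS = ("pMalposition", "pPneumothorax")
WAGE_LABELS = ("mdWage", "radiologistWage", "rnWage", "techWage")

_WAGE_ROLE = {
    "mdWage": "bedside-physician",
    "radiologistWage": "radiologist",
    "rnWage": "registered-nurse",
    "techWage": "radiology-technician",
}


@dataclass(frozen=True)
class SensitivityRecord:
    """One-way evaluation of a single parameter at its two bounds."""

    parameter: str
    low_input: float
    high_input: float
    cost_a_low: float
    cost_a_high: float
    cost_b_low: float
    cost_b_high: float

    @property
    def diff_low(self) -> float:
        return self.cost_a_low - self.cost_b_low

    @property
    def diff_high(self) -> float:
        return self.cost_a_high - self.cost_b_high


@dataclass(frozen=True)
class TornadoEntry:
    """Swing of the incremental cost over one parameter's range."""

    parameter: str
    swing: float
    #: which extreme of the parameter favors the radiograph protocol
    direction: str  # "low" or "high"
    diff_low: float
    diff_high: float


@dataclass(frozen=True)
class TwoWayGrid:
    parameter_x: str
    parameter_y: str
    x_values: np.ndarray
    y_values: np.ndarray
    #: diff[i, j] = costA - costB at (x_values[i], y_values[j])
    diff: np.ndarray


def parameter_labels(include_wages: bool = True) -> Tuple[str, ...]:
    labels = TIME_LABELS + PROBABILITY_LABELS
    if include_wages:
        labels = labels + WAGE_LABELS
    return labels


def parameter_range(params: ModelParameters, label: str) -> Range:
    """The (central, low, high) range declared for a parameter label."""
    if label in TIME_LABELS:
        return params.time(label)
    if label in PROBABILITY_LABELS:
        return getattr(params.probabilities, label)
    if label in _WAGE_ROLE:
        return params.wage(_WAGE_ROLE[label])
    raise KeyError(
        f"unknown parameter {label!r}; valid labels: {sorted(parameter_labels())}"
    )


def apply_to_dict(data: dict, label: str, value: float) -> None:
    """Set one parameter's central value in a ``model_dump`` dict, in place.

    The declared [low, high] range is widened if ``value`` falls outside
    it, so off-range evaluations (break-even search) remain valid
    parameter sets.
    """
    if label in TIME_LABELS:
        entry = data["times"][label]
    elif label in PROBABILITY_LABELS:
        entry = data["probabilities"][label]
    elif label in _WAGE_ROLE:
        entry = data["wages"][_WAGE_ROLE[label]]
    else:
        raise KeyError(
            f"unknown parameter {label!r}; valid labels: {sorted(parameter_labels())}"
        )
    entry["central"] = value
    entry["low"] = min(entry["low"], value)
    entry["high"] = max(entry["high"], value)


def set_parameter(params: ModelParameters, label: str, value: float) -> ModelParameters:
    """A new parameter set with one quantity's central value replaced."""
    parameter_range(params, label)  # raises KeyError for unknown labels
    data = params.model_dump()
    apply_to_dict(data, label, value)
    return ModelParameters.model_validate(data)


def _diff_fn(
    params: ModelParameters, label: str, convention: DiversionConvention
) -> Callable[[float], float]:
    def diff(value: float) -> float:
        return incremental_result(set_parameter(params, label, value), convention).absolute_savings

    return diff


def one_way(
    params: ModelParameters,
    parameter: str,
    convention: DiversionConvention = DiversionConvention.SEQUENTIAL,
) -> SensitivityRecord:
    """Evaluate the full model at one parameter's low and high bound."""
    rng = parameter_range(params, parameter)
    results = {}
    for bound in ("low", "high"):
        perturbed = set_parameter(params, parameter, getattr(rng, bound))
        results[bound] = incremental_result(perturbed, convention)
    return SensitivityRecord(
        parameter=parameter,
        low_input=rng.low,
        high_input=rng.high,
        cost_a_low=results["low"].cost_a,
        cost_a_high=results["high"].cost_a,
        cost_b_low=results["low"].cost_b,
        cost_b_high=results["high"].cost_b,
    )


def one_way_all(
    params: ModelParameters,
    convention: DiversionConvention = DiversionConvention.SEQUENTIAL,
    include_wages: bool = True,
) -> List[SensitivityRecord]:
    return [one_way(params, label, convention) for label in parameter_labels(include_wages)]


def tornado(
    params: ModelParameters,
    convention: DiversionConvention = DiversionConvention.SEQUENTIAL,
    include_wages: bool = False,
) -> List[TornadoEntry]:
    """One-way swings sorted descending; ties broken by label."""
    entries = []
    for record in one_way_all(params, convention, include_wages):
        swing = abs(record.diff_high - record.diff_low)
        # the extreme with the smaller savings A - B is the one favoring A
        direction = "low" if record.diff_low < record.diff_high else "high"
        entries.append(
            TornadoEntry(
                parameter=record.parameter,
                swing=swing,
                direction=direction,
                diff_low=record.diff_low,
                diff_high=record.diff_high,
            )
        )
    return sorted(entries, key=lambda e: (-e.swing, e.parameter))


def two_way(
    params: ModelParameters,
    parameter_x: str,
    parameter_y: str,
    grid_points: int = 11,
    convention: DiversionConvention = DiversionConvention.SEQUENTIAL,
) -> TwoWayGrid:
    """Incremental cost over an evenly spaced grid of two parameters."""
    if parameter_x == parameter_y:
        raise ValueError(f"two-way analysis needs distinct parameters, got {parameter_x!r} twice")
    if grid_points < 2:
        raise ValueError(f"grid_points must be >= 2, got {grid_points}")
    rng_x = parameter_range(params, parameter_x)
    rng_y = parameter_range(params, parameter_y)
    x_values = np.linspace(rng_x.low, rng_x.high, grid_points)
    y_values = np.linspace(rng_y.low, rng_y.high, grid_points)
    diff = np.empty((grid_points, grid_points))
    for i, x in enumerate(x_values):
        px = set_parameter(params, parameter_x, float(x))
        for j, y in enumerate(y_values):
            pxy = set_parameter(px, parameter_y, float(y))
            diff[i, j] = incremental_result(pxy, convention).absolute_savings
    return TwoWayGrid(parameter_x, parameter_y, x_values, y_values, diff)


def break_even(
    params: ModelParameters,
    parameter: str,
    convention: DiversionConvention = DiversionConvention.SEQUENTIAL,
) -> Optional[float]:
    """Parameter value at which the two protocols cost the same.

    The incremental cost is affine in any single parameter, so the root
    is solved in closed form from two evaluations.  The search window is
    the declared range extended 10-fold about its midpoint (clamped to
    the parameter's natural domain); ``None`` if no root lies inside.
    """
    rng = parameter_range(params, parameter)
    diff = _diff_fn(params, parameter, convention)
    width = rng.high - rng.low
    mid = 0.5 * (rng.low + rng.high)
    lo = mid - 5.0 * width
    hi = mid + 5.0 * width
    if parameter in PROBABILITY_LABELS:
        other = (
            params.probabilities.pPneumothorax.central
            if parameter == "pMalposition"
            else params.probabilities.pMalposition.central
        )
        lo, hi = max(lo, 0.0), min(hi, 1.0 - other)
    else:
        lo = max(lo, 1e-9)
    if hi <= lo:
        lo, hi = rng.low, rng.high
    if hi == lo:  # degenerate range: the model is constant in this parameter
        return rng.central if abs(diff(rng.central)) < 1e-12 else None

    d_lo, d_hi = diff(lo), diff(hi)
    slope = (d_hi - d_lo) / (hi - lo)
    if slope == 0.0:
        return rng.central if abs(d_lo) < 1e-12 else None
    root = lo - d_lo / slope
    if not (lo <= root <= hi):
        return None
    return root
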