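"""Probabilistic sensitivity analysis (Monte Carlo).

The deterministic analysis varies one parameter at a time; the PSA
propagates joint parameter uncertainty by sampling every varying
quantity from a distribution over its declared range and evaluating the
full model per draw.  The published inputs carry only ranges (salary
percentiles, reported standard deviations), not distributional shapes,
so the defaults are deliberately modest: triangular(low, mode=central,
high) for task times and probabilities, uniform(low, high) for wages;
all overridable per parameter.  Draws are independent across
parameters — no correlation information exists to do better.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import DiversionConvention, incremental_result
from .parameters import ModelParameters
from .sensitivity import (
    PROBABILITY_LABELS,
    apply_to_dict,
    parameter_labels,
    parameter_range,
)

DEFAULT_N_DRAWS = 10_000
DEFAULT_SEED = 20220915

_FAMILIES = ("uniform", "triangular", "fixed")


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution for one parameter.

    ``mode`` is the triangular mode (ignored by uniform); ``fixed``
    pins the parameter at ``mode`` and ignores the bounds.
    """

    parameter: str
    family: str
    low: float
    mode: float
    high: float

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {_FAMILIES}")
        if self.family != "fixed" and not (self.low <= self.mode <= self.high):
            raise ValueError(
                f"spec for {self.parameter!r} must satisfy low <= mode <= high, "
                f"got ({self.low}, {self.mode}, {self.high})"
            )

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "fixed" or self.low == self.high:
            return np.full(n, self.mode)
        if self.family == "uniform":
            return rng.uniform(self.low, self.high, n)
        return rng.triangular(self.low, self.mode, self.high, n)


@dataclass(frozen=True)
class PsaDraw:
    index: int
    parameters: ModelParameters
    cost_a: float
    cost_b: float

    @property
    def diff(self) -> float:
        return self.cost_a - self.cost_b


@dataclass(frozen=True)
class PsaSummary:
    n_draws: int
    seed: Optional[int]
    mean_diff: float
    #: central 95% interval of the incremental cost (2.5th, 97.5th percentile)
    interval_diff: Tuple[float, float]
    prob_b_cheaper: float


def default_specs(params: ModelParameters) -> List[DistributionSpec]:
    """Triangular specs for times and probabilities, uniform for wages."""
    specs = []
    for label in parameter_labels(include_wages=True):
        rng = parameter_range(params, label)
        family = "uniform" if label.endswith("Wage") else "triangular"
        specs.append(
            DistributionSpec(
                parameter=label, family=family, low=rng.low, mode=rng.central, high=rng.high
            )
        )
    return specs


def sample_parameters(
    specs: Sequence[DistributionSpec],
    n: int,
    seed: int,
    base: ModelParameters,
) -> List[ModelParameters]:
    """``n`` independent parameter sets drawn from ``specs``.

    Reproducible given (specs, n, seed).  Parameters without a spec stay
    at their value in ``base``; probability draws are truncated to [0, 1].
    """
    if n < 1:
        raise ValueError(f"need at least one draw, got n={n}")
    seen = [s.parameter for s in specs]
    if len(set(seen)) != len(seen):
        raise ValueError("duplicate parameter in distribution specs")
    rng = np.random.default_rng(seed)
    columns: Dict[str, np.ndarray] = {}
    for spec in specs:
        parameter_range(base, spec.parameter)  # validate the label
        values = spec.sample(rng, n)
        if spec.parameter in PROBABILITY_LABELS:
            values = np.clip(values, 0.0, 1.0)
        columns[spec.parameter] = values
    base_data = base.model_dump()
    draws = []
    for i in range(n):
        data = copy.deepcopy(base_data)
        for label, values in columns.items():
            apply_to_dict(data, label, float(values[i]))
        draws.append(ModelParameters.model_validate(data))
    return draws


def run_psa(
    draws: Sequence[ModelParameters],
    convention: DiversionConvention = DiversionConvention.SEQUENTIAL,
    seed: Optional[int] = None,
) -> Tuple[PsaSummary, List[PsaDraw]]:
    """Evaluate the full model on every draw and summarize A - B."""
    if not draws:
        raise ValueError("PSA needs a nonempty sequence of draws")
    results = []
    for i, p in enumerate(draws):
        res = incremental_result(p, convention)
        results.append(PsaDraw(index=i, parameters=p, cost_a=res.cost_a, cost_b=res.cost_b))
    diffs = np.array([d.diff for d in results])
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    summary = PsaSummary(
        n_draws=len(results),
        seed=seed,
        mean_diff=float(diffs.mean()),
        interval_diff=(float(lo), float(hi)),
        prob_b_cheaper=float((diffs > 0).mean()),
    )
    return summary, results


def draws_to_frame(draws: Sequence[PsaDraw]) -> pd.DataFrame:
    """One row per draw: index, every sampled parameter, costs, diff."""
    labels = parameter_labels(include_wages=True)
    rows = []
    for d in draws:
        row = {"index": d.index}
        for label in labels:
            row[label] = parameter_range(d.parameters, label).central
        row.update(costA=d.cost_a, costB=d.cost_b, diff=d.diff)
        rows.append(row)
    return pd.DataFrame(rows)
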