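"""JSON parameter/configuration files.

One file holds everything the model needs, under four top-level keys —
``wages``, ``times``, ``probabilities``, ``population`` — plus an
optional ``run`` section (diversion convention, output directory).
Each wage/time/probability entry is ``{"central": x, "low": lo,
"high": hi}``; a bare number is accepted as a degenerate range.  A
packaged default file carries the published central values and
sensitivity ranges.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Any, Dict, Tuple, Union

from pydantic import BaseModel, ConfigDict, ValidationError

from .model import DiversionConvention
from .parameters import ROLES, TASKS, ModelParameters

_DEFAULT_RESOURCE = "default_params.json"


class ConfigError(ValueError):
    """A parameter file that parses but violates the schema or an invariant."""


class RunConfig(BaseModel):
    """Run-level options carried alongside the model parameters."""

    model_config = ConfigDict(frozen=True)

    convention: DiversionConvention = DiversionConvention.SEQUENTIAL
    output_dir: Path = Path("cvccost-output")
    #: display rounding: decimal places for per-patient costs, and the
    #: units for hospital- and national-scale totals
    per_patient_decimals: int = 2
    hospital_unit: float = 1.0
    national_unit: float = 100_000.0  # $0.1M


def _as_range(entry: Any, path: str) -> Dict[str, float]:
    if isinstance(entry, (int, float)) and not isinstance(entry, bool):
        return {"central": float(entry), "low": float(entry), "high": float(entry)}
    if isinstance(entry, dict):
        missing = {"central", "low", "high"} - set(entry)
        if missing:
            raise ConfigError(f"{path}: missing keys {sorted(missing)}")
        return entry
    raise ConfigError(f"{path}: expected a number or a {{central, low, high}} object")


def parse_parameters(raw: Dict[str, Any]) -> ModelParameters:
    """Validate a decoded JSON document into a ``ModelParameters``."""
    for key in ("wages", "times", "probabilities", "population"):
        if key not in raw:
            raise ConfigError(f"missing top-level key {key!r}")
    wages = {}
    for role in ROLES:
        if role not in raw["wages"]:
            raise ConfigError(f"wages.{role}: missing")
        wages[role] = {**_as_range(raw["wages"][role], f"wages.{role}"), "role": role}
    times = {}
    for task in TASKS:
        if task not in raw["times"]:
            raise ConfigError(f"times.{task}: missing")
        times[task] = {**_as_range(raw["times"][task], f"times.{task}"), "task": task}
    probs_raw = raw["probabilities"]
    probs = {
        "pMalposition": _as_range(probs_raw.get("pMalposition"), "probabilities.pMalposition"),
        "pPneumothorax": _as_range(probs_raw.get("pPneumothorax"), "probabilities.pPneumothorax"),
    }
    if "source" in probs_raw:
        probs["source"] = probs_raw["source"]
    try:
        return ModelParameters.model_validate(
            {
                "wages": wages,
                "times": times,
                "probabilities": probs,
                "population": raw["population"],
            }
        )
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: Union[str, Path]) -> Tuple[ModelParameters, RunConfig]:
    """Read and validate a parameter file; returns (parameters, run config)."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: not valid JSON: {exc}") from exc
    params = parse_parameters(raw)
    run_raw = raw.get("run", {})
    try:
        run = RunConfig.model_validate(run_raw)
    except ValidationError as exc:
        raise ConfigError(f"run: {exc}") from exc
    return params, run


def load_default_parameters() -> ModelParameters:
    """The packaged default parameter set."""
    text = resources.files("cvccost.data").joinpath(_DEFAULT_RESOURCE).read_text()
    return parse_parameters(json.loads(text))


def default_config_path() -> Path:
    """Filesystem path of the packaged default parameter file."""
    return Path(str(resources.files("cvccost.data").joinpath(_DEFAULT_RESOURCE)))


def parameters_to_dict(params: ModelParameters) -> Dict[str, Any]:
    """Serialize parameters back to the documented JSON layout."""
    return {
        "wages": {
            role: {"central": w.central, "low": w.low, "high": w.high}
            for role, w in params.wages.items()
        },
        "times": {
            task: {"central": t.central, "low": t.low, "high": t.high}
            for task, t in params.times.items()
        },
        "probabilities": {
            "pMalposition": {
                "central": params.probabilities.pMalposition.central,
                "low": params.probabilities.pMalposition.low,
                "high": params.probabilities.pMalposition.high,
            },
            "pPneumothorax": {
                "central": params.probabilities.pPneumothorax.central,
                "low": params.probabilities.pPneumothorax.low,
                "high": params.probabilities.pPneumothorax.high,
            },
            "source": params.probabilities.source,
        },
        "population": params.population.model_dump(),
    }


def write_parameters(params: ModelParameters, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(parameters_to_dict(params), indent=2) + "\n")
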