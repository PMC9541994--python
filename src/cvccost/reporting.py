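"""Display rounding and machine-readable report tables.

Every number the model computes is carried at full floating precision;
this module is the only place values are rounded — to cents for
per-patient costs, whole dollars for hospital-year totals, $0.1M for
national totals, whole percent for relative savings.  Deriving the
scaled totals from the *displayed* per-patient values does not
reproduce the reports; they are always derived from full precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from . import __version__
from .model import (
    CostBreakdown,
    DiversionConvention,
    IncrementalResult,
    cost_protocol_A,
    cost_protocol_B,
    incremental_result,
    scale_to_population,
)
from .parameters import ModelParameters
from .sensitivity import SensitivityRecord, TornadoEntry, TwoWayGrid


def round_to(value: float, unit: float = 1.0) -> float:
    """Round to the nearest multiple of ``unit``, halves away from zero.

    Uses decimal arithmetic so that e.g. 381.5 cents rounds to exactly
    the double nearest 3.82 rather than accumulating binary round-off.
    """
    if unit <= 0:
        raise ValueError(f"rounding unit must be positive, got {unit}")
    d_unit = Decimal(str(unit))
    n = (Decimal(str(value)) / d_unit).quantize(Decimal(1), rounding=ROUND_HALF_UP)
    return float(n * d_unit)


def round_cents(value: float) -> float:
    return round_to(value, 0.01)


def round_dollars(value: float) -> float:
    return round_to(value, 1.0)


def to_tenth_million(value: float) -> float:
    """Express dollars in millions, rounded to $0.1M."""
    return round_to(value, 100_000.0) / 1e6


def whole_percent(fraction: float) -> int:
    return int(round_to(100.0 * fraction, 1.0))


def fmt_dollars(value: float, decimals: int = 0) -> str:
    """Fixed period-decimal, comma-thousands formatting."""
    return f"${value:,.{decimals}f}"


@dataclass(frozen=True)
class ReportBundle:
    """Per-patient, scaling and incremental tables plus run metadata."""

    per_patient: pd.DataFrame
    scaling: pd.DataFrame
    incremental: Dict[str, float]
    metadata: Dict[str, str]

    def write(self, output_dir: Union[str, Path]) -> List[Path]:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for name, frame in (("per_patient", self.per_patient), ("scaling", self.scaling)):
            path = out / f"{name}.csv"
            frame.to_csv(path, index=False)
            written.append(path)
        path = out / "report.json"
        path.write_text(
            json.dumps(
                {
                    "per_patient": self.per_patient.to_dict(orient="records"),
                    "scaling": self.scaling.to_dict(orient="records"),
                    "incremental": self.incremental,
                    "metadata": self.metadata,
                },
                indent=2,
            )
            + "\n"
        )
        written.append(path)
        return written


def breakdown_rows(breakdown: CostBreakdown) -> List[Dict[str, object]]:
    rows: List[Dict[str, object]] = []
    for line in breakdown.lines:
        rows.append(
            {
                "protocol": breakdown.protocol,
                "item": line.description,
                "minutes": line.minutes,
                "wage_per_minute": line.wage_per_minute,
                "cost": round_cents(line.cost),
            }
        )
    if breakdown.protocol == "B":
        rows.append(
            {
                "protocol": "B",
                "item": "Diversion to CXR protocol (malposition)",
                "minutes": None,
                "wage_per_minute": None,
                "cost": round_cents(breakdown.diversion_malposition),
            }
        )
        rows.append(
            {
                "protocol": "B",
                "item": "Diversion to CXR protocol (pneumothorax)",
                "minutes": None,
                "wage_per_minute": None,
                "cost": round_cents(breakdown.diversion_pneumothorax),
            }
        )
    rows.append(
        {
            "protocol": breakdown.protocol,
            "item": "Total cost per patient",
            "minutes": None,
            "wage_per_minute": None,
            "cost": round_cents(breakdown.total),
        }
    )
    return rows


def render_cost_report(
    params: ModelParameters,
    convention: DiversionConvention = DiversionConvention.SEQUENTIAL,
) -> ReportBundle:
    """Per-patient cost table, population scaling table, savings summary."""
    a = cost_protocol_A(params)
    b = cost_protocol_B(params, convention)
    inc = incremental_result(params, convention)

    per_patient = pd.DataFrame(breakdown_rows(a) + breakdown_rows(b))

    pop = params.population
    scaling_rows = []
    for label, n, unit in (
        (f"hospital-year (n={pop.hospitalCxrConfirmed})", pop.hospitalCxrConfirmed, "dollars"),
        ("per 1 million CVCs", 1_000_000, "millions"),
        (f"national eligible (n={pop.nationalEligible})", pop.nationalEligible, "millions"),
    ):
        tot_a = scale_to_population(a.total, n)
        tot_b = scale_to_population(b.total, n)
        if unit == "dollars":
            row = {
                "scale": label,
                "costA": round_dollars(tot_a),
                "costB": round_dollars(tot_b),
                "savings": round_dollars(tot_a - tot_b),
                "units": "USD",
            }
        else:
            row = {
                "scale": label,
                "costA": to_tenth_million(tot_a),
                "costB": to_tenth_million(tot_b),
                "savings": to_tenth_million(tot_a - tot_b),
                "units": "USD millions",
            }
        scaling_rows.append(row)
    scaling = pd.DataFrame(scaling_rows)

    incremental = {
        "costA": round_cents(inc.cost_a),
        "costB": round_cents(inc.cost_b),
        "absoluteSavings": round_cents(inc.absolute_savings),
        "relativeSavingsPercent": whole_percent(inc.relative_savings),
    }
    metadata = {"version": __version__, "convention": DiversionConvention(convention).value}
    return ReportBundle(per_patient, scaling, incremental, metadata)


def one_way_frame(records: Sequence[SensitivityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": r.parameter,
            "low_input": r.low_input,
            "high_input": r.high_input,
            "costA_low": r.cost_a_low,
            "costA_high": r.cost_a_high,
            "costB_low": r.cost_b_low,
            "costB_high": r.cost_b_high,
            "diff_low": r.diff_low,
            "diff_high": r.diff_high,
        }
        for r in records
    )


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": e.parameter,
            "swing": e.swing,
            "direction": e.direction,
            "diff_low": e.diff_low,
            "diff_high": e.diff_high,
        }
        for e in entries
    )


def two_way_frame(grid: TwoWayGrid) -> pd.DataFrame:
    """Long-format grid: one row per (x, y) cell."""
    rows = []
    for i, x in enumerate(grid.x_values):
        for j, y in enumerate(grid.y_values):
            rows.append(
                {
                    grid.parameter_x: float(x),
                    grid.parameter_y: float(y),
                    "diff": float(grid.diff[i, j]),
                }
            )
    return pd.DataFrame(rows)


def plot_tornado(
    entries: Sequence[TornadoEntry],
    base_diff: float,
    path: Optional[Union[str, Path]] = None,
):
    """Convenience horizontal-bar tornado of the one-way swings."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    entries = list(entries)
    labels = [e.parameter for e in entries][::-1]
    lows = [min(e.diff_low, e.diff_high) for e in entries][::-1]
    highs = [max(e.diff_low, e.diff_high) for e in entries][::-1]
    fig, ax = plt.subplots(figsize=(7, 0.5 * len(entries) + 1.5))
    ax.barh(labels, [h - l for l, h in zip(lows, highs)], left=lows, color="#4878a8")
    ax.axvline(base_diff, color="black", lw=1, ls="--", label="base case")
    ax.set_xlabel("cost savings A - B ($ per patient)")
    ax.legend(loc="lower right")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
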