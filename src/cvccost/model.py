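"""Closed-form labor-cost evaluation of the two confirmation protocols.

Protocol A (chest radiograph): a radiology technician acquires a
portable film, the bedside physician reviews it, and a radiologist
interprets it.  Protocol B (point-of-care ultrasound): the bedside
physician performs a three-step ultrasound confirmation assisted by a
registered nurse; a suspected malposition or pneumothorax diverts the
patient to the full protocol-A pathway, so the expected cost of B
carries probability-weighted diversion terms on top of the two base
line items.

All arithmetic is carried at full floating precision.  Rounding to
cents, whole dollars or $0.1M is strictly a display concern handled by
:mod:`cvccost.reporting`; rounding line items before summing does not
reproduce the model's totals.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Tuple

from .parameters import ComplicationProbabilities, ModelParameters


class DiversionConvention(str, enum.Enum):
    """How the two diversion probabilities combine.

    ``sequential``: pneumothorax is only assessed when no malposition
    was suspected, so its path weight is (1 - pMal) * pPtx.
    ``additive``: the two probabilities simply add.
    """

    SEQUENTIAL = "sequential"
    ADDITIVE = "additive"


@dataclass(frozen=True)
class CostLine:
    """One labor line item: minutes of one role's time at its wage."""

    description: str
    role: str
    minutes: float
    wage_per_minute: float
    cost: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "cost", line_cost(self.minutes, self.wage_per_minute)
        )


@dataclass(frozen=True)
class CostBreakdown:
    """Itemized per-patient labor cost for one protocol."""

    protocol: str
    lines: Tuple[CostLine, ...]
    diversion_malposition: float = 0.0
    diversion_pneumothorax: float = 0.0

    @property
    def base_cost(self) -> float:
        return sum(line.cost for line in self.lines)

    @property
    def total(self) -> float:
        return self.base_cost + self.diversion_malposition + self.diversion_pneumothorax


@dataclass(frozen=True)
class IncrementalResult:
    """Per-patient cost of each protocol and the savings from switching."""

    cost_a: float
    cost_b: float

    @property
    def absolute_savings(self) -> float:
        return self.cost_a - self.cost_b

    @property
    def relative_savings(self) -> float:
        return self.absolute_savings / self.cost_a


def line_cost(minutes: float, wage: float) -> float:
    """Labor cost of ``minutes`` of one role's time at ``wage`` $/minute."""
    if minutes < 0:
        raise ValueError(f"minutes must be non-negative, got minutes={minutes}")
    if wage <= 0:
        raise ValueError(f"wage must be positive, got wage={wage}")
    return minutes * wage


def cost_protocol_A(params: ModelParameters) -> CostBreakdown:
    """Per-patient labor cost of radiograph-based confirmation.

    Three line items; no diversion terms (the radiograph pathway is
    terminal).
    """
    lines = (
        CostLine(
            "CXR by radiology technician",
            "radiology-technician",
            params.time("techTimeA").central,
            params.wage("radiology-technician").central,
        ),
        CostLine(
            "CXR review by bedside MD",
            "bedside-physician",
            params.time("mdTimeA").central,
            params.wage("bedside-physician").central,
        ),
        CostLine(
            "CXR review by radiologist",
            "radiologist",
            params.time("radiologistRead").central,
            params.wage("radiologist").central,
        ),
    )
    return CostBreakdown(protocol="A", lines=lines)


def cost_protocol_B(
    params: ModelParameters,
    convention: DiversionConvention = DiversionConvention.SEQUENTIAL,
) -> CostBreakdown:
    """Expected per-patient labor cost of ultrasound-based confirmation.

    Two base line items plus diversion terms: a diverted patient incurs
    the full protocol-A cost in addition to the ultrasound time already
    spent.  Under the sequential convention the pneumothorax term is
    weighted by (1 - pMal) * pPtx; under the additive convention by
    pPtx alone.
    """
    convention = DiversionConvention(convention)
    lines = (
        CostLine(
            "POCUS confirmation by bedside MD",
            "bedside-physician",
            params.time("mdTimeB").central,
            params.wage("bedside-physician").central,
        ),
        CostLine(
            "POCUS confirmation assisted by bedside RN",
            "registered-nurse",
            params.time("rnTimeB").central,
            params.wage("registered-nurse").central,
        ),
    )
    a_total = cost_protocol_A(params).total
    p_mal = params.probabilities.pMalposition.central
    p_ptx = params.probabilities.pPneumothorax.central
    div_mal = p_mal * a_total
    if convention is DiversionConvention.SEQUENTIAL:
        div_ptx = (1.0 - p_mal) * p_ptx * a_total
    else:
        div_ptx = p_ptx * a_total
    return CostBreakdown(
        protocol="B",
        lines=lines,
        diversion_malposition=div_mal,
        diversion_pneumothorax=div_ptx,
    )


def incremental_result(
    params: ModelParameters,
    convention: DiversionConvention = DiversionConvention.SEQUENTIAL,
) -> IncrementalResult:
    """Cost of each protocol and the (full-precision) savings A - B."""
    return IncrementalResult(
        cost_a=cost_protocol_A(params).total,
        cost_b=cost_protocol_B(params, convention).total,
    )


def diversion_probability(
    probs: ComplicationProbabilities,
    convention: DiversionConvention = DiversionConvention.SEQUENTIAL,
) -> float:
    """Overall probability that an ultrasound-protocol patient is
    diverted to the radiograph pathway."""
    convention = DiversionConvention(convention)
    p_mal = probs.pMalposition.central
    p_ptx = probs.pPneumothorax.central
    if convention is DiversionConvention.ADDITIVE:
        return p_mal + p_ptx
    return p_mal + (1.0 - p_mal) * p_ptx


def scale_to_population(per_patient: float, n: int) -> float:
    """Annual cost of ``n`` confirmations at ``per_patient`` dollars each.

    ``per_patient`` must be the full-precision value, not a
    cent-rounded display value; the reporter rounds the product.
    """
    if n < 0:
        raise ValueError(f"population count must be non-negative, got n={n}")
    return per_patient * n
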