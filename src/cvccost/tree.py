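"""Decision-tree representation and expected-value rollback.

The tree mirrors the model's structure: the radiograph arm is a single
terminal payoff; the ultrasound arm is a chance node with three paths
(no complication, suspected malposition, suspected pneumothorax), the
two complication paths paying the ultrasound base cost plus the full
radiograph cost.  Rollback of the ultrasound arm must agree with the
closed-form expected cost to floating precision — the tree is the
independent route to the same number, not a reparameterization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple, Union

from .model import DiversionConvention, cost_protocol_A, cost_protocol_B
from .parameters import ModelParameters

PROB_SUM_TOL = 1e-9


@dataclass(frozen=True)
class TerminalNode:
    label: str
    payoff: float


@dataclass(frozen=True)
class ChanceNode:
    label: str
    branches: Tuple[Tuple[float, "Node"], ...]

    def __post_init__(self) -> None:
        for p, _ in self.branches:
            if not (0.0 <= p <= 1.0):
                raise ValueError(
                    f"chance node {self.label!r} has branch probability {p} outside [0, 1]"
                )


Node = Union[TerminalNode, ChanceNode]


@dataclass(frozen=True)
class DecisionTree:
    """Two-armed decision: radiograph (A) vs ultrasound (B) confirmation."""

    protocol_a: Node
    protocol_b: Node


def build_decision_tree(
    params: ModelParameters,
    convention: DiversionConvention = DiversionConvention.SEQUENTIAL,
) -> DecisionTree:
    """Build the two-arm confirmation tree from a parameter set."""
    convention = DiversionConvention(convention)
    a_total = cost_protocol_A(params).total
    b_base = cost_protocol_B(params, convention).base_cost
    p_mal = params.probabilities.pMalposition.central
    p_ptx = params.probabilities.pPneumothorax.central
    if convention is DiversionConvention.SEQUENTIAL:
        w_ptx = (1.0 - p_mal) * p_ptx
    else:
        w_ptx = p_ptx
    w_clear = 1.0 - p_mal - w_ptx
    branches = (
        (w_clear, TerminalNode("no complication suspected", b_base)),
        (p_mal, TerminalNode("malposition suspected -> divert to CXR", b_base + a_total)),
        (w_ptx, TerminalNode("pneumothorax suspected -> divert to CXR", b_base + a_total)),
    )
    return DecisionTree(
        protocol_a=TerminalNode("CXR confirmation", a_total),
        protocol_b=ChanceNode("POCUS confirmation", branches),
    )


def rollback(node: Node) -> float:
    """Expected payoff of a (sub)tree.

    Terminal nodes return their payoff; chance nodes return the
    probability-weighted sum of their children's rollbacks.  Branch
    probabilities must sum to 1 within 1e-9.
    """
    if isinstance(node, TerminalNode):
        return node.payoff
    total_p = sum(p for p, _ in node.branches)
    if abs(total_p - 1.0) > PROB_SUM_TOL:
        raise ValueError(
            f"branch probabilities of chance node {node.label!r} sum to "
            f"{total_p!r}, expected 1 within {PROB_SUM_TOL}"
        )
    return sum(p * rollback(child) for p, child in node.branches)
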