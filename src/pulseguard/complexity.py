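"""Analytic forward-pass cost estimation for the five network families.

Costs are expressed in FLOPs with the convention 1 multiply-accumulate =
1 FLOP.  The order-level estimator assigns

* ``L x V_dim^2``            to the fully connected and LSTM families,
* ``L x V_dim^2 x k_size``   to the convolutional families (WaveNet,
  WaveNet+LSTM, ResNet+LSTM),

where L is the layer count and V_dim the representation width.  Because
the width enters quadratically, doubling the input dimensionality (PPG ->
PPG+ECG, with widths scaled accordingly) multiplies the cost by ~4.
Activation and pooling costs are ignored at the order level and can be
included in the exact per-model count behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

from .architectures import FAMILIES, Model
from .errors import ConfigurationError

__all__ = ["CostEstimate", "estimate_cost", "count_model_cost"]

_ORDER_QUADRATIC = ("fully_connected", "lstm")
_ORDER_KERNEL = ("wavenet", "wavenet_lstm", "resnet_lstm")


@dataclass
class CostEstimate:
    flops: float
    order: str
    breakdown: List[Tuple[str, float]] = field(default_factory=list)

    def __post_init__(self):
        total = sum(v for _, v in self.breakdown)
        if self.breakdown and abs(total - self.flops) > 1e-9 * max(1.0, total):
            raise ConfigurationError(
                "CostEstimate.flops must equal the sum of its breakdown")


def estimate_cost(family: str, L: int, V_dim: int, k_size: int = 1) -> CostEstimate:
    """Order-level cost of an ``L``-layer network of width ``V_dim``."""
    if family not in FAMILIES:
        raise ConfigurationError(
            f"unknown family '{family}'; expected one of {FAMILIES}")
    if L < 1 or V_dim < 1 or k_size < 1:
        raise ConfigurationError("L, V_dim and k_size must all be >= 1")
    if family in _ORDER_QUADRATIC:
        per_layer = float(V_dim) ** 2
        order = "O(L × V_dim^2)"
    else:
        per_layer = float(V_dim) ** 2 * k_size
        order = "O(L × V_dim^2 × k_size)"
    breakdown = [(f"layer{i + 1}", per_layer) for i in range(L)]
    return CostEstimate(flops=per_layer * L, order=order, breakdown=breakdown)


def count_model_cost(model: Model, include_activations: bool = False) -> CostEstimate:
    """Exact per-layer MAC count of a built model's forward pass.

    With ``include_activations`` the (order-irrelevant) elementwise
    activation and pooling comparisons are added as one entry.
    """
    breakdown = [(name, float(macs)) for name, macs in model.cost_breakdown()]
    if include_activations:
        extra = 0.0
        for conv in model._conv_layers:
            length = conv.length if conv.length is not None else 1
            extra += conv.out_ch * length        # ReLU passes
        for pool in model._pool_layers:
            extra += model.width * model.spec.window_len  # comparisons
        breakdown.append(("activations_and_pools", extra))
    family = model.spec.family
    order = ("O(L × V_dim^2)" if family in _ORDER_QUADRATIC
             else "O(L × V_dim^2 × k_size)")
    return CostEstimate(flops=sum(v for _, v in breakdown), order=order,
                        breakdown=breakdown)
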