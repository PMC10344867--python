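"""Event-table gating for flow-cytometry-style readouts.

Gates are explicit conjunctions of per-channel threshold predicates; the
vendor-software interactive gating they replace is parameterized instead.
Three readouts: generic gate fractions, the dual-reporter lipophagy
fraction (GFP-low AND mCherry-retained), and a surface-marker positive
fraction thresholded at a percentile of a negative control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_data import FlowEvents


@dataclass(frozen=True)
class GatePredicate:
    """Single-channel predicate: intensity above/below a threshold."""

    channel: str
    op: str  # "above" (>=) or "below" (<)
    threshold: float
    log10: bool = False

    def __post_init__(self) -> None:
        if self.op not in ("above", "below"):
            raise ValueError("op must be 'above' or 'below'")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def evaluate(self, events: FlowEvents) -> np.ndarray:
        if self.channel not in events.channels:
            raise KeyError(
                f"channel {self.channel!r} not in events (have {events.channels})"
            )
        x = events.data[self.channel].to_numpy(dtype=float)
        thr = self.threshold
        if self.log10:
            x = np.log10(x + 1.0)
        return x >= thr if self.op == "above" else x < thr


@dataclass(frozen=True)
class GateSpec:
    """Conjunction of predicates; an event passes iff all predicates pass."""

    predicates: tuple[GatePredicate, ...]

    def __post_init__(self) -> None:
        if len(self.predicates) == 0:
            raise ValueError("GateSpec needs at least one predicate")

    def mask(self, events: FlowEvents) -> np.ndarray:
        out = np.ones(len(events), dtype=bool)
        for pred in self.predicates:
            out &= pred.evaluate(events)
        return out


def gate_fraction(events: FlowEvents, gate: GateSpec) -> float:
    """Fraction of events satisfying every predicate of the gate."""
    if len(events) == 0:
        raise ValueError("empty event table")
    return float(gate.mask(events).mean())


def lipophagy_positive_fraction(
    events: FlowEvents, gfp_cut: float, mcherry_cut: float
) -> float:
    """Fraction with GFP < gfp_cut and mCherry >= mcherry_cut.

    GFP quenches at lysosomal pH while mCherry persists, so this fraction
    reads out reporter delivery to acidic compartments.
    """
    gate = GateSpec(
        (
            GatePredicate("GFP", "below", gfp_cut),
            GatePredicate("mCherry", "above", mcherry_cut),
        )
    )
    return gate_fraction(events, gate)


def surface_positive_fraction(
    events: FlowEvents,
    negative_control: FlowEvents,
    channel: str,
    percentile: float = 99.0,
) -> float:
    """Fraction of sample events above a negative-control percentile.

    The threshold is the stated percentile of the negative control's
    channel; events strictly above it count as positive.
    """
    if len(events) == 0 or len(negative_control) == 0:
        raise ValueError("empty event table")
    if not (0 <= percentile <= 100):
        raise ValueError("percentile must be in [0, 100]")
    for tbl, name in ((events, "sample"), (negative_control, "negative control")):
        if channel not in tbl.channels:
            raise KeyError(f"channel {channel!r} not in {name} events")
    threshold = float(
        np.percentile(negative_control.data[channel].to_numpy(dtype=float), percentile)
    )
    x = events.data[channel].to_numpy(dtype=float)
    return float((x > threshold).mean())
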