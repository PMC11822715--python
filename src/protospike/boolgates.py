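"""Boolean-logic encoding of analog potential traces.

Each sample is thresholded into two binary channels — ``high`` (potential
strictly above +2 mV by default) and ``low`` (strictly below -2 mV) —
and the seven classic gates are evaluated row-wise on the (high, low)
pair.  NOT is unary and applied to the high state.  Values exactly at a
threshold yield state 0 (the states require the potential to *exceed*
or *fall below* the threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trace import VoltageTrace

GATE_COLUMNS = ["time", "high", "low", "AND", "OR", "XOR", "NOT", "NAND", "NOR", "XNOR"]


@dataclass(frozen=True)
class ThresholdConfig:
    threshold_high: float = 2.0   # mV
    threshold_low: float = -2.0   # mV

    def __post_init__(self):
        if not self.threshold_high > self.threshold_low:
            raise ValueError("threshold_high must exceed threshold_low")


def threshold_states(trace: VoltageTrace, cfg: ThresholdConfig | None = None):
    """Binary (high, low) state arrays for each sample of a trace.

    high = [v > threshold_high], low = [v < threshold_low]; with
    properly ordered thresholds the two states are mutually exclusive.
    """
    cfg = cfg or ThresholdConfig()
    v = trace.potential
    high = (v > cfg.threshold_high).astype(np.int8)
    low = (v < cfg.threshold_low).astype(np.int8)
    return high, low


_GATES = {
    "AND": lambda x, y: x & y,
    "OR": lambda x, y: x | y,
    "XOR": lambda x, y: x ^ y,
    "NOT": lambda x, y: 1 - x,
    "NAND": lambda x, y: 1 - (x & y),
    "NOR": lambda x, y: 1 - (x | y),
    "XNOR": lambda x, y: 1 - (x ^ y),
}


def gate(x, y, name: str):
    """Evaluate one named gate on bits (y is ignored for NOT)."""
    if name not in _GATES:
        raise ValueError(f"unknown gate {name!r}; choose from {sorted(_GATES)}")
    xa = np.asarray(x, dtype=np.int8)
    ya = np.asarray(y, dtype=np.int8)
    if np.any((xa < 0) | (xa > 1)) or np.any((ya < 0) | (ya > 1)):
        raise ValueError("gate inputs must be bits (0 or 1)")
    out = _GATES[name](xa, ya)
    return int(out) if np.isscalar(x) else out


def gate_table(time, high, low, not_input: str = "high") -> pd.DataFrame:
    """Per-sample outputs of all seven gates on the (high, low) states.

    ``not_input`` selects which state the unary NOT inverts ("high",
    the reported convention, or "low" for exploration).  Returns a
    DataFrame with the canonical column order; the complement
    identities (NAND = 1-AND, NOR = 1-OR, XNOR = 1-XOR) are asserted
    on every emitted table.
    """
    t = np.asarray(time, dtype=float)
    h = np.asarray(high, dtype=np.int8)
    l = np.asarray(low, dtype=np.int8)
    if t.size == 0:
        raise ValueError("empty state series")
    if not (t.size == h.size == l.size):
        raise ValueError("time, high and low must have equal length")
    if not_input not in ("high", "low"):
        raise ValueError("not_input must be 'high' or 'low'")
    not_src = h if not_input == "high" else l
    df = pd.DataFrame({
        "time": t,
        "high": h,
        "low": l,
        "AND": gate(h, l, "AND"),
        "OR": gate(h, l, "OR"),
        "XOR": gate(h, l, "XOR"),
        "NOT": gate(not_src, not_src, "NOT"),
        "NAND": gate(h, l, "NAND"),
        "NOR": gate(h, l, "NOR"),
        "XNOR": gate(h, l, "XNOR"),
    })[GATE_COLUMNS]
    validate_gate_table(df)
    return df


def validate_gate_table(df: pd.DataFrame) -> None:
    """Assert the structural invariants of a gate table."""
    bits = df[GATE_COLUMNS[1:]].to_numpy()
    if not np.isin(bits, (0, 1)).all():
        raise ValueError("gate table entries must be bits")
    if not ((df["NAND"] == 1 - df["AND"]).all()
            and (df["NOR"] == 1 - df["OR"]).all()
            and (df["XNOR"] == 1 - df["XOR"]).all()):
        raise ValueError("complement identities violated")


def boolean_pipeline(trace: VoltageTrace, cfg: ThresholdConfig | None = None,
                     not_input: str = "high") -> pd.DataFrame:
    """Threshold a trace and evaluate the full gate table."""
    high, low = threshold_states(trace, cfg)
    return gate_table(trace.time, high, low, not_input=not_input)
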