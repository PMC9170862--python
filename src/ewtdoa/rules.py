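"""Rule-based anaesthetic-state classification of the depth index.

The four conventional states and their reference index ranges are
AW (awake, 80-100), LA (light, 60-80), MA (moderate, 40-60) and
DA (deep, 0-40).  Rather than reusing those fixed cut-offs, per-state rule
boundaries are *derived from the training data*: for each state the central
80% interval (10th-90th percentile at the default coverage) of the index
values observed during that state's stable periods becomes its
``[lower, upper]`` rule.

Classification assigns a value inside exactly one interval to that state;
values in a gap or overlap go to the nearest interval by boundary distance,
with ties resolved toward the deeper state (the conservative call for
patient safety).  Values outside [0, 100] are UNCLASSIFIED.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import STATES
from .model import IndexTrace

__all__ = ["StateRuleSet", "StateTrace", "derive_rules", "classify_state"]

logger = logging.getLogger(__name__)

UNCLASSIFIED = "UNCLASSIFIED"

# conventional reference index ranges, deepest first
REFERENCE_RANGES = {
    "DA": (0.0, 40.0),
    "MA": (40.0, 60.0),
    "LA": (60.0, 80.0),
    "AW": (80.0, 100.0),
}


@dataclass(frozen=True)
class StateRuleSet:
    """Per-state [lower, upper] index bounds, in 0-100 index units."""

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for s in STATES:
            if s not in self.bounds:
                raise ValueError(f"rule set lacks state {s}")
            lo, hi = self.bounds[s]
            if not lo < hi:
                raise ValueError(f"state {s}: lower bound must be below upper")
        mids = [np.mean(self.bounds[s]) for s in STATES]
        if not all(a < b for a, b in zip(mids, mids[1:])):
            logger.warning(
                "state intervals are not ordered DA < MA < LA < AW by "
                "midpoint: %s",
                self.bounds,
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s, *self.bounds[s]) for s in reversed(STATES)],
            columns=["state", "lower", "upper"],
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "StateRuleSet":
        df = pd.read_csv(path)
        return cls(
            bounds={
                str(r.state): (float(r.lower), float(r.upper))
                for r in df.itertuples()
            }
        )


@dataclass(frozen=True)
class StateTrace:
    """Predicted state per timestamp."""

    t: np.ndarray
    state: np.ndarray  # of str, in {AW, LA, MA, DA, UNCLASSIFIED}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "state": self.state})


def derive_rules(
    index_values: np.ndarray,
    true_states: np.ndarray,
    coverage: float = 0.80,
) -> StateRuleSet:
    """Per-state central ``coverage`` interval of the training index values.

    At the default coverage of 0.80 the bounds are the 10th and 90th
    empirical percentiles of the index values labelled with each state.
    Every state must be represented by at least 20 samples.  Overlapping or
    out-of-order intervals are returned as-is (with a warning) — they are a
    property of the data, not something to correct silently.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    v = np.asarray(index_values, dtype=float)
    s = np.asarray(true_states)
    if v.shape != s.shape:
        raise ValueError("index_values and true_states must align")
    tail = 100.0 * (1.0 - coverage) / 2.0
    bounds = {}
    for state in STATES:
        vals = v[s == state]
        if vals.size < 20:
            raise ValueError(
                f"state {state} has only {vals.size} training samples (need >= 20)"
            )
        bounds[state] = (
            float(np.percentile(vals, tail)),
            float(np.percentile(vals, 100.0 - tail)),
        )
    return StateRuleSet(bounds=bounds)


def classify_state(rules: StateRuleSet, trace: IndexTrace) -> StateTrace:
    """Classify each index value into a state under the rule set.

    Values inside exactly one interval take that state; gap/overlap values
    go to the nearest interval (distance to the closer boundary), ties to
    the deeper state; values beyond [0, 100] (or missing) are UNCLASSIFIED.
    """
    out = np.empty(trace.value.size, dtype=object)
    for i, val in enumerate(trace.value):
        out[i] = _classify_value(rules, val)
    return StateTrace(t=trace.t.copy(), state=out)


def _classify_value(rules: StateRuleSet, val: float) -> str:
    if not np.isfinite(val) or val < 0.0 or val > 100.0:
        return UNCLASSIFIED
    inside = [
        s for s in STATES if rules.bounds[s][0] <= val <= rules.bounds[s][1]
    ]
    if len(inside) == 1:
        return inside[0]
    # gap (0 hits) or overlap (>1): nearest interval; STATES runs deepest
    # first, and min() keeps the earliest minimiser, i.e. the deeper state.
    candidates = inside if inside else list(STATES)
    return min(
        candidates,
        key=lambda s: max(rules.bounds[s][0] - val, val - rules.bounds[s][1], 0.0),
    )


def states_from_depth(depth: np.ndarray) -> np.ndarray:
    """Map depth values to states by the conventional reference ranges."""
    d = np.asarray(depth, dtype=float)
    out = np.empty(d.size, dtype=object)
    for s, (lo, hi) in REFERENCE_RANGES.items():
        mask = (d >= lo) & (d < hi) if s != "AW" else (d >= lo) & (d <= hi)
        out[mask] = s
    return out
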