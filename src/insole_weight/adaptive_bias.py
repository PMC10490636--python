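"""Adaptive additive bias correction for zero-inflated sensor channels.

Insole channels frequently read exactly 0 when a participant's posture or
shoe keeps load off a sensor.  Feeding such streams to a regressor breaks
the positive force/pressure-vs-weight relationship the model depends on.
The correction computed here is additive, per feature and per weight-class
index: for feature ``j`` the smallest strictly positive sample observed at
the heaviest carried weight (falling back to the next-heaviest weight until
one exists) defines a scale ``m_j``, and the bias applied at weight-class
index ``i`` (1-based position in the sorted weight list, length ``L``) is

    B[j][i] = m_j * i / L

so the offset grows linearly with the carried-weight index.  Two
application modes exist: ZRAB adds the bias only where a sample is exactly
0; FAB adds it to every sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd


class BiasMode(str, Enum):
    NONE = "none"
    ZRAB = "zrab"  # zero-reading adaptive bias
    FAB = "fab"    # full adaptive bias


class AllZeroFeatureError(ValueError):
    """A feature is zero across every weight's recordings."""


@dataclass(frozen=True)
class WeightClass:
    """Ordered set of carried weights (lbs) in a participant's protocol."""

    weights: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("weight class must be non-empty")
        if self.weights[0] != 0:
            raise ValueError("weight class must start at 0 lbs (no carried weight)")
        if any(b <= a for a, b in zip(self.weights, self.weights[1:])):
            raise ValueError("weight class must be strictly increasing")

    def __len__(self) -> int:
        return len(self.weights)

    def index_of(self, carried_weight: int) -> int:
        """1-based index of ``carried_weight`` in the sorted class."""
        try:
            return self.weights.index(carried_weight) + 1
        except ValueError:
            raise KeyError(
                f"{carried_weight} lbs is not in weight class {self.weights}"
            ) from None


@dataclass
class BiasTable:
    """Per-feature bias scales and the weight whose recordings supplied each."""

    weight_class: WeightClass
    minima: dict[str, float]          # m_j per feature
    source_weight: dict[str, int]     # carried weight whose data gave m_j

    @property
    def features(self) -> list[str]:
        return list(self.minima)

    def bias(self, feature: str, index: int) -> float:
        """B[j][i] = m_j * i / L for 1-based weight-class index ``i``."""
        if not 1 <= index <= len(self.weight_class):
            raise IndexError(f"weight-class index {index} out of range 1..{len(self.weight_class)}")
        return self.minima[feature] * index / len(self.weight_class)

    def bias_vector(self, index: int) -> pd.Series:
        return pd.Series(
            {f: self.bias(f, index) for f in self.minima}, dtype=float
        )

    def as_frame(self) -> pd.DataFrame:
        """Full B[j][i] table, features as rows, weight-class indices as columns."""
        idx = range(1, len(self.weight_class) + 1)
        return pd.DataFrame(
            {i: [self.bias(f, i) for f in self.minima] for i in idx},
            index=list(self.minima),
        )


def compute_bias(
    samples_by_weight: Mapping[int, pd.DataFrame],
    weight_class: WeightClass,
    on_all_zero: str = "error",
) -> BiasTable:
    """Derive the bias table from per-weight sample pools.

    ``samples_by_weight`` maps each carried weight in the class to a frame
    of per-sample feature values (all frames must share their columns; pool
    multiple recordings for a weight by concatenation before calling).

    For each feature the scale is the minimum strictly positive sample at
    the maximum weight; when a feature is all-zero there, the search falls
    back to the next-highest weight and repeats until a positive minimum is
    found.  A feature that is zero everywhere raises
    :class:`AllZeroFeatureError` (``on_all_zero="error"``) or gets a zero
    bias with a warning (``on_all_zero="zero"``).
    """
    if on_all_zero not in {"error", "zero"}:
        raise ValueError("on_all_zero must be 'error' or 'zero'")
    missing = [w for w in weight_class.weights if w not in samples_by_weight]
    if missing:
        raise ValueError(f"missing sample pools for weights {missing}")

    features = list(next(iter(samples_by_weight.values())).columns)
    for w, df in samples_by_weight.items():
        if list(df.columns) != features:
            raise ValueError(f"feature columns for weight {w} differ from the rest")

    minima: dict[str, float] = {}
    source: dict[str, int] = {}
    for feat in features:
        for w in sorted(weight_class.weights, reverse=True):
            vals = samples_by_weight[w][feat].to_numpy()
            positive = vals[vals > 0]
            if positive.size:
                minima[feat] = float(positive.min())
                source[feat] = w
                break
        else:
            if on_all_zero == "error":
                raise AllZeroFeatureError(
                    f"feature {feat!r} is zero across all weight classes"
                )
            warnings.warn(
                f"feature {feat!r} is zero across all weight classes; bias set to 0",
                stacklevel=2,
            )
            minima[feat] = 0.0
            source[feat] = weight_class.weights[-1]
    return BiasTable(weight_class=weight_class, minima=minima, source_weight=source)


def apply_bias(
    features: pd.DataFrame,
    table: BiasTable | None,
    carried_weight: int,
    mode: BiasMode | str,
) -> pd.DataFrame:
    """Apply the additive correction to a frame of per-sample features.

    NONE returns a copy unchanged; FAB adds B[j][i] to every sample of
    feature j; ZRAB adds it only where the sample is exactly 0.  The result
    carries an ``attrs["bias_applied"]`` flag, and re-applying to an
    already-corrected frame raises — the correction must happen exactly once.
    """
    mode = BiasMode(mode)
    if features.attrs.get("bias_applied") not in (None, BiasMode.NONE.value):
        raise ValueError(
            f"bias already applied (mode={features.attrs['bias_applied']!r}); "
            "refusing to correct twice"
        )
    out = features.copy()
    if mode is not BiasMode.NONE:
        if table is None:
            raise ValueError(f"mode {mode.value!r} requires a bias table")
        index = table.weight_class.index_of(carried_weight)
        b = table.bias_vector(index)
        extra = set(b.index) - set(out.columns)
        if extra:
            raise ValueError(f"bias table has features absent from input: {sorted(extra)}")
        cols = list(b.index)
        if mode is BiasMode.FAB:
            out[cols] = out[cols] + b
        else:  # ZRAB: exact zeros only — no epsilon band
            block = out[cols]
            out[cols] = block.mask(block == 0.0, b, axis=1)
    out.attrs["bias_applied"] = mode.value
    return out
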