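"""Dynamic windowing, alpha-trimmed aggregation, and feature-matrix assembly.

Recording lengths vary between weights and participants, so a fixed window
size would yield unbalanced instance counts.  Window geometry is instead
derived from the sequence length ``L_data`` and two user parameters — the
sample-length divisor ``L_samples`` and the initial overlap rate
``olap_init``:

    win_init = L_data / L_samples
    olap_new = olap_init * win_init
    win_new  = (L_data + olap_new * win_init) / L_samples

Windows of ``round(win_new)`` samples slide with stride
``round(win_new) - round(olap_new)`` (floored at 1); a trailing partial
window is dropped.  Each window of each channel is collapsed to a single
value by the alpha-trimmed mean, which discards ``k = floor(alpha*n/100)``
samples from each end of the sorted window (``alpha=0`` is the arithmetic
mean, ``alpha=50`` the median).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import schema
from .adaptive_bias import BiasMode, BiasTable, apply_bias
from .moticon_io import SensorRecording

#: Provenance columns carried alongside the 40 model features.
PROVENANCE_COLUMNS = ("participant", "iteration", "carried_weight", "window_index")
LABEL_COLUMN = "total_weight"


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class WindowPlan:
    """Derived window geometry for one recording."""

    l_data: int
    l_samples: int
    olap_init: float
    win_init: float
    olap_new: float
    win_new: float
    window_length: int
    stride: int
    bounds: tuple[tuple[int, int], ...]  # half-open [start, end) sample intervals

    @property
    def n_windows(self) -> int:
        return len(self.bounds)


def plan_windows(l_data: int, l_samples: int, olap_init: float) -> WindowPlan:
    """Compute the dynamic window geometry and materialize window bounds.

    Requires ``l_samples >= 1`` and ``0 <= olap_init < 1``.  A sequence
    shorter than ``l_samples`` degrades to a single full-length window with
    a warning.
    """
    if l_samples < 1:
        raise ValueError("l_samples must be >= 1")
    if not 0 <= olap_init < 1:
        raise ValueError("olap_init must be in [0, 1)")
    if l_data < 1:
        raise ValueError("l_data must be >= 1")
    if l_data < l_samples:
        warnings.warn(
            f"sequence of {l_data} samples is shorter than l_samples={l_samples}; "
            "using a single full-sequence window",
            stacklevel=2,
        )
        return WindowPlan(l_data, l_samples, olap_init, win_init=1.0, olap_new=0.0,
                          win_new=float(l_data), window_length=l_data, stride=l_data,
                          bounds=((0, l_data),))

    win_init = l_data / l_samples
    olap_new = olap_init * win_init
    win_new = (l_data + olap_new * win_init) / l_samples

    window_length = max(1, _round_half_up(win_new))
    overlap = _round_half_up(olap_new)
    stride = max(1, window_length - overlap)

    bounds = tuple(
        (start, start + window_length)
        for start in range(0, l_data - window_length + 1, stride)
    )
    return WindowPlan(l_data, l_samples, olap_init, win_init, olap_new, win_new,
                      window_length, stride, bounds)


def trim_count(n: int, alpha: float) -> int:
    """Samples trimmed from each end: k = floor(alpha*n/100), capped so at
    least one sample survives."""
    if not 0 <= alpha <= 50:
        raise ValueError("alpha must be in [0, 50]")
    k = int(alpha * n / 100)
    if 2 * k >= n:
        k = (n - 1) // 2
    return k


def trimmed_mean(values: Sequence[float] | np.ndarray, alpha: float) -> float:
    """Alpha-trimmed mean: sort, drop ``k`` from each end, average the rest.

    ``alpha=0`` reduces to the arithmetic mean; ``alpha=50`` reduces to the
    median (for even lengths the cap on ``k`` leaves the middle two values).
    """
    arr = np.sort(np.asarray(values, dtype=float))
    n = arr.size
    if n == 0:
        raise ValueError("trimmed_mean of an empty sequence")
    k = trim_count(n, alpha)
    return float(arr[k:n - k].mean())


def _window_aggregate(block: np.ndarray, alpha: float) -> np.ndarray:
    """Column-wise trimmed mean of a (window_length, n_features) block."""
    n = block.shape[0]
    k = trim_count(n, alpha)
    srt = np.sort(block, axis=0)
    return srt[k:n - k].mean(axis=0)


def synthesize_features(raw: pd.DataFrame) -> pd.DataFrame:
    """Extend 34 aggregated raw channels to the 40-feature model schema.

    Appends the left/right/combined pressure sums, the combined per-sensor
    pressure average, and the combined total-force sum and average.
    """
    missing = set(schema.RAW_MODEL_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(f"missing raw feature columns: {sorted(missing)}")
    out = raw.copy()
    left_p = [c for c in schema.PRESSURE_COLUMNS if c.startswith("left_")]
    right_p = [c for c in schema.PRESSURE_COLUMNS if c.startswith("right_")]
    out["left_pressure_sum"] = raw[left_p].sum(axis=1)
    out["right_pressure_sum"] = raw[right_p].sum(axis=1)
    out["pressure_sum"] = out["left_pressure_sum"] + out["right_pressure_sum"]
    out["pressure_avg"] = out["pressure_sum"] / len(schema.PRESSURE_COLUMNS)
    out["force_sum"] = raw["left_total_force"] + raw["right_total_force"]
    out["force_avg"] = out["force_sum"] / 2.0
    return out


def windowed_features_for_recording(
    recording: SensorRecording,
    bias_table: BiasTable | None,
    mode: BiasMode | str,
    l_samples: int,
    olap_init: float,
    alpha: float,
) -> pd.DataFrame:
    """Correct, window, and aggregate one recording into 40-feature rows."""
    raw = recording.data[list(schema.RAW_MODEL_COLUMNS)]
    corrected = apply_bias(raw, bias_table, recording.key.carried_weight, mode)
    plan = plan_windows(len(corrected), l_samples, olap_init)
    arr = corrected.to_numpy()
    rows = np.stack([_window_aggregate(arr[s:e], alpha) for s, e in plan.bounds])
    agg = pd.DataFrame(rows, columns=list(schema.RAW_MODEL_COLUMNS))
    feats = synthesize_features(agg)
    feats[PROVENANCE_COLUMNS[1]] = recording.key.iteration
    feats[PROVENANCE_COLUMNS[2]] = recording.key.carried_weight
    feats[PROVENANCE_COLUMNS[3]] = np.arange(plan.n_windows)
    return feats


def build_feature_matrix(
    recordings: Iterable[SensorRecording],
    bias_table: BiasTable | None,
    mode: BiasMode | str,
    l_samples: int,
    olap_init: float,
    alpha: float,
    body_weight: float,
    participant_id: str | None = None,
) -> pd.DataFrame:
    """Assemble the labeled per-window feature matrix for one participant.

    One row per window per recording; the label is the participant's body
    weight plus the recording's carried dumbbell weight (lbs).  Empty
    recordings are skipped with a warning.
    """
    frames = []
    for rec in recordings:
        if rec.n_samples == 0:
            warnings.warn(f"empty recording {rec.key.filename()} skipped", stacklevel=2)
            continue
        feats = windowed_features_for_recording(
            rec, bias_table, mode, l_samples, olap_init, alpha
        )
        feats[LABEL_COLUMN] = body_weight + rec.key.carried_weight
        feats[PROVENANCE_COLUMNS[0]] = participant_id or rec.participant_id or ""
        frames.append(feats)
    if not frames:
        raise ValueError("no usable recordings; feature matrix would be empty")
    matrix = pd.concat(frames, ignore_index=True)
    cols = list(schema.MODEL_COLUMNS) + [LABEL_COLUMN, *PROVENANCE_COLUMNS]
    matrix = matrix[cols]
    if matrix[list(schema.MODEL_COLUMNS)].isna().to_numpy().any():
        raise ValueError("feature matrix contains missing values")
    return matrix
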