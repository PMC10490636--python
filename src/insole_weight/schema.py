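"""Canonical column schema for insole sensor recordings.

Each recording is a timestamped table with 51 columns: a time stamp plus,
per foot, 16 pressure channels (N/cm^2), a 3-axis accelerometer (g), a
3-axis gyroscope (dps), center-of-pressure x/y (fractions of insole
length/width), and the total force (N).

The exact column order of vendor text exports is not standardized; this
module fixes the package's canonical order.  Loaders accept files with a
header in any column order, or headerless files in this canonical order.
"""

from __future__ import annotations

FEET = ("left", "right")
N_PRESSURE_SENSORS = 16

TIME_COLUMN = "time"


def _foot_columns(side: str) -> list[str]:
    cols = [f"{side}_pressure_{i:02d}" for i in range(1, N_PRESSURE_SENSORS + 1)]
    cols += [f"{side}_acc_{ax}" for ax in "xyz"]
    cols += [f"{side}_gyro_{ax}" for ax in "xyz"]
    cols += [f"{side}_cop_x", f"{side}_cop_y"]
    cols += [f"{side}_total_force"]
    return cols


#: Canonical 51-column order: time stamp, then all left-foot channels,
#: then all right-foot channels.
COLUMNS: tuple[str, ...] = (TIME_COLUMN, *_foot_columns("left"), *_foot_columns("right"))

N_COLUMNS = len(COLUMNS)  # 51

#: The 32 per-sensor pressure channels (left then right).
PRESSURE_COLUMNS: tuple[str, ...] = tuple(
    c for side in FEET for c in COLUMNS if c.startswith(f"{side}_pressure_")
)

#: The two per-foot total ground-reaction-force channels.
FORCE_COLUMNS: tuple[str, ...] = ("left_total_force", "right_total_force")

#: The 34 raw channels the weight model consumes (32 pressures + 2 forces).
RAW_MODEL_COLUMNS: tuple[str, ...] = PRESSURE_COLUMNS + FORCE_COLUMNS

#: The 6 columns synthesized from the raw model channels.
SYNTHESIZED_COLUMNS: tuple[str, ...] = (
    "left_pressure_sum",
    "right_pressure_sum",
    "pressure_sum",
    "pressure_avg",
    "force_sum",
    "force_avg",
)

#: Full 40-feature schema of the per-window feature matrix.
MODEL_COLUMNS: tuple[str, ...] = RAW_MODEL_COLUMNS + SYNTHESIZED_COLUMNS

#: Columns that must be non-negative in any valid recording.
NON_NEGATIVE_COLUMNS: tuple[str, ...] = PRESSURE_COLUMNS + FORCE_COLUMNS

assert N_COLUMNS == 51
assert len(RAW_MODEL_COLUMNS) == 34
assert len(MODEL_COLUMNS) == 40
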