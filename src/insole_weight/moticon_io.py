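"""Dataset I/O: recording filenames, sensor text files, ground truth, inventory.

The on-disk layout mirrors the study dataset: a setup root containing one
folder per participant, each with activity subfolders (``sitting``,
``standing``, ``walking``) holding delimited text recordings named
``{weight}lbs_{activity}{iteration}.txt`` (the iteration suffix is omitted
for iteration 1).  A ground-truth table (CSV or XLSX) maps participants to
their scale-measured body weight in pounds.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import schema

logger = logging.getLogger(__name__)

ACTIVITIES = ("sitting", "standing", "walking")

_FILENAME_RE = re.compile(
    r"^(?P<weight>\d+)lbs_(?P<activity>[a-z]+?)(?P<iteration>\d+)?\.txt$"
)


class FilenameError(ValueError):
    """Recording filename does not follow ``{w}lbs_{activity}{iter?}.txt``."""


class SchemaError(ValueError):
    """Sensor file violates the 51-column recording schema."""


@dataclass(frozen=True, order=True)
class RecordingKey:
    """Identity of one recording: what was carried, doing what, which repeat."""

    carried_weight: int
    activity: str
    iteration: int = 1

    def __post_init__(self) -> None:
        if self.carried_weight < 0:
            raise ValueError(f"carried_weight must be >= 0, got {self.carried_weight}")
        if self.activity not in ACTIVITIES:
            raise ValueError(f"unknown activity {self.activity!r}; expected one of {ACTIVITIES}")
        if self.iteration < 1:
            raise ValueError(f"iteration must be >= 1, got {self.iteration}")

    def filename(self) -> str:
        suffix = "" if self.iteration == 1 else str(self.iteration)
        return f"{self.carried_weight}lbs_{self.activity}{suffix}.txt"


def parse_filename(name: str) -> RecordingKey:
    """Decode a recording filename into its :class:`RecordingKey`.

    ``"0lbs_sitting.txt"`` is iteration 1 at 0 lbs; ``"11lbs_standing2.txt"``
    is iteration 2 at 11 lbs.  Raises :class:`FilenameError` naming the
    offending field for anything that does not fit the grammar.
    """
    m = _FILENAME_RE.match(name)
    if m is None:
        raise FilenameError(
            f"{name!r} does not match '<int>lbs_<activity>[<int>].txt'"
        )
    activity = m.group("activity")
    if activity not in ACTIVITIES:
        raise FilenameError(f"{name!r}: unknown activity field {activity!r}")
    iteration = int(m.group("iteration")) if m.group("iteration") else 1
    if iteration < 1:
        raise FilenameError(f"{name!r}: iteration field must be >= 1")
    return RecordingKey(int(m.group("weight")), activity, iteration)


@dataclass
class SensorRecording:
    """One validated multichannel stream for a (weight, activity, iteration)."""

    key: RecordingKey
    data: pd.DataFrame  # 51 canonical columns
    sampling_rate: float  # Hz
    participant_id: str | None = None

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        if cols != list(schema.COLUMNS):
            missing = set(schema.COLUMNS) - set(cols)
            extra = set(cols) - set(schema.COLUMNS)
            raise SchemaError(
                f"recording columns do not match canonical schema; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        if len(self.data) < 1:
            raise SchemaError("recording must contain at least one sample")
        ts = self.data[schema.TIME_COLUMN].to_numpy()
        if np.any(np.diff(ts) < 0):
            raise SchemaError("timestamps must be monotone non-decreasing")
        neg = [
            c for c in schema.NON_NEGATIVE_COLUMNS
            if (self.data[c].to_numpy() < 0).any()
        ]
        if neg:
            raise SchemaError(f"negative pressure/force values in columns {neg}")
        if self.sampling_rate <= 0:
            raise SchemaError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def timestamps(self) -> np.ndarray:
        return self.data[schema.TIME_COLUMN].to_numpy()


@dataclass(frozen=True)
class ParticipantGroundTruth:
    participant_id: str
    body_weight: float  # lbs

    def __post_init__(self) -> None:
        if not self.body_weight > 0:
            raise ValueError(f"body_weight must be positive, got {self.body_weight}")


def _infer_sampling_rate(timestamps: np.ndarray) -> float:
    if len(timestamps) < 2:
        return 1.0
    dt = float(np.median(np.diff(timestamps)))
    return 1.0 / dt if dt > 0 else 1.0


def load_recording(
    path: str | Path,
    key: RecordingKey | None = None,
    participant_id: str | None = None,
    sampling_rate: float | None = None,
    column_map: Mapping[str, str] | None = None,
) -> SensorRecording:
    """Load a delimited sensor text file into a validated recording.

    Files may be tab- or whitespace-delimited.  A header row is detected by
    its non-numeric first token; headered files may use any column order
    (optionally renamed through ``column_map``), headerless files must be in
    the canonical :data:`~insole_weight.schema.COLUMNS` order.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    tokens = first.split()
    try:
        float(tokens[0])
        has_header = False
    except (ValueError, IndexError):
        has_header = True

    df = pd.read_csv(path, sep=r"\s+", header=0 if has_header else None)
    if column_map:
        df = df.rename(columns=dict(column_map))
    if not has_header:
        if df.shape[1] != schema.N_COLUMNS:
            raise SchemaError(
                f"{path.name}: expected {schema.N_COLUMNS} columns, found {df.shape[1]}"
            )
        df.columns = list(schema.COLUMNS)
    else:
        if df.shape[1] != schema.N_COLUMNS:
            raise SchemaError(
                f"{path.name}: expected {schema.N_COLUMNS} columns, found {df.shape[1]}"
            )
        try:
            df = df[list(schema.COLUMNS)]
        except KeyError as exc:
            raise SchemaError(f"{path.name}: header missing canonical columns: {exc}")

    bad = df.apply(lambda s: pd.to_numeric(s, errors="coerce")).isna()
    if bad.to_numpy().any():
        row = int(bad.any(axis=1).idxmax())
        raise SchemaError(f"{path.name}: non-numeric value at data row {row}")
    df = df.astype(float)

    if key is None:
        key = parse_filename(path.name)
    if sampling_rate is None:
        sampling_rate = _infer_sampling_rate(df[schema.TIME_COLUMN].to_numpy())
    return SensorRecording(key=key, data=df, sampling_rate=sampling_rate,
                           participant_id=participant_id)


def write_recording(recording: SensorRecording, path: str | Path) -> Path:
    """Write a recording as tab-delimited text with a canonical header.

    Uses full-precision float formatting so that write-then-read round-trips
    value-exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    recording.data.to_csv(path, sep="\t", index=False)
    return path


def load_ground_truth(path: str | Path) -> dict[str, float]:
    """Read a ground-truth body-weight table (CSV or XLSX) into a dict.

    Expects columns ``participant_id`` and ``body_weight_lbs`` (any
    two-column table with those semantics is accepted positionally).
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SchemaError(f"{path.name}: ground-truth table needs >= 2 columns")
    cols = {c.lower(): c for c in df.columns}
    pid_col = cols.get("participant_id", df.columns[0])
    w_col = cols.get("body_weight_lbs", cols.get("body_weight", df.columns[1]))
    out: dict[str, float] = {}
    for _, row in df.iterrows():
        gt = ParticipantGroundTruth(str(row[pid_col]), float(row[w_col]))
        out[gt.participant_id] = gt.body_weight
    return out


@dataclass(frozen=True)
class RecordingRef:
    """Lazy handle on one recording file inside a dataset tree."""

    path: Path
    key: RecordingKey
    participant_id: str

    def load(self, **kwargs) -> SensorRecording:
        return load_recording(self.path, key=self.key,
                              participant_id=self.participant_id, **kwargs)


@dataclass
class DatasetInventory:
    """Nested index participant -> iteration -> carried weight -> recording."""

    recordings: dict[str, dict[int, dict[int, RecordingRef]]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def participants(self) -> list[str]:
        return sorted(self.recordings)

    def iterations(self, participant_id: str) -> list[int]:
        return sorted(self.recordings.get(participant_id, {}))

    def weights(self, participant_id: str, iteration: int) -> list[int]:
        return sorted(self.recordings.get(participant_id, {}).get(iteration, {}))

    def get(self, participant_id: str, iteration: int, weight: int) -> RecordingRef:
        return self.recordings[participant_id][iteration][weight]

    def to_json_dict(self) -> dict:
        return {
            pid: {
                str(it): {str(w): str(ref.path) for w, ref in by_w.items()}
                for it, by_w in by_it.items()
            }
            for pid, by_it in self.recordings.items()
        }


def scan_dataset(
    root_dir: str | Path,
    activities: Iterable[str] = ("standing",),
) -> DatasetInventory:
    """Walk a dataset tree and index every recording matching ``activities``.

    Unknown activity folders, malformed filenames, and duplicate
    (iteration, weight) entries are reported in ``inventory.warnings``
    rather than silently dropped.  An empty root yields an empty inventory
    with a warning.
    """
    root = Path(root_dir)
    activities = set(activities)
    inv = DatasetInventory()
    if not root.is_dir():
        inv.warnings.append(f"dataset root {root} does not exist")
        return inv

    participant_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not participant_dirs:
        inv.warnings.append(f"dataset root {root} contains no participant folders")
        return inv

    for pdir in participant_dirs:
        pid = pdir.name
        for adir in sorted(p for p in pdir.iterdir() if p.is_dir()):
            if adir.name not in ACTIVITIES:
                inv.warnings.append(f"{pid}: unknown activity folder {adir.name!r}, skipped")
                continue
            if adir.name not in activities:
                continue
            for f in sorted(adir.glob("*.txt")):
                try:
                    key = parse_filename(f.name)
                except FilenameError as exc:
                    inv.warnings.append(f"{pid}: {exc}")
                    continue
                if key.activity != adir.name:
                    inv.warnings.append(
                        f"{pid}: file {f.name} activity does not match folder {adir.name}"
                    )
                    continue
                by_it = inv.recordings.setdefault(pid, {})
                by_w = by_it.setdefault(key.iteration, {})
                if key.carried_weight in by_w:
                    inv.warnings.append(
                        f"{pid}: duplicate recording for iteration {key.iteration}, "
                        f"{key.carried_weight} lbs ({f.name} ignored)"
                    )
                    continue
                by_w[key.carried_weight] = RecordingRef(f, key, pid)

    for msg in inv.warnings:
        logger.warning(msg)
    return inv


def select_participants(inventory: DatasetInventory, min_iterations: int = 2) -> list[str]:
    """Return participants eligible for train/test modeling.

    A participant qualifies when they have at least ``min_iterations``
    iterations and every iteration contains a recording for every carried
    weight in the participant's weight class (the union of weights seen
    across their iterations) — i.e. no missing weight files.
    """
    if min_iterations < 2:
        raise ValueError("min_iterations must be >= 2 (need train and test iterations)")
    selected = []
    for pid in inventory.participants:
        iterations = inventory.iterations(pid)
        if len(iterations) < min_iterations:
            continue
        weight_class = set()
        for it in iterations:
            weight_class.update(inventory.weights(pid, it))
        if all(set(inventory.weights(pid, it)) == weight_class for it in iterations):
            selected.append(pid)
    return selected
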