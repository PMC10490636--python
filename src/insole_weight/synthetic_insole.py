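"""Synthetic insole-dataset generator.

Emulates the statistical structure the pipeline assumes, so every
downstream stage is testable without the (private) study recordings:

* total ground-reaction force proportional to body weight + carried weight,
  split across 32 pressure sensors by participant-specific load shares
  (each participant has their own distribution — their "gait pattern");
* per-recording sensor dropouts that read exactly 0, concentrated in
  "unbalanced" participants;
* multiplicative Gaussian noise and sporadic outlier samples;
* multiple experimental iterations per participant, carried-dumbbell
  protocols for both study setups, and the on-disk layout and filename
  grammar of the real dataset.

Everything is reproducible from integer seeds: each recording derives its
own generator from (participant seed, weight index, iteration).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import schema
from .moticon_io import RecordingKey, SensorRecording, write_recording

#: Unit bridge between the lbs ground truth and newton force channels.
LBS_TO_NEWTON = 4.448

#: Nominal contact area per pressure sensor (cm^2); pressure = force / area.
SENSOR_AREA_CM2 = 10.0

#: Carried-weight protocols of the two experimental setups (lbs).
SETUP1_WEIGHTS = tuple(range(0, 13))           # 0..12 lbs
SETUP2_WEIGHTS = (0, 2, 3, 5, 7, 9, 11, 13)    # graded dumbbells


def total_force_newtons(body_weight_lbs: float, carried_weight_lbs: float) -> float:
    """Deterministic two-foot ground-reaction force at quiet standing."""
    return LBS_TO_NEWTON * (body_weight_lbs + carried_weight_lbs)


@dataclass(frozen=True)
class SyntheticParticipantSpec:
    """Everything needed to synthesize one participant's dataset."""

    participant_id: str
    body_weight: float                       # lbs
    weight_class: tuple[int, ...] = SETUP2_WEIGHTS
    n_iterations: int = 2
    sampling_rate: float = 50.0              # Hz
    duration_per_weight: float = 8.0         # seconds
    load_shares: tuple[float, ...] | None = None   # 32 shares summing to 1
    dropout_prob: float = 0.0                # per sensor, per recording
    noise_sd: float = 0.02                   # relative (multiplicative) noise
    drift_sd: float = 0.0                    # per-step sd of shared baseline walk
    drift_reset: int = 60                    # samples between baseline re-zeroing
    outlier_prob: float = 0.0                # per sample row
    outlier_scale: float = 3.0
    burst_prob: float = 0.0                  # per-sample prob a burst starts
    burst_len: int = 30                      # samples per disturbance burst
    burst_scale: float = 0.6                 # load multiplier during a burst
    sway_amp: float = 0.0                    # relative amplitude of sway cycle
    sway_persist: int = 4                    # mean samples between sway flips
    sway_jitter: float = 0.2                 # per-recording amplitude variability
    sway_balance: float = 0.5                # fraction of time in the low phase
    activity: str = "standing"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValueError("body_weight must be positive")
        if self.n_iterations < 2:
            raise ValueError("need n_iterations >= 2 (train + test)")
        if sorted(set(self.weight_class)) != list(self.weight_class) or self.weight_class[0] != 0:
            raise ValueError("weight_class must be strictly increasing and start at 0")
        if self.sampling_rate not in (25.0, 50.0, 25, 50):
            raise ValueError("sampling_rate must be 25 or 50 Hz")
        if self.load_shares is not None:
            shares = np.asarray(self.load_shares, dtype=float)
            if shares.shape != (2 * schema.N_PRESSURE_SENSORS,):
                raise ValueError("load_shares must have 32 entries")
            if (shares < 0).any() or abs(shares.sum() - 1.0) > 1e-9:
                raise ValueError("load_shares must be non-negative and sum to 1")
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout_prob must be in [0, 1]")
        if self.noise_sd < 0 or self.outlier_prob < 0 or self.outlier_scale <= 0:
            raise ValueError("noise/outlier parameters must be non-negative")
        if self.drift_sd < 0 or self.drift_reset < 1:
            raise ValueError("drift_sd must be >= 0 and drift_reset >= 1")
        if not 0 <= self.burst_prob <= 1 or self.burst_len < 1 or self.burst_scale <= 0:
            raise ValueError("invalid burst parameters")
        if self.sway_amp < 0 or self.sway_persist < 1 or self.sway_jitter < 0:
            raise ValueError("sway parameters must be non-negative (persist >= 1)")
        if not 0 < self.sway_balance < 1:
            raise ValueError("sway_balance must be in (0, 1)")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_per_weight * self.sampling_rate))

    def resolved_shares(self) -> np.ndarray:
        if self.load_shares is not None:
            return np.asarray(self.load_shares, dtype=float)
        n = 2 * schema.N_PRESSURE_SENSORS
        return np.full(n, 1.0 / n)


def _baseline_drift(rng: np.random.Generator, n: int, drift_sd: float, reset: int
                    ) -> np.ndarray:
    """Shared baseline wander: a random walk re-zeroed every ``reset`` samples.

    Models slow load shifting between the sensor auto-zero corrections the
    insole firmware applies: within each segment the relative baseline
    accumulates a random walk with per-step sd ``drift_sd``, then snaps back
    to 0.  The same offset multiplies every sensor.  Because a random walk's
    window mean has variance growing with the window length, aggregating
    over larger windows does NOT average this component away — larger
    windows carry more baseline noise.
    """
    if drift_sd == 0:
        return np.zeros(n)
    steps = rng.normal(0.0, drift_sd, size=n)
    drift = np.empty(n)
    for start in range(0, n, reset):
        stop = min(start + reset, n)
        drift[start:stop] = np.cumsum(steps[start:stop])
    return drift


def _sway(rng: np.random.Generator, n: int, amp: float, persist: int,
          jitter: float, balance: float) -> np.ndarray:
    """Postural-sway load oscillation: a zero-mean two-state lean cycle.

    Quiet standing is not static — the body sways, and the vertical
    center-of-mass acceleration makes the measured ground-reaction force
    oscillate around its static value.  Modeled as a Markov two-state
    process: a "low" phase at ``-amp`` occupied a ``balance`` fraction of
    the time and a "high" phase at ``+amp*balance/(1-balance)`` (so the
    cycle is zero-mean even when dwell times are unequal), with mean phase
    length ~``persist`` samples; the same factor multiplies every sensor.
    The amplitude differs from recording to recording (``jitter`` — people
    sway more on some days), so the per-sample force distribution is
    bimodal with modes that move between recordings: aggregators that track
    an order statistic instead of averaging over the whole cycle inherit
    that variability, while plain or lightly-trimmed means cancel it.
    """
    if amp == 0:
        return np.zeros(n)
    amp = amp * max(0.0, 1.0 + jitter * rng.normal())
    low, high = -amp, amp * balance / (1.0 - balance)
    # transition probs giving stationary occupancy `balance` in the low state
    p_low_to_high = 2.0 * (1.0 - balance) / persist
    p_high_to_low = 2.0 * balance / persist
    u = rng.random(n)
    in_low = rng.random() < balance
    out = np.empty(n)
    for t in range(n):
        if in_low:
            if u[t] < p_low_to_high:
                in_low = False
        else:
            if u[t] < p_high_to_low:
                in_low = True
        out[t] = low if in_low else high
    return out


def _recording_rng(spec: SyntheticParticipantSpec, weight_index: int, iteration: int
                   ) -> np.random.Generator:
    seq = np.random.SeedSequence(spec.seed, spawn_key=(weight_index, iteration))
    return np.random.default_rng(seq)


def generate_recording(
    spec: SyntheticParticipantSpec, carried_weight: int, iteration: int
) -> SensorRecording:
    """Synthesize one recording for (carried weight, iteration).

    Per-sensor forces are the participant's load shares times the total
    ground-reaction force; dropped-out sensors emit exactly 0 for the whole
    recording; each sample gets multiplicative noise and, with
    ``outlier_prob``, a whole-row outlier multiplication.  Per-foot total
    force is the row sum of that foot's (possibly corrupted) sensor forces,
    and pressure is sensor force over the nominal contact area.
    """
    if carried_weight not in spec.weight_class:
        raise ValueError(f"{carried_weight} lbs is not in this spec's weight class")
    weight_index = spec.weight_class.index(carried_weight)
    rng = _recording_rng(spec, weight_index, iteration)

    n = spec.n_samples
    n_sensors = 2 * schema.N_PRESSURE_SENSORS
    f_total = total_force_newtons(spec.body_weight, carried_weight)
    base = spec.resolved_shares() * f_total                     # (32,)

    dropped = rng.random(n_sensors) < spec.dropout_prob         # per recording
    forces = np.tile(base, (n, 1))
    forces *= 1.0 + _baseline_drift(rng, n, spec.drift_sd, spec.drift_reset)[:, None]
    forces *= 1.0 + _sway(rng, n, spec.sway_amp, spec.sway_persist,
                          spec.sway_jitter, spec.sway_balance)[:, None]
    forces *= 1.0 + rng.normal(0.0, spec.noise_sd, size=(n, n_sensors))
    outlier_rows = rng.random(n) < spec.outlier_prob
    forces[outlier_rows] *= spec.outlier_scale
    # transient posture-shift bursts: contiguous stretches of off-baseline load
    burst_starts = np.flatnonzero(rng.random(n) < spec.burst_prob)
    for start in burst_starts:
        forces[start:start + spec.burst_len] *= spec.burst_scale
    forces = np.clip(forces, 0.0, None)
    forces[:, dropped] = 0.0

    left = forces[:, : schema.N_PRESSURE_SENSORS]
    right = forces[:, schema.N_PRESSURE_SENSORS:]

    data = pd.DataFrame(index=range(n), columns=list(schema.COLUMNS), dtype=float)
    data[schema.TIME_COLUMN] = np.arange(n) / spec.sampling_rate
    for side, block in (("left", left), ("right", right)):
        for s in range(schema.N_PRESSURE_SENSORS):
            data[f"{side}_pressure_{s + 1:02d}"] = block[:, s] / SENSOR_AREA_CM2
        data[f"{side}_total_force"] = block.sum(axis=1)
        # IMU and CoP: stationary noise around quiet-standing constants;
        # carried through I/O but unused by the weight model.
        data[f"{side}_acc_x"] = rng.normal(0.0, 0.02, n)
        data[f"{side}_acc_y"] = rng.normal(0.0, 0.02, n)
        data[f"{side}_acc_z"] = rng.normal(1.0, 0.02, n)
        for ax in "xyz":
            data[f"{side}_gyro_{ax}"] = rng.normal(0.0, 0.5, n)
        data[f"{side}_cop_x"] = np.clip(rng.normal(0.5, 0.02, n), 0.0, 1.0)
        data[f"{side}_cop_y"] = np.clip(rng.normal(0.5, 0.02, n), 0.0, 1.0)

    key = RecordingKey(carried_weight, spec.activity, iteration)
    return SensorRecording(key=key, data=data, sampling_rate=float(spec.sampling_rate),
                           participant_id=spec.participant_id)


def generate_participant(spec: SyntheticParticipantSpec, out_dir: str | Path) -> list[Path]:
    """Write the participant's full dataset tree; returns the file paths.

    Layout: ``out_dir/<participant>/<activity>/<w>lbs_<activity><iter>.txt``
    with ``n_iterations * len(weight_class)`` files, byte-reproducible from
    the spec's seed.
    """
    if spec.n_samples < 1:
        raise ValueError("duration_per_weight x sampling_rate must yield >= 1 sample")
    adir = Path(out_dir) / spec.participant_id / spec.activity
    paths = []
    for iteration in range(1, spec.n_iterations + 1):
        for w in spec.weight_class:
            rec = generate_recording(spec, w, iteration)
            paths.append(write_recording(rec, adir / rec.key.filename()))
    return paths


@dataclass(frozen=True)
class CohortSpec:
    """Shared generation parameters for a cohort of participants."""

    weight_class: tuple[int, ...] = SETUP2_WEIGHTS
    n_iterations: int = 2
    sampling_rate: float = 50.0
    duration_per_weight: float = 20.0
    noise_sd: float = 0.02
    drift_sd: float = 0.001
    drift_reset: int = 60
    outlier_prob: float = 0.0
    outlier_scale: float = 3.0
    burst_prob: float = 0.0
    burst_len: int = 30
    burst_scale: float = 0.6
    sway_amp: float = 0.0
    sway_persist: int = 4
    sway_jitter: float = 0.2
    sway_balance: float = 0.5
    body_weight_range: tuple[float, float] = (110.0, 220.0)
    balanced_concentration: float = 5.0      # Dirichlet alpha for even load shares
    unbalanced_concentration: float = 0.5    # skewed load shares
    unbalanced_dropout: float = 0.25
    activity: str = "standing"


def noise_floor_mae(
    base_spec: CohortSpec,
    l_samples: int = 100,
    olap_init: float = 0.2,
    alpha: float = 15.0,
) -> float:
    """Analytic reference MAE (lbs) for a linear readout of window features.

    Approximates the error of an ideal estimator that inverts the combined
    total-force window aggregate back to a weight.  The relative sd of that
    aggregate combines (i) per-sensor i.i.d. noise, averaged over the 32
    sensors (Dirichlet load shares give E[sum p^2] = (a+1)/(32a+1)) and the
    surviving window samples, and (ii) the shared baseline walk, whose
    window mean over a segment of length R has variance ~ sd^2 (R/2 - w/6).
    For a folded Gaussian error the expected absolute error is
    sqrt(2/pi) x sd.  Trained models may beat this linear-readout reference
    (discrete carried-weight labels allow classification-like behavior);
    it serves as a noise-scale yardstick, not a strict lower bound.
    """
    from .windowed_features import plan_windows, trim_count

    n = int(round(base_spec.duration_per_weight * base_spec.sampling_rate))
    plan = plan_windows(n, l_samples, olap_init)
    w = plan.window_length
    w_eff = w - 2 * trim_count(w, alpha)
    conc = base_spec.balanced_concentration
    k = 2 * schema.N_PRESSURE_SENSORS
    share_sq = (conc + 1.0) / (k * conc + 1.0)
    iid_var = base_spec.noise_sd**2 * share_sq / w_eff
    drift_var = base_spec.drift_sd**2 * max(
        base_spec.drift_reset / 2.0 - w / 6.0, w / 3.0
    )
    sigma_rel = float(np.sqrt(iid_var + drift_var))
    mean_total = float(np.mean(base_spec.body_weight_range)) + float(
        np.mean(base_spec.weight_class)
    )
    return float(np.sqrt(2.0 / np.pi) * sigma_rel * mean_total)


def generate_cohort(
    n_balanced: int,
    n_unbalanced: int,
    base_spec: CohortSpec,
    out_dir: str | Path,
    seed: int = 0,
) -> dict:
    """Generate a cohort dataset plus ground-truth table.

    Balanced participants get near-uniform load shares and no dropouts;
    unbalanced participants get skewed shares and per-recording dropouts.
    Participant ids, body weights, load shares, and per-participant seeds
    all derive deterministically from ``seed``.  Returns a manifest dict
    (participant ids, body weights, per-participant seeds, file counts).
    """
    if n_balanced + n_unbalanced < 1:
        raise ValueError("cohort must contain at least one participant")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(np.random.SeedSequence(seed))
    n_sensors = 2 * schema.N_PRESSURE_SENSORS

    manifest: dict = {"seed": seed, "participants": []}
    gt_rows = []
    for idx in range(n_balanced + n_unbalanced):
        balanced = idx < n_balanced
        pid = f"P{idx + 1:02d}"
        body_weight = float(np.round(master.uniform(*base_spec.body_weight_range), 1))
        conc = (base_spec.balanced_concentration if balanced
                else base_spec.unbalanced_concentration)
        shares = master.dirichlet(np.full(n_sensors, conc))
        shares = shares / shares.sum()
        pseed = int(master.integers(0, 2**31 - 1))
        spec = SyntheticParticipantSpec(
            participant_id=pid,
            body_weight=body_weight,
            weight_class=base_spec.weight_class,
            n_iterations=base_spec.n_iterations,
            sampling_rate=base_spec.sampling_rate,
            duration_per_weight=base_spec.duration_per_weight,
            load_shares=tuple(shares),
            dropout_prob=0.0 if balanced else base_spec.unbalanced_dropout,
            noise_sd=base_spec.noise_sd,
            drift_sd=base_spec.drift_sd,
            drift_reset=base_spec.drift_reset,
            outlier_prob=base_spec.outlier_prob,
            outlier_scale=base_spec.outlier_scale,
            burst_prob=base_spec.burst_prob,
            burst_len=base_spec.burst_len,
            burst_scale=base_spec.burst_scale,
            sway_amp=base_spec.sway_amp,
            sway_persist=base_spec.sway_persist,
            sway_jitter=base_spec.sway_jitter,
            sway_balance=base_spec.sway_balance,
            activity=base_spec.activity,
            seed=pseed,
        )
        paths = generate_participant(spec, out_dir)
        gt_rows.append((pid, body_weight))
        manifest["participants"].append(
            {
                "participant_id": pid,
                "balanced": balanced,
                "body_weight_lbs": body_weight,
                "seed": pseed,
                "dropout_prob": spec.dropout_prob,
                "n_files": len(paths),
            }
        )

    gt_path = out_dir / "ground_truth.csv"
    with open(gt_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", "body_weight_lbs"])
        writer.writerows(gt_rows)
    manifest["ground_truth"] = gt_path.name
    return manifest
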