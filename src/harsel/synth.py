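"""Synthetic MIMU cohort generation.

Emulates a thigh-worn miniature magnetic-inertial measurement unit (MIMU)
recording protocol: tri-axial accelerometer (m·s⁻²), tri-axial gyroscope
(deg·s⁻¹) and tri-axial magnetometer sampled at 80 Hz while a subject
performs one of seven activities:

    1  resting (sitting / lying)
    2  upright standing
    3  level walking
    4  ascending stairs
    5  descending stairs
    6  uphill walking
    7  downhill walking

Axis convention (sensor on the lateral right thigh): x = antero-posterior,
y = vertical (down-top, so gravity reads +9.81 m·s⁻² on acc-y when
upright), z = medio-lateral.

The generator is a statistical stand-in, not a biomechanical gait model:
static activities are gravity plus low-amplitude sway and noise; dynamic
activities are sums of 2-3 harmonics of a per-subject cadence with
activity-specific amplitude, bias and phase-asymmetry signatures on
acc-x, acc-y and gyro-z, plus i.i.d. Gaussian noise.  By construction the
static/dynamic rule thresholds (gyro-z variance 600, acc-y mean 8.5) hold
with wide margins, and the five dynamic classes are separable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

GRAVITY = 9.81  # m·s⁻²
DEFAULT_FS = 80.0  # Hz
DEFAULT_DURATION_S = 60.0
ACTIVITIES = (1, 2, 3, 4, 5, 6, 7)
STATIC_ACTIVITIES = (1, 2)
DYNAMIC_ACTIVITIES = (3, 4, 5, 6, 7)

CHANNEL_NAMES = ("acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z")

# Dynamic-activity signature table: harmonic amplitudes of the cadence
# fundamental on each driven channel, a constant antero-posterior bias,
# and a phase offset on gyro-z creating per-activity waveform asymmetry.
# Units: m·s⁻² for acc rows, deg·s⁻¹ for gyro rows.
_DYNAMIC_PARAMS: dict[int, dict] = {
    3: dict(cadence_factor=1.00, acc_x=(2.0, 1.0, 0.3), acc_x_bias=0.0,
            acc_y=(3.0, 1.5, 0.5), gyro_z=(100.0, 40.0, 10.0), gz_phase=0.0),
    4: dict(cadence_factor=0.80, acc_x=(2.5, 1.2, 0.4), acc_x_bias=1.2,
            acc_y=(4.5, 2.5, 0.8), gyro_z=(130.0, 70.0, 20.0), gz_phase=0.9),
    5: dict(cadence_factor=0.85, acc_x=(3.0, 0.8, 0.5), acc_x_bias=-1.2,
            acc_y=(5.5, 2.0, 1.0), gyro_z=(150.0, 50.0, 30.0), gz_phase=-0.9),
    6: dict(cadence_factor=0.95, acc_x=(2.2, 1.5, 0.2), acc_x_bias=2.5,
            acc_y=(3.5, 1.0, 0.4), gyro_z=(90.0, 25.0, 8.0), gz_phase=0.4),
    7: dict(cadence_factor=1.05, acc_x=(2.4, 0.6, 0.6), acc_x_bias=-2.5,
            acc_y=(4.0, 0.8, 0.3), gyro_z=(110.0, 35.0, 15.0), gz_phase=-0.4),
}

# Noise standard deviations (per channel family, scaled by the subject's
# noise_sd multiplier).  Gyro static noise must keep var(gyro-z) well
# below the 600 rule threshold: sd 3 deg·s⁻¹ gives variance ≈ 9.
_ACC_NOISE_SD = 0.10   # m·s⁻²
_GYRO_NOISE_SD = 3.0   # deg·s⁻¹
_MAG_NOISE_SD = 0.02   # a.u. (Gauss-scale), generated but unused downstream


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject random effects for the generator."""

    subject_id: int
    cadence_hz: float = 1.8
    amplitude_scale: float = 1.0
    noise_sd: float = 1.0  # multiplier on the channel noise table

    def __post_init__(self) -> None:
        if not (1.2 <= self.cadence_hz <= 2.5):
            raise ValueError(f"cadence_hz must be in [1.2, 2.5], got {self.cadence_hz}")
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class MimuRecording:
    """One labeled multi-channel recording at a fixed sampling rate."""

    subject_id: int
    activity: int
    repetition: int
    fs: float
    acc: np.ndarray   # 3 × n, m·s⁻²
    gyro: np.ndarray  # 3 × n, deg·s⁻¹
    mag: np.ndarray | None = None  # 3 × n, optional

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.mag is not None:
            self.mag = np.asarray(self.mag, dtype=float)
        if self.acc.shape[0] != 3 or self.gyro.shape[0] != 3:
            raise ValueError("acc and gyro must be 3 × n arrays")
        if self.acc.shape[1] != self.gyro.shape[1]:
            raise ValueError("all channels must have the same length")
        if self.mag is not None and self.mag.shape != self.acc.shape:
            raise ValueError("mag must match acc/gyro shape")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.activity not in ACTIVITIES:
            raise ValueError(f"unknown activity code {self.activity}")

    @property
    def n_samples(self) -> int:
        return self.acc.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channels(self) -> np.ndarray:
        """The six inertial channels as a 6 × n array (acc xyz, gyro xyz)."""
        return np.vstack([self.acc, self.gyro])


def _harmonics(t: np.ndarray, f0: float, amps, phase: float = 0.0) -> np.ndarray:
    out = np.zeros_like(t)
    for k, a in enumerate(amps, start=1):
        out += a * np.sin(2 * np.pi * k * f0 * t + k * phase)
    return out


def generate_recording(
    profile: SubjectProfile,
    activity: int,
    duration_s: float = DEFAULT_DURATION_S,
    fs: float = DEFAULT_FS,
    seed: int = 0,
    with_mag: bool = True,
) -> MimuRecording:
    """Generate one synthetic recording.

    Deterministic function of ``(profile, activity, duration_s, fs, seed)``.

    Parameters
    ----------
    profile : SubjectProfile
        Subject random effects (cadence, amplitude, noise multiplier).
    activity : int
        Activity code 1-7.
    duration_s, fs : float
        Recording length (s) and sampling rate (Hz); must be positive.
    seed : int
        Seeds phases and noise.
    with_mag : bool
        Also synthesize magnetometer channels (ignored by the pipeline).
    """
    if activity not in ACTIVITIES:
        raise ValueError(f"unknown activity code {activity}")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    acc = np.zeros((3, n))
    gyro = np.zeros((3, n))

    if activity in STATIC_ACTIVITIES:
        sway_phase = rng.uniform(0, 2 * np.pi)
        if activity == 1:
            # lying/sitting: gravity mostly off the vertical axis
            acc[0] += GRAVITY
            acc[1] += 0.3
            acc[1] += 0.10 * np.sin(2 * np.pi * 0.3 * t + sway_phase)
        else:
            # upright standing: gravity on vertical (y), light postural sway
            acc[1] += GRAVITY
            acc[1] += 0.15 * np.sin(2 * np.pi * 0.5 * t + sway_phase)
            acc[0] += 0.10 * np.sin(2 * np.pi * 0.4 * t + sway_phase)
        gyro[2] += 2.0 * np.sin(2 * np.pi * 0.4 * t + sway_phase)
    else:
        p = _DYNAMIC_PARAMS[activity]
        f0 = profile.cadence_hz * p["cadence_factor"]
        a = profile.amplitude_scale
        phase = rng.uniform(0, 2 * np.pi)
        acc[0] += p["acc_x_bias"] + a * _harmonics(t, f0, p["acc_x"], phase)
        acc[1] += GRAVITY + a * _harmonics(t, f0, p["acc_y"], phase + 0.5)
        acc[2] += 0.4 * a * _harmonics(t, f0, (0.8, 0.3), phase + 1.1)
        gyro[0] += a * _harmonics(t, f0, (25.0, 8.0), phase + 0.7)
        gyro[1] += a * _harmonics(t, f0, (18.0, 6.0), phase + 1.9)
        gyro[2] += a * _harmonics(t, f0, p["gyro_z"], phase + p["gz_phase"])

    acc += rng.normal(0.0, _ACC_NOISE_SD * profile.noise_sd, size=acc.shape)
    gyro += rng.normal(0.0, _GYRO_NOISE_SD * profile.noise_sd, size=gyro.shape)

    mag = None
    if with_mag:
        # constant Earth-field direction plus noise; excluded downstream
        mag = np.tile(np.array([[0.2], [0.1], [0.4]]), (1, n))
        mag = mag + rng.normal(0.0, _MAG_NOISE_SD, size=mag.shape)

    return MimuRecording(
        subject_id=profile.subject_id,
        activity=activity,
        repetition=0,
        fs=fs,
        acc=acc,
        gyro=gyro,
        mag=mag,
    )


def _draw_profile(subject_id: int, rng: np.random.Generator) -> SubjectProfile:
    return SubjectProfile(
        subject_id=subject_id,
        cadence_hz=float(rng.uniform(1.4, 2.2)),
        amplitude_scale=float(rng.uniform(0.8, 1.2)),
        noise_sd=float(rng.uniform(0.7, 1.3)),
    )


def _recording_seed(seed: int, subject: int, activity: int, rep: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(subject, activity, rep))
    return int(ss.generate_state(1)[0] % (2**31))


def iter_cohort(
    n_subjects: int,
    reps: int = 5,
    duration_s: float = DEFAULT_DURATION_S,
    fs: float = DEFAULT_FS,
    seed: int = 0,
    with_mag: bool = True,
) -> Iterator[MimuRecording]:
    """Lazily yield a full cohort: ``n_subjects × 7 activities × reps``.

    Subject profiles are drawn from seeded distributions; each recording
    gets an independent seed derived from ``(seed, subject, activity, rep)``
    so the stream is deterministic and order-independent.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    profile_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(999,)))
    for subject in range(1, n_subjects + 1):
        profile = _draw_profile(subject, profile_rng)
        for activity in ACTIVITIES:
            for rep in range(1, reps + 1):
                rec = generate_recording(
                    profile, activity, duration_s, fs,
                    seed=_recording_seed(seed, subject, activity, rep),
                    with_mag=with_mag,
                )
                rec.repetition = rep
                yield rec


def generate_cohort(
    n_subjects: int,
    reps: int = 5,
    duration_s: float = DEFAULT_DURATION_S,
    fs: float = DEFAULT_FS,
    seed: int = 0,
    with_mag: bool = True,
) -> list[MimuRecording]:
    """Materialized :func:`iter_cohort` (use the iterator for large cohorts)."""
    return list(iter_cohort(n_subjects, reps, duration_s, fs, seed, with_mag))


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

def write_recording_csv(rec: MimuRecording, path: str | Path) -> None:
    """Write one recording as CSV with a JSON metadata comment header."""
    path = Path(path)
    meta = {
        "subject_id": rec.subject_id,
        "activity": rec.activity,
        "repetition": rec.repetition,
        "fs": rec.fs,
    }
    n = rec.n_samples
    cols = {"t": np.arange(n) / rec.fs}
    for i, name in enumerate(("acc_x", "acc_y", "acc_z")):
        cols[name] = rec.acc[i]
    for i, name in enumerate(("gyro_x", "gyro_y", "gyro_z")):
        cols[name] = rec.gyro[i]
    if rec.mag is not None:
        for i, name in enumerate(("mag_x", "mag_y", "mag_z")):
            cols[name] = rec.mag[i]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def read_recording_csv(path: str | Path) -> MimuRecording:
    """Read a recording written by :func:`write_recording_csv`."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing JSON metadata header")
        meta = json.loads(header.lstrip("#").strip())
        df = pd.read_csv(fh)
    acc = df[["acc_x", "acc_y", "acc_z"]].to_numpy().T
    gyro = df[["gyro_x", "gyro_y", "gyro_z"]].to_numpy().T
    mag = None
    if "mag_x" in df.columns:
        mag = df[["mag_x", "mag_y", "mag_z"]].to_numpy().T
    return MimuRecording(
        subject_id=int(meta["subject_id"]),
        activity=int(meta["activity"]),
        repetition=int(meta["repetition"]),
        fs=float(meta["fs"]),
        acc=acc,
        gyro=gyro,
        mag=mag,
    )
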