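"""Synthetic 130 Hz single-lead ECG with class-dependent RR structure.

The generator emulates the kind of data a chest-strap ECG study produces:
per-subject records of PQRST-like waveforms whose beat-to-beat (RR) interval
statistics differ between a fatigued (F) and a non-fatigued (N) autonomic
state, corrupted by white noise, baseline wander and powerline interference,
and accompanied by a visual-analogue-scale (VAS) fatigue trajectory.  It is a
controllable benchmark fixture, not a biophysical heart model.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from fatiguecg.errors import InvalidParameterError

FS_DEFAULT = 130.0
#: Hard floor for a physiologically possible RR interval (s).
RR_FLOOR = 0.3

LABEL_FATIGUE = "F"
LABEL_NON_FATIGUE = "N"

GENDERS = ("male", "female")


@dataclass(frozen=True)
class BeatTemplate:
    """Single-beat morphology as five Gaussian bumps (P, Q, R, S, T).

    Offsets are in seconds relative to the R peak, amplitudes in arbitrary
    mV-scaled units, widths are Gaussian standard deviations in seconds.
    """

    offsets: tuple[float, ...] = (-0.2, -0.05, 0.0, 0.05, 0.3)
    amplitudes: tuple[float, ...] = (0.15, -0.1, 1.0, -0.25, 0.35)
    widths: tuple[float, ...] = (0.025, 0.01, 0.012, 0.012, 0.04)

    def __post_init__(self) -> None:
        if not (len(self.offsets) == len(self.amplitudes) == len(self.widths)):
            raise InvalidParameterError("offsets/amplitudes/widths length mismatch")
        if any(w <= 0 for w in self.widths):
            raise InvalidParameterError("wave widths must be strictly positive")
        if self.r_amplitude <= 0:
            raise InvalidParameterError("R amplitude must be strictly positive")

    @property
    def r_amplitude(self) -> float:
        # R is the wave centered at offset 0 by convention (index of offset 0,
        # falling back to the largest amplitude).
        try:
            idx = self.offsets.index(0.0)
        except ValueError:
            idx = int(np.argmax(self.amplitudes))
        return self.amplitudes[idx]


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject metadata consumed by the physiological encoder."""

    subject_id: str
    age: int
    gender: str
    label: str  # "F" or "N"

    def __post_init__(self) -> None:
        if not 0 <= int(self.age) <= 99:
            raise InvalidParameterError(
                f"age {self.age} outside [0, 99] (must index a 100-dim one-hot)"
            )
        if self.label not in (LABEL_FATIGUE, LABEL_NON_FATIGUE):
            raise InvalidParameterError(f"label must be 'F' or 'N', got {self.label!r}")


@dataclass(frozen=True)
class RRModel:
    """RR-interval model: i.i.d. Gaussian (optionally AR(1)) around ``mean_rr``.

    ``sdnn`` is the standard deviation of normal-to-normal intervals; ``ar1``
    adds first-order temporal correlation for dependence tests.  Intervals are
    clipped at ``RR_FLOOR`` so every sampled interval stays positive.
    """

    mean_rr: float = 0.8
    sdnn: float = 0.05
    ar1: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_rr <= 0:
            raise InvalidParameterError("mean RR must be positive")
        if self.sdnn < 0:
            raise InvalidParameterError("SDNN must be non-negative")
        if not -1.0 < self.ar1 < 1.0:
            raise InvalidParameterError("AR(1) coefficient must lie in (-1, 1)")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise mixture: white + baseline wander + powerline.

    Amplitudes are in the same units as the rendered ECG (R amplitude 1.0 by
    default); frequencies in Hz.
    """

    white_sd: float = 0.05
    baseline_amplitude: float = 0.1
    baseline_freq: float = 0.3
    powerline_amplitude: float = 0.02
    powerline_freq: float = 50.0

    def __post_init__(self) -> None:
        if min(self.white_sd, self.baseline_amplitude, self.powerline_amplitude) < 0:
            raise InvalidParameterError("noise amplitudes must be non-negative")
        if min(self.baseline_freq, self.powerline_freq) < 0:
            raise InvalidParameterError("noise frequencies must be non-negative")

    @classmethod
    def silent(cls) -> "NoiseSpec":
        return cls(white_sd=0.0, baseline_amplitude=0.0, powerline_amplitude=0.0)


@dataclass
class ECGRecord:
    """One subject-session: samples at 130 Hz plus VAS score and profile."""

    samples: np.ndarray
    fs: float
    vas: float
    profile: SubjectProfile
    vas_trajectory: np.ndarray = field(default_factory=lambda: np.empty(0))
    record_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs != FS_DEFAULT:
            raise InvalidParameterError(f"sampling rate must be {FS_DEFAULT} Hz")
        if not 0.0 <= self.vas <= 100.0:
            raise InvalidParameterError("VAS score must lie in [0, 100]")
        if not self.record_id:
            self.record_id = self.profile.subject_id

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


# Default class-conditional RR models.  These are fixture parameters creating
# a learnable, physiologically plausible HRV contrast (fatigue: slower, less
# variable rhythm); they are fully configurable and claim no fidelity to any
# real cohort.
DEFAULT_CLASS_PARAMS: dict[str, RRModel] = {
    LABEL_NON_FATIGUE: RRModel(mean_rr=0.80, sdnn=0.06),
    LABEL_FATIGUE: RRModel(mean_rr=0.90, sdnn=0.02),
}


def generate_rr_series(model: RRModel, n_beats: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw ``n_beats`` RR intervals (s) from ``model``, seeded.

    With ``ar1 == 0`` the intervals are i.i.d. Gaussian truncated below at
    ``RR_FLOOR``; otherwise a stationary AR(1) process with the same marginal
    mean and SD is used.
    """
    if n_beats < 1:
        raise InvalidParameterError("n_beats must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if model.sdnn == 0:
        rr = np.full(n_beats, model.mean_rr)
    elif model.ar1 == 0:
        rr = rng.normal(model.mean_rr, model.sdnn, size=n_beats)
    else:
        # innovations scaled so the stationary SD equals sdnn
        innov_sd = model.sdnn * np.sqrt(1 - model.ar1**2)
        z = rng.normal(0.0, innov_sd, size=n_beats)
        dev = np.empty(n_beats)
        dev[0] = rng.normal(0.0, model.sdnn)
        for i in range(1, n_beats):
            dev[i] = model.ar1 * dev[i - 1] + z[i]
        rr = model.mean_rr + dev
    return np.maximum(rr, RR_FLOOR)


def render_ecg(
    rr: np.ndarray, template: BeatTemplate | None = None, fs: float = FS_DEFAULT
) -> np.ndarray:
    """Render a clean ECG trace with beats at cumulative RR times.

    The trace spans ``floor(sum(rr) * fs)`` samples; beat ``i``'s R peak sits
    at time ``sum(rr[:i+1]) - rr[0]``, i.e. the first R peak is at t=0 and
    successive peaks are separated by the programmed intervals.
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size == 0:
        raise InvalidParameterError("rr sequence must be non-empty")
    if fs <= 0:
        raise InvalidParameterError("fs must be positive")
    template = template or BeatTemplate()
    n = int(np.floor(rr.sum() * fs))
    t = np.arange(n) / fs
    signal = np.zeros(n)
    r_times = np.cumsum(rr) - rr[0]
    for r_t in r_times:
        for off, amp, width in zip(template.offsets, template.amplitudes, template.widths):
            c = r_t + off
            # Gaussian support is effectively ±5 widths; skip off-trace bumps.
            lo = int(max(0, np.floor((c - 5 * width) * fs)))
            hi = int(min(n, np.ceil((c + 5 * width) * fs) + 1))
            if hi <= lo:
                continue
            signal[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - c) / width) ** 2)
    return signal


def add_noise(
    clean: np.ndarray, spec: NoiseSpec, seed: int | np.random.Generator = 0, fs: float = FS_DEFAULT
) -> np.ndarray:
    """Add white + baseline-wander + powerline noise; length-preserving."""
    clean = np.asarray(clean, dtype=float)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = clean.shape[0]
    out = clean.copy()
    if spec.white_sd > 0:
        out += rng.normal(0.0, spec.white_sd, size=n)
    t = np.arange(n) / fs
    if spec.baseline_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        out += spec.baseline_amplitude * np.sin(2 * np.pi * spec.baseline_freq * t + phase)
    if spec.powerline_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        out += spec.powerline_amplitude * np.sin(2 * np.pi * spec.powerline_freq * t + phase)
    return out


def _vas_trajectory(final_vas: float, n_points: int, rng: np.random.Generator) -> np.ndarray:
    """Monotone increasing VAS trace from a low start to ``final_vas``."""
    start = rng.uniform(5.0, 25.0)
    start = min(start, final_vas)
    steps = rng.uniform(0.5, 1.0, size=max(n_points - 1, 1))
    traj = start + np.concatenate([[0.0], np.cumsum(steps)]) / np.sum(steps) * (final_vas - start)
    return traj[:n_points]


def generate_record(
    profile: SubjectProfile,
    rr_model: RRModel,
    duration_s: float,
    noise: NoiseSpec,
    seed: int | np.random.Generator,
    template: BeatTemplate | None = None,
) -> ECGRecord:
    """Generate one noisy labeled record of ``duration_s`` seconds."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_beats = int(np.ceil(duration_s / max(rr_model.mean_rr - 4 * rr_model.sdnn, RR_FLOOR))) + 2
    rr = generate_rr_series(rr_model, n_beats, rng)
    clean = render_ecg(rr, template)
    n_target = int(np.floor(duration_s * FS_DEFAULT))
    if clean.shape[0] < n_target:  # pragma: no cover - defensive, margin above suffices
        clean = np.pad(clean, (0, n_target - clean.shape[0]))
    clean = clean[:n_target]
    samples = add_noise(clean, noise, rng)
    if profile.label == LABEL_FATIGUE:
        final_vas = rng.uniform(82.0, 95.0)
    else:
        final_vas = rng.uniform(30.0, 75.0)
    traj = _vas_trajectory(final_vas, n_points=7, rng=rng)  # six task rounds + baseline
    return ECGRecord(
        samples=samples,
        fs=FS_DEFAULT,
        vas=final_vas,
        profile=profile,
        vas_trajectory=traj,
    )


def generate_cohort(
    n_subjects: int,
    class_params: dict[str, RRModel] | None = None,
    duration_s: float = 120.0,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    age_range: tuple[int, int] = (18, 27),
    male_fraction: float = 2 / 3,
    template: BeatTemplate | None = None,
) -> list[ECGRecord]:
    """Generate a balanced two-class cohort of seeded records.

    Subjects alternate F/N so both classes are always represented; ages are
    uniform on ``age_range`` and genders drawn with a 2:1 male:female ratio by
    default, mirroring a young athletic cohort.
    """
    if n_subjects < 2:
        raise InvalidParameterError("a cohort needs at least 2 subjects (both classes)")
    class_params = class_params or DEFAULT_CLASS_PARAMS
    noise = noise if noise is not None else NoiseSpec()
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_subjects):
        label = LABEL_FATIGUE if i % 2 == 0 else LABEL_NON_FATIGUE
        profile = SubjectProfile(
            subject_id=f"S{i:03d}",
            age=int(rng.integers(age_range[0], age_range[1] + 1)),
            gender=GENDERS[0] if rng.random() < male_fraction else GENDERS[1],
            label=label,
        )
        records.append(
            generate_record(profile, class_params[label], duration_s, noise, rng, template)
        )
    return records


def detect_r_peaks(signal: np.ndarray, fs: float = FS_DEFAULT, threshold: float = 0.5) -> np.ndarray:
    """Threshold-and-local-maximum R-peak detector (oracle-grade, clean signals).

    Returns sample indices of local maxima above ``threshold`` times the signal
    maximum, separated by at least ``RR_FLOOR`` seconds.
    """
    signal = np.asarray(signal, dtype=float)
    thr = threshold * signal.max()
    padded = np.concatenate([[-np.inf], signal, [-np.inf]])  # boundary peaks count
    candidates = np.flatnonzero(
        (signal > thr) & (signal >= padded[:-2]) & (signal > padded[2:])
    )
    if candidates.size == 0:
        return candidates
    min_gap = int(RR_FLOOR * fs)
    peaks = [candidates[0]]
    for c in candidates[1:]:
        if c - peaks[-1] >= min_gap:
            peaks.append(c)
        elif signal[c] > signal[peaks[-1]]:
            peaks[-1] = c
    return np.asarray(peaks)


# ---------------------------------------------------------------------------
# On-disk layout: <id>.csv with (timestamp_s, ecg) columns + <id>.meta.json.
# Real chest-strap CSV exports can be adapted by renaming their time/value
# columns to timestamp_s/ecg and writing the sidecar by hand.
# ---------------------------------------------------------------------------

def write_record(record: ECGRecord, out_dir: str | Path) -> Path:
    """Write one record as CSV + JSON sidecar; returns the CSV path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{record.record_id}.csv"
    t = np.arange(len(record.samples)) / record.fs
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["timestamp_s", "ecg"])
        for ti, vi in zip(t, record.samples):
            writer.writerow([f"{ti:.6f}", f"{vi:.8f}"])
    meta = {
        "subject_id": record.profile.subject_id,
        "age": record.profile.age,
        "gender": record.profile.gender,
        "label": record.profile.label,
        "vas": record.vas,
        "vas_trajectory": [float(v) for v in record.vas_trajectory],
        "fs": record.fs,
        "record_id": record.record_id,
    }
    (out_dir / f"{record.record_id}.meta.json").write_text(json.dumps(meta, indent=2))
    return csv_path


def read_record(csv_path: str | Path) -> ECGRecord:
    """Read a record written by :func:`write_record`."""
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix("").with_suffix(".meta.json").read_text())
    samples = np.loadtxt(csv_path, delimiter=",", skiprows=1, usecols=1)
    profile = SubjectProfile(
        subject_id=meta["subject_id"],
        age=meta["age"],
        gender=meta["gender"],
        label=meta["label"],
    )
    return ECGRecord(
        samples=samples,
        fs=meta["fs"],
        vas=meta["vas"],
        profile=profile,
        vas_trajectory=np.asarray(meta.get("vas_trajectory", []), dtype=float),
        record_id=meta["record_id"],
    )


def read_cohort(directory: str | Path) -> list[ECGRecord]:
    return [read_record(p) for p in sorted(Path(directory).glob("*.csv"))]
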