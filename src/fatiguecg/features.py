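"""Segmentation, labeling and STFT spectrogram features.

Preprocessed records are cut into non-overlapping 1 s segments of 130
samples, grouped ten at a time into 10 s units, and each segment is turned
into a short-time Fourier transform magnitude spectrogram

    S[n, k] = | sum_m x_m g_{n-m} e^{-j 2 pi k m / N} |

where g is an N-sample analysis window shifted by a fixed hop.  A window
position n covers samples [n*hop, n*hop + N); positions where the window
would overhang the segment are dropped, so spectrograms never mix adjacent
segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fatiguecg.errors import InvalidInputError, InvalidParameterError
from fatiguecg.preprocess import WaveletSpec, preprocess_record
from fatiguecg.synthetic import ECGRecord, SubjectProfile, LABEL_FATIGUE, LABEL_NON_FATIGUE

SEGMENT_LENGTH = 130
GROUP_SIZE = 10
VAS_FATIGUE_THRESHOLD = 80.0


@dataclass(frozen=True)
class Segment:
    """130 consecutive standardized samples from one record."""

    samples: np.ndarray
    record_id: str
    start: int  # 0-based sample offset; window is [start, start+130)

    def __post_init__(self) -> None:
        if self.samples.shape[0] != SEGMENT_LENGTH:
            raise InvalidInputError(
                f"a segment must hold exactly {SEGMENT_LENGTH} samples, got {self.samples.shape[0]}"
            )


@dataclass(frozen=True)
class SegmentGroup:
    """Ten contiguous segments (10 s of signal) — the model's unit of input."""

    segments: tuple[Segment, ...]
    label: str
    profile: SubjectProfile

    def __post_init__(self) -> None:
        if len(self.segments) != GROUP_SIZE:
            raise InvalidInputError(f"a group must hold exactly {GROUP_SIZE} segments")
        rid = self.segments[0].record_id
        for prev, nxt in zip(self.segments, self.segments[1:]):
            if nxt.record_id != rid or nxt.start != prev.start + SEGMENT_LENGTH:
                raise InvalidInputError("group segments must be contiguous and from one record")

    @property
    def signal(self) -> np.ndarray:
        """The concatenated 1300-sample group signal."""
        return np.concatenate([s.samples for s in self.segments])


@dataclass(frozen=True)
class STFTSpec:
    """Window length ``n_window`` (samples), hop, window shape, output scaling."""

    n_window: int = 32
    hop: int = 4
    window: str = "hann"  # "hann" or "rect"
    log_magnitude: bool = True
    log_floor: float = 1e-8

    def __post_init__(self) -> None:
        if not 1 <= self.hop <= self.n_window:
            raise InvalidParameterError("hop must satisfy 1 <= hop <= n_window")
        if self.window not in ("hann", "rect"):
            raise InvalidParameterError("window must be 'hann' or 'rect'")
        if self.log_floor <= 0:
            raise InvalidParameterError("log_floor must be positive")

    def window_values(self) -> np.ndarray:
        if self.window == "rect":
            return np.ones(self.n_window)
        # periodic Hann, the standard analysis choice
        return 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(self.n_window) / self.n_window)


@dataclass(frozen=True)
class Spectrogram:
    """Magnitude matrix: rows = window positions n, columns = frequency bins k."""

    values: np.ndarray  # (n_frames, n_window), all >= 0
    spec: STFTSpec


def segment_signal(signal: np.ndarray, record_id: str = "", segment_length: int = SEGMENT_LENGTH) -> list[Segment]:
    """Cut a signal into floor(len/130) non-overlapping segments.

    A trailing remainder shorter than one segment is discarded; signals below
    one segment length yield an empty list (not an error).
    """
    signal = np.asarray(signal, dtype=float)
    n_segments = signal.shape[0] // segment_length
    return [
        Segment(
            samples=signal[i * segment_length : (i + 1) * segment_length],
            record_id=record_id,
            start=i * segment_length,
        )
        for i in range(n_segments)
    ]


def group_segments(
    segments: list[Segment], label: str = LABEL_NON_FATIGUE, profile: SubjectProfile | None = None
) -> list[SegmentGroup]:
    """Group consecutive segments ten at a time; the remainder is discarded."""
    profile = profile or SubjectProfile("anon", 25, "male", label)
    n_groups = len(segments) // GROUP_SIZE
    return [
        SegmentGroup(
            segments=tuple(segments[i * GROUP_SIZE : (i + 1) * GROUP_SIZE]),
            label=label,
            profile=profile,
        )
        for i in range(n_groups)
    ]


def label_from_vas(vas_percent: float) -> str:
    """Fatigue iff the VAS score is strictly above 80%."""
    if not 0.0 <= vas_percent <= 100.0:
        raise InvalidInputError(f"VAS score {vas_percent} outside [0, 100]")
    return LABEL_FATIGUE if vas_percent > VAS_FATIGUE_THRESHOLD else LABEL_NON_FATIGUE


def stft(samples: np.ndarray, spec: STFTSpec | None = None) -> Spectrogram:
    """Magnitude STFT with windows placed entirely inside the signal.

    Frame i covers samples [i*hop, i*hop + N); its row holds
    |DFT(x[frame] * g)| over all N bins.  Dropping the absolute-sample phase
    factor leaves magnitudes unchanged.
    """
    spec = spec or STFTSpec()
    samples = np.asarray(samples, dtype=float)
    n = samples.shape[0]
    if spec.n_window > n:
        raise InvalidParameterError(
            f"window of {spec.n_window} samples exceeds signal length {n}"
        )
    g = spec.window_values()
    n_frames = (n - spec.n_window) // spec.hop + 1
    starts = np.arange(n_frames) * spec.hop
    frames = samples[starts[:, None] + np.arange(spec.n_window)] * g
    mags = np.abs(np.fft.fft(frames, axis=1))
    return Spectrogram(values=mags, spec=spec)


def spectrogram_image(spectrogram: Spectrogram) -> np.ndarray:
    """Model-ready image: non-redundant bins k in [0, N/2], freq rows x time cols.

    Real input makes bins k and N-k mirror images, so only the first
    floor(N/2)+1 bins are kept.  Log scaling applies log(max(S, floor)).
    """
    spec = spectrogram.spec
    keep = spec.n_window // 2 + 1
    img = spectrogram.values[:, :keep].T  # (freq, time)
    if spec.log_magnitude:
        img = np.log(np.maximum(img, spec.log_floor))
    return img


@dataclass
class Example:
    """One labeled training example: 10 s signal, 10 spectrogram images, physio."""

    group: SegmentGroup
    images: np.ndarray  # (10, freq, time)
    label: str

    @property
    def signal(self) -> np.ndarray:
        return self.group.signal

    @property
    def profile(self) -> SubjectProfile:
        return self.group.profile


def build_examples_from_preprocessed(
    record: ECGRecord, stft_spec: STFTSpec | None = None
) -> list[Example]:
    """Segment + group an already-preprocessed record and attach spectrograms."""
    stft_spec = stft_spec or STFTSpec()
    label = label_from_vas(record.vas)
    segments = segment_signal(record.samples, record.record_id)
    groups = group_segments(segments, label=label, profile=record.profile)
    examples = []
    for group in groups:
        images = np.stack(
            [spectrogram_image(stft(seg.samples, stft_spec)) for seg in group.segments]
        )
        examples.append(Example(group=group, images=images, label=label))
    return examples


def save_examples(examples: list[Example], out_dir) -> None:
    """Persist a featurized dataset: manifest.csv + examples.npz.

    The manifest carries one row per example (id, record, label, subject
    fields); the npz holds the stacked signal/image arrays in the same order.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, ex in enumerate(examples):
        p = ex.profile
        rows.append(
            f"{i},{ex.group.segments[0].record_id},{ex.label},{p.subject_id},{p.age},{p.gender}"
        )
    header = "example_id,record_id,label,subject_id,age,gender"
    (out_dir / "manifest.csv").write_text("\n".join([header, *rows]) + "\n")
    np.savez(
        out_dir / "examples.npz",
        signal=np.stack([ex.signal for ex in examples]),
        images=np.stack([ex.images for ex in examples]),
        starts=np.array([ex.group.segments[0].start for ex in examples]),
    )


def load_examples(data_dir) -> list[Example]:
    """Reload a dataset written by :func:`save_examples`."""
    from pathlib import Path

    data_dir = Path(data_dir)
    arrays = np.load(data_dir / "examples.npz")
    lines = (data_dir / "manifest.csv").read_text().strip().splitlines()[1:]
    examples = []
    for line, signal, images, start in zip(
        lines, arrays["signal"], arrays["images"], arrays["starts"]
    ):
        _, record_id, label, subject_id, age, gender = line.split(",")
        profile = SubjectProfile(subject_id, int(age), gender, label)
        segments = [
            Segment(
                samples=signal[j * SEGMENT_LENGTH : (j + 1) * SEGMENT_LENGTH],
                record_id=record_id,
                start=int(start) + j * SEGMENT_LENGTH,
            )
            for j in range(GROUP_SIZE)
        ]
        group = SegmentGroup(tuple(segments), label, profile)
        examples.append(Example(group=group, images=images, label=label))
    return examples


def build_dataset(
    records: list[ECGRecord],
    wavelet_spec: WaveletSpec | None = None,
    stft_spec: STFTSpec | None = None,
    preprocess: bool = True,
) -> list[Example]:
    """Full featurization: preprocess each record, segment, group, label, STFT."""
    examples: list[Example] = []
    for record in records:
        if preprocess:
            record, _ = preprocess_record(record, wavelet_spec)
        examples.extend(build_examples_from_preprocessed(record, stft_spec))
    return examples
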