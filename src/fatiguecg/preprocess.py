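"""Denoising and standardization of raw ECG.

A record passes through three stages, in order: Daubechies-5 wavelet
denoising (9-level decomposition, detail-band thresholding, reconstruction),
DC removal, and per-record z-scoring.  The wavelet stage subsumes powerline
and white-noise suppression; no separate notch filter is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

from fatiguecg.errors import DegenerateInputError, InvalidInputError, InvalidParameterError
from fatiguecg.synthetic import ECGRecord

#: Minimum signal length for a 9-level decomposition without degenerate bands.
MIN_SIGNAL_LENGTH = 512

THRESHOLD_RULES = ("sure-soft", "universal-soft", "universal-hard", "fixed")


@dataclass(frozen=True)
class WaveletSpec:
    """Wavelet denoising configuration.

    A 9-level DB-5 decomposition yields one approximation band (cA9) and nine
    detail bands (cD9 ... cD1).  Threshold rules (noise level sigma_hat is the
    robust estimate MAD(cD1)/0.6745 throughout):

    * ``sure-soft`` (default) — per-band soft threshold chosen by minimizing
      Stein's unbiased risk estimate, with the universal threshold as the
      sparse-band fallback (the SureShrink hybrid scheme).  Adapts to bands
      that carry signal, avoiding the over-smoothing of a single global
      threshold on oscillatory biosignals.
    * ``universal-soft`` / ``universal-hard`` — sigma_hat * sqrt(2 ln L), L
      the signal length, applied to every detail band.
    * ``fixed`` — ``fixed_threshold`` applied (soft) to every detail band.
    """

    wavelet: str = "db5"
    levels: int = 9
    threshold_rule: str = "sure-soft"
    fixed_threshold: float = 0.0
    mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.threshold_rule not in THRESHOLD_RULES:
            raise InvalidParameterError(
                f"threshold_rule must be one of {THRESHOLD_RULES}, got {self.threshold_rule!r}"
            )
        if self.levels < 1:
            raise InvalidParameterError("levels must be >= 1")
        if self.fixed_threshold < 0:
            raise InvalidParameterError("fixed_threshold must be non-negative")


@dataclass
class PreprocessReport:
    """Provenance for one preprocessing run (before/after inspection)."""

    energy_in: float = 0.0
    energy_denoised: float = 0.0
    thresholds: list[float] = field(default_factory=list)
    dc_offset: float = 0.0
    standardize_mean: float = 0.0
    standardize_sd: float = 1.0


def _noise_sigma(detail_finest: np.ndarray) -> float:
    """Robust noise-level estimate from the finest detail band (MAD/0.6745)."""
    return float(np.median(np.abs(detail_finest)) / 0.6745)


def _sure_threshold(band: np.ndarray, sigma: float) -> float:
    """SureShrink hybrid threshold for one detail band.

    Minimizes Stein's unbiased risk estimate of the soft-threshold MSE over
    the candidate thresholds |y_k|; for bands whose standardized energy looks
    sparse, falls back to the universal threshold (Donoho & Johnstone's
    hybrid scheme).
    """
    n = band.size
    if n == 0 or sigma == 0:
        return 0.0
    t_univ = sigma * np.sqrt(2.0 * np.log(max(n, 2)))
    y = band / sigma
    # sparsity test: weak signal -> SURE is unreliable, use universal
    if (np.sum(y**2) - n) / n <= np.log2(max(n, 2)) ** 1.5 / np.sqrt(n):
        return t_univ
    a = np.sort(np.abs(y))
    cum = np.concatenate([[0.0], np.cumsum(a**2)])
    k = np.arange(n)
    # risk at t = a[k]: n - 2*(n-k) + sum_{i<=k} a_i^2 + (n-k-1)*a_k^2... use
    # standard form: SURE(t) = n - 2*#{|y|<=t} + sum min(y^2, t^2)
    risks = n - 2.0 * (k + 1) + cum[k + 1] + (n - k - 1) * a[k] ** 2
    t_sure = a[int(np.argmin(risks))]
    return float(min(t_sure, t_univ) * sigma)


def wavelet_denoise(
    signal: np.ndarray, spec: WaveletSpec | None = None
) -> tuple[np.ndarray, PreprocessReport]:
    """Denoise by decomposition, detail-band thresholding and reconstruction.

    Only detail bands are thresholded; the approximation band cA9 passes
    through untouched.  Output length equals input length.
    """
    spec = spec or WaveletSpec()
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise InvalidInputError("signal must be one-dimensional")
    if signal.shape[0] < MIN_SIGNAL_LENGTH:
        raise InvalidInputError(
            f"signal has {signal.shape[0]} samples; a {spec.levels}-level decomposition "
            f"requires at least {MIN_SIGNAL_LENGTH}"
        )
    with warnings.catch_warnings():
        # pywt warns when the level exceeds dwt_max_level for the filter
        # length; the decomposition remains exactly invertible.
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(signal, spec.wavelet, mode=spec.mode, level=spec.levels)
    report = PreprocessReport(energy_in=float(np.sum(signal**2)))

    sigma = _noise_sigma(coeffs[-1])
    if spec.threshold_rule == "fixed":
        per_band = [spec.fixed_threshold] * (len(coeffs) - 1)
        mode = "soft"
    elif spec.threshold_rule == "sure-soft":
        per_band = [_sure_threshold(d, sigma) for d in coeffs[1:]]
        mode = "soft"
    else:
        thr = sigma * np.sqrt(2.0 * np.log(signal.shape[0]))
        per_band = [thr] * (len(coeffs) - 1)
        mode = "soft" if spec.threshold_rule == "universal-soft" else "hard"

    new_coeffs = [coeffs[0]]  # cA untouched
    for d, thr in zip(coeffs[1:], per_band):
        new_coeffs.append(pywt.threshold(d, thr, mode=mode) if thr > 0 else d)
        report.thresholds.append(float(thr))
    denoised = pywt.waverec(new_coeffs, spec.wavelet, mode=spec.mode)[: signal.shape[0]]
    report.energy_denoised = float(np.sum(denoised**2))
    return denoised, report


def remove_dc(signal: np.ndarray) -> np.ndarray:
    """Subtract the sample mean; output mean is 0 to within rounding."""
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise InvalidInputError("cannot remove DC from an empty signal")
    return signal - signal.mean()


def standardize(signal: np.ndarray) -> np.ndarray:
    """Z-score using the population standard deviation over the record."""
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise InvalidInputError("cannot standardize an empty signal")
    sd = signal.std()
    if sd == 0:
        raise DegenerateInputError("constant signal has zero variance")
    return (signal - signal.mean()) / sd


def preprocess_record(
    record: ECGRecord, spec: WaveletSpec | None = None
) -> tuple[ECGRecord, PreprocessReport]:
    """Apply wavelet denoising, DC removal and z-scoring to one record."""
    denoised, report = wavelet_denoise(record.samples, spec)
    report.dc_offset = float(denoised.mean())
    centered = remove_dc(denoised)
    sd = centered.std()
    if sd == 0:
        raise DegenerateInputError("denoised signal is constant; cannot standardize")
    report.standardize_mean = report.dc_offset
    report.standardize_sd = float(sd)
    out = replace_samples(record, centered / sd)
    return out, report


def replace_samples(record: ECGRecord, samples: np.ndarray) -> ECGRecord:
    """Copy a record with new samples, preserving metadata."""
    return ECGRecord(
        samples=samples,
        fs=record.fs,
        vas=record.vas,
        profile=record.profile,
        vas_trajectory=record.vas_trajectory,
        record_id=record.record_id,
    )
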