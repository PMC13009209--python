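"""Extraction of the three oriented REM-gating features.

All three features are oriented so that larger values indicate tighter
gating of internally generated content:

* ``coupling_vl`` — slow-oscillation/spindle coupling, summarized as the
  mean vector length of spindle-event SO phases (in [0, 1]);
* ``rem_mean_bout_min`` — REM continuity, the mean REM bout duration in
  minutes;
* ``one_over_f_steepness`` — minus the aperiodic (log-log) spectral slope;
  larger steepness indexes lower cortical excitability.

The composite is amplitude-free by construction: the coupling metric uses
only event phases, bout durations come from the hypnogram, and the 1/f
slope is invariant to rescaling the signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt, welch

from .exceptions import InsufficientDataError, InvalidConfigError
from .synthetic import EpochSignal, FEATURE_CSV_COLUMNS, Hypnogram

__all__ = [
    "SpindleEvent",
    "DEFAULT_SO_BAND",
    "DEFAULT_SPINDLE_BAND",
    "DEFAULT_FIT_BAND",
    "so_phase_series",
    "detect_spindle_events",
    "coupling_vector_length",
    "aperiodic_steepness",
    "rem_mean_bout_duration",
    "extract_subject_features",
]

DEFAULT_SO_BAND = (0.3, 1.5)
DEFAULT_SPINDLE_BAND = (11.0, 16.0)
DEFAULT_FIT_BAND = (30.0, 45.0)


@dataclass(frozen=True)
class SpindleEvent:
    """A detected spindle burst: peak time, SO phase at the peak, amplitude."""

    peak_time: float
    so_phase_at_peak: float
    amplitude: float


def _bandpass(x: np.ndarray, fs: float, band: tuple[float, float], order: int = 4) -> np.ndarray:
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise InvalidConfigError(f"band {band} must satisfy 0 < lo < hi < fs/2 = {fs / 2}")
    sos = butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def so_phase_series(epoch: EpochSignal, so_band: tuple[float, float] = DEFAULT_SO_BAND) -> np.ndarray:
    """Instantaneous slow-oscillation phase, one value per sample.

    The signal is band-passed to ``so_band`` and the analytic-signal angle
    is returned, wrapped to (-pi, pi]. Phase convention: 0 at the positive
    peak of the filtered slow oscillation (a cosine has phase 0 at its
    maximum). Only phase *differences* matter downstream, but the
    convention is fixed so generator and extractor agree.
    """
    if epoch.duration_s < 10.0 / so_band[0]:
        raise InsufficientDataError(
            f"epoch of {epoch.duration_s:.1f}s too short for SO phase "
            f"(need >= {10.0 / so_band[0]:.1f}s at lo={so_band[0]} Hz)"
        )
    filtered = _bandpass(epoch.samples, epoch.fs, so_band)
    return np.angle(hilbert(filtered))


def detect_spindle_events(
    epoch: EpochSignal,
    spindle_band: tuple[float, float] = DEFAULT_SPINDLE_BAND,
    threshold_sd: float = 1.5,
    min_duration_s: float = 0.3,
    smooth_s: float = 0.2,
    so_band: tuple[float, float] = DEFAULT_SO_BAND,
) -> list[SpindleEvent]:
    """Envelope-threshold spindle detection with SO phase attached.

    The epoch is band-passed to ``spindle_band``; the Hilbert envelope is
    smoothed with a ``smooth_s`` moving average; samples exceeding
    mean + ``threshold_sd`` * SD of the envelope for at least
    ``min_duration_s`` form one event, timestamped at the envelope peak.
    An empty list is a valid result.
    """
    if epoch.fs < 4 * spindle_band[1]:
        raise InvalidConfigError("fs must be >= 4x the spindle-band upper edge")
    filtered = _bandpass(epoch.samples, epoch.fs, spindle_band)
    envelope = np.abs(hilbert(filtered))
    k = max(1, int(round(smooth_s * epoch.fs)))
    envelope = np.convolve(envelope, np.ones(k) / k, mode="same")
    thr = envelope.mean() + threshold_sd * envelope.std()
    above = envelope > thr
    if not above.any():
        return []
    phases = so_phase_series(epoch, so_band)
    # run boundaries
    idx = np.flatnonzero(np.diff(np.concatenate(([0], above.astype(int), [0]))))
    run_starts, run_ends = idx[0::2], idx[1::2]
    min_len = int(round(min_duration_s * epoch.fs))
    events: list[SpindleEvent] = []
    for s, e in zip(run_starts, run_ends):
        if e - s < min_len:
            continue
        peak = s + int(np.argmax(envelope[s:e]))
        events.append(
            SpindleEvent(
                peak_time=peak / epoch.fs,
                so_phase_at_peak=float(phases[peak]),
                amplitude=float(envelope[peak]),
            )
        )
    return events


def coupling_vector_length(
    events: Sequence[SpindleEvent] | Iterable[float],
) -> tuple[float, float]:
    """Mean resultant vector of event phases.

    Accepts either detected :class:`SpindleEvent` objects or raw phases in
    radians. Returns ``(R, preferred_phase)`` where R is the modulus of the
    mean unit phasor (in [0, 1]) and ``preferred_phase`` its argument.
    """
    events = list(events)
    if len(events) == 0:
        raise InsufficientDataError("no spindle events: coupling is missing, not 0")
    if isinstance(events[0], SpindleEvent):
        phases = np.array([e.so_phase_at_peak for e in events], dtype=float)
    else:
        phases = np.asarray(events, dtype=float)
    z = np.exp(1j * phases).mean()
    return float(np.abs(z)), float(np.angle(z))


def aperiodic_steepness(
    epoch: EpochSignal,
    fit_band: tuple[float, float] = DEFAULT_FIT_BAND,
    nperseg_s: float = 4.0,
) -> float:
    """1/f steepness = minus the slope of log10(power) on log10(frequency).

    Welch PSD (``nperseg_s``-second Hann segments, 50% overlap), ordinary
    least squares over ``fit_band``. The default band sits above sleep
    oscillatory peaks so a plain log-log fit is unbiased by them. Invariant
    to multiplying the signal by a positive constant.
    """
    lo, hi = fit_band
    if not 0 < lo < hi < epoch.fs / 2:
        raise InvalidConfigError("fit_band must lie inside (0, fs/2)")
    if epoch.duration_s < 60:
        raise InsufficientDataError("aperiodic fit requires epochs of >= 60 s")
    f, pxx = welch(epoch.samples, fs=epoch.fs, nperseg=int(round(nperseg_s * epoch.fs)))
    mask = (f >= lo) & (f <= hi) & (pxx > 0)
    if mask.sum() < 5:
        raise InsufficientDataError("fewer than 5 PSD bins in the fit band")
    slope = np.polyfit(np.log10(f[mask]), np.log10(pxx[mask]), 1)[0]
    return float(-slope)


def rem_mean_bout_duration(h: Hypnogram) -> float:
    """Mean REM bout duration in minutes; NaN (with a warning) if no REM."""
    durations = h.stage_durations("REM")
    if durations.size == 0:
        warnings.warn("hypnogram has no REM bouts; REM continuity is missing", stacklevel=2)
        return float("nan")
    return float(durations.mean() / 60.0)


def extract_subject_features(
    epoch: EpochSignal,
    hypnogram: Hypnogram,
    subject_id: str,
    group: str,
    so_band: tuple[float, float] = DEFAULT_SO_BAND,
    spindle_band: tuple[float, float] = DEFAULT_SPINDLE_BAND,
    fit_band: tuple[float, float] = DEFAULT_FIT_BAND,
    threshold_sd: float = 1.5,
) -> dict:
    """One feature-CSV row for a subject; missing features stay NaN."""
    events = detect_spindle_events(
        epoch, spindle_band=spindle_band, threshold_sd=threshold_sd, so_band=so_band
    )
    if events:
        r, _ = coupling_vector_length(events)
    else:
        warnings.warn(f"{subject_id}: no spindle events detected; coupling missing", stacklevel=2)
        r = float("nan")
    row = {
        "subject_id": subject_id,
        "group": group,
        "channel": epoch.channel,
        "coupling_vl": r,
        "rem_mean_bout_min": rem_mean_bout_duration(hypnogram),
        "one_over_f_steepness": aperiodic_steepness(epoch, fit_band=fit_band),
    }
    assert set(row) == set(FEATURE_CSV_COLUMNS)
    return row
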