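"""Wavelet spectrogram and oscillatory-event detection.

A complex Morlet wavelet transform (default seven cycles) produces a
time-frequency power matrix on a 1-100 Hz grid with 0.5 Hz steps.  Each
frequency row is normalized by its own median power; local maxima whose
normalized power exceeds the median threshold (4.0) seed candidate events.
A bounding box is grown around each maximum, expanding along time at the
peak frequency and along frequency at the peak time until the normalized
power falls below half the detection threshold (equivalently, half the
peak value for an event sitting exactly at threshold).  Boxes overlapping
more than the overlap threshold (0.5, as a fraction of the smaller box)
are pruned, keeping the higher-peak event.  Per-event features: duration,
frequency span, cycle count (duration x peak frequency) and wave height
(peak-to-trough amplitude of the signal band-passed to the event's
frequency box within its time window).

Median normalization makes detection invariant to an overall positive
rescaling of the signal; wave height scales linearly with it.

Events are classified into bands by their peak frequency: delta 0.5-4,
theta 4-9, alpha 9-15, beta 15-29, low gamma 30-40, gamma 40-80 Hz
(half-open intervals).  The 29-30 Hz gap in this table is preserved
verbatim; peaks inside it map to the nearer band and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps
from scipy.ndimage import maximum_filter

__all__ = [
    "EventDetectionParams",
    "OscEvent",
    "BAND_TABLE",
    "wavelet_spectrogram",
    "detect_events",
    "event_features",
    "classify_band",
    "analyze_events",
]

#: band table (label, lo, hi) in Hz, half-open [lo, hi)
BAND_TABLE = (
    ("delta", 0.5, 4.0),
    ("theta", 4.0, 9.0),
    ("alpha", 9.0, 15.0),
    ("beta", 15.0, 29.0),
    ("low_gamma", 30.0, 40.0),
    ("gamma", 40.0, 80.0),
)


@dataclass
class EventDetectionParams:
    """Detection settings (reference values of the source protocol, with a
    configurable sampling rate for desk-scale signals)."""

    medthresh: float = 4.0
    freq_min: float = 1.0
    freq_max: float = 100.0
    freq_step: float = 0.5
    winsz: float = 24.0          # s
    overlapth: float = 0.5
    fs: float = 1000.0
    n_cycles: float = 7.0        # Morlet width

    def __post_init__(self) -> None:
        if self.medthresh <= 1.0:
            raise ValueError("medthresh must exceed 1")
        if not 0.0 <= self.overlapth <= 1.0:
            raise ValueError("overlapth must lie in [0, 1]")

    @property
    def freqs(self) -> np.ndarray:
        return np.arange(self.freq_min, self.freq_max + self.freq_step / 2,
                         self.freq_step)


@dataclass
class OscEvent:
    """One detected oscillation event and its features."""

    peak_freq: float             # Hz
    peak_time: float             # s
    t_start: float
    t_end: float
    f_lo: float
    f_hi: float
    peak_norm_power: float
    duration: float = np.nan     # s
    freq_span: float = np.nan    # Hz
    cycles: float = np.nan
    wave_height: float = np.nan  # signal units, peak-to-trough
    band: str = ""
    in_band_gap: bool = False

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("event duration must be positive")


def wavelet_spectrogram(x, fs: float,
                        params: EventDetectionParams | None = None,
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Morlet-wavelet power matrix.

    Returns (power[(n_freqs, n_times)], freqs, times).  The complex Morlet
    bandwidth is chosen so the wavelet spans ``n_cycles`` cycles
    (sd_t = n_cycles / (2 pi f)).
    """
    params = params or EventDetectionParams(fs=fs)
    x = np.asarray(x, dtype=float)
    if fs < 2.0 * params.freq_max:
        raise ValueError(
            f"fs={fs} Hz too low for freq_max={params.freq_max} Hz")
    if x.size < int(params.winsz * fs):
        raise ValueError("signal shorter than the analysis window")
    freqs = params.freqs
    # cmorB-C: psi(u) ~ exp(2 pi i C u) exp(-u^2 / B); sd_u = sqrt(B/2)
    # scale s maps u = t/(s dt); want sd_t = n_cycles/(2 pi f)
    fc = 1.0
    B = 2.0 * (params.n_cycles / (2.0 * np.pi)) ** 2
    wavelet = f"cmor{B}-{fc}"
    dt = 1.0 / fs
    scales = fc / (freqs * dt)
    coef, _ = pywt.cwt(x, scales, wavelet, sampling_period=dt, method="fft")
    power = np.abs(coef) ** 2
    times = np.arange(x.size) * dt
    return power, freqs, times


def _grow_box(normpow: np.ndarray, fi: int, ti: int,
              stop_level: float) -> tuple[int, int, int, int]:
    """Expand a bounding box around a local maximum until the normalized
    power falls below ``stop_level`` (along time at the peak frequency, and
    along frequency at the peak time)."""
    row = normpow[fi]
    t_lo = ti
    while t_lo > 0 and row[t_lo - 1] >= stop_level:
        t_lo -= 1
    t_hi = ti
    while t_hi < row.size - 1 and row[t_hi + 1] >= stop_level:
        t_hi += 1
    col = normpow[:, ti]
    f_lo = fi
    while f_lo > 0 and col[f_lo - 1] >= stop_level:
        f_lo -= 1
    f_hi = fi
    while f_hi < col.size - 1 and col[f_hi + 1] >= stop_level:
        f_hi += 1
    return f_lo, f_hi, t_lo, t_hi


def _overlap_fraction(a: OscEvent, b: OscEvent) -> float:
    """Bounding-box overlap as a fraction of the smaller box area."""
    dt = min(a.t_end, b.t_end) - max(a.t_start, b.t_start)
    df = min(a.f_hi, b.f_hi) - max(a.f_lo, b.f_lo)
    if dt <= 0 or df <= 0:
        return 0.0
    inter = dt * df
    area_a = (a.t_end - a.t_start) * (a.f_hi - a.f_lo)
    area_b = (b.t_end - b.t_start) * (b.f_hi - b.f_lo)
    return inter / min(area_a, area_b)


def detect_events(power: np.ndarray, freqs: np.ndarray, times: np.ndarray,
                  params: EventDetectionParams | None = None) -> list:
    """Detect oscillation events on a wavelet power matrix.

    Per frequency row the power is normalized by that row's median; local
    maxima above ``medthresh`` seed events, boxes grow to the half-peak
    level, and overlapping boxes (> ``overlapth`` of the smaller box) are
    pruned keeping the higher peak.
    """
    params = params or EventDetectionParams()
    power = np.asarray(power, dtype=float)
    if not np.any(power > 0):
        return []
    med = np.median(power, axis=1, keepdims=True)
    med[med <= 0] = np.inf  # silent rows cannot produce events
    normpow = power / med

    local_max = (power == maximum_filter(power, size=3)) \
        & (normpow >= params.medthresh)
    cand = np.argwhere(local_max)
    # strongest first so pruning keeps the higher-peak event
    order = np.argsort(-normpow[local_max])
    cand = cand[order]

    dt = times[1] - times[0] if times.size > 1 else 1.0
    df = freqs[1] - freqs[0] if freqs.size > 1 else 1.0
    events: list[OscEvent] = []
    # the box stops where the normalized power falls below half the
    # detection threshold; for a peak sitting exactly at threshold this
    # equals half the peak value, and for stronger peaks it lets the box
    # cover the full extent of the event rather than its tip
    stop_level = params.medthresh / 2.0
    for fi, ti in cand:
        peak_norm = normpow[fi, ti]
        f_lo, f_hi, t_lo, t_hi = _grow_box(normpow, fi, ti,
                                           min(peak_norm / 2.0, stop_level))
        ev = OscEvent(
            peak_freq=float(freqs[fi]), peak_time=float(times[ti]),
            t_start=float(times[t_lo]), t_end=float(times[t_hi] + dt),
            f_lo=float(freqs[f_lo]), f_hi=float(freqs[f_hi] + df),
            peak_norm_power=float(peak_norm))
        if any(_overlap_fraction(ev, kept) > params.overlapth
               for kept in events):
            continue
        band, in_gap = classify_band(ev.peak_freq)
        ev.band = band
        ev.in_band_gap = in_gap
        events.append(ev)
    return events


def event_features(event: OscEvent, x, fs: float) -> OscEvent:
    """Fill duration, span, cycle count and wave height from the raw signal.

    Wave height is the maximum peak-to-trough amplitude of the signal
    band-pass filtered to the event's frequency box, inside the event's
    time window."""
    x = np.asarray(x, dtype=float)
    event.duration = event.t_end - event.t_start
    event.freq_span = event.f_hi - event.f_lo
    event.cycles = event.duration * event.peak_freq
    lo = max(event.f_lo, 0.1)
    hi = min(event.f_hi, 0.99 * fs / 2.0)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, x)
    i0 = max(0, int(event.t_start * fs))
    i1 = min(x.size, int(np.ceil(event.t_end * fs)) + 1)
    seg = filtered[i0:i1]
    event.wave_height = float(seg.max() - seg.min()) if seg.size else np.nan
    return event


def classify_band(peak_freq: float) -> tuple[str, bool]:
    """Band label for a peak frequency; half-open [lo, hi) intervals.

    Returns (label, in_gap): frequencies inside the 29-30 Hz gap of the
    band table map to the nearer band with ``in_gap=True``; frequencies
    outside 0.5-80 Hz are 'unclassified'."""
    f = float(peak_freq)
    for label, lo, hi in BAND_TABLE:
        if lo <= f < hi:
            return label, False
    if 29.0 <= f < 30.0:
        return ("beta", True) if f < 29.5 else ("low_gamma", True)
    return "unclassified", False


def analyze_events(x, fs: float,
                   params: EventDetectionParams | None = None) -> list:
    """Spectrogram -> detection -> feature extraction in one call."""
    params = params or EventDetectionParams(fs=fs)
    power, freqs, times = wavelet_spectrogram(x, fs, params)
    evts = detect_events(power, freqs, times, params)
    return [event_features(ev, x, fs) for ev in evts]
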