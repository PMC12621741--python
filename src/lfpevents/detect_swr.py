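"""Sharp wave-ripple detection from the ripple-band envelope.

The envelope is the magnitude of the analytic signal of the 120-180 Hz
filtered trace; instantaneous frequency is the derivative of its unwrapped
phase, clipped to the ripple band. Candidate peaks of the envelope must
exceed a peak threshold (in SDs of the envelope over the whole recording),
span a contiguous supra-edge-threshold region of at least the minimum
duration, and carry a mean instantaneous frequency at or above the band's
lower edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import EventTable, default_event_row
from .params import ParamSet

__all__ = [
    "SwrDetectionParams",
    "ripple_envelope",
    "instantaneous_frequency",
    "detect_swr_channel",
]


@dataclass
class SwrDetectionParams:
    peak_threshold_sd: float = 5.0
    edge_threshold_sd: float = 2.5
    min_duration_ms: float = 20.0
    min_mean_freq_hz: float = 120.0
    min_interval_ms: float = 100.0
    cycle_reindex_window_ms: float = 40.0
    freq_clip_hz: tuple[float, float] = (120.0, 180.0)

    @staticmethod
    def from_paramset(p: ParamSet) -> "SwrDetectionParams":
        return SwrDetectionParams(
            peak_threshold_sd=p.swr_peak_threshold_sd,
            edge_threshold_sd=p.swr_edge_threshold_sd,
            min_duration_ms=p.swr_min_duration_ms,
            min_mean_freq_hz=p.swr_min_mean_freq_hz,
            min_interval_ms=p.swr_min_interval_ms,
            cycle_reindex_window_ms=p.swr_cycle_reindex_window_ms,
            freq_clip_hz=(p.ripple_low_hz, p.ripple_high_hz),
        )


def ripple_envelope(ripple_filtered: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic (Hilbert) signal; >= 0 everywhere."""
    return np.abs(signal.hilbert(np.asarray(ripple_filtered, dtype=float), axis=-1))


def instantaneous_frequency(ripple_filtered: np.ndarray, fs: float,
                            clip: tuple[float, float] = (120.0, 180.0)) -> np.ndarray:
    """Instantaneous frequency (Hz) of the ripple-filtered trace.

    Computed from the discrete derivative of the unwrapped analytic phase
    (central gradient), then clipped to the ripple band so out-of-band
    excursions saturate at the edges.
    """
    phase = np.unwrap(np.angle(signal.hilbert(np.asarray(ripple_filtered, dtype=float),
                                              axis=-1)), axis=-1)
    freq = np.gradient(phase, axis=-1) * fs / (2 * np.pi)
    return np.clip(freq, clip[0], clip[1])


def _edge_crossing(env: np.ndarray, idx_inside: int, idx_outside: int,
                   thr: float) -> float:
    """Fractional sample index where env crosses thr between two samples."""
    a, b = env[idx_outside], env[idx_inside]
    if b == a:
        return float(idx_inside)
    frac = (thr - a) / (b - a)
    return idx_outside + frac * (idx_inside - idx_outside)


def detect_swr_channel(
    ripple_filtered: np.ndarray,
    raw: np.ndarray,
    fs: float,
    params: SwrDetectionParams,
    channel: int = 0,
    t0: float = 0.0,
    probe_id: int = 0,
    shank_id: int = 0,
) -> tuple[EventTable, dict]:
    """Detect SPW-R events on one channel.

    Returns the event table plus a dict of the per-channel absolute
    thresholds actually applied (envelope SD, peak and edge levels), which
    are recorded alongside the saved tables.
    """
    ripple_filtered = np.asarray(ripple_filtered, dtype=float)
    raw = np.asarray(raw, dtype=float)
    env = ripple_envelope(ripple_filtered)
    sd = env.std()
    mean = env.mean()
    # thresholds are z-scores of the envelope: the envelope of band-limited
    # noise is Rayleigh-distributed with a large positive mean, so bare
    # multiples of the SD would sit inside the noise floor
    thresholds = {
        "envelope_mean": float(mean),
        "envelope_sd": float(sd),
        "peak_level": float(mean + params.peak_threshold_sd * sd),
        "edge_level": float(mean + params.edge_threshold_sd * sd),
    }
    if sd == 0:
        return EventTable(), thresholds

    freq = instantaneous_frequency(ripple_filtered, fs, params.freq_clip_hz)
    min_gap = max(1, int(round(params.min_interval_ms * fs / 1000)))
    peaks, _ = signal.find_peaks(env, height=thresholds["peak_level"],
                                 distance=min_gap)
    n = len(env)
    edge = thresholds["edge_level"]
    rows = []
    prev_extent_end = -np.inf
    for pk in peaks:
        # contiguous supra-edge region around the peak
        lo = pk
        while lo > 0 and env[lo - 1] >= edge:
            lo -= 1
        hi = pk
        while hi < n - 1 and env[hi + 1] >= edge:
            hi += 1
        # sub-sample duration via linear interpolation at the crossings
        left = _edge_crossing(env, lo, lo - 1, edge) if lo > 0 else float(lo)
        right = _edge_crossing(env, hi, hi + 1, edge) if hi < n - 1 else float(hi)
        duration_ms = (right - left) / fs * 1000
        if duration_ms < params.min_duration_ms:
            continue
        mean_freq = float(freq[lo:hi + 1].mean())
        if mean_freq < params.min_mean_freq_hz:
            continue
        if lo <= prev_extent_end:   # extents on one channel never overlap
            continue
        prev_extent_end = hi
        # re-index to the largest positive ripple cycle near the peak
        half_w = int(round(params.cycle_reindex_window_ms * fs / 2000))
        wlo, whi = max(0, pk - half_w), min(n, pk + half_w + 1)
        cyc = wlo + int(np.argmax(ripple_filtered[wlo:whi]))
        rows.append(default_event_row(
            kind="swr", probe_id=probe_id, shank_id=shank_id, channel=channel,
            sample_index=cyc, time_s=t0 + cyc / fs,
            amplitude_mV=float(raw[cyc]),
            duration_ms=duration_ms,
            mean_inst_freq_Hz=mean_freq,
            envelope_peak=float(env[pk]),
        ))
    table = EventTable.from_rows(rows)
    if len(table):
        table.df["event_id"] = np.arange(len(table))
    return table, thresholds
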