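"""Dentate-spike candidate detection on the 5-100 Hz filtered LFP.

Positive peaks exceeding a height threshold and a minimum prominence are
kept; within any minimum-interval window only the most prominent peak
survives, so multi-peaked DSs are not split into several events. Each
event is then re-indexed to the maximum of the raw LFP within a 20 ms
window around the filtered peak, and waveform properties (half-width,
asymmetry, height above the surround) are measured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import EventTable, default_event_row
from .params import ParamSet

logger = logging.getLogger(__name__)

__all__ = ["DsDetectionParams", "detect_ds_channel", "ds_waveform_properties"]


@dataclass
class DsDetectionParams:
    """Detection thresholds for one channel.

    ``height_threshold`` and ``min_prominence`` are in SD units of the
    DS-band filtered trace when ``units == 'sd'`` (per-channel calibration),
    or absolute millivolts when ``units == 'mv'``.
    """

    height_threshold: float = 4.0
    min_prominence: float = 2.0
    units: str = "sd"
    min_interval_ms: float = 50.0
    props_window_ms: float = 100.0
    raw_reindex_window_ms: float = 20.0

    @staticmethod
    def from_paramset(p: ParamSet) -> "DsDetectionParams":
        return DsDetectionParams(
            height_threshold=p.ds_height_threshold,
            min_prominence=p.ds_min_prominence,
            units=p.ds_threshold_units,
            min_interval_ms=p.ds_min_interval_ms,
            props_window_ms=p.ds_props_window_ms,
            raw_reindex_window_ms=p.ds_raw_reindex_window_ms,
        )


def _suppress_close_peaks(peaks: np.ndarray, prominences: np.ndarray,
                          min_gap: int) -> np.ndarray:
    """Greedy suppression: keep the most prominent peak in any min-gap
    window; ties break toward the earlier peak."""
    if len(peaks) == 0:
        return peaks
    # order by descending prominence, earlier peak first on ties
    order = np.lexsort((peaks, -prominences))
    keep: list[int] = []
    for idx in order:
        p = peaks[idx]
        if all(abs(p - peaks[k]) >= min_gap for k in keep):
            keep.append(idx)
    return peaks[np.sort(keep)]


def detect_ds_channel(
    filtered: np.ndarray,
    raw: np.ndarray,
    fs: float,
    params: DsDetectionParams,
    channel: int = 0,
    t0: float = 0.0,
    probe_id: int = 0,
    shank_id: int = 0,
) -> EventTable:
    """Detect DS events on one channel.

    *filtered* is the DS-band (5-100 Hz) trace, *raw* the unfiltered LFP,
    both in millivolts. Returns an :class:`EventTable` of active auto
    events sorted by time.
    """
    filtered = np.asarray(filtered, dtype=float)
    raw = np.asarray(raw, dtype=float)
    if filtered.shape != raw.shape:
        raise ValueError("filtered and raw traces must have the same length")
    sd = filtered.std()
    if params.units == "sd":
        height = params.height_threshold * sd
        prominence = params.min_prominence * sd
    else:
        height = params.height_threshold
        prominence = params.min_prominence
    if sd == 0:
        return EventTable()

    peaks, props = signal.find_peaks(filtered, height=height, prominence=prominence)
    if len(peaks) == 0:
        return EventTable()
    min_gap = max(1, int(round(params.min_interval_ms * fs / 1000)))
    peaks = _suppress_close_peaks(peaks, props["prominences"], min_gap)

    half_reindex = int(round(params.raw_reindex_window_ms * fs / 2000))
    rows = []
    n = len(filtered)
    for pk in peaks:
        lo = pk - half_reindex
        hi = pk + half_reindex + 1
        if lo < 0 or hi > n:
            logger.warning("DS at sample %d too close to trace edge; dropped", pk)
            continue
        raw_pk = lo + int(np.argmax(raw[lo:hi]))
        props_dict = ds_waveform_properties(filtered, raw, pk, raw_pk, fs, params)
        rows.append(default_event_row(
            kind="ds", probe_id=probe_id, shank_id=shank_id, channel=channel,
            sample_index=raw_pk, time_s=t0 + raw_pk / fs, **props_dict,
        ))
    table = EventTable.from_rows(rows)
    if len(table):
        table.df["event_id"] = np.arange(len(table))
    return table


def ds_waveform_properties(
    filtered: np.ndarray,
    raw: np.ndarray,
    peak_index: int,
    raw_peak_index: int | None,
    fs: float,
    params: DsDetectionParams,
) -> dict:
    """Waveform properties of one DS peak.

    amplitude: raw LFP at the re-indexed peak (mV).
    half_width: width of the filtered peak at half prominence (ms).
    asymmetry: (t_right - t_left) / (t_right + t_left), where t_left/t_right
        are the times from the half-prominence crossings to the peak;
        positive values mean a slower falling flank.
    height_above_surround: peak amplitude minus the mean raw LFP over the
        flanking windows [-50, -25] and [+25, +50] ms.

    When a half-prominence crossing cannot be located, the width-derived
    properties come back NaN and the event is retained.
    """
    if raw_peak_index is None:
        raw_peak_index = peak_index
    n = len(filtered)
    try:
        widths, _, left_ips, right_ips = signal.peak_widths(
            filtered, [peak_index], rel_height=0.5)
        half_width_ms = float(widths[0]) / fs * 1000
        t_left = (peak_index - float(left_ips[0])) / fs
        t_right = (float(right_ips[0]) - peak_index) / fs
        denom = t_left + t_right
        asym = (t_right - t_left) / denom if denom > 0 else np.nan
        # reject crossings outside the props window
        half_props = params.props_window_ms / 2000 * fs
        if (peak_index - left_ips[0]) > half_props or (right_ips[0] - peak_index) > half_props:
            half_width_ms, asym = np.nan, np.nan
    except ValueError:
        half_width_ms, asym = np.nan, np.nan

    prominences, _, _ = signal.peak_prominences(filtered, [peak_index])
    amplitude = float(raw[raw_peak_index])

    flank = []
    for lo_ms, hi_ms in ((-50, -25), (25, 50)):
        lo = raw_peak_index + int(round(lo_ms * fs / 1000))
        hi = raw_peak_index + int(round(hi_ms * fs / 1000))
        lo, hi = max(0, min(lo, hi)), min(n, max(lo, hi))
        if hi > lo:
            flank.append(raw[lo:hi])
    surround = float(np.mean(np.concatenate(flank))) if flank else np.nan

    return {
        "amplitude_mV": amplitude,
        "half_width_ms": half_width_ms,
        "prominence_mV": float(prominences[0]),
        "asymmetry": asym,
        "height_above_surround_mV": amplitude - surround,
    }
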