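"""Channel summaries, recommended event channels, and event curation.

The headless counterpart of interactive channel selection: per-channel
event statistics, a deterministic recommendation of the theta (fissure),
SPW-R (CA1) and DS (hilus) channels, and programmatic add / delete /
restore / erase curation of event tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .core import ConfigurationError, EventTable, default_event_row
from .csd import CsdParams, compute_csd
from .detect_ds import DsDetectionParams, ds_waveform_properties
from .preprocess import BandProfile

logger = logging.getLogger(__name__)

__all__ = [
    "ChannelChoice",
    "summarize_channels",
    "recommend_channels",
    "add_event",
    "set_event_status",
    "interval_csd",
]


@dataclass
class ChannelChoice:
    """The three landmark channels (analysis indices) with provenance."""

    ds_channel: int            # hilus
    swr_channel: int           # CA1 pyramidal layer
    theta_channel: int         # hippocampal fissure
    origin: str = "auto"       # auto | user

    def to_array(self) -> np.ndarray:
        """[ds, swr, theta] in the fixed NPY order."""
        return np.array([self.ds_channel, self.swr_channel, self.theta_channel],
                        dtype=int)

    @staticmethod
    def from_array(arr: np.ndarray, origin: str = "auto") -> "ChannelChoice":
        ds, swr, theta = (int(v) for v in np.asarray(arr).ravel()[:3])
        return ChannelChoice(ds, swr, theta, origin=origin)


def summarize_channels(ds_table: EventTable, swr_table: EventTable,
                       band_profile: BandProfile) -> pd.DataFrame:
    """One row per channel: event counts, mean amplitudes, ripple/theta ratio.

    Channels with no events carry NaN means; noise channels (NaN in the
    band profile) carry NaN throughout.
    """
    channels = band_profile.raw.index
    ds = ds_table.active()
    swr = swr_table.active()
    out = pd.DataFrame(index=channels)
    ds_by = ds.groupby("channel")
    swr_by = swr.groupby("channel")
    out["ds_count"] = ds_by.size().reindex(channels, fill_value=0)
    out["ds_mean_amplitude"] = ds_by["amplitude_mV"].mean().reindex(channels)
    out["ds_mean_height_above_surround"] = (
        ds_by["height_above_surround_mV"].mean().reindex(channels))
    out["swr_count"] = swr_by.size().reindex(channels, fill_value=0)
    out["swr_mean_amplitude"] = swr_by["envelope_peak"].mean().reindex(channels)
    theta = band_profile.raw["theta"]
    out["ripple_theta_ratio"] = band_profile.raw["ripple"] / theta
    noise = band_profile.raw["theta"].isna()
    out.loc[noise, :] = np.nan
    out.loc[noise, ["ds_count", "swr_count"]] = np.nan
    return out


def _argmax_shallowest(series: pd.Series) -> int:
    """Index of the maximum; ties go to the shallowest (lowest index)."""
    s = series.dropna()
    if s.empty:
        raise ConfigurationError("no valid channels to choose from")
    return int(s.index[np.argmax(s.to_numpy())])   # np.argmax takes first max


def recommend_channels(summary: pd.DataFrame,
                       band_profile: BandProfile) -> ChannelChoice:
    """Deterministic landmark-channel recommendation.

    theta channel: argmax normalized theta amplitude (the fissure);
    SPW-R channel: argmax ripple/theta band ratio;
    DS channel: argmax mean DS amplitude among channels *deeper* than the
    theta channel — the hilus lies below the fissure, and candidate "events"
    above it are likely spurious. All argmax ties break to the shallowest
    channel. Falls back (with a warning) when constraints cannot be met.
    """
    if summary.empty:
        raise ConfigurationError("empty channel summary")
    theta_ch = _argmax_shallowest(band_profile.normalized["theta"])
    swr_ch = _argmax_shallowest(summary["ripple_theta_ratio"])
    deeper = summary.loc[summary.index > theta_ch, "ds_mean_amplitude"].dropna()
    if deeper.empty:
        logger.warning("no channel deeper than the theta channel; "
                       "using the global DS-amplitude argmax")
        ds_ch = _argmax_shallowest(summary["ds_mean_amplitude"])
    else:
        ds_ch = _argmax_shallowest(deeper)
    if len({ds_ch, swr_ch, theta_ch}) < 3:
        logger.warning("recommended channels are not distinct: ds=%d swr=%d theta=%d",
                       ds_ch, swr_ch, theta_ch)
    return ChannelChoice(ds_channel=ds_ch, swr_channel=swr_ch,
                         theta_channel=theta_ch, origin="auto")


def add_event(table: EventTable, channel: int, time_s: float, kind: str,
              raw: np.ndarray, fs: float, filtered: np.ndarray | None = None,
              t0: float = 0.0, min_interval_ms: float = 50.0,
              search_window_ms: float = 50.0) -> EventTable:
    """Manually add an event at the raw-LFP peak nearest *time_s*.

    The event lands on the closest local maximum of the raw trace within
    +/- half of ``search_window_ms``; in a flat region the nearest sample is
    used and the event is flagged low-confidence (NaN prominence). A
    duplicate within ``min_interval_ms`` of an active same-kind event on
    the same channel is rejected.
    """
    raw = np.asarray(raw, dtype=float)
    n = len(raw)
    idx = int(round((time_s - t0) * fs))
    if idx < 0 or idx >= n:
        raise ConfigurationError(f"time {time_s} s outside the recording")
    half = int(round(search_window_ms * fs / 2000))
    lo, hi = max(0, idx - half), min(n, idx + half + 1)
    local_peaks, _ = sp_signal.find_peaks(raw[lo:hi])
    if len(local_peaks):
        peaks = local_peaks + lo
        target = int(peaks[np.argmin(np.abs(peaks - idx))])
        low_confidence = False
    else:
        target = idx
        low_confidence = True
        logger.warning("no local LFP peak near %.3f s; using nearest sample", time_s)
    new_time = t0 + target / fs

    same = table.active()
    same = same[(same["kind"] == kind) & (same["channel"] == channel)]
    if len(same) and (np.abs(same["time_s"] - new_time) * 1000 < min_interval_ms).any():
        raise ConfigurationError(
            f"an active {kind} event already exists within {min_interval_ms} ms")

    row = default_event_row(
        kind=kind, channel=channel, sample_index=target, time_s=new_time,
        amplitude_mV=float(raw[target]), origin="manual",
    )
    if kind == "ds" and filtered is not None and not low_confidence:
        try:
            props = ds_waveform_properties(np.asarray(filtered, dtype=float), raw,
                                           target, target, fs, DsDetectionParams())
            row.update(props)
        except (ValueError, IndexError):
            pass
    out = table.copy()
    next_id = int(out.df["event_id"].max()) + 1 if len(out) else 0
    row["event_id"] = next_id
    if len(out.df):
        out.df.loc[len(out.df)] = [row[c] for c in out.df.columns]
        return EventTable(out.df, out.erased_ids)
    return EventTable(pd.DataFrame([row]), out.erased_ids)


def set_event_status(table: EventTable, event_ids, action: str) -> EventTable:
    """Curation state machine.

    delete -> status "deleted" (restorable); restore -> back to "active";
    erase -> row removed permanently (a later restore of that id errors).
    """
    ids = [int(i) for i in np.atleast_1d(event_ids)]
    out = table.copy()
    known = set(out.df["event_id"].astype(int))
    for i in ids:
        if i not in known:
            if action == "restore" and i in out.erased_ids:
                raise ConfigurationError(
                    f"event {i} was erased and must be manually re-added")
            raise ConfigurationError(f"unknown event id {i}")
    mask = out.df["event_id"].astype(int).isin(ids)
    if action == "delete":
        out.df.loc[mask, "status"] = "deleted"
    elif action == "restore":
        out.df.loc[mask & (out.df["status"] == "deleted"), "status"] = "active"
    elif action == "erase":
        out.df = out.df[~mask].reset_index(drop=True)
        out.erased_ids |= set(ids)
    else:
        raise ConfigurationError(f"unknown curation action {action!r}")
    return EventTable(out.df, out.erased_ids)


def interval_csd(data: np.ndarray, fs: float, channels: np.ndarray,
                 electrode_z_um: np.ndarray, t_start: float, t_end: float,
                 params: CsdParams | None = None, t0: float = 0.0) -> np.ndarray:
    """Instantaneous CSD of a highlighted time interval (raw LFP path).

    Delegates to the CSD module on the [t_start, t_end) slice of the
    depth-ordered data restricted to *channels*.
    """
    params = params or CsdParams()
    i0 = int(round((t_start - t0) * fs))
    i1 = int(round((t_end - t0) * fs))
    if i1 <= i0:
        raise ConfigurationError("empty interval")
    i0 = max(0, i0)
    i1 = min(data.shape[1], i1)
    window = np.asarray(data, dtype=float)[np.ix_(np.asarray(channels, dtype=int),
                                                  np.arange(i0, i1))]
    return compute_csd(window, np.asarray(electrode_z_um, dtype=float), params)
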