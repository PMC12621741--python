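"""End-to-end orchestration: process -> select -> classify.

These functions chain the modules in the order the headless workflow runs
them, and back the CLI subcommands. Each stage records the parameters it
ran with in the ParameterLog when one is supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import ClassificationResult, classify_ds
from .core import ConfigurationError, EventTable, ProbeLayout, Recording, \
    sort_channels_by_depth
from .csd import CsdParams, CSDStack, event_csd_stack
from .detect_ds import DsDetectionParams, detect_ds_channel
from .detect_swr import SwrDetectionParams, detect_swr_channel
from .io_files import ParameterLog
from .params import ParamSet
from .preprocess import BandProfile, band_amplitude_profile, downsample_recording, \
    filter_bank
from .selection import ChannelChoice, recommend_channels, summarize_channels

logger = logging.getLogger(__name__)

__all__ = ["ProcessedRecording", "process_recording", "select_channels",
           "classify_recording"]


@dataclass
class ProcessedRecording:
    """Everything the later stages need, in depth-sorted analysis order."""

    recording: Recording            # downsampled; ordered_data() is depth-sorted
    probe: ProbeLayout
    shank_id: int
    bank: dict                      # band -> channels x samples (analysis order)
    band_profile: BandProfile
    ds_table: EventTable            # all channels
    swr_table: EventTable
    swr_thresholds: pd.DataFrame    # per channel
    params: ParamSet
    electrode_z_um: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def data(self) -> np.ndarray:
        return self.recording.ordered_data()


def process_recording(recording: Recording, probe: ProbeLayout,
                      params: ParamSet | None = None, shank_id: int = 0,
                      probe_id: int = 0,
                      log: ParameterLog | None = None) -> ProcessedRecording:
    """Depth-sort, downsample, filter, and detect events on every channel.

    Noise channels are excluded from band profiles and detection. Channel
    indices everywhere downstream are depth-sorted analysis indices
    (0 = shallowest) on the given probe and shank.
    """
    params = params or ParamSet()
    rec = sort_channels_by_depth(recording, probe, shank_id)
    rec = downsample_recording(rec, params)
    data = rec.ordered_data()
    noise = rec.ordered_noise_mask()
    bank = filter_bank(data, rec.fs, params)
    profile = band_amplitude_profile(bank, noise)

    contacts = probe.depth_order(shank_id)
    z = probe.contact_xy[contacts, 1]

    ds_params = DsDetectionParams.from_paramset(params)
    swr_params = SwrDetectionParams.from_paramset(params)
    ds_tables, swr_tables, thr_rows = [], [], []
    for c in range(data.shape[0]):
        if noise[c]:
            thr_rows.append({"channel": c, "envelope_sd": np.nan,
                             "peak_level": np.nan, "edge_level": np.nan})
            continue
        ds_tables.append(detect_ds_channel(
            bank["ds_band"][c], data[c], rec.fs, ds_params, channel=c,
            t0=rec.t0, probe_id=probe_id, shank_id=shank_id))
        swr_t, thr = detect_swr_channel(
            bank["ripple"][c], data[c], rec.fs, swr_params, channel=c,
            t0=rec.t0, probe_id=probe_id, shank_id=shank_id)
        swr_tables.append(swr_t)
        thr_rows.append({"channel": c, **thr})
    ds_table = EventTable.concat(ds_tables)
    swr_table = EventTable.concat(swr_tables)
    thresholds = pd.DataFrame(thr_rows).set_index("channel")

    if log is not None:
        log.record("preprocess", {
            "fs": rec.fs, "downsample_target_hz": params.downsample_target_hz,
            **{f"{b}_band": f"{lo}-{hi} Hz" for b, (lo, hi) in params.bands().items()},
        })
        log.record("ds_detection", {
            "height_threshold": params.ds_height_threshold,
            "threshold_units": params.ds_threshold_units,
            "min_prominence": params.ds_min_prominence,
            "min_interval_ms": params.ds_min_interval_ms,
        })
        log.record("swr_detection", {
            "peak_threshold_sd": params.swr_peak_threshold_sd,
            "edge_threshold_sd": params.swr_edge_threshold_sd,
            "min_duration_ms": params.swr_min_duration_ms,
            "min_mean_freq_hz": params.swr_min_mean_freq_hz,
        })
    return ProcessedRecording(
        recording=rec, probe=probe, shank_id=shank_id, bank=bank,
        band_profile=profile, ds_table=ds_table, swr_table=swr_table,
        swr_thresholds=thresholds, params=params, electrode_z_um=np.asarray(z),
    )


def select_channels(processed: ProcessedRecording,
                    log: ParameterLog | None = None) -> tuple[pd.DataFrame, ChannelChoice]:
    """Summarize channels and recommend the three landmark channels."""
    summary = summarize_channels(processed.ds_table, processed.swr_table,
                                 processed.band_profile)
    choice = recommend_channels(summary, processed.band_profile)
    if log is not None:
        log.record("channel_selection", {
            "ds_channel": choice.ds_channel, "swr_channel": choice.swr_channel,
            "theta_channel": choice.theta_channel, "origin": choice.origin,
        })
    return summary, choice


def classify_recording(processed: ProcessedRecording, choice: ChannelChoice,
                       seed: int | None = None,
                       log: ParameterLog | None = None
                       ) -> tuple[EventTable, CSDStack, ClassificationResult]:
    """CSD -> PCA -> clustering -> DS1/DS2 labels on the chosen DS channel.

    The CSD window spans the theta (fissure) channel down to the DS (hilus)
    channel, computed on the DS-band filtered LFP. Returns the DS table of
    the chosen channel with the ds_type column filled, the CSD stack, and
    the classification result.
    """
    params = processed.params
    if choice.theta_channel >= choice.ds_channel:
        raise ConfigurationError("theta channel must be shallower than DS channel")
    seed = params.cluster_seed if seed is None else seed
    channels = np.arange(choice.theta_channel, choice.ds_channel + 1)
    csd_params = CsdParams.from_paramset(params)
    ds_events = EventTable(
        processed.ds_table.df[processed.ds_table.df["channel"] == choice.ds_channel],
        processed.ds_table.erased_ids)
    active = ds_events.active()
    if len(active) < 2:
        raise ConfigurationError(
            f"classification needs at least 2 DS events, found {len(active)}")
    stack = event_csd_stack(
        processed.bank["ds_band"], processed.recording.fs, ds_events, channels,
        processed.electrode_z_um[channels], csd_params, t0=processed.recording.t0)
    result = classify_ds(
        stack, theta_channel=choice.theta_channel, ds_channel=choice.ds_channel,
        algorithm=params.cluster_algorithm, k=params.cluster_k,
        epsilon=params.dbscan_epsilon, min_samples=params.dbscan_min_samples,
        seed=seed)

    table = ds_events.copy()
    label_by_id = dict(zip(map(int, result.event_ids), result.labels))
    stacked = set(map(int, stack.event_ids))
    new_types = []
    for _, row in table.df.iterrows():
        eid = int(row["event_id"])
        if eid in label_by_id:
            new_types.append(label_by_id[eid])
        elif eid in stacked:
            new_types.append("undefined")   # excluded from clustering
        else:
            new_types.append(row["ds_type"])
    table.df["ds_type"] = new_types

    if log is not None:
        log.record("csd", {
            "method": params.csd_method,
            "smoothing_sigma": params.csd_smoothing_sigma,
            "vaknin": params.csd_vaknin,
            "event_window_ms": params.csd_event_window_ms,
            "channel_window": f"{choice.theta_channel}-{choice.ds_channel}",
        })
        log.record("classification", {
            "algorithm": result.provenance.get("algorithm"),
            "seed": seed,
            "params": result.provenance.get("params"),
            "counts": result.counts,
            "sink_channels": result.sink_channel,
            "explained_variance": np.round(result.explained_variance, 4).tolist(),
        })
    return table, stack, result
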