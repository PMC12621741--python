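"""Core domain types: recordings, probe layouts, and event tables.

A :class:`Recording` is a channels x samples LFP matrix in millivolts with a
sampling rate; a :class:`ProbeLayout` maps electrode contacts (with x/y
positions in micrometers) onto rows of the data matrix; an
:class:`EventTable` holds detected dentate-spike (DS) or sharp wave-ripple
(SPW-R) events with their waveform properties and curation status.

Depth convention: larger y = shallower (closer to the brain surface), so
"deepest" means smallest y, and sorting a shank's contacts by decreasing y
yields the shallowest-to-deepest analysis order used by every downstream
stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "MappingError",
    "ProbeLayout",
    "Recording",
    "EventTable",
    "EVENT_COLUMNS",
    "build_probe_linear",
    "build_probe_paste",
    "sort_channels_by_depth",
]


class ConfigurationError(ValueError):
    """Invalid probe/parameter configuration."""


class MappingError(ValueError):
    """Data rows cannot be mapped onto probe contacts."""


@dataclass
class ProbeLayout:
    """Electrode geometry plus the wiring onto data rows.

    Parameters
    ----------
    name : str
        Probe identifier, used as the base of the ``<name>_config.json``
        file name.
    contact_xy : (n_contacts, 2) array
        Contact positions in micrometers. Larger y = shallower.
    shank_ids : (n_contacts,) int array
    device_indices : (n_contacts,) int array
        Row of the raw data matrix recorded by each contact. Must be unique.
    """

    name: str
    contact_xy: np.ndarray
    shank_ids: np.ndarray
    device_indices: np.ndarray
    contact_shape: str = "circle"
    contact_size_um: float = 10.0

    def __post_init__(self) -> None:
        self.contact_xy = np.asarray(self.contact_xy, dtype=float).reshape(-1, 2)
        n = len(self.contact_xy)
        self.shank_ids = np.asarray(self.shank_ids, dtype=int)
        self.device_indices = np.asarray(self.device_indices, dtype=int)
        if len(self.shank_ids) != n or len(self.device_indices) != n:
            raise ConfigurationError(
                "contact_xy, shank_ids and device_indices must have equal length"
            )
        if len(np.unique(self.device_indices)) != n:
            raise ConfigurationError("device_indices must be unique")
        # duplicate physical positions are almost always a data-entry error
        if len({(x, y) for x, y in map(tuple, self.contact_xy)}) != n:
            raise ConfigurationError("duplicate contact position (x, y)")

    @property
    def n_contacts(self) -> int:
        return len(self.contact_xy)

    def shanks(self) -> np.ndarray:
        return np.unique(self.shank_ids)

    def depth_order(self, shank: int) -> np.ndarray:
        """Contact indices of one shank, shallowest (largest y) first.

        Ties in y are broken by contact index so the order is deterministic
        and invariant to the order contacts were declared in.
        """
        contacts = np.flatnonzero(self.shank_ids == shank)
        if contacts.size == 0:
            raise ConfigurationError(f"probe {self.name!r} has no shank {shank}")
        y = self.contact_xy[contacts, 1]
        # stable sort on -y; equal depths keep ascending contact index
        return contacts[np.argsort(-y, kind="stable")]


@dataclass
class Recording:
    """Multichannel LFP in millivolts.

    ``channel_order`` is a permutation of data rows giving the
    shallowest-to-deepest analysis order (set by
    :func:`sort_channels_by_depth`); ``noise_mask`` flags rows excluded from
    every analysis stage.
    """

    data: np.ndarray
    fs: float
    t0: float = 0.0
    units: str = "mV"
    channel_order: np.ndarray | None = None
    noise_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ConfigurationError("sampling rate must be positive")
        n = self.n_channels
        if self.channel_order is None:
            self.channel_order = np.arange(n)
        else:
            self.channel_order = np.asarray(self.channel_order, dtype=int)
            if sorted(self.channel_order.tolist()) != list(range(n)) and not set(
                self.channel_order.tolist()
            ) <= set(range(n)):
                raise ConfigurationError("channel_order must index data rows")
        if self.noise_mask is None:
            self.noise_mask = np.zeros(n, dtype=bool)
        else:
            self.noise_mask = np.asarray(self.noise_mask, dtype=bool)
            if self.noise_mask.shape != (n,):
                raise ConfigurationError("noise_mask must have one flag per channel")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def ordered_data(self) -> np.ndarray:
        """Data rows permuted into depth order (shallowest first)."""
        return self.data[self.channel_order]

    def ordered_noise_mask(self) -> np.ndarray:
        return self.noise_mask[self.channel_order]


# Fixed event-table schema; DS-specific and SPW-R-specific columns are NaN
# for the other kind.
EVENT_COLUMNS = [
    "event_id",
    "kind",            # "ds" | "swr"
    "probe_id",
    "shank_id",
    "channel",
    "sample_index",
    "time_s",
    "amplitude_mV",
    "half_width_ms",
    "prominence_mV",
    "asymmetry",
    "height_above_surround_mV",
    "duration_ms",
    "mean_inst_freq_Hz",
    "envelope_peak",
    "status",          # active | deleted  (erased rows are removed)
    "origin",          # auto | manual
    "ds_type",         # 1 | 2 | undefined | unset
]

_INT_COLS = ["event_id", "probe_id", "shank_id", "channel", "sample_index"]


class EventTable:
    """Table of detected events with curation state.

    Thin wrapper around a :class:`pandas.DataFrame` with the fixed
    :data:`EVENT_COLUMNS` schema. Erased event ids are remembered for the
    session so an erased event can never be restored.
    """

    def __init__(self, df: pd.DataFrame | None = None, erased_ids: set[int] | None = None):
        if df is None:
            df = pd.DataFrame(columns=EVENT_COLUMNS)
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"event table missing columns: {missing}")
        df = df[EVENT_COLUMNS].reset_index(drop=True)
        for c in _INT_COLS:
            if len(df):
                df[c] = df[c].astype(int)
        self.df = df
        self.erased_ids: set[int] = set(erased_ids or ())

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "EventTable":
        return EventTable(self.df.copy(), set(self.erased_ids))

    def active(self) -> pd.DataFrame:
        return self.df[self.df["status"] == "active"]

    @staticmethod
    def from_rows(rows: Iterable[dict]) -> "EventTable":
        rows = list(rows)
        if not rows:
            return EventTable()
        df = pd.DataFrame(rows)
        for c in EVENT_COLUMNS:
            if c not in df.columns:
                df[c] = np.nan
        return EventTable(df)

    @staticmethod
    def concat(tables: Sequence["EventTable"]) -> "EventTable":
        frames = [t.df for t in tables if len(t)]
        if not frames:
            return EventTable()
        df = pd.concat(frames, ignore_index=True)
        df["event_id"] = np.arange(len(df))
        erased: set[int] = set()
        for t in tables:
            erased |= t.erased_ids
        return EventTable(df, erased)


def default_event_row(**kwargs) -> dict:
    row = {c: np.nan for c in EVENT_COLUMNS}
    row.update(
        event_id=-1, kind="ds", probe_id=0, shank_id=0, channel=-1,
        sample_index=-1, status="active", origin="auto", ds_type="unset",
    )
    row.update(kwargs)
    return row


def build_probe_linear(
    n_channels: int,
    spacing_um: float,
    tip_offset_um: float = 0.0,
    n_shanks: int = 1,
    mapping: Sequence[int] | None = None,
    name: str = "linear",
    shank_pitch_um: float = 200.0,
) -> ProbeLayout:
    """Build a linear (single- or multi-shank) probe layout.

    Contacts sit on vertical columns, one per shank; contact 0 of each
    shank is shallowest and y decreases by ``spacing_um`` per contact down
    to ``tip_offset_um`` at the tip. ``mapping`` (device index per contact)
    defaults to identity — the physical layout is assumed to match the
    logical data order when no wiring is given.
    """
    if n_channels <= 0 or n_shanks <= 0:
        raise ConfigurationError("channel and shank counts must be positive")
    if n_channels % n_shanks != 0:
        raise ConfigurationError(
            f"{n_channels} channels not divisible by {n_shanks} shanks"
        )
    if spacing_um <= 0:
        raise ConfigurationError("contact spacing must be positive")
    per = n_channels // n_shanks
    xy = np.empty((n_channels, 2))
    shank_ids = np.empty(n_channels, dtype=int)
    for s in range(n_shanks):
        rows = slice(s * per, (s + 1) * per)
        xy[rows, 0] = s * shank_pitch_um
        xy[rows, 1] = tip_offset_um + spacing_um * np.arange(per - 1, -1, -1)
        shank_ids[rows] = s
    if mapping is None:
        device = np.arange(n_channels)
    else:
        device = np.asarray(list(mapping), dtype=int)
        if len(device) != n_channels:
            raise ConfigurationError("mapping length must equal channel count")
    return ProbeLayout(name, xy, shank_ids, device)


def build_probe_paste(
    xs: Sequence[float],
    ys: Sequence[float],
    shank_ids: Sequence[int] | None = None,
    mapping: Sequence[int] | None = None,
    name: str = "pasted",
) -> ProbeLayout:
    """Build a probe from explicit contact coordinates (arbitrary geometry)."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape:
        raise ConfigurationError("xs and ys must have the same length")
    n = len(xs)
    if shank_ids is None:
        shank_ids = np.zeros(n, dtype=int)
    else:
        shank_ids = np.asarray(list(shank_ids), dtype=int)
        if len(shank_ids) != n:
            raise ConfigurationError("shank_ids length must match coordinates")
    device = np.arange(n) if mapping is None else np.asarray(list(mapping), dtype=int)
    return ProbeLayout(name, np.column_stack([xs, ys]), shank_ids, device)


def sort_channels_by_depth(
    recording: Recording, probe: ProbeLayout, shank: int = 0
) -> Recording:
    """Return a copy of *recording* with ``channel_order`` set to the given
    shank's channels, shallowest first.

    Raises :class:`MappingError` if any contact's device index does not
    address a data row (the headless analogue of a blank cell in the
    channel-map table).
    """
    contacts = probe.depth_order(shank)
    device = probe.device_indices[contacts]
    if device.min() < 0 or device.max() >= recording.n_channels:
        raise MappingError(
            f"probe {probe.name!r} device indices {device.tolist()} do not all "
            f"map to the {recording.n_channels} data rows"
        )
    return Recording(
        data=recording.data,
        fs=recording.fs,
        t0=recording.t0,
        units=recording.units,
        channel_order=device,
        noise_mask=recording.noise_mask,
    )
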