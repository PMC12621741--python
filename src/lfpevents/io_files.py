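"""Readers and writers: probe JSON, event CSVs, channel-choice NPY,
the parameter log, and the per-probe recording directory.

Probe configurations use the probeinterface JSON schema (specification /
version / probes with contact_positions, shank_ids, device_channel_indices)
and the ``<name>_config.json`` naming convention, so files are
interchangeable with tools built on that package. CSVs are comma-separated
UTF-8 with Unix newlines and full-precision floats.
"""

from __future__ import annotations

import datetime
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ConfigurationError, EventTable, ProbeLayout, Recording, EVENT_COLUMNS
from .params import ParamSet, read_params, write_params
from .preprocess import BandProfile
from .selection import ChannelChoice

logger = logging.getLogger(__name__)

__all__ = [
    "write_probe_json", "read_probe_json",
    "write_event_csv", "read_event_csv",
    "write_channel_choice", "read_channel_choice",
    "ParameterLog", "read_recording_array", "write_recording_directory",
]

PROBEINTERFACE_VERSION = "0.2.21"


def write_probe_json(probe: ProbeLayout, path) -> Path:
    """Write a probeinterface-schema JSON; returns the path written.

    When *path* is a directory, the file is named ``<name>_config.json``.
    """
    path = Path(path)
    if path.is_dir():
        path = path / f"{probe.name}_config.json"
    n = probe.n_contacts
    payload = {
        "specification": "probeinterface",
        "version": PROBEINTERFACE_VERSION,
        "probes": [{
            "ndim": 2,
            "si_units": "um",
            "annotations": {"name": probe.name, "manufacturer": ""},
            "contact_annotations": {},
            "contact_positions": probe.contact_xy.tolist(),
            "contact_plane_axes": [[[1.0, 0.0], [0.0, 1.0]]] * n,
            "contact_shapes": [probe.contact_shape] * n,
            "contact_shape_params": [{"radius": probe.contact_size_um / 2}] * n,
            "shank_ids": [str(s) for s in probe.shank_ids],
            "device_channel_indices": probe.device_indices.tolist(),
        }],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    return path


def read_probe_json(path) -> ProbeLayout:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("specification") != "probeinterface":
        raise ConfigurationError(f"{path}: not a probeinterface JSON file")
    try:
        p = payload["probes"][0]
        xy = np.asarray(p["contact_positions"], dtype=float)
        shanks = np.asarray([int(s) for s in p["shank_ids"]], dtype=int)
        device = np.asarray(p["device_channel_indices"], dtype=int)
    except (KeyError, IndexError, ValueError) as exc:
        raise ConfigurationError(f"{path}: malformed probe JSON ({exc})") from exc
    name = p.get("annotations", {}).get("name", Path(path).stem.removesuffix("_config"))
    shape = p.get("contact_shapes", ["circle"])[0]
    params = p.get("contact_shape_params", [{"radius": 5.0}])[0]
    size = 2 * params.get("radius", 5.0) if shape == "circle" else params.get("width", 10.0)
    return ProbeLayout(name, xy, shanks, device, contact_shape=shape,
                       contact_size_um=size)


def write_event_csv(table: EventTable, path) -> None:
    """Fixed column order, full float precision, Unix newlines."""
    df = table.df[EVENT_COLUMNS]
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.17g")


def read_event_csv(path) -> EventTable:
    # round_trip parsing: the default fast path can be off by one ulp,
    # breaking the exact write->read identity the tables guarantee
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing mandatory columns {missing}")
    if len(df) == 0:
        return EventTable()
    df["ds_type"] = df["ds_type"].astype(str)
    return EventTable(df)


def _suffix(probe_id: int, shank_id: int) -> str:
    return f"probe{probe_id}_shank{shank_id}"


def write_channel_choice(choice: ChannelChoice, directory, probe_id: int = 0,
                         shank_id: int = 0) -> Path:
    """NPY array [ds, swr, theta] (0-based analysis channel indices)."""
    path = Path(directory) / f"event_channels_{_suffix(probe_id, shank_id)}.npy"
    np.save(path, choice.to_array())
    return path


def read_channel_choice(directory, probe_id: int = 0, shank_id: int = 0,
                        origin: str = "auto") -> ChannelChoice:
    path = Path(directory) / f"event_channels_{_suffix(probe_id, shank_id)}.npy"
    return ChannelChoice.from_array(np.load(path), origin=origin)


class ParameterLog:
    """Append-only plain-text log of the parameters each stage ran with.

    Each record is ``[timestamp] stage | name = value``. The log body
    (timestamps stripped) is deterministic for identical inputs, so reruns
    can be diffed.
    """

    def __init__(self, path):
        self.path = Path(path)

    def record(self, stage: str, params: dict) -> None:
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        with open(self.path, "a", encoding="utf-8") as fh:
            for name, value in params.items():
                fh.write(f"[{stamp}] {stage} | {name} = {value}\n")

    def body(self) -> list[str]:
        """Log lines with timestamps stripped (for determinism checks)."""
        if not self.path.exists():
            return []
        out = []
        for line in self.path.read_text(encoding="utf-8").splitlines():
            out.append(line.partition("] ")[2] if line.startswith("[") else line)
        return out


def read_recording_array(path, fs: float, units: str = "mV",
                         orientation: str = "channels_first",
                         scale_to_mv: float | None = None) -> Recording:
    """Load a generic array file (.npy, or delimited text) as a Recording.

    *fs* and *units* must be supplied by the caller when the file carries
    no metadata. ``orientation`` says whether rows are channels
    (``channels_first``) or samples (``samples_first``). ``scale_to_mv``
    overrides the unit-based scaling (uV -> 1e-3, V -> 1e3, mV -> 1).
    """
    path = Path(path)
    if path.suffix == ".npy":
        data = np.load(path)
    else:
        data = np.loadtxt(path, delimiter="," if path.suffix == ".csv" else None)
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if orientation == "samples_first":
        data = data.T
    elif orientation != "channels_first":
        raise ConfigurationError(f"unknown orientation {orientation!r}")
    if scale_to_mv is None:
        scale_to_mv = {"mV": 1.0, "uV": 1e-3, "V": 1e3}.get(units)
        if scale_to_mv is None:
            raise ConfigurationError(f"unknown voltage units {units!r}")
    return Recording(data=data * scale_to_mv, fs=fs, units="mV")


def write_recording_directory(
    outdir,
    probe: ProbeLayout,
    params: ParamSet,
    recording: Recording,
    bank: dict[str, np.ndarray],
    band_profile: BandProfile,
    ds_table: EventTable,
    swr_table: EventTable,
    swr_thresholds: pd.DataFrame | None = None,
    probe_id: int = 0,
    shank_id: int = 0,
    overwrite: bool = False,
    save_signals: bool = True,
) -> Path:
    """Lay out one probe's processed outputs under ``outdir/probe<k>/``.

    Contains the scaled/downsampled LFP and filtered bands (NPY), the band
    profile CSV, the per-channel DS and SPW-R event CSVs, a copy of the
    probe JSON and parameter file, and the parameter log.
    """
    outdir = Path(outdir)
    probe_dir = outdir / f"probe{probe_id}"
    if probe_dir.exists() and not overwrite:
        raise ConfigurationError(
            f"{probe_dir} exists; pass overwrite=True to replace it")
    probe_dir.mkdir(parents=True, exist_ok=True)
    sfx = _suffix(probe_id, shank_id)
    if save_signals:
        np.save(probe_dir / f"lfp_{sfx}.npy", recording.ordered_data())
        for band, mat in bank.items():
            np.save(probe_dir / f"lfp_{band}_{sfx}.npy", mat)
    band_profile.to_frame().to_csv(probe_dir / f"band_profile_{sfx}.csv",
                                   index=False, lineterminator="\n")
    write_event_csv(ds_table, probe_dir / f"ds_events_{sfx}.csv")
    write_event_csv(swr_table, probe_dir / f"swr_events_{sfx}.csv")
    if swr_thresholds is not None:
        swr_thresholds.to_csv(probe_dir / f"swr_thresholds_{sfx}.csv",
                              lineterminator="\n")
    write_probe_json(probe, probe_dir)
    write_params(params, probe_dir / "params.txt")
    with open(probe_dir / "recording_info.json", "w", encoding="utf-8") as fh:
        json.dump({"fs": recording.fs, "t0": recording.t0,
                   "n_channels": int(recording.n_channels),
                   "n_samples": int(recording.n_samples),
                   "shank_id": shank_id,
                   "channel_order": recording.channel_order.tolist(),
                   "noise_mask": recording.noise_mask.tolist()}, fh, indent=2)
    return probe_dir


def load_processed_directory(outdir, probe_id: int = 0,
                             shank_id: int | None = None):
    """Rebuild a :class:`~lfpevents.pipeline.ProcessedRecording` from a
    recording directory written by :func:`write_recording_directory`."""
    from .params import read_params
    from .pipeline import ProcessedRecording   # local import to avoid a cycle

    probe_dir = Path(outdir) / f"probe{probe_id}"
    with open(probe_dir / "recording_info.json", "r", encoding="utf-8") as fh:
        info = json.load(fh)
    if shank_id is None:
        shank_id = info.get("shank_id", 0)
    sfx = _suffix(probe_id, shank_id)
    order = np.asarray(info["channel_order"], dtype=int)
    noise = np.asarray(info["noise_mask"], dtype=bool)
    data = np.load(probe_dir / f"lfp_{sfx}.npy")
    # saved signals are already depth-ordered: identity order, ordered mask
    rec = Recording(data=data, fs=info["fs"], t0=info["t0"],
                    noise_mask=noise[order])
    params = read_params(probe_dir / "params.txt")
    bank = {}
    for band in ("theta", "slow_gamma", "fast_gamma", "ripple", "ds_band"):
        bank[band] = np.load(probe_dir / f"lfp_{band}_{sfx}.npy")
    prof_long = pd.read_csv(probe_dir / f"band_profile_{sfx}.csv")
    raw = prof_long.pivot(index="channel", columns="band", values="raw")
    norm = prof_long.pivot(index="channel", columns="band", values="normalized")
    raw.columns.name = norm.columns.name = None
    raw.index.name = norm.index.name = "channel"
    profile = BandProfile(raw=raw, normalized=norm)
    ds_table = read_event_csv(probe_dir / f"ds_events_{sfx}.csv")
    swr_table = read_event_csv(probe_dir / f"swr_events_{sfx}.csv")
    thr_path = probe_dir / f"swr_thresholds_{sfx}.csv"
    thresholds = pd.read_csv(thr_path, index_col="channel") if thr_path.exists() \
        else pd.DataFrame()
    probe = read_probe_json(next(probe_dir.glob("*_config.json")))
    contacts = probe.depth_order(shank_id)
    z = probe.contact_xy[contacts, 1]
    return ProcessedRecording(
        recording=rec, probe=probe, shank_id=shank_id, bank=bank,
        band_profile=profile, ds_table=ds_table, swr_table=swr_table,
        swr_thresholds=thresholds, params=params, electrode_z_um=np.asarray(z),
    )
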