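"""Scaling, downsampling, the five-band filter bank, and band profiles.

The filter bank isolates theta (6-10 Hz), slow gamma (25-55 Hz), fast gamma
(60-100 Hz), ripple (120-180 Hz) and the broad 5-100 Hz band used for DS
detection. Filters are 4th-order Butterworth band-passes applied
forward-backward (zero phase) with reflect padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .core import ConfigurationError, Recording
from .params import ParamSet

__all__ = [
    "DownsamplePlan",
    "decide_downsampling",
    "downsample_bin_average",
    "downsample_recording",
    "bandpass",
    "filter_bank",
    "BandProfile",
    "band_amplitude_profile",
]

BAND_NAMES = ["theta", "slow_gamma", "fast_gamma", "ripple", "ds_band"]


@dataclass(frozen=True)
class DownsamplePlan:
    """Either no downsampling or bin-averaging by an integer factor."""

    kind: str               # "none" | "bin_average"
    factor: int = 1

    @property
    def none(self) -> bool:
        return self.kind == "none"


def decide_downsampling(fs: float, target: float = 1000.0,
                        max_fs: float = 2500.0) -> DownsamplePlan:
    """Decide whether to downsample.

    Sampling rates at or below ``max_fs`` (2.5 kHz) are within the
    recommended range and left untouched; higher rates are bin-averaged
    down to ``target`` (1 kHz by default).
    """
    if fs <= 0 or target <= 0:
        raise ConfigurationError("fs and target must be positive")
    if target > fs:
        raise ConfigurationError(f"target rate {target} exceeds sampling rate {fs}")
    if fs <= max_fs:
        return DownsamplePlan("none")
    return DownsamplePlan("bin_average", int(round(fs / target)))


def downsample_bin_average(data: np.ndarray, factor: int) -> np.ndarray:
    """Average bins of ``factor`` consecutive samples (last axis).

    The trailing partial bin is dropped so output timing stays uniform.
    """
    if factor < 1:
        raise ConfigurationError("downsampling factor must be >= 1")
    data = np.asarray(data, dtype=float)
    if factor == 1:
        return data.copy()
    n_out = data.shape[-1] // factor
    trimmed = data[..., : n_out * factor]
    return trimmed.reshape(*data.shape[:-1], n_out, factor).mean(axis=-1)


def downsample_recording(rec: Recording, params: ParamSet) -> Recording:
    """Apply the recommended downsampling plan to a recording.

    Output timestamps are bin centers, so t0 shifts by half a bin minus
    half an original sample period.
    """
    plan = decide_downsampling(rec.fs, params.downsample_target_hz,
                               params.downsample_max_fs_hz)
    if plan.none:
        return rec
    data = downsample_bin_average(rec.data, plan.factor)
    new_fs = rec.fs / plan.factor
    new_t0 = rec.t0 + (plan.factor - 1) / (2 * rec.fs)
    return Recording(data=data, fs=new_fs, t0=new_t0, units=rec.units,
                     channel_order=rec.channel_order, noise_mask=rec.noise_mask)


def bandpass(data: np.ndarray, low: float, high: float, fs: float,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    nyq = fs / 2
    if not (0 < low < high):
        raise ConfigurationError(f"need 0 < low < high, got {low}-{high}")
    if high >= nyq:
        raise ConfigurationError(
            f"band edge {high} Hz at or above Nyquist ({nyq} Hz)"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=-1)


def filter_bank(data: np.ndarray, fs: float, params: ParamSet) -> dict[str, np.ndarray]:
    """Filter all five analysis bands; returns band name -> filtered matrix."""
    return {name: bandpass(data, lo, hi, fs) for name, (lo, hi) in params.bands().items()}


@dataclass
class BandProfile:
    """Per-channel band amplitudes.

    ``raw`` is the standard deviation of each band's filtered trace over the
    entire recording (mV); ``normalized`` divides by the per-band maximum
    over non-noise channels, so each band's profile peaks at 1. Noise
    channels carry NaN.
    """

    raw: pd.DataFrame          # index: analysis channel, columns: bands
    normalized: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: channel, band, raw, normalized."""
        raw = self.raw.stack().rename("raw")
        norm = self.normalized.stack().rename("normalized")
        out = pd.concat([raw, norm], axis=1).reset_index()
        out.columns = ["channel", "band", "raw", "normalized"]
        return out


def band_amplitude_profile(bank: dict[str, np.ndarray],
                           noise_mask: np.ndarray | None = None) -> BandProfile:
    """Per-channel, per-band amplitude (std over the whole recording)."""
    bands = list(bank)
    n_ch = next(iter(bank.values())).shape[0]
    if noise_mask is None:
        noise_mask = np.zeros(n_ch, dtype=bool)
    noise_mask = np.asarray(noise_mask, dtype=bool)
    if noise_mask.all():
        raise ConfigurationError("all channels are flagged as noise")
    raw = pd.DataFrame(
        {b: bank[b].std(axis=-1) for b in bands},
        index=pd.RangeIndex(n_ch, name="channel"),
    )
    raw[noise_mask] = np.nan
    norm = raw / raw.max(axis=0)
    return BandProfile(raw=raw, normalized=norm)
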