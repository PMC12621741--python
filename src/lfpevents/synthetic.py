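"""Forward-model generator of laminar hippocampal LFP with ground truth.

The simulated probe spans CA1, the hippocampal fissure, the dentate outer
and middle molecular layers (OML/MML), and the hilus, shallowest to deepest
in analysis order. Dentate spikes are planted as depth-localized current
dipoles — a sink Gaussian at the OML (DS1) or MML (DS2) channel balanced by
a source toward the hilus — converted to LFP by discrete double integration
of the CSD profile, so the standard second-difference CSD is an exact
inverse on interior channels (the keystone oracle of the test suite).
SPW-Rs are ripple-frequency bursts under a Gaussian envelope on the CA1
channel with depth decay. Background holds theta (maximal at the fissure),
two gamma bands, a ripple-band component confined to the CA1 pyramidal
layer, and white plus 1/f noise.

Defaults state a 10-minute, 16-channel, 50-um-spacing, 1 kHz recording with
DS1/DS2/SPW-R rates of 5 per minute each and hilar DS amplitude 2 mV
(dentate spikes are large, >1 mV, and brief, <50 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .core import ConfigurationError, EventTable, Recording, build_probe_linear
from .preprocess import bandpass

__all__ = ["SimConfig", "SimResult", "simulate_recording", "ground_truth_match",
           "dipole_lfp_profile"]


@dataclass
class SimConfig:
    n_channels: int = 16
    spacing_um: float = 50.0
    fs: float = 1000.0
    duration_s: float = 600.0
    seed: int = 0
    # channel roles, analysis index (shallow -> deep)
    ca1_channel: int = 2
    fissure_channel: int = 6
    oml_channel: int = 8
    mml_channel: int = 10
    hilus_channel: int = 13
    # event rates (per minute); exact counts override rates when set
    ds1_rate: float = 5.0
    ds2_rate: float = 5.0
    swr_rate: float = 5.0
    n_ds1: int | None = None
    n_ds2: int | None = None
    n_swr: int | None = None
    min_separation_ms: float = 250.0
    # dentate spikes
    ds_amplitude_mv: float = 2.0        # hilar LFP peak
    ds_width_ms: float = 8.0            # temporal Gaussian FWHM ~ 1.18 * width
    ds_sink_sigma_ch: float = 0.8       # depth extent of the sink
    # sharp wave-ripples
    ripple_freq_hz: float = 150.0
    ripple_duration_ms: float = 50.0
    ripple_amplitude_mv: float = 0.35
    ripple_depth_sigma_ch: float = 1.0
    # background
    theta_freq_hz: float = 8.0
    theta_peak_mv: float = 0.25         # sine amplitude at the fissure
    theta_depth_sigma_ch: float = 3.0
    theta_baseline_frac: float = 0.15   # volume-conducted theta floor
    slow_gamma_mv: float = 0.03
    fast_gamma_mv: float = 0.02
    ca1_ripple_background_mv: float = 0.05   # pyramidal-layer high-freq power
    white_noise_mv: float = 0.03
    pink_noise_mv: float = 0.05
    noise_channels: tuple = ()
    noise_channel_mv: float = 1.0

    def validate(self) -> None:
        roles = [self.ca1_channel, self.fissure_channel, self.oml_channel,
                 self.mml_channel, self.hilus_channel]
        if roles != sorted(roles) or len(set(roles)) != 5:
            raise ConfigurationError(
                "role channels must be ordered ca1 < fissure < oml < mml < hilus")
        if roles[-1] >= self.n_channels or roles[0] < 0:
            raise ConfigurationError("role channels out of range")
        if min(self.ds1_rate, self.ds2_rate, self.swr_rate) < 0:
            raise ConfigurationError("event rates must be >= 0")


@dataclass
class SimResult:
    recording: Recording
    probe: "ProbeLayout"                # noqa: F821 - imported lazily for type only
    truth: pd.DataFrame                 # kind, ds_type, time_s, sample_index, channel
    config: SimConfig
    lfp_profiles: dict = field(default_factory=dict)   # ds1/ds2 depth profiles


def dipole_lfp_profile(config: SimConfig, sink_channel: int) -> np.ndarray:
    """Depth profile of LFP from a sink at *sink_channel* balanced by a
    source toward the hilus.

    Built by discrete double integration of the target CSD profile, so the
    standard second-difference CSD recovers the planted sink/source pattern
    exactly on interior channels. Normalized so the hilus channel reads +1.
    """
    n = config.n_channels
    ch = np.arange(n)
    sink = -np.exp(-0.5 * ((ch - sink_channel) / config.ds_sink_sigma_ch) ** 2)
    src_center = min(sink_channel + 3, n - 2)
    source = np.exp(-0.5 * ((ch - src_center) / config.ds_sink_sigma_ch) ** 2)
    source *= -sink.sum() / source.sum()          # zero net current
    csd = sink + source
    # V_{i+1} = 2 V_i - V_{i-1} - C_i  (unit spacing/conductivity)
    v = np.zeros(n)
    for i in range(1, n - 1):
        v[i + 1] = 2 * v[i] - v[i - 1] - csd[i]
    # far-field decay below the hilus (the 1-D plane model alone would hold
    # the potential constant arbitrarily deep, which no real probe shows)
    deep = ch > config.hilus_channel
    v[deep] *= np.exp(-(ch[deep] - config.hilus_channel) / 1.5)
    hilar = v[config.hilus_channel]
    if hilar == 0:
        raise ConfigurationError("degenerate dipole: zero hilar potential")
    return v / hilar


def _place_events(rng: np.random.Generator, n: int, duration_s: float,
                  margin_s: float, occupied: list[float],
                  min_sep_s: float) -> np.ndarray:
    """Uniform event times with a global minimum separation (rejection)."""
    times: list[float] = []
    attempts = 0
    max_attempts = 2000 * max(n, 1)
    while len(times) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ConfigurationError(
                "event rates too high to enforce the minimum separation")
        t = rng.uniform(margin_s, duration_s - margin_s)
        if all(abs(t - u) >= min_sep_s for u in occupied) and \
           all(abs(t - u) >= min_sep_s for u in times):
            times.append(t)
    occupied.extend(times)
    return np.sort(times)


def _pink_noise(rng: np.random.Generator, shape: tuple, fs: float) -> np.ndarray:
    """1/f noise via spectral shaping of white noise, unit std per channel."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1 / fs)
    shaping = np.where(freqs > 0, 1 / np.sqrt(np.maximum(freqs, 1.0)), 0.0)
    out = np.fft.irfft(spec * shaping, n=n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def simulate_recording(config: SimConfig | None = None) -> SimResult:
    """Generate a laminar LFP recording with ground-truth event tables.

    Deterministic for a fixed seed (bitwise-reproducible).
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_ch, fs = config.n_channels, config.fs
    n_samp = int(round(config.duration_s * fs))
    t = np.arange(n_samp) / fs
    ch = np.arange(n_ch)
    data = np.zeros((n_ch, n_samp))

    # --- background -------------------------------------------------------
    theta_amp = config.theta_peak_mv * (
        config.theta_baseline_frac + (1 - config.theta_baseline_frac) * np.exp(
            -0.5 * ((ch - config.fissure_channel) / config.theta_depth_sigma_ch) ** 2))
    theta_phase = rng.uniform(0, 2 * np.pi)
    # small depth-dependent phase gradient, as seen across the real laminae
    phase_by_depth = theta_phase + 0.1 * ch
    data += theta_amp[:, None] * np.sin(
        2 * np.pi * config.theta_freq_hz * t[None, :] + phase_by_depth[:, None])
    for f, amp in ((40.0, config.slow_gamma_mv), (80.0, config.fast_gamma_mv)):
        phases = rng.uniform(0, 2 * np.pi, n_ch)
        data += amp * np.sin(2 * np.pi * f * t[None, :] + phases[:, None])
    if config.ca1_ripple_background_mv > 0:
        prof = np.exp(-0.5 * ((ch - config.ca1_channel)
                              / config.ripple_depth_sigma_ch) ** 2)
        hf = bandpass(rng.standard_normal(n_samp), 120.0, 180.0, fs)
        hf /= hf.std()
        data += config.ca1_ripple_background_mv * prof[:, None] * hf[None, :]
    data += config.white_noise_mv * rng.standard_normal((n_ch, n_samp))
    data += config.pink_noise_mv * _pink_noise(rng, (n_ch, n_samp), fs)

    # --- events -----------------------------------------------------------
    def draw_count(rate: float, override: int | None) -> int:
        if override is not None:
            return int(override)
        return int(rng.poisson(rate * config.duration_s / 60.0))

    occupied: list[float] = []
    margin = 0.3
    min_sep = config.min_separation_ms / 1000.0
    counts = {
        "ds1": draw_count(config.ds1_rate, config.n_ds1),
        "ds2": draw_count(config.ds2_rate, config.n_ds2),
        "swr": draw_count(config.swr_rate, config.n_swr),
    }
    times = {k: _place_events(rng, v, config.duration_s, margin, occupied, min_sep)
             for k, v in counts.items()}

    sigma_t = config.ds_width_ms / 1000.0 / 2.0     # temporal Gaussian sigma
    profiles = {
        "ds1": dipole_lfp_profile(config, config.oml_channel),
        "ds2": dipole_lfp_profile(config, config.mml_channel),
    }
    half = int(round(5 * sigma_t * fs))
    rows = []
    for kind in ("ds1", "ds2"):
        prof = config.ds_amplitude_mv * profiles[kind]
        for t_ev in times[kind]:
            c = int(round(t_ev * fs))
            lo, hi = c - half, c + half + 1
            bump = np.exp(-0.5 * ((np.arange(lo, hi) / fs - t_ev) / sigma_t) ** 2)
            data[:, lo:hi] += prof[:, None] * bump[None, :]
            rows.append({"kind": "ds", "ds_type": int(kind[-1]), "time_s": t_ev,
                         "sample_index": c, "channel": config.hilus_channel})

    rip_sigma = config.ripple_duration_ms / 1000.0 / 4.0
    rip_prof = config.ripple_amplitude_mv * np.exp(
        -0.5 * ((ch - config.ca1_channel) / config.ripple_depth_sigma_ch) ** 2)
    rip_half = int(round(4 * rip_sigma * fs))
    for t_ev in times["swr"]:
        c = int(round(t_ev * fs))
        lo, hi = c - rip_half, c + rip_half + 1
        tt = np.arange(lo, hi) / fs - t_ev
        burst = np.exp(-0.5 * (tt / rip_sigma) ** 2) * np.sin(
            2 * np.pi * config.ripple_freq_hz * tt)
        data[:, lo:hi] += rip_prof[:, None] * burst[None, :]
        rows.append({"kind": "swr", "ds_type": 0, "time_s": t_ev,
                     "sample_index": c, "channel": config.ca1_channel})

    noise_mask = np.zeros(n_ch, dtype=bool)
    for nc in config.noise_channels:
        data[nc] = config.noise_channel_mv * rng.standard_normal(n_samp)
        noise_mask[nc] = True

    truth = pd.DataFrame(rows, columns=["kind", "ds_type", "time_s",
                                        "sample_index", "channel"])
    truth = truth.sort_values("time_s").reset_index(drop=True)
    recording = Recording(data=data, fs=fs, noise_mask=noise_mask)
    probe = build_probe_linear(n_ch, config.spacing_um, name="simulated")
    return SimResult(recording=recording, probe=probe, truth=truth,
                     config=config, lfp_profiles=profiles)


def ground_truth_match(detected: pd.DataFrame | EventTable,
                       truth: pd.DataFrame,
                       tolerance_ms: float = 10.0) -> dict:
    """Greedy one-to-one matching of detected to planted events by time.

    Pairs are matched in order of increasing time difference; each truth
    and each detection is used at most once. Returns recall, precision and
    the matched pairs (truth index, detection index, dt_ms). Invariant to
    row order of either table.
    """
    if isinstance(detected, EventTable):
        detected = detected.active()
    det_times = np.asarray(detected["time_s"], dtype=float)
    tru_times = np.asarray(truth["time_s"], dtype=float)
    tol = tolerance_ms / 1000.0
    pairs = []
    for i, tt in enumerate(tru_times):
        dt = np.abs(det_times - tt)
        for j in np.flatnonzero(dt <= tol):
            pairs.append((abs(det_times[j] - tt), i, j))
    pairs.sort()
    used_t, used_d, matches = set(), set(), []
    for dt, i, j in pairs:
        if i in used_t or j in used_d:
            continue
        used_t.add(i)
        used_d.add(j)
        matches.append((i, j, dt * 1000))
    n_match = len(matches)
    recall = n_match / len(tru_times) if len(tru_times) else np.nan
    precision = n_match / len(det_times) if len(det_times) else np.nan
    return {"recall": recall, "precision": precision, "matches": matches,
            "n_truth": len(tru_times), "n_detected": len(det_times)}
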