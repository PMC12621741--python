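"""Current source density estimation on laminar LFP.

Standard CSD is the negative scaled second spatial difference of the
potential, with Vaknin's boundary-duplication so the estimate spans all
recorded channels, followed by Gaussian smoothing along the channel axis.
The inverse CSD (iCSD) variants invert explicit forward models of planar
sources: infinitely thin disks at the electrode depths (delta), uniform
slabs between electrode midpoints (step), or a cubic-spline-parameterized
continuous profile (spline).

Sign convention: sinks (inward current) are negative. With potentials in
millivolts, depth in millimeters and conductivity sigma in S/m, values are
proportional to -sigma * d2V/dz2; classification normalizes per event, so
the absolute scale never matters downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter1d

from .core import ConfigurationError, EventTable

logger = logging.getLogger(__name__)

__all__ = [
    "CsdParams",
    "CSDStack",
    "standard_csd",
    "icsd",
    "icsd_forward_matrix",
    "compute_csd",
    "event_csd_stack",
]


@dataclass
class CsdParams:
    method: str = "standard"            # standard|delta_icsd|step_icsd|spline_icsd
    conductivity_s_per_m: float = 0.3
    source_radius_um: float = 500.0
    smoothing_sigma: float = 1.0        # channels; 0 = no smoothing
    smoothing_truncation: float = 3.0   # kernel truncated at this many sigma
    vaknin: bool = True
    event_window_ms: float = 100.0

    @staticmethod
    def from_paramset(p) -> "CsdParams":
        return CsdParams(
            method=p.csd_method,
            conductivity_s_per_m=p.csd_conductivity_s_per_m,
            source_radius_um=p.csd_source_radius_um,
            smoothing_sigma=p.csd_smoothing_sigma,
            smoothing_truncation=p.csd_smoothing_truncation,
            vaknin=p.csd_vaknin,
            event_window_ms=p.csd_event_window_ms,
        )


def _smooth_channels(csd: np.ndarray, params: CsdParams) -> np.ndarray:
    if params.smoothing_sigma <= 0:
        return csd
    return gaussian_filter1d(csd, params.smoothing_sigma, axis=0,
                             mode="nearest", truncate=params.smoothing_truncation)


def standard_csd(lfp_window: np.ndarray, spacing_um: float,
                 params: CsdParams | None = None) -> np.ndarray:
    """Second-spatial-difference CSD of a channels x time LFP window.

    With ``vaknin=True`` the first and last channels are duplicated before
    differencing so the output keeps the input channel count; otherwise the
    two boundary channels are dropped. Gaussian smoothing along channels
    follows the differencing.
    """
    params = params or CsdParams()
    V = np.atleast_2d(np.asarray(lfp_window, dtype=float))
    if V.shape[0] < 3:
        raise ConfigurationError("standard CSD needs at least 3 channels")
    if spacing_um <= 0:
        raise ConfigurationError("spacing must be positive and uniform; "
                                 "use an iCSD method for irregular geometries")
    if params.vaknin:
        V = np.vstack([V[:1], V, V[-1:]])
    h_mm = spacing_um / 1000.0
    csd = -params.conductivity_s_per_m * (V[:-2] - 2 * V[1:-1] + V[2:]) / h_mm**2
    return _smooth_channels(csd, params)


def _point_plane_kernel(z_obs: np.ndarray, z_src: np.ndarray,
                        radius_mm: float, sigma: float) -> np.ndarray:
    """Potential at depths z_obs from unit planar disks at depths z_src.

    Disk of radius R carrying uniform current surface density: the
    potential on the axis is (1/2 sigma) * (sqrt(dz^2 + R^2) - |dz|).
    Depths in mm.
    """
    dz = z_obs[:, None] - z_src[None, :]
    return (np.sqrt(dz**2 + radius_mm**2) - np.abs(dz)) / (2 * sigma)


def icsd_forward_matrix(electrode_z_um: np.ndarray, method: str,
                        params: CsdParams) -> np.ndarray:
    """Forward matrix F mapping source amplitudes at electrodes to
    potentials at electrodes, for the chosen source model."""
    z = np.asarray(electrode_z_um, dtype=float) / 1000.0   # mm
    if len(z) < 3:
        raise ConfigurationError("iCSD needs at least 3 channels")
    dz = np.diff(z)
    if not (np.all(dz > 0) or np.all(dz < 0)):
        raise ConfigurationError("electrode depths must be strictly monotone")
    R = params.source_radius_um / 1000.0
    sigma = params.conductivity_s_per_m

    if method == "delta_icsd":
        return _point_plane_kernel(z, z, R, sigma)

    if method == "step_icsd":
        # slab j spans the midpoints around electrode j (half-slabs at ends)
        mids = np.concatenate([[z[0] - dz[0] / 2], (z[:-1] + z[1:]) / 2,
                               [z[-1] + dz[-1] / 2]])
        F = np.empty((len(z), len(z)))
        n_quad = 64
        for j in range(len(z)):
            lo, hi = sorted((mids[j], mids[j + 1]))
            grid = np.linspace(lo, hi, n_quad)
            K = _point_plane_kernel(z, grid, R, sigma)      # (n_el, n_quad)
            F[:, j] = np.trapezoid(K, grid, axis=1)
        return F

    if method == "spline_icsd":
        # basis j: natural cubic spline through a unit impulse at electrode j
        F = np.empty((len(z), len(z)))
        lo, hi = min(z[0], z[-1]), max(z[0], z[-1])
        grid = np.linspace(lo, hi, 40 * len(z))
        K = _point_plane_kernel(z, grid, R, sigma)
        for j in range(len(z)):
            e = np.zeros(len(z))
            e[j] = 1.0
            basis = CubicSpline(np.sort(z), e[np.argsort(z)], bc_type="natural")(grid)
            F[:, j] = np.trapezoid(K * basis[None, :], grid, axis=1)
        return F

    raise ConfigurationError(f"unknown iCSD method {method!r}")


def icsd(lfp_window: np.ndarray, electrode_z_um: np.ndarray,
         params: CsdParams) -> np.ndarray:
    """Inverse CSD on a channels x time window; output at electrode depths.

    The solved planar source amplitudes are already in the standard sign
    convention (sources positive, sinks negative): a positive source
    produces a positive potential through the kernel, so no sign flip is
    needed to match :func:`standard_csd`.
    """
    V = np.atleast_2d(np.asarray(lfp_window, dtype=float))
    F = icsd_forward_matrix(electrode_z_um, params.method, params)
    cond = np.linalg.cond(F)
    if cond > 1e12:
        raise ConfigurationError(
            f"iCSD forward matrix ill-conditioned (cond={cond:.2e}); "
            "try a larger source radius or fewer channels")
    sources = np.linalg.solve(F, V)
    return _smooth_channels(sources, params)


def compute_csd(lfp_window: np.ndarray, electrode_z_um: np.ndarray,
                params: CsdParams) -> np.ndarray:
    """Dispatch on ``params.method``; standard CSD requires uniform spacing."""
    if params.method == "standard":
        dz = np.abs(np.diff(np.asarray(electrode_z_um, dtype=float)))
        if len(dz) and not np.allclose(dz, dz[0], rtol=1e-6):
            raise ConfigurationError(
                "standard CSD requires uniform spacing; use an iCSD method")
        return standard_csd(lfp_window, float(dz[0]) if len(dz) else 1.0, params)
    return icsd(lfp_window, electrode_z_um, params)


@dataclass
class CSDStack:
    """Per-event CSD maps over a fixed channel window, plus mean maps."""

    csd: np.ndarray              # (n_events, n_channels, n_times)
    lfp: np.ndarray              # (n_events, n_channels, n_times)
    channels: np.ndarray         # analysis channel indices of the window
    event_ids: np.ndarray
    times_ms: np.ndarray         # relative to the event center
    mean_csd: np.ndarray = field(init=False)
    mean_lfp: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.mean_csd = self.csd.mean(axis=0)
        self.mean_lfp = self.lfp.mean(axis=0)

    @property
    def n_events(self) -> int:
        return self.csd.shape[0]

    @property
    def center_bin(self) -> int:
        return self.csd.shape[2] // 2


def event_csd_stack(
    data: np.ndarray,
    fs: float,
    events: EventTable,
    channels: np.ndarray,
    electrode_z_um: np.ndarray,
    params: CsdParams,
    t0: float = 0.0,
) -> CSDStack:
    """Peri-event CSD maps.

    *data* is the depth-ordered (shallowest first) channels x samples
    matrix the CSD should be computed on — the DS-band filtered LFP for
    classification, raw LFP for interval viewing. *channels* are row
    indices into *data* (the fissure-to-hilus window), *electrode_z_um*
    their depths. Events whose window does not fit inside the recording
    are dropped with a logged count.
    """
    channels = np.asarray(channels, dtype=int)
    active = events.active()
    active = active[active["kind"] == "ds"] if "kind" in active else active
    if len(active) == 0:
        raise ConfigurationError("no active events to stack")
    half = int(round(params.event_window_ms * fs / 2000))
    n_t = 2 * half + 1
    n = data.shape[1]
    keep_ids, windows = [], []
    for _, row in active.iterrows():
        c = int(row["sample_index"])
        if c - half < 0 or c + half + 1 > n:
            continue
        keep_ids.append(int(row["event_id"]))
        windows.append(data[np.ix_(channels, np.arange(c - half, c + half + 1))])
    dropped = len(active) - len(keep_ids)
    if dropped:
        logger.warning("%d events dropped (window outside recording)", dropped)
    if not keep_ids:
        raise ConfigurationError("no events with a full peri-event window")
    lfp = np.stack(windows)
    flat = lfp.transpose(1, 0, 2).reshape(len(channels), -1)
    csd_flat = compute_csd(flat, np.asarray(electrode_z_um, dtype=float), params)
    csd = csd_flat.reshape(len(channels), len(keep_ids), n_t).transpose(1, 0, 2)
    times_ms = (np.arange(n_t) - half) / fs * 1000
    return CSDStack(csd=csd, lfp=lfp, channels=channels,
                    event_ids=np.asarray(keep_ids), times_ms=times_ms)
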