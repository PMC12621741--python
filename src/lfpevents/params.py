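"""Analysis parameters and their plain-text (TXT) serialization.

All tunable inputs of the pipeline live in one :class:`ParamSet`, grouped in
sections ordered by pipeline stage (preprocessing -> frequency bands ->
DS detection -> SPW-R detection -> CSD -> classification). The file format
is line-oriented ``name = value`` under ``[section]`` headers; unknown keys
are preserved on a round trip (with a warning) so files written by newer
versions stay usable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

from .core import ConfigurationError

logger = logging.getLogger(__name__)

# section -> parameter names, in pipeline order (fixed for serialization)
SECTIONS: dict[str, list[str]] = {
    "preprocessing": ["downsample_target_hz", "downsample_max_fs_hz"],
    "frequency_bands": [
        "theta_low_hz", "theta_high_hz",
        "slow_gamma_low_hz", "slow_gamma_high_hz",
        "fast_gamma_low_hz", "fast_gamma_high_hz",
        "ripple_low_hz", "ripple_high_hz",
        "ds_band_low_hz", "ds_band_high_hz",
    ],
    "ds_detection": [
        "ds_height_threshold", "ds_threshold_units", "ds_min_prominence",
        "ds_min_interval_ms", "ds_props_window_ms", "ds_raw_reindex_window_ms",
    ],
    "swr_detection": [
        "swr_peak_threshold_sd", "swr_edge_threshold_sd", "swr_min_duration_ms",
        "swr_min_mean_freq_hz", "swr_min_interval_ms", "swr_cycle_reindex_window_ms",
    ],
    "csd": [
        "csd_method", "csd_conductivity_s_per_m", "csd_source_radius_um",
        "csd_smoothing_sigma", "csd_smoothing_truncation", "csd_vaknin",
        "csd_event_window_ms",
    ],
    "classification": [
        "cluster_algorithm", "cluster_k", "dbscan_epsilon",
        "dbscan_min_samples", "cluster_seed",
    ],
}


@dataclass
class ParamSet:
    """Named analysis parameters with validated defaults.

    Thresholds for DS detection default to per-channel SD units of the
    DS-band filtered trace (height 4 SD, prominence 2 SD); SPW-R thresholds
    are SDs of the ripple envelope. Band edges are Hz; windows and
    intervals are milliseconds.
    """

    # preprocessing
    downsample_target_hz: float = 1000.0
    downsample_max_fs_hz: float = 2500.0   # at or below: no downsampling
    # frequency bands (Hz)
    theta_low_hz: float = 6.0
    theta_high_hz: float = 10.0
    slow_gamma_low_hz: float = 25.0
    slow_gamma_high_hz: float = 55.0
    fast_gamma_low_hz: float = 60.0
    fast_gamma_high_hz: float = 100.0
    ripple_low_hz: float = 120.0
    ripple_high_hz: float = 180.0
    ds_band_low_hz: float = 5.0
    ds_band_high_hz: float = 100.0
    # DS detection
    ds_height_threshold: float = 4.0
    ds_threshold_units: str = "sd"         # "sd" (per-channel) or "mv"
    ds_min_prominence: float = 2.0
    ds_min_interval_ms: float = 50.0       # DSs are brief (<50 ms)
    ds_props_window_ms: float = 100.0
    ds_raw_reindex_window_ms: float = 20.0
    # SPW-R detection
    swr_peak_threshold_sd: float = 5.0
    swr_edge_threshold_sd: float = 2.5
    swr_min_duration_ms: float = 20.0
    swr_min_mean_freq_hz: float = 120.0
    swr_min_interval_ms: float = 100.0
    swr_cycle_reindex_window_ms: float = 40.0
    # CSD
    csd_method: str = "standard"           # standard|delta_icsd|step_icsd|spline_icsd
    csd_conductivity_s_per_m: float = 0.3
    csd_source_radius_um: float = 500.0
    csd_smoothing_sigma: float = 1.0       # channels
    csd_smoothing_truncation: float = 3.0  # kernel cut at this many sigma
    csd_vaknin: bool = True
    csd_event_window_ms: float = 100.0     # centered peri-event window
    # classification
    cluster_algorithm: str = "kmeans"      # kmeans|dbscan
    cluster_k: int = 2
    dbscan_epsilon: float = 0.5            # in normalized PC units
    dbscan_min_samples: int = 5
    cluster_seed: int = 0
    # unknown keys read from file, preserved verbatim on re-write
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        bands = [
            ("theta", self.theta_low_hz, self.theta_high_hz),
            ("slow_gamma", self.slow_gamma_low_hz, self.slow_gamma_high_hz),
            ("fast_gamma", self.fast_gamma_low_hz, self.fast_gamma_high_hz),
            ("ripple", self.ripple_low_hz, self.ripple_high_hz),
            ("ds_band", self.ds_band_low_hz, self.ds_band_high_hz),
        ]
        for name, lo, hi in bands:
            if not (0 < lo < hi):
                raise ConfigurationError(f"band {name}: need 0 < low < high, got {lo}-{hi}")
        for name in (
            "ds_height_threshold", "ds_min_prominence", "swr_peak_threshold_sd",
            "swr_edge_threshold_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.swr_edge_threshold_sd >= self.swr_peak_threshold_sd:
            raise ConfigurationError("swr edge threshold must be below peak threshold")
        for name in ("ds_min_interval_ms", "swr_min_duration_ms", "swr_min_interval_ms"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.ds_threshold_units not in ("sd", "mv"):
            raise ConfigurationError("ds_threshold_units must be 'sd' or 'mv'")
        if self.csd_method not in ("standard", "delta_icsd", "step_icsd", "spline_icsd"):
            raise ConfigurationError(f"unknown csd method {self.csd_method!r}")
        if self.cluster_algorithm not in ("kmeans", "dbscan"):
            raise ConfigurationError(f"unknown clustering algorithm {self.cluster_algorithm!r}")
        if self.csd_smoothing_sigma < 0:
            raise ConfigurationError("csd_smoothing_sigma must be >= 0")
        if self.csd_source_radius_um <= 0:
            raise ConfigurationError("csd_source_radius_um must be > 0")

    def bands(self) -> dict[str, tuple[float, float]]:
        """Band name -> (low, high) Hz, in the fixed filter-bank order."""
        return {
            "theta": (self.theta_low_hz, self.theta_high_hz),
            "slow_gamma": (self.slow_gamma_low_hz, self.slow_gamma_high_hz),
            "fast_gamma": (self.fast_gamma_low_hz, self.fast_gamma_high_hz),
            "ripple": (self.ripple_low_hz, self.ripple_high_hz),
            "ds_band": (self.ds_band_low_hz, self.ds_band_high_hz),
        }


def _format_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _parse_value(text: str, target_type: type):
    text = text.strip()
    if target_type is bool:
        if text.lower() in ("true", "1", "yes"):
            return True
        if text.lower() in ("false", "0", "no"):
            return False
        raise ValueError(f"not a boolean: {text!r}")
    if target_type is int:
        return int(text)
    if target_type is float:
        return float(text)
    return text


def write_params(params: ParamSet, path) -> None:
    """Serialize a :class:`ParamSet` to the plain-text parameter file."""
    lines = []
    for section, names in SECTIONS.items():
        lines.append(f"[{section}]")
        for name in names:
            lines.append(f"{name} = {_format_value(getattr(params, name))}")
        lines.append("")
    if params.extras:
        lines.append("[extras]")
        for k, v in params.extras.items():
            lines.append(f"{k} = {v}")
        lines.append("")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))


def read_params(path) -> ParamSet:
    """Parse a parameter file back into a :class:`ParamSet`.

    Malformed lines raise :class:`ConfigurationError` naming the line
    number; unknown keys are kept in ``extras`` with a warning.
    """
    types = {f.name: f.type for f in fields(ParamSet)}
    # dataclass stores annotations as strings under `from __future__ import
    # annotations`; resolve the handful of concrete types we use
    type_map = {"float": float, "int": int, "bool": bool, "str": str}
    kwargs: dict = {}
    extras: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or (line.startswith("[") and line.endswith("]")):
                continue
            if "=" not in line:
                raise ConfigurationError(f"{path}:{lineno}: malformed line {line!r}")
            name, _, value = line.partition("=")
            name = name.strip()
            value = value.strip()
            if name in types and name != "extras":
                t = type_map.get(str(types[name]), str)
                try:
                    kwargs[name] = _parse_value(value, t)
                except ValueError as exc:
                    raise ConfigurationError(f"{path}:{lineno}: {exc}") from exc
            else:
                logger.warning("unknown parameter %r preserved in extras", name)
                extras[name] = value
    return ParamSet(**kwargs, extras=extras)
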