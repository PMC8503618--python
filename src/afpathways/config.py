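"""Analysis configuration.

All thresholds of the pipeline live here with their defaults: the
frame increment between optical-flow frame pairs (40 samples ~ 20 ms at
the clinical 2034.5 Hz sampling rate), the 10 s averaging window, the
0.9 normalized-derivative isoline with >3 connected pixels, the 0.7 rad
streamline stopping angle, the 0.5 px streamline spacing, and the 90°
inward cone of the PV activation flow metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Literal


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the activation-flow pipeline.

    Parameters
    ----------
    frame_increment_samples:
        Samples between the two frames of each optical-flow pair.
        40 samples at 2034.5 Hz is approximately 20 ms, enough for
        visible pixel motion between frames.
    window_s:
        Length of the vector-averaging window in seconds.
    isoline_level:
        Normalized-filtered-derivative level defining activation
        wavefronts (super-level-set boundary pixels).
    min_isoline_pixels:
        Minimum size of a connected wavefront component that is kept
        (components of fewer pixels are discarded; "greater than three
        connected pixels" means components of size >= 4 survive).
    hs_alpha, hs_iters:
        Horn-Schunck regularization weight and Jacobi iteration count.
    angular_stop_rad:
        Streamline tracing stops when the turn angle between
        consecutive integration steps exceeds this value.
    min_streamline_spacing_px:
        Minimum distance between retained streamlines.
    pv_cone_deg:
        Full width of the acceptance cone, centred on the inward
        direction, for tagging PV-to-body flow vectors.
    magnitude_rule:
        How the magnitude threshold for tagging is computed; only
        ``mean_over_array`` (mean |v| over all valid pixels) is defined.
    """

    frame_increment_samples: int = 40
    window_s: float = 10.0
    isoline_level: float = 0.9
    min_isoline_pixels: int = 4
    hs_alpha: float = 1.0
    hs_iters: int = 100
    angular_stop_rad: float = 0.7
    min_streamline_spacing_px: float = 0.5
    pv_cone_deg: float = 90.0
    magnitude_rule: Literal["mean_over_array"] = "mean_over_array"

    # electrogram-processing parameters
    bandpass_hz: tuple[float, float] = (40.0, 250.0)
    lowpass_hz: float = 20.0
    min_peak_separation_ms: float = 50.0
    peak_min_height: float = 0.5
    qrs_window_ms: float = 60.0
    filter_warmup_s: float = 1.0
    flat_range_eps: float = 1e-9

    # streamline tracing parameters
    streamline_step_px: float = 0.25
    streamline_mag_eps: float = 1e-6
    streamline_max_length_factor: float = 4.0

    # PV box geometry (fractions of the interpolated grid)
    box_col_fraction: float = 0.2
    box_row_fraction: float = 0.6
    pooled_box_denominator: bool = False

    def __post_init__(self) -> None:
        if self.frame_increment_samples <= 0:
            raise ValueError("frame_increment_samples must be positive")
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if not 0.0 < self.isoline_level < 1.0:
            raise ValueError("isoline_level must be in (0, 1)")
        if self.min_isoline_pixels <= 0:
            raise ValueError("min_isoline_pixels must be positive")
        if self.hs_alpha <= 0 or self.hs_iters <= 0:
            raise ValueError("hs_alpha and hs_iters must be positive")
        if self.angular_stop_rad <= 0:
            raise ValueError("angular_stop_rad must be positive")
        if self.min_streamline_spacing_px <= 0:
            raise ValueError("min_streamline_spacing_px must be positive")
        if not 0.0 < self.pv_cone_deg <= 180.0:
            raise ValueError("pv_cone_deg must be in (0, 180]")

    def with_increment_for_fs(self, fs: float) -> "AnalysisConfig":
        """Return a copy whose frame increment spans ~20 ms at ``fs``.

        The default 40-sample increment corresponds to the clinical
        2034.5 Hz rate; movies sampled at other rates keep the same
        physical inter-frame interval.
        """
        target_s = 40.0 / 2034.5
        inc = max(1, round(target_s * fs))
        return replace(self, frame_increment_samples=inc)

    def replace(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bandpass_hz"] = list(self.bandpass_hz)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "bandpass_hz" in d:
            d["bandpass_hz"] = tuple(d["bandpass_hz"])
        return cls(**d)


DEFAULT_CONFIG = AnalysisConfig()
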