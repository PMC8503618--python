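"""Unipolar electrogram processing.

Raw unipolar voltages are turned into normalized filtered derivative
signals whose peaks mark local activation: after far-field ventricular
(QRS) template subtraction, each channel is differentiated and passed
through the canonical pre-dominant-frequency filter chain (band-pass
40-250 Hz, full-wave rectification, low-pass 20 Hz) to make the signal
more sinusoidal, then min-max normalized to [0, 1] over the analysis
window.  A phase signal is the analytic-signal angle of the
mean-subtracted filtered derivative.  Cycle length (CL) at an electrode
is the mean interval between successive peaks; the chamber CL averages
over in-contact electrodes.

All filters are zero-phase (forward-backward) so that activation
timing, and hence downstream flow direction, is not biased by filter
lag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .config import AnalysisConfig, DEFAULT_CONFIG

__all__ = [
    "Recording",
    "ProcessedSignals",
    "CycleLengthSummary",
    "subtract_qrs",
    "derivative_chain",
    "cycle_lengths",
]


@dataclass
class Recording:
    """Raw multichannel unipolar electrogram recording."""

    voltages: np.ndarray  # (electrodes, samples), mV or arbitrary units
    fs: float
    chamber: str = "LA"
    layout: object = None
    contact_mask: Optional[np.ndarray] = None
    qrs_times: Optional[np.ndarray] = None  # sample indices

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.voltages.ndim != 2:
            raise ValueError("voltages must be (electrodes, samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.isfinite(self.voltages).all():
            bad = np.nonzero(~np.isfinite(self.voltages).all(axis=1))[0]
            raise ValueError(f"non-finite voltages on channels {bad.tolist()}")
        if self.contact_mask is None:
            self.contact_mask = np.ones(self.voltages.shape[0], dtype=bool)
        self.contact_mask = np.asarray(self.contact_mask, dtype=bool)
        if self.contact_mask.shape[0] != self.voltages.shape[0]:
            raise ValueError("contact_mask length must equal electrode count")
        if self.qrs_times is not None:
            self.qrs_times = np.asarray(self.qrs_times, dtype=int)

    @property
    def n_channels(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[1]

    def time_slice(self, start_s: float, stop_s: float) -> "Recording":
        i0, i1 = int(round(start_s * self.fs)), int(round(stop_s * self.fs))
        if i1 > self.n_samples:
            raise ValueError("slice exceeds recording duration")
        q = None
        if self.qrs_times is not None:
            q = self.qrs_times[(self.qrs_times >= i0) & (self.qrs_times < i1)] - i0
        return Recording(
            voltages=self.voltages[:, i0:i1],
            fs=self.fs,
            chamber=self.chamber,
            layout=self.layout,
            contact_mask=self.contact_mask.copy(),
            qrs_times=q,
        )


@dataclass
class ProcessedSignals:
    """Normalized filtered derivative, phase, and activation peaks."""

    nd: np.ndarray  # (electrodes, samples) in [0, 1]
    phase: np.ndarray  # radians in (-pi, pi]
    peak_times: list  # per-electrode arrays of sample indices
    fs: float
    contact_mask: np.ndarray = None
    flat_mask: np.ndarray = None  # channels with no usable signal range

    def __post_init__(self) -> None:
        if self.contact_mask is None:
            self.contact_mask = np.ones(self.nd.shape[0], dtype=bool)
        if self.flat_mask is None:
            self.flat_mask = np.zeros(self.nd.shape[0], dtype=bool)


@dataclass
class CycleLengthSummary:
    per_electrode_cl: np.ndarray  # ms, NaN where undefined
    chamber_mean_cl: float  # ms


# ---------------------------------------------------------------------------
# QRS subtraction
# ---------------------------------------------------------------------------


def subtract_qrs(rec: Recording, *, window_ms: Optional[float] = None,
                 detect: bool = False) -> Recording:
    """Remove the far-field ventricular artifact by template subtraction.

    For each channel, the average beat in a window (default +/-60 ms)
    around each QRS time is taken as that channel's template and
    subtracted at each occurrence.  Samples outside the windows are
    untouched.  With fewer than two QRS times the input is returned
    unchanged (with a warning).  If ``qrs_times`` is absent and
    ``detect`` is true, QRS times are picked as peaks of the
    cross-channel mean (the far-field artifact is common-mode).
    """
    window_ms = window_ms if window_ms is not None else DEFAULT_CONFIG.qrs_window_ms
    qrs = rec.qrs_times
    if qrs is None and detect:
        mean_sig = np.abs(rec.voltages.mean(axis=0))
        min_dist = int(0.3 * rec.fs)  # ventricular rate < 200 bpm
        height = mean_sig.mean() + 2.0 * mean_sig.std()
        qrs, _ = sps.find_peaks(mean_sig, distance=min_dist, height=height)
    if qrs is None:
        return rec
    if len(qrs) < 2:
        warnings.warn("fewer than 2 QRS times; returning recording unchanged")
        return rec

    half = int(round(window_ms * rec.fs / 1000.0))
    n = rec.n_samples
    out = rec.voltages.copy()
    # collect only full windows for the template
    full = [q for q in qrs if q - half >= 0 and q + half + 1 <= n]
    if len(full) < 2:
        warnings.warn("fewer than 2 complete QRS windows; returning unchanged")
        return rec
    stack = np.stack([rec.voltages[:, q - half:q + half + 1] for q in full], axis=0)
    template = stack.mean(axis=0)  # (channels, window)
    for q in qrs:
        lo, hi = q - half, q + half + 1
        tlo, thi = max(0, -lo), (half * 2 + 1) - max(0, hi - n)
        lo, hi = max(0, lo), min(n, hi)
        out[:, lo:hi] -= template[:, tlo:thi]
    return Recording(
        voltages=out,
        fs=rec.fs,
        chamber=rec.chamber,
        layout=rec.layout,
        contact_mask=rec.contact_mask.copy(),
        qrs_times=rec.qrs_times,
    )


# ---------------------------------------------------------------------------
# filter chain
# ---------------------------------------------------------------------------


def _zero_phase(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    return sps.sosfiltfilt(sos, x, axis=-1)


def derivative_chain(rec: Recording, cfg: AnalysisConfig = DEFAULT_CONFIG) -> ProcessedSignals:
    """Compute normalized filtered derivative, phase, and peaks.

    Per channel: first difference -> zero-phase band-pass (default
    40-250 Hz) -> full-wave rectification -> zero-phase low-pass
    (default 20 Hz) -> min-max normalization to [0, 1] over the window.
    Channels whose filtered-derivative range is below
    ``cfg.flat_range_eps`` are flagged flat and set to zero.  Peaks are
    local maxima of nd of height at least ``cfg.peak_min_height`` (the
    low-pass stage rings at ~0.4 of the activation peak; true
    activations sit near 1 after normalization) with minimum separation
    ``cfg.min_peak_separation_ms``.
    """
    if rec.n_samples / rec.fs < cfg.filter_warmup_s:
        raise ValueError(
            f"window shorter than filter warm-up ({cfg.filter_warmup_s} s)"
        )
    nyq = rec.fs / 2.0
    lo, hi = cfg.bandpass_hz
    hi = min(hi, 0.95 * nyq)
    sos_bp = sps.butter(3, [lo / nyq, hi / nyq], btype="band", output="sos")
    sos_lp = sps.butter(3, cfg.lowpass_hz / nyq, btype="low", output="sos")

    deriv = np.diff(rec.voltages, axis=1, prepend=rec.voltages[:, :1])
    filt = _zero_phase(sos_bp, deriv)
    filt = np.abs(filt)
    filt = _zero_phase(sos_lp, filt)
    filt = np.maximum(filt, 0.0)

    rng = filt.max(axis=1) - filt.min(axis=1)
    flat = rng < cfg.flat_range_eps
    nd = np.zeros_like(filt)
    ok = ~flat
    nd[ok] = (filt[ok] - filt[ok].min(axis=1, keepdims=True)) / rng[ok, None]

    centered = nd - nd.mean(axis=1, keepdims=True)
    phase = np.angle(sps.hilbert(centered, axis=1))

    min_dist = max(1, int(round(cfg.min_peak_separation_ms * rec.fs / 1000.0)))
    # forward-backward filtering leaves edge transients; peaks there are
    # artifacts of the window boundary, not activations
    margin = int(round(0.1 * rec.fs))
    peaks = []
    for ch in range(rec.n_channels):
        if flat[ch]:
            peaks.append(np.empty(0, dtype=int))
            continue
        p, _ = sps.find_peaks(nd[ch], distance=min_dist,
                              height=cfg.peak_min_height, prominence=0.2)
        p = p[(p >= margin) & (p < rec.n_samples - margin)]
        peaks.append(p)
    return ProcessedSignals(
        nd=nd,
        phase=phase,
        peak_times=peaks,
        fs=rec.fs,
        contact_mask=rec.contact_mask.copy(),
        flat_mask=flat,
    )


def cycle_lengths(ps: ProcessedSignals, fs: Optional[float] = None) -> CycleLengthSummary:
    """Mean inter-peak interval per electrode and chamber mean (ms).

    An electrode's CL is defined only with >= 2 peaks; the chamber mean
    averages defined CLs over in-contact electrodes.
    """
    fs = fs if fs is not None else ps.fs
    n = len(ps.peak_times)
    cl = np.full(n, np.nan)
    for ch, p in enumerate(ps.peak_times):
        if len(p) >= 2:
            cl[ch] = np.mean(np.diff(p)) / fs * 1000.0
    usable = ps.contact_mask & np.isfinite(cl)
    if not usable.any():
        raise ValueError("no in-contact electrode has >= 2 peaks")
    return CycleLengthSummary(per_electrode_cl=cl, chamber_mean_cl=float(cl[usable].mean()))
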