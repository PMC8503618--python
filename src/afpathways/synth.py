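"""Kinematic synthetic activation scenes.

Generates ground-truth activation "movies" and basket-sampled unipolar
electrograms for known driver archetypes — planar wave, anchored rotor,
focal source, multi-wavelet — on a small 2D grid standing in for the
electrode array of an 8-spline basket catheter. Waves are kinematic
(closed-form activation-time maps, not membrane electrophysiology):
each driver prescribes when every pixel activates, and the renderers
turn those times into normalized-derivative frames or biphasic unipolar
deflections with configurable noise, far-field ventricular ("QRS")
artifact, and contact dropout.

Default conditions mirror the clinical recordings the analysis was
designed for: 2034.5 Hz sampling, 8x8 electrode grid, AF-range cycle
lengths of 160-200 ms, and conduction of 0.10 grid-pixels/ms (~0.7 m/s
at a 7 mm inter-electrode spacing — ordinary atrial conduction).  The
conduction speed also sets the spatial sharpness of the rendered
wavefront (spatial width = speed x pulse width); below ~0.08 px/ms the
0.9 isoline of an oblique front falls between electrodes and the
wavefront detector is blind to it, so speeds are kept in the
physiological 0.08-0.12 px/ms range where the array spatially resolves
the front, as the clinical basket does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DriverSpec",
    "SynthScene",
    "activation_times",
    "render_movie",
    "render_electrograms",
    "qrs_sample_times",
    "planar_scene",
    "focal_scene",
    "rotor_scene",
    "multiwavelet_scene",
    "make_cohort",
]

DRIVER_KINDS = ("planar", "rotor", "focal", "multiwavelet")

#: fraction of the driving period during which a pixel cannot re-activate
REFRACTORY_FRACTION = 0.4


@dataclass(frozen=True)
class DriverSpec:
    """One activation driver.

    ``origin`` is a continuous (row, col) grid coordinate.  ``period``
    is the driving cycle length in ms.  ``direction`` (radians, planar
    only) follows the grid convention 0 = rightward (+col), pi/2 =
    downward (+row).  ``chirality`` (rotor only) is +1 for
    counter-clockwise phase advance in (row, col) coordinates.
    ``t_start``/``t_stop`` (seconds) optionally confine the driver to a
    sub-interval of the scene, enabling e.g. driver-switch scenes.
    """

    kind: str
    origin: tuple[float, float] = (0.0, 0.0)
    period: float = 180.0
    direction: float = 0.0
    chirality: int = 1
    wavelet_count: int = 3
    drift_speed: float = 0.0
    t_start: float = 0.0
    t_stop: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in DRIVER_KINDS:
            raise ValueError(
                f"unknown driver kind {self.kind!r}; expected one of {DRIVER_KINDS}"
            )
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.wavelet_count < 1:
            raise ValueError("wavelet_count must be >= 1")
        if self.chirality not in (-1, 1):
            raise ValueError("chirality must be +1 or -1")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "origin": list(self.origin),
            "period": self.period,
            "direction": self.direction,
            "chirality": self.chirality,
            "wavelet_count": self.wavelet_count,
            "drift_speed": self.drift_speed,
            "t_start": self.t_start,
            "t_stop": self.t_stop,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DriverSpec":
        d = dict(d)
        d["origin"] = tuple(d.get("origin", (0.0, 0.0)))
        return cls(**d)


@dataclass(frozen=True)
class SynthScene:
    """A complete synthetic recording scenario.

    ``conduction_speed`` is in grid pixels per ms; ``noise_sd`` is the
    additive Gaussian noise standard deviation as a fraction of unit
    signal amplitude; ``qrs_artifact`` is ``(period_ms, amplitude)`` or
    None.  All randomness (noise, multiwavelet burst placement, drift
    direction) derives from ``seed``.
    """

    grid_shape: tuple[int, int] = (8, 8)
    fs: float = 2034.5
    duration: float = 10.0
    drivers: tuple[DriverSpec, ...] = ()
    conduction_speed: float = 0.10
    noise_sd: float = 0.02
    qrs_artifact: Optional[tuple[float, float]] = None
    pulse_width_ms: float = 10.0
    # conduction heterogeneity (fibrosis stand-in): a frozen per-pixel
    # activation delay field, and beat-to-beat timing jitter of the whole
    # wave (AF cycle-length variability); both off by default so the
    # closed-form activation-time maps hold exactly
    delay_noise_sd_ms: float = 0.0
    cycle_jitter_sd_ms: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if min(self.grid_shape) < 4:
            raise ValueError("grid_shape dimensions must each be >= 4")
        if self.conduction_speed <= 0:
            raise ValueError("conduction_speed must be positive")
        object.__setattr__(self, "drivers", tuple(self.drivers))
        # drivers may sit up to 4 px beyond the mapped patch: a circuit
        # around a PV lies behind the grid edge, the basket only sees the
        # wavefronts it emits into the patch
        margin = 4.0
        for drv in self.drivers:
            r, c = drv.origin
            rows, cols = self.grid_shape
            if not (-margin <= r <= rows - 1 + margin and -margin <= c <= cols - 1 + margin):
                raise ValueError(f"driver origin {drv.origin} outside grid bounds")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    def to_dict(self) -> dict:
        return {
            "grid_shape": list(self.grid_shape),
            "fs": self.fs,
            "duration": self.duration,
            "drivers": [d.to_dict() for d in self.drivers],
            "conduction_speed": self.conduction_speed,
            "noise_sd": self.noise_sd,
            "qrs_artifact": list(self.qrs_artifact) if self.qrs_artifact else None,
            "pulse_width_ms": self.pulse_width_ms,
            "delay_noise_sd_ms": self.delay_noise_sd_ms,
            "cycle_jitter_sd_ms": self.cycle_jitter_sd_ms,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SynthScene":
        d = dict(d)
        d["grid_shape"] = tuple(d["grid_shape"])
        d["drivers"] = tuple(DriverSpec.from_dict(x) for x in d.get("drivers", []))
        if d.get("qrs_artifact"):
            d["qrs_artifact"] = tuple(d["qrs_artifact"])
        return cls(**d)


# ---------------------------------------------------------------------------
# activation-time maps
# ---------------------------------------------------------------------------


def _driver_window_ms(drv: DriverSpec, scene: SynthScene) -> tuple[float, float]:
    t0 = drv.t_start * 1000.0
    t1 = (drv.t_stop if drv.t_stop is not None else scene.duration) * 1000.0
    return t0, t1


def _planar_times(drv, scene, rr, cc):
    rows, cols = scene.grid_shape
    v = scene.conduction_speed
    proj = cc * math.cos(drv.direction) + rr * math.sin(drv.direction)
    proj = proj - proj.min()
    delay = proj / v
    t0, t1 = _driver_window_ms(drv, scene)
    n_beats = int(math.ceil((t1 - t0 + delay.max()) / drv.period)) + 1
    beats = t0 + np.arange(n_beats) * drv.period
    times = beats[None, None, :] + delay[:, :, None]
    return times, t0, t1


def _focal_times(drv, scene, rr, cc, drift_vel=(0.0, 0.0)):
    v = scene.conduction_speed
    t0, t1 = _driver_window_ms(drv, scene)
    diag = math.hypot(*scene.grid_shape)
    n_beats = int(math.ceil((t1 - t0 + diag / v) / drv.period)) + 1
    times = np.empty((*scene.grid_shape, n_beats))
    for k in range(n_beats):
        beat_t = t0 + k * drv.period
        orow = drv.origin[0] + drift_vel[0] * beat_t / 1000.0
        ocol = drv.origin[1] + drift_vel[1] * beat_t / 1000.0
        dist = np.hypot(rr - orow, cc - ocol)
        times[:, :, k] = beat_t + dist / v
    return times, t0, t1


def _rotor_times(drv, scene, rr, cc, drift_vel=(0.0, 0.0)):
    # activation when the rotating phase arm, advancing at 2*pi/period,
    # sweeps past the pixel's angular coordinate; radial propagation delay
    # dist/v on top.  Consecutive intervals are exactly one period.
    v = scene.conduction_speed
    t0, t1 = _driver_window_ms(drv, scene)
    diag = math.hypot(*scene.grid_shape)
    n_beats = int(math.ceil((t1 - t0 + diag / v) / drv.period)) + 2
    times = np.empty((*scene.grid_shape, n_beats))
    for k in range(n_beats):
        beat_t = t0 + k * drv.period
        orow = drv.origin[0] + drift_vel[0] * beat_t / 1000.0
        ocol = drv.origin[1] + drift_vel[1] * beat_t / 1000.0
        theta = np.arctan2(rr - orow, cc - ocol)
        dist = np.hypot(rr - orow, cc - ocol)
        angfrac = np.mod(drv.chirality * theta, 2.0 * math.pi) / (2.0 * math.pi)
        times[:, :, k] = beat_t + angfrac * drv.period + dist / v
    return times, t0, t1


def _multiwavelet_times(drv, scene, rr, cc, rng):
    """Poisson-seeded short-lived focal bursts, ~2 periods each."""
    v = scene.conduction_speed
    t0, t1 = _driver_window_ms(drv, scene)
    lifetime = 2.0 * drv.period
    rate = drv.wavelet_count / lifetime  # bursts per ms, keeps ~wavelet_count alive
    rows, cols = scene.grid_shape
    radius = v * drv.period  # one wavelength of local capture
    per_pixel: list[np.ndarray] = []
    t = t0 - lifetime  # bursts started before t0 may still be active
    bursts = []
    while t < t1:
        t += rng.exponential(1.0 / rate)
        site = (rng.uniform(0, rows - 1), rng.uniform(0, cols - 1))
        bursts.append((t, site))
    all_times = np.full((rows, cols, 0), np.nan)
    chunks = []
    n_beats = max(1, int(round(lifetime / drv.period)))
    for bt, (orow, ocol) in bursts:
        dist = np.hypot(rr - orow, cc - ocol)
        reach = dist <= radius
        for j in range(n_beats):
            tt = np.where(reach, bt + j * drv.period + dist / v, np.nan)
            chunks.append(tt)
    if chunks:
        all_times = np.stack(chunks, axis=-1)
    return all_times, t0, t1


def activation_times(scene: SynthScene) -> list[list[np.ndarray]]:
    """Per-pixel sorted activation times (ms) for a scene.

    Returns a nested ``rows x cols`` list of sorted 1D float arrays.
    Drivers superpose; a refractory rule drops any activation closer
    than ``REFRACTORY_FRACTION`` of the shortest driver period to the
    previous accepted activation at that pixel.
    """
    rows, cols = scene.grid_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    rr = rr.astype(float)
    cc = cc.astype(float)
    rng = np.random.default_rng(scene.seed)
    delay_field = (
        rng.normal(0.0, scene.delay_noise_sd_ms, size=scene.grid_shape)
        if scene.delay_noise_sd_ms > 0 else None
    )
    stacks = []
    min_period = math.inf
    for drv in scene.drivers:
        drift_vel = (0.0, 0.0)
        if drv.drift_speed:
            ang = rng.uniform(0, 2 * math.pi)
            drift_vel = (drv.drift_speed * math.sin(ang), drv.drift_speed * math.cos(ang))
        if drv.kind == "planar":
            times, t0, t1 = _planar_times(drv, scene, rr, cc)
        elif drv.kind == "focal":
            times, t0, t1 = _focal_times(drv, scene, rr, cc, drift_vel)
        elif drv.kind == "rotor":
            times, t0, t1 = _rotor_times(drv, scene, rr, cc, drift_vel)
        elif drv.kind == "multiwavelet":
            times, t0, t1 = _multiwavelet_times(drv, scene, rr, cc, rng)
        else:  # pragma: no cover - guarded by DriverSpec
            raise ValueError(f"unknown driver kind {drv.kind!r}")
        if scene.cycle_jitter_sd_ms > 0 and drv.kind != "multiwavelet":
            jitter = rng.normal(0.0, scene.cycle_jitter_sd_ms, size=times.shape[2])
            times = times + jitter[None, None, :]
        with np.errstate(invalid="ignore"):
            times = np.where((times >= t0) & (times <= t1 + drv.period), times, np.nan)
        stacks.append(times)
        min_period = min(min_period, drv.period)

    duration_ms = scene.duration * 1000.0
    refractory = REFRACTORY_FRACTION * (min_period if math.isfinite(min_period) else 0.0)
    multi = len(scene.drivers) > 1 or any(d.kind == "multiwavelet" for d in scene.drivers)
    out: list[list[np.ndarray]] = []
    for r in range(rows):
        row_out = []
        for c in range(cols):
            if stacks:
                t = np.concatenate([s[r, c, :] for s in stacks])
                if delay_field is not None:
                    t = t + delay_field[r, c]
                t = np.sort(t[np.isfinite(t)])
                t = t[(t >= 0.0) & (t <= duration_ms)]
                if multi and t.size > 1 and refractory > 0:
                    kept = [t[0]]
                    for x in t[1:]:
                        if x - kept[-1] >= refractory:
                            kept.append(x)
                    t = np.asarray(kept)
            else:
                t = np.empty(0)
            row_out.append(t)
        out.append(row_out)
    return out


# ---------------------------------------------------------------------------
# renderers
# ---------------------------------------------------------------------------


def render_movie(times, scene: SynthScene, *, noise: bool = True):
    """Render activation times to normalized-derivative frames.

    Each activation contributes a unit-amplitude Gaussian pulse of
    ``scene.pulse_width_ms`` standard deviation; frames are clipped to
    [0, 1], Gaussian noise of ``scene.noise_sd`` added, and re-clipped.
    Returns a :class:`afpathways.grid.GridMovie` (raw grid).
    """
    from .grid import GridMovie  # local import to avoid cycle

    if scene.pulse_width_ms <= 0:
        raise ValueError("pulse width must be positive")
    rows, cols = scene.grid_shape
    n = scene.n_samples
    t_ms = np.arange(n) / scene.fs * 1000.0
    sigma = scene.pulse_width_ms
    frames = np.zeros((n, rows, cols), dtype=np.float32)
    half = int(math.ceil(4.0 * sigma * scene.fs / 1000.0))
    for r in range(rows):
        for c in range(cols):
            sig = np.zeros(n)
            for t0 in times[r][c]:
                i0 = int(round(t0 * scene.fs / 1000.0))
                lo, hi = max(0, i0 - half), min(n, i0 + half + 1)
                if lo >= hi:
                    continue
                sig[lo:hi] += np.exp(-0.5 * ((t_ms[lo:hi] - t0) / sigma) ** 2)
            frames[:, r, c] = sig
    np.clip(frames, 0.0, 1.0, out=frames)
    if noise and scene.noise_sd > 0:
        rng = np.random.default_rng(scene.seed + 1)
        frames += rng.normal(0.0, scene.noise_sd, size=frames.shape).astype(np.float32)
        np.clip(frames, 0.0, 1.0, out=frames)
    return GridMovie(
        frames=frames,
        fs=scene.fs,
        grid_kind="raw_8x8" if rows == 8 else "raw_9x8" if rows == 9 else "raw_8x8",
        valid_mask=np.ones((rows, cols), dtype=bool),
    )


def qrs_sample_times(scene: SynthScene) -> np.ndarray:
    """Sample indices of the far-field artifact occurrences, if any."""
    if scene.qrs_artifact is None:
        return np.empty(0, dtype=int)
    period_ms, _ = scene.qrs_artifact
    n = scene.n_samples
    t = np.arange(period_ms / 2.0, n / scene.fs * 1000.0, period_ms)
    return np.round(t * scene.fs / 1000.0).astype(int)


def render_electrograms(times, scene: SynthScene, layout=None):
    """Render synthetic unipolar electrograms at basket electrode sites.

    Each activation at an electrode's pixel contributes a biphasic
    deflection (difference of two Gaussians: a positive lobe followed by
    a larger negative lobe, widths 5 and 8 ms).  An optional periodic
    far-field artifact is added identically to all channels, then
    Gaussian noise.  Deterministic given the scene seed.

    Returns an :class:`afpathways.egm.Recording`.
    """
    from .egm import Recording
    from .grid import BasketLayout, electrode_positions

    if layout is None:
        layout = BasketLayout()
    positions = electrode_positions(layout)
    rows, cols = scene.grid_shape
    bad = [
        i
        for i, (r, c) in enumerate(positions)
        if not (0 <= r < rows and 0 <= c < cols)
    ]
    if bad:
        raise ValueError(f"electrodes mapped outside grid: {bad}")

    n = scene.n_samples
    t_ms = np.arange(n) / scene.fs * 1000.0
    s_pos, s_neg, offset = 5.0, 8.0, 4.0  # ms
    a_pos, a_neg = 0.5, 1.0
    half = int(math.ceil((4.0 * s_neg + offset) * scene.fs / 1000.0))
    volts = np.zeros((len(positions), n))
    for ch, (r, c) in enumerate(positions):
        sig = np.zeros(n)
        for t0 in times[r][c]:
            i0 = int(round(t0 * scene.fs / 1000.0))
            lo, hi = max(0, i0 - half), min(n, i0 + half + 1)
            if lo >= hi:
                continue
            tt = t_ms[lo:hi] - t0
            sig[lo:hi] += a_pos * np.exp(-0.5 * ((tt + offset) / s_pos) ** 2)
            sig[lo:hi] -= a_neg * np.exp(-0.5 * ((tt - offset) / s_neg) ** 2)
        volts[ch] = sig

    qrs_idx = qrs_sample_times(scene)
    if qrs_idx.size:
        _, amp = scene.qrs_artifact
        s_qrs = 25.0  # ms
        wav = np.zeros(n)
        halfq = int(math.ceil(4.0 * s_qrs * scene.fs / 1000.0))
        for i0 in qrs_idx:
            lo, hi = max(0, i0 - halfq), min(n, i0 + halfq + 1)
            tt = t_ms[lo:hi] - t_ms[i0]
            wav[lo:hi] += amp * np.exp(-0.5 * (tt / s_qrs) ** 2)
        volts += wav[None, :]

    if scene.noise_sd > 0:
        rng = np.random.default_rng(scene.seed + 2)
        volts += rng.normal(0.0, scene.noise_sd, size=volts.shape)

    return Recording(
        voltages=volts,
        fs=scene.fs,
        chamber="LA",
        layout=layout,
        contact_mask=np.ones(len(positions), dtype=bool),
        qrs_times=qrs_idx if qrs_idx.size else None,
    )


# ---------------------------------------------------------------------------
# scene factories — the study conditions for synthetic cohorts
# ---------------------------------------------------------------------------


def _jitter(rng, lo, hi):
    return float(rng.uniform(lo, hi))


def planar_scene(direction: float = 0.0, speed: float = 0.10, *, period: float = 180.0,
                 seed: int = 0, **kw) -> SynthScene:
    """A single planar wave crossing the grid."""
    drv = DriverSpec(kind="planar", direction=direction, period=period)
    return SynthScene(drivers=(drv,), conduction_speed=speed, seed=seed, **kw)


def focal_scene(origin=(3.5, 3.5), *, period: float = 180.0, seed: int = 0, **kw) -> SynthScene:
    """A repetitive focal source at ``origin``."""
    drv = DriverSpec(kind="focal", origin=origin, period=period)
    return SynthScene(drivers=(drv,), seed=seed, **kw)


def rotor_scene(origin=(3.5, 3.5), chirality: int = 1, *, period: float = 180.0,
                seed: int = 0, **kw) -> SynthScene:
    """An anchored rotor at ``origin``."""
    drv = DriverSpec(kind="rotor", origin=origin, period=period, chirality=chirality)
    return SynthScene(drivers=(drv,), seed=seed, **kw)


def multiwavelet_scene(wavelet_count: int = 4, *, period: float = 180.0,
                       seed: int = 0, **kw) -> SynthScene:
    """Disorganised multi-wavelet activation with no dominant pathway."""
    drv = DriverSpec(kind="multiwavelet", wavelet_count=wavelet_count, period=period)
    return SynthScene(drivers=(drv,), seed=seed, **kw)


#: AF-realistic heterogeneity used for cohort scenes: frozen per-pixel
#: conduction delays (fibrotic slowing) and beat-to-beat timing jitter
#: (cycle-length variability)
COHORT_CONDITIONS = dict(delay_noise_sd_ms=4.0, cycle_jitter_sd_ms=8.0)


def make_cohort(n_per_group: int = 20, seed: int = 0, **scene_kw):
    """Build a paired synthetic cohort of PVI-responder-like and
    non-responder-like scenes.

    Responder analogues are driven from a pulmonary vein: the driver
    origin sits 2-3.5 px *behind* the left or right grid edge (the vein
    lies beyond the mapped patch; the basket sees the wavefronts it
    emits through the antrum), alternating repetitive focal triggers
    and re-entry around the vein.  Non-responder analogues have a
    central-body rotor or disorganised multi-wavelet activation.
    Periods (AF cycle lengths 160-200 ms), origins and chirality are
    jittered per case, and all scenes carry the ``COHORT_CONDITIONS``
    conduction heterogeneity unless overridden.

    Returns ``(responders, nonresponders)`` lists of scenes; each
    scene's driver kind identifies its subtype for subgroup analysis.
    """
    kw = {**COHORT_CONDITIONS, **scene_kw}
    rng = np.random.default_rng(seed)
    rows, cols = kw.get("grid_shape", (8, 8))
    responders, nonresponders = [], []
    for i in range(n_per_group):
        period = _jitter(rng, 160.0, 200.0)
        side_left = i % 2 == 0
        depth = _jitter(rng, 2.0, 3.5)
        edge_col = -depth if side_left else (cols - 1) + depth
        edge_row = _jitter(rng, rows / 2 - 2.0, rows / 2 + 1.5)
        kind = "focal" if (i // 2) % 2 == 0 else "rotor"
        drv = DriverSpec(
            kind=kind,
            origin=(edge_row, edge_col),
            period=period,
            chirality=1 if rng.uniform() < 0.5 else -1,
        )
        responders.append(
            SynthScene(drivers=(drv,), seed=int(rng.integers(1 << 30)), **kw)
        )
    for i in range(n_per_group):
        period = _jitter(rng, 160.0, 200.0)
        if i % 2 == 0:
            drv = DriverSpec(
                kind="rotor",
                origin=(
                    _jitter(rng, rows / 2 - 1.5, rows / 2 + 0.5),
                    _jitter(rng, cols / 2 - 1.5, cols / 2 + 0.5),
                ),
                period=period,
                chirality=1 if rng.uniform() < 0.5 else -1,
            )
        else:
            drv = DriverSpec(kind="multiwavelet", wavelet_count=4, period=period)
        nonresponders.append(
            SynthScene(drivers=(drv,), seed=int(rng.integers(1 << 30)), **kw)
        )
    return responders, nonresponders
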