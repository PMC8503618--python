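"""Wavefront detection and time-averaged activation flow.

Activation wavefronts are isolines of high normalized filtered
derivative: per analyzed frame, boundary pixels of the super-level set
nd >= 0.9 on the depolarizing (leading) edge — the temporal derivative
discriminates wavefront from wave back — kept only when they form
8-connected components of more than three pixels.  Optical-flow vectors
at wavefront pixels are then averaged over the 10 s analysis window by
vector addition, normalized by the number of analyzed frames, so the
averaged magnitude encodes how repeatably a direction recurs: coherent
propagation accumulates, disorganised activation cancels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .config import AnalysisConfig, DEFAULT_CONFIG
from .flow import FlowField, lattice_frames
from .grid import GridMovie

__all__ = ["WavefrontMask", "AveragedFlowField", "detect_wavefronts", "average_flow"]

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-neighbour erosion
_EIGHT = ndimage.generate_binary_structure(2, 2)  # 8-connected labelling


@dataclass
class WavefrontMask:
    """Wavefront pixels per analyzed frame.

    ``masks`` is (frames, rows, cols) boolean; ``labels`` the matching
    connected-component label arrays; ``lattice`` the sample index of
    each analyzed frame.
    """

    masks: np.ndarray
    labels: np.ndarray
    lattice: np.ndarray
    fs: float


@dataclass
class AveragedFlowField:
    """Flow vectors averaged over wavefront occurrences in one window."""

    u_avg: np.ndarray
    v_avg: np.ndarray
    contribution_count: np.ndarray
    window: tuple[float, float]  # (start_s, end_s)
    valid_mask: np.ndarray

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u_avg, self.v_avg)


def detect_wavefronts(gm: GridMovie, cfg: AnalysisConfig = DEFAULT_CONFIG,
                      start_s: float = 0.0) -> WavefrontMask:
    """Detect leading-edge isoline components on the analysis lattice.

    Per analyzed frame: threshold at ``cfg.isoline_level``, take the
    boundary pixels of the super-level set (4-neighbour erosion;
    invalid regions and the grid border do not create boundaries), keep
    pixels whose temporal derivative is positive, label 8-connected
    components and discard components smaller than
    ``cfg.min_isoline_pixels``.  Empty masks are allowed.
    """
    inc = cfg.frame_increment_samples
    i0 = int(round(start_s * gm.fs))
    n_window = int(round(cfg.window_s * gm.fs))
    if i0 + n_window > gm.n_frames:
        raise ValueError("analysis window exceeds movie duration")
    lat = lattice_frames(n_window, inc) + i0
    valid = gm.valid_mask
    n = gm.n_frames
    masks = np.zeros((len(lat), *gm.grid_shape), dtype=bool)
    labels = np.zeros((len(lat), *gm.grid_shape), dtype=np.int32)
    for k, t in enumerate(lat):
        frame = gm.frames[t]
        S = (frame >= cfg.isoline_level) & valid
        if not S.any():
            continue
        # boundaries only against valid sub-threshold tissue
        eroded = ndimage.binary_erosion(S | ~valid, structure=_CROSS, border_value=1)
        boundary = S & ~eroded
        dndt = gm.frames[min(t + 1, n - 1)] - gm.frames[max(t - 1, 0)]
        leading = boundary & (dndt > 0)
        if not leading.any():
            continue
        lab, n_comp = ndimage.label(leading, structure=_EIGHT)
        if n_comp:
            sizes = np.bincount(lab.ravel())
            keep = np.zeros(n_comp + 1, dtype=bool)
            keep[1:] = sizes[1:] >= cfg.min_isoline_pixels
            good = keep[lab]
            lab = np.where(good, lab, 0)
            masks[k] = good
            labels[k] = lab
    return WavefrontMask(masks=masks, labels=labels, lattice=lat, fs=gm.fs)


def average_flow(fields: Sequence[FlowField], mask: WavefrontMask,
                 cfg: AnalysisConfig = DEFAULT_CONFIG) -> AveragedFlowField:
    """Vector-average flow at wavefront pixels over the window.

    Pair ``k`` contributes where the "from" frame's wavefront mask is
    set.  The vector sum is divided by the number of analyzed frame
    pairs (not by the per-pixel contribution count), so pixels that are
    rarely wavefront, or whose directions cancel, end up with small
    averaged vectors.
    """
    n_pairs = len(fields)
    if n_pairs == 0:
        raise ValueError("window contains no analyzed frame pairs")
    if mask.masks.shape[0] not in (n_pairs, n_pairs + 1):
        raise ValueError("wavefront mask and flow fields are not frame-aligned")
    shape = fields[0].u.shape
    u_sum = np.zeros(shape)
    v_sum = np.zeros(shape)
    count = np.zeros(shape, dtype=np.int64)
    for k, f in enumerate(fields):
        m = mask.masks[k]
        u_sum += np.where(m, f.u, 0.0)
        v_sum += np.where(m, f.v, 0.0)
        count += m
    valid = fields[0].valid_mask
    t0 = fields[0].frame_time
    t1 = fields[-1].frame_time + cfg.frame_increment_samples / mask.fs
    return AveragedFlowField(
        u_avg=u_sum / n_pairs,
        v_avg=v_sum / n_pairs,
        contribution_count=count,
        window=(t0, t1),
        valid_mask=valid,
    )
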