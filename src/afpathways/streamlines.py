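"""Preferential-pathway streamlines on the averaged flow field.

Streamlines are seeded at the centroids of a Delaunay triangulation of
the valid grid nodes and integrated both forward and backward along
the direction of the time-averaged flow field with small fixed Euler
steps.  A branch stops when it leaves the valid region, the local field
magnitude vanishes, or the turn between consecutive steps exceeds the
angular stopping criterion (0.7 rad).  The displayed set is built
greedily by decreasing streamline length subject to a minimum spacing
(0.5 px) against all previously retained lines; per-point field
magnitudes are attached so renderers can scale thickness by how often
the direction repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import Delaunay, cKDTree

from .config import AnalysisConfig, DEFAULT_CONFIG
from .wavefront import AveragedFlowField

__all__ = ["StreamlineSet", "triangulate_seeds", "trace", "trace_all",
           "select", "plot_streamlines"]


@dataclass
class Streamline:
    points: np.ndarray  # (n, 2) continuous (row, col) coordinates
    magnitudes: np.ndarray  # field |v| at each point
    seed_id: int

    @property
    def length(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


@dataclass
class StreamlineSet:
    streamlines: list
    config: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def to_json_obj(self) -> dict:
        return {
            "streamlines": [
                {
                    "seed_id": s.seed_id,
                    "points": s.points.tolist(),
                    "magnitudes": s.magnitudes.tolist(),
                }
                for s in self.streamlines
            ]
        }


def triangulate_seeds(points: np.ndarray) -> np.ndarray:
    """Seed coordinates: centroids of the Delaunay triangles of ``points``.

    ``points`` are (n, 2) recording-node coordinates; at least three
    non-collinear points are required.  A full n x m grid yields
    2 (n-1)(m-1) triangles, one seed each.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 3:
        raise ValueError("need at least 3 points to triangulate")
    try:
        tri = Delaunay(points)
    except Exception as exc:  # qhull raises on degenerate input
        raise ValueError(f"triangulation failed (collinear points?): {exc}") from exc
    if tri.simplices.shape[0] == 0:
        raise ValueError("triangulation produced no triangles (collinear points?)")
    return points[tri.simplices].mean(axis=1)


class _FieldSampler:
    """Bilinear sampler of (u, v) and validity on the pixel lattice."""

    def __init__(self, avg: AveragedFlowField):
        rows, cols = avg.u_avg.shape
        gr = np.arange(rows, dtype=float)
        gc = np.arange(cols, dtype=float)
        self._u = RegularGridInterpolator((gr, gc), avg.u_avg, bounds_error=False,
                                          fill_value=0.0)
        self._v = RegularGridInterpolator((gr, gc), avg.v_avg, bounds_error=False,
                                          fill_value=0.0)
        self._valid = avg.valid_mask
        self._shape = (rows, cols)
        self.max_mag = float(np.hypot(avg.u_avg, avg.v_avg).max())

    def vector(self, p: np.ndarray) -> np.ndarray:
        # (row, col) displacement: u is the col component, v the row component
        return np.array([self._v(p).item(), self._u(p).item()])

    def inside(self, p: np.ndarray) -> bool:
        r, c = p
        rows, cols = self._shape
        if not (0.0 <= r <= rows - 1 and 0.0 <= c <= cols - 1):
            return False
        return bool(self._valid[int(round(r)), int(round(c))])


def _trace_branch(sampler: _FieldSampler, seed: np.ndarray, sign: float,
                  cfg: AnalysisConfig, max_steps: int):
    pts = []
    mags = []
    p = np.asarray(seed, dtype=float)
    prev_dir = None
    eps = cfg.streamline_mag_eps * max(sampler.max_mag, 1e-300)
    for _ in range(max_steps):
        if not sampler.inside(p):
            break
        vec = sign * sampler.vector(p)
        mag = float(np.linalg.norm(vec))
        if mag < eps:
            break
        d = vec / mag
        if prev_dir is not None:
            cosang = float(np.clip(np.dot(d, prev_dir), -1.0, 1.0))
            if np.arccos(cosang) > cfg.angular_stop_rad:
                break
        pts.append(p.copy())
        mags.append(mag)
        p = p + cfg.streamline_step_px * d
        prev_dir = d
    return pts, mags


def trace(seed, avg: AveragedFlowField, cfg: AnalysisConfig = DEFAULT_CONFIG,
          seed_id: int = 0, _sampler: _FieldSampler = None) -> Streamline:
    """Trace one streamline through ``seed``, forward then backward.

    Integration is fixed-step Euler (``cfg.streamline_step_px``) on the
    normalized field direction; branches stop on leaving the valid
    region, on vanishing field magnitude, or when the step-to-step turn
    exceeds ``cfg.angular_stop_rad``.  A zero field at the seed yields
    an empty polyline.
    """
    sampler = _sampler if _sampler is not None else _FieldSampler(avg)
    rows, cols = avg.u_avg.shape
    diag = float(np.hypot(rows - 1, cols - 1))
    max_steps = int(cfg.streamline_max_length_factor * diag / cfg.streamline_step_px)
    fwd_p, fwd_m = _trace_branch(sampler, seed, +1.0, cfg, max_steps)
    bwd_p, bwd_m = _trace_branch(sampler, seed, -1.0, cfg, max_steps)
    if not fwd_p and not bwd_p:
        return Streamline(points=np.empty((0, 2)), magnitudes=np.empty(0),
                          seed_id=seed_id)
    # backward branch reversed, then forward (seed point shared; drop dup)
    pts = bwd_p[::-1] + fwd_p[1:] if fwd_p and bwd_p else (bwd_p[::-1] or fwd_p)
    mags = bwd_m[::-1] + fwd_m[1:] if fwd_p and bwd_p else (bwd_m[::-1] or fwd_m)
    return Streamline(points=np.asarray(pts), magnitudes=np.asarray(mags),
                      seed_id=seed_id)


def trace_all(avg: AveragedFlowField, cfg: AnalysisConfig = DEFAULT_CONFIG,
              seeds: np.ndarray = None) -> list:
    """Trace streamlines from every Delaunay-element centroid seed."""
    if seeds is None:
        vr, vc = np.nonzero(avg.valid_mask)
        seeds = triangulate_seeds(np.column_stack([vr, vc]).astype(float))
    sampler = _FieldSampler(avg)
    return [
        trace(s, avg, cfg, seed_id=i, _sampler=sampler)
        for i, s in enumerate(seeds)
    ]


def plot_streamlines(ss: StreamlineSet, ax=None, *, max_linewidth: float = 3.0):
    """Render a streamline set with thickness by field magnitude.

    Thin plotting helper over matplotlib; the tested core is the
    geometry, not the drawing.  Each streamline is drawn with line
    width proportional to its mean field magnitude and an arrow at its
    midpoint.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mags = [s.magnitudes.mean() for s in ss.streamlines if len(s.points)]
    top = max(mags) if mags else 1.0
    for s in ss.streamlines:
        if len(s.points) < 2:
            continue
        w = max_linewidth * s.magnitudes.mean() / top
        ax.plot(s.points[:, 1], s.points[:, 0], lw=max(w, 0.3), color="tab:blue")
        mid = len(s.points) // 2
        if mid + 1 < len(s.points):
            d = s.points[mid + 1] - s.points[mid]
            ax.annotate("", xy=(s.points[mid, 1] + d[1], s.points[mid, 0] + d[0]),
                        xytext=(s.points[mid, 1], s.points[mid, 0]),
                        arrowprops=dict(arrowstyle="->", lw=max(w, 0.3),
                                        color="tab:blue"))
    ax.set_aspect("equal")
    ax.invert_yaxis()  # row 0 (anterior MV) at the top
    return ax


def select(traces, cfg: AnalysisConfig = DEFAULT_CONFIG) -> StreamlineSet:
    """Greedy spacing-constrained selection, longest streamlines first.

    Traces are sorted by arc length descending (ties broken by seed id
    ascending, making the output deterministic) and retained only if
    every point lies at least ``cfg.min_streamline_spacing_px`` from
    all previously retained streamlines.
    """
    order = sorted(traces, key=lambda s: (-s.length, s.seed_id))
    retained = []
    retained_pts: list[np.ndarray] = []
    tree = None
    for s in order:
        if len(s.points) < 2:
            continue
        if tree is not None:
            dmin = tree.query(s.points, k=1)[0].min()
            if dmin < cfg.min_streamline_spacing_px:
                continue
        retained.append(s)
        retained_pts.append(s.points)
        tree = cKDTree(np.concatenate(retained_pts, axis=0))
    return StreamlineSet(streamlines=retained, config=cfg)
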