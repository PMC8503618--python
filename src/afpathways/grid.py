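"""Anatomical grid arrangement of basket-catheter channels.

The 64 electrodes of an 8-spline basket are laid out on a 2D grid:
rows are splines ordered top (anterior mitral valve) to bottom, columns
are the eight electrodes along each spline.  For the left atrium the
edges read: top = anterior MV, bottom = posterior MV, left = lateral
wall / left PV, right = septal wall / right PV.  The valve-adjacent
spline may be duplicated on the opposite edge (9x8 grid) so that
propagation across the valve annulus is representable; the alternative
is a plain 8x8 grid.  Grids are then linearly interpolated to higher
resolution with two extra points per gap (9x8 -> 25x22), and electrodes
without tissue contact are masked out of the interpolation support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import Delaunay

__all__ = [
    "BasketLayout",
    "GridMovie",
    "electrode_positions",
    "arrange",
    "interpolate",
    "apply_dropout",
]

LA_EDGE_LABELS = {
    "top": "anterior MV",
    "bottom": "posterior MV",
    "left": "lateral / left PV",
    "right": "septal / right PV",
}
RA_EDGE_LABELS = {
    "top": "SVC",
    "bottom": "IVC",
    "left": "septal TV",
    "right": "lateral TV",
}


@dataclass(frozen=True)
class BasketLayout:
    """Mapping from basket channels to grid positions.

    ``spline_order`` lists spline indices from the top grid row to the
    bottom; ``valve_spline`` is the anterior-MV (or septal-TV) spline
    and must be first in ``spline_order`` when the duplicated 9x8 grid
    is used.  Channel numbering is ``spline * 8 + electrode``.
    """

    spline_count: int = 8
    electrodes_per_spline: int = 8
    spline_order: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6, 7)
    valve_spline: int = 0
    edge_labels: dict = field(default_factory=lambda: dict(LA_EDGE_LABELS))

    def __post_init__(self) -> None:
        if sorted(self.spline_order) != list(range(self.spline_count)):
            raise ValueError("spline_order must be a permutation of 0..spline_count-1")
        if not 0 <= self.valve_spline < self.spline_count:
            raise ValueError("valve_spline out of range")
        object.__setattr__(self, "spline_order", tuple(self.spline_order))

    @property
    def n_channels(self) -> int:
        return self.spline_count * self.electrodes_per_spline

    def row_of_spline(self, spline: int) -> int:
        return self.spline_order.index(spline)

    def to_dict(self) -> dict:
        return {
            "spline_order": list(self.spline_order),
            "valve_spline": self.valve_spline,
            "edge_labels": dict(self.edge_labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BasketLayout":
        return cls(
            spline_order=tuple(d.get("spline_order", range(8))),
            valve_spline=d.get("valve_spline", 0),
            edge_labels=d.get("edge_labels", dict(LA_EDGE_LABELS)),
        )


@dataclass
class GridMovie:
    """Time-ordered frames of normalized filtered derivative on a grid.

    ``frames`` has shape (time, rows, cols) with values in [0, 1] where
    ``valid_mask`` is true.  ``grid_kind`` distinguishes raw electrode
    grids from the interpolated high-resolution grid.
    """

    frames: np.ndarray
    fs: float
    grid_kind: str = "raw_8x8"
    valid_mask: Optional[np.ndarray] = None
    edge_labels: dict = field(default_factory=lambda: dict(LA_EDGE_LABELS))

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (time, rows, cols)")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.frames.shape[1:], dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.frames.shape[1:]:
            raise ValueError("valid_mask shape mismatch")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def time_slice(self, start_s: float, stop_s: float) -> "GridMovie":
        i0 = int(round(start_s * self.fs))
        i1 = int(round(stop_s * self.fs))
        if i1 > self.n_frames:
            raise ValueError("slice exceeds movie duration")
        return GridMovie(
            frames=self.frames[i0:i1],
            fs=self.fs,
            grid_kind=self.grid_kind,
            valid_mask=self.valid_mask.copy(),
            edge_labels=dict(self.edge_labels),
        )


def electrode_positions(layout: BasketLayout) -> list[tuple[int, int]]:
    """Grid (row, col) of each channel on the un-duplicated 8x8 grid."""
    pos = []
    for ch in range(layout.n_channels):
        spline, electrode = divmod(ch, layout.electrodes_per_spline)
        pos.append((layout.row_of_spline(spline), electrode))
    return pos


# ---------------------------------------------------------------------------
# arrangement and duplication
# ---------------------------------------------------------------------------


def arrange(ps, layout: BasketLayout, duplicate_valve_spline: bool = True) -> GridMovie:
    """Arrange processed channel signals on the anatomical grid.

    With ``duplicate_valve_spline`` the valve spline (which must sit at
    the top row, i.e. first in ``spline_order``) is copied to the
    opposite edge, giving a 9x8 grid; otherwise the grid is 8x8.
    Out-of-contact channels are marked invalid.
    """
    nd = np.asarray(ps.nd)
    if nd.shape[0] != layout.n_channels:
        raise ValueError(f"expected {layout.n_channels} channels, got {nd.shape[0]}")
    contact = getattr(ps, "contact_mask", None)
    if contact is None:
        contact = np.ones(layout.n_channels, dtype=bool)
    rows = layout.spline_count
    cols = layout.electrodes_per_spline
    frames = np.empty((nd.shape[1], rows, cols), dtype=nd.dtype)
    valid = np.empty((rows, cols), dtype=bool)
    for r, spline in enumerate(layout.spline_order):
        for c in range(cols):
            ch = spline * cols + c
            frames[:, r, c] = nd[ch]
            valid[r, c] = contact[ch]
    if duplicate_valve_spline:
        if layout.spline_order[0] != layout.valve_spline:
            raise ValueError(
                "valve_spline must be the first entry of spline_order for the "
                "duplicated 9x8 arrangement"
            )
        frames = np.concatenate([frames, frames[:, :1, :]], axis=1)
        valid = np.concatenate([valid, valid[:1, :]], axis=0)
        kind = "raw_9x8"
    else:
        kind = "raw_8x8"
    return GridMovie(
        frames=frames,
        fs=ps.fs,
        grid_kind=kind,
        valid_mask=valid,
        edge_labels=dict(layout.edge_labels),
    )


def duplicate_valve_row(gm: GridMovie) -> GridMovie:
    """Copy the top (valve-spline) row to the bottom edge of a raw movie."""
    if gm.grid_kind not in ("raw_8x8",):
        raise ValueError("duplicate_valve_row expects a raw 8x8 movie")
    frames = np.concatenate([gm.frames, gm.frames[:, :1, :]], axis=1)
    valid = np.concatenate([gm.valid_mask, gm.valid_mask[:1, :]], axis=0)
    return GridMovie(frames=frames, fs=gm.fs, grid_kind="raw_9x8",
                     valid_mask=valid, edge_labels=dict(gm.edge_labels))


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------


def _linear_1d_matrix(n: int, factor: int = 3) -> np.ndarray:
    """(factor*n - factor + 1, n) linear-interpolation weights.

    At node positions the weight row is an exact unit vector, so
    original values are preserved to machine precision.
    """
    m = factor * n - (factor - 1)
    pos = np.arange(m) / factor
    i0 = np.minimum(pos.astype(int), n - 2)
    w = pos - i0
    W = np.zeros((m, n))
    W[np.arange(m), i0] = 1.0 - w
    W[np.arange(m), i0 + 1] += w
    return W


def _separable_linear(frames: np.ndarray, factor: int = 3) -> np.ndarray:
    """Bilinear upsampling with ``factor - 1`` points per gap, node-exact.

    Realized as one matmul against the Kronecker product of the two 1D
    weight matrices.
    """
    T, rows, cols = frames.shape
    W = np.kron(_linear_1d_matrix(rows, factor), _linear_1d_matrix(cols, factor))
    W = W.astype(frames.dtype)
    out = frames.reshape(T, rows * cols) @ W.T
    return out.reshape(T, factor * rows - (factor - 1), factor * cols - (factor - 1))


def _barycentric_weights(valid_rc: np.ndarray, targets: np.ndarray):
    """Per-target vertex indices + weights for linear interpolation over
    the Delaunay triangulation of valid nodes.  Targets outside the
    convex hull get simplex index -1."""
    tri = Delaunay(valid_rc)
    simplex = tri.find_simplex(targets, tol=1e-12)
    inside = simplex >= 0
    verts = np.zeros((targets.shape[0], 3), dtype=int)
    weights = np.zeros((targets.shape[0], 3))
    s = simplex[inside]
    T = tri.transform[s]
    delta = targets[inside] - T[:, 2]
    bary = np.einsum("nij,nj->ni", T[:, :2], delta)
    weights[inside, :2] = bary
    weights[inside, 2] = 1.0 - bary.sum(axis=1)
    verts[inside] = tri.simplices[s]
    return verts, weights, inside


def interpolate(gm: GridMovie) -> GridMovie:
    """Interpolate a raw grid movie to higher resolution.

    Two additional points are introduced between every two original
    grid points (9x8 -> 25x22, 8x8 -> 22x22).  Values at original node
    positions are preserved exactly.  When some nodes are invalid the
    interpolation uses only valid nodes (linear over their Delaunay
    triangulation); interpolated pixels outside the convex hull of
    valid nodes are marked invalid.
    """
    if not gm.grid_kind.startswith("raw"):
        raise ValueError("interpolate expects a raw grid movie")
    rows, cols = gm.grid_shape
    out_shape = (3 * rows - 2, 3 * cols - 2)
    if not gm.valid_mask.any():
        raise ValueError("all grid nodes invalid; nothing to interpolate")

    if gm.valid_mask.all():
        frames = _separable_linear(gm.frames.astype(np.float32, copy=False))
        valid = np.ones(out_shape, dtype=bool)
    else:
        vr, vc = np.nonzero(gm.valid_mask)
        if vr.size < 3:
            raise ValueError("fewer than 3 valid nodes; cannot interpolate")
        valid_rc = np.column_stack([vr, vc]).astype(float)
        R, C = np.meshgrid(
            np.arange(out_shape[0]) / 3.0, np.arange(out_shape[1]) / 3.0, indexing="ij"
        )
        targets = np.column_stack([R.ravel(), C.ravel()])
        verts, weights, inside = _barycentric_weights(valid_rc, targets)
        node_vals = gm.frames[:, vr, vc]  # (T, n_valid)
        interp = (
            node_vals[:, verts[:, 0]] * weights[:, 0]
            + node_vals[:, verts[:, 1]] * weights[:, 1]
            + node_vals[:, verts[:, 2]] * weights[:, 2]
        )
        interp[:, ~inside] = 0.0
        frames = interp.reshape(gm.frames.shape[0], *out_shape).astype(np.float32)
        valid = inside.reshape(out_shape)

    np.clip(frames, 0.0, 1.0, out=frames)
    return GridMovie(
        frames=frames,
        fs=gm.fs,
        grid_kind="interpolated",
        valid_mask=valid,
        edge_labels=dict(gm.edge_labels),
    )


# ---------------------------------------------------------------------------
# contact dropout
# ---------------------------------------------------------------------------


def apply_dropout(
    gm: GridMovie,
    drop=None,
    *,
    splines: Optional[Sequence[int]] = None,
    seed: int = 0,
    layout: Optional[BasketLayout] = None,
) -> GridMovie:
    """Mark electrodes or whole splines as out of contact.

    ``drop`` is either a fraction in [0, 0.9] of electrodes to remove at
    random (deterministic given ``seed``), or an explicit sequence of
    channel indices.  ``splines`` removes whole splines.  On a 9x8 grid
    the duplicated valve row mirrors its source row.  Dropping every
    node is an error.
    """
    if layout is None:
        layout = BasketLayout()
    rows_raw = layout.spline_count
    has_dup = gm.grid_shape[0] == rows_raw + 1
    valid = gm.valid_mask.copy()
    rng = np.random.default_rng(seed)

    drop_channels: set[int] = set()
    if drop is not None:
        if np.isscalar(drop) and not isinstance(drop, (list, tuple, set)):
            frac = float(drop)
            if not 0.0 <= frac <= 0.9:
                raise ValueError("dropout fraction must be in [0, 0.9]")
            n_drop = int(round(frac * layout.n_channels))
            drop_channels.update(
                rng.choice(layout.n_channels, size=n_drop, replace=False).tolist()
            )
        else:
            drop_channels.update(int(i) for i in drop)
    if splines is not None:
        for s in splines:
            drop_channels.update(
                int(s) * layout.electrodes_per_spline + e
                for e in range(layout.electrodes_per_spline)
            )

    for ch in drop_channels:
        spline, electrode = divmod(ch, layout.electrodes_per_spline)
        r = layout.row_of_spline(spline)
        valid[r, electrode] = False
        if has_dup and r == 0:
            valid[rows_raw, electrode] = False

    if not valid.any():
        raise ValueError("dropout would remove every grid node")
    return GridMovie(
        frames=gm.frames,
        fs=gm.fs,
        grid_kind=gm.grid_kind,
        valid_mask=valid,
        edge_labels=dict(gm.edge_labels),
    )
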