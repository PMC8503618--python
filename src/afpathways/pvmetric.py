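"""PV activation flow metric.

Quantifies how strongly activation flows from the pulmonary-vein antra
into the left-atrial body.  Within a box adjacent to the left PV edge
and one adjacent to the right PV edge of the interpolated grid, an
averaged-flow vector is tagged as PV-to-body flow when (i) its
magnitude exceeds the mean magnitude over the whole array — a degree of
repeatability — and (ii) its direction lies within a 90 degree cone
centred on the inward (toward grid centre) direction.  Each box scores
the percentage of its valid pixels tagged; the PV activation flow
metric is the maximum of the left and right box percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import AnalysisConfig, DEFAULT_CONFIG
from .wavefront import AveragedFlowField

__all__ = ["PVBoxes", "PVFlowResult", "default_boxes", "tag_vectors"]


@dataclass(frozen=True)
class Box:
    """Pixel-index rectangle [row0, row1) x [col0, col1)."""

    row0: int
    row1: int
    col0: int
    col1: int

    def mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.row0:self.row1, self.col0:self.col1] = True
        return m

    def to_dict(self) -> dict:
        return {"row0": self.row0, "row1": self.row1,
                "col0": self.col0, "col1": self.col1}


@dataclass(frozen=True)
class PVBoxes:
    """Left/right PV assessment boxes and their inward directions.

    ``inward_direction`` is in radians with 0 = +col (rightward); the
    left box therefore points ~0 (into the body, rightward) and the
    right box ~pi.
    """

    left_box: Box
    right_box: Box
    left_inward: float
    right_inward: float

    def to_dict(self) -> dict:
        return {
            "left_box": self.left_box.to_dict(),
            "right_box": self.right_box.to_dict(),
            "left_inward": self.left_inward,
            "right_inward": self.right_inward,
        }


@dataclass
class PVFlowResult:
    left_pct: float
    right_pct: float
    metric_pct: float
    tagged_left: np.ndarray
    tagged_right: np.ndarray
    mean_magnitude: float

    def to_dict(self) -> dict:
        return {
            "left_pct": self.left_pct,
            "right_pct": self.right_pct,
            "metric_pct": self.metric_pct,
            "mean_magnitude": self.mean_magnitude,
        }


def default_boxes(grid_shape, cfg: AnalysisConfig = DEFAULT_CONFIG) -> PVBoxes:
    """Default PV boxes on an interpolated LA grid.

    Each box spans the outermost ``cfg.box_col_fraction`` of columns on
    its side and the middle ``cfg.box_row_fraction`` of rows; the
    inward direction points toward the grid centre along the column
    axis (left box -> 0 rad, right box -> pi).
    """
    rows, cols = grid_shape
    n_cols = int(cfg.box_col_fraction * cols)
    n_rows = int(cfg.box_row_fraction * rows)
    if n_cols < 1 or n_rows < 1:
        raise ValueError("grid too small for nonempty PV boxes")
    row0 = (rows - n_rows) // 2
    left = Box(row0, row0 + n_rows, 0, n_cols)
    right = Box(row0, row0 + n_rows, cols - n_cols, cols)
    return PVBoxes(left_box=left, right_box=right,
                   left_inward=0.0, right_inward=math.pi)


def _angle_within(u, v, centre: float, half_width_rad: float) -> np.ndarray:
    ang = np.arctan2(v, u)  # v: row component (y), u: col component (x)
    diff = np.angle(np.exp(1j * (ang - centre)))
    return np.abs(diff) <= half_width_rad


def _box_pct(avg, box: Box, inward: float, mean_mag: float, half_cone: float,
             denominator: int = None):
    m = box.mask(avg.u_avg.shape) & avg.valid_mask
    n_valid = int(m.sum())
    if n_valid == 0:
        return None, np.zeros_like(m)
    mag = avg.magnitude
    tagged = m & (mag > mean_mag) & _angle_within(avg.u_avg, avg.v_avg, inward, half_cone)
    denom = denominator if denominator is not None else n_valid
    return 100.0 * tagged.sum() / denom, tagged


def tag_vectors(avg: AveragedFlowField, boxes: PVBoxes,
                cfg: AnalysisConfig = DEFAULT_CONFIG) -> PVFlowResult:
    """Tag PV-to-body flow vectors and compute the metric.

    The magnitude threshold is the mean |v| over all valid pixels of
    the whole array; the direction test is a cone of full width
    ``cfg.pv_cone_deg`` about each box's inward direction.  Box
    percentages use each box's own valid-pixel denominator (a pooled
    denominator across both boxes is available via
    ``cfg.pooled_box_denominator``); the metric is their maximum.
    """
    if not avg.valid_mask.any():
        raise ValueError("averaged field has no valid pixels")
    mean_mag = float(avg.magnitude[avg.valid_mask].mean())
    half_cone = math.radians(cfg.pv_cone_deg / 2.0)

    pooled = None
    if cfg.pooled_box_denominator:
        pooled = int(
            (boxes.left_box.mask(avg.u_avg.shape) & avg.valid_mask).sum()
            + (boxes.right_box.mask(avg.u_avg.shape) & avg.valid_mask).sum()
        )
    left_pct, tag_l = _box_pct(avg, boxes.left_box, boxes.left_inward,
                               mean_mag, half_cone, pooled)
    right_pct, tag_r = _box_pct(avg, boxes.right_box, boxes.right_inward,
                                mean_mag, half_cone, pooled)
    if left_pct is None and right_pct is None:
        raise ValueError("both PV boxes have zero valid pixels")
    candidates = [p for p in (left_pct, right_pct) if p is not None]
    return PVFlowResult(
        left_pct=float(left_pct) if left_pct is not None else float("nan"),
        right_pct=float(right_pct) if right_pct is not None else float("nan"),
        metric_pct=float(max(candidates)),
        tagged_left=tag_l,
        tagged_right=tag_r,
        mean_magnitude=mean_mag,
    )
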