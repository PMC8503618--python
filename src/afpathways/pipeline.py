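"""End-to-end analysis pipelines.

Chains the stages of the method: (synthetic scene or recording) ->
normalized-derivative grid movie -> interpolation -> Horn-Schunck flow
on the frame lattice -> wavefront-averaged flow field -> streamlines /
PV activation flow metric.  These helpers are what the experiments
module, the CLI and cohort runs call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import egm, flow, grid, pvmetric, streamlines, synth, wavefront
from .config import AnalysisConfig, DEFAULT_CONFIG

__all__ = ["WindowAnalysis", "analyze_window", "scene_movie", "scene_metric",
           "recording_movie"]


@dataclass
class WindowAnalysis:
    """All per-window artifacts of one pipeline run."""

    movie: grid.GridMovie  # interpolated
    fields: list
    mask: wavefront.WavefrontMask
    averaged: wavefront.AveragedFlowField
    result: pvmetric.PVFlowResult
    boxes: pvmetric.PVBoxes
    streamline_set: Optional[streamlines.StreamlineSet] = None


def scene_movie(scene: synth.SynthScene, *, duplicate_valve_spline: bool = True
                ) -> grid.GridMovie:
    """Render a scene to a raw grid movie (9x8 if duplicated, else 8x8)."""
    times = synth.activation_times(scene)
    gm = synth.render_movie(times, scene)
    if duplicate_valve_spline:
        gm = grid.duplicate_valve_row(gm)
    return gm


def recording_movie(rec: egm.Recording, cfg: AnalysisConfig = DEFAULT_CONFIG,
                    *, duplicate_valve_spline: bool = True,
                    subtract: bool = True) -> grid.GridMovie:
    """Process a recording through the electrogram chain onto the grid."""
    if subtract:
        rec = egm.subtract_qrs(rec)
    ps = egm.derivative_chain(rec, cfg)
    layout = rec.layout if rec.layout is not None else grid.BasketLayout()
    return grid.arrange(ps, layout, duplicate_valve_spline=duplicate_valve_spline)


def analyze_window(gm_raw: grid.GridMovie, cfg: AnalysisConfig = DEFAULT_CONFIG,
                   start_s: float = 0.0, *, with_streamlines: bool = False,
                   dropout=None, dropout_splines=None, dropout_seed: int = 0,
                   layout: Optional[grid.BasketLayout] = None) -> WindowAnalysis:
    """Run interpolation, flow, averaging and the PV metric on one window."""
    if dropout is not None or dropout_splines is not None:
        gm_raw = grid.apply_dropout(gm_raw, dropout, splines=dropout_splines,
                                    seed=dropout_seed, layout=layout)
    gm = grid.interpolate(gm_raw)
    fields = flow.flow_sequence(gm, cfg, start_s=start_s)
    mask = wavefront.detect_wavefronts(gm, cfg, start_s=start_s)
    averaged = wavefront.average_flow(fields, mask, cfg)
    boxes = pvmetric.default_boxes(gm.grid_shape, cfg)
    result = pvmetric.tag_vectors(averaged, boxes, cfg)
    out = WindowAnalysis(movie=gm, fields=fields, mask=mask,
                         averaged=averaged, result=result, boxes=boxes)
    if with_streamlines:
        traces = streamlines.trace_all(averaged, cfg)
        out.streamline_set = streamlines.select(traces, cfg)
    return out


def scene_metric(scene: synth.SynthScene, cfg: Optional[AnalysisConfig] = None,
                 **kw) -> float:
    """PV activation flow metric (%) of a synthetic scene."""
    if cfg is None:
        cfg = DEFAULT_CONFIG.with_increment_for_fs(scene.fs)
    gm = scene_movie(scene)
    return analyze_window(gm, cfg, **kw).result.metric_pct
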