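"""Sensitivity experiments on synthetic cohorts.

Scripted analogues of the method's robustness checks: stability of the
PV activation flow metric across 10 s analysis windows through a
recording, degradation of responder/non-responder separation under
random electrode (or whole-spline) dropout, shrinking the sampled
patch to emulate a smaller basket, and the 9x8-vs-8x8 grid variant
comparison.  All experiments are deterministic given their seeds.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import grid, pipeline, stats, synth
from .config import AnalysisConfig, DEFAULT_CONFIG

__all__ = [
    "window_sweep",
    "cohort_metrics",
    "dropout_experiment",
    "grid_variant_comparison",
    "basket_size_experiment",
]


def window_sweep(source, n_windows: int = 10,
                 cfg: Optional[AnalysisConfig] = None,
                 *, relative_tolerance: bool = False,
                 tolerance: float = 10.0):
    """Metric per analysis window plus a stability fraction.

    ``source`` is a SynthScene (rendered once) or a raw GridMovie.
    ``n_windows`` windows of ``cfg.window_s`` are spaced at regular
    intervals through the recording; stability is the fraction of
    windows whose metric lies within ``tolerance`` percentage points
    (or, with ``relative_tolerance``, within that percentage of the
    first window's value) of the first window.
    """
    if isinstance(source, synth.SynthScene):
        if cfg is None:
            cfg = DEFAULT_CONFIG.with_increment_for_fs(source.fs)
        gm = pipeline.scene_movie(source)
    else:
        gm = source
        if cfg is None:
            cfg = DEFAULT_CONFIG.with_increment_for_fs(gm.fs)
    total_s = gm.n_frames / gm.fs
    if total_s < n_windows * cfg.window_s - 1e-9:
        raise ValueError(
            f"recording of {total_s:.1f}s too short for {n_windows} windows of "
            f"{cfg.window_s}s"
        )
    if n_windows == 1:
        starts = [0.0]
    else:
        starts = np.linspace(0.0, total_s - cfg.window_s, n_windows)
    metrics = [
        pipeline.analyze_window(gm, cfg, start_s=float(s)).result.metric_pct
        for s in starts
    ]
    first = metrics[0]
    if relative_tolerance:
        band = abs(first) * tolerance / 100.0
    else:
        band = tolerance
    stable = [abs(m - first) <= band for m in metrics]
    table = pd.DataFrame({"start_s": starts, "metric_pct": metrics, "stable": stable})
    return table, float(np.mean(stable))


def cohort_metrics(responders: Sequence[synth.SynthScene],
                   nonresponders: Sequence[synth.SynthScene],
                   cfg: Optional[AnalysisConfig] = None,
                   *, dropout=None, dropout_splines=None, dropout_seed: int = 0,
                   movies=None):
    """Metric per case for both groups; optionally with contact dropout.

    ``movies`` may carry pre-rendered raw movies (two lists matching the
    scene lists) so dropout levels can be swept without re-rendering.
    """
    out = []
    for gi, scenes in enumerate((responders, nonresponders)):
        vals = []
        for si, scene in enumerate(scenes):
            c = cfg if cfg is not None else DEFAULT_CONFIG.with_increment_for_fs(scene.fs)
            gm = movies[gi][si] if movies is not None else pipeline.scene_movie(scene)
            res = pipeline.analyze_window(
                gm, c, dropout=dropout, dropout_splines=dropout_splines,
                dropout_seed=dropout_seed + 1000 * gi + si,
            )
            vals.append(res.result.metric_pct)
        out.append(np.asarray(vals))
    return out[0], out[1]


def dropout_experiment(responders, nonresponders,
                       fractions: Sequence[float] = (0.0, 0.25, 0.5),
                       seeds: Sequence[int] = (0,),
                       cfg: Optional[AnalysisConfig] = None,
                       *, splines: Optional[Sequence[int]] = None,
                       movies=None) -> pd.DataFrame:
    """Group comparison at each dropout level (fractions or n-splines).

    Returns one row per (level, seed): group medians, rank-sum p value
    and AUC.  With ``splines`` the levels are numbers of whole splines
    removed instead of electrode fractions.
    """
    if movies is None:
        movies = (
            [pipeline.scene_movie(s) for s in responders],
            [pipeline.scene_movie(s) for s in nonresponders],
        )
    rows = []
    levels = splines if splines is not None else fractions
    baseline = None  # level 0 does not depend on the dropout seed
    for level in levels:
        for seed in seeds:
            if splines is not None:
                rng = np.random.default_rng(seed)
                drop_spl = rng.choice(8, size=int(level), replace=False).tolist()
                kw = dict(dropout_splines=drop_spl if level else None)
            else:
                kw = dict(dropout=float(level) if level else None)
            if not level and baseline is not None:
                resp, nonr = baseline
            else:
                resp, nonr = cohort_metrics(responders, nonresponders, cfg,
                                            dropout_seed=seed, movies=movies,
                                            **kw)
                if not level:
                    baseline = (resp, nonr)
            cmp = stats.compare_groups(resp, nonr)
            rows.append({
                "level": level,
                "seed": seed,
                "median_responders": float(np.median(resp)),
                "median_nonresponders": float(np.median(nonr)),
                "separation": float(np.median(resp) - np.median(nonr)),
                "p_value": cmp.p_value,
                "auc": cmp.auc,
            })
    return pd.DataFrame(rows)


def grid_variant_comparison(scenes: Sequence[synth.SynthScene],
                            cfg: Optional[AnalysisConfig] = None) -> pd.DataFrame:
    """Paired 9x8 (duplicated valve spline) vs 8x8 metrics per case.

    The returned frame has one row per case plus the mean absolute
    difference in its ``attrs``.
    """
    rows = []
    for i, scene in enumerate(scenes):
        c = cfg if cfg is not None else DEFAULT_CONFIG.with_increment_for_fs(scene.fs)
        gm8 = pipeline.scene_movie(scene, duplicate_valve_spline=False)
        gm9 = grid.duplicate_valve_row(gm8)
        m9 = pipeline.analyze_window(gm9, c).result.metric_pct
        m8 = pipeline.analyze_window(gm8, c).result.metric_pct
        rows.append({"case": i, "metric_9x8": m9, "metric_8x8": m8,
                     "abs_diff": abs(m9 - m8)})
    table = pd.DataFrame(rows)
    table.attrs["mean_abs_diff"] = float(table["abs_diff"].mean())
    return table


def basket_size_experiment(responders, nonresponders, shrink: float = 0.7,
                           cfg: Optional[AnalysisConfig] = None) -> pd.DataFrame:
    """Smaller-basket analogue: electrodes sample a shrunken patch.

    Scenes are re-sampled with their driver origins scaled about the
    grid centre by 1/``shrink`` (equivalently the electrode patch
    covers ``shrink`` of the tissue), and the group comparison is
    repeated at both sizes.
    """
    rows = []
    for label, factor in (("full", 1.0), ("small", shrink)):
        groups = []
        for scenes in (responders, nonresponders):
            vals = []
            for scene in scenes:
                c = cfg if cfg is not None else DEFAULT_CONFIG.with_increment_for_fs(scene.fs)
                if factor == 1.0:
                    s2 = scene
                else:
                    rows_g, cols_g = scene.grid_shape
                    centre = ((rows_g - 1) / 2.0, (cols_g - 1) / 2.0)
                    new_drv = []
                    for d in scene.drivers:
                        o = (
                            centre[0] + (d.origin[0] - centre[0]) / factor,
                            centre[1] + (d.origin[1] - centre[1]) / factor,
                        )
                        o = (min(max(o[0], -0.5), rows_g - 0.5),
                             min(max(o[1], -0.5), cols_g - 0.5))
                        new_drv.append(synth.DriverSpec(
                            kind=d.kind, origin=o, period=d.period,
                            direction=d.direction, chirality=d.chirality,
                            wavelet_count=d.wavelet_count,
                            drift_speed=d.drift_speed,
                            t_start=d.t_start, t_stop=d.t_stop,
                        ))
                    s2 = synth.SynthScene(
                        grid_shape=scene.grid_shape, fs=scene.fs,
                        duration=scene.duration, drivers=tuple(new_drv),
                        conduction_speed=scene.conduction_speed / factor,
                        noise_sd=scene.noise_sd, qrs_artifact=scene.qrs_artifact,
                        pulse_width_ms=scene.pulse_width_ms, seed=scene.seed,
                    )
                vals.append(pipeline.scene_metric(s2, c))
            groups.append(np.asarray(vals))
        cmp = stats.compare_groups(groups[0], groups[1])
        rows.append({"basket": label,
                     "median_responders": float(np.median(groups[0])),
                     "median_nonresponders": float(np.median(groups[1])),
                     "p_value": cmp.p_value, "auc": cmp.auc})
    return pd.DataFrame(rows)
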