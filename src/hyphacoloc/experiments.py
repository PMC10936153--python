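"""Simulation experiments of the colocalization study, in reusable form.

Each function runs one complete in-silico experiment — generate ground-
truthed scenes, image them through the forward model, run the analysis
pipeline — and returns plain data.  The analysis drivers, the test suite
and the acceptance script all call these, so every entry point measures
the same protocol.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

from . import presets
from .colocalization import AnalysisConfig, coloc_image, coloc_timeseries
from .objects4d import label_components, link_objects
from .segmentation import segment_green, segment_red
from .synthetic_scene import make_scene, render, simulate_timeseries

F_LEVELS = (0.0, 0.25, 0.5, 0.75, 1.0)


def pcc_vs_fraction(
    f_levels: Sequence[float] = F_LEVELS,
    n_seeds: int = 20,
    base_seed: int = 0,
    config: AnalysisConfig = AnalysisConfig(),
) -> pd.DataFrame:
    """Masked PCC across the colocalization fraction f.

    Per replicate one scene is generated and imaged once; the f = 1 level
    uses the low-noise acquisition (the high-colocalization regime is
    measured on bright, fixed samples), the rest the standard one.
    Returns a tidy frame with columns (f, seed, pcc, true_f).
    """
    rows = []
    for f in f_levels:
        for i in range(n_seeds):
            scene = make_scene(presets.scene_spec(f, seed=base_seed + i))
            acq = (
                presets.acq_low_noise(seed=base_seed + 1000 + i)
                if f == 1.0
                else presets.acq_standard(seed=base_seed + 1000 + i)
            )
            res = coloc_image(render(scene, acq), config)
            rows.append({"f": f, "seed": base_seed + i, "pcc": res.pcc,
                         "true_f": scene.true_f})
    return pd.DataFrame(rows)


def bleaching_slopes(
    n_seeds: int = 20,
    t_steps: int = 10,
    base_seed: int = 0,
    red_rate: float = 0.18,
) -> list[float]:
    """PCC-vs-time slope under red photobleaching with a fixed noise floor.

    One fully colocalized live scene per replicate, imaged for ``t_steps``
    frames while the red channel bleaches; returns the least-squares slope
    of PCC against t per replicate (negative = decaying correlation).
    """
    slopes = []
    for i in range(n_seeds):
        scene = make_scene(presets.scene_spec(1.0, seed=base_seed + i))
        acq = presets.acq_bleaching(seed=base_seed + 500 + i, red_rate=red_rate)
        series = coloc_timeseries(render(scene, acq, t_steps=t_steps))
        slopes.append(series.pcc_slope)
    return slopes


def bleed_paired_pcc(
    n_reps: int = 20,
    base_seed: int = 0,
    alpha: float = 0.3,
) -> pd.DataFrame:
    """Paired effect of green-to-red bleed-through on the measured PCC.

    Uses the cytosolic-control scene (bright diffuse GFP, compartmentalized
    red marker, zero true colocalization); each replicate images the same
    scene with and without cross-talk using the same acquisition seed.
    """
    rows = []
    for i in range(n_reps):
        scene = make_scene(presets.scene_cytosolic_control(seed=base_seed + i))
        seed = base_seed + 701 + i
        p0 = coloc_image(render(scene, presets.acq_standard(seed=seed))).pcc
        p1 = coloc_image(render(
            scene, presets.acq_standard(seed=seed, bleed_alpha=alpha))).pcc
        rows.append({"seed": base_seed + i, "pcc_alpha0": p0, "pcc_bleed": p1})
    return pd.DataFrame(rows)


def motion_pcc_step_variance(
    n_seeds: int = 10,
    t_steps: int = 8,
    motion_sd_um: float = 0.25,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Per-step PCC variance: moving vesicles against a static control."""
    rows = []
    for i in range(n_seeds):
        spec = presets.scene_spec(0.5, seed=base_seed + i)
        acq = presets.acq_standard(seed=base_seed + 300 + i)
        moving, _ = simulate_timeseries(spec, acq, t_steps, motion_sd_um)
        static, _ = simulate_timeseries(spec, acq, t_steps, 0.0)
        var_m = float(np.nanvar(np.diff(coloc_timeseries(moving).pcc_values)))
        var_s = float(np.nanvar(np.diff(coloc_timeseries(static).pcc_values)))
        rows.append({"seed": base_seed + i, "step_var_moving": var_m,
                     "step_var_static": var_s})
    return pd.DataFrame(rows)


def object_count_check(seed: int = 0, n_vesicles: int = 7) -> dict:
    """Noiseless rendering: labeled component counts vs ground truth."""
    scene = make_scene(presets.scene_objects_truth(seed=seed, n_vesicles=n_vesicles))
    pair = render(scene, presets.acq_noiseless())
    vs = scene.spec.voxel_size_um
    n_green = label_components(segment_green(pair.green).mask, vs).n_objects
    n_red = label_components(segment_red(pair.red).mask, vs).n_objects
    return {
        "true_vesicles": len(scene.vesicles),
        "expected_components": len(scene.vesicles) + 1,  # + ER tube
        "green_components": n_green,
        "red_components": n_red,
    }


def tracking_accuracy(
    seed: int = 0,
    t_steps: int = 10,
    motion_sd_um: float = 0.1,
    max_step_um: float = 0.5,
) -> float:
    """Fraction of frame-to-frame links that connect the same true vesicle."""
    spec = presets.scene_objects_truth(seed=seed)
    pair, scenes = simulate_timeseries(
        spec, presets.acq_noiseless(), t_steps, motion_sd_um)
    tables = []
    for t in range(t_steps):
        fr = pair.frame(t)
        tables.append(label_components(
            segment_green(fr.green).mask, spec.voxel_size_um, 26,
            fr.red, fr.green, t=t))
    linked = link_objects(tables, max_step_um)

    def truth_id(row):
        scene = scenes[int(row.t)]
        c = np.array([row.centroid_z_um, row.centroid_y_um, row.centroid_x_um])
        cands = [o for o in scene.objects if o.in_green and o.kind != "cytosol"]
        return min(cands, key=lambda o: np.linalg.norm(c - np.array(o.center_zyx_um))).id

    truth = np.array([truth_id(r) for r in linked.itertuples()])
    linked = linked.assign(truth=truth)
    good = total = 0
    for _, sub in linked.groupby("track_id"):
        tr = sub.sort_values("t")["truth"].to_numpy()
        good += int(np.sum(tr[1:] == tr[:-1]))
        total += len(tr) - 1
    return good / total if total else float("nan")
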