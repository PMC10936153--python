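#!/usr/bin/env python
"""4D object analysis: counts, per-object overlap and tracking vs truth.

On noiseless renderings of ground-truthed scenes: labeled component counts
against the known object inventory, green-over-red masking, per-object
channel overlap, and greedy frame-to-frame tracking accuracy under vesicle
motion.
"""

from pathlib import Path

import pandas as pd

from hyphacoloc import experiments, presets
from hyphacoloc.objects4d import label_components, mask_green_over_red, object_overlap
from hyphacoloc.segmentation import segment_green, segment_red
from hyphacoloc.synthetic_scene import make_scene, render

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0) -> None:
    OUT.mkdir(exist_ok=True)
    rows = [experiments.object_count_check(seed=seed + k) for k in range(5)]
    counts = pd.DataFrame(rows)
    counts.to_csv(OUT / "object_counts.csv", index=False)
    exact = int((counts["green_components"] == counts["expected_components"]).sum())
    print(f"noiseless component counts match ground truth in {exact}/5 scenes")

    scene = make_scene(presets.scene_objects_truth(seed=seed))
    pair = render(scene, presets.acq_noiseless())
    mask_r = segment_red(pair.red)
    mask_g = segment_green(pair.green)
    vs = scene.spec.voxel_size_um
    tab_r = label_components(mask_r.mask, vs, 26, pair.red, pair.green)
    tab_g = label_components(mask_g.mask, vs, 26, pair.red, pair.green)
    tab_r, tab_g = object_overlap(tab_r, tab_g, mask_r.mask, mask_g.mask)
    tab_r.table.to_csv(OUT / "objects_red.csv", index=False)
    tab_g.table.to_csv(OUT / "objects_green.csv", index=False)
    _, summary = mask_green_over_red(pair, mask_g.mask)
    print(f"green-over-red masking retains {summary['retained_red_fraction']:.1%} "
          "of the red intensity in this fully colocalized scene")

    acc = experiments.tracking_accuracy(seed=seed)
    print(f"tracking under vesicle motion: {acc:.1%} of frame-to-frame links "
          "connect the same true vesicle")


if __name__ == "__main__":
    main()
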