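#!/usr/bin/env python
"""Live-cell time-series regimes: photobleaching decay and vesicle motion.

Two experiments on simulated 4D series:
  (1) red-channel photobleaching against a fixed noise floor -> the PCC
      declines steadily with time (negative slope per series);
  (2) vesicle motion -> the per-step PCC changes are sharper (larger
      frame-to-frame variance) than in a static control.
Writes per-series tables to results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hyphacoloc import experiments

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0) -> None:
    OUT.mkdir(exist_ok=True)
    slopes = experiments.bleaching_slopes(n_seeds=20, t_steps=10, base_seed=seed)
    pd.DataFrame({"seed": range(seed, seed + 20), "pcc_slope": slopes}).to_csv(
        OUT / "bleaching_slopes.csv", index=False)
    neg = sum(s < 0 for s in slopes)
    print(f"photobleaching: PCC slope negative in {neg}/20 series "
          f"(mean slope {np.mean(slopes):+.4f} per frame)")

    motion = experiments.motion_pcc_step_variance(n_seeds=10, base_seed=seed)
    motion.to_csv(OUT / "motion_step_variance.csv", index=False)
    larger = int((motion["step_var_moving"] > motion["step_var_static"]).sum())
    print(f"vesicle motion: per-step PCC variance larger than static control "
          f"in {larger}/10 series "
          f"({motion['step_var_moving'].mean():.2g} vs "
          f"{motion['step_var_static'].mean():.2g})")


if __name__ == "__main__":
    main()
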