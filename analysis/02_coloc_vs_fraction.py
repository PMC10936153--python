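#!/usr/bin/env python
"""Masked PCC as a function of the true colocalization fraction.

Runs the full per-image pipeline (channel-specific segmentation, region =
overlapping foreground voxels, Pearson correlation) on simulated scenes at
f = 0, 0.25, 0.5, 0.75, 1 with 20 replicates each, and writes the per-image
and per-level tables.  This is the in-silico counterpart of comparing
compartmentalized enzymes (high PCC) against the cytosolic control and the
micro-segregated regime (PCC near zero).
"""

from pathlib import Path

from hyphacoloc import experiments

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0) -> None:
    frame = experiments.pcc_vs_fraction(n_seeds=20, base_seed=seed)
    OUT.mkdir(exist_ok=True)
    frame.to_csv(OUT / "pcc_vs_fraction.csv", index=False)
    summary = frame.groupby("f")["pcc"].agg(["mean", "sem", "count"])
    summary.to_csv(OUT / "pcc_vs_fraction_summary.csv")
    print("mean masked PCC by simulated colocalization fraction:")
    print(summary.round(3).to_string())
    increasing = (summary["mean"].diff().dropna() > 0).all()
    print(f"strictly increasing in f: {increasing}")


if __name__ == "__main__":
    main()
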