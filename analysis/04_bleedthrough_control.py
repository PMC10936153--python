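#!/usr/bin/env python
"""Bleed-through artifact on the cytosolic-control strain.

Images the same control scene (bright diffuse GFP, compartmentalized red
marker, zero true colocalization) with and without green-to-red cross-talk
(alpha = 0.3) using paired acquisition seeds, and quantifies the artificial
PCC inflation the cross-talk produces.
"""

from pathlib import Path

from hyphacoloc import experiments

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0) -> None:
    frame = experiments.bleed_paired_pcc(n_reps=20, base_seed=seed, alpha=0.3)
    OUT.mkdir(exist_ok=True)
    frame.to_csv(OUT / "bleedthrough_paired_pcc.csv", index=False)
    delta = frame["pcc_bleed"] - frame["pcc_alpha0"]
    wins = int((delta > 0).sum())
    print(f"bleed-through (alpha=0.3) raised the measured PCC in "
          f"{wins}/20 paired acquisitions")
    print(f"mean PCC without cross-talk: {frame['pcc_alpha0'].mean():+.3f}; "
          f"with cross-talk: {frame['pcc_bleed'].mean():+.3f} "
          f"(mean gain {delta.mean():+.3f})")


if __name__ == "__main__":
    main()
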