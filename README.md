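# hyphacoloc

Quantification of enzyme colocalization in two-channel 3D/4D confocal
volumes of fungal hyphae.

Biosynthetic enzymes in filamentous fungi are distributed between the
cytosol, the endoplasmic reticulum (ER) and sub-micron ER-derived
vesicles. Whether two tagged proteins occupy the same compartment is
decided quantitatively, from voxel statistics, not by eye: this package
implements the full measurement pipeline — channel-specific thresholding
(two-class Otsu for the green channel; three-class multi-Otsu plus
morphological opening for the noisier red channel), masked Pearson
correlation over the overlapping foreground voxels, Manders split
coefficients and mask overlap, per-timepoint analysis of 4D live-cell
series, object-level analysis (labeling, per-object channel overlap,
green-over-red masking, frame-to-frame tracking), and strain-level
statistics (mean ± SEM, one-way ANOVA, Dunnett's many-to-one test with
Monte-Carlo critical values).

At its core is the masked Pearson coefficient

    PCC = Σ (R_i − R̄)(G_i − Ḡ) / sqrt( Σ (R_i − R̄)² · Σ (G_i − Ḡ)² )

over the voxels `i` of the region where both channels' foreground masks
overlap, together with Manders' `M1 = Σ_{red∩green} R / Σ_{red} R` (and
symmetric `M2`).

Because raw microscopy of this kind is rarely available for method
validation, the package also contains a first-class synthetic-scene
generator: ground-truthed two-channel hyphal scenes (tubular ER,
perinuclear rings, mobile sub-micron vesicles, diffuse cytosol) with a
controllable true colocalization fraction, Gaussian PSF blur,
Poisson + Gaussian noise, channel bleed-through, photobleaching and
vesicle motion. Every stage of the pipeline is tested against this
ground truth; see `docs/methods.md` for the models and their limits.

## Worked example

Simulate a scene whose vesicles carry both fluorophores half of the
time, then measure it:

```
$ hyphacoloc simulate --out-dir scene --seed 3
true colocalization fraction: 0.6
red: scene/red.tif
green: scene/green.tif
labels: scene/labels.tif
truth: scene/ground_truth.csv
$ hyphacoloc analyze --red scene/red.tif --green scene/green.tif --out coloc.csv
pcc=0.6508 m1=0.9289 m2=0.3724 overlap=0.2223 qc_fail=False
```

In this draw 6 of the 10 vesicles carry both fluorophores (realized
fraction 0.6), and the masked PCC over the overlapping foreground voxels
comes out at 0.65: partial co-compartmentalization, clearly above a
segregated control but well below full colocalization. `M1 = 0.93` says
almost all red (ER-marker) intensity lies under the green mask — the
green channel's bright cytosolic pool covers the whole cell — while
`M2 = 0.37` says only 37% of the green intensity falls inside the red
compartments. The `analysis/` directory holds the
numbered study drivers; for example the dose-response of the measured
PCC to the simulated ground-truth fraction `f`:

```
$ python analysis/02_coloc_vs_fraction.py
mean masked PCC by simulated colocalization fraction:
       mean    sem  count
f
0.00 -0.025  0.015     20
0.25  0.161  0.038     20
0.50  0.408  0.067     20
0.75  0.597  0.048     20
1.00  0.972  0.001     20
strictly increasing in f: True
```

Fully segregated scenes measure near zero, fully co-compartmentalized
scenes near 1, and the mean response is strictly monotone — the
separation that lets a cytosolic control strain be told apart from
compartmentalized enzymes. Other drivers reproduce the live-cell
regimes (PCC decay under red photobleaching; sharper PCC fluctuations
under vesicle motion), the bleed-through artifact (cross-talk from a
bright cytosolic GFP inflates the control's PCC in 20/20 paired
acquisitions), object-level ground-truth agreement, and the strain-level
statistics table.

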