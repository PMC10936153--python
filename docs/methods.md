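# Methods

`hyphacoloc` quantifies the colocalization of two fluorescently tagged
proteins in 3D and 4D confocal volumes of fungal hyphae, and ships a
ground-truthed scene simulator so that every step of the pipeline can be
validated against known answers. This note documents the models, the
parameters that matter, and the choices made where the design was open.

## The measurement pipeline

**Segmentation.** The two channels are segmented independently, because
their backgrounds differ. The green channel (a GFP-tagged enzyme, with a
bright diffuse cytosolic pool) is thresholded with the two-class Otsu
criterion: the histogram (256 equal-width bins over the observed range;
candidates are bin centers) is split at the cut maximizing the
between-class variance `w0*w1*(mu0-mu1)^2`, foreground = intensity
strictly above the cut. The red channel (a DsRed-tagged ER/SPT marker
with a noisier diffuse background) uses the three-class multi-Otsu
criterion — the extra class absorbs the diffuse cytosolic signal — and
keeps the top class, followed by a binary morphological opening
(6-connected 3D cross, radius 1 voxel) that removes single-voxel specks.
Ties in the variance search resolve to the smallest threshold
(lexicographically smallest pair), so results are identical across
platforms. Both searches are exhaustive over the binned candidates and
are tested against independent brute-force enumeration. Thresholding and
opening are applied in that order — threshold, binarize, open — the only
order in which an opening of a *binary* image is well defined. Opening is
performed in 3D, not per slice.

Note one inherent quantization: with empty histogram bins, several cut
positions give exactly the same class partition and the same variance;
any of them is a valid Otsu threshold, and the tie rule picks the
smallest. Comparisons with other implementations should therefore compare
achieved variance, not raw threshold values.

**Colocalization coefficients.** For one image the pipeline reports:

- **PCC**, Pearson's correlation of the two channels over a voxel region.
  The default region is the *intersection* of the two foreground masks —
  the overlapping red-and-green voxels — with union and whole-image modes
  selectable. PCC is computed over the full 3D region in double
  precision with the two-pass formula; it is invariant under per-channel
  affine rescaling with positive gain.
- **M1/M2**, Manders split coefficients: the fraction of red integrated
  intensity (within the red mask) that falls inside the green mask, and
  vice versa.
- **overlap**, the Jaccard index of the two masks.

An empty region is an error distinct from a zero-variance region; inside
the batch pipeline both become QC-flagged rows (NaN coefficients,
`qc_fail=true`) rather than exceptions, so a run over many images always
completes. 4D inputs are analyzed per timepoint; the series reports the
sign of the least-squares slope of PCC against time.

**Object analysis.** Foreground masks are decomposed into connected
components (26-connectivity by default; 6 and 18 available), with
centroids and volumes in physical micrometres. Per-object channel
overlap is `|object ∩ other mask| / |object|`; its volume-weighted mean
equals the mask-level overlap exactly. Green-over-red masking retains
red intensity only under the green mask and reports the retained
intensity fraction. Tracking links objects between consecutive frames by
greedy nearest-centroid matching (candidates sorted by distance, then by
label ids for determinism), rejecting links longer than `max_step_um`.
Greedy matching was chosen over global assignment because scenes contain
few, well-separated objects and deterministic behavior matters more than
optimality here; splitting/merging events are out of scope.

**Group statistics.** Per-strain values are summarized as mean ± SEM
(n−1 sd). Strains are compared with one-way ANOVA (classical
between/within sums of squares) followed by Dunnett's many-to-one test
against the control. Dunnett critical values are obtained by seeded
Monte-Carlo simulation of the null max-|t| distribution under the
pooled-variance normal model — the contrasts share the control and are
therefore correlated, which the simulation reproduces exactly — rather
than from multivariate-t quadrature or printed tables; 10^5 draws give
adjusted p-values accurate to ~0.003. The unadjusted per-contrast
p-value is estimated from the same draws, which guarantees
`p_adj >= p_unadj` for every comparison. With a single treatment group
the adjusted p converges to the two-sided pooled t-test. Calibration is
verified two ways: agreement with an independent Dunnett implementation,
and a family-wise error rate of ~0.05 under the global null over 2·10^4
simulated experiments. Significance tiers (*, **, ***) at
0.05/0.01/0.001 are reported purely as labels.

## The scene simulator

The simulator emulates the structures of a two-color hyphal field of
view: a cylindrical hypha (radius 1.3 µm) containing an axial ER tube
(radius 0.25 µm), an optional perinuclear ER ring, spherical ER-derived
vesicles of 0.6–0.84 µm diameter (sub-micron, as such vesicles are), and
diffuse cytosolic background in both channels. Geometry is generated in
physical micrometres and discretized onto an anisotropic voxel grid
(default 24×64×64 voxels at 0.2×0.1×0.1 µm), so `dz ≠ dxy` exactly as in
real confocal stacks.

**Colocalization ground truth.** A single fraction `f ∈ [0,1]` controls
co-compartmentalization: each vesicle carries both fluorophores with
probability f (seeded Bernoulli; single-labeled vesicles alternate
between the channels), and the ER structures carry the green fluorophore
with the same probability (one draw per scene) — an enzyme that fully
co-compartmentalizes with the ER-resident marker decorates the ER as
well as the vesicles. The realized fraction of dual-labeled vesicles is
recorded as `true_f` (NaN when the scene has no vesicles). A
`cytosolic_green_only` variant models the control strain whose green tag
is purely cytosolic.

**Placement.** Vesicles are rejection-sampled uniformly inside the hypha
with a minimum surface gap (0.1 µm) from each other, the tube and the
rings, with at most 1000 retries per vesicle before an explicit error.
Vesicle radii are drawn from 0.30–0.42 µm; the lower bound guarantees a
vesicle spans at least three z-slices, so the red channel's radius-1
opening can never erase a real vesicle. Per-vesicle brightness is
log-normal (σ = 0.25), shared between the channels of a dual-labeled
vesicle.

**Diffuse signal.** Cytosolic intensity follows the chord length through
the cylindrical cell, `sqrt(1 - (rho/R)^2)` — diffuse fluorophore
integrates over the optical path, so the cell appears brightest along
its axis. The green cytosol is bright (0.35 of vesicle intensity;
0.8 in the cytosolic-control strain) and the red diffuse background
weaker but noticeable (0.15), mirroring the typical contrast between a
partly cytosolic GFP-tagged enzyme and a compartmentalized DsRed marker.
A consequence worth knowing: the green Otsu mask is then the whole cell,
so the default PCC region (mask intersection) is the set of red
structures — a large, stable region, rather than a thin unstable band of
blur halos.

**Imaging model.** Per frame, in order: green→red bleed-through (`red +=
alpha * green_clean`; one-directional by default, since the artifact of
interest is a bright cytosolic GFP leaking into the red detector, with a
symmetric option), Gaussian PSF blur (σz = 0.25 µm, σxy = 0.10 µm —
modest widths emulating post-deconvolution images), per-channel
exponential photobleaching `exp(-k t)`, Poisson shot noise at
`photon_gain` expected photons per unit intensity (default 150), and
additive Gaussian read noise (sd 0.02). Setting σ = 0, gain = ∞, read
noise = 0 makes rendering the exact identity on the painted volumes,
which the truth-comparison tests exploit. All randomness flows from
explicit seeds; identical spec and seeds give bit-identical volumes.

Because PCC is scale-invariant, photobleaching *alone* cannot change it;
the decaying PCC in bleached time series arises from the fixed noise
floor (growing relative shot noise plus constant read noise) against
which the red signal loses contrast. This is deliberate and is the
regime the time-series experiments measure.

**Motion.** `advance_time` applies seeded Gaussian steps to vesicle
centers (ER static, ids preserved), clipped so spheres stay inside the
volume; mean squared displacement grows linearly in step count until
clipping intervenes.

**A model finding on bleed-through.** In the cytosolic-control
configuration, adding α = 0.3 cross-talk raises the measured PCC in
every paired acquisition — the artifact the control experiment exists to
catch. In a scene with green *structures* and zero true colocalization
the model predicts the opposite sign: the bleed ghost of a green vesicle
enters the red mask with below-native red intensity and forms an
anticorrelated cluster. Apparent-colocalization inflation by cross-talk
is thus specific to diffuse sources in this model, which is why the
bleed experiment is run on the control-strain scene.

## What the simulator does not model

Hyphal branching, septation and nuclei; realistic optical aberrations
beyond a Gaussian PSF; deconvolution artifacts; depth-dependent
attenuation; vesicle fission/fusion; intensity saturation. Passing tests
on synthetic scenes show the *pipeline* is correct and that the regimes
(monotone PCC in f, bleaching decay, bleed-through inflation) behave as
in the real study; they do not certify performance on real images with
structured backgrounds or segmentation-hostile noise.

## Problem sizes and numerical choices

Simulated volumes are 24×64×64 voxels with 10 vesicles, 20 replicates
per condition, 10-frame time series; Dunnett uses 10^5 draws (2·10^5 for
critical-value calibration over 2·10^4 simulated experiments). These
sizes make the full validation suite run in well under a minute per
experiment while leaving Monte-Carlo errors far below the effect sizes
measured. Histogram thresholding uses 256 bins (equal-width over the
observed range); PCC is computed in float64 and matches a two-pass
oracle to 1e-12; degenerate inputs (constant channels, empty regions,
zero denominators) are defined errors or QC flags, never silent NaNs.
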