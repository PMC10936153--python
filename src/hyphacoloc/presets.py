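"""Reference simulation conditions shared by tests, drivers and scripts.

The scene defaults live on :class:`~hyphacoloc.synthetic_scene.SceneSpec`;
these helpers only pin the acquisition regimes used throughout the
analyses (standard, low-noise, noiseless, bleaching) so every entry point
simulates the same conditions.
"""

from __future__ import annotations

import math

from .synthetic_scene import AcquisitionSpec, SceneSpec

__all__ = [
    "scene_spec",
    "acq_standard",
    "acq_low_noise",
    "acq_noiseless",
    "acq_bleaching",
]


def scene_spec(coloc_fraction: float = 0.5, seed: int = 0, **overrides) -> SceneSpec:
    """Default hyphal scene with the requested colocalization fraction."""
    return SceneSpec(coloc_fraction=coloc_fraction, seed=seed, **overrides)


def scene_cytosolic_control(seed: int = 0, **overrides) -> SceneSpec:
    """Cytosolic-control strain: very bright diffuse GFP, no green structures.

    This is the configuration in which channel bleed-through inflates the
    apparent colocalization of the compartmentalized red marker.
    """
    kw = dict(
        coloc_fraction=0.0, cytosolic_green_only=True, cytosol_level=(0.15, 0.8)
    )
    kw.update(overrides)
    return SceneSpec(seed=seed, **kw)


def scene_objects_truth(seed: int = 0, n_vesicles: int = 7, **overrides) -> SceneSpec:
    """Scene for exact object-level ground-truth comparisons.

    Uniform vesicle brightness, no ring, no green cytosol, a thicker ER tube
    and generous inter-object gaps so that, under noiseless imaging, every
    structure maps to exactly one labeled component.
    """
    kw = dict(
        coloc_fraction=1.0, n_vesicles=n_vesicles, cytosol_level=(0.15, 0.0),
        n_perinuclear_rings=0, vesicle_intensity_sd=0.0,
        vesicle_margin_um=0.3, er_tube_radius_um=0.35, hypha_radius_um=1.5,
    )
    kw.update(overrides)
    return SceneSpec(seed=seed, **kw)


def acq_standard(seed: int = 0, **overrides) -> AcquisitionSpec:
    """Moderate shot + read noise, post-deconvolution-like PSF."""
    return AcquisitionSpec(seed=seed, **overrides)


def acq_low_noise(seed: int = 0, **overrides) -> AcquisitionSpec:
    """High photon budget; used for the high-colocalization regime."""
    kw = dict(photon_gain=2000.0, read_noise_sd=0.005)
    kw.update(overrides)
    return AcquisitionSpec(seed=seed, **kw)


def acq_noiseless(seed: int = 0) -> AcquisitionSpec:
    """Identity imaging model: no blur, no noise (rendered == painted)."""
    return AcquisitionSpec(
        psf_sigma_um=(0.0, 0.0), photon_gain=math.inf, read_noise_sd=0.0, seed=seed
    )


def acq_bleaching(seed: int = 0, red_rate: float = 0.18) -> AcquisitionSpec:
    """Standard noise floor plus exponential photobleaching of the red channel."""
    return AcquisitionSpec(bleach_rate=(red_rate, 0.0), seed=seed)
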