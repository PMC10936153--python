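"""Ground-truthed synthetic two-channel hyphal scenes.

The generator emulates the structures seen in two-color confocal stacks of
fungal hyphae: a tubular ER strand running along the hypha, optional
perinuclear ER rings, sub-micron ER-derived vesicles, and diffuse cytosolic
background, imaged in a red (ER/SPT marker) and a green (tagged enzyme)
channel.  The degree of co-compartmentalization is controlled by a single
fraction ``f``: each vesicle carries both fluorophores with probability
``f`` and exactly one otherwise.

Geometry is generated in physical micrometres and discretized onto an
anisotropic voxel grid (``dz != dxy``, as in real confocal stacks).  The
forward imaging model applies (in order) green-to-red bleed-through,
Gaussian PSF blur, per-channel exponential photobleaching, Poisson shot
noise and additive Gaussian read noise.

All randomness flows from explicit integer seeds; no global RNG state is
touched.  Identical spec + seeds give bit-identical output.

Note on bleaching and correlation: the Pearson coefficient is invariant
under positive rescaling, so photobleaching alone cannot change it.  The
decay of the measured PCC over time arises from the *fixed* noise floor
(shot noise at lower photon counts plus constant read noise), against which
the bleached signal loses contrast.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .errors import SceneGenerationError
from .volume_io import ChannelPairVolume

__all__ = [
    "SceneSpec",
    "AcquisitionSpec",
    "SceneObject",
    "GroundTruthScene",
    "make_scene",
    "render",
    "advance_time",
    "simulate_timeseries",
    "paint_channels",
    "structure_support",
    "write_scene",
]

ObjectKind = Literal["ER_tube", "perinuclear_ring", "vesicle", "cytosol"]


@dataclass(frozen=True)
class SceneSpec:
    """Geometry and composition of a synthetic hyphal scene.

    Defaults describe a small spinning-disk field of view: anisotropic
    voxels of 0.2 x 0.1 x 0.1 um, a hypha of radius 1 um along x, one ER
    tube, one perinuclear ring and a dozen vesicles of 0.5-0.9 um diameter.
    """

    shape_zyx: tuple[int, int, int] = (24, 64, 64)
    voxel_size_um: tuple[float, float, float] = (0.2, 0.1, 0.1)
    hypha_radius_um: float = 1.3
    n_vesicles: int = 10
    vesicle_radius_um_range: tuple[float, float] = (0.30, 0.42)
    coloc_fraction: float = 0.5
    #: diffuse cytosolic intensity per channel (red, green); the green tag is
    #: on an enzyme with a bright cytosolic pool, the red ER marker has a
    #: weaker but noticeable diffuse background.
    cytosol_level: tuple[float, float] = (0.15, 0.35)
    seed: int = 0
    # -- secondary geometry knobs -------------------------------------------
    er_tube_radius_um: float = 0.25
    er_intensity: float = 1.0
    n_perinuclear_rings: int = 1
    ring_radius_um: float = 0.65
    ring_thickness_um: float = 0.2
    #: log-normal sigma of per-vesicle brightness (shared by both channels)
    vesicle_intensity_sd: float = 0.25
    #: model of the cytosolic-control strain: the green fluorophore is purely
    #: diffuse (no green structures), as when tagging a cytosolic enzyme
    cytosolic_green_only: bool = False
    #: minimum surface-to-surface gap between a vesicle and other structures,
    #: so distinct objects stay distinct after voxelization
    vesicle_margin_um: float = 0.1
    max_placement_retries: int = 1000

    def validate(self) -> None:
        if any(n <= 0 for n in self.shape_zyx) or len(self.shape_zyx) != 3:
            raise ValueError(f"invalid shape {self.shape_zyx}")
        if any(d <= 0 for d in self.voxel_size_um):
            raise ValueError(f"invalid voxel size {self.voxel_size_um}")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError(f"coloc_fraction must be in [0,1], got {self.coloc_fraction}")
        rmin, rmax = self.vesicle_radius_um_range
        if not (0 < rmin <= rmax <= self.hypha_radius_um):
            raise ValueError(
                f"vesicle radii {self.vesicle_radius_um_range} must be positive "
                f"and <= hypha radius {self.hypha_radius_um}"
            )
        if self.n_vesicles < 0:
            raise ValueError("n_vesicles must be >= 0")
        if min(self.cytosol_level) < 0:
            raise ValueError("cytosol levels must be >= 0")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(n * d for n, d in zip(self.shape_zyx, self.voxel_size_um))  # type: ignore[return-value]


@dataclass(frozen=True)
class AcquisitionSpec:
    """Forward imaging model parameters.

    ``psf_sigma_um`` is (sigma_z, sigma_xy) of the Gaussian blur; the modest
    defaults emulate images after deconvolution.  ``photon_gain`` is the
    expected photon count at unit painted intensity (``inf`` disables shot
    noise).  ``bleach_rate`` is the per-channel exponential decay constant
    (red, green) per time step; ``bleed_alpha`` adds that fraction of the
    clean green signal to the red channel (detector cross-talk of a bright
    cytosolic GFP), optionally symmetrically.
    """

    psf_sigma_um: tuple[float, float] = (0.25, 0.10)
    photon_gain: float = 150.0
    read_noise_sd: float = 0.02
    bleed_alpha: float = 0.0
    bleed_symmetric: bool = False
    bleach_rate: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def validate(self) -> None:
        if min(self.psf_sigma_um) < 0:
            raise ValueError("PSF sigma must be >= 0")
        if not self.photon_gain > 0:
            raise ValueError("photon_gain must be > 0")
        if not 0.0 <= self.bleed_alpha < 1.0:
            raise ValueError("bleed_alpha must be in [0,1)")
        if min(self.bleach_rate) < 0:
            raise ValueError("bleach rates must be >= 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")


@dataclass
class SceneObject:
    """One labeled structure: id, kind, geometry, channel membership."""

    id: int
    kind: ObjectKind
    center_zyx_um: tuple[float, float, float]
    radius_um: float
    in_red: bool
    in_green: bool
    intensity_red: float
    intensity_green: float


@dataclass
class GroundTruthScene:
    """Object list + integer label volume + realized colocalization fraction.

    ``true_f`` is the realized fraction of vesicles carrying both
    fluorophores (NaN when the scene has no vesicles).  The scene carries
    its own RNG (seeded from the spec) which :func:`advance_time` consumes,
    so a fixed spec yields a bit-identical trajectory.
    """

    spec: SceneSpec
    objects: list[SceneObject]
    label_volume: np.ndarray
    true_f: float
    rng: np.random.Generator = field(repr=False, compare=False, default=None)  # type: ignore[assignment]

    @property
    def vesicles(self) -> list[SceneObject]:
        return [o for o in self.objects if o.kind == "vesicle"]


# ---------------------------------------------------------------------------
# geometry helpers (all in physical um; voxel centers at (i + 0.5) * d)


def _axis_coords(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return tuple(
        (np.arange(n) + 0.5) * d
        for n, d in zip(spec.shape_zyx, spec.voxel_size_um)
    )  # type: ignore[return-value]


def _sphere_footprint(spec: SceneSpec, center: tuple[float, float, float],
                      radius: float) -> np.ndarray:
    z, y, x = _axis_coords(spec)
    dz = (z - center[0]) ** 2
    dy = (y - center[1]) ** 2
    dx = (x - center[2]) ** 2
    return (
        dz[:, None, None] + dy[None, :, None] + dx[None, None, :]
    ) <= radius**2


def _tube_footprint(spec: SceneSpec, center_zy: tuple[float, float],
                    radius: float) -> np.ndarray:
    """Cylinder along x of the given radius (full x extent)."""
    z, y, _ = _axis_coords(spec)
    r2 = (z - center_zy[0])[:, None] ** 2 + (y - center_zy[1])[None, :] ** 2
    disc = r2 <= radius**2
    return np.repeat(disc[:, :, None], spec.shape_zyx[2], axis=2)


def _shell_footprint(spec: SceneSpec, center: tuple[float, float, float],
                     outer: float, thickness: float) -> np.ndarray:
    z, y, x = _axis_coords(spec)
    d2 = (
        (z - center[0])[:, None, None] ** 2
        + (y - center[1])[None, :, None] ** 2
        + (x - center[2])[None, None, :] ** 2
    )
    return (d2 <= outer**2) & (d2 >= (outer - thickness) ** 2)


def _cytosol_profile(spec: SceneSpec, center_zy: tuple[float, float]) -> np.ndarray:
    """Apparent diffuse-signal weight inside the hypha.

    Diffuse fluorophore fills the cylindrical cell, so its apparent
    brightness tracks the chord length through the hypha:
    sqrt(1 - (rho/R)^2) at distance rho from the axis, 0 outside.
    """
    z, y, _ = _axis_coords(spec)
    r2 = (z - center_zy[0])[:, None] ** 2 + (y - center_zy[1])[None, :] ** 2
    frac = np.clip(1.0 - r2 / spec.hypha_radius_um**2, 0.0, None)
    profile = np.sqrt(frac)
    return np.repeat(profile[:, :, None], spec.shape_zyx[2], axis=2)


def _object_footprint(spec: SceneSpec, obj: SceneObject) -> np.ndarray:
    if obj.kind == "cytosol":
        return _tube_footprint(spec, obj.center_zyx_um[:2], spec.hypha_radius_um)
    if obj.kind == "ER_tube":
        return _tube_footprint(spec, obj.center_zyx_um[:2], obj.radius_um)
    if obj.kind == "perinuclear_ring":
        return _shell_footprint(
            spec, obj.center_zyx_um, obj.radius_um, spec.ring_thickness_um
        )
    if obj.kind == "vesicle":
        return _sphere_footprint(spec, obj.center_zyx_um, obj.radius_um)
    raise ValueError(f"unknown object kind {obj.kind!r}")


# ---------------------------------------------------------------------------
# scene construction


def make_scene(spec: SceneSpec) -> GroundTruthScene:
    """Build the object list and label volume for one scene.

    One axial ER tube (red channel) plus ``n_vesicles`` non-overlapping
    spheres placed inside the hypha but clear of the tube and any rings.
    Each vesicle is dual-labeled with probability ``coloc_fraction``;
    single-labeled vesicles alternate between red and green.  Raises
    :class:`SceneGenerationError` when a vesicle cannot be placed within
    the retry budget.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ez, ey, ex = spec.extent_um
    axis_zy = (ez / 2.0, ey / 2.0)

    objects: list[SceneObject] = []
    next_id = 1
    objects.append(
        SceneObject(
            next_id, "cytosol", (axis_zy[0], axis_zy[1], ex / 2.0),
            spec.hypha_radius_um, True, True,
            spec.cytosol_level[0], spec.cytosol_level[1],
        )
    )
    next_id += 1
    # A fully co-compartmentalized enzyme decorates the ER itself, not only
    # the vesicles; the ER structures therefore carry the green fluorophore
    # with the same probability f (one seeded draw per scene).
    er_green = bool(rng.uniform() < spec.coloc_fraction) and not spec.cytosolic_green_only
    er_green_level = spec.er_intensity if er_green else 0.0
    objects.append(
        SceneObject(
            next_id, "ER_tube", (axis_zy[0], axis_zy[1], ex / 2.0),
            spec.er_tube_radius_um, True, er_green,
            spec.er_intensity, er_green_level,
        )
    )
    next_id += 1

    rings: list[SceneObject] = []
    if spec.n_perinuclear_rings > 0:
        xs = np.linspace(0.0, ex, spec.n_perinuclear_rings + 2)[1:-1]
        for cx in xs:
            rings.append(
                SceneObject(
                    next_id, "perinuclear_ring",
                    (axis_zy[0], axis_zy[1], float(cx)),
                    spec.ring_radius_um, True, er_green,
                    spec.er_intensity, er_green_level,
                )
            )
            next_id += 1
    objects.extend(rings)

    # vesicle placement: uniform in the hypha cylinder, rejection-sampled to
    # avoid overlap with other vesicles, the ER tube and ring shells
    rmin, rmax = spec.vesicle_radius_um_range
    placed: list[tuple[tuple[float, float, float], float]] = []
    vesicles: list[SceneObject] = []
    for i in range(spec.n_vesicles):
        radius = float(rng.uniform(rmin, rmax))
        ok = False
        for _ in range(spec.max_placement_retries):
            rho_max = spec.hypha_radius_um - radius
            rho = rho_max * math.sqrt(rng.uniform())
            theta = rng.uniform(0.0, 2.0 * math.pi)
            cz = axis_zy[0] + rho * math.sin(theta)
            cy = axis_zy[1] + rho * math.cos(theta)
            cx = rng.uniform(radius, ex - radius)
            if not (radius <= cz <= ez - radius and radius <= cy <= ey - radius):
                continue
            margin = spec.vesicle_margin_um
            if rho < spec.er_tube_radius_um + radius + margin:
                continue  # would merge with the ER tube
            if any(
                math.dist((cz, cy, cx), r.center_zyx_um)
                < r.radius_um + radius + margin
                for r in rings
            ):
                continue  # would intersect a perinuclear ring shell
            if any(
                math.dist((cz, cy, cx), c) < r + radius + margin
                for c, r in placed
            ):
                continue
            placed.append(((cz, cy, cx), radius))
            ok = True
            break
        if not ok:
            raise SceneGenerationError(
                f"could not place vesicle {i + 1}/{spec.n_vesicles} after "
                f"{spec.max_placement_retries} retries; scene spec too crowded: {spec}"
            )
        brightness = float(np.exp(rng.normal(0.0, spec.vesicle_intensity_sd)))
        vesicles.append(
            SceneObject(
                next_id, "vesicle", placed[-1][0], radius,
                False, False, 0.0, 0.0,
            )
        )
        # channel membership decided below so brightness draws stay aligned
        vesicles[-1]._brightness = brightness  # type: ignore[attr-defined]
        next_id += 1

    # channel assignment: dual with probability f, singles alternate
    dual_draws = rng.uniform(size=len(vesicles)) < spec.coloc_fraction
    start_red = bool(rng.integers(0, 2))
    single_idx = 0
    n_dual = 0
    for obj, dual in zip(vesicles, dual_draws):
        b = obj._brightness  # type: ignore[attr-defined]
        if spec.cytosolic_green_only:
            obj.in_red, obj.in_green = True, False
            obj.intensity_red, obj.intensity_green = b, 0.0
            del obj._brightness  # type: ignore[attr-defined]
            continue
        if dual:
            obj.in_red = obj.in_green = True
            obj.intensity_red = obj.intensity_green = b
            n_dual += 1
        else:
            red = (single_idx % 2 == 0) == start_red
            obj.in_red, obj.in_green = red, not red
            obj.intensity_red = b if red else 0.0
            obj.intensity_green = 0.0 if red else b
            single_idx += 1
        del obj._brightness  # type: ignore[attr-defined]
    objects.extend(vesicles)

    true_f = n_dual / len(vesicles) if vesicles else float("nan")
    label = _build_label_volume(spec, objects)
    return GroundTruthScene(spec, objects, label, true_f, rng)


def _build_label_volume(spec: SceneSpec, objects: list[SceneObject]) -> np.ndarray:
    label = np.zeros(spec.shape_zyx, dtype=np.int32)
    for obj in objects:  # later objects overwrite: each voxel one id
        label[_object_footprint(spec, obj)] = obj.id
    return label


def advance_time(scene: GroundTruthScene, motion_sd_um: float) -> GroundTruthScene:
    """One diffusion step: vesicle centers take seeded Gaussian steps.

    ER structures stay static; vesicle centers are clipped so each sphere
    remains inside the volume; object ids and channel memberships are
    preserved.  Consumes the scene's RNG, so repeated calls on a scene made
    from a fixed spec are deterministic.
    """
    if motion_sd_um < 0:
        raise ValueError("motion_sd_um must be >= 0")
    rng = scene.rng if scene.rng is not None else np.random.default_rng(scene.spec.seed)
    spec = scene.spec
    extent = spec.extent_um
    new_objects: list[SceneObject] = []
    for obj in scene.objects:
        if obj.kind != "vesicle" or motion_sd_um == 0.0:
            if obj.kind == "vesicle" and motion_sd_um == 0.0:
                new_objects.append(dataclasses.replace(obj))
            else:
                new_objects.append(dataclasses.replace(obj))
            continue
        step = rng.normal(0.0, motion_sd_um, size=3)
        center = tuple(
            float(np.clip(c + s, obj.radius_um, e - obj.radius_um))
            for c, s, e in zip(obj.center_zyx_um, step, extent)
        )
        new_objects.append(dataclasses.replace(obj, center_zyx_um=center))
    label = (
        scene.label_volume.copy()
        if motion_sd_um == 0.0
        else _build_label_volume(spec, new_objects)
    )
    return GroundTruthScene(spec, new_objects, label, scene.true_f, rng)


# ---------------------------------------------------------------------------
# rendering


def paint_channels(scene: GroundTruthScene) -> tuple[np.ndarray, np.ndarray]:
    """Additively paint clean (noise- and blur-free) red/green volumes.

    Total painted intensity per channel equals the sum over member objects
    of object volume (in voxels) times its intensity.
    """
    spec = scene.spec
    red = np.zeros(spec.shape_zyx, dtype=np.float64)
    green = np.zeros(spec.shape_zyx, dtype=np.float64)
    for obj in scene.objects:
        if not (obj.in_red or obj.in_green):
            continue
        if obj.kind == "cytosol":
            # diffuse signal is weighted by the chord length through the cell
            weight = _cytosol_profile(spec, obj.center_zyx_um[:2])
            red += obj.intensity_red * weight
            green += obj.intensity_green * weight
            continue
        fp = _object_footprint(spec, obj)
        if obj.in_red:
            red[fp] += obj.intensity_red
        if obj.in_green:
            green[fp] += obj.intensity_green
    return red, green


def structure_support(scene: GroundTruthScene, channel: str) -> np.ndarray:
    """Union of non-cytosol member-object footprints for one channel."""
    spec = scene.spec
    support = np.zeros(spec.shape_zyx, dtype=bool)
    for obj in scene.objects:
        if obj.kind == "cytosol":
            continue
        if (channel == "red" and obj.in_red) or (channel == "green" and obj.in_green):
            support |= _object_footprint(spec, obj)
    return support


def _render_frame(
    clean_red: np.ndarray,
    clean_green: np.ndarray,
    spec: SceneSpec,
    acq: AcquisitionSpec,
    t: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    red = clean_red.copy()
    green = clean_green.copy()
    # detector cross-talk (bright cytosolic GFP bleeding into the red channel)
    if acq.bleed_alpha > 0.0:
        red = red + acq.bleed_alpha * clean_green
        if acq.bleed_symmetric:
            green = green + acq.bleed_alpha * clean_red
    sz, sxy = acq.psf_sigma_um
    if sz > 0 or sxy > 0:
        dz, dy, dx = spec.voxel_size_um
        sigma_vox = (sz / dz, sxy / dy, sxy / dx)
        red = ndimage.gaussian_filter(red, sigma=sigma_vox)
        green = ndimage.gaussian_filter(green, sigma=sigma_vox)
    kr, kg = acq.bleach_rate
    red = red * math.exp(-kr * t)
    green = green * math.exp(-kg * t)
    out = []
    for img in (red, green):
        if math.isfinite(acq.photon_gain):
            img = rng.poisson(img * acq.photon_gain).astype(np.float64) / acq.photon_gain
        if acq.read_noise_sd > 0:
            img = img + rng.normal(0.0, acq.read_noise_sd, size=img.shape)
        out.append(np.clip(img, 0.0, None))
    return out[0], out[1]


def render(
    scene: GroundTruthScene, acq: AcquisitionSpec, t_steps: int = 1
) -> ChannelPairVolume:
    """Render a (static) scene through the imaging model.

    For ``t_steps > 1`` the same geometry is imaged repeatedly with
    per-step photobleaching and fresh noise, giving a 4D ``(t,z,y,x)``
    pair; ``t_steps == 1`` gives a 3D pair.  Deterministic under fixed
    seeds.
    """
    acq.validate()
    if t_steps < 1:
        raise ValueError("t_steps must be >= 1")
    rng = np.random.default_rng(acq.seed)
    clean_red, clean_green = paint_channels(scene)
    frames_r, frames_g = [], []
    for t in range(t_steps):
        r, g = _render_frame(clean_red, clean_green, scene.spec, acq, t, rng)
        frames_r.append(r)
        frames_g.append(g)
    if t_steps == 1:
        return ChannelPairVolume(frames_r[0], frames_g[0], scene.spec.voxel_size_um)
    return ChannelPairVolume(
        np.stack(frames_r), np.stack(frames_g), scene.spec.voxel_size_um
    )


def simulate_timeseries(
    spec: SceneSpec,
    acq: AcquisitionSpec,
    t_steps: int,
    motion_sd_um: float = 0.0,
) -> tuple[ChannelPairVolume, list[GroundTruthScene]]:
    """Time-lapse with vesicle motion: render, diffuse, repeat.

    Returns the 4D pair and the per-frame ground-truth scenes (frame ``t``
    was rendered from ``scenes[t]``).
    """
    acq.validate()
    if t_steps < 1:
        raise ValueError("t_steps must be >= 1")
    rng = np.random.default_rng(acq.seed)
    scene = make_scene(spec)
    scenes = [scene]
    frames_r, frames_g = [], []
    for t in range(t_steps):
        clean_red, clean_green = paint_channels(scene)
        r, g = _render_frame(clean_red, clean_green, spec, acq, t, rng)
        frames_r.append(r)
        frames_g.append(g)
        if t < t_steps - 1:
            scene = advance_time(scene, motion_sd_um)
            scenes.append(scene)
    pair = ChannelPairVolume(
        np.stack(frames_r), np.stack(frames_g), spec.voxel_size_um
    )
    return pair, scenes


# ---------------------------------------------------------------------------
# on-disk outputs (used by the `simulate` CLI subcommand)


def scene_truth_table(scene: GroundTruthScene) -> pd.DataFrame:
    rows = [
        {
            "object_id": o.id,
            "kind": o.kind,
            "center_z_um": o.center_zyx_um[0],
            "center_y_um": o.center_zyx_um[1],
            "center_x_um": o.center_zyx_um[2],
            "radius_um": o.radius_um,
            "in_red": o.in_red,
            "in_green": o.in_green,
        }
        for o in scene.objects
    ]
    return pd.DataFrame(rows)


def write_scene(
    scene: GroundTruthScene,
    pair: ChannelPairVolume,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write rendered channels, the label volume and the ground-truth CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "red": out / "red.tif",
        "green": out / "green.tif",
        "labels": out / "labels.tif",
        "truth": out / "ground_truth.csv",
    }
    tifffile.imwrite(str(paths["red"]), pair.red.astype(np.float32),
                     photometric="minisblack")
    tifffile.imwrite(str(paths["green"]), pair.green.astype(np.float32),
                     photometric="minisblack")
    tifffile.imwrite(str(paths["labels"]), scene.label_volume,
                     photometric="minisblack")
    scene_truth_table(scene).to_csv(paths["truth"], index=False)
    return paths
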