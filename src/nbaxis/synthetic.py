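"""Synthetic 4D-microscopy scenes with known ground truth.

A scene is one neuroblast (NB) lineage imaged over successive asymmetric
divisions.  Each cycle is rendered as three frames:

* interphase — the NB as an elongated ellipsoid (not yet round),
* metaphase  — the NB rounded up, with two centrosome spots on the spindle,
* telophase  — the classic dumbbell: a large apical lobe and a small basal
  lobe (the nascent GMC) whose centres lie on the true division axis.

Rendered channels are ``membrane`` (a thin high-intensity shell at every
cell boundary), ``centrosome`` (3D Gaussian spots) and ``glia`` (a shell
wrapping a spherical-cap fraction of the NB).  Rendering applies an
anisotropic Gaussian PSF stand-in, then Poisson photon noise, then Gaussian
read noise.  Default voxel spacing is (0.8, 0.26, 0.26) µm — a confocal
z-step of 0.8 µm over ~3x finer xy sampling.

The division-axis *direction* process: the first axis is uniform on the
sphere; each subsequent axis deviates from its predecessor (or from the
direction toward the last-born GMC, see ``centre_on``) by an angle drawn
from a normal distribution truncated to [0°, 180°], about a uniformly
random azimuth.  The truncated-normal parameters come from
:data:`CONDITION_PRESETS`, whose values are the published per-condition
summaries this generator emulates.

Everything is reproducible: a fixed seed and configuration give a
bit-identical :class:`SceneTruth` and identical rendered stacks.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, stats

from .geometry import Axis3D, Point3D, VoxelSpacing, axis_angle
from .stack_io import VoxelGrid

__all__ = [
    "NoiseModel",
    "ConditionPreset",
    "CycleTruth",
    "SceneTruth",
    "CONDITION_PRESETS",
    "sample_division_series",
    "render_stack",
    "render_probability_map",
    "save_scene",
    "load_scene_truth",
]

DEFAULT_SPACING = VoxelSpacing(0.8, 0.26, 0.26)

#: Default NB radius, µm.  Set to match the ~10 µm cell diameters implied by
#: the 5 µm scale bars of typical larval-brain NB imagery; configurable.
DEFAULT_NB_RADIUS = 5.0

#: NB:GMC lobe volume ratio at telophase (asymmetric division), configurable.
DEFAULT_VOLUME_RATIO = 4.0


@dataclass(frozen=True)
class NoiseModel:
    """Imaging noise description.

    photon_scale: expected photon count at unit normalized intensity
        (Poisson shot noise; larger = cleaner).
    read_sigma: Gaussian read-noise SD on the normalized intensity scale.
    psf_sigma_zyx: anisotropic Gaussian blur SD in µm standing in for the
        point-spread function.
    background: constant background level on the normalized scale.
    """

    photon_scale: float = 200.0
    read_sigma: float = 0.02
    psf_sigma_zyx: tuple[float, float, float] = (0.6, 0.2, 0.2)
    background: float = 0.03

    def __post_init__(self) -> None:
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be > 0")
        if self.read_sigma < 0 or self.background < 0 or any(s < 0 for s in self.psf_sigma_zyx):
            raise ValueError("noise parameters must be nonnegative")

    @property
    def snr(self) -> float:
        """Peak signal over noise SD at peak (signal 1 + background)."""
        peak = 1.0 + self.background
        var = peak / self.photon_scale + self.read_sigma**2
        return peak / math.sqrt(var) if var > 0 else math.inf


@dataclass(frozen=True)
class ConditionPreset:
    """Per-condition division-axis deviation distribution (degrees).

    ``deviation_mean``/``deviation_sd`` parametrize the normal distribution
    (truncated to [0, 180]) of the angle between successive division axes.
    ``contact_mean``/``contact_sd`` optionally carry the NB/glia surface
    contact percentage for conditions where that was measured.
    """

    name: str
    deviation_mean: float
    deviation_sd: float
    contact_mean: float | None = None
    contact_sd: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.deviation_mean <= 180.0):
            raise ValueError("deviation_mean must be in [0, 180] degrees")
        if self.deviation_sd < 0:
            raise ValueError("deviation_sd must be >= 0")


#: Published per-condition summaries (mean ± SD, degrees unless noted).
CONDITION_PRESETS: dict[str, ConditionPreset] = {
    p.name: p
    for p in [
        ConditionPreset("control", 24.0, 15.0),                 # alpha, unperturbed
        ConditionPreset("control_beta", 14.0, 7.0),             # beta, unperturbed
        ConditionPreset("no_ablation", 24.0, 15.0),
        ConditionPreset("control_ablation", 23.0, 16.0),
        ConditionPreset("gmc_ablation", 36.0, 20.0),
        ConditionPreset("post_ablation", 59.0, 14.0),           # division after ablation
        ConditionPreset("recovery", 25.0, 11.0),                # third division, recovered
        ConditionPreset("sas4", 33.0, 26.0),
        ConditionPreset("sas4_gmc_ablation", 49.0, 28.0),
        ConditionPreset("sep1_rnai", 32.0, 27.0),
        ConditionPreset("contact_control", 24.0, 15.0, contact_mean=79.0, contact_sd=5.0),
        ConditionPreset("contact_cindr", 24.0, 15.0, contact_mean=71.0, contact_sd=9.0),
    ]
}


@dataclass(frozen=True)
class CycleTruth:
    """Ground truth for one division cycle."""

    true_axis: Axis3D                 # apical pole -> basal pole, µm
    gmc_centre: Point3D               # daughter centre (basal lobe centre)
    gmc_radius: float
    interphase_frame: int
    rounding_frame: int
    telophase_frame: int
    apical_centrosome: Point3D
    basal_centrosome: Point3D
    deviation_drawn: float | None     # θ drawn vs previous axis, degrees; None for cycle 0
    settled_dir: tuple[float, float, float] | None = None
    """Unit direction (z,y,x) toward the daughter once settled beside the
    NB (includes any post-birth movement); None before settling is known."""


@dataclass(frozen=True)
class SceneTruth:
    """Complete ground-truth description of a synthetic scene."""

    nb_centre: Point3D
    nb_radius: float
    cycles: tuple[CycleTruth, ...]
    glia_coverage_fraction: float
    glia_cap_axis: tuple[float, float, float]  # unit (z,y,x): centre of the UNcovered cap
    spacing: VoxelSpacing
    noise: NoiseModel
    seed: int
    preset_name: str = ""
    interphase_elongation: float = 2.8

    def __post_init__(self) -> None:
        if not (0.0 <= self.glia_coverage_fraction <= 1.0):
            raise ValueError("glia_coverage_fraction must be in [0, 1]")
        if not self.cycles:
            raise ValueError("a scene needs at least one division cycle")
        for c in self.cycles:
            if c.gmc_radius >= self.nb_radius:
                raise ValueError("asymmetric division requires gmc_radius < nb_radius")

    @property
    def n_frames(self) -> int:
        return max(c.telophase_frame for c in self.cycles) + 1

    def true_deviations(self) -> np.ndarray:
        """axis_angle between consecutive true axes, degrees."""
        return np.array(
            [
                axis_angle(self.cycles[i].true_axis, self.cycles[i + 1].true_axis)
                for i in range(len(self.cycles) - 1)
            ]
        )


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _orthonormal_pair(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing u to an orthonormal basis."""
    helper = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(u, helper))
    e2 = np.cross(u, e1)
    return e1, e2


def _rotate_by_angle(u: np.ndarray, theta_deg: float, phi: float) -> np.ndarray:
    """Rotate unit vector u by theta about a uniformly chosen azimuth phi."""
    e1, e2 = _orthonormal_pair(u)
    t = math.radians(theta_deg)
    return math.cos(t) * u + math.sin(t) * (math.cos(phi) * e1 + math.sin(phi) * e2)


def _draw_deviation(rng: np.random.Generator, mean: float, sd: float) -> float:
    """One draw from normal(mean, sd) truncated to [0, 180] degrees."""
    if sd == 0.0:
        return mean
    a = (0.0 - mean) / sd
    b = (180.0 - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def truncated_normal_moments(mean: float, sd: float) -> tuple[float, float]:
    """Analytic mean and SD of normal(mean, sd) truncated to [0, 180] deg."""
    if sd == 0.0:
        return mean, 0.0
    a = (0.0 - mean) / sd
    b = (180.0 - mean) / sd
    return (
        float(stats.truncnorm.mean(a, b, loc=mean, scale=sd)),
        float(stats.truncnorm.std(a, b, loc=mean, scale=sd)),
    )


def sample_division_series(
    preset: ConditionPreset | str,
    n_cycles: int,
    seed: int,
    *,
    nb_radius: float = DEFAULT_NB_RADIUS,
    volume_ratio: float = DEFAULT_VOLUME_RATIO,
    spacing: VoxelSpacing = DEFAULT_SPACING,
    noise: NoiseModel = NoiseModel(),
    glia_coverage_fraction: float = 0.79,
    centre_on: str = "previous_axis",
    gmc_displacement: float = 0.0,
) -> SceneTruth:
    """Draw the ground truth for a multi-cycle division series.

    Parameters
    ----------
    preset
        A :class:`ConditionPreset` or the name of one in
        :data:`CONDITION_PRESETS`; sets the deviation-angle distribution.
    n_cycles
        Number of divisions (>= 2, so at least one deviation exists).
    seed
        Seed for all randomness; fixed seed => bit-identical truth.
    centre_on
        ``"previous_axis"`` draws each new axis around the previous one
        (the process whose deviation is the measured angle alpha);
        ``"gmc"`` draws it around the current direction toward the
        last-born GMC, producing beta < alpha when the GMC has moved.
    gmc_displacement
        SD (µm) of a random tangential displacement applied to each GMC
        after its birth, emulating daughter-cell movement between
        divisions.  0 disables movement.
    """
    if isinstance(preset, str):
        preset = CONDITION_PRESETS[preset]
    if n_cycles < 2:
        raise ValueError("n_cycles must be >= 2 (need consecutive divisions)")
    if centre_on not in ("previous_axis", "gmc"):
        raise ValueError("centre_on must be 'previous_axis' or 'gmc'")

    rng = np.random.default_rng(seed)
    gmc_radius = nb_radius / volume_ratio ** (1.0 / 3.0)
    # telophase lobe-centre separation: 0.8 x the sum of radii overlaps the
    # spheres enough to leave an open cytoplasmic channel (~2.4 µm radius
    # neck for the default sizes) while keeping an unambiguous dumbbell
    lobe_sep = 0.8 * (nb_radius + gmc_radius)

    centre = np.zeros(3)
    # first axis direction: uniform on the sphere
    u = _unit(rng.normal(size=3))
    cycles: list[CycleTruth] = []
    gmc_dir = u.copy()  # direction toward last-born GMC
    for c in range(n_cycles):
        theta: float | None = None
        if c > 0:
            base = gmc_dir if centre_on == "gmc" else _unit(
                cycles[-1].true_axis.vector
            )
            theta = _draw_deviation(rng, preset.deviation_mean, preset.deviation_sd)
            phi = rng.uniform(0.0, 2.0 * math.pi)
            u = _rotate_by_angle(base, theta, phi)

        apical_pole = centre - nb_radius * u
        gmc_centre = centre + lobe_sep * u
        basal_pole = gmc_centre + gmc_radius * u
        cycles.append(
            CycleTruth(
                true_axis=Axis3D(Point3D.from_array(apical_pole), Point3D.from_array(basal_pole)),
                gmc_centre=Point3D.from_array(gmc_centre),
                gmc_radius=gmc_radius,
                interphase_frame=3 * c,
                rounding_frame=3 * c + 1,
                telophase_frame=3 * c + 2,
                apical_centrosome=Point3D.from_array(centre - 0.6 * nb_radius * u),
                basal_centrosome=Point3D.from_array(centre + 0.6 * nb_radius * u),
                deviation_drawn=theta,
            )
        )
        # optional daughter movement before the next division
        gmc_pos = gmc_centre.copy()
        if gmc_displacement > 0.0:
            e1, e2 = _orthonormal_pair(u)
            shift = rng.normal(0.0, gmc_displacement, size=2)
            gmc_pos = gmc_pos + shift[0] * e1 + shift[1] * e2
        gmc_dir = _unit(gmc_pos - centre)
        cycles[-1] = dataclasses.replace(cycles[-1], settled_dir=tuple(float(v) for v in gmc_dir))

    cap = _unit(rng.normal(size=3))  # orientation of the uncovered glia cap
    return SceneTruth(
        nb_centre=Point3D.from_array(centre),
        nb_radius=nb_radius,
        cycles=tuple(cycles),
        glia_coverage_fraction=glia_coverage_fraction,
        glia_cap_axis=tuple(float(v) for v in cap),
        spacing=spacing,
        noise=noise,
        seed=int(seed),
        preset_name=preset.name,
        interphase_elongation=2.8,
    )


# ---------------------------------------------------------------------------
# rendering

_MEMBRANE_SIGMA = 0.3  # µm, membrane shell Gaussian half-width before PSF
# (thick enough that the shell survives the anisotropic PSF where its
# normal points along z; a thinner shell breaks up at the z-facing poles)


def _physical_grids(shape: tuple[int, int, int], spacing: VoxelSpacing, origin: np.ndarray):
    """Open µm coordinate grids (z, y, x) for a raster of given shape."""
    zs = origin[0] + np.arange(shape[0]) * spacing.dz
    ys = origin[1] + np.arange(shape[1]) * spacing.dy
    xs = origin[2] + np.arange(shape[2]) * spacing.dx
    return np.meshgrid(zs, ys, xs, indexing="ij", sparse=True)


def _shell_union(coords, bodies: list[tuple[np.ndarray, float | np.ndarray]]) -> np.ndarray:
    """Membrane shell of a union of (possibly anisotropically scaled) spheres.

    Each body is (centre, radius) or (centre, (rz, ry, rx)).  The shell sits
    on the union's outer surface: intensity exp(-f²/2σ²) of the union signed
    distance f = min_i(|p − c_i| − r_i).
    """
    Z, Y, X = coords
    f = None
    for centre, radius in bodies:
        if np.ndim(radius) == 0:
            d = np.sqrt((Z - centre[0]) ** 2 + (Y - centre[1]) ** 2 + (X - centre[2]) ** 2) - radius
        else:
            rz, ry, rx = radius
            # ellipsoid: approximate signed distance via normalized radius
            q = np.sqrt(
                ((Z - centre[0]) / rz) ** 2 + ((Y - centre[1]) / ry) ** 2 + ((X - centre[2]) / rx) ** 2
            )
            d = (q - 1.0) * min(rz, ry, rx)
        f = d if f is None else np.minimum(f, d)
    return np.exp(-(f**2) / (2.0 * _MEMBRANE_SIGMA**2))


def _scene_bodies(truth: SceneTruth, frame: int) -> tuple[list, list]:
    """(cells, centrosome points) for one frame.

    ``cells`` is a list of cells, each a list of (centre, radius) spheres:
    spheres within one cell merge into a single membrane shell (the
    telophase dumbbell is one cell), while distinct cells each get their
    own membrane, so touching neighbours stay separated.
    """
    centre = truth.nb_centre.as_array()
    r = truth.nb_radius
    cyc = None
    for c in truth.cycles:
        if c.interphase_frame <= frame <= c.telophase_frame:
            cyc = c
            break
    if cyc is None:
        raise ValueError(f"frame {frame} outside scene timeline (0..{truth.n_frames - 1})")

    idx = truth.cycles.index(cyc)
    u = _unit(cyc.true_axis.vector)
    nb_cell: list = []
    spots: list = []
    if frame == cyc.interphase_frame:
        # interphase: elongated capsule-like blob (union of two offset
        # spheres along the upcoming axis), volume roughly preserved
        k = truth.interphase_elongation
        s = k ** (-1.0 / 3.0)
        off = (k - 1.0) * 0.5 * r * s
        nb_cell.append((centre - off * u, r * s))
        nb_cell.append((centre + off * u, r * s))
    elif frame == cyc.rounding_frame:
        nb_cell.append((centre, r))
        spots.append(cyc.apical_centrosome.as_array())
        spots.append(cyc.basal_centrosome.as_array())
    else:  # telophase dumbbell: still one cell
        nb_cell.append((centre, r))
        nb_cell.append((cyc.gmc_centre.as_array(), cyc.gmc_radius))
    cells = [nb_cell]
    # The last-born daughter persists as its own cell, settled tangent to
    # the NB along its birth direction, until the next telophase (where it
    # is omitted so the nascent daughter's lobe stays unobstructed).
    if idx > 0 and frame < cyc.telophase_frame:
        prev = truth.cycles[idx - 1]
        if prev.settled_dir is not None:
            u_prev = np.asarray(prev.settled_dir)
        else:
            u_prev = _unit(prev.gmc_centre.as_array() - centre)
        pos = centre + (r + prev.gmc_radius + 0.05) * u_prev
        cells.append([(pos, prev.gmc_radius)])
    return cells, spots


def required_extent(truth: SceneTruth, margin: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """(origin, size) in µm of the bounding box the scene needs."""
    pts = [truth.nb_centre.as_array()]
    r = truth.nb_radius
    for c in truth.cycles:
        pts.append(c.gmc_centre.as_array() + c.gmc_radius)
        pts.append(c.gmc_centre.as_array() - c.gmc_radius)
        pts.append(c.true_axis.a.as_array())
        pts.append(c.true_axis.b.as_array())
    pts = np.array(pts)
    lo = pts.min(axis=0) - r - margin
    hi = pts.max(axis=0) + r + margin
    return lo, hi - lo


def render_frame(
    truth: SceneTruth,
    frame: int,
    *,
    channels: tuple[str, ...] = ("membrane", "centrosome", "glia"),
    fov_um: tuple[float, float, float] | None = None,
    noiseless: bool = False,
    tight: bool = False,
    rng: np.random.Generator | None = None,
) -> dict[str, VoxelGrid]:
    """Render one frame of the scene; see :func:`render_stack`.

    ``tight=True`` crops the raster to this frame's cell bodies (plus a
    margin) instead of the whole-scene extent; the grid's ``origin_um``
    keeps coordinates consistent with the scene.
    """
    sp = truth.spacing
    cells, spots = _scene_bodies(truth, frame)
    if tight:
        pts = []
        for cell in cells:
            for c, radius in cell:
                rmax = float(np.max(radius))
                pts.append(np.asarray(c) - rmax)
                pts.append(np.asarray(c) + rmax)
        for p in spots:
            pts.append(np.asarray(p))
        pts = np.array(pts)
        margin = 1.5
        origin = pts.min(axis=0) - margin
        size = pts.max(axis=0) + margin - origin
    else:
        origin, size = required_extent(truth)
    if fov_um is not None:
        if any(fv < sz for fv, sz in zip(fov_um, size)):
            raise ValueError(
                f"field of view {tuple(fov_um)} µm too small; scene requires "
                f"{tuple(round(float(s), 2) for s in size)} µm"
            )
        bbox_centre = origin + size / 2.0
        size = np.asarray(fov_um, dtype=float)
        origin = bbox_centre - size / 2.0
    shape = tuple(int(np.ceil(s / d)) + 1 for s, d in zip(size, sp.as_array()))
    coords = _physical_grids(shape, sp, origin)

    out: dict[str, VoxelGrid] = {}
    noise = truth.noise
    if rng is None:
        rng = np.random.default_rng([truth.seed & 0x7FFFFFFF, frame])

    for name in channels:
        if name == "membrane":
            img = np.maximum.reduce([_shell_union(coords, cell) for cell in cells])
        elif name == "centrosome":
            Z, Y, X = coords
            img = np.zeros(shape)
            s2 = 2.0 * 0.25**2  # 0.25 µm spot SD
            for p in spots:
                img += np.exp(-((Z - p[0]) ** 2 + (Y - p[1]) ** 2 + (X - p[2]) ** 2) / s2)
        elif name == "glia":
            img = _render_glia(coords, truth)
        else:
            raise ValueError(f"unknown channel {name!r}")

        if not noiseless:
            sig_vox = tuple(s / d for s, d in zip(noise.psf_sigma_zyx, sp.as_array()))
            img = ndimage.gaussian_filter(img, sig_vox, mode="reflect")
            img = img + noise.background
            img = rng.poisson(np.maximum(img, 0.0) * noise.photon_scale) / noise.photon_scale
            if noise.read_sigma > 0:
                img = img + rng.normal(0.0, noise.read_sigma, size=img.shape)
        out[name] = VoxelGrid(
            img.astype(np.float32), sp, channel=name, origin_um=tuple(float(o) for o in origin)
        )
    return out


def _render_glia(coords, truth: SceneTruth) -> np.ndarray:
    """Glia shell: spherical-cap complement around the NB sphere.

    Coverage fraction f leaves an uncovered polar cap of half-angle
    θ = arccos(2f − 1) about ``glia_cap_axis`` (cap area fraction
    (1 − cos θ)/2 = 1 − f).
    """
    f = truth.glia_coverage_fraction
    if f == 0.0:
        return np.zeros(tuple(len(np.ravel(c)) for c in coords))
    Z, Y, X = coords
    c = truth.nb_centre.as_array()
    gap = 0.4  # µm between NB surface and glia sheet
    r_glia = truth.nb_radius + gap
    dz, dy, dx = Z - c[0], Y - c[1], X - c[2]
    rad = np.sqrt(dz**2 + dy**2 + dx**2)
    shell = np.exp(-((rad - r_glia) ** 2) / (2.0 * _MEMBRANE_SIGMA**2))
    if f < 1.0:
        ax = np.asarray(truth.glia_cap_axis)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos_polar = (dz * ax[0] + dy * ax[1] + dx * ax[2]) / np.where(rad > 0, rad, 1.0)
        cos_open = 2.0 * f - 1.0  # polar angles with cosθ > cos_open are uncovered
        shell = np.where(cos_polar > cos_open, 0.0, shell)
    return shell


def render_stack(
    truth: SceneTruth,
    frames: int | list[int] | None = None,
    *,
    channels: tuple[str, ...] = ("membrane", "centrosome", "glia"),
    fov_um: tuple[float, float, float] | None = None,
    noiseless: bool = False,
) -> dict[str, VoxelGrid]:
    """Render the scene into per-channel (t, z, y, x) stacks.

    ``frames`` may be a count (render frames 0..n-1), an explicit frame
    list, or None for the scene's full timeline.  PSF blur, Poisson photon
    noise and Gaussian read noise are applied unless ``noiseless``.  The
    noise stream is seeded from ``truth.seed`` and the frame index, so a
    fixed truth renders identically every time.
    """
    if frames is None:
        frame_list = list(range(truth.n_frames))
    elif isinstance(frames, int):
        frame_list = list(range(frames))
    else:
        frame_list = list(frames)

    per_frame = [
        render_frame(truth, f, channels=channels, fov_um=fov_um, noiseless=noiseless)
        for f in frame_list
    ]
    return {
        name: VoxelGrid(
            np.stack([pf[name].values for pf in per_frame]), truth.spacing, channel=name
        )
        for name in channels
    }


# ---------------------------------------------------------------------------
# probability-map stand-in

def render_probability_map(
    volume_um3: float,
    shape: tuple[int, int, int],
    spacing: VoxelSpacing,
    seed: int = 0,
) -> VoxelGrid:
    """A [0, 1] probability map whose ≥0.5 super-level set has a known volume.

    Emulates a pixel-classifier output for a roughly ball-shaped signal
    region: exactly ``round(volume_um3 / voxel_volume)`` voxels receive
    probability ≥ 0.5 (ranked by distance from a seeded centre, ties broken
    deterministically), all others strictly < 0.5 and decaying outward.
    """
    if volume_um3 < 0:
        raise ValueError("volume must be nonnegative")
    voxvol = spacing.voxel_volume
    n_total = int(np.prod(shape))
    target_n = int(round(volume_um3 / voxvol))
    if target_n > n_total:
        raise ValueError(
            f"requested volume {volume_um3} µm³ ({target_n} voxels) exceeds the "
            f"field of view ({n_total} voxels, {n_total * voxvol:.1f} µm³)"
        )
    rng = np.random.default_rng(seed)
    centre_vox = np.array(shape) / 2.0 + rng.uniform(-0.5, 0.5, size=3)
    zs = (np.arange(shape[0]) - centre_vox[0]) * spacing.dz
    ys = (np.arange(shape[1]) - centre_vox[1]) * spacing.dy
    xs = (np.arange(shape[2]) - centre_vox[2]) * spacing.dx
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij", sparse=True)
    d2 = (Z**2 + Y**2 + X**2).ravel()
    order = np.argsort(d2, kind="stable")  # stable sort: deterministic tie-break
    ranks = np.empty(n_total, dtype=np.int64)
    ranks[order] = np.arange(n_total)

    p = np.empty(n_total)
    if target_n > 0:
        inside = ranks < target_n
        p[inside] = 1.0 - 0.5 * ranks[inside] / target_n  # in (0.5, 1.0]
    else:
        inside = np.zeros(n_total, dtype=bool)
    n_out = n_total - target_n
    if n_out > 0:
        j = ranks[~inside] - target_n
        p[~inside] = 0.5 * (n_out - j) / (n_out + 1.0)  # strictly < 0.5
    return VoxelGrid(p.reshape(shape), spacing, channel="probability")


# ---------------------------------------------------------------------------
# persistence

def _truth_to_jsonable(truth: SceneTruth) -> dict:
    def pt(p: Point3D):
        return [p.z, p.y, p.x]

    d = dataclasses.asdict(truth)
    d["nb_centre"] = pt(truth.nb_centre)
    d["spacing"] = list(truth.spacing.as_array())
    d["cycles"] = [
        {
            "true_axis": {"a": pt(c.true_axis.a), "b": pt(c.true_axis.b)},
            "gmc_centre": pt(c.gmc_centre),
            "gmc_radius": c.gmc_radius,
            "interphase_frame": c.interphase_frame,
            "rounding_frame": c.rounding_frame,
            "telophase_frame": c.telophase_frame,
            "apical_centrosome": pt(c.apical_centrosome),
            "basal_centrosome": pt(c.basal_centrosome),
            "deviation_drawn": c.deviation_drawn,
            "settled_dir": list(c.settled_dir) if c.settled_dir is not None else None,
        }
        for c in truth.cycles
    ]
    return d


def save_scene(out_dir: str | Path, truth: SceneTruth, stacks: dict[str, VoxelGrid]) -> None:
    """Write rendered channels as OME-TIFF plus a JSON ground-truth sidecar."""
    from .stack_io import write_stack

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, grid in stacks.items():
        write_stack(out / f"{name}.ome.tif", grid)
    (out / "truth.json").write_text(json.dumps(_truth_to_jsonable(truth), indent=1))


def load_scene_truth(path: str | Path) -> SceneTruth:
    """Read a ground-truth sidecar written by :func:`save_scene`."""
    d = json.loads(Path(path).read_text())

    def pt(v):
        return Point3D(*v)

    cycles = tuple(
        CycleTruth(
            true_axis=Axis3D(pt(c["true_axis"]["a"]), pt(c["true_axis"]["b"])),
            gmc_centre=pt(c["gmc_centre"]),
            gmc_radius=c["gmc_radius"],
            interphase_frame=c["interphase_frame"],
            rounding_frame=c["rounding_frame"],
            telophase_frame=c["telophase_frame"],
            apical_centrosome=pt(c["apical_centrosome"]),
            basal_centrosome=pt(c["basal_centrosome"]),
            deviation_drawn=c["deviation_drawn"],
            settled_dir=tuple(c["settled_dir"]) if c.get("settled_dir") else None,
        )
        for c in d["cycles"]
    )
    return SceneTruth(
        nb_centre=pt(d["nb_centre"]),
        nb_radius=d["nb_radius"],
        cycles=cycles,
        glia_coverage_fraction=d["glia_coverage_fraction"],
        glia_cap_axis=tuple(d["glia_cap_axis"]),
        spacing=VoxelSpacing(*d["spacing"]),
        noise=NoiseModel(**{**d["noise"], "psf_sigma_zyx": tuple(d["noise"]["psf_sigma_zyx"])}),
        seed=d["seed"],
        preset_name=d.get("preset_name", ""),
        interphase_elongation=d.get("interphase_elongation", 2.8),
    )
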