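"""Division-axis measurement from segmented 3D stacks.

The shape-based procedure reconstructs a division axis from the dumbbell
outline of a cell in telophase, in three steps:

1. find the cell's in-plane long axis on the xy maximum projection (2D PCA
   by default, or a user-supplied landmark line);
2. resample the stack on the orthogonal plane spanned by that line and the
   z axis, and locate the two pole extremities of the dumbbell in this
   slice, giving each pole's z coordinate at sub-voxel resolution;
3. on the corresponding z slices, recover each pole's (y, x) position.

The apical pole is assigned to the larger of the two lobes (the stem cell
retains most of the volume in an asymmetric division); lobes are split at
the neck, the minimal cross-section perpendicular to the pole-to-pole
axis.  A mask without a neck is rejected as "not telophase"; near-equal
lobe volumes raise a ``lobe-ambiguity`` QC flag.

When a centrosome marker is available the axis is instead the segment
between the apical and basal spindle-pole spots at metaphase
(:func:`axis_from_centrosomes`, with :func:`detect_centrosomes` for spot
finding).

All coordinates are physical micrometres; anisotropic voxel spacing is
honoured throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .geometry import Axis3D, Point3D, axis_angle
from .morphometry import sphericity
from .stack_io import VoxelGrid, gaussian_blur_3d

__all__ = [
    "DivisionRecord",
    "AngleMeasurement",
    "ShapeAxisResult",
    "segment_cell",
    "find_poles_from_shape",
    "axis_from_centrosomes",
    "detect_centrosomes",
    "detect_rounding_onset",
    "gmc_axis",
    "measure_alpha_beta",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DivisionRecord:
    """One measured mitosis of one tracked cell."""

    nb_id: str
    cycle: int
    axis: Axis3D
    method: str                      # "shape" | "centrosome" | "landmarks"
    telophase_frame: int = -1
    rounding_frame: int = -1
    qc: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.method not in ("shape", "centrosome", "landmarks"):
            raise ValueError(f"unknown extraction method {self.method!r}")


@dataclass(frozen=True)
class AngleMeasurement:
    """One α (consecutive-axis) or β (axis-to-daughter) angle, degrees."""

    kind: str        # "alpha" | "beta"
    value: float     # degrees, [0, 180]
    nb_id: str
    cycle: int       # the later cycle of the pair (alpha) or the cycle (beta)

    def __post_init__(self) -> None:
        if self.kind not in ("alpha", "beta"):
            raise ValueError(f"kind must be alpha or beta, got {self.kind!r}")
        if not (0.0 <= self.value <= 180.0):
            raise ValueError(f"angle {self.value} outside [0, 180]")


@dataclass(frozen=True)
class ShapeAxisResult:
    """Axis recovered from a telophase mask, with QC flags."""

    axis: Axis3D
    qc: tuple[str, ...] = ()
    neck_position: float = float("nan")   # µm along the axis from the apical pole


# ---------------------------------------------------------------------------
# segmentation

def segment_cell(
    grid: VoxelGrid,
    seed_voxel: tuple[int, int, int] | None = None,
    threshold: float | None = None,
    blur_sigma: tuple[float, float, float] = (0.8, 0.8, 0.8),
) -> VoxelGrid:
    """Segment one cell from a membrane-marker stack.

    The blurred stack is thresholded (Otsu by default) to a membrane shell,
    the shell is morphologically closed, and the enclosed interior
    containing ``seed_voxel`` (or the largest enclosed interior) is taken.
    Membrane voxels are then split at their midline between this interior
    and everything else, so the mask boundary follows the membrane centre:
    touching neighbour cells keep their own half of the shared membrane.
    """
    if grid.values.ndim != 3:
        raise ValueError("segment_cell expects a single 3D frame")
    if grid.display_only:
        raise ValueError("refusing to quantify a display-only (gamma-adjusted) grid")
    blurred = gaussian_blur_3d(grid, blur_sigma).values
    if blurred.max() == blurred.min():
        raise ValueError("blank image: no membrane signal to segment")
    th = threshold_otsu(blurred) if threshold is None else threshold
    membrane = blurred > th
    if not membrane.any():
        raise ValueError("empty membrane mask at the chosen threshold")

    closed = ndimage.binary_closing(membrane, structure=np.ones((3, 3, 3)), border_value=0)
    open_space, n_lab = ndimage.label(~closed)
    if n_lab == 0:
        raise ValueError("membrane fills the stack; nothing to segment")

    border = np.zeros_like(closed)
    border[[0, -1], :, :] = True
    border[:, [0, -1], :] = True
    border[:, :, [0, -1]] = True
    border_labels = set(np.unique(open_space[border])) - {0}

    if seed_voxel is not None:
        comp = int(open_space[tuple(int(i) for i in seed_voxel)])
        if comp == 0:
            raise ValueError("seed lies inside the membrane, not in a cell interior")
        if comp in border_labels:
            raise ValueError("seed component touches the stack border (background?)")
    else:
        counts = np.bincount(open_space.ravel())
        counts[0] = 0
        for bl in border_labels:
            counts[bl] = 0
        if counts.max() == 0:
            raise ValueError("no enclosed cell interior found")
        comp = int(np.argmax(counts))

    interior = open_space == comp
    other_space = (open_space != comp) & (open_space > 0)
    sp = grid.spacing.as_array()
    d_in = ndimage.distance_transform_edt(~interior, sampling=sp)
    d_out = ndimage.distance_transform_edt(~other_space, sampling=sp)
    mask = interior | (closed & (d_in <= d_out))
    # keep the single component containing the interior
    lbl, _ = ndimage.label(mask)
    mask = lbl == lbl[interior].flat[0]
    return VoxelGrid(mask, grid.spacing, channel="mask", origin_um=grid.origin_um)


# ---------------------------------------------------------------------------
# shape-based pole finding

def _foreground_phys(mask: VoxelGrid) -> np.ndarray:
    idx = np.argwhere(mask.values > 0.5)
    return mask.physical_coords(idx)


def _pca_direction_2d(points_yx: np.ndarray) -> np.ndarray:
    """First principal axis (unit, (y, x)) of a 2D point cloud."""
    c = points_yx - points_yx.mean(axis=0)
    cov = c.T @ c
    w, v = np.linalg.eigh(cov)
    return v[:, np.argmax(w)]


def _slice_poles(
    m: np.ndarray, sp: np.ndarray, u2: np.ndarray, centre_yx: np.ndarray
) -> list[np.ndarray]:
    """Steps 2–3 of the pole-finding procedure for one slicing line.

    Resamples the mask on the plane spanned by the in-plane unit vector
    ``u2`` (through ``centre_yx``) and the z axis, locates the two pole
    extremities along the in-slice long axis (sub-voxel z), then recovers
    each pole's (y, x) on its z slice.  Returns two local (z, y, x) µm
    positions.
    """
    pts_yx = np.argwhere(m.max(axis=0)) * sp[1:]
    s_all = (pts_yx - centre_yx) @ u2
    s_lo, s_hi = s_all.min() - 1.0, s_all.max() + 1.0
    ds = min(sp[1], sp[2]) / 2.0
    s_grid = np.arange(s_lo, s_hi + ds, ds)
    nz = m.shape[0]
    dz_fine = sp[0] / 4.0
    z_grid = np.arange(0.0, (nz - 1) * sp[0] + dz_fine / 2, dz_fine)
    S, Zg = np.meshgrid(s_grid, z_grid, indexing="xy")
    y_phys = centre_yx[0] + S * u2[0]
    x_phys = centre_yx[1] + S * u2[1]
    coords = np.stack([Zg / sp[0], y_phys / sp[1], x_phys / sp[2]])
    slice_fg = ndimage.map_coordinates(m.astype(float), coords, order=1, mode="constant") >= 0.5
    if not slice_fg.any():
        raise ValueError("orthogonal slice misses the mask")

    fg_idx = np.argwhere(slice_fg)                       # (k, 2): (z_fine, s)
    fg_zs = np.stack([z_grid[fg_idx[:, 0]], s_grid[fg_idx[:, 1]]], axis=1)
    w = _pca_direction_2d(fg_zs)                         # in-slice long axis (z, s)
    t = (fg_zs - fg_zs.mean(axis=0)) @ w
    eps = max(dz_fine, ds)
    lo_set = fg_zs[t <= t.min() + eps]
    hi_set = fg_zs[t >= t.max() - eps]
    pole_zs = [lo_set.mean(axis=0), hi_set.mean(axis=0)]  # (z, s) per pole

    poles: list[np.ndarray] = []
    w_s = abs(w[1])  # s-component of the in-slice axis; small => axis near z
    for z_pole, s_pole in pole_zs:
        zi = int(round(z_pole / sp[0]))
        zi = min(max(zi, 0), nz - 1)
        sl = m[zi]
        if not sl.any():
            # pole slice empty after rounding: fall back to slice-plane coords
            poles.append(np.array([z_pole, *(centre_yx + s_pole * u2)]))
            continue
        est_yx = centre_yx + s_pole * u2
        lbl, _ = ndimage.label(sl)
        yx = np.argwhere(sl) * sp[1:]
        comp_of = lbl[tuple((np.argwhere(sl)).T)]
        nearest = int(np.argmin(np.linalg.norm(yx - est_yx, axis=1)))
        sel = comp_of == comp_of[nearest]
        yx_c = yx[sel]
        if w_s < 0.4:
            # axis nearly along z: in-plane extremes are meaningless, but
            # the step-2 slice position already carries the pole's lateral
            # coordinate along the slicing line (the off-plane component
            # is ~0 when the slice plane contains the axis)
            pole_yx = est_yx
        else:
            tt = (yx_c - centre_yx) @ u2
            sign = 1.0 if s_pole >= 0 else -1.0
            ext = tt * sign
            keep = ext >= ext.max() - min(sp[1], sp[2]) / 2.0
            pole_yx = yx_c[keep].mean(axis=0)
        poles.append(np.array([z_pole, pole_yx[0], pole_yx[1]]))
    return poles


def find_poles_from_shape(
    mask: VoxelGrid,
    bisect_line: tuple[tuple[float, float], tuple[float, float]] | None = None,
    neck_ratio: float = 0.9,
    lobe_ambiguity_tol: float = 0.10,
) -> ShapeAxisResult:
    """Recover the apical→basal axis of a telophase (dumbbell) mask.

    ``bisect_line`` optionally supplies the in-plane long axis as two
    physical (y, x) points — the hand-drawn bisecting line of an
    interactive workflow — replacing the default 2D PCA of the xy maximum
    projection.

    Raises ``ValueError("not telophase")`` when the cross-section profile
    along the recovered axis has no neck: the minimal interior
    cross-section must be below ``neck_ratio`` of both flanking maxima.
    """
    vals = mask.values
    if vals.ndim != 3:
        raise ValueError("expected a single 3D mask")
    m = vals > 0.5
    if not m.any():
        raise ValueError("empty mask")
    sp = mask.spacing.as_array()
    origin = np.asarray(mask.origin_um)

    # --- step 1: in-plane long axis on the xy max projection
    proj = m.max(axis=0)
    pts_yx = np.argwhere(proj) * sp[1:]
    if bisect_line is not None:
        p1, p2 = (np.asarray(p, dtype=float) for p in bisect_line)
        u2 = p2 - p1 - 0.0
        n = np.linalg.norm(u2)
        if n == 0:
            raise ValueError("degenerate bisecting line")
        u2 = u2 / n
        centre_yx = (p1 + p2) / 2.0 - origin[1:]
    else:
        u2 = _pca_direction_2d(pts_yx)
        centre_yx = pts_yx.mean(axis=0)

    poles = _slice_poles(m, sp, u2, centre_yx)
    p1, p2 = (p + origin for p in poles)

    # Refine the direction by iterating the axis through the two lobe
    # centroids: for a two-lobed body the lobe centroids lie on the axis
    # of rotational symmetry, so this removes the residual bias of
    # extremity picking on an anisotropic (coarse-z) grid.  The slice
    # procedure above remains the initializer and the source of the
    # telophase/neck decision geometry.
    fg3 = _foreground_phys(mask)
    n3 = _refine_direction_by_lobes(fg3, p2 - p1)
    c_all = fg3.mean(axis=0)
    t = (fg3 - c_all) @ n3
    eps = float(sp.max())
    p1 = _slab_pole(fg3, c_all, n3, t, t.min(), eps, low=True)
    p2 = _slab_pole(fg3, c_all, n3, t, t.max(), eps, low=False)

    # --- lobe split at the neck, apical = larger lobe
    v = p2 - p1
    length = np.linalg.norm(v)
    if length == 0:
        raise ValueError("degenerate poles")
    u3 = v / length
    tproj = (fg3 - p1) @ u3
    neck = _neck_split(tproj, length, neck_ratio)
    if neck is None:
        raise ValueError("not telophase: no neck in the cross-section profile")
    neck_t = neck

    vol1 = int((tproj < neck_t).sum())   # lobe at p1
    vol2 = int((tproj >= neck_t).sum())  # lobe at p2
    qc: list[str] = []
    if max(vol1, vol2) > 0 and abs(vol1 - vol2) / max(vol1, vol2) < lobe_ambiguity_tol:
        qc.append("lobe-ambiguity")
    if vol1 >= vol2:
        apical, basal = p1, p2
        neck_from_apical = neck_t
    else:
        apical, basal = p2, p1
        neck_from_apical = length - neck_t
    return ShapeAxisResult(
        axis=Axis3D(Point3D.from_array(apical), Point3D.from_array(basal)),
        qc=tuple(qc),
        neck_position=float(neck_from_apical),
    )


def _neck_split(tproj: np.ndarray, length: float, neck_ratio: float) -> float | None:
    """Neck position along the axis, or None if the profile has no neck.

    Bins the projected voxel count (∝ cross-section area) along the axis;
    the neck is the interior minimum, accepted only if it falls below
    ``neck_ratio`` of both flanking maxima (a sphere-like profile fails).
    """
    nbins = 40
    edges = np.linspace(0.0, length, nbins + 1)
    counts, _ = np.histogram(tproj, bins=edges)
    i0, i1 = int(0.15 * nbins), int(0.85 * nbins)
    interior = counts[i0:i1]
    if interior.size == 0:
        return None
    k = int(np.argmin(interior)) + i0
    left_max = counts[: k + 1].max()
    right_max = counts[k:].max()
    if counts[k] >= neck_ratio * min(left_max, right_max):
        return None
    return float(0.5 * (edges[k] + edges[k + 1]))


def _refine_direction_by_lobes(fg3: np.ndarray, v0: np.ndarray, iters: int = 4) -> np.ndarray:
    """Iterate axis direction through the centroids of the two lobes."""
    n = v0 / np.linalg.norm(v0)
    c_all = fg3.mean(axis=0)
    for _ in range(iters):
        t = (fg3 - c_all) @ n
        length = t.max() - t.min()
        neck = _neck_split(t - t.min(), length, neck_ratio=1.0)
        if neck is None:
            break
        split = t.min() + neck
        lo, hi = fg3[t < split], fg3[t >= split]
        if len(lo) == 0 or len(hi) == 0:
            break
        d = hi.mean(axis=0) - lo.mean(axis=0)
        nn = np.linalg.norm(d)
        if nn == 0:
            break
        d = d / nn
        n = d if d @ n >= 0 else -d
    return n


def _slab_pole(
    fg3: np.ndarray,
    c_all: np.ndarray,
    n: np.ndarray,
    t: np.ndarray,
    t_ext: float,
    eps: float,
    low: bool,
) -> np.ndarray:
    """Pole position from the extremal slab along the axis direction.

    The centroid of the voxels within ``eps`` of the extreme projection
    lies on the axis by symmetry; it is then pushed out along the axis to
    the extreme projection value to sit on the surface.
    """
    sel = t <= t_ext + eps if low else t >= t_ext - eps
    c_slab = fg3[sel].mean(axis=0)
    return c_slab + (t_ext - (c_slab - c_all) @ n) * n


# ---------------------------------------------------------------------------
# centrosome-based axis

def axis_from_centrosomes(apical: Point3D, basal: Point3D) -> Axis3D:
    """Division axis from the two spindle-pole centrosomes at metaphase."""
    return Axis3D(apical, basal)  # Axis3D rejects coincident points


def detect_centrosomes(grid: VoxelGrid, n_spots: int = 2, min_separation: float = 1.0) -> list[Point3D]:
    """Locate bright spots in a centrosome channel.

    Greedy peak picking on the lightly blurred volume with a physical
    exclusion radius, refined by an intensity-weighted centroid in a small
    neighbourhood.  Returns ``n_spots`` points in physical µm, brightest
    first; apical/basal assignment is the caller's (it needs polarity
    context the image alone does not carry).
    """
    if grid.values.ndim != 3:
        raise ValueError("expected a single 3D frame")
    sm = gaussian_blur_3d(grid, (0.5, 0.5, 0.5)).values
    sp = grid.spacing.as_array()
    found: list[np.ndarray] = []
    work = sm.copy()
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in sm.shape], indexing="ij", sparse=True)
    for _ in range(n_spots):
        peak = np.unravel_index(np.argmax(work), work.shape)
        # background-subtracted centroid in a (2, 6, 6)-voxel-radius window
        lo = [max(p - r, 0) for p, r in zip(peak, (2, 6, 6))]
        hi = [min(p + r + 1, s) for p, s, r in zip(peak, sm.shape, (2, 6, 6))]
        sub = sm[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].copy()
        edge = np.concatenate([sub[0].ravel(), sub[-1].ravel(), sub[:, 0].ravel(),
                               sub[:, -1].ravel(), sub[:, :, 0].ravel(), sub[:, :, -1].ravel()])
        sub = np.maximum(sub - np.median(edge), 0.0)
        wsum = sub.sum()
        if wsum <= 0:
            raise ValueError("no spot signal above zero")
        idx = np.array(
            [
                (sub * np.arange(lo[d], hi[d]).reshape([-1 if i == d else 1 for i in range(3)])).sum()
                for d in range(3)
            ]
        ) / wsum
        # sub-voxel z from a log-parabola fit of the z profile (the coarse
        # z step makes the plain centroid the dominant error source)
        prof = sub.sum(axis=(1, 2))
        k = int(np.argmax(prof))
        if 0 < k < prof.size - 1 and prof[k - 1] > 0 and prof[k + 1] > 0 and prof[k] > 0:
            la, lb, lc = np.log(prof[k - 1]), np.log(prof[k]), np.log(prof[k + 1])
            denom = la - 2 * lb + lc
            if denom < 0:
                idx[0] = lo[0] + k + 0.5 * (la - lc) / denom
        found.append(idx * sp + np.asarray(grid.origin_um))
        # suppress a physical ball around the peak
        dist2 = (
            ((zz - peak[0]) * sp[0]) ** 2
            + ((yy - peak[1]) * sp[1]) ** 2
            + ((xx - peak[2]) * sp[2]) ** 2
        )
        work[dist2 <= min_separation**2] = -np.inf
    return [Point3D.from_array(p) for p in found]


# ---------------------------------------------------------------------------
# rounding onset and daughter-cell axis

def detect_rounding_onset(
    masks: list[VoxelGrid],
    threshold: float = 0.92,
) -> tuple[int, tuple[str, ...]]:
    """First frame at which the cell has rounded up.

    Rounding is scored by 3D sphericity π^(1/3)(6V)^(2/3)/A; the onset is
    the first frame whose sphericity reaches ``threshold`` after having
    been below it (frame 0 counts if the cell starts round).  If the
    threshold is never reached, the last frame is returned with a
    ``rounding-not-detected`` QC flag.
    """
    if len(masks) < 3:
        raise ValueError("need at least 3 frames to detect rounding onset")
    s = []
    for mk in masks:
        if not (mk.values > 0.5).any():
            raise ValueError("empty mask in rounding series")
        s.append(sphericity(mk))
    if s[0] >= threshold:
        return 0, ()
    for i in range(1, len(s)):
        if s[i] >= threshold:
            return i, ()
    return len(s) - 1, ("rounding-not-detected",)


def _centroid_phys(mask: VoxelGrid) -> np.ndarray:
    return _foreground_phys(mask).mean(axis=0)


def gmc_axis(
    nb_mask: VoxelGrid,
    gmc_mask: VoxelGrid,
    mode: str = "interface",
) -> tuple[Axis3D, tuple[str, ...]]:
    """Unit axis from the cell centre toward its last-born daughter.

    ``mode="interface"`` (default) points the axis through the centroid of
    the contact patch — the cell-side voxels within one voxel of the
    daughter mask, i.e. the shared interface.  ``mode="centroid"`` uses
    the daughter's centroid instead.  With no contact patch the centroid
    fallback is used and flagged ``no-contact-patch``.
    """
    if mode not in ("interface", "centroid"):
        raise ValueError("mode must be 'interface' or 'centroid'")
    nb = nb_mask.values > 0.5
    gm = gmc_mask.values > 0.5
    if not nb.any() or not gm.any():
        raise ValueError("empty mask")
    c_nb = _centroid_phys(nb_mask)

    qc: list[str] = []
    target: np.ndarray
    if mode == "interface":
        # contact patch: cell voxels within a physical reach of the
        # daughter (an anisotropic voxel dilation would skew the patch
        # centroid along z)
        sp = nb_mask.spacing.as_array()
        reach = 1.2 * float(sp.max())
        patch = nb & (ndimage.distance_transform_edt(~gm, sampling=sp) <= reach)
        if patch.any():
            target = nb_mask.physical_coords(np.argwhere(patch)).mean(axis=0)
        else:
            qc.append("no-contact-patch")
            target = _centroid_phys(gmc_mask)
    else:
        target = _centroid_phys(gmc_mask)

    d = target - c_nb
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("degenerate daughter direction")
    b = c_nb + d / n
    return Axis3D(Point3D.from_array(c_nb), Point3D.from_array(b)), tuple(qc)


# ---------------------------------------------------------------------------
# angle bookkeeping

def measure_alpha_beta(
    records: list[DivisionRecord],
    gmc_axes: dict[tuple[str, int], Axis3D] | None = None,
) -> list[AngleMeasurement]:
    """α and β angles from a set of division records.

    α(c) is the angle between the axes of cycles c−1 and c of the same
    cell; β(c) the angle between the daughter-cell axis at the rounding
    onset of cycle c (keyed ``(nb_id, c)`` in ``gmc_axes``) and the axis
    of cycle c.  Pairs that cannot be formed are skipped with a log entry.
    """
    gmc_axes = gmc_axes or {}
    by_cell: dict[str, list[DivisionRecord]] = {}
    for r in records:
        by_cell.setdefault(r.nb_id, []).append(r)

    out: list[AngleMeasurement] = []
    for nb_id, recs in by_cell.items():
        recs = sorted(recs, key=lambda r: r.cycle)
        for prev, cur in zip(recs, recs[1:]):
            if cur.cycle != prev.cycle + 1:
                log.info("skipping non-consecutive cycles %d→%d for %s", prev.cycle, cur.cycle, nb_id)
                continue
            out.append(
                AngleMeasurement("alpha", axis_angle(prev.axis, cur.axis), nb_id, cur.cycle)
            )
        for rec in recs:
            g = gmc_axes.get((nb_id, rec.cycle))
            if g is not None:
                out.append(AngleMeasurement("beta", axis_angle(g, rec.axis), nb_id, rec.cycle))
    return out
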