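"""End-to-end convenience layer: simulate a lineage, measure it, compare.

These functions wire the synthetic generator to the extraction and
statistics modules so that a full parameter-recovery experiment is a few
calls.  They are also the reference usage patterns for the lower-level
API (see examples/).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .axis_extraction import (
    AngleMeasurement,
    DivisionRecord,
    find_poles_from_shape,
    gmc_axis,
    measure_alpha_beta,
    segment_cell,
)
from .geometry import Axis3D
from .stack_io import VoxelGrid
from .synthetic import ConditionPreset, SceneTruth, render_frame, sample_division_series

__all__ = [
    "records_from_truth",
    "extract_division_records",
    "extract_gmc_axes",
    "measure_scene",
    "sample_condition_angles",
    "records_to_dataframe",
    "angles_to_dataframe",
]


def _seed_voxel(truth: SceneTruth, grid: VoxelGrid, point=None) -> tuple[int, int, int]:
    p = (point if point is not None else truth.nb_centre.as_array()) - np.asarray(grid.origin_um)
    idx = np.round(p / grid.spacing.as_array()).astype(int)
    idx = np.clip(idx, 0, np.array(grid.values.shape) - 1)
    return tuple(int(i) for i in idx)


def records_from_truth(truth: SceneTruth, nb_id: str = "nb0") -> list[DivisionRecord]:
    """Division records taken directly from the scene's true axes.

    The stand-in for landmark-annotated measurements: no imaging or
    segmentation error, only the generative angle process.
    """
    return [
        DivisionRecord(
            nb_id=nb_id,
            cycle=i,
            axis=c.true_axis,
            method="landmarks",
            telophase_frame=c.telophase_frame,
            rounding_frame=c.rounding_frame,
        )
        for i, c in enumerate(truth.cycles)
    ]


def extract_division_records(
    truth: SceneTruth,
    nb_id: str = "nb0",
    noiseless: bool = False,
) -> list[DivisionRecord]:
    """Render every telophase frame and measure its axis from cell shape.

    Each frame is rendered tight around the dividing cell (membrane
    channel only), segmented seeded at the known cell centre, and passed
    to the three-step pole finder.  Cycles whose mask fails the telophase
    test are skipped.
    """
    records: list[DivisionRecord] = []
    for i, cyc in enumerate(truth.cycles):
        frame = render_frame(
            truth, cyc.telophase_frame, channels=("membrane",), noiseless=noiseless, tight=True
        )["membrane"]
        mask = segment_cell(frame, seed_voxel=_seed_voxel(truth, frame))
        try:
            res = find_poles_from_shape(mask)
        except ValueError:
            continue
        records.append(
            DivisionRecord(
                nb_id=nb_id,
                cycle=i,
                axis=res.axis,
                method="shape",
                telophase_frame=cyc.telophase_frame,
                rounding_frame=cyc.rounding_frame,
                qc=res.qc,
            )
        )
    return records


def extract_gmc_axes(
    truth: SceneTruth,
    nb_id: str = "nb0",
    noiseless: bool = False,
    mode: str = "interface",
) -> dict[tuple[str, int], Axis3D]:
    """Daughter-direction axes at each cycle's rounding frame.

    For cycle c >= 1 the rounding frame shows the rounded cell beside its
    settled last-born daughter; both are segmented from the membrane
    channel and the axis through the contact interface (or the daughter
    centroid) is returned, keyed (nb_id, c).
    """
    axes: dict[tuple[str, int], Axis3D] = {}
    centre = truth.nb_centre.as_array()
    for i, cyc in enumerate(truth.cycles):
        if i == 0:
            continue
        prev = truth.cycles[i - 1]
        if prev.settled_dir is None:
            continue
        frame = render_frame(
            truth, cyc.rounding_frame, channels=("membrane",), noiseless=noiseless, tight=True
        )["membrane"]
        nb_mask = segment_cell(frame, seed_voxel=_seed_voxel(truth, frame))
        gmc_pos = centre + (truth.nb_radius + prev.gmc_radius + 0.05) * np.asarray(prev.settled_dir)
        try:
            gmc_mask = segment_cell(frame, seed_voxel=_seed_voxel(truth, frame, gmc_pos))
        except ValueError:
            continue
        axis, _qc = gmc_axis(nb_mask, gmc_mask, mode=mode)
        axes[(nb_id, i)] = axis
    return axes


def measure_scene(
    truth: SceneTruth,
    nb_id: str = "nb0",
    noiseless: bool = False,
    with_beta: bool = False,
) -> list[AngleMeasurement]:
    """Full shape-based measurement of one scene: α (and optionally β)."""
    records = extract_division_records(truth, nb_id=nb_id, noiseless=noiseless)
    gmc = extract_gmc_axes(truth, nb_id=nb_id, noiseless=noiseless) if with_beta else None
    return measure_alpha_beta(records, gmc)


def sample_condition_angles(
    preset: ConditionPreset | str,
    n_angles: int,
    seed: int,
    kind: str = "alpha",
    render: bool = False,
    noiseless: bool = False,
    **scene_kwargs,
) -> np.ndarray:
    """Measured deviation angles for one condition.

    Builds a single lineage of ``n_angles + 1`` divisions and measures the
    angle between consecutive axes.  ``render=False`` measures the true
    axes directly (generator + bookkeeping only); ``render=True`` runs the
    full raster pipeline (render, segment, pole-find) on every telophase.
    For β, the generator centres each new axis on the daughter direction
    (``centre_on="gmc"``).
    """
    if kind not in ("alpha", "beta"):
        raise ValueError("kind must be 'alpha' or 'beta'")
    if kind == "beta":
        scene_kwargs.setdefault("centre_on", "gmc")
    truth = sample_division_series(preset, n_angles + 1, seed, **scene_kwargs)
    if render:
        records = extract_division_records(truth, noiseless=noiseless)
        gmc = extract_gmc_axes(truth, noiseless=noiseless) if kind == "beta" else None
    else:
        records = records_from_truth(truth)
        gmc = None
        if kind == "beta":
            gmc = {}
            centre = truth.nb_centre.as_array()
            for i, cyc in enumerate(truth.cycles[:-1]):
                if cyc.settled_dir is not None:
                    gmc[("nb0", i + 1)] = Axis3D.from_arrays(
                        centre, centre + np.asarray(cyc.settled_dir)
                    )
    angles = measure_alpha_beta(records, gmc)
    return np.array([a.value for a in angles if a.kind == kind])


def records_to_dataframe(records: list[DivisionRecord]) -> pd.DataFrame:
    """Divisions table: one row per measured mitosis, coordinates in µm."""
    rows = []
    for r in records:
        a, b = r.axis.a, r.axis.b
        rows.append(
            dict(
                nb_id=r.nb_id,
                cycle=r.cycle,
                frame_telophase=r.telophase_frame,
                frame_rounding=r.rounding_frame,
                method=r.method,
                az=a.z, ay=a.y, ax=a.x,
                bz=b.z, by=b.y, bx=b.x,
                qc=";".join(r.qc),
            )
        )
    return pd.DataFrame(rows)


def angles_to_dataframe(angles: list[AngleMeasurement]) -> pd.DataFrame:
    """Angles table: one row per α/β measurement, degrees."""
    return pd.DataFrame(
        [dict(nb_id=a.nb_id, kind=a.kind, cycle_ref=a.cycle, angle_deg=a.value) for a in angles]
    )
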