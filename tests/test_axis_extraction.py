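"""Axis extraction: segmentation, telophase pole finding, centrosome
spots, rounding detection and angle bookkeeping, validated against the
generator's ground truth."""

import math

import numpy as np
import pytest

from conftest import scene_with_axis, voxelized_ball
from nbaxis.axis_extraction import (
    AngleMeasurement,
    DivisionRecord,
    axis_from_centrosomes,
    detect_centrosomes,
    detect_rounding_onset,
    find_poles_from_shape,
    gmc_axis,
    measure_alpha_beta,
    segment_cell,
)
from nbaxis.geometry import Axis3D, Point3D, VoxelSpacing, axis_angle
from nbaxis.morphometry import mask_volume
from nbaxis.pipeline import _seed_voxel, extract_division_records, extract_gmc_axes
from nbaxis.stack_io import VoxelGrid
from nbaxis.synthetic import render_frame, sample_division_series

ANISO = VoxelSpacing(0.8, 0.26, 0.26)
ISO = VoxelSpacing(0.26, 0.26, 0.26)


def _telophase_mask(truth, noiseless=True):
    fr = render_frame(
        truth, truth.cycles[0].telophase_frame, channels=("membrane",), noiseless=noiseless, tight=True
    )["membrane"]
    return segment_cell(fr, seed_voxel=_seed_voxel(truth, fr))


class TestSegmentCell:
    def test_sphere_volume_within_5_percent(self):
        t = sample_division_series("control", 2, seed=1, spacing=ISO)
        fr = render_frame(
            t, t.cycles[0].rounding_frame, channels=("membrane",), noiseless=True, tight=True
        )["membrane"]
        mask = segment_cell(fr, seed_voxel=_seed_voxel(t, fr))
        analytic = 4.0 / 3.0 * math.pi * 5.0**3
        assert mask_volume(mask) == pytest.approx(analytic, rel=0.05)

    def test_touching_neighbour_excluded(self):
        """Seeded in one of two touching cells, the mask leaves the
        neighbour's interior out."""
        t = sample_division_series("control", 2, seed=6)
        cyc1 = t.cycles[1]
        fr = render_frame(t, cyc1.rounding_frame, channels=("membrane",), noiseless=True, tight=True)[
            "membrane"
        ]
        nb_mask = segment_cell(fr, seed_voxel=_seed_voxel(t, fr))
        # the settled daughter ball in physical coords
        prev = t.cycles[0]
        pos = t.nb_centre.as_array() + (t.nb_radius + prev.gmc_radius + 0.05) * np.asarray(
            prev.settled_dir
        )
        idx = np.argwhere(nb_mask.values)
        phys = nb_mask.physical_coords(idx)
        inside_gmc = np.linalg.norm(phys - pos, axis=1) <= prev.gmc_radius
        gmc_voxels = (4 / 3 * math.pi * prev.gmc_radius**3) / nb_mask.spacing.voxel_volume
        assert inside_gmc.sum() / gmc_voxels < 0.05

    def test_blank_image_rejected(self):
        with pytest.raises(ValueError, match="blank"):
            segment_cell(VoxelGrid(np.zeros((8, 8, 8)), ISO))


class TestFindPolesFromShape:
    def test_axis_along_x_recovered_within_2_degrees(self):
        t = scene_with_axis((0, 0, 1), spacing=ANISO)
        res = find_poles_from_shape(_telophase_mask(t))
        assert axis_angle(res.axis, t.cycles[0].true_axis) < 2.0

    def test_rotated_and_tilted_axis_within_5_degrees(self):
        # 30 deg about z from x, then tilted 20 deg out of plane
        tilt, rot = math.radians(20), math.radians(30)
        u = (math.sin(tilt), math.cos(tilt) * math.sin(rot), math.cos(tilt) * math.cos(rot))
        t = scene_with_axis(u, spacing=ANISO)
        res = find_poles_from_shape(_telophase_mask(t))
        assert axis_angle(res.axis, t.cycles[0].true_axis) < 5.0

    @pytest.mark.parametrize("seed", range(8))
    def test_random_noiseless_axes_within_5_degrees(self, seed):
        t = sample_division_series("control", 2, seed=seed)
        res = find_poles_from_shape(_telophase_mask(t))
        assert axis_angle(res.axis, t.cycles[0].true_axis) < 5.0

    def test_sphere_is_not_telophase(self, iso_spacing):
        ball = voxelized_ball(5.0, iso_spacing)
        with pytest.raises(ValueError, match="not telophase"):
            find_poles_from_shape(ball)

    def test_apical_pole_lies_in_larger_lobe(self):
        """Orientation convention: the returned apical pole is the true
        apical pole (the big lobe's tip), not its mirror."""
        for seed in range(5):
            t = sample_division_series("control", 2, seed=seed)
            res = find_poles_from_shape(_telophase_mask(t))
            true_ap = t.cycles[0].true_axis.a.as_array()
            true_ba = t.cycles[0].true_axis.b.as_array()
            rec_ap = res.axis.a.as_array()
            assert np.linalg.norm(rec_ap - true_ap) < np.linalg.norm(rec_ap - true_ba)

    def test_near_symmetric_division_flagged(self):
        t = scene_with_axis((0, 1, 1), volume_ratio=1.05)
        res = find_poles_from_shape(_telophase_mask(t))
        assert "lobe-ambiguity" in res.qc

    def test_user_bisect_line_accepted(self):
        t = scene_with_axis((0, 0.3, 1), spacing=ANISO)
        mask = _telophase_mask(t)
        # the hand-drawn line: the true axis projected to xy, in absolute µm
        u = t.cycles[0].true_axis.vector
        c = t.nb_centre.as_array()
        line = ((c[1] - 5 * u[1], c[2] - 5 * u[2]), (c[1] + 5 * u[1], c[2] + 5 * u[2]))
        res = find_poles_from_shape(mask, bisect_line=line)
        assert axis_angle(res.axis, t.cycles[0].true_axis) < 5.0

    def test_empty_mask_rejected(self, iso_spacing):
        with pytest.raises(ValueError, match="empty"):
            find_poles_from_shape(VoxelGrid(np.zeros((5, 5, 5)), iso_spacing))


class TestCentrosomeAxis:
    def test_axis_from_points(self):
        ax = axis_from_centrosomes(Point3D(0, 0, 0), Point3D(0, 0, 4))
        assert ax.magnitude == pytest.approx(4.0)
        assert axis_angle(ax, Axis3D.from_arrays((0, 0, 0), (0, 0, 1))) == pytest.approx(0.0)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            axis_from_centrosomes(Point3D(1, 1, 1), Point3D(1, 1, 1))

    def test_detected_spots_give_axis_near_truth(self):
        errs = []
        for seed in range(5):
            t = sample_division_series("control", 2, seed=seed)
            cyc = t.cycles[0]
            fr = render_frame(
                t, cyc.rounding_frame, channels=("centrosome",), noiseless=True, tight=True
            )["centrosome"]
            spots = detect_centrosomes(fr)
            tp = cyc.apical_centrosome.as_array()
            ap, ba = (
                (spots[0], spots[1])
                if np.linalg.norm(spots[0].as_array() - tp) < 2.0
                else (spots[1], spots[0])
            )
            errs.append(axis_angle(axis_from_centrosomes(ap, ba), cyc.true_axis))
        assert np.median(errs) < 2.0
        assert max(errs) < 3.0

    def test_method_agreement_shape_vs_centrosomes(self):
        """On noiseless scenes the two measurement routes agree within 3°."""
        for seed in (1, 4, 9):
            t = sample_division_series("control", 2, seed=seed)
            cyc = t.cycles[0]
            shape_ax = find_poles_from_shape(_telophase_mask(t)).axis
            fr = render_frame(
                t, cyc.rounding_frame, channels=("centrosome",), noiseless=True, tight=True
            )["centrosome"]
            spots = detect_centrosomes(fr)
            tp = cyc.apical_centrosome.as_array()
            ap, ba = (
                (spots[0], spots[1])
                if np.linalg.norm(spots[0].as_array() - tp) < 2.0
                else (spots[1], spots[0])
            )
            cen_ax = axis_from_centrosomes(ap, ba)
            assert axis_angle(shape_ax, cen_ax) < 3.0

    def test_anisotropy_invariance(self):
        """The same scene sampled at (0.8, 0.26, 0.26) and isotropic 0.26
        µm yields shape axes within 3° of each other."""
        u = (0.5, 0.6, 0.63)
        res_a = find_poles_from_shape(_telophase_mask(scene_with_axis(u, spacing=ANISO)))
        res_i = find_poles_from_shape(_telophase_mask(scene_with_axis(u, spacing=ISO)))
        assert axis_angle(res_a.axis, res_i.axis) < 3.0


class TestRoundingOnset:
    def test_round_from_start(self, iso_spacing):
        masks = [voxelized_ball(5.0, iso_spacing) for _ in range(3)]
        frame, qc = detect_rounding_onset(masks)
        assert frame == 0 and qc == ()

    def test_onset_matches_truth_within_one_frame(self):
        t = sample_division_series("control", 2, seed=3)
        cyc = t.cycles[0]
        masks = []
        for f in (cyc.interphase_frame, cyc.rounding_frame, cyc.telophase_frame):
            fr = render_frame(t, f, channels=("membrane",), noiseless=True)["membrane"]
            masks.append(segment_cell(fr, seed_voxel=_seed_voxel(t, fr)))
        frame, qc = detect_rounding_onset(masks)
        assert abs(frame - 1) <= 1  # truth: rounding at series index 1
        assert qc == ()

    def test_never_rounding_flags_last_frame(self, iso_spacing):
        def capsule(elong):
            sp = iso_spacing.as_array()
            half = 12.0
            ax = [np.arange(int(2 * half / d)) * d - half for d in sp]
            zz, yy, xx = np.meshgrid(*ax, indexing="ij", sparse=True)
            a = 4.0
            off = elong * a
            m = (np.sqrt(zz**2 + yy**2 + (xx - off) ** 2) <= a) | (
                np.sqrt(zz**2 + yy**2 + (xx + off) ** 2) <= a
            )
            return VoxelGrid(m, iso_spacing)

        masks = [capsule(e) for e in (0.8, 1.0, 1.2, 1.4)]
        frame, qc = detect_rounding_onset(masks)
        assert frame == 3
        assert "rounding-not-detected" in qc

    def test_too_few_frames_rejected(self, iso_spacing):
        with pytest.raises(ValueError):
            detect_rounding_onset([voxelized_ball(3.0, iso_spacing)] * 2)


class TestGmcAxis:
    def _two_balls(self, iso_spacing, gap=0.0):
        sp = iso_spacing.as_array()
        half = 12.0
        ax = [np.arange(int(2 * half / d)) * d - half for d in sp]
        zz, yy, xx = np.meshgrid(*ax, indexing="ij", sparse=True)
        nb = np.sqrt(zz**2 + yy**2 + xx**2) <= 3.0
        gmc = np.sqrt(zz**2 + yy**2 + (xx + 5.0 + gap) ** 2) <= 2.0
        return VoxelGrid(nb, iso_spacing), VoxelGrid(gmc, iso_spacing)

    def test_unit_axis_toward_interface(self, iso_spacing):
        nb, gmc = self._two_balls(iso_spacing)
        ax, qc = gmc_axis(nb, gmc)
        assert qc == ()
        assert ax.magnitude == pytest.approx(1.0, abs=1e-9)
        assert axis_angle(ax, Axis3D.from_arrays((0, 0, 0), (0, 0, -1))) < 3.0

    def test_synthetic_scene_axis_close_to_settled_direction(self):
        t = sample_division_series("control", 3, seed=2)
        axes = extract_gmc_axes(t)
        assert axes, "no daughter axes extracted"
        for (nb_id, c), ax in axes.items():
            ref = Axis3D.from_arrays(
                t.nb_centre.as_array(),
                t.nb_centre.as_array() + np.asarray(t.cycles[c - 1].settled_dir),
            )
            assert axis_angle(ax, ref) < 3.0

    def test_non_touching_masks_fall_back_to_centroid(self, iso_spacing):
        nb, gmc = self._two_balls(iso_spacing, gap=4.0)
        ax, qc = gmc_axis(nb, gmc)
        assert "no-contact-patch" in qc
        assert axis_angle(ax, Axis3D.from_arrays((0, 0, 0), (0, 0, -1))) < 3.0

    def test_empty_mask_rejected(self, iso_spacing):
        nb, _ = self._two_balls(iso_spacing)
        with pytest.raises(ValueError, match="empty"):
            gmc_axis(nb, VoxelGrid(np.zeros(nb.values.shape, bool), iso_spacing))


class TestAngleBookkeeping:
    def _rec(self, nb, cycle, v):
        return DivisionRecord(nb, cycle, Axis3D.from_arrays((0, 0, 0), v), "landmarks")

    def test_identical_axes_give_zero_alpha(self):
        recs = [self._rec("nb", 0, (0, 0, 1)), self._rec("nb", 1, (0, 0, 1))]
        out = measure_alpha_beta(recs)
        assert len(out) == 1
        assert out[0].kind == "alpha" and out[0].value == pytest.approx(0.0)

    def test_non_consecutive_cycles_skipped(self):
        recs = [self._rec("nb", 0, (0, 0, 1)), self._rec("nb", 2, (0, 1, 0))]
        assert measure_alpha_beta(recs) == []

    def test_beta_uses_daughter_axis(self):
        recs = [self._rec("nb", 0, (0, 0, 1)), self._rec("nb", 1, (0, 1, 0))]
        gmc = {("nb", 1): Axis3D.from_arrays((0, 0, 0), (0, 0, 1))}
        out = measure_alpha_beta(recs, gmc)
        betas = [a for a in out if a.kind == "beta"]
        assert len(betas) == 1
        assert betas[0].value == pytest.approx(90.0)

    def test_cells_kept_separate(self):
        recs = [self._rec("a", 0, (0, 0, 1)), self._rec("b", 1, (0, 1, 0))]
        assert measure_alpha_beta(recs) == []

    def test_angle_measurement_validation(self):
        with pytest.raises(ValueError):
            AngleMeasurement("gamma", 10.0, "nb", 1)
        with pytest.raises(ValueError):
            AngleMeasurement("alpha", 190.0, "nb", 1)
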