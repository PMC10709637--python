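"""Tests of GRO I/O, leaflet assignment, scrambling series and grid maps."""

import numpy as np
import pytest

import scramkit as sk
from scramkit.trajectory import TrajectoryFrame, read_gro, write_gro


def bilayer_frame(n_per_leaflet=4, offset=2.0, box=(4.0, 4.0, 8.0), time_ps=0.0, z_override=None):
    """Minimal bilayer: phosphates on an xy grid at +/- offset about mid-z."""
    n = 2 * n_per_leaflet
    xy = np.array([[(i % 2) + 1.0, (i // 2) + 1.0] for i in range(n_per_leaflet)])
    zmid = box[2] / 2
    z = np.concatenate([np.full(n_per_leaflet, zmid + offset), np.full(n_per_leaflet, zmid - offset)])
    if z_override is not None:
        for rid, zval in z_override.items():
            z[rid - 1] = zval
    pos = np.column_stack([np.vstack([xy, xy]), z])
    return TrajectoryFrame(
        resids=np.arange(1, n + 1),
        resnames=np.array(["POPC"] * n, dtype=object),
        atomnames=np.array(["PO4"] * n, dtype=object),
        positions=pos,
        box=np.array(box),
        time_ps=time_ps,
    )


class TestGroRoundTrip:
    def test_multi_frame_round_trip(self, tmp_path):
        frames = sk.generate_trajectory(
            sk.TrajectorySpec(n_lipids=16, n_waters=20, n_frames=3, seed=1)
        )
        path = tmp_path / "traj.gro"
        write_gro(frames, path)
        back = read_gro(path)
        assert len(back) == 3
        for a, b in zip(frames, back):
            assert np.array_equal(a.resids, b.resids)
            assert list(a.atomnames) == list(b.atomnames)
            assert np.allclose(a.positions, b.positions, atol=5e-4)
            assert a.time_ps == pytest.approx(b.time_ps)

    def test_single_frame_read_by_mdanalysis(self, tmp_path):
        MDAnalysis = pytest.importorskip("MDAnalysis")
        frame = bilayer_frame()
        path = tmp_path / "frame.gro"
        write_gro(frame, path)
        u = MDAnalysis.Universe(str(path))
        assert len(u.atoms) == frame.n_beads
        # MDAnalysis reports Angstrom; ours are nm
        assert np.allclose(u.atoms.positions / 10.0, frame.positions, atol=5e-4)

    def test_malformed_stream_rejected(self):
        with pytest.raises(ValueError, match="GRO"):
            read_gro("title line only\nnot-a-number\n")


class TestLeafletAssignment:
    def test_symmetric_bilayer_splits_evenly(self):
        la = sk.assign_leaflets(bilayer_frame())
        labels = list(la.labels.values())
        assert labels.count("upper") == 4 and labels.count("lower") == 4

    def test_single_flipped_lipid_labeled_lower(self):
        frame = bilayer_frame(z_override={1: 2.0})  # resid 1 down at zmid - 2
        la = sk.assign_leaflets(frame)
        assert la.labels[1] == "lower"

    def test_generator_construction_labels_match(self):
        frames = sk.generate_trajectory(
            sk.TrajectorySpec(n_lipids=50, n_waters=0, n_frames=1, seed=3)
        )
        la = sk.assign_leaflets(frames[0])
        uppers = [rid for rid, lab in la.labels.items() if lab == "upper"]
        assert sorted(uppers) == list(range(1, 26))

    def test_phosphate_at_center_uses_previous_frame_label(self):
        ref = sk.assign_leaflets(bilayer_frame())
        # place resid 1 exactly at the resulting mean phosphate z:
        # remaining 3 upper (+2) and 4 lower (-2) give mean (26 + z1)/8,
        # which equals z1 at z1 = 26/7
        frame = bilayer_frame(z_override={1: 26.0 / 7.0})
        la = sk.assign_leaflets(frame, previous=ref)
        assert la.labels[1] == "upper"
        with pytest.raises(ValueError, match="center"):
            sk.assign_leaflets(frame)


class TestScrambledSeries:
    def test_no_flips_zero_everywhere(self):
        frames = sk.generate_trajectory(
            sk.TrajectorySpec(n_lipids=20, n_waters=0, n_frames=8, seed=5)
        )
        series = sk.scrambled_series(frames)
        assert np.all(series.percent == 0.0)
        assert series.rate_percent_per_us == pytest.approx(0.0, abs=1e-9)

    def test_five_planted_flips_among_hundred(self):
        flips = tuple((lid, 3) for lid in (2, 5, 8, 55, 60))
        frames = sk.generate_trajectory(
            sk.TrajectorySpec(n_lipids=100, n_waters=0, n_frames=6, planted_flips=flips, seed=6)
        )
        series = sk.scrambled_series(frames)
        assert series.percent[-1] == pytest.approx(5.0)

    def test_step_positions_match_plant_schedule(self):
        flips = ((1, 1), (2, 3), (3, 3), (4, 5))
        frames = sk.generate_trajectory(
            sk.TrajectorySpec(n_lipids=100, n_waters=0, n_frames=7, planted_flips=flips, seed=7)
        )
        series = sk.scrambled_series(frames)
        # brute-force expected series from the plant schedule
        expected = [100.0 * sum(1 for _, f in flips if fi >= f) / 100 for fi in range(7)]
        assert np.allclose(series.percent, expected)
        assert series.rate_percent_per_us > 0

    def test_running_average_smooths_step(self):
        flips = ((1, 5),)
        frames = sk.generate_trajectory(
            sk.TrajectorySpec(n_lipids=10, n_waters=0, n_frames=40, planted_flips=flips, seed=8)
        )
        series = sk.scrambled_series(frames, window_ns=200.0)
        step = series.percent >= 10.0
        # the raw series is a step; the average rises through intermediate values
        assert series.running_average[np.argmax(step)] < 10.0

    def test_missing_phosphate_named_in_error(self):
        frames = sk.generate_trajectory(
            sk.TrajectorySpec(n_lipids=10, n_waters=0, n_frames=2, seed=9)
        )
        f1 = frames[1]
        keep = ~((f1.resids == 3) & (f1.atomnames == "PO4"))
        frames[1] = TrajectoryFrame(
            f1.resids[keep], f1.resnames[keep], f1.atomnames[keep],
            f1.positions[keep], f1.box, f1.time_ps,
        )
        with pytest.raises(ValueError, match="3"):
            sk.scrambled_series(frames)


class TestWaterDefectMap:
    def test_dry_core_gives_zero_map(self):
        frames = sk.generate_trajectory(
            sk.TrajectorySpec(
                n_lipids=16, n_waters=30, box=(4.0, 4.0, 12.0), n_frames=100,
                frame_interval_ps=100.0, seed=10,
            )
        )
        gm = sk.water_defect_map(frames)
        assert np.all(gm.values[~gm.mask] == 0.0)

    def test_planted_defect_disc_counts(self):
        disc = sk.DiscRegion(cx=2.0, cy=2.0, radius=0.6, waters_per_frame=25)
        frames = sk.generate_trajectory(
            sk.TrajectorySpec(
                n_lipids=16, n_waters=0, box=(4.0, 4.0, 12.0), n_frames=120,
                frame_interval_ps=100.0, defect_region=disc, seed=11,
            )
        )
        gm = sk.water_defect_map(frames)
        # planted beads sit within 1 nm of the exact midplane; the measured
        # center jitters with the phosphates, so allow a small leakage
        assert np.nansum(gm.values) == pytest.approx(25.0, rel=0.02)
        # and the defect is confined to the disc
        xc = (gm.x_edges[:-1] + gm.x_edges[1:]) / 2
        yc = (gm.y_edges[:-1] + gm.y_edges[1:]) / 2
        xx, yy = np.meshgrid(xc, yc, indexing="ij")
        outside = (xx - 2.0) ** 2 + (yy - 2.0) ** 2 > 0.8**2
        assert np.nansum(np.where(outside, gm.values, 0.0)) == 0.0

    def test_short_trajectory_fully_masked(self):
        frames = sk.generate_trajectory(
            sk.TrajectorySpec(n_lipids=16, n_waters=10, n_frames=5, frame_interval_ps=100.0, seed=12)
        )
        gm = sk.water_defect_map(frames)
        assert gm.mask.all()
        assert np.all(np.isnan(gm.values))

    def test_no_water_warns(self):
        frames = sk.generate_trajectory(
            sk.TrajectorySpec(n_lipids=16, n_waters=0, n_frames=101, frame_interval_ps=100.0, seed=13)
        )
        with pytest.warns(UserWarning, match="water"):
            gm = sk.water_defect_map(frames)
        assert np.all(gm.values[~gm.mask] == 0.0)

    def test_bin_pitch_is_exact(self):
        frames = sk.generate_trajectory(
            sk.TrajectorySpec(n_lipids=16, n_waters=0, n_frames=1, box=(5.0, 5.0, 10.0), seed=14)
        )
        gm = sk.water_defect_map(frames, min_samples=1)
        assert np.allclose(np.diff(gm.x_edges), 0.1)
        assert gm.x_edges.size - 1 == 50


class TestThicknessMap:
    def _flat_frames(self, n_frames=100, thin=None):
        return sk.generate_trajectory(
            sk.TrajectorySpec(
                n_lipids=32, n_waters=0, box=(4.0, 4.0, 8.0), n_frames=n_frames,
                frame_interval_ps=100.0, z_jitter_sd=1e-9, thinned_region=thin, seed=15,
            )
        )

    def test_flat_bilayer_uniform_thickness(self):
        gm = sk.thickness_map(self._flat_frames())
        vals = gm.values[~gm.mask]
        assert vals.size > 0
        assert np.allclose(vals, 4.0, atol=1e-6)

    def test_planted_thinned_disc(self):
        thin = sk.DiscRegion(cx=2.0, cy=2.0, radius=1.2, phosphate_offset_nm=1.05)
        gm = sk.thickness_map(self._flat_frames(thin=thin))
        xc = (gm.x_edges[:-1] + gm.x_edges[1:]) / 2
        yc = (gm.y_edges[:-1] + gm.y_edges[1:]) / 2
        xx, yy = np.meshgrid(xc, yc, indexing="ij")
        inside = (xx - 2.0) ** 2 + (yy - 2.0) ** 2 <= 1.2**2
        thin_vals = gm.values[inside & ~gm.mask]
        thick_vals = gm.values[~inside & ~gm.mask]
        assert thin_vals.size and thick_vals.size
        assert np.allclose(thin_vals, 2.1, atol=1e-6)
        assert np.allclose(thick_vals, 4.0, atol=1e-6)

    def test_invariant_under_rigid_z_translation(self):
        frames = self._flat_frames()
        shifted = []
        for fr in frames:
            pos = fr.positions.copy()
            pos[:, 2] += 0.7
            shifted.append(
                TrajectoryFrame(fr.resids, fr.resnames, fr.atomnames, pos, fr.box, fr.time_ps)
            )
        a = sk.thickness_map(frames)
        b = sk.thickness_map(shifted)
        assert np.array_equal(a.mask, b.mask)
        assert np.allclose(a.values[~a.mask], b.values[~b.mask], atol=1e-9)

    def test_masking_rule_consistency(self):
        gm = sk.thickness_map(self._flat_frames(n_frames=120))
        assert not np.any(~np.isnan(gm.values) & gm.mask)
        assert np.all(gm.counts[~gm.mask] >= 100)


class TestMapEquivariance:
    def test_integer_bin_translation_rolls_the_map(self):
        disc = sk.DiscRegion(cx=1.5, cy=1.5, radius=0.5, waters_per_frame=10)
        spec = sk.TrajectorySpec(
            n_lipids=16, n_waters=0, box=(4.0, 4.0, 12.0), n_frames=110,
            frame_interval_ps=100.0, defect_region=disc, seed=16,
        )
        frames = sk.generate_trajectory(spec)
        shift_nm = 1.0  # integer number of 0.1-nm bins
        shifted = []
        for fr in frames:
            pos = fr.positions.copy()
            pos[:, 0] += shift_nm
            shifted.append(
                TrajectoryFrame(fr.resids, fr.resnames, fr.atomnames, pos, fr.box, fr.time_ps)
            )
        a = sk.water_defect_map(frames)
        b = sk.water_defect_map(shifted)
        rolled = np.roll(np.nan_to_num(a.values), int(round(shift_nm / 0.1)), axis=0)
        assert np.allclose(np.nan_to_num(b.values), rolled)


class TestCenterOnProtein:
    def _frames(self, n_frames=3):
        return sk.generate_trajectory(
            sk.TrajectorySpec(n_lipids=16, n_waters=10, n_frames=n_frames, n_protein_beads=6, seed=17)
        )

    def _protein_centroid(self, fr):
        mask = fr.kind_mask("protein")
        return fr.positions[mask, :2].mean(axis=0)

    def test_already_centered_unchanged(self):
        frames = self._frames(1)
        out = sk.center_on_protein(frames)
        assert np.allclose(out[0].positions, frames[0].positions, atol=1e-9)

    def test_shifted_frame_restored(self):
        fr = self._frames(1)[0]
        pos = fr.positions.copy()
        pos[:, :2] += 1.0
        shifted = TrajectoryFrame(fr.resids, fr.resnames, fr.atomnames, pos, fr.box, fr.time_ps)
        out = sk.center_on_protein([shifted])[0]
        assert np.allclose(self._protein_centroid(out), fr.box[:2] / 2, atol=1e-9)

    def test_random_shifts_give_zero_centroid_variance(self):
        rng = np.random.default_rng(0)
        frames = []
        for fr in self._frames(6):
            pos = fr.positions.copy()
            pos[:, :2] += rng.uniform(-2, 2, 2)
            frames.append(TrajectoryFrame(fr.resids, fr.resnames, fr.atomnames, pos, fr.box, fr.time_ps))
        centered = sk.center_on_protein(frames)
        cents = np.array([self._protein_centroid(fr) for fr in centered])
        assert np.allclose(cents.var(axis=0), 0.0, atol=1e-12)

    def test_no_protein_is_identity_with_warning(self):
        frames = sk.generate_trajectory(
            sk.TrajectorySpec(n_lipids=16, n_waters=0, n_frames=1, seed=18)
        )
        with pytest.warns(UserWarning, match="protein"):
            out = sk.center_on_protein(frames)
        assert np.allclose(out[0].positions, frames[0].positions)
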