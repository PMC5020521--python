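"""Phantom generation, rescanning and common-region registration."""

import numpy as np
import pandas as pd
import pytest

from voxelfe import (DensityVolume, PhantomSpec, RescanSpec, cohort_metadata,
                     generate_cohort, generate_phantom, phantom_truth_labels,
                     register_common_region, rescan)


def tube_spec(**kw) -> PhantomSpec:
    """A plain hollow tube: no lattice, no taper, no wobble, no noise."""
    defaults = dict(grid_shape=(24, 24), n_slices=20, lattice=False,
                    flare_rate=0.0, wobble_amplitude=0.0,
                    background_noise_sd=0.0, cortical_density=1200.0,
                    outer_radius=0.7, cortical_thickness=0.2)
    defaults.update(kw)
    return PhantomSpec(**defaults)


class TestGeneratePhantom:
    def test_hollow_tube_densities(self):
        """Noiseless tube: every shell voxel is exactly cortical density,
        everything else exactly zero."""
        vol = generate_phantom(tube_spec())
        assert set(np.unique(vol.data)) == {0.0, 1200.0}

    def test_shell_count_matches_membership_oracle(self):
        """Shell voxel count agrees with a brute-force voxel-by-voxel
        annulus membership test."""
        spec = tube_spec()
        vol = generate_phantom(spec)
        h = spec.voxel_size
        count = 0
        for i in range(24):
            for j in range(24):
                x = (i - 11.5) * h
                y = (j - 11.5) * h
                r = np.hypot(x, y)
                if spec.outer_radius - spec.cortical_thickness < r \
                        <= spec.outer_radius:
                    count += 1
        assert (vol.data == 1200.0).sum() == count * spec.n_slices

    def test_deterministic(self):
        spec = PhantomSpec(grid_shape=(20, 20), n_slices=16,
                           outer_radius=0.6, cortical_thickness=0.2,
                           background_noise_sd=20.0, seed=7)
        a, b = generate_phantom(spec), generate_phantom(spec)
        np.testing.assert_array_equal(a.data, b.data)

    def test_unresolvable_cortex(self):
        with pytest.raises(ValueError, match="unresolvable cortex"):
            generate_phantom(tube_spec(cortical_thickness=0.05,
                                       outer_radius=0.7))

    def test_truth_labels_partition(self):
        spec = PhantomSpec(grid_shape=(24, 24), n_slices=24,
                           outer_radius=0.7, cortical_thickness=0.25)
        truth = phantom_truth_labels(spec)
        vol = generate_phantom(spec)
        # bone density exactly where truth says bone
        assert ((vol.data > 0) == (truth > 0)).all()


class TestRescan:
    def test_identity(self):
        vol = generate_phantom(tube_spec())
        out = rescan(vol, RescanSpec())
        np.testing.assert_array_equal(out.data, vol.data)

    def test_integer_shift_maps_slices(self):
        """Positive shift 11: output slice z equals input slice z+11."""
        spec = PhantomSpec(grid_shape=(24, 24), n_slices=110,
                           outer_radius=0.6, cortical_thickness=0.22)
        vol = generate_phantom(spec)
        out = rescan(vol, RescanSpec(slice_shift=11))
        np.testing.assert_array_equal(out.data[:, :, :99], vol.data[:, :, 11:])
        assert np.all(out.data[:, :, 99:] == 0)  # filled with zero-SD noise

    def test_noise_seeds_differ(self):
        vol = generate_phantom(tube_spec())
        a = rescan(vol, RescanSpec(noise_sd=20.0, seed=1))
        b = rescan(vol, RescanSpec(noise_sd=20.0, seed=2))
        assert not np.array_equal(a.data, b.data)

    def test_no_overlap_rejected(self):
        vol = generate_phantom(tube_spec())
        with pytest.raises(ValueError, match="no overlap"):
            rescan(vol, RescanSpec(slice_shift=20))

    def test_motion_blur_applied(self):
        vol = generate_phantom(tube_spec())
        out = rescan(vol, RescanSpec(motion_amplitude=0.8))
        assert not np.array_equal(out.data, vol.data)


class TestRegistration:
    def test_identity(self, phantom_vol):
        res = register_common_region(phantom_vol, phantom_vol)
        assert res.slice_shift_est == 0
        assert res.common_region_pct == 100.0

    def test_shift_arithmetic_110_slices(self):
        """Imposed shift 11 on a 110-slice scan: 90 % common region."""
        spec = PhantomSpec(grid_shape=(28, 28), n_slices=110,
                           outer_radius=0.78, cortical_thickness=0.26)
        vol = generate_phantom(spec)
        res = register_common_region(vol, rescan(vol, RescanSpec(slice_shift=11)))
        assert res.slice_shift_est == 11
        assert res.common_region_pct == pytest.approx(90.0)

    def test_large_negative_shift_in_observed_range(self):
        """Shift -19 gives a 82.7 % common region, inside the 81-99 % band
        observed at the distal radius."""
        spec = PhantomSpec(grid_shape=(28, 28), n_slices=110,
                           outer_radius=0.78, cortical_thickness=0.26)
        vol = generate_phantom(spec)
        res = register_common_region(vol, rescan(vol, RescanSpec(slice_shift=-19)))
        assert res.common_region_pct == pytest.approx(82.7, abs=0.05)
        assert 81.0 <= res.common_region_pct <= 99.0

    def test_exhaustive_integer_recovery(self, phantom_vol):
        """Noiseless shift-only rescans: the true shift is recovered exactly
        for every shift in -20..20, and the common region is non-increasing
        in the shift magnitude."""
        last_pct = {1: 100.0, -1: 100.0}
        for s in range(-20, 21):
            if s == 0:
                continue
            moved = rescan(phantom_vol, RescanSpec(slice_shift=s))
            res = register_common_region(phantom_vol, moved)
            assert res.slice_shift_est == s
            sign = 1 if s > 0 else -1
            assert res.common_region_pct <= last_pct[sign]

    def test_mismatched_grids_rejected(self, phantom_vol):
        other = generate_phantom(tube_spec())
        with pytest.raises(ValueError):
            register_common_region(phantom_vol, other)

    def test_no_plausible_overlap(self):
        a = DensityVolume(np.zeros((8, 8, 12), dtype=np.float32))
        with pytest.raises(ValueError, match="overlap"):
            register_common_region(a, a)


SMALL_PV = {"outer_radius": (0.55, 0.02),
            "cortical_thickness": (0.25, 0.01)}


class TestCohort:
    def test_radius_arm_size(self):
        pairs = generate_cohort(27, seed=3, phantom_variability=SMALL_PV,
                                grid_shape=(20, 20), n_slices=24)
        assert len(pairs) == 27
        assert len({p.participant_id for p in pairs}) == 27

    def test_zero_motion_full_common_region(self):
        pairs = generate_cohort(3, rescan_distribution={"shift_range": (0, 0)},
                                phantom_variability=SMALL_PV,
                                seed=5, grid_shape=(24, 24), n_slices=32)
        for p in pairs:
            res = register_common_region(p.baseline, p.followup)
            assert res.common_region_pct == 100.0
            np.testing.assert_array_equal(p.baseline.data, p.followup.data)

    def test_deterministic_metadata(self):
        kw = dict(seed=11, phantom_variability=SMALL_PV,
                  grid_shape=(20, 20), n_slices=24)
        a = cohort_metadata(generate_cohort(4, **kw))
        b = cohort_metadata(generate_cohort(4, **kw))
        pd.testing.assert_frame_equal(a, b)

    def test_metadata_columns(self, tmp_path):
        pairs = generate_cohort(2, seed=1, phantom_variability=SMALL_PV,
                                grid_shape=(20, 20), n_slices=24)
        meta = cohort_metadata(pairs)
        assert list(meta.columns) == ["participant_id", "site",
                                      "interval_days", "true_shift",
                                      "motion_amplitude", "seed"]
        path = tmp_path / "meta.csv"
        meta.to_csv(path, index=False)
        pd.testing.assert_frame_equal(pd.read_csv(path), meta)

    def test_degenerate_distributions_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(3, rescan_distribution={"noise_sd": -1.0},
                            phantom_variability=SMALL_PV, seed=0,
                            grid_shape=(20, 20), n_slices=24)
        with pytest.raises(ValueError):
            generate_cohort(1, seed=0)

    def test_shifted_followup_captures_new_anatomy(self):
        """A shifted follow-up window contains real shifted anatomy: its
        overlap with baseline matches slice-for-slice."""
        pairs = generate_cohort(2, rescan_distribution={"shift_range": (6, 6)},
                                phantom_variability=SMALL_PV,
                                seed=2, grid_shape=(24, 24), n_slices=32)
        p = pairs[0]
        assert p.true_shift == 6
        np.testing.assert_allclose(p.followup.data[:, :, :26],
                                   p.baseline.data[:, :, 6:], atol=1e-5)
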