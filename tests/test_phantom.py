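import hashlib

import numpy as np
import pandas as pd
import pytest

from defaceqc import (
    DefaceSimSpec,
    FACIAL_FEATURES,
    GroundTruthRule,
    PhantomSpec,
    brain_to_head_ratio,
    generate_cohort,
    generate_phantom,
    impacted_voxels,
    label,
    normalize,
    removed_voxels,
    simulate_defacing,
)
from conftest import removal


class TestGeneratePhantom:
    def test_same_seed_bit_identical(self):
        spec = PhantomSpec(grid_size=32, seed=9)
        a = generate_phantom(spec)
        b = generate_phantom(spec)
        np.testing.assert_array_equal(
            a.volume.intensities, b.volume.intensities
        )
        np.testing.assert_array_equal(a.head.voxels, b.head.voxels)

    def test_default_bhr_plausible(self, phantom):
        assert 0.2 < brain_to_head_ratio(phantom.brain, phantom.head) < 0.8

    def test_masks_consistent_with_intensity_support(self, phantom):
        support = phantom.volume.intensities > 0
        np.testing.assert_array_equal(support, phantom.head.voxels)
        assert np.all(phantom.head.voxels | ~phantom.brain.voxels)

    def test_brain_outside_head_rejected(self):
        with pytest.raises(ValueError):
            generate_phantom(PhantomSpec(grid_size=32, brain_scale=0.999,
                                         head_semiaxes=(0.2, 0.5, 0.2)))

    def test_features_visible_in_frontal_render(self, quiet_phantom):
        from defaceqc import render_view, ViewSpec, Volume, Mask

        ph = quiet_phantom
        spec_no_face = PhantomSpec(
            grid_size=ph.spec.grid_size, seed=ph.spec.seed,
            noise_sigma=0.0, features=(),
        )
        bare = generate_phantom(spec_no_face)
        view = ViewSpec("frontal", 0.0, 64)
        a = render_view(normalize(ph.volume), ph.head, view)
        b = render_view(normalize(bare.volume), bare.head, view)
        assert np.any(a.pixels != b.pixels)


class TestSimulateDefacing:
    def test_full_removal_voxel_accounting(self, quiet_phantom):
        """Removing every feature zeroes exactly the features' share of head
        voxels and leaves the brain untouched."""
        ph = quiet_phantom
        sim = DefaceSimSpec(removal=removal(), seed=1)
        defaced = simulate_defacing(ph, sim)
        feature_voxels = np.zeros(ph.head.shape, bool)
        for m in ph.feature_masks.values():
            feature_voxels |= m
        expected = 100.0 * feature_voxels.sum() / ph.head.count
        assert removed_voxels(
            normalize(ph.volume), normalize(defaced), ph.head
        ) == pytest.approx(expected, abs=1e-9)
        assert removed_voxels(
            normalize(ph.volume), normalize(defaced), ph.brain
        ) == 0.0

    def test_no_op_is_identity(self, phantom):
        sim = DefaceSimSpec(removal={f: 0.0 for f in FACIAL_FEATURES})
        defaced = simulate_defacing(phantom, sim)
        np.testing.assert_array_equal(
            defaced.intensities, phantom.volume.intensities
        )

    def test_global_perturbation_impacts_all_head_voxels(self, phantom):
        sim = DefaceSimSpec(
            removal={f: 0.0 for f in FACIAL_FEATURES},
            global_perturbation=0.002,
        )
        defaced = simulate_defacing(phantom, sim)
        assert impacted_voxels(
            phantom.volume, defaced, phantom.head, eps=0.0
        ) == 100.0
        assert removed_voxels(phantom.volume, defaced, phantom.head) == 0.0

    def test_partial_removal_is_surface_inward(self, quiet_phantom):
        """At r = 0.5 the zeroed nose voxels are the outermost half."""
        ph = quiet_phantom
        sim = DefaceSimSpec(removal={"nose": 0.5}, seed=0)
        defaced = simulate_defacing(ph, sim)
        nose = ph.feature_masks["nose"]
        zeroed = nose & (defaced.intensities == 0.0)
        kept = nose & (defaced.intensities != 0.0)
        # along the outward (anterior) direction, every zeroed voxel is at
        # least as superficial as the deepest kept voxel
        direction = np.array([0.0, 0.97, -0.24])
        direction /= np.linalg.norm(direction)
        depth_zeroed = np.argwhere(zeroed) @ direction
        depth_kept = np.argwhere(kept) @ direction
        assert depth_zeroed.min() >= depth_kept.max() - 1.0

    def test_brain_clip_zeroes_requested_fraction(self, phantom):
        sim = DefaceSimSpec(
            removal={f: 0.0 for f in FACIAL_FEATURES},
            brain_clip=0.1, seed=5,
        )
        defaced = simulate_defacing(phantom, sim)
        zeroed = (
            (defaced.intensities == 0.0) & phantom.brain.voxels
        ).sum()
        assert zeroed == int(0.1 * phantom.brain.count)

    def test_deterministic_given_seed(self, phantom):
        sim = DefaceSimSpec(removal=removal(nose=0.3), brain_clip=0.05,
                            seed=77)
        a = simulate_defacing(phantom, sim)
        b = simulate_defacing(phantom, sim)
        np.testing.assert_array_equal(a.intensities, b.intensities)


class TestLabelRules:
    def test_all_removed_succeeds_everywhere(self):
        sim = DefaceSimSpec(removal=removal())
        assert label(sim, GroundTruthRule("strict")) == 0
        assert label(sim, GroundTruthRule("lenient")) == 0

    def test_single_partial_residual(self):
        """One feature at r = 0.7: a strict failure, tolerated leniently."""
        sim = DefaceSimSpec(removal=removal(nose=0.7))
        assert label(sim, GroundTruthRule("strict")) == 1
        assert label(sim, GroundTruthRule("lenient")) == 0

    def test_two_partial_residuals_fail_both(self):
        sim = DefaceSimSpec(removal=removal(nose=0.7, mouth=0.8))
        assert label(sim, GroundTruthRule("strict")) == 1
        assert label(sim, GroundTruthRule("lenient")) == 1

    def test_single_severe_residual_fails_lenient(self):
        sim = DefaceSimSpec(removal=removal(left_eye=0.2))
        assert label(sim, GroundTruthRule("lenient")) == 1

    def test_residual_threshold_configurable(self):
        sim = DefaceSimSpec(removal=removal(nose=0.9))
        assert label(sim, GroundTruthRule("strict",
                                          residual_threshold=0.85)) == 0


class TestGenerateCohort:
    def test_pair_count_arithmetic(self):
        manifest = generate_cohort(
            n_subjects=20, scans_per_subject=(2, 2), master_seed=1
        )
        assert len(manifest) == 20 * 2 * 4
        assert manifest["subject_id"].nunique() == 20

    def test_requested_balance_achieved(self):
        manifest = generate_cohort(
            n_subjects=25, scans_per_subject=(1, 3),
            positive_fraction=0.4, balance_criterion="lenient",
            master_seed=3,
        )
        realized = manifest["label_lenient"].mean()
        assert abs(realized - 0.4) <= 0.05

    def test_same_master_seed_identical_manifest(self):
        kw = dict(n_subjects=8, scans_per_subject=(1, 4), master_seed=11)
        a = generate_cohort(**kw)
        b = generate_cohort(**kw)
        ha = hashlib.sha256(
            pd.util.hash_pandas_object(a).values.tobytes()
        ).hexdigest()
        hb = hashlib.sha256(
            pd.util.hash_pandas_object(b).values.tobytes()
        ).hexdigest()
        assert ha == hb

    def test_labels_rederivable_from_manifest(self):
        from defaceqc.phantom import sim_from_row

        manifest = generate_cohort(
            n_subjects=10, scans_per_subject=(1, 3), master_seed=4
        )
        for _, row in manifest.iterrows():
            sim = sim_from_row(row)
            assert label(sim, GroundTruthRule("strict")) == row["label_strict"]
            assert label(sim, GroundTruthRule("lenient")) == row["label_lenient"]

    def test_scans_per_subject_within_range(self):
        manifest = generate_cohort(
            n_subjects=30, scans_per_subject=(1, 7), master_seed=2
        )
        per_subject = manifest.groupby("subject_id")["scan_id"].nunique()
        assert per_subject.between(1, 7).all()

    def test_volumes_written_to_disk(self, tmp_path):
        from defaceqc import load_volume

        manifest = generate_cohort(
            n_subjects=2, scans_per_subject=(1, 1), master_seed=6,
            grid_size=24, out_dir=tmp_path,
        )
        assert (tmp_path / "manifest.csv").exists()
        first = manifest.iloc[0]
        orig = load_volume(tmp_path / f"{first['scan_id']}.nii.gz")
        defaced = load_volume(
            tmp_path / f"{first['scan_id']}_{first['method']}.nii.gz"
        )
        assert orig.shape == defaced.shape == (24, 24, 24)


class TestMonotonicity:
    def test_increasing_removal_monotone_features(self, quiet_phantom):
        """More nose removal never raises frontal similarity and never
        lowers the removed-voxel share."""
        from defaceqc import fsim, render_view, ViewSpec, head_mask

        ph = quiet_phantom
        vol_n = normalize(ph.volume)
        hm = head_mask(vol_n)
        spec = ViewSpec("frontal", 0.0, 64)
        base = render_view(vol_n, hm, spec)
        fsims, removed = [], []
        for r in (0.0, 0.25, 0.5, 0.75, 1.0):
            defaced = simulate_defacing(
                ph, DefaceSimSpec(removal={"nose": r}, seed=1)
            )
            dn = normalize(defaced)
            fsims.append(fsim(base, render_view(dn, hm, spec)))
            removed.append(removed_voxels(vol_n, dn, hm))
        assert all(a >= b - 1e-9 for a, b in zip(fsims, fsims[1:]))
        assert all(a <= b + 1e-9 for a, b in zip(removed, removed[1:]))
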