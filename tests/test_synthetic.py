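"""Synthetic cohort generator: determinism, ground-truth structure,
tumor-mask round trips and cognition coupling."""

import numpy as np
import pytest
from scipy import stats

from neuroignite import (
    CohortSpec,
    IgnitionParams,
    ValidationError,
    bin_fraction,
    compute_profile,
    generate_bold,
    generate_cognition,
    generate_tumor_masks,
    mask_to_region_fraction,
    run_preprocess,
    toy_atlas,
)
from neuroignite.synthetic import default_network_assignment


def mean_ignition(bold):
    _, raster = run_preprocess(bold)
    return compute_profile(raster, IgnitionParams.for_tr(bold.tr_ms)).mean_ignition


class TestSpecValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_control", 0),
            ("coupling_within", 1.5),
            ("glioma_global_attenuation", 0.0),
            ("noise_sd", -1.0),
            ("event_rate", 0.0),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(ValidationError, match=field):
            CohortSpec(**{field: value})

    def test_network_assignment_covers_all_regions(self):
        with pytest.raises(ValidationError, match="network_assignment"):
            CohortSpec(n_regions=10, network_assignment=np.zeros(9, dtype=int))

    def test_default_assignment_partition(self):
        a = default_network_assignment(268, 7)
        assert a.shape == (268,)
        assert set(np.unique(a)) == set(range(7))


class TestGenerateBold:
    def test_deterministic_given_seed(self, small_spec):
        c1, t1 = generate_bold(small_spec)
        c2, t2 = generate_bold(small_spec)
        for sub in c1:
            np.testing.assert_array_equal(c1[sub].signal, c2[sub].signal)

    def test_adding_subject_does_not_perturb_others(self, small_spec):
        import dataclasses

        bigger = dataclasses.replace(small_spec, n_glioma=small_spec.n_glioma + 1)
        c1, _ = generate_bold(small_spec)
        c2, _ = generate_bold(bigger)
        for sub in c1:
            np.testing.assert_array_equal(c1[sub].signal, c2[sub].signal)

    def test_zero_coupling_zero_noise_is_own_seed_train(self):
        spec = CohortSpec(
            n_control=2, n_meningioma=1, n_glioma=1, n_regions=20,
            n_timepoints=60, coupling_within=0.0, coupling_between=0.0,
            noise_sd=0.0, event_rate=5.0, seed=3,
        )
        cohort, _ = generate_bold(spec)
        sig = cohort["ctl-01"].signal
        # no noise, no propagation: cross-region signals are independent
        # smoothed Bernoulli trains; no co-activation structure above chance
        corr = np.corrcoef(sig + 1e-12 * np.arange(60))  # guard all-zero rows
        off = corr[~np.eye(20, dtype=bool)]
        assert np.nanmax(np.abs(off)) < 0.9

    def test_ground_truth_control_invariants(self, small_spec):
        _, truth = generate_bold(small_spec)
        for sub, grp in truth.groups.items():
            if grp == "control":
                assert (truth.multipliers[sub] == 1).all()
                assert (truth.tumor_fractions[sub] == 0).all()

    def test_attenuation_lowers_ignition_sign_test(self):
        """Monte-Carlo over replicate cohorts: halving propagation lowers
        mean subject-level ignition (sign test)."""
        wins = 0
        n_rep = 10
        for seed in range(n_rep):
            base = dict(
                n_control=5, n_meningioma=1, n_glioma=5, n_regions=60,
                n_timepoints=120, event_rate=0.8, coupling_within=0.6,
                coupling_between=0.25, seed=seed,
            )
            cohort, truth = generate_bold(
                CohortSpec(glioma_global_attenuation=0.5, **base)
            )
            ctl = [mean_ignition(b) for s, b in cohort.items() if s.startswith("ctl")]
            gli = [mean_ignition(b) for s, b in cohort.items() if s.startswith("gli")]
            wins += np.mean(gli) < np.mean(ctl)
        # one-sided sign test at p < 0.05: >= 9 of 10 successes
        assert wins >= 9

    def test_mixed_tr_assignment(self):
        spec = CohortSpec()
        trs = [spec.subject_tr(s) for s in spec.subjects]
        assert set(trs) == {2100, 2400}


class TestTumorMasks:
    def test_controls_all_zero(self, small_spec):
        overlaps = generate_tumor_masks(small_spec)
        for sub, ov in overlaps.items():
            if sub.startswith("ctl"):
                assert (ov.fractions == 0).all()

    def test_meningioma_spans_all_nonzero_bins(self, small_spec):
        overlaps = generate_tumor_masks(small_spec)
        for sub, ov in overlaps.items():
            if sub.startswith("men"):
                bins = {bin_fraction(f) for f in ov.fractions if f > 0}
                assert bins == {"(0.0,0.33)", "[0.33,0.66)", "[0.66,1.0]"}

    def test_meningioma_focal_contiguous_glioma_diffuse(self, small_spec):
        overlaps = generate_tumor_masks(small_spec)
        men = next(ov for s, ov in overlaps.items() if s.startswith("men"))
        idx = np.flatnonzero(men.fractions > 0)
        assert idx.max() - idx.min() + 1 == len(idx)  # contiguous block
        gli = next(ov for s, ov in overlaps.items() if s.startswith("gli"))
        gdx = np.flatnonzero(gli.fractions > 0)
        assert gdx.max() - gdx.min() + 1 > len(gdx)  # scattered

    def test_voxel_round_trip(self, small_spec):
        overlaps, masks, atlas = generate_tumor_masks(small_spec, with_voxels=True)
        sub = "men-01"
        recovered = mask_to_region_fraction(masks[sub], atlas)
        for k in range(small_spec.n_regions):
            n_vox = (atlas == k + 1).sum()
            assert abs(recovered.fractions[k] - overlaps[sub].fractions[k]) <= 1.0 / n_vox

    def test_toy_atlas_covers_all_labels(self):
        atlas = toy_atlas(268)
        assert atlas.shape == (20, 20, 20)
        assert set(np.unique(atlas)) == set(range(1, 269))


class TestCognition:
    def make_truth(self, spec):
        _, truth = generate_bold(spec)
        return truth

    def test_noise_free_affine_map_r_minus_one(self, small_spec):
        truth = self.make_truth(small_spec)
        ign = {s: float(i) for i, s in enumerate(truth.groups)}
        lat = generate_cognition(
            truth, ign, intercept=1.0,
            slopes={"control": -1.0, "meningioma": 0.0, "glioma": 0.0},
            noise_sd=0.0, standardize=False,
        )
        ctl = [s for s, g in truth.groups.items() if g == "control"]
        r = stats.pearsonr([ign[s] for s in ctl], [lat[s] for s in ctl]).statistic
        assert r == pytest.approx(-1.0)

    def test_missing_subject_listed(self, small_spec):
        truth = self.make_truth(small_spec)
        ign = {s: 1.0 for s in truth.groups}
        ign.pop("gli-01")
        with pytest.raises(ValueError, match="gli-01"):
            generate_cognition(truth, ign)

    def test_control_r_negative_in_most_replicates(self, small_spec):
        truth = self.make_truth(small_spec)
        neg = 0
        for rep in range(100):
            rng = np.random.default_rng(rep)
            ign = {s: float(rng.normal(30, 2)) for s in truth.groups}
            lat = generate_cognition(truth, ign, rng=np.random.default_rng(10_000 + rep))
            ctl = [s for s, g in truth.groups.items() if g == "control"]
            r = stats.pearsonr([ign[s] for s in ctl], [lat[s] for s in ctl]).statistic
            neg += r < 0
        assert neg >= 95

    def test_patient_coupling_weak(self):
        # null |r| needs a realistic group size: 10 glioma-like subjects
        spec = CohortSpec(
            n_control=4, n_meningioma=1, n_glioma=10, n_regions=21,
            n_timepoints=60, seed=2,
        )
        truth = self.make_truth(spec)
        weak = 0
        for rep in range(50):
            rng = np.random.default_rng(rep)
            ign = {s: float(rng.normal(30, 2)) for s in truth.groups}
            lat = generate_cognition(truth, ign, rng=np.random.default_rng(20_000 + rep))
            gli = [s for s, g in truth.groups.items() if g == "glioma"]
            r = stats.pearsonr([ign[s] for s in gli], [lat[s] for s in gli]).statistic
            weak += abs(r) < 0.4
        assert weak > 25  # majority of replicates

    def test_group_means_equalized(self, small_spec):
        truth = self.make_truth(small_spec)
        rng = np.random.default_rng(5)
        ign = {s: float(rng.normal(30, 2)) for s in truth.groups}
        lat = generate_cognition(truth, ign, noise_sd=0.0)
        by_group = {}
        for s, g in truth.groups.items():
            by_group.setdefault(g, []).append(lat[s])
        means = [np.mean(v) for v in by_group.values()]
        assert np.ptp(means) < 1e-9
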