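"""Synthetic cohort generator: volume curves, rasterization fidelity,
degradation budget/allocation, and cohort-level distributions."""

import numpy as np
import pytest

from cinetfc.cohort import (CohortConfig, DegradationSpec, largest_remainder,
                            degrade_segmentation, generate_cohort, iter_cohort,
                            rasterize_phantom, render_image, volume_profile)
from cinetfc.agreement import attribute_errors
from cinetfc.measure import compute_measurements, select_phases, volume_curve
from cinetfc.volume import BACKGROUND, LV, RV, CineLabelVolume

from conftest import small_cohort_config, small_grid


# --------------------------------------------------------------------- curves
class TestVolumeProfile:
    def test_extremes_at_configured_phases(self):
        c = volume_profile(100.0, 40.0, 25, 0.4)
        assert c.max() == pytest.approx(100.0) and c.argmax() == 0
        assert c.min() == pytest.approx(40.0) and c.argmin() == 10

    def test_degenerate_constant_curve(self):
        c = volume_profile(80.0, 80.0, 20, 0.4)
        assert np.allclose(c, 80.0)

    def test_rejects_edv_below_esv(self):
        with pytest.raises(ValueError):
            volume_profile(40.0, 100.0, 25, 0.4)

    @pytest.mark.parametrize("n_phases", [8, 25, 40])
    @pytest.mark.parametrize("es_frac", [0.3, 0.4, 0.5])
    def test_unimodal_and_recovered_by_phase_selection(self, n_phases, es_frac):
        """Exhaustive grid: the curve decreases to ES then increases, and
        argmax/argmin phase selection recovers the construction."""
        c = volume_profile(130.0, 55.0, n_phases, es_frac)
        es = int(round(es_frac * n_phases))
        assert np.all(np.diff(c[: es + 1]) < 0)
        assert np.all(np.diff(c[es:]) > 0)
        assert select_phases(c) == (0, es)


# --------------------------------------------------------------- rasterization
class TestRasterize:
    def test_round_trip_volume_within_tolerance(self, rng):
        """Measured voxel volumes match the requested curves within 5%
        (voxel-count oracle) for random physiological curves."""
        grid = small_grid()
        for _ in range(10):
            edv_lv = rng.uniform(80, 220)
            edv_rv = rng.uniform(90, 260)
            lv = volume_profile(edv_lv, edv_lv * rng.uniform(0.35, 0.7), 6, 0.4)
            rv = volume_profile(edv_rv, edv_rv * rng.uniform(0.35, 0.7), 6, 0.4)
            vol = rasterize_phantom(lv, rv, grid)
            for curve, structure in ((lv, "LV"), (rv, "RV")):
                measured = volume_curve(vol, structure).volumes_ml
                assert np.all(np.abs(measured - curve) / curve <= 0.05)

    def test_structures_never_overlap_and_are_contiguous(self, phantom_pair):
        ref, _ = phantom_pair
        assert not np.any((ref.labels == LV) & (ref.labels == RV))
        for structure in (LV, RV):
            for ph in range(ref.n_phases):
                slices = np.flatnonzero((ref.labels[ph] == structure).any(axis=(1, 2)))
                assert np.array_equal(slices, np.arange(slices[0], slices[-1] + 1))

    def test_zero_volume_structure_absent(self):
        grid = small_grid()
        rv = volume_profile(120.0, 60.0, 4, 0.5)
        vol = rasterize_phantom(np.zeros(4), rv, grid)
        assert not (vol.labels == LV).any()
        assert (vol.labels == RV).any()

    def test_unachievable_volume_raises(self):
        grid = small_grid(shape=(32, 32))
        big = volume_profile(500.0, 400.0, 3, 0.5)
        with pytest.raises(ValueError, match="unachievable"):
            rasterize_phantom(big, big, grid)


# ----------------------------------------------------------------- degradation
class TestDegradation:
    def test_zero_error_fraction_is_identity(self, phantom_pair):
        ref, _ = phantom_pair
        out = degrade_segmentation(ref, DegradationSpec("RV", 0.0), seed=0)
        assert np.array_equal(out.labels, ref.labels)

    def test_deterministic_for_fixed_seed(self, phantom_pair):
        ref, _ = phantom_pair
        spec = {s: DegradationSpec(s, 0.05) for s in ("LV", "RV")}
        a = degrade_segmentation(ref, spec, seed=9)
        b = degrade_segmentation(ref, spec, seed=9)
        assert np.array_equal(a.labels, b.labels)

    def test_forced_basal_allocation(self, phantom_pair):
        """With all error mass on the basal slice, every misclassified voxel
        is attributed there."""
        ref, _ = phantom_pair
        spec = DegradationSpec("RV", 0.05, slice_allocation=(1, 0, 0, 0))
        auto = degrade_segmentation(ref, spec, seed=3)
        ed, es = 0, int(np.argmin(volume_curve(ref, "RV").volumes_ml))
        att = attribute_errors(auto, ref, "RV", (ed, es))
        assert att.total_errors > 0
        assert att.basal == pytest.approx(1.0)

    def test_error_budget_conserved(self, phantom_pair):
        """Symmetric-difference size equals the requested error budget."""
        ref, auto = phantom_pair
        es = int(np.argmin(volume_curve(ref, "RV").volumes_ml))
        for structure in (LV, RV):
            for ph in (0, es):
                n_ref = int((ref.labels[ph] == structure).sum())
                diff = int(((auto.labels[ph] == structure)
                            ^ (ref.labels[ph] == structure)).sum())
                assert diff == round(0.05 * n_ref)

    def test_allocation_recovered_within_binomial_error(self, small_cohort):
        """Empirical slice-category fractions converge to the configured
        allocation (pooled over the cohort, 3 SE binomial band)."""
        for structure, spec in (("RV", DegradationSpec("RV")),
                                ("LV", DegradationSpec("LV"))):
            counts = np.zeros(4)
            total = 0
            for rec, auto in small_cohort:
                ed, es = rec.truth.ed_phase, rec.truth.es_phase
                att = attribute_errors(auto, rec.reference, structure, (ed, es))
                counts += att.fractions * att.total_errors
                total += att.total_errors
            p = np.asarray(spec.slice_allocation)
            se = np.sqrt(p * (1 - p) / total)
            assert np.all(np.abs(counts / total - p) <= 3 * se + 0.01)


# ---------------------------------------------------------------- cohort draws
class TestCohort:
    def test_largest_remainder_reproduces_reported_group_sizes(self):
        sizes = largest_remainder(157, np.array(CohortConfig().group_proportions))
        assert tuple(sizes) == (54, 66, 37)

    def test_empty_cohort(self):
        assert generate_cohort(small_cohort_config(n_subjects=0)) == []

    def test_determinism(self):
        cfg = small_cohort_config(n_subjects=3, seed=7)
        a = list(iter_cohort(cfg))
        b = list(iter_cohort(cfg))
        for ra, rb in zip(a, b):
            assert ra.subject == rb.subject
            assert np.array_equal(ra.reference.labels, rb.reference.labels)

    def test_group_sizes_and_measurements_match_configuration(self):
        cfg = small_cohort_config(n_subjects=15, seed=2)
        groups = []
        for rec in iter_cohort(cfg):
            groups.append(rec.subject.group)
            ms = compute_measurements(rec.reference, rec.subject.bsa_m2)
            gp = cfg.group_params[rec.subject.group]
            for value, (mean, sd) in ((ms.rv.edvi_ml_per_m2, gp.rvedvi),
                                      (ms.rv.ef_percent, gp.rvef),
                                      (ms.lv.edvi_ml_per_m2, gp.lvedvi),
                                      (ms.lv.ef_percent, gp.lvef)):
                # rasterization adds <5% on top of the configured spread
                assert abs(value - mean) <= 3 * sd + 0.05 * abs(mean)
        expected = largest_remainder(15, np.array(cfg.group_proportions))
        observed = [groups.count(g) for g in ("control", "at_risk", "arvc")]
        assert observed == list(expected)

    def test_arvc_group_rwma_rate(self):
        cfg = small_cohort_config(n_subjects=60, seed=3)
        flags = [rec.subject.rwma for rec in iter_cohort(cfg)
                 if rec.subject.group == "arvc"]
        p = cfg.group_params["arvc"].rwma_probability
        se = np.sqrt(p * (1 - p) / len(flags))
        assert abs(np.mean(flags) - p) <= 3 * se + 1e-9


# ------------------------------------------------------------------- rendering
class TestRenderImage:
    def test_noise_free_image_is_piecewise_constant(self, phantom_pair):
        ref, _ = phantom_pair
        img = render_image(ref, noise_sd=0.0, seed=0)
        assert 3 <= len(np.unique(img)) <= 4

    def test_seed_reproducibility(self, phantom_pair):
        ref, _ = phantom_pair
        a = render_image(ref, noise_sd=10.0, bias_field=True, seed=5)
        b = render_image(ref, noise_sd=10.0, bias_field=True, seed=5)
        assert np.array_equal(a, b)

    def test_class_means_recovered(self, phantom_pair):
        """Sample-mean oracle: per-class mean intensity matches the
        configured value within 2 standard errors at noise_sd=10."""
        ref, _ = phantom_pair
        img = render_image(ref, noise_sd=10.0, seed=1)
        for label, key in ((LV, "lv"), (RV, "rv")):
            vals = img[ref.labels == label]
            from cinetfc.cohort import CLASS_INTENSITY
            se = 10.0 / np.sqrt(len(vals))
            assert abs(vals.mean() - CLASS_INTENSITY[key]) <= 2 * se + 0.1


def test_nifti_round_trip(tmp_path, phantom_pair):
    ref, _ = phantom_pair
    path = tmp_path / "ref.nii.gz"
    ref.to_nifti(path)
    back = CineLabelVolume.from_nifti(path)
    assert np.array_equal(back.labels, ref.labels)
    assert back.in_plane_spacing_mm == pytest.approx(ref.in_plane_spacing_mm)
    assert back.slice_thickness_mm == pytest.approx(ref.slice_thickness_mm)
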