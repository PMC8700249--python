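import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from metgrade.phantom import (
    BACKGROUND_SUV,
    CohortSpec,
    LesionSpec,
    ScannerProfile,
    cohort_composition,
    generate_cohort,
    lesion_bounding_box,
    make_default_profiles,
    null_cohort_spec,
    reference_histology,
    synthesize_volume,
    who_grade_is_high,
)
from metgrade.segmentation import BoundingBox, threshold_voi
from metgrade.volume import ValidationError


def _clean_profile(spacing=(1.0, 1.0, 1.0)):
    return ScannerProfile(name="clean", voxel_spacing=spacing, psf_fwhm=0.0, noise_sd=0.0)


class TestProfiles:
    def test_default_voxel_geometries(self):
        a, b = make_default_profiles()
        assert a.voxel_spacing == pytest.approx((0.4821, 0.4821, 3.0))
        assert b.voxel_spacing == pytest.approx((1.17, 1.17, 3.27))

    def test_defaults_have_positive_blur_and_noise(self):
        for p in make_default_profiles():
            assert p.psf_fwhm > 0 and p.noise_sd > 0

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValidationError):
            ScannerProfile(name="x", voxel_spacing=(1, 0, 1))
        with pytest.raises(ValidationError):
            ScannerProfile(name="x", voxel_spacing=(1, 1, 1), noise_sd=-0.1)


class TestSynthesizeVolume:
    def test_noise_free_case_is_exact_radial_ramp(self):
        lesion = LesionSpec(centre=(10, 10, 8), semi_axes=(5, 5, 5), peak_suv=8.0, grade=0)
        vol = synthesize_volume(lesion, _clean_profile(), seed=0, grid_shape=(21, 21, 17))
        x = np.arange(21) - 10.0
        z = np.arange(17) - 8.0
        r2 = (
            (x[:, None, None] / 5) ** 2
            + (x[None, :, None] / 5) ** 2
            + (z[None, None, :] / 5) ** 2
        )
        expected = np.full((21, 21, 17), BACKGROUND_SUV)
        inside = r2 <= 1
        expected[inside] += (8.0 - BACKGROUND_SUV) * (1 - r2[inside] ** lesion.edge_power)
        np.testing.assert_allclose(vol.values, expected, rtol=0, atol=1e-12)

    def test_same_seed_bit_identical(self):
        lesion = LesionSpec(
            centre=(10, 10, 8), semi_axes=(5, 5, 5), peak_suv=8.0, grade=1, heterogeneity_amp=0.5
        )
        profile = make_default_profiles()[1]
        v1 = synthesize_volume(lesion, profile, seed=42, grid_shape=(21, 21, 17))
        v2 = synthesize_volume(lesion, profile, seed=42, grid_shape=(21, 21, 17))
        np.testing.assert_array_equal(v1.values, v2.values)

    def test_lesion_must_fit_grid(self):
        lesion = LesionSpec(centre=(5, 5, 5), semi_axes=(20, 20, 20), peak_suv=8.0, grade=0)
        with pytest.raises(ValidationError, match="does not fit"):
            synthesize_volume(lesion, _clean_profile(), seed=0, grid_shape=(11, 11, 11))

    def test_heterogeneity_raises_within_lesion_cv(self):
        """Grade-1 texture must raise the intra-lesion coefficient of variation."""
        profile = _clean_profile()
        grid = (31, 31, 25)
        base = dict(centre=(15, 15, 12), semi_axes=(8.0, 8.0, 8.0), peak_suv=8.0)
        x = np.arange(31) - 15.0
        z = np.arange(25) - 12.0
        r2 = (
            (x[:, None, None] / 8) ** 2
            + (x[None, :, None] / 8) ** 2
            + (z[None, None, :] / 8) ** 2
        )
        inside = r2 <= 1
        cvs = {0.0: [], 0.5: []}
        for amp in cvs:
            for seed in range(20):
                les = LesionSpec(grade=int(amp > 0), heterogeneity_amp=amp, **base)
                v = synthesize_volume(les, profile, seed=seed, grid_shape=grid).values
                cvs[amp].append(v[inside].std() / v[inside].mean())
        assert np.mean(cvs[0.5]) > np.mean(cvs[0.0])

    def test_threshold_voi_recovers_ground_truth_ellipsoid(self):
        """In the noise- and blur-free setting the 40% VOI overlaps the true lesion."""
        lesion = LesionSpec(centre=(15, 15, 12), semi_axes=(8, 8, 8), peak_suv=8.0, grade=0)
        grid = (31, 31, 25)
        vol = synthesize_volume(lesion, _clean_profile(), seed=0, grid_shape=grid)
        lo, hi = lesion_bounding_box(lesion, (1.0, 1.0, 1.0), grid)
        voi = threshold_voi(vol, BoundingBox(lo, hi)).to_dense()
        x = np.arange(31) - 15.0
        z = np.arange(25) - 12.0
        r2 = (
            (x[:, None, None] / 8) ** 2
            + (x[None, :, None] / 8) ** 2
            + (z[None, None, :] / 8) ** 2
        )
        truth = r2 <= 1
        dice = 2 * (voi & truth).sum() / (voi.sum() + truth.sum())
        assert dice > 0.5


class TestGenerateCohort:
    def test_default_class_counts_match_cohort(self, small_cohort):
        _, manifest = small_cohort
        assert set(manifest["grade"]) == {0, 1}

    @pytest.mark.parametrize(
        "n,fraction,expected_high,expected_low",
        [(56, 0.70, 39, 17), (10, 0.5, 5, 5)],
    )
    def test_class_count_rounding(self, tmp_path, n, fraction, expected_high, expected_low):
        spec = CohortSpec(n_patients=n, high_grade_fraction=fraction, seed=1)
        manifest = generate_cohort(spec, tmp_path)
        assert (manifest["grade"] == 1).sum() == expected_high
        assert (manifest["grade"] == 0).sum() == expected_low

    def test_rerun_is_identical(self, tmp_path):
        spec = CohortSpec(n_patients=4, seed=9)
        m1 = generate_cohort(spec, tmp_path / "a")
        m2 = generate_cohort(spec, tmp_path / "b")
        pd.testing.assert_frame_equal(m1, m2)
        v1 = (tmp_path / "a" / "volumes" / "P001.nii.gz").read_bytes()
        v2 = (tmp_path / "b" / "volumes" / "P001.nii.gz").read_bytes()
        assert v1 == v2

    def test_null_spec_removes_grade_dependence(self):
        null = null_cohort_spec(CohortSpec())
        assert null.amp_low == null.amp_high
        assert null.peak_range_low == null.peak_range_high
        assert null.necrotic_fraction_high == 0.0


class TestSeparabilityDial:
    def test_texture_effect_size_grows_with_heterogeneity(self):
        """Class effect size of texture features rises with the amp dial."""
        from metgrade.discretization import BinningConfig, discretize
        from metgrade.features.texture import glcm_features
        from metgrade.segmentation import BoundingBox, threshold_voi

        profile = make_default_profiles()[1]
        grid = (31, 31, 25)
        base = dict(centre=(15, 15, 12), semi_axes=(8.0, 8.0, 8.0), peak_suv=8.0)
        binning = BinningConfig()

        def corr_values(amp, seeds):
            out = []
            for seed in seeds:
                les = LesionSpec(grade=int(amp > 0.05), heterogeneity_amp=amp, **base)
                vol = synthesize_volume(les, profile, seed=seed, grid_shape=grid)
                lo, hi = lesion_bounding_box(les, profile.voxel_spacing, grid)
                mask = threshold_voi(vol, BoundingBox(lo, hi))
                levels = discretize(vol, mask, binning)
                out.append(glcm_features(levels, mask.to_dense())["GLCM_Correlation"])
            return np.asarray(out)

        low = corr_values(0.05, range(16))
        effects = []
        amps = [0.1, 0.35, 0.5]
        for amp in amps:
            high = corr_values(amp, range(100, 116))
            pooled_sd = np.sqrt((low.std() ** 2 + high.std() ** 2) / 2)
            effects.append(abs(high.mean() - low.mean()) / pooled_sd)
        rho, _ = spearmanr(amps, effects)
        assert rho > 0


class TestReferenceBookkeeping:
    def test_histology_totals(self):
        table = reference_histology()
        assert int(table[["siemens", "ge"]].to_numpy().sum()) == 56

    def test_who_grade_binarization(self):
        assert not who_grade_is_high("I") and not who_grade_is_high("II")
        assert who_grade_is_high("III") and who_grade_is_high("IV")
        with pytest.raises(ValidationError):
            who_grade_is_high("V")

    def test_subgroup_composition(self):
        comp = cohort_composition()
        assert comp["all"] == (39, 17)
        assert comp["ge"] == (23, 9)
        assert comp["siemens"] == (16, 8)
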