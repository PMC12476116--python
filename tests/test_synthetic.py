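"""Generator contracts: determinism, planted effects, spatial structure."""

import numpy as np
import pandas as pd
import pytest

from crpmap import falff as F
from crpmap.synthetic import (CohortSpec, ConfigurationError, GridSpec,
                              generate_annotation_maps, generate_expression,
                              generate_skeleton_panel, generate_subject_table,
                              iter_bold, make_atlas)


class TestSubjectTable:
    def test_default_cohort_size_matches_study_sample(self):
        df = generate_subject_table(CohortSpec(seed=0))
        assert len(df) == 238
        assert (df["group"] == "MDD").sum() == 120
        assert (df["group"] == "HC").sum() == 118

    def test_crp_positive_and_within_assay_range(self):
        df = generate_subject_table(CohortSpec(seed=3))
        assert (df["crp"] > 0).all()
        assert df["crp"].between(0.02, 6.39).all()

    def test_same_seed_reproduces_table_exactly(self):
        a = generate_subject_table(CohortSpec(seed=9))
        b = generate_subject_table(CohortSpec(seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_changes_table(self):
        a = generate_subject_table(CohortSpec(seed=9))
        b = generate_subject_table(CohortSpec(seed=10))
        assert not a["crp"].equals(b["crp"])

    @pytest.mark.parametrize("field,value", [
        ("n_patients", 2), ("n_controls", 0), ("age_sd", -1.0),
        ("female_prop", 1.5), ("a", 1.2),
    ])
    def test_invalid_spec_raises_naming_field(self, field, value):
        spec = CohortSpec(seed=0, **{field: value})
        with pytest.raises(ConfigurationError):
            generate_subject_table(spec)

    def test_planted_indirect_effect_is_product_of_paths(self):
        spec = CohortSpec(a=0.5, b=0.5, c_prime=0.0)
        assert spec.a * spec.b == pytest.approx(0.25)

    def test_mediation_structure_present_in_patients(self):
        df = generate_subject_table(CohortSpec(n_patients=2000,
                                               n_controls=4, seed=5))
        pat = df[df["group"] == "MDD"]
        r_xm = np.corrcoef(pat["crp_z"], pat["m_latent"])[0, 1]
        assert r_xm == pytest.approx(0.5, abs=0.06)


class TestBold:
    def test_out_of_mask_voxel_is_all_zero(self):
        mask = np.ones((6, 6, 6), bool)
        mask[0, 0, 0] = False
        grid = GridSpec(shape=(6, 6, 6), n_timepoints=64, mask=mask,
                        cluster_seed_voxels=np.array([[3, 3, 3]]))
        spec = CohortSpec(n_patients=4, n_controls=4, seed=0)
        sub = generate_subject_table(spec)
        _, vol = next(iter_bold(spec, grid, sub))
        assert np.all(vol[0, 0, 0] == 0)
        assert np.any(vol[3, 3, 3] != 0)

    def test_too_short_record_rejected(self):
        with pytest.raises(ConfigurationError):
            GridSpec(shape=(6, 6, 6), n_timepoints=64, tr=1.0).validate()

    def test_null_effect_gives_near_zero_correlation(self):
        spec = CohortSpec(n_patients=120, n_controls=4, seed=21,
                          beta_crp_falff=0.0)
        grid = GridSpec(shape=(6, 6, 6), n_timepoints=128)
        sub = generate_subject_table(spec)
        amp = []
        for _, vol in iter_bold(spec, grid, sub):
            _, a = F.spectral_amplitudes(vol[grid.cluster_mask], grid.tr)
            inb, _ = F.band_bins(grid.n_timepoints, grid.tr)
            amp.append(a[:, inb].sum(1).mean())
        pat = (sub["group"] == "MDD").to_numpy()
        r = np.corrcoef(np.array(amp)[pat], sub["crp_z"][pat])[0, 1]
        assert abs(r) < 0.2

    def test_planted_falff_correlation_recovers_target(self):
        """Monte-Carlo over replicate cohorts: mean planted-voxel fALFF-CRP
        correlation within +-0.1 of the requested effect size."""
        target = 0.6
        rs = []
        for rep in range(15):
            spec = CohortSpec(n_patients=120, n_controls=4, seed=300 + rep,
                              beta_crp_falff=target)
            grid = GridSpec(shape=(8, 8, 8), n_timepoints=200)
            sub = generate_subject_table(spec)
            vox = [F.compute_falff(vol[grid.cluster_mask], grid.tr)
                   for _, vol in iter_bold(spec, grid, sub)]
            vox = np.array(vox)
            pat = (sub["group"] == "MDD").to_numpy()
            x = sub["crp_z"][pat].to_numpy()
            rs.append(np.mean([np.corrcoef(vox[pat, j], x)[0, 1]
                               for j in range(vox.shape[1])]))
        assert np.mean(rs) == pytest.approx(target, abs=0.1)

    def test_same_seed_reproduces_volume(self):
        spec = CohortSpec(n_patients=4, n_controls=4, seed=8)
        grid = GridSpec(shape=(6, 6, 6), n_timepoints=64)
        sub = generate_subject_table(spec)
        _, v1 = next(iter_bold(spec, grid, sub))
        _, v2 = next(iter_bold(spec, grid, sub))
        np.testing.assert_array_equal(v1, v2)


class TestSkeleton:
    def test_planted_strip_slope_recovery(self):
        rs = []
        for rep in range(30):
            spec = CohortSpec(n_patients=120, n_controls=4, seed=400 + rep,
                              beta_crp_ad=-0.6)
            sub = generate_subject_table(spec)
            panel, edges, strip = generate_skeleton_panel(spec, sub)
            pat = (sub["group"] == "MDD").to_numpy()
            x = sub["crp_z"][pat].to_numpy()
            strip_mean = panel[pat, strip].mean(1)
            rs.append(np.corrcoef(strip_mean, x)[0, 1])
        assert np.mean(rs) == pytest.approx(-0.6, abs=0.1)

    def test_null_build_and_determinism(self):
        spec = CohortSpec(n_patients=120, n_controls=4, seed=31,
                          beta_crp_ad=0.0)
        sub = generate_subject_table(spec)
        p1, e1, s1 = generate_skeleton_panel(spec, sub)
        p2, _, _ = generate_skeleton_panel(spec, sub)
        np.testing.assert_array_equal(p1, p2)
        pat = (sub["group"] == "MDD").to_numpy()
        r = np.corrcoef(p1[pat, s1].mean(1), sub["crp_z"][pat])[0, 1]
        assert abs(r) < 0.2
        assert e1 == [(i, i + 1) for i in range(p1.shape[1] - 1)]


class TestExpression:
    def test_matrix_shape_and_no_missing(self, small_atlas):
        expr, cats, pheno = generate_expression(small_atlas, n_genes=150,
                                                seed=0)
        assert expr.shape == (60, 150)
        assert expr.notna().all().all()
        assert cats["category_id"].nunique() >= 20

    def test_planted_genes_approach_phenotype_as_noise_vanishes(
            self, small_atlas):
        expr, cats, pheno = generate_expression(
            small_atlas, n_genes=100, planted_noise_sd=1e-8, seed=1)
        planted = cats.loc[cats["category_id"] == "planted", "gene_id"]
        z = (pheno - pheno.mean()) / pheno.std()
        for g in planted:
            r = np.corrcoef(expr[g], z)[0, 1]
            assert r == pytest.approx(1.0, abs=1e-6)

    def test_non_planted_genes_uncorrelated_on_average(self, small_atlas):
        rs = []
        for rep in range(10):
            expr, cats, pheno = generate_expression(small_atlas,
                                                    n_genes=100,
                                                    seed=100 + rep)
            planted = set(cats.loc[cats["category_id"] == "planted",
                                   "gene_id"])
            others = [g for g in expr.columns if g not in planted]
            z = (pheno - pheno.mean()) / pheno.std()
            rs.append(np.mean([np.corrcoef(expr[g], z)[0, 1]
                               for g in others]))
        assert np.mean(rs) == pytest.approx(0.0, abs=0.08)

    def test_gene_maps_are_spatially_autocorrelated(self, small_atlas):
        """Empirical variogram increases with distance up to the stated
        length scale."""
        from crpmap.spatial import variogram
        expr, _, _ = generate_expression(small_atlas, n_genes=60,
                                         length_scale=30.0, seed=2)
        sv = np.mean([variogram(expr[g].to_numpy(),
                                small_atlas.centroids)[1]
                      for g in expr.columns], axis=0)
        assert sv[0] < sv[2] < sv[-1]


class TestAtlasAndAnnotations:
    def test_atlas_regions_nonempty_and_valid(self, small_atlas):
        small_atlas.validate()
        assert small_atlas.n_regions == 60

    def test_planted_annotation_correlation(self, small_atlas):
        from crpmap.synthetic import _grf
        pheno = _grf(small_atlas.centroids, 1, 30.0,
                     np.random.default_rng(7))[0]
        rs = []
        for rep in range(20):
            maps = generate_annotation_maps(
                small_atlas, k_maps=5, planted={"hit": 0.6},
                phenotype=pheno, seed=rep)
            rs.append(np.corrcoef(maps["hit"], pheno)[0, 1])
        assert np.mean(rs) == pytest.approx(0.6, abs=0.1)

    def test_annotation_determinism(self, small_atlas):
        from crpmap.synthetic import _grf
        pheno = _grf(small_atlas.centroids, 1, 30.0,
                     np.random.default_rng(7))[0]
        m1 = generate_annotation_maps(small_atlas, 4, {"hit": 0.3}, pheno,
                                      seed=5)
        m2 = generate_annotation_maps(small_atlas, 4, {"hit": 0.3}, pheno,
                                      seed=5)
        pd.testing.assert_frame_equal(m1, m2)
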