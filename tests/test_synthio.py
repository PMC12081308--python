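"""Generator properties: determinism, truth completeness, null behavior and
statistical fidelity of the simulated data."""

import numpy as np
import pandas as pd
import pytest

from trophoflux.synthio import (
    ImageConfig,
    MetabConfig,
    MsConfig,
    ReferenceConfig,
    ScConfig,
    ScPopulation,
    SimConfig,
)
from trophoflux.synthio.image import gen_aggregate_image
from trophoflux.synthio.metab import gen_metabolomics_table
from trophoflux.synthio.ms import gen_histone_peak_table
from trophoflux.synthio.reference import gen_reference_embedding
from trophoflux.synthio.sc import gen_sc_dataset


class TestDeterminism:
    def test_ms_same_seed_identical_tables(self):
        cfg = SimConfig(seed=5)
        t1, _ = gen_histone_peak_table(cfg)
        t2, _ = gen_histone_peak_table(SimConfig(seed=5))
        pd.testing.assert_frame_equal(t1, t2)
        t3, _ = gen_histone_peak_table(SimConfig(seed=6))
        assert not t1["area"].equals(t3["area"])

    def test_sc_same_seed_identical(self):
        a1, h1, tr1 = gen_sc_dataset(SimConfig(seed=5))
        a2, h2, tr2 = gen_sc_dataset(SimConfig(seed=5))
        np.testing.assert_array_equal(np.asarray(a1.X), np.asarray(a2.X))
        pd.testing.assert_frame_equal(h1, h2)

    def test_image_same_seed_identical(self):
        s1, _ = gen_aggregate_image(SimConfig(seed=5))
        s2, _ = gen_aggregate_image(SimConfig(seed=5))
        np.testing.assert_array_equal(s1.channels["polarity"], s2.channels["polarity"])
        np.testing.assert_array_equal(s1.nuclei, s2.nuclei)

    def test_reference_same_seed_identical(self):
        e1 = gen_reference_embedding(SimConfig(seed=5))
        e2 = gen_reference_embedding(SimConfig(seed=5))
        np.testing.assert_array_equal(e1.ref_points, e2.ref_points)


class TestMsGenerator:
    def test_null_config_treated_equals_control(self):
        cfg = SimConfig(seed=9, ms=MsConfig(noise_cv=0.0, spikein_cv=0.0, label_fractions=0.0))
        t, truth = gen_histone_peak_table(cfg)
        ctrl = t[t["sample"] == "ctrl_1"].drop(columns="sample").reset_index(drop=True)
        trt = t[t["sample"] == "treated_1"].drop(columns="sample").reset_index(drop=True)
        pd.testing.assert_frame_equal(ctrl, trt)

    def test_truth_covers_every_singly_acetylated_form(self):
        t, truth = gen_histone_peak_table(SimConfig(seed=9))
        forms = t[(t["ms_level"] == 1) & ~t["heavy_flag"]][["peptide", "mods"]].drop_duplicates()
        singly = forms[forms["mods"].str.count("ac") == 1]
        assert set(map(tuple, singly.to_numpy())) == set(truth["label_fractions"])

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError):
            MsConfig(noise_cv=-0.1)

    def test_unknown_modification_rejected(self):
        cfg = SimConfig(seed=9, ms=MsConfig(peptidoforms=(("KSTGGKAPR", 8, "K9ub"),)))
        with pytest.raises(Exception, match="ub"):
            gen_histone_peak_table(cfg)

    def test_heavy_standards_in_every_sample(self):
        t, _ = gen_histone_peak_table(SimConfig(seed=9))
        per_sample = t[t["heavy_flag"]].groupby("sample").size()
        assert (per_sample > 0).all() and per_sample.nunique() == 1


class TestScGenerator:
    def test_zero_doublet_rate_truth_has_no_doublets(self):
        cfg = SimConfig(seed=9, sc=ScConfig(doublet_rate=0.0))
        _, _, truth = gen_sc_dataset(cfg)
        assert not truth["is_doublet"].any()

    def test_truth_complete_one_record_per_barcode(self):
        adata, hto, truth = gen_sc_dataset(SimConfig(seed=9))
        assert list(adata.obs_names) == list(truth.index) == list(hto.columns)
        assert truth.index.is_unique

    def test_per_gene_mean_matches_configuration(self):
        cfg = SimConfig(
            seed=9,
            sc=ScConfig(
                populations=(ScPopulation("p", 10000, "A0251"),),
                doublet_rate=0.0,
                n_genes=600,
                mean_depth=6000.0,
            ),
        )
        adata, _, _ = gen_sc_dataset(cfg)
        emp = np.asarray(adata.X).mean(axis=0)
        cfgd = adata.var["true_mean"].to_numpy()
        sel = cfgd >= 1.0
        assert sel.sum() > 100
        np.testing.assert_allclose(emp[sel], cfgd[sel], rtol=0.05)

    def test_delta_zero_populations_indistinguishable(self):
        cfg = SimConfig(
            seed=9,
            sc=ScConfig(
                populations=(
                    ScPopulation("a", 300, "A0251", {"pTE": 0.0}),
                    ScPopulation("b", 300, "A0252", {"mTE": 0.0}),
                ),
                doublet_rate=0.0,
            ),
        )
        from sklearn.metrics import roc_auc_score

        from trophoflux import sc

        adata, _, truth = gen_sc_dataset(cfg)
        expr = sc.log_normalize(adata)
        auc = roc_auc_score(truth["population"] == "a", sc.maturity_score(expr))
        assert abs(auc - 0.5) < 0.06

    def test_unknown_signature_rejected(self):
        cfg = SimConfig(
            seed=9,
            sc=ScConfig(populations=(ScPopulation("a", 10, "A0251", {"nope": 1.0}),)),
        )
        with pytest.raises(ValueError, match="nope"):
            gen_sc_dataset(cfg)

    def test_mito_fraction_tracks_beta_truth(self):
        adata, _, truth = gen_sc_dataset(SimConfig(seed=9))
        counts = np.asarray(adata.X)
        mito = adata.var["mito"].to_numpy()
        emp = counts[:, mito].sum(axis=1) / counts.sum(axis=1)
        singlet = ~truth["is_doublet"].to_numpy()
        assert np.corrcoef(emp[singlet], truth["true_mito_fraction"][singlet])[0, 1] > 0.95


class TestImageGenerator:
    def test_unit_enrichment_uniform_inside(self):
        scene, _ = gen_aggregate_image(
            SimConfig(seed=9, image=ImageConfig(apical_enrichment=1.0, noise_sd=0.0))
        )
        inside = scene.channels["polarity"][scene.mask()]
        assert np.unique(inside).size == 1

    def test_rim_mean_ratio_exact_by_construction(self):
        scene, truth = gen_aggregate_image(
            SimConfig(seed=9, image=ImageConfig(apical_enrichment=3.0, noise_sd=0.0))
        )
        img = scene.channels["polarity"]
        rim = truth["rim_mask"]
        other = scene.mask() & ~rim & ~(scene.nuclei > 0)
        assert img[rim].mean() / img[other].mean() == pytest.approx(3.0, abs=1e-12)

    def test_every_nucleus_has_a_layer_truth(self):
        scene, truth = gen_aggregate_image(SimConfig(seed=9))
        labels = set(np.unique(scene.nuclei)) - {0}
        assert set(truth["layers"]) == labels

    def test_impossible_packing_fails_after_bounded_retries(self):
        cfg = SimConfig(
            seed=9,
            image=ImageConfig(n_inner=200, max_retries=50),
        )
        with pytest.raises(RuntimeError, match="retries|tries"):
            gen_aggregate_image(cfg)


class TestMetabGenerator:
    def test_noise_free_area_over_concentration_constant(self):
        cfg = SimConfig(
            seed=9, metab=MetabConfig(noise_cv=0.0, sample_factor_cv=0.0, fold_changes=1.0)
        )
        tables, truth = gen_metabolomics_table(cfg)
        t = tables["analytes"]
        conc = truth["concentrations"]
        for analyte, grp in t.groupby("analyte"):
            ratio = grp["area"].to_numpy() / conc.loc[grp["sample"], analyte].to_numpy()
            np.testing.assert_allclose(ratio, ratio[0], rtol=1e-12)

    def test_configured_fold_change_exact_without_noise(self):
        cfg = SimConfig(
            seed=9, metab=MetabConfig(noise_cv=0.0, sample_factor_cv=0.0, fold_changes=2.0)
        )
        tables, truth = gen_metabolomics_table(cfg)
        t = tables["analytes"]
        means = t.groupby(["analyte", "group"])["area"].mean().unstack()
        np.testing.assert_allclose(means["4mM"] / means["0mM"], 2.0, rtol=1e-12)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            MetabConfig(base_concentration=0.0)

    def test_area_ratio_cv_near_configured(self):
        cfg = SimConfig(
            seed=9,
            metab=MetabConfig(n_analytes=500, noise_cv=0.10, sample_factor_cv=0.3, fold_changes=1.0),
        )
        tables, _ = gen_metabolomics_table(cfg)
        from trophoflux.metabolomics import is_normalize

        norm = is_normalize(tables["analytes"], tables["is_map"], tables["internal_standards"])
        cvs = norm.groupby("analyte")["normalized_area"].apply(lambda v: v.std() / v.mean())
        # analyte/IS ratio carries two independent CV-0.10 noise terms
        expected = np.sqrt(2) * 0.10
        assert np.median(cvs) == pytest.approx(expected, rel=0.20)


class TestReferenceGenerator:
    def test_well_separated_clusters_neighbors_share_stage(self):
        cfg = SimConfig(
            seed=9, reference=ReferenceConfig(cluster_sd=0.5, centroid_spacing=50.0)
        )
        emb = gen_reference_embedding(cfg)
        for q, stage in zip(emb.query_points, emb.query_truth):
            d = np.linalg.norm(emb.ref_points - q, axis=1)
            nearest = np.argsort(d, kind="stable")[:3]
            assert all(emb.ref_labels[i] == stage for i in nearest)

    def test_single_stage_all_assignments_that_label(self):
        from trophoflux import sc

        cfg = SimConfig(seed=9, reference=ReferenceConfig(stages=("E6",)))
        emb = gen_reference_embedding(cfg)
        out = sc.nhood_stage_knn(emb.ref_points, emb.ref_labels, emb.query_points)
        assert set(out) == {"E6"}

    def test_reference_smaller_than_k_rejected(self):
        cfg = SimConfig(seed=9, reference=ReferenceConfig(stages=("E6",), n_per_stage=2))
        with pytest.raises(ValueError):
            gen_reference_embedding(cfg)
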