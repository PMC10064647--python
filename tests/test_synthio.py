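import dataclasses

import numpy as np
import pandas as pd
import pytest

from epirepress import methylome as me, synthio
from epirepress.methylome import REGULATORY_REGIONS


class TestConfigValidation:
    def test_fraction_bounds(self):
        with pytest.raises(ValueError, match="frac_hyper_probes"):
            synthio.SynthConfig(frac_hyper_probes=1.2)

    def test_hyper_plus_hypo_capped(self):
        with pytest.raises(ValueError, match="≤ 1"):
            synthio.SynthConfig(frac_hyper_probes=0.7, frac_hypo_probes=0.5)

    def test_set_size_range_within_universe(self):
        with pytest.raises(ValueError, match="gene universe"):
            synthio.SynthConfig(n_genes=50, set_size_range=(20, 80))


class TestMethylationDataset:
    def test_nothing_planted_when_fractions_zero(self):
        cfg = synthio.SynthConfig(seed=1, n_probes=500, n_genes=100,
                                  frac_hyper_probes=0, frac_hypo_probes=0,
                                  n_repressed_genes=0)
        *_, truth = synthio.make_methylation_dataset(cfg)
        assert not truth.hyper_probe_ids and not truth.hypo_probe_ids
        assert not truth.repressed_gene_ids

    def test_planted_counts_exact(self):
        cfg = synthio.SynthConfig(seed=2, n_probes=1000, n_genes=200,
                                  frac_hyper_probes=0.1, frac_hypo_probes=0.02,
                                  n_repressed_genes=20)
        *_, truth = synthio.make_methylation_dataset(cfg)
        assert len(truth.hyper_probe_ids) == 100
        assert len(truth.hypo_probe_ids) == 20

    def test_determinism(self, small_cfg):
        M1, U1, d1, a1, t1 = synthio.make_methylation_dataset(small_cfg)
        M2, U2, d2, a2, t2 = synthio.make_methylation_dataset(small_cfg)
        pd.testing.assert_frame_equal(M1, M2)
        pd.testing.assert_frame_equal(U1, U2)
        pd.testing.assert_frame_equal(d1, d2)
        assert t1.hyper_probe_ids == t2.hyper_probe_ids

    def test_intensities_recover_intended_beta(self, meth_dataset):
        M, U, _, _, truth = meth_dataset
        beta = (M / (M + U)).to_numpy()
        assert ((beta >= 0) & (beta <= 1)).all()

    def test_marginal_beta_is_bimodal(self, meth_dataset):
        M, U, *_ = meth_dataset
        beta = (M / (M + U)).to_numpy().ravel()
        hist, edges = np.histogram(beta, bins=20, range=(0, 1))
        centers = (edges[:-1] + edges[1:]) / 2
        top_two = centers[np.argsort(hist)[-2:]]
        assert min(top_two) <= 0.25 and max(top_two) >= 0.75

    def test_every_repressed_gene_has_regulatory_hyper_plant(self, meth_dataset):
        *_, ann, truth = meth_dataset
        assign = ann.assignments
        hyper_reg = assign[assign["probe_id"].isin(truth.hyper_probe_ids)
                           & assign["region"].isin(["promoter", "enhancer"])]
        assert truth.repressed_gene_ids <= set(hyper_reg["gene_id"])

    def test_oversized_effect_rejected(self):
        cfg = synthio.SynthConfig(seed=3, n_probes=500, n_genes=100,
                                  n_repressed_genes=5, planted_delta_beta=0.99)
        with pytest.raises(ValueError, match="outside"):
            synthio.make_methylation_dataset(cfg)

    def test_failed_probes_fail_detection(self, meth_dataset):
        _, _, det, _, truth = meth_dataset
        failing = det.gt(0.05).any(axis=1)
        assert failing.sum() > 0
        assert not (set(det.index[failing]) & (truth.hyper_probe_ids | truth.hypo_probe_ids))


class TestExpressionDataset:
    def test_null_fold_change_means_match(self):
        cfg = synthio.SynthConfig(seed=4, n_probes=100, n_genes=2000, expr_log2fc=0.0,
                                  n_repressed_genes=5)
        *_, truth = synthio.make_methylation_dataset(cfg)
        expr = synthio.make_expression_dataset(cfg, truth)
        log2 = np.log2(expr + 1)
        diff = log2.iloc[:, 3:].mean(axis=1) - log2.iloc[:, :3].mean(axis=1)
        assert abs(diff.mean()) < 0.02

    def test_planted_halving_of_case_mean(self):
        cfg = synthio.SynthConfig(seed=5, n_probes=2000, n_genes=3000, expr_log2fc=1.0,
                                  n_repressed_genes=50)
        *_, truth = synthio.make_methylation_dataset(cfg)
        expr = synthio.make_expression_dataset(cfg, truth)
        rep = sorted(truth.repressed_gene_ids)
        ratio = expr.loc[rep].iloc[:, 3:].mean(axis=1) / expr.loc[rep].iloc[:, :3].mean(axis=1)
        # 2^-1 halving, Monte-Carlo tolerance over 50 genes
        assert ratio.mean() == pytest.approx(0.5, rel=0.05)
        other = expr.drop(index=rep)
        ratio0 = other.iloc[:, 3:].mean(axis=1) / other.iloc[:, :3].mean(axis=1)
        assert ratio0.mean() == pytest.approx(1.0, rel=0.05)

    def test_nonnegative(self, small_cfg, meth_dataset):
        expr = synthio.make_expression_dataset(small_cfg, meth_dataset[-1])
        assert (expr.to_numpy() >= 0).all()


class TestGeneSets:
    def test_sizes_within_range(self, small_cfg, meth_dataset):
        sets = synthio.make_gene_sets(small_cfg, meth_dataset[-1])
        lo, hi = small_cfg.set_size_range
        assert all(lo <= len(s.genes) <= hi for s in sets)
        assert len(sets) == small_cfg.n_gene_sets

    def test_full_enrichment_means_all_members_planted(self):
        cfg = synthio.SynthConfig(seed=6, n_probes=2000, n_genes=300,
                                  n_repressed_genes=80, causal_enrichment=1.0,
                                  set_size_range=(10, 40))
        *_, truth = synthio.make_methylation_dataset(cfg)
        sets = synthio.make_gene_sets(cfg, truth)
        for name in truth.causal_set_names:
            assert sets[name].genes <= truth.repressed_gene_ids

    def test_class_labels_present(self, small_cfg, meth_dataset):
        sets = synthio.make_gene_sets(small_cfg, meth_dataset[-1])
        assert {s.set_class for s in sets} == {"TSG-A", "OG-I"}


class TestCohort:
    def test_no_censoring_means_all_events(self):
        cfg = synthio.SynthConfig(seed=7, n_genes=200, censor_rate=0.0,
                                  set_size_range=(10, 50))
        expr, clinical, _ = synthio.make_cohort(cfg, ["g00001", "g00002"])
        assert (clinical["event"] == 1).all()

    def test_tiny_cohort_rejected(self):
        cfg = synthio.SynthConfig(seed=8, n_genes=200, n_patients=5,
                                  set_size_range=(10, 50))
        with pytest.raises(ValueError, match="n_patients"):
            synthio.make_cohort(cfg, ["g00001"])

    def test_empty_signature_rejected(self):
        cfg = synthio.SynthConfig(seed=8, n_genes=200, set_size_range=(10, 50))
        with pytest.raises(ValueError, match="nonempty"):
            synthio.make_cohort(cfg, [])

    def test_score_sign_bookkeeping(self):
        # negative loading: high latent score -> low expression -> high computed score
        from epirepress.signature import signature_score
        from scipy.stats import spearmanr
        cfg = synthio.SynthConfig(seed=9, n_genes=200, n_patients=150,
                                  cohort_loading=-0.5, set_size_range=(10, 50))
        genes = [f"g{i:05d}" for i in range(20)]
        expr, _, latent = synthio.make_cohort(cfg, genes)
        score = signature_score(np.log2(expr + 1), genes).scores
        rho, _ = spearmanr(score.to_numpy(), latent.to_numpy())
        assert rho > 0.5

    def test_determinism(self):
        cfg = synthio.SynthConfig(seed=10, n_genes=200, set_size_range=(10, 50))
        a = synthio.make_cohort(cfg, ["g00001"])
        b = synthio.make_cohort(cfg, ["g00001"])
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])
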