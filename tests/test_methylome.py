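import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from epirepress import methylome as me
from epirepress.methylome import BetaMatrix, ProbeAnnotation


def _ann(probe_ids, design="I", chrom="chr1", cross=False, snp=False):
    n = len(probe_ids)
    probes = pd.DataFrame({
        "design_type": [design] * n if isinstance(design, str) else design,
        "chrom": [chrom] * n if isinstance(chrom, str) else chrom,
        "cross_reactive": [cross] * n if isinstance(cross, bool) else cross,
        "snp_overlap": [snp] * n if isinstance(snp, bool) else snp,
    }, index=pd.Index(probe_ids, name="probe_id"))
    assignments = pd.DataFrame({"probe_id": probe_ids, "gene_id": "gX", "region": "promoter"})
    return ProbeAnnotation(probes, assignments)


class TestComputeBeta:
    @pytest.mark.parametrize("m,u,expected", [(100, 100, 0.5), (0, 500, 0.0), (300, 100, 0.75)])
    def test_beta_arithmetic(self, m, u, expected):
        M = pd.DataFrame({"s1": [float(m)], "s2": [float(m)]}, index=["p1"])
        U = pd.DataFrame({"s1": [float(u)], "s2": [float(u)]}, index=["p1"])
        bm = me.compute_beta(M, U, {"s1": "control", "s2": "case"})
        assert bm.values.iloc[0, 0] == pytest.approx(expected)

    def test_zero_total_is_missing(self):
        M = pd.DataFrame({"s1": [0.0], "s2": [1.0]}, index=["p1"])
        U = pd.DataFrame({"s1": [0.0], "s2": [1.0]}, index=["p1"])
        bm = me.compute_beta(M, U, {"s1": "control", "s2": "case"})
        assert np.isnan(bm.values.loc["p1", "s1"])
        assert bm.values.loc["p1", "s2"] == pytest.approx(0.5)

    def test_negative_intensity_rejected(self):
        M = pd.DataFrame({"s1": [-1.0], "s2": [1.0]}, index=["p1"])
        U = pd.DataFrame({"s1": [1.0], "s2": [1.0]}, index=["p1"])
        with pytest.raises(ValueError, match="negative"):
            me.compute_beta(M, U, {"s1": "control", "s2": "case"})


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.floats(min_value=1e-5, max_value=1 - 1e-5))
def test_beta_m_round_trip(beta):
    assert me.m_to_beta(me.beta_to_m(np.array([beta])))[0] == pytest.approx(beta, abs=1e-9)


class TestFilterProbes:
    def _beta(self, probe_ids, n_samples=4):
        cols = [f"s{i}" for i in range(n_samples)]
        vals = pd.DataFrame(0.5, index=probe_ids, columns=cols)
        cond = pd.Series(["control", "control", "case", "case"], index=cols)
        return BetaMatrix(vals, cond)

    def test_sex_chromosome_probe_removed_despite_perfect_detection(self):
        ids = ["p1", "p2"]
        ann = _ann(ids, chrom=["chrX", "chr2"])
        det = pd.DataFrame(0.001, index=ids, columns=[f"s{i}" for i in range(4)])
        kept, log = me.filter_probes(self._beta(ids), ann, det)
        assert list(kept.values.index) == ["p2"]
        assert log.set_index("probe_id").loc["p1", "reason"] == "sex_chromosome"

    def test_clean_autosomal_probe_retained(self):
        ids = ["p1"]
        det = pd.DataFrame(0.01, index=ids, columns=[f"s{i}" for i in range(4)])
        kept, _ = me.filter_probes(self._beta(ids), _ann(ids), det)
        assert list(kept.values.index) == ["p1"]

    def test_toy_counting(self):
        # 10 probes: 2 cross-reactive, 1 on chrY, 1 failing detection -> 6 retained
        ids = [f"p{i}" for i in range(10)]
        ann = _ann(ids,
                   chrom=["chr1"] * 9 + ["chrY"],
                   cross=[True, True] + [False] * 8)
        det = pd.DataFrame(0.01, index=ids, columns=[f"s{i}" for i in range(4)])
        det.loc["p5", "s2"] = 0.2
        kept, log = me.filter_probes(self._beta(ids), ann, det)
        assert len(kept.values) == 6
        assert set(log["reason"]) == {"detection", "cross_reactive", "sex_chromosome"}

    def test_unannotated_probe_is_an_error(self):
        ids = ["p1", "p2"]
        ann = _ann(["p1"])
        det = pd.DataFrame(0.01, index=ids, columns=[f"s{i}" for i in range(4)])
        with pytest.raises(ValueError, match="p2"):
            me.filter_probes(self._beta(ids), ann, det)


class TestPeakCorrect:
    def test_identical_type_distributions_are_unchanged(self):
        rng = np.random.default_rng(0)
        base = np.concatenate([rng.beta(3, 19, 200), rng.beta(19, 3, 200)])
        vals = np.stack([base, base], axis=1)  # type I and II interleaved below
        ids = [f"p{i}" for i in range(800)]
        beta = pd.DataFrame(np.concatenate([vals, vals]),
                            index=ids, columns=["s1", "s2"])
        ann = _ann(ids, design=["I"] * 400 + ["II"] * 400)
        bm = BetaMatrix(beta, pd.Series({"s1": "control", "s2": "case"}))
        out = me.peak_correct(bm, ann)
        assert out.corrected
        np.testing.assert_allclose(out.values.to_numpy(), bm.values.to_numpy(), atol=1e-6)

    def test_rank_order_preserved_within_each_side(self):
        rng = np.random.default_rng(1)
        b1 = np.concatenate([rng.beta(3, 19, 150), rng.beta(19, 3, 150)])
        b2 = 0.5 + 0.8 * (np.concatenate([rng.beta(3, 19, 150), rng.beta(19, 3, 150)]) - 0.5)
        ids = [f"p{i}" for i in range(600)]
        beta = pd.DataFrame({"s1": np.concatenate([b1, b2]),
                             "s2": np.concatenate([b1, b2])}, index=ids)
        ann = _ann(ids, design=["I"] * 300 + ["II"] * 300)
        bm = BetaMatrix(beta, pd.Series({"s1": "control", "s2": "case"}))
        out = me.peak_correct(bm, ann)
        raw = beta["s1"].to_numpy()[300:]
        corr = out.values["s1"].to_numpy()[300:]
        for side in (raw < 0.5, raw > 0.5):
            order = np.argsort(raw[side])
            assert (np.diff(corr[side][order]) >= -1e-12).all()

    def test_too_few_probes_passes_through_with_warning(self):
        ids = [f"p{i}" for i in range(60)]
        beta = pd.DataFrame(0.3, index=ids, columns=["s1", "s2"])
        ann = _ann(ids, design=["I"] * 55 + ["II"] * 5)
        bm = BetaMatrix(beta, pd.Series({"s1": "control", "s2": "case"}))
        with pytest.warns(UserWarning, match="skipped"):
            out = me.peak_correct(bm, ann)
        np.testing.assert_array_equal(out.values.to_numpy(), bm.values.to_numpy())


def _beta_matrix(ctrl_rows, case_rows, probe_ids):
    ctrl = np.asarray(ctrl_rows, dtype=float)
    case = np.asarray(case_rows, dtype=float)
    cols = [f"c{i}" for i in range(ctrl.shape[1])] + [f"t{i}" for i in range(case.shape[1])]
    vals = pd.DataFrame(np.hstack([ctrl, case]), index=probe_ids, columns=cols)
    cond = pd.Series(["control"] * ctrl.shape[1] + ["case"] * case.shape[1], index=cols)
    return BetaMatrix(vals, cond, corrected=True)


class TestDiffMethylation:
    def test_identical_conditions_unchanged(self):
        bm = _beta_matrix([[0.4, 0.41, 0.4]], [[0.4, 0.41, 0.4]], ["p1"])
        dmc = me.diff_methylation(bm)
        assert dmc.loc["p1", "delta_beta"] == pytest.approx(0.0, abs=1e-12)
        assert dmc.loc["p1", "status"] == "unchanged"

    def test_hyper_call_above_threshold(self):
        bm = _beta_matrix([[0.30, 0.30, 0.301]], [[0.55, 0.549, 0.551]], ["p1"])
        dmc = me.diff_methylation(bm)
        assert dmc.loc["p1", "delta_beta"] == pytest.approx(0.25)
        assert dmc.loc["p1", "p_adj"] < 0.05
        assert dmc.loc["p1", "status"] == "hyper"

    def test_boundary_delta_exactly_at_threshold_is_unchanged(self):
        # Δβ hits the threshold exactly: the rule is strictly "above 0.2"
        bm = _beta_matrix([[0.0, 0.0, 0.00001]], [[0.19, 0.2, 0.21]], ["p1"])
        dmc = me.diff_methylation(bm)
        assert dmc.loc["p1", "delta_beta"] == 0.2
        assert dmc.loc["p1", "p_value"] < 0.05
        assert dmc.loc["p1", "status"] == "unchanged"

    def test_zero_variance_everywhere_gives_p_one(self):
        bm = _beta_matrix([[0.3, 0.3, 0.3], [0.3, 0.31, 0.29]],
                          [[0.8, 0.8, 0.8], [0.8, 0.81, 0.79]], ["flat", "noisy"])
        dmc = me.diff_methylation(bm)
        assert dmc.loc["flat", "p_value"] == 1.0
        assert dmc.loc["noisy", "p_value"] < 0.05

    def test_single_sample_condition_rejected(self):
        bm = _beta_matrix([[0.3]], [[0.5, 0.5, 0.5]], ["p1"])
        with pytest.raises(ValueError, match="≥2 samples"):
            me.diff_methylation(bm)

    def test_bh_adjustment_dominates_raw_p(self):
        rng = np.random.default_rng(2)
        bm = _beta_matrix(rng.uniform(0.2, 0.8, (50, 3)), rng.uniform(0.2, 0.8, (50, 4)),
                          [f"p{i}" for i in range(50)])
        dmc = me.diff_methylation(bm)
        assert (dmc["p_adj"] >= dmc["p_value"] - 1e-15).all()
        ordered = dmc.sort_values("p_value")
        assert (np.diff(ordered["p_adj"].to_numpy()) >= -1e-12).all()


class TestSummarizeDmc:
    @pytest.mark.parametrize("n_hyper,n_hypo,pct_hyper,pct_hypo", [
        (41431, 47578 - 41431, 87.1, 12.9),
        (79419, 90441 - 79419, 87.8, 12.2),
    ])
    def test_percentage_accounting(self, n_hyper, n_hypo, pct_hyper, pct_hypo):
        dmc = pd.DataFrame({"status": ["hyper"] * n_hyper + ["hypo"] * n_hypo})
        s = me.summarize_dmc(dmc)
        assert (s.n_dmc, s.pct_hyper, s.pct_hypo) == (n_hyper + n_hypo, pct_hyper, pct_hypo)

    def test_empty_table_no_division_error(self):
        s = me.summarize_dmc(pd.DataFrame({"status": []}))
        assert (s.n_dmc, s.pct_hyper, s.pct_hypo) == (0, 0.0, 0.0)
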