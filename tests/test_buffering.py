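"""NB contrasts, ratio-method half-life, direction labels, categorization."""

import numpy as np
import pandas as pd
import pytest

from ratebuffer import buffering as bf
from ratebuffer import simdata as sd


def _records(gene_ids, log2fc, lfcse=0.1, padj=0.01, contrast="TR", pvalue=None):
    log2fc = np.broadcast_to(np.asarray(log2fc, float), (len(gene_ids),))
    return pd.DataFrame({
        "gene_id": gene_ids, "contrast": contrast, "log2fc": log2fc,
        "lfcse": np.broadcast_to(np.asarray(lfcse, float), (len(gene_ids),)),
        "pvalue": np.broadcast_to(np.asarray(pvalue if pvalue is not None else padj,
                                             float), (len(gene_ids),)),
        "padj": np.broadcast_to(np.asarray(padj, float), (len(gene_ids),)),
    })


class TestNbLog2fc:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        a = pd.DataFrame(rng.poisson(500, (200, 3)), index=[f"g{i}" for i in range(200)])
        out = bf.nb_log2fc(a, a.copy())
        assert out["log2fc"].abs().max() < 1e-9
        assert (out["pvalue"] > 0.99).all()

    def test_min_counts_filter(self):
        a = pd.DataFrame({"a1": [4, 100], "a2": [4, 100]}, index=["low", "hi"])
        b = pd.DataFrame({"b1": [4, 100], "b2": [5, 100]}, index=["low", "hi"])
        out = bf.nb_log2fc(a, b, min_counts=20)
        assert list(out["gene_id"]) == ["hi"]

    def test_needs_two_replicates(self):
        a = pd.DataFrame({"a1": [10]}, index=["g"])
        with pytest.raises(ValueError):
            bf.nb_log2fc(a, a.copy())

    def test_poisson_type_one_error_calibrated(self):
        """Nominal 0.05 test rejects 3-7% of 5000 null Poisson genes."""
        rng = np.random.default_rng(11)
        n = 5000
        idx = [f"g{i}" for i in range(n)]
        a = pd.DataFrame(rng.poisson(500, (n, 4)), index=idx,
                         columns=[f"a{i}" for i in range(4)])
        b = pd.DataFrame(rng.poisson(500, (n, 4)), index=idx,
                         columns=[f"b{i}" for i in range(4)])
        out = bf.nb_log2fc(a, b)
        assert 0.03 <= (out["pvalue"] < 0.05).mean() <= 0.07

    def test_true_fc_recovered_with_coverage(self):
        rng = np.random.default_rng(12)
        n = 2000
        idx = [f"g{i}" for i in range(n)]
        a = pd.DataFrame(rng.poisson(500, (n, 4)), index=idx,
                         columns=[f"a{i}" for i in range(4)])
        b = pd.DataFrame(rng.poisson(1000, (n, 4)), index=idx,
                         columns=[f"b{i}" for i in range(4)])
        out = bf.nb_log2fc(a, b)
        cover = ((out["log2fc"] - 1.96 * out["lfcse"] <= 1.0)
                 & (out["log2fc"] + 1.96 * out["lfcse"] >= 1.0))
        assert cover.mean() > 0.90
        assert out["log2fc"].mean() == pytest.approx(1.0, abs=0.02)

    def test_padj_monotone_and_at_least_pvalue(self):
        rng = np.random.default_rng(13)
        a = pd.DataFrame(rng.poisson(100, (300, 2)), index=[f"g{i}" for i in range(300)])
        b = pd.DataFrame(rng.poisson(120, (300, 2)), index=a.index)
        out = bf.nb_log2fc(a, b).sort_values("pvalue")
        assert (out["padj"].to_numpy() >= out["pvalue"].to_numpy()).all()
        assert (np.diff(out["padj"].to_numpy()) >= -1e-12).all()


class TestRatioHalfLife:
    def test_decomposition_identity(self):
        """log2FC_SS = log2FC_TR + log2FC_HL holds exactly by construction."""
        genes = [f"g{i}" for i in range(10)]
        rng = np.random.default_rng(1)
        ss = _records(genes, rng.normal(0, 1, 10), contrast="SS")
        tr = _records(genes, rng.normal(0, 1, 10), contrast="TR")
        hl = bf.ratio_half_life_fc(ss, tr)
        np.testing.assert_allclose(
            ss["log2fc"].to_numpy(),
            tr["log2fc"].to_numpy() + hl["log2fc"].to_numpy(), atol=1e-12)

    def test_worked_example(self):
        ss = _records(["g"], 0.2, lfcse=0.3, contrast="SS")
        tr = _records(["g"], 1.5, lfcse=0.4, contrast="TR")
        hl = bf.ratio_half_life_fc(ss, tr)
        assert hl["log2fc"][0] == pytest.approx(-1.3)
        assert hl["lfcse"][0] == pytest.approx(0.5)

    def test_missing_gene_skipped(self):
        ss = _records(["g1", "g2"], 1.0, contrast="SS")
        tr = _records(["g1"], 0.5, contrast="TR")
        hl = bf.ratio_half_life_fc(ss, tr)
        assert list(hl["gene_id"]) == ["g1"]


class TestZfc:
    def test_arithmetic(self):
        assert bf.z_fc(1.3, 0.25, 0.6) == pytest.approx(2.0)

    def test_zero_fc(self):
        assert bf.z_fc(0.0, 0.2, 0.3) == 0.0

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError):
            bf.z_fc(1.0, 0.0, 0.5)

    def test_null_distribution_half_normal(self):
        """Z_FC over simulated no-change NB genes follows a half-normal."""
        from scipy import stats

        rng = np.random.default_rng(21)
        n, reps = 3000, 8
        mu, disp = 800.0, 0.02  # the generator's count-noise model
        size, pnb = 1.0 / disp, (1.0 / disp) / (1.0 / disp + mu)
        idx = [f"g{i}" for i in range(n)]

        def draw(prefix):
            return pd.DataFrame(rng.negative_binomial(size, pnb, (n, reps)),
                                index=idx,
                                columns=[f"{prefix}{i}" for i in range(reps)])

        ss = bf.nb_log2fc(draw("a"), draw("b"), contrast="SS")
        tr = bf.nb_log2fc(draw("c"), draw("d"), contrast="TR")
        hl = bf.ratio_half_life_fc(ss, tr)
        z = (hl["log2fc"].abs() / hl["lfcse"]).to_numpy()
        _, p = stats.kstest(z, lambda x: 2 * stats.norm.cdf(x) - 1)
        assert p > 0.01


class TestDirectionLabels:
    def test_human_thresholds(self):
        genes = ["a", "b", "c"]
        tr = _records(genes, [1.2, 1.2, -0.5], padj=0.05)
        hl = _records(genes, [0.0, 0.0, 0.0], contrast="HL")
        lab = bf.assign_direction_labels(tr, hl, mode="human").set_index("gene_id")
        assert lab.loc["a", "tr_label"] == "up"
        assert lab.loc["c", "tr_label"] == "not"  # below threshold

    def test_hl_label_needs_zfc_above_median(self):
        genes = [f"g{i}" for i in range(10)]
        # gene 0 has |fc| > 1 but a z_fc (0.5) below the table median (2.0)
        fc = np.array([1.5] + [0.2] * 9)
        se = np.array([3.0] + [0.1] * 9)
        hl = pd.DataFrame({"gene_id": genes, "contrast": "HL", "log2fc": fc,
                           "lfcse": se, "pvalue": 0.5, "padj": 0.5})
        tr = _records(genes, 0.0, padj=1.0)
        lab = bf.assign_direction_labels(tr, hl, mode="human").set_index("gene_id")
        assert lab.loc["g0", "hl_label"] == "not"

    def test_transite_threshold_is_half(self):
        genes = ["a"]
        tr = _records(genes, 0.7, padj=0.01)
        hl = _records(genes, 0.0, contrast="HL")
        lab_t = bf.assign_direction_labels(tr, hl, mode="transite").set_index("gene_id")
        lab_h = bf.assign_direction_labels(tr, hl, mode="human").set_index("gene_id")
        assert lab_t.loc["a", "tr_label"] == "up"
        assert lab_h.loc["a", "tr_label"] == "not"

    def test_unknown_mode(self):
        tr = _records(["a"], 1.0)
        with pytest.raises(ValueError):
            bf.assign_direction_labels(tr, tr, mode="zebrafish")


class TestCategorize:
    def _triple(self, tr_fc, tr_p, ss_fc, ss_p, hl_fc, hl_se=0.1, n_pad=30):
        """One focal gene plus null padding genes to anchor the Z_FC median."""
        genes = ["focal"] + [f"pad{i}" for i in range(n_pad)]
        tr = _records(genes, [tr_fc] + [0.0] * n_pad,
                      padj=np.array([tr_p] + [1.0] * n_pad))
        ss = _records(genes, [ss_fc] + [0.0] * n_pad, contrast="SS",
                      padj=np.array([ss_p] + [1.0] * n_pad))
        hl = pd.DataFrame({"gene_id": genes, "contrast": "HL",
                           "log2fc": [hl_fc] + [0.01] * n_pad,
                           "lfcse": hl_se, "pvalue": 0.5, "padj": 0.5})
        table, _ = bf.categorize_buffering(tr, ss, hl)
        return table.set_index("gene_id").loc["focal", "category"]

    def test_tr_only_25pct_rule(self):
        assert self._triple(2.0, 0.01, 1.9, 0.01, -0.1) == "TR_only"

    def test_full_buffering(self):
        assert self._triple(2.0, 0.01, 0.05, 0.9, -2.0) == "full_buffered"

    def test_partial_buffering(self):
        assert self._triple(2.0, 0.01, 1.0, 0.01, -1.0) == "partial_buffered"

    def test_hl_only(self):
        assert self._triple(0.05, 0.9, 2.0, 0.01, 1.95) == "HL_only"

    def test_concordant(self):
        assert self._triple(1.5, 0.01, 3.0, 0.01, 1.5) == "concordant"

    def test_unchanged(self):
        assert self._triple(0.0, 0.9, 0.0, 0.9, 0.0) == "unchanged"

    def test_counts_invariant_to_gene_order(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(50)]
        tr = _records(genes, rng.normal(0, 2, 50), padj=rng.uniform(0, 1, 50))
        ss = _records(genes, rng.normal(0, 2, 50), contrast="SS",
                      padj=rng.uniform(0, 1, 50))
        hl = bf.ratio_half_life_fc(ss, tr)
        _, c1 = bf.categorize_buffering(tr, ss, hl)
        perm = rng.permutation(50)
        _, c2 = bf.categorize_buffering(tr.iloc[perm], ss.iloc[perm], hl.iloc[perm])
        pd.testing.assert_series_equal(c1, c2)


class TestMouseProxy:
    @pytest.fixture(scope="class")
    @staticmethod
    def proxy_setup():
        cfg = sd.SimConfig(n_genes=600, seed=17, depth=5e6,
                           hl_effect_log2=1.0, tr_effect_log2=1.0,
                           category_proportions={"HL_only": 0.3, "unchanged": 0.7})
        truth = sd.sample_gene_kinetics(cfg)
        return cfg, truth

    def test_identical_genotypes_interaction_zero(self):
        cfg = sd.SimConfig(n_genes=300, seed=18,
                           category_proportions={"unchanged": 1.0})
        truth = sd.sample_gene_kinetics(cfg)
        exp = sd.simulate_fraction_experiment(truth, cfg, n_replicates=6)
        from ratebuffer.pipeline import run_mouse_proxy_analysis, PipelineConfig

        res = run_mouse_proxy_analysis(exp, PipelineConfig(mode="mouse_proxy"))
        assert abs(res["hl"]["log2fc"].median()) < 0.1

    def test_planted_hl_shift_recovered(self, proxy_setup):
        cfg, truth = proxy_setup
        exp = sd.simulate_fraction_experiment(truth, cfg, n_replicates=10)
        from ratebuffer.pipeline import run_mouse_proxy_analysis, PipelineConfig

        res = run_mouse_proxy_analysis(exp, PipelineConfig(mode="mouse_proxy"))
        hl = res["hl"].set_index("gene_id")
        tru_a = truth[truth.genotype == "WT"].set_index("gene_id")
        tru_b = truth[truth.genotype == "MUT"].set_index("gene_id")
        d_hl = np.log2(tru_b["half_life_h"] / tru_a["half_life_h"])
        genes = hl.index[tru_a.loc[hl.index, "category"] == "HL_only"]
        cover = (np.abs(hl.loc[genes, "log2fc"] - d_hl.loc[genes])
                 <= 1.96 * hl.loc[genes, "lfcse"])
        assert cover.mean() >= 0.90

    def test_nuclear_and_chromatin_agree(self, proxy_setup):
        cfg, truth = proxy_setup
        out = {}
        for fraction in ("nuclear", "chromatin"):
            exp = sd.simulate_fraction_experiment(truth, cfg, fraction=fraction,
                                                  n_replicates=10)
            from ratebuffer.pipeline import run_mouse_proxy_analysis, PipelineConfig

            res = run_mouse_proxy_analysis(
                exp, PipelineConfig(mode="mouse_proxy", fraction=fraction))
            out[fraction] = res["hl"].set_index("gene_id")["log2fc"]
        genes = out["nuclear"].index.intersection(out["chromatin"].index)
        r = np.corrcoef(out["nuclear"].loc[genes], out["chromatin"].loc[genes])[0, 1]
        assert r > 0.9

    def test_missing_fraction_refused(self):
        cfg = sd.SimConfig(n_genes=50, seed=19)
        truth = sd.sample_gene_kinetics(cfg)
        exp = sd.simulate_fraction_experiment(truth, cfg, fraction="nuclear",
                                              n_replicates=3)
        from ratebuffer.pipeline import run_mouse_proxy_analysis, PipelineConfig

        with pytest.raises(ValueError, match="chromatin"):
            run_mouse_proxy_analysis(exp, PipelineConfig(mode="mouse_proxy",
                                                         fraction="chromatin"))
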