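"""Ground-truth generator: kinetic truth, counts, sequences, motifs, small RNA."""

import math

import numpy as np
import pandas as pd
import pytest

from ratebuffer import simdata as sd


class TestSimConfig:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(sd.ConfigurationError):
            sd.SimConfig(category_proportions={"unchanged": 0.5})

    def test_unknown_category_rejected(self):
        with pytest.raises(sd.ConfigurationError):
            sd.SimConfig(category_proportions={"mystery": 1.0})

    def test_timepoints_must_increase(self):
        with pytest.raises(sd.ConfigurationError):
            sd.SimConfig(timepoints_h=(1.0, 0.5))


class TestSampleGeneKinetics:
    def test_steady_state_identity(self, small_truth):
        """alpha / beta = Y_ss holds exactly for every truth row."""
        np.testing.assert_allclose(small_truth["alpha"] / small_truth["beta"],
                                   small_truth["y_ss"], rtol=1e-12)
        np.testing.assert_allclose(small_truth["half_life_h"],
                                   math.log(2) / small_truth["beta"], rtol=1e-12)

    @pytest.mark.parametrize("category,da,db,dss", [
        ("full_buffered", True, True, False),   # alpha and beta shift, Y_ss fixed
        ("HL_only", False, True, True),         # beta shift drives Y_ss
        ("TR_only", True, False, True),
        ("unchanged", False, False, False),
    ])
    def test_planted_category_geometry(self, small_truth, small_cfg, category, da, db, dss):
        a = small_truth[small_truth.genotype == "WT"].set_index("gene_id")
        b = small_truth[small_truth.genotype == "MUT"].set_index("gene_id")
        genes = a.index[a.category == category]
        if not len(genes):
            pytest.skip(f"no {category} genes at this size")
        d_alpha = np.log2(b.loc[genes, "alpha"] / a.loc[genes, "alpha"])
        d_beta = np.log2(b.loc[genes, "beta"] / a.loc[genes, "beta"])
        d_ss = np.log2(b.loc[genes, "y_ss"] / a.loc[genes, "y_ss"])
        for shifted, delta, mag in ((da, d_alpha, small_cfg.tr_effect_log2),
                                    (db, d_beta, None), (dss, d_ss, None)):
            if shifted:
                assert (np.abs(delta) > 0.5).all()
            else:
                np.testing.assert_allclose(delta, 0.0, atol=1e-9)

    def test_full_buffered_forced_identities(self, small_truth):
        """Delta alpha = +e forces delta beta = +e and delta Y_ss = 0."""
        a = small_truth[small_truth.genotype == "WT"].set_index("gene_id")
        b = small_truth[small_truth.genotype == "MUT"].set_index("gene_id")
        genes = a.index[a.category == "full_buffered"]
        np.testing.assert_allclose(
            np.log2(b.loc[genes, "alpha"] / a.loc[genes, "alpha"]),
            np.log2(b.loc[genes, "beta"] / a.loc[genes, "beta"]), atol=1e-9)

    def test_hl_only_half_life_mirrors_beta(self, small_truth):
        a = small_truth[small_truth.genotype == "WT"].set_index("gene_id")
        b = small_truth[small_truth.genotype == "MUT"].set_index("gene_id")
        genes = a.index[a.category == "HL_only"]
        d_beta = np.log2(b.loc[genes, "beta"] / a.loc[genes, "beta"])
        d_hl = np.log2(b.loc[genes, "half_life_h"] / a.loc[genes, "half_life_h"])
        np.testing.assert_allclose(d_hl, -d_beta, atol=1e-9)

    def test_global_shift_moves_median(self):
        """Planted 2.5 -> 3.0 h medians are recovered in the truth table."""
        cfg = sd.SimConfig(
            n_genes=5000, seed=9, median_half_life_h=2.5,
            global_hl_shift_log2=math.log2(3.0 / 2.5),
            category_proportions={"unchanged": 1.0},
        )
        truth = sd.sample_gene_kinetics(cfg)
        med = truth.groupby("genotype")["half_life_h"].median()
        assert med["WT"] == pytest.approx(2.5, rel=0.05)
        assert med["MUT"] == pytest.approx(3.0, rel=0.05)

    def test_determinism(self, small_cfg, small_truth):
        again = sd.sample_gene_kinetics(small_cfg)
        pd.testing.assert_frame_equal(small_truth, again)


class TestSimulateLabelingCounts:
    def test_expected_saturation_mean(self):
        """beta=0.3, y_ss=1000, t=4: expected labeled signal 1000(1-e^-1.2)."""
        assert 1000 * -math.expm1(-0.3 * 4) == pytest.approx(698.806, abs=5e-3)

    def test_columns_match_sheet_and_counts_nonnegative(self, small_experiment):
        exp = small_experiment
        assert set(exp.counts.columns) == set(exp.sample_sheet.index)
        assert (exp.counts.to_numpy() >= 0).all()
        assert exp.counts.to_numpy().dtype.kind in "iu"

    def test_fly_spikeins_positive_in_labeled_samples(self, small_experiment):
        exp = small_experiment
        fly = exp.spikeins[exp.spikeins.kind == "fly"].drop(columns="kind")
        labeled = exp.sample_sheet.index[exp.sample_sheet.assay == "labeled"]
        assert (fly[labeled].sum(axis=0) > 0).all()

    def test_zero_contamination_means_zero_yeast(self, small_truth):
        cfg = sd.SimConfig(n_genes=300, seed=42, contamination_fraction=0.0)
        exp = sd.simulate_labeling_counts(sd.sample_gene_kinetics(cfg), cfg)
        yeast = exp.spikeins[exp.spikeins.kind == "yeast"].drop(columns="kind")
        labeled = exp.sample_sheet.index[exp.sample_sheet.assay == "labeled"]
        assert (yeast[labeled].to_numpy() == 0).all()

    def test_ercc_ladder_spans_four_decades(self, small_experiment):
        ercc = small_experiment.spikeins[small_experiment.spikeins.kind == "ercc"]
        tot = ercc.drop(columns="kind").sum(axis=1)
        assert tot.max() / max(tot[tot > 0].min(), 1) > 1e3

    def test_mean_counts_monotone_in_time(self, small_experiment):
        """Expected labeled counts (after fly normalization) rise toward saturation."""
        from ratebuffer.normalization import spikein_normalize

        exp = small_experiment
        norm = spikein_normalize(exp.counts, exp.spikeins, exp.sample_sheet)
        sheet = exp.sample_sheet
        tp = pd.to_numeric(sheet["timepoint_h"], errors="coerce")
        means = {}
        for t in (0.5, 4.0, 24.0):
            cols = sheet.index[(sheet.genotype == "WT") & (tp == t)]
            means[t] = norm.values[cols].mean(axis=1)
        slow = means[0.5].sum()
        assert slow < means[4.0].sum() < means[24.0].sum()

    def test_omit_1h_drops_samples(self):
        cfg = sd.SimConfig(n_genes=50, seed=0, omit_1h_for=("MUT",))
        exp = sd.simulate_labeling_counts(sd.sample_gene_kinetics(cfg), cfg)
        sheet = exp.sample_sheet
        tp = pd.to_numeric(sheet["timepoint_h"], errors="coerce")
        assert not ((sheet.genotype == "MUT") & (tp == 1.0)).any()
        assert ((sheet.genotype == "WT") & (tp == 1.0)).any()

    def test_byte_identical_given_seed(self, small_cfg, small_truth, small_experiment):
        again = sd.simulate_labeling_counts(small_truth, small_cfg)
        pd.testing.assert_frame_equal(small_experiment.counts, again.counts)
        pd.testing.assert_frame_equal(small_experiment.spikeins, again.spikeins)


class TestGenerateSequences:
    def test_untilted_chain_gives_chance_oracle(self):
        rng = np.random.default_rng(0)
        n = 400
        dirs = pd.Series(rng.permutation(["up", "down"] * (n // 2)),
                         index=[f"g{i}" for i in range(n)])
        cfg = sd.SequenceConfig(seed=1)
        seqs = sd.generate_sequences(pd.Series("none", index=dirs.index), cfg)
        tau = seqs.attrs["tau"]
        lo = np.array([sd.sequence_log_odds(s, cfg.planted_dinucleotides, tau)
                       for s in seqs["gene_body"]])
        acc = ((lo > 0) == (dirs.to_numpy() == "up")).mean()
        assert abs(acc - 0.5) < 1.96 * math.sqrt(0.25 / n)

    def test_oracle_reaches_configured_bayes_accuracy(self):
        n = 2000
        rng = np.random.default_rng(1)
        dirs = pd.Series(rng.permutation(["up", "down"] * (n // 2)),
                         index=[f"g{i}" for i in range(n)])
        cfg = sd.SequenceConfig(seed=2, bayes_accuracy=0.85)
        seqs = sd.generate_sequences(dirs, cfg)
        tau = seqs.attrs["tau"]
        lo = np.array([sd.sequence_log_odds(s, cfg.planted_dinucleotides, tau)
                       for s in seqs["gene_body"]])
        acc = ((lo > 0) == (dirs.to_numpy() == "up")).mean()
        assert acc == pytest.approx(0.85, abs=2.5 * math.sqrt(0.85 * 0.15 / n))

    def test_length_independent_of_direction(self):
        n = 1000
        rng = np.random.default_rng(2)
        dirs = pd.Series(rng.permutation(["up", "down"] * (n // 2)),
                         index=[f"g{i}" for i in range(n)])
        seqs = sd.generate_sequences(dirs, sd.SequenceConfig(seed=3))
        lengths = seqs["gene_body"].str.len().to_numpy(float)
        sign = np.where(seqs["planted_direction"] == "up", 1.0, -1.0)
        r = np.corrcoef(lengths, sign)[0, 1]
        assert abs(r) < 0.08

    def test_cds_divisible_by_three_and_alphabet(self):
        dirs = pd.Series(["up", "down"] * 10, index=[f"g{i}" for i in range(20)])
        seqs = sd.generate_sequences(dirs, sd.SequenceConfig(seed=4))
        assert (seqs["cds"].str.len() % 3 == 0).all()
        for col in ("gene_body", "cds", "utr3"):
            assert not seqs[col].str.contains("[^ACGT]", regex=True).any()

    def test_bad_bayes_accuracy_rejected(self):
        with pytest.raises(sd.ConfigurationError):
            sd.SequenceConfig(bayes_accuracy=1.2)
        with pytest.raises(sd.ConfigurationError):
            sd.SequenceConfig(bayes_accuracy=0.5)


class TestPlantMotifs:
    @pytest.fixture(scope="class")
    @staticmethod
    def seqs():
        dirs = pd.Series("none", index=[f"g{i:04d}" for i in range(500)])
        return sd.generate_sequences(dirs, sd.SequenceConfig(seed=5))

    def test_planted_motifs_present(self, seqs):
        fg = seqs.index[:100]
        out = sd.plant_motifs(seqs, "ATTTTTA", fg, fg_rate=1.0, bg_rate=0.0, seed=0)
        planted = out["planted_ATTTTTA"]
        assert planted[fg].all()
        assert out.loc[fg, "utr3"].str.contains("ATTTTTA").all()
        assert not planted[~out.index.isin(fg)].any()

    def test_lengths_preserved(self, seqs):
        out = sd.plant_motifs(seqs, "ATTTTTA", seqs.index[:50], 1.0, 0.0, seed=1)
        assert (out["utr3"].str.len() == seqs["utr3"].str.len()).all()

    def test_rate_zero_means_no_planting(self, seqs):
        out = sd.plant_motifs(seqs, "ATTTTTA", seqs.index[:50], 0.0, 0.0, seed=2)
        assert not out["planted_ATTTTTA"].any()

    def test_motif_longer_than_utr_rejected(self, seqs):
        with pytest.raises(sd.ConfigurationError):
            sd.plant_motifs(seqs, "A" * 10000, seqs.index[:10], 0.5, 0.1, seed=0)

    def test_rate_ordering_enforced(self, seqs):
        with pytest.raises(sd.ConfigurationError):
            sd.plant_motifs(seqs, "ATTTTTA", seqs.index[:10], 0.1, 0.4, seed=0)


class TestSimulateSmallRna:
    def test_no_change_gives_zero_fc(self):
        counts, sheet, truth = sd.simulate_small_rna(300, global_scale_B=1.0, seed=0)
        mat = counts.drop(columns="kind")
        mirna = mat[counts["kind"] == "mirna"]
        ladder = mat[counts["kind"] == "ladder"]
        scaled = mirna / ladder.sum(axis=0)
        a = scaled[[c for c in mat.columns if c.startswith("WT")]].mean(axis=1)
        b = scaled[[c for c in mat.columns if c.startswith("MUT")]].mean(axis=1)
        fc = np.log2((b + 0.5) / (a + 0.5))
        assert abs(np.median(fc)) < 0.1

    def test_low_ladder_member_detection_rate(self):
        """A ladder member with expectation 0.5 is seen in <= ~40% of samples."""
        ladder = pd.Series([0.5] * 200, index=[f"s{i}" for i in range(200)])
        counts, _, _ = sd.simulate_small_rna(
            10, spikein_ladder=ladder, seed=1, dispersion=0.0, depth_noise_sigma=0.0)
        det = (counts[counts["kind"] == "ladder"].drop(columns="kind") > 0).mean(axis=None)
        assert det == pytest.approx(-math.expm1(-0.5), abs=0.06)

    def test_invalid_scale_rejected(self):
        with pytest.raises(sd.ConfigurationError):
            sd.simulate_small_rna(10, global_scale_B=0.0)
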