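import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest

from riboshift import differential_expression as de
from riboshift import synthetic_data as sd
from riboshift.read_counting import CountMatrix

from .oracles import bh_brute_force


def _cm(counts, conditions, assay="ribo"):
    df = pd.DataFrame(counts)
    meta = pd.DataFrame(
        {
            "assay": assay,
            "condition": conditions,
            "replicate": list(range(1, len(df.columns) + 1)),
        },
        index=df.columns,
    )
    return CountMatrix(df, df.sum(), meta)


def _null_cm(seed, n_genes=2000, depth=5e6, disp=0.1, reps=3):
    rng = np.random.default_rng(seed)
    lam = rng.lognormal(3, 1, n_genes)
    m = lam / lam.sum() * depth
    n = 1 / disp
    counts = {f"s{i}": rng.negative_binomial(n, n / (n + m)) for i in range(2 * reps)}
    return _cm(counts, ["normal"] * reps + ["stress"] * reps)


class TestSubsampleCounts:
    def test_full_depth_returns_columns_unchanged(self):
        cm = _null_cm(0, n_genes=100, depth=1e4)
        target = int(cm.counts.sum().min())
        sub = de.subsample_counts(cm, target, seed=1)
        col = sub.counts.columns[np.argmin(cm.counts.sum().to_numpy())]
        assert (sub.counts[col] == cm.counts[col]).all()
        assert (sub.counts.sum() == target).all()

    def test_zero_target_gives_all_zeros(self):
        cm = _null_cm(0, n_genes=50, depth=1e4)
        sub = de.subsample_counts(cm, 0, seed=1)
        assert (sub.counts.to_numpy() == 0).all()

    def test_excessive_target_names_sample(self):
        cm = _null_cm(0, n_genes=50, depth=1e4)
        with pytest.raises(ValueError, match="s0"):
            de.subsample_counts(cm, 10**9, seed=1)

    def test_half_depth_means_match_hypergeometric_expectation(self):
        cm = _null_cm(5, n_genes=60, depth=2e4, reps=1)
        col = cm.counts["s0"]
        target = int(col.sum()) // 2
        draws = np.stack(
            [
                de.subsample_counts(cm, target, seed=s).counts["s0"].to_numpy()
                for s in range(60)
            ]
        )
        frac = target / col.sum()
        exp = col.to_numpy() * frac
        var = exp * (1 - frac) * (col.sum() - target) / max(col.sum() - 1, 1)
        se = np.sqrt(np.maximum(var, 1e-9) / 60)
        assert (np.abs(draws.mean(axis=0) - exp) < 4 * se + 0.5).all()


class TestTmmFactors:
    def test_identical_columns_give_unit_factors(self):
        col = np.random.default_rng(1).integers(1, 300, size=200)
        counts = pd.DataFrame({f"s{i}": col for i in range(4)})
        assert np.allclose(de.tmm_factors(counts), 1.0)

    def test_pure_depth_difference_gives_unit_factors(self):
        col = np.random.default_rng(2).integers(1, 300, size=200)
        counts = pd.DataFrame({"a": col, "b": col * 2})
        assert np.allclose(de.tmm_factors(counts), 1.0)

    def test_matches_edger_reference_implementation(self):
        rng = np.random.default_rng(3)
        mu = rng.lognormal(3, 1.2, 400)
        counts = pd.DataFrame(
            {f"s{i}": rng.negative_binomial(5, 5 / (5 + mu * rng.uniform(0.5, 2)))
             for i in range(5)}
        )
        ours = de.tmm_factors(counts).to_numpy()
        with tempfile.NamedTemporaryFile("w", suffix=".csv") as fh:
            counts.to_csv(fh.name, index=False)
            r = subprocess.run(
                ["Rscript", "-e",
                 f'suppressMessages(library(edgeR));'
                 f'x<-as.matrix(read.csv("{fh.name}"));'
                 f'cat(sprintf("%.12f ", calcNormFactors(x)))'],
                capture_output=True, text=True, check=True,
            )
        ref = np.array([float(v) for v in r.stdout.split()])
        assert np.abs(ours - ref).max() < 1e-8


class TestModeratedTest:
    def test_identical_groups_give_zero_statistic(self):
        col = np.random.default_rng(4).integers(5, 500, size=100)
        cm = _cm(
            {"n1": col, "n2": col, "s1": col, "s2": col},
            ["normal", "normal", "stress", "stress"],
        )
        res = de.moderated_test(cm)
        assert np.allclose(res["log2fc_model"], 0.0)
        assert (res["pvalue"] > 0.99).all()

    def test_type_one_error_calibrated_on_null(self):
        res = de.moderated_test(_null_cm(11))
        frac = (res["pvalue"] < 0.05).mean()
        assert 0.035 <= frac <= 0.065

    def test_planted_effects_detected(self):
        rng = np.random.default_rng(12)
        n_genes, reps = 2000, 3
        lam = rng.lognormal(3, 1, n_genes)
        m = lam / lam.sum() * 5e6
        eff = np.ones(n_genes)
        hot = rng.choice(n_genes, size=n_genes // 10, replace=False)
        eff[hot] = 4.0
        n = 1 / 0.1
        counts = {}
        for i in range(reps):
            counts[f"n{i}"] = rng.negative_binomial(n, n / (n + m))
        for i in range(reps):
            me = m * eff
            counts[f"s{i}"] = rng.negative_binomial(n, n / (n + me))
        cm = _cm(counts, ["normal"] * reps + ["stress"] * reps)
        res = de.moderated_test(cm, norm_factors=de.tmm_factors(cm))
        sens = (res["adj_pvalue"].to_numpy()[hot] < 0.05).mean()
        assert sens >= 0.8

    def test_single_replicate_is_error(self):
        cm = _cm({"n1": [1], "s1": [2], "s2": [3]}, ["normal", "stress", "stress"])
        with pytest.raises(ValueError):
            de.moderated_test(cm)


class TestSdThreshold:
    def test_degenerate_distribution(self):
        dge = pd.DataFrame({"log2fc_model": np.full(10, 2.0)})
        assert de.sd_threshold(dge) == 0.0

    def test_plus_minus_one_sample_sd(self):
        dge = pd.DataFrame({"log2fc_model": np.tile([-1.0, 1.0], 1000)})
        assert de.sd_threshold(dge) == pytest.approx(1.00025, abs=1e-4)

    def test_standard_normal_logfcs(self):
        rng = np.random.default_rng(13)
        n = 5000
        dge = pd.DataFrame({"log2fc_model": rng.standard_normal(n)})
        se = 1 / np.sqrt(2 * (n - 1))
        assert abs(de.sd_threshold(dge) - 1.0) < 3 * se


class TestBhAdjust:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(5):
            p = rng.random(200)
            got = de.bh_adjust(p)
            want = bh_brute_force(p)
            assert np.allclose(got, want, atol=1e-12)
            assert (got >= p - 1e-12).all() and got.max() <= 1.0


class TestClassifyRegulation:
    def _dge(self, rows):
        # rows: list of (gene, log2fc, adj_p)
        return pd.DataFrame(
            {
                "log2fc_model": [r[1] for r in rows],
                "adj_pvalue": [r[2] for r in rows],
            },
            index=[r[0] for r in rows],
        )

    def test_full_truth_table(self):
        up, down, ns = (3.0, 0.01), (-3.0, 0.01), (0.5, 0.8)
        cells = {
            ("up", "up"): "transcriptional_up",
            ("down", "down"): "transcriptional_down",
            ("ns", "up"): "translational_up",
            ("ns", "down"): "translational_down",
            ("up", "ns"): "buffering_up",
            ("down", "ns"): "buffering_down",
            ("up", "down"): "discordant",
            ("down", "up"): "discordant",
            ("ns", "ns"): "unchanged",
        }
        lookup = {"up": up, "down": down, "ns": ns}
        genes = list(cells)
        rna = self._dge([(f"{a}_{b}", *lookup[a]) for a, b in genes])
        ribo = self._dge([(f"{a}_{b}", *lookup[b]) for a, b in genes])
        res = de.classify_regulation(rna, ribo, rna_sd=1.0, ribo_sd=1.0)
        for (a, b), expected in cells.items():
            assert res.loc[f"{a}_{b}", "reg_class"] == expected

    def test_gene_missing_from_one_assay_is_flagged_unchanged(self):
        rna = self._dge([("gA", 3.0, 0.01), ("gB", 3.0, 0.01)])
        ribo = self._dge([("gA", 3.0, 0.01)])
        res = de.classify_regulation(rna, ribo, rna_sd=1.0, ribo_sd=1.0)
        assert res.loc["gB", "reg_class"] == "unchanged"
        assert not res.loc["gB", "tested_both"]

    def test_classes_are_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(15)
        spec_rna = [(f"g{i}", rng.normal(0, 2), rng.random()) for i in range(300)]
        spec_ribo = [(f"g{i}", rng.normal(0, 2), rng.random()) for i in range(300)]
        res = de.classify_regulation(
            self._dge(spec_rna), self._dge(spec_ribo), rna_sd=1.0, ribo_sd=1.0
        )
        assert set(res["reg_class"]) <= set(de.REG_CLASSES)
        assert len(res) == 300


class TestTeChangeTest:
    def test_identical_counts_give_zero_interaction(self):
        col = np.random.default_rng(16).integers(20, 400, size=40)
        conditions = ["normal", "normal", "stress", "stress"]
        rna = _cm({f"r{i}": col for i in range(4)}, conditions, assay="rna")
        ribo = _cm({f"b{i}": col for i in range(4)}, conditions, assay="ribo")
        res = de.te_change_test(rna, ribo)
        assert np.allclose(res["interaction_log2"].dropna(), 0.0, atol=1e-6)

    def test_null_calibration_when_both_assays_shift_together(self):
        # both assays scaled in stress -> no TE change
        cfg = sd.SimConfig(
            seed=17, n_genes=2000, depth=5_000_000, cds_arrest_tau=1.0,
            class_proportions={"unchanged": 1.0},
        )
        sim = sd.simulate_counts(cfg)
        res = de.te_change_test(sim.rna_cds, sim.ribo_cds)
        frac = (res["pvalue"].dropna() < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_planted_te_effects_detected(self):
        # planted effects in a mostly-null background, so composition
        # normalization does not absorb the shift
        cfg = sd.SimConfig(
            seed=18, n_genes=800, depth=5_000_000, cds_arrest_tau=1.0,
            class_proportions={"translational_up": 0.2, "unchanged": 0.8},
        )
        sim = sd.simulate_counts(cfg)
        res = de.te_change_test(sim.rna_cds, sim.ribo_cds)
        hot = sim.truth.index[sim.truth.reg_class == "translational_up"]
        assert (res["adj_pvalue"].reindex(hot) < 0.05).mean() >= 0.8
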