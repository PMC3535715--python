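"""Length-matched sampling and the permutation empirical p-values."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import crossrank as cr
from crossrank.permutation import (
    PermutationConfig,
    SamplingError,
    permutation_pvalues,
    sample_matched,
)
from crossrank.simulate import SimulationConfig, generate_evidence, generate_gene_universe, generate_gwas


def _uniform_universe(n, length=20_000):
    return pd.DataFrame(
        {
            "gene_id": [f"G{i}" for i in range(n)],
            "symbol": [f"S{i}" for i in range(n)],
            "chrom": ["chr1"] * n,
            "start": [1 + i * (length + 10) for i in range(n)],
            "end": [length + i * (length + 10) for i in range(n)],
        }
    )


class TestMeanLength:
    def test_single_gene(self, toy_genes):
        assert cr.mean_length(["G1"], toy_genes) == 20_001

    def test_hand_summed_mean(self, toy_genes):
        lengths = [20_001, 25_001, 50_001, 30_001, 40_001]
        assert cr.mean_length(toy_genes["gene_id"], toy_genes) == pytest.approx(
            np.mean(lengths)
        )

    def test_empty_list_raises(self, toy_genes):
        with pytest.raises(ValueError, match="empty"):
            cr.mean_length([], toy_genes)


class TestSampleMatched:
    def test_equal_lengths_all_qualify(self):
        uni = _uniform_universe(30)
        cfg = PermutationConfig()
        got = sample_matched(uni, 10, 20_000, cfg, np.random.default_rng(0))
        assert len(got) == len(set(got)) == 10

    def test_pool_of_exactly_n_is_forced(self):
        uni = _uniform_universe(6)
        cfg = PermutationConfig(length_tol_bp=100)
        got = sample_matched(uni, 6, 20_000, cfg, np.random.default_rng(0))
        assert set(got) == set(uni["gene_id"])

    def test_exhausted_pool_without_widening_raises(self):
        uni = _uniform_universe(6)
        cfg = PermutationConfig(length_tol_bp=10, widen_on_small_pool=False)
        with pytest.raises(SamplingError, match="pool"):
            sample_matched(uni, 5, 500_000, cfg, np.random.default_rng(0))

    def test_widening_warns_and_succeeds(self):
        uni = _uniform_universe(6)
        cfg = PermutationConfig(length_tol_bp=10, widen_on_small_pool=True)
        with pytest.warns(UserWarning, match="widened"):
            got = sample_matched(uni, 5, 500_000, cfg, np.random.default_rng(0))
        assert len(got) == 5

    def test_inclusion_uniform_over_pool(self):
        # chi-square goodness of fit over a 20-gene pool, 5000 draws of n=5
        uni = _uniform_universe(20)
        cfg = PermutationConfig()
        rng = np.random.default_rng(1)
        counts = {g: 0 for g in uni["gene_id"]}
        draws = 5000
        for _ in range(draws):
            for g in sample_matched(uni, 5, 20_000, cfg, rng):
                counts[g] += 1
        observed = np.array(list(counts.values()))
        expected = draws * 5 / 20
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=19) > 0.01

    def test_matched_sample_lengths_within_tolerance(self, small_study):
        genes = small_study.genes
        cfg = PermutationConfig(length_tol_bp=50_000, widen_on_small_pool=False)
        rng = np.random.default_rng(2)
        target = cr.mean_length(genes["gene_id"][:40], genes)
        for _ in range(50):
            got = sample_matched(genes, 20, target, cfg, rng)
            assert abs(cr.mean_length(got, genes) - target) <= cfg.length_tol_bp


class TestPermutationPvalues:
    def _tiny_setup(self, seed=0, planted_effect=0.15, planted=None, n_genes=600,
                    n_snps=6000):
        cfg = SimulationConfig(seed=seed, planted_effect=planted_effect,
                               n_genes=n_genes, n_snps=n_snps)
        genes = generate_gene_universe(cfg)
        bundle, truth = generate_evidence(genes, cfg)
        sets = dict(bundle.source_sets)
        sets["HuLink"] = cr.assign_linkage(genes, bundle.linkage_intervals)
        profiles, _ = cr.build_profiles(genes, sets)
        ranked = cr.rank_genes(profiles, "WSM3")
        if planted == "top":
            cfg.planted_genes = list(cr.select_top(ranked, 2, "ge")["gene_id"])
        snps = generate_gwas(genes, truth, cfg)
        snps, _ = cr.qc_filter(snps)
        _, gene_index, _ = cr.map_snps_to_genes(snps, genes)
        return genes, ranked, snps, gene_index

    def test_degenerate_pool_gives_zero_p_under_strict_rule(self):
        # a universe whose matched pool is exactly the observed set makes
        # every permutation a tie; "larger than" never fires
        uni = _uniform_universe(8)
        profiles = pd.DataFrame(
            {
                "gene_id": uni["gene_id"], "symbol": uni["symbol"],
                **{t: [True] * 8 for t in ("MuAc",)},
                **{t: [False] * 8 for t in ("MuPref", "HuAlc", "HuAddChip",
                                            "HuLink", "Ce", "Dr", "Cross")},
                "in_initial_list": [True] * 8,
            }
        )
        ranked = cr.rank_genes(profiles, "WSM3")
        snps = pd.DataFrame(
            {
                "snp_id": [f"rs{i}" for i in range(16)],
                "chrom": ["chr1"] * 16,
                "pos": np.linspace(1000, 230_000, 16).astype(int),
                "p": np.linspace(0.05, 1.0, 16),
            }
        )
        _, gene_index, _ = cr.map_snps_to_genes(snps, uni)
        cfg = PermutationConfig(B=25, cutoffs=(0.5,), eq_cutoffs=(),
                                q_bins=(0.9, 0.8), fdr_method="bh")
        rep = permutation_pvalues(ranked, gene_index, snps, uni, cfg,
                                  rng=np.random.default_rng(0))
        populated = rep.table.dropna(subset=["empirical_p"])
        assert len(populated) and (populated["empirical_p"] == 0.0).all()

    def test_observed_row_invariant_to_B(self):
        genes, ranked, snps, gene_index = self._tiny_setup(seed=3)
        obs_cols = ["cutoff", "q_threshold", "observed_count",
                    "observed_proportion", "n_observed_snps"]
        reps = [
            permutation_pvalues(
                ranked, gene_index, snps, genes,
                PermutationConfig(B=b, cutoffs=(0.5, 2.0), eq_cutoffs=()),
                rng=np.random.default_rng(9),
            )
            for b in (5, 20)
        ]
        pd.testing.assert_frame_equal(reps[0].table[obs_cols], reps[1].table[obs_cols])

    def test_seeded_report_determinism(self):
        genes, ranked, snps, gene_index = self._tiny_setup(seed=4)
        cfg = PermutationConfig(B=10, cutoffs=(1.0, 2.0), eq_cutoffs=())
        a = permutation_pvalues(ranked, gene_index, snps, genes, cfg,
                                rng=np.random.default_rng(11))
        b = permutation_pvalues(ranked, gene_index, snps, genes, cfg,
                                rng=np.random.default_rng(11))
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_planted_signal_detected_at_top_cutoff(self):
        # signal planted in the score>=2 stratum: its cells should be extreme
        hits = 0
        for seed in range(20):
            genes, ranked, snps, gene_index = self._tiny_setup(
                seed=seed, planted="top", planted_effect=0.1
            )
            cfg = PermutationConfig(B=200, cutoffs=(2.0,), eq_cutoffs=())
            rep = permutation_pvalues(ranked, gene_index, snps, genes, cfg,
                                      rng=np.random.default_rng(100 + seed))
            t = rep.table.dropna(subset=["empirical_p"])
            stringent = t[t["q_threshold"] == t["q_threshold"].min()]
            if len(stringent) and (stringent["empirical_p"] < 0.05).all():
                hits += 1
        assert hits >= 18


class TestSelectBestMatrix:
    def test_single_matrix_selected(self):
        from crossrank.permutation import PermutationReport
        rep = PermutationReport("WSM3", pd.DataFrame(
            {"cutoff": [], "q_threshold": [], "observed_count": [],
             "observed_proportion": [], "perm_mean_proportion": [],
             "empirical_p": [], "p_add_one": [], "n_observed_snps": []}),
            pd.DataFrame({"cutoff": [], "n_genes": [], "n_snps": [], "min_q": []}),
            B=10)
        best, ranking = cr.select_best_matrix({"WSM3": rep})
        assert best == "WSM3" and len(ranking) == 1

    def test_smaller_min_q_wins_and_order_invariant(self):
        from crossrank.permutation import PermutationReport

        def rep(name, min_q):
            empty = pd.DataFrame(
                {"cutoff": ["≥2"], "q_threshold": [0.5], "observed_count": [0],
                 "observed_proportion": [0.0], "perm_mean_proportion": [0.0],
                 "empirical_p": [np.nan], "p_add_one": [np.nan],
                 "n_observed_snps": [5]})
            summary = pd.DataFrame(
                {"cutoff": ["≥2"], "n_genes": [3], "n_snps": [5], "min_q": [min_q]})
            return PermutationReport(name, empty, summary, B=10)

        # mirrors a 0.357-vs-0.605 minimum-q comparison between two matrices
        a, b = rep("A", 0.357), rep("B", 0.605)
        best1, _ = cr.select_best_matrix({"A": a, "B": b})
        best2, _ = cr.select_best_matrix({"B": b, "A": a})
        assert best1 == best2 == "A"
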