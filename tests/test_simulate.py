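"""Generator behavior: determinism, calibration of the planted quantities,
and the statistical laws of the emitted p-values."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import crossrank as cr
from crossrank import io as crio
from crossrank.simulate import (
    ConfigError,
    SOURCE_SPECIES,
    SimulationConfig,
    generate_evidence,
    generate_gene_universe,
    generate_gwas,
    simulate_study,
    write_study,
)


def _species_of_genes(source_sets):
    out = {}
    for src, members in source_sets.items():
        for g in members:
            out.setdefault(g, set()).add(SOURCE_SPECIES[src])
    return out


class TestGeneUniverse:
    def test_seeded_determinism(self):
        cfg = SimulationConfig(n_genes=100, seed=7)
        a = generate_gene_universe(cfg)
        b = generate_gene_universe(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_genes_gives_header_only(self):
        df = generate_gene_universe(SimulationConfig(n_genes=0))
        assert len(df) == 0 and list(df.columns) == crio.GENE_COLUMNS

    def test_uniform_length_law_mean(self):
        # mean of U(10000, 200000) is 105000; sample mean within 3 SE
        cfg = SimulationConfig(
            n_genes=2000, gene_length_law=("uniform", (10_000, 200_000)), seed=3
        )
        df = generate_gene_universe(cfg)
        lengths = df["end"] - df["start"] + 1
        se = (200_000 - 10_000) / np.sqrt(12 * 2000)
        assert abs(lengths.mean() - 105_000) < 3 * se

    def test_coordinates_valid(self):
        cfg = SimulationConfig(n_genes=500, seed=1)
        df = generate_gene_universe(cfg)
        sizes = dict(cfg.chrom_layout)
        assert (df["end"] >= df["start"]).all()
        assert (df["start"] >= 1).all()
        assert all(e <= sizes[c] for c, e in zip(df["chrom"], df["end"]))
        assert df["gene_id"].is_unique and df["symbol"].is_unique

    def test_non_overlapping_placement(self):
        cfg = SimulationConfig(
            n_genes=60,
            allow_gene_overlap=False,
            gene_length_law=("uniform", (10_000, 50_000)),
            seed=2,
        )
        df = generate_gene_universe(cfg)
        for _, grp in df.groupby("chrom"):
            g = grp.sort_values("start")
            assert (g["start"].values[1:] > g["end"].values[:-1]).all()

    def test_oversized_gene_raises_naming_chromosome(self):
        cfg = SimulationConfig(
            n_genes=5,
            chrom_layout=(("chrT", 5_000),),
            gene_length_law=("uniform", (10_000, 20_000)),
        )
        with pytest.raises(ConfigError, match="chrT"):
            generate_gene_universe(cfg)


class TestEvidence:
    def test_zero_counts_gives_empty_sets(self, toy_genes):
        cfg = SimulationConfig(
            n_genes=5, evidence_counts={s: 0 for s in cr.SOURCES if s != "HuLink"}
        )
        bundle, truth = generate_evidence(toy_genes, cfg)
        assert all(not v for v in bundle.source_sets.values())
        assert all(not truth.memberships[s] for s in bundle.source_sets)

    def test_full_overlap_forces_worm_genes_shared(self):
        cfg = SimulationConfig(
            n_genes=200,
            evidence_counts={"MuAc": 40, "MuPref": 30, "HuAlc": 20,
                             "HuAddChip": 20, "Ce": 10, "Dr": 10},
            cross_species_overlap=1.0,
            seed=5,
        )
        genes = generate_gene_universe(cfg)
        bundle, _ = generate_evidence(genes, cfg)
        non_worm = set().union(
            *(bundle.source_sets[s] for s in bundle.source_sets if s != "Ce")
        )
        assert bundle.source_sets["Ce"] <= non_worm

    def test_overlap_calibrated_across_seeds(self):
        # ~510 evidence genes at target overlap 0.3; replicate mean in band
        counts = {"MuAc": 150, "MuPref": 120, "HuAlc": 90,
                  "HuAddChip": 100, "Ce": 20, "Dr": 30}
        vals = []
        for seed in range(20):
            cfg = SimulationConfig(
                n_genes=4000, evidence_counts=counts,
                cross_species_overlap=0.3, seed=seed,
            )
            genes = generate_gene_universe(cfg)
            bundle, _ = generate_evidence(genes, cfg)
            species = _species_of_genes(bundle.source_sets)
            vals.append(np.mean([len(v) >= 2 for v in species.values()]))
        assert 0.27 <= np.mean(vals) <= 0.33

    def test_infeasible_overlap_raises(self, toy_genes):
        cfg = SimulationConfig(
            n_genes=5,
            evidence_counts={"MuAc": 4, "MuPref": 0, "HuAlc": 1,
                             "HuAddChip": 0, "Ce": 0, "Dr": 0},
            cross_species_overlap=0.95,
        )
        with pytest.raises(ConfigError, match="overlap"):
            generate_evidence(toy_genes, cfg)

    def test_truth_matches_emitted_lists(self, small_study):
        for src, members in small_study.evidence.source_sets.items():
            assert small_study.truth.memberships[src] == members


class TestGwas:
    def test_null_p_fraction_below_005(self):
        cfg = SimulationConfig(
            n_genes=500, n_snps=50_000, planted_genes=[], seed=11, defect_rate=0.0
        )
        genes = generate_gene_universe(cfg)
        _, truth = generate_evidence(genes, cfg)
        snps = generate_gwas(genes, truth, cfg)
        frac = float((snps["p"] < 0.05).mean())
        assert 0.045 <= frac <= 0.055

    def test_beta_one_is_uniform_in_law(self):
        # a = 1 makes planted p-values indistinguishable from null ones
        rejected = 0
        for seed in range(20):
            cfg = SimulationConfig(
                n_genes=400, n_snps=6000, planted_effect=1.0, seed=seed,
                defect_rate=0.0,
            )
            genes = generate_gene_universe(cfg)
            _, truth = generate_evidence(genes, cfg)
            snps = generate_gwas(genes, truth, cfg)
            alt = np.array([truth.snp_is_alt[s] for s in snps["snp_id"]])
            if alt.sum() < 20:
                continue
            ks = stats.ks_2samp(snps["p"][alt], snps["p"][~alt])
            rejected += ks.pvalue < 0.01
        assert rejected <= 1

    def test_planted_effect_shifts_median(self):
        # Beta(0.2, 1) stochastically dominates toward small p
        for seed in range(20):
            cfg = SimulationConfig(
                n_genes=400, n_snps=6000, planted_effect=0.2, seed=seed,
                defect_rate=0.0,
            )
            genes = generate_gene_universe(cfg)
            _, truth = generate_evidence(genes, cfg)
            snps = generate_gwas(genes, truth, cfg)
            alt = np.array([truth.snp_is_alt[s] for s in snps["snp_id"]])
            assert snps["p"][alt].median() < snps["p"][~alt].median()

    def test_every_snp_labelled_exactly_once(self, small_study):
        assert set(small_study.truth.snp_is_alt) == set(small_study.snps["snp_id"])

    def test_invalid_configs_raise(self, toy_genes):
        with pytest.raises(ConfigError):
            SimulationConfig(planted_effect=-0.5).validate()
        cfg = SimulationConfig(chrom_layout=())
        with pytest.raises(ConfigError):
            generate_gwas(toy_genes, cr.TruthSet(), cfg)

    def test_genotype_counts_consistent(self):
        cfg = SimulationConfig(
            n_genes=100, n_snps=500, emit_genotypes=True, seed=9, defect_rate=0.0,
            evidence_counts={"MuAc": 15, "MuPref": 10, "HuAlc": 8,
                             "HuAddChip": 10, "Ce": 2, "Dr": 4},
        )
        genes = generate_gene_universe(cfg)
        _, truth = generate_evidence(genes, cfg)
        snps = generate_gwas(genes, truth, cfg)
        n_case = snps[["case_AA", "case_Aa", "case_aa"]].sum(axis=1)
        assert (n_case <= cfg.n_cases).all() and (n_case >= 0.9 * cfg.n_cases).all()


class TestNullQCalibration:
    def test_null_min_q_matches_stepup_law(self):
        # Under the global null P(min q <= a) = a*pi0 for step-up FDR, so
        # roughly half the null runs dip below 0.5; check a wide band.
        below = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            qv = cr.storey_q(rng.uniform(size=10_000))
            below += qv.min_q <= 0.5
        assert 0.25 * n_seeds <= below <= 0.75 * n_seeds


def test_study_round_trip(tmp_path, small_study):
    write_study(small_study, tmp_path)
    genes = crio.read_gene_table(tmp_path / "genes.tsv")
    pd.testing.assert_frame_equal(genes, small_study.genes)
    snps = crio.read_snp_table(tmp_path / "snps.tsv")
    assert list(snps["snp_id"]) == list(small_study.snps["snp_id"])
    np.testing.assert_allclose(snps["p"], small_study.snps["p"])
    gmt = crio.read_gmt(tmp_path / "annotations.gmt")
    assert gmt == small_study.annotations
    # worm list is written in worm ids and maps back through the ortholog file
    worm = crio.read_evidence_list(tmp_path / "evidence_Ce.tsv")
    assert all(w.startswith("cel-") for w in worm)
    mapped, _ = cr.load_evidence_list(
        tmp_path / "evidence_Ce.tsv", "worm", tmp_path / "orthologs_worm.tsv"
    )
    assert mapped == small_study.evidence.source_sets["Ce"]


def test_full_study_determinism():
    cfg = SimulationConfig(seed=42, n_genes=300, n_snps=2000)
    a = simulate_study(cfg)
    b = simulate_study(cfg)
    pd.testing.assert_frame_equal(a.genes, b.genes)
    pd.testing.assert_frame_equal(a.snps, b.snps)
    assert a.annotations == b.annotations
    assert a.truth.memberships == b.truth.memberships
    assert a.truth.snp_is_alt == b.truth.snp_is_alt
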