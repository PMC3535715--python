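"""Synthetic study generator: gene universe, evidence tracks, GWAS markers,
and annotation sets with a recorded ground truth.

The generator emulates the shape of a cross-species candidate-gene study:
a genome of protein-coding genes with realistic length variation, six
evidence gene lists from four species (two mouse microarray sets, a human
alcoholic-cortex set, an addiction-chip list, and short worm and fly
lists), linkage intervals, and a case-control GWAS marker panel whose
p-values are uniform under the null with a planted Beta(a, 1) signal
(a < 1, right-skewed toward small p) inside designated genes.  Everything
is driven by one integer seed and is byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as crio

#: list-type evidence sources, in species processing order (mouse, human,
#: fly, worm).  HuLink is positional and comes from linkage intervals.
LIST_SOURCES = ("MuAc", "MuPref", "HuAlc", "HuAddChip", "Dr", "Ce")

SOURCE_SPECIES = {
    "MuAc": "mouse",
    "MuPref": "mouse",
    "HuAlc": "human",
    "HuAddChip": "human",
    "Dr": "fly",
    "Ce": "worm",
}

#: id prefix used when writing non-human lists to disk
NONHUMAN_PREFIX = {"worm": "cel-", "fly": "dme-"}


class ConfigError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a compact version of an alcoholism candidate-gene
    study: ~10% of the universe carries microarray evidence, four species
    contribute lists, three multi-megabase linkage intervals, and a dense
    genotyped marker panel with 1205 cases and 700 controls.
    """

    n_genes: int = 2000
    chrom_layout: tuple[tuple[str, int], ...] = (
        ("chr1", 60_000_000),
        ("chr2", 60_000_000),
        ("chr3", 50_000_000),
        ("chr4", 40_000_000),
    )
    # ("uniform", (low, high)) or ("lognormal", (mean_of_log, sigma_of_log)) in bp
    gene_length_law: tuple[str, tuple[float, float]] = ("lognormal", (10.1, 1.1))
    allow_gene_overlap: bool = True
    evidence_counts: dict = field(
        default_factory=lambda: {
            "MuAc": 120,
            "MuPref": 100,
            "HuAlc": 60,
            "HuAddChip": 130,
            "Ce": 15,
            "Dr": 25,
        }
    )
    cross_species_overlap: float = 0.3
    n_linkage_intervals: int = 3
    interval_span_bp: int = 15_000_000
    n_snps: int = 20_000
    snp_density: float = 2.0  # relative marker density inside gene±flank regions
    flank_bp: int = 10_000
    planted_genes: list | str = "top-evidence"
    n_planted: int = 25
    planted_effect: float = 0.2  # Beta(a, 1) shape for alternative p-values
    emit_genotypes: bool = False
    defect_rate: float = 0.02  # fraction of SNPs given call-rate/MAF/HWE defects
    maf_law: tuple[float, float] = (0.05, 0.5)
    n_cases: int = 1205
    n_controls: int = 700
    n_gene_sets: int = 50
    gene_set_size_range: tuple[int, int] = (10, 200)
    annotation_enrichment_odds: float = 20.0
    seed: int = 0

    def validate(self, check_evidence: bool = True) -> None:
        if self.n_genes < 0 or self.n_snps < 0 or self.n_linkage_intervals < 0:
            raise ConfigError("counts must be non-negative")
        if not (0.0 <= self.cross_species_overlap <= 1.0):
            raise ConfigError("cross_species_overlap must be in [0, 1]")
        if not (0.0 < self.planted_effect <= 1.0):
            raise ConfigError("planted_effect (Beta shape a) must be in (0, 1]")
        if check_evidence:
            for src, c in self.evidence_counts.items():
                if c < 0:
                    raise ConfigError(f"negative evidence count for {src}")
                if c > self.n_genes:
                    raise ConfigError(f"evidence count for {src} exceeds n_genes")


@dataclass
class TruthSet:
    """Exact generator-side memberships used to verify downstream stages."""

    memberships: dict[str, set[str]] = field(default_factory=dict)
    planted_genes: list[str] = field(default_factory=list)
    snp_is_alt: dict[str, bool] = field(default_factory=dict)


@dataclass
class EvidenceBundle:
    source_sets: dict[str, set[str]]          # human gene ids per list source
    ortholog_maps: dict[str, list[tuple[str, str]]]  # species -> (src id, human id)
    linkage_intervals: pd.DataFrame


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _draw_lengths(law, n, rng) -> np.ndarray:
    name, params = law
    if name == "uniform":
        low, high = params
        lens = rng.uniform(low, high, size=n)
    elif name == "lognormal":
        mu, sigma = params
        lens = rng.lognormal(mu, sigma, size=n)
    else:
        raise ConfigError(f"unknown gene_length_law {name!r}")
    return np.maximum(1, np.round(lens)).astype(np.int64)


def generate_gene_universe(config: SimulationConfig, rng=None) -> pd.DataFrame:
    """Place ``n_genes`` genes on the configured chromosomes.

    Coordinates are 1-based inclusive.  Genes may overlap unless
    ``allow_gene_overlap`` is off, in which case each chromosome is packed
    with random gaps.
    """
    config.validate(check_evidence=False)
    rng = rng if rng is not None else _rng(config, 1)
    cols = crio.GENE_COLUMNS
    if config.n_genes == 0:
        return pd.DataFrame(columns=cols)
    chroms = list(config.chrom_layout)
    if not chroms:
        raise ConfigError("chrom_layout is empty")
    names = np.array([c[0] for c in chroms])
    sizes = np.array([c[1] for c in chroms], dtype=np.int64)
    lengths = _draw_lengths(config.gene_length_law, config.n_genes, rng)
    probs = sizes / sizes.sum()
    chrom_idx = rng.choice(len(chroms), size=config.n_genes, p=probs)

    starts = np.empty(config.n_genes, dtype=np.int64)
    for ci in range(len(chroms)):
        mask = chrom_idx == ci
        if not mask.any():
            continue
        lens_c = lengths[mask]
        too_long = lens_c > sizes[ci]
        if too_long.any():
            raise ConfigError(
                f"gene of length {int(lens_c[too_long].max())} bp cannot be "
                f"placed on {names[ci]} ({int(sizes[ci])} bp)"
            )
        if config.allow_gene_overlap:
            starts[mask] = rng.integers(1, sizes[ci] - lens_c + 2)
        else:
            free = sizes[ci] - int(lens_c.sum())
            if free < 0:
                raise ConfigError(
                    f"total gene footprint exceeds chromosome {names[ci]}"
                )
            k = int(mask.sum())
            gaps = np.floor(rng.dirichlet(np.ones(k + 1)) * free).astype(np.int64)
            pos, ss = 1, []
            for g, ln in zip(gaps[:-1], lens_c):
                pos += int(g)
                ss.append(pos)
                pos += int(ln)
            starts[mask] = np.array(ss, dtype=np.int64)

    df = pd.DataFrame(
        {
            "gene_id": [f"G{i:05d}" for i in range(config.n_genes)],
            "symbol": [f"GENE{i:05d}" for i in range(config.n_genes)],
            "chrom": names[chrom_idx],
            "start": starts,
            "end": starts + lengths - 1,
        }
    )
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def _reuse_probability(f: float, m: int, later: int) -> float:
    """Per-slot probability that a later-species draw reuses a gene already
    used by exactly one other species, so that the expected fraction of
    distinct evidence genes seen in ≥2 species equals ``f``."""
    if later == 0:
        return 0.0
    p = f * (m + later) / (later * (1.0 + f))
    return min(1.0, max(0.0, p))


def generate_evidence(
    gene_table: pd.DataFrame, config: SimulationConfig, rng=None
) -> tuple[EvidenceBundle, TruthSet]:
    """Draw the six evidence lists with controlled cross-species overlap,
    build 1:1 ortholog maps for worm and fly, and place linkage intervals.

    Sources within one species are drawn disjoint; the controlled quantity
    is the fraction of distinct evidence genes that appear in at least two
    species.
    """
    config.validate()
    rng = rng if rng is not None else _rng(config, 2)
    counts = {s: int(config.evidence_counts.get(s, 0)) for s in LIST_SOURCES}
    species_order = ["mouse", "human", "fly", "worm"]
    per_species = {
        sp: [s for s in LIST_SOURCES if SOURCE_SPECIES[s] == sp and counts[s] > 0]
        for sp in species_order
    }
    active = [sp for sp in species_order if per_species[sp]]
    gene_ids = list(gene_table["gene_id"]) if len(gene_table) else []
    total_needed = {sp: sum(counts[s] for s in per_species[sp]) for sp in active}
    for sp in active:
        if total_needed[sp] > len(gene_ids):
            raise ConfigError(f"{sp} sources request more genes than the universe holds")

    f = config.cross_species_overlap
    if active:
        m = total_needed[active[0]]
        later = sum(total_needed[sp] for sp in active[1:])
        p_reuse = _reuse_probability(f, m, later)
        if f < 1.0 and later > 0 and f * m > later:
            raise ConfigError(
                "requested cross_species_overlap is infeasible for these counts"
            )
    else:
        p_reuse = 0.0

    species_of: dict[str, set[str]] = {}
    never_used = list(gene_ids)
    rng.shuffle(never_used)
    source_sets: dict[str, set[str]] = {s: set() for s in LIST_SOURCES}

    for si, sp in enumerate(active):
        sp_genes: set[str] = set()
        for src in per_species[sp]:
            chosen: set[str] = set()
            for _ in range(counts[src]):
                gid = None
                if si > 0 and rng.uniform() < p_reuse:
                    pool = [
                        g
                        for g, sps in species_of.items()
                        if len(sps) == 1 and sp not in sps and g not in sp_genes
                    ]
                    if pool:
                        gid = pool[int(rng.integers(len(pool)))]
                if gid is None:
                    while never_used and (
                        never_used[-1] in sp_genes or never_used[-1] in species_of
                    ):
                        never_used.pop()
                    if never_used:
                        gid = never_used.pop()
                    else:  # universe exhausted: reuse any gene not yet in species
                        pool = [g for g in species_of if g not in sp_genes]
                        if not pool:
                            raise ConfigError("cannot satisfy evidence counts")
                        gid = pool[int(rng.integers(len(pool)))]
                chosen.add(gid)
                sp_genes.add(gid)
                species_of.setdefault(gid, set()).add(sp)
            source_sets[src] = chosen

    ortholog_maps = {
        sp: [(NONHUMAN_PREFIX[sp] + g, g) for src in per_species.get(sp, []) for g in sorted(source_sets[src])]
        for sp in ("worm", "fly")
    }

    intervals = _place_intervals(config, rng)
    hulink = _genes_in_intervals(gene_table, intervals)

    truth = TruthSet(
        memberships={**{s: set(v) for s, v in source_sets.items()}, "HuLink": hulink}
    )
    return EvidenceBundle(source_sets, ortholog_maps, intervals), truth


def _place_intervals(config: SimulationConfig, rng) -> pd.DataFrame:
    rows = []
    chroms = list(config.chrom_layout)
    for i in range(config.n_linkage_intervals):
        ci = int(rng.integers(len(chroms)))
        name, size = chroms[ci]
        span = min(config.interval_span_bp, size)
        start = int(rng.integers(1, size - span + 2))
        rows.append(
            {"chrom": name, "start": start, "end": start + span - 1, "label": f"L{i + 1}"}
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


def _genes_in_intervals(gene_table: pd.DataFrame, intervals: pd.DataFrame) -> set[str]:
    hits: set[str] = set()
    if not len(gene_table):
        return hits
    for _, iv in intervals.iterrows():
        sel = (
            (gene_table["chrom"] == iv["chrom"])
            & (gene_table["start"] <= iv["end"])
            & (gene_table["end"] >= iv["start"])
        )
        hits.update(gene_table.loc[sel, "gene_id"])
    return hits


def _resolve_planted(gene_table, truth: TruthSet, config: SimulationConfig) -> list[str]:
    if isinstance(config.planted_genes, str):
        if config.planted_genes != "top-evidence":
            raise ConfigError(f"unknown planted_genes spec {config.planted_genes!r}")
        species_count: dict[str, set[str]] = {}
        source_count: dict[str, int] = {}
        for src, members in truth.memberships.items():
            if src == "HuLink":
                continue
            for g in members:
                species_count.setdefault(g, set()).add(SOURCE_SPECIES[src])
                source_count[g] = source_count.get(g, 0) + 1
        ranked = sorted(
            species_count,
            key=lambda g: (-len(species_count[g]), -source_count[g], g),
        )
        return ranked[: config.n_planted]
    planted = list(config.planted_genes)
    universe = set(gene_table["gene_id"])
    missing = [g for g in planted if g not in universe]
    if missing:
        raise ConfigError(f"planted genes absent from universe: {missing[:5]}")
    return planted


def _merged_regions(gene_table, gene_ids, flank, chrom_sizes):
    """Merged (chrom -> list of [lo, hi]) 1-based inclusive gene±flank windows."""
    regions: dict[str, list[list[int]]] = {}
    sel = gene_table[gene_table["gene_id"].isin(set(gene_ids))]
    for chrom, grp in sel.groupby("chrom"):
        ivs = sorted(
            (max(1, int(s) - flank), min(chrom_sizes[chrom], int(e) + flank))
            for s, e in zip(grp["start"], grp["end"])
        )
        merged = []
        for lo, hi in ivs:
            if merged and lo <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        regions[chrom] = merged
    return regions


def _sample_positions(regions_bp: list[tuple[str, int, int]], n, rng):
    """Uniform positions over a list of (chrom, lo, hi) 1-based segments."""
    if n == 0 or not regions_bp:
        return np.array([], dtype=object), np.array([], dtype=np.int64)
    lens = np.array([hi - lo + 1 for _, lo, hi in regions_bp], dtype=np.int64)
    cum = np.cumsum(lens)
    draws = rng.integers(0, cum[-1], size=n)
    seg = np.searchsorted(cum, draws, side="right")
    offset = draws - (cum[seg] - lens[seg])
    chroms = np.array([regions_bp[i][0] for i in seg], dtype=object)
    pos = np.array([regions_bp[i][1] for i in seg], dtype=np.int64) + offset
    return chroms, pos


def generate_gwas(
    gene_table: pd.DataFrame,
    truth: TruthSet,
    config: SimulationConfig,
    rng=None,
) -> pd.DataFrame:
    """Emit the GWAS marker table and record per-SNP null/alternative truth.

    Marker density inside gene±flank windows is ``snp_density`` times the
    intergenic density.  Null markers draw p ~ Uniform(0,1); markers inside
    planted-gene windows draw p ~ Beta(a,1).  A ``defect_rate`` fraction of
    markers receives a QC defect (low call rate, MAF below 1%, or an
    HWE-violating genotype distribution) to exercise the filters.
    """
    config.validate(check_evidence=False)
    rng = rng if rng is not None else _rng(config, 3)
    if not config.chrom_layout:
        raise ConfigError("zero chromosomes")
    chrom_sizes = dict(config.chrom_layout)
    planted = _resolve_planted(gene_table, truth, config)
    truth.planted_genes = planted

    genic = _merged_regions(gene_table, gene_table["gene_id"], config.flank_bp, chrom_sizes)
    genic_bp = [(c, lo, hi) for c, segs in genic.items() for lo, hi in segs]
    g_len = sum(hi - lo + 1 for _, lo, hi in genic_bp)
    t_len = sum(chrom_sizes.values())
    inter_len = t_len - g_len
    d = config.snp_density
    w_genic = (g_len * d) / (g_len * d + inter_len) if g_len else 0.0
    n_genic = int(rng.binomial(config.n_snps, w_genic)) if config.n_snps else 0

    gc, gp = _sample_positions(genic_bp, n_genic, rng)
    # intergenic complement per chromosome
    inter_bp = []
    for chrom, size in chrom_sizes.items():
        pos = 1
        for lo, hi in genic.get(chrom, []):
            if lo > pos:
                inter_bp.append((chrom, pos, lo - 1))
            pos = hi + 1
        if pos <= size:
            inter_bp.append((chrom, pos, size))
    ic, ip = _sample_positions(inter_bp, config.n_snps - n_genic, rng)
    chroms = np.concatenate([gc, ic]) if len(gc) or len(ic) else np.array([], dtype=object)
    pos = np.concatenate([gp, ip]) if len(gp) or len(ip) else np.array([], dtype=np.int64)

    order = np.lexsort((pos, chroms.astype(str)))
    chroms, pos = chroms[order], pos[order]
    n = len(pos)
    snp_ids = [f"rs{i:06d}" for i in range(n)]

    planted_regions = _merged_regions(gene_table, planted, config.flank_bp, chrom_sizes)
    is_alt = np.zeros(n, dtype=bool)
    for chrom, segs in planted_regions.items():
        if not segs:
            continue
        los = np.array([s[0] for s in segs])
        his = np.array([s[1] for s in segs])
        mask = chroms == chrom
        idx = np.searchsorted(los, pos[mask], side="right") - 1
        ok = (idx >= 0) & (pos[mask] <= his[np.clip(idx, 0, len(his) - 1)])
        sub = np.where(mask)[0]
        is_alt[sub[ok]] = True

    a = config.planted_effect
    p = rng.uniform(size=n)
    if is_alt.any():
        p[is_alt] = rng.beta(a, 1.0, size=int(is_alt.sum()))
    p = np.clip(p, 1e-300, 1.0)

    call_rate = rng.uniform(0.97, 1.0, size=n)
    maf = rng.uniform(*config.maf_law, size=n)
    hwe_p = rng.uniform(1e-6, 1.0, size=n)
    n_def = int(rng.binomial(n, config.defect_rate)) if n else 0
    def_idx = rng.choice(n, size=n_def, replace=False) if n_def else np.array([], dtype=int)
    def_kind = rng.integers(0, 3, size=n_def)
    hwe_defect = np.zeros(n, dtype=bool)
    for i, kind in zip(def_idx, def_kind):
        if kind == 0:
            call_rate[i] = rng.uniform(0.85, 0.9499)
        elif kind == 1:
            maf[i] = rng.uniform(0.0, 0.0099)
        else:
            hwe_p[i] = rng.uniform(0.0, 1e-8)
            hwe_defect[i] = True

    df = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chroms.astype(str),
            "pos": pos,
            "p": p,
            "call_rate": np.round(call_rate, 6),
            "maf": np.round(maf, 6),
            "hwe_p": hwe_p,
        }
    )
    if config.emit_genotypes:
        for grp, n_ind in (("case", config.n_cases), ("ctrl", config.n_controls)):
            counts = _genotype_counts(maf, call_rate, hwe_defect, n_ind, rng)
            for j, gt in enumerate(("AA", "Aa", "aa")):
                df[f"{grp}_{gt}"] = counts[:, j]
    truth.snp_is_alt = dict(zip(snp_ids, is_alt.tolist()))
    return df


def _genotype_counts(maf, call_rate, hwe_defect, n_ind, rng):
    n = len(maf)
    out = np.zeros((n, 3), dtype=np.int64)
    n_obs = np.round(call_rate * n_ind).astype(int)
    q = maf
    f_inbreed = np.where(hwe_defect, 0.6, 0.0)
    p_AA = (1 - q) ** 2 + f_inbreed * q * (1 - q)
    p_Aa = np.clip(2 * q * (1 - q) * (1 - f_inbreed), 0, 1)
    p_aa = np.clip(1 - p_AA - p_Aa, 0, 1)
    probs = np.stack([p_AA, p_Aa, p_aa], axis=1)
    probs /= probs.sum(axis=1, keepdims=True)
    for i in range(n):
        out[i] = rng.multinomial(n_obs[i], probs[i])
    return out


def generate_annotations(
    gene_table: pd.DataFrame,
    truth: TruthSet,
    config: SimulationConfig,
    rng=None,
) -> dict[str, list[str]]:
    """Build a GMT-style collection; one designated set ("enriched_set") is
    loaded with planted genes at the configured membership odds."""
    config.validate(check_evidence=False)
    if config.n_gene_sets < 1:
        raise ConfigError("n_gene_sets must be ≥ 1")
    rng = rng if rng is not None else _rng(config, 4)
    gene_ids = np.array(gene_table["gene_id"])
    n_universe = len(gene_ids)
    lo, hi = config.gene_set_size_range
    if lo > n_universe:
        raise ConfigError("gene set size exceeds the universe")
    sets: dict[str, list[str]] = {}
    planted = set(truth.planted_genes)
    if planted:
        size = min(max(lo, 2 * len(planted)), n_universe)
        w = np.where(np.isin(gene_ids, list(planted)), config.annotation_enrichment_odds, 1.0)
        w /= w.sum()
        members = rng.choice(gene_ids, size=size, replace=False, p=w)
        sets["enriched_set"] = sorted(members)
    for i in range(config.n_gene_sets - (1 if planted else 0)):
        size = int(rng.integers(lo, min(hi, n_universe) + 1))
        members = rng.choice(gene_ids, size=size, replace=False)
        sets[f"random_set_{i + 1:03d}"] = sorted(members)
    return sets


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    genes: pd.DataFrame
    evidence: EvidenceBundle
    snps: pd.DataFrame
    annotations: dict[str, list[str]]
    truth: TruthSet


def simulate_study(config: SimulationConfig, outdir=None) -> SimulatedStudy:
    """Run all four generators with seeds fanned out from ``config.seed``;
    optionally write every artifact to ``outdir`` in its on-disk format."""
    genes = generate_gene_universe(config)
    bundle, truth = generate_evidence(genes, config)
    snps = generate_gwas(genes, truth, config)
    annotations = generate_annotations(genes, truth, config)
    study = SimulatedStudy(config, genes, bundle, snps, annotations, truth)
    if outdir is not None:
        write_study(study, outdir)
    return study


def write_study(study: SimulatedStudy, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    crio.write_gene_table(study.genes, outdir / "genes.tsv")
    for src in LIST_SOURCES:
        members = sorted(study.evidence.source_sets.get(src, set()))
        sp = SOURCE_SPECIES[src]
        if sp in NONHUMAN_PREFIX:
            members = [NONHUMAN_PREFIX[sp] + g for g in members]
        crio.write_evidence_list(members, outdir / f"evidence_{src}.tsv", comment=src)
    for sp, pairs in study.evidence.ortholog_maps.items():
        crio.write_ortholog_map(pairs, outdir / f"orthologs_{sp}.tsv")
    crio.write_intervals_bed(study.evidence.linkage_intervals, outdir / "linkage.bed")
    crio.write_snp_table(study.snps, outdir / "snps.tsv")
    crio.write_gmt(study.annotations, outdir / "annotations.gmt")
    crio.write_json_report(
        {
            "planted_genes": sorted(study.truth.planted_genes),
            "memberships": {k: sorted(v) for k, v in study.truth.memberships.items()},
            "config": dataclasses.asdict(study.config),
        },
        outdir / "truth.json",
    )
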