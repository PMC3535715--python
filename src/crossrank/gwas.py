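"""GWAS marker QC and SNP-to-gene mapping.

QC keeps markers whose per-SNP failure rate (1 − call rate) is at most
0.05, whose minor allele frequency is at least 0.01, and whose exact
Hardy-Weinberg test (in controls by default) is not significant at 1e-6.
A marker belongs to a gene if it lies within 10 kb upstream to 10 kb
downstream of the gene body, inclusive at both ends; a marker may belong
to several genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from scipy.special import gammaln

GENOTYPE_COLS = ("case_AA", "case_Aa", "case_aa", "ctrl_AA", "ctrl_Aa", "ctrl_aa")


@dataclass
class QcConfig:
    max_fail_rate: float = 0.05
    min_maf: float = 0.01
    hwe_alpha: float = 1e-6
    hwe_group: str = "controls"  # or "all"

    def __post_init__(self):
        for v in (self.max_fail_rate, self.min_maf, self.hwe_alpha):
            if not (0.0 <= v <= 1.0):
                raise ValueError("QC thresholds must lie in [0, 1]")
        if self.hwe_group not in {"controls", "all"}:
            raise ValueError("hwe_group must be 'controls' or 'all'")


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test p-value for one genotype triple.

    Sums the probabilities of all heterozygote configurations (with allele
    counts fixed) no more probable than the observed one.  Monomorphic
    markers return 1 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype counts")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all-zero genotype counts: HWE undefined")
    n_a = 2 * n_aa + n_Aa
    n_A = 2 * n_AA + n_Aa
    if n_a == 0 or n_A == 0:
        return 1.0
    rare = min(n_a, n_A)
    het_values = np.arange(rare % 2, rare + 1, 2)
    # log P(het) ∝ het·log 2 − log het! − log n_AA! − log n_aa!, allele counts fixed
    n_homr = (rare - het_values) // 2
    n_homc = n - het_values - n_homr
    logp = het_values * math.log(2.0) - (
        gammaln(het_values + 1) + gammaln(n_homr + 1) + gammaln(n_homc + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = n_Aa
    p_obs = probs[het_values == obs]
    if not len(p_obs):  # inconsistent het parity cannot occur with valid counts
        raise ValueError("genotype counts inconsistent with allele counts")
    return float(min(1.0, probs[probs <= p_obs[0] * (1 + 1e-12)].sum()))


def snp_stats(
    case_counts=None,
    control_counts=None,
    n_cases: int | None = None,
    n_controls: int | None = None,
    hwe_group: str = "controls",
):
    """(call_rate, maf, hwe_p) from per-group genotype counts (AA, Aa, aa).

    MAF pools alleles over both groups; the HWE exact test runs in the
    group named by ``hwe_group``.  Call rate is observed/expected genotypes
    when sample totals are given, else NaN.
    """
    groups = [g for g in (case_counts, control_counts) if g is not None]
    if not groups:
        raise ValueError("at least one group's genotype counts required")
    tot = np.sum(groups, axis=0)
    n_geno = int(tot.sum())
    if n_geno == 0:
        raise ValueError("all-zero genotype counts: statistics undefined")
    n_a = 2 * int(tot[2]) + int(tot[1])
    freq = n_a / (2 * n_geno)
    maf = min(freq, 1.0 - freq)
    if hwe_group == "controls" and control_counts is not None:
        hwe_src = control_counts
    else:
        hwe_src = tot
    hwe_p = hwe_exact_p(int(hwe_src[0]), int(hwe_src[1]), int(hwe_src[2]))
    expected = 0
    if n_cases is not None and case_counts is not None:
        expected += n_cases
    if n_controls is not None and control_counts is not None:
        expected += n_controls
    call_rate = n_geno / expected if expected else float("nan")
    return call_rate, maf, hwe_p


def compute_stats_columns(snps: pd.DataFrame, cfg: QcConfig | None = None,
                          n_cases: int | None = None, n_controls: int | None = None) -> pd.DataFrame:
    """Fill call_rate/maf/hwe_p columns from genotype counts where present."""
    cfg = cfg or QcConfig()
    if not all(c in snps.columns for c in GENOTYPE_COLS):
        return snps
    out = snps.copy()
    stats_rows = [
        snp_stats(
            (r.case_AA, r.case_Aa, r.case_aa),
            (r.ctrl_AA, r.ctrl_Aa, r.ctrl_aa),
            n_cases=n_cases,
            n_controls=n_controls,
            hwe_group=cfg.hwe_group,
        )
        for r in out.itertuples()
    ]
    cr, maf, hwe = zip(*stats_rows)
    if n_cases is not None or n_controls is not None:
        out["call_rate"] = cr
    out["maf"] = maf
    out["hwe_p"] = hwe
    return out


def qc_filter(snps: pd.DataFrame, cfg: QcConfig | None = None) -> tuple[pd.DataFrame, dict]:
    """Apply the marker filters; report exclusions by first-failing rule
    (call rate, then MAF, then HWE).  Markers lacking a statistic pass the
    corresponding rule.  Idempotent; order preserved."""
    cfg = cfg or QcConfig()
    n = len(snps)
    fail_call = (
        (1.0 - snps["call_rate"]) > cfg.max_fail_rate
        if "call_rate" in snps.columns
        else pd.Series(False, index=snps.index)
    )
    fail_maf = (
        snps["maf"] < cfg.min_maf
        if "maf" in snps.columns
        else pd.Series(False, index=snps.index)
    )
    fail_hwe = (
        snps["hwe_p"] < cfg.hwe_alpha
        if "hwe_p" in snps.columns
        else pd.Series(False, index=snps.index)
    )
    first_maf = fail_maf & ~fail_call
    first_hwe = fail_hwe & ~fail_call & ~fail_maf
    keep = ~(fail_call | fail_maf | fail_hwe)
    report = {
        "n_input": int(n),
        "n_passed": int(keep.sum()),
        "excluded_call_rate": int(fail_call.sum()),
        "excluded_maf": int(first_maf.sum()),
        "excluded_hwe": int(first_hwe.sum()),
    }
    return snps[keep].reset_index(drop=True), report


def allelic_test(case_alleles, control_alleles) -> float:
    """2×2 allelic chi-square p-value (1 df, no continuity correction).

    ``case_alleles`` / ``control_alleles`` are (count_A, count_a).  A table
    with a zero margin carries no information and returns p = 1.
    """
    a, b = (int(x) for x in case_alleles)
    c, d = (int(x) for x in control_alleles)
    if min(a, b, c, d) < 0:
        raise ValueError("negative allele counts")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty allele table")
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if 0 in margins:
        return 1.0
    chi2 = n * (a * d - b * c) ** 2 / math.prod(margins)
    return float(stats.chi2.sf(chi2, df=1))


def map_snps_to_genes(
    snps: pd.DataFrame, gene_table: pd.DataFrame, flank_bp: int = 10_000
) -> tuple[dict[str, set[str]], dict[str, list[str]], float]:
    """Map each marker to every gene whose ±``flank_bp`` window contains it.

    Returns (snp_id → set of gene_ids incl. empty sets for unmapped
    markers, gene_id → list of snp_ids, mapped fraction).
    """
    trees: dict[str, IntervalTree] = {}
    for r in gene_table.itertuples():
        lo = max(1, int(r.start) - flank_bp)
        hi = int(r.end) + flank_bp
        trees.setdefault(str(r.chrom), IntervalTree()).addi(lo, hi + 1, r.gene_id)
    mapping: dict[str, set[str]] = {}
    gene_index: dict[str, list[str]] = {}
    for r in snps.itertuples():
        tree = trees.get(str(r.chrom))
        hits = {iv.data for iv in tree[int(r.pos)]} if tree is not None else set()
        mapping[r.snp_id] = hits
        for g in hits:
            gene_index.setdefault(g, []).append(r.snp_id)
    n_mapped = sum(1 for v in mapping.values() if v)
    frac = n_mapped / len(mapping) if mapping else 0.0
    return mapping, gene_index, frac


def mapped_percent(n_mapped: int, n_total: int) -> float:
    """Mapped-marker percentage, rounded to one decimal."""
    return round(100.0 * n_mapped / n_total, 1)
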