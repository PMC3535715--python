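"""Gene-length-matched permutation evaluation of a weighting matrix.

For each score cutoff the observed gene set's subset-restricted q-value
bin proportions are compared against B random gene sets of the same size
drawn from the universe restricted to genes within ±50 kb of the observed
set's mean length (longer genes host more markers, so unmatched sampling
would bias the null).  The empirical p for a (cutoff × q-bin) cell is the
fraction of permutations whose bin proportion exceeds the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import qvalue as qv
from .ranking import select_top


class SamplingError(RuntimeError):
    """Matched-length pool too small for the requested sample."""


@dataclass
class PermutationConfig:
    B: int = 100                    # screening default; refinement uses 1000
    length_tol_bp: int = 50_000
    cutoffs: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)   # score ≥ cutoff
    eq_cutoffs: tuple[float, ...] = (2.5,)              # score = cutoff
    q_bins: tuple[float, ...] = qv.DEFAULT_Q_THRESHOLDS
    seed: int = 0
    tie_rule: str = "strict_greater"  # the estimator's "larger than"; or "greater_equal"
    widen_on_small_pool: bool = True
    fdr_method: str = "smoother"

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be ≥ 1")
        if self.length_tol_bp < 0:
            raise ValueError("length_tol_bp must be ≥ 0")
        if self.tie_rule not in {"strict_greater", "greater_equal"}:
            raise ValueError("tie_rule must be strict_greater or greater_equal")


@dataclass
class PermutationReport:
    wsm: str
    table: pd.DataFrame          # one row per (cutoff × q-bin)
    cutoff_summary: pd.DataFrame  # one row per cutoff: n_genes, n_snps, min_q
    B: int

    def min_q(self) -> float:
        vals = self.cutoff_summary["min_q"].dropna()
        return float(vals.min()) if len(vals) else float("nan")

    def pivot(self) -> pd.DataFrame:
        """Rows = q-bins, columns = cutoffs, cells = 'p (observed count)'."""
        t = self.table.copy()
        t["cell"] = [
            "N/A" if not np.isfinite(p) else f"{p:.3f} ({int(c)})"
            for p, c in zip(t["empirical_p"], t["observed_count"])
        ]
        return t.pivot(index="q_threshold", columns="cutoff", values="cell")


def mean_length(gene_ids, gene_table: pd.DataFrame) -> float:
    """Arithmetic mean gene length (end − start + 1) in bp."""
    sel = gene_table[gene_table["gene_id"].isin(set(gene_ids))]
    if not len(sel):
        raise ValueError("empty gene list")
    return float((sel["end"] - sel["start"] + 1).mean())


def sample_matched(
    universe: pd.DataFrame,
    n: int,
    target_len: float,
    cfg: PermutationConfig,
    rng: np.random.Generator,
) -> list[str]:
    """Sample ``n`` distinct genes uniformly from the length-matched pool
    {g : |length(g) − target_len| ≤ length_tol_bp}; optionally double the
    tolerance until the pool is large enough."""
    if not len(universe):
        raise SamplingError("empty universe")
    lengths = (universe["end"] - universe["start"] + 1).to_numpy()
    tol = cfg.length_tol_bp
    widened = 0
    while True:
        pool = universe.loc[np.abs(lengths - target_len) <= tol, "gene_id"].to_numpy()
        if len(pool) >= n:
            break
        if not cfg.widen_on_small_pool:
            raise SamplingError(
                f"matched pool has {len(pool)} genes for a sample of {n} "
                f"(tolerance {tol} bp, widening disabled)"
            )
        tol *= 2
        widened += 1
        if tol > 2 ** 40:
            raise SamplingError("tolerance widening failed to populate the pool")
    if widened:
        warnings.warn(
            f"matched pool widened {widened}× to ±{tol} bp", stacklevel=2
        )
    return list(rng.choice(pool, size=n, replace=False))


def _cutoff_specs(cfg: PermutationConfig):
    return [(f"≥{c:g}", "ge", c) for c in cfg.cutoffs] + [
        (f"={c:g}", "eq", c) for c in cfg.eq_cutoffs
    ]


def permutation_pvalues(
    scores: pd.DataFrame,
    gene_index: dict[str, list[str]],
    snps: pd.DataFrame,
    universe: pd.DataFrame,
    cfg: PermutationConfig,
    rng: np.random.Generator | None = None,
    wsm_name: str = "",
) -> PermutationReport:
    """Empirical permutation p-values for every (score cutoff × q-bin) cell.

    Cells whose observed bin count is zero are reported as N/A (NaN).  The
    add-one estimator (x+1)/(B+1) is reported alongside the plain x/B.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    rows, summary = [], []
    for label, mode, value in _cutoff_specs(cfg):
        obs_genes = list(select_top(scores, value, mode)["gene_id"])
        if not obs_genes:
            summary.append(
                {"cutoff": label, "n_genes": 0, "n_snps": 0, "min_q": float("nan")}
            )
            continue
        target_len = mean_length(obs_genes, universe)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            obs_qv = qv.subset_q(
                snps, obs_genes, gene_index=gene_index, pi0_method=cfg.fdr_method
            )
            obs_bins = qv.bin_q(obs_qv, cfg.q_bins)
            n_bins = len(cfg.q_bins)
            exceed = np.zeros(n_bins, dtype=int)
            perm_prop_sum = np.zeros(n_bins)
            for _ in range(cfg.B):
                rand_genes = sample_matched(universe, len(obs_genes), target_len, cfg, rng)
                rand_qv = qv.subset_q(
                    snps, rand_genes, gene_index=gene_index, pi0_method=cfg.fdr_method
                )
                rand_bins = qv.bin_q(rand_qv, cfg.q_bins)
                for i, (rp, op) in enumerate(
                    zip(rand_bins.proportions, obs_bins.proportions)
                ):
                    perm_prop_sum[i] += rp
                    if (rp > op) if cfg.tie_rule == "strict_greater" else (rp >= op):
                        exceed[i] += 1
        for i, thr in enumerate(cfg.q_bins):
            populated = obs_bins.counts[i] > 0
            rows.append(
                {
                    "cutoff": label,
                    "q_threshold": thr,
                    "observed_count": obs_bins.counts[i],
                    "observed_proportion": obs_bins.proportions[i],
                    "perm_mean_proportion": perm_prop_sum[i] / cfg.B,
                    "empirical_p": exceed[i] / cfg.B if populated else float("nan"),
                    "p_add_one": (exceed[i] + 1) / (cfg.B + 1) if populated else float("nan"),
                    "n_observed_snps": len(obs_qv),
                }
            )
        summary.append(
            {
                "cutoff": label,
                "n_genes": len(obs_genes),
                "n_snps": len(obs_qv),
                "min_q": obs_qv.min_q,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "cutoff",
            "q_threshold",
            "observed_count",
            "observed_proportion",
            "perm_mean_proportion",
            "empirical_p",
            "p_add_one",
            "n_observed_snps",
        ],
    )
    return PermutationReport(wsm_name, table, pd.DataFrame(summary), cfg.B)


def _snps_below(report: PermutationReport, thr: float = 0.5) -> int:
    t = report.table
    sel = t[np.isclose(t["q_threshold"], thr)]
    return int(sel["observed_count"].sum()) if len(sel) else 0


def _stringent_p(report: PermutationReport) -> float:
    t = report.table
    pop = t[(t["observed_count"] > 0) & np.isfinite(t["empirical_p"])]
    if not len(pop):
        return float("nan")
    thr_min = pop["q_threshold"].min()
    return float(pop.loc[pop["q_threshold"] == thr_min, "empirical_p"].min())


def select_best_matrix(
    reports: dict[str, PermutationReport],
) -> tuple[str, pd.DataFrame]:
    """Order matrices by smallest observed min q over all cutoffs; break
    ties by more observed SNPs with q < 0.5, then by smaller empirical p at
    the most stringent populated bin, then by name.  The full criterion
    values are returned so the choice is auditable."""
    if not reports:
        raise ValueError("no reports to select from")
    rows = []
    for name in sorted(reports):
        rep = reports[name]
        rows.append(
            {
                "wsm": name,
                "min_q": rep.min_q(),
                "n_snps_q_lt_0.5": _snps_below(rep, 0.5),
                "stringent_bin_p": _stringent_p(rep),
            }
        )
    ranking = pd.DataFrame(rows)
    key = ranking.assign(
        _minq=ranking["min_q"].fillna(np.inf),
        _neg=-ranking["n_snps_q_lt_0.5"],
        _p=ranking["stringent_bin_p"].fillna(np.inf),
    ).sort_values(["_minq", "_neg", "_p", "wsm"], kind="stable")
    ranking = key.drop(columns=["_minq", "_neg", "_p"]).reset_index(drop=True)
    return ranking.loc[0, "wsm"], ranking
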