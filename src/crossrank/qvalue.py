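"""False-discovery-rate q-values.

A marker's q-value estimates the proportion of false discoveries among
all markers declared significant when that marker's p-value is used as
the cut-off.  The default estimator is Storey's: π₀ (the null fraction)
is estimated from the flat right tail of the p-value distribution over a
λ grid with a cubic-smoother extrapolation to λ→1, and

    q(i) = min over j with p(j) ≥ p(i) of  π₀ · m · p(j) / rank(j).

With π₀ fixed at 1 this is exactly the Benjamini-Hochberg step-up
adjustment, kept as a fallback and cross-check.  Subset-restricted
q-values are always recomputed from scratch within the subset, never
sliced from a global vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline
from statsmodels.stats.multitest import multipletests

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.96, 0.05), 2)
DEFAULT_Q_THRESHOLDS = (0.9, 0.8, 0.7, 0.6, 0.5, 0.4)

#: below this vector length the λ-grid tail counts are too sparse for the
#: smoother; fall back to a fixed λ = 0.5 estimate
MIN_M_FOR_SMOOTHER = 100


@dataclass
class QVector:
    p: np.ndarray
    q: np.ndarray
    pi0: float
    method: str
    snp_ids: list[str] | None = None

    def __len__(self) -> int:
        return len(self.p)

    @property
    def min_q(self) -> float:
        return float(np.min(self.q)) if len(self.q) else float("nan")


def _validate_p(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = _validate_p(p)
    return multipletests(p, method="fdr_bh")[1]


def estimate_pi0(p, lambda_grid=DEFAULT_LAMBDA_GRID, method: str = "smoother") -> float:
    """Estimate the null proportion π₀ ∈ (0, 1].

    ``method`` is "smoother" (cubic smoothing spline over the λ grid,
    evaluated at the largest λ), "fixed:<λ>", or "bh" (π₀ := 1).
    """
    p = _validate_p(p)
    m = len(p)
    if method == "bh":
        return 1.0
    if method.startswith("fixed"):
        lam = float(method.split(":", 1)[1]) if ":" in method else 0.5
        return _pi0_at(p, m, lam)
    if method != "smoother":
        raise ValueError(f"unknown pi0 method {method!r}")
    if m < MIN_M_FOR_SMOOTHER:
        warnings.warn(
            f"m={m} too small for the π₀ smoother; using fixed λ=0.5", stacklevel=2
        )
        return _pi0_at(p, m, 0.5)
    lam = np.asarray(lambda_grid, dtype=float)
    pi0_vals = np.array([_pi0_at(p, m, l, clip=False) for l in lam])
    spline = UnivariateSpline(lam, pi0_vals, k=3)
    pi0 = float(spline(lam.max()))
    return float(min(1.0, max(pi0, 1.0 / m)))


def _pi0_at(p, m, lam, clip=True) -> float:
    est = np.mean(p > lam) / (1.0 - lam)
    if clip:
        est = min(1.0, max(est, 1.0 / m))
    return float(est)


def storey_q(
    p,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    pi0_method: str = "smoother",
    snp_ids=None,
) -> QVector:
    """Storey q-values for a p-value vector (ties share the max-rank q)."""
    p = _validate_p(p)
    m = len(p)
    pi0 = estimate_pi0(p, lambda_grid, pi0_method)
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    ranks = np.arange(1, m + 1)
    raw = pi0 * m * p_sorted / ranks
    q_sorted = np.minimum(1.0, np.minimum.accumulate(raw[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return QVector(p=p, q=q, pi0=pi0, method=f"storey[{pi0_method}]", snp_ids=snp_ids)


def subset_q(
    snps: pd.DataFrame,
    gene_subset,
    mapping: dict[str, set[str]] | None = None,
    gene_index: dict[str, list[str]] | None = None,
    pi0_method: str = "smoother",
) -> QVector:
    """Q-values recomputed from scratch over the markers mapped to a gene
    subset.  A marker mapped to several subset genes counts once.  Either
    ``mapping`` (snp → genes) or ``gene_index`` (gene → snps) may be given.
    """
    subset = set(gene_subset)
    if gene_index is not None:
        ids = sorted({s for g in subset for s in gene_index.get(g, ())})
    elif mapping is not None:
        ids = sorted(s for s, genes in mapping.items() if genes & subset)
    else:
        raise ValueError("need mapping or gene_index")
    if not ids:
        warnings.warn("empty SNP subset; returning empty QVector", stacklevel=2)
        return QVector(np.array([]), np.array([]), float("nan"), "empty", snp_ids=[])
    sel = snps[snps["snp_id"].isin(ids)]
    return storey_q(sel["p"].to_numpy(), pi0_method=pi0_method, snp_ids=list(sel["snp_id"]))


@dataclass
class QBinTable:
    thresholds: tuple[float, ...]
    counts: list[int]
    proportions: list[float]
    n: int
    min_q: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "q_threshold": self.thresholds,
                "count": self.counts,
                "proportion": self.proportions,
            }
        )


def bin_q(qv: QVector, thresholds=DEFAULT_Q_THRESHOLDS) -> QBinTable:
    """Cumulative counts of q-values strictly below each threshold.

    Thresholds must be strictly decreasing, so counts are non-increasing.
    """
    thresholds = tuple(thresholds)
    if any(b >= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly decreasing")
    n = len(qv)
    counts = [int(np.sum(qv.q < t)) for t in thresholds]
    props = [c / n if n else 0.0 for c in counts]
    return QBinTable(thresholds, counts, props, n, qv.min_q)
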