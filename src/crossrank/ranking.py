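"""Weighted evidence scoring and gene ranking.

Each gene's score is the weighted sum of its eight boolean indicators,

    S = w1·MuAc + w2·MuPref + w3·HuAlc + w4·HuAddChip
        + w5·HuLink + w6·Ce + w7·Dr + w8·Cross,

with the weights supplied by a named weighting score matrix (WSM).  The
ten preset matrices use weights in {0.5, 1} and differ in which evidence
classes they emphasize (human association data, mouse expression, the
cross-species bonus, ...).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evidence import SOURCES

SCORE_TERMS = (*SOURCES, "Cross")  # MuAc, MuPref, HuAlc, HuAddChip, HuLink, Ce, Dr, Cross

#: float tolerance for score threshold comparisons (guards accumulation
#: error with non-preset weights; preset scores are exactly representable)
SCORE_TOL = 1e-9


@dataclass(frozen=True)
class WeightingMatrix:
    name: str
    weights: tuple[float, ...]

    def __post_init__(self):
        if len(self.weights) != len(SCORE_TERMS):
            raise ValueError("a weighting matrix needs exactly 8 weights")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=SCORE_TERMS)


def _wsm(name, *w) -> WeightingMatrix:
    return WeightingMatrix(name, tuple(float(x) for x in w))


#: the ten preset matrices (order of weights follows SCORE_TERMS)
PRESETS: dict[str, WeightingMatrix] = {
    m.name: m
    for m in [
        _wsm("WSM1", 0.5, 0.5, 1, 1, 0.5, 0.5, 0.5, 1),
        _wsm("WSM2", 0.5, 0.5, 1, 1, 0.5, 0.5, 0.5, 0.5),
        _wsm("WSM3", 0.5, 0.5, 0.5, 1, 0.5, 0.5, 0.5, 0.5),
        _wsm("WSM4", 0.5, 0.5, 1, 1, 1, 0.5, 0.5, 0.5),
        _wsm("WSM5", 1, 1, 1, 1, 0.5, 0.5, 0.5, 0.5),
        _wsm("WSM6", 1, 1, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5),
        _wsm("WSM7", 1, 1, 1, 1, 1, 0.5, 0.5, 0.5),
        _wsm("WSM8", 0.5, 0.5, 0.5, 1, 0.5, 0.5, 0.5, 1),
        _wsm("WSM9", 1, 1, 1, 1, 1, 1, 1, 1),
        _wsm("WSM10", 1, 1, 1, 1, 1, 1, 1, 0.5),
    ]
}


def get_matrix(spec) -> WeightingMatrix:
    """Resolve a WeightingMatrix from a preset name, an 8-vector, or itself."""
    if isinstance(spec, WeightingMatrix):
        return spec
    if isinstance(spec, str):
        try:
            return PRESETS[spec]
        except KeyError:
            raise KeyError(f"unknown preset {spec!r}; presets are WSM1..WSM10") from None
    return WeightingMatrix("custom", tuple(float(x) for x in spec))


def score_gene(profile, wsm) -> float:
    """Weighted sum of the eight indicators for one profile (mapping or row)."""
    wsm = get_matrix(wsm)
    return float(
        sum(w * (1.0 if profile[t] else 0.0) for t, w in zip(SCORE_TERMS, wsm.weights))
    )


def rank_genes(
    profiles: pd.DataFrame, wsm, restrict_initial: bool = True
) -> pd.DataFrame:
    """Score every (initial-list) gene and sort by descending score.

    Ties are broken lexicographically by symbol so the order is stable
    across runs.  Returns gene_id, symbol, score plus the indicator columns.
    """
    if not len(profiles):
        raise ValueError("no profiles to rank")
    wsm = get_matrix(wsm)
    sel = profiles[profiles["in_initial_list"]] if restrict_initial else profiles
    ind = sel[list(SCORE_TERMS)].to_numpy(dtype=float)
    scores = ind @ np.asarray(wsm.weights)
    out = sel[["gene_id", "symbol", *SCORE_TERMS]].copy()
    out.insert(2, "score", scores)
    return out.sort_values(
        ["score", "symbol"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def score_distribution(scores: pd.DataFrame) -> pd.Series:
    """Gene count per exact score value (preset scores are multiples of 0.5).

    Counts sum to the number of scored genes.
    """
    if not len(scores):
        return pd.Series(dtype=int)
    return scores["score"].round(9).value_counts().sort_index()


def select_top(scores: pd.DataFrame, threshold: float, mode: str = "ge") -> pd.DataFrame:
    """Genes at or above (mode='ge') or exactly at (mode='eq') a score
    threshold, preserving rank order."""
    if mode == "ge":
        mask = scores["score"] >= threshold - SCORE_TOL
    elif mode == "eq":
        mask = (scores["score"] - threshold).abs() <= SCORE_TOL
    else:
        raise ValueError(f"mode must be 'ge' or 'eq', got {mode!r}")
    return scores[mask].reset_index(drop=True)
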