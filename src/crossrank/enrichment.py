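"""Flat gene-set over-representation analysis and the min-p baseline.

Over-representation of a query gene list in a GMT collection is tested
with the hypergeometric upper tail (computed in log space so the extreme
tails seen with genome-sized backgrounds stay accurate), followed by
Benjamini-Hochberg adjustment within the collection.  The min-p ranking
assigns each gene the smallest association p-value among its mapped
markers — the classic gene-length-biased baseline that cross-species
ranking is compared against.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .qvalue import bh_adjust


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper(k: int, n: int, K: int, N: int) -> float:
    """P(X ≥ k) for X ~ Hypergeometric(N population, K successes, n draws).

    Summed in log space from the largest term for numerical stability at
    very small tail probabilities.
    """
    k, n, K, N = int(k), int(n), int(K), int(N)
    if min(k, n, K, N) < 0 or n > N or K > N or k > min(n, K):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    upper = min(n, K)
    xs = np.arange(k, upper + 1)
    log_terms = _log_comb(K, xs) + _log_comb(N - K, n - xs) - _log_comb(N, n)
    mx = log_terms.max()
    return float(min(1.0, np.exp(mx) * np.exp(log_terms - mx).sum()))


def enrich(
    query,
    collection: dict[str, list[str]],
    background,
    min_overlap: int = 1,
    adjust: str = "within",
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each set of a GMT
    collection, BH-adjusted, sorted ascending by p.

    ``background`` is an iterable of gene ids (the universe) or an explicit
    integer N.  Query genes outside the background are dropped with a
    logged count; set members outside the background are ignored.
    """
    if not collection:
        raise ValueError("empty collection")
    query = set(query)
    if isinstance(background, (int, np.integer)):
        N = int(background)
        bg = None
    else:
        bg = set(background)
        N = len(bg)
        dropped = len(query - bg)
        if dropped:
            warnings.warn(
                f"{dropped} query gene(s) outside the background; dropped",
                stacklevel=2,
            )
        query &= bg
    n = len(query)
    rows = []
    for name, members in collection.items():
        mset = set(members) if bg is None else set(members) & bg
        K = len(mset)
        if K > N:
            raise ValueError(f"set {name!r} larger than the background")
        k = len(query & mset)
        if k < min_overlap:
            continue
        rows.append(
            {
                "set": name,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p": hypergeom_upper(k, n, K, N),
            }
        )
    out = pd.DataFrame(rows, columns=["set", "k", "n", "K", "N", "p"])
    if len(out):
        if adjust == "within":
            out["p_BH"] = bh_adjust(out["p"].to_numpy())
        elif adjust != "none":
            raise ValueError("adjust must be 'within' or 'none'")
        out = out.sort_values(["p", "set"], kind="stable").reset_index(drop=True)
    return out


def min_p_gene_ranking(
    gene_index: dict[str, list[str]],
    snps: pd.DataFrame,
    k: int,
    gene_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Top ``k`` genes by smallest mapped-marker p-value.

    Ties are broken by marker count (more markers first) then by symbol
    (gene_id when no symbol table is supplied).  Genes with no mapped
    markers are excluded; asking for more genes than exist returns all of
    them with a warning.
    """
    if not gene_index:
        raise ValueError("empty SNP-to-gene mapping")
    pmap = dict(zip(snps["snp_id"], snps["p"]))
    symbols = (
        dict(zip(gene_table["gene_id"], gene_table["symbol"]))
        if gene_table is not None
        else {}
    )
    rows = []
    for gid, snp_ids in gene_index.items():
        ps = [pmap[s] for s in snp_ids if s in pmap]
        if not ps:
            continue
        rows.append(
            {
                "gene_id": gid,
                "symbol": symbols.get(gid, gid),
                "min_p": float(min(ps)),
                "n_snps": len(ps),
            }
        )
    df = pd.DataFrame(rows, columns=["gene_id", "symbol", "min_p", "n_snps"])
    df = df.sort_values(
        ["min_p", "n_snps", "symbol"], ascending=[True, False, True], kind="stable"
    ).reset_index(drop=True)
    if k > len(df):
        warnings.warn(
            f"requested top {k} but only {len(df)} genes have mapped markers",
            stacklevel=2,
        )
    return df.head(max(0, int(k))).reset_index(drop=True)
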