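"""Bundled reference tables.

``alcoholism_top47.tsv`` is a published reference list of 47 alcoholism
candidate genes (symbol, Entrez gene id, cross-species evidence score
under the HuAddChip-emphasizing weighting matrix WSM3); six genes score
2.5 and forty-one score 2.0.

``alcoholism_top47_profiles_synthetic.tsv`` is a synthetic reconstruction
of per-source indicator profiles for those 47 genes: only the aggregate
scores are published, so indicator combinations were chosen that
reproduce each printed score under WSM3 while satisfying the Cross rule
(2.5 = MuAc+HuAlc+HuAddChip+Cross; 2.0 = MuAc+MuPref+HuAlc+Cross).  The
file is a test fixture, not biological truth about which sources listed
which gene.

``wsm_score_summary.tsv`` is the published gene-count-per-score summary
for all ten preset weighting matrices over the 2458-gene initial list.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .evidence import SOURCES


def _data_path(name: str):
    return resources.files("crossrank").joinpath("data", name)


def load_top47() -> pd.DataFrame:
    """Published 47-gene candidate list: symbol, gene_id, score."""
    with resources.as_file(_data_path("alcoholism_top47.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"symbol": str, "gene_id": str})


def load_top47_profiles() -> pd.DataFrame:
    """Synthetic indicator profiles reproducing the published scores."""
    with resources.as_file(_data_path("alcoholism_top47_profiles_synthetic.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype={"gene_id": str, "symbol": str})
    for col in (*SOURCES, "Cross", "in_initial_list"):
        df[col] = df[col].astype(bool)
    return df


def load_score_summary() -> pd.DataFrame:
    """Published per-matrix score distribution (long format: wsm, score, count)."""
    with resources.as_file(_data_path("wsm_score_summary.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"wsm": str})
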