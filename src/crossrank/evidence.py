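"""Evidence integration: harmonize per-source gene lists to the human gene
universe, assign linkage-interval membership, and build per-gene evidence
profiles with the cross-species bonus flag.

The seven evidence tracks are MuAc and MuPref (mouse microarray: acute
ethanol response and preference drinking), HuAlc (human alcoholic
prefrontal cortex microarray), HuAddChip (addiction/alcoholism candidate
chip), HuLink (human linkage intervals), Ce (worm) and Dr (fly).  The
Cross flag marks genes with evidence from at least two distinct species,
where linkage-interval membership never counts toward the species tally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from . import io as crio

SOURCES = ("MuAc", "MuPref", "HuAlc", "HuAddChip", "HuLink", "Ce", "Dr")

#: species each source contributes to the Cross tally (HuLink contributes none)
CROSS_SPECIES = {
    "MuAc": "mouse",
    "MuPref": "mouse",
    "HuAlc": "human",
    "HuAddChip": "human",
    "Ce": "worm",
    "Dr": "fly",
}

DEFAULT_INITIAL_SOURCES = ("MuAc", "MuPref", "HuAlc")


@dataclass
class MappingReport:
    n_listed: int = 0
    n_mapped: int = 0
    n_unmapped: int = 0
    unmapped_ids: list[str] = field(default_factory=list)
    n_excluded_not_in_universe: int = 0

    def to_dict(self) -> dict:
        return {
            "n_listed": self.n_listed,
            "n_mapped": self.n_mapped,
            "n_unmapped": self.n_unmapped,
            "unmapped_ids": self.unmapped_ids,
            "n_excluded_not_in_universe": self.n_excluded_not_in_universe,
        }


def load_evidence_list(
    path, species: str, ortholog_map=None
) -> tuple[set[str], MappingReport]:
    """Read one evidence list and return the set of human gene ids it maps to.

    ``species`` is one of human/mouse/worm/fly.  Non-human lists require an
    ortholog map (a path or a list of (source_id, human_id) pairs); a source
    id mapping to several human genes credits every one of them, and ids with
    no mapping are reported, not fatal.  Mouse lists in this pipeline arrive
    already symbol-harmonized, so a map is optional there.
    """
    if species not in {"human", "mouse", "worm", "fly"}:
        raise ValueError(f"unknown species {species!r}")
    listed = crio.read_evidence_list(path)
    report = MappingReport(n_listed=len(listed))
    if ortholog_map is None:
        if species in {"worm", "fly"}:
            raise ValueError(f"{species} evidence list requires an ortholog map")
        report.n_mapped = len(set(listed))
        return set(listed), report
    pairs = (
        crio.read_ortholog_map(ortholog_map)
        if isinstance(ortholog_map, (str, bytes)) or hasattr(ortholog_map, "__fspath__")
        else list(ortholog_map)
    )
    lut: dict[str, set[str]] = {}
    for src, hum in pairs:
        lut.setdefault(src, set()).add(hum)
    mapped: set[str] = set()
    for sid in listed:
        targets = lut.get(sid)
        if targets:
            mapped.update(targets)
            report.n_mapped += 1
        else:
            report.n_unmapped += 1
            report.unmapped_ids.append(sid)
    return mapped, report


def assign_linkage(gene_table: pd.DataFrame, intervals: pd.DataFrame) -> set[str]:
    """Genes whose body [start, end] overlaps any linkage interval by ≥1 bp.

    No flank is applied; a gene spanning several intervals is a member once.
    """
    bad = intervals[intervals["end"] < intervals["start"]]
    if len(bad):
        raise ValueError("malformed linkage interval with end < start")
    members: set[str] = set()
    for _, iv in intervals.iterrows():
        sel = (
            (gene_table["chrom"] == iv["chrom"])
            & (gene_table["start"] <= iv["end"])
            & (gene_table["end"] >= iv["start"])
        )
        members.update(gene_table.loc[sel, "gene_id"])
    return members


def build_profiles(
    gene_table: pd.DataFrame,
    source_sets: dict[str, set[str]],
    initial_sources: tuple[str, ...] = DEFAULT_INITIAL_SOURCES,
) -> tuple[pd.DataFrame, MappingReport]:
    """One evidence profile per universe gene.

    Returns a DataFrame keyed by gene_id with the seven source indicator
    columns, the derived ``Cross`` flag, and ``in_initial_list`` (membership
    in any of ``initial_sources``, the microarray-derived starting list).
    Evidence ids absent from the universe are dropped with a warning and
    counted in the report.
    """
    unknown = set(source_sets) - set(SOURCES)
    if unknown:
        raise ValueError(f"unknown evidence sources: {sorted(unknown)}")
    universe = set(gene_table["gene_id"])
    report = MappingReport()
    clean: dict[str, set[str]] = {}
    for src in SOURCES:
        members = set(source_sets.get(src, set()))
        stray = members - universe
        if stray:
            warnings.warn(
                f"{len(stray)} {src} evidence gene(s) absent from universe; excluded",
                stacklevel=2,
            )
            report.n_excluded_not_in_universe += len(stray)
        clean[src] = members & universe

    prof = gene_table[["gene_id", "symbol"]].copy()
    for src in SOURCES:
        prof[src] = prof["gene_id"].isin(clean[src])
    species_sets = {}
    for src, sp in CROSS_SPECIES.items():
        species_sets.setdefault(sp, []).append(prof[src])
    n_species = sum(
        pd.concat(cols, axis=1).any(axis=1).astype(int) for cols in species_sets.values()
    )
    prof["Cross"] = n_species >= 2
    init = [prof[s] for s in initial_sources]
    prof["in_initial_list"] = pd.concat(init, axis=1).any(axis=1) if init else False
    return prof.reset_index(drop=True), report


def profiles_to_tsv(profiles: pd.DataFrame, path) -> None:
    out = profiles.copy()
    for col in (*SOURCES, "Cross", "in_initial_list"):
        out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", index=False)


def profiles_from_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "symbol": str})
    for col in (*SOURCES, "Cross", "in_initial_list"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df
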