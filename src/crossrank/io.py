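"""Readers and writers for the flat-file formats the pipeline exchanges.

All tables travel as pandas DataFrames.  Genomic coordinates are 1-based
inclusive in memory; BED files on disk are 0-based half-open and converted
at this boundary.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

GENE_COLUMNS = ["gene_id", "symbol", "chrom", "start", "end"]
SNP_COLUMNS = ["snp_id", "chrom", "pos", "p"]


def write_gene_table(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False, columns=[c for c in genes.columns])


def read_gene_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "symbol": str, "chrom": str})
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene table {path} missing columns: {missing}")
    return df


def write_evidence_list(ids: Sequence[str], path, comment: str | None = None) -> None:
    """One identifier per line; lines starting with '#' are comments."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        for gid in ids:
            fh.write(f"{gid}\n")


def read_evidence_list(path) -> list[str]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(line)
    return out


def write_ortholog_map(pairs: Sequence[tuple[str, str]], path) -> None:
    """Two tab-separated columns: source-species id, human gene id."""
    with open(path, "w") as fh:
        fh.write("# source_id\thuman_gene_id\n")
        for src, hum in pairs:
            fh.write(f"{src}\t{hum}\n")


def read_ortholog_map(path) -> list[tuple[str, str]]:
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            src, hum = line.split("\t")[:2]
            pairs.append((src, hum))
    return pairs


def write_intervals_bed(intervals: pd.DataFrame, path) -> None:
    """Write 1-based inclusive intervals as 0-based half-open BED."""
    bed = intervals.copy()
    bed["start"] = bed["start"].astype(int) - 1
    with open(path, "w") as fh:
        for _, row in bed.iterrows():
            label = row.get("label", ".")
            fh.write(f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}\t{label}\n")


def read_intervals_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else "."
            rows.append({"chrom": chrom, "start": start + 1, "end": end, "label": label})
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    bad = df[df["end"] < df["start"]]
    if len(bad):
        raise ValueError(f"malformed interval(s) with end < start in {path}")
    return df


def write_snp_table(snps: pd.DataFrame, path) -> None:
    snps.to_csv(path, sep="\t", index=False)


def read_snp_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    missing = [c for c in SNP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SNP table {path} missing columns: {missing}")
    return df


def read_plink_assoc(path) -> pd.DataFrame:
    """Read a PLINK .assoc-like whitespace table (CHR, SNP, BP, P) into the
    native SNP-table layout."""
    df = pd.read_csv(path, sep=r"\s+", dtype={"SNP": str, "CHR": str})
    need = {"CHR", "SNP", "BP", "P"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"assoc file {path} missing columns: {sorted(missing)}")
    return pd.DataFrame(
        {"snp_id": df["SNP"], "chrom": df["CHR"], "pos": df["BP"], "p": df["P"]}
    )


def write_gmt(sets: Mapping[str, Sequence[str]], path, descriptions: Mapping[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    """GMT: set name, description, then member genes, tab-separated."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed GMT line in {path}: {line!r}")
            out[parts[0]] = parts[2:]
    return out


def write_json_report(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable))


def _jsonable(x):
    try:
        return x.item()  # numpy scalars
    except AttributeError:
        return str(x)
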