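"""Readers and writers for the plain-text formats the pipeline exchanges.

SEG-like segment tables are written 1-based inclusive (the common SEG
convention) and converted to the package's internal 0-based half-open
coordinates at the boundary.  BED arm definitions stay 0-based half-open.
Gene sets use the GMT format; matrices, sample sheets and growth tables are
plain TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .copy_number import SegmentedProfile
from .synthetic_data import GenomeCatalog

SEG_HEADER = ["sample", "chrom", "start", "end", "num_mark", "seg_mean"]


# ---------------------------------------------------------------------------
# SEG segment tables (1-based inclusive on disk)

def write_seg(profiles, path) -> None:
    """Write one or more SegmentedProfiles as a SEG-like TSV."""
    if isinstance(profiles, SegmentedProfile):
        profiles = [profiles]
    rows = []
    for prof in profiles:
        for seg in prof.segments.itertuples(index=False):
            rows.append({
                "sample": prof.sample_id,
                "chrom": seg.chromosome,
                "start": int(seg.start) + 1,     # to 1-based inclusive
                "end": int(seg.end),
                "num_mark": int(seg.n_bins),
                "seg_mean": seg.mean_log2,
            })
    pd.DataFrame(rows, columns=SEG_HEADER).to_csv(path, sep="\t", index=False)


def read_seg(path) -> list[SegmentedProfile]:
    """Read a SEG-like TSV into SegmentedProfiles (one per sample)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    profiles = []
    for sample, grp in df.groupby("sample", sort=False):
        segments = pd.DataFrame({
            "chromosome": grp["chrom"],
            "start": grp["start"].astype(int) - 1,   # to 0-based half-open
            "end": grp["end"].astype(int),
            "mean_log2": grp["seg_mean"].astype(float),
            "median_log2": grp.get("seg_median", grp["seg_mean"]).astype(float),
            "n_bins": grp["num_mark"].astype(int),
        })
        profiles.append(SegmentedProfile(sample_id=str(sample),
                                         segments=segments))
    return profiles


# ---------------------------------------------------------------------------
# BED arm definitions and gene catalog

def write_arms_bed(catalog: GenomeCatalog, path) -> None:
    """Write chromosome arm definitions as BED (chrom, start, end, name)."""
    rows = catalog.arms.assign(
        name=catalog.arms["chromosome"].astype(str) + catalog.arms["arm"])
    rows[["chromosome", "start", "end", "name"]].to_csv(
        path, sep="\t", index=False, header=False)


def read_arms_bed(path) -> pd.DataFrame:
    """Read a BED arm file back into an arms table."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chromosome", "start", "end", "name"],
                     dtype={"chromosome": str})
    df["arm"] = df["name"].str[-1]
    return df[["chromosome", "arm", "start", "end"]]


def write_gene_catalog(catalog: GenomeCatalog, path) -> None:
    catalog.genes.to_csv(path, sep="\t", index=False)


def read_gene_catalog(genes_path, arms_path) -> GenomeCatalog:
    genes = pd.read_csv(genes_path, sep="\t", dtype={"chromosome": str})
    arms = read_arms_bed(arms_path)
    return GenomeCatalog(arms=arms, genes=genes)


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: one set per line (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(gene_sets: dict, path, description: str = "na") -> None:
    lines = ["\t".join([name, description, *map(str, genes)])
             for name, genes in gene_sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# matrices and tables

def read_matrix(path) -> pd.DataFrame:
    """Read a TSV matrix with row ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(table: pd.DataFrame, path, index: bool = False) -> None:
    table.to_csv(path, sep="\t", index=index)
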