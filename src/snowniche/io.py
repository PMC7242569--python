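"""Readers and writers for the pipeline's external formats.

All tabular inputs are tab-separated UTF-8 text with a header row; trees
are newick.  Readers validate strictly and raise :class:`FormatError`
with the offending record named; no science happens here.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

from .containers import (
    AbundanceTable,
    Depth,
    FormatError,
    Location,
    Timepoint,
    TrophicMode,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_metadata",
    "read_abundance_table",
    "write_abundance_table",
    "read_newick",
    "write_newick",
    "read_taxonomy",
    "read_guild_table",
    "write_guild_table",
]

TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus")


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc


def _check_enum(series: pd.Series, enum_cls, column: str) -> None:
    allowed = {e.value for e in enum_cls}
    bad = set(series) - allowed
    if bad:
        raise FormatError(
            f"column {column!r}: invalid value(s) {sorted(bad)}; "
            f"allowed: {sorted(allowed)}"
        )


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata TSV (sample_id, location, depth, timepoint, replicate)."""
    df = _read_tsv(path)
    required = ["sample_id", "location", "depth", "timepoint", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: metadata missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{path}: duplicate sample_id(s) {dupes}")
    _check_enum(df["location"], Location, "location")
    _check_enum(df["depth"], Depth, "depth")
    _check_enum(df["timepoint"], Timepoint, "timepoint")
    return df.set_index("sample_id")


def read_abundance_table(path, metadata_path) -> AbundanceTable:
    """Read an OTU x sample table and its metadata; normalize per sample.

    The table may contain counts or proportions; each column is divided
    by its sum, so the result always holds within-sample proportions.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].tolist()
        raise FormatError(f"{path}: duplicate OTU id(s) {dupes}")
    if raw.columns.has_duplicates:
        dupes = raw.columns[raw.columns.duplicated()].tolist()
        raise FormatError(f"{path}: duplicate sample id(s) {dupes}")
    values = raw.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        raise FormatError(f"{path}: non-numeric or missing abundance values")
    if (values.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative abundance values")
    sums = values.sum(axis=0)
    zero = sums.index[sums == 0].tolist()
    if zero:
        raise FormatError(f"{path}: sample(s) with zero total abundance: {zero}")
    metadata = read_metadata(metadata_path)
    missing = values.columns.difference(metadata.index).tolist()
    if missing:
        raise FormatError(f"samples missing from metadata: {missing}")
    table = AbundanceTable(values, metadata.loc[values.columns])
    return table.normalize()


def write_abundance_table(table: AbundanceTable, path, metadata_path=None) -> None:
    table.data.to_csv(path, sep="\t", index_label="otu_id", float_format="%.12g")
    if metadata_path is not None:
        table.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")


def read_newick(path) -> skbio.TreeNode:
    """Read a single rooted newick tree with branch lengths.

    Raises :class:`FormatError` on duplicate tip labels or negative
    branch lengths; unlabeled internal nodes are permitted.
    """
    try:
        tree = skbio.TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parse error types
        raise FormatError(f"{path}: cannot parse newick ({exc})") from exc
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        seen: set = set()
        dupes = sorted({name for name in tips if name in seen or seen.add(name)})
        raise FormatError(f"{path}: duplicate tip label(s) {dupes}")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise FormatError(
                f"{path}: negative branch length at {node.name or 'internal node'}"
            )
    return tree


def write_newick(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_taxonomy(path) -> pd.DataFrame:
    """Read OTU -> ranked lineage TSV; missing ranks become 'unassigned'."""
    df = _read_tsv(path)
    if "otu_id" not in df.columns:
        raise FormatError(f"{path}: taxonomy must have an 'otu_id' column")
    if df["otu_id"].duplicated().any():
        dupes = df.loc[df["otu_id"].duplicated(), "otu_id"].tolist()
        raise FormatError(f"{path}: duplicate otu_id(s) {dupes}")
    df = df.set_index("otu_id")
    df = df.fillna("unassigned").replace("", "unassigned")
    return df


def read_guild_table(path) -> pd.Series:
    """Read OTU -> trophic mode TSV.

    Recognized modes are matched case-insensitively; unrecognized
    strings map to ``other`` with a logged warning, and missing/blank
    annotations map to ``unknown``.  Returns a Series indexed by otu_id.
    """
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: guild table needs otu_id and trophic_mode columns")
    otu_col, guild_col = df.columns[:2]
    if df[otu_col].duplicated().any():
        dupes = df.loc[df[otu_col].duplicated(), otu_col].tolist()
        raise FormatError(f"{path}: duplicate otu_id(s) {dupes}")
    lookup = {m.value.lower(): m.value for m in TrophicMode}
    out = {}
    n_other = 0
    for otu, raw in zip(df[otu_col], df[guild_col]):
        if pd.isna(raw) or str(raw).strip() == "":
            out[otu] = TrophicMode.UNKNOWN.value
            continue
        mode = lookup.get(str(raw).strip().lower())
        if mode is None:
            n_other += 1
            logger.warning("unrecognized guild %r for %s; mapped to 'other'", raw, otu)
            mode = TrophicMode.OTHER.value
        out[otu] = mode
    if n_other:
        logger.warning("%d OTU(s) had unrecognized guild strings", n_other)
    return pd.Series(out, name="trophic_mode", dtype=object)


def write_guild_table(guilds: pd.Series, path) -> None:
    guilds.rename("trophic_mode").to_csv(path, sep="\t", index_label="otu_id")
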