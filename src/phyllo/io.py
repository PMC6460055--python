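"""Readers and writers for the pipeline's plain-text formats.

Count tables, taxonomy and metadata travel as TSV; trees as newick;
z-stacks as multi-page TIFF. Readers validate structure and report the
offending line on parse failures; write → read round-trips are exact.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skbio import TreeNode

from .containers import ASVTable, ValidationError, ZStack

__all__ = [
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "read_newick",
    "write_newick",
    "read_stack",
    "write_stack",
    "load_asv_table",
    "write_ground_truth",
]


def _parse_error(path, line_no: int, msg: str) -> ValidationError:
    return ValidationError(f"{path}:{line_no}: {msg}")


def read_counts(path) -> pd.DataFrame:
    """Read a samples × ASVs count TSV (first column ``sample_id``)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if len(cols) < 2 or cols[0] != "sample_id":
            raise _parse_error(path, 1, "header must start with 'sample_id'")
        asv_ids = cols[1:]
        if len(set(asv_ids)) != len(asv_ids):
            raise _parse_error(path, 1, "duplicated ASV ids in header")
        rows, ids = [], []
        for line_no, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(cols):
                raise _parse_error(
                    path, line_no, f"expected {len(cols)} fields, got {len(parts)}"
                )
            sid = parts[0]
            if sid in ids:
                raise _parse_error(path, line_no, f"duplicated sample id {sid!r}")
            try:
                rows.append([int(v) for v in parts[1:]])
            except ValueError as exc:
                raise _parse_error(path, line_no, f"count parse failure: {exc}")
            ids.append(sid)
    counts = pd.DataFrame(rows, index=ids, columns=asv_ids, dtype=np.int64)
    counts.index.name = "sample_id"
    return counts


def write_counts(counts: pd.DataFrame, path) -> None:
    counts = counts.copy()
    counts.index.name = "sample_id"
    counts.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id, site, year, replicate)."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "site", "year", "replicate"):
        if col not in meta.columns:
            raise ValidationError(f"{path}: metadata lacks column {col!r}")
    meta = meta.set_index("sample_id")
    meta["year"] = meta["year"].astype(int)
    meta["replicate"] = meta["replicate"].astype(int)
    return meta


def write_metadata(metadata: pd.DataFrame, path) -> None:
    out = metadata.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_taxonomy(path) -> pd.Series:
    """Read an ASV → 7-rank lineage TSV (asv_id TAB lineage)."""
    tax = pd.read_csv(
        path, sep="\t", header=0, dtype=str, keep_default_na=False
    )
    if tax.shape[1] < 2:
        raise ValidationError(f"{path}: taxonomy needs asv_id and lineage columns")
    tax = tax.set_index(tax.columns[0])
    series = tax[tax.columns[0]]
    series.name = "lineage"
    if series.index.has_duplicates:
        dups = series.index[series.index.duplicated()].unique()
        raise ValidationError(f"{path}: duplicated ASV ids: {', '.join(dups)}")
    return series


def write_taxonomy(taxonomy: pd.Series, path) -> None:
    out = taxonomy.rename("lineage").to_frame()
    out.index.name = "asv_id"
    out.to_csv(path, sep="\t")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_stack(
    path, pixel_xy_um: float = 1.8, z_step_um: float = 6.6, bit_depth: int = 8
) -> ZStack:
    """Read a multi-page TIFF as a z-stack; geometry comes from the caller."""
    vol = tifffile.imread(str(path))
    if vol.ndim == 2:
        vol = vol[None, :, :]
    return ZStack(
        intensities=vol,
        pixel_xy_um=pixel_xy_um,
        z_step_um=z_step_um,
        bit_depth=bit_depth,
    )


def write_stack(stack: ZStack, path) -> None:
    tifffile.imwrite(str(path), stack.intensities, photometric="minisblack")


def load_asv_table(counts_path, metadata_path) -> ASVTable:
    """Load counts + metadata and validate that they cover each other."""
    counts = read_counts(counts_path)
    metadata = read_metadata(metadata_path)
    missing = counts.index.difference(metadata.index)
    if len(missing):
        raise ValidationError(
            f"{metadata_path}: metadata missing samples: "
            + ", ".join(map(str, missing))
        )
    return ASVTable(counts=counts, metadata=metadata.loc[counts.index])


def write_ground_truth(truth, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth.to_jsonable(), fh, indent=1)


def tree_to_newick(tree: TreeNode) -> str:
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()
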