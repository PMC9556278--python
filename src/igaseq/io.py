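"""Readers and writers for the pipeline's file formats.

Dialect: tab-separated UTF-8 text, lines starting with ``#`` ignored,
and the first header cell of a count table is literally ``taxon_id``.
Trees are newick; missing branch lengths are treated as 0 with a
warning, and a trifurcating (unrooted-style) root is midpoint-rooted.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

from .tables import (CountTable, SampleManifest, TaxonomyMap,
                     MANIFEST_REQUIRED, MANIFEST_OPTIONAL)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str,
                       header=0, keep_default_na=False, na_values=[""])


def read_count_table(path) -> CountTable:
    """Read a taxon x sample count table from TSV.

    First column is the taxon id (header cell ``taxon_id``); remaining
    columns are samples.  Non-integer, negative, or duplicated entries
    raise ValueError naming the offending row/column.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                header = line.rstrip("\n").split("\t")
                break
        else:
            raise ValueError(f"{path}: no header line found")
    if header[0] != "taxon_id":
        raise ValueError(
            f"{path}: first header cell must be 'taxon_id', got {header[0]!r}")
    seen = set()
    for cell in header[1:]:
        if cell in seen:
            raise ValueError(f"{path}: duplicated sample header {cell!r}")
        seen.add(cell)
    raw = _read_tsv(path)
    data = raw.set_index("taxon_id")
    parsed = {}
    for col in data.columns:
        # strict integer parse so 1.5 or 'x' is caught with its location
        try:
            parsed[col] = data[col].astype(np.int64)
        except (ValueError, TypeError):
            for taxon, cell in data[col].items():
                try:
                    int(str(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-integer count {cell!r} at taxon "
                        f"{taxon!r}, sample {col!r}"
                    ) from None
            raise
    frame = pd.DataFrame(parsed, index=data.index)
    frame.index.name = "taxon_id"
    return CountTable(frame)


def write_count_table(table: CountTable, path) -> None:
    out = table.data.copy()
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


def read_manifest(path) -> SampleManifest:
    """Read and validate a sample manifest TSV.

    Required columns: sample_id, subject_id, site, fraction, group.
    Optional: basdai (blank = missing), sex, age.
    """
    path = Path(path)
    raw = _read_tsv(path)
    missing = [c for c in MANIFEST_REQUIRED if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing required column(s) {missing}")
    keep = [c for c in raw.columns if c in MANIFEST_REQUIRED + MANIFEST_OPTIONAL]
    return SampleManifest(raw[keep])


def write_manifest(manifest: SampleManifest, path) -> None:
    manifest.data.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_taxonomy(path) -> TaxonomyMap:
    """Read a taxon_id -> lineage TSV (columns taxon_id, kingdom..genus[,species])."""
    return TaxonomyMap(_read_tsv(path))


def read_tree(path_or_str) -> skbio.TreeNode:
    """Read a rooted phylogenetic tree from newick.

    Missing branch lengths become 0 with a warning.  A trifurcating
    root (the usual serialization of an unrooted tree) is midpoint
    rooted, with a warning, because UniFrac needs a root.
    """
    if isinstance(path_or_str, str) and path_or_str.lstrip().startswith("("):
        handle = _io.StringIO(path_or_str)
        name = "<string>"
    else:
        handle = str(path_or_str)
        name = str(path_or_str)
    try:
        tree = skbio.TreeNode.read(handle, format="newick")
    except Exception as exc:
        raise ValueError(f"{name}: unparseable newick ({exc})") from exc
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
    if n_missing:
        logger.warning("%s: %d branch(es) lacked a length; set to 0", name, n_missing)
    if len(tree.children) > 2:
        logger.warning("%s: trifurcating root; midpoint-rooting", name)
        tree = tree.root_at_midpoint()
        for node in tree.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
    if len(tree.children) > 2:
        # midpoint of a perfectly balanced polytomy is the root itself;
        # resolve with a zero-length internal branch (distance-neutral)
        rest = tree.children[1:]
        for child in rest:
            tree.remove(child)
        group = skbio.TreeNode(length=0.0, children=list(rest))
        tree.append(group)
    return tree


def write_tree(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def write_result_table(frame: pd.DataFrame, path, index: bool = False) -> None:
    """Write an analysis result table with a fixed float format.

    One writer for every emitted TSV keeps runs byte-reproducible.
    """
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
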