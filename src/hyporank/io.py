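"""Readers and writers: counts TSV, labels TSV, 10x triplet dirs, tree JSON.

Readers validate and reject malformed input rather than silently coercing;
every writer produces files its paired reader accepts unchanged.  The tree
JSON schema is the canonical exchange format for ensembles; unknown fields
on nodes and documents are preserved across a load/save round trip.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from hyporank.cart import DecisionTree, Leaf, Node, Split
from hyporank.ensemble import TreeEnsemble
from hyporank.ranks import ExpressionMatrix
from hyporank.simulate import LabeledDataset

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_labels_tsv",
    "write_labels_tsv",
    "read_mtx_dir",
    "write_mtx_dir",
    "read_spot_coords",
    "load_trees",
    "save_trees",
]

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# counts / labels TSV


def read_counts_tsv(path: Union[str, Path]) -> ExpressionMatrix:
    """Read a genes-by-samples TSV (gene IDs in the first column).

    Non-numeric cells are rejected with their row and column; duplicate
    gene IDs and negative values are rejected by matrix validation.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        gene_i, sample_i = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {raw.iat[gene_i, sample_i]!r} at gene "
            f"{raw.index[gene_i]!r}, sample {raw.columns[sample_i]!r} in {path}"
        )
    if numeric.isna().to_numpy().any():
        raise ValueError(f"missing values in counts file {path}")
    return ExpressionMatrix(numeric)


def write_counts_tsv(matrix: ExpressionMatrix, path: Union[str, Path]) -> None:
    frame = matrix.data
    if np.allclose(frame.to_numpy() % 1, 0):
        frame = frame.astype(np.int64)
    frame.to_csv(path, sep="\t", index_label="gene")


def read_labels_tsv(path: Union[str, Path]) -> pd.Series:
    """Read a two-column sample/label TSV into a Series."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"labels file {path} needs two columns (sample, label)")
    labels = pd.Series(
        frame.iloc[:, 1].to_numpy(), index=frame.iloc[:, 0].to_numpy(), name="label"
    )
    if labels.index.has_duplicates:
        raise ValueError(f"duplicate sample IDs in labels file {path}")
    return labels


def write_labels_tsv(labels: pd.Series, path: Union[str, Path]) -> None:
    labels.rename("label").rename_axis("sample").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# 10x-style Matrix Market triplet directories


def _find(dirpath: Path, stems: list[str]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            candidate = dirpath / name
            if candidate.exists():
                return candidate
    raise FileNotFoundError(f"none of {stems} found in {dirpath}")


def _read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, dtype=str)


def _deduplicate(names: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}-{seen[name]}")
        else:
            seen[name] = 0
            out.append(name)
    return out


def read_mtx_dir(path: Union[str, Path]) -> ExpressionMatrix:
    """Read a 10x-style triplet directory into a dense genes-by-spots matrix.

    Expects ``matrix.mtx``, ``features.tsv`` (or ``genes.tsv``) and
    ``barcodes.tsv``, each optionally gzipped.  The feature table's
    gene-symbol column (second, when present) provides gene IDs, with
    duplicates made unique by suffixing.
    """
    dirpath = Path(path)
    mtx = _find(dirpath, ["matrix.mtx"])
    features = _read_table(_find(dirpath, ["features.tsv", "genes.tsv"]))
    barcodes = _read_table(_find(dirpath, ["barcodes.tsv"]))
    if mtx.suffix == ".gz":
        with gzip.open(mtx, "rt") as handle:
            sparse = scipy.io.mmread(handle)
    else:
        sparse = scipy.io.mmread(mtx)
    n_genes, n_spots = sparse.shape
    if len(features) != n_genes:
        raise ValueError(
            f"feature table has {len(features)} rows but matrix header "
            f"declares {n_genes} genes"
        )
    if len(barcodes) != n_spots:
        raise ValueError(
            f"barcode table has {len(barcodes)} rows but matrix header "
            f"declares {n_spots} spots"
        )
    symbol_col = 1 if features.shape[1] > 1 else 0
    gene_ids = _deduplicate(list(features.iloc[:, symbol_col]))
    dense = np.asarray(sparse.todense(), dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(dense, index=gene_ids, columns=list(barcodes.iloc[:, 0]))
    )


def read_spot_coords(path: Union[str, Path]) -> Optional[pd.DataFrame]:
    """Read ``coords.tsv`` (barcode, x, y) from a triplet directory, if present."""
    candidate = Path(path) / "coords.tsv"
    if not candidate.exists():
        return None
    coords = pd.read_csv(candidate, sep="\t", index_col=0)
    return coords[["x", "y"]]


def write_mtx_dir(
    data: Union[ExpressionMatrix, LabeledDataset],
    path: Union[str, Path],
    compress: bool = False,
) -> None:
    """Write a triplet directory (matrix.mtx, features.tsv, barcodes.tsv).

    For a :class:`LabeledDataset`, spot coordinates and labels are written
    alongside as ``coords.tsv`` and ``labels.tsv``.
    """
    dirpath = Path(path)
    dirpath.mkdir(parents=True, exist_ok=True)
    if isinstance(data, LabeledDataset):
        matrix = data.matrix
        if not isinstance(matrix, ExpressionMatrix):
            raise TypeError("write_mtx_dir expects raw counts, not percentiles")
        if data.coords is not None:
            data.coords.rename_axis("barcode").to_csv(dirpath / "coords.tsv", sep="\t")
        write_labels_tsv(data.labels, dirpath / "labels.tsv")
    else:
        matrix = data

    suffix = ".gz" if compress else ""
    values = matrix.values
    coo = scipy.sparse.coo_matrix(values)
    target = dirpath / "matrix.mtx"
    field = "integer" if np.allclose(values % 1, 0) else "real"
    if field == "integer":
        coo = coo.astype(np.int64)
    scipy.io.mmwrite(target, coo, field=field)
    if compress:
        with open(target, "rb") as fin, gzip.open(str(target) + ".gz", "wb") as fout:
            fout.write(fin.read())
        target.unlink()

    features = pd.DataFrame(
        {0: matrix.gene_ids, 1: matrix.gene_ids, 2: "Gene Expression"}
    )
    features.to_csv(
        dirpath / f"features.tsv{suffix}", sep="\t", header=False, index=False
    )
    pd.Series(matrix.sample_ids).to_csv(
        dirpath / f"barcodes.tsv{suffix}", sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# tree JSON


_NODE_KEYS_SPLIT = {"gene", "threshold", "high", "low", "probability", "fraction"}
_NODE_KEYS_LEAF = {"leaf"}
_LEAF_KEYS = {"class", "probability", "fraction"}


def _node_to_doc(node: Node) -> dict:
    if isinstance(node, Leaf):
        doc = {
            "leaf": {
                "class": node.label,
                "probability": node.probability,
                "fraction": node.fraction,
                **node.extra,
            }
        }
        return doc
    assert isinstance(node, Split)
    doc = {
        "gene": node.gene,
        "threshold": node.threshold,
        "probability": node.probability,
        "fraction": node.fraction,
        "high": _node_to_doc(node.high),
        "low": _node_to_doc(node.low),
        **node.extra,
    }
    return doc


def _node_from_doc(doc: dict, where: str) -> Node:
    if not isinstance(doc, dict):
        raise ValueError(f"malformed node at {where}: expected object, got {type(doc).__name__}")
    if "leaf" in doc:
        leaf = doc["leaf"]
        if not isinstance(leaf, dict) or "probability" not in leaf:
            raise ValueError(f"malformed leaf at {where}: {leaf!r}")
        prob = float(leaf["probability"])
        if not 0.0 <= prob <= 1.0:
            raise ValueError(f"leaf probability {prob} out of [0,1] at {where}")
        extra = {k: v for k, v in leaf.items() if k not in _LEAF_KEYS}
        return Leaf(probability=prob, fraction=float(leaf.get("fraction", np.nan)), extra=extra)
    for key in ("gene", "threshold", "high", "low"):
        if key not in doc:
            raise ValueError(f"malformed node at {where}: missing {key!r} in {sorted(doc)}")
    threshold = float(doc["threshold"])
    if not 0.0 <= threshold <= 100.0:
        raise ValueError(f"threshold {threshold} out of [0,100] at {where}")
    extra = {k: v for k, v in doc.items() if k not in _NODE_KEYS_SPLIT}
    return Split(
        gene=str(doc["gene"]),
        threshold=threshold,
        low=_node_from_doc(doc["low"], where + "/low"),
        high=_node_from_doc(doc["high"], where + "/high"),
        probability=float(doc.get("probability", np.nan)),
        fraction=float(doc.get("fraction", np.nan)),
        extra=extra,
    )


def _tree_to_doc(tree: DecisionTree) -> dict:
    return {
        "tree_id": tree.tree_id,
        "metadata": tree.metadata,
        "root": _node_to_doc(tree.root),
    }


def _tree_from_doc(doc: dict) -> DecisionTree:
    if "root" not in doc:
        raise ValueError(f"tree document missing 'root': {sorted(doc)}")
    tree_id = str(doc.get("tree_id", ""))
    root = _node_from_doc(doc["root"], where=f"tree {tree_id or '?'} root")
    return DecisionTree(root=root, tree_id=tree_id, metadata=dict(doc.get("metadata", {})))


def save_trees(ensemble: TreeEnsemble, path: Union[str, Path]) -> None:
    """Serialize an ensemble to a JSON document."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "provenance": ensemble.provenance,
        "trees": [_tree_to_doc(t) for t in ensemble.trees],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def _id_sort_key(tree: DecisionTree):
    return (0, int(tree.tree_id)) if tree.tree_id.isdigit() else (1, tree.tree_id)


def load_trees(path: Union[str, Path]) -> TreeEnsemble:
    """Load an ensemble from a JSON file or a directory of JSON files.

    Trees are ordered by ``tree_id`` (numeric IDs first, numerically).
    """
    p = Path(path)
    files = sorted(p.glob("*.json")) if p.is_dir() else [p]
    if not files:
        raise FileNotFoundError(f"no tree JSON files found in {p}")
    trees: list[DecisionTree] = []
    provenance: dict = {}
    for file in files:
        doc = json.loads(file.read_text())
        if isinstance(doc, list):
            docs = doc
        elif "trees" in doc:
            provenance.update(doc.get("provenance") or {})
            docs = doc["trees"]
        else:
            docs = [doc]
        trees.extend(_tree_from_doc(d) for d in docs)
    trees.sort(key=_id_sort_key)
    return TreeEnsemble(trees=tuple(trees), provenance=provenance)
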