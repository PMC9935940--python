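"""Reading and writing the plain-text formats the pipeline exchanges.

Counts travel as TSV (genes x samples) or as a MatrixMarket triplet with
``.rows``/``.cols`` name sidecars; annotation as TSV; metadata, proportions,
sizes and ELISA tables as CSV; ground-truth and summary records as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import CountMatrix


def _validate_counts_frame(df: pd.DataFrame) -> pd.DataFrame:
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        col = numeric.columns[numeric.isna().any()][0]
        row = numeric.index[numeric[col].isna()][0]
        raise ValueError(f"non-numeric count at gene {row!r}, sample {col!r}")
    if (numeric < 0).any().any():
        col = numeric.columns[numeric.lt(0).any()][0]
        row = numeric.index[numeric[col].lt(0)][0]
        raise ValueError(f"negative count at gene {row!r}, sample {col!r}")
    return numeric.astype(np.int64)


def write_counts(cm: CountMatrix, path: str | Path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "tsv":
        cm.counts.rename_axis("gene_id").to_csv(path, sep="\t")
    elif fmt == "mtx":
        spio.mmwrite(path, sparse.coo_matrix(cm.counts.to_numpy()))
        path.with_suffix(".rows").write_text("\n".join(map(str, cm.counts.index)) + "\n")
        path.with_suffix(".cols").write_text("\n".join(map(str, cm.counts.columns)) + "\n")
    else:
        raise ValueError(f"unknown counts format {fmt!r}")


def read_counts(path: str | Path, annotation: pd.DataFrame | str | Path) -> CountMatrix:
    """Load counts (TSV or MTX triplet, by extension) plus gene annotation."""
    path = Path(path)
    if path.suffix == ".mtx":
        mat = spio.mmread(path).toarray()
        genes = path.with_suffix(".rows").read_text().splitlines()
        samples = path.with_suffix(".cols").read_text().splitlines()
        df = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    df = _validate_counts_frame(df)
    df.index.name = "gene_id"
    df.columns.name = None
    if not isinstance(annotation, pd.DataFrame):
        annotation = read_annotation(annotation)
    return CountMatrix(df, annotation.loc[df.index])


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.rename_axis("gene_id").to_csv(path, sep="\t")


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col=0)
    ann["is_ribo_or_mito"] = ann["is_ribo_or_mito"].astype(bool)
    return ann


def write_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.rename_axis("sample_id").to_csv(path)


def read_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, index_col=0)
    meta["trisomic"] = meta["trisomic"].astype(bool)
    return meta


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")
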