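"""Readers and writers for the plain-text interchange formats.

Counts travel as MatrixMarket (.mtx) plus gene and sample TSVs, gene sets
as GMT, expression and result tables as TSV with genes in rows and a
mandatory header.  Every writer here round-trips with its reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse

from .containers import CohortCounts, ExprMatrix


# ---------------------------------------------------------------- counts

def write_counts(cohort: CohortCounts, prefix: str | Path) -> None:
    """Write counts as ``<prefix>.mtx`` + ``<prefix>.genes.tsv`` + ``<prefix>.samples.tsv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mat = sparse.csr_matrix(cohort.counts.values)
    sio.mmwrite(str(prefix) + ".mtx", mat, field="integer")
    pd.Series(cohort.counts.index, name="gene").to_csv(
        str(prefix) + ".genes.tsv", sep="\t", index=False
    )
    cohort.samples.to_csv(str(prefix) + ".samples.tsv", sep="\t", index_label="sample_id")


def read_counts(prefix: str | Path) -> CohortCounts:
    prefix = Path(prefix)
    mat = sio.mmread(str(prefix) + ".mtx")
    genes = pd.read_csv(str(prefix) + ".genes.tsv", sep="\t")["gene"].tolist()
    samples = pd.read_csv(str(prefix) + ".samples.tsv", sep="\t", index_col="sample_id")
    counts = pd.DataFrame(
        np.asarray(mat.todense(), dtype=np.int64), index=genes, columns=samples.index
    )
    return CohortCounts(counts=counts, samples=samples)


# ------------------------------------------------------------ expression

def write_expr(expr: ExprMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    expr.values.to_csv(str(prefix) + ".tsv", sep="\t", index_label="gene")
    meta = expr.norm_factors.rename("norm_factor").to_frame()
    meta["offset"] = expr.offset
    meta.to_csv(str(prefix) + ".factors.tsv", sep="\t", index_label="sample_id")


def read_expr(prefix: str | Path) -> ExprMatrix:
    prefix = Path(prefix)
    values = pd.read_csv(str(prefix) + ".tsv", sep="\t", index_col="gene")
    meta = pd.read_csv(str(prefix) + ".factors.tsv", sep="\t", index_col="sample_id")
    return ExprMatrix(
        values=values,
        norm_factors=meta["norm_factor"],
        offset=float(meta["offset"].iloc[0]),
    )


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


# ------------------------------------------------------------------- GMT

def write_gmt(sets: dict, path: str | Path, description: str = "na") -> None:
    """Write gene sets in GMT format: name <tab> description <tab> genes..."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *sorted(map(str, genes))]) + "\n")


def read_gmt(path: str | Path) -> dict:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


# ------------------------------------------------------------------ JSON

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in (sorted(obj) if isinstance(obj, (set, frozenset)) else obj)]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="index"))
    return obj


def write_json(obj, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=1, sort_keys=True)


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
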