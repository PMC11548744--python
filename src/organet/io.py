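"""Readers and writers for the pipeline's plain-text artifacts.

Measurements travel as a long-format Ct CSV (sample_id, gene, Ct) with
a companion per-sample metadata CSV; matrices (normalized expression,
interaction coefficients) are labeled CSV with genes or (organ:gene)
nodes as rows.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

META_COLUMNS = ["strain", "sex", "organ", "age_weeks", "animal_id", "chip_id"]


def write_ct_long(ct: pd.DataFrame, path: str | Path) -> Path:
    """Gene x sample Ct matrix -> long CSV; missing entries are omitted."""
    long = (ct.rename_axis(index="gene", columns="sample_id")
            .stack().rename("Ct").reset_index()
            [["sample_id", "gene", "Ct"]])
    long.to_csv(path, index=False, float_format="%.6f")
    return Path(path)


def read_ct_long(path: str | Path, genes: list[str] | None = None,
                 samples: list[str] | None = None) -> pd.DataFrame:
    """Long CSV -> gene x sample matrix with NaN for absent reactions."""
    long = pd.read_csv(path)
    wide = long.pivot(index="gene", columns="sample_id", values="Ct")
    if genes is not None:
        wide = wide.reindex(genes)
    if samples is not None:
        wide = wide.reindex(columns=samples)
    wide.index.name = None
    wide.columns.name = None
    return wide


def write_meta(meta: pd.DataFrame, path: str | Path) -> Path:
    meta.rename_axis("sample_id").reset_index().to_csv(path, index=False)
    return Path(path)


def read_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path).set_index("sample_id")
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    return meta


def write_node_matrix(K: pd.DataFrame, path: str | Path) -> Path:
    """(organ,gene)-labeled square matrix -> CSV with 'organ:gene' labels."""
    flat = K.copy()
    flat.index = [f"{o}:{g}" for o, g in K.index]
    flat.columns = [f"{o}:{g}" for o, g in K.columns]
    flat.to_csv(path, float_format="%.17g")
    return Path(path)


def read_node_matrix(path: str | Path) -> pd.DataFrame:
    flat = pd.read_csv(path, index_col=0)
    idx = pd.MultiIndex.from_tuples([tuple(s.split(":", 1)) for s in flat.index],
                                    names=["organ", "gene"])
    cols = pd.MultiIndex.from_tuples([tuple(s.split(":", 1)) for s in flat.columns],
                                     names=["organ", "gene"])
    return pd.DataFrame(flat.to_numpy(), index=idx, columns=cols)


def write_matrix(df: pd.DataFrame, path: str | Path) -> Path:
    df.to_csv(path, float_format="%.10g")
    return Path(path)


def write_json(obj: dict, path: str | Path) -> Path:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_default) + "\n")
    return Path(path)


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
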