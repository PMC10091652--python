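"""Readers and writers for the pipeline's on-disk formats.

Formats: MatrixMarket coordinate (genes as rows, 1-based, integer
counts), TSV metadata tables, GMT gene-set collections, one-id-per-line
gene lists, and JSON for truth/diagnostics/manifests. All round-trip
losslessly through these functions.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


def read_mtx(path) -> sp.csr_matrix:
    """Read a MatrixMarket coordinate file into CSR (genes x cells)."""
    try:
        mat = scipy.io.mmread(str(path))
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise ValueError(f"malformed MatrixMarket file {path}: {exc}") from exc
    return sp.csr_matrix(mat)


def write_mtx(path, matrix) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(matrix)
    if np.allclose(mat.data, np.round(mat.data)):
        mat = mat.astype(np.int64)
        scipy.io.mmwrite(str(path), mat, field="integer")
    else:
        scipy.io.mmwrite(str(path), mat)


def read_tsv(path, index_col: int | None = 0) -> pd.DataFrame:
    """TSV reader; tolerates CRLF line endings."""
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_tsv(df: pd.DataFrame, path, index: bool = True, float_format: str = "%.10g") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=float_format)


def read_gene_list(path) -> list[str]:
    """One gene id per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("".join(f"{g}\n" for g in genes))


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: name <tab> description <tab> member genes.

    Returns an ordered mapping set_name -> member list. Duplicate
    members within a set are removed (first occurrence kept); duplicate
    set names or lines with fewer than three fields are errors.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            members = list(dict.fromkeys(g for g in fields[2:] if g))
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, list[str]], path, descriptions: dict[str, str] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_clinical(path) -> pd.DataFrame:
    """Clinical score table: patient_id, A, B_verbal, B_nonverbal, C, D."""
    df = read_tsv(path, index_col=0)
    expected = ["A", "B_verbal", "B_nonverbal", "C", "D"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table {path} missing columns {missing}")
    return df[expected]


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
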