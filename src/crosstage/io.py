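"""TSV/MTX export helpers with reproducibility headers."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from scipy import io as spio
from scipy import sparse


def params_hash(params: dict) -> str:
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path, seed=None, params: dict | None = None):
    """Write a TSV with a comment header recording version, seed, parameters."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# crosstage {__version__}")
        if seed is not None:
            fh.write(f" seed={seed}")
        if params is not None:
            fh.write(f" params={params_hash(params)}")
        fh.write("\n")
        df.to_csv(fh, sep="\t")
    return path


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def write_matrix_mtx(df: pd.DataFrame, prefix):
    """Write a genes x cells matrix as MTX plus row/column TSVs."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(prefix) + ".mtx", sparse.csr_matrix(df.values))
    pd.Series(df.index).to_csv(str(prefix) + ".genes.tsv", sep="\t", index=False, header=False)
    pd.Series(df.columns).to_csv(str(prefix) + ".cells.tsv", sep="\t", index=False, header=False)


def read_matrix_mtx(prefix) -> pd.DataFrame:
    prefix = str(prefix)
    mat = spio.mmread(prefix + ".mtx").toarray()
    genes = pd.read_csv(prefix + ".genes.tsv", sep="\t", header=None)[0]
    cells = pd.read_csv(prefix + ".cells.tsv", sep="\t", header=None)[0]
    return pd.DataFrame(mat, index=genes, columns=cells)
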