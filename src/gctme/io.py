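"""Plain-text I/O: MTX count matrices with TSV annotation sidecars, and
TSV tables for pseudobulk, signatures, fractions, scores and clinical data.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


def write_annotated_counts(adata: ad.AnnData, prefix: str | Path) -> None:
    """Write counts as <prefix>.mtx (genes x cells) with <prefix>.genes.tsv
    and <prefix>.annot.tsv (cell_id, cell_type, subject, stage) sidecars."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(prefix) + ".mtx", sparse.csr_matrix(adata.X).T)
    pd.Series(adata.var_names).to_csv(
        str(prefix) + ".genes.tsv", sep="\t", index=False, header=False
    )
    annot = adata.obs[["cell_type", "subject", "stage"]].copy()
    annot.insert(0, "cell_id", adata.obs_names)
    annot.to_csv(str(prefix) + ".annot.tsv", sep="\t", index=False)


def read_annotated_counts(prefix: str | Path) -> ad.AnnData:
    """Read the MTX + sidecar layout written by :func:`write_annotated_counts`."""
    prefix = str(prefix)
    X = sparse.csr_matrix(spio.mmread(prefix + ".mtx")).T.tocsr()
    genes = pd.read_csv(prefix + ".genes.tsv", sep="\t", header=None)[0].astype(str)
    annot = pd.read_csv(prefix + ".annot.tsv", sep="\t").set_index("cell_id")
    adata = ad.AnnData(
        X=X,
        obs=annot[["cell_type", "subject", "stage"]].astype("category"),
        var=pd.DataFrame(index=genes),
    )
    adata.obs_names = annot.index.astype(str)
    return adata


def write_pseudobulk(pb: pd.DataFrame, path: str | Path) -> None:
    """Pseudobulk TSV with a two-row header (group level 0, group level 1)."""
    pb.to_csv(path, sep="\t")


def read_pseudobulk(path: str | Path) -> pd.DataFrame:
    pb = pd.read_csv(path, sep="\t", header=[0, 1], index_col=0)
    pb.attrs["normalized"] = bool(np.allclose(pb.sum(axis=0), 1e6, atol=1e-3))
    return pb


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_signature(path: str | Path) -> pd.DataFrame:
    """Genes x populations signature TSV (header row of population names)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Clinical TSV with os_time, os_event and optional covariate columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not {"os_time", "os_event"} <= set(df.columns):
        raise ValueError("clinical table needs os_time and os_event columns")
    return df
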