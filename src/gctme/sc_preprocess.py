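"""Single-cell QC filtering, pseudobulk summarization and TPM normalization.

QC applies three filters in a fixed order: cell types are retained only if
they have more than ``min_cells_per_type`` cells and appear at
``min_stages_per_type`` or more disease stages; then cells with fewer than
``min_genes_per_cell`` expressed genes are dropped; then genes detected in
fewer than ``min_gene_cell_fraction`` of the remaining cells are dropped.
Pseudobulk columns are element-wise count sums over cells sharing a grouping
key, and TPM normalization scales each column to one million (length-free,
appropriate for 3'-tag data; a gene-length vector may be supplied for
full-length protocols).
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd


class AllFilteredError(ValueError):
    """Raised when QC filtering removes every cell or gene."""


class QcConfig:
    """QC thresholds; boundaries follow a literal reading of the filters.

    'fewer than 500 expressed genes' removes cells with < 500 (a 500-gene
    cell is kept); 'less than 2% of cells' removes genes detected in < 2%;
    'more than 20 cells' keeps types with strictly more than 20.
    """

    def __init__(
        self,
        min_genes_per_cell: int = 500,
        min_gene_cell_fraction: float = 0.02,
        min_cells_per_type: int = 20,
        min_stages_per_type: int = 2,
    ):
        if min(min_genes_per_cell, min_cells_per_type, min_stages_per_type) <= 0:
            raise ValueError("QC thresholds must be positive")
        if not 0 < min_gene_cell_fraction <= 1:
            raise ValueError("min_gene_cell_fraction must be in (0, 1]")
        self.min_genes_per_cell = min_genes_per_cell
        self.min_gene_cell_fraction = min_gene_cell_fraction
        self.min_cells_per_type = min_cells_per_type
        self.min_stages_per_type = min_stages_per_type


def qc_filter(adata: ad.AnnData, cfg: QcConfig | None = None) -> ad.AnnData:
    """Apply type-level, then cell-level, then gene-level QC filters."""
    cfg = cfg or QcConfig()
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise AllFilteredError("input dataset is empty")

    # type level: > min_cells_per_type cells and >= min_stages_per_type stages
    per_type = adata.obs.groupby("cell_type", observed=True).agg(
        n_cells=("cell_type", "size"),
        n_stages=("stage", lambda s: s.nunique()),
    )
    keep_types = per_type.index[
        (per_type["n_cells"] > cfg.min_cells_per_type)
        & (per_type["n_stages"] >= cfg.min_stages_per_type)
    ]
    out = adata[adata.obs["cell_type"].isin(keep_types)]
    if out.n_obs == 0:
        raise AllFilteredError("no cell type passed the type-level filter")

    # cell level: keep cells expressing >= min_genes_per_cell genes
    n_expressed = np.asarray((out.X > 0).sum(axis=1)).ravel()
    out = out[n_expressed >= cfg.min_genes_per_cell]
    if out.n_obs == 0:
        raise AllFilteredError("no cell passed the expressed-gene filter")

    # gene level: keep genes detected in >= min_gene_cell_fraction of cells
    detect_frac = np.asarray((out.X > 0).sum(axis=0)).ravel() / out.n_obs
    out = out[:, detect_frac >= cfg.min_gene_cell_fraction]
    if out.n_vars == 0:
        raise AllFilteredError("no gene passed the detection-fraction filter")

    out = out.copy()
    for col in ("cell_type", "subject", "stage"):
        out.obs[col] = out.obs[col].cat.remove_unused_categories()
    return out


def pseudobulk_summarize(
    adata: ad.AnnData, group_by: tuple[str, str] = ("cell_type", "subject")
) -> pd.DataFrame:
    """Sum counts over cells sharing a grouping key.

    Returns a genes x groups DataFrame whose columns are a MultiIndex of the
    grouping labels; groups with zero cells are absent.
    """
    for col in group_by:
        if col not in adata.obs.columns:
            raise KeyError(f"unknown grouping label: {col!r}")
    labels = adata.obs[list(group_by)].astype(str)
    indices = labels.groupby(list(group_by), observed=True).indices
    groups = {
        (key if isinstance(key, tuple) else (key,)): np.asarray(
            adata.X[idx].sum(axis=0)
        ).ravel()
        for key, idx in indices.items()
    }
    pb = pd.DataFrame(groups, index=adata.var_names)
    pb.columns = pd.MultiIndex.from_tuples(pb.columns, names=list(group_by))
    pb = pb.sort_index(axis=1)
    pb.attrs["normalized"] = False
    return pb


def tpm_normalize(
    pb: pd.DataFrame, gene_lengths: pd.Series | None = None
) -> pd.DataFrame:
    """Scale each pseudobulk column to sum to 1e6 (transcripts per million).

    Without ``gene_lengths`` this is counts-per-million, the appropriate TPM
    for 3'-tag counts; with lengths, counts are divided by length (kb)
    before scaling, as for full-length protocols.
    """
    values = pb.to_numpy(dtype=float)
    if gene_lengths is not None:
        lengths = gene_lengths.reindex(pb.index).to_numpy(dtype=float)
        if np.isnan(lengths).any() or (lengths <= 0).any():
            raise ValueError("gene_lengths must be positive for all genes")
        values = values / (lengths[:, None] / 1e3)
    totals = values.sum(axis=0)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise ValueError(
            f"all-zero pseudobulk column(s): {[pb.columns[i] for i in zero]}"
        )
    out = pd.DataFrame(values / totals * 1e6, index=pb.index, columns=pb.columns)
    out.attrs["normalized"] = True
    return out
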