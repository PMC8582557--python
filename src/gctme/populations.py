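"""Cell-population discovery from pseudobulk profiles.

Genes are ranked by a two-way ANOVA criterion — how strongly a gene's
pseudobulk expression varies with cell type relative to subject — and the
top genes drive agglomerative clustering of (cell type, stage) mean profiles
into cell populations.

The ANOVA is additive (main effects of cell type and subject, no
interaction) on log2(TPM + 1), with type-II sums of squares so unbalanced
designs are handled.  Genes whose F for subject is exactly zero are ranked
by the cell-type F alone, above all finite ratios.  The clustering distance
is 1 - r^2 (r = Pearson correlation between log-transformed mean profiles),
with Ward linkage; 1 - r is available as an alternative but the default
follows the squared form, under which perfect anti-correlation is as close
as perfect correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


@dataclass
class ClusterConfig:
    n_top_genes: int = 100
    pseudocount: float = 1.0
    linkage: str = "ward"
    distance: str = "one_minus_r2"  # or "one_minus_r"

    def __post_init__(self):
        if self.n_top_genes < 2:
            raise ValueError("n_top_genes must be >= 2")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.distance not in {"one_minus_r2", "one_minus_r"}:
            raise ValueError(f"unknown distance: {self.distance}")


def _residual_maker(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Annihilator matrix I - X (X'X)^+ X' and the rank of X."""
    pinv = np.linalg.pinv(X)
    rank = np.linalg.matrix_rank(X)
    return np.eye(X.shape[0]) - X @ pinv, rank


def rank_genes_anova(
    pb: pd.DataFrame, cfg: ClusterConfig | None = None
) -> pd.DataFrame:
    """Rank genes by F(cell type) / F(subject) from a two-way ANOVA.

    ``pb`` is a TPM pseudobulk matrix (genes x (cell_type, subject) columns,
    MultiIndex).  Returns a DataFrame with one row per retained gene,
    columns ``F_celltype``, ``F_subject``, ``ratio``, ``rank``, sorted by
    rank; the top ``cfg.n_top_genes`` rows carry ``selected=True``.
    Zero-variance genes are excluded (their count is in
    ``result.attrs['n_zero_variance']``).
    """
    cfg = cfg or ClusterConfig()
    ct = pb.columns.get_level_values(0)
    subj = pb.columns.get_level_values(1)
    if ct.nunique() < 2 or subj.nunique() < 2:
        raise ValueError("need >= 2 cell types and >= 2 subjects")

    Y = np.log2(pb.to_numpy(dtype=float).T + cfg.pseudocount)  # obs x genes
    n = Y.shape[0]
    A = pd.get_dummies(pd.Series(ct)).to_numpy(dtype=float)
    B = pd.get_dummies(pd.Series(subj)).to_numpy(dtype=float)
    one = np.ones((n, 1))
    M_full, r_full = _residual_maker(np.hstack([one, A[:, 1:], B[:, 1:]]))
    M_noA, r_noA = _residual_maker(np.hstack([one, B[:, 1:]]))
    M_noB, r_noB = _residual_maker(np.hstack([one, A[:, 1:]]))

    rss_full = ((M_full @ Y) ** 2).sum(axis=0)
    ss_A = ((M_noA @ Y) ** 2).sum(axis=0) - rss_full
    ss_B = ((M_noB @ Y) ** 2).sum(axis=0) - rss_full
    df_A, df_B = r_full - r_noA, r_full - r_noB
    df_res = n - r_full
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom in the design")

    mse = rss_full / df_res
    variance = Y.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F_A = np.where(mse > 0, (ss_A / df_A) / mse, np.inf)
        F_B = np.where(mse > 0, (ss_B / df_B) / mse, np.inf)
    F_A = np.clip(F_A, 0, None)
    F_B = np.clip(F_B, 0, None)

    keep = variance > 1e-12
    res = pd.DataFrame(
        {
            "F_celltype": F_A[keep],
            "F_subject": F_B[keep],
        },
        index=pb.index[keep],
    )
    res.attrs["n_zero_variance"] = int((~keep).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        res["ratio"] = res["F_celltype"] / res["F_subject"]
    # F_subject == 0: rank by F_celltype alone, above all finite ratios
    res["ratio"] = res["ratio"].where(res["F_subject"] > 0, np.inf)
    res = res.sort_values(
        ["ratio", "F_celltype"], ascending=[False, False], kind="mergesort"
    )
    res["rank"] = np.arange(1, len(res) + 1)
    res["selected"] = res["rank"] <= cfg.n_top_genes
    return res


@dataclass
class ClusterTree:
    """Agglomerative tree over (cell type, stage) mean profiles."""

    leaves: list[tuple[str, str]]
    linkage_matrix: np.ndarray
    profiles: pd.DataFrame = field(repr=False, default=None)

    def cut(self, k: int) -> pd.Series:
        """Cut into k clusters; returns integer labels per leaf (1..k)."""
        if k > len(self.leaves):
            raise ValueError(
                f"requested {k} clusters from {len(self.leaves)} leaves"
            )
        labels = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(
            labels, index=pd.MultiIndex.from_tuples(self.leaves), name="cluster"
        )

    def to_newick(self) -> str:
        """Newick string with leaf labels '<celltype>|<stage>'."""
        tree = hierarchy.to_tree(self.linkage_matrix)
        names = [f"{t}|{s}" for t, s in self.leaves]

        def rec(node) -> str:
            if node.is_leaf():
                return names[node.id]
            length = max(node.dist, 0.0)
            return (
                f"({rec(node.left)},{rec(node.right)}):{length:.6g}"
            )

        return rec(tree) + ";"


def mean_stage_profiles(
    pb_by_type_subject: pd.DataFrame,
    subject_stage: pd.Series | dict,
    genes: list[str] | pd.Index,
) -> pd.DataFrame:
    """Mean TPM per (cell type, stage) over subjects, restricted to ``genes``."""
    stage_map = dict(subject_stage) if not isinstance(subject_stage, dict) else subject_stage
    cols = pd.MultiIndex.from_tuples(
        [
            (ct, stage_map[subj])
            for ct, subj in pb_by_type_subject.columns
        ],
        names=["cell_type", "stage"],
    )
    sub = pb_by_type_subject.loc[list(genes)]
    sub.columns = cols
    return sub.T.groupby(level=["cell_type", "stage"], observed=True).mean().T


def build_cluster_tree(
    mean_profiles: pd.DataFrame, cfg: ClusterConfig | None = None
) -> ClusterTree:
    """Ward-linkage tree on 1 - r^2 distances between log mean profiles.

    ``mean_profiles`` is genes x (cell type, stage) mean TPM restricted to
    the top-ranked genes; the log2(x + pseudocount) transform is applied
    here.
    """
    cfg = cfg or ClusterConfig()
    if mean_profiles.shape[1] < 2:
        raise ValueError("need at least 2 leaves to build a tree")
    logged = np.log2(mean_profiles.to_numpy(dtype=float) + cfg.pseudocount)
    r = np.corrcoef(logged.T)
    r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
    if cfg.distance == "one_minus_r2":
        D = 1.0 - r**2
    else:
        D = 1.0 - r
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(D, checks=False), method=cfg.linkage)
    return ClusterTree(
        leaves=[tuple(c) for c in mean_profiles.columns],
        linkage_matrix=Z,
        profiles=mean_profiles,
    )


def assign_populations(
    tree: ClusterTree,
    cell_meta: pd.DataFrame,
    k: int = 10,
    label_map: dict[int, str] | None = None,
) -> pd.Series:
    """Assign each cell the population of its (cell type, stage) leaf.

    ``cell_meta`` needs ``cell_type`` and ``stage`` columns.  ``label_map``
    maps cluster ids (1..k) to population names; unnamed clusters keep
    'population<k>' labels.
    """
    leaf_clusters = tree.cut(k)
    if label_map is not None:
        missing = set(leaf_clusters.unique()) - set(label_map)
        if missing:
            raise KeyError(f"label_map missing cluster ids: {sorted(missing)}")
        names = leaf_clusters.map(label_map)
    else:
        names = leaf_clusters.map(lambda c: f"population{c}")
    lookup = dict(zip(leaf_clusters.index, names))
    keys = list(zip(cell_meta["cell_type"].astype(str), cell_meta["stage"].astype(str)))
    unknown = {key for key in keys if key not in lookup}
    if unknown:
        raise KeyError(f"(cell type, stage) pairs missing from tree: {sorted(unknown)}")
    return pd.Series([lookup[key] for key in keys], index=cell_meta.index, name="population")


def anova_f_oracle_balanced(table: np.ndarray) -> tuple[float, float]:
    """Textbook two-way ANOVA F statistics for a balanced a x b table.

    One observation per cell; main effects only; residual is the
    interaction mean square.  Used as an independent cross-check of
    :func:`rank_genes_anova` on balanced designs.
    """
    table = np.asarray(table, dtype=float)
    a, b = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = b * ((row_means - grand) ** 2).sum()
    ss_cols = a * ((col_means - grand) ** 2).sum()
    resid = table - row_means[:, None] - col_means[None, :] + grand
    ss_res = (resid**2).sum()
    ms_res = ss_res / ((a - 1) * (b - 1))
    return (ss_rows / (a - 1)) / ms_res, (ss_cols / (b - 1)) / ms_res
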