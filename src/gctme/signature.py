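"""Signature-matrix construction from population pseudobulk profiles.

Marker genes for a population are genes at least two-fold elevated over the
mean of all other populations and significant at p <= 0.01 in a one-way
ANOVA of that population's (population, subject) pseudobulk profiles against
the rest; survivors are ranked by descending fold change and the top M per
population are kept.  The signature matrix holds per-population mean TPM
over the union of markers.  The marker depth M is chosen by deconvolving an
artificial bulk (per-biopsy count sums from the single-cell data, whose true
fractions are known) and minimizing the mean per-biopsy RMSE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class MarkerConfig:
    min_fold_change: float = 2.0
    max_p: float = 0.01
    M_per_population: int = 150
    M_grid: list[int] = field(default_factory=lambda: [50, 100, 150, 200, 250])
    pseudocount: float = 1.0

    def __post_init__(self):
        if not self.M_grid:
            raise ValueError("M_grid must be non-empty")
        self.M_grid = sorted(self.M_grid)


def select_markers(
    pb: pd.DataFrame, cfg: MarkerConfig | None = None
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Select per-population marker genes from a (population, subject) TPM matrix.

    Returns ``(markers, stats_table)``: an ordered gene list per population
    and a long-format table of fold change, p-value and selection flag for
    every (gene, population) pair that passed at least the fold screen.
    Ties in fold change are broken by smaller p, then gene id, so selection
    is deterministic.
    """
    cfg = cfg or MarkerConfig()
    pops = pb.columns.get_level_values(0)
    unique_pops = pops.unique()
    if len(unique_pops) < 2:
        raise ValueError("need >= 2 populations to select markers")

    X = pb.to_numpy(dtype=float)
    markers: dict[str, list[str]] = {}
    rows = []
    for pop in unique_pops:
        in_pop = np.asarray(pops == pop)
        mean_in = X[:, in_pop].mean(axis=1)
        mean_out = X[:, ~in_pop].mean(axis=1)
        fc = (mean_in + cfg.pseudocount) / (mean_out + cfg.pseudocount)
        _, p = stats.f_oneway(X[:, in_pop], X[:, ~in_pop], axis=1)
        p = np.nan_to_num(p, nan=1.0)
        ok = (fc >= cfg.min_fold_change) & (p <= cfg.max_p)
        cand = pd.DataFrame(
            {
                "gene": pb.index[ok],
                "population": pop,
                "fold_change": fc[ok],
                "p_value": p[ok],
            }
        ).sort_values(
            ["fold_change", "p_value", "gene"],
            ascending=[False, True, True],
            kind="mergesort",
        )
        cand["selected"] = np.arange(len(cand)) < cfg.M_per_population
        if len(cand) == 0:
            warnings.warn(f"no marker gene survived for population {pop!r}")
        markers[pop] = cand.loc[cand["selected"], "gene"].tolist()
        rows.append(cand)
    stats_table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    return markers, stats_table


def build_signature(
    pb: pd.DataFrame, markers: dict[str, list[str]], name: str = "signature"
) -> pd.DataFrame:
    """Per-population mean TPM restricted to the union of marker genes.

    Genes marking multiple populations appear once.  The result is a
    genes x populations DataFrame with ``attrs['markers']`` holding the
    ordered per-population lists and ``attrs['name']``.
    """
    union: list[str] = []
    seen = set()
    for pop, genes in markers.items():
        for g in genes:
            if g not in seen:
                seen.add(g)
                union.append(g)
    if not union:
        raise ValueError("marker union is empty")
    means = pb.T.groupby(level=0, observed=True).mean().T
    sig = means.loc[union, list(markers)]
    sig.attrs["markers"] = {p: list(g) for p, g in markers.items()}
    sig.attrs["name"] = name
    return sig


def make_artificial_bulk(
    adata: ad.AnnData,
    population: pd.Series,
    weight: str = "cells",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-biopsy bulk profiles with known population fractions.

    Sums counts over each subject's (biopsy's) cells; the true fraction of a
    population is its share of the biopsy's cells (``weight='cells'``) or of
    the biopsy's total UMI mass (``weight='umi'``).
    """
    if weight not in {"cells", "umi"}:
        raise ValueError("weight must be 'cells' or 'umi'")
    subjects = adata.obs["subject"].astype(str)
    pop = population.reindex(adata.obs_names).astype(str)
    bulk_cols, frac_rows, ids = {}, [], []
    for subj in subjects.unique():
        mask = (subjects == subj).to_numpy()
        if not mask.any():
            continue
        bulk_cols[subj] = np.asarray(adata.X[mask].sum(axis=0)).ravel()
        if weight == "cells":
            shares = pop[mask].value_counts(normalize=True)
        else:
            umi = pd.Series(
                np.asarray(adata.X[mask].sum(axis=1)).ravel(),
                index=pop[mask].to_numpy(),
            )
            shares = umi.groupby(level=0).sum() / umi.sum()
        frac_rows.append(shares)
        ids.append(subj)
    bulk = pd.DataFrame(bulk_cols, index=adata.var_names)
    fractions = (
        pd.DataFrame(frac_rows, index=ids).fillna(0.0).sort_index(axis=1)
    )
    return bulk, fractions


def choose_M(
    pb: pd.DataFrame,
    artificial_bulk: pd.DataFrame,
    true_fractions: pd.DataFrame,
    cfg: MarkerConfig | None = None,
    deconv_config=None,
) -> tuple[int, pd.DataFrame]:
    """Pick the marker depth M minimizing deconvolution RMSE.

    For each M in ``cfg.M_grid`` the signature is rebuilt with M markers per
    population and the artificial bulk is deconvolved; accuracy is the mean
    per-biopsy RMSE between estimated and true fractions (Pearson r is
    reported alongside).  Ties go to the smallest M.  Grid values exceeding
    the available markers are scored with the truncated lists and flagged.
    """
    from .deconvolution import DeconvConfig, deconvolve

    cfg = cfg or MarkerConfig()
    deconv_config = deconv_config or DeconvConfig()
    rows = []
    for M in cfg.M_grid:
        m_cfg = MarkerConfig(
            min_fold_change=cfg.min_fold_change,
            max_p=cfg.max_p,
            M_per_population=M,
            M_grid=cfg.M_grid,
            pseudocount=cfg.pseudocount,
        )
        markers, _ = select_markers(pb, m_cfg)
        truncated = any(len(g) < M for g in markers.values())
        sig = build_signature(pb, markers, name=f"M{M}")
        est = deconvolve(sig, artificial_bulk, deconv_config)
        est_f = est[true_fractions.columns].loc[true_fractions.index]
        err = est_f.to_numpy() - true_fractions.to_numpy()
        rmse = float(np.sqrt((err**2).mean(axis=1)).mean())
        r = float(
            np.corrcoef(est_f.to_numpy().ravel(), true_fractions.to_numpy().ravel())[0, 1]
        )
        rows.append({"M": M, "rmse": rmse, "pearson_r": r, "truncated": truncated})
    table = pd.DataFrame(rows)
    best = int(table.loc[table["rmse"].idxmin(), "M"])  # idxmin: first (smallest M) on ties
    return best, table


def merge_lineages(
    fractions: pd.DataFrame, lineage_map: dict[str, str]
) -> pd.DataFrame:
    """Sum fine-type fractions into lineages; row sums are conserved."""
    unmapped = set(fractions.columns) - set(lineage_map)
    if unmapped:
        raise KeyError(f"fine types missing from lineage map: {sorted(unmapped)}")
    out = fractions.T.groupby(
        fractions.columns.map(lineage_map), observed=True
    ).sum().T
    return out
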