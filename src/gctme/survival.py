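"""Survival statistics: Kaplan-Meier/log-rank, Cox models, FDR,
fixed-effects meta-analysis, and the prognostic marker-gene screen.

Cox models use the Efron approximation for tied event times.  The
marker-gene screen standardizes expression per cohort (hazard ratios are
per standard deviation), fits a multivariate Cox model per cohort with
whatever clinical covariates that cohort carries, applies per-cohort
significance and direction filters (HR > 1 for stromal markers, HR < 1 for
EMEC markers), and pools the surviving genes' log hazard ratios by
inverse-variance fixed-effects meta-analysis with a z-test for the overall
effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Clinical covariates in the canonical order; ``stage`` is categorical with
#: level I as the reference.
CLINICAL_COVARIATES = ["age", "sex", "stage", "lauren", "chemo", "radiation"]


def km_logrank(
    groups: pd.Series, survival: pd.DataFrame
) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Kaplan-Meier curves per group plus the log-rank test.

    Returns ``(curves, chi2, p)`` where ``curves`` maps group label to a
    survival-function DataFrame.
    """
    groups = pd.Series(groups)
    surv = survival.loc[groups.index]
    labels = groups.unique()
    if len(labels) < 2:
        raise ValueError("need at least 2 groups for a log-rank test")
    if surv["os_event"].sum() < 1:
        raise ValueError("need at least one event")
    curves = {}
    for lab in labels:
        mask = groups == lab
        kmf = KaplanMeierFitter()
        kmf.fit(surv.loc[mask, "os_time"], surv.loc[mask, "os_event"], label=str(lab))
        curves[lab] = kmf.survival_function_
    res = multivariate_logrank_test(surv["os_time"], groups, surv["os_event"])
    return curves, float(res.test_statistic), float(res.p_value)


def _design_frame(
    survival: pd.DataFrame, terms: list[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Build the Cox design: numeric terms as-is, stage dummied vs level I."""
    cols = {"os_time": survival["os_time"], "os_event": survival["os_event"]}
    out_terms: list[str] = []
    for term in terms:
        x = survival[term]
        if term == "stage" or not pd.api.types.is_numeric_dtype(x):
            levels = sorted(x.astype(str).unique())
            for lev in levels[1:]:
                name = f"{term}_{lev}"
                cols[name] = (x.astype(str) == lev).astype(float)
                out_terms.append(name)
        else:
            cols[term] = x.astype(float)
            out_terms.append(term)
    return pd.DataFrame(cols, index=survival.index), out_terms


def cox_fit(
    survival: pd.DataFrame,
    terms: list[str],
    mode: str = "univariate",
) -> pd.DataFrame:
    """Cox proportional-hazards fits (Efron ties) with Wald CIs.

    ``mode='univariate'`` fits each term alone; ``'multivariate'`` fits all
    terms jointly.  Categorical terms (``stage`` and any non-numeric column)
    are expanded against their first level.  Non-convergence is flagged in
    the ``converged`` column rather than raised.
    """
    if mode not in {"univariate", "multivariate"}:
        raise ValueError("mode must be 'univariate' or 'multivariate'")
    term_groups = [[t] for t in terms] if mode == "univariate" else [list(terms)]
    rows = []
    for group in term_groups:
        df, design_terms = _design_frame(survival, group)
        if survival["os_event"].sum() < len(design_terms) + 1:
            raise ValueError("too few events for the number of terms")
        cph = CoxPHFitter()
        converged = True
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="os_time", event_col="os_event")
        except Exception:
            converged = False
        for t in design_terms:
            if converged and t in cph.summary.index:
                s = cph.summary.loc[t]
                rows.append(
                    {
                        "term": t,
                        "beta": float(s["coef"]),
                        "HR": float(np.exp(s["coef"])),
                        "CI_low": float(np.exp(s["coef lower 95%"])),
                        "CI_high": float(np.exp(s["coef upper 95%"])),
                        "se": float(s["se(coef)"]),
                        "z": float(s["z"]),
                        "p": float(s["p"]),
                        "converged": True,
                    }
                )
            else:
                rows.append(
                    {"term": t, "beta": np.nan, "HR": np.nan, "CI_low": np.nan,
                     "CI_high": np.nan, "se": np.nan, "z": np.nan, "p": np.nan,
                     "converged": False}
                )
    res = pd.DataFrame(rows).set_index("term")
    res["fdr_adjusted_p"] = fdr_adjust(res["p"].to_numpy())
    return res


def fdr_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (NaNs passed through)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


@dataclass
class MetaResult:
    pooled_beta: float
    pooled_se: float
    pooled_HR: float
    CI_low: float
    CI_high: float
    z: float
    p_overall: float
    weights: np.ndarray
    per_study: pd.DataFrame
    note: str = ""


def meta_fixed(betas, ses) -> MetaResult:
    """Inverse-variance fixed-effects pooling of per-study log hazard ratios."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.shape != ses.shape:
        raise ValueError("betas and ses must have the same length")
    if (ses <= 0).any():
        raise ValueError("standard errors must be positive")
    note = "single study: passthrough" if len(betas) == 1 else ""
    w = 1.0 / ses**2
    w_norm = w / w.sum()
    pooled_beta = float((w_norm * betas).sum())
    pooled_se = float(1.0 / np.sqrt(w.sum()))
    z = pooled_beta / pooled_se
    p = 2.0 * stats.norm.sf(abs(z))
    return MetaResult(
        pooled_beta=pooled_beta,
        pooled_se=pooled_se,
        pooled_HR=float(np.exp(pooled_beta)),
        CI_low=float(np.exp(pooled_beta - 1.959963984540054 * pooled_se)),
        CI_high=float(np.exp(pooled_beta + 1.959963984540054 * pooled_se)),
        z=float(z),
        p_overall=float(p),
        weights=w_norm,
        per_study=pd.DataFrame({"beta": betas, "se": ses}),
        note=note,
    )


def prognostic_gene_screen(
    cohorts: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    genes: list[str],
    direction: str,
    per_cohort_p: float = 0.05,
    meta_p: float = 1e-5,
    min_cohorts: int | None = None,
    standardize: bool = True,
) -> pd.DataFrame:
    """Screen marker genes for prognostic value across cohorts.

    ``cohorts`` maps cohort name to ``(expression, clinical)`` where
    expression is genes x samples and clinical carries ``os_time``,
    ``os_event`` and any subset of the clinical covariates.  ``direction``
    is ``'risk'`` (stromal markers: HR > 1) or ``'protective'`` (EMEC
    markers: HR < 1).  A gene passes a cohort when its multivariate Cox p is
    below ``per_cohort_p`` with the required direction; genes passing in at
    least ``min_cohorts`` cohorts (default: all, falling back to all-but-one
    when the strict rule selects nothing) are pooled by fixed-effects
    meta-analysis and selected at overall p < ``meta_p``.
    """
    if direction not in {"risk", "protective"}:
        raise ValueError("direction must be 'risk' or 'protective'")
    n_cohorts = len(cohorts)
    per_gene: dict[str, dict[str, dict]] = {g: {} for g in genes}

    for name, (expr, clinical) in cohorts.items():
        covars = [c for c in CLINICAL_COVARIATES if c in clinical.columns]
        for gene in genes:
            if gene not in expr.index:
                continue
            x = expr.loc[gene].reindex(clinical.index).astype(float)
            if standardize:
                sd = x.std()
                if sd == 0:
                    continue
                x = (x - x.mean()) / sd
            df = clinical[["os_time", "os_event"] + covars].copy()
            df["expr"] = x
            try:
                res = cox_fit(df, ["expr"] + covars, mode="multivariate")
            except ValueError:
                continue
            if not res.loc["expr", "converged"]:
                continue
            per_gene[gene][name] = {
                "beta": res.loc["expr", "beta"],
                "se": res.loc["expr", "se"],
                "HR": res.loc["expr", "HR"],
                "p": res.loc["expr", "p"],
            }

    def passes(rec) -> bool:
        ok_dir = rec["HR"] > 1 if direction == "risk" else rec["HR"] < 1
        return ok_dir and rec["p"] < per_cohort_p

    def build(k_required: int) -> pd.DataFrame:
        rows = []
        for gene in genes:
            recs = per_gene[gene]
            if not recs:
                continue
            n_sig = sum(passes(r) for r in recs.values())
            row = {"gene": gene, "n_cohorts_fit": len(recs), "n_cohorts_significant": n_sig}
            if n_sig >= k_required and len(recs) >= 1:
                meta = meta_fixed(
                    [r["beta"] for r in recs.values()],
                    [r["se"] for r in recs.values()],
                )
                dir_ok = meta.pooled_HR > 1 if direction == "risk" else meta.pooled_HR < 1
                row.update(
                    meta_beta=meta.pooled_beta,
                    meta_HR=meta.pooled_HR,
                    meta_p=meta.p_overall,
                    direction_ok=dir_ok,
                    selected=bool(dir_ok and meta.p_overall < meta_p),
                )
            else:
                row.update(meta_beta=np.nan, meta_HR=np.nan, meta_p=np.nan,
                           direction_ok=False, selected=False)
            rows.append(row)
        return pd.DataFrame(rows).set_index("gene")

    k_all = min_cohorts if min_cohorts is not None else n_cohorts
    result = build(k_all)
    if min_cohorts is None and not result["selected"].any() and n_cohorts > 1:
        # fallback: significant in all but one cohort
        result = build(n_cohorts - 1)
        result.attrs["fallback_min_cohorts"] = n_cohorts - 1
    return result
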