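"""Patient stratification: survival-optimal score cutoffs and TME subtypes.

The optimal cutoff scans a dense quantile grid (default 0.10..0.90 step
0.01), dichotomizes the cohort at each empirical quantile, tests the binary
split with a univariate Cox model (log-rank available by config), and keeps
the cutoff minimizing the p-value.  The grid-minimal p is optimistically
biased by multiplicity and is reported as a selection criterion, not an
honest test.

TME subtyping runs spectral clustering on the four STEM population
fractions (EMEC, Stromal, adaptive T, Monocytes) with an RBF affinity whose
bandwidth defaults to the median pairwise distance.  The cluster count is
chosen by majority vote of four validity indices (silhouette,
Calinski-Harabasz, Davies-Bouldin, gap statistic) computed on Ward/Euclidean
hierarchical partitions, unless fixed.  Clusters are named by composition:
H = highest mean Stromal + Monocyte, L = highest mean EMEC + adaptive T
among the rest, M = remainder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import AgglomerativeClustering, SpectralClustering
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)


@dataclass
class CutoffConfig:
    q_min: float = 0.10
    q_max: float = 0.90
    q_step: float = 0.01
    test: str = "cox"  # or "logrank"

    def grid(self) -> np.ndarray:
        if not (0 < self.q_min < self.q_max < 1):
            raise ValueError("quantile grid must lie within (0, 1)")
        n = int(round((self.q_max - self.q_min) / self.q_step))
        return np.round(self.q_min + self.q_step * np.arange(n + 1), 10)


@dataclass
class CutoffResult:
    cutoff_value: float
    cutoff_quantile: float
    p_value: float
    table: pd.DataFrame


def optimal_cutoff(
    scores: pd.Series,
    survival: pd.DataFrame,
    cfg: CutoffConfig | None = None,
) -> CutoffResult:
    """Scan score quantiles for the split minimizing the univariate p-value.

    ``survival`` needs ``os_time`` and ``os_event`` columns aligned with
    ``scores``.  Grid points where either group has zero events are skipped
    with a warning; ties in p go to the smaller quantile.
    """
    cfg = cfg or CutoffConfig()
    scores = pd.Series(scores).astype(float)
    surv = survival.loc[scores.index]
    if surv["os_event"].sum() < 2:
        raise ValueError("need at least 2 events")
    if scores.nunique() == 1:
        raise ValueError("score vector is constant; no cutoff can split it")

    rows = []
    for q in cfg.grid():
        cut = float(np.quantile(scores, q))
        high = (scores > cut).astype(int)
        if high.nunique() < 2:
            continue
        ev_high = surv.loc[high == 1, "os_event"].sum()
        ev_low = surv.loc[high == 0, "os_event"].sum()
        if ev_high == 0 or ev_low == 0:
            warnings.warn(f"quantile {q}: a group has zero events; skipped")
            continue
        if cfg.test == "cox":
            df = pd.DataFrame(
                {"t": surv["os_time"], "e": surv["os_event"], "high": high}
            )
            cph = CoxPHFitter()
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cph.fit(df, duration_col="t", event_col="e")
                p = float(cph.summary.loc["high", "p"])
            except Exception:
                continue
        else:
            res = logrank_test(
                surv.loc[high == 1, "os_time"],
                surv.loc[high == 0, "os_time"],
                surv.loc[high == 1, "os_event"],
                surv.loc[high == 0, "os_event"],
            )
            p = float(res.p_value)
        rows.append({"quantile": q, "cutoff": cut, "p": p})
    if not rows:
        raise ValueError("no evaluable grid point")
    table = pd.DataFrame(rows)
    best = table.loc[table["p"].idxmin()]  # idxmin returns first minimum: smaller q
    return CutoffResult(
        cutoff_value=float(best["cutoff"]),
        cutoff_quantile=float(best["quantile"]),
        p_value=float(best["p"]),
        table=table,
    )


@dataclass
class SubtypeConfig:
    features: tuple[str, str, str, str] = ("EMEC", "Stromal", "Tadaptive", "Monocytes")
    k: int | None = None  # None: majority vote over validity indices
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    rbf_sigma: float | None = None  # None: median pairwise distance
    gap_n_ref: int = 10
    seed: int = 0


def _gap_statistic(X: np.ndarray, k_range, rng: np.random.Generator, n_ref: int) -> int:
    """Tibshirani gap statistic with Ward clustering and uniform-box reference."""
    lo, hi = X.min(axis=0), X.max(axis=0)

    def within_dispersion(data, labels):
        w = 0.0
        for lab in np.unique(labels):
            pts = data[labels == lab]
            if len(pts) > 1:
                w += ((pts - pts.mean(axis=0)) ** 2).sum()
        return max(w, 1e-300)

    log_w, gap, sk = {}, {}, {}
    for k in k_range:
        labels = AgglomerativeClustering(n_clusters=k).fit_predict(X)
        log_w[k] = np.log(within_dispersion(X, labels))
        ref = []
        for _ in range(n_ref):
            Xr = rng.uniform(lo, hi, size=X.shape)
            lr = AgglomerativeClustering(n_clusters=k).fit_predict(Xr)
            ref.append(np.log(within_dispersion(Xr, lr)))
        ref = np.asarray(ref)
        gap[k] = ref.mean() - log_w[k]
        sk[k] = ref.std(ddof=0) * np.sqrt(1 + 1 / n_ref)
    ks = sorted(k_range)
    for i, k in enumerate(ks[:-1]):
        if gap[k] >= gap[ks[i + 1]] - sk[ks[i + 1]]:
            return k
    return ks[-1]


def select_k(X: np.ndarray, cfg: SubtypeConfig) -> tuple[int, pd.DataFrame]:
    """Majority vote of four validity indices over Ward partitions."""
    rng = np.random.default_rng(cfg.seed)
    k_range = [k for k in cfg.k_range if k < len(X)]
    votes, rows = [], []
    sil, ch, db = {}, {}, {}
    for k in k_range:
        labels = AgglomerativeClustering(n_clusters=k).fit_predict(X)
        sil[k] = silhouette_score(X, labels)
        ch[k] = calinski_harabasz_score(X, labels)
        db[k] = davies_bouldin_score(X, labels)
        rows.append({"k": k, "silhouette": sil[k], "calinski_harabasz": ch[k],
                     "davies_bouldin": db[k]})
    votes.append(max(sil, key=sil.get))
    votes.append(max(ch, key=ch.get))
    votes.append(min(db, key=db.get))
    votes.append(_gap_statistic(X, k_range, rng, cfg.gap_n_ref))
    counts = pd.Series(votes).value_counts()
    if counts.iloc[0] >= 2:
        k_best = int(counts.index[counts == counts.iloc[0]].min())
    else:
        k_best = 3  # no majority: fall back to the reproduction default
    table = pd.DataFrame(rows).set_index("k")
    table.attrs["votes"] = votes
    return k_best, table


def tme_subtype(
    features: pd.DataFrame, cfg: SubtypeConfig | None = None
) -> tuple[pd.Series, dict]:
    """Spectral clustering of samples on the four STEM population fractions.

    Returns per-sample subtype labels ('TMEsubtype-H'/'-M'/'-L' when k = 3)
    and an info dict with the chosen k, index table, bandwidth, and cluster
    composition means.  Deterministic given ``cfg.seed``.
    """
    cfg = cfg or SubtypeConfig()
    cols = [c for c in cfg.features if c in features.columns]
    if len(cols) != len(cfg.features):
        missing = set(cfg.features) - set(features.columns)
        raise KeyError(f"feature columns missing: {sorted(missing)}")
    X = features[list(cfg.features)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("features contain missing values")

    if cfg.k is None:
        k, index_table = select_k(X, cfg)
    else:
        k, index_table = cfg.k, None
    if k >= len(X):
        raise ValueError(f"k={k} must be below the sample count {len(X)}")

    dists = pdist(X)
    sigma = cfg.rbf_sigma if cfg.rbf_sigma is not None else float(np.median(dists))
    if sigma <= 0:
        sigma = 1.0
    affinity = np.exp(-squareform(dists) ** 2 / (2 * sigma**2))
    labels = SpectralClustering(
        n_clusters=k, affinity="precomputed", random_state=cfg.seed,
        assign_labels="kmeans", n_init=20,
    ).fit_predict(affinity)

    emec, stromal, tad, mono = cfg.features
    comp = (
        pd.DataFrame(X, columns=list(cfg.features), index=features.index)
        .assign(cluster=labels)
        .groupby("cluster")
        .mean()
    )
    order_h = (comp[stromal] + comp[mono]).sort_values(ascending=False)
    name_of = {}
    h_cluster = order_h.index[0]
    name_of[h_cluster] = "TMEsubtype-H"
    remaining = [c for c in comp.index if c != h_cluster]
    if remaining:
        order_l = (comp.loc[remaining, emec] + comp.loc[remaining, tad]).sort_values(
            ascending=False
        )
        name_of[order_l.index[0]] = "TMEsubtype-L"
        for c in order_l.index[1:]:
            name_of[c] = "TMEsubtype-M"
    named = pd.Series(
        [name_of[c] for c in labels], index=features.index, name="tme_subtype"
    )
    info = {
        "k": k,
        "index_table": index_table,
        "sigma": sigma,
        "cluster_means": comp.rename(index=name_of),
        "raw_labels": pd.Series(labels, index=features.index),
    }
    return named, info
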