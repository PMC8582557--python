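"""Cell-fraction estimation by nu-support-vector regression.

Each bulk sample is regressed on the signature-matrix columns with a linear
nu-SVR over a small grid of nu values; the nu whose reconstruction has the
lowest RMSE on the signature genes wins.  Negative coefficients are clipped
to zero and the remainder renormalized, so the output rows are relative
fractions on the probability simplex.  Mixture and signature are
standardized before fitting (the mixture per sample to zero mean / unit
variance, the signature globally), which makes the estimates invariant to
positive rescaling of a mixture.

This follows the published CIBERSORT recipe; estimated fractions are
relative within a compartment, never absolute abundances.  Cross-platform
batch correction is reduced to an optional per-gene quantile matching of the
bulk to the signature's source distribution (off by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import NuSVR


@dataclass
class DeconvConfig:
    nu_grid: tuple[float, ...] = (0.25, 0.5, 0.75)
    scaling: bool = True
    min_overlap_genes: int = 100
    C: float = 1.0
    tol: float = 1e-5
    quantile_match: bool = False

    def __post_init__(self):
        if not all(0 < nu < 1 for nu in self.nu_grid):
            raise ValueError("nu values must lie in (0, 1)")


def _quantile_match(bulk: np.ndarray, signature: np.ndarray) -> np.ndarray:
    """Map each bulk sample's values onto the signature's pooled distribution."""
    ref = np.sort(signature.ravel())
    out = np.empty_like(bulk, dtype=float)
    grid = np.linspace(0, 1, len(ref))
    for j in range(bulk.shape[1]):
        ranks = stats.rankdata(bulk[:, j], method="average") - 1
        out[:, j] = np.interp(ranks / max(len(ranks) - 1, 1), grid, ref)
    return out


def deconvolve(
    signature: pd.DataFrame, bulk: pd.DataFrame, cfg: DeconvConfig | None = None
) -> pd.DataFrame:
    """Estimate relative population fractions of bulk samples.

    ``signature`` is genes x populations, ``bulk`` genes x samples; gene ids
    are intersected and at least ``cfg.min_overlap_genes`` must be shared.
    Returns samples x populations fractions (non-negative, rows sum to 1)
    with diagnostics columns ``rmse_``, ``pearson_r_`` and ``best_nu_``
    describing the reconstruction on the standardized scale.
    """
    cfg = cfg or DeconvConfig()
    shared = signature.index.intersection(bulk.index)
    if len(shared) < cfg.min_overlap_genes:
        raise ValueError(
            f"only {len(shared)} genes shared between signature "
            f"({signature.shape[0]}) and bulk ({bulk.shape[0]}); "
            f"need >= {cfg.min_overlap_genes}"
        )
    S = signature.loc[shared].to_numpy(dtype=float)
    B = bulk.loc[shared].to_numpy(dtype=float)
    if cfg.quantile_match:
        B = _quantile_match(B, S)

    if cfg.scaling:
        Xs = (S - S.mean()) / S.std()
    else:
        Xs = S

    n_samples = B.shape[1]
    pops = list(signature.columns)
    fracs = np.zeros((n_samples, len(pops)))
    diag = {"rmse_": np.zeros(n_samples), "pearson_r_": np.zeros(n_samples),
            "best_nu_": np.zeros(n_samples)}
    for j in range(n_samples):
        y = B[:, j]
        if not np.any(y):
            raise ValueError(f"bulk sample {bulk.columns[j]!r} is all zero")
        if cfg.scaling:
            sd = y.std()
            if sd == 0:
                raise ValueError(
                    f"bulk sample {bulk.columns[j]!r} is constant on signature genes"
                )
            ys = (y - y.mean()) / sd
        else:
            ys = y
        best = None
        for nu in cfg.nu_grid:
            model = NuSVR(kernel="linear", nu=nu, C=cfg.C, tol=cfg.tol)
            model.fit(Xs, ys)
            pred = model.predict(Xs)
            rmse = float(np.sqrt(((pred - ys) ** 2).mean()))
            if best is None or rmse < best[0]:
                best = (rmse, nu, model.coef_.ravel().copy(), pred)
        rmse, nu, coef, pred = best
        w = np.clip(coef, 0.0, None)
        total = w.sum()
        if total == 0:  # degenerate fit: fall back to uniform
            w = np.full(len(pops), 1.0 / len(pops))
        else:
            w = w / total
        fracs[j] = w
        diag["rmse_"][j] = rmse
        diag["pearson_r_"][j] = float(np.corrcoef(pred, ys)[0, 1])
        diag["best_nu_"][j] = nu

    out = pd.DataFrame(fracs, index=bulk.columns, columns=pops)
    for k, v in diag.items():
        out[k] = v
    return out


def fraction_columns(fractions: pd.DataFrame) -> list[str]:
    """Population columns of a fraction table (diagnostics excluded)."""
    return [c for c in fractions.columns if not str(c).endswith("_")]


def reconstruct_and_score(
    signature: pd.DataFrame, fractions: pd.DataFrame, bulk: pd.DataFrame
) -> pd.DataFrame:
    """Goodness of fit of ``signature @ fractions`` against each bulk sample.

    Both reconstruction and mixture are compared on the standardized scale
    used in fitting.  Returns per-sample ``rmse`` and ``pearson_r``.
    """
    shared = signature.index.intersection(bulk.index)
    S = signature.loc[shared].to_numpy(dtype=float)
    Xs = (S - S.mean()) / S.std()
    pops = fraction_columns(fractions)
    W = fractions[pops].to_numpy(dtype=float)
    rows = []
    for j, sample in enumerate(bulk.columns):
        y = bulk[sample].loc[shared].to_numpy(dtype=float)
        ys = (y - y.mean()) / y.std()
        pred = Xs @ W[fractions.index.get_loc(sample)]
        # renormalized fractions lose the coefficient scale the SVR fit
        # carried; standardize both sides so the comparison is affine-free
        sd = pred.std()
        pred = (pred - pred.mean()) / (sd if sd > 0 else 1.0)
        rows.append(
            {
                "sample": sample,
                "rmse": float(np.sqrt(((pred - ys) ** 2).mean())),
                "pearson_r": float(np.corrcoef(pred, ys)[0, 1]),
            }
        )
    return pd.DataFrame(rows).set_index("sample")
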