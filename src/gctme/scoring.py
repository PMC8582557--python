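"""Ratio-based prognostic scores over cell-population fractions.

A population is "non-rare" when its cohort-mean fraction exceeds a threshold
(default 5% of its compartment).  Ratio scores are computed for every
ordered pair of non-rare populations, and the STEM score combines the two
most prognostic factors of the gastric-cancer microenvironment:

    STEM = f_EMEC / f_Stromal + f_Tadaptive / f_Monocytes

with a small epsilon stabilizing denominators, since deconvolution can emit
exact zeros after clipping.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .deconvolution import fraction_columns


@dataclass
class ScoreConfig:
    rare_threshold: float = 0.05
    ratio_epsilon: float = 1e-6

    def __post_init__(self):
        if not 0 < self.rare_threshold < 1:
            raise ValueError("rare_threshold must be in (0, 1)")
        if self.ratio_epsilon < 0:
            raise ValueError("ratio_epsilon must be >= 0")


def nonrare_populations(
    fractions: pd.DataFrame, cfg: ScoreConfig | None = None
) -> list[str]:
    """Populations whose cohort-mean fraction exceeds the rare threshold."""
    cfg = cfg or ScoreConfig()
    pops = fraction_columns(fractions)
    means = fractions[pops].mean(axis=0)
    return [p for p in pops if means[p] > cfg.rare_threshold]


def ratio_scores(
    fractions: pd.DataFrame,
    populations: list[str] | None = None,
    cfg: ScoreConfig | None = None,
) -> pd.DataFrame:
    """Pairwise fraction ratios ``f_A / (f_B + eps)`` for ordered pairs.

    Both orders of each pair are emitted (columns named ``"A/B"``).
    """
    cfg = cfg or ScoreConfig()
    if populations is None:
        populations = nonrare_populations(fractions, cfg)
    missing = set(populations) - set(fractions.columns)
    if missing:
        raise KeyError(f"populations absent from fractions: {sorted(missing)}")
    out = {}
    for a in populations:
        for b in populations:
            if a == b:
                continue
            out[f"{a}/{b}"] = fractions[a] / (fractions[b] + cfg.ratio_epsilon)
    return pd.DataFrame(out, index=fractions.index)


def stem_score(
    fractions_nonimmune: pd.DataFrame,
    fractions_immune: pd.DataFrame,
    cfg: ScoreConfig | None = None,
    emec: str = "EMEC",
    stromal: str = "Stromal",
    t_adaptive: str = "Tadaptive",
    monocytes: str = "Monocytes",
) -> pd.Series:
    """STEM score: EMEC/Stromal (non-immune) + Tadaptive/Monocytes (immune)."""
    cfg = cfg or ScoreConfig()
    for name, table in ((emec, fractions_nonimmune), (stromal, fractions_nonimmune),
                        (t_adaptive, fractions_immune), (monocytes, fractions_immune)):
        if name not in table.columns:
            raise KeyError(f"required population column missing: {name!r}")
    ni = fractions_nonimmune.loc[:, [emec, stromal]]
    im = fractions_immune.loc[fractions_nonimmune.index, [t_adaptive, monocytes]]
    score = ni[emec] / (ni[stromal] + cfg.ratio_epsilon) + im[t_adaptive] / (
        im[monocytes] + cfg.ratio_epsilon
    )
    score.name = "stem_score"
    return score
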