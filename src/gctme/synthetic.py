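"""Synthetic single-cell, bulk-mixture, and survival data generators.

These generators plant known structure (marker genes, mixing proportions,
a log-hazard effect of the STEM score) so that every downstream stage of the
pipeline can be validated against ground truth.  Single-cell counts are
negative-binomial with per-subject multiplicative effects; bulk mixtures are
signature-weighted linear combinations with multiplicative log-normal noise;
survival times are exponential (optionally Weibull) with independent
exponential censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimScConfig:
    """Configuration for the single-cell count generator.

    Parameters
    ----------
    n_genes
        Total number of genes simulated.
    cell_types
        Mapping of cell-type label to number of cells of that type.
    subjects
        Subject (biopsy) labels; cells are assigned to subjects uniformly
        at random.
    subject_stage
        Mapping of each subject to its disease stage (e.g. NAG/CAG/IM/EGC).
    n_markers_per_type
        Number of marker genes planted per cell type; marker sets of
        distinct types are disjoint by construction.
    marker_fold
        Fold-elevation of a marker gene's mean in its own cell type (>= 1;
        1 means no planted signal).
    baseline_dispersion
        Negative-binomial dispersion alpha (variance = mu + alpha * mu^2);
        0 gives Poisson counts.
    subject_effect_sd
        Standard deviation of per-(subject, gene) log-normal multiplicative
        effects; 0 disables subject structure.
    mean_scale
        Scale of baseline gene means (mean UMI per gene per cell before
        marker/subject effects).
    seed
        Seed for the generator.
    """

    n_genes: int = 2000
    cell_types: dict[str, int] = field(
        default_factory=lambda: {"typeA": 200, "typeB": 200, "typeC": 200}
    )
    subjects: list[str] = field(
        default_factory=lambda: [f"S{i}" for i in range(1, 10)]
    )
    subject_stage: dict[str, str] = field(
        default_factory=lambda: {
            "S1": "NAG", "S2": "NAG", "S3": "CAG", "S4": "CAG",
            "S5": "IM", "S6": "IM", "S7": "IM", "S8": "EGC", "S9": "EGC",
        }
    )
    n_markers_per_type: int = 50
    marker_fold: float = 8.0
    baseline_dispersion: float = 0.5
    subject_effect_sd: float = 0.2
    mean_scale: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_markers_per_type <= 0:
            raise ConfigError("n_genes and n_markers_per_type must be positive")
        if self.marker_fold < 1:
            raise ConfigError("marker_fold must be >= 1")
        if self.baseline_dispersion < 0 or self.subject_effect_sd < 0:
            raise ConfigError("dispersion and subject_effect_sd must be >= 0")
        if self.n_markers_per_type * len(self.cell_types) > self.n_genes:
            raise ConfigError(
                "marker sets would overlap: "
                f"{len(self.cell_types)} types x {self.n_markers_per_type} "
                f"markers exceed {self.n_genes} genes"
            )
        missing = set(self.subjects) - set(self.subject_stage)
        if missing:
            raise ConfigError(f"subjects without a stage: {sorted(missing)}")


@dataclass
class SimMixtureConfig:
    """Configuration for signature-weighted bulk mixtures.

    ``proportions`` is a samples x populations matrix whose rows are points
    on the probability simplex; ``noise_sd`` is the standard deviation of
    additive Gaussian noise on the natural-log scale of expression.
    """

    proportions: pd.DataFrame | np.ndarray = None
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self, n_populations: int) -> pd.DataFrame:
        if self.proportions is None:
            raise ConfigError("proportions must be provided")
        props = pd.DataFrame(self.proportions)
        if props.shape[1] != n_populations:
            raise ConfigError(
                f"proportions have {props.shape[1]} columns but the "
                f"signature has {n_populations} populations"
            )
        vals = props.to_numpy(dtype=float)
        if (vals < 0).any():
            raise ConfigError("proportions must be non-negative")
        if not np.allclose(vals.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigError("each proportions row must sum to 1 within 1e-9")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        return props


@dataclass
class SimSurvivalConfig:
    """Configuration for survival outcomes with a planted score effect.

    The hazard for sample *i* is
    ``baseline_hazard * exp(beta_stem * (score_i - mean(score)))`` with an
    exponential baseline (``weibull_shape`` = 1) or a Weibull baseline of
    the given shape.  Censoring is independent exponential with rate
    ``censor_rate`` (0 disables censoring).
    """

    beta_stem: float = 0.0
    baseline_hazard: float = 0.1
    censor_rate: float = 0.02
    weibull_shape: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be > 0")
        if self.censor_rate < 0:
            raise ConfigError("censor_rate must be >= 0")
        if self.weibull_shape <= 0:
            raise ConfigError("weibull_shape must be > 0")


def simulate_sc_dataset(cfg: SimScConfig) -> tuple[ad.AnnData, dict[str, list[str]]]:
    """Simulate an annotated single-cell count matrix with planted markers.

    Returns an :class:`anndata.AnnData` (cells x genes, sparse counts, obs
    columns ``cell_type``/``subject``/``stage``) and the planted marker sets
    per cell type.  Counts are negative-binomial around a per-gene baseline
    mean, multiplied by ``marker_fold`` for a type's markers in that type's
    cells and by a log-normal per-(subject, gene) effect.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    gene_names = [f"g{i:05d}" for i in range(cfg.n_genes)]
    base_mean = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes) * cfg.mean_scale

    types = list(cfg.cell_types)
    marker_sets: dict[str, list[str]] = {}
    marker_idx: dict[str, np.ndarray] = {}
    pool = rng.permutation(cfg.n_genes)
    for i, t in enumerate(types):
        idx = pool[i * cfg.n_markers_per_type : (i + 1) * cfg.n_markers_per_type]
        marker_idx[t] = np.sort(idx)
        marker_sets[t] = [gene_names[j] for j in marker_idx[t]]

    subj_effect = {
        s: rng.lognormal(mean=0.0, sigma=cfg.subject_effect_sd, size=cfg.n_genes)
        if cfg.subject_effect_sd > 0
        else np.ones(cfg.n_genes)
        for s in cfg.subjects
    }

    blocks, cell_type_lab, subject_lab = [], [], []
    for t in types:
        n_cells = cfg.cell_types[t]
        type_mean = base_mean.copy()
        type_mean[marker_idx[t]] *= cfg.marker_fold
        cell_subjects = rng.choice(cfg.subjects, size=n_cells)
        for s in cfg.subjects:
            n_s = int((cell_subjects == s).sum())
            if n_s == 0:
                continue
            mu = np.broadcast_to(type_mean * subj_effect[s], (n_s, cfg.n_genes))
            if cfg.baseline_dispersion > 0:
                r = 1.0 / cfg.baseline_dispersion
                counts = rng.negative_binomial(r, r / (r + mu))
            else:
                counts = rng.poisson(mu)
            blocks.append(sparse.csr_matrix(counts))
            cell_type_lab.extend([t] * n_s)
            subject_lab.extend([s] * n_s)

    X = sparse.vstack(blocks).tocsr()
    obs = pd.DataFrame(
        {
            "cell_type": pd.Categorical(cell_type_lab),
            "subject": pd.Categorical(subject_lab),
        },
        index=[f"cell{i:06d}" for i in range(X.shape[0])],
    )
    obs["stage"] = pd.Categorical([cfg.subject_stage[s] for s in subject_lab])
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=gene_names))
    adata.uns["planted_markers"] = marker_sets
    return adata, marker_sets


def simulate_mixtures(
    signature: pd.DataFrame, cfg: SimMixtureConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate bulk profiles as signature-weighted mixtures.

    Each sample's expression is ``signature @ proportions`` perturbed by
    multiplicative log-normal noise (``exp(N(0, noise_sd))`` per entry).
    Returns ``(bulk, true_fractions)`` with bulk genes x samples and
    fractions samples x populations.
    """
    if signature.shape[1] < 2:
        raise ConfigError("signature must have at least 2 populations")
    props = cfg.validate(signature.shape[1])
    props.columns = signature.columns
    rng = np.random.default_rng(cfg.seed)

    expr = signature.to_numpy(dtype=float) @ props.to_numpy(dtype=float).T
    if cfg.noise_sd > 0:
        expr = expr * np.exp(rng.normal(0.0, cfg.noise_sd, size=expr.shape))
    sample_ids = [f"mix{i:03d}" for i in range(props.shape[0])]
    bulk = pd.DataFrame(expr, index=signature.index, columns=sample_ids)
    fractions = pd.DataFrame(
        props.to_numpy(dtype=float), index=sample_ids, columns=signature.columns
    )
    return bulk, fractions


#: Fine immune cell types and their seven-lineage grouping, mirroring the
#: merge of sorted-immune signature types into major lineages.
IMMUNE_LINEAGE_MAP: dict[str, str] = {
    "cd4_naive": "Tadaptive",
    "cd4_memory": "Tadaptive",
    "cd8_naive": "Tadaptive",
    "cd8_memory": "Tadaptive",
    "gd_T": "Tinnate",
    "MAIT": "Tinnate",
    "B_naive": "Badaptive",
    "B_memory": "Badaptive",
    "NK_bright": "NK",
    "NK_dim": "NK",
    "mono_classical": "Monocytes",
    "mono_nonclassical": "Monocytes",
    "mDC": "Dendritic",
    "pDC": "Dendritic",
    "neutrophil": "Granulocytes",
    "eosinophil": "Granulocytes",
    "basophil": "Granulocytes",
}


def synthetic_immune_signature(
    n_genes: int = 400, seed: int = 0
) -> tuple[pd.DataFrame, dict[str, str]]:
    """A synthetic fine-type immune signature plus its lineage map.

    Stands in for a sorted-immune reference signature in tests and demos:
    17 fine immune types, each given a block of strongly elevated marker
    genes over a shared low baseline.  Returns ``(signature, lineage_map)``
    where the map merges the fine types into 7 major lineages.
    """
    rng = np.random.default_rng(seed)
    fine_types = list(IMMUNE_LINEAGE_MAP)
    base = rng.lognormal(1.0, 0.6, size=(n_genes, len(fine_types)))
    per = n_genes // len(fine_types)
    for j in range(len(fine_types)):
        base[j * per : (j + 1) * per, j] *= rng.uniform(8.0, 20.0, size=per)
    sig = pd.DataFrame(
        base,
        index=[f"im{i:04d}" for i in range(n_genes)],
        columns=fine_types,
    )
    return sig, dict(IMMUNE_LINEAGE_MAP)


def simulate_survival(
    stem_scores: pd.Series | np.ndarray, cfg: SimSurvivalConfig
) -> pd.DataFrame:
    """Simulate right-censored survival times driven by a score.

    The log hazard is linear in the centered score with slope
    ``cfg.beta_stem``.  Returns a DataFrame with columns ``os_time`` and
    ``os_event`` indexed like ``stem_scores``.
    """
    cfg.validate()
    scores = pd.Series(stem_scores, dtype=float)
    if not np.isfinite(scores.to_numpy()).all():
        raise ConfigError("stem_scores must be finite")
    rng = np.random.default_rng(cfg.seed)

    hazard = cfg.baseline_hazard * np.exp(
        cfg.beta_stem * (scores.to_numpy() - scores.mean())
    )
    e = rng.exponential(1.0, size=len(scores))
    event_time = (e / hazard) ** (1.0 / cfg.weibull_shape)
    if cfg.censor_rate > 0:
        censor_time = rng.exponential(1.0 / cfg.censor_rate, size=len(scores))
    else:
        censor_time = np.full(len(scores), np.inf)
    os_time = np.minimum(event_time, censor_time)
    os_event = (event_time <= censor_time).astype(int)
    return pd.DataFrame(
        {"os_time": os_time, "os_event": os_event}, index=scores.index
    )
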