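"""Quality-control the single-cell reference, summarize it into TPM
pseudobulk, rank genes by the cell-type-vs-subject two-way ANOVA criterion,
and cut the Ward tree over (cell type, stage) mean profiles into cell
populations.

Reads results/reference/, writes the gene ranking, the tree (Newick), the
population assignment per cell, and a stability diagnostic across the
top-N grid to results/populations/.
"""

from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from gctme import io, populations, sc_preprocess

REF = Path("results/reference")
OUT = Path("results/populations")
K_POPULATIONS = 10

# population names follow the dominant member cell type of each cluster;
# cancer-led clusters are the early-malignant (EMEC) population, enterocyte-
# led ones premalignant (PMEC), fibroblast/smooth-muscle are stromal
TYPE_PRIORITY = ["cancer", "fibroblast", "SM", "enterocyte", "endothelial",
                 "GMC", "goblet", "enteroendocrine", "MSC", "PC", "PMC"]
TYPE_NAME = {
    "cancer": "EMEC", "enterocyte": "PMEC", "fibroblast": "Stromal",
    "SM": "Stromal", "endothelial": "Endothelial", "GMC": "GMC",
    "goblet": "Goblet", "enteroendocrine": "Enteroendocrine",
    "MSC": "MSC", "PC": "PC", "PMC": "PMC",
}


def name_clusters(cut: pd.Series) -> dict[int, str]:
    """Name each cluster after its highest-priority member cell type."""
    label_map: dict[int, str] = {}
    used: dict[str, int] = {}
    for cluster in sorted(cut.unique()):
        types = {t for t, _ in cut.index[cut == cluster]}
        lead = next(t for t in TYPE_PRIORITY if t in types)
        name = TYPE_NAME[lead]
        if name in used.values() or name in label_map.values():
            name = f"{name}2"
        label_map[cluster] = name
    return label_map


def main() -> None:
    adata = io.read_annotated_counts(REF / "sc")
    filtered = sc_preprocess.qc_filter(adata, sc_preprocess.QcConfig())
    print(f"QC: {adata.n_obs} -> {filtered.n_obs} cells, "
          f"{adata.n_vars} -> {filtered.n_vars} genes")

    pb = sc_preprocess.pseudobulk_summarize(filtered)
    tpm = sc_preprocess.tpm_normalize(pb)
    ranking = populations.rank_genes_anova(tpm, populations.ClusterConfig())
    subject_stage = dict(
        filtered.obs.drop_duplicates("subject")[["subject", "stage"]]
        .astype(str).itertuples(index=False)
    )

    # stability of the population assignment across the top-N grid
    cuts = {}
    for n_top in (50, 100, 150, 200):
        genes = ranking.index[ranking["rank"] <= n_top]
        profiles = populations.mean_stage_profiles(tpm, subject_stage, genes)
        tree = populations.build_cluster_tree(profiles)
        cuts[n_top] = tree.cut(K_POPULATIONS)
    for n_top, cut in cuts.items():
        ari = adjusted_rand_score(cuts[100].to_numpy(), cut.to_numpy())
        print(f"top-{n_top} genes: ARI vs top-100 cut = {ari:.3f}")

    genes = ranking.index[ranking["selected"]]
    profiles = populations.mean_stage_profiles(tpm, subject_stage, genes)
    tree = populations.build_cluster_tree(profiles)
    label_map = name_clusters(tree.cut(K_POPULATIONS))
    assignment = populations.assign_populations(
        tree, filtered.obs, k=K_POPULATIONS, label_map=label_map
    )
    print(f"{K_POPULATIONS} populations over {len(tree.leaves)} "
          f"(cell type, stage) leaves; per-population cell counts:")
    print(assignment.value_counts().to_string())

    OUT.mkdir(parents=True, exist_ok=True)
    io.write_table(ranking, OUT / "gene_ranking.tsv")
    (OUT / "cluster_tree.nwk").write_text(tree.to_newick() + "\n")
    io.write_table(assignment.to_frame(), OUT / "population_assignment.tsv")
    io.write_pseudobulk(tpm, OUT / "pseudobulk_tpm.tsv")


if __name__ == "__main__":
    main()
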