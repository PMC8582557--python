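"""Select population marker genes, pick the marker depth M by deconvolving
the artificial per-biopsy bulk, and build the non-immune signature matrix.

Reads results/reference/ and results/populations/, writes the chosen-M
accuracy table, marker lists and the signature matrix to
results/signature/.
"""

from pathlib import Path

import pandas as pd

from gctme import io, sc_preprocess, signature
from gctme.deconvolution import DeconvConfig

REF = Path("results/reference")
POP = Path("results/populations")
OUT = Path("results/signature")

# marker-depth grid scaled to the synthetic reference's 60 planted
# markers per cell type
M_GRID = [25, 50, 75, 100, 125]


def main() -> None:
    adata = io.read_annotated_counts(REF / "sc")
    filtered = sc_preprocess.qc_filter(adata, sc_preprocess.QcConfig())
    assignment = pd.read_csv(
        POP / "population_assignment.tsv", sep="\t", index_col=0
    )["population"]

    filtered.obs["population"] = assignment.reindex(filtered.obs_names)
    pb = sc_preprocess.pseudobulk_summarize(
        filtered, group_by=("population", "subject")
    )
    tpm = sc_preprocess.tpm_normalize(pb)

    bulk, true_fr = signature.make_artificial_bulk(filtered, assignment)
    best_m, table = signature.choose_M(
        tpm, bulk, true_fr,
        signature.MarkerConfig(M_grid=M_GRID),
        DeconvConfig(min_overlap_genes=50),
    )
    print("marker-depth selection (mean per-biopsy RMSE on artificial bulk):")
    print(table.to_string(index=False))
    print(f"chosen M = {best_m}")

    markers, stats = signature.select_markers(
        tpm, signature.MarkerConfig(M_per_population=best_m, M_grid=M_GRID)
    )
    sig = signature.build_signature(tpm, markers, name=f"synthetic-GC{len(markers)}")
    print(f"signature matrix: {sig.shape[0]} genes x {sig.shape[1]} populations")

    OUT.mkdir(parents=True, exist_ok=True)
    io.write_table(table, OUT / "choose_m.tsv", index=False)
    io.write_table(sig, OUT / "signature.tsv")
    io.write_table(stats, OUT / "marker_stats.tsv", index=False)
    marker_lists = pd.DataFrame.from_dict(markers, orient="index").T
    io.write_table(marker_lists, OUT / "marker_lists.tsv", index=False)


if __name__ == "__main__":
    main()
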