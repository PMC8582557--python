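"""Simulate the single-cell reference: a gastric biopsy cohort of nine
subjects spanning the gastritis-to-early-cancer cascade (NAG, CAG, IM, EGC),
with eleven non-immune cell types and planted marker genes.

Writes the annotated counts (MTX + TSV sidecars) and the planted marker
sets under results/reference/.
"""

import json
from pathlib import Path

from gctme import io, synthetic

OUT = Path("results/reference")

CELL_TYPES = {
    "cancer": 180, "enterocyte": 150, "enteroendocrine": 120, "GMC": 150,
    "goblet": 150, "MSC": 150, "PC": 150, "PMC": 150,
    "endothelial": 130, "fibroblast": 150, "SM": 120,
}
SUBJECT_STAGE = {
    "S1": "NAG", "S2": "NAG", "S3": "CAG", "S4": "CAG",
    "S5": "IM", "S6": "IM", "S7": "IM", "S8": "EGC", "S9": "EGC",
}


def main(seed: int = 20) -> None:
    cfg = synthetic.SimScConfig(
        n_genes=3000,
        cell_types=CELL_TYPES,
        subjects=list(SUBJECT_STAGE),
        subject_stage=SUBJECT_STAGE,
        n_markers_per_type=60,
        marker_fold=8.0,
        baseline_dispersion=0.5,
        subject_effect_sd=0.2,
        seed=seed,
    )
    adata, markers = synthetic.simulate_sc_dataset(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    io.write_annotated_counts(adata, OUT / "sc")
    (OUT / "planted_markers.json").write_text(json.dumps(markers, indent=1))
    print(f"simulated {adata.n_obs} cells x {adata.n_vars} genes "
          f"({len(CELL_TYPES)} cell types, {len(SUBJECT_STAGE)} subjects)")
    print(f"wrote {OUT}/sc.mtx (+ sidecars) and planted marker sets")


if __name__ == "__main__":
    main()
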