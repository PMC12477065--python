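"""Generate the synthetic multi-metastasis cohort used by every later step.

Writes the full cohort bundle (transcripts, proteome, per-sample VCFs and
PSM tables, raw abundance matrix, clinical table, AF reference table, gene
sets and the ground-truth JSON) under results/cohort/ using the default
study conditions: 24 patients with 1-9 metastases, 120 genes, 168 planted
variants, four abundance clusters and cluster-linked survival.
"""

import sys
from pathlib import Path

from proteohet import synth

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main(seed: int = 42) -> None:
    cfg = synth.SynthConfig(seed=seed)
    cohort = synth.simulate_cohort(cfg)
    cohort.write(OUT)
    truth = cohort.ground_truth
    print(f"cohort written to {OUT}")
    print(f"  patients: {cfg.n_patients}, metastasis samples: {len(cohort.samples)}")
    print(f"  planted variants: {len(truth.planted_variants)} "
          f"({(truth.planted_variants['frame_effect'] == 'frameshift').sum()} frameshift)")
    n_peps = sum(len(v) for v in truth.planted_peptides.values())
    print(f"  planted non-reference peptides (sample-level): {n_peps}")
    print(f"  abundance matrix: {cohort.abundance_raw.shape[0]} proteins x "
          f"{cohort.abundance_raw.shape[1]} replicates, "
          f"{cohort.abundance_raw.isna().mean().mean():.1%} missing")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 42)
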