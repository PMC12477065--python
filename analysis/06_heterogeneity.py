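"""Heterogeneity analyses: consensus clustering, cluster-specific proteins,
NRP enrichment and sample similarity.

Consensus-clusters the prepared abundance matrix (PAM on 1 - Pearson
distance, 100 resamples of 80% of samples, k = 2..6, delta-area elbow),
compares the recovered partition to the planted truth, derives
cluster-specific upregulated proteins, tests each NRP for one-sided Fisher
enrichment in each cluster and writes the similarity matrices.
"""

import json
from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from proteohet import hetero_stats
from proteohet import io as phio

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohort"
OUT = ROOT / "results"


def main(seed: int = 42) -> None:
    matrix = phio.read_matrix_tsv(OUT / "abundance_prepared.tsv")
    presence = phio.read_matrix_tsv(OUT / "nrp_presence.tsv")

    params = hetero_stats.ConsensusParams(n_resamples=100, seed=seed)
    res = hetero_stats.consensus_cluster(matrix, params)
    assign = res.assignments[res.chosen_k]
    assign.rename("cluster").to_frame().to_csv(OUT / "assignments.tsv", sep="\t")
    for k, cons in res.consensus.items():
        phio.write_matrix_tsv(cons.round(4), OUT / f"consensus_k{k}.tsv")

    with open(COHORT / "groundtruth.json") as fh:
        truth = pd.Series(json.load(fh)["true_cluster_assignment"])
    ari = adjusted_rand_score(truth.loc[assign.index], assign)
    print(f"chosen k = {res.chosen_k} "
          f"(delta-area: {({k: round(v, 3) for k, v in res.delta_area.items()})})")
    print(f"adjusted Rand index vs planted clusters: {ari:.3f}")
    print(f"cluster sizes: {dict(assign.value_counts().sort_index())}")

    up = hetero_stats.cluster_specific_upregulation(matrix, assign)
    for c in sorted(up):
        print(f"  cluster {c}: {len(up[c])} specifically upregulated proteins")
    pd.DataFrame(
        [(c, p) for c, prots in up.items() for p in prots], columns=["cluster", "protein"]
    ).to_csv(OUT / "cluster_upregulated.tsv", sep="\t", index=False)

    shared = [s for s in assign.index if s in presence.columns]
    rows = []
    for key, row in presence[shared].iterrows():
        for c in sorted(assign.unique()):
            p = hetero_stats.fisher_enrichment(row.to_numpy(), (assign[shared] == c).to_numpy())
            rows.append({"nrp": key, "cluster": c, "p": p})
    enr = pd.DataFrame(rows)
    enr.to_csv(OUT / "nrp_cluster_enrichment.tsv", sep="\t", index=False)
    print(f"NRP-cluster enrichments with p < .01: {(enr['p'] < 0.01).sum()}")

    pearson, jaccard = hetero_stats.similarity_matrices(matrix, presence[shared])
    phio.write_matrix_tsv(pearson.round(4), OUT / "similarity_pearson.tsv")
    phio.write_matrix_tsv(jaccard.round(4), OUT / "similarity_jaccard.tsv")


if __name__ == "__main__":
    main()
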