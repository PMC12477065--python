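"""Call non-reference peptides from the PSM tables against the variant DB.

Filters PSMs (1% FDR + validation + I/L-collapsed reference subtraction),
maps the survivors cohort-wide against the variant database, merges
missed-cleavage variants and writes the NRP catalogue, the binary presence
matrix and the min-3-patients association subset under results/. Also
reports recall against the planted ground truth.
"""

import json
from pathlib import Path

from proteohet import io as phio
from proteohet import nrpcall, variantdb

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohort"
OUT = ROOT / "results"


def main() -> None:
    reference = phio.read_fasta(COHORT / "proteome.fasta")
    db = variantdb.CohortVariantDb.read(OUT / "cohort_db.fasta", OUT / "provenance.tsv")
    clinical = phio.read_tsv(COHORT / "clinical.tsv")
    samples = list(clinical["sample_id"])
    patient_map = dict(zip(clinical["sample_id"], clinical["patient_id"]))
    psms = [phio.read_tsv(COHORT / f"psm.{s}.tsv") for s in samples]

    records, matrix, n_patients = nrpcall.call_nrps(psms, reference, db, samples, patient_map)
    assert nrpcall.warn_if_reference_hits(records, reference) == 0

    catalog = nrpcall.catalog_frame(records)
    phio.write_tsv(catalog, OUT / "nrp_catalog.tsv")
    phio.write_matrix_tsv(matrix, OUT / "nrp_presence.tsv")
    assoc = nrpcall.filter_min_patients(matrix, n_patients, min_patients=3)
    phio.write_matrix_tsv(assoc, OUT / "nrp_presence_min3.tsv")

    with open(COHORT / "groundtruth.json") as fh:
        truth = json.load(fh)
    planted = {
        p.replace("I", "L") for peps in truth["planted_peptides"].values() for p in peps
    }
    detected = {m.replace("I", "L") for r in records for m in r.member_peptides}
    recall = sum(1 for p in planted if p in detected) / len(planted)

    print(f"NRP catalogue: {len(records)} entries "
          f"({dict(catalog['variant_class'].value_counts())})")
    print(f"present in >=3 patients: {len(assoc)}")
    print(f"recall of planted variant peptides: {recall:.3f}")


if __name__ == "__main__":
    main()
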