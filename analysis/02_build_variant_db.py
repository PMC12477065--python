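"""Build the cohort-wide variant protein database from per-sample VCFs.

Reads the transcripts and per-sample variant calls written by
01_simulate_cohort.py, expands them into variant protein sequences
(30-aa-window combinations for in-frame variants, single shifted
translations for frameshifts, 10 000-combination per-gene cap) and writes
the MD5-deduplicated FASTA plus the provenance TSV under results/.
"""

from pathlib import Path

import pandas as pd

from proteohet import io as phio
from proteohet import variantdb

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohort"
OUT = ROOT / "results"


def main() -> None:
    cds = phio.read_fasta(COHORT / "transcripts.fasta")
    table = phio.read_tsv(COHORT / "transcript_table.tsv")
    transcripts = {
        row.transcript_id: variantdb.TranscriptModel(row.gene_id, row.transcript_id, cds[row.transcript_id])
        for row in table.itertuples()
    }
    all_records = []
    dropped_total = []
    for vcf_path in sorted(COHORT.glob("variants.*.vcf")):
        sample = vcf_path.name[len("variants."):-len(".vcf")]
        calls = [
            variantdb.VariantCall(sample, chrom, pos, ref, alt)
            for chrom, pos, ref, alt in phio.read_vcf(vcf_path)
        ]
        records, dropped = variantdb.predict_sample_records(transcripts, calls)
        all_records.extend(records)
        dropped_total.extend((sample, g) for g in dropped)

    db = variantdb.build_cohort_db(all_records)
    db.write(OUT / "cohort_db.fasta", OUT / "provenance.tsv")
    print(f"variant DB: {len(db.fasta_records)} unique sequences from "
          f"{len(db.provenance)} per-sample predictions")
    print(f"genes dropped by the combination cap: {len(dropped_total)}")
    by_type = db.provenance["prediction_type"].value_counts()
    print("predictions by type:", dict(by_type))


if __name__ == "__main__":
    main()
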