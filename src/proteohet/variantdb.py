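"""Cohort-wide variant protein database construction.

Per-sample small variants called on coding transcripts are expanded into
putative variant protein sequences: all combinations of in-frame variants
within a 30-residue window are applied and translated, frameshift variants
are translated singly through to the first downstream stop, genes whose
combination count explodes (> 10 000 per sample) are dropped, and the
cohort-wide set of sequences is deduplicated by MD5 with a provenance
table mapping each sequence back to the samples and predictions that
produced it.

Variant coordinates are transcript-relative, 0-based, half-open.
"""

from __future__ import annotations

import hashlib
import itertools
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

from . import io as phio

PREDICTION_TYPES = ("in_frame", "frameshift", "splice", "novel_orf")

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class TranscriptModel:
    """One coding transcript: an intronless CDS from start codon to stop."""

    gene_id: str
    transcript_id: str
    cds_seq: str
    strand: str = "+"

    def __post_init__(self):
        cds = self.cds_seq.upper()
        if len(cds) % 3 != 0:
            raise ValueError(f"{self.transcript_id}: CDS length not a multiple of 3")
        if not cds.startswith("ATG"):
            raise ValueError(f"{self.transcript_id}: CDS does not start with ATG")
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if codons[-1] not in STOP_CODONS:
            raise ValueError(f"{self.transcript_id}: CDS does not end in a stop codon")
        if any(c in STOP_CODONS for c in codons[:-1]):
            raise ValueError(f"{self.transcript_id}: internal stop codon")
        object.__setattr__(self, "cds_seq", cds)

    @property
    def protein(self) -> str:
        """Translated protein, stop codon excluded."""
        return str(Seq(self.cds_seq).translate(to_stop=True))


@dataclass(frozen=True)
class VariantCall:
    """One called small variant in transcript-relative CDS coordinates."""

    sample_id: str
    transcript_id: str
    pos: int  # 0-based offset into the CDS
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles are identical")
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("empty alleles are not supported (use anchored alleles)")

    @property
    def frame_effect(self) -> str:
        return classify_frame_effect(self)

    @property
    def residue(self) -> int:
        """First affected protein residue (0-based)."""
        return self.pos // 3

    @property
    def end(self) -> int:
        """End of the replaced reference span (0-based, exclusive)."""
        return self.pos + len(self.ref_allele)

    def key(self) -> str:
        return f"{self.transcript_id}:{self.pos}:{self.ref_allele}>{self.alt_allele}"


@dataclass(frozen=True)
class VariantDbParams:
    window_aa: int = 30
    max_combinations_per_gene: int = 10_000

    def __post_init__(self):
        if self.window_aa < 1 or self.max_combinations_per_gene < 1:
            raise ValueError("window_aa and max_combinations_per_gene must be >= 1")


def classify_frame_effect(variant: VariantCall) -> str:
    """In-frame iff the allele length difference is a multiple of 3 (SNVs included)."""
    delta = abs(len(variant.alt_allele) - len(variant.ref_allele))
    return "in_frame" if delta % 3 == 0 else "frameshift"


def _overlaps(a: VariantCall, b: VariantCall) -> bool:
    return a.pos < b.end and b.pos < a.end


def _subset_key(subset: Sequence[VariantCall]) -> tuple:
    return tuple((v.pos, v.ref_allele, v.alt_allele) for v in subset)


def enumerate_window_combinations(
    variants: Sequence[VariantCall], params: VariantDbParams = VariantDbParams()
) -> list[tuple[VariantCall, ...]]:
    """All co-occurrence combinations of in-frame variants within 30-aa windows.

    Windows are anchored at each variant's first affected residue and extend
    ``window_aa`` residues. For each anchor, every non-empty subset of the
    in-frame variants falling inside that window is generated; subsets seen in
    several windows are emitted once. Variants whose reference spans overlap
    are mutually exclusive and never combined.
    """
    inframe = sorted(
        (v for v in variants if classify_frame_effect(v) == "in_frame"),
        key=lambda v: (v.pos, v.ref_allele, v.alt_allele),
    )
    seen: set[tuple] = set()
    out: list[tuple[VariantCall, ...]] = []
    for anchor in inframe:
        members = [
            v for v in inframe if anchor.residue <= v.residue < anchor.residue + params.window_aa
        ]
        if len(members) > 25:
            raise ValueError(
                f"{anchor.transcript_id}: {len(members)} in-frame variants in one "
                f"{params.window_aa}-aa window; combination enumeration refused"
            )
        for r in range(1, len(members) + 1):
            for combo in itertools.combinations(members, r):
                if any(
                    _overlaps(a, b) for a, b in itertools.combinations(combo, 2)
                ):
                    continue
                key = _subset_key(combo)
                if key not in seen:
                    seen.add(key)
                    out.append(combo)
    out.sort(key=_subset_key)
    return out


def count_and_cap_gene(
    gene_id: str,
    subsets_per_transcript: dict[str, Sequence],
    params: VariantDbParams = VariantDbParams(),
) -> tuple[int, bool]:
    """Total combination count for one gene in one sample, and the drop decision.

    Returns ``(count, keep)``; the gene is dropped iff the count exceeds
    ``max_combinations_per_gene``. The decision is per (gene, sample).
    """
    count = sum(len(s) for s in subsets_per_transcript.values())
    return count, count <= params.max_combinations_per_gene


@dataclass(frozen=True)
class VariantSeqRecord:
    """One predicted variant protein (sub)sequence with its provenance header."""

    sample_id: str
    prediction_type: str
    header: str
    seq: str


def _apply_variants(cds: str, subset: Sequence[VariantCall]) -> str:
    parts: list[str] = []
    cursor = 0
    for v in sorted(subset, key=lambda v: v.pos):
        found = cds[v.pos : v.end]
        if found != v.ref_allele:
            raise ValueError(
                f"{v.transcript_id}: ref allele mismatch at CDS offset {v.pos} "
                f"(expected {v.ref_allele!r}, CDS has {found!r})"
            )
        parts.append(cds[cursor : v.pos])
        parts.append(v.alt_allele)
        cursor = v.end
    parts.append(cds[cursor:])
    return "".join(parts)


def _make_header(transcript: TranscriptModel, subset: Sequence[VariantCall], ptype: str) -> str:
    desc = ";".join(
        f"{v.pos}{v.ref_allele}>{v.alt_allele}" for v in sorted(subset, key=lambda v: v.pos)
    )
    return f"{transcript.transcript_id}|{transcript.gene_id}|{ptype}|{desc}"


def gene_of_header(header: str) -> str:
    """Gene id encoded in a variant-record FASTA header."""
    return header.split("|")[1]


def apply_and_translate(
    transcript: TranscriptModel,
    subset: Sequence[VariantCall],
    params: VariantDbParams = VariantDbParams(),
) -> VariantSeqRecord | None:
    """Apply a variant subset to a transcript and emit the affected protein region.

    In-frame subsets yield the translated window of affected residues plus
    ``window_aa`` flanking residues on each side (clipped at the protein
    ends); a frameshift variant (always applied singly) yields the shifted
    translation from its first affected codon to the first downstream stop,
    plus the upstream flank. Returns ``None`` when the subset leaves the
    protein unchanged (synonymous) — the reference sequence is never emitted.
    """
    if not subset:
        return None
    subset = sorted(subset, key=lambda v: v.pos)
    frame_effects = {classify_frame_effect(v) for v in subset}
    if "frameshift" in frame_effects and len(subset) > 1:
        raise ValueError("frameshift variants must be applied singly")
    ptype = "frameshift" if "frameshift" in frame_effects else "in_frame"

    mutant_cds = _apply_variants(transcript.cds_seq, subset)
    # partial trailing codon after a frameshift is dropped
    usable = mutant_cds[: len(mutant_cds) - len(mutant_cds) % 3]
    mutant_prot = str(Seq(usable).translate(to_stop=True))
    ref_prot = transcript.protein
    if mutant_prot == ref_prot:
        return None

    first_res = subset[0].pos // 3
    if ptype == "frameshift":
        start = max(0, first_res - params.window_aa)
        seq = mutant_prot[start:]
    else:
        shift_before_last = sum(
            len(v.alt_allele) - len(v.ref_allele) for v in subset[:-1]
        )
        last = subset[-1]
        last_nt_end = last.pos + shift_before_last + len(last.alt_allele)
        last_res = max(first_res, (last_nt_end - 1) // 3)
        start = max(0, first_res - params.window_aa)
        end = min(len(mutant_prot), last_res + 1 + params.window_aa)
        seq = mutant_prot[start:end]
    if not seq:
        return None
    sample = subset[0].sample_id
    return VariantSeqRecord(sample, ptype, _make_header(transcript, subset, ptype), seq)


def predict_sample_records(
    transcripts: dict[str, TranscriptModel],
    variants: Sequence[VariantCall],
    params: VariantDbParams = VariantDbParams(),
) -> tuple[list[VariantSeqRecord], list[str]]:
    """All variant sequence records for one sample, honouring the per-gene cap.

    Variants are grouped per transcript; in-frame variants are combined within
    windows, frameshifts emitted singly. Genes whose total combination count
    (across all their transcripts) exceeds the cap are dropped for this
    sample; the dropped gene ids are returned alongside the records.
    """
    by_transcript: dict[str, list[VariantCall]] = {}
    for v in variants:
        if v.transcript_id not in transcripts:
            warnings.warn(f"variant on unknown transcript {v.transcript_id}; skipped")
            continue
        t = transcripts[v.transcript_id]
        if not (0 <= v.pos and v.end <= len(t.cds_seq)):
            warnings.warn(f"variant {v.key()} outside CDS; rejected")
            continue
        by_transcript.setdefault(v.transcript_id, []).append(v)

    per_gene: dict[str, dict[str, dict]] = {}
    for tid, tvars in by_transcript.items():
        t = transcripts[tid]
        subsets = enumerate_window_combinations(tvars, params)
        fs = [
            (v,)
            for v in sorted(tvars, key=lambda v: (v.pos, v.ref_allele, v.alt_allele))
            if classify_frame_effect(v) == "frameshift"
        ]
        per_gene.setdefault(t.gene_id, {})[tid] = {"subsets": list(subsets) + fs}

    records: list[VariantSeqRecord] = []
    dropped: list[str] = []
    for gene_id in sorted(per_gene):
        counts = {tid: d["subsets"] for tid, d in per_gene[gene_id].items()}
        _, keep = count_and_cap_gene(gene_id, counts, params)
        if not keep:
            dropped.append(gene_id)
            continue
        for tid in sorted(per_gene[gene_id]):
            t = transcripts[tid]
            for subset in per_gene[gene_id][tid]["subsets"]:
                rec = apply_and_translate(t, subset, params)
                if rec is not None:
                    records.append(rec)
    return records, dropped


def md5_hex(seq: str) -> str:
    return hashlib.md5(seq.encode("ascii")).hexdigest()


@dataclass
class CohortVariantDb:
    """Deduplicated cohort-wide variant sequences keyed by MD5, with provenance.

    ``fasta_records`` maps MD5 hex digests to amino-acid sequences;
    ``provenance`` has one row per (sample, prediction) with columns
    sample_id, prediction_type, original_header, md5.
    """

    fasta_records: dict[str, str] = field(default_factory=dict)
    provenance: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["sample_id", "prediction_type", "original_header", "md5"]
        )
    )

    def __eq__(self, other) -> bool:
        if not isinstance(other, CohortVariantDb):
            return NotImplemented
        return self.fasta_records == other.fasta_records and self.provenance.reset_index(
            drop=True
        ).equals(other.provenance.reset_index(drop=True))

    def gene_map(self) -> dict[str, set[str]]:
        """md5 -> set of gene ids, parsed from the original headers."""
        out: dict[str, set[str]] = {}
        for _, row in self.provenance.iterrows():
            out.setdefault(row["md5"], set()).add(gene_of_header(row["original_header"]))
        return out

    def type_map(self) -> dict[str, set[str]]:
        """md5 -> set of prediction types."""
        out: dict[str, set[str]] = {}
        for _, row in self.provenance.iterrows():
            out.setdefault(row["md5"], set()).add(row["prediction_type"])
        return out

    def write(self, fasta_path: str | os.PathLike, tsv_path: str | os.PathLike) -> None:
        phio.write_fasta(self.fasta_records, fasta_path)
        phio.write_tsv(self.provenance, tsv_path)

    @classmethod
    def read(cls, fasta_path: str | os.PathLike, tsv_path: str | os.PathLike) -> "CohortVariantDb":
        fasta = phio.read_fasta(fasta_path)
        prov = phio.read_tsv(tsv_path)
        db = cls(dict(sorted(fasta.items())), _canonical_provenance(prov))
        for md5, seq in db.fasta_records.items():
            if md5_hex(seq) != md5:
                raise ValueError(f"FASTA header {md5} does not match sequence digest")
        return db


def _canonical_provenance(prov: pd.DataFrame) -> pd.DataFrame:
    return (
        prov.sort_values(["sample_id", "md5", "prediction_type", "original_header"])
        .reset_index(drop=True)
    )


def build_cohort_db(records: Iterable[VariantSeqRecord]) -> CohortVariantDb:
    """Deduplicate records by sequence MD5 into a cohort-wide database.

    One FASTA entry per unique sequence (header = MD5 hex), one provenance row
    per input record. Output is invariant to input order.
    """
    fasta: dict[str, str] = {}
    rows = []
    for rec in records:
        if rec.prediction_type not in PREDICTION_TYPES:
            raise ValueError(f"unknown prediction type {rec.prediction_type!r}")
        digest = md5_hex(rec.seq)
        if digest in fasta:
            if fasta[digest] != rec.seq:  # pragma: no cover - astronomically unlikely
                raise RuntimeError(f"MD5 collision on {digest}")
        else:
            fasta[digest] = rec.seq
        rows.append(
            {
                "sample_id": rec.sample_id,
                "prediction_type": rec.prediction_type,
                "original_header": rec.header,
                "md5": digest,
            }
        )
    prov = pd.DataFrame(rows, columns=["sample_id", "prediction_type", "original_header", "md5"])
    prov = _canonical_provenance(prov.drop_duplicates())
    return CohortVariantDb(dict(sorted(fasta.items())), prov)
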