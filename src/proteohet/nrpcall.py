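"""Non-reference peptide (NRP) calling from peptide-spectrum-match tables.

PSMs that pass the 1% FDR filter and an external validation step, and whose
peptide — with isoleucine and leucine collapsed to one symbol, since MS
cannot distinguish them — cannot be mapped to any reference protein, are
matched cohort-wide against the variant protein database. Peptides mapping
to more than one gene are discarded; peptides differing only by missed
cleavages are merged; the result is a binary NRP x sample presence matrix
annotated with per-patient breadth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pyteomics import parser as pparser

from .variantdb import CohortVariantDb

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

# cleave C-terminal of K/R except when followed by P
TRYPSIN_RULE = r"[KR](?=[^P])"


def collapse_il(peptide: str) -> str:
    """Canonical peptide key with every I replaced by L (idempotent)."""
    bad = set(peptide) - AMINO_ACIDS
    if bad or not peptide:
        raise ValueError(f"invalid peptide {peptide!r}: non-amino-acid {sorted(bad)}")
    return peptide.replace("I", "L")


@dataclass(frozen=True)
class DigestParams:
    enzyme: str = "trypsin"
    max_missed_cleavages: int = 2
    min_len: int = 7
    max_len: int = 50

    def __post_init__(self):
        if self.enzyme != "trypsin":
            raise ValueError("only trypsin digestion is supported")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")


def digest(protein: str, params: DigestParams = DigestParams()) -> set[str]:
    """Tryptic peptides of a protein with up to ``max_missed_cleavages``."""
    if not protein:
        raise ValueError("empty protein")
    peps = pparser.cleave(protein, TRYPSIN_RULE, missed_cleavages=params.max_missed_cleavages)
    return {p for p in peps if params.min_len <= len(p) <= params.max_len}


def _collapsed_reference_blob(reference: Mapping[str, str]) -> str:
    if not reference:
        raise ValueError("empty reference proteome")
    return "|" + "|".join(seq.replace("I", "L") for seq in reference.values()) + "|"


def filter_nonreference(
    psms: pd.DataFrame,
    reference: Mapping[str, str],
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Keep PSMs that are validated, pass the FDR filter, and are non-reference.

    A PSM survives iff its I/L-collapsed peptide is not a substring of any
    I/L-collapsed reference protein, its q-value is <= ``q_threshold`` and its
    external validation flag is set. Reference mapping takes precedence over
    variant-database mapping: any reference-mappable peptide is removed here.
    """
    blob = _collapsed_reference_blob(reference)
    keep = []
    cache: dict[str, bool] = {}
    for pep, q, val in zip(psms["peptide"], psms["q_value"], psms["validated"]):
        if q > q_threshold or not val:
            keep.append(False)
            continue
        hit = cache.get(pep)
        if hit is None:
            hit = collapse_il(pep) in blob
            cache[pep] = hit
        keep.append(not hit)
    return psms.loc[keep].reset_index(drop=True)


@dataclass
class NrpRecord:
    """A validated non-reference peptide aggregated to the cohort level."""

    key: str  # I/L-collapsed peptide (shortest member after merging)
    member_peptides: set[str]
    gene_id: str
    variant_class: str  # in_frame | frameshift | splice | novel_orf | multi
    presence: dict[str, int]  # sample -> {0,1}
    md5_hits: set[str] = field(default_factory=set)
    n_patients: int = 0


def _variant_class(types: set[str]) -> str:
    return types.pop() if len(types) == 1 else "multi"


def map_to_variant_db(
    candidates: pd.DataFrame,
    db: CohortVariantDb,
    samples: Sequence[str],
) -> list[NrpRecord]:
    """Map candidate NRP PSMs against the cohort variant database.

    Each distinct collapsed peptide is searched against every I/L-collapsed
    database sequence (cohort-wide: a peptide predicted in any sample is
    searched in all samples). Peptides hitting sequences of more than one
    gene, or hitting nothing, are discarded. The variant class comes from the
    prediction types of the matched records ("multi" if they disagree).
    """
    gene_map = db.gene_map()
    type_map = db.type_map()
    collapsed_db = {md5: seq.replace("I", "L") for md5, seq in db.fasta_records.items()}

    by_key: dict[str, dict] = {}
    for pep, sample in zip(candidates["peptide"], candidates["sample_id"]):
        key = collapse_il(pep)
        entry = by_key.setdefault(key, {"members": set(), "samples": set()})
        entry["members"].add(pep)
        entry["samples"].add(sample)

    records: list[NrpRecord] = []
    for key in sorted(by_key):
        hits = {md5 for md5, seq in collapsed_db.items() if key in seq}
        if not hits:
            continue  # unexplained peptide
        genes = set().union(*(gene_map[m] for m in hits))
        if len(genes) != 1:
            continue  # not uniquely mappable to a single gene
        types = set().union(*(type_map[m] for m in hits))
        presence = {s: int(s in by_key[key]["samples"]) for s in samples}
        records.append(
            NrpRecord(
                key=key,
                member_peptides=set(by_key[key]["members"]),
                gene_id=genes.pop(),
                variant_class=_variant_class(types),
                presence=presence,
                md5_hits=hits,
            )
        )
    return records


def merge_missed_cleavages(records: Sequence[NrpRecord]) -> list[NrpRecord]:
    """Merge NRPs that differ only by missed cleavages.

    Two records of the same gene merge when one collapsed peptide is an
    extension of the other across cleavage sites and both cover the same
    variant evidence (their database-record hit sets intersect). Merging is
    transitive; the result is the fixpoint, invariant to input order. The
    merged key is the shortest member (ties broken lexicographically).
    """
    recs = sorted(records, key=lambda r: (r.gene_id, len(r.key), r.key))
    parent = list(range(len(recs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            a, b = recs[i], recs[j]
            if a.gene_id != b.gene_id:
                continue
            if not (a.key in b.key or b.key in a.key):
                continue
            if not (a.md5_hits & b.md5_hits):
                continue
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[NrpRecord]] = {}
    for i, rec in enumerate(recs):
        groups.setdefault(find(i), []).append(rec)

    merged = []
    for members in groups.values():
        key = min((r.key for r in members), key=lambda k: (len(k), k))
        presence: dict[str, int] = {}
        for r in members:
            for s, v in r.presence.items():
                presence[s] = max(presence.get(s, 0), v)
        merged.append(
            NrpRecord(
                key=key,
                member_peptides=set().union(*(r.member_peptides for r in members)),
                gene_id=members[0].gene_id,
                variant_class=_variant_class({r.variant_class for r in members}),
                presence=presence,
                md5_hits=set().union(*(r.md5_hits for r in members)),
            )
        )
    merged.sort(key=lambda r: (r.gene_id, r.key))
    return merged


def build_presence_matrix(
    records: Sequence[NrpRecord],
    samples: Sequence[str],
    patient_map: Mapping[str, str],
) -> tuple[pd.DataFrame, pd.Series]:
    """Binary NRP x sample matrix and per-record patient counts.

    A cell is 1 iff the NRP was identified and validated in that sample with
    at least one PSM. ``n_patients`` counts distinct patients among the
    positive samples; the record objects are annotated in place as well.
    """
    missing = [s for s in samples if s not in patient_map]
    if missing:
        raise KeyError(f"samples missing from patient map: {missing}")
    mat = pd.DataFrame(
        [[r.presence.get(s, 0) for s in samples] for r in records],
        index=[r.key for r in records],
        columns=list(samples),
        dtype=int,
    )
    n_patients = pd.Series(
        [
            len({patient_map[s] for s in samples if r.presence.get(s, 0)})
            for r in records
        ],
        index=mat.index,
        name="n_patients",
        dtype=int,
    )
    for r, n in zip(records, n_patients):
        r.n_patients = int(n)
    return mat, n_patients


def filter_min_patients(
    matrix: pd.DataFrame, n_patients: pd.Series, min_patients: int = 3
) -> pd.DataFrame:
    """Keep NRPs detected across at least ``min_patients`` patients."""
    keep = n_patients[n_patients >= min_patients].index
    return matrix.loc[matrix.index.intersection(keep, sort=False)]


def call_nrps(
    psm_tables: Iterable[pd.DataFrame],
    reference: Mapping[str, str],
    db: CohortVariantDb,
    samples: Sequence[str],
    patient_map: Mapping[str, str],
    q_threshold: float = 0.01,
) -> tuple[list[NrpRecord], pd.DataFrame, pd.Series]:
    """End-to-end NRP calling: filter, map, merge, tabulate."""
    psms = pd.concat(list(psm_tables), ignore_index=True)
    candidates = filter_nonreference(psms, reference, q_threshold)
    records = map_to_variant_db(candidates, db, samples)
    records = merge_missed_cleavages(records)
    matrix, n_patients = build_presence_matrix(records, samples, patient_map)
    return records, matrix, n_patients


def catalog_frame(records: Sequence[NrpRecord]) -> pd.DataFrame:
    """NRP catalogue as a table (key, gene, class, n_patients, members)."""
    return pd.DataFrame(
        {
            "key": [r.key for r in records],
            "gene_id": [r.gene_id for r in records],
            "variant_class": [r.variant_class for r in records],
            "n_patients": [r.n_patients for r in records],
            "member_peptides": [";".join(sorted(r.member_peptides)) for r in records],
        }
    )


def warn_if_reference_hits(records: Sequence[NrpRecord], reference: Mapping[str, str]) -> int:
    """Sanity scan: count emitted NRPs that map to the collapsed reference."""
    blob = _collapsed_reference_blob(reference)
    n = sum(1 for r in records if r.key in blob)
    if n:
        warnings.warn(f"{n} emitted NRPs map to the reference proteome")
    return n
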