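"""Synthetic multi-metastasis cohort generator with known ground truth.

Emulates the data structure of a post-mortem multi-metastasis tumour cohort:
patients with 1-9 metastases, coding transcripts with planted SNVs and
in-frame/frameshift indels carrying known population allele frequencies,
per-sample peptide-spectrum-match tables containing tryptic peptides from
reference and variant proteins, a cluster-block-structured protein abundance
matrix with intensity-dependent (MNAR) missingness, and cluster-linked
exponential survival times. Every downstream stage of the pipeline can be
scored against the planted truth.

All randomness flows from a single integer seed; identical configurations
produce byte-identical outputs.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as phio
from .nrpcall import DigestParams, digest
from .variantdb import (
    TranscriptModel,
    VariantCall,
    VariantDbParams,
    VariantSeqRecord,
    predict_sample_records,
)

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]
_ORGANS = (
    "liver",
    "brain",
    "intestine",
    "adrenal_gland",
    "spleen",
    "lung",
    "lymph_node",
    "kidney",
    "heart",
    "skin",
)
_ORGAN_W = np.array([0.18, 0.15, 0.12, 0.10, 0.09, 0.09, 0.09, 0.07, 0.06, 0.05])

_CODON_TABLE = {}


def _translate_codon(codon: str) -> str:
    if not _CODON_TABLE:
        from Bio.Seq import Seq

        for c in [a + b + d for a in _BASES for b in _BASES for d in _BASES]:
            _CODON_TABLE[c] = str(Seq(c).translate())
    return _CODON_TABLE[codon]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated cohort structure: 24 patients with 1-9
    metastases each, four proteomic clusters, a population AF spectrum mixing
    population-absent ("novel"), rare and frequent variants, exponential
    survival with a ~49-month baseline median and elevated hazard for two of
    the four clusters.
    """

    n_patients: int = 24
    metastases_per_patient: tuple[int, int] = (1, 9)
    n_genes: int = 120
    n_transcripts_per_gene: int = 1
    cds_length_range: tuple[int, int] = (300, 600)  # nt, multiples of 3
    n_snv: int = 120
    n_inframe_indel: int = 24
    n_frameshift_indel: int = 24
    # mixture weights over {absent-from-reference, (0,1%], >1%}
    af_spectrum: tuple[float, float, float] = (0.40, 0.15, 0.45)
    variant_concordance: float = 0.8  # P(shared across a patient's metastases)
    n_clusters: int = 4
    cluster_cohesion: float = 0.6  # P(metastasis takes its patient's preferred cluster)
    cluster_effect_size: float = 2.5  # log2 shift of planted pathway blocks
    noise_sd: float = 0.5  # within-cluster log2 spread
    replicate_sd: float = 0.2
    n_replicates: int = 2
    missing_frac: float = 0.10
    artifact_frac: float = 0.01
    survival_hazard_ratio_per_cluster: tuple[float, ...] = (3.0, 1.0, 3.0, 1.0)
    baseline_median_months: float = 49.0
    censor_months: float = 120.0
    n_ref_psms_per_sample: int = 40
    n_noise_psms_per_sample: int = 40
    planted_invalid_frac: float = 0.05
    seed: int = 42

    def __post_init__(self):
        lo, hi = self.cds_length_range
        if lo % 3 or hi % 3:
            raise ValueError("cds_length_range bounds must be multiples of 3")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        for frac in (self.missing_frac, self.artifact_frac, self.variant_concordance,
                     self.planted_invalid_frac, self.cluster_cohesion):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(self.af_spectrum) - 1) > 1e-9:
            raise ValueError("af_spectrum weights must sum to 1")
        if len(self.survival_hazard_ratio_per_cluster) != self.n_clusters:
            raise ValueError("need one hazard multiplier per cluster")
        if any(h <= 0 for h in self.survival_hazard_ratio_per_cluster):
            raise ValueError("hazard multipliers must be positive")


@dataclass
class GroundTruth:
    planted_variants: pd.DataFrame  # key, transcript, pos, ref, alt, type, af, af_class, patient
    planted_peptides: dict[str, list[str]]  # sample -> original peptide strings
    true_cluster_assignment: pd.Series  # sample -> cluster index
    true_survival_params: dict  # per-cluster hazard multipliers + patient multipliers


@dataclass
class SynthCohort:
    config: SynthConfig
    samples: pd.DataFrame  # sample_id, patient_id
    transcripts: dict[str, TranscriptModel]
    proteome: dict[str, str]  # transcript_id -> protein
    gene_sets: dict[str, list[str]]
    variants_by_sample: dict[str, list[VariantCall]]
    variant_records: dict[str, list[VariantSeqRecord]]
    psm_tables: dict[str, pd.DataFrame]
    abundance_raw: pd.DataFrame  # proteins x replicate columns, NaN = missing
    replicate_map: dict[str, str]
    clinical: pd.DataFrame
    af_table: pd.DataFrame  # variant_key, gene_id, af
    ground_truth: GroundTruth

    def patient_map(self) -> dict[str, str]:
        return dict(zip(self.samples["sample_id"], self.samples["patient_id"]))

    def write(self, out_dir: str | os.PathLike) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        phio.write_fasta(
            {t.transcript_id: t.cds_seq for t in self.transcripts.values()},
            out / "transcripts.fasta",
        )
        phio.write_fasta(self.proteome, out / "proteome.fasta")
        phio.write_tsv(
            pd.DataFrame(
                [
                    {"transcript_id": t.transcript_id, "gene_id": t.gene_id, "strand": t.strand}
                    for t in self.transcripts.values()
                ]
            ),
            out / "transcript_table.tsv",
        )
        phio.write_gmt(self.gene_sets, out / "genesets.gmt")
        contigs = {t.transcript_id: len(t.cds_seq) for t in self.transcripts.values()}
        for sample in self.samples["sample_id"]:
            variants = [
                (v.transcript_id, v.pos, v.ref_allele, v.alt_allele, v.frame_effect)
                for v in self.variants_by_sample.get(sample, [])
            ]
            phio.write_vcf(variants, contigs, out / f"variants.{sample}.vcf")
            phio.write_tsv(self.psm_tables[sample], out / f"psm.{sample}.tsv")
        raw = self.abundance_raw.round(4)
        phio.write_matrix_tsv(raw, out / "abundance.tsv")
        phio.write_tsv(
            pd.DataFrame(
                {"replicate": list(self.replicate_map), "sample_id": list(self.replicate_map.values())}
            ),
            out / "replicate_map.tsv",
        )
        phio.write_tsv(self.clinical, out / "clinical.tsv")
        phio.write_tsv(self.af_table, out / "af_reference.tsv")
        gt = {
            "planted_variants": self.ground_truth.planted_variants.to_dict(orient="records"),
            "planted_peptides": self.ground_truth.planted_peptides,
            "true_cluster_assignment": self.ground_truth.true_cluster_assignment.to_dict(),
            "true_survival_params": self.ground_truth.true_survival_params,
            "config": asdict(self.config),
        }
        with open(out / "groundtruth.json", "w") as fh:
            json.dump(gt, fh, indent=1, sort_keys=True)


# ------------------------------------------------------------------ pieces


def make_cohort_layout(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = config.metastases_per_patient
    rows = []
    for i in range(config.n_patients):
        patient = f"MF{i + 1:02d}"
        n_mets = int(rng.integers(lo, hi + 1))
        for j in range(n_mets):
            rows.append({"sample_id": f"{patient}_M{j + 1}", "patient_id": patient})
    return pd.DataFrame(rows)


def _random_cds(rng: np.random.Generator, length_nt: int) -> str:
    n_codons = length_nt // 3 - 2
    body = rng.choice(len(_NONSTOP_CODONS), size=n_codons)
    stop = ["TAA", "TAG", "TGA"][int(rng.integers(3))]
    return "ATG" + "".join(_NONSTOP_CODONS[i] for i in body) + stop


def generate_reference(
    config: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, TranscriptModel], dict[str, str], dict[str, list[str]]]:
    """Reference transcripts, proteome and gene sets.

    Gene sets partition the genes into named pathways; the first
    ``n_clusters`` pathways double as the planted abundance blocks.
    """
    rng = rng or np.random.default_rng(config.seed)
    lo, hi = config.cds_length_range
    transcripts: dict[str, TranscriptModel] = {}
    for g in range(config.n_genes):
        gene = f"G{g + 1:04d}"
        for t in range(config.n_transcripts_per_gene):
            length = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
            tid = f"{gene}.t{t + 1}"
            transcripts[tid] = TranscriptModel(gene, tid, _random_cds(rng, length))
    proteome = {tid: t.protein for tid, t in transcripts.items()}

    genes = [f"G{g + 1:04d}" for g in range(config.n_genes)]
    n_pathways = max(config.n_clusters * 2, config.n_clusters)
    chunks = np.array_split(np.array(genes), n_pathways)
    gene_sets = {}
    for i, chunk in enumerate(chunks):
        name = (
            f"PATHWAY_C{i + 1}" if i < config.n_clusters else f"PATHWAY_BG{i - config.n_clusters + 1}"
        )
        gene_sets[name] = list(chunk)
    return transcripts, proteome, gene_sets


def _plant_one_variant(
    rng: np.random.Generator, t: TranscriptModel, vtype: str
) -> tuple[int, str, str]:
    cds = t.cds_seq
    n = len(cds)
    if vtype == "snv":
        for _ in range(50):
            pos = int(rng.integers(3, n - 3))
            ref = cds[pos]
            alt = _BASES[int(rng.integers(4))]
            if alt == ref:
                continue
            cstart = pos - pos % 3
            codon = cds[cstart : cstart + 3]
            mutant = codon[: pos % 3] + alt + codon[pos % 3 + 1 :]
            if mutant in _STOPS:
                continue
            if _translate_codon(mutant) != _translate_codon(codon):
                return pos, ref, alt
        raise RuntimeError("failed to plant a non-synonymous SNV")
    if vtype == "inframe":
        if rng.random() < 0.5:
            pos = int(rng.integers(3, n - 6))
            ins = "".join(_BASES[int(rng.integers(4))] for _ in range(3))
            return pos, cds[pos], cds[pos] + ins
        pos = int(rng.integers(3, n - 9))
        return pos, cds[pos : pos + 4], cds[pos]
    if vtype == "frameshift":
        k = int(rng.integers(1, 3))
        if rng.random() < 0.5:
            pos = int(rng.integers(3, n - 6))
            ins = "".join(_BASES[int(rng.integers(4))] for _ in range(k))
            return pos, cds[pos], cds[pos] + ins
        pos = int(rng.integers(3, n - 6 - k))
        return pos, cds[pos : pos + 1 + k], cds[pos]
    raise ValueError(vtype)


def plant_variants(
    transcripts: dict[str, TranscriptModel],
    samples: pd.DataFrame,
    config: SynthConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, list[VariantCall]], pd.DataFrame]:
    """Plant SNVs and indels with known AF classes and per-patient sharing.

    Each variant has an anchor patient that always carries it; other patients
    carry it with the Hardy-Weinberg carrier probability implied by its
    population allele frequency (so frequent variants recur across patients,
    population-absent ones stay private). Within a carrying patient one
    anchor metastasis always shows the variant and the remaining metastases
    share it with probability ``variant_concordance``.
    """
    tids = sorted(transcripts)
    patients = sorted(samples["patient_id"].unique())
    mets_of = {p: list(samples.loc[samples["patient_id"] == p, "sample_id"]) for p in patients}

    plan = (["snv"] * config.n_snv + ["inframe"] * config.n_inframe_indel
            + ["frameshift"] * config.n_frameshift_indel)
    rows = []
    variants_by_sample: dict[str, list[VariantCall]] = {s: [] for s in samples["sample_id"]}
    used: set[tuple] = set()
    for i, vtype in enumerate(plan):
        for _ in range(50):
            tid = tids[int(rng.integers(len(tids)))]
            t = transcripts[tid]
            pos, ref, alt = _plant_one_variant(rng, t, vtype)
            span = (tid, pos, pos + len(ref))
            if any(s[0] == tid and s[1] < span[2] and span[1] < s[2] for s in used):
                continue  # avoid overlapping plants on one transcript
            used.add(span)
            break
        else:  # pragma: no cover
            raise RuntimeError("could not place variant without overlap")

        cls = ["absent", "rare", "frequent"][
            int(rng.choice(3, p=np.asarray(config.af_spectrum)))
        ]
        if cls == "absent":
            af = 0.0
        elif cls == "rare":
            af = float(rng.uniform(1e-4, 0.01))
        else:
            af = float(rng.uniform(0.011, 0.5))

        anchor_patient = patients[int(rng.integers(len(patients)))]
        carrier_p = 2 * af * (1 - af) + af * af  # Hardy-Weinberg carrier frequency
        carrier_patients = [
            p
            for p in patients
            if p == anchor_patient or rng.random() < carrier_p
        ]
        carriers = []
        for p in carrier_patients:
            mets = mets_of[p]
            anchor = mets[int(rng.integers(len(mets)))]
            carriers.extend(
                m
                for m in mets
                if m == anchor or rng.random() < config.variant_concordance
            )
        frame = "in_frame" if abs(len(alt) - len(ref)) % 3 == 0 else "frameshift"
        key = f"{tid}:{pos}:{ref}>{alt}"
        rows.append(
            {
                "variant_key": key,
                "transcript_id": tid,
                "gene_id": t.gene_id,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "variant_type": vtype,
                "frame_effect": frame,
                "af": af,
                "af_class": {"absent": "novel", "rare": "removed", "frequent": "frequent"}[cls],
                "patient_id": anchor_patient,
                "samples": ";".join(carriers),
            }
        )
        for m in carriers:
            variants_by_sample[m].append(VariantCall(m, tid, pos, ref, alt))
    truth = pd.DataFrame(rows)
    return variants_by_sample, truth


def _calibrate_mnar(
    rng: np.random.Generator, log2_vals: np.ndarray, missing_frac: float, scale: float = 1.0
) -> np.ndarray:
    """MNAR missingness mask: P(missing) is a logistic function of intensity,
    with the midpoint calibrated so the expected missing fraction matches."""
    if missing_frac <= 0:
        return np.zeros_like(log2_vals, dtype=bool)
    flat = log2_vals.ravel()

    def mean_prob(x0):
        return np.mean(1.0 / (1.0 + np.exp((flat - x0) / scale)))

    lo, hi = flat.min() - 10, flat.max() + 10
    for _ in range(80):
        mid = (lo + hi) / 2
        if mean_prob(mid) < missing_frac:
            lo = mid
        else:
            hi = mid
    probs = 1.0 / (1.0 + np.exp((log2_vals - (lo + hi) / 2) / scale))
    return rng.random(log2_vals.shape) < probs


def _qvalues(scores: np.ndarray, is_noise: np.ndarray) -> np.ndarray:
    """Rank-based q-values using the known noise population as decoys."""
    order = np.argsort(-scores, kind="mergesort")
    n_noise = np.cumsum(is_noise[order])
    fdr = n_noise / np.arange(1, len(scores) + 1)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = np.clip(q_sorted, 1e-4, 1.0)
    return q


def simulate_observations(
    transcripts: dict[str, TranscriptModel],
    proteome: dict[str, str],
    gene_sets: dict[str, list[str]],
    variants_by_sample: dict[str, list[VariantCall]],
    samples: pd.DataFrame,
    config: SynthConfig,
    rng: np.random.Generator,
) -> dict:
    """PSM tables, abundance matrix, clinical table and planted-peptide truth."""
    dparams = DigestParams()
    collapsed_ref = "|" + "|".join(s.replace("I", "L") for s in proteome.values()) + "|"

    ref_pool = sorted(
        {
            p
            for prot in proteome.values()
            for p in digest(prot, DigestParams(max_missed_cleavages=0, min_len=7, max_len=30))
        }
    )

    variant_records: dict[str, list[VariantSeqRecord]] = {}
    planted_peptides: dict[str, list[str]] = {}
    psm_tables: dict[str, pd.DataFrame] = {}
    sample_ids = list(samples["sample_id"])
    for sample in sample_ids:
        records, _dropped = predict_sample_records(
            transcripts, variants_by_sample.get(sample, []), VariantDbParams()
        )
        variant_records[sample] = records
        planted = sorted(
            {
                pep
                for rec in records
                for pep in digest(rec.seq, dparams)
                if pep.replace("I", "L") not in collapsed_ref
            }
        )
        planted_peptides[sample] = planted

        rows = []
        for pep in planted:
            rows.append(
                {
                    "peptide": pep,
                    "score": float(rng.normal(25, 5)),
                    "validated": bool(rng.random() >= config.planted_invalid_frac),
                    "_noise": False,
                }
            )
        ref_idx = rng.choice(len(ref_pool), size=min(config.n_ref_psms_per_sample, len(ref_pool)), replace=False)
        for i in sorted(ref_idx):
            rows.append(
                {"peptide": ref_pool[i], "score": float(rng.normal(25, 5)), "validated": True, "_noise": False}
            )
        for _ in range(config.n_noise_psms_per_sample):
            length = int(rng.integers(8, 15))
            pep = "".join("ACDEFGHKLMNPQRSTVWY"[int(rng.integers(19))] for _ in range(length))
            rows.append(
                {"peptide": pep, "score": float(rng.normal(10, 3)), "validated": False, "_noise": True}
            )
        df = pd.DataFrame(rows)
        df.insert(0, "sample_id", sample)
        df["q_value"] = _qvalues(df["score"].to_numpy(), df["_noise"].to_numpy())
        df = df.drop(columns="_noise")
        psm_tables[sample] = df

    # ---- abundance matrix with planted cluster blocks
    # metastases of one patient are correlated: each patient has a preferred
    # cluster (balanced over patients) that each metastasis adopts with
    # probability cluster_cohesion, else a uniform draw
    n_samples = len(sample_ids)
    patient_list = sorted(samples["patient_id"].unique())
    shuffled_patients = list(patient_list)
    rng.shuffle(shuffled_patients)
    preferred = {p: i % config.n_clusters for i, p in enumerate(shuffled_patients)}
    patient_of = dict(zip(samples["sample_id"], samples["patient_id"]))
    cluster_of = {}
    for s in sample_ids:
        if rng.random() < config.cluster_cohesion:
            cluster_of[s] = preferred[patient_of[s]]
        else:
            cluster_of[s] = int(rng.integers(config.n_clusters))
    clusters = pd.Series({s: cluster_of[s] for s in sample_ids}, name="cluster")

    genes = sorted({t.gene_id for t in transcripts.values()})
    block_genes = {
        c: set(gene_sets.get(f"PATHWAY_C{c + 1}", [])) for c in range(config.n_clusters)
    }
    base = rng.normal(19.0, 1.5, size=len(genes))
    log2 = np.empty((len(genes), n_samples))
    for j, s in enumerate(sample_ids):
        c = cluster_of[s]
        shift = np.array([config.cluster_effect_size if g in block_genes[c] else 0.0 for g in genes])
        log2[:, j] = base + shift + rng.normal(0, config.noise_sd, size=len(genes))

    rep_cols, rep_map = [], {}
    rep_vals = []
    for j, s in enumerate(sample_ids):
        for r in range(config.n_replicates):
            col = f"{s}_r{r + 1}"
            rep_cols.append(col)
            rep_map[col] = s
            rep_vals.append(log2[:, j] + rng.normal(0, config.replicate_sd, size=len(genes)))
    rep = np.column_stack(rep_vals)

    artifacts = rng.random(rep.shape) < config.artifact_frac
    raw = np.power(2.0, rep)
    raw[artifacts] = rng.uniform(2.0, 1000.0, size=int(artifacts.sum()))
    miss = _calibrate_mnar(rng, np.log2(raw), config.missing_frac)
    raw[miss] = np.nan
    abundance = pd.DataFrame(raw, index=genes, columns=rep_cols)

    # ---- clinical table with cluster-linked survival
    hr = np.asarray(config.survival_hazard_ratio_per_cluster, dtype=float)
    patients = sorted(samples["patient_id"].unique())
    patient_mult = {}
    for p in patients:
        mets = list(samples.loc[samples["patient_id"] == p, "sample_id"])
        patient_mult[p] = float(np.mean([hr[cluster_of[m]] for m in mets]))
    base_scale = config.baseline_median_months / np.log(2)
    clin_rows = []
    patient_time, patient_event = {}, {}
    for p in patients:
        t = float(rng.exponential(base_scale / patient_mult[p]))
        t = max(t, 0.1)
        event = 1 if t <= config.censor_months else 0
        patient_time[p] = round(min(t, config.censor_months), 1)
        patient_event[p] = event
    for _, row in samples.iterrows():
        s, p = row["sample_id"], row["patient_id"]
        clin_rows.append(
            {
                "sample_id": s,
                "patient_id": p,
                "location": _ORGANS[int(rng.choice(len(_ORGANS), p=_ORGAN_W))],
                "tumour_content": round(100 * float(rng.beta(6, 1.5)), 1),
                "time": patient_time[p],
                "event": patient_event[p],
            }
        )
    clinical = pd.DataFrame(clin_rows)

    return {
        "variant_records": variant_records,
        "planted_peptides": planted_peptides,
        "psm_tables": psm_tables,
        "abundance_raw": abundance,
        "replicate_map": rep_map,
        "clinical": clinical,
        "clusters": clusters,
        "patient_mult": patient_mult,
    }


def simulate_cohort(config: SynthConfig = SynthConfig()) -> SynthCohort:
    """Generate the full synthetic cohort deterministically from the config."""
    rng = np.random.default_rng(config.seed)
    samples = make_cohort_layout(config, rng)
    transcripts, proteome, gene_sets = generate_reference(config, rng)
    variants_by_sample, truth = plant_variants(transcripts, samples, config, rng)
    obs = simulate_observations(
        transcripts, proteome, gene_sets, variants_by_sample, samples, config, rng
    )
    af_table = truth[["variant_key", "gene_id", "af"]].copy()
    ground_truth = GroundTruth(
        planted_variants=truth,
        planted_peptides=obs["planted_peptides"],
        true_cluster_assignment=obs["clusters"],
        true_survival_params={
            "hazard_per_cluster": list(config.survival_hazard_ratio_per_cluster),
            "patient_multiplier": obs["patient_mult"],
        },
    )
    return SynthCohort(
        config=config,
        samples=samples,
        transcripts=transcripts,
        proteome=proteome,
        gene_sets=gene_sets,
        variants_by_sample=variants_by_sample,
        variant_records=obs["variant_records"],
        psm_tables=obs["psm_tables"],
        abundance_raw=obs["abundance_raw"],
        replicate_map=obs["replicate_map"],
        clinical=obs["clinical"],
        af_table=af_table,
        ground_truth=ground_truth,
    )
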