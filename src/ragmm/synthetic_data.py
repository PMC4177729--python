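"""Seeded synthetic cohorts with known ground truth.

Each patient is generated by sampling category membership from per-category
prevalences (adverse lesions co-occur more often than independence predicts,
controlled by ``cosegregation_boost``), realising each sampled category as a
concrete lesion (a FISH translocation/deletion/gain, a karyotype trisomy
subset for Hyperdiploidy, or a sequencing mutation in a random candidate
gene for functional categories), and drawing log-normal clinical values for
ISS staging.  Synonymous decoy mutations are injected so the VCF filter is
exercised; they must never change a score.

The ground truth records the intended category set and the exact expected
mean score, making end-to-end recovery (write fixtures → parse → match →
score) exactly checkable.  Randomness comes from a single
``random.Random(seed)`` stream, so a fixed seed reproduces a cohort
byte-for-byte across platforms.
"""

from __future__ import annotations

import csv
import json
import math
import random
from fractions import Fraction
from pathlib import Path
from typing import Optional, Union

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .knowledge_base import KnowledgeBase, PatternKind, build_default_kb
from .lesion_io import (
    Aberration,
    AberrationKind,
    Consequence,
    DetectionMethod,
    IssInput,
    Sample,
    parse_lesion_table,
    parse_vcf,
)
from .scoring import ADVERSE_CATEGORIES, Band, RagResult, classify_risk, score_sample

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "Cohort",
    "CohortConfigError",
    "generate_cohort",
    "write_fixture_files",
    "score_fixtures",
]


class CohortConfigError(ValueError):
    """Invalid cohort configuration."""


class CohortConfig(BaseModel):
    """Study conditions for a synthetic cohort.

    Defaults: uniform category prevalence 0.1 (no published lesion
    frequencies accompany the model, so a flat placeholder is used);
    adverse-lesion co-segregation boost ×2; synonymous decoy rate 0.05 per
    patient (silent mutations are expected to be rare in the model's genes);
    β2-microglobulin ~ LogNormal(ln 4.3, 0.55) mg/L and albumin ~
    LogNormal(ln 3.9, 0.15) g/dL, placing roughly a third of patients in
    each ISS stage so every staging branch is exercised.
    """

    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(ge=1)
    seed: int = 0
    prevalence: Optional[dict[str, float]] = None
    cosegregation_boost: float = Field(default=2.0, ge=1.0)
    synonymous_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    beta2m_log_mu: float = math.log(4.3)
    beta2m_log_sigma: float = Field(default=0.55, ge=0.0)
    albumin_log_mu: float = math.log(3.9)
    albumin_log_sigma: float = Field(default=0.15, ge=0.0)

    @model_validator(mode="after")
    def _check_prevalence(self) -> "CohortConfig":
        if self.prevalence is not None:
            for name, p in self.prevalence.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"prevalence[{name!r}]={p} outside [0, 1]")
        return self


class GroundTruth(BaseModel):
    model_config = ConfigDict(frozen=True)

    categories: frozenset[str]
    expected_score: Optional[float]
    band: Band


class Cohort(BaseModel):
    model_config = ConfigDict(frozen=True)

    samples: tuple[Sample, ...]
    ground_truth: dict[str, GroundTruth]
    kb_version: str
    config: CohortConfig


_HYPERDIPLOID_CHROMS = ["1", "3", "5", "7", "9", "11", "15", "19", "21"]


def _realize(category, rng: random.Random) -> list[Aberration]:
    pattern = category.cytogenetic_pattern
    if pattern is None:
        gene = rng.choice(sorted(category.candidate_genes))
        return [
            Aberration(
                kind=AberrationKind.MUTATION,
                gene=gene,
                method=DetectionMethod.SEQUENCING,
                consequence=Consequence.NONSYNONYMOUS,
            )
        ]
    if pattern.kind is PatternKind.TRISOMY:
        k = rng.randint(2, len(_HYPERDIPLOID_CHROMS))
        chroms = sorted(rng.sample(_HYPERDIPLOID_CHROMS, k), key=int)
        return [
            Aberration(
                kind=AberrationKind.TRISOMY,
                descriptor=c,
                method=DetectionMethod.KARYOTYPE,
            )
            for c in chroms
        ]
    descriptor = sorted(pattern.canonical_descriptors())[0]
    kind = AberrationKind(pattern.kind.value)
    return [Aberration(kind=kind, descriptor=descriptor, method=DetectionMethod.FISH)]


def generate_cohort(config: CohortConfig, kb: Optional[KnowledgeBase] = None) -> Cohort:
    """Generate a seeded cohort with per-patient ground truth.

    Category membership is drawn independently from the prevalences, then
    adverse categories are re-drawn at ``min(1, p × cosegregation_boost)``
    for any patient already carrying at least one adverse lesion, emulating
    the observed co-segregation of adverse lesions.
    """
    kb = kb or build_default_kb()
    names = kb.category_names()
    prev = {name: 0.1 for name in names}
    if config.prevalence:
        unknown = set(config.prevalence) - set(names)
        if unknown:
            raise CohortConfigError(f"prevalence for unknown categories: {sorted(unknown)}")
        prev.update(config.prevalence)

    rng = random.Random(config.seed)
    all_genes = sorted(kb.gene_census())
    samples: list[Sample] = []
    truth: dict[str, GroundTruth] = {}
    for i in range(config.n_patients):
        sid = f"P{i + 1:04d}"
        present = {name: rng.random() < prev[name] for name in names}
        if config.cosegregation_boost > 1.0 and any(
            present[n] for n in names if n in ADVERSE_CATEGORIES
        ):
            for n in names:
                if n in ADVERSE_CATEGORIES and not present[n]:
                    present[n] = rng.random() < min(1.0, prev[n] * config.cosegregation_boost)
        aberrations: list[Aberration] = []
        weights: list[int] = []
        chosen: list[str] = []
        for cat in kb.categories:
            if present[cat.name]:
                aberrations.extend(_realize(cat, rng))
                weights.append(cat.weight_int)
                chosen.append(cat.name)
        # decoy gene is drawn unconditionally so cohorts differing only in
        # synonymous_rate share identical category memberships
        decoy_gene = rng.choice(all_genes)
        if rng.random() < config.synonymous_rate:
            aberrations.append(
                Aberration(
                    kind=AberrationKind.MUTATION,
                    gene=decoy_gene,
                    method=DetectionMethod.SEQUENCING,
                    consequence=Consequence.SYNONYMOUS,
                )
            )
        beta2m = rng.lognormvariate(config.beta2m_log_mu, config.beta2m_log_sigma)
        albumin = rng.lognormvariate(config.albumin_log_mu, config.albumin_log_sigma)
        clinical = IssInput(beta2m=beta2m, albumin=albumin)
        samples.append(
            Sample(
                sample_id=sid,
                collection_time=0,
                aberrations=tuple(aberrations),
                clinical=clinical,
            )
        )
        if weights:
            score = float(Fraction(sum(weights), len(weights)))
            truth[sid] = GroundTruth(
                categories=frozenset(chosen),
                expected_score=score,
                band=classify_risk(Fraction(sum(weights), len(weights))),
            )
        else:
            truth[sid] = GroundTruth(
                categories=frozenset(), expected_score=None, band=Band.UNSCORABLE
            )
    return Cohort(
        samples=tuple(samples),
        ground_truth=truth,
        kb_version=kb.version,
        config=config,
    )


_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##contig=<ID=1,length=249250621>\n'
    '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: '
    "'Allele | Annotation | Annotation_Impact | Gene_Name'\">\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def write_fixture_files(cohort: Cohort, directory: Union[str, Path]) -> dict:
    """Write the cohort as the file dialects the parsers consume.

    Per patient: ``<id>.lesions.tsv`` (cytogenetic lesions) and ``<id>.vcf``
    (sequencing mutations, SnpEff-style ANN annotations).  Cohort-wide:
    ``clinical.csv`` (β2m, albumin) and ``manifest.json`` listing paths and
    ground truth.  Returns the manifest dict.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    patients = []
    clinical_rows = []
    for sample in cohort.samples:
        sid = sample.sample_id
        lesions_name = f"{sid}.lesions.tsv"
        vcf_name = f"{sid}.vcf"
        with (directory / lesions_name).open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["sample_id", "kind", "descriptor", "gene", "method", "timepoint"])
            for ab in sample.aberrations:
                if ab.kind is AberrationKind.MUTATION:
                    continue
                writer.writerow(
                    [sid, ab.kind.value, ab.descriptor, "", ab.method.value, sample.collection_time]
                )
        with (directory / vcf_name).open("w", encoding="utf-8") as fh:
            fh.write(_VCF_HEADER)
            pos = 0
            for ab in sample.aberrations:
                if ab.kind is not AberrationKind.MUTATION:
                    continue
                pos += 1000
                if ab.consequence is Consequence.SYNONYMOUS:
                    term, impact = "synonymous_variant", "LOW"
                else:
                    term, impact = "missense_variant", "MODERATE"
                fh.write(
                    f"1\t{pos}\t.\tA\tG\t.\tPASS\tANN=G|{term}|{impact}|{ab.gene}\n"
                )
        clinical_rows.append((sid, sample.clinical.beta2m, sample.clinical.albumin))
        gt = cohort.ground_truth[sid]
        patients.append(
            {
                "sample_id": sid,
                "lesions": lesions_name,
                "vcf": vcf_name,
                "truth": {
                    "categories": sorted(gt.categories),
                    "expected_score": gt.expected_score,
                    "band": gt.band.value,
                },
            }
        )
    with (directory / "clinical.csv").open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "beta2m", "albumin"])
        for sid, b, a in clinical_rows:
            writer.writerow([sid, repr(b), repr(a)])
    manifest = {
        "kb_version": cohort.kb_version,
        "seed": cohort.config.seed,
        "n_patients": cohort.config.n_patients,
        "clinical": "clinical.csv",
        "patients": patients,
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest


def score_fixtures(
    directory: Union[str, Path], kb: Optional[KnowledgeBase] = None
) -> dict[str, RagResult]:
    """Re-parse a fixture directory (manifest.json) and score every patient —
    the end-to-end path the generator's ground truth is checked against."""
    directory = Path(directory)
    kb = kb or build_default_kb()
    manifest = json.loads((directory / "manifest.json").read_text(encoding="utf-8"))
    results: dict[str, RagResult] = {}
    for patient in manifest["patients"]:
        sid = patient["sample_id"]
        aberrations = list(parse_lesion_table(directory / patient["lesions"]))
        aberrations.extend(parse_vcf(directory / patient["vcf"]).aberrations)
        sample = Sample(sample_id=sid, aberrations=tuple(aberrations))
        results[sid], _ = score_sample(kb, sample)
    return results
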