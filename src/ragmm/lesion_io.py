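"""Read patient lesion evidence (VCF, lesion tables) and write result reports.

All evidence — FISH/karyotype cytogenetics and sequencing mutations — is
unified into the :class:`Aberration` model.  Gene symbols are the unit of
sequence evidence; coordinates are never interpreted.  Synonymous variants
are filtered at VCF parse time (they leave protein structure unchanged and
carry no weight in the model); variants with an unknown consequence are
kept, as silent mutations are expected to be rare among the model's
recurrently mutated genes.
"""

from __future__ import annotations

import csv
import json
import math
import re
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Optional, Sequence, Union

from pydantic import BaseModel, ConfigDict, Field, model_validator

if TYPE_CHECKING:  # pragma: no cover
    from .scoring import CombinedReport

import enum

__all__ = [
    "AberrationKind",
    "DetectionMethod",
    "Consequence",
    "Aberration",
    "IssInput",
    "Sample",
    "LesionParseError",
    "VcfParseError",
    "normalize_descriptor",
    "parse_lesion_table",
    "load_samples",
    "parse_vcf",
    "VcfParseResult",
    "write_report",
    "read_report",
]


class LesionParseError(ValueError):
    """A lesion table row or VCF record could not be interpreted."""


class VcfParseError(LesionParseError):
    pass


class AberrationKind(str, enum.Enum):
    TRANSLOCATION = "translocation"
    TRISOMY = "trisomy"
    DELETION = "deletion"
    GAIN = "gain"
    MUTATION = "mutation"


CYTOGENETIC_KINDS = frozenset(
    {
        AberrationKind.TRANSLOCATION,
        AberrationKind.TRISOMY,
        AberrationKind.DELETION,
        AberrationKind.GAIN,
    }
)


class DetectionMethod(str, enum.Enum):
    FISH = "FISH"
    KARYOTYPE = "karyotype"
    GEP = "GEP"
    SEQUENCING = "sequencing"


class Consequence(str, enum.Enum):
    NONSYNONYMOUS = "nonsynonymous"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


_T_RE = re.compile(r"^t?\(?(\d{1,2})[;,](\d{1,2})\)?$", re.IGNORECASE)
_DEL_RE = re.compile(r"^(?:del)?\(?(\d{1,2}[pq]?)\)?$", re.IGNORECASE)
_GAIN_RE = re.compile(r"^(?:\+|gain)?\(?(\d{1,2}[pq]?)\)?\+?$", re.IGNORECASE)
_TRI_RE = re.compile(r"^(?:\+|trisomy)?(\d{1,2})$", re.IGNORECASE)


def normalize_descriptor(kind: AberrationKind, raw: str) -> str:
    """Canonicalize a cytogenetic lesion string.

    ``t(4;14)``/``T(4,14)`` -> ``t(4;14)``; ``Del(17p)``/``del17p`` ->
    ``del(17p)``; ``1q+``/``gain(1q)`` -> ``+1q``; ``+9``/``trisomy 9`` ->
    ``9``.  Raises :class:`LesionParseError` on unrecognisable notation.
    """
    s = "".join(str(raw).split())
    if not s:
        raise LesionParseError(f"empty descriptor for kind {kind.value!r}")
    if kind is AberrationKind.TRANSLOCATION:
        m = _T_RE.match(s)
        if not m:
            raise LesionParseError(f"unrecognised translocation descriptor {raw!r}")
        return f"t({int(m.group(1))};{int(m.group(2))})"
    if kind is AberrationKind.DELETION:
        m = _DEL_RE.match(s)
        if not m:
            raise LesionParseError(f"unrecognised deletion descriptor {raw!r}")
        return f"del({m.group(1).lower()})"
    if kind is AberrationKind.GAIN:
        m = _GAIN_RE.match(s)
        if not m:
            raise LesionParseError(f"unrecognised gain descriptor {raw!r}")
        return f"+{m.group(1).lower()}"
    if kind is AberrationKind.TRISOMY:
        m = _TRI_RE.match(s)
        if not m:
            raise LesionParseError(f"unrecognised trisomy descriptor {raw!r}")
        return str(int(m.group(1)))
    raise LesionParseError(f"kind {kind.value!r} takes no descriptor")


class Aberration(BaseModel):
    """One detected genetic lesion: a cytogenetic event or a gene mutation."""

    model_config = ConfigDict(frozen=True)

    kind: AberrationKind
    descriptor: Optional[str] = None
    gene: Optional[str] = None
    method: DetectionMethod
    consequence: Optional[Consequence] = None

    @model_validator(mode="after")
    def _check_fields(self) -> "Aberration":
        if self.kind is AberrationKind.MUTATION:
            if not self.gene:
                raise ValueError("mutation aberration requires a gene symbol")
        else:
            if not self.descriptor:
                raise ValueError(f"{self.kind.value} aberration requires a descriptor")
        return self


class IssInput(BaseModel):
    """Clinical biochemistry for ISS staging: serum β2-microglobulin (mg/L)
    and serum albumin (g/dL), both finite and non-negative."""

    model_config = ConfigDict(frozen=True)

    beta2m: float = Field(ge=0)
    albumin: float = Field(ge=0)

    @model_validator(mode="after")
    def _finite(self) -> "IssInput":
        if not (math.isfinite(self.beta2m) and math.isfinite(self.albumin)):
            raise ValueError("beta2m and albumin must be finite")
        return self


class Sample(BaseModel):
    """All evidence for one patient sample (optionally at one timepoint)."""

    model_config = ConfigDict(frozen=True)

    sample_id: str = Field(min_length=1)
    collection_time: Optional[int] = None
    aberrations: tuple[Aberration, ...] = ()
    clinical: Optional[IssInput] = None


# ---------------------------------------------------------------------------
# lesion tables (TSV/CSV): header sample_id  kind  descriptor  gene  method  timepoint
# ---------------------------------------------------------------------------

_KIND_TOKENS = {k.value: k for k in AberrationKind}
_METHOD_TOKENS = {m.value.lower(): m for m in DetectionMethod}


def _row_to_aberration(row: dict, line_no: int) -> Aberration:
    kind_token = (row.get("kind") or "").strip().lower()
    if kind_token not in _KIND_TOKENS:
        raise LesionParseError(f"row {line_no}: unknown lesion kind {row.get('kind')!r}")
    kind = _KIND_TOKENS[kind_token]
    method_token = (row.get("method") or "").strip().lower()
    if method_token not in _METHOD_TOKENS:
        raise LesionParseError(f"row {line_no}: unknown method {row.get('method')!r}")
    method = _METHOD_TOKENS[method_token]
    if kind is AberrationKind.MUTATION:
        gene = (row.get("gene") or "").strip()
        if not gene:
            raise LesionParseError(f"row {line_no}: mutation row lacks a gene symbol")
        cons = (row.get("consequence") or "").strip().lower() or None
        try:
            return Aberration(
                kind=kind,
                gene=gene,
                method=method,
                consequence=Consequence(cons) if cons else None,
            )
        except ValueError as exc:
            raise LesionParseError(f"row {line_no}: {exc}") from exc
    raw = (row.get("descriptor") or "").strip()
    if not raw:
        raise LesionParseError(f"row {line_no}: {kind.value} row lacks a descriptor")
    try:
        descriptor = normalize_descriptor(kind, raw)
    except LesionParseError as exc:
        raise LesionParseError(f"row {line_no}: {exc}") from exc
    return Aberration(kind=kind, descriptor=descriptor, method=method)


def _read_rows(path: Union[str, Path]) -> list[tuple[int, dict]]:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    delimiter = "\t" if "\t" in lines[0] else ","
    reader = csv.DictReader(lines, delimiter=delimiter, skipinitialspace=True)
    if reader.fieldnames is None or "kind" not in [f.strip() for f in reader.fieldnames]:
        raise LesionParseError(f"{path}: lesion table header must include a 'kind' column")
    reader.fieldnames = [f.strip() for f in reader.fieldnames]
    return [(i, row) for i, row in enumerate(reader, start=2)]


def parse_lesion_table(path: Union[str, Path]) -> list[Aberration]:
    """Parse every row of a lesion table into validated Aberrations (in order)."""
    return [_row_to_aberration(row, n) for n, row in _read_rows(path)]


def load_samples(path: Union[str, Path]) -> list[Sample]:
    """Group lesion-table rows into Samples by (sample_id, timepoint).

    Rows without a sample_id column fall under the id ``"sample"``; an empty
    timepoint is ``None``.  Groups keep first-appearance order.
    """
    groups: dict[tuple[str, Optional[int]], list[Aberration]] = {}
    for n, row in _read_rows(path):
        sid = (row.get("sample_id") or "").strip() or "sample"
        tp_raw = (row.get("timepoint") or "").strip()
        try:
            tp = int(tp_raw) if tp_raw else None
        except ValueError as exc:
            raise LesionParseError(f"row {n}: timepoint {tp_raw!r} is not an integer") from exc
        groups.setdefault((sid, tp), []).append(_row_to_aberration(row, n))
    return [
        Sample(sample_id=sid, collection_time=tp, aberrations=tuple(abs_))
        for (sid, tp), abs_ in groups.items()
    ]


# ---------------------------------------------------------------------------
# VCF parsing (annotated VCF 4.x; gene symbols from an INFO annotation)
# ---------------------------------------------------------------------------

_SYN_TERMS = ("synonymous_variant", "stop_retained_variant", "start_retained_variant")
_NONSYN_HINTS = (
    "missense",
    "stop_gained",
    "stop_lost",
    "start_lost",
    "frameshift",
    "inframe",
    "splice_acceptor",
    "splice_donor",
    "protein_altering",
    "nonsynonymous",
    "disruptive",
    "coding_sequence_variant",
)


def classify_consequence(term: str) -> Consequence:
    """Map an annotation term (e.g. SnpEff/VEP SO term) onto the model's
    three-way consequence: synonymous terms are filtered, protein-altering
    terms are nonsynonymous, anything unknown is 'other' (kept)."""
    t = term.strip().lower()
    if not t:
        return Consequence.OTHER
    if any(s in t for s in _SYN_TERMS) or t == "synonymous":
        return Consequence.SYNONYMOUS
    if any(h in t for h in _NONSYN_HINTS):
        return Consequence.NONSYNONYMOUS
    return Consequence.OTHER


_CONSEQUENCE_RANK = {
    Consequence.NONSYNONYMOUS: 2,
    Consequence.OTHER: 1,
    Consequence.SYNONYMOUS: 0,
}


class VcfParseResult(BaseModel):
    """Mutations kept from a VCF plus the synonymous-filter bookkeeping."""

    model_config = ConfigDict(frozen=True)

    aberrations: tuple[Aberration, ...]
    synonymous_filtered: int
    gene_annotated_records: int

    def __iter__(self):  # allow `for ab in result`
        return iter(self.aberrations)


def parse_vcf(
    path: Union[str, Path],
    annotation_key: str = "ANN",
    gene_subfield: int = 3,
) -> VcfParseResult:
    """Extract gene mutations from an annotated VCF.

    One :class:`Aberration` (kind=mutation, method=sequencing) is emitted per
    record–gene pair whose worst annotated consequence is nonsynonymous or
    unknown; pairs annotated only as synonymous are dropped and counted in
    ``synonymous_filtered``.  Annotation entries are read from the INFO field
    ``annotation_key``; pipe-delimited entries (SnpEff/VEP ``ANN``/``CSQ``
    dialect) take the gene from position ``gene_subfield`` and the
    consequence term from position 1, while plain values (e.g. ``GENE=TP53``)
    are treated as bare gene symbols with unknown consequence.
    """
    import cyvcf2

    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"VCF not found: {path}")
    try:
        vcf = cyvcf2.VCF(str(path))
    except Exception as exc:
        raise VcfParseError(f"{path}: unreadable or malformed VCF ({exc})") from exc

    aberrations: list[Aberration] = []
    filtered = 0
    gene_records = 0
    saw_record = False
    saw_key = False
    try:
        for rec in vcf:
            saw_record = True
            raw = rec.INFO.get(annotation_key)
            if raw is None:
                continue
            saw_key = True
            per_gene: dict[str, Consequence] = {}
            for entry in str(raw).split(","):
                entry = entry.strip()
                if not entry:
                    continue
                if "|" in entry:
                    fields = entry.split("|")
                    gene = fields[gene_subfield].strip() if len(fields) > gene_subfield else ""
                    term = fields[1] if len(fields) > 1 else ""
                else:
                    gene, term = entry, ""
                if not gene:
                    continue
                cons = classify_consequence(term)
                prev = per_gene.get(gene)
                if prev is None or _CONSEQUENCE_RANK[cons] > _CONSEQUENCE_RANK[prev]:
                    per_gene[gene] = cons
            for gene, cons in per_gene.items():
                gene_records += 1
                if cons is Consequence.SYNONYMOUS:
                    filtered += 1
                else:
                    aberrations.append(
                        Aberration(
                            kind=AberrationKind.MUTATION,
                            gene=gene,
                            method=DetectionMethod.SEQUENCING,
                            consequence=cons,
                        )
                    )
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(f"{path}: malformed VCF record ({exc})") from exc
    if saw_record and not saw_key:
        raise VcfParseError(
            f"{path}: no record carries the INFO annotation key {annotation_key!r}"
        )
    return VcfParseResult(
        aberrations=tuple(aberrations),
        synonymous_filtered=filtered,
        gene_annotated_records=gene_records,
    )


# ---------------------------------------------------------------------------
# reports (JSON / TSV)
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "sample_id",
    "row_type",
    "category",
    "group",
    "weight",
    "n_supporting",
    "supporting",
    "score",
    "band",
    "iss_stage",
    "adverse_count",
    "ultrahigh",
    "kb_version",
]


def _aberration_to_dict(ab: Aberration) -> dict:
    return {
        "kind": ab.kind.value,
        "descriptor": ab.descriptor,
        "gene": ab.gene,
        "method": ab.method.value,
        "consequence": ab.consequence.value if ab.consequence else None,
    }


def report_to_dict(report: "CombinedReport") -> dict:
    rag = report.rag
    return {
        "sample_id": rag.sample_id,
        "kb_version": rag.kb_version,
        "score": rag.score,
        "band": rag.band.value,
        "matches": [
            {
                "category": m.category.name,
                "group": m.category.group.label.value,
                "weight": m.category.weight,
                "supporting": [_aberration_to_dict(ab) for ab in m.supporting],
            }
            for m in rag.matches
        ],
        "iss_stage": report.iss.stage.value if report.iss else None,
        "adverse_count": report.adverse_count,
        "ultrahigh": report.ultrahigh,
    }


def write_report(report: "CombinedReport", path: Union[str, Path], format: str = "json") -> None:
    """Serialize a combined RAG+ISS report as JSON (schema shipped in
    ``data/report.schema.json``) or TSV (one row per matched category plus a
    summary row)."""
    path = Path(path)
    doc = report_to_dict(report)
    if format == "json":
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        return
    if format != "tsv":
        raise ValueError(f"unsupported report format {format!r}")
    rows = []
    for m in doc["matches"]:
        supporting = ";".join(
            (ab["gene"] or ab["descriptor"] or "") for ab in m["supporting"]
        )
        rows.append(
            {
                "sample_id": doc["sample_id"],
                "row_type": "category",
                "category": m["category"],
                "group": m["group"],
                "weight": m["weight"],
                "n_supporting": len(m["supporting"]),
                "supporting": supporting,
                "kb_version": doc["kb_version"],
            }
        )
    rows.append(
        {
            "sample_id": doc["sample_id"],
            "row_type": "summary",
            "score": "" if doc["score"] is None else doc["score"],
            "band": doc["band"],
            "iss_stage": doc["iss_stage"] or "",
            "adverse_count": doc["adverse_count"],
            "ultrahigh": str(doc["ultrahigh"]).lower(),
            "kb_version": doc["kb_version"],
        }
    )
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_TSV_COLUMNS, delimiter="\t", restval="")
        writer.writeheader()
        writer.writerows(rows)


def read_report(path: Union[str, Path], kb=None) -> "CombinedReport":
    """Reconstruct a :class:`CombinedReport` from its JSON serialization.

    Categories are resolved against ``kb`` (default knowledge base if
    omitted), so ``read_report(write_report(r)) == r`` holds whenever the
    report was produced with the same KB.
    """
    from .knowledge_base import build_default_kb
    from .scoring import Band, CategoryMatch, CombinedReport, IssStage, RagResult, Stage

    kb = kb or build_default_kb()
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    matches = tuple(
        CategoryMatch(
            category=kb.get(m["category"]),
            supporting=tuple(
                Aberration(
                    kind=AberrationKind(ab["kind"]),
                    descriptor=ab["descriptor"],
                    gene=ab["gene"],
                    method=DetectionMethod(ab["method"]),
                    consequence=Consequence(ab["consequence"]) if ab["consequence"] else None,
                )
                for ab in m["supporting"]
            ),
        )
        for m in doc["matches"]
    )
    rag = RagResult(
        sample_id=doc["sample_id"],
        matches=matches,
        score=doc["score"],
        band=Band(doc["band"]),
        kb_version=doc["kb_version"],
    )
    iss = IssStage(stage=Stage(doc["iss_stage"])) if doc["iss_stage"] else None
    return CombinedReport(
        rag=rag,
        iss=iss,
        adverse_count=doc["adverse_count"],
        ultrahigh=doc["ultrahigh"],
    )
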