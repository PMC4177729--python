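"""Editable knowledge base for the RAG (Red-Amber-Green) myeloma model.

The model collates the clinically important genetic lesions of multiple
myeloma into 22 categories: hyperdiploidy, the primary IGH translocations,
chromosome-arm gains/deletions, the secondary t(8;14), and seven functional
mutation categories (e.g. Proliferation, NF-κB, Epigenetic).  Each category
belongs to a traffic-light group — red (weight 3.0, adverse prognosis),
amber (2.0, intermediate/uncharacterised) or green (1.0, favourable) — and
carries its candidate genes plus an evidence level/grade.

The default knowledge base ships as YAML (``data/default_kb.yaml``) so the
tiering can be edited without touching code; ``load_kb`` validates any
user-supplied document against the same invariants.
"""

from __future__ import annotations

import enum
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator

__all__ = [
    "GroupLabel",
    "RagGroup",
    "EvidenceLevel",
    "EvidenceGrade",
    "EvidenceAssessment",
    "PatternKind",
    "CytogeneticPattern",
    "EventClass",
    "RagCategory",
    "KnowledgeBase",
    "KBValidationError",
    "build_default_kb",
    "load_kb",
    "serialize_kb",
    "lookup_gene",
    "GROUP_WEIGHTS",
]

#: Fixed traffic-light weights. These are the model's only admissible values.
GROUP_WEIGHTS: dict[str, float] = {"red": 3.0, "amber": 2.0, "green": 1.0}

#: Integer numerators used for exact rational score arithmetic.
GROUP_WEIGHTS_INT: dict[str, int] = {"red": 3, "amber": 2, "green": 1}


class KBValidationError(ValueError):
    """A knowledge-base document violates the schema or an invariant."""


class GroupLabel(str, enum.Enum):
    RED = "red"
    AMBER = "amber"
    GREEN = "green"

    @property
    def weight(self) -> float:
        return GROUP_WEIGHTS[self.value]

    @property
    def weight_int(self) -> int:
        return GROUP_WEIGHTS_INT[self.value]


class RagGroup(BaseModel):
    """A traffic-light group with its fixed score weight."""

    model_config = ConfigDict(frozen=True)

    label: GroupLabel
    weight: float = None  # type: ignore[assignment]  # filled from label

    @model_validator(mode="before")
    @classmethod
    def _fill_weight(cls, data):
        if isinstance(data, dict):
            label = data.get("label")
            if isinstance(label, GroupLabel):
                label = label.value
            if label in GROUP_WEIGHTS:
                expected = GROUP_WEIGHTS[label]
                got = data.get("weight")
                if got is None:
                    data = {**data, "weight": expected}
                elif float(got) != expected:
                    raise ValueError(
                        f"group {label!r} must weigh exactly {expected}, got {got}"
                    )
        return data

    @property
    def weight_int(self) -> int:
        return GROUP_WEIGHTS_INT[self.label.value]


class EvidenceLevel(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"


class EvidenceGrade(str, enum.Enum):
    A = "A"
    B = "B"
    C = "C"
    D = "D"


class EvidenceAssessment(BaseModel):
    """Level of evidence (I–V) and grade of recommendation (A–D)."""

    model_config = ConfigDict(frozen=True)

    level: EvidenceLevel
    grade: EvidenceGrade
    note: str = ""


class EventClass(str, enum.Enum):
    INITIATION_PRIMARY = "initiation_primary"
    PROGRESSION_SECONDARY = "progression_secondary"


class PatternKind(str, enum.Enum):
    TRANSLOCATION = "translocation"
    DELETION = "deletion"
    GAIN = "gain"
    TRISOMY = "trisomy"


class CytogeneticPattern(BaseModel):
    """Lesion descriptor a karyotypic category matches against.

    ``loci`` holds chromosome numbers for translocations/trisomies
    (e.g. ("4", "14") or the hyperdiploid odd-chromosome set) and
    chromosome-arm strings for deletions/gains (e.g. ("13", "13q"), ("1q",)).
    """

    model_config = ConfigDict(frozen=True)

    kind: PatternKind
    loci: tuple[str, ...] = Field(min_length=1)

    @model_validator(mode="after")
    def _check_arity(self) -> "CytogeneticPattern":
        if self.kind is PatternKind.TRANSLOCATION and len(self.loci) != 2:
            raise ValueError("translocation pattern needs exactly two chromosomes")
        if self.kind is PatternKind.GAIN and len(self.loci) != 1:
            raise ValueError("gain pattern needs exactly one locus")
        return self

    def canonical_descriptors(self) -> frozenset[str]:
        """Canonical lesion strings this pattern accepts (trisomies: bare chromosome)."""
        if self.kind is PatternKind.TRANSLOCATION:
            return frozenset({f"t({self.loci[0]};{self.loci[1]})"})
        if self.kind is PatternKind.DELETION:
            return frozenset(f"del({locus})" for locus in self.loci)
        if self.kind is PatternKind.GAIN:
            return frozenset({f"+{self.loci[0]}"})
        return frozenset(self.loci)  # trisomy: chromosome numbers

    def matches(self, aberration_kind: str, descriptor: str) -> bool:
        """True if a normalized cytogenetic aberration matches this pattern."""
        if aberration_kind != self.kind.value:
            return False
        return descriptor in self.canonical_descriptors()


def _normalize_symbol(gene: str) -> str:
    return "".join(gene.split()).upper()


class RagCategory(BaseModel):
    """One category row of the model: name, event class, genes, group, evidence."""

    model_config = ConfigDict(frozen=True)

    name: str = Field(min_length=1)
    event_class: EventClass
    candidate_genes: frozenset[str] = Field(min_length=1)
    group: RagGroup
    evidence: EvidenceAssessment
    cytogenetic_pattern: Optional[CytogeneticPattern] = None

    @field_validator("candidate_genes", mode="before")
    @classmethod
    def _normalize_genes(cls, v):
        if isinstance(v, (list, tuple, set, frozenset)):
            return frozenset(_normalize_symbol(str(g)) for g in v)
        return v

    @field_validator("group", mode="before")
    @classmethod
    def _coerce_group(cls, v):
        # allow the YAML shorthand `group: red`
        if isinstance(v, str):
            return {"label": v}
        return v

    @property
    def weight(self) -> float:
        return self.group.weight

    @property
    def weight_int(self) -> int:
        return self.group.weight_int

    @property
    def is_cytogenetic(self) -> bool:
        return self.cytogenetic_pattern is not None

    def has_gene(self, gene: str) -> bool:
        return _normalize_symbol(gene) in self.candidate_genes


class KnowledgeBase(BaseModel):
    """An ordered, versioned collection of RAG categories."""

    model_config = ConfigDict(frozen=True)

    version: str
    provenance: str = ""
    categories: tuple[RagCategory, ...] = Field(min_length=1)
    #: optional alias -> canonical symbol map (e.g. NSD2 -> MMSET); empty by
    #: default, i.e. the model's legacy spellings are the only vocabulary.
    aliases: dict[str, str] = Field(default_factory=dict)

    @field_validator("aliases", mode="before")
    @classmethod
    def _normalize_aliases(cls, v):
        if isinstance(v, dict):
            return {_normalize_symbol(k): _normalize_symbol(val) for k, val in v.items()}
        return v

    @model_validator(mode="after")
    def _unique_names(self) -> "KnowledgeBase":
        names = [c.name for c in self.categories]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate category names: {sorted(dupes)}")
        return self

    def category_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.categories)

    def get(self, name: str) -> RagCategory:
        for c in self.categories:
            if c.name == name:
                return c
        raise KeyError(name)

    def gene_census(self) -> frozenset[str]:
        """Union of all candidate-gene symbols in the knowledge base."""
        out: set[str] = set()
        for c in self.categories:
            out |= c.candidate_genes
        return frozenset(out)


def lookup_gene(kb: KnowledgeBase, gene: str) -> frozenset[RagCategory]:
    """Every category whose candidate genes contain ``gene``.

    Matching is case-insensitive and whitespace-stripped, with the KB's
    alias table applied first.  An unknown symbol returns the empty set —
    dual-listed genes (e.g. MMSET in both t(4;14) and Epigenetic) return
    more than one category.
    """
    symbol = _normalize_symbol(gene)
    symbol = kb.aliases.get(symbol, symbol)
    return frozenset(c for c in kb.categories if symbol in c.candidate_genes)


def load_kb(source: Union[str, Path, IO[str], dict]) -> KnowledgeBase:
    """Load and validate a knowledge-base document.

    ``source`` may be a filesystem path, an open text stream, a YAML string,
    or an already-parsed mapping.  Raises :class:`KBValidationError` naming
    the offending field on any schema or invariant violation.
    """
    if isinstance(source, dict):
        doc = source
    else:
        if isinstance(source, Path):
            text = source.read_text(encoding="utf-8")
        elif isinstance(source, str):
            # a path-looking short string without newlines is treated as a file
            try:
                is_file = "\n" not in source and Path(source).is_file()
            except (OSError, ValueError):
                is_file = False
            text = Path(source).read_text(encoding="utf-8") if is_file else source
        elif hasattr(source, "read"):
            text = source.read()
        else:  # pragma: no cover - defensive
            raise TypeError(f"unsupported KB source type: {type(source)!r}")
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise KBValidationError(f"malformed KB document: {exc}") from exc
    if not isinstance(doc, dict):
        raise KBValidationError("KB document must be a mapping with 'version' and 'categories'")
    try:
        return KnowledgeBase.model_validate(doc)
    except ValidationError as exc:
        raise KBValidationError(str(exc)) from exc


def serialize_kb(kb: KnowledgeBase) -> str:
    """YAML serialization that round-trips through :func:`load_kb`."""
    doc = {
        "version": kb.version,
        "provenance": kb.provenance,
        "aliases": dict(sorted(kb.aliases.items())),
        "categories": [
            {
                "name": c.name,
                "event_class": c.event_class.value,
                "group": c.group.label.value,
                "candidate_genes": sorted(c.candidate_genes),
                **(
                    {
                        "cytogenetic_pattern": {
                            "kind": c.cytogenetic_pattern.kind.value,
                            "loci": list(c.cytogenetic_pattern.loci),
                        }
                    }
                    if c.cytogenetic_pattern is not None
                    else {}
                ),
                "evidence": {
                    "level": c.evidence.level.value,
                    "grade": c.evidence.grade.value,
                    "note": c.evidence.note,
                },
            }
            for c in kb.categories
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


_DEFAULT_KB: Optional[KnowledgeBase] = None


def build_default_kb() -> KnowledgeBase:
    """The packaged 22-category default knowledge base (cached)."""
    global _DEFAULT_KB
    if _DEFAULT_KB is None:
        text = resources.files("ragmm").joinpath("data/default_kb.yaml").read_text(encoding="utf-8")
        _DEFAULT_KB = load_kb(text)
    return _DEFAULT_KB
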