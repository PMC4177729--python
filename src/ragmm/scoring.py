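"""RAG scoring: category matching, mean-weight score, risk bands, ISS, trajectories.

The score is the arithmetic mean of the red(3.0)/amber(2.0)/green(1.0)
weights of a sample's matched categories, so it always lies in [1.0, 3.0].
A mean rather than a sum keeps the score independent of how exhaustively a
sample was assayed.  Matching is de-duplicated at category granularity:
three hyperdiploid trisomies are one Hyperdiploidy match, and extra
supporting evidence for an already-matched category never moves the score.

Dual-listed genes are resolved by detection route: cytogenetic evidence
matches the chromosomal category via its lesion pattern, while a sequence
mutation matches only the functional (pattern-less) categories — an MMSET
point mutation is an Epigenetic hit, not a t(4;14).

Scores are computed as exact rationals (integer weight sum over match
count), so classification at the 1.5/2.0/2.5 band boundaries is exact.
"""

from __future__ import annotations

import enum
import math
from fractions import Fraction
from itertools import product
from typing import Iterable, Optional, Sequence, Union

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .knowledge_base import GroupLabel, KnowledgeBase, RagCategory, build_default_kb
from .lesion_io import Aberration, AberrationKind, Consequence, IssInput, Sample

__all__ = [
    "CategoryMatch",
    "MatchResult",
    "Band",
    "RagResult",
    "Stage",
    "IssStage",
    "IssInput",
    "CombinedReport",
    "TrajectoryPoint",
    "ScoreDomainError",
    "TrajectoryError",
    "ADVERSE_CATEGORIES",
    "match_lesions",
    "compute_rag_score",
    "classify_risk",
    "score_sample",
    "iss_stage",
    "combined_report",
    "trajectory",
    "score_extremes",
]

#: Adverse lesion set from the MRC Myeloma IX multivariate analysis:
#: +1q21, del(17p13) and the adverse IGH translocations.
ADVERSE_CATEGORIES = frozenset({"+1q", "Del(17p)", "t(4;14)", "t(14;16)", "t(14;20)"})


class ScoreDomainError(ValueError):
    """A score outside the model's [1.0, 3.0] range."""


class TrajectoryError(ValueError):
    """Invalid longitudinal input (e.g. duplicate timepoints)."""


class CategoryMatch(BaseModel):
    """A matched category with all aberrations supporting it."""

    model_config = ConfigDict(frozen=True)

    category: RagCategory
    supporting: tuple[Aberration, ...] = Field(min_length=1)


class MatchResult(BaseModel):
    """Matched categories (KB order, one entry per category) plus the
    aberrations that matched nothing — never silently dropped."""

    model_config = ConfigDict(frozen=True)

    matches: tuple[CategoryMatch, ...]
    unmatched: tuple[Aberration, ...]


class Band(str, enum.Enum):
    LOW = "low"
    LOW_INTERMEDIATE = "low_intermediate"
    HIGH_INTERMEDIATE = "high_intermediate"
    HIGH = "high"
    UNSCORABLE = "unscorable"


class RagResult(BaseModel):
    """Matched categories, mean score and risk band for one sample."""

    model_config = ConfigDict(frozen=True)

    sample_id: str
    matches: tuple[CategoryMatch, ...]
    score: Optional[float]
    band: Band
    kb_version: str

    @model_validator(mode="after")
    def _consistent(self) -> "RagResult":
        if (self.score is None) != (len(self.matches) == 0):
            raise ValueError("score must be present exactly when matches are non-empty")
        if self.score is not None and not (1.0 <= self.score <= 3.0):
            raise ValueError(f"score {self.score} outside [1.0, 3.0]")
        return self


def match_lesions(
    kb: KnowledgeBase, aberrations: Iterable[Aberration]
) -> MatchResult:
    """Match aberrations to knowledge-base categories.

    Cytogenetic aberrations match by lesion pattern (any trisomy from the
    hyperdiploid odd-chromosome set counts as Hyperdiploidy); mutations
    match by candidate gene among pattern-less functional categories only.
    Mutations explicitly annotated synonymous never match.  Each category
    appears at most once, with supporting aberrations aggregated in input
    order; matches are returned in knowledge-base order.
    """
    support: dict[str, list[Aberration]] = {}
    unmatched: list[Aberration] = []
    for ab in aberrations:
        hits: list[RagCategory] = []
        if ab.kind is AberrationKind.MUTATION:
            if ab.consequence is not Consequence.SYNONYMOUS:
                hits = [
                    c
                    for c in kb.categories
                    if c.cytogenetic_pattern is None and c.has_gene(ab.gene)
                ]
        else:
            hits = [
                c
                for c in kb.categories
                if c.cytogenetic_pattern is not None
                and c.cytogenetic_pattern.matches(ab.kind.value, ab.descriptor)
            ]
        if hits:
            for c in hits:
                support.setdefault(c.name, []).append(ab)
        else:
            unmatched.append(ab)
    matches = tuple(
        CategoryMatch(category=c, supporting=tuple(support[c.name]))
        for c in kb.categories
        if c.name in support
    )
    return MatchResult(matches=matches, unmatched=tuple(unmatched))


def _exact_mean(matches: Sequence[CategoryMatch]) -> Optional[Fraction]:
    if not matches:
        return None
    return Fraction(sum(m.category.weight_int for m in matches), len(matches))


def compute_rag_score(matches: Sequence[CategoryMatch]) -> Optional[float]:
    """Arithmetic mean of the matched categories' group weights; ``None``
    for an empty match set (an unscorable sample, never 0 or 1.0)."""
    mean = _exact_mean(matches)
    return None if mean is None else float(mean)


def classify_risk(score: Union[float, Fraction]) -> Band:
    """Risk band for a score: [1.0,1.5) low, [1.5,2.0) low-intermediate,
    [2.0,2.5) high-intermediate, [2.5,3.0] high (lower-inclusive)."""
    if isinstance(score, float) and not math.isfinite(score):
        raise ScoreDomainError(f"score must be finite, got {score}")
    if not (1 <= score <= 3):
        raise ScoreDomainError(f"score {score} outside the model range [1.0, 3.0]")
    if score < Fraction(3, 2):
        return Band.LOW
    if score < 2:
        return Band.LOW_INTERMEDIATE
    if score < Fraction(5, 2):
        return Band.HIGH_INTERMEDIATE
    return Band.HIGH


def score_sample(
    kb: KnowledgeBase, sample: Sample
) -> tuple[RagResult, tuple[Aberration, ...]]:
    """Match and score one sample; returns the result and the unmatched
    aberrations (for reporting/logging)."""
    mr = match_lesions(kb, sample.aberrations)
    mean = _exact_mean(mr.matches)
    band = Band.UNSCORABLE if mean is None else classify_risk(mean)
    result = RagResult(
        sample_id=sample.sample_id,
        matches=mr.matches,
        score=None if mean is None else float(mean),
        band=band,
        kb_version=kb.version,
    )
    return result, mr.unmatched


class Stage(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"


class IssStage(BaseModel):
    model_config = ConfigDict(frozen=True)

    stage: Stage


def iss_stage(clinical: IssInput) -> IssStage:
    """International Staging System stage from serum β2-microglobulin (mg/L)
    and albumin (g/dL).

    Stage I: β2m < 3.5 and albumin ≥ 3.5.  Stage III: β2m ≥ 5.5.
    Stage II: neither — i.e. β2m < 3.5 with albumin < 3.5, or
    3.5 ≤ β2m < 5.5 irrespective of albumin.
    """
    if clinical.beta2m >= 5.5:
        return IssStage(stage=Stage.III)
    if clinical.beta2m < 3.5 and clinical.albumin >= 3.5:
        return IssStage(stage=Stage.I)
    return IssStage(stage=Stage.II)


class CombinedReport(BaseModel):
    """RAG result combined with ISS staging and the ultrahigh-risk flag."""

    model_config = ConfigDict(frozen=True)

    rag: RagResult
    iss: Optional[IssStage] = None
    adverse_count: int = Field(ge=0)
    ultrahigh: bool

    @model_validator(mode="after")
    def _ultrahigh_consistent(self) -> "CombinedReport":
        if self.ultrahigh:
            if self.iss is None or self.iss.stage is Stage.I or self.adverse_count <= 1:
                raise ValueError(
                    "ultrahigh requires ISS stage II/III and more than one adverse lesion"
                )
        return self


def combined_report(rag: RagResult, iss: Optional[IssStage] = None) -> CombinedReport:
    """Combine a RAG result with ISS: ultrahigh risk = ISS II/III plus more
    than one matched adverse lesion (+1q, del(17p), t(4;14), t(14;16),
    t(14;20))."""
    adverse = sum(1 for m in rag.matches if m.category.name in ADVERSE_CATEGORIES)
    ultra = iss is not None and iss.stage in (Stage.II, Stage.III) and adverse > 1
    return CombinedReport(rag=rag, iss=iss, adverse_count=adverse, ultrahigh=ultra)


class TrajectoryPoint(BaseModel):
    """One timepoint of a longitudinal RAG trajectory."""

    model_config = ConfigDict(frozen=True)

    timepoint: int
    result: RagResult
    delta: Optional[float] = None
    new_categories: frozenset[str] = frozenset()
    lost_categories: frozenset[str] = frozenset()


def trajectory(samples: Sequence[Sample], kb: Optional[KnowledgeBase] = None) -> list[TrajectoryPoint]:
    """Score one patient's samples over time (clonal tides: lesion sets may
    grow or shrink between timepoints).

    Samples must carry distinct integer timepoints; output is sorted
    ascending, each sample scored independently, with per-interval score
    deltas and newly appearing/lost categories.  The delta is ``None`` for
    the first timepoint and whenever either flanking score is absent.
    """
    kb = kb or build_default_kb()
    if not samples:
        raise TrajectoryError("trajectory requires at least one sample")
    if any(s.collection_time is None for s in samples):
        raise TrajectoryError("every trajectory sample needs a collection_time")
    times = [s.collection_time for s in samples]
    if len(set(times)) != len(times):
        raise TrajectoryError(f"duplicate timepoints: {sorted(times)}")
    ordered = sorted(samples, key=lambda s: s.collection_time)
    points: list[TrajectoryPoint] = []
    prev: Optional[RagResult] = None
    for s in ordered:
        result, _ = score_sample(kb, s)
        names = {m.category.name for m in result.matches}
        if prev is None:
            points.append(TrajectoryPoint(timepoint=s.collection_time, result=result))
        else:
            prev_names = {m.category.name for m in prev.matches}
            delta = (
                result.score - prev.score
                if result.score is not None and prev.score is not None
                else None
            )
            points.append(
                TrajectoryPoint(
                    timepoint=s.collection_time,
                    result=result,
                    delta=delta,
                    new_categories=frozenset(names - prev_names),
                    lost_categories=frozenset(prev_names - names),
                )
            )
        prev = result
    return points


def score_extremes(kb: Optional[KnowledgeBase] = None) -> tuple[float, float, int]:
    """Exact (min, max, n_subsets) of the mean score over every non-empty
    subset of the knowledge base's categories.

    A subset's score depends only on how many red/amber/green categories it
    contains, so enumerating the per-group count triples (with Fraction
    arithmetic) covers all 2^k − 1 subsets exactly.
    """
    kb = kb or build_default_kb()
    counts = {g: 0 for g in GroupLabel}
    for c in kb.categories:
        counts[c.group.label] += 1
    lo: Optional[Fraction] = None
    hi: Optional[Fraction] = None
    for r, a, g in product(
        range(counts[GroupLabel.RED] + 1),
        range(counts[GroupLabel.AMBER] + 1),
        range(counts[GroupLabel.GREEN] + 1),
    ):
        n = r + a + g
        if n == 0:
            continue
        score = Fraction(3 * r + 2 * a + g, n)
        lo = score if lo is None or score < lo else lo
        hi = score if hi is None or score > hi else hi
    return float(lo), float(hi), 2 ** len(kb.categories) - 1
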