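"""Candidate classification and target-gene assessment.

Candidate regulators returned by the queries are triaged against an
existing network map and two evidence layers:

* **a** — already documented members of the network map (e.g. the CCK2R
  gastrin-response map); nothing new to test;
* **b** — everything else, split by model-system responsiveness:

  * **b1** — responsive in the expression time series; of these,

    * **b1i** — with literature evidence of responding to other stimuli:
      the most promising new putative network members (priority 1);
    * **b1j** — without such evidence (priority 2);

  * **b_other** — not responsive (priority 3).

Shared target genes are assessed the same way: a gene is a *candidate*
target iff it is expressed in the model system and responsive to the
stimulus; a candidate is *dual-supported* iff additionally its novel
regulator is itself expressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .integration import read_table
from .model import Curie
from .query import SharedTarget

CATEGORY_PRIORITY = {"a": 0, "b1i": 1, "b1j": 2, "b_other": 3}


def _norm(entity) -> str:
    if isinstance(entity, Curie):
        return entity.local_id.upper()
    return str(entity).strip().upper()


@dataclass
class ExpressionEvidence:
    """Boolean expression calls per entity (protein or gene symbol).

    Entities are matched case-insensitively; an absent entity counts as
    neither expressed nor responsive.
    """

    flags: dict[str, tuple[bool, bool]] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Mapping[str, tuple[bool, bool]]) -> "ExpressionEvidence":
        return cls({_norm(k): (bool(e), bool(r)) for k, (e, r) in pairs.items()})

    @classmethod
    def from_table(cls, stream) -> "ExpressionEvidence":
        df = read_table(stream, ["entity", "expressed", "responsive"])
        truthy = {"yes", "true", "1"}
        return cls({
            _norm(r.entity): (r.expressed.strip().lower() in truthy,
                              r.responsive.strip().lower() in truthy)
            for r in df.itertuples()
        })

    def expressed(self, entity) -> bool:
        return self.flags.get(_norm(entity), (False, False))[0]

    def responsive(self, entity) -> bool:
        return self.flags.get(_norm(entity), (False, False))[1]


@dataclass
class LiteratureEvidence:
    """Literature flags: is the entity responsive to other stimuli?"""

    entities: set[str] = field(default_factory=set)

    @classmethod
    def from_entities(cls, entities: Iterable) -> "LiteratureEvidence":
        return cls({_norm(e) for e in entities})

    @classmethod
    def from_table(cls, stream) -> "LiteratureEvidence":
        df = read_table(stream, ["entity"])
        return cls({_norm(r.entity) for r in df.itertuples()})

    def responsive_to_other_stimuli(self, entity) -> bool:
        return _norm(entity) in self.entities


@dataclass(frozen=True)
class Classification:
    protein: Curie
    category: str  # a / b1i / b1j / b_other
    priority: int

    def __post_init__(self) -> None:
        assert self.priority == CATEGORY_PRIORITY[self.category]


def classify_candidates(candidates: Iterable[Curie],
                        membership: set[Curie],
                        expression: ExpressionEvidence,
                        literature: LiteratureEvidence) -> list[Classification]:
    """Assign each candidate its a / b1i / b1j / b_other category.

    Membership in the network map takes precedence over everything else;
    the categories partition the candidate set.  Output is sorted by
    (priority, protein).
    """
    out = []
    for p in candidates:
        if p in membership:
            cat = "a"
        elif expression.responsive(p):
            cat = "b1i" if literature.responsive_to_other_stimuli(p) else "b1j"
        else:
            cat = "b_other"
        out.append(Classification(p, cat, CATEGORY_PRIORITY[cat]))
    out.sort(key=lambda c: (c.priority, str(c.protein)))
    return out


def category_counts(classifications: Sequence[Classification]) -> dict[str, int]:
    counts = {cat: 0 for cat in CATEGORY_PRIORITY}
    for c in classifications:
        counts[c.category] += 1
    return counts


@dataclass(frozen=True)
class AssessedTarget:
    """A shared-target row annotated with expression evidence."""

    row: SharedTarget
    expressed: bool
    responsive: bool
    candidate: bool       # expressed and responsive
    dual_supported: bool  # candidate and novel regulator expressed


def assess_target_genes(rows: Sequence[SharedTarget],
                        expression: ExpressionEvidence,
                        regulator_expression: ExpressionEvidence,
                        ) -> list[AssessedTarget]:
    """Annotate shared-target rows with expression-based support.

    A target gene is a *candidate* iff it is expressed in the model system
    and responsive to the stimulus; a candidate is *dual-supported* iff its
    novel regulator is also expressed — targets of expressed regulators
    carry more weight.
    """
    out = []
    for row in rows:
        expressed = expression.expressed(row.target_gene)
        responsive = expression.responsive(row.target_gene)
        candidate = expressed and responsive
        dual = candidate and regulator_expression.expressed(row.novel)
        out.append(AssessedTarget(row, expressed, responsive, candidate, dual))
    return out


def candidate_genes(assessed: Sequence[AssessedTarget]) -> set[str]:
    return {a.row.target_gene for a in assessed if a.candidate}


def dual_supported_genes(assessed: Sequence[AssessedTarget]) -> set[str]:
    return {a.row.target_gene for a in assessed if a.dual_supported}


def assessment_table(assessed: Sequence[AssessedTarget]):
    """The assessment as a DataFrame mirroring the published report layout."""
    import pandas as pd

    return pd.DataFrame([
        {
            "novel_dbtf": str(a.row.novel),
            "mode": a.row.mode,
            "core_dbtf": str(a.row.core),
            "target_gene": a.row.target_gene,
            "expressed": "Yes" if a.expressed else "No",
            "responsive": "Yes" if a.responsive else "No",
            "candidate": a.candidate,
            "dual_supported": a.dual_supported,
        }
        for a in assessed
    ])
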