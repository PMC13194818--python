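"""Five-criterion rubric scoring, rater aggregation and winner tallies.

Answers are scored 0-10 on accuracy, completeness, logical consistency,
clarity/conciseness and evidence support; the total (0-50) is their sum.
Two raters are aggregated by per-criterion means (which may be
half-integers).  Per question, the system with the strictly unique highest
total is credited as the winner; shared maxima count as ties attributed to
no system.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, fields
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from varqa.prompting import PromptBundle
from varqa.rag_pipeline import LlmBackendContract

__all__ = [
    "CRITERIA",
    "AnswerEvaluation",
    "CriterionScores",
    "JudgeResult",
    "JudgingError",
    "WinnerTally",
    "aggregate_raters",
    "llm_judge",
    "load_rubric",
    "load_score_table",
    "save_score_table",
    "tally_percentages",
    "total_score",
    "winner_tally",
]

CRITERIA = (
    "accuracy",
    "completeness",
    "logical_consistency",
    "clarity_conciseness",
    "evidence_support",
)


class JudgingError(ValueError):
    """The judge backend produced unusable scores."""


@dataclass(frozen=True)
class CriterionScores:
    """One answer's scores on the five rubric criteria (each in [0, 10]).

    Raw rater scores are integers; rater-averaged scores may be
    half-integers, so values are stored as floats and range-checked only.
    """

    accuracy: float
    completeness: float
    logical_consistency: float
    clarity_conciseness: float
    evidence_support: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (0 <= v <= 10):
                raise ValueError(f"{f.name} must lie in [0, 10], got {v}")

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in CRITERIA}

    @property
    def is_integral(self) -> bool:
        return all(float(v).is_integer() for v in self.as_dict().values())


def total_score(scores: CriterionScores) -> float:
    """Sum of the five criterion scores; lies in [0, 50]."""
    return sum(scores.as_dict().values())


@dataclass(frozen=True)
class AnswerEvaluation:
    """Scores assigned by one rater to one (question, system) answer."""

    template_id: str
    rs_id: str
    system: str
    rater: str
    scores: CriterionScores

    @property
    def total(self) -> float:
        return total_score(self.scores)


def aggregate_raters(e1: AnswerEvaluation, e2: AnswerEvaluation) -> AnswerEvaluation:
    """Per-criterion mean of two raters' evaluations of the same answer.

    The mean total equals the sum of mean criteria (and the mean of totals).
    """
    if (e1.template_id, e1.rs_id, e1.system) != (e2.template_id, e2.rs_id, e2.system):
        raise ValueError(
            "evaluations refer to different answers: "
            f"{(e1.template_id, e1.rs_id, e1.system)} vs "
            f"{(e2.template_id, e2.rs_id, e2.system)}"
        )
    mean_scores = CriterionScores(
        **{c: (getattr(e1.scores, c) + getattr(e2.scores, c)) / 2 for c in CRITERIA}
    )
    return AnswerEvaluation(e1.template_id, e1.rs_id, e1.system, "mean", mean_scores)


@dataclass(frozen=True)
class WinnerTally:
    """Per-system counts of uniquely highest-scoring answers, plus ties."""

    counts: Mapping[str, int]
    ties: int
    total: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) + self.ties != self.total:
            raise ValueError("system counts plus ties must equal the question total")


def winner_tally(totals: Mapping[object, Mapping[str, float]]) -> WinnerTally:
    """Credit, per question, the system with the strictly unique maximum
    total; equal maxima increment the tie count instead.
    """
    if not totals:
        raise ValueError("totals is empty")
    systems: Optional[frozenset[str]] = None
    counts: dict[str, int] = {}
    ties = 0
    for question, by_system in totals.items():
        current = frozenset(by_system)
        if systems is None:
            systems = current
            counts = {s: 0 for s in sorted(systems)}
        elif current != systems:
            raise ValueError(
                f"question {question!r} has system set {sorted(current)}, "
                f"expected {sorted(systems)}"
            )
        best = max(by_system.values())
        winners = [s for s, v in by_system.items() if v == best]
        if len(winners) == 1:
            counts[winners[0]] += 1
        else:
            ties += 1
    return WinnerTally(counts=counts, ties=ties, total=len(totals))


def tally_percentages(tally: WinnerTally) -> dict[str, float]:
    """Winner shares as percentages, rounded half-up to one decimal.

    Includes the tie share under the key ``"tie"``.
    """
    if tally.total <= 0:
        raise ValueError("tally total must be positive")

    def pct(count: int) -> float:
        return float(
            (Decimal(count) * 100 / Decimal(tally.total)).quantize(
                Decimal("0.1"), rounding=ROUND_HALF_UP
            )
        )

    out = {system: pct(c) for system, c in tally.counts.items()}
    out["tie"] = pct(tally.ties)
    return out


def load_rubric(path: Union[str, Path, None] = None) -> str:
    if path is not None:
        return Path(path).read_text(encoding="utf-8")
    return (
        resources.files("varqa.resources")
        .joinpath("judge_rubric.txt")
        .read_text(encoding="utf-8")
    )


@dataclass(frozen=True)
class JudgeResult:
    scores: CriterionScores
    raw_text: str


_JSON_BLOCK_RE = re.compile(r"\{[^{}]*\}")


def llm_judge(
    question: str,
    answer: str,
    llm: LlmBackendContract,
    rubric: Optional[str] = None,
) -> JudgeResult:
    """Score one answer with an LLM judge following the shipped rubric.

    The judge must emit a JSON object with one integer 0-10 per criterion;
    unparsable or out-of-range output raises :class:`JudgingError` (never
    silently clamped).  The raw judge text is retained for audit.
    """
    rubric = rubric if rubric is not None else load_rubric()
    prompt = rubric.replace("{question}", question).replace("{answer}", answer)
    bundle = PromptBundle(
        system_text=prompt, question_text=question, retrieval_used=False
    )
    raw = llm.complete(bundle)

    block = None
    for m in _JSON_BLOCK_RE.finditer(raw):
        try:
            candidate = json.loads(m.group(0))
        except json.JSONDecodeError:
            continue
        if set(candidate) == set(CRITERIA):
            block = candidate
            break
    if block is None:
        raise JudgingError(f"no parsable score block in judge output: {raw!r}")
    for criterion, value in block.items():
        if not isinstance(value, int) or isinstance(value, bool) or not 0 <= value <= 10:
            raise JudgingError(
                f"judge emitted invalid {criterion} score {value!r} (must be an integer in 0..10)"
            )
    return JudgeResult(scores=CriterionScores(**block), raw_text=raw)


# ---------------------------------------------------------------------------
# Long-format score tables (CSV, UTF-8, header required)

SCORE_COLUMNS = ["template_id", "rs_id", "system", "rater", *CRITERIA]


def save_score_table(evals: Sequence[AnswerEvaluation], path: Union[str, Path]) -> None:
    rows = [
        {
            "template_id": e.template_id,
            "rs_id": e.rs_id,
            "system": e.system,
            "rater": e.rater,
            **e.scores.as_dict(),
        }
        for e in evals
    ]
    pd.DataFrame(rows, columns=SCORE_COLUMNS).to_csv(path, index=False)


def load_score_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a long-format score CSV and add the ``total`` column."""
    df = pd.read_csv(path)
    missing = set(SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    df["total"] = df[list(CRITERIA)].sum(axis=1)
    return df
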