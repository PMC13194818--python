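"""The question-template registry and benchmark pool/sample construction.

Fifty templates in eight categories, each carrying an ``{rs}`` placeholder,
are crossed with a user-supplied list of rs numbers to form the full
benchmark pool; a constrained random sample guarantees that every template
appears at least once.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "BenchmarkQuestion",
    "QuestionTemplate",
    "RegistryError",
    "build_pool",
    "load_templates",
    "sample_constrained",
]

EXPECTED_TEMPLATE_COUNT = 50
EXPECTED_CATEGORY_COUNT = 8
RS_PLACEHOLDER = "{rs}"


class RegistryError(ValueError):
    """The template registry failed validation."""


@dataclass(frozen=True)
class QuestionTemplate:
    id: str
    category: str
    text: str

    def __post_init__(self) -> None:
        if RS_PLACEHOLDER not in self.text:
            raise RegistryError(f"template {self.id} lacks the {RS_PLACEHOLDER} placeholder")


@dataclass(frozen=True)
class BenchmarkQuestion:
    template_id: str
    rs_id: str
    question_text: str
    category: str


def load_templates(
    source: Union[str, Path, None] = None,
) -> list[QuestionTemplate]:
    """Load the template registry (packaged TSV by default).

    Validates the registry shape: 50 templates, 8 distinct categories,
    unique ids, placeholder present in every template.
    """
    if source is not None:
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = (
            resources.files("varqa.resources")
            .joinpath("question_templates.tsv")
            .read_text(encoding="utf-8")
        )
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    if reader.fieldnames != ["id", "category", "text"]:
        raise RegistryError(f"unexpected registry columns: {reader.fieldnames}")
    templates = [QuestionTemplate(row["id"], row["category"], row["text"]) for row in reader]

    ids = [t.id for t in templates]
    if len(set(ids)) != len(ids):
        raise RegistryError("duplicate template ids in registry")
    if len(templates) != EXPECTED_TEMPLATE_COUNT:
        raise RegistryError(
            f"registry must hold {EXPECTED_TEMPLATE_COUNT} templates, found {len(templates)}"
        )
    categories = {t.category for t in templates}
    if len(categories) != EXPECTED_CATEGORY_COUNT:
        raise RegistryError(
            f"registry must span {EXPECTED_CATEGORY_COUNT} categories, found {len(categories)}"
        )
    return templates


def build_pool(
    templates: Sequence[QuestionTemplate], rs_list: Sequence[str]
) -> list[BenchmarkQuestion]:
    """Cross every template with every rs number (template-major order)."""
    if len(set(rs_list)) != len(rs_list):
        raise ValueError("rs_list contains duplicates")
    pool = []
    for template in templates:
        for rs in rs_list:
            pool.append(
                BenchmarkQuestion(
                    template_id=template.id,
                    rs_id=rs,
                    question_text=template.text.replace(RS_PLACEHOLDER, rs),
                    category=template.category,
                )
            )
    return pool


def sample_constrained(
    pool: Sequence[BenchmarkQuestion], n: int, seed: Optional[int] = None
) -> list[BenchmarkQuestion]:
    """Draw ``n`` distinct questions so that every template appears at least
    once.

    One question is drawn uniformly per template, then the remainder is
    filled uniformly without replacement from the rest of the pool.  The
    result is deterministic for a fixed seed.
    """
    template_ids = sorted({q.template_id for q in pool})
    if n < len(template_ids):
        raise ValueError(
            f"n={n} cannot cover all {len(template_ids)} templates at least once"
        )
    if n > len(pool):
        raise ValueError(f"n={n} exceeds pool size {len(pool)}")

    rng = np.random.default_rng(seed)
    chosen_idx: set[int] = set()
    by_template: dict[str, list[int]] = {}
    for i, q in enumerate(pool):
        by_template.setdefault(q.template_id, []).append(i)
    for tid in template_ids:
        chosen_idx.add(int(rng.choice(by_template[tid])))
    remaining = [i for i in range(len(pool)) if i not in chosen_idx]
    extra = n - len(chosen_idx)
    if extra:
        chosen_idx.update(
            int(i) for i in rng.choice(remaining, size=extra, replace=False)
        )
    return [pool[i] for i in sorted(chosen_idx)]
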