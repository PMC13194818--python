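"""Assembly of the three-section prompt and its retrieval-free baseline.

The template has three sections: an expert-assistant role statement, the
six items every answer should cover, and a final section where the JSON
retrieved from the variant database replaces the ``{togovar_response}``
placeholder.  The baseline prompt (used when retrieval is disabled or
nothing was retrieved) is the same template minus the retrieval section and
minus every sentence that refers to the retrieval API — so the two arms of
a comparison differ only in the retrieval instruction, not in the task.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Union

__all__ = [
    "PLACEHOLDER",
    "PromptBundle",
    "build_baseline_prompt",
    "build_rag_prompt",
    "load_template",
]

PLACEHOLDER = "{togovar_response}"
RETRIEVAL_SECTION_HEADER = "### Information Retrieved from the TogoVar API"
_API_SENTENCE_MARKER = "TogoVar API"


@dataclass(frozen=True)
class PromptBundle:
    """A fully assembled prompt: system text plus the user's question."""

    system_text: str
    question_text: str
    retrieval_used: bool
    retrieved_json: Optional[str] = None

    def __post_init__(self) -> None:
        if self.retrieval_used != (self.retrieved_json is not None):
            raise ValueError("retrieval_used must match presence of retrieved_json")
        if PLACEHOLDER in self.system_text:
            raise ValueError("placeholder survived into system_text")
        if self.retrieval_used:
            if RETRIEVAL_SECTION_HEADER not in self.system_text:
                raise ValueError("retrieval section header missing from system_text")
            if self.system_text.count(self.retrieved_json) != 1:
                raise ValueError("retrieved JSON must appear exactly once in system_text")


def load_template(path: Union[str, Path, None] = None) -> str:
    """Read the prompt template (packaged resource, or an override file)."""
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
    else:
        text = (
            resources.files("varqa.resources")
            .joinpath("prompt_template.txt")
            .read_text(encoding="utf-8")
        )
    if text.count(PLACEHOLDER) != 1:
        raise ValueError(
            f"template must contain the placeholder {PLACEHOLDER!r} exactly once"
        )
    return text


def build_rag_prompt(
    question: str, retrieved_json: str, template: Optional[str] = None
) -> PromptBundle:
    """Substitute ``retrieved_json`` into the template's final section."""
    try:
        json.loads(retrieved_json)
    except (json.JSONDecodeError, TypeError) as exc:
        raise ValueError(f"retrieved payload is not valid JSON: {exc}") from exc
    template = template if template is not None else load_template()
    system_text = template.replace(PLACEHOLDER, retrieved_json)
    return PromptBundle(
        system_text=system_text,
        question_text=question,
        retrieval_used=True,
        retrieved_json=retrieved_json,
    )


def build_baseline_prompt(question: str, template: Optional[str] = None) -> PromptBundle:
    """The same prompt with the retrieval section and API references removed."""
    template = template if template is not None else load_template()
    system_text = _strip_retrieval(template)
    return PromptBundle(
        system_text=system_text,
        question_text=question,
        retrieval_used=False,
        retrieved_json=None,
    )


def _strip_retrieval(template: str) -> str:
    # Drop the final section (header + placeholder) wholesale.
    head, sep, _ = template.partition(RETRIEVAL_SECTION_HEADER)
    if not sep:
        raise ValueError("template lacks the retrieval section header")
    # Remove every sentence mentioning the retrieval API from the remainder.
    paragraphs = []
    for paragraph in head.split("\n"):
        if _API_SENTENCE_MARKER in paragraph:
            sentences = re.split(r"(?<=[.!?])\s+", paragraph)
            kept = [s for s in sentences if _API_SENTENCE_MARKER not in s]
            paragraph = " ".join(kept)
        paragraphs.append(paragraph)
    return "\n".join(paragraphs).rstrip() + "\n"
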