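"""Orchestration of the six-step answer pipeline over pluggable backends.

extract → normalise → fetch → assemble prompt → complete → return.
Questions without an identifier, and questions whose variant is unknown to
the store, fall back to the baseline (retrieval-free) prompt; the envelope
records which path was taken and why.
"""

from __future__ import annotations

import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence, Union

from varqa.identifiers import (
    GenomicAllele,
    IdentifierError,
    RecoderContract,
    VariantIdentifier,
    extract_identifier,
    normalize_identifier,
)
from varqa.prompting import PromptBundle, build_baseline_prompt, build_rag_prompt
from varqa.variant_store import VariantClientContract, fetch_variant

__all__ = [
    "AnswerEnvelope",
    "LlmBackendContract",
    "PipelineError",
    "answer_batch",
    "answer_question",
]


class LlmBackendContract(Protocol):
    """A completion backend: prompt bundle in, answer text out."""

    name: str

    def complete(self, bundle: PromptBundle) -> str: ...


class PipelineError(RuntimeError):
    """A backend failure, labelled with the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnswerEnvelope:
    """One question's answer plus full provenance of how it was produced."""

    question: str
    answer_text: str
    retrieval_used: bool
    identifier: Optional[VariantIdentifier] = None
    normalized_query: Optional[Union[str, GenomicAllele]] = None
    retrieved_json: Optional[str] = None
    lookup_miss: bool = False
    backend: str = ""
    elapsed_s: float = 0.0
    error: Optional[str] = None

    def __post_init__(self) -> None:
        if self.retrieval_used and not (
            self.identifier and self.normalized_query and self.retrieved_json
        ):
            raise ValueError(
                "retrieval_used requires identifier, normalized_query and retrieved_json"
            )


def answer_question(
    question: str,
    recoder: RecoderContract,
    client: VariantClientContract,
    llm: LlmBackendContract,
) -> AnswerEnvelope:
    """Run one question through the full pipeline.

    The variant client is contacted only when an identifier was found; an
    identifier whose variant is unknown falls back to the baseline prompt
    with the miss recorded on the envelope.
    """
    start = time.perf_counter()

    try:
        identifier = extract_identifier(question)
    except IdentifierError as exc:
        raise PipelineError("extract", exc) from exc

    normalized: Optional[Union[str, GenomicAllele]] = None
    retrieved: Optional[str] = None
    lookup_miss = False

    if identifier is not None:
        try:
            normalized = normalize_identifier(identifier, recoder)
        except IdentifierError as exc:
            raise PipelineError("recode", exc) from exc
        try:
            retrieved = fetch_variant(client, normalized)
        except Exception as exc:
            raise PipelineError("fetch", exc) from exc
        lookup_miss = retrieved is None

    if retrieved is not None:
        bundle = build_rag_prompt(question, retrieved)
    else:
        bundle = build_baseline_prompt(question)

    try:
        answer_text = llm.complete(bundle)
    except Exception as exc:
        raise PipelineError("complete", exc) from exc

    return AnswerEnvelope(
        question=question,
        answer_text=answer_text,
        retrieval_used=bundle.retrieval_used,
        identifier=identifier,
        normalized_query=normalized,
        retrieved_json=retrieved,
        lookup_miss=lookup_miss,
        backend=getattr(llm, "name", type(llm).__name__),
        elapsed_s=time.perf_counter() - start,
    )


def answer_batch(
    questions: Sequence[str],
    recoder: RecoderContract,
    client: VariantClientContract,
    llm: LlmBackendContract,
    concurrency: int = 1,
) -> list[AnswerEnvelope]:
    """Answer many questions; output order always matches input order.

    Per-question failures become error envelopes instead of aborting the
    batch.
    """
    if not questions:
        raise ValueError("questions must be non-empty")
    if concurrency < 1:
        raise ValueError("concurrency must be a positive integer")

    def run_one(question: str) -> AnswerEnvelope:
        try:
            return answer_question(question, recoder, client, llm)
        except Exception as exc:
            return AnswerEnvelope(
                question=question,
                answer_text="",
                retrieval_used=False,
                error=str(exc),
                backend=getattr(llm, "name", type(llm).__name__),
            )

    if concurrency == 1:
        return [run_one(q) for q in questions]
    with ThreadPoolExecutor(max_workers=concurrency) as pool:
        return list(pool.map(run_one, questions))
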