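"""Synthetic inputs for the test surface: variant-record fixtures, the
deterministic stub LLM, and simulated two-rater score tables with known
ground truth.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from varqa.evaluation import CRITERIA
from varqa.prompting import PromptBundle
from varqa.variant_store import (
    ClinicalSignificance,
    Consequence,
    Prediction,
    VariantRecord,
    render_record,
)

__all__ = [
    "CANONICAL_RS",
    "DEFAULT_RS_IDS",
    "ScoreSimulationConfig",
    "StubJudge",
    "StubLlm",
    "canonical_record_json",
    "generate_variant_record",
    "simulate_scores",
    "stub_llm_answer",
    "write_fixture_dir",
]

CANONICAL_RS = "rs34637584"

# 30 synthetic-but-valid rs ids so every benchmark count reproduces without
# the (unpublished) original selection.
DEFAULT_RS_IDS = tuple(f"rs{1000001 + 7 * i}" for i in range(30))

_GENES = (
    "LRRK2", "BRCA1", "BRCA2", "TP53", "CFTR", "APOE", "ALDH2", "EGFR",
    "MTHFR", "ABCB1", "CYP2D6", "HBB", "PAH", "GBA", "SNCA", "PSEN1",
)
_DATASETS = ("ToMMo", "gnomAD Genomes", "gnomAD Exomes", "GEM-J WGA", "NCBN")
_CONDITIONS = (
    "Autosomal dominant Parkinson disease 8",
    "Hereditary breast and ovarian cancer",
    "Cystic fibrosis",
    "Familial hypercholesterolemia",
    "Maturity-onset diabetes of the young",
)
_INTERPRETATIONS = ("pathogenic", "likely pathogenic", "uncertain significance",
                    "likely benign", "benign")
_CONSEQUENCES = (
    ("SO_0001583", "missense variant"),
    ("SO_0001819", "synonymous variant"),
    ("SO_0001627", "intron variant"),
    ("SO_0001587", "stop gained"),
)
_NUCLEOTIDES = ("A", "C", "G", "T")


def canonical_record_json() -> str:
    """The worked-example record (rs34637584), shipped as a resource."""
    return (
        resources.files("varqa.resources")
        .joinpath("rs34637584.json")
        .read_text(encoding="utf-8")
    )


def generate_variant_record(seed: int, rs_id: str) -> VariantRecord:
    """A random but internally consistent variant record.

    Deterministic in (seed, rs_id): the rs id is folded into the stream so
    distinct variants generated under one seed differ.
    """
    rng = np.random.default_rng([seed, int(rs_id.removeprefix("rs"))])
    chromosome = str(rng.choice([str(i) for i in range(1, 23)] + ["X", "Y", "MT"]))
    position = int(rng.integers(10_000, 200_000_000))
    ref = str(rng.choice(_NUCLEOTIDES))
    alt = str(rng.choice([n for n in _NUCLEOTIDES if n != ref]))
    gene = str(rng.choice(_GENES))
    am_score = float(np.round(rng.uniform(), 3))
    sig = ClinicalSignificance(
        condition=str(rng.choice(_CONDITIONS)),
        interpretations=[str(rng.choice(_INTERPRETATIONS))],
    )
    accession, label = _CONSEQUENCES[int(rng.integers(len(_CONSEQUENCES)))]
    freqs = {
        ds: float(np.round(10 ** rng.uniform(-6, -0.5), 8)) for ds in _DATASETS
    }
    return VariantRecord(
        togovar_id=f"tgv{int(rng.integers(10_000_000, 99_999_999))}",
        rs_id=rs_id,
        chromosome=chromosome,
        position=position,
        ref=ref,
        alt=alt,
        gene_symbol=gene,
        clinical_significance=[sig],
        most_severe_consequence=Consequence(accession=accession, label=label),
        hgvs={"genomic": f"chr{chromosome}:g.{position}{ref}>{alt}"},
        predictions={
            "SIFT": Prediction(score=float(np.round(rng.uniform(), 3)), label="deleterious"),
            "AlphaMissense": Prediction(
                score=am_score,
                label="likely pathogenic" if am_score > 0.56 else "likely benign",
            ),
        },
        allele_frequencies=freqs,
        external_links={"dbSNP": f"https://identifiers.org/dbsnp/{rs_id}"},
    )


def write_fixture_dir(
    out_dir: Union[str, Path],
    rs_ids: Sequence[str] = DEFAULT_RS_IDS,
    seed: int = 0,
    include_canonical: bool = True,
) -> Path:
    """Materialise one ``<rs>.json`` per variant (plus the worked example)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rs in rs_ids:
        (out / f"{rs}.json").write_text(
            render_record(generate_variant_record(seed, rs)), encoding="utf-8"
        )
    if include_canonical:
        (out / f"{CANONICAL_RS}.json").write_text(
            canonical_record_json(), encoding="utf-8"
        )
    return out


# ---------------------------------------------------------------------------
# Stub backends

_ITEM_TOPICS = (
    ("Variant identification", "rs_id"),
    ("Disease associations", "clinical_significance"),
    ("Literature evidence", None),
    ("Allele frequency comparison", "allele_frequencies"),
    ("GWAS findings", None),
    ("TogoVar link", "togovar_id"),
)


def stub_llm_answer(bundle: PromptBundle) -> str:
    """Deterministic answer text covering the six rubric items.

    With retrieval, fields are read straight out of the bundle's JSON; any
    absent field — and every item on the baseline path — is answered with
    an explicit no-data statement.
    """
    data: dict = {}
    if bundle.retrieval_used:
        data = json.loads(bundle.retrieved_json)

    lines = [f"Question: {bundle.question_text}", ""]
    for idx, (topic, key) in enumerate(_ITEM_TOPICS, start=1):
        value = data.get(key) if key else None
        if not value:
            lines.append(f"{idx}. {topic}: There are no data for this item.")
            continue
        if key == "rs_id":
            gene = data.get("gene_symbol", "an unknown gene")
            lines.append(
                f"{idx}. {topic}: {value} in {gene}"
                f" (chr{data.get('chromosome')}:{data.get('position')}"
                f" {data.get('ref')}>{data.get('alt')})."
            )
        elif key == "clinical_significance":
            parts = [
                f"{entry.get('condition')} ({', '.join(entry.get('interpretations', []))})"
                for entry in value
            ]
            lines.append(f"{idx}. {topic}: {'; '.join(parts)}.")
        elif key == "allele_frequencies":
            freqs = ", ".join(f"{ds}: {f}" for ds, f in value.items())
            lines.append(f"{idx}. {topic}: {freqs}.")
        elif key == "togovar_id":
            lines.append(f"{idx}. {topic}: https://togovar.org/variant/{value}")
    return "\n".join(lines)


class StubLlm:
    """Deterministic completion backend: identical bundle, identical text."""

    name = "stub"

    def complete(self, bundle: PromptBundle) -> str:
        return stub_llm_answer(bundle)


class StubJudge:
    """Judge backend that always emits one fixed score block."""

    name = "stub-judge"

    def __init__(self, scores: dict[str, int], decorate: str = ""):
        self.scores = dict(scores)
        self.decorate = decorate

    def complete(self, bundle: PromptBundle) -> str:
        return self.decorate + json.dumps(self.scores)


# ---------------------------------------------------------------------------
# Score-table simulation


class ScoreSimulationConfig(BaseModel):
    """Ground-truth parameters for a simulated two-rater score table."""

    model_config = ConfigDict(extra="forbid")

    n_questions: int = Field(ge=1)
    systems: dict[str, float]
    rater_noise_sd: float = Field(ge=0.0)
    between_question_sd: float = Field(ge=0.0)
    seed: int = 0

    @property
    def system_names(self) -> list[str]:
        return list(self.systems)


def simulate_scores(config: ScoreSimulationConfig) -> pd.DataFrame:
    """Long-format score table for 2 raters x systems x questions.

    Each (question, system) draws one latent quality around the system mean
    with the between-question sd; each rater observes the latent value plus
    independent Gaussian noise per criterion, rounded and clipped to 0-10.
    Noiseless raters therefore agree exactly.
    """
    for name, mean in config.systems.items():
        if not 0 <= mean <= 10:
            raise ValueError(f"system {name!r} mean must lie in [0, 10], got {mean}")
    rng = np.random.default_rng(config.seed)
    rows = []
    for q in range(config.n_questions):
        template_id = f"sim{q + 1}"
        rs_id = f"rs{q + 1}"
        for system, mean in config.systems.items():
            latent = rng.normal(mean, config.between_question_sd)
            for rater in ("rater1", "rater2"):
                observed = {
                    criterion: int(
                        np.clip(
                            np.rint(latent + rng.normal(0, config.rater_noise_sd)),
                            0,
                            10,
                        )
                    )
                    for criterion in CRITERIA
                }
                rows.append(
                    {
                        "template_id": template_id,
                        "rs_id": rs_id,
                        "system": system,
                        "rater": rater,
                        **observed,
                    }
                )
    df = pd.DataFrame(rows)
    df["total"] = df[list(CRITERIA)].sum(axis=1)
    return df
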