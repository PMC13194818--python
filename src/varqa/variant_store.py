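"""The integrated variant-record data model and its mock retrieval service.

A :class:`VariantRecord` carries one variant's annotation: identifiers,
GRCh38 position and alleles, gene symbol, clinical significance, the most
severe consequence, HGVS descriptions at up to three levels, pathogenicity
predictions, per-dataset allele frequencies and external resource links.
The record round-trips through JSON, and a fixture-backed mock client
stands in for the live annotation API.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Protocol, Union

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from varqa.identifiers import VALID_CHROMOSOMES, GenomicAllele

__all__ = [
    "ClinicalSignificance",
    "Consequence",
    "MockVariantClient",
    "Prediction",
    "RecordValidationError",
    "VariantClientContract",
    "VariantRecord",
    "VariantRetrievalError",
    "fetch_variant",
    "parse_record",
    "render_record",
]

HGVS_LEVELS = ("protein", "cdna", "genomic")
PREDICTION_TOOLS = ("SIFT", "PolyPhen", "AlphaMissense")


class RecordValidationError(ValueError):
    """A variant-record document violated the schema."""


class VariantRetrievalError(RuntimeError):
    """Transport-level retrieval failure (distinct from 'variant unknown')."""


class ClinicalSignificance(BaseModel):
    """One curated condition with its interpretation terms."""

    model_config = ConfigDict(extra="forbid")

    condition: str
    interpretations: list[str] = Field(default_factory=list)


class Consequence(BaseModel):
    """Most severe consequence as a Sequence Ontology accession + label."""

    model_config = ConfigDict(extra="forbid")

    accession: str
    label: str


class Prediction(BaseModel):
    """A pathogenicity prediction score with its qualitative label."""

    model_config = ConfigDict(extra="forbid")

    score: float = Field(ge=0.0, le=1.0)
    label: str


class VariantRecord(BaseModel):
    model_config = ConfigDict(extra="forbid")

    togovar_id: str = Field(min_length=1)
    rs_id: Optional[str] = None
    chromosome: str
    position: int = Field(ge=1)
    ref: str = Field(min_length=1)
    alt: str = Field(min_length=1)
    gene_symbol: Optional[str] = None
    clinical_significance: list[ClinicalSignificance] = Field(default_factory=list)
    most_severe_consequence: Optional[Consequence] = None
    hgvs: dict[str, str] = Field(default_factory=dict)
    predictions: dict[str, Prediction] = Field(default_factory=dict)
    allele_frequencies: dict[str, float] = Field(default_factory=dict)
    external_links: dict[str, str] = Field(default_factory=dict)

    @field_validator("chromosome")
    @classmethod
    def _chromosome_allowed(cls, v: str) -> str:
        if v not in VALID_CHROMOSOMES:
            raise ValueError(f"chromosome must be one of 1-22, X, Y, MT; got {v!r}")
        return v

    @field_validator("hgvs")
    @classmethod
    def _hgvs_levels(cls, v: dict[str, str]) -> dict[str, str]:
        bad = set(v) - set(HGVS_LEVELS)
        if bad:
            raise ValueError(f"unknown HGVS level(s): {sorted(bad)}")
        return v

    @field_validator("predictions")
    @classmethod
    def _prediction_tools(cls, v: dict[str, Prediction]) -> dict[str, Prediction]:
        bad = set(v) - set(PREDICTION_TOOLS)
        if bad:
            raise ValueError(f"unknown prediction tool(s): {sorted(bad)}")
        return v

    @field_validator("allele_frequencies")
    @classmethod
    def _frequencies_in_unit_interval(cls, v: dict[str, float]) -> dict[str, float]:
        for dataset, freq in v.items():
            if not (0.0 <= freq <= 1.0):
                raise ValueError(
                    f"allele_frequencies[{dataset!r}] must lie in [0, 1], got {freq}"
                )
        return v

    @model_validator(mode="after")
    def _ref_ne_alt(self) -> "VariantRecord":
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        return self

    @property
    def allele(self) -> GenomicAllele:
        return GenomicAllele(self.chromosome, self.position, self.ref, self.alt)


def parse_record(json_text: str) -> VariantRecord:
    """Parse and validate a variant-record JSON document.

    Absent optional fields stay empty; out-of-range values raise a
    :class:`RecordValidationError` naming the offending field.
    """
    try:
        payload = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise RecordValidationError(f"invalid JSON: {exc}") from exc
    try:
        return VariantRecord.model_validate(payload)
    except ValueError as exc:
        raise RecordValidationError(str(exc)) from exc


def render_record(record: VariantRecord) -> str:
    """Serialise a record to JSON, omitting absent optional fields.

    ``parse_record(render_record(r))`` reproduces ``r`` field for field.
    """
    payload = record.model_dump(exclude_none=True)
    for key in ("clinical_significance", "hgvs", "predictions",
                "allele_frequencies", "external_links"):
        if not payload.get(key):
            payload.pop(key, None)
    return json.dumps(payload, indent=2, ensure_ascii=False)


class VariantClientContract(Protocol):
    """Fetches raw variant JSON by rs number or genomic allele."""

    def fetch(self, query: Union[str, GenomicAllele]) -> Optional[str]: ...


class MockVariantClient:
    """Deterministic fixture-directory client.

    Fixtures are one ``<rs>.json`` (or ``<chrom>-<pos>-<ref>-<alt>.json``)
    per variant.  Every call is appended to :attr:`call_log` so tests can
    assert on retrieval behaviour.
    """

    def __init__(self, fixture_dir: Union[str, Path]):
        self.fixture_dir = Path(fixture_dir)
        self.call_log: list[str] = []

    def fetch(self, query: Union[str, GenomicAllele]) -> Optional[str]:
        key = query if isinstance(query, str) else query.key
        self.call_log.append(key)
        if not self.fixture_dir.is_dir():
            raise VariantRetrievalError(
                f"fixture directory not readable: {self.fixture_dir}"
            )
        path = self.fixture_dir / f"{key}.json"
        if not path.is_file():
            return None
        try:
            return path.read_text(encoding="utf-8")
        except OSError as exc:
            raise VariantRetrievalError(f"cannot read fixture {path}: {exc}") from exc


def fetch_variant(
    client: VariantClientContract, query: Union[str, GenomicAllele]
) -> Optional[str]:
    """Fetch the raw JSON for a normalised query, or ``None`` when unknown.

    The raw text is preserved verbatim so prompt substitution is
    byte-faithful to what the service returned.
    """
    return client.fetch(query)
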