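"""Detection and GRCh38 normalisation of variant identifiers in free text.

A question is expected to carry at most one variant identifier: either a
dbSNP rs number or an HGVS description.  rs numbers are queried directly;
HGVS descriptions are normalised to a GRCh38 genomic allele, locally when
they are genomic-level single-nucleotide substitutions and through a
pluggable recoder otherwise.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Union

__all__ = [
    "AmbiguousIdentifierError",
    "GenomicAllele",
    "HgvsParseError",
    "IdentifierError",
    "RecoderContract",
    "TableRecoder",
    "UnresolvableIdentifierError",
    "VariantIdentifier",
    "extract_identifier",
    "normalize_identifier",
    "parse_genomic_hgvs",
    "render_genomic_hgvs",
]

VALID_CHROMOSOMES = frozenset([str(i) for i in range(1, 23)] + ["X", "Y", "MT"])


class IdentifierError(ValueError):
    """Base class for identifier handling failures."""


class AmbiguousIdentifierError(IdentifierError):
    """More than one distinct identifier (or recoder candidate) was found."""

    def __init__(self, message: str, candidates: tuple = ()):
        super().__init__(message)
        self.candidates = tuple(candidates)


class UnresolvableIdentifierError(IdentifierError):
    """An HGVS description could not be resolved to any genomic allele."""


class HgvsParseError(IdentifierError):
    """A genomic HGVS string was recognised but malformed."""


@dataclass(frozen=True)
class VariantIdentifier:
    """A single identifier as matched in a question.

    ``kind`` is ``"rs"`` or ``"hgvs"``; ``raw`` is the matched text
    (lower-cased for rs numbers, verbatim for HGVS).
    """

    kind: str
    raw: str

    def __post_init__(self) -> None:
        if self.kind not in ("rs", "hgvs"):
            raise ValueError(f"unknown identifier kind: {self.kind!r}")
        if self.kind == "rs" and not re.fullmatch(r"rs\d+", self.raw):
            raise ValueError(f"malformed rs identifier: {self.raw!r}")
        if self.kind == "hgvs" and (":" not in self.raw or not self.raw):
            raise ValueError(f"malformed HGVS identifier: {self.raw!r}")


@dataclass(frozen=True)
class GenomicAllele:
    """A GRCh38-normalised allele: chromosome, 1-based position, REF, ALT."""

    chromosome: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.chromosome not in VALID_CHROMOSOMES:
            raise ValueError(f"invalid chromosome: {self.chromosome!r}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not re.fullmatch(r"[ACGT]+", allele):
                raise ValueError(f"{name} must be a non-empty uppercase nucleotide string, got {allele!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ, both are {self.ref!r}")

    @property
    def key(self) -> str:
        """``chrom-pos-ref-alt`` key used by the mock variant service."""
        return f"{self.chromosome}-{self.position}-{self.ref}-{self.alt}"


class RecoderContract(Protocol):
    """Resolves an HGVS text to zero or more GRCh38 genomic alleles."""

    def resolve(self, hgvs: str) -> list[GenomicAllele]: ...


class TableRecoder:
    """Pure lookup-table recoder (the fixture stand-in for a live recoding
    service).

    The table maps HGVS text to one or more ``chrom:pos:ref:alt`` strings.
    """

    def __init__(self, table: dict[str, Union[str, list[str]]]):
        self._table: dict[str, list[GenomicAllele]] = {}
        for hgvs, value in table.items():
            entries = [value] if isinstance(value, str) else list(value)
            self._table[hgvs] = [_parse_allele_key(e) for e in entries]

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "TableRecoder":
        """Load a mapping from JSON (object) or TSV (two columns)."""
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix.lower() == ".json":
            return cls(json.loads(text))
        table: dict[str, list[str]] = {}
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            hgvs, _, value = line.partition("\t")
            table.setdefault(hgvs.strip(), []).append(value.strip())
        return cls(table)

    def resolve(self, hgvs: str) -> list[GenomicAllele]:
        return list(self._table.get(hgvs, []))


def _parse_allele_key(key: str) -> GenomicAllele:
    parts = key.split(":")
    if len(parts) != 4:
        raise ValueError(f"expected 'chrom:pos:ref:alt', got {key!r}")
    chrom, pos, ref, alt = parts
    return GenomicAllele(chrom.removeprefix("chr"), int(pos), ref, alt)


# rs numbers are word-bounded and case-insensitive on the prefix.
_RS_RE = re.compile(r"\brs(\d+)\b", re.IGNORECASE)

# An HGVS-like token: a reference sequence (accession or chr-name), a colon,
# a level code (g/c/n/m/r/p) and a description.  This is deliberately a
# recogniser, not a validator; full validation happens downstream.
_HGVS_RE = re.compile(
    r"\b(?:chr)?[A-Za-z0-9_]+(?:\.\d+)?:[gcnmrp]\.[A-Za-z0-9_>+*?()\[\]=~-]+"
)

_GENOMIC_SNV_RE = re.compile(r"chr(?P<chrom>\w+):g\.(?P<pos>\d+)(?P<ref>[A-Za-z]+)>(?P<alt>[A-Za-z]+)$")
_GENOMIC_PREFIX_RE = re.compile(r"chr\w+:g\.")


def extract_identifier(question: str) -> VariantIdentifier | None:
    """Find the single variant identifier mentioned in ``question``.

    rs numbers win over HGVS notations when both are present (an rs query
    needs no recoding).  Repeated mentions of the same rs number are
    deduplicated; distinct identifiers of the same kind raise
    :class:`AmbiguousIdentifierError` because the supported question format
    carries a single identifier only.
    """
    if not question:
        raise ValueError("question must be non-empty text")

    rs_matches = {m.group(0).lower() for m in _RS_RE.finditer(question)}
    if len(rs_matches) > 1:
        raise AmbiguousIdentifierError(
            f"question contains {len(rs_matches)} distinct rs numbers: "
            + ", ".join(sorted(rs_matches)),
            candidates=sorted(rs_matches),
        )
    if rs_matches:
        return VariantIdentifier("rs", rs_matches.pop())

    hgvs_matches: list[str] = []
    for m in _HGVS_RE.finditer(question):
        token = m.group(0).rstrip(".,;:!?")
        if token not in hgvs_matches:
            hgvs_matches.append(token)
    if len(hgvs_matches) > 1:
        raise AmbiguousIdentifierError(
            f"question contains {len(hgvs_matches)} distinct HGVS notations: "
            + ", ".join(hgvs_matches),
            candidates=hgvs_matches,
        )
    if hgvs_matches:
        return VariantIdentifier("hgvs", hgvs_matches[0])
    return None


def parse_genomic_hgvs(hgvs: str) -> GenomicAllele | None:
    """Parse a ``chr{C}:g.{POS}{REF}>{ALT}`` single-nucleotide substitution.

    Returns ``None`` for anything outside that grammar (protein/cDNA levels,
    accession-style references, indels) — those travel through the recoder.
    Raises :class:`HgvsParseError` when the string *is* a chr-style genomic
    substitution but carries an invalid position or allele pair.
    """
    m = _GENOMIC_SNV_RE.fullmatch(hgvs)
    if m is None:
        return None
    chrom, pos, ref, alt = m.group("chrom", "pos", "ref", "alt")
    if chrom not in VALID_CHROMOSOMES:
        return None
    if len(ref) != 1 or len(alt) != 1:
        # multi-nucleotide substitution: recoder territory
        return None
    try:
        return GenomicAllele(chrom, int(pos), ref.upper(), alt.upper())
    except ValueError as exc:
        raise HgvsParseError(f"invalid genomic HGVS {hgvs!r}: {exc}") from exc


def render_genomic_hgvs(allele: GenomicAllele) -> str:
    """Inverse of :func:`parse_genomic_hgvs` on the accepted grammar."""
    return f"chr{allele.chromosome}:g.{allele.position}{allele.ref}>{allele.alt}"


def normalize_identifier(
    identifier: VariantIdentifier, recoder: RecoderContract
) -> Union[str, GenomicAllele]:
    """Turn an identifier into the exact query the variant client will use.

    rs identifiers pass through unchanged.  Genomic-level HGVS SNVs are
    parsed locally without touching the recoder; every other HGVS goes to
    ``recoder``, which must yield exactly one allele.
    """
    if identifier.kind == "rs":
        return identifier.raw

    local = parse_genomic_hgvs(identifier.raw)
    if local is not None:
        return local

    candidates = recoder.resolve(identifier.raw)
    if not candidates:
        raise UnresolvableIdentifierError(
            f"recoder returned no GRCh38 allele for {identifier.raw!r}"
        )
    if len(candidates) > 1:
        raise AmbiguousIdentifierError(
            f"recoder returned {len(candidates)} alleles for {identifier.raw!r}: "
            + ", ".join(a.key for a in candidates),
            candidates=candidates,
        )
    return candidates[0]
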