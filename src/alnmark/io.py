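"""Alignment input/output, sequence identity parsing and the consensus row.

Alignments are plain FASTA: every record carries a gapped sequence and all
gapped lengths must agree.  Sequences are normalised on ingest — uppercased,
with ``.`` gaps rewritten to ``-`` — so downstream code only ever sees
``A``–``Z`` and ``-``.

Sequence headers are mined for database accessions (UniProt, NCBI RefSeq,
Ensembl) so that row labels in rendered output can hyperlink to the source
database.
"""

from __future__ import annotations

import io as _io
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Union

from Bio import SeqIO

from .errors import FastaParseError, RaggedAlignmentError

__all__ = [
    "SequenceRecord",
    "Alignment",
    "SequenceIdentity",
    "ConsensusRow",
    "read_fasta",
    "write_fasta",
    "parse_identity",
    "consensus",
]

#: letters counted as nucleotide evidence by the alphabet heuristic
_NUC_LETTERS = frozenset("ACGTUN")
#: fraction of non-gap letters that must look nucleotide-like
_NUC_THRESHOLD = 0.9

_URL_TEMPLATES = {
    "uniprot": "https://www.uniprot.org/uniprotkb/{acc}",
    "ncbi": "https://www.ncbi.nlm.nih.gov/protein/{acc}",
    "ensembl": "https://www.ensembl.org/id/{acc}",
}

_UNIPROT_RE = re.compile(r"^(?:sp|tr)\|([A-Z0-9][A-Za-z0-9-]*)\|")
_NCBI_RE = re.compile(r"^((?:NP|XP|NM|XM|YP)_\d+(?:\.\d+)?)$")
_ENSEMBL_RE = re.compile(r"^(ENS[A-Z]*[PGT]\d{11})(?:\.\d+)?$")

_VALID_LETTERS = frozenset("ABCDEFGHIJKLMNOPQRSTUVWXYZ-")


@dataclass(frozen=True)
class SequenceIdentity:
    """A database cross-reference extracted from a FASTA header.

    ``database`` is one of ``uniprot``, ``ncbi``, ``ensembl`` or
    ``unknown``; when unknown, ``accession`` and ``url`` are empty.
    """

    database: str = "unknown"
    accession: str = ""
    url: str = ""


@dataclass(frozen=True)
class SequenceRecord:
    """One row of an alignment: raw header, display label, gapped letters."""

    header: str
    label: str
    letters: str
    alphabet: str = "unknown"

    @property
    def ungapped_length(self) -> int:
        return len(self.letters) - self.letters.count("-")

    @property
    def identity(self) -> SequenceIdentity:
        return parse_identity(self.header)


@dataclass(frozen=True)
class Alignment:
    """An ordered, rectangular set of gapped sequence records."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise FastaParseError("no records: an alignment needs at least one sequence")
        width = len(self.records[0].letters)
        for rec in self.records[1:]:
            if len(rec.letters) != width:
                raise RaggedAlignmentError(
                    f"ragged alignment: record '{rec.header}' has length "
                    f"{len(rec.letters)}, expected {width}"
                )

    @property
    def n_columns(self) -> int:
        return len(self.records[0].letters)

    def __len__(self) -> int:
        return len(self.records)

    def labels(self) -> list[str]:
        return [rec.label for rec in self.records]


@dataclass(frozen=True)
class ConsensusRow:
    """Per-column majority residue (gaps excluded) plus the raw tallies."""

    letters: str
    counts: tuple[dict[str, int], ...] = field(repr=False, default=())


def _detect_alphabet(letters: str) -> str:
    residues = letters.replace("-", "")
    if not residues:
        return "unknown"
    nuc = sum(1 for ch in residues if ch in _NUC_LETTERS)
    return "nucleotide" if nuc / len(residues) > _NUC_THRESHOLD else "protein"


def _make_label(header: str) -> str:
    # Display label: free text after the accession token, else the
    # accession, else the raw header (rendered rows show species names).
    parts = header.split(None, 1)
    if len(parts) == 2:
        return parts[1].strip()
    ident = parse_identity(header)
    if ident.accession:
        return ident.accession
    return header.strip()


def _normalise(raw: str, header: str) -> str:
    letters = raw.upper().replace(".", "-")
    bad = set(letters) - _VALID_LETTERS
    if bad:
        shown = ", ".join(repr(ch) for ch in sorted(bad))
        raise FastaParseError(
            f"record '{header}' contains characters outside A-Z/'-'/'.': {shown}"
        )
    return letters


def read_fasta(source: Union[str, bytes, IO]) -> Alignment:
    """Parse FASTA text (or a stream) into an :class:`Alignment`.

    Sequences are uppercased and ``.`` gaps become ``-``; wrapped lines are
    concatenated; record order is preserved.  Raises
    :class:`FastaParseError` on empty or non-FASTA input and
    :class:`RaggedAlignmentError` if gapped lengths differ.
    """
    if isinstance(source, bytes):
        text = source.decode("utf-8")
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
        if isinstance(text, bytes):
            text = text.decode("utf-8")

    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.lstrip().startswith(">"):
                raise FastaParseError(
                    f"line {lineno}: expected a '>' FASTA header, found {line.strip()[:30]!r}"
                )
            break
    else:
        raise FastaParseError("no records: input is empty")

    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        header = rec.description
        letters = _normalise(str(rec.seq), header)
        if not letters:
            raise FastaParseError(f"record '{header}' has an empty sequence")
        records.append(
            SequenceRecord(
                header=header,
                label=_make_label(header),
                letters=letters,
                alphabet=_detect_alphabet(letters),
            )
        )
    if not records:
        raise FastaParseError("no records: input is empty")
    return Alignment(records=tuple(records))


def write_fasta(aln: Alignment, width: int = 60) -> str:
    """Serialise an alignment back to FASTA, wrapping at ``width`` columns.

    Headers are preserved verbatim; ``read_fasta(write_fasta(aln))`` is the
    identity on headers and letters.
    """
    if width < 1:
        raise ValueError(f"width must be >= 1, got {width}")
    chunks: list[str] = []
    for rec in aln.records:
        chunks.append(f">{rec.header}\n")
        for i in range(0, len(rec.letters), width):
            chunks.append(rec.letters[i : i + width] + "\n")
    return "".join(chunks)


def parse_identity(header: str) -> SequenceIdentity:
    """Extract a database cross-reference from a FASTA description line.

    Dialects are tried in order — UniProt (``sp|ACC|NAME`` / ``tr|...``),
    NCBI RefSeq (NP_/XP_/NM_/XM_/YP_ with optional version), Ensembl stable
    IDs — and the first match wins.  Always returns; no match yields
    ``database="unknown"`` with empty accession and url.
    """
    header = header.lstrip(">").strip()
    m = _UNIPROT_RE.match(header)
    if m:
        acc = m.group(1)
        return SequenceIdentity("uniprot", acc, _URL_TEMPLATES["uniprot"].format(acc=acc))
    first = header.split(None, 1)[0] if header else ""
    m = _NCBI_RE.match(first)
    if m:
        acc = m.group(1)
        return SequenceIdentity("ncbi", acc, _URL_TEMPLATES["ncbi"].format(acc=acc))
    m = _ENSEMBL_RE.match(first)
    if m:
        acc = m.group(1)
        return SequenceIdentity("ensembl", acc, _URL_TEMPLATES["ensembl"].format(acc=acc))
    return SequenceIdentity()


def consensus(aln: Alignment) -> ConsensusRow:
    """Compute the per-column majority residue.

    Gaps never enter the tally: a column's consensus letter is the most
    frequent residue among non-gap letters, ties broken alphabetically, and
    ``-`` only when the whole column is gaps.
    """
    letters: list[str] = []
    counts: list[dict[str, int]] = []
    for col in range(aln.n_columns):
        tally = Counter(
            rec.letters[col] for rec in aln.records if rec.letters[col] != "-"
        )
        counts.append(dict(tally))
        if not tally:
            letters.append("-")
            continue
        best = max(tally.values())
        letters.append(min(ch for ch, n in tally.items() if n == best))
    return ConsensusRow(letters="".join(letters), counts=tuple(counts))
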