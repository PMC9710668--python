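"""Annotation documents: schema validation, token parsing, column projection
and cross-species co-located variant (OrthoVar) grouping.

Annotations arrive as a JSON document with optional top-level lists
``variants``, ``modifications`` and ``regions`` (the shipped
``schema/annotations-v1.json`` documents every field).  Positions are
UNGAPPED sequence coordinates, 1-based — the native numbering HGVS-style
tokens use.  That choice is what makes cross-species co-location work: the
human RYR2 variant at residue 4957 and the mouse Ryr2 variant at residue
4956 have different native positions yet project to the same alignment
column, which is exactly the definition of an orthologous variant pair.

Regions may instead be GLOBAL, in which case ``start``/``end`` are
alignment columns.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Optional, Union

from .coords import GAP, build_position_map, resolve_selector, ungapped_to_column
from .errors import AnnotationError, SelectorError, TokenError
from .io import Alignment

__all__ = [
    "GLOBAL",
    "VariantAnnotation",
    "ModificationAnnotation",
    "RegionAnnotation",
    "AnnotationSet",
    "ColumnIndex",
    "OrthoGroup",
    "SequenceChange",
    "load_annotations",
    "parse_change",
    "index_by_column",
    "ortho_groups",
    "validate_change_against_sequence",
    "collect_warnings",
]

#: sentinel sequence_ref for regions expressed in alignment-column space
GLOBAL = "__global__"

_AA = "ACDEFGHIKLMNPQRSTVWYX*"
# tokens are uppercased before matching, so the prefixes are P. / C.
_PROTEIN_RE = re.compile(
    r"^\s*P\.\s*([%s])\s*(\d+)\s*([%s])\s*$" % (re.escape(_AA), re.escape(_AA))
)
_CODING_RE = re.compile(r"^\s*C\.\s*(\d+)\s*([ACGTU])\s*>\s*([ACGTU])\s*$")


@dataclass(frozen=True)
class SequenceChange:
    """A parsed substitution token: level, reference, position, alternate."""

    level: str  # "protein" | "nucleotide"
    ref: str
    position: int
    alt: str


@dataclass
class VariantAnnotation:
    """A genetic variant pinned to one residue/nucleotide of one sequence."""

    sequence_ref: Union[int, str]
    position: int
    token: str = ""
    source: str = ""
    note: str = ""
    variant_id: str = ""
    url: str = ""
    attributes: dict[str, str] = field(default_factory=dict)
    seq_index: Optional[int] = None  # resolved at binding

    kind = "variant"


@dataclass
class ModificationAnnotation:
    """A post-translational (or other positional) modification, e.g. K2563-ub."""

    sequence_ref: Union[int, str]
    position: int
    mod_type: str = ""
    note: str = ""
    url: str = ""
    attributes: dict[str, str] = field(default_factory=dict)
    seq_index: Optional[int] = None

    kind = "modification"


@dataclass
class RegionAnnotation:
    """A labelled interval: protein domain, sgRNA target, deletion, ...

    ``sequence_ref`` may be :data:`GLOBAL`, in which case ``start``/``end``
    are alignment columns rather than ungapped positions.
    """

    sequence_ref: Union[int, str]
    start: int
    end: int
    label: str = ""
    color: str = ""
    url: str = ""
    attributes: dict[str, str] = field(default_factory=dict)
    seq_index: Optional[int] = None  # None when GLOBAL

    kind = "region"

    @property
    def is_global(self) -> bool:
        return self.sequence_ref == GLOBAL


@dataclass
class AnnotationSet:
    """A validated, sequence-bound collection of annotations."""

    variants: list[VariantAnnotation] = field(default_factory=list)
    modifications: list[ModificationAnnotation] = field(default_factory=list)
    regions: list[RegionAnnotation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.variants) + len(self.modifications) + len(self.regions)


@dataclass(frozen=True)
class ColumnIndex:
    """Per-column buckets of positional annotations after projection.

    Bucket entries are ``(kind, annotation)`` pairs ordered by
    (sequence index, kind — variants first, insertion order), so serialised
    output is deterministic.
    """

    buckets: dict[int, list[tuple[str, object]]]

    def columns(self) -> list[int]:
        return sorted(self.buckets)

    def total_members(self) -> int:
        return sum(len(b) for b in self.buckets.values())


@dataclass(frozen=True)
class OrthoGroup:
    """Variants from >= 2 distinct sequences sharing one alignment column."""

    column: int
    members: tuple[VariantAnnotation, ...]


def parse_change(token: str) -> SequenceChange:
    """Parse an HGVS-like substitution token.

    Supported forms are ``p.<AA><pos><AA>`` (e.g. ``p.C4957Y``) and
    ``c.<pos><base>><base>`` (e.g. ``c.88C>G``); interior whitespace as in
    ``p. C4957Y`` is tolerated.  Anything else raises :class:`TokenError`
    — callers typically keep such tokens as display-only text.
    """
    if not isinstance(token, str):
        raise TokenError(f"change token must be text, got {type(token).__name__}")
    m = _PROTEIN_RE.match(token.upper())
    if m:
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        if pos < 1:
            raise TokenError(f"position in {token!r} must be >= 1")
        return SequenceChange("protein", ref, pos, alt)
    m = _CODING_RE.match(token.upper())
    if m:
        pos, ref, alt = int(m.group(1)), m.group(2), m.group(3)
        if pos < 1:
            raise TokenError(f"position in {token!r} must be >= 1")
        return SequenceChange("nucleotide", ref, pos, alt)
    raise TokenError(
        f"unsupported change token {token!r} (expected 'p.C4957Y'-style or 'c.88C>G'-style)"
    )


# ---------------------------------------------------------------------------
# JSON loading / binding

_VARIANT_KEYS = {
    "sequence": "sequence_ref",
    "position": "position",
    "token": "token",
    "source": "source",
    "note": "note",
    "id": "variant_id",
    "url": "url",
}
_MOD_KEYS = {
    "sequence": "sequence_ref",
    "position": "position",
    "type": "mod_type",
    "note": "note",
    "url": "url",
}
_REGION_KEYS = {
    "sequence": "sequence_ref",
    "start": "start",
    "end": "end",
    "label": "label",
    "color": "color",
    "url": "url",
}


def _require(obj: dict, key: str, where: str):
    if key not in obj:
        raise AnnotationError(f"{where}: missing required key {key!r}")
    return obj[key]


def _as_position(value, where: str) -> int:
    if isinstance(value, bool) or not isinstance(value, int):
        raise AnnotationError(f"{where}: position must be an integer, got {value!r}")
    if value < 1:
        raise AnnotationError(f"{where}: positions are 1-based, got {value}")
    return value


def _split_known(obj: dict, keymap: dict[str, str], where: str) -> tuple[dict, dict]:
    if not isinstance(obj, dict):
        raise AnnotationError(f"{where}: expected a JSON object, got {type(obj).__name__}")
    known: dict = {}
    extra: dict[str, str] = {}
    for k, v in obj.items():
        if k in keymap:
            known[keymap[k]] = v
        else:
            extra[str(k)] = v if isinstance(v, str) else json.dumps(v)
    return known, extra


def _bind_ref(ref, aln: Alignment, where: str) -> int:
    try:
        return resolve_selector(aln, ref)
    except SelectorError as exc:
        raise AnnotationError(f"{where}: cannot bind sequence reference: {exc}") from exc


def load_annotations(source: Union[str, bytes], aln: Alignment) -> AnnotationSet:
    """Parse, validate and bind a JSON annotation document.

    Every ``sequence`` reference is resolved to a record of ``aln``; every
    position is checked against that record's ungapped length; region
    intervals must satisfy ``start <= end`` and fit their coordinate space.
    A ``token`` that parses must agree with the ``position`` field.
    Unknown keys are preserved in ``attributes`` (they feed the pop-ups).
    """
    if isinstance(source, bytes):
        source = source.decode("utf-8")
    try:
        doc = json.loads(source)
    except json.JSONDecodeError as exc:
        raise AnnotationError(
            f"annotation JSON syntax error at line {exc.lineno}, column {exc.colno}: {exc.msg}"
        ) from exc
    if not isinstance(doc, dict):
        raise AnnotationError("annotation document must be a JSON object at top level")
    unknown_top = set(doc) - {"variants", "modifications", "regions"}
    if unknown_top:
        raise AnnotationError(
            "unknown top-level keys: " + ", ".join(sorted(unknown_top))
        )

    lengths = [rec.ungapped_length for rec in aln.records]
    aset = AnnotationSet()

    for i, obj in enumerate(doc.get("variants") or []):
        where = f"variants[{i}]"
        known, extra = _split_known(obj, _VARIANT_KEYS, where)
        ref = _require(obj, "sequence", where)
        pos = _as_position(_require(obj, "position", where), where)
        idx = _bind_ref(ref, aln, where)
        if pos > lengths[idx]:
            raise AnnotationError(
                f"{where}: position {pos} exceeds ungapped length {lengths[idx]} "
                f"of sequence '{aln.records[idx].label}'"
            )
        var = VariantAnnotation(**{**known, "attributes": extra}, seq_index=idx)
        if var.token:
            try:
                change = parse_change(var.token)
            except TokenError:
                pass  # display-only token
            else:
                if change.position != pos:
                    raise AnnotationError(
                        f"{where}: token {var.token!r} encodes position "
                        f"{change.position} but the position field is {pos}"
                    )
        aset.variants.append(var)

    for i, obj in enumerate(doc.get("modifications") or []):
        where = f"modifications[{i}]"
        known, extra = _split_known(obj, _MOD_KEYS, where)
        ref = _require(obj, "sequence", where)
        pos = _as_position(_require(obj, "position", where), where)
        idx = _bind_ref(ref, aln, where)
        if pos > lengths[idx]:
            raise AnnotationError(
                f"{where}: position {pos} exceeds ungapped length {lengths[idx]} "
                f"of sequence '{aln.records[idx].label}'"
            )
        aset.modifications.append(
            ModificationAnnotation(**{**known, "attributes": extra}, seq_index=idx)
        )

    for i, obj in enumerate(doc.get("regions") or []):
        where = f"regions[{i}]"
        known, extra = _split_known(obj, _REGION_KEYS, where)
        start = _as_position(_require(obj, "start", where), where)
        end = _as_position(_require(obj, "end", where), where)
        if start > end:
            raise AnnotationError(f"{where}: start {start} > end {end}")
        ref = obj.get("sequence", GLOBAL)
        if ref in (GLOBAL, None, "global"):
            if end > aln.n_columns:
                raise AnnotationError(
                    f"{where}: end column {end} exceeds alignment width {aln.n_columns}"
                )
            region = RegionAnnotation(
                **{**known, "sequence_ref": GLOBAL, "attributes": extra}, seq_index=None
            )
        else:
            idx = _bind_ref(ref, aln, where)
            if end > lengths[idx]:
                raise AnnotationError(
                    f"{where}: end {end} exceeds ungapped length {lengths[idx]} "
                    f"of sequence '{aln.records[idx].label}'"
                )
            region = RegionAnnotation(**{**known, "attributes": extra}, seq_index=idx)
        aset.regions.append(region)

    return aset


def index_by_column(aset: AnnotationSet, aln: Alignment) -> ColumnIndex:
    """Project every positional annotation onto its alignment column.

    Variants and modifications (not regions) are mapped through their
    sequence's position map into per-column buckets; within a bucket,
    entries are ordered by (sequence index, variants before modifications,
    insertion order).
    """
    pmaps: dict[int, object] = {}

    def pmap(idx: int):
        if idx not in pmaps:
            pmaps[idx] = build_position_map(aln, idx)
        return pmaps[idx]

    entries: list[tuple[int, int, int, int, str, object]] = []
    for order, var in enumerate(aset.variants):
        if var.seq_index is None:
            raise AnnotationError("annotation set is not bound; call load_annotations")
        col = ungapped_to_column(pmap(var.seq_index), var.position)
        entries.append((col, var.seq_index, 0, order, "variant", var))
    for order, mod in enumerate(aset.modifications):
        if mod.seq_index is None:
            raise AnnotationError("annotation set is not bound; call load_annotations")
        col = ungapped_to_column(pmap(mod.seq_index), mod.position)
        entries.append((col, mod.seq_index, 1, order, "modification", mod))

    buckets: dict[int, list[tuple[str, object]]] = {}
    for col, _seq, _rank, _order, kind, ann in sorted(
        entries, key=lambda e: (e[0], e[1], e[2], e[3])
    ):
        buckets.setdefault(col, []).append((kind, ann))
    return ColumnIndex(buckets=buckets)


def ortho_groups(index: ColumnIndex) -> list[OrthoGroup]:
    """Group co-located variants across sequences (orthologous variants).

    A column yields one group when its bucket holds variants from at least
    two distinct sequences; modifications never join, and several variants
    on a single sequence never form a group by themselves.  Groups come
    back sorted by column.
    """
    groups: list[OrthoGroup] = []
    for col in index.columns():
        variants = [ann for kind, ann in index.buckets[col] if kind == "variant"]
        if len({v.seq_index for v in variants}) >= 2:
            groups.append(OrthoGroup(column=col, members=tuple(variants)))
    return groups


def validate_change_against_sequence(
    var: VariantAnnotation, aln: Alignment
) -> list[str]:
    """Check that a variant token's reference letter matches the sequence.

    Returns a (possibly empty) list of warning strings; mismatches are
    never fatal because isoform or version drift between the annotation
    source and the aligned sequence is common.
    """
    if var.seq_index is None or not var.token:
        return []
    try:
        change = parse_change(var.token)
    except TokenError:
        return []
    rec = aln.records[var.seq_index]
    residues = rec.letters.replace("-", "")
    if not 1 <= change.position <= len(residues):
        return [
            f"token {var.token!r}: position {change.position} outside sequence "
            f"'{rec.label}' (length {len(residues)})"
        ]
    found = residues[change.position - 1]
    if found != change.ref:
        return [
            f"token {var.token!r}: expected {change.ref!r} at position "
            f"{change.position} of '{rec.label}', found {found!r}"
        ]
    return []


def collect_warnings(aset: AnnotationSet, aln: Alignment) -> list[str]:
    """Run the reference-letter consistency check over every variant."""
    warnings: list[str] = []
    for var in aset.variants:
        warnings.extend(validate_change_against_sequence(var, aln))
    return warnings
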