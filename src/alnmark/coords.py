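"""Gapped/ungapped coordinate maps and position search.

A residue lives at two addresses: its 1-based position in the ungapped
sequence (the coordinate HGVS-style tokens use — ``p.C4957Y`` means the
4957th residue) and the 1-based alignment column it occupies once gaps are
inserted.  :class:`PositionMap` holds both directions for one sequence;
columns where the sequence has a gap map to the :data:`GAP` sentinel rather
than to any integer, so gap positions can never leak into arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

from .errors import PositionError, SelectorError
from .io import Alignment

__all__ = [
    "GAP",
    "PositionMap",
    "build_position_map",
    "ungapped_to_column",
    "column_to_ungapped",
    "resolve_selector",
    "find_position",
]


class _GapSentinel:
    """Distinguished value marking a gap column; not an integer."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "GAP"

    def __bool__(self) -> bool:
        return False


GAP = _GapSentinel()


@dataclass(frozen=True)
class PositionMap:
    """Bidirectional 1-based map between residue positions and columns."""

    seq_index: int
    col_of_pos: tuple[int, ...]
    pos_of_col: tuple[Union[int, _GapSentinel], ...]
    ungapped_length: int

    @property
    def n_columns(self) -> int:
        return len(self.pos_of_col)


def build_position_map(aln: Alignment, seq_index: int) -> PositionMap:
    """Scan one record's letters once and build its :class:`PositionMap`."""
    if not 0 <= seq_index < len(aln.records):
        raise IndexError(
            f"sequence index {seq_index} out of range (alignment has {len(aln.records)} records)"
        )
    letters = aln.records[seq_index].letters
    col_of_pos: list[int] = []
    pos_of_col: list[Union[int, _GapSentinel]] = []
    pos = 0
    for col, ch in enumerate(letters, start=1):
        if ch == "-":
            pos_of_col.append(GAP)
        else:
            pos += 1
            col_of_pos.append(col)
            pos_of_col.append(pos)
    return PositionMap(
        seq_index=seq_index,
        col_of_pos=tuple(col_of_pos),
        pos_of_col=tuple(pos_of_col),
        ungapped_length=pos,
    )


def ungapped_to_column(pmap: PositionMap, pos: int) -> int:
    """Column of the ``pos``-th residue (both 1-based)."""
    if not 1 <= pos <= pmap.ungapped_length:
        raise PositionError(
            f"position {pos} beyond sequence: ungapped length is {pmap.ungapped_length}"
        )
    return pmap.col_of_pos[pos - 1]


def column_to_ungapped(pmap: PositionMap, col: int):
    """Residue position at alignment column ``col``, or :data:`GAP`."""
    if not 1 <= col <= pmap.n_columns:
        raise IndexError(f"column {col} out of range 1..{pmap.n_columns}")
    return pmap.pos_of_col[col - 1]


def resolve_selector(aln: Alignment, selector: Union[int, str]) -> int:
    """Resolve an integer index or a label to a unique record index.

    String matching is exact against labels and full headers first, then a
    case-insensitive unique prefix of the labels.  Ambiguity or no match
    raises :class:`SelectorError` listing the candidates.
    """
    if isinstance(selector, bool):
        raise SelectorError(f"invalid sequence selector {selector!r}")
    if isinstance(selector, int):
        if not 0 <= selector < len(aln.records):
            raise SelectorError(
                f"sequence index {selector} out of range (0..{len(aln.records) - 1})"
            )
        return selector

    text = str(selector).strip()
    exact = [
        i
        for i, rec in enumerate(aln.records)
        if rec.label == text or rec.header == text
    ]
    if len(exact) == 1:
        return exact[0]
    if len(exact) > 1:
        names = ", ".join(aln.records[i].label for i in exact)
        raise SelectorError(f"selector {text!r} is ambiguous: matches {names}")

    low = text.lower()
    prefix = [i for i, rec in enumerate(aln.records) if rec.label.lower().startswith(low)]
    if len(prefix) == 1:
        return prefix[0]
    if len(prefix) > 1:
        names = ", ".join(aln.records[i].label for i in prefix)
        raise SelectorError(f"selector {text!r} is ambiguous: matches {names}")
    raise SelectorError(
        f"selector {text!r} matches no sequence; labels are: "
        + ", ".join(aln.labels())
    )


def find_position(
    aln: Alignment, sequence_selector: Union[int, str], pos: int
) -> tuple[int, int]:
    """Locate the alignment column of residue ``pos`` in one sequence.

    Returns ``(seq_index, column)`` so a renderer or the CLI can jump
    straight to the cell — e.g. the 4th residue of the first protein.
    """
    idx = resolve_selector(aln, sequence_selector)
    pmap = build_position_map(aln, idx)
    return idx, ungapped_to_column(pmap, pos)
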