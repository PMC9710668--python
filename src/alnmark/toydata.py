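"""Deterministic synthetic fixtures with planted ground truth.

The generator copies a random ancestral sequence into every row of an
alignment and then inserts gaps independently per row, so each row keeps
the full ancestral residue content while its gapped coordinates diverge.
On top of that it plants:

* **variant pairs** — two variants on two distinct rows whose ungapped
  positions are recomputed through each row's own gap pattern so that they
  land on one shared alignment column.  These are the ground truth for
  co-located (orthologous) variant detection: native positions differ,
  columns coincide, exactly as with the human RYR2 residue-4957 / mouse
  Ryr2 residue-4956 pair.
* **lone variants** on columns of their own (must never join a group);
* random modifications and region intervals.

Everything is reproducible from the seed: same spec, same bytes.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field

from .errors import FixtureError
from .io import Alignment, read_fasta

__all__ = ["ToySpec", "Fixture", "PlantedGroup", "make_fixture"]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NUC = "ACGT"
_SPECIES = [
    "Homo sapiens",
    "Mus musculus",
    "Danio rerio",
    "Caenorhabditis elegans",
    "Drosophila melanogaster",
    "Rattus norvegicus",
    "Gallus gallus",
    "Xenopus laevis",
    "Bos taurus",
    "Canis familiaris",
    "Sus scrofa",
    "Macaca mulatta",
]
_MOD_TYPES = ["ubiquitination", "phosphorylation", "acetylation", "methylation"]
_REGION_COLORS = ["#c6dbef", "#fdd0a2", "#c7e9c0", "#dadaeb"]


@dataclass(frozen=True)
class ToySpec:
    """Parameters of one synthetic fixture."""

    n_sequences: int = 6
    ungapped_length: int = 120
    gap_rate: float = 0.1
    n_variant_pairs: int = 4
    n_lone_variants: int = 3
    n_modifications: int = 3
    n_regions: int = 2
    seed: int = 0
    alphabet: str = "protein"  # "protein" | "nucleotide"

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.ungapped_length < 1:
            raise FixtureError("need at least 1 sequence and length >= 1")
        if not 0 <= self.gap_rate < 1:
            raise FixtureError(f"gap_rate must be in [0, 1), got {self.gap_rate}")
        for name in ("n_variant_pairs", "n_lone_variants", "n_modifications", "n_regions"):
            if getattr(self, name) < 0:
                raise FixtureError(f"{name} must be >= 0")
        if self.alphabet not in ("protein", "nucleotide"):
            raise FixtureError(f"alphabet must be protein or nucleotide, got {self.alphabet!r}")


@dataclass(frozen=True)
class PlantedGroup:
    """Ground truth for one planted co-located variant pair."""

    column: int
    members: tuple[tuple[int, int, str], ...]  # (seq_index, position, token)


@dataclass(frozen=True)
class Fixture:
    fasta_text: str
    json_text: str
    groups: tuple[PlantedGroup, ...]
    lone_variants: tuple[tuple[int, int, str], ...] = ()

    @property
    def alignment(self) -> Alignment:
        return read_fasta(self.fasta_text)

    def truth_tsv(self) -> str:
        """Planted groups in the same TSV shape the orthovars command emits."""
        lines = ["column\tsequence\tposition\ttoken"]
        for grp in sorted(self.groups, key=lambda g: g.column):
            for seq_index, pos, token in grp.members:
                lines.append(f"{grp.column}\tseq{seq_index}\t{pos}\t{token}")
        return "\n".join(lines) + "\n"


def _headers(n: int) -> list[str]:
    out = []
    for i in range(n):
        species = _SPECIES[i % len(_SPECIES)]
        suffix = "" if i < len(_SPECIES) else f" isolate {i // len(_SPECIES) + 1}"
        out.append(f"toy{i + 1:03d} {species}{suffix}")
    return out


def make_fixture(spec: ToySpec) -> Fixture:
    """Generate (FASTA text, JSON annotation text, ground truth) for a spec.

    Raises :class:`FixtureError` when more planted columns are requested
    than the alignment can host.
    """
    rng = random.Random(spec.seed)
    L = spec.ungapped_length
    alphabet = _AA if spec.alphabet == "protein" else _NUC
    ancestor = "".join(rng.choice(alphabet) for _ in range(L))

    # Same gap COUNT per row (keeps the alignment rectangular and every
    # ungapped length equal to L), random gap placement per row.
    n_gaps = round(spec.gap_rate / (1.0 - spec.gap_rate) * L) if spec.gap_rate else 0
    n_cols = L + n_gaps
    gap_cols: list[set[int]] = []
    rows: list[str] = []
    for _ in range(spec.n_sequences):
        gaps = set(rng.sample(range(n_cols), n_gaps)) if n_gaps else set()
        gap_cols.append(gaps)
        letters = []
        it = iter(ancestor)
        for c in range(n_cols):
            letters.append("-" if c in gaps else next(it))
        rows.append("".join(letters))

    # Columns where at least two rows carry a residue can host a pair;
    # columns with at least one residue can host a lone variant.
    residue_rows = {
        c: [i for i in range(spec.n_sequences) if c not in gap_cols[i]]
        for c in range(n_cols)
    }
    pairable = [c for c, rs in residue_rows.items() if len(rs) >= 2]
    n_planted = spec.n_variant_pairs + spec.n_lone_variants
    usable = [c for c, rs in residue_rows.items() if len(rs) >= 1]
    if spec.n_variant_pairs > len(pairable) or n_planted > len(usable):
        raise FixtureError(
            f"cannot plant {spec.n_variant_pairs} pairs + {spec.n_lone_variants} "
            f"lone variants: only {len(pairable)} pairable / {len(usable)} usable "
            f"columns in a {n_cols}-column alignment"
        )
    pair_columns = rng.sample(pairable, spec.n_variant_pairs)
    remaining = [c for c in usable if c not in set(pair_columns)]
    if spec.n_lone_variants > len(remaining):
        raise FixtureError("not enough free columns for lone variants")
    lone_columns = rng.sample(remaining, spec.n_lone_variants)

    def pos_in_row(row: int, col0: int) -> int:
        # 1-based ungapped position of 0-based column col0 in a row.
        return sum(1 for c in range(col0 + 1) if c not in gap_cols[row])

    def token_for(row: int, pos: int) -> str:
        ref = rows[row].replace("-", "")[pos - 1]
        alt = rng.choice([ch for ch in alphabet if ch != ref])
        if spec.alphabet == "protein":
            return f"p.{ref}{pos}{alt}"
        return f"c.{pos}{ref}>{alt}"

    variants: list[dict] = []
    groups: list[PlantedGroup] = []
    for k, col0 in enumerate(pair_columns):
        r1, r2 = rng.sample(residue_rows[col0], 2)
        members = []
        for row in (r1, r2):
            pos = pos_in_row(row, col0)
            token = token_for(row, pos)
            members.append((row, pos, token))
            variants.append(
                {
                    "sequence": row,
                    "position": pos,
                    "token": token,
                    "source": "toydata",
                    "id": f"pair{k + 1}",
                    "note": f"planted pair {k + 1}",
                }
            )
        groups.append(PlantedGroup(column=col0 + 1, members=tuple(members)))

    lone: list[tuple[int, int, str]] = []
    for k, col0 in enumerate(lone_columns):
        row = rng.choice(residue_rows[col0])
        pos = pos_in_row(row, col0)
        token = token_for(row, pos)
        lone.append((row, pos, token))
        variants.append(
            {
                "sequence": row,
                "position": pos,
                "token": token,
                "source": "toydata",
                "id": f"lone{k + 1}",
                "note": f"planted lone variant {k + 1}",
            }
        )

    modifications = []
    for k in range(spec.n_modifications):
        row = rng.randrange(spec.n_sequences)
        modifications.append(
            {
                "sequence": row,
                "position": rng.randint(1, L),
                "type": rng.choice(_MOD_TYPES),
                "note": f"planted modification {k + 1}",
            }
        )

    regions = []
    for k in range(spec.n_regions):
        row = rng.randrange(spec.n_sequences)
        start = rng.randint(1, L)
        end = rng.randint(start, min(L, start + max(1, L // 4)))
        regions.append(
            {
                "sequence": row,
                "start": start,
                "end": end,
                "label": f"domain {k + 1}",
                "color": _REGION_COLORS[k % len(_REGION_COLORS)],
            }
        )

    headers = _headers(spec.n_sequences)
    fasta = "".join(
        f">{hdr}\n" + "\n".join(row[i : i + 60] for i in range(0, len(row), 60)) + "\n"
        for hdr, row in zip(headers, rows)
    )
    doc = {"variants": variants, "modifications": modifications, "regions": regions}
    return Fixture(
        fasta_text=fasta,
        json_text=json.dumps(doc, indent=1, sort_keys=True) + "\n",
        groups=tuple(sorted(groups, key=lambda g: g.column)),
        lone_variants=tuple(lone),
    )
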