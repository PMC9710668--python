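"""Colour-scheme registry: 13 predefined palettes.

Twelve protein schemes (clustal, clustalx, zappo, taylor, hydrophobicity,
helix/strand/turn propensity, buried index, cinema, lesk, mae) plus one
nucleotide scheme — the classic palette family shared by Jalview-style
alignment viewers.  Every scheme is total over its family alphabet plus the
gap character, so a renderer can look up any cell without a fallback path.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import SchemeError

__all__ = ["ColorScheme", "list_schemes", "get_scheme", "PROTEIN_ALPHABET", "NUCLEOTIDE_ALPHABET"]

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
NUCLEOTIDE_ALPHABET = "ACGTUN"

_GAP_COLOR = "#ffffff"
_DEFAULT = "#ffffff"


@dataclass(frozen=True)
class ColorScheme:
    """A named, total mapping from residue letters to CSS colours."""

    name: str
    family: str  # "protein" | "nucleotide"
    colors: dict

    @property
    def alphabet(self) -> str:
        return PROTEIN_ALPHABET if self.family == "protein" else NUCLEOTIDE_ALPHABET

    def color_of(self, letter: str) -> str:
        """Colour for any letter; letters outside the alphabet render white."""
        return self.colors.get(letter, _DEFAULT)


def _scheme(name: str, family: str, groups: dict[str, str]) -> ColorScheme:
    colors: dict[str, str] = {}
    for letters, color in groups.items():
        for ch in letters:
            colors[ch] = color
    alphabet = PROTEIN_ALPHABET if family == "protein" else NUCLEOTIDE_ALPHABET
    for ch in alphabet:
        colors.setdefault(ch, _DEFAULT)
    colors.setdefault("-", _GAP_COLOR)
    return ColorScheme(name=name, family=family, colors=colors)


_REGISTRY: dict[str, ColorScheme] = {}

for s in [
    # Classic terminal-Clustal grouping: hydrophobic red, acidic blue,
    # basic magenta, polar green.
    _scheme("clustal", "protein", {
        "AVFPMILW": "#e06c6c", "DE": "#6c8fe0", "RK": "#d66cd6",
        "STYHCNGQ": "#6cd66c", "X": "#c8c8c8",
    }),
    _scheme("clustalx", "protein", {
        "AILMFWV": "#80a0f0", "KR": "#f01505", "ED": "#c048c0",
        "NQST": "#15c015", "C": "#f08080", "G": "#f09048",
        "P": "#c0c000", "HY": "#15a4a4", "X": "#c8c8c8",
    }),
    _scheme("zappo", "protein", {
        "ILVAM": "#ffafaf", "FWY": "#ffc800", "KRH": "#6464ff",
        "DE": "#ff0000", "STNQ": "#00ff00", "PG": "#ff00ff",
        "C": "#ffff00",
    }),
    _scheme("taylor", "protein", {
        "A": "#ccff00", "R": "#0000ff", "N": "#cc00ff", "D": "#ff0000",
        "C": "#ffff00", "Q": "#ff00cc", "E": "#ff0066", "G": "#ff9900",
        "H": "#0066ff", "I": "#66ff00", "L": "#33ff00", "K": "#6600ff",
        "M": "#00ff00", "F": "#00ff66", "P": "#ffcc00", "S": "#ff3300",
        "T": "#ff6600", "W": "#00ccff", "Y": "#00ffcc", "V": "#99ff00",
    }),
    # Kyte-Doolittle hydropathy, red (hydrophobic) to blue (hydrophilic).
    _scheme("hydrophobicity", "protein", {
        "I": "#ff0000", "V": "#f60009", "L": "#ea0015", "F": "#cb0034",
        "C": "#c2003d", "M": "#b0004f", "A": "#ad0052", "G": "#6a0095",
        "T": "#61009e", "S": "#5e00a1", "W": "#5b00a4", "Y": "#4f00b0",
        "P": "#4600b9", "H": "#1500ea", "E": "#0c00f3", "Q": "#0c00f3",
        "D": "#0c00f3", "N": "#0c00f3", "K": "#0000ff", "R": "#0000ff",
        "X": "#680093",
    }),
    # Chou-Fasman style propensities, magenta (high) to green (low).
    _scheme("helix-propensity", "protein", {
        "E": "#ff00ff", "M": "#ef10ef", "A": "#e718e7", "L": "#ae51ae",
        "K": "#a05fa0", "F": "#986798", "Q": "#926d92", "I": "#8a758a",
        "W": "#8a758a", "V": "#857a85", "D": "#778877", "H": "#708f70",
        "R": "#6f906f", "T": "#38c738", "S": "#24db24", "C": "#23dc23",
        "Y": "#21de21", "P": "#13ec13", "N": "#1be41b", "G": "#00ff00",
        "X": "#758a75",
    }),
    _scheme("strand-propensity", "protein", {
        "V": "#ff00ff", "I": "#ec13ec", "Y": "#d53ad5", "C": "#c848c8",
        "W": "#c05fc0", "F": "#be61be", "T": "#b567b5", "L": "#a57ba5",
        "M": "#9d849d", "Q": "#8c8c8c", "R": "#858585", "A": "#787878",
        "G": "#4949b6", "K": "#4747b8", "S": "#4343bc", "H": "#3b3bc4",
        "N": "#2c2cd3", "P": "#2323dc", "D": "#2121de", "E": "#0000ff",
        "X": "#797979",
    }),
    _scheme("turn-propensity", "protein", {
        "N": "#ff0000", "G": "#ff0000", "P": "#f20d0d", "D": "#e81717",
        "S": "#e11e1e", "C": "#a85757", "Y": "#9d6262", "K": "#7e8181",
        "Q": "#778888", "W": "#738c8c", "T": "#738c8c", "R": "#708f8f",
        "H": "#708f8f", "E": "#5ba4a4", "A": "#2cd3d3", "F": "#1ee1e1",
        "M": "#1ee1e1", "L": "#1ce3e3", "V": "#07f8f8", "I": "#00ffff",
        "X": "#7c8383",
    }),
    # Burial preference, blue (buried) to green (exposed).
    _scheme("buried-index", "protein", {
        "C": "#0000ff", "I": "#0054ab", "V": "#005fa0", "L": "#007b84",
        "F": "#008778", "M": "#009768", "G": "#009d62", "A": "#00a35c",
        "W": "#00a857", "S": "#00d52a", "H": "#00d52a", "T": "#00db24",
        "P": "#00e01f", "Y": "#00e619", "N": "#00eb14", "D": "#00eb14",
        "Q": "#00f10e", "E": "#00f10e", "K": "#00fa05", "R": "#00fc03",
        "X": "#00b649",
    }),
    _scheme("cinema", "protein", {
        "HKR": "#00ffff", "DE": "#ff0000", "STNQ": "#00ff00",
        "AVLIM": "#bbbbbb", "FWY": "#ff00ff", "PG": "#996600",
        "C": "#ffff00", "X": "#666666",
    }),
    _scheme("lesk", "protein", {
        "GAST": "#ffa500", "CVILPFYMW": "#00ff00", "NQH": "#ff00ff",
        "DE": "#ff0000", "KR": "#0000ff",
    }),
    _scheme("mae", "protein", {
        "ILV": "#add8e6", "FWY": "#87cefa", "AG": "#d3f0d3",
        "C": "#f4f49c", "DE": "#f08080", "KR": "#9cc3f4",
        "NQH": "#c3f4c3", "ST": "#c9f4a5", "PM": "#f4c9a5",
    }),
    _scheme("nucleotide", "nucleotide", {
        "A": "#64f73f", "C": "#ffb340", "G": "#eb413c",
        "TU": "#3c88ee", "N": "#ffffff",
    }),
]:
    _REGISTRY[s.name] = s


def list_schemes() -> list[str]:
    """Names of the 13 predefined colour schemes, in stable registry order."""
    return list(_REGISTRY)


def get_scheme(name: str) -> ColorScheme:
    """Look up a scheme by name, case-insensitively."""
    key = name.strip().lower()
    if key not in _REGISTRY:
        raise SchemeError(
            f"unknown colour scheme {name!r}; valid schemes: " + ", ".join(_REGISTRY)
        )
    return _REGISTRY[key]


def default_scheme_for(alphabet: str) -> ColorScheme:
    """Pick the default family scheme for a detected alphabet."""
    return get_scheme("nucleotide" if alphabet == "nucleotide" else "clustal")
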