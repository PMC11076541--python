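"""IUPAC nucleotide-ambiguity algebra.

An amplicon consensus sequence from a genome that carries several divergent
copies of a locus shows an IUPAC ambiguity code wherever the copies disagree.
This module provides the exact algebra on those codes: expansion of a symbol
to its nucleotide set, the inverse consensus encoding, classification of a
site by how many nucleotides alternate there (invariant / SND / SNT / SNP),
and the transition-versus-transversion type of a dimorphic site.

Terminology follows the intragenomic-heterogeneity literature: a *single
nucleotide dimorphism* (SND) is a site where exactly two nucleotides
alternate among the copies within one genome; SNT and SNP denote three- and
four-fold alternation, implying at least three or four locus copies.
"""

from __future__ import annotations

from typing import FrozenSet, Iterable, Optional

GAP = "-"

#: symbol -> nucleotide subset of {A,C,G,T}; the gap expands to nothing.
EXPANSION: dict[str, FrozenSet[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    GAP: frozenset(),
}

_ENCODE: dict[FrozenSet[str], str] = {v: k for k, v in EXPANSION.items() if k != GAP}

#: The two transition pairs; the remaining four unordered pairs are transversions.
TRANSITION_PAIRS = (frozenset("AG"), frozenset("CT"))

SYMBOLS = tuple(s for s in EXPANSION if s != GAP)

MORPHISM_LABELS = ("invariant", "SND", "SNT", "SNP")


class AmbiguityError(ValueError):
    """Raised for symbols or nucleotide sets outside the IUPAC algebra."""


def normalize_symbol(symbol: str, position: Optional[int] = None) -> str:
    """Map one input character to its canonical code.

    Case-insensitive; RNA 'U'/'u' maps to 'T'. Anything outside the 15 IUPAC
    symbols plus the gap '-' is rejected, naming the character and (when
    given) its 1-based position.
    """
    s = symbol.upper()
    if s == "U":
        s = "T"
    if s not in EXPANSION:
        where = f" at position {position}" if position is not None else ""
        raise AmbiguityError(f"illegal nucleotide code {symbol!r}{where}")
    return s


def expand_code(symbol: str, position: Optional[int] = None) -> FrozenSet[str]:
    """Return the nucleotide subset a symbol stands for (e.g. Y -> {C,T}).

    The gap '-' returns the empty set: it is a non-nucleotide code, never a
    wildcard.
    """
    return EXPANSION[normalize_symbol(symbol, position)]


def encode_consensus(nucs: Iterable[str]) -> str:
    """Inverse of :func:`expand_code`: encode a nonempty nucleotide subset.

    ``encode_consensus(expand_code(x)) == x`` for every non-gap symbol.
    """
    canon = frozenset(normalize_symbol(n) for n in nucs)
    if not canon:
        raise AmbiguityError("cannot encode an empty nucleotide set")
    if not canon <= frozenset("ACGT"):
        bad = sorted(canon - frozenset("ACGT"))
        raise AmbiguityError(f"not plain nucleotides: {bad}")
    return _ENCODE[canon]


def classify_morphism(nucs: Iterable[str]) -> str:
    """Classify a site by the number of alternating nucleotides.

    1 -> 'invariant', 2 -> 'SND', 3 -> 'SNT', 4 -> 'SNP'.
    """
    size = len(frozenset(normalize_symbol(n) for n in nucs))
    if size == 0:
        raise AmbiguityError("cannot classify an empty nucleotide set")
    return MORPHISM_LABELS[size - 1]


def substitution_type(pair: Iterable[str]) -> str:
    """'transition' for {A,G} and {C,T}; 'transversion' for the other four pairs."""
    canon = frozenset(normalize_symbol(n) for n in pair)
    if len(canon) != 2 or not canon <= frozenset("ACGT"):
        raise AmbiguityError(
            f"substitution type needs exactly two distinct nucleotides, got {sorted(canon)}"
        )
    return "transition" if canon in TRANSITION_PAIRS else "transversion"
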