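"""Codon-level effect of ambiguous sites in a protein-coding segment.

Given the position of a sequenced segment inside its ORF, each ambiguous
site maps to a codon index and an intra-codon position. A codon carrying
ambiguity resolves into several unambiguous codons; translating all of them
tells whether the underlying nucleotide dimorphism is synonymous or changes
the amino acid. Two tallies of "affected" codons are kept: per isolate
(nonsynonymous within at least one sequence on its own) and pooled (the
cross-sequence union of alternatives at each site, the way substitutions
from many isolates are displayed stacked on one reference sequence).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import FrozenSet, Optional, Sequence

from Bio.Data import CodonTable

from .iupac import GAP, encode_consensus, expand_code
from .scan import AmbiguousSequence, SiteRecord

#: supported genetic codes: the standard nuclear code and the alternative
#: yeast nuclear code (CTG read as Ser), relevant for CUG-Ser clade yeasts.
CODE_TABLES = {"standard": 1, "alternative_yeast": 12}


@dataclass(frozen=True)
class CodingFrame:
    """Anchors a segment inside its ORF; positions are 1-based."""

    orf_start_position: int
    code_table: str = "standard"

    def __post_init__(self) -> None:
        if self.orf_start_position < 1:
            raise ValueError("orf_start_position must be >= 1")
        if self.code_table not in CODE_TABLES:
            raise ValueError(
                f"unknown code table {self.code_table!r}; choose from {sorted(CODE_TABLES)}"
            )

    def codon_index(self, segment_position: int) -> int:
        return (self.orf_start_position + segment_position - 2) // 3 + 1

    def codon_position(self, segment_position: int) -> int:
        return (self.orf_start_position + segment_position - 2) % 3 + 1


@dataclass(frozen=True)
class CodonEffect:
    codon_index: int
    codon: str
    variable_positions_in_codon: FrozenSet[int]
    resolutions: tuple[str, ...]
    amino_acids: FrozenSet[str]
    effect: str  # none | synonymous | nonsynonymous | unresolvable


@dataclass
class CodonEffectTable:
    effects: list[CodonEffect]
    n_codons_total: int
    n_affected_union: int
    n_affected_per_sequence: int
    n_synonymous_union: int
    third_position_fraction: Optional[float]
    excluded_partial_positions: list[int] = field(default_factory=list)

    @property
    def pct_affected(self) -> float:
        if not self.n_codons_total:
            return 0.0
        return 100.0 * self.n_affected_union / self.n_codons_total


def _translate(codon: str, table_id: int) -> str:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


def map_to_codons(
    sites: Sequence[SiteRecord], frame: CodingFrame
) -> list[tuple[int, int, int]]:
    """Map site positions to ``(segment_position, codon_index, codon_position)``."""
    return [
        (r.position, frame.codon_index(r.position), frame.codon_position(r.position))
        for r in sites
    ]


def classify_codon(
    codon: str, code_table: str = "standard", codon_index: int = 0
) -> CodonEffect:
    """Resolve one (possibly ambiguous) codon and classify its effect.

    A codon containing a gap cannot be resolved and is marked
    ``unresolvable``; callers exclude such codons from totals.
    """
    if len(codon) != 3:
        raise ValueError(f"codon must have length 3, got {codon!r}")
    if GAP in codon:
        return CodonEffect(
            codon_index=codon_index,
            codon=codon,
            variable_positions_in_codon=frozenset(),
            resolutions=(),
            amino_acids=frozenset(),
            effect="unresolvable",
        )
    table_id = CODE_TABLES[code_table]
    expansions = [expand_code(c, position=i) for i, c in enumerate(codon, start=1)]
    variable = frozenset(i + 1 for i, e in enumerate(expansions) if len(e) > 1)
    resolutions = tuple(
        "".join(c) for c in itertools.product(*(sorted(e) for e in expansions))
    )
    amino_acids = frozenset(_translate(r, table_id) for r in resolutions)
    if not variable:
        effect = "none"
    elif len(amino_acids) == 1:
        effect = "synonymous"
    else:
        effect = "nonsynonymous"
    return CodonEffect(
        codon_index=codon_index,
        codon=codon.upper().replace("U", "T"),
        variable_positions_in_codon=variable,
        resolutions=resolutions,
        amino_acids=amino_acids,
        effect=effect,
    )


def summarize_coding(
    seqs: Sequence[AmbiguousSequence], frame: CodingFrame
) -> CodonEffectTable:
    """Codon-effect table for a set of equal-length, gap-free coding sequences.

    Only codons lying entirely inside the segment enter the totals; leading
    or trailing partial codons are listed as excluded positions. The
    ``union`` tally classifies, per codon, the site-wise union of all
    sequences' nucleotides; the ``per_sequence`` tally counts codons that are
    nonsynonymous within at least one single sequence.
    """
    if not seqs:
        raise ValueError("summarize_coding needs at least one sequence")
    length = len(seqs[0])
    bad = [s.id for s in seqs if len(s) != length]
    if bad:
        raise ValueError(f"coding sequences differ in length: {bad}")
    for s in seqs:
        if GAP in s.residues:
            raise ValueError(f"sequence {s.id!r} contains gaps; ungapped input required")

    # first segment position opening a codon, and last closing one
    first = next(
        (p for p in range(1, length + 1) if frame.codon_position(p) == 1), None
    )
    effects: list[CodonEffect] = []
    excluded: list[int] = []
    n_union = n_per_seq = n_syn_union = 0
    var_positions: list[int] = []

    if first is not None:
        last_full_start = first + 3 * ((length - first + 1) // 3) - 3
    else:
        last_full_start = 0
    excluded.extend(p for p in range(1, (first or length + 1)))
    if first is not None:
        excluded.extend(range(last_full_start + 3, length + 1))

    unions = None
    if first is not None and last_full_start >= first:
        expansions = [s.expansions() for s in seqs]
        unions = [frozenset().union(*(e[j] for e in expansions)) for j in range(length)]
        for start in range(first, last_full_start + 1, 3):
            idx = frame.codon_index(start)
            union_codon = "".join(encode_consensus(unions[start - 1 + o]) for o in range(3))
            union_eff = classify_codon(union_codon, frame.code_table, codon_index=idx)
            effects.append(union_eff)
            if union_eff.effect == "nonsynonymous":
                n_union += 1
            elif union_eff.effect == "synonymous":
                n_syn_union += 1
            if any(
                classify_codon(
                    s.residues[start - 1 : start + 2], frame.code_table, codon_index=idx
                ).effect
                == "nonsynonymous"
                for s in seqs
            ):
                n_per_seq += 1
        for p in range(1, length + 1):
            if len(unions[p - 1]) > 1:
                var_positions.append(p)

    third_fraction = None
    if var_positions:
        third_fraction = sum(
            1 for p in var_positions if frame.codon_position(p) == 3
        ) / len(var_positions)

    n_total = len(effects)
    return CodonEffectTable(
        effects=effects,
        n_codons_total=n_total,
        n_affected_union=n_union,
        n_affected_per_sequence=n_per_seq,
        n_synonymous_union=n_syn_union,
        third_position_fraction=third_fraction,
        excluded_partial_positions=excluded,
    )
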