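"""Per-position variability census of ambiguity-coded sequences and alignments.

The census answers the questions a heterogeneity survey asks of an amplicon
consensus: how many sites are variable, of which morphism class (SND / SNT /
SNP), how the dimorphic sites split into transitions and transversions, where
indel columns fall, and whether the variable sites cluster into blocks.

All reported coordinates are 1-based inclusive.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Optional, Sequence

from .iupac import (
    GAP,
    AmbiguityError,
    classify_morphism,
    expand_code,
    normalize_symbol,
    substitution_type,
)


@dataclass(frozen=True)
class AmbiguousSequence:
    """An IUPAC-coded nucleotide sequence (optionally aligned, with gaps).

    ``coordinate_offset`` is the 1-based position of the first residue in an
    external reference frame (e.g. ORF coordinates); it defaults to 1 and is
    used only by downstream coordinate mapping, never by the scan itself.
    """

    id: str
    residues: str
    coordinate_offset: int = 1

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        if self.coordinate_offset < 1:
            raise ValueError("coordinate_offset must be >= 1")
        canon = "".join(
            normalize_symbol(c, position=i) for i, c in enumerate(self.residues, start=1)
        )
        object.__setattr__(self, "residues", canon)

    def __len__(self) -> int:
        return len(self.residues)

    def expansions(self) -> list[FrozenSet[str]]:
        return [expand_code(c) for c in self.residues]

    @property
    def n_nongap(self) -> int:
        return sum(1 for c in self.residues if c != GAP)


@dataclass(frozen=True)
class SiteRecord:
    position: int
    observed: FrozenSet[str]
    morphism: str
    substitution: Optional[str]
    is_indel_column: bool = False
    majority_called: bool = False


@dataclass
class DiversityCensus:
    n_sites_total: int
    n_variable: int
    n_SND: int
    n_SNT: int
    n_SNP: int
    n_transitions: int
    n_transversions: int
    n_indel_columns: int
    per_sequence_counts: dict[str, int] = field(default_factory=dict)
    per_sequence_indel_events: dict[str, int] = field(default_factory=dict)

    @property
    def pct_variable(self) -> float:
        """Percent variable sites over the non-indel denominator, full precision."""
        denom = self.n_sites_total - self.n_indel_columns
        return 100.0 * self.n_variable / denom if denom else 0.0

    @property
    def pct_variable_rounded(self) -> int:
        """Headline percent, rounded half away from zero."""
        return _round_half_away(self.pct_variable)

    def as_dict(self) -> dict:
        return {
            "n_sites_total": self.n_sites_total,
            "n_variable": self.n_variable,
            "pct_variable": self.pct_variable,
            "pct_variable_rounded": self.pct_variable_rounded,
            "n_SND": self.n_SND,
            "n_SNT": self.n_SNT,
            "n_SNP": self.n_SNP,
            "n_transitions": self.n_transitions,
            "n_transversions": self.n_transversions,
            "n_indel_columns": self.n_indel_columns,
            "per_sequence_counts": dict(self.per_sequence_counts),
            "per_sequence_indel_events": dict(self.per_sequence_indel_events),
        }


@dataclass(frozen=True)
class VariabilityBlock:
    label: str
    start: int
    end: int
    site_count: int


def _round_half_away(x: float) -> int:
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _roman(n: int) -> str:
    numerals = [
        (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
        (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
        (5, "V"), (4, "IV"), (1, "I"),
    ]
    out = []
    for value, sym in numerals:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


def _census_from_columns(
    columns: Sequence[FrozenSet[str]],
    indel_flags: Sequence[bool],
    seqs: Sequence[AmbiguousSequence],
) -> tuple[list[SiteRecord], DiversityCensus]:
    records: list[SiteRecord] = []
    n_snd = n_snt = n_snp = n_ti = n_tv = 0
    for pos, (union, has_gap) in enumerate(zip(columns, indel_flags), start=1):
        if len(union) <= 1 and not has_gap:
            continue
        morphism = classify_morphism(union) if union else "invariant"
        sub = None
        if morphism == "SND":
            sub = substitution_type(union)
            n_snd += 1
            if sub == "transition":
                n_ti += 1
            else:
                n_tv += 1
        elif morphism == "SNT":
            n_snt += 1
        elif morphism == "SNP":
            n_snp += 1
        if len(union) > 1 or has_gap:
            records.append(
                SiteRecord(
                    position=pos,
                    observed=union,
                    morphism=morphism,
                    substitution=sub,
                    is_indel_column=has_gap,
                )
            )
    per_seq = {
        s.id: sum(1 for e in s.expansions() if len(e) > 1) for s in seqs
    }
    per_seq_indels = {
        s.id: sum(1 for run, grp in itertools.groupby(s.residues) if run == GAP)
        for s in seqs
    }
    census = DiversityCensus(
        n_sites_total=len(columns),
        n_variable=n_snd + n_snt + n_snp,
        n_SND=n_snd,
        n_SNT=n_snt,
        n_SNP=n_snp,
        n_transitions=n_ti,
        n_transversions=n_tv,
        n_indel_columns=sum(indel_flags),
        per_sequence_counts=per_seq,
        per_sequence_indel_events=per_seq_indels,
    )
    return records, census


def scan_sequence(seq: AmbiguousSequence) -> tuple[list[SiteRecord], DiversityCensus]:
    """Census of a single consensus sequence: one record per ambiguous position."""
    cols = seq.expansions()
    gaps = [c == GAP for c in seq.residues]
    return _census_from_columns(cols, gaps, [seq])


def scan_alignment(
    seqs: Sequence[AmbiguousSequence],
) -> tuple[list[SiteRecord], DiversityCensus]:
    """Column-wise census of pre-aligned, equal-length sequences.

    A column is variable iff the union of the per-sequence expansions has size
    greater than one; gaps never enter the union but flag the column as an
    indel column, counted separately.
    """
    if not seqs:
        raise ValueError("scan_alignment needs at least one sequence")
    length = len(seqs[0])
    bad = [s.id for s in seqs if len(s) != length]
    if bad:
        raise ValueError(
            f"alignment length mismatch: {bad} differ from {seqs[0].id!r} (length {length})"
        )
    expansions = [s.expansions() for s in seqs]
    columns: list[FrozenSet[str]] = []
    indel_flags: list[bool] = []
    for j in range(length):
        union: FrozenSet[str] = frozenset()
        has_gap = False
        for i, s in enumerate(seqs):
            if s.residues[j] == GAP:
                has_gap = True
            else:
                union = union | expansions[i][j]
        columns.append(union)
        indel_flags.append(has_gap)
    return _census_from_columns(columns, indel_flags, seqs)


def detect_blocks(
    sites: Sequence[SiteRecord],
    max_gap: int = 10,
    min_block_sites: int = 2,
) -> list[VariabilityBlock]:
    """Group variable sites into blocks of nearby positions.

    A block is a maximal run of variable sites in which consecutive member
    positions are at most ``max_gap`` apart; runs with fewer than
    ``min_block_sites`` sites are dropped. Blocks are labelled with Roman
    numerals in positional order, matching the convention of naming variable
    regions I, II, III, ... along a barcode.
    """
    if max_gap < 0 or min_block_sites < 1:
        raise ValueError("max_gap must be >= 0 and min_block_sites >= 1")
    positions = [r.position for r in sites if len(r.observed) > 1]
    if positions != sorted(positions):
        raise ValueError("site records must be sorted by position")
    blocks: list[VariabilityBlock] = []
    run: list[int] = []

    def flush() -> None:
        if len(run) >= min_block_sites:
            blocks.append(
                VariabilityBlock(
                    label=_roman(len(blocks) + 1),
                    start=run[0],
                    end=run[-1],
                    site_count=len(run),
                )
            )

    for p in positions:
        if run and p - run[-1] > max_gap:
            flush()
            run = []
        run.append(p)
    if run:
        flush()
    # relabel in case earlier runs were dropped
    return [
        VariabilityBlock(_roman(i + 1), b.start, b.end, b.site_count)
        for i, b in enumerate(blocks)
    ]


def pairwise_census(
    a: AmbiguousSequence,
    b: AmbiguousSequence,
    distance_model: str = "expected_mismatch",
) -> float:
    """Distance in [0,1] between two equal-length ambiguity-coded sequences.

    ``expected_mismatch``: at each site, the probability that two uniform
    draws from the respective expansions differ, averaged over sites where
    neither sequence has a gap. ``incompatibility``: a site contributes 1 only
    when the expansions are disjoint (no shared resolution). For unambiguous
    sequences both reduce to the Hamming p-distance.
    """
    if len(a) != len(b):
        raise ValueError(
            f"pairwise_census needs equal lengths: {a.id!r}={len(a)}, {b.id!r}={len(b)}"
        )
    if distance_model not in ("expected_mismatch", "incompatibility"):
        raise ValueError(f"unknown distance model {distance_model!r}")
    total = 0.0
    n = 0
    for ea, eb in zip(a.expansions(), b.expansions()):
        if not ea or not eb:
            continue
        n += 1
        if distance_model == "incompatibility":
            total += 1.0 if ea.isdisjoint(eb) else 0.0
        else:
            shared = len(ea & eb)
            total += 1.0 - shared / (len(ea) * len(eb))
    return total / n if n else 0.0
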