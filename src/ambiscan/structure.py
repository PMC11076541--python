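"""Secondary-structure context of variable sites.

rRNA barcode segments fold into hairpin-stem loops; whether a variable site
sits in a loop or in a paired (double-helical) region constrains which
substitutions the structure tolerates. Structures enter as Vienna
dot-bracket strings (folding itself is upstream and out of scope). At a
paired site the substitution can still be structurally silent when every
alternative base keeps a legal pairing — Watson–Crick or G·U wobble — with
the partner strand; that is the wobble-neutrality test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional

from .scan import AmbiguousSequence

#: legal RNA pairs (on the DNA alphabet, T standing for U): Watson-Crick + G·U wobble.
LEGAL_PAIRS = frozenset({frozenset("AT"), frozenset("CG"), frozenset("GT")})


@dataclass(frozen=True)
class SecondaryStructure:
    dotbracket: str
    pair_map: Dict[int, int] = field(hash=False)

    def __len__(self) -> int:
        return len(self.dotbracket)

    def partner(self, position: int) -> Optional[int]:
        return self.pair_map.get(position)

    def is_paired(self, position: int) -> bool:
        return position in self.pair_map


@dataclass
class SiteContextReport:
    contexts: Dict[int, str]  # position -> "loop" | "paired"
    loop_fraction_of_variable_sites: Optional[float]
    wobble_neutral_fraction: Optional[float] = None
    wobble_neutral_fraction_strict: Optional[float] = None

    @property
    def empty(self) -> bool:
        return not self.contexts


def parse_dotbracket(s: str) -> SecondaryStructure:
    """Stack-match a dot-bracket string into a symmetric 1-based pair map.

    Single bracket tier only; pseudoknots are unsupported.
    """
    pair_map: Dict[int, int] = {}
    stack: list[int] = []
    for i, c in enumerate(s, start=1):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pair_map[i] = j
            pair_map[j] = i
        elif c != ".":
            raise ValueError(f"illegal structure character {c!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return SecondaryStructure(dotbracket=s, pair_map=pair_map)


def site_context(
    struct: SecondaryStructure,
    sites: Iterable[int],
    seq: Optional[AmbiguousSequence] = None,
) -> SiteContextReport:
    """Label sites loop/paired; with a sequence, also score wobble neutrality.

    ``wobble_neutral_fraction`` is the share of *paired* variable sites whose
    verdict from :func:`wobble_check` is neutral (existential contract);
    the strict variant requires every base-pair combination to be legal.
    Fractions are ``None`` when their denominator is empty.
    """
    positions = sorted(set(sites))
    out_of_range = [p for p in positions if not 1 <= p <= len(struct)]
    if out_of_range:
        raise ValueError(f"positions outside structure of length {len(struct)}: {out_of_range}")
    contexts = {p: ("paired" if struct.is_paired(p) else "loop") for p in positions}
    n = len(positions)
    loop_fraction = (
        sum(1 for c in contexts.values() if c == "loop") / n if n else None
    )
    neutral = strict = None
    if seq is not None:
        paired = [p for p in positions if struct.is_paired(p)]
        if paired:
            verdicts = [wobble_check(seq, struct, p) for p in paired]
            strict_verdicts = [wobble_check(seq, struct, p, mode="universal") for p in paired]
            neutral = sum(1 for v in verdicts if v == "neutral") / len(paired)
            strict = sum(1 for v in strict_verdicts if v == "neutral") / len(paired)
    return SiteContextReport(
        contexts=contexts,
        loop_fraction_of_variable_sites=loop_fraction,
        wobble_neutral_fraction=neutral,
        wobble_neutral_fraction_strict=strict,
    )


def wobble_check(
    seq: AmbiguousSequence,
    struct: SecondaryStructure,
    position: int,
    mode: str = "existential",
) -> str:
    """Classify a site as ``neutral``, ``disruptive`` or ``unpaired``.

    Existential contract (default): every base in the site's expansion must
    form a legal pair with *at least one* base of the partner's expansion.
    Universal contract: every combination of site base and partner base must
    be a legal pair.
    """
    if mode not in ("existential", "universal"):
        raise ValueError(f"unknown wobble mode {mode!r}")
    if len(seq) != len(struct):
        raise ValueError("sequence and structure lengths differ")
    partner = struct.partner(position)
    if partner is None:
        return "unpaired"
    mine = seq.expansions()[position - 1]
    theirs = seq.expansions()[partner - 1]
    if not mine or not theirs:
        return "disruptive"  # a gap cannot pair

    def legal(x: str, y: str) -> bool:
        return frozenset((x, y)) in LEGAL_PAIRS

    if mode == "universal":
        ok = all(legal(x, y) for x in mine for y in theirs)
    else:
        ok = all(any(legal(x, y) for y in theirs) for x in mine)
    return "neutral" if ok else "disruptive"
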