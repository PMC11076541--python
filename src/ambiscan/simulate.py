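"""Synthetic chimeric genomes, repeat arrays and fingerprints with ground truth.

Every generator here emulates a feature of heterogeneous yeast genomes that
the analysis modules are built to detect:

* :func:`simulate_chimera` — a genome carrying several divergent copies
  (alleles) of one locus, with planted single-nucleotide differences that
  are transition-biased and optionally confined to blocks or loop positions;
* :func:`evolve_repeat_array` — an rDNA-like repeat array evolving either
  under homogenisation (gene conversion keeps copies identical) or under a
  birth-and-death regime (duplication/deletion with no conversion, letting
  copies diverge);
* :func:`call_consensus` — the amplicon consensus caller: a site shows an
  ambiguity code only when the summed weight of the minority bases reaches
  the peak-call threshold, otherwise the majority base alone is written and
  the suppressed minority is recorded as ground truth;
* :func:`simulate_fingerprints` — strain-structured binary band matrices;
* :func:`pul4_like` — a ready-made dataset shaped like a survey of a
  protein-coding heterozygosity marker: 37 strains, two alleles each, a
  380 nt segment anchored at ORF position 754, a 70-site union of dimorphic
  positions biased to transitions and third codon positions.

All randomness flows from explicit integer seeds; identical seed and
parameters give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .codons import CodingFrame
from .fingerprint import BandMatrix
from .iupac import encode_consensus, substitution_type
from .scan import AmbiguousSequence

BASES = np.array(list("ACGT"))
_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSION_PARTNERS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


@dataclass(frozen=True)
class PlantedSite:
    position: int  # 1-based
    reference: str
    alternative: str

    @property
    def substitution(self) -> str:
        return substitution_type({self.reference, self.alternative})


@dataclass
class ChimeraModel:
    """Parameters of a chimeric locus with ``n_alleles`` divergent copies."""

    n_alleles: int = 2
    allele_divergence: float = 0.05  # expected per-site difference fraction
    transition_bias: float = 0.8
    block_spec: Optional[list[tuple[int, int]]] = None
    loop_positions: Optional[Sequence[int]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_alleles < 1:
            raise ValueError("n_alleles must be >= 1")
        if not 0.0 <= self.allele_divergence <= 1.0:
            raise ValueError("allele_divergence must be in [0, 1]")
        if not 0.0 <= self.transition_bias <= 1.0:
            raise ValueError("transition_bias must be in [0, 1]")


@dataclass
class ChimeraResult:
    alleles: list[AmbiguousSequence]
    planted: list[PlantedSite]
    allele_strings: list[str] = field(default_factory=list)


def _alternative_base(rng: np.random.Generator, ref: str, transition_bias: float) -> str:
    if rng.random() < transition_bias:
        return _TRANSITION_PARTNER[ref]
    return _TRANSVERSION_PARTNERS[ref][int(rng.integers(2))]


def simulate_chimera(
    model: ChimeraModel, length: int, n_sites: Optional[int] = None
) -> ChimeraResult:
    """Plant exactly ``n_sites`` (default: round(divergence * length))
    dimorphic differences between the copies of one locus.

    Every planted site is dimorphic: one reference and one alternative base;
    each non-reference allele carries the alternative at a random subset of
    sites, re-drawn so that at least one allele differs at every planted
    site. With two alleles this makes the Hamming distance between them
    exactly the number of planted sites.
    """
    rng = np.random.default_rng(model.seed)
    if n_sites is None:
        n_sites = round(model.allele_divergence * length)

    if model.block_spec is not None:
        candidates = sorted(
            {
                p
                for start, end in model.block_spec
                for p in range(start, end + 1)
            }
        )
        if any(p < 1 or p > length for p in candidates):
            raise ValueError("block_spec interval outside sequence length")
    elif model.loop_positions is not None:
        candidates = sorted(set(model.loop_positions))
        if any(p < 1 or p > length for p in candidates):
            raise ValueError("loop_positions outside sequence length")
    else:
        candidates = list(range(1, length + 1))
    if n_sites > len(candidates):
        raise ValueError(
            f"cannot plant {n_sites} sites in {len(candidates)} candidate positions"
        )

    ancestor = _random_sequence(rng, length)
    positions = sorted(rng.choice(candidates, size=n_sites, replace=False).tolist())
    planted = [
        PlantedSite(
            position=p,
            reference=ancestor[p - 1],
            alternative=_alternative_base(rng, ancestor[p - 1], model.transition_bias),
        )
        for p in positions
    ]

    allele_chars = [list(ancestor) for _ in range(model.n_alleles)]
    if model.n_alleles > 1:
        for site in planted:
            carriers = rng.random(model.n_alleles - 1) < 0.5
            if not carriers.any():
                carriers[int(rng.integers(model.n_alleles - 1))] = True
            for a, carries in enumerate(carriers, start=1):
                if carries:
                    allele_chars[a][site.position - 1] = site.alternative
    strings = ["".join(chars) for chars in allele_chars]
    alleles = [
        AmbiguousSequence(id=f"allele_{i + 1}", residues=s)
        for i, s in enumerate(strings)
    ]
    return ChimeraResult(alleles=alleles, planted=planted, allele_strings=strings)


@dataclass
class RepeatArrayModel:
    """Per-generation dynamics of a tandem repeat array."""

    n_repeats: int = 8
    regime: str = "birth_death"  # birth_death | homogenise
    mutation_rate: float = 1e-3  # per site per generation
    duplication_rate: float = 0.05  # per generation
    deletion_rate: float = 0.05
    homogenisation_rate: float = 0.0  # gene-conversion events per generation
    generations: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in ("birth_death", "homogenise"):
            raise ValueError(f"unknown regime {self.regime!r}")
        for name in (
            "mutation_rate",
            "duplication_rate",
            "deletion_rate",
            "homogenisation_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_repeats < 1 or self.generations < 0:
            raise ValueError("n_repeats must be >= 1 and generations >= 0")


def evolve_repeat_array(
    model: RepeatArrayModel, ancestors: Sequence[str]
) -> list[str]:
    """Evolve repeats for ``model.generations`` generations.

    Each generation, every repeat mutates per-site at the mutation rate;
    then, with the respective per-generation probabilities, a random repeat
    is duplicated, one is deleted (never below one repeat), and one is
    overwritten with a copy of another (gene conversion / homogenisation).
    """
    rng = np.random.default_rng(model.seed)
    repeats = [list(r.upper()) for r in ancestors]
    if not repeats:
        raise ValueError("need at least one ancestral repeat")
    length = len(repeats[0])
    if any(len(r) != length for r in repeats):
        raise ValueError("ancestral repeats must have equal length")

    for _ in range(model.generations):
        for r in repeats:
            n_mut = rng.binomial(length, model.mutation_rate)
            for pos in rng.choice(length, size=n_mut, replace=False):
                current = r[pos]
                others = [b for b in "ACGT" if b != current]
                r[pos] = others[int(rng.integers(3))]
        if rng.random() < model.duplication_rate:
            repeats.append(list(repeats[int(rng.integers(len(repeats)))]))
        if len(repeats) > 1 and rng.random() < model.deletion_rate:
            repeats.pop(int(rng.integers(len(repeats))))
        if len(repeats) > 1 and rng.random() < model.homogenisation_rate:
            target = int(rng.integers(len(repeats)))
            source = int(rng.integers(len(repeats) - 1))
            if source >= target:
                source += 1
            repeats[target] = list(repeats[source])
    return ["".join(r) for r in repeats]


@dataclass
class PeakCallModel:
    """Consensus peak-calling: minority bases below ``minor_call_threshold``
    are suppressed, mimicking a chromatogram where one peak dwarfs the other."""

    allele_weights: Optional[Sequence[float]] = None  # None = equal weights
    minor_call_threshold: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 < self.minor_call_threshold <= 1.0:
            raise ValueError("minor_call_threshold must be in (0, 1]")
        if self.allele_weights is not None:
            w = np.asarray(self.allele_weights, dtype=float)
            if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
                raise ValueError("allele_weights must be nonnegative and sum to 1")


def call_consensus(
    repeats: Sequence[str | AmbiguousSequence],
    peaks: PeakCallModel | None = None,
    consensus_id: str = "consensus",
) -> tuple[AmbiguousSequence, list[bool]]:
    """Call an ambiguity-coded consensus from equal-length unambiguous repeats.

    Returns the consensus and a per-position ``majority_called`` flag: True
    where a minority base existed but fell below the peak-call threshold and
    only the majority base was written.
    """
    peaks = peaks or PeakCallModel()
    strings = [r.residues if isinstance(r, AmbiguousSequence) else r.upper() for r in repeats]
    if not strings:
        raise ValueError("need at least one repeat")
    length = len(strings[0])
    if any(len(s) != length for s in strings):
        raise ValueError("repeats must have equal length")
    for s in strings:
        if any(c not in "ACGT" for c in s):
            raise ValueError("repeats must be unambiguous A/C/G/T sequences")
    weights = (
        np.full(len(strings), 1.0 / len(strings))
        if peaks.allele_weights is None
        else np.asarray(peaks.allele_weights, dtype=float)
    )
    if weights.size != len(strings):
        raise ValueError("one weight per repeat required")

    out = []
    flags = []
    for j in range(length):
        tally: dict[str, float] = {}
        for s, w in zip(strings, weights):
            tally[s[j]] = tally.get(s[j], 0.0) + float(w)
        observed = {b: w for b, w in tally.items() if w > 0}
        majority = min(b for b, w in observed.items() if w == max(observed.values()))
        minority_sum = sum(w for b, w in observed.items() if b != majority)
        if len(observed) > 1 and minority_sum >= peaks.minor_call_threshold:
            out.append(encode_consensus(observed))
            flags.append(False)
        else:
            out.append(majority)
            flags.append(len(observed) > 1)
    return AmbiguousSequence(id=consensus_id, residues="".join(out)), flags


def simulate_fingerprints(
    n_strains: int,
    n_bands: int,
    n_groups: int,
    within_group_flip_prob: float = 0.0,
    seed: int = 0,
) -> tuple[BandMatrix, list[int]]:
    """Strain-structured binary band matrix plus the true group labels.

    Group prototypes are independent uniform band vectors; each member flips
    every band independently with ``within_group_flip_prob``.
    """
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    if not 1 <= n_groups <= n_strains:
        raise ValueError("need 1 <= n_groups <= n_strains")
    if not 0.0 <= within_group_flip_prob < 0.5:
        raise ValueError("within_group_flip_prob must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    prototypes = rng.random((n_groups, n_bands)) < 0.5
    labels = [i % n_groups for i in range(n_strains)]
    flips = rng.random((n_strains, n_bands)) < within_group_flip_prob
    presence = np.array([prototypes[g] for g in labels]) ^ flips
    matrix = BandMatrix(
        strain_ids=[f"S{i + 1:02d}" for i in range(n_strains)],
        band_ids=[f"B{j + 1:02d}" for j in range(n_bands)],
        presence=presence,
    )
    return matrix, labels


@dataclass
class Pul4Fixture:
    """A survey-shaped dataset: per-strain two-allele genomes, their called
    consensus sequences, the planted union of dimorphic sites, and the frame."""

    consensus: dict[str, AmbiguousSequence]
    alleles: dict[str, tuple[str, str]]
    union_positions: list[int]
    alternatives: dict[int, str]  # position -> planted alternative base
    reference: str
    per_strain_sites: dict[str, list[int]]
    frame: CodingFrame


def pul4_like(
    seed: int = 0,
    n_strains: int = 37,
    length: int = 380,
    n_union_sites: int = 70,
    transition_bias: float = 0.8,
    third_position_fraction: float = 0.75,
    site_inclusion_prob: float = 0.3,
    orf_start: int = 754,
    minor_call_threshold: float = 0.3,
) -> Pul4Fixture:
    """Generate a dataset shaped like a protein-coding heterozygosity survey.

    Defaults encode the study conditions this generator emulates: 37 strains,
    a 380 nt segment starting at ORF position 754, a union of 70 dimorphic
    sites over all strains, transitions favoured 4:1 and three quarters of
    the sites at third codon positions. Each strain carries two alleles
    differing at its own subset of the union sites (inclusion probability
    ``site_inclusion_prob`` per site, topped up so every union site occurs
    in at least one strain).
    """
    rng = np.random.default_rng(seed)
    frame = CodingFrame(orf_start_position=orf_start)
    reference = _random_sequence(rng, length)

    thirds = [p for p in range(1, length + 1) if frame.codon_position(p) == 3]
    others = [p for p in range(1, length + 1) if frame.codon_position(p) != 3]
    n_third = min(round(third_position_fraction * n_union_sites), len(thirds))
    n_other = n_union_sites - n_third
    positions = sorted(
        rng.choice(thirds, size=n_third, replace=False).tolist()
        + rng.choice(others, size=n_other, replace=False).tolist()
    )
    alternatives = {
        p: _alternative_base(rng, reference[p - 1], transition_bias) for p in positions
    }

    inclusion = rng.random((n_strains, n_union_sites)) < site_inclusion_prob
    for j in range(n_union_sites):  # every union site in >= 1 strain
        if not inclusion[:, j].any():
            inclusion[int(rng.integers(n_strains)), j] = True
    for i in range(n_strains):  # every strain heterozygous somewhere
        if not inclusion[i].any():
            inclusion[i, int(rng.integers(n_union_sites))] = True

    peaks = PeakCallModel(minor_call_threshold=minor_call_threshold)
    consensus: dict[str, AmbiguousSequence] = {}
    alleles: dict[str, tuple[str, str]] = {}
    per_strain_sites: dict[str, list[int]] = {}
    for i in range(n_strains):
        sid = f"MP{i + 1:02d}"
        sites = [positions[j] for j in range(n_union_sites) if inclusion[i, j]]
        b = list(reference)
        for p in sites:
            b[p - 1] = alternatives[p]
        allele_b = "".join(b)
        cons, _ = call_consensus([reference, allele_b], peaks, consensus_id=sid)
        consensus[sid] = AmbiguousSequence(
            id=sid, residues=cons.residues, coordinate_offset=orf_start
        )
        alleles[sid] = (reference, allele_b)
        per_strain_sites[sid] = sites
    return Pul4Fixture(
        consensus=consensus,
        alleles=alleles,
        union_positions=positions,
        alternatives=alternatives,
        reference=reference,
        per_strain_sites=per_strain_sites,
        frame=frame,
    )
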