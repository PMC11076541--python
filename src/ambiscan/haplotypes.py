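"""Haplotype space of an ambiguity-coded consensus sequence.

A consensus with k ambiguous sites is compatible with every sequence obtained
by choosing one nucleotide per site — the Cartesian product of the per-site
expansions. These resolutions are the candidate locus copies (alleles or
repeat variants) hiding behind the consensus. The module enumerates them
(with a cap), bounds their pairwise divergence in closed form, infers the
minimum number of distinct alleles the genome must carry, and asks whether
two resolutions of the *same* genome would be split into different OTUs at a
fixed similarity threshold — the mechanism by which intragenomic
heterogeneity inflates diversity estimates in threshold-based metabarcoding.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional

from .iupac import GAP
from .scan import AmbiguousSequence

DEFAULT_ENUMERATION_CAP = 2 ** 20


@dataclass
class HaplotypeSpace:
    source_id: str
    n_ambiguous_sites: int
    n_haplotypes: int
    haplotypes: Optional[list[str]]
    max_pairwise_divergence: float
    min_allele_count: int
    sequence_length: int

    @property
    def enumerated(self) -> bool:
        return self.haplotypes is not None


@dataclass(frozen=True)
class OtuSplitReport:
    source_id: str
    threshold: float
    max_pairwise_divergence: float
    splits: bool
    margin: float


def enumerate_haplotypes(
    seq: AmbiguousSequence, cap: int = DEFAULT_ENUMERATION_CAP
) -> HaplotypeSpace:
    """Resolve a consensus into its haplotype space.

    The haplotype count (product of per-site expansion sizes) and the
    divergence bound are always exact; the explicit list is produced only
    when the count does not exceed ``cap``. The maximum pairwise divergence
    between two resolutions is k / L: any two resolutions can be made to
    differ at every ambiguous site and nowhere else.
    """
    if GAP in seq.residues:
        raise ValueError(f"sequence {seq.id!r} contains gaps; ungapped input required")
    expansions = seq.expansions()
    k = sum(1 for e in expansions if len(e) > 1)
    n = math.prod(len(e) for e in expansions)
    length = len(seq)
    haplos: Optional[list[str]] = None
    if n <= cap:
        haplos = [
            "".join(choice)
            for choice in itertools.product(*(sorted(e) for e in expansions))
        ]
    return HaplotypeSpace(
        source_id=seq.id,
        n_ambiguous_sites=k,
        n_haplotypes=n,
        haplotypes=haplos,
        max_pairwise_divergence=k / length,
        min_allele_count=max(len(e) for e in expansions),
        sequence_length=length,
    )


def haplotype_in_space(consensus: AmbiguousSequence, candidate: str) -> bool:
    """Is ``candidate`` one of the resolutions of ``consensus``?

    Checked site-wise against the expansions, so it works for any number of
    ambiguous sites, far beyond the explicit enumeration cap.
    """
    cand = candidate.upper().replace("U", "T")
    if len(cand) != len(consensus):
        return False
    return all(c in e for c, e in zip(cand, consensus.expansions()))


def min_allele_count(seq: AmbiguousSequence) -> int:
    """Lower bound on the number of distinct locus copies in the genome.

    A site where m nucleotides alternate requires at least m copies; the
    bound is the maximum expansion size over all sites. An SND-only sequence
    gives 2 — the "at least two alleles" inference for a dimorphic gene.
    """
    return max(len(e) for e in seq.expansions() if e) if seq.n_nongap else 1


def otu_split(seq: AmbiguousSequence, threshold: float) -> OtuSplitReport:
    """Would two resolutions of this one genome land in different OTUs?

    ``splits`` is true iff the worst-case similarity between two resolutions,
    1 - k/L, falls below the clustering threshold (similarity = 1 - p-distance,
    no evolutionary correction).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    space = enumerate_haplotypes(seq, cap=0)
    similarity = 1.0 - space.max_pairwise_divergence
    return OtuSplitReport(
        source_id=seq.id,
        threshold=threshold,
        max_pairwise_divergence=space.max_pairwise_divergence,
        splits=similarity < threshold,
        margin=similarity - threshold,
    )
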