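# Methods

This note documents the models, conventions and numerical choices behind
`ambiscan`, in the order data flows through the package.

## Sites, morphism classes and coordinates

A consensus sequence is a string over the 15 IUPAC nucleotide symbols plus
the gap `-`. Each symbol expands to its defining subset of {A,C,G,T}; the
gap expands to nothing and is never treated as a wildcard. A site's
*morphism class* is the size of the nucleotide set observed there:
invariant (1), SND (2), SNT (3), SNP (4). Dimorphic sites are further
typed as transitions ({A,G}, {C,T}) or transversions (the other four
pairs). Input is case-insensitive and accepts `U` for `T` (rRNA-derived
sequences are often reported on the RNA alphabet); output is upper-case
DNA. All positions in reports are 1-based inclusive.

In an alignment census, a column's observed set is the union of the
per-sequence expansions; gaps are excluded from the union but flag the
column as an indel column, which is counted separately and removed from
the percent-variable denominator. A run of consecutive gaps in one
sequence counts as one indel *event* for that sequence, since a single
deletion of several bases is one mutational event. Headline percentages
are rounded half-away-from-zero to integer percent; machine output keeps
full precision.

## Variability blocks

Variable sites often cluster. A *block* is a maximal run of variable sites
in which consecutive members are at most `max_gap` apart, kept only if it
contains at least `min_block_sites` sites. There is no field-standard
definition of such blocks, so both parameters are exposed rather than
asserted; the defaults (`max_gap = 10`, `min_block_sites = 2`) mark dense
clusters a reader would circle by eye on a 300–600 nt barcode while
ignoring isolated singletons. Blocks are labelled I, II, III, … in
positional order.

## Haplotype space and the OTU-split test

A consensus with per-site expansions E₁…E_L resolves into the Cartesian
product ∏Eᵢ of haplotypes. The count is reported exactly as an integer;
the explicit list is produced only up to a cap (default 2²⁰ resolutions)
because ITS-like sequences can carry dozens of ambiguous sites. Two exact
closed forms hold regardless of the cap and are verified against brute
force in the tests:

- maximum pairwise divergence between resolutions = k/L, where k is the
  number of ambiguous sites and L the (non-gap) length — at every
  ambiguous site two resolutions can be made to differ, and nowhere else;
- minimum allele count = max per-site expansion size — a site with m
  alternating bases requires at least m distinct copies. An SND-only
  sequence therefore proves at least two alleles, never how many more, and
  nothing about dosage.

Similarity is 1 − p-distance with no evolutionary correction, matching how
metabarcoding OTU thresholds are applied. The split test asks whether the
*worst-case* similarity between two resolutions of one genome, 1 − k/L,
falls below the clustering threshold; if it does, a single genome can be
scattered across OTUs.

## Codon effects

A sequenced segment is anchored by the 1-based ORF position of its first
residue; codon index and intra-codon position follow by integer
arithmetic, and codons not fully inside the segment are excluded from all
denominators (and listed). An ambiguous codon resolves into at most 64
unambiguous codons; it is *synonymous* when all resolutions translate to
one amino acid and *nonsynonymous* otherwise (stops count as a distinct
residue). Two affected-codon tallies are reported: *per-sequence* (a codon
is nonsynonymous within at least one isolate's own sequence) and *union*
(alternatives from all isolates pooled onto one reference before
classification, the way substitution surveys display stacked alternatives).
The union tally is the headline number; both are kept because they answer
different questions (what any one genome encodes vs what the population
can encode).

Translation uses Biopython's codon tables. The default is the standard
nuclear code; the alternative yeast nuclear code (CTG → Ser) is selectable
because *Metschnikowia* and relatives belong to the CUG-Ser clade. The
choice changes only verdicts on codons whose resolutions include CTG, and
no headline count in this package's own datasets.

## Secondary-structure context and wobble neutrality

Structures are consumed as single-tier Vienna dot-bracket strings
(pseudoknots unsupported; hairpin-stem loops need none); folding is
upstream of this package, which keeps the module deterministic. A variable
site is *loop* or *paired* by the pair map. At a paired site the legal
pairings are Watson–Crick plus G·U wobble. The default *existential*
neutrality contract asks that every base in the site's expansion pair
legally with at least one base of the partner's expansion — the partner
strand is itself polymorphic, so some copy can always provide the match. A
stricter *universal* variant (every combination legal) is computed
alongside, since the two contracts genuinely differ (Y paired with R is
existentially neutral but universally disruptive via C·A) and the
qualitative wobble argument does not choose between them.

## Fingerprint clustering

Band patterns are boolean strain × band matrices, optionally with fragment
sizes. Size filters are strict ("larger than 1 kb" keeps > 1000 bp;
strictness is a flag). Distances are 1 − similarity under Jaccard, Dice or
simple matching; Dice is the default, as is common for dominant markers
like RAPD where shared absence is weak evidence. Two all-empty patterns
are assigned distance 0 with a warning rather than NaN. UPGMA uses
size-weighted average linkage with node height = half the merge distance,
so cophenetic distances reproduce merge distances; ties are broken by the
lowest (row, column) pair after lexicographic id ordering, making
dendrograms deterministic without a seed. Trees are held as scikit-bio
`TreeNode` objects and serialised to Newick. On any exactly ultrametric
input UPGMA returns the generating tree; the tests verify this on random
ultrametric trees and cross-check cophenetics against SciPy's
average-linkage implementation on general matrices. Pattern counting
groups bitwise-identical rows and also lists every pair of strains the
fingerprint cannot distinguish.

## Synthetic data: what it emulates and what it does not

All generators take explicit integer seeds; identical seed and parameters
give byte-identical output.

**Chimeric locus** (`simulate_chimera`): an ancestral random sequence plus
n ≥ 2 allele copies differing at planted sites. Every planted site is
dimorphic (one alternative base), drawn as a transition with probability
`transition_bias` (default 0.8, reflecting the strong transition excess
seen in dimorphic barcode sites) and optionally confined to blocks or loop
positions. With two alleles the planted count k is exactly the Hamming
distance between them.

**Repeat array** (`evolve_repeat_array`): per generation, every repeat
mutates per-site (uniform substitution); then with per-generation
probabilities one repeat is duplicated, one deleted (floor of one), and
one overwritten by a copy of another (gene conversion). The *homogenise*
regime has a positive conversion rate; *birth_death* sets it to zero so
copies diverge. No rates for the real process are known; defaults
(8 repeats, 200 nt, 30 generations, mutation 10⁻³/site/gen,
duplication = deletion = 0.05, conversion 0.5 when homogenising) are
illustrative, and every claim about the regimes is comparative — mean
consensus ambiguity under birth-and-death exceeds that under
homogenisation — not absolute.

**Consensus caller** (`call_consensus`): weighted base tallies per site;
an ambiguity code is written only when the summed weight of the
non-majority bases reaches `minor_call_threshold` (default 0.3),
mimicking a chromatogram where only comparable double peaks are scored.
Suppressed minorities are recorded as `majority_called` ground truth —
information a deposited FASTA record cannot carry, which is why the scan
treats only explicit ambiguity codes as variable and the simulator keeps
the truth for sensitivity analysis.

**Survey-shaped dataset** (`pul4_like`): 37 strains, each with two alleles
of a 380 nt coding segment anchored at ORF position 754, a pooled union of
70 dimorphic sites, 75 % of them at third codon positions and 80 %
transitions; each strain carries each union site with probability 0.3
(about 21 sites per strain), topped up so every union site occurs
somewhere and every strain is heterozygous somewhere. These defaults *are*
the study conditions the generator emulates; the inclusion probability and
the two bias fractions are the only free choices, picked once as values a
sequence survey of this kind would report. The generator does not emulate
sequencing error, alignment uncertainty, indels in coding sequence, or
more than one alternative base per site; tests passing on it therefore
show the analysis chain is exact on clean dimorphic data, not that it is
robust to base-calling noise.

## Problem sizes and tolerances

Property suites run at desk scale: 200 two-allele replicates (k = 1…30,
L = 380), 200 random consensus sequences against a vectorised brute-force
divergence oracle (haplotype products capped at 4096), 10⁴ random
ambiguity codons plus the exhaustive single-ambiguity set against an
enumerate-and-translate oracle, 100 random ultrametric trees (n ≤ 16)
recovered to 1e-9, and 100 replicate pairs for the regime contrast tested
one-sided at α = 0.01 (Mann–Whitney). Exact integer quantities are
asserted exactly; the only numeric tolerance in the package is the 1e-9
ultrametricity bound on dendrogram heights.

## Known limitations

- Majority-called (suppressed-minority) sites are invisible in real FASTA
  input; ground truth exists only for simulated data.
- `min_allele_count` is a lower bound; equal dosage is never assumed and
  copy number beyond the bound is not inferred.
- The denominator conventions (non-indel sites for percent-variable,
  complete codons for percent-affected) are stated in every report but
  other tools may divide differently; compare denominators before
  comparing percentages.
- Fingerprint analytics assume bands are already scored; co-migration of
  unequal fragments and gel-to-gel size error are upstream problems.
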