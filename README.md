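# ambiscan

Analytics for IUPAC ambiguity-coded amplicon consensus sequences from
heterogeneous genomes.

## The problem

In yeasts such as *Metschnikowia pulcherrima*, the loci used for molecular
identification — the rRNA-cistron barcodes (ITS, LSU D1/D2) and duplicated
nuclear genes — can exist within a single genome as several *divergent*
copies: repeat arrays that are not homogenised, or alleles of distinct
phylogenetic origin brought together by hybridisation. Direct Sanger
sequencing of the PCR amplicon then returns a consensus riddled with IUPAC
ambiguity codes: a site where two copies disagree appears as a *single
nucleotide dimorphism* (SND, e.g. `Y` = C/T), and sites with three- or
four-fold alternation (SNT, SNP) imply at least three or four copies.

This intragenomic heterogeneity breaks the assumptions behind
threshold-based species delimitation: two resolutions of one genome's
consensus can be less similar to each other than the OTU threshold
(commonly 97 %) that is supposed to separate species, so one strain can be
counted as several taxa. `ambiscan` quantifies this effect and everything
around it:

- **`ambiscan.iupac`** — the exact ambiguity-code algebra (expansion,
  consensus encoding, SND/SNT/SNP morphism, transition/transversion type);
- **`ambiscan.scan`** — per-site variability census of single sequences and
  pre-aligned sets, indel accounting, variability-block detection, and
  ambiguity-aware pairwise distances;
- **`ambiscan.haplotypes`** — enumeration of the haplotype space behind a
  consensus, exact divergence bounds (max pairwise p-distance = k/L for k
  ambiguous sites over length L), minimum-allele-count inference, and the
  OTU-split test;
- **`ambiscan.codons`** — mapping of dimorphic sites into codons of an
  ORF-anchored segment and synonymous/nonsynonymous classification
  (standard or alternative yeast nuclear genetic code);
- **`ambiscan.structure`** — loop vs paired context of variable sites from
  dot-bracket secondary structures and the wobble-neutrality test
  (Watson–Crick + G·U pairing);
- **`ambiscan.fingerprint`** — RAPD/RFLP band-pattern analytics: band-size
  filtering, Jaccard/Dice/simple-matching distances, deterministic UPGMA
  dendrograms with Newick output, distinct-pattern counting;
- **`ambiscan.simulate`** — generators with ground truth: chimeric loci
  with planted transition-biased dimorphisms, repeat arrays evolving under
  homogenisation vs birth-and-death dynamics, a majority-peak consensus
  caller, strain-structured fingerprints, and a ready-made 37-strain
  survey-shaped dataset (`pul4_like`);
- **`ambiscan.pipeline` / `ambiscan.cli`** — a YAML-configured pipeline and
  the `ambiscan` command with subcommands `scan`, `haplo`, `codons`,
  `structure`, `cluster`, `simulate`, `run`.

## Worked example

```python
from ambiscan import pul4_like, scan_alignment, summarize_coding, otu_split

fx = pul4_like(seed=1)                      # 37 strains, 2 alleles each
seqs = list(fx.consensus.values())
records, census = scan_alignment(seqs)
print(f"union of variable sites: {census.n_variable} "
      f"({census.pct_variable_rounded}% of {census.n_sites_total} nt)")
print(f"all dimorphic: SND={census.n_SND}, SNT={census.n_SNT}, SNP={census.n_SNP}")
print(f"transitions : transversions = {census.n_transitions}:{census.n_transversions}")

table = summarize_coding(seqs, fx.frame)    # segment anchored at ORF pos 754
print(f"codons affected (pooled alternatives): {table.n_affected_union} of {table.n_codons_total}")

report = otu_split(seqs[0], threshold=0.97)
print(f"{seqs[0].id}: worst-case self-similarity "
      f"{1 - report.max_pairwise_divergence:.3f} -> splits at 97%: {report.splits}")
```

prints

```
union of variable sites: 70 (18% of 380 nt)
all dimorphic: SND=70, SNT=0, SNP=0
transitions : transversions = 55:15
codons affected (pooled alternatives): 25 of 126
MP01: worst-case self-similarity 0.947 -> splits at 97%: True
```

Reading: pooled over the 37 simulated strains, 70 of 380 sites are
dimorphic (18 %), every one a two-base alternation — so each strain carries
exactly two alleles of the locus — with transitions dominating. 25 of the
126 complete codons change the encoded amino acid once alternatives from
all strains are pooled onto the reference. And strain MP01's own two
alleles are only 94.7 % similar: an OTU pipeline at 97 % would file one
genome under two species.

The same analyses run from the shell, e.g.

```sh
ambiscan simulate --seed 3 --length 120 --divergence 0.1
# planted 12 sites; consensus has 12 ambiguous positions
ambiscan scan consensus.fasta
ambiscan haplo consensus.fasta --threshold 0.97
```

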