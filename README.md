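# apiscout

Whole-genome association toolkit for **scout** and **recruit** behavioral
castes in honey bees (*Apis mellifera*), built around the genetics of a
**one-patriline colony**: a single diploid queen inseminated by a single
haploid drone.

Among foragers, scouts independently search for new food sources and
communicate their location; recruits are enlisted by dance language to
collect them. Scouting is a predilection, not a deterministic trait, and
sequencing individual scouts and recruits from one patriline gives an
unusually clean case-control design: because drones are haploid, the father
transmits the same allele to every daughter, so the workers resemble an
inbred backcross at every locus where the queen is heterozygous. Two full
sisters then share an expected **75%** of their allele copies (paternal
allele always identical, maternal allele identical half the time), versus
50% under ordinary diploid biparental inheritance — the extra relatedness is
what gives a 22-vs-22 bee design its power.

The package is aimed at researchers who want to run, extend or stress-test
this style of analysis without access to the original reads: every input can
be simulated with the correct genetic and noise structure.

## What it implements

* **`apiscout.colony`** — the synthetic study. Parental genotypes per locus
  (queen genotype ∈ {RR, RN, NN}, drone allele ∈ {R, N} where R = reference
  allele and N = non-reference allele), Mendelian worker genotypes,
  a logistic caste-predilection model
  `P(scout) = logistic(logit(p0) + Σ βj · dosej)` on N-allele dose,
  noisy genotype calls at ~10X Poisson depth (capped at 100 reads), paired
  FASTQ with planted QC violations, and BLAST-tabular homology hits with a
  taxon map.
* **`apiscout.readqc`** — read-pair filtering: a pair is dropped when either
  mate has ≥ 10% N bases, > 50% bases under Phred 5, or an ungapped adapter
  alignment covering > 10 nt with ≤ 10% mismatches; up to 6 trailing
  bases under Phred 5 are trimmed from the 3' end.
* **`apiscout.taxonomy`** — best BLAST hit per read at e-value < 1e-10,
  classification into Apis / Arthropoda (each split repeat / ribosomal /
  other), *Nosema*, other Eukaryota, the five dominant honey bee gut-bacteria
  genera, other Bacteria and other species; per-caste count and percentage
  summary; flagging of reference scaffolds whose hits are exclusively
  bacterial.
* **`apiscout.assoc`** — the five-test battery per biallelic position:
  genotypic (2×3 Freeman–Halton exact), allelic (2×2 Fisher on allele
  counts), dominant (RR∪RN vs NN) and recessive (RR vs RN∪NN) collapses, and
  the Cochran–Armitage trend test on 0/1/2 genotype scores
  (χ² = N·r², 1 df). Positions are filtered for coverage (< 3X individuals
  removed) and monomorphism; Benjamini–Hochberg FDR is computed per test
  family, significance is called at raw p < 1e-4, and results cross-tabulate
  against variant location classes.
* **`apiscout.annotate`** — GFF3-based location classes with precedence
  coding > 5'UTR > 3'UTR > intron > upstream/downstream (within 5 kb) >
  intergenic; ncRNA exons count as coding; strand-aware synonymous /
  codon-change / frameshift / inframe-indel effects.
* **`apiscout.ld`** — within-caste Pearson correlation between positions on
  0/1/2-coded genotypes (NA where a caste is fixed), single-linkage
  clustering of positions < 300 kb apart, and a combined scout-below /
  recruit-above matrix export.
* **`apiscout.tfbs`** — PWM scanning of ±1000 bp windows around significant
  variants on both strands, reporting matches with min-max-normalized
  log-odds relative score ≥ 0.80.

## Worked example

Run the whole synthetic study end to end (2,000 loci, a 600-worker colony,
22 scouts + 22 recruits sampled, one scout sequenced at 2X and removed by
the coverage filter, one planted caste-effect locus with β = +4):

```sh
apiscout all --out runs/demo --seed 2
```

The run directory contains every stage's TSV output plus `manifest.json`.
With seed 2 the manifest reports:

* `qc`: 300 pairs in, 258 kept; 16 dropped for adapter and 26 for low
  quality — exactly the planted violations.
* `assoc`: 2,000 positions → 1,478 tested, 244 monomorphic-heterozygous,
  139 monomorphic-NN, 139 non-variant; **1 significant position**.
* the significant position is the planted effect locus `LG01:331` with
  p_genotypic = 3.9e-08, p_trend = 8.4e-08, p_allelic = 3e-06 and
  significance pattern `S/S/S/S` (genotypic / trend / allelic / ref-allele
  gene action) — the backcross locus where scouts are enriched for the RN
  genotype.
* `taxonomy`: 758 of 800 unmapped reads retain a hit below e-value 1e-10;
  the summary's within-group percentages show the planted scout-rich
  *Gilliamella* and recruit-rich *Snodgrassella* mixtures.
* `tfbs`: the ±1000 bp window around the significant variant contains
  matches to both bundled insect-like profiles.

Each stage can also be run standalone on files from the previous stage
(`apiscout qc`, `apiscout taxprofile`, `apiscout assoc`, `apiscout annotate`,
`apiscout ld`, `apiscout tfbsscan`); see `apiscout --help`.

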