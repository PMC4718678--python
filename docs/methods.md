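# Methods

## The genetic model

A one-patriline honey bee colony is founded by a single diploid queen and a
single haploid drone. Every worker inherits the drone's only allele plus one
of the queen's two alleles, drawn uniformly and independently per locus and
worker. Consequences encoded throughout the package:

* a queen-homozygous locus is monomorphic among workers;
* a queen-heterozygous locus segregates exactly two genotypes, both
  containing the drone allele, in expected 1:1 proportion (an inbred
  backcross);
* full sisters share allele copies with expected frequency
  (1 + 1/2)/2 = 3/4: the paternal copy is always identical, the maternal
  copy identical with probability 1/2. With a diploid heterozygous sire both
  copies are shared with probability 1/2, giving 1/2. These closed forms are
  `assoc.sister_sharing_probability`; `colony.simulate_sister_sharing` is
  the Monte-Carlo counterpart.

Alleles are abstracted to R (reference) / N (non-reference); only biallelic
loci are modelled. Multiallelic sites are out of scope.

## Caste predilection

Scouting is modelled as a bias, never a deterministic trait: worker *i*
scouts with probability

    P(scout_i) = logistic( logit(p0) + Σ_j β_j · dose_ij )

where `dose_ij` is *i*'s N-allele count at effect locus *j*. The logistic
form is the simplest monotone predilection model; it is a design choice, not
an inference about any real locus architecture. Default `p0 = 0.3` sits
inside the 5–35% range reported for scouts among foragers. The default
planted effect (β = +4 at one locus) is placed at a queen-heterozygous locus
whose drone allele is R, so worker genotypes split RR:RN and the colony's
overall scout fraction stays moderate (≈ 0.63 at p0 = 0.3) instead of
saturating.

## Genotype-call noise

Per bee × locus the read depth is Poisson(`mean_depth`, default 10 — the
study-scale median coverage) truncated at `depth_cap = 100` (the calling
depth cap). Each read samples one chromosome copy and reports its base
correctly with probability 1 − e (default e = 0.01); a misread lands
uniformly on the three other bases, so only e/3 mimics the opposite allele
and third-base reads are discarded from the biallelic tally. The call rule
is a transparent, configurable stand-in for a likelihood caller: homozygous
when ≥ 90% of informative reads support one allele, heterozygous when both
alleles are seen above the complementary 10%, missing below
`min_call_depth`. Under the defaults this yields ≈ 1.4% call error at 10X;
modelling every misread as the opposite allele would roughly double that,
which is why the third-base model is the default.

Per-individual coverage is the realized mean depth; individuals below 3X are
removed before association, mirroring the removal of one atypical
low-coverage scout in the emulated design (the pipeline plants one scout at
2X by default).

## Read quality control

Boundary semantics follow the stated rules exactly: the N-fraction rule is
inclusive (≥ 10%), the low-quality-fraction rule strict (> 50% of bases with
Phred < 5), and the adapter rule requires strictly more than 10 aligned
nucleotides with ≤ 10% mismatches. Adapter detection is an ungapped sliding
alignment of the adapter over every offset in both orientations; the overlap
is the full overlapping region and N bases count as mismatches. Low-quality
rules are checked before the adapter rule, and mate 1 before mate 2, so a
pair's drop reason is deterministic. 3' trimming removes at most 6 trailing
bases below Phred 5. Both mates are trimmed by default; an asymmetric mode
(`trim_both_mates = False`) trims mate 1 only, reproducing the handling
described for part of the emulated study's samples. Phred encoding is fixed
to +33.

The FASTQ generator plants three violation types (12% N bases; 60% of bases
at Phred < 5; a full adapter insertion or a 15-nt 3' adapter read-through)
and rejection-samples clean reads against an independently coded
sliding-window checker so that no clean read accidentally trips the adapter
rule — the planted manifest is therefore exactly the set QC must drop.

## Unmapped-read taxonomy

Hits are retained at e-value strictly below 1e-10; the best hit per read is
the maximum bitscore, with ties broken by lower e-value then
lexicographically smallest accession (determinism under row reordering).
Groups follow the published summary's label set; the genus list for named
bacteria is configurable. Keyword subclassification checks repeat
("repeat", "microsatellite") before ribosomal ("ribosomal", "18S", "28S")
because repeat annotations are unambiguous while ribosomal keywords are
broad. Percentage columns are rounded as printed: shares of all matched
reads to 2 decimals, within-group caste splits to 1 decimal. Scaffolds with
zero retained hits are never flagged as bacterial-only.

## Association battery

Per tested position and caste, genotype counts (n_RR, n_RN, n_NN) feed five
tests: Freeman–Halton exact on the 2×3 genotype table; 2×2 Fisher on allele
counts (R copies = 2·n_RR + n_RN); dominant (RR∪RN vs NN) and recessive
(RR vs RN∪NN) collapses; and the Cochran–Armitage trend test with scores
(0, 1, 2), using the score-form variance (denominator N, no continuity
correction), which satisfies χ² = N·r². Two-sided exact p-values sum the
probabilities of all margin-consistent tables no more probable than the
observed one (relative tie tolerance 1e-7, the convention of standard exact
test codes). Degenerate collapses return NA; when fewer than two genotype
classes are present no test carries information and all five are NA.
Missing calls are excluded per position (complete case). All-RR columns are
dropped as non-variant — a caller only reports positions with N-allele
evidence — and monomorphic-NN / monomorphic-het columns are tallied and
dropped before testing.

FDR is Benjamini–Hochberg within each test family across positions, with
NAs excluded from m; the headline significance call remains raw p < 1e-4
(reported alongside the adjusted values). The significance pattern has four
symbols — genotypic, trend, allelic, and a combined reference-allele
gene-action symbol that is S if either collapse is significant and NA only
if both are undefined — and the cross-tab against location classes is a
strict partition of positions.

## Variant annotation

Coordinates are 1-based inclusive; a variant's position is its first
affected base (deletions anchored at the first deleted base). Location
precedence is coding > 5'UTR > 3'UTR > intron > upstream/downstream >
intergenic, with a 5,000 bp flank separating the last two (configurable).
UTRs missing from the GFF3 are derived as the exonic stretches flanking the
CDS. Variants inside ncRNA exons are classed coding for cross-tab purposes.
When a variant lies within the flank of several genes the nearer gene wins;
an exact distance tie resolves to upstream (deterministic). Effects:
strand-aware codon translation with the standard genetic code for SNPs;
indel length mod 3 for frameshift vs inframe; a variant spanning a
coding-interval boundary is "other". For ncRNA transcripts the exons stand
in for the CDS with the frame anchored at the first exon base — a
convention, flagged as such, since ncRNA reading frames are not annotated.

## Correlation and clustering

Genotypes are coded 0/1/2; correlations are pairwise-complete Pearson within
each caste, requiring at least 3 complete pairs (the sources are silent on
missing-data handling; pairwise-complete preserves the most bees). A
position with zero variance within a caste has an entirely NA row/column,
including the diagonal, matching the grey cells of the published heatmaps.
Distance clustering is single-linkage chaining of same-chromosome positions
strictly less than 300 kb apart (the published LD-based pairing distance);
the plot is cosmetic, the numeric matrix is the tested artifact.

## PWM scanning

"80% identity to a profile" is implemented as the min-max-normalized
log-odds relative score ≥ 0.80 — the convention of classical binding-site
scanners — because a literal per-column consensus identity is much cruder; a
strict consensus-identity mode is provided behind `mode="consensus"` for
comparison. Pseudocount 0.8 distributed by background frequency (default
uniform 0.25) regularizes the count matrices. N bases contribute the
background log-odds of 0, which lies between every column's minimum and
maximum, so scores stay in [0, 1]. Both strands are scanned at every offset
of the ±1000 bp window (truncated at sequence ends) and overlapping hits are
all reported.

## Problem sizes and what the tests show

The synthetic defaults mirror the emulated study where stated (22 + 22 bees,
one < 3X scout removed leaving 21 + 22; ~10X depth; 100-read calling cap;
α = 1e-4; 5 kb flank; 300 kb cluster gap; ±1 kb TFBS windows at 80%).
Colony sizes, locus counts and mixture compositions are package choices
picked to keep the suite's statistical checks well-powered: null calibration
uses 20,000 positions; power uses 200 replicates of a 12-locus colony with
the planted β = +4 locus; QC-manifest recovery uses 1,000 pairs.

The generator emulates the genetic structure, call noise, planted read
contamination and taxon mixtures of the real study but not alignment-level
artifacts (mapping bias, indel realignment, duplicate reads), linked
inheritance along chromosomes (loci are exchangeable draws, except where a
test plants linkage explicitly), or polyandry. Passing tests therefore
demonstrate correctness of the statistical machinery and pipeline plumbing
under the stated model, not robustness to alignment artifacts in real data.

## Known limitations

* The exact 2×3 test enumerates margin-consistent tables; it is cached by
  margins and fast at study scale (n ≤ 44) but not intended for large
  counts.
* The annotator resolves overlapping genes by class precedence only; it does
  not report per-transcript multi-annotations.
* The TFBS scanner has no phylogenetic footprinting and never downloads
  profile databases; profiles are user-supplied JASPAR files.
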