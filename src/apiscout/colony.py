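"""Synthetic one-patriline honey bee colony and fixture generators.

Honey bees are haplodiploid: drones develop from unfertilized eggs and are
haploid, while the queen and her worker daughters are diploid.  A colony
founded by one queen inseminated by a single drone therefore behaves like an
inbred backcross at every locus where the queen is heterozygous — each worker
carries the drone allele plus one of the two queen alleles — and is
genetically uniform where the queen is homozygous.

This module simulates such a colony (ground-truth genotypes, probabilistic
caste predilection, noisy genotype calls at ~10X depth) together with the
raw-data fixtures the downstream stages consume: paired FASTQ files with
planted quality-control violations and BLAST-tabular homology hits with a
taxon map.  Everything is reproducible from explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assoc import GenotypeMatrix

ALLELES = ("R", "N")
GT_BY_DOSE = np.array(["RR", "RN", "NN"])

#: Illumina TruSeq universal adapter (read-through target of the QC rule)
TRUSEQ_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Locus:
    """One biallelic position: queen genotype plus the drone's single allele."""

    chrom: str
    pos: int
    queen_gt: tuple[str, str]
    drone_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if len(self.queen_gt) != 2 or any(a not in ALLELES for a in self.queen_gt):
            raise ValueError("queen_gt must be two alleles from {R, N}")
        if self.drone_allele not in ALLELES:
            raise ValueError("drone_allele must be 'R' or 'N'")

    @property
    def queen_heterozygous(self) -> bool:
        return self.queen_gt[0] != self.queen_gt[1]


@dataclass
class ColonyDesign:
    """Ground truth of a single-queen x single-drone colony."""

    loci: list[Locus]
    n_workers: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_workers <= 0:
            raise ValueError("n_workers must be positive")
        keys = [(l.chrom, l.pos) for l in self.loci]
        if keys != sorted(keys):
            raise ValueError("loci must be sorted by (chrom, pos)")


@dataclass
class CasteModel:
    """Probabilistic scout predilection: a logistic model on N-allele dose.

    Scouting is a behavioral bias, not a deterministic trait, so each worker
    scouts with probability logistic(logit(base_scout_prob) + sum of
    effect_size * N-allele dose over the effect loci).  The default base
    probability of 0.3 sits inside the observed 5-35% range of scouts among
    foragers.
    """

    effect_loci: tuple[int, ...] = ()
    effect_sizes: tuple[float, ...] = ()
    base_scout_prob: float = 0.3

    def __post_init__(self) -> None:
        if len(self.effect_loci) != len(self.effect_sizes):
            raise ValueError("effect_loci and effect_sizes must have equal length")
        if not 0.0 < self.base_scout_prob < 1.0:
            raise ValueError("base_scout_prob must lie in (0, 1)")


@dataclass
class CallNoiseModel:
    """Read-level noise for genotype calling at a capped sequencing depth.

    Per cell the depth is Poisson(mean_depth) truncated at depth_cap (the cap
    used during calling); each read reports the wrong allele with probability
    allele_error; cells with depth below min_call_depth are missing.
    """

    mean_depth: float = 10.0
    depth_cap: int = 100
    allele_error: float = 0.01
    min_call_depth: int = 1
    hom_support: float = 0.90  # min read fraction for a homozygous call

    def __post_init__(self) -> None:
        if not (self.depth_cap >= self.mean_depth >= 0):
            raise ValueError("require depth_cap >= mean_depth >= 0")
        if not 0.0 <= self.allele_error < 0.5:
            raise ValueError("allele_error must lie in [0, 0.5)")


# ---------------------------------------------------------------------------
# colony genetics
# ---------------------------------------------------------------------------

def simulate_colony(
    n_loci: int,
    n_workers: int,
    queen_het_fraction: float,
    seed: int,
    n_chroms: int = 16,
) -> ColonyDesign:
    """Draw the parental genotypes of a one-patriline colony.

    Each locus is independently queen-heterozygous with probability
    ``queen_het_fraction`` (otherwise homozygous R or N equiprobably) and
    receives a drone allele drawn uniformly from {R, N}.  Loci are laid out
    in blocks over ``n_chroms`` linkage groups with random spacing.
    """
    if n_loci <= 0 or n_workers <= 0:
        raise ValueError("n_loci and n_workers must be positive")
    if not 0.0 <= queen_het_fraction <= 1.0:
        raise ValueError("queen_het_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    het = rng.random(n_loci) < queen_het_fraction
    hom_allele = rng.integers(0, 2, size=n_loci)  # 0 -> R, 1 -> N
    drone = rng.integers(0, 2, size=n_loci)
    gaps = rng.integers(200, 5001, size=n_loci)
    per_chrom = -(-n_loci // n_chroms)  # ceil
    loci: list[Locus] = []
    pos = 0
    for i in range(n_loci):
        chrom_idx = i // per_chrom
        if i % per_chrom == 0:
            pos = 0
        pos += int(gaps[i])
        queen = ("R", "N") if het[i] else (ALLELES[hom_allele[i]],) * 2
        loci.append(Locus(
            chrom=f"LG{chrom_idx + 1:02d}",
            pos=pos,
            queen_gt=queen,
            drone_allele=ALLELES[drone[i]],
        ))
    return ColonyDesign(loci=loci, n_workers=n_workers, seed=seed)


def _dose(design: ColonyDesign) -> np.ndarray:
    """Worker x locus matrix of true N-allele doses (0, 1 or 2)."""
    rng = np.random.default_rng([design.seed, 1])
    n_w, n_l = design.n_workers, len(design.loci)
    queen_pick = rng.integers(0, 2, size=(n_w, n_l))
    queen_alleles = np.array([[int(a == "N") for a in l.queen_gt] for l in design.loci])
    drone_dose = np.array([int(l.drone_allele == "N") for l in design.loci])
    maternal = queen_alleles[np.arange(n_l)[None, :], queen_pick]
    return maternal + drone_dose[None, :]


def position_keys(design: ColonyDesign) -> list[str]:
    return [f"{l.chrom}:{l.pos}" for l in design.loci]


def worker_ids(design: ColonyDesign) -> list[str]:
    width = len(str(design.n_workers))
    return [f"bee{i + 1:0{width}d}" for i in range(design.n_workers)]


def inherit_worker_genotypes(design: ColonyDesign) -> pd.DataFrame:
    """True diploid worker genotypes (strings "RR"/"RN"/"NN").

    Every worker inherits the drone allele plus one queen allele drawn
    uniformly and independently per locus, so a queen-heterozygous locus
    segregates two genotypes in expected 1:1 proportion and a
    queen-homozygous locus is monomorphic.
    """
    dose = _dose(design)
    return pd.DataFrame(GT_BY_DOSE[dose], index=worker_ids(design),
                        columns=position_keys(design))


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def assign_castes(
    true_genotypes: pd.DataFrame, model: CasteModel, seed: int
) -> pd.Series:
    """Draw scout/recruit labels from the logistic predilection model."""
    if true_genotypes.shape[0] == 0 or true_genotypes.shape[1] == 0:
        raise ValueError("empty genotype table")
    n_loci = true_genotypes.shape[1]
    for idx in model.effect_loci:
        if not 0 <= idx < n_loci:
            raise ValueError(f"effect locus index {idx} out of range")
    dose = np.zeros(true_genotypes.shape[0])
    for idx, beta in zip(model.effect_loci, model.effect_sizes):
        col = true_genotypes.iloc[:, idx].map({"RR": 0, "RN": 1, "NN": 2}).to_numpy()
        dose = dose + beta * col
    logits = _logit(model.base_scout_prob) + dose
    p_scout = 1.0 / (1.0 + np.exp(-logits))
    rng = np.random.default_rng(seed)
    labels = np.where(rng.random(len(p_scout)) < p_scout, "scout", "recruit")
    return pd.Series(labels, index=true_genotypes.index, name="caste")


def simulate_genotype_calls(
    true_genotypes: pd.DataFrame,
    noise: CallNoiseModel,
    seed: int,
    mean_depth_per_individual: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Noisy genotype calls plus realized per-individual coverage.

    Per cell, ``depth ~ Poisson(mean_depth)`` truncated at ``depth_cap``.
    Each read samples one of the two chromosome copies and reports its base
    correctly with probability ``1 - allele_error``; a misread lands
    uniformly on the three other bases, so only a third of misreads mimic
    the opposite allele while the rest show a third base and are discarded
    from the biallelic tally.  The call is homozygous when at least
    ``hom_support`` (default 90%) of the informative reads support one
    allele, heterozygous when both alleles are seen above the complementary
    10% fraction, and missing below ``min_call_depth``.  Coverage is the
    realized mean depth across loci.
    """
    rng = np.random.default_rng(seed)
    n_w, n_l = true_genotypes.shape
    lam = np.full(n_w, float(noise.mean_depth))
    if mean_depth_per_individual is not None:
        lam = np.asarray(mean_depth_per_individual, dtype=float)
        if lam.shape != (n_w,):
            raise ValueError("mean_depth_per_individual must have one entry per worker")
    depth = np.minimum(rng.poisson(lam[:, None], size=(n_w, n_l)), noise.depth_cap)
    dose = true_genotypes.map(lambda g: {"RR": 0, "RN": 1, "NN": 2}[g]).to_numpy()
    p_true = dose / 2.0
    e = noise.allele_error
    # third-base misreads carry no R/N information
    n_junk = rng.binomial(depth, 2.0 * e / 3.0)
    informative = depth - n_junk
    p_read_n = (p_true * (1.0 - e) + (1.0 - p_true) * e / 3.0) / (1.0 - 2.0 * e / 3.0)
    n_reads_n = rng.binomial(informative, p_read_n)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_n = np.where(informative > 0, n_reads_n / np.maximum(informative, 1), np.nan)
    calls = np.where(frac_n >= noise.hom_support, "NN",
                     np.where(frac_n <= 1.0 - noise.hom_support, "RR", "RN"))
    calls = calls.astype(object)
    missing = (informative < max(noise.min_call_depth, 1))
    calls[missing] = np.nan
    calls_df = pd.DataFrame(calls, index=true_genotypes.index,
                            columns=true_genotypes.columns)
    coverage = pd.Series(depth.mean(axis=1), index=true_genotypes.index,
                         name="coverage")
    return calls_df, coverage


def variant_metadata(design: ColonyDesign, indel_fraction: float = 0.1) -> pd.DataFrame:
    """Invent ref/alt alleles (mostly SNPs, some 1-2 bp indels) per locus."""
    rng = np.random.default_rng([design.seed, 2])
    bases = np.array(list("ACGT"))
    rows = []
    for locus in design.loci:
        ref = str(rng.choice(bases))
        if rng.random() < indel_fraction:
            if rng.random() < 0.5:  # deletion relative to the reference
                ref, alt = ref + str(rng.choice(bases)), ref
            else:
                ref, alt = ref, ref + str(rng.choice(bases))
            vtype = "indel"
        else:
            alt = str(rng.choice(bases[bases != ref]))
            vtype = "SNP"
        rows.append({"chrom": locus.chrom, "pos": locus.pos,
                     "ref": ref, "alt": alt, "vtype": vtype})
    return pd.DataFrame(rows, index=position_keys(design))


def first_backcross_locus(design: ColonyDesign, drone_allele: str = "R") -> int:
    """Index of the first queen-heterozygous locus with the given drone allele.

    Useful for planting caste effects: with drone allele R the workers split
    RR:RN in expected 1:1, so an N-dose effect shifts the caste balance
    without saturating the colony with scouts.
    """
    for i, locus in enumerate(design.loci):
        if locus.queen_heterozygous and locus.drone_allele == drone_allele:
            return i
    raise ValueError("no queen-heterozygous locus with the requested drone allele")


def sample_balanced_castes(
    caste: pd.Series, n_scouts: int, n_recruits: int, seed: int
) -> list[str]:
    """Sample a fixed number of scouts and recruits from a colony's workers."""
    rng = np.random.default_rng(seed)
    picked: list[str] = []
    for label, n in (("scout", n_scouts), ("recruit", n_recruits)):
        pool = caste.index[caste == label].to_numpy()
        if len(pool) < n:
            raise ValueError(f"only {len(pool)} {label}s available, need {n}")
        picked.extend(rng.choice(pool, size=n, replace=False))
    return picked


def simulate_observed_matrix(
    design: ColonyDesign,
    caste_model: CasteModel,
    noise: CallNoiseModel,
    seed: int,
    n_scouts: int = 22,
    n_recruits: int = 22,
    n_low_coverage_scouts: int = 0,
    low_coverage_depth: float = 2.0,
) -> GenotypeMatrix:
    """Full study emulation: colony -> castes -> balanced sample -> noisy calls.

    Workers are drawn from the colony, castes assigned by the predilection
    model, and a balanced sample of ``n_scouts`` + ``n_recruits`` bees is
    sequenced.  Optionally the first ``n_low_coverage_scouts`` sampled scouts
    are sequenced at ``low_coverage_depth`` X, emulating atypical
    low-coverage individuals that the coverage filter must remove.
    """
    truth = inherit_worker_genotypes(design)
    caste = assign_castes(truth, caste_model, seed=seed + 11)
    picked = sample_balanced_castes(caste, n_scouts, n_recruits, seed=seed + 13)
    truth = truth.loc[picked]
    caste = caste.loc[picked]
    lam = np.full(len(picked), float(noise.mean_depth))
    lam[:n_low_coverage_scouts] = low_coverage_depth
    calls, coverage = simulate_genotype_calls(
        truth, noise, seed=seed + 17, mean_depth_per_individual=lam)
    return GenotypeMatrix(calls=calls, caste=caste, coverage=coverage,
                          variants=variant_metadata(design))


def simulate_sister_sharing(n_pairs: int, system: str, seed: int) -> float:
    """Monte-Carlo fraction of allele copies shared by random full-sister pairs.

    Sisters are drawn at a locus where both parents are maximally informative
    (queen heterozygous; diploid sire heterozygous in the diploid system).
    Under haplodiploidy the haploid father transmits the same allele to every
    daughter, so only the maternal allele can differ.
    """
    rng = np.random.default_rng(seed)
    mat_same = rng.integers(0, 2, size=(2, n_pairs))
    maternal_shared = mat_same[0] == mat_same[1]
    if system == "haplodiploid":
        paternal_shared = np.ones(n_pairs, dtype=bool)
    elif system == "diploid":
        pat = rng.integers(0, 2, size=(2, n_pairs))
        paternal_shared = pat[0] == pat[1]
    else:
        raise ValueError(f"unknown inheritance system: {system!r}")
    return float((paternal_shared.astype(float) + maternal_shared).mean() / 2.0)


# ---------------------------------------------------------------------------
# FASTQ fixture generator with planted QC violations
# ---------------------------------------------------------------------------

@dataclass
class ContaminationSpec:
    """Fractions of read pairs planted with each quality-control violation."""

    frac_n_rich: float = 0.0
    frac_low_quality: float = 0.0
    frac_adapter: float = 0.0
    adapter: str = TRUSEQ_ADAPTER

    def __post_init__(self) -> None:
        fracs = (self.frac_n_rich, self.frac_low_quality, self.frac_adapter)
        if any(f < 0 for f in fracs) or sum(fracs) > 1.0:
            raise ValueError("contamination fractions must be >= 0 and sum to <= 1")


def _seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _adapter_like(seq: str, adapter: str, min_overlap: int = 10,
                  max_mismatch_frac: float = 0.10) -> bool:
    """Planted-truth oracle: ungapped sliding match against both orientations."""
    read = _seq_to_array(seq)
    for ad_seq in (adapter, _revcomp(adapter)):
        ad = _seq_to_array(ad_seq)
        for offset in range(-(len(ad) - 1), len(read)):
            start, end = max(0, offset), min(len(read), offset + len(ad))
            overlap = end - start
            if overlap <= min_overlap:
                continue
            mism = int(np.count_nonzero(read[start:end] != ad[start - offset:end - offset]))
            if mism <= max_mismatch_frac * overlap:
                return True
    return False


def simulate_fastq_pairs(
    n_pairs: int,
    spec: ContaminationSpec,
    seed: int,
    out1,
    out2,
    read_length: int = 100,
) -> pd.DataFrame:
    """Write a paired FASTQ fixture (Phred+33) with planted QC violations.

    Clean reads have qualities in [30, 40] and are rejection-sampled so they
    contain no accidental adapter-like stretch.  Planted violations:
    12% N bases (trips the >= 10% rule), 60% of bases below Phred 5 (trips
    the > 50% rule), or an embedded 15-nt exact adapter prefix (trips the
    "> 10 aligned, <= 10% mismatch" rule).  Returns the planted-truth
    manifest (pair_id, mate, rule) for pairs that must be dropped.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    categories = ("n_rich", "low_quality", "adapter")
    probs = (spec.frac_n_rich, spec.frac_low_quality, spec.frac_adapter)
    draw = rng.choice(4, size=n_pairs,
                      p=(*probs, 1.0 - sum(probs)))

    def clean_read() -> tuple[str, np.ndarray]:
        while True:
            seq = "".join(rng.choice(bases, size=read_length))
            if not _adapter_like(seq, spec.adapter):
                return seq, rng.integers(30, 41, size=read_length)

    def planted_read(category: str) -> tuple[str, np.ndarray]:
        seq, qual = clean_read()
        arr = np.array(list(seq))
        if category == "n_rich":
            n_n = int(np.ceil(0.12 * read_length))
            pos = rng.choice(read_length, size=n_n, replace=False)
            arr[pos] = "N"
            qual = qual.copy()
            qual[pos] = 2
        elif category == "low_quality":
            n_low = int(np.ceil(0.60 * read_length))
            pos = rng.choice(read_length, size=n_low, replace=False)
            qual = qual.copy()
            qual[pos] = rng.integers(0, 5, size=n_low)
        elif category == "adapter":
            if rng.random() < 0.5 and len(spec.adapter) <= read_length:
                # full adapter read into the insert
                insert = spec.adapter
                start = int(rng.integers(0, read_length - len(insert) + 1))
                arr[start:start + len(insert)] = list(insert)
            else:
                # 3' read-through: adapter prefix at the end of the read
                insert = spec.adapter[:15]
                arr[read_length - len(insert):] = list(insert)
        return "".join(arr), qual

    manifest_rows = []
    with open(out1, "w") as f1, open(out2, "w") as f2:
        for i in range(n_pairs):
            pair_id = f"pair{i:06d}"
            mates: list[tuple[str, np.ndarray]] = [clean_read(), clean_read()]
            if draw[i] < 3:
                category = categories[draw[i]]
                mate = int(rng.integers(0, 2))
                mates[mate] = planted_read(category)
                manifest_rows.append(
                    {"pair_id": pair_id, "mate": mate + 1, "rule": category})
            for f, (seq, qual), mate_no in ((f1, mates[0], 1), (f2, mates[1], 2)):
                qstr = "".join(chr(q + 33) for q in qual)
                f.write(f"@{pair_id}/{mate_no}\n{seq}\n+\n{qstr}\n")
    return pd.DataFrame(manifest_rows, columns=["pair_id", "mate", "rule"])


# ---------------------------------------------------------------------------
# BLAST-hit fixture generator for the taxonomy stage
# ---------------------------------------------------------------------------

#: taxonomic groups mirroring the unmapped-read homology summary, with
#: annotation strings that exercise the repeat/ribosomal subclassification
GROUP_CATALOG: dict[str, dict] = {
    "Apis-repeat": dict(kingdom="Eukaryota", label="Apis", is_apis=True,
                        is_arthropoda=True, is_nosema=False,
                        annotations=["Apis mellifera AvaI repeat region",
                                     "Apis mellifera microsatellite locus"]),
    "Apis-ribosomal": dict(kingdom="Eukaryota", label="Apis", is_apis=True,
                           is_arthropoda=True, is_nosema=False,
                           annotations=["Apis mellifera 18S ribosomal RNA gene",
                                        "Apis dorsata 28S ribosomal RNA gene"]),
    "Apis-other": dict(kingdom="Eukaryota", label="Apis", is_apis=True,
                       is_arthropoda=True, is_nosema=False,
                       annotations=["Apis dorsata titin-like mRNA",
                                    "Apis florea mucin-2-like mRNA"]),
    "Arthropoda-repeat": dict(kingdom="Eukaryota", label="Arthropoda",
                              is_apis=False, is_arthropoda=True, is_nosema=False,
                              annotations=["Bombus terrestris microsatellite 4A46"]),
    "Arthropoda-ribosomal": dict(kingdom="Eukaryota", label="Arthropoda",
                                 is_apis=False, is_arthropoda=True, is_nosema=False,
                                 annotations=["Drosophila melanogaster 28S ribosomal RNA"]),
    "Arthropoda-other": dict(kingdom="Eukaryota", label="Arthropoda",
                             is_apis=False, is_arthropoda=True, is_nosema=False,
                             annotations=["Tribolium castaneum linkage group 3"]),
    "Nosema": dict(kingdom="Eukaryota", label="Nosema", is_apis=False,
                   is_arthropoda=False, is_nosema=True,
                   annotations=["Nosema ceranae BRL01 genomic scaffold"]),
    "Other Eukaryota": dict(kingdom="Eukaryota", label="Other Eukaryota",
                            is_apis=False, is_arthropoda=False, is_nosema=False,
                            annotations=["Homo sapiens chromosome 7 contig",
                                         "Zea mays chromosome 1 clone"]),
    "Bartonella": dict(kingdom="Bacteria", label="Bartonella", is_apis=False,
                       is_arthropoda=False, is_nosema=False,
                       annotations=["Bartonella apis strain BBC0122 genome"]),
    "Bifidobacterium": dict(kingdom="Bacteria", label="Bifidobacterium",
                            is_apis=False, is_arthropoda=False, is_nosema=False,
                            annotations=["Bifidobacterium asteroides PRL2011 genome"]),
    "Gilliamella": dict(kingdom="Bacteria", label="Gilliamella", is_apis=False,
                        is_arthropoda=False, is_nosema=False,
                        annotations=["Gilliamella apicola wkB1 complete genome"]),
    "Lactobacillus": dict(kingdom="Bacteria", label="Lactobacillus", is_apis=False,
                          is_arthropoda=False, is_nosema=False,
                          annotations=["Lactobacillus kunkeei genome assembly"]),
    "Snodgrassella": dict(kingdom="Bacteria", label="Snodgrassella", is_apis=False,
                          is_arthropoda=False, is_nosema=False,
                          annotations=["Snodgrassella alvi wkB2 complete genome"]),
    "Other Bacteria": dict(kingdom="Bacteria", label="Other Bacteria", is_apis=False,
                           is_arthropoda=False, is_nosema=False,
                           annotations=["Escherichia coli str. K-12 complete genome"]),
    "Other species": dict(kingdom="Other", label="Other species", is_apis=False,
                          is_arthropoda=False, is_nosema=False,
                          annotations=["synthetic construct cloning vector"]),
}


def make_taxon_map() -> pd.DataFrame:
    """Accession -> taxon table covering every catalog group."""
    rows = {}
    for gi, (group, info) in enumerate(GROUP_CATALOG.items()):
        prefix = "".join(ch for ch in group if ch.isalnum())[:8].upper()
        for j, ann in enumerate(info["annotations"]):
            acc = f"{prefix}{gi:02d}_{j:03d}.1"
            rows[acc] = {
                "kingdom": info["kingdom"], "label": info["label"],
                "is_apis": info["is_apis"], "is_arthropoda": info["is_arthropoda"],
                "is_nosema": info["is_nosema"], "annotation": ann,
            }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "accession"
    return df


def simulate_blast_hits(
    reads_per_caste: Mapping[str, int],
    taxon_mixture_per_caste: Mapping[str, Mapping[str, float]],
    seed: int,
    weak_hit_frac: float = 0.05,
    decoy_frac: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate BLASTN tabular hits of unmapped reads for each caste.

    Every read receives at least one hit row.  A ``weak_hit_frac`` fraction
    of reads gets only an e-value of 1e-5 (above the 1e-10 retention
    threshold, so the read ends up unmatched); the rest get a strong best hit
    drawn from the caste's taxon mixture, and a ``decoy_frac`` fraction a
    second lower-bitscore hit.  Returns (hits, taxon_map, truth) where truth
    records the planted group per read (NaN for reads planted unmatched).
    """
    rng = np.random.default_rng(seed)
    taxon_map = make_taxon_map()
    acc_by_group = {
        group: [acc for acc, row in taxon_map.iterrows()
                if row["annotation"] in info["annotations"]]
        for group, info in GROUP_CATALOG.items()
    }
    hit_rows, truth_rows = [], []
    for caste, n_reads in reads_per_caste.items():
        mixture = taxon_mixture_per_caste[caste]
        groups = list(mixture)
        pvec = np.array([mixture[g] for g in groups], dtype=float)
        if not np.isclose(pvec.sum(), 1.0) or (pvec < 0).any():
            raise ValueError(f"mixture for caste {caste!r} is not a probability vector")
        for i in range(n_reads):
            read_id = f"{caste}_read{i:07d}"
            if rng.random() < weak_hit_frac:
                group = groups[rng.choice(len(groups), p=pvec)]
                acc = acc_by_group[group][int(rng.integers(len(acc_by_group[group])))]
                hit_rows.append((read_id, acc, 85.0, 60, 1e-5, 40.0,
                                 str(taxon_map.loc[acc, "annotation"]), caste))
                truth_rows.append((read_id, caste, np.nan))
                continue
            group = groups[rng.choice(len(groups), p=pvec)]
            acc = acc_by_group[group][int(rng.integers(len(acc_by_group[group])))]
            evalue = 10.0 ** -rng.uniform(12, 40)
            bitscore = float(rng.uniform(90, 200))
            hit_rows.append((read_id, acc, float(rng.uniform(90, 100)), 100,
                             evalue, bitscore,
                             str(taxon_map.loc[acc, "annotation"]), caste))
            truth_rows.append((read_id, caste, group))
            if rng.random() < decoy_frac:
                other = groups[rng.choice(len(groups), p=pvec)]
                acc2 = acc_by_group[other][int(rng.integers(len(acc_by_group[other])))]
                hit_rows.append((read_id, acc2, float(rng.uniform(80, 95)), 80,
                                 evalue * 10, bitscore - float(rng.uniform(5, 30)),
                                 str(taxon_map.loc[acc2, "annotation"]), caste))
    hits = pd.DataFrame(hit_rows, columns=[
        "qseqid", "sseqid", "pident", "length", "evalue", "bitscore",
        "stitle", "caste"])
    truth = pd.DataFrame(truth_rows, columns=["read_id", "caste", "group"])
    return hits, taxon_map.drop(columns="annotation"), truth


# ---------------------------------------------------------------------------
# toy reference genome + gene models (for annotation / TFBS stages)
# ---------------------------------------------------------------------------

def simulate_reference_genome(
    seed: int,
    chrom_lengths: Mapping[str, int] | None = None,
    genes_per_chrom: int = 2,
) -> tuple[dict[str, str], str]:
    """Random reference sequences plus a small GFF3 gene annotation.

    Genes alternate strand, each with one mRNA of two exons and a CDS whose
    flanking exon stretches become the untranslated regions.  Returns
    (sequences by chrom, GFF3 text).
    """
    if chrom_lengths is None:
        chrom_lengths = {"LG01": 30000, "LG02": 30000}
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seqs = {c: "".join(rng.choice(bases, size=n)) for c, n in chrom_lengths.items()}
    lines = ["##gff-version 3"]
    gene_no = 0
    for chrom, length in chrom_lengths.items():
        lines.append(f"##sequence-region {chrom} 1 {length}")
        spacing = length // (genes_per_chrom + 1)
        for g in range(genes_per_chrom):
            gene_no += 1
            start = spacing * (g + 1)
            strand = "+" if gene_no % 2 else "-"
            gid, tid = f"gene{gene_no}", f"mRNA{gene_no}"
            # exon1 [start, start+499], intron 500, exon2 [start+1000, start+1599]
            e1 = (start, start + 499)
            e2 = (start + 1000, start + 1599)
            if strand == "+":
                cds = [(start + 100, start + 499), (start + 1000, start + 1499)]
            else:
                cds = [(start + 100, start + 499), (start + 1000, start + 1499)]
            end = e2[1]
            lines.append(f"{chrom}\tsim\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid};Name={gid}")
            lines.append(f"{chrom}\tsim\tmRNA\t{start}\t{end}\t.\t{strand}\t.\tID={tid};Parent={gid}")
            for (a, b) in (e1, e2):
                lines.append(f"{chrom}\tsim\texon\t{a}\t{b}\t.\t{strand}\t.\tParent={tid}")
            for (a, b) in cds:
                lines.append(f"{chrom}\tsim\tCDS\t{a}\t{b}\t.\t{strand}\t0\tParent={tid}")
    return seqs, "\n".join(lines) + "\n"
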