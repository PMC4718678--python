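"""End-to-end orchestration of the synthetic scout/recruit study.

Stages run in order: simulate -> qc -> taxonomy -> assoc -> annotate ->
ld -> tfbs.  Every stage reads and writes plain TSV/FASTQ/FASTA/GFF3 files
in the run directory, so each stage can also be rerun standalone from the
previous stage's outputs; a JSON manifest records the configuration, seed
and per-stage tallies, which together reproduce a run exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib.metadata import version as pkg_version
from pathlib import Path

import pandas as pd
import yaml

from . import annotate as ann
from . import assoc, colony, io, ld, readqc, taxonomy, tfbs

ALL_STAGES = ("simulate", "qc", "taxonomy", "assoc", "annotate", "ld", "tfbs")

DEFAULT_MIXTURES = {
    "scout": {
        "Apis-ribosomal": 0.10, "Apis-repeat": 0.05, "Apis-other": 0.05,
        "Arthropoda-ribosomal": 0.05, "Nosema": 0.05,
        "Gilliamella": 0.25, "Snodgrassella": 0.20, "Lactobacillus": 0.08,
        "Bifidobacterium": 0.07, "Bartonella": 0.03, "Other Bacteria": 0.05,
        "Other Eukaryota": 0.02,
    },
    "recruit": {
        "Apis-ribosomal": 0.20, "Apis-repeat": 0.10, "Apis-other": 0.10,
        "Arthropoda-ribosomal": 0.10,
        "Snodgrassella": 0.30, "Gilliamella": 0.10, "Other Bacteria": 0.05,
        "Other Eukaryota": 0.05,
    },
}


@dataclass
class PipelineConfig:
    """All knobs of a synthetic end-to-end run (YAML round-trippable)."""

    seed: int = 1
    stages: tuple[str, ...] = ALL_STAGES
    # colony
    n_loci: int = 2000
    n_workers: int = 600
    queen_het_fraction: float = 0.5
    n_scouts: int = 22
    n_recruits: int = 22
    n_low_coverage_scouts: int = 1
    # with auto_effect_locus the effect is planted at the first
    # queen-heterozygous locus whose drone allele is R (RR:RN backcross split)
    auto_effect_locus: bool = True
    effect_loci: tuple[int, ...] = ()
    effect_sizes: tuple[float, ...] = (4.0,)
    base_scout_prob: float = 0.3
    # genotype calling noise
    mean_depth: float = 10.0
    depth_cap: int = 100
    allele_error: float = 0.01
    min_call_depth: int = 1
    # read QC
    n_fastq_pairs: int = 300
    frac_n_rich: float = 0.05
    frac_low_quality: float = 0.05
    frac_adapter: float = 0.05
    adapter: str = colony.TRUSEQ_ADAPTER
    # taxonomy
    blast_reads_per_caste: int = 400
    evalue_threshold: float = 1e-10
    # association
    alpha: float = 1e-4
    min_coverage: float = 3.0
    # annotation / LD / TFBS
    flank: int = 5000
    max_gap: int = 300_000
    tfbs_threshold: float = 0.80
    tfbs_half_width: int = 1000

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.tfbs_threshold <= 1.0 + 1e-9:
            raise ValueError("tfbs_threshold must lie in (0, 1]")

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["stages"] = list(self.stages)
        data["effect_loci"] = list(self.effect_loci)
        data["effect_sizes"] = list(self.effect_sizes)
        with open(path, "w") as out:
            yaml.safe_dump(data, out, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("stages", "effect_loci", "effect_sizes"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def run_pipeline(config: PipelineConfig, run_dir) -> dict:
    """Execute the enabled stages; returns the run manifest (also on disk)."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "apiscout",
        "version": pkg_version("apiscout"),
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=list)),
        "stages": {},
    }
    paths = {
        "calls": run_dir / "genotypes.tsv",
        "samples": run_dir / "samples.tsv",
        "variants": run_dir / "variants.tsv",
        "fastq1": run_dir / "reads_1.fastq",
        "fastq2": run_dir / "reads_2.fastq",
        "qc1": run_dir / "reads_1.qc.fastq",
        "qc2": run_dir / "reads_2.qc.fastq",
        "qc_manifest": run_dir / "qc_planted_manifest.tsv",
        "hits": run_dir / "unmapped_hits.tsv",
        "taxa": run_dir / "taxon_map.tsv",
        "tax_summary": run_dir / "taxonomy_summary.tsv",
        "fasta": run_dir / "reference.fasta",
        "gff": run_dir / "genes.gff3",
        "pwms": run_dir / "profiles.jaspar",
        "assoc": run_dir / "assoc_results.tsv",
        "crosstab": run_dir / "significance_by_location.tsv",
        "annot": run_dir / "variant_annotations.tsv",
        "corr": run_dir / "caste_correlations.tsv",
        "clusters": run_dir / "position_clusters.tsv",
        "tfbs": run_dir / "tfbs_hits.tsv",
    }
    if "simulate" in config.stages:
        _stage_simulate(config, paths, manifest)
    if "qc" in config.stages:
        _stage_qc(config, paths, manifest)
    if "taxonomy" in config.stages:
        _stage_taxonomy(config, paths, manifest)
    if "assoc" in config.stages:
        _stage_assoc(config, paths, manifest)
    if "annotate" in config.stages:
        _stage_annotate(config, paths, manifest)
    if "ld" in config.stages:
        _stage_ld(config, paths, manifest)
    if "tfbs" in config.stages:
        _stage_tfbs(config, paths, manifest)
    with open(run_dir / "manifest.json", "w") as out:
        json.dump(manifest, out, indent=2, sort_keys=True)
    return manifest


def _stage_simulate(config: PipelineConfig, paths, manifest) -> None:
    design = colony.simulate_colony(
        config.n_loci, config.n_workers, config.queen_het_fraction, config.seed)
    effect_loci = tuple(config.effect_loci)
    if config.auto_effect_locus and config.effect_sizes:
        effect_loci = (colony.first_backcross_locus(design),)
    caste_model = colony.CasteModel(
        effect_loci=effect_loci,
        effect_sizes=tuple(config.effect_sizes)[:len(effect_loci)],
        base_scout_prob=config.base_scout_prob)
    noise = colony.CallNoiseModel(
        mean_depth=config.mean_depth, depth_cap=config.depth_cap,
        allele_error=config.allele_error, min_call_depth=config.min_call_depth)
    matrix = colony.simulate_observed_matrix(
        design, caste_model, noise, seed=config.seed,
        n_scouts=config.n_scouts, n_recruits=config.n_recruits,
        n_low_coverage_scouts=config.n_low_coverage_scouts)
    io.write_genotype_matrix(matrix, paths["calls"], paths["samples"], paths["variants"])
    spec = colony.ContaminationSpec(
        frac_n_rich=config.frac_n_rich, frac_low_quality=config.frac_low_quality,
        frac_adapter=config.frac_adapter, adapter=config.adapter)
    qc_manifest = colony.simulate_fastq_pairs(
        config.n_fastq_pairs, spec, seed=config.seed + 101,
        out1=paths["fastq1"], out2=paths["fastq2"])
    qc_manifest.to_csv(paths["qc_manifest"], sep="\t", index=False)
    hits, taxon_map, _truth = colony.simulate_blast_hits(
        {"scout": config.blast_reads_per_caste,
         "recruit": config.blast_reads_per_caste},
        DEFAULT_MIXTURES, seed=config.seed + 103)
    io.write_blast_tab(hits, paths["hits"])
    io.write_taxon_map(taxon_map, paths["taxa"])
    chrom_lengths = {f"LG{i + 1:02d}": 30000 for i in range(2)}
    seqs, gff_text = colony.simulate_reference_genome(
        config.seed + 107, chrom_lengths=chrom_lengths)
    io.write_fasta(seqs, paths["fasta"])
    paths["gff"].write_text(gff_text)
    paths["pwms"].write_text(tfbs.EXAMPLE_JASPAR)
    manifest["stages"]["simulate"] = {
        "effect_loci": list(effect_loci),
        "n_loci": config.n_loci,
        "n_sampled_bees": matrix.n_individuals,
        "n_planted_qc_violations": int(len(qc_manifest)),
    }


def _stage_qc(config: PipelineConfig, paths, manifest) -> None:
    rules = readqc.QCRuleSet(adapter=config.adapter)
    stats = readqc.run_qc(paths["fastq1"], paths["fastq2"],
                          paths["qc1"], paths["qc2"], rules)
    manifest["stages"]["qc"] = {
        "pairs_in": stats.pairs_in,
        "pairs_kept": stats.pairs_kept,
        "dropped_by_rule": dict(stats.dropped_by_rule),
        "bases_trimmed": stats.bases_trimmed,
    }


def _stage_taxonomy(config: PipelineConfig, paths, manifest) -> None:
    hits = io.read_blast_tab(paths["hits"])
    taxon_map = io.read_taxon_map(paths["taxa"])
    caste_of_read = pd.Series(
        {rid: rid.split("_", 1)[0] for rid in hits["qseqid"].unique()})
    best = taxonomy.best_hit_per_read(hits, evalue_threshold=config.evalue_threshold)
    summary = taxonomy.summarize(best, caste_of_read, taxon_map)
    summary.to_csv(paths["tax_summary"], sep="\t", index_label="group")
    manifest["stages"]["taxonomy"] = {
        "reads_matched": int(len(best)),
        "groups": int(len(summary) - 1),
    }


def _stage_assoc(config: PipelineConfig, paths, manifest) -> None:
    matrix = io.read_genotype_matrix(paths["calls"], paths["samples"], paths["variants"])
    results, tally = assoc.run_association(
        matrix, alpha=config.alpha, min_coverage=config.min_coverage)
    results.to_csv(paths["assoc"], sep="\t", na_rep="NA", index_label="position")
    manifest["stages"]["assoc"] = {
        "position_classes": tally,
        "significant": int(results["significant"].sum()) if len(results) else 0,
    }


def _load_results(paths) -> pd.DataFrame:
    return pd.read_csv(paths["assoc"], sep="\t", index_col="position",
                       na_values="NA")


def _stage_annotate(config: PipelineConfig, paths, manifest) -> None:
    results = _load_results(paths)
    genes = ann.read_gff3(paths["gff"])
    reference = io.read_fasta(paths["fasta"])
    variants_meta = pd.read_csv(paths["variants"], sep="\t", index_col="position")
    variants = []
    for key in results.index:
        row = variants_meta.loc[key]
        chrom = str(row["chrom"])
        # loci beyond the toy reference keep their class via the gene models only
        variants.append(ann.Variant(chrom=chrom, pos=int(row["pos"]),
                                    ref=str(row["ref"]), alt=str(row["alt"]),
                                    vtype=str(row["vtype"])))
    rows = ann.annotate_variants(variants, genes, reference=None, flank=config.flank)
    annot = pd.DataFrame(rows, index=results.index)
    annot.to_csv(paths["annot"], sep="\t", na_rep="NA", index_label="position")
    patterns = {k: tuple(p.split("/")) for k, p in results["pattern"].items()}
    locations = dict(annot["location"])
    table = assoc.cross_tab(patterns, locations)
    table.to_csv(paths["crosstab"], sep="\t", index_label="pattern")
    manifest["stages"]["annotate"] = {
        "location_counts": annot["location"].value_counts().to_dict(),
    }


def _stage_ld(config: PipelineConfig, paths, manifest) -> None:
    results = _load_results(paths)
    matrix = io.read_genotype_matrix(paths["calls"], paths["samples"], paths["variants"])
    matrix = assoc.filter_individuals(matrix, min_coverage=config.min_coverage)
    sig = results.index[results["significant"].astype(bool)]
    if len(sig) < 2:  # fall back to the most associated positions
        pcols = [c for c in results.columns if c.startswith("p_")]
        sig = results[pcols].min(axis=1).nsmallest(10).index
    encoded = ld.encode_genotypes(matrix.calls[list(sig)])
    scout_m = ld.caste_correlation(encoded, matrix.caste, "scout")
    recruit_m = ld.caste_correlation(encoded, matrix.caste, "recruit")
    ld.heatmap_export(scout_m, recruit_m, paths["corr"])
    clusters = ld.cluster_by_distance(
        results.loc[sig, ["chrom", "pos"]], max_gap=config.max_gap)
    pd.DataFrame(
        [{"cluster": i + 1, "position": p} for i, cl in enumerate(clusters) for p in cl]
    ).to_csv(paths["clusters"], sep="\t", index=False)
    manifest["stages"]["ld"] = {"positions": int(len(sig)),
                                "clusters": len(clusters)}


def _stage_tfbs(config: PipelineConfig, paths, manifest) -> None:
    results = _load_results(paths)
    reference = io.read_fasta(paths["fasta"])
    pwms = tfbs.read_jaspar(paths["pwms"])
    sig = results[results["significant"].astype(bool)]
    if sig.empty:
        pcols = [c for c in results.columns if c.startswith("p_")]
        sig = results.loc[results[pcols].min(axis=1).nsmallest(5).index]
    targets = [(str(r["chrom"]), int(r["pos"])) for _, r in sig.iterrows()
               if str(r["chrom"]) in reference and int(r["pos"]) <= len(reference[str(r["chrom"])])]
    rows = tfbs.scan_variants(targets, reference, pwms,
                              threshold=config.tfbs_threshold,
                              half_width=config.tfbs_half_width)
    pd.DataFrame(rows, columns=["chrom", "pos", "profile", "strand", "start", "score"]
                 ).to_csv(paths["tfbs"], sep="\t", index=False)
    manifest["stages"]["tfbs"] = {
        "variants_scanned": len(targets),
        "profile_tally": tfbs.profile_tally(rows),
    }
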