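"""Shared fixtures: small colonies, printed summary tables, toy gene models."""

import numpy as np
import pandas as pd
import pytest

from apiscout import colony
from apiscout.assoc import GenotypeMatrix

# Matched-read counts (recruit, scout) per taxonomic group from the published
# unmapped-read homology summary; used as input to the percentage recomputation.
TABLE1_COUNTS = {
    "Apis-repeat": (431411, 445544),
    "Apis-ribosomal": (896949, 959250),
    "Apis-other": (478225, 443472),
    "Arthropoda-repeat": (465, 462),
    "Arthropoda-ribosomal": (766865, 828812),
    "Arthropoda-other": (28727, 59427),
    "Nosema": (1277165, 1424226),
    "Other Eukaryota": (689079, 1031932),
    "Bartonella": (151884, 313601),
    "Bifidobacterium": (678905, 3483258),
    "Gilliamella": (2254533, 12546569),
    "Lactobacillus": (316338, 2693381),
    "Snodgrassella": (8595784, 20063286),
    "Other Bacteria": (1053110, 3015850),
    "Other species": (8552, 25439),
}

# Published per-location counts of variants significant for at least one test,
# keyed by the (Genotype, Trend, Allelic, R/N) significance pattern.  Location
# order: coding, intron, 3'UTR, 5'UTR, downstream, upstream, intergenic, other.
TABLE2_SIGNIFICANT_ROWS = {
    ("NS", "NS", "NS", "S"): (0, 1, 0, 0, 0, 0, 0, 0),
    ("NS", "NS", "S", "NS"): (1, 16, 1, 0, 1, 2, 15, 0),
    ("NS", "S", "NS", "NS"): (1, 4, 1, 0, 3, 0, 7, 0),
    ("NS", "S", "S", "NS"): (0, 0, 0, 0, 0, 0, 1, 0),
    ("S", "NS", "NS", "NS"): (1, 7, 0, 0, 0, 3, 13, 0),
    ("S", "NS", "NS", "S"): (0, 1, 0, 0, 1, 0, 0, 0),
    ("S", "S", "NS", "NS"): (0, 24, 0, 1, 3, 0, 17, 0),
    ("S", "S", "NS", "S"): (0, 5, 0, 0, 0, 1, 3, 0),
    ("S", "S", "S", "S"): (0, 2, 0, 0, 0, 0, 1, 0),
}


@pytest.fixture(scope="session")
def table1_counts() -> pd.DataFrame:
    return pd.DataFrame(
        {g: {"recruit": r, "scout": s} for g, (r, s) in TABLE1_COUNTS.items()}
    ).T.rename_axis("group")


def make_matrix(calls: dict, castes: dict, coverage: dict | None = None,
                variants: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Hand-build a GenotypeMatrix from plain dicts (calls keyed by position)."""
    calls_df = pd.DataFrame(calls, dtype=object)
    caste = pd.Series(castes).loc[calls_df.index]
    if coverage is None:
        coverage = {i: 10.0 for i in calls_df.index}
    cov = pd.Series(coverage, dtype=float).loc[calls_df.index]
    if variants is None:
        rows = []
        for key in calls_df.columns:
            chrom, pos = key.split(":")
            rows.append({"chrom": chrom, "pos": int(pos), "ref": "A",
                         "alt": "G", "vtype": "SNP"})
        variants = pd.DataFrame(rows, index=calls_df.columns)
    return GenotypeMatrix(calls=calls_df, caste=caste, coverage=cov,
                          variants=variants)


@pytest.fixture(scope="session")
def small_colony() -> colony.ColonyDesign:
    return colony.simulate_colony(n_loci=120, n_workers=400,
                                  queen_het_fraction=0.5, seed=11)


# GFF3 with one forward-strand coding gene (explicit UTRs derived from
# CDS/exon difference), one reverse-strand coding gene and one ncRNA gene.
TOY_GFF = """\
##gff-version 3
##sequence-region chrA 1 40000
chrA\ttoy\tgene\t10000\t12999\t.\t+\t.\tID=geneF
chrA\ttoy\tmRNA\t10000\t12999\t.\t+\t.\tID=mrnaF;Parent=geneF
chrA\ttoy\texon\t10000\t10999\t.\t+\t.\tParent=mrnaF
chrA\ttoy\texon\t12000\t12999\t.\t+\t.\tParent=mrnaF
chrA\ttoy\tCDS\t10200\t10999\t.\t+\t0\tParent=mrnaF
chrA\ttoy\tCDS\t12000\t12399\t.\t+\t1\tParent=mrnaF
chrA\ttoy\tgene\t20000\t22999\t.\t-\t.\tID=geneR
chrA\ttoy\tmRNA\t20000\t22999\t.\t-\t.\tID=mrnaR;Parent=geneR
chrA\ttoy\texon\t20000\t20999\t.\t-\t.\tParent=mrnaR
chrA\ttoy\texon\t22000\t22999\t.\t-\t.\tParent=mrnaR
chrA\ttoy\tCDS\t20500\t20999\t.\t-\t0\tParent=mrnaR
chrA\ttoy\tCDS\t22000\t22599\t.\t-\t2\tParent=mrnaR
chrA\ttoy\tgene\t30000\t30999\t.\t+\t.\tID=geneNC
chrA\ttoy\tncRNA\t30000\t30999\t.\t+\t.\tID=ncR;Parent=geneNC
chrA\ttoy\texon\t30000\t30399\t.\t+\t.\tParent=ncR
chrA\ttoy\texon\t30600\t30999\t.\t+\t.\tParent=ncR
"""


@pytest.fixture(scope="session")
def toy_gff_path(tmp_path_factory):
    path = tmp_path_factory.mktemp("gff") / "toy.gff3"
    path.write_text(TOY_GFF)
    return path


@pytest.fixture(scope="session")
def toy_genes(toy_gff_path):
    from apiscout import annotate
    return annotate.read_gff3(toy_gff_path)


@pytest.fixture(scope="session")
def toy_reference():
    rng = np.random.default_rng(5)
    return {"chrA": "".join(rng.choice(list("ACGT"), size=40000))}
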