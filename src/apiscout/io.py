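"""Readers and writers for the pipeline's plain-text interchange formats.

All intermediates are TSV (gzip-transparent) so every stage can be rerun
standalone: genotype tables (rows = individuals, columns = chrom:pos, values
RR/RN/NN/NA), caste-label and coverage tables, BLAST outfmt-6-like hit
tables with a trailing subject-annotation column, two-column taxon maps, and
FASTA via Biopython.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .assoc import GenotypeMatrix

BLAST_COLUMNS = ["qseqid", "sseqid", "pident", "length", "evalue", "bitscore", "stitle"]


def xopen(path, mode: str = "rt"):
    """Open a text file, transparently decompressing .gz paths."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# -- genotype matrix --------------------------------------------------------

def write_genotype_matrix(matrix: GenotypeMatrix, calls_path, samples_path,
                          variants_path) -> None:
    """Write calls, per-individual metadata and per-position metadata TSVs."""
    matrix.calls.to_csv(calls_path, sep="\t", na_rep="NA", index_label="individual")
    meta = pd.DataFrame({"caste": matrix.caste, "coverage": matrix.coverage})
    meta.to_csv(samples_path, sep="\t", index_label="individual")
    matrix.variants.to_csv(variants_path, sep="\t", index_label="position")


def read_genotype_matrix(calls_path, samples_path, variants_path) -> GenotypeMatrix:
    calls = pd.read_csv(calls_path, sep="\t", index_col="individual",
                        na_values="NA", dtype=object)
    bad = set(pd.unique(calls.values.ravel())) - {"RR", "RN", "NN"}
    bad = {v for v in bad if not pd.isna(v)}
    if bad:
        raise ValueError(f"{calls_path}: unknown genotype calls {sorted(bad)}")
    meta = pd.read_csv(samples_path, sep="\t", index_col="individual")
    variants = pd.read_csv(variants_path, sep="\t", index_col="position")
    return GenotypeMatrix(
        calls=calls,
        caste=meta["caste"],
        coverage=meta["coverage"].astype(float),
        variants=variants,
    )


# -- BLAST tabular ----------------------------------------------------------

def read_blast_tab(path) -> pd.DataFrame:
    """Read outfmt-6-like TSV with an appended subject-annotation column."""
    rows = []
    with xopen(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < len(BLAST_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(BLAST_COLUMNS)} fields, "
                    f"got {len(fields)}")
            try:
                rows.append({
                    "qseqid": fields[0], "sseqid": fields[1],
                    "pident": float(fields[2]), "length": int(fields[3]),
                    "evalue": float(fields[4]), "bitscore": float(fields[5]),
                    "stitle": fields[6],
                })
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return pd.DataFrame(rows, columns=BLAST_COLUMNS)


def write_blast_tab(hits: pd.DataFrame, path) -> None:
    hits[BLAST_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_taxon_map(path) -> pd.DataFrame:
    """Read an accession -> taxon TSV (kingdom, label, flags)."""
    df = pd.read_csv(path, sep="\t", index_col="accession")
    required = {"kingdom", "label", "is_apis", "is_arthropoda", "is_nosema"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: taxon map lacks columns {sorted(missing)}")
    return df


def write_taxon_map(taxon_map: pd.DataFrame, path) -> None:
    taxon_map.to_csv(path, sep="\t", index_label="accession")


# -- FASTA ------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    with xopen(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with xopen(path, "wt") as out:
        for name, seq in seqs.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i:i + width] + "\n")
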