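"""Within-caste genotype correlation and physical-distance clustering.

Genotypes are coded 0 (RR), 1 (RN), 2 (NN); for each behavioral caste the
pairwise Pearson correlation between positions summarizes caste-specific
co-segregation (a haplodiploid stand-in for linkage disequilibrium).
Positions with no genotypic variation within a caste have undefined
correlations (NA), mirroring the grey cells of the published heatmaps.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

GENOTYPE_CODE = {"RR": 0.0, "RN": 1.0, "NN": 2.0}
CODE_GENOTYPE = {0.0: "RR", 1.0: "RN", 2.0: "NN"}


def encode_genotypes(calls: pd.DataFrame) -> pd.DataFrame:
    """Map RR/RN/NN calls to 0/1/2 (missing -> NaN)."""

    def enc(v):
        if pd.isna(v):
            return np.nan
        try:
            return GENOTYPE_CODE[v]
        except KeyError:
            raise ValueError(f"unknown genotype call {v!r}") from None

    return calls.map(enc).astype(float)


def decode_genotypes(encoded: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`encode_genotypes` (NaN -> missing)."""

    def dec(v):
        if np.isnan(v):
            return np.nan
        try:
            return CODE_GENOTYPE[float(v)]
        except KeyError:
            raise ValueError(f"unknown genotype code {v!r}") from None

    return encoded.map(dec)


def caste_correlation(
    encoded: pd.DataFrame,
    caste_labels: pd.Series,
    caste: str,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation between positions within a caste.

    Rows/columns of positions with zero genotype variance within the caste
    are entirely NA (including the diagonal), and any pair with fewer than
    ``min_pairs`` complete observations is NA.
    """
    members = caste_labels.index[caste_labels == caste]
    if len(members) < 2:
        raise ValueError(f"caste {caste!r} has fewer than 2 individuals")
    sub = encoded.loc[members]
    corr = sub.corr(method="pearson", min_periods=min_pairs)
    variances = sub.var(skipna=True)
    fixed = variances.index[(variances == 0) | variances.isna()]
    corr.loc[fixed, :] = np.nan
    corr.loc[:, fixed] = np.nan
    return corr


def cluster_by_distance(
    positions: pd.DataFrame, max_gap: int = 300_000
) -> list[list[str]]:
    """Single-linkage chaining of positions closer than ``max_gap`` bp.

    ``positions`` is indexed by position key with columns chrom and pos.
    Consecutive same-chromosome positions strictly less than ``max_gap``
    apart join one cluster; positions on different chromosomes never
    cluster.  Returns clusters in coordinate order (singletons allowed).
    """
    ordered = positions.sort_values(["chrom", "pos"])
    clusters: list[list[str]] = []
    prev_chrom, prev_pos = None, None
    for key, row in ordered.iterrows():
        if (row["chrom"] == prev_chrom and prev_pos is not None
                and row["pos"] - prev_pos < max_gap):
            clusters[-1].append(key)
        else:
            clusters.append([key])
        prev_chrom, prev_pos = row["chrom"], row["pos"]
    return clusters


def combine_triangles(
    scout_matrix: pd.DataFrame, recruit_matrix: pd.DataFrame
) -> pd.DataFrame:
    """One square matrix: scout correlations below the diagonal, recruit above.

    The diagonal is 1 where the position varies in both castes, NA otherwise.
    """
    if not scout_matrix.index.equals(recruit_matrix.index) or \
            not scout_matrix.columns.equals(recruit_matrix.columns):
        raise ValueError("matrices must share the same position order")
    n = len(scout_matrix)
    scout = scout_matrix.to_numpy(dtype=float, copy=True)
    recruit = recruit_matrix.to_numpy(dtype=float)
    upper = np.triu_indices(n, k=1)
    scout[upper] = recruit[upper]
    diag = np.where(
        np.isnan(np.diag(scout_matrix.to_numpy(dtype=float)))
        | np.isnan(np.diag(recruit)), np.nan, 1.0)
    np.fill_diagonal(scout, diag)
    return pd.DataFrame(scout, index=scout_matrix.index, columns=scout_matrix.columns)


def heatmap_export(
    scout_matrix: pd.DataFrame,
    recruit_matrix: pd.DataFrame,
    tsv_path,
    plot_path=None,
) -> pd.DataFrame:
    """Write the combined correlation matrix as TSV (and optionally a plot)."""
    combined = combine_triangles(scout_matrix, recruit_matrix)
    combined.to_csv(tsv_path, sep="\t", na_rep="NA")
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(combined.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(combined)), combined.columns, rotation=90, fontsize=5)
        ax.set_yticks(range(len(combined)), combined.index, fontsize=5)
        fig.colorbar(im, ax=ax, label="Pearson r (lower: scouts, upper: recruits)")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return combined


def read_correlation_matrix(tsv_path) -> pd.DataFrame:
    """Read a matrix written by :func:`heatmap_export`."""
    return pd.read_csv(tsv_path, sep="\t", index_col=0, na_values="NA")
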