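"""Taxonomic profiling of unmapped-read homology hits.

Unmapped reads are searched against a nucleotide collection with BLASTN; the
tabular hits are filtered at e-value < 1e-10, reduced to the best hit per
read, and classified into the taxonomic groups used to summarize honey bee
unmapped reads: Apis and non-Apis Arthropoda (each subdivided into
repeat / ribosomal / other by annotation keywords), Nosema, other Eukaryota,
the five dominant gut-bacteria genera (Bartonella, Bifidobacterium,
Gilliamella, Lactobacillus, Snodgrassella), other Bacteria, and other
species.  The summary reports per-group per-caste matched-read counts and
four percentage columns; reference scaffolds whose retained hits are all
bacterial can be flagged for exclusion from association testing.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EVALUE_THRESHOLD = 1e-10  # retained iff strictly below

BACTERIAL_GENERA = (
    "Bartonella", "Bifidobacterium", "Gilliamella", "Lactobacillus", "Snodgrassella",
)

GROUP_ORDER = (
    "Apis-repeat", "Apis-ribosomal", "Apis-other",
    "Arthropoda-repeat", "Arthropoda-ribosomal", "Arthropoda-other",
    "Nosema", "Other Eukaryota",
    *BACTERIAL_GENERA, "Other Bacteria", "Other species",
)

KINGDOM_OF_GROUP = {
    **{g: "Eukaryota" for g in GROUP_ORDER[:8]},
    **{g: "Bacteria" for g in (*BACTERIAL_GENERA, "Other Bacteria")},
    "Other species": "Other",
}

REPEAT_KEYWORDS = ("repeat", "microsatellite")
RIBOSOMAL_KEYWORDS = ("ribosomal", "18s", "28s")


def best_hit_per_read(hits: pd.DataFrame, evalue_threshold: float = EVALUE_THRESHOLD) -> pd.DataFrame:
    """Retain the best hit per read after the e-value filter.

    Rows with e-value >= threshold are discarded; per read the
    maximum-bitscore row is kept, with ties broken by lower e-value and then
    by lexicographically smallest subject accession.
    """
    required = {"qseqid", "sseqid", "evalue", "bitscore"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"hit table lacks required columns: {sorted(missing)}")
    retained = hits[hits["evalue"] < evalue_threshold]
    if retained.empty:
        return retained
    ordered = retained.sort_values(
        ["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    return ordered.drop_duplicates(subset="qseqid", keep="first")


def _subclassify(annotation: str) -> str:
    """Repeat before ribosomal before other (repeat keywords are unambiguous)."""
    text = annotation.lower()
    if any(k in text for k in REPEAT_KEYWORDS):
        return "repeat"
    if any(k in text for k in RIBOSOMAL_KEYWORDS):
        return "ribosomal"
    return "other"


def classify_group(
    accession: str,
    annotation: str,
    taxon_map: pd.DataFrame,
    bacterial_genera: Iterable[str] = BACTERIAL_GENERA,
) -> str:
    """Taxonomic group label of one best hit.

    ``taxon_map`` is indexed by accession with columns kingdom, label,
    is_apis, is_arthropoda, is_nosema.  Unresolvable accessions fall into
    "Other species" with a warning.
    """
    if accession not in taxon_map.index:
        logger.warning("accession %s not in taxon map; classified 'Other species'", accession)
        return "Other species"
    row = taxon_map.loc[accession]
    if row["is_apis"]:
        return f"Apis-{_subclassify(annotation)}"
    if row["is_arthropoda"]:
        return f"Arthropoda-{_subclassify(annotation)}"
    if row["is_nosema"]:
        return "Nosema"
    if row["kingdom"] == "Eukaryota":
        return "Other Eukaryota"
    if row["kingdom"] == "Bacteria":
        return row["label"] if row["label"] in tuple(bacterial_genera) else "Other Bacteria"
    return "Other species"


def classify_hits(best_hits: pd.DataFrame, taxon_map: pd.DataFrame,
                  annotation_col: str = "stitle") -> pd.Series:
    """Vector of group labels for a best-hit table."""
    return pd.Series(
        [classify_group(acc, ann, taxon_map)
         for acc, ann in zip(best_hits["sseqid"], best_hits[annotation_col])],
        index=best_hits.index, name="group",
    )


def summarize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Build the per-group taxonomy summary from matched-read counts.

    ``counts`` has one row per group with columns ``recruit`` and ``scout``.
    The output adds the four percentage columns: the share of each
    group-caste count among all matched reads (2 decimals) and the caste
    split within each group (1 decimal), plus a Total row.
    """
    for col in ("recruit", "scout"):
        if col not in counts.columns:
            raise ValueError(f"counts table lacks column {col!r}")
    out = counts[["recruit", "scout"]].copy()
    grand_total = int(out.to_numpy().sum())
    out["total"] = out["recruit"] + out["scout"]
    if grand_total == 0:
        for col in ("pct_of_all_matched_recruit", "pct_of_all_matched_scout",
                    "pct_recruits_within_group", "pct_scouts_within_group"):
            out[col] = np.nan
        return out
    out["pct_of_all_matched_recruit"] = (100.0 * out["recruit"] / grand_total).round(2)
    out["pct_of_all_matched_scout"] = (100.0 * out["scout"] / grand_total).round(2)
    group_total = out["total"].replace(0, np.nan)
    out["pct_recruits_within_group"] = (100.0 * out["recruit"] / group_total).round(1)
    out["pct_scouts_within_group"] = (100.0 * out["scout"] / group_total).round(1)
    total = pd.Series({
        "recruit": out["recruit"].sum(), "scout": out["scout"].sum(),
        "total": grand_total,
        "pct_of_all_matched_recruit": round(100.0 * out["recruit"].sum() / grand_total, 2),
        "pct_of_all_matched_scout": round(100.0 * out["scout"].sum() / grand_total, 2),
        "pct_recruits_within_group": round(100.0 * out["recruit"].sum() / grand_total, 1),
        "pct_scouts_within_group": round(100.0 * out["scout"].sum() / grand_total, 1),
    })
    out.loc["Total"] = total
    return out


def summarize(
    best_hits: pd.DataFrame,
    caste_labels: Mapping[str, str] | pd.Series,
    taxon_map: pd.DataFrame,
    annotation_col: str = "stitle",
) -> pd.DataFrame:
    """Classify best hits and aggregate matched-read counts per group x caste."""
    if best_hits.empty:
        return summarize_counts(
            pd.DataFrame(columns=["recruit", "scout"], dtype=int))
    caste = pd.Series(caste_labels)
    missing = set(best_hits["qseqid"]) - set(caste.index)
    if missing:
        raise ValueError(f"{len(missing)} reads lack a caste label")
    groups = classify_hits(best_hits, taxon_map, annotation_col=annotation_col)
    table = pd.crosstab(groups, caste.loc[best_hits["qseqid"]].to_numpy())
    for col in ("recruit", "scout"):
        if col not in table.columns:
            table[col] = 0
    order = [g for g in GROUP_ORDER if g in table.index]
    table = table.loc[order, ["recruit", "scout"]]
    table.index.name = "group"
    return summarize_counts(table)


def kingdom_shares(counts: pd.DataFrame) -> pd.Series:
    """Percent of all matched reads per kingdom (from a per-group count table)."""
    totals = counts["recruit"] + counts["scout"]
    kingdoms = pd.Series({g: KINGDOM_OF_GROUP[g] for g in counts.index})
    shares = totals.groupby(kingdoms).sum() / totals.sum() * 100.0
    return shares


def group_share_of_all_matched(counts: pd.DataFrame, group: str) -> float:
    """Percent of all matched reads that fall in one taxonomic group."""
    totals = counts["recruit"] + counts["scout"]
    return float(totals[group] / totals.sum() * 100.0)


def caste_share_within_caste(counts: pd.DataFrame, group: str, caste: str) -> float:
    """Percent of one caste's matched reads that fall in one group."""
    return float(counts.loc[group, caste] / counts[caste].sum() * 100.0)


def flag_bacterial_scaffolds(
    scaffold_hits: pd.DataFrame,
    taxon_map: pd.DataFrame,
    evalue_threshold: float = EVALUE_THRESHOLD,
) -> set[str]:
    """Scaffolds whose retained hits are exclusively bacterial.

    ``scaffold_hits`` needs columns scaffold, sseqid, evalue.  A scaffold is
    flagged iff it has at least one retained hit (e-value < threshold) and
    every retained hit resolves to the Bacteria kingdom; scaffolds with no
    retained hits are never flagged.
    """
    retained = scaffold_hits[scaffold_hits["evalue"] < evalue_threshold]
    flagged: set[str] = set()
    for scaffold, sub in retained.groupby("scaffold"):
        kingdoms = [
            taxon_map.loc[acc, "kingdom"] if acc in taxon_map.index else "Other"
            for acc in sub["sseqid"]
        ]
        if kingdoms and all(k == "Bacteria" for k in kingdoms):
            flagged.add(str(scaffold))
    return flagged
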