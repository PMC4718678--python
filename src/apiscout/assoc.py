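"""Case-control association battery for haplodiploid one-patriline colonies.

A colony founded by a single queen and a single haploid drone yields diploid
workers whose genotypes at a queen-heterozygous locus segregate like an inbred
backcross: every worker carries the drone allele plus one of the two queen
alleles, so at most two genotypes occur, in expected 1:1 proportion.  This
module encodes those expectations, the position/individual filtering rules,
five complementary case-control tests (genotypic Freeman-Halton, allelic
Fisher, dominant and recessive collapses, Cochran-Armitage trend),
Benjamini-Hochberg FDR, and the significance cross-tabulation by variant
location class.

Alleles are written R (reference) and N (non-reference); genotype calls are
"RR", "RN", "NN" or missing (NaN).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

GENOTYPES = ("RR", "RN", "NN")
TEST_NAMES = ("genotypic", "allelic", "dominant", "recessive", "trend")

#: location classes used in the significance cross-tab
LOCATION_CLASSES = (
    "coding", "intron", "3'UTR", "5'UTR",
    "downstream", "upstream", "intergenic", "other",
)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Observed genotype calls for a set of individually sequenced bees.

    Parameters
    ----------
    calls
        individuals x positions DataFrame with values in {"RR","RN","NN"} or
        NaN for missing calls.  Columns are "chrom:pos" keys.
    caste
        per-individual behavioral caste, "scout" or "recruit".
    coverage
        per-individual genome coverage in X.
    variants
        per-position metadata indexed by the same "chrom:pos" keys, with
        columns chrom, pos, ref, alt, vtype ("SNP" or "indel").
    """

    calls: pd.DataFrame
    caste: pd.Series
    coverage: pd.Series
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.calls.index.equals(self.caste.index):
            raise ValueError("caste labels must be indexed by the call matrix rows")
        if not self.calls.index.equals(self.coverage.index):
            raise ValueError("coverage must be indexed by the call matrix rows")
        if not self.calls.columns.equals(self.variants.index):
            raise ValueError("variant metadata must be indexed by the call matrix columns")
        if (self.coverage < 0).any():
            raise ValueError("coverage must be non-negative")
        bad = set(self.caste.unique()) - {"scout", "recruit"}
        if bad:
            raise ValueError(f"unknown caste labels: {sorted(bad)}")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_positions(self) -> int:
        return self.calls.shape[1]

    def subset_individuals(self, keep: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            calls=self.calls.loc[keep],
            caste=self.caste.loc[keep],
            coverage=self.coverage.loc[keep],
            variants=self.variants,
        )

    def subset_positions(self, keep: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            calls=self.calls.loc[:, keep],
            caste=self.caste,
            coverage=self.coverage,
            variants=self.variants.loc[keep],
        )


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts (n_RR, n_RN, n_NN) per caste at one position."""

    scout: tuple[int, int, int]
    recruit: tuple[int, int, int]

    def __post_init__(self) -> None:
        for row in (self.scout, self.recruit):
            if len(row) != 3 or any(c < 0 for c in row):
                raise ValueError("counts must be three non-negative integers per caste")

    @property
    def table(self) -> np.ndarray:
        return np.array([self.scout, self.recruit], dtype=np.int64)


# ---------------------------------------------------------------------------
# haplodiploid expectations
# ---------------------------------------------------------------------------

def expected_offspring_distribution(
    queen_gt: tuple[str, str], drone_allele: str
) -> dict[str, float]:
    """Genotype distribution of workers from a queen x haploid-drone cross.

    The drone transmits its single allele to every daughter, like a homozygous
    diploid sire; the queen transmits one of her two alleles equiprobably.
    """
    for a in (*queen_gt, drone_allele):
        if a not in ("R", "N"):
            raise ValueError(f"alleles must be 'R' or 'N', got {a!r}")
    dist: dict[str, float] = {}
    for queen_allele in queen_gt:
        gt = "".join(sorted((queen_allele, drone_allele)))  # "NR" -> sorted "NR"
        gt = {"NR": "RN", "RR": "RR", "NN": "NN", "RN": "RN"}[gt]
        dist[gt] = dist.get(gt, 0.0) + 0.5
    return dist


def sister_sharing_probability(system: str) -> float:
    """Expected fraction of allele copies shared identically by full sisters.

    Under haplodiploidy the haploid father transmits the same allele to every
    daughter (shared with probability 1) while the mother's allele is shared
    with probability 1/2; averaging the two allele copies gives 0.75.  With a
    diploid heterozygous sire both parental alleles are shared with
    probability 1/2, giving 0.50.
    """
    if system == "haplodiploid":
        paternal = 1.0
    elif system == "diploid":
        paternal = 0.5
    else:
        raise ValueError(f"unknown inheritance system: {system!r}")
    maternal = 0.5
    return (paternal + maternal) / 2.0


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_individuals(matrix: GenotypeMatrix, min_coverage: float = 3.0) -> GenotypeMatrix:
    """Drop individuals with genome coverage below ``min_coverage`` X."""
    keep = matrix.coverage.index[matrix.coverage >= min_coverage]
    dropped = matrix.coverage.index.difference(keep)
    for ind in dropped:
        logger.info(
            "removing %s (%s) with %.2fX coverage",
            ind, matrix.caste[ind], matrix.coverage[ind],
        )
    if len(keep) == 0:
        raise ValueError("all individuals removed by the coverage filter")
    return matrix.subset_individuals(list(keep))


#: classes assigned by filter_positions to non-tested columns
POSITION_CLASSES = (
    "tested", "monomorphic-NN", "monomorphic-het", "monomorphic-ref",
    "all-missing", "excluded-scaffold",
)


def filter_positions(
    matrix: GenotypeMatrix, excluded_scaffolds: Iterable[str] = ()
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Keep only positions segregating among the bees.

    Positions on excluded scaffolds are dropped first.  Columns where every
    non-missing call is the same genotype carry no information about caste
    and are tallied as monomorphic-NN / monomorphic-het / monomorphic-ref
    (all NN: neither parent carried the reference allele; all RN: the parents
    carried different alleles; all RR: non-variant).
    """
    if matrix.n_positions == 0:
        raise ValueError("empty genotype matrix")
    excluded = set(excluded_scaffolds)
    tally = {c: 0 for c in POSITION_CLASSES}
    keep: list[str] = []
    mono_class = {"NN": "monomorphic-NN", "RN": "monomorphic-het", "RR": "monomorphic-ref"}
    on_excluded = matrix.variants["chrom"].isin(excluded)
    for key, col in matrix.calls.items():
        if on_excluded[key]:
            tally["excluded-scaffold"] += 1
            continue
        seen = col.dropna().unique()
        if len(seen) == 0:
            tally["all-missing"] += 1
        elif len(seen) == 1:
            tally[mono_class[seen[0]]] += 1
        else:
            tally["tested"] += 1
            keep.append(key)
    return matrix.subset_positions(keep), tally


def genotype_counts(matrix: GenotypeMatrix, position: str) -> GenotypeCounts:
    """Per-caste genotype counts at one position (complete-case)."""
    col = matrix.calls[position]
    out = {}
    for caste in ("scout", "recruit"):
        sub = col[matrix.caste == caste].dropna()
        out[caste] = tuple(int((sub == g).sum()) for g in GENOTYPES)
    return GenotypeCounts(scout=out["scout"], recruit=out["recruit"])


# ---------------------------------------------------------------------------
# exact tests
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-tailed Fisher exact p for a 2x2 table; NaN on a zero margin.

    Two-sided in the conventional exact sense: the p-value sums the
    hypergeometric probabilities of all tables with the observed margins that
    are no more probable than the observed one.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be a 2x2 array of non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return float("nan")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def _log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


@lru_cache(maxsize=1 << 18)
def _fh_margin_distribution(
    r1: int, cols: tuple[int, ...]
) -> tuple[dict[tuple[int, ...], float], np.ndarray, np.ndarray]:
    """Enumerate all 2xk tables with margins (r1, n-r1) x cols.

    Returns (logp per first-row cell tuple, sorted probabilities, cumulative
    sums) of the multivariate hypergeometric distribution over the first row.
    """
    n = sum(cols)
    denom = _log_binom(n, r1)
    logps: dict[tuple[int, ...], float] = {}

    def rec(idx: int, remaining: int, prefix: tuple[int, ...], acc: float) -> None:
        if idx == len(cols) - 1:
            if remaining <= cols[idx]:
                logps[prefix + (remaining,)] = acc + _log_binom(cols[idx], remaining) - denom
            return
        tail = sum(cols[idx + 1:])
        lo = max(0, remaining - tail)
        hi = min(cols[idx], remaining)
        for a in range(lo, hi + 1):
            rec(idx + 1, remaining - a, prefix + (a,), acc + _log_binom(cols[idx], a))

    rec(0, r1, (), 0.0)
    probs = np.sort(np.exp(np.fromiter(logps.values(), dtype=float)))
    return logps, probs, np.cumsum(probs)


def fisher_exact_2x3(table: Sequence[Sequence[int]]) -> float:
    """Two-tailed Freeman-Halton exact p for a 2x3 contingency table.

    Enumerates every table sharing the observed margins and sums the
    multivariate hypergeometric probabilities that do not exceed the observed
    table's probability.  Columns with a zero margin are removed first; with
    only one informative column (or an empty row) the test is undefined and
    NaN is returned; with two informative columns the table reduces to the
    2x2 Fisher test.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape[0] != 2 or (t < 0).any():
        raise ValueError("table must be 2xk with non-negative integer counts")
    t = t[:, t.sum(axis=0) > 0]
    if t.shape[1] < 2 or (t.sum(axis=1) == 0).any():
        return float("nan")
    if t.shape[1] == 2:
        return fisher_exact_2x2(t)
    r1 = int(t[0].sum())
    cols = tuple(int(c) for c in t.sum(axis=0))
    logps, probs, cums = _fh_margin_distribution(r1, cols)
    logp_obs = logps[tuple(int(a) for a in t[0])]
    p_obs = math.exp(logp_obs)
    # tables whose probability is <= observed, with a relative tolerance for
    # floating-point ties (same convention as common exact-test codes)
    idx = np.searchsorted(probs, p_obs * (1.0 + 1e-7), side="right")
    return float(min(1.0, cums[idx - 1])) if idx > 0 else 0.0


def trend_test(counts: GenotypeCounts) -> tuple[float, float]:
    """Cochran-Armitage trend test with genotype scores (0, 1, 2).

    Chi-square score statistic (1 df) for a linear trend in the scout
    proportion across the RR/RN/NN genotype classes; the p-value is the
    upper chi-square tail.  Undefined (NaN, NaN) when either caste is empty
    or only one genotype class is observed.
    """
    t = counts.table
    n_col = t.sum(axis=0)
    if (t.sum(axis=1) == 0).any() or (n_col > 0).sum() < 2:
        return float("nan"), float("nan")
    scores = np.array([0.0, 1.0, 2.0])
    n = t.sum()
    r1 = t[0].sum()
    pbar = r1 / n
    num = float(np.sum(scores * (t[0] - pbar * n_col)))
    den = pbar * (1 - pbar) * (np.sum(scores**2 * n_col) - np.sum(scores * n_col) ** 2 / n)
    if den <= 0:
        return float("nan"), float("nan")
    stat = num * num / den
    return float(stat), float(stats.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# the five-test battery
# ---------------------------------------------------------------------------

@dataclass
class AssocResult:
    """Raw p-values of the five tests at one position (NaN = undefined)."""

    position: str
    p_genotypic: float
    p_allelic: float
    p_dominant: float
    p_recessive: float
    p_trend: float

    def pvalues(self) -> dict[str, float]:
        return {
            "genotypic": self.p_genotypic,
            "allelic": self.p_allelic,
            "dominant": self.p_dominant,
            "recessive": self.p_recessive,
            "trend": self.p_trend,
        }


def allele_counts(row: tuple[int, int, int]) -> tuple[int, int]:
    """(R, N) allele copies carried by one caste's genotype counts."""
    rr, rn, nn = row
    return 2 * rr + rn, 2 * nn + rn


def run_battery(counts: GenotypeCounts, position: str = "") -> AssocResult:
    """Run the five complementary association tests on one position.

    1. Genotypic: RR vs RN vs NN (Freeman-Halton exact).
    2. Allelic:   R vs N allele copies (2x2 Fisher).
    3. Dominant reference gene action:  RR or RN  vs  NN.
    4. Recessive reference gene action: RR  vs  RN or NN.
    5. Cochran-Armitage trend on 0/1/2 N-allele dose.

    Each test returns NaN when its collapsed table is degenerate (a zero
    margin).  With fewer than two genotype classes present — e.g. every bee
    heterozygous — no test carries information and all five are NA.
    """
    s, r = counts.scout, counts.recruit
    nan = float("nan")
    if (counts.table.sum(axis=0) > 0).sum() < 2:
        return AssocResult(position, nan, nan, nan, nan, nan)
    p_geno = fisher_exact_2x3([s, r])
    p_alle = fisher_exact_2x2([allele_counts(s), allele_counts(r)])
    p_dom = fisher_exact_2x2([[s[0] + s[1], s[2]], [r[0] + r[1], r[2]]])
    p_rec = fisher_exact_2x2([[s[0], s[1] + s[2]], [r[0], r[1] + r[2]]])
    _, p_trend = trend_test(counts)
    return AssocResult(position, p_geno, p_alle, p_dom, p_rec, p_trend)


def fdr_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through unchanged.

    NaN entries (undefined tests) are excluded from the number of tests m.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.sum() > 0:
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# significance classification and cross-tab
# ---------------------------------------------------------------------------

def _flag(p: float, alpha: float) -> str:
    if math.isnan(p):
        return "NA"
    return "S" if p < alpha else "NS"


def classify_significance(result: AssocResult, alpha: float = 1e-4) -> tuple[str, str, str, str]:
    """Four-symbol significance pattern (Genotype, Trend, Allelic, R/N).

    The R/N symbol summarizes reference-allele gene action: S if the dominant
    or the recessive collapse is significant, NA if both are undefined, NS
    otherwise.  A position is "significant for at least one test" iff any
    symbol is S.
    """
    geno = _flag(result.p_genotypic, alpha)
    trend = _flag(result.p_trend, alpha)
    alle = _flag(result.p_allelic, alpha)
    dom, rec = _flag(result.p_dominant, alpha), _flag(result.p_recessive, alpha)
    if "S" in (dom, rec):
        rn = "S"
    elif dom == "NA" and rec == "NA":
        rn = "NA"
    else:
        rn = "NS"
    return geno, trend, alle, rn


def is_significant(pattern: Sequence[str]) -> bool:
    return "S" in pattern


def cross_tab(
    patterns: Mapping[str, Sequence[str]],
    locations: Mapping[str, str],
) -> pd.DataFrame:
    """Cross-tabulate significance patterns against variant location classes.

    Rows are '/'-joined patterns plus three margin rows ("Significant for at
    least one test", "Non-significant for any test", "Total"); columns are the
    location classes plus a "Total" column.  Every position contributes to
    exactly one pattern row.
    """
    if set(patterns) != set(locations):
        raise ValueError("patterns and locations must cover the same positions")
    cols = list(LOCATION_CLASSES)
    rows: dict[str, np.ndarray] = {}
    sig = np.zeros(len(cols), dtype=np.int64)
    nonsig = np.zeros(len(cols), dtype=np.int64)
    for pos, pat in patterns.items():
        loc = locations[pos]
        if loc not in cols:
            raise ValueError(f"unknown location class {loc!r} at {pos}")
        key = "/".join(pat)
        rows.setdefault(key, np.zeros(len(cols), dtype=np.int64))
        j = cols.index(loc)
        rows[key][j] += 1
        if is_significant(pat):
            sig[j] += 1
        else:
            nonsig[j] += 1
    table = pd.DataFrame.from_dict(rows, orient="index", columns=cols).sort_index()
    table.loc["Significant for at least one test"] = sig
    table.loc["Non-significant for any test"] = nonsig
    table.loc["Total"] = sig + nonsig
    table["Total"] = table.sum(axis=1)
    return table


def run_association(
    matrix: GenotypeMatrix,
    alpha: float = 1e-4,
    min_coverage: float = 3.0,
    excluded_scaffolds: Iterable[str] = (),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Filter, test and classify every position of a genotype matrix.

    Returns a per-position results table (chrom, pos, five raw p-values,
    five BH-adjusted p-values, the 4-symbol pattern and a significance flag)
    and the position-class tally from filtering.
    """
    matrix = filter_individuals(matrix, min_coverage=min_coverage)
    tested, tally = filter_positions(matrix, excluded_scaffolds=excluded_scaffolds)
    records = []
    patterns = {}
    for key in tested.calls.columns:
        res = run_battery(genotype_counts(tested, key), position=key)
        pat = classify_significance(res, alpha=alpha)
        patterns[key] = pat
        records.append({
            "position": key,
            "chrom": tested.variants.loc[key, "chrom"],
            "pos": tested.variants.loc[key, "pos"],
            **{f"p_{t}": p for t, p in res.pvalues().items()},
            "pattern": "/".join(pat),
            "significant": is_significant(pat),
        })
    results = pd.DataFrame.from_records(records).set_index("position") if records else (
        pd.DataFrame(columns=["chrom", "pos", "pattern", "significant"])
    )
    for t in TEST_NAMES:
        if len(results):
            results[f"q_{t}"] = fdr_adjust(results[f"p_{t}"].to_numpy())
    return results, tally
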