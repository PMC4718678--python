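"""Paired-end FASTQ quality control and 3' trimming.

Rules applied to every read pair (a pair is removed when at least one mate
fails):

* low quality — at least 10% unidentified (N) nucleotides, or more than 50%
  of bases with Phred quality below 5 (the N rule is inclusive, the
  low-quality-fraction rule strict, exactly as stated);
* adapter — an ungapped sliding alignment of the adapter (either
  orientation) covers more than 10 nucleotides with at most 10% mismatches;
* 3' trimming — up to 6 terminal bases with Phred below 5 are removed from
  the 3' end of surviving reads.

Phred encoding is fixed to +33.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33


@dataclass
class QCRuleSet:
    """Thresholds of the read-pair filtering and trimming rules."""

    adapter: str
    max_n_frac: float = 0.10        # >= this fraction of Ns -> low quality
    max_lowq_frac: float = 0.50     # > this fraction below lowq_phred -> low quality
    lowq_phred: int = 5
    min_adapter_overlap: int = 10   # strictly more aligned bases required
    max_adapter_mismatch_frac: float = 0.10
    max_trim_3prime: int = 6
    trim_phred: int = 5
    trim_both_mates: bool = True    # False: asymmetric, trim mate 1 only

    def __post_init__(self) -> None:
        for frac in (self.max_n_frac, self.max_lowq_frac, self.max_adapter_mismatch_frac):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("rule fractions must lie in [0, 1]")
        if min(self.lowq_phred, self.min_adapter_overlap,
               self.max_trim_3prime, self.trim_phred) < 0:
            raise ValueError("rule thresholds must be non-negative")
        if not self.adapter:
            raise ValueError("an adapter sequence is required")


def decode_quality(qual_str: str) -> list[int]:
    quals = [ord(c) - PHRED_OFFSET for c in qual_str]
    if any(q < 0 or q > 60 for q in quals):
        raise ValueError("quality string is not valid Phred+33")
    return quals


def encode_quality(quals: list[int]) -> str:
    return "".join(chr(q + PHRED_OFFSET) for q in quals)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _matches_adapter(seq: str, rules: QCRuleSet) -> bool:
    """Ungapped sliding alignment over all offsets, both adapter orientations.

    N in the read counts as a mismatch.
    """
    n = len(seq)
    for adapter in (rules.adapter, _revcomp(rules.adapter)):
        m = len(adapter)
        for offset in range(-(m - 1), n):
            start = max(0, offset)
            end = min(n, offset + m)
            overlap = end - start
            if overlap <= rules.min_adapter_overlap:
                continue
            read_part = seq[start:end]
            ad_part = adapter[start - offset:end - offset]
            mismatches = sum(a != b for a, b in zip(read_part, ad_part))
            if mismatches <= rules.max_adapter_mismatch_frac * overlap:
                return True
    return False


def classify_read(seq: str, qual: list[int], rules: QCRuleSet) -> str:
    """Verdict for one read: "pass", "low_quality" or "adapter".

    The low-quality rules are checked before the adapter rule.
    """
    if len(seq) == 0:
        raise ValueError("empty read")
    if len(seq) != len(qual):
        raise ValueError("sequence and quality lengths differ")
    n = len(seq)
    n_frac = sum(base in "Nn" for base in seq) / n
    lowq_frac = sum(q < rules.lowq_phred for q in qual) / n
    if n_frac >= rules.max_n_frac or lowq_frac > rules.max_lowq_frac:
        return "low_quality"
    if _matches_adapter(seq.upper(), rules):
        return "adapter"
    return "pass"


def qc_pair(
    pair: tuple[str, str, list[int], str, list[int]], rules: QCRuleSet
) -> tuple[str, tuple[int, str] | None]:
    """Keep/drop decision for one (id, seq1, qual1, seq2, qual2) pair.

    Returns ("keep", None) or ("drop", (mate, rule)) where the reason records
    the first failing mate (mate 1 checked before mate 2) and its rule.
    """
    _, seq1, qual1, seq2, qual2 = pair
    for mate_no, (seq, qual) in ((1, (seq1, qual1)), (2, (seq2, qual2))):
        verdict = classify_read(seq, qual, rules)
        if verdict != "pass":
            return "drop", (mate_no, verdict)
    return "keep", None


def trim_3prime(seq: str, qual: list[int], rules: QCRuleSet) -> tuple[str, list[int]]:
    """Remove up to ``max_trim_3prime`` trailing bases with Phred < trim_phred."""
    removed = 0
    end = len(seq)
    while removed < rules.max_trim_3prime and end > 0 and qual[end - 1] < rules.trim_phred:
        end -= 1
        removed += 1
    return seq[:end], qual[:end]


@dataclass
class QCStats:
    """Bookkeeping of one QC run; pairs_in == pairs_kept + pairs dropped."""

    pairs_in: int = 0
    pairs_kept: int = 0
    dropped_by_rule: Counter = field(default_factory=Counter)
    bases_trimmed: int = 0
    dropped_pairs: list = field(default_factory=list)  # (pair_id, mate, rule)

    @property
    def pairs_dropped(self) -> int:
        return sum(self.dropped_by_rule.values())


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _pair_id(title: str) -> str:
    head = title.split()[0]
    if head.endswith("/1") or head.endswith("/2"):
        head = head[:-2]
    return head


def _iter_pairs(fastq1, fastq2) -> Iterator[tuple[str, str, str, str, str, str]]:
    with _open_text(fastq1) as f1, _open_text(fastq2) as f2:
        it1, it2 = FastqGeneralIterator(f1), FastqGeneralIterator(f2)
        for rec1 in it1:
            try:
                rec2 = next(it2)
            except StopIteration:
                raise ValueError(f"{fastq2} ended before {fastq1}: desynchronized mates")
            if _pair_id(rec1[0]) != _pair_id(rec2[0]):
                raise ValueError(
                    f"mate identifiers disagree: {rec1[0]!r} vs {rec2[0]!r}")
            yield (*rec1, *rec2)
        if next(it2, None) is not None:
            raise ValueError(f"{fastq1} ended before {fastq2}: desynchronized mates")


def run_qc(fastq_in_1, fastq_in_2, fastq_out_1, fastq_out_2,
           rules: QCRuleSet) -> QCStats:
    """Filter and trim a pair of FASTQ files, preserving order and synchrony.

    Surviving pairs are written in input order.  Both mates are 3'-trimmed by
    default; with ``rules.trim_both_mates = False`` only mate 1 is trimmed
    (asymmetric handling).
    """
    stats = QCStats()
    with _open_text(fastq_out_1, "wt") as o1, _open_text(fastq_out_2, "wt") as o2:
        for title1, seq1, q1, title2, seq2, q2 in _iter_pairs(fastq_in_1, fastq_in_2):
            stats.pairs_in += 1
            qual1, qual2 = decode_quality(q1), decode_quality(q2)
            verdict, reason = qc_pair(("", seq1, qual1, seq2, qual2), rules)
            if verdict == "drop":
                mate, rule = reason
                stats.dropped_by_rule[rule] += 1
                stats.dropped_pairs.append((_pair_id(title1), mate, rule))
                continue
            stats.pairs_kept += 1
            t_seq1, t_qual1 = trim_3prime(seq1, qual1, rules)
            stats.bases_trimmed += len(seq1) - len(t_seq1)
            if rules.trim_both_mates:
                t_seq2, t_qual2 = trim_3prime(seq2, qual2, rules)
                stats.bases_trimmed += len(seq2) - len(t_seq2)
            else:
                t_seq2, t_qual2 = seq2, qual2
            o1.write(f"@{title1}\n{t_seq1}\n+\n{encode_quality(t_qual1)}\n")
            o2.write(f"@{title2}\n{t_seq2}\n+\n{encode_quality(t_qual2)}\n")
    return stats
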