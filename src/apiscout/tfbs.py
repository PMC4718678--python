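"""Position-weight-matrix scanning of windows around significant variants.

A ±1000 bp window (truncated at sequence ends) around each variant is
scanned on both strands with every transcription-factor profile; matches at
or above an 80% relative score are reported.  The relative score is the
min-max-normalized log-odds sum

    rel(s) = (S(s) - S_min) / (S_max - S_min)

where S is the log2-odds of the window subsequence under the PWM
frequencies (with a pseudocount of 0.8 distributed by the background
frequencies) against the background, and S_min / S_max are the per-column
minimal / maximal attainable sums.  The consensus of a profile therefore
always scores 1.0 and its anti-consensus 0.0; N bases contribute the
background log-odds of 0.  A literal per-column consensus-identity mode is
available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import motifs as bio_motifs

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class PWM:
    """A transcription-factor binding profile as a 4 x L count matrix."""

    name: str
    counts: np.ndarray  # shape (4, L), rows A, C, G, T
    pseudocount: float = 0.8
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 4:
            raise ValueError("counts must be 4 x L with L >= 4")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        bg = np.asarray(self.background, dtype=float)
        if not np.isclose(bg.sum(), 1.0) or (bg <= 0).any():
            raise ValueError("background must be a positive probability vector")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        """Column-normalized frequencies with the background-weighted pseudocount."""
        bg = np.asarray(self.background)[:, None]
        padded = self.counts + self.pseudocount * bg
        return padded / padded.sum(axis=0, keepdims=True)

    @property
    def log_odds(self) -> np.ndarray:
        bg = np.asarray(self.background)[:, None]
        return np.log2(self.frequencies / bg)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.log_odds.argmax(axis=0))

    @property
    def anti_consensus(self) -> str:
        return "".join(BASES[i] for i in self.log_odds.argmin(axis=0))


def read_jaspar(path) -> list[PWM]:
    """Read one or more JASPAR-format profiles."""
    with open(path) as handle:
        records = bio_motifs.parse(handle, "jaspar")
    pwms = []
    for m in records:
        counts = np.array([m.counts[b] for b in BASES], dtype=float)
        pwms.append(PWM(name=m.name or m.matrix_id, counts=counts))
    return pwms


def write_jaspar(pwms: Iterable[PWM], path) -> None:
    with open(path, "w") as out:
        for pwm in pwms:
            out.write(f">{pwm.name} {pwm.name}\n")
            for i, base in enumerate(BASES):
                vals = " ".join(f"{v:.2f}" for v in pwm.counts[i])
                out.write(f"{base}  [ {vals} ]\n")


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3, anything else (N) -> 4."""
    arr = np.full(len(seq), 4, dtype=np.int8)
    for base, idx in BASE_INDEX.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return arr


def relative_score(pwm: PWM, subsequence: str, strand: str = "+") -> float:
    """Min-max-normalized log-odds score of one L-length subsequence."""
    if len(subsequence) != pwm.length:
        raise ValueError(f"subsequence must have length {pwm.length}")
    if strand == "-":
        subsequence = reverse_complement(subsequence)
    elif strand != "+":
        raise ValueError("strand must be '+' or '-'")
    lo = pwm.log_odds
    lo_ext = np.vstack([lo, np.zeros(pwm.length)])  # N contributes 0
    codes = _encode(subsequence.upper())
    score = float(lo_ext[codes, np.arange(pwm.length)].sum())
    smin, smax = float(lo.min(axis=0).sum()), float(lo.max(axis=0).sum())
    return (score - smin) / (smax - smin)


def consensus_identity(pwm: PWM, subsequence: str, strand: str = "+") -> float:
    """Fraction of positions matching the profile consensus (strict mode)."""
    if len(subsequence) != pwm.length:
        raise ValueError(f"subsequence must have length {pwm.length}")
    if strand == "-":
        subsequence = reverse_complement(subsequence)
    cons = pwm.consensus
    return sum(a == b for a, b in zip(subsequence.upper(), cons)) / pwm.length


@dataclass(frozen=True)
class PWMHit:
    """One super-threshold profile match inside a variant window."""

    profile: str
    strand: str
    offset: int  # 1-based start of the match within the window
    score: float


def extract_window(
    chrom: str, pos: int, reference: Mapping[str, str], half_width: int = 1000
) -> tuple[str, int, int]:
    """±half_width window around a position, truncated at sequence ends.

    Returns (subsequence, start, end) with 1-based inclusive coordinates.
    """
    seq = reference[chrom]
    if not 1 <= pos <= len(seq):
        raise ValueError(f"position {pos} outside {chrom} (length {len(seq)})")
    start = max(1, pos - half_width)
    end = min(len(seq), pos + half_width)
    return seq[start - 1:end], start, end


def _scores_all_offsets(pwm: PWM, window: str, mode: str) -> tuple[np.ndarray, np.ndarray]:
    """(forward, reverse) score vectors over all start offsets."""
    L = pwm.length
    n = len(window) - L + 1
    if n <= 0:
        return np.empty(0), np.empty(0)
    if mode == "relative":
        lo = pwm.log_odds
        lo_ext = np.vstack([lo, np.zeros(L)])
        smin, smax = lo.min(axis=0).sum(), lo.max(axis=0).sum()
        fwd_codes = _encode(window.upper())
        rev_codes = _encode(reverse_complement(window.upper()))
        fwd = np.zeros(n)
        rev = np.zeros(n)
        for j in range(L):
            fwd += lo_ext[fwd_codes[j:j + n], j]
            rev += lo_ext[rev_codes[j:j + n], j]
        fwd = (fwd - smin) / (smax - smin)
        rev = ((rev - smin) / (smax - smin))[::-1]  # align to forward offsets
        return fwd, rev
    if mode == "consensus":
        fwd = np.array([consensus_identity(pwm, window[i:i + L]) for i in range(n)])
        rev = np.array([consensus_identity(pwm, window[i:i + L], "-") for i in range(n)])
        return fwd, rev
    raise ValueError("mode must be 'relative' or 'consensus'")


def scan_window(
    window: str,
    pwms: Sequence[PWM],
    threshold: float = 0.80,
    mode: str = "relative",
) -> list[PWMHit]:
    """All profile matches at relative score >= threshold, both strands.

    Offsets are 1-based starts within the window (forward-strand
    coordinates for both strands).  Overlapping hits are all reported.
    """
    hits: list[PWMHit] = []
    for pwm in pwms:
        fwd, rev = _scores_all_offsets(pwm, window, mode)
        for strand, scores in (("+", fwd), ("-", rev)):
            for i in np.nonzero(scores >= threshold)[0]:
                hits.append(PWMHit(profile=pwm.name, strand=strand,
                                   offset=int(i) + 1, score=float(scores[i])))
    return sorted(hits, key=lambda h: (h.offset, h.profile, h.strand))


def scan_variants(
    variants: Iterable[tuple[str, int]],
    reference: Mapping[str, str],
    pwms: Sequence[PWM],
    threshold: float = 0.80,
    half_width: int = 1000,
    mode: str = "relative",
) -> list[dict]:
    """Scan the window around every (chrom, pos) variant; one row per hit."""
    rows = []
    for chrom, pos in variants:
        window, start, _ = extract_window(chrom, pos, reference, half_width)
        for hit in scan_window(window, pwms, threshold=threshold, mode=mode):
            rows.append({
                "chrom": chrom, "pos": pos, "profile": hit.profile,
                "strand": hit.strand, "start": start + hit.offset - 1,
                "score": hit.score,
            })
    return rows


def profile_tally(hit_rows: Sequence[dict]) -> dict[str, int]:
    """Number of distinct variants with at least one hit, per profile."""
    seen: dict[str, set] = {}
    for row in hit_rows:
        seen.setdefault(row["profile"], set()).add((row["chrom"], row["pos"]))
    return {profile: len(variants) for profile, variants in sorted(seen.items())}


#: two toy insect-like profiles (Broad-complex- and Hunchback-flavoured)
#: used by the synthetic pipeline; JASPAR text format
EXAMPLE_JASPAR = """\
>BRC4 Broad-complex-4-like
A  [ 12  0  0 20  2  0  0  3 ]
C  [  2  0  0  0  0 18  0  5 ]
G  [  4  0 20  0  0  0  2  8 ]
T  [  2 20  0  0 18  2 18  4 ]
>HB Hunchback-like
A  [ 18  2  0  0  0  0  1  2  3 ]
C  [  0  0  0  0  2  0  1 14  2 ]
G  [  2  0  0  0  0  0  0  2  2 ]
T  [  0 18 20 20 18 20 18  2 13 ]
"""
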