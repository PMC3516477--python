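"""Both-strand PWM scanning of intergenic regions.

Every window of motif length, on both strands, is scored against the PWM
and reported when its exact p-value is strictly below the chosen threshold
(``p < alpha``, matching PATSER-style selection). Coordinates are 1-based,
inclusive, and a match's anchor is the leftmost base of the window on the
forward strand regardless of strand, so overlapping forward/reverse matches
share a coordinate. Windows containing ambiguous bases (N) are skipped:
there is no defensible score for them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .motif_model import (
    PositionWeightMatrix,
    ScoreDistribution,
    exact_score_distribution,
)

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
_COMPLEMENT_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_RC_TABLE = str.maketrans("ACGTN", "TGCAN")
_VALID_SEQ = re.compile(r"^[ACGTN]*$")

_ROMAN = {"I": 1, "V": 5, "X": 10, "L": 50, "C": 100, "D": 500, "M": 1000}


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over the alphabet ACGTN."""
    s = seq.upper()
    if not _VALID_SEQ.match(s):
        bad = sorted(set(s) - set("ACGTN"))
        raise ValueError(f"invalid characters in sequence: {bad}")
    return s.translate(_RC_TABLE)[::-1]


def _roman_value(s: str) -> int | None:
    if not s or any(ch not in _ROMAN for ch in s):
        return None
    total = 0
    prev = 0
    for ch in reversed(s):
        v = _ROMAN[ch]
        total += v if v >= prev else -v
        prev = max(prev, v)
    return total


def chromosome_sort_key(name: str) -> tuple[int, int, str]:
    """Deterministic chromosome ordering: numeric/roman first, then lexical.

    Understands plain integers, roman numerals (yeast convention) and a
    ``chr`` prefix; anything else sorts lexically after the numbered ones.
    """
    core = name[3:] if name.lower().startswith("chr") else name
    if core.isdigit():
        return (0, int(core), "")
    roman = _roman_value(core.upper())
    if roman is not None:
        return (0, roman, "")
    return (1, 0, name)


@dataclass(frozen=True)
class IntergenicRegion:
    """One intergenic region: genomic interval, flanking genes, sequence.

    ``start``/``end`` are 1-based inclusive; the sequence length must equal
    ``end - start + 1``. Sequences are uppercased on construction.
    """

    region_id: str
    species: str
    chromosome: str
    start: int
    end: int
    left_gene: str
    right_gene: str
    sequence: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"region {self.region_id}: end {self.end} < start {self.start}"
            )
        seq = self.sequence.upper()
        if not _VALID_SEQ.match(seq):
            bad = sorted(set(seq) - set("ACGTN"))
            raise ValueError(f"region {self.region_id}: invalid characters {bad}")
        if len(seq) != self.end - self.start + 1:
            raise ValueError(
                f"region {self.region_id}: sequence length {len(seq)} does not "
                f"match span {self.end - self.start + 1}"
            )
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class MotifMatch:
    """One scored motif occurrence.

    ``position`` is the 1-based genomic coordinate of the match's leftmost
    base on the forward strand (for both strands).
    """

    motif_id: str
    region_id: str
    chromosome: str
    position: int
    strand: str
    score: float
    pvalue: float

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError("pvalue must lie in [0, 1]")


def _strand_rank(strand: str) -> int:
    return 0 if strand == "+" else 1


def scan_sequence(
    pwm: PositionWeightMatrix,
    region: IntergenicRegion,
    alpha: float,
    both_strands: bool = True,
    dist: ScoreDistribution | None = None,
) -> list[MotifMatch]:
    """All windows of ``region`` with exact p-value strictly below ``alpha``.

    Output is sorted by position, then strand (+ before -). Overlapping
    matches are all reported; a region shorter than the motif yields an
    empty list. Pass a precomputed ``dist`` when scanning many regions with
    the same PWM.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    L = pwm.length
    n = region.length - L + 1
    if n <= 0:
        return []
    if dist is None:
        dist = exact_score_distribution(pwm)

    codes = _ENCODE[np.frombuffer(region.sequence.encode("ascii"), dtype=np.uint8)]
    lo5 = np.full((L, 5), np.nan)
    lo5[:, :4] = pwm.logodds

    # Forward-strand scores, accumulated in the same position order as
    # score_word so the two routes are bit-identical.
    fwd = np.zeros(n)
    for i in range(L):
        fwd += lo5[i, codes[i : i + n]]

    matches: list[MotifMatch] = []
    fwd_p = dist.pvalues(fwd)
    for pos in np.nonzero(~np.isnan(fwd) & (fwd_p < alpha))[0]:
        matches.append(
            MotifMatch(
                motif_id=pwm.motif_id,
                region_id=region.region_id,
                chromosome=region.chromosome,
                position=region.start + int(pos),
                strand="+",
                score=float(fwd[pos]),
                pvalue=float(fwd_p[pos]),
            )
        )

    if both_strands:
        comp = _COMPLEMENT_CODE[codes]
        # Score of the reverse-complement word, summed in the order
        # score_word(pwm, reverse_complement(window)) would use: term i reads
        # the complement of the window base at offset L-1-i.
        rev = np.zeros(n)
        for i in range(L):
            rev += lo5[i, comp[L - 1 - i : L - 1 - i + n]]
        rev_p = dist.pvalues(rev)
        for pos in np.nonzero(~np.isnan(rev) & (rev_p < alpha))[0]:
            matches.append(
                MotifMatch(
                    motif_id=pwm.motif_id,
                    region_id=region.region_id,
                    chromosome=region.chromosome,
                    position=region.start + int(pos),
                    strand="-",
                    score=float(rev[pos]),
                    pvalue=float(rev_p[pos]),
                )
            )

    matches.sort(key=lambda m: (m.position, _strand_rank(m.strand)))
    return matches


def scan_region_set(
    pwm: PositionWeightMatrix,
    regions: Sequence[IntergenicRegion],
    alpha: float,
    both_strands: bool = True,
    dist: ScoreDistribution | None = None,
) -> list[MotifMatch]:
    """Scan many regions with one PWM; deterministic genome-wide ordering.

    Region ids must be unique. Output is sorted by (chromosome, position,
    strand) with chromosomes in natural (numeric/roman-aware) order.
    """
    ids = [r.region_id for r in regions]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate region ids: {dupes}")
    if dist is None and regions:
        dist = exact_score_distribution(pwm)
    matches: list[MotifMatch] = []
    for region in regions:
        matches.extend(
            scan_sequence(pwm, region, alpha, both_strands=both_strands, dist=dist)
        )
    matches.sort(
        key=lambda m: (chromosome_sort_key(m.chromosome), m.position, _strand_rank(m.strand))
    )
    return matches
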