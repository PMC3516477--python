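"""Position weight matrices and exact match significance.

A transcription-factor binding motif is modelled as a position weight
matrix (PWM): per-position base probabilities estimated from counts of
aligned binding sites, optionally regularised with a background-proportional
pseudocount. Sequence windows are scored as summed natural-log odds of the
motif model versus a mononucleotide background model, and the significance
of a score is the probability that a random background word of motif length
scores at least as high. That null distribution is computed *exactly* by
dynamic programming: the per-position score distributions (four atoms each,
weighted by background frequencies) are discretised onto a common grid and
convolved column by column — the same construction behind PATSER-style
match p-values.

Conventions used throughout:

* Bases are ordered ``A, C, G, T``; matrices are ``(L, 4)`` numpy arrays.
* Log-odds are natural-log; information content alone is reported in bits.
* A base with probability zero (possible when ``pseudocount_total == 0``)
  has log-odds ``-inf``; such words can never be reported as matches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

BASES = "ACGT"
BASE_INDEX: Mapping[str, int] = {b: i for i, b in enumerate(BASES)}

#: Default number of discretisation bins spanning the widest column score
#: range when no granularity is supplied. Keeps the discretisation error far
#: below the spacing between adjacent achievable word scores for motif
#: lengths up to ~20, so tails in the 1e-9 regime stay distinguishable.
DEFAULT_BINS_PER_COLUMN = 10_000


def _freqs_to_array(freqs: Mapping[str, float]) -> np.ndarray:
    if set(freqs) != set(BASES):
        raise ValueError(f"background must define exactly the bases {BASES!r}")
    arr = np.array([float(freqs[b]) for b in BASES])
    if np.any(arr <= 0):
        raise ValueError("background frequencies must all be positive")
    if abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError("background frequencies must sum to 1 (within 1e-9)")
    return arr


@dataclass(frozen=True)
class BackgroundModel:
    """Mononucleotide background: one probability per base, summing to 1."""

    freqs: Mapping[str, float]

    def __post_init__(self) -> None:
        arr = _freqs_to_array(self.freqs)
        object.__setattr__(self, "freqs", {b: float(arr[i]) for i, b in enumerate(BASES)})
        object.__setattr__(self, "_array", arr)

    @property
    def array(self) -> np.ndarray:
        """Frequencies as a length-4 array in A,C,G,T order."""
        return self._array  # type: ignore[attr-defined]

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls({b: 0.25 for b in BASES})

    @classmethod
    def from_gc(cls, gc: float) -> "BackgroundModel":
        """Strand-symmetric background with the given G+C content."""
        if not 0 < gc < 1:
            raise ValueError("gc must be in (0, 1)")
        at = (1.0 - gc) / 2.0
        return cls({"A": at, "C": gc / 2.0, "G": gc / 2.0, "T": at})

    @classmethod
    def from_sequences(cls, sequences: Sequence[str]) -> "BackgroundModel":
        """Estimate frequencies from the scanned sequence set.

        Characters other than A/C/G/T (e.g. N) are ignored. A small floor
        keeps every frequency positive even for skewed inputs.
        """
        counts = np.zeros(4)
        for seq in sequences:
            for ch in seq.upper():
                idx = BASE_INDEX.get(ch)
                if idx is not None:
                    counts[idx] += 1
        if counts.sum() == 0:
            raise ValueError("no A/C/G/T characters in the supplied sequences")
        counts += 0.5  # Jeffreys-style floor so no frequency is exactly zero
        arr = counts / counts.sum()
        return cls({b: arr[i] for i, b in enumerate(BASES)})


@dataclass(frozen=True)
class CountMatrix:
    """Per-position base counts for a motif, columns ordered A,C,G,T."""

    motif_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4 or arr.shape[0] < 1:
            raise ValueError("counts must be an (L, 4) array with L >= 1")
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise ValueError("counts must be finite and non-negative")
        if not np.any(arr.sum(axis=1) > 0):
            raise ValueError("at least one position must have a positive total")
        object.__setattr__(self, "counts", arr)

    @property
    def length(self) -> int:
        return self.counts.shape[0]


def sites_to_counts(
    aligned_sites: Sequence[str],
    weights: Sequence[float] | None = None,
    motif_id: str = "sites",
) -> CountMatrix:
    """Tally aligned binding sites (equal-length, ACGT only) into counts.

    ``weights`` default to 1 per site; weighted tallies support sites pooled
    across species or replicate maps.
    """
    if len(aligned_sites) == 0:
        raise ValueError("aligned_sites must not be empty")
    length = len(aligned_sites[0])
    if length == 0:
        raise ValueError("sites must be non-empty strings")
    if weights is None:
        weights = [1.0] * len(aligned_sites)
    if len(weights) != len(aligned_sites):
        raise ValueError("one weight per site required")
    counts = np.zeros((length, 4))
    for site, w in zip(aligned_sites, weights):
        site = site.upper()
        if len(site) != length:
            raise ValueError(f"site {site!r} has length {len(site)}, expected {length}")
        for i, ch in enumerate(site):
            idx = BASE_INDEX.get(ch)
            if idx is None:
                raise ValueError(f"non-ACGT character {ch!r} in site {site!r}")
            counts[i, idx] += float(w)
    return CountMatrix(motif_id=motif_id, counts=counts)


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Probability and log-odds view of a motif against a background model."""

    motif_id: str
    probs: np.ndarray
    logodds: np.ndarray
    background: BackgroundModel
    pseudocount_total: float

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        lo = np.asarray(self.logodds, dtype=float)
        if probs.shape != lo.shape or probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("probs and logodds must be matching (L, 4) arrays")
        if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("each position's probabilities must sum to 1")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "logodds", lo)

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        """Most probable base at each position (ties broken A<C<G<T)."""
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=1))

    @property
    def max_score(self) -> float:
        return float(np.max(self.logodds, axis=1).sum())

    def reverse_complement(self) -> "PositionWeightMatrix":
        """The motif as read on the opposite strand.

        The background is assumed strand-symmetric for scoring purposes; the
        complement background is used so the log-odds stay self-consistent.
        """
        probs = self.probs[::-1, ::-1].copy()
        bg = self.background.freqs
        comp_bg = BackgroundModel(
            {"A": bg["T"], "C": bg["G"], "G": bg["C"], "T": bg["A"]}
        )
        with np.errstate(divide="ignore"):
            lo = np.log(probs) - np.log(comp_bg.array)
        return PositionWeightMatrix(
            motif_id=self.motif_id + "_rc",
            probs=probs,
            logodds=lo,
            background=comp_bg,
            pseudocount_total=self.pseudocount_total,
        )


def build_pwm(
    counts: CountMatrix,
    background: BackgroundModel | None = None,
    pseudocount_total: float = 1.0,
) -> PositionWeightMatrix:
    """Turn counts into a PWM with a background-proportional pseudocount.

    ``probs[i][b] = (counts[i][b] + pseudocount_total * background[b])
    / (total_i + pseudocount_total)``. With ``pseudocount_total = 0`` this is
    the maximum-likelihood frequency estimate, and columns may contain exact
    zeros (log-odds ``-inf``).
    """
    if background is None:
        background = BackgroundModel.uniform()
    if pseudocount_total < 0:
        raise ValueError("pseudocount_total must be >= 0")
    c = counts.counts
    totals = c.sum(axis=1)
    if pseudocount_total == 0 and np.any(totals == 0):
        raise ValueError(
            "all-zero count column with pseudocount_total=0: probabilities undefined"
        )
    bg = background.array
    probs = (c + pseudocount_total * bg) / (totals + pseudocount_total)[:, None]
    with np.errstate(divide="ignore"):
        logodds = np.log(probs) - np.log(bg)
    return PositionWeightMatrix(
        motif_id=counts.motif_id,
        probs=probs,
        logodds=logodds,
        background=background,
        pseudocount_total=float(pseudocount_total),
    )


def information_content(pwm: PositionWeightMatrix) -> np.ndarray:
    """Per-position information content in bits: ``2 + sum_b p log2 p``.

    This is the column height of a sequence logo (without small-sample
    correction); 0 for a uniform column, 2 for a deterministic one.
    """
    p = pwm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    bits = 2.0 + terms.sum(axis=1)
    return np.clip(bits, 0.0, 2.0)


def score_word(pwm: PositionWeightMatrix, word: str) -> float:
    """Log-odds score of one word of exactly motif length.

    Ambiguous bases are not scorable: no defensible score exists for N, so
    callers (the scanner) must decide the skip policy explicitly.
    """
    if len(word) != pwm.length:
        raise ValueError(
            f"word length {len(word)} does not match motif length {pwm.length}"
        )
    lo = pwm.logodds
    score = 0.0
    for i, ch in enumerate(word.upper()):
        idx = BASE_INDEX.get(ch)
        if idx is None:
            raise ValueError(f"non-scorable character {ch!r} at position {i}")
        score += lo[i, idx]
    return score


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact null distribution of word scores on a discretised grid.

    ``probs[k]`` is the probability that a random background word falls in
    integer bin ``min_bin + k``; a bin's representative score is
    ``bin * granularity``. The survival function is precomputed so p-value
    lookups are O(1).
    """

    granularity: float
    min_bin: int
    probs: np.ndarray
    motif_length: int

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if self.granularity <= 0:
            raise ValueError("granularity must be positive")
        sf = np.cumsum(probs[::-1])[::-1]
        sf[0] = 1.0  # total probability is 1 by construction
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "_sf", sf)

    @property
    def max_bin(self) -> int:
        return self.min_bin + len(self.probs) - 1

    @property
    def min_score(self) -> float:
        return self.min_bin * self.granularity

    @property
    def max_score(self) -> float:
        return self.max_bin * self.granularity

    @property
    def pmf(self) -> dict[int, float]:
        """Sparse map of integer bin -> probability (zero bins omitted)."""
        nz = np.nonzero(self.probs)[0]
        return {int(self.min_bin + k): float(self.probs[k]) for k in nz}

    def pvalues(self, scores: np.ndarray) -> np.ndarray:
        """Vectorised ``P(random word score >= s)`` with floor-to-bin mapping."""
        s = np.asarray(scores, dtype=float)
        out = np.ones(s.shape)
        sf = self._sf  # type: ignore[attr-defined]
        with np.errstate(invalid="ignore"):
            bins = np.floor(s / self.granularity + 1e-9)
        out[np.isnan(s)] = np.nan
        neg_inf = np.isneginf(s)
        pos_inf = np.isposinf(s)
        finite = np.isfinite(s)
        above = finite & (bins > self.max_bin)
        below = finite & (bins < self.min_bin)
        inside = finite & ~above & ~below
        out[above | pos_inf] = 0.0
        out[below | neg_inf] = 1.0
        idx = (bins[inside] - self.min_bin).astype(np.int64)
        out[inside] = sf[idx]
        return out

    def pvalue(self, score: float) -> float:
        return float(self.pvalues(np.array([score]))[0])


def exact_score_distribution(
    pwm: PositionWeightMatrix, granularity: float | None = None
) -> ScoreDistribution:
    """Exact score distribution under the PWM's background model.

    Column score atoms are rounded to the nearest multiple of
    ``granularity`` and convolved position by position (sparse shifts, four
    atoms per column). The default granularity spans the widest finite
    column score range with :data:`DEFAULT_BINS_PER_COLUMN` bins.

    Bases with probability zero (log-odds ``-inf``) are clamped onto a
    finite bin separated from the finite support by a gap larger than the
    whole finite span, so every tail above the finite minimum is exact and
    the pmf still sums to 1.
    """
    lo = pwm.logodds
    L = pwm.length
    finite = np.isfinite(lo)
    if not finite.any(axis=1).all():
        raise ValueError("every column needs at least one finite log-odds score")
    col_min = np.where(finite, lo, np.inf).min(axis=1)
    col_max = np.where(finite, lo, -np.inf).max(axis=1)
    col_range = col_max - col_min
    if granularity is None:
        widest = float(col_range.max())
        if widest <= 0:
            # Degenerate columns (single achievable score): fall back to a
            # grid fine relative to the scores' magnitude.
            widest = max(float(np.abs(lo[finite]).max()), 1.0)
        granularity = widest / DEFAULT_BINS_PER_COLUMN
    if granularity <= 0:
        raise ValueError("granularity must be positive")

    bins = np.zeros((L, 4), dtype=np.int64)
    bins[finite] = np.rint(lo[finite] / granularity).astype(np.int64)
    if not finite.all():
        span_bins = int(np.rint(col_range / granularity).sum()) + L
        gap = span_bins + DEFAULT_BINS_PER_COLUMN
        for i in range(L):
            if not finite[i].all():
                floor_bin = bins[i][finite[i]].min() - gap
                bins[i][~finite[i]] = floor_bin

    bg = pwm.background.array
    arr = np.array([1.0])
    offset = 0
    for i in range(L):
        b = bins[i]
        lo_b = int(b.min())
        hi_b = int(b.max())
        new = np.zeros(len(arr) + hi_b - lo_b)
        for base in range(4):
            shift = int(b[base]) - lo_b
            new[shift : shift + len(arr)] += bg[base] * arr
        arr = new
        offset += lo_b
    return ScoreDistribution(
        granularity=float(granularity), min_bin=offset, probs=arr, motif_length=L
    )


def pvalue(dist: ScoreDistribution, score: float) -> float:
    """P(random background word scores >= ``score``); monotone non-increasing."""
    return dist.pvalue(score)


def threshold_for_pvalue(dist: ScoreDistribution, alpha: float) -> float:
    """Smallest achievable score whose tail probability is strictly < alpha.

    The search is over the distribution's support: if even the maximal score
    has tail >= alpha (i.e. no word can be called significant at alpha),
    ``math.inf`` is returned as an unattainable sentinel.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    sf = dist._sf  # type: ignore[attr-defined]
    hits = np.nonzero(sf < alpha)[0]
    if len(hits) == 0:
        return math.inf
    return float((dist.min_bin + int(hits[0])) * dist.granularity)
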