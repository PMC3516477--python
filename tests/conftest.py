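"""Shared fixtures: PWMs, regions, and the naive scanning oracle."""

from __future__ import annotations

import numpy as np
import pytest

from silencerscan import (
    BackgroundModel,
    CountMatrix,
    IntergenicRegion,
    MotifMatch,
    build_pwm,
    reverse_complement,
    score_word,
    sites_to_counts,
)
from silencerscan.fixtures import RAP1_GENOME_WIDE_CONSENSUS


@pytest.fixture
def uniform_bg() -> BackgroundModel:
    return BackgroundModel.uniform()


@pytest.fixture
def rap1_pwm():
    """Soft Rap1 PWM: consensus counts with the default unit pseudocount."""
    counts = sites_to_counts([RAP1_GENOME_WIDE_CONSENSUS], motif_id="Rap1")
    return build_pwm(counts, pseudocount_total=1.0)


@pytest.fixture
def rap1_consensus_pwm_fixture():
    """Deterministic Rap1 PWM (zero pseudocount): exact-consensus model."""
    counts = sites_to_counts([RAP1_GENOME_WIDE_CONSENSUS], motif_id="Rap1")
    return build_pwm(counts, pseudocount_total=0.0)


def make_region(
    sequence: str,
    region_id: str = "r1",
    start: int = 1,
    chromosome: str = "chrI",
    species: str = "Scer",
) -> IntergenicRegion:
    return IntergenicRegion(
        region_id=region_id,
        species=species,
        chromosome=chromosome,
        start=start,
        end=start + len(sequence) - 1,
        left_gene="gL",
        right_gene="gR",
        sequence=sequence,
    )


def random_sequence(rng: np.random.Generator, n: int, gc: float = 0.38) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join("ACGT"[i] for i in rng.choice(4, size=n, p=p))


def naive_scan(pwm, region, alpha, dist, both_strands=True):
    """Brute-force per-window rescoring oracle, independent of the scanner.

    Iterates every window in pure Python, scores via score_word (reverse
    strand: the reverse-complemented window), takes the p-value from the
    same exact distribution, and applies the strict p < alpha rule.
    """
    L = pwm.length
    seq = region.sequence
    out = []
    for off in range(len(seq) - L + 1):
        window = seq[off : off + L]
        strands = [("+", window)]
        if both_strands:
            strands.append(("-", reverse_complement(window)))
        for strand, word in strands:
            if "N" in word:
                continue
            s = score_word(pwm, word)
            p = dist.pvalue(s)
            if p < alpha:
                out.append(
                    MotifMatch(
                        motif_id=pwm.motif_id,
                        region_id=region.region_id,
                        chromosome=region.chromosome,
                        position=region.start + off,
                        strand=strand,
                        score=s,
                        pvalue=p,
                    )
                )
    out.sort(key=lambda m: (m.position, 0 if m.strand == "+" else 1))
    return out


def random_pwm(rng: np.random.Generator, length: int, motif_id: str = "m"):
    """A random PWM over a random Dirichlet background, positive pseudocount."""
    counts = rng.integers(0, 30, size=(length, 4)).astype(float)
    counts[rng.integers(0, length), rng.integers(0, 4)] += 5  # avoid all-flat
    bg_vec = rng.dirichlet([5.0] * 4)
    bg = BackgroundModel({b: float(bg_vec[i]) for i, b in enumerate("ACGT")})
    pc = float(rng.uniform(0.1, 2.0))
    return build_pwm(CountMatrix(motif_id, counts), background=bg, pseudocount_total=pc)
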