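"""Proto-silencer detection, conservation statistics, and motif frequency.

A *proto-silencer* is an intergenic region in which a Rap1 and an Abf1
binding-site match lie within a fixed distance of each other (50 bp by
default) — the silencer-like two-factor architecture occurring outside the
silenced loci. This module implements the statistics built on that
definition:

* co-occurrence detection over per-motif match lists;
* reciprocal-best-hit (RBH) orthology of intergenic regions from a
  flanking-gene similarity table;
* cross-species presence calls ("conserved in >= k of the sensu stricto
  species") and the 2x2 chi-squared comparison of proto-silencer versus
  genome-wide conservation;
* per-transcription-factor binding-site frequency (matches per 10 kb of
  factor-bound intergenic sequence) with the ChIP filtering rule
  (binding p strictly < 0.05 in at least 60 distinct regions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .motif_model import PositionWeightMatrix, ScoreDistribution
from .scanner import IntergenicRegion, MotifMatch, chromosome_sort_key, scan_sequence


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds of the analysis; defaults are the study's stated values."""

    cooccurrence_window: int = 50
    min_species_conserved: int = 3
    scan_alpha: float = 1e-9
    chip_p_max: float = 0.05
    chip_min_regions: int = 60
    frequency_scale: int = 10_000

    def __post_init__(self) -> None:
        if self.cooccurrence_window <= 0 or self.min_species_conserved <= 0:
            raise ValueError("window and min_species_conserved must be positive")
        if self.chip_min_regions <= 0 or self.frequency_scale <= 0:
            raise ValueError("chip_min_regions and frequency_scale must be positive")
        for p in (self.scan_alpha, self.chip_p_max):
            if not 0 < p <= 1:
                raise ValueError("probabilities must lie in (0, 1]")


@dataclass(frozen=True)
class ProtoSilencer:
    """A qualifying Rap1-Abf1 match pair within the co-occurrence window."""

    region_id: str
    chromosome: str
    rap1_match: MotifMatch
    abf1_match: MotifMatch
    distance: int

    def __post_init__(self) -> None:
        if self.distance != abs(self.rap1_match.position - self.abf1_match.position):
            raise ValueError("distance must equal |rap1.position - abf1.position|")


def find_proto_silencers(
    rap1_matches: Sequence[MotifMatch],
    abf1_matches: Sequence[MotifMatch],
    window: int = 50,
) -> list[ProtoSilencer]:
    """All (Rap1, Abf1) pairs sharing a region with anchor distance <= window.

    Every qualifying pair is emitted (no greedy matching), so a region with
    clustered sites can yield several proto-silencers. The boundary is
    inclusive and the distance is the absolute difference of the two
    leftmost-base anchors. Output is sorted by chromosome (natural order),
    then Rap1 position, then Abf1 position.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    by_region: dict[str, list[MotifMatch]] = {}
    for m in abf1_matches:
        by_region.setdefault(m.region_id, []).append(m)
    out: list[ProtoSilencer] = []
    for r in rap1_matches:
        for a in by_region.get(r.region_id, ()):
            d = abs(r.position - a.position)
            if d <= window:
                out.append(
                    ProtoSilencer(
                        region_id=r.region_id,
                        chromosome=r.chromosome,
                        rap1_match=r,
                        abf1_match=a,
                        distance=d,
                    )
                )
    out.sort(
        key=lambda p: (
            chromosome_sort_key(p.chromosome),
            p.rap1_match.position,
            p.abf1_match.position,
        )
    )
    return out


@dataclass(frozen=True)
class OrthologyMap:
    """Region orthology: (reference region_id, species) -> target region_id."""

    entries: Mapping[tuple[str, str], str]

    def get(self, region_id: str, species: str) -> str | None:
        return self.entries.get((region_id, species))

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted({s for (_, s) in self.entries}))


def _best_hits(
    similarities: pd.DataFrame,
) -> dict[tuple[str, str, str], str | None]:
    """Unique top-scoring partner per (gene, own species, other species).

    Rows are treated symmetrically (a similarity score is shared by both
    directions). A tied top score between different partners leaves the gene
    without a best hit — ties break nothing.
    """
    best: dict[tuple[str, str, str], tuple[float, str | None]] = {}

    def consider(gene: str, sp: str, other_sp: str, partner: str, score: float) -> None:
        key = (gene, sp, other_sp)
        cur = best.get(key)
        if cur is None or score > cur[0]:
            best[key] = (score, partner)
        elif score == cur[0] and partner != cur[1]:
            best[key] = (score, None)

    for row in similarities.itertuples(index=False):
        a, sa, b, sb, score = (
            row.gene_a,
            row.species_a,
            row.gene_b,
            row.species_b,
            float(row.score),
        )
        consider(a, sa, sb, b, score)
        consider(b, sb, sa, a, score)
    return {k: v[1] for k, v in best.items()}


def rbh_orthology(
    similarities: pd.DataFrame,
    regions_by_species: Mapping[str, Sequence[IntergenicRegion]],
    reference_species: str,
) -> OrthologyMap:
    """Reciprocal-best-hit orthology of intergenic regions via flanking genes.

    ``similarities`` needs columns ``gene_a, species_a, gene_b, species_b,
    score`` (higher = more similar). A reference region maps to a target
    region iff both flanking genes are RBHs and their partners flank exactly
    one region in the target species; unresolved regions are simply absent.
    """
    required = {"gene_a", "species_a", "gene_b", "species_b", "score"}
    if not required.issubset(similarities.columns):
        raise ValueError(f"similarity table needs columns {sorted(required)}")
    if reference_species not in regions_by_species:
        raise ValueError(f"unknown reference species {reference_species!r}")
    best = _best_hits(similarities)

    def rbh_partner(gene: str, target_sp: str) -> str | None:
        partner = best.get((gene, reference_species, target_sp))
        if partner is None:
            return None
        back = best.get((partner, target_sp, reference_species))
        return partner if back == gene else None

    entries: dict[tuple[str, str], str] = {}
    for sp, regions in regions_by_species.items():
        if sp == reference_species:
            continue
        flank_index: dict[frozenset[str], list[IntergenicRegion]] = {}
        for reg in regions:
            flank_index.setdefault(
                frozenset((reg.left_gene, reg.right_gene)), []
            ).append(reg)
        for ref_reg in regions_by_species[reference_species]:
            pl = rbh_partner(ref_reg.left_gene, sp)
            pr = rbh_partner(ref_reg.right_gene, sp)
            if pl is None or pr is None:
                continue
            candidates = flank_index.get(frozenset((pl, pr)), [])
            if len(candidates) == 1:
                entries[(ref_reg.region_id, sp)] = candidates[0].region_id
    return OrthologyMap(entries=entries)


@dataclass(frozen=True)
class ConservationCall:
    """Per-species presence of one binding site and its conserved/not flag."""

    site: MotifMatch
    present_in: Mapping[str, bool]
    conserved: bool


def _site_key(match: MotifMatch) -> tuple[str, str, int, str]:
    return (match.motif_id, match.region_id, match.position, match.strand)


def call_conservation(
    site: MotifMatch,
    orthology: OrthologyMap,
    species_regions: Mapping[str, Mapping[str, IntergenicRegion] | Sequence[IntergenicRegion]],
    pwm: PositionWeightMatrix,
    alpha: float,
    min_species: int = 3,
    reference_species: str | None = None,
    include_reference: bool = True,
    dist: ScoreDistribution | None = None,
) -> ConservationCall:
    """Presence of ``site`` across species and the >= min_species verdict.

    A site is present in species ``s`` when the orthologous region exists
    and contains at least one match to ``pwm`` at ``p < alpha`` on either
    strand, at any offset (no positional tolerance — orthologous intergenic
    regions are short). The reference species counts as present by
    definition; ``include_reference`` controls whether it counts toward the
    ``min_species`` tally.
    """
    lookup: dict[str, dict[str, IntergenicRegion]] = {}
    for sp, regs in species_regions.items():
        if isinstance(regs, Mapping):
            lookup[sp] = dict(regs)
        else:
            lookup[sp] = {r.region_id: r for r in regs}
    if reference_species is None:
        hosts = [sp for sp, regs in lookup.items() if site.region_id in regs]
        if len(hosts) != 1:
            raise ValueError(
                "reference species is ambiguous; pass reference_species explicitly"
            )
        reference_species = hosts[0]

    present: dict[str, bool] = {reference_species: True}
    for sp in sorted(lookup):
        if sp == reference_species:
            continue
        target_id = orthology.get(site.region_id, sp)
        region = lookup[sp].get(target_id) if target_id is not None else None
        present[sp] = bool(
            region is not None and scan_sequence(pwm, region, alpha, dist=dist)
        )
    tally = sum(
        ok for sp, ok in present.items() if include_reference or sp != reference_species
    )
    return ConservationCall(
        site=site, present_in=present, conserved=tally >= min_species
    )


def conservation_fraction(calls: Sequence[ConservationCall]) -> float:
    """Fraction of sites called conserved."""
    if len(calls) == 0:
        raise ValueError("conservation_fraction needs at least one call")
    return sum(c.conserved for c in calls) / len(calls)


class ChiSquareResult(NamedTuple):
    statistic: float
    pvalue: float


def chi_square_2x2(
    table: Sequence[Sequence[float]] | np.ndarray, yates: bool = False
) -> ChiSquareResult:
    """Pearson chi-squared test of independence on a 2x2 count table.

    ``statistic = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))``; with the Yates
    continuity correction, ``n/2`` is subtracted from ``|ad - bc|`` first
    (floored at zero). The p-value comes from the chi-squared distribution
    with one degree of freedom. All marginals must be positive.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("counts must be finite and non-negative")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins):
        raise ValueError("all row and column marginals must be positive")
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    statistic = n * diff**2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(stats.chi2.sf(statistic, df=1))
    return ChiSquareResult(statistic=float(statistic), pvalue=p)


@dataclass(frozen=True)
class ConservationComparison:
    """Proto-silencer versus genome-wide conservation, with the chi-squared test.

    ``table`` rows are (proto-silencer, genome-wide) and columns are
    (conserved, not conserved); proto-silencer sites are excluded from the
    genome-wide cells so the cells are disjoint.
    """

    genomewide_fraction: float
    protosilencer_fraction: float
    table: np.ndarray
    statistic: float
    pvalue: float


def compare_conservation(
    genomewide_calls: Sequence[ConservationCall],
    protosilencer_calls: Sequence[ConservationCall],
    yates: bool = False,
) -> ConservationComparison:
    """Test whether proto-silencer sites are conserved differently.

    Builds the 2x2 table of conserved/not by site class and applies
    :func:`chi_square_2x2`. Sites appearing in the proto-silencer list are
    removed from the genome-wide list first (by motif, region, position and
    strand) to keep the two classes disjoint.
    """
    if len(protosilencer_calls) == 0 or len(genomewide_calls) == 0:
        raise ValueError("both call lists must be non-empty")
    ps_keys = {_site_key(c.site) for c in protosilencer_calls}
    gw = [c for c in genomewide_calls if _site_key(c.site) not in ps_keys]
    if len(gw) == 0:
        raise ValueError("no genome-wide sites remain outside the proto-silencers")
    ps_cons = sum(c.conserved for c in protosilencer_calls)
    gw_cons = sum(c.conserved for c in gw)
    table = np.array(
        [
            [ps_cons, len(protosilencer_calls) - ps_cons],
            [gw_cons, len(gw) - gw_cons],
        ],
        dtype=float,
    )
    stat, p = chi_square_2x2(table, yates=yates)
    return ConservationComparison(
        genomewide_fraction=gw_cons / len(gw),
        protosilencer_fraction=ps_cons / len(protosilencer_calls),
        table=table,
        statistic=stat,
        pvalue=p,
    )


@dataclass(frozen=True)
class TFBindingSet:
    """Regions bound by one factor after the ChIP filtering rule."""

    factor: str
    bound_regions: frozenset[str]
    binding_pvalues: Mapping[str, float]


def filter_tf_sets(
    chip_records: pd.DataFrame,
    p_max: float = 0.05,
    min_regions: int = 60,
) -> list[TFBindingSet]:
    """Keep factors binding >= ``min_regions`` distinct regions at p < ``p_max``.

    Both thresholds follow the stated conventions exactly: strict ``<`` on
    the binding p-value, ``>=`` on the distinct-region count. Input needs
    columns ``factor, region_id, p``.
    """
    required = {"factor", "region_id", "p"}
    if not required.issubset(chip_records.columns):
        raise ValueError(f"chip table needs columns {sorted(required)}")
    out: list[TFBindingSet] = []
    qualifying = chip_records[chip_records["p"] < p_max]
    for factor, grp in qualifying.groupby("factor", sort=True):
        pvals = grp.groupby("region_id")["p"].min()
        if len(pvals) >= min_regions:
            out.append(
                TFBindingSet(
                    factor=str(factor),
                    bound_regions=frozenset(pvals.index),
                    binding_pvalues={str(r): float(p) for r, p in pvals.items()},
                )
            )
    return out


@dataclass(frozen=True)
class FrequencyRecord:
    """Motif matches per unit of factor-bound intergenic sequence."""

    factor: str
    motif_id: str
    n_matches: int
    total_length: int
    freq_per_10kb: float


def motif_frequency(
    tf_set: TFBindingSet,
    matches: Sequence[MotifMatch],
    regions: Mapping[str, int] | Sequence[IntergenicRegion],
    scale: int = 10_000,
) -> FrequencyRecord:
    """Matches per ``scale`` bp of the factor's bound intergenic sequence.

    ``regions`` supplies region lengths (a region_id -> length mapping or a
    region list). Counts matches whose region is in the bound set, divides
    by the summed bound-region lengths and multiplies by ``scale``.
    """
    if isinstance(regions, Mapping):
        lengths = dict(regions)
    else:
        lengths = {r.region_id: r.length for r in regions}
    missing = [r for r in tf_set.bound_regions if r not in lengths]
    if missing:
        raise ValueError(f"no known length for bound regions: {sorted(missing)[:5]}")
    total = sum(lengths[r] for r in tf_set.bound_regions)
    if total == 0:
        raise ValueError("total bound-region length is zero")
    n = sum(m.region_id in tf_set.bound_regions for m in matches)
    motif_id = matches[0].motif_id if matches else ""
    return FrequencyRecord(
        factor=tf_set.factor,
        motif_id=motif_id,
        n_matches=int(n),
        total_length=int(total),
        freq_per_10kb=n / total * scale,
    )
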