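"""Truth-known synthetic multi-species cohorts.

The generator emulates the inputs of the real analysis without any
downloads: a set of yeast-like intergenic regions (lognormal lengths,
AT-rich background), motif instances planted at known non-overlapping
positions, a star phylogeny of diverged species (i.i.d. Jukes-Cantor-like
substitutions from a common ancestor, no indels), per-site retention of
planted instances, a bijective region-orthology truth, a flanking-gene
similarity table for RBH stress-testing, and a ChIP-style factor-binding
table. Every output is a pure function of (config, seed).

Planted instances are drawn from the planting PWM's per-position
probabilities; with the default zero-pseudocount consensus matrices this
means exact consensus words. In a derived species a planted site survives
intact with probability ``site_retention_prob``; otherwise it is left to
mutate like the surrounding background, which degrades but does not always
destroy it — matching how real conservation calls behave.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import fixtures
from .motif_model import BASES, PositionWeightMatrix
from .scanner import IntergenicRegion, reverse_complement
from .silencer_analysis import OrthologyMap

#: Species labels for the default five-way cohort; the first is the
#: reference. Extra species beyond five get generic labels.
SENSU_STRICTO_LABELS = ("Scer", "Spar", "Smik", "Skud", "Sbay")

_REGION_GAP = 100  # bp of unmodelled spacer between synthetic regions


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    ``log_length_mean``/``log_length_sd`` parameterise the natural-log
    region length (median ~446 bp at the defaults, the scale of yeast
    intergenic regions); ``gc_content`` 0.38 is yeast-like intergenic
    background; ``substitution_prob`` is the per-site substitution
    probability on each derived branch of the star phylogeny;
    ``planting_rate`` is the expected number of planted instances per
    region per motif (Poisson). ``sites_per_region`` overrides the Poisson
    draw with a fixed per-region, per-motif count; conservation
    calibrations use 1 because presence is called at region level, so the
    closed-form expectation assumes a 1:1 site-region correspondence.
    """

    n_regions: int = 150
    log_length_mean: float = 6.1
    log_length_sd: float = 0.5
    gc_content: float = 0.38
    n_species: int = 5
    substitution_prob: float = 0.25
    site_retention_prob: float = 0.8
    planting_rate: float = 1.0
    sites_per_region: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1 or self.n_species < 1:
            raise ValueError("n_regions and n_species must be >= 1")
        for name in ("gc_content", "substitution_prob", "site_retention_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must lie in (0, 1)")
        if self.planting_rate < 0 or self.log_length_sd < 0:
            raise ValueError("planting_rate and log_length_sd must be >= 0")
        if self.sites_per_region is not None and self.sites_per_region < 0:
            raise ValueError("sites_per_region must be >= 0 when set")


def species_labels(n_species: int) -> tuple[str, ...]:
    labels = list(SENSU_STRICTO_LABELS[:n_species])
    labels += [f"Sp{i}" for i in range(len(labels) + 1, n_species + 1)]
    return tuple(labels)


@dataclass
class SyntheticCohort:
    """A generated cohort with full ground truth.

    ``sites`` has one row per planted instance (site_id, region_id,
    motif_id, offset [0-based within region], position [1-based genomic],
    strand, sequence as planted on the forward strand of the site's own
    orientation); ``retention`` has one row per (site, derived species).
    """

    config: SimulationConfig
    species: tuple[str, ...]
    regions: dict[str, list[IntergenicRegion]]
    sites: pd.DataFrame
    retention: pd.DataFrame
    orthology: OrthologyMap
    gene_orthologs: pd.DataFrame
    similarities: pd.DataFrame
    chip: pd.DataFrame

    @property
    def reference_species(self) -> str:
        return self.species[0]

    def regions_by_id(self, species: str) -> dict[str, IntergenicRegion]:
        return {r.region_id: r for r in self.regions[species]}

    def retained(self, site_id: int, species: str) -> bool:
        rows = self.retention
        hit = rows[(rows["site_id"] == site_id) & (rows["species"] == species)]
        return bool(hit["retained"].iloc[0])


def _background_codes(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _codes_to_seq(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def _sample_site(rng: np.random.Generator, pwm: PositionWeightMatrix) -> str:
    return "".join(
        BASES[rng.choice(4, p=pwm.probs[i])] for i in range(pwm.length)
    )


def _mutate(
    codes: np.ndarray, prob: float, rng: np.random.Generator
) -> np.ndarray:
    """i.i.d. substitution of each base to one of the other three."""
    out = codes.copy()
    mask = rng.random(len(codes)) < prob
    if mask.any():
        out[mask] = (out[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
    return out


def generate_cohort(
    config: SimulationConfig,
    motifs: Sequence[PositionWeightMatrix] | None = None,
) -> SyntheticCohort:
    """Generate a cohort; byte-identical for a fixed config (incl. seed).

    ``motifs`` are the planting models; the default pair is the Rap1
    consensus PWM and the synthetic Abf1-like consensus PWM (both
    zero-pseudocount, so planted instances are exact consensus words).
    Raises if the planting density leaves no room for non-overlapping
    placement.
    """
    if motifs is None:
        motifs = [fixtures.rap1_consensus_pwm(), fixtures.abf1_synthetic_pwm()]
    rng = np.random.default_rng(config.seed)
    labels = species_labels(config.n_species)
    ref = labels[0]
    max_len = max((m.length for m in motifs), default=0)

    min_region = max(3 * max_len + 10, 40)
    lengths = np.rint(
        rng.lognormal(config.log_length_mean, config.log_length_sd, config.n_regions)
    ).astype(int)
    lengths = np.maximum(lengths, min_region)

    ancestors: list[np.ndarray] = []
    starts: list[int] = []
    cursor = 1
    site_rows: list[dict] = []
    site_id = 0
    for i in range(config.n_regions):
        n = int(lengths[i])
        codes = _background_codes(rng, n, config.gc_content)
        starts.append(cursor)
        occupied: list[tuple[int, int]] = []
        for pwm in motifs:
            if config.sites_per_region is not None:
                k = config.sites_per_region
            else:
                k = rng.poisson(config.planting_rate)
            for _ in range(k):
                L = pwm.length
                placed = False
                for _attempt in range(1000):
                    off = int(rng.integers(0, n - L + 1))
                    if all(off + L <= s or off >= e for s, e in occupied):
                        placed = True
                        break
                if not placed:
                    raise ValueError(
                        "planting density too high to place sites without overlap "
                        f"(region {i}, motif {pwm.motif_id})"
                    )
                occupied.append((off, off + L))
                site_seq = _sample_site(rng, pwm)
                strand = "+" if rng.random() < 0.5 else "-"
                fwd = site_seq if strand == "+" else reverse_complement(site_seq)
                codes[off : off + L] = [BASES.index(ch) for ch in fwd]
                site_rows.append(
                    {
                        "site_id": site_id,
                        "region_id": f"ig{i:04d}",
                        "motif_id": pwm.motif_id,
                        "offset": off,
                        "position": cursor + off,
                        "strand": strand,
                        "sequence": site_seq,
                    }
                )
                site_id += 1
        ancestors.append(codes)
        cursor += n + _REGION_GAP

    sites = pd.DataFrame(
        site_rows,
        columns=[
            "site_id",
            "region_id",
            "motif_id",
            "offset",
            "position",
            "strand",
            "sequence",
        ],
    )

    def region_obj(sp: str, i: int, codes: np.ndarray) -> IntergenicRegion:
        rid = f"ig{i:04d}" if sp == ref else f"{sp}.ig{i:04d}"
        return IntergenicRegion(
            region_id=rid,
            species=sp,
            chromosome="chr_syn",
            start=starts[i],
            end=starts[i] + len(codes) - 1,
            left_gene=f"{sp}.g{i:04d}L" if sp != ref else f"g{i:04d}L",
            right_gene=f"{sp}.g{i:04d}R" if sp != ref else f"g{i:04d}R",
            sequence=_codes_to_seq(codes),
        )

    regions: dict[str, list[IntergenicRegion]] = {
        ref: [region_obj(ref, i, ancestors[i]) for i in range(config.n_regions)]
    }
    retention_rows: list[dict] = []
    ortho_entries: dict[tuple[str, str], str] = {}
    by_region_sites = sites.groupby("region_id") if len(sites) else None

    for sp in labels[1:]:
        sp_regions: list[IntergenicRegion] = []
        for i in range(config.n_regions):
            rid = f"ig{i:04d}"
            derived = _mutate(ancestors[i], config.substitution_prob, rng)
            if by_region_sites is not None and rid in by_region_sites.groups:
                for row in by_region_sites.get_group(rid).itertuples(index=False):
                    keep = bool(rng.random() < config.site_retention_prob)
                    if keep:
                        fwd = (
                            row.sequence
                            if row.strand == "+"
                            else reverse_complement(row.sequence)
                        )
                        derived[row.offset : row.offset + len(fwd)] = [
                            BASES.index(ch) for ch in fwd
                        ]
                    retention_rows.append(
                        {"site_id": row.site_id, "species": sp, "retained": keep}
                    )
            sp_regions.append(region_obj(sp, i, derived))
            ortho_entries[(rid, sp)] = f"{sp}.ig{i:04d}"
        regions[sp] = sp_regions

    retention = pd.DataFrame(
        retention_rows, columns=["site_id", "species", "retained"]
    )
    orthology = OrthologyMap(entries=ortho_entries)

    gene_rows: list[dict] = []
    for sp in labels[1:]:
        for i in range(config.n_regions):
            for side in ("L", "R"):
                gene_rows.append(
                    {
                        "gene_a": f"g{i:04d}{side}",
                        "species_a": ref,
                        "gene_b": f"{sp}.g{i:04d}{side}",
                        "species_b": sp,
                    }
                )
    gene_orthologs = pd.DataFrame(
        gene_rows, columns=["gene_a", "species_a", "gene_b", "species_b"]
    )

    similarities = perturb_similarities(
        gene_orthologs, noise_prob=0.0, seed=int(rng.integers(2**31))
    )
    cohort = SyntheticCohort(
        config=config,
        species=labels,
        regions=regions,
        sites=sites,
        retention=retention,
        orthology=orthology,
        gene_orthologs=gene_orthologs,
        similarities=similarities,
        chip=pd.DataFrame(columns=["factor", "region_id", "p"]),
    )
    cohort.chip = emit_chip_table(
        cohort, n_factors=5, bound_fraction=0.4, seed=int(rng.integers(2**31))
    )
    return cohort


def emit_chip_table(
    cohort: SyntheticCohort,
    n_factors: int = 5,
    bound_fraction: float = 0.4,
    seed: int = 0,
) -> pd.DataFrame:
    """ChIP-style factor->region binding table with p-values.

    Each factor binds a random ``bound_fraction`` of the reference regions
    with p-values drawn below 0.05; unbound regions get p-values above it.
    Deterministic for a fixed seed.
    """
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    if not 0 < bound_fraction <= 1:
        raise ValueError("bound_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    region_ids = [r.region_id for r in cohort.regions[cohort.reference_species]]
    n_bound = max(1, int(round(bound_fraction * len(region_ids))))
    rows: list[dict] = []
    for j in range(n_factors):
        factor = f"TF{j + 1}"
        bound = set(rng.choice(region_ids, size=n_bound, replace=False))
        for rid in region_ids:
            if rid in bound:
                p = float(rng.uniform(1e-6, 0.0499))
            else:
                p = float(rng.uniform(0.051, 1.0))
            rows.append({"factor": factor, "region_id": rid, "p": p})
    return pd.DataFrame(rows, columns=["factor", "region_id", "p"])


def perturb_similarities(
    gene_orthologs: pd.DataFrame,
    noise_prob: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Similarity table from an ortholog truth, with controlled corruption.

    True ortholog pairs receive top scores (uniform 400-600) and each
    reference gene additionally hits two random decoy genes at lower scores
    (uniform 50-300). A ``noise_prob`` fraction of true pairs have their
    score shuffled below the decoy range, which breaks reciprocal-best-hit
    recovery for exactly that gene pair.
    """
    if not 0 <= noise_prob < 1:
        raise ValueError("noise_prob must lie in [0, 1)")
    required = {"gene_a", "species_a", "gene_b", "species_b"}
    if not required.issubset(gene_orthologs.columns):
        raise ValueError(f"ortholog truth needs columns {sorted(required)}")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for (sp_a, sp_b), grp in gene_orthologs.groupby(
        ["species_a", "species_b"], sort=True
    ):
        genes_b = list(grp["gene_b"])
        for row in grp.itertuples(index=False):
            broken = rng.random() < noise_prob
            score = (
                float(rng.uniform(1.0, 40.0))
                if broken
                else float(rng.uniform(400.0, 600.0))
            )
            rows.append(
                {
                    "gene_a": row.gene_a,
                    "species_a": sp_a,
                    "gene_b": row.gene_b,
                    "species_b": sp_b,
                    "score": score,
                }
            )
            if len(genes_b) > 1:
                for decoy in rng.choice(genes_b, size=min(2, len(genes_b) - 1), replace=False):
                    if decoy == row.gene_b:
                        continue
                    rows.append(
                        {
                            "gene_a": row.gene_a,
                            "species_a": sp_a,
                            "gene_b": str(decoy),
                            "species_b": sp_b,
                            "score": float(rng.uniform(50.0, 300.0)),
                        }
                    )
    return pd.DataFrame(
        rows, columns=["gene_a", "species_a", "gene_b", "species_b", "score"]
    )
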