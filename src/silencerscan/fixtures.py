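"""Packaged sequence fixtures and the proto-silencer locus catalogue.

These are the small reference inputs the pipeline is exercised against:

* the genome-wide Rap1 consensus binding sequence and the reported variants
  of the silencer (HMR-E / HML-E) Rap1 sites in *S. cerevisiae* — the
  literature prints the native HMR-E site in three slightly different
  forms, so all three ship here, labelled, with no canonical choice made;
* a *synthetic* Abf1-like motif (consensus plus aligned site variants)
  standing in for a ChIP-derived Abf1 matrix, which has no plain-text
  deposition — every use of it is labelled synthetic;
* the catalogue of 25 published *S. cerevisiae* proto-silencer loci:
  per-chromosome coordinates of Rap1 and Abf1 binding-site matches lying
  within 50 bp of each other in euchromatic intergenic regions.
"""

from __future__ import annotations

from pathlib import Path

from .motif_model import (
    BackgroundModel,
    PositionWeightMatrix,
    build_pwm,
    sites_to_counts,
)
from .scanner import MotifMatch

#: Genome-wide Rap1 consensus binding sequence (S. cerevisiae).
RAP1_GENOME_WIDE_CONSENSUS = "ACACCCATACATT"

#: The native HMR-E Rap1 binding site as reported, in its three printed
#: forms; no single form is asserted as canonical.
HMR_E_RAP1_VARIANTS = {
    "hmr_e_rap1_v1": "AAACCCATCAACC",
    "hmr_e_rap1_v2": "AAAACCCATCAAC",
    "hmr_e_rap1_v3": "AAACCCATAAC",
}

#: The HML-E Rap1 binding site, likewise a weak match to the consensus.
HML_E_RAP1_SITE = "AAAACCCATTCAT"

#: Synthetic Abf1-like consensus (13 bp): a stand-in constructed around the
#: field's RTCRYN...ACG core, NOT a measured Abf1 matrix.
ABF1_SYNTHETIC_CONSENSUS = "ATCACTAAAACGA"

#: Synthetic aligned Abf1-like sites: the consensus plus single-base
#: variants, giving a soft matrix when tallied. Synthetic stand-in only.
ABF1_SYNTHETIC_SITES = (
    "ATCACTAAAACGA",
    "ATCACTAAAACGA",
    "ATCACTAAAACGA",
    "GTCACTAAAACGA",
    "ATCATTAAAACGA",
    "ATCACTATAACGA",
    "ATCACTAACACGA",
    "ATCACTAAAACGT",
)

#: The 25 published proto-silencer loci: (chromosome, Rap1 binding-site
#: coordinate, Abf1 binding-site coordinate), 1-based. Each locus is a
#: distinct euchromatic intergenic region where the two sites co-occur
#: within 50 bp.
PROTO_SILENCER_LOCI: tuple[tuple[str, int, int], ...] = (
    ("I", 141851, 141829),
    ("II", 682048, 682084),
    ("IV", 43804, 43828),
    ("IV", 836178, 836216),
    ("V", 491217, 491253),
    ("VI", 58434, 58387),
    ("VII", 197190, 197205),
    ("IX", 254357, 254318),
    ("X", 651339, 651294),
    ("X", 684313, 684307),
    ("XI", 39028, 39012),
    ("XI", 327627, 327609),
    ("XI", 407935, 407972),
    ("XI", 416723, 416684),
    ("XII", 202816, 202847),
    ("XII", 636493, 636519),
    ("XII", 1064491, 1064536),
    ("XIII", 551528, 551491),
    ("XIV", 57801, 57820),
    ("XIV", 355971, 355965),
    ("XV", 216461, 216412),
    ("XV", 274433, 274471),
    ("XV", 780709, 780747),
    ("XV", 1009784, 1009821),
    ("XVI", 866585, 866602),
)


def rap1_consensus_pwm(
    pseudocount_total: float = 0.0,
    background: BackgroundModel | None = None,
) -> PositionWeightMatrix:
    """PWM built from the genome-wide Rap1 consensus sequence.

    With the default zero pseudocount the matrix is deterministic (each
    column probability 1 on the consensus base), which is the planting model
    used by the synthetic-data generator.
    """
    counts = sites_to_counts([RAP1_GENOME_WIDE_CONSENSUS], motif_id="Rap1")
    return build_pwm(counts, background=background, pseudocount_total=pseudocount_total)


def abf1_synthetic_pwm(
    pseudocount_total: float = 0.0,
    background: BackgroundModel | None = None,
    soft: bool = False,
) -> PositionWeightMatrix:
    """Synthetic Abf1-like PWM (stand-in, see module docstring).

    ``soft=True`` tallies the aligned site variants instead of the bare
    consensus, giving a matrix with within-column diversity.
    """
    sites = ABF1_SYNTHETIC_SITES if soft else [ABF1_SYNTHETIC_CONSENSUS]
    counts = sites_to_counts(list(sites), motif_id="Abf1")
    return build_pwm(counts, background=background, pseudocount_total=pseudocount_total)


def proto_silencer_matches() -> tuple[list[MotifMatch], list[MotifMatch]]:
    """The locus catalogue as (Rap1, Abf1) coordinate-only match lists.

    Each locus becomes its own region (``locus_01`` ...); scores and
    p-values are placeholders (0.0) because the catalogue records map
    coordinates, not rescored windows.
    """
    rap1: list[MotifMatch] = []
    abf1: list[MotifMatch] = []
    for i, (chrom, rpos, apos) in enumerate(PROTO_SILENCER_LOCI, start=1):
        region_id = f"locus_{i:02d}"
        rap1.append(
            MotifMatch(
                motif_id="Rap1",
                region_id=region_id,
                chromosome=chrom,
                position=rpos,
                strand="+",
                score=0.0,
                pvalue=0.0,
            )
        )
        abf1.append(
            MotifMatch(
                motif_id="Abf1",
                region_id=region_id,
                chromosome=chrom,
                position=apos,
                strand="+",
                score=0.0,
                pvalue=0.0,
            )
        )
    return rap1, abf1


def write_fixture_files(out_dir: str | Path) -> list[Path]:
    """Materialise the packaged fixtures as plain-text files.

    Writes the proto-silencer locus table (TSV), the Rap1 consensus/variant
    sequences (FASTA) and the synthetic Abf1-like aligned sites (one per
    line). Returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    loci = out / "proto_silencer_loci.tsv"
    with loci.open("w") as fh:
        fh.write("chromosome\trap1_position\tabf1_position\n")
        for chrom, rpos, apos in PROTO_SILENCER_LOCI:
            fh.write(f"{chrom}\t{rpos}\t{apos}\n")
    written.append(loci)

    fasta = out / "rap1_sites.fasta"
    with fasta.open("w") as fh:
        fh.write(f">rap1_genome_wide_consensus\n{RAP1_GENOME_WIDE_CONSENSUS}\n")
        for name, seq in HMR_E_RAP1_VARIANTS.items():
            fh.write(f">{name}\n{seq}\n")
        fh.write(f">hml_e_rap1\n{HML_E_RAP1_SITE}\n")
    written.append(fasta)

    sites = out / "abf1_synthetic_sites.txt"
    sites.write_text("".join(s + "\n" for s in ABF1_SYNTHETIC_SITES))
    written.append(sites)
    return written
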