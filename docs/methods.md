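# Methods

## Motif model and exact significance

A motif of length L is a position weight matrix over A,C,G,T. Counts are
regularised with a background-proportional pseudocount:
`p_i(b) = (c_i(b) + t·q(b)) / (Σ_b c_i(b) + t)` with total `t` (default 1.0
per column, the standard PATSER-family choice; `t = 0` gives the
maximum-likelihood frequencies, and columns may then contain exact zeros).
Scores are summed natural-log odds against a mononucleotide background
`q`; information content alone is reported in bits,
`IC_i = 2 + Σ_b p_i(b) log₂ p_i(b)`, without a small-sample correction.

The background defaults to frequencies estimated from the scanned sequence
set (with a 0.5-count floor so no frequency is zero); a uniform model and a
strand-symmetric GC-parameterised model are available as overrides.

Match significance is exact: the null distribution of word scores under the
background is built by discretising each column's four score atoms to the
nearest multiple of a granularity g and convolving column by column. The
default g spans the widest column score range with 10,000 bins, keeping the
discretisation error (at most L·g/2 on any word score) far below the
spacing that matters in the 10⁻⁹ tail regime for motifs up to ~20 bp.
P-values use floor-to-bin lookup of the precomputed survival function and
the selection rule is strictly `p < α`. Two numerical consequences are
deliberate and documented:

* a word whose true score sits within the discretisation error of the
  distribution's top edge can fall past the last bin and report p = 0;
  selection behaviour is unaffected because scanner and oracle share the
  same lookup;
* bases with probability zero have log-odds −∞. In the distribution they
  are clamped onto a finite bin separated from the finite support by a gap
  larger than the entire finite span, so the pmf still sums to 1 and every
  tail above the finite minimum is exact. Words containing such bases can
  never satisfy any `p < α`.

`threshold_for_pvalue` returns the smallest *achievable* score whose tail
is strictly below α, searching the support only; when even the maximal
score has tail ≥ α (e.g. any 13 bp matrix at α = 10⁻⁹, since the most
extreme achievable tail under a uniform background is 0.25¹³ ≈ 1.5×10⁻⁸)
it returns +∞, meaning no window can be called significant at that α. For
that reason the synthetic-cohort conservation calls and recall checks use
α = 10⁻⁶..10⁻⁷ with the 13 bp consensus matrices: α thresholds in the
10⁻⁹ regime are meaningful only for longer or richer matrices.

## Scanner conventions

Both strands are scanned by default; a match's anchor is the leftmost base
of the window on the forward strand regardless of strand, coordinates are
1-based inclusive, output is ordered by (chromosome, position, strand) with
`+` before `-` and chromosomes in natural (numeric/roman) order. Windows
containing N are skipped — no defensible score exists. Overlapping and
same-position opposite-strand matches are all reported; deduplication is
left to callers. No multiple-testing adjustment is made across windows.
BED exports are 0-based half-open; conversion is confined to the IO layer
(BED start s ↔ internal start s+1).

## Proto-silencers

Within each region every (Rap1, Abf1) match pair with
`|pos_R − pos_A| ≤ w` (default w = 50, boundary inclusive) is emitted — no
greedy matching, so clustered sites can yield several pairs, and the
detector is symmetric in its two inputs. Distance is the absolute
difference of the two anchors: on the packaged 25-locus catalogue this rule
qualifies all 25 pairs with a maximum of 49 bp. Whether the published
coordinates denote site starts, centres or ends is not stated in the
source maps; the leftmost-anchor convention is this package's reproducible
choice, and users mixing their own maps should check the convention.
Subtelomeric exclusion is delegated to an optional region filter rather
than a built-in coordinate heuristic.

## Orthology and conservation

Region orthology uses reciprocal best hits of both flanking genes over a
user-supplied similarity table (scores comparable, higher = more similar;
the package deliberately does not run an aligner). A gene's best hit must
be unique — tied top scores break the assignment — and a region maps only
when both partners flank exactly one region in the target species;
unresolved regions are absent from the map.

A site is present in species s when the orthologous region exists and
contains ≥ 1 match at `p < α` on either strand, anywhere in the region.
This region-level rule avoids a whole-genome-alignment dependency and is
reasonable because orthologous intergenic regions are short; its
consequence — any equivalent site in the region counts — is exactly why
the conservation calibration below uses one planted site per region.
"Conserved" means presence in ≥ k species (default k = 3) counting the
reference species, with a toggle to exclude it.

The proto-silencer versus genome-wide comparison builds a 2×2 table
(conserved/not × proto-silencer/other), removing proto-silencer sites from
the genome-wide cells so the classes are disjoint, and applies the Pearson
χ² statistic with 1 df (p from `scipy.stats.chi2`). Yates' continuity
correction is off by default, matching the plain χ² convention of the
analysis this package reimplements; it is available as a flag, and for
n ≈ 25 users may prefer it or an exact test.

## ChIP filtering and frequency

Factors qualify with ≥ 60 distinct regions at binding p strictly < 0.05
(both thresholds exactly as stated; p = 0.05 does not qualify, 59 regions
do not qualify). Frequency is `matches in bound regions / Σ bound-region
lengths × 10,000` — matches per 10 kb.

## Synthetic cohorts

The generator emulates the real inputs with known truth. Ancestral
intergenic regions have lognormal lengths (log-mean 6.1, log-sd 0.5 ≈
median 446 bp — yeast intergenic scale) and i.i.d. background bases at GC
0.38. Planted instances are drawn from the planting PWM's per-position
probabilities at non-overlapping uniform positions and random strands;
with the default zero-pseudocount consensus matrices instances are exact
consensus words. Counts per region per motif are Poisson(`planting_rate`),
or exactly `sites_per_region` when set. Derived species form a star
phylogeny: each is the ancestor with i.i.d. substitutions to one of the
other three bases at `substitution_prob` (default 0.25 per branch, the
scale of *sensu stricto* intergenic divergence). A planted site survives
intact with `site_retention_prob` (default 0.8); otherwise it mutates like
background, which degrades but does not always destroy it. Orthology truth
is the identity on region indices; the similarity generator gives true
gene pairs top scores (U(400,600)) plus two decoy hits per gene
(U(50,300)), and a `noise_prob` fraction of true pairs are rank-shuffled
below the decoy range, which severs RBH recovery for exactly that pair.
ChIP tables give each factor a random bound subset with p < 0.05 and the
rest above. Everything is a pure function of (config, seed).

What the cohorts do **not** model: indels and alignment, branch-length
heterogeneity, dinucleotide background structure, binding-site turnover by
gain at new positions, and correlated site evolution. Passing tests
therefore demonstrate correctness of the statistics under the stated
generative model, not biological realism of any particular number.

### Calibration identities used by the tests

With one planted site per region, retention r, 4 derived species and
k = 3 counting the reference, the expected conserved fraction is
`P(Binomial(4, r) + 1 ≥ 3)`; at r = 0.8 this is 0.9728. The measured value
sits slightly above it because a non-retained site still re-matches when
its 13 bases escape mutation (0.75¹³ ≈ 0.024 per species at the default
divergence); at the test sizes (500 sites) this bias is well inside the
3-binomial-SE band the tests assert. The χ² type-I calibration simulates
equal true conservation rates (p₀ = 0.5, 200 vs 500 sites, 1000
replicates), sizes at which the Pearson test's true level is ≈ 0.050. The
problem sizes throughout (100–500 regions, 2–5 species) were chosen as the
smallest that leave these statistical checks well-powered.

## Pipeline and IO

The pipeline chains scan → proto-silencer detection → conservation → χ² →
frequency, or starts from a precomputed match coordinate table (as the
original analysis consumed published site maps) so the co-occurrence and
conservation stages can run without rescanning. Runs are deterministic for
fixed inputs: the structured log carries stage/event/count lines without
timestamps and the manifest records a sha256 per written file, so repeated
runs produce identical checksums. CLI exit codes: 0 success, 2
configuration error, 3 data error.

## Known limitations

* Gapped motifs, dinucleotide backgrounds and whole-genome-alignment-based
  conservation are out of scope.
* The packaged Abf1 motif is a synthetic stand-in (labelled as such); real
  analyses should supply a ChIP-derived Abf1 matrix, for which the
  10⁻⁹-scale thresholds are attainable.
* The native silencer Rap1 site is shipped in all three printed variants
  without asserting a canonical one.
* p-values are per window; genome-wide error control (if desired) is the
  caller's responsibility.
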