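"""Proto-silencers, orthology, conservation statistics, motif frequency."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from silencerscan import (
    ConservationCall,
    MotifMatch,
    OrthologyMap,
    SimulationConfig,
    TFBindingSet,
    call_conservation,
    chi_square_2x2,
    compare_conservation,
    conservation_fraction,
    exact_score_distribution,
    filter_tf_sets,
    find_proto_silencers,
    generate_cohort,
    motif_frequency,
    rbh_orthology,
    reverse_complement,
)
from silencerscan.fixtures import (
    RAP1_GENOME_WIDE_CONSENSUS,
    proto_silencer_matches,
    rap1_consensus_pwm,
)

from conftest import make_region


def mk(motif, region, pos, chrom="chrI", strand="+"):
    return MotifMatch(motif, region, chrom, pos, strand, 0.0, 0.0)


class TestFindProtoSilencers:
    def test_published_locus_catalogue(self):
        """The 25 catalogued Rap1/Abf1 coordinate pairs all qualify at the
        50 bp window, with a maximum anchor distance of 49."""
        rap1, abf1 = proto_silencer_matches()
        proto = find_proto_silencers(rap1, abf1, window=50)
        assert len(proto) == 25
        assert all(p.distance <= 50 for p in proto)
        assert max(p.distance for p in proto) == 49
        chr1 = [p for p in proto if p.chromosome == "I"]
        assert len(chr1) == 1 and chr1[0].distance == 22

    def test_window_boundary_is_inclusive(self):
        r = [mk("Rap1", "r", 100)]
        assert find_proto_silencers(r, [mk("Abf1", "r", 150)], 50)[0].distance == 50
        assert find_proto_silencers(r, [mk("Abf1", "r", 151)], 50) == []

    def test_all_qualifying_pairs_reported(self):
        r = [mk("Rap1", "r", 100)]
        a = [mk("Abf1", "r", 90), mk("Abf1", "r", 140)]
        proto = find_proto_silencers(r, a, 50)
        assert sorted(p.distance for p in proto) == [10, 40]

    def test_matches_in_different_regions_never_pair(self):
        proto = find_proto_silencers(
            [mk("Rap1", "r1", 100)], [mk("Abf1", "r2", 101)], 50
        )
        assert proto == []

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            find_proto_silencers([], [], -1)

    def test_role_symmetry_and_order_invariance(self):
        rng = np.random.default_rng(0)
        rap1 = [mk("Rap1", f"r{i%7}", int(p)) for i, p in enumerate(rng.integers(1, 500, 40))]
        abf1 = [mk("Abf1", f"r{i%7}", int(p)) for i, p in enumerate(rng.integers(1, 500, 40))]
        fwd = find_proto_silencers(rap1, abf1, 50)
        swapped = find_proto_silencers(abf1, rap1, 50)
        assert {(p.rap1_match.position, p.abf1_match.position, p.region_id) for p in fwd} == {
            (p.abf1_match.position, p.rap1_match.position, p.region_id) for p in swapped
        }
        shuffled = find_proto_silencers(list(reversed(rap1)), list(reversed(abf1)), 50)
        assert fwd == shuffled

    def test_window_monotonicity(self):
        rng = np.random.default_rng(1)
        rap1 = [mk("Rap1", f"r{i%5}", int(p)) for i, p in enumerate(rng.integers(1, 400, 30))]
        abf1 = [mk("Abf1", f"r{i%5}", int(p)) for i, p in enumerate(rng.integers(1, 400, 30))]
        small = {
            (p.region_id, p.rap1_match.position, p.abf1_match.position)
            for p in find_proto_silencers(rap1, abf1, 20)
        }
        large = {
            (p.region_id, p.rap1_match.position, p.abf1_match.position)
            for p in find_proto_silencers(rap1, abf1, 60)
        }
        assert small <= large


def _sim_table(rows):
    return pd.DataFrame(
        rows, columns=["gene_a", "species_a", "gene_b", "species_b", "score"]
    )


def _toy_regions():
    from silencerscan import IntergenicRegion

    ref = IntergenicRegion(
        region_id="ig0", species="A", chromosome="chrI", start=1, end=40,
        left_gene="gL", right_gene="gR", sequence="ACGT" * 10,
    )
    tgt = IntergenicRegion(
        region_id="B.ig0", species="B", chromosome="chrI", start=1, end=40,
        left_gene="B.gL", right_gene="B.gR", sequence="ACGT" * 10,
    )
    return {"A": [ref], "B": [tgt]}


class TestRbhOrthology:
    def test_reciprocal_unique_top_hits_map_the_region(self):
        sims = _sim_table(
            [
                ("gL", "A", "B.gL", "B", 500.0),
                ("gR", "A", "B.gR", "B", 450.0),
                ("gL", "A", "B.gR", "B", 100.0),
            ]
        )
        om = rbh_orthology(sims, _toy_regions(), "A")
        assert om.get("ig0", "B") == "B.ig0"

    def test_non_reciprocal_best_leaves_region_unmapped(self):
        # gL's best is B.gL, but B.gL's best is gR -> no RBH for gL
        sims = _sim_table(
            [
                ("gL", "A", "B.gL", "B", 500.0),
                ("gR", "A", "B.gL", "B", 600.0),
                ("gR", "A", "B.gR", "B", 650.0),
            ]
        )
        om = rbh_orthology(sims, _toy_regions(), "A")
        assert om.get("ig0", "B") is None

    def test_tied_top_scores_break_nothing(self):
        sims = _sim_table(
            [
                ("gL", "A", "B.gL", "B", 500.0),
                ("gL", "A", "B.gR", "B", 500.0),
                ("gR", "A", "B.gR", "B", 450.0),
            ]
        )
        om = rbh_orthology(sims, _toy_regions(), "A")
        assert om.get("ig0", "B") is None


def _cohort_calls(seed=11, n_regions=200, retention=0.8, alpha=1e-6, min_species=3):
    pwm = rap1_consensus_pwm()
    cfg = SimulationConfig(
        n_regions=n_regions,
        sites_per_region=1,
        site_retention_prob=retention,
        seed=seed,
    )
    cohort = generate_cohort(cfg, motifs=[pwm])
    dist = exact_score_distribution(pwm)
    species_regions = {sp: cohort.regions_by_id(sp) for sp in cohort.species}
    calls = []
    for row in cohort.sites.itertuples(index=False):
        site = MotifMatch("Rap1", row.region_id, "chr_syn", row.position, row.strand, 0.0, 0.0)
        calls.append(
            call_conservation(
                site,
                cohort.orthology,
                species_regions,
                pwm,
                alpha,
                min_species=min_species,
                reference_species=cohort.reference_species,
                dist=dist,
            )
        )
    return cohort, calls


class TestConservation:
    def test_verbatim_retention_in_all_species_is_conserved(self):
        cohort, calls = _cohort_calls(seed=3, n_regions=25, retention=1.0)
        assert all(c.conserved for c in calls)
        assert all(all(c.present_in.values()) for c in calls)

    def test_no_retention_and_high_divergence_is_rarely_conserved(self):
        pwm = rap1_consensus_pwm()
        cfg = SimulationConfig(
            n_regions=40,
            sites_per_region=1,
            site_retention_prob=0.0,
            substitution_prob=0.5,
            seed=5,
        )
        cohort = generate_cohort(cfg, motifs=[pwm])
        dist = exact_score_distribution(pwm)
        species_regions = {sp: cohort.regions_by_id(sp) for sp in cohort.species}
        calls = [
            call_conservation(
                MotifMatch("Rap1", row.region_id, "chr_syn", row.position, row.strand, 0.0, 0.0),
                cohort.orthology,
                species_regions,
                pwm,
                1e-6,
                reference_species=cohort.reference_species,
                dist=dist,
            )
            for row in cohort.sites.itertuples(index=False)
        ]
        assert conservation_fraction(calls) < 0.2

    def test_absent_orthologs_mean_not_conserved(self):
        pwm = rap1_consensus_pwm()
        site = mk("Rap1", "ig0", 10)
        regions = {"A": [make_region("A" * 40, region_id="ig0", species="A")]}
        call = call_conservation(
            site, OrthologyMap(entries={}), regions, pwm, 1e-6,
            reference_species="A",
        )
        assert not call.conserved
        assert call.present_in == {"A": True}

    def test_fraction_limits_and_empty_error(self):
        c = ConservationCall(site=mk("m", "r", 1), present_in={}, conserved=True)
        n = ConservationCall(site=mk("m", "r", 2), present_in={}, conserved=False)
        assert conservation_fraction([c, c]) == 1.0
        assert conservation_fraction([n]) == 0.0
        with pytest.raises(ValueError):
            conservation_fraction([])

    def test_fraction_matches_binomial_closed_form(self):
        """Seeded 1-site-per-region cohort: the measured conserved fraction
        sits within 3 binomial SE of P(Binomial(4, retention) + ref >= 3)."""
        cohort, calls = _cohort_calls(seed=11, n_regions=200, retention=0.8)
        frac = conservation_fraction(calls)
        expected = 1.0 - stats.binom.cdf(1, 4, 0.8)
        se = np.sqrt(expected * (1 - expected) / len(calls))
        assert abs(frac - expected) < 3 * se


class TestChiSquare:
    def test_balanced_table_is_null(self):
        res = chi_square_2x2([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_closed_form_example(self):
        res = chi_square_2x2([[20, 10], [10, 20]])
        assert res.statistic == pytest.approx(60 * (400 - 100) ** 2 / 30**4, abs=1e-9)
        assert res.statistic == pytest.approx(6.6667, abs=1e-3)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_2x2([[0, 0], [5, 5]])

    def test_yates_shrinks_the_statistic(self):
        plain = chi_square_2x2([[20, 10], [10, 20]])
        corrected = chi_square_2x2([[20, 10], [10, 20]], yates=True)
        assert 0 < corrected.statistic < plain.statistic

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_scipy_contingency(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(1, 80, size=(2, 2))
        ours = chi_square_2x2(t)
        ref_stat, ref_p, _, _ = stats.chi2_contingency(t, correction=False)
        assert ours.statistic == pytest.approx(ref_stat, rel=1e-12)
        assert ours.pvalue == pytest.approx(ref_p, rel=1e-12)

    def test_pvalue_decreases_with_association(self):
        stats_seq = [
            chi_square_2x2([[15 + d, 15 - d], [15 - d, 15 + d]]).pvalue
            for d in range(0, 15, 3)
        ]
        assert all(a >= b for a, b in zip(stats_seq, stats_seq[1:]))


def _call_list(n, k, prefix, motif="Rap1"):
    return [
        ConservationCall(
            site=mk(motif, f"{prefix}{i}", i + 1), present_in={}, conserved=i < k
        )
        for i in range(n)
    ]


class TestCompareConservation:
    def test_identical_rates_give_null_pvalue(self):
        res = compare_conservation(_call_list(200, 100, "g"), _call_list(100, 50, "p"))
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)
        assert res.genomewide_fraction == res.protosilencer_fraction == 0.5

    def test_extreme_separation_is_significant(self):
        res = compare_conservation(_call_list(50, 0, "g"), _call_list(50, 50, "p"))
        assert res.pvalue < 0.05

    def test_proto_silencer_sites_excluded_from_genomewide_cell(self):
        shared = _call_list(30, 30, "s")
        gw = shared + _call_list(70, 0, "g")
        res = compare_conservation(gw, shared)
        # the 30 shared (all conserved) sites must not also count genome-wide
        assert res.table[1].sum() == 70
        assert res.genomewide_fraction == 0.0

    def test_empty_lists_rejected(self):
        with pytest.raises(ValueError):
            compare_conservation([], _call_list(5, 1, "p"))
        with pytest.raises(ValueError):
            compare_conservation(_call_list(5, 1, "g"), [])

    def test_type_one_error_calibration_under_the_null(self):
        """Equal true conservation rates: rejection at 0.05 lands in
        [0.03, 0.07] over 1000 seeded replicates."""
        rng = np.random.default_rng(2024)
        n_ps, n_gw, p0 = 200, 500, 0.5
        rejections = 0
        reps = 1000
        for _ in range(reps):
            k_ps = int(rng.binomial(n_ps, p0))
            k_gw = int(rng.binomial(n_gw, p0))
            res = compare_conservation(
                _call_list(n_gw, k_gw, "g"), _call_list(n_ps, k_ps, "p")
            )
            if res.pvalue < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07


class TestTFSetsAndFrequency:
    def _chip(self, rows):
        return pd.DataFrame(rows, columns=["factor", "region_id", "p"])

    def test_sixty_regions_at_low_p_kept(self):
        rows = [("tf", f"r{i}", 0.01) for i in range(60)]
        kept = filter_tf_sets(self._chip(rows))
        assert len(kept) == 1 and len(kept[0].bound_regions) == 60

    def test_fifty_nine_regions_dropped(self):
        rows = [("tf", f"r{i}", 0.01) for i in range(59)]
        assert filter_tf_sets(self._chip(rows)) == []

    def test_p_exactly_at_cutoff_does_not_qualify(self):
        rows = [("tf", f"r{i}", 0.05) for i in range(100)]
        assert filter_tf_sets(self._chip(rows)) == []
        rows = [("tf", f"r{i}", 0.049) for i in range(100)]
        assert len(filter_tf_sets(self._chip(rows))) == 1

    def test_duplicate_regions_counted_once(self):
        rows = [("tf", f"r{i % 30}", 0.01) for i in range(120)]
        assert filter_tf_sets(self._chip(rows)) == []

    def test_output_never_violates_thresholds(self):
        rng = np.random.default_rng(6)
        rows = [
            (f"tf{rng.integers(5)}", f"r{rng.integers(120)}", float(rng.uniform()))
            for _ in range(2000)
        ]
        for tf_set in filter_tf_sets(self._chip(rows), p_max=0.3, min_regions=20):
            assert len(tf_set.bound_regions) >= 20
            assert all(p < 0.3 for p in tf_set.binding_pvalues.values())

    def test_frequency_arithmetic(self):
        tf_set = TFBindingSet(
            factor="tf", bound_regions=frozenset({"a", "b", "c"}), binding_pvalues={}
        )
        lengths = {"a": 5000, "b": 5000, "c": 5000}
        matches = [mk("Abf1", r, 10) for r in ("a", "b", "c")]
        rec = motif_frequency(tf_set, matches, lengths, scale=10_000)
        assert rec.freq_per_10kb == 2.0
        assert rec.n_matches == 3 and rec.total_length == 15_000

    def test_matches_outside_bound_regions_ignored(self):
        tf_set = TFBindingSet(
            factor="tf", bound_regions=frozenset({"a"}), binding_pvalues={}
        )
        rec = motif_frequency(tf_set, [mk("Abf1", "zzz", 10)], {"a": 1000})
        assert rec.n_matches == 0 and rec.freq_per_10kb == 0.0

    def test_zero_total_length_rejected(self):
        tf_set = TFBindingSet(
            factor="tf", bound_regions=frozenset({"a"}), binding_pvalues={}
        )
        with pytest.raises(ValueError):
            motif_frequency(tf_set, [], {"a": 0})
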