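"""Nearest-distance computation and the null-model statistics."""

import math

import numpy as np
import pytest

from rbsprox.motifs import (MotifOccurrence, OccurrenceIndex,
                            build_occurrence_index, compile_motif,
                            restriction_cut_index)
from rbsprox.proximity import (BackgroundModel, DistanceSample, GenomicSite,
                               IneligibleContigError, distance_sample,
                               empirical_background, exact_background,
                               exclude_regions, nearest_distance,
                               restriction_matched_controls, two_sample_t,
                               z_test)

from conftest import random_sequence


def make_index(cover_intervals, length, contig="c"):
    occs = [MotifOccurrence(contig, s, e, "+", 0) for s, e in cover_intervals]
    return OccurrenceIndex(
        spec=compile_motif("GAGC", 0),
        occurrences={contig: occs},
        cover={contig: np.array(cover_intervals).reshape(-1, 2)},
        contig_lengths={contig: length},
    )


def brute_nearest(pos, intervals):
    best = None
    for s, e in intervals:
        if s <= pos < e:
            return 0
        d = min(abs(pos - s), abs(pos - (e - 1)))
        best = d if best is None else min(best, d)
    return best


class TestNearestDistance:
    def test_inside_occurrence_is_zero(self):
        idx = make_index([(10, 18)], 100)
        assert nearest_distance(GenomicSite("c", 12), idx) == 0

    def test_left_of_cover(self):
        idx = make_index([(10, 18)], 100)
        assert nearest_distance(GenomicSite("c", 7), idx) == 3

    def test_ineligible_contig_raises(self):
        idx = make_index([(10, 18)], 100)
        with pytest.raises(IneligibleContigError):
            nearest_distance(GenomicSite("other", 5), idx)

    def test_matches_linear_scan(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n_iv = int(rng.integers(1, 8))
            starts = np.sort(rng.choice(np.arange(0, 960, 12), size=n_iv,
                                        replace=False))
            ivs = [(int(s), int(s) + int(rng.integers(1, 10))) for s in starts]
            idx = make_index(ivs, 1000)
            for pos in rng.integers(0, 1000, size=20):
                got = nearest_distance(GenomicSite("c", int(pos)), idx)
                assert got == brute_nearest(int(pos), ivs)


class TestExactBackground:
    def test_full_cover_gives_zero(self):
        idx = make_index([(0, 50)], 50)
        bg = exact_background(idx)
        assert bg.mu == 0 and bg.sigma == 0

    def test_single_covered_base_length_11(self):
        # enumeration over the 11 positions: distances 5,4,3,2,1,0,1,2,3,4,5
        idx = make_index([(5, 6)], 11)
        bg = exact_background(idx)
        assert bg.mu == pytest.approx(30 / 11, rel=1e-12)
        assert bg.sigma == pytest.approx(math.sqrt(110 / 11 - (30 / 11) ** 2),
                                         rel=1e-12)
        assert bg.support == 11

    def test_matches_full_enumeration_on_random_indexes(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            length = int(rng.integers(1_000, 50_000))
            genome = {"g": random_sequence(rng, length, gc=0.5)}
            spec = compile_motif("GAGYGAGC", int(rng.integers(0, 2)))
            idx = build_occurrence_index(genome, spec)
            if not idx.is_eligible("g"):
                continue
            cover = idx.cover["g"]
            pos = np.arange(length)
            # independent oracle: min distance over all intervals, per position
            d = np.full(length, np.iinfo(np.int64).max)
            for s, e in cover:
                inside = (pos >= s) & (pos < e)
                d = np.minimum(d, np.minimum(np.abs(pos - s),
                                             np.abs(pos - (e - 1))))
                d[inside] = 0
            bg = exact_background(idx)
            assert bg.mu == pytest.approx(d.mean(), rel=1e-9)
            assert bg.sigma == pytest.approx(d.std(ddof=0), rel=1e-9, abs=1e-9)

    def test_no_eligible_contig(self):
        idx = OccurrenceIndex(spec=compile_motif("GAGC", 0),
                              occurrences={"c": []},
                              cover={"c": np.zeros((0, 2), dtype=np.int64)},
                              contig_lengths={"c": 100})
        with pytest.raises(IneligibleContigError):
            exact_background(idx)


class TestMatchedControls:
    @pytest.fixture(scope="class")
    def cut_genome(self):
        rng = np.random.default_rng(9)
        genome = {"c1": random_sequence(rng, 80_000),
                  "c2": random_sequence(rng, 80_000)}
        return genome, restriction_cut_index(genome, "PvuII")

    def test_controls_preserve_cut_distance(self, cut_genome):
        genome, cuts = cut_genome
        sites = [GenomicSite("c1", 1234), GenomicSite("c2", 40_000)]
        controls = restriction_matched_controls(sites, cuts, m=200, seed=1)
        assert len(controls) == 400
        for site, group in zip(sites, [controls[:200], controls[200:]]):
            d = nearest_distance(site, cuts)
            for ctrl in group:
                # distance to the chosen cut equals d; the nearest may be closer
                assert nearest_distance(ctrl, cuts) <= d
                ctrl_pos = ctrl.pos
                cut_pos = np.array([o.start for o in
                                    cuts.occurrences[ctrl.contig]])
                assert (np.abs(cut_pos - ctrl_pos) == d).any()

    def test_site_on_cut_yields_controls_on_cuts(self, cut_genome):
        genome, cuts = cut_genome
        cut0 = cuts.occurrences["c1"][0].start
        controls = restriction_matched_controls([GenomicSite("c1", cut0)],
                                                cuts, m=100, seed=3)
        assert all(nearest_distance(c, cuts) == 0 for c in controls)

    def test_deterministic_under_seed(self, cut_genome):
        genome, cuts = cut_genome
        sites = [GenomicSite("c1", 500)]
        a = restriction_matched_controls(sites, cuts, m=50, seed=42)
        b = restriction_matched_controls(sites, cuts, m=50, seed=42)
        assert a == b


class TestEmpiricalBackground:
    def test_hand_computed_moments(self):
        idx = make_index([(0, 1)], 100)
        controls = [GenomicSite("c", p) for p in (10, 20, 30)]
        bg = empirical_background(controls, idx)
        assert bg.mu == pytest.approx(20.0)
        assert bg.sigma == pytest.approx(math.sqrt(200 / 3))  # population SD

    def test_converges_to_exact_background(self, small_index):
        bg_exact = exact_background(small_index)
        rng = np.random.default_rng(5)
        contig = small_index.eligible_contigs[0]
        n = 200_000
        sites = [GenomicSite(contig, int(p)) for p in
                 rng.integers(0, small_index.contig_lengths[contig], size=n)]
        # restrict exact model to the same contig for comparability
        sub = OccurrenceIndex(spec=small_index.spec,
                              occurrences={contig: small_index.occurrences[contig]},
                              cover={contig: small_index.cover[contig]},
                              contig_lengths={contig: small_index.contig_lengths[contig]})
        bg_sub = exact_background(sub)
        bg_emp = empirical_background(sites, sub)
        assert abs(bg_emp.mu - bg_sub.mu) < 3 * bg_sub.sigma / math.sqrt(n)


class TestZTest:
    def test_null_mean_gives_half(self):
        s = DistanceSample(np.full(10, 100.0))
        bg = BackgroundModel("random_exact", 100.0, 10.0, 1000)
        r = z_test(s, bg)
        assert r.statistic == 0
        assert r.one_sided_p == pytest.approx(0.5)

    def test_closed_form_example(self):
        s = DistanceSample(np.full(100, 40_000.0))
        bg = BackgroundModel("random_exact", 50_000.0, 50_000.0, 10**6)
        r = z_test(s, bg)
        assert r.statistic == pytest.approx(-2.0)
        assert r.one_sided_p == pytest.approx(0.02275, abs=1e-5)
        assert r.two_sided_p == pytest.approx(2 * 0.02275, abs=2e-5)

    def test_shift_down_decreases_p(self):
        bg = BackgroundModel("random_exact", 500.0, 100.0, 1000)
        vals = np.linspace(100, 900, 20)
        p1 = z_test(DistanceSample(vals), bg).one_sided_p
        p2 = z_test(DistanceSample(vals - 50), bg).one_sided_p
        assert p2 < p1

    def test_zero_sigma_rejected(self):
        with pytest.raises(ValueError):
            z_test(DistanceSample(np.array([1.0])),
                   BackgroundModel("random_exact", 0.0, 0.0, 1))

    def test_tiers(self):
        bg = BackgroundModel("random_exact", 1.0, 1.0, 10)
        strong = z_test(DistanceSample(np.zeros(100)), bg)
        assert strong.tier == "highly significant"
        null = z_test(DistanceSample(np.ones(10)), bg)
        assert null.tier == "n.s."


class TestTwoSampleT:
    def test_identical_samples(self):
        a = DistanceSample(np.array([1.0, 2, 3, 4, 5]))
        r = two_sample_t(a, DistanceSample(np.array([1.0, 2, 3, 4, 5])))
        assert r.statistic == pytest.approx(0.0)
        assert r.two_sided_p == pytest.approx(1.0)

    def test_welch_example(self):
        a = DistanceSample(np.array([1.0, 2, 3, 4, 5]))
        b = DistanceSample(np.array([2.0, 3, 4, 5, 6]))
        r = two_sample_t(a, b)
        assert r.statistic == pytest.approx(-1.0)
        assert r.df == pytest.approx(8.0)
        assert r.two_sided_p == pytest.approx(0.3466, abs=2e-4)

    def test_antisymmetry(self):
        rng = np.random.default_rng(6)
        a = DistanceSample(rng.exponential(100, size=30))
        b = DistanceSample(rng.exponential(150, size=40))
        r1, r2 = two_sample_t(a, b), two_sample_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.two_sided_p == pytest.approx(r2.two_sided_p)

    def test_small_sample_rejected(self):
        a = DistanceSample(np.array([1.0]))
        b = DistanceSample(np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            two_sample_t(a, b)


class TestExcludeRegions:
    SITES = [GenomicSite("c1", 10), GenomicSite("c1", 100),
             GenomicSite("c2", 50)]

    def test_empty_region_set_is_identity(self):
        assert exclude_regions(self.SITES, []) == self.SITES

    def test_all_inside(self):
        assert exclude_regions(self.SITES, [("c1", 0, 200), ("c2", 0, 60)]) == []

    def test_half_open_boundary(self):
        kept = exclude_regions(self.SITES, [("c1", 0, 100)])
        # site at the region end coordinate is retained
        assert kept == [GenomicSite("c1", 100), GenomicSite("c2", 50)]


class TestCalibration:
    def test_uniform_sites_match_null_and_targeted_sites_reject(self, small_index):
        """Directional sanity: targeted sites give far smaller p than uniform."""
        from rbsprox.proximity import _nearest_from_cover
        bg = exact_background(small_index)
        rng = np.random.default_rng(77)
        contigs = small_index.eligible_contigs
        lens = np.array([small_index.contig_lengths[c] for c in contigs])
        w = lens / lens.sum()
        # uniform sites: z-test p should be unremarkable on average
        ps = []
        for _ in range(50):
            ci = rng.choice(len(contigs), size=117, p=w)
            d = np.concatenate([
                _nearest_from_cover(rng.integers(0, lens[k], size=(ci == k).sum()),
                                    small_index.cover[contigs[k]])
                for k in range(len(contigs)) if (ci == k).any()])
            ps.append(z_test(DistanceSample(d.astype(float)), bg).one_sided_p)
        assert 0.2 < np.median(ps) < 0.8
        # sites at the motifs themselves: overwhelming rejection
        occ = [o for c in contigs for o in small_index.occurrences[c]]
        d0 = np.zeros(117)
        assert z_test(DistanceSample(d0), bg).one_sided_p < 1e-10
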