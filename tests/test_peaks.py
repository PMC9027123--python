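"""Peak calling: window binning, Poisson/binomial statistics, island
construction against a brute-force oracle, and classification."""

import numpy as np
import pytest

from chipshift.intervals import GenomicInterval
from chipshift.peaks import (
    ClassifiedPeakSet,
    PeakCallingConfig,
    PeakRecord,
    bin_tags,
    call_differential,
    call_islands,
    classify,
    local_background,
    poisson_upper_tail,
)
from chipshift.synthetic import TagSet

from _oracles import islands_bruteforce, poisson_sf_series


def tagset(positions, chrom="chr1", antibody="x", condition="control"):
    return TagSet(antibody, condition, {chrom: np.sort(np.asarray(positions))})


class TestBinTags:
    def test_boundary_assignment(self):
        counts = bin_tags(tagset([0, 199, 200]), 200)["chr1"]
        assert list(counts) == [2, 1]

    def test_empty(self):
        ts = TagSet("x", "control", {})
        assert bin_tags(ts, 200) == {}

    def test_count_conservation(self, rng):
        pos = rng.integers(0, 50_000, size=1000)
        counts = bin_tags(tagset(pos), 137, {"chr1": 50_000})
        assert counts["chr1"].sum() == 1000

    def test_out_of_bounds_tag_rejected(self):
        with pytest.raises(ValueError):
            bin_tags(tagset([60_000]), 200, {"chr1": 50_000})


class TestPoisson:
    @pytest.mark.parametrize("lam", [0.1, 1.0, 10.0])
    def test_matches_series_oracle_to_12_digits(self, lam):
        for count in range(0, 101):
            got = float(poisson_upper_tail(count, lam))
            want = poisson_sf_series(count, lam)
            assert got == pytest.approx(want, rel=1e-12)

    def test_count_zero_is_certain(self):
        assert float(poisson_upper_tail(0, 5.0)) == 1.0


class TestLocalBackground:
    def test_flat_counts_unchanged(self):
        c = np.full(50, 4)
        assert np.allclose(local_background(c, 200, 1000), 4.0)

    def test_dip_is_lifted_to_neighbourhood(self):
        c = np.full(21, 10)
        c[10] = 0
        lb = local_background(c, 50, 1000)
        assert lb[10] > 9.0  # local mean replaces the dip

    def test_disabled_when_span_too_small(self):
        c = np.array([1, 5, 2])
        assert np.array_equal(local_background(c, 200, 200), c.astype(float))


class TestCallIslands:
    def test_island_p_is_poisson_survival_of_island_totals(self):
        """Single-window island: p equals the closed-form Poisson upper
        tail of the island count at the island expectation."""
        cfg = PeakCallingConfig(window=200, gap=600, p_cutoff=0.5,
                                local_background_bp=0)
        t = tagset([1000 + i for i in range(10)])       # 10 tags in window 5
        c = tagset(list(range(0, 10_000, 1000)))         # uniform control
        (rec,) = call_islands(t, c, cfg, {"chr1": 10_000})
        assert rec.count == 10
        assert rec.pvalue == pytest.approx(
            poisson_sf_series(10, rec.expected), rel=1e-12
        )

    def test_no_tags_no_islands(self):
        cfg = PeakCallingConfig.broad(1e-5)
        empty = TagSet("x", "control", {"chr1": np.empty(0, dtype=np.int64)})
        ctrl = tagset(list(range(0, 10_000, 100)))
        assert call_islands(empty, ctrl, cfg, {"chr1": 10_000}) == []

    def test_self_comparison_yields_nothing(self, rng):
        pos = rng.integers(0, 100_000, size=2_000)
        t = tagset(pos)
        cfg = PeakCallingConfig.broad(1e-5)
        assert call_islands(t, t, cfg, {"chr1": 100_000}) == []
        assert call_differential(t, t, cfg, {"chr1": 100_000}) == []

    def test_zero_tag_control_uses_pseudocount(self):
        cfg = PeakCallingConfig(window=100, gap=0, p_cutoff=0.999,
                                eligibility_p=0.999)
        t = tagset([10, 20, 30])
        c = TagSet("input", "input", {})
        recs = call_islands(t, c, cfg, {"chr1": 1_000})
        assert recs and recs[0].expected == pytest.approx(cfg.pseudocount)

    def test_island_gap_invariant(self, rng):
        cfg = PeakCallingConfig.broad(1e-5)
        pos = np.concatenate([
            rng.integers(0, 50_000, size=500),
            rng.integers(10_000, 11_000, size=300),
            rng.integers(30_000, 30_500, size=200),
        ])
        ctrl = tagset(rng.integers(0, 50_000, size=500))
        recs = call_islands(tagset(pos), ctrl, cfg, {"chr1": 50_000})
        for a, b in zip(recs, recs[1:]):
            assert b.interval.start - a.interval.end > cfg.gap

    def test_cutoff_monotonicity(self, rng):
        """Loosening p_cutoff never removes an island; every strict-cutoff
        island is contained in a loose-cutoff island."""
        pos = np.concatenate([
            rng.integers(0, 50_000, size=400),
            rng.integers(20_000, 21_000, size=150),
        ])
        ctrl = tagset(rng.integers(0, 50_000, size=400))
        cfg_strict = PeakCallingConfig.broad(1e-10)
        cfg_loose = PeakCallingConfig.broad(1e-3)
        strict = call_islands(tagset(pos), ctrl, cfg_strict, {"chr1": 50_000})
        loose = call_islands(tagset(pos), ctrl, cfg_loose, {"chr1": 50_000})
        for s in strict:
            assert any(
                l.interval.start <= s.interval.start
                and l.interval.end >= s.interval.end
                for l in loose
            )

    @pytest.mark.parametrize("two_sample", [False, True])
    @pytest.mark.parametrize("mode", ["broad", "narrow"])
    def test_matches_bruteforce_enumeration(self, rng, mode, two_sample):
        """Random toy genomes: islands equal the eligible-window +
        transitive-gap-closure + island-p-filter enumeration exactly."""
        if mode == "broad":
            cfg = PeakCallingConfig.broad(1e-5)
        else:
            cfg = PeakCallingConfig.narrow(1e-5)
        genome_len = 30_000
        for _ in range(5):
            n_bg = int(rng.integers(200, 600))
            peak_at = int(rng.integers(5_000, 25_000))
            t_pos = np.concatenate([
                rng.integers(0, genome_len, size=n_bg),
                rng.integers(peak_at, peak_at + 800, size=int(rng.integers(50, 200))),
            ])
            c_pos = rng.integers(0, genome_len, size=int(rng.integers(200, 600)))
            t, c = tagset(t_pos), tagset(c_pos)
            if two_sample:
                got = call_differential(t, c, cfg, {"chr1": genome_len})
            else:
                got = call_islands(t, c, cfg, {"chr1": genome_len})
            want = islands_bruteforce(
                sorted(t_pos), sorted(c_pos), genome_len, cfg, two_sample
            )
            assert [
                (r.interval.start, r.interval.end, r.count) for r in got
            ] == [(s, e, n) for s, e, n, _ in want]
            for r, (_, _, _, p) in zip(got, want):
                assert r.pvalue == pytest.approx(p, rel=1e-9)

    def test_differential_is_reciprocal(self, rng):
        """Swapping the arguments returns the b-over-a regions."""
        base = rng.integers(0, 50_000, size=800)
        gained = np.concatenate([base, rng.integers(10_000, 11_000, size=300)])
        lost = np.concatenate([base, rng.integers(30_000, 31_000, size=300)])
        cfg = PeakCallingConfig.broad(1e-5)
        a_over_b = call_differential(tagset(lost), tagset(gained), cfg, {"chr1": 50_000})
        b_over_a = call_differential(tagset(gained), tagset(lost), cfg, {"chr1": 50_000})
        assert any(p.interval.start <= 30_000 <= p.interval.end for p in a_over_b)
        assert any(p.interval.start <= 10_000 <= p.interval.end for p in b_over_a)
        assert all(p.interval.end < 30_000 or p.interval.start > 31_000
                   for p in b_over_a)


def rec(start, end, chrom="chr1", count=50, expected=1.0, p=1e-20):
    return PeakRecord(GenomicInterval(chrom, start, end), count, expected, p)


class TestClassify:
    def test_identical_conditions_all_common(self):
        peaks = [rec(100, 400), rec(1000, 1600)]
        cps = classify("ab", peaks, peaks, [], [])
        assert [p.interval for p in cps.common] == [p.interval for p in peaks]
        assert cps.increase == [] and cps.decrease == []

    def test_ctrl_peak_with_differential_becomes_decrease(self):
        ctrl = [rec(100, 400)]
        diff = [rec(200, 300)]
        cps = classify("ab", ctrl, [], diff, [])
        assert [p.interval.start for p in cps.decrease] == [100]
        assert cps.common == []

    def test_reported_regions_are_standard_peak_intervals(self):
        kd = [rec(1000, 2000)]
        diff = [rec(1500, 2600)]
        cps = classify("ab", [], kd, [], diff)
        assert cps.increase[0].interval == kd[0].interval

    def test_conflict_resolved_by_larger_overlap(self):
        ctrl = [rec(0, 1000)]
        kd = [rec(0, 1000)]
        dec_diff = [rec(0, 100)]     # 100 bp overlap with ctrl peak
        inc_diff = [rec(0, 600)]     # 600 bp overlap with kd peak
        cps = classify("ab", ctrl, kd, dec_diff, inc_diff)
        assert len(cps.increase) == 1 and len(cps.decrease) == 0

    def test_exact_tie_dropped_and_flagged(self):
        ctrl = [rec(0, 1000)]
        kd = [rec(0, 1000)]
        tie = [rec(0, 300)]
        cps = classify("ab", ctrl, kd, tie, tie)
        assert cps.increase == [] and cps.decrease == []
        assert len(cps.conflicts) == 2

    def test_increase_and_decrease_never_overlap(self, small_run):
        result, _ = small_run
        for cps in result.classified.values():
            for d in cps.decrease:
                for i in cps.increase:
                    assert d.interval.intersection_length(i.interval) == 0
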