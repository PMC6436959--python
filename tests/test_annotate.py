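"""Locus calling, precursor/cleavage extraction, and size factors."""

import numpy as np
import pytest

from pirnakit.annotate import (
    PiRNALocus,
    call_pirna_loci,
    extract_cleavage_fragments,
    extract_precursors,
    scan_upstream_windows,
    size_factors_median_ratios,
    size_factors_slope,
)
from pirnakit.core import GenomicInterval, ReadSite
from pirnakit.motif import MotifHit, fit_score_threshold


@pytest.fixture(scope="module")
def scanned(ctype_bundle, ctype_library):
    sites = [r.interval for r in ctype_library.reads_21u]
    return scan_upstream_windows(sites, ctype_bundle.genome, ctype_bundle.pwm)


@pytest.fixture(scope="module")
def threshold(scanned):
    scores = [h.score for _, h, _ in scanned if h is not None]
    return fit_score_threshold(scores, seed=0).threshold


class TestCallLoci:
    def test_planted_recovery(self, ctype_bundle, scanned, threshold):
        result = call_pirna_loci(scanned, threshold)
        called = {l.id for l in result.loci}
        planted = set(ctype_bundle.truth.locus_id)
        sensitivity = len(called & planted) / len(planted)
        fdr = len(called - planted) / max(len(called), 1)
        assert sensitivity >= 0.95
        assert fdr <= 0.01

    def test_below_threshold_site_not_called(self):
        site = GenomicInterval("c", 100, 121, "+", "s1")
        result = call_pirna_loci([(site, MotifHit("s1", 1.0, 0), 42)], threshold=5.0)
        assert result.loci == []
        assert result.n_below_threshold == 1

    def test_distance_window_enforced(self):
        site = GenomicInterval("c", 100, 121, "+", "s1")
        ok = call_pirna_loci([(site, MotifHit("s1", 10.0, 0), 45)], 5.0)
        far = call_pirna_loci([(site, MotifHit("s1", 10.0, 0), 60)], 5.0)
        assert len(ok.loci) == 1
        assert far.loci == [] and far.n_outside_window == 1

    def test_exclusion_set_drops_and_counts(self):
        sites = [
            (GenomicInterval("c", 100, 121, "+", "a"), MotifHit("a", 10.0, 0), 42),
            (GenomicInterval("c", 500, 521, "+", "b"), MotifHit("b", 10.0, 0), 42),
        ]
        exclusion = [GenomicInterval("c", 110, 130, ".", "snRNA")]
        result = call_pirna_loci(sites, 5.0, exclusion=exclusion)
        assert [l.id for l in result.loci] == ["b"]
        assert result.n_excluded == 1

    def test_order_independent(self, scanned, threshold, rng):
        shuffled = list(scanned)
        rng.shuffle(shuffled)
        a = call_pirna_loci(scanned, threshold)
        b = call_pirna_loci(shuffled, threshold)
        assert [l.id for l in a.loci] == [l.id for l in b.loci]

    def test_tss_geometry(self, scanned, threshold):
        for locus in call_pirna_loci(scanned, threshold).loci:
            if locus.strand == "+":
                assert locus.tss == locus.site_21u.start - 2
            else:
                assert locus.tss == locus.site_21u.end - 1 + 2


def _locus(contig="c", u=1000, strand="+", lid="L1"):
    if strand == "+":
        iv = GenomicInterval(contig, u, u + 21, "+", lid)
        tss = u - 2
    else:
        iv = GenomicInterval(contig, u - 20, u + 1, "-", lid)
        tss = u + 2
    return PiRNALocus(lid, iv, tss, 10.0, 42)


def _read(contig, start, end, strand, count=1, unique=True):
    return ReadSite(GenomicInterval(contig, start, end, strand), count,
                    "capped", unique)


class TestPrecursors:
    locus = _locus()

    def test_length_21_at_tss_excluded(self):
        r = _read("c", 998, 1019, "+")  # 5' at TSS but only 21 nt
        assert extract_precursors([r], [self.locus])["L1"] == []

    def test_five_prime_off_by_one_excluded(self):
        r = _read("c", 997, 1027, "+")  # 30 nt but 5' at TSS-1
        assert extract_precursors([r], [self.locus])["L1"] == []

    def test_matches_brute_force_filter(self, rng):
        loci = [_locus(u=1000, lid="L1"), _locus(u=5000, strand="-", lid="L2")]
        reads = []
        for _ in range(20):
            u = int(rng.choice([998, 1000, 4998, 5002]))
            length = int(rng.integers(20, 40))
            strand = rng.choice(["+", "-"])
            if strand == "+":
                reads.append(_read("c", u, u + length, "+"))
            else:
                reads.append(_read("c", u - length + 1, u + 1, "-"))
        got = extract_precursors(reads, loci)
        expected = {"L1": [], "L2": []}
        for r in reads:
            for l in loci:
                fp = r.interval.five_prime
                if (
                    r.interval.strand == l.strand
                    and fp == l.tss
                    and r.length >= 23
                ):
                    expected[l.id].append((r.length, r.count))
        assert {k: sorted(v) for k, v in got.items()} == {
            k: sorted(v) for k, v in expected.items()
        }


class TestCleavage:
    locus = _locus()

    def test_empty_reads_all_zero(self):
        res = extract_cleavage_fragments([], [self.locus], 1000, 1000)
        assert res.per_locus_reads == {"L1": 0}

    def test_window_boundary(self):
        # TSS = 998; fragment 5' at +27 excluded, +28 included
        at27 = _read("c", 998 + 27, 998 + 27 + 15, "+")
        at28 = _read("c", 998 + 28, 998 + 28 + 15, "+")
        res = extract_cleavage_fragments([at27, at28], [self.locus], 1000, 1000)
        assert res.per_locus_reads["L1"] == 1

    def test_21u_reads_removed_first(self):
        # a mature 21U read of locus A lands at +28 of a nearby locus B and
        # would be counted as a cleavage fragment there if 21U reads were
        # not removed first
        locus_a = _locus(u=1000, lid="A")
        locus_b = _locus(u=974, lid="B")  # TSS 972; 1000 - 972 = +28
        r21 = _read("c", 1000, 1021, "+")
        res = extract_cleavage_fragments([r21], [locus_a, locus_b], 1000, 1000)
        assert res.per_locus_reads == {"A": 0, "B": 0}

    def test_non_unique_excluded_and_toy_oracle(self, rng):
        reads = []
        for _ in range(15):
            rel = int(rng.integers(20, 45))
            length = int(rng.integers(8, 20))
            unique = bool(rng.random() < 0.7)
            reads.append(_read("c", 998 + rel, 998 + rel + length, "+",
                               unique=unique))
        res = extract_cleavage_fragments(reads, [self.locus], 2000, 1500)
        expected = sum(
            1 for r in reads
            if r.unique_mapping and r.length > 10
            and 28 <= (r.interval.start - 998) <= 38
        )
        assert res.per_locus_reads["L1"] == expected
        assert res.normalized_reads["L1"] == pytest.approx(
            expected * 1e6 / 2000
        )


class TestSizeFactors:
    def test_identical_libraries_factor_one(self):
        m = np.tile(np.array([10.0, 20, 30, 40])[:, None], (1, 3))
        sf = size_factors_median_ratios(m)
        assert np.allclose(sf.factors, 1.0)

    def test_doubled_library_ratio_two(self):
        a = np.array([10.0, 20, 55, 40, 8])
        m = np.column_stack([a, 2 * a])
        sf = size_factors_median_ratios(m)
        assert sf.factors[1] / sf.factors[0] == pytest.approx(2.0)

    def test_poisson_planted_factors_recovered(self, rng):
        true = np.array([0.5, 1.0, 2.0])
        means = rng.uniform(100, 2000, size=2000)
        m = rng.poisson(means[:, None] * true[None, :])
        sf = size_factors_median_ratios(m)
        est = sf.factors / sf.factors[1]
        assert np.allclose(est, true, rtol=0.05)

    def test_all_zero_gene_set_rejected(self):
        with pytest.raises(ValueError):
            size_factors_median_ratios(np.array([[0, 1], [2, 0]]))

    def test_slope_exact_multiple(self):
        x = np.arange(1.0, 21)
        sf = size_factors_slope(x, 3 * x)
        assert sf.factors[1] == pytest.approx(3.0)
        assert sf.slope_interval[0] == pytest.approx(3.0)
        assert sf.slope_interval[1] == pytest.approx(3.0)

    def test_slope_interval_coverage(self):
        hits = 0
        n_sim = 1000
        for seed in range(n_sim):
            r = np.random.default_rng(seed)
            x = r.uniform(10, 100, 50)
            y = x + r.normal(0, 5, 50)
            sf = size_factors_slope(x, y)
            lo, hi = sf.slope_interval
            hits += lo <= 1.0 <= hi
        assert hits / n_sim >= 0.93

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            size_factors_slope(np.array([1.0]), np.array([2.0]))
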