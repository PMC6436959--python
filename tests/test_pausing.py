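"""Tm profiles, pausing strength, BILD scores, and precursor statistics."""

import math

import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import ks_2samp, spearmanr

from pirnakit.core import Genome
from pirnakit.pausing import (
    BRESLAUER_1986,
    R_GAS,
    TmParams,
    TmProfile,
    bild_columns,
    bild_profile,
    cross_species_range_metric,
    mean_profile,
    pausing_strength,
    precursor_length_test,
    rrna_length_control,
    stratify_by_signal,
    tm_profile,
    valley_center,
    weighted_resampling_test,
)


def naive_tm(kmer: str, params: TmParams) -> float:
    """Independent per-window summation oracle."""
    dh = sum(BRESLAUER_1986[kmer[i : i + 2]][0] for i in range(len(kmer) - 1))
    ds = sum(BRESLAUER_1986[kmer[i : i + 2]][1] for i in range(len(kmer) - 1))
    tm_k = 1000.0 * dh / (ds - R_GAS * math.log(params.dna_conc / 4.0))
    return tm_k - 273.15 + 16.6 * math.log10(params.salt_conc)


class TestTmProfile:
    params = TmParams()

    def test_homopolymer_flat_profile(self):
        g = Genome({"c": "A" * 500})
        prof = tm_profile(g, 250, "c", "+", self.params)
        assert np.allclose(prof.tm, prof.tm[0])

    def test_gc_window_melts_above_at_window(self):
        assert self.params.tm_kmer("GCGCGCGCG") > self.params.tm_kmer("ATATATATA")

    def test_profile_matches_summation_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=417))
        g = Genome({"c": seq})
        prof = tm_profile(g, 208, "c", "+", self.params)
        for pos, tm in zip(prof.positions, prof.tm):
            start = 208 + pos
            kmer = seq[start : start + 9]
            assert tm == pytest.approx(naive_tm(kmer, self.params), abs=1e-9)

    def test_minus_strand_uses_transcribed_strand(self):
        from pirnakit.core import reverse_complement

        seq = "".join(np.random.default_rng(5).choice(list("ACGT"), size=500))
        g = Genome({"c": seq})
        prof = tm_profile(g, 250, "c", "-", TmParams(), flank=50)
        # window at position p covers transcribed-strand bases p..p+8,
        # i.e. genomic bases 250-p-8..250-p reverse-complemented
        for pos, tm in zip(prof.positions, prof.tm):
            kmer = reverse_complement(seq[250 - pos - 8 : 250 - pos + 1])
            assert tm == pytest.approx(naive_tm(kmer, TmParams()), abs=1e-9)

    def test_n_window_undefined(self):
        g = Genome({"c": "A" * 200 + "N" + "A" * 200})
        prof = tm_profile(g, 190, "c", "+", self.params, flank=50)
        covered = (prof.positions >= 2) & (prof.positions <= 10)
        assert np.isnan(prof.tm[covered]).all()
        assert np.isfinite(prof.tm[~covered]).all()


def step_profile(b=40.0, high=5.0, low=5.0):
    positions = np.arange(-200, 201)
    tm = np.full(len(positions), b)
    tm[(positions >= 0) & (positions <= 19)] = b + high
    tm[(positions >= 20) & (positions <= 40)] = b - low
    return TmProfile(positions, tm, "test")


class TestPausingStrength:
    def test_flat_profile_zero(self):
        prof = TmProfile(np.arange(-200, 201), np.full(401, 37.0), "test")
        assert pausing_strength(prof).strength == pytest.approx(0.0)

    def test_step_profile_closed_form(self):
        # +5 over 20 high positions and -5 over 21 low positions:
        # S = 100 + 105 = 205 degC*nt
        score = pausing_strength(step_profile())
        assert score.strength == pytest.approx(205.0)
        assert score.background == pytest.approx(40.0)

    def test_invariant_under_constant_shift(self):
        a = pausing_strength(step_profile(b=40.0))
        b = pausing_strength(step_profile(b=90.0))
        assert a.strength == pytest.approx(b.strength)

    def test_insufficient_flank_coverage_rejected(self):
        positions = np.arange(-200, 201)
        tm = np.full(401, np.nan)
        tm[(positions >= -50)] = 40.0
        with pytest.raises(ValueError, match="flank"):
            pausing_strength(TmProfile(positions, tm, "test"))

    def test_recovery_on_planted_loci(self, ctype_bundle):
        params = TmParams()
        s, planted = [], []
        for row in ctype_bundle.truth.itertuples():
            prof = tm_profile(
                ctype_bundle.genome, row.tss, row.contig, row.strand, params
            )
            s.append(pausing_strength(prof).strength)
            planted.append(row.valley_depth)
        assert spearmanr(s, planted).statistic >= 0.8


class TestBILD:
    q = np.array([0.3, 0.2, 0.2, 0.3])

    def test_single_observation_column_zero(self):
        counts = np.zeros((5, 4))
        counts[np.arange(5), [0, 1, 2, 3, 0]] = 1
        assert np.allclose(bild_columns(counts, self.q), 0.0, atol=1e-12)

    def test_conserved_column_beats_background_column(self):
        conserved = np.array([[100, 0, 0, 0]])
        matching = np.array([[30, 20, 20, 30]])
        uniform = np.full(4, 0.25)
        assert bild_columns(conserved, uniform)[0] > bild_columns(matching, uniform)[0]

    def test_columns_match_log_gamma_oracle(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=401)) for _ in range(50)]
        prof = bild_profile(seqs, self.q, alpha0=1.0,
                            positions=np.arange(-200, 201))
        counts = np.zeros((401, 4))
        for s in seqs:
            for i, b in enumerate(s):
                counts[i, "ACGT".index(b)] += 1
        alpha = 1.0 * self.q
        for i in range(401):
            n = counts[i].sum()
            expected = (
                gammaln(1.0) - gammaln(1.0 + n)
                + sum(
                    gammaln(alpha[b] + counts[i, b]) - gammaln(alpha[b])
                    for b in range(4)
                )
                - sum(counts[i, b] * math.log(self.q[b]) for b in range(4))
            )
            assert prof.scores[i] == pytest.approx(expected, abs=1e-9)

    def test_termination_peak_area_on_conserved_window(self):
        rng = np.random.default_rng(0)
        seqs = []
        for _ in range(60):
            s = list(rng.choice(list("ACGT"), size=401))
            s[220:241] = list("T" * 21)  # conserved tract at +20..+40
            seqs.append("".join(s))
        prof = bild_profile(seqs, np.full(4, 0.25),
                            positions=np.arange(-200, 201))
        assert prof.termination_area > 0

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(ValueError):
            bild_profile(["ACGT"], np.full(4, 0.25))


class TestValleyAndStratification:
    def test_v_shape_center(self):
        positions = np.arange(-200, 201)
        tm = 40.0 - 10.0 * np.exp(-((positions - 30) ** 2) / 20.0)
        res = valley_center(TmProfile(positions, tm, "t"))
        assert res.position == 30 and not res.flat

    def test_flat_window_flagged_midpoint(self):
        prof = TmProfile(np.arange(-200, 201), np.full(401, 40.0), "t")
        res = valley_center(prof)
        assert res.flat and res.position == 35

    def test_monotone_decreasing_hits_boundary(self):
        positions = np.arange(-200, 201)
        tm = 40.0 - 0.05 * positions
        res = valley_center(TmProfile(positions, tm, "t"))
        assert res.position == 60

    def test_range_metric_shift_invariant(self):
        a = cross_species_range_metric(step_profile(b=40.0))
        b = cross_species_range_metric(step_profile(b=75.0))
        assert a == pytest.approx(b)
        assert a == pytest.approx(10.0)

    def test_stratify_sizes_and_determinism(self):
        scores = {f"l{i:03d}": float(i) for i in range(100)}
        top, bottom = stratify_by_signal(scores)
        assert len(top) == len(bottom) == 10
        assert set(bottom) == {f"l{i:03d}" for i in range(10)}

    def test_stratify_tie_rule_stable(self):
        scores = {f"l{i:02d}": 1.0 for i in range(30)}
        top1 = stratify_by_signal(scores)
        top2 = stratify_by_signal(dict(reversed(list(scores.items()))))
        assert top1 == top2


class TestPrecursorLengthTests:
    def test_identical_multisets_p_one(self):
        a = [28, 29, 29, 30, 31]
        assert precursor_length_test(a, list(a)) == pytest.approx(1.0)

    def test_one_sided_matches_enumeration(self):
        from tests.test_stats import rank_sum_oracle

        a = list(range(1, 11))
        b = list(range(11, 21))
        p = precursor_length_test(b, a, alternative="greater")
        assert p == pytest.approx(
            rank_sum_oracle(np.array(b, float), np.array(a, float), "greater"),
            abs=1e-9,
        )

    def test_planted_shift_detected(self, rng):
        a = rng.normal(30, 2, 50)
        p = precursor_length_test(a + 10, rng.normal(30, 2, 50),
                                  alternative="greater")
        assert p < 0.001

    def test_minimum_sizes_enforced(self):
        with pytest.raises(ValueError):
            precursor_length_test([28, 29], [30, 31, 32, 33, 34])


@pytest.fixture(scope="module")
def precursor_sets(rng):
    lengths = 28 + rng.geometric(0.25, size=1500)
    counts = rng.integers(1, 30, size=1500)
    return list(zip(lengths.tolist(), counts.tolist()))


class TestResampling:
    def test_same_library_null_indistinguishable(self, precursor_sets):
        res = weighted_resampling_test(
            precursor_sets, precursor_sets, n_sub=500, n_reps=150, seed=3,
            alternative="greater",
        )
        assert ks_2samp(res.p_values, res.null_p_values).pvalue > 0.05

    def test_planted_shift_separates_from_null(self, precursor_sets):
        shifted = [(l + 10, c) for l, c in precursor_sets]
        res = weighted_resampling_test(
            shifted, precursor_sets, n_sub=500, n_reps=150, seed=3,
            alternative="greater",
        )
        null5 = np.quantile(res.null_p_values, 0.05)
        assert (res.p_values < null5).mean() >= 0.95

    def test_single_rep(self, precursor_sets):
        res = weighted_resampling_test(
            precursor_sets, precursor_sets, n_sub=100, n_reps=1, seed=0
        )
        assert len(res.p_values) == 1


class TestRrnaControl:
    def test_identical_distributions_uniform_p(self, rng):
        lengths = (28 + rng.geometric(0.2, size=3000)).tolist()
        ps = rrna_length_control(lengths, list(lengths), 200, 200,
                                 n_reps=200, seed=1)
        # roughly uniform: no mass concentration at small p
        assert (ps < 0.05).mean() < 0.12

    def test_truncated_size_selection_shifts_p(self, rng):
        a = (28 + rng.geometric(0.2, size=3000)).tolist()
        b = [l for l in a if l <= 35] * 2
        ps = rrna_length_control(a, b, 200, 200, n_reps=100, seed=1)
        assert np.median(ps) < 0.01

    def test_zero_reps_rejected(self, rng):
        with pytest.raises(ValueError):
            rrna_length_control([30] * 100, [30] * 100, 10, 10, n_reps=0)


def test_mean_profile_and_valley_shift_recovery():
    from pirnakit.synth import SpeciesConfig, generate_species

    params = TmParams()

    def species_center(shift):
        b = generate_species(
            SpeciesConfig(mode="C-type", n_pirna_loci=80, seed=21,
                          valley_shift=shift)
        )
        profs = [
            tm_profile(b.genome, r.tss, r.contig, r.strand, params)
            for r in b.truth.itertuples()
        ]
        return valley_center(mean_profile(profs)).position

    assert abs((species_center(10) - species_center(0)) - 10) <= 2
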