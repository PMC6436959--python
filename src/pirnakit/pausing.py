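"""DNA melting-temperature profiles and Pol II pausing-signal statistics.

piRNA precursors are short capped Pol II transcripts whose release is
associated with a sequence signature downstream of the TSS: a high-Tm
(GC-rich) region over the nascent transcript body (TSS to +19) followed by a
low-Tm "valley" (+20 to +40) that destabilizes the elongation complex. This
module computes sliding-window duplex Tm profiles (nearest-neighbor
thermodynamics, 9-nt window, 1-nt shift), a per-locus pausing strength, the
Bayesian Integral Log-Odds (BILD) entropy profile used for cross-species
comparison, and the resampling machinery for precursor-length statistics.

Conventions:

* Profile positions are relative to the TSS on the transcribed strand;
  the Tm of a 9-mer window is assigned to the window start.
* Pausing strength S = sum_{i in [0,19]} (Tm_i - B) + sum_{i in [20,40]}
  (B - Tm_i), with background B the mean Tm over the flanks
  [-200,-100] and [+100,+200]. Deviations are signed (not clipped); a
  ``clip`` option provides the max(.,0) variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from pirnakit.core import Genome, extract_sequence, GenomicInterval
from pirnakit.stats import rank_sum_test

# Breslauer 1986 nearest-neighbor duplex parameters.
# dH in kcal/mol and dS in cal/(mol K), stored as positive magnitudes for
# the dissociation direction used in the Tm formula below.
BRESLAUER_1986 = {
    "AA": (9.1, 24.0), "TT": (9.1, 24.0),
    "AT": (8.6, 23.9),
    "TA": (6.0, 16.9),
    "CA": (5.8, 12.9), "TG": (5.8, 12.9),
    "GT": (6.5, 17.3), "AC": (6.5, 17.3),
    "CT": (7.8, 20.8), "AG": (7.8, 20.8),
    "GA": (5.6, 13.5), "TC": (5.6, 13.5),
    "CG": (11.9, 27.8),
    "GC": (11.1, 26.7),
    "GG": (11.0, 26.6), "CC": (11.0, 26.6),
}

R_GAS = 1.987  # cal / (mol K)


@dataclass
class TmParams:
    """Thermodynamic settings for duplex Tm: nearest-neighbor table id,
    total strand concentration (M) and monovalent salt (M)."""

    table_id: str = "breslauer1986"
    dna_conc: float = 50e-9   # 50 nM
    salt_conc: float = 0.05   # 50 mM Na+
    window: int = 9
    table: dict = field(default_factory=lambda: dict(BRESLAUER_1986))

    def tm_kmer(self, kmer: str) -> float:
        """Duplex Tm (deg C) of one window sequence; NaN if it contains N."""
        dh = 0.0
        ds = 0.0
        for i in range(len(kmer) - 1):
            pair = kmer[i : i + 2]
            if pair not in self.table:
                return float("nan")
            h, s = self.table[pair]
            dh += h
            ds += s
        # association dH, dS are negative; with magnitudes h, s:
        # Tm = h / (s - R ln(C/4)), and ln(C/4) < 0 at nM concentrations
        denom = ds - R_GAS * math.log(self.dna_conc / 4.0)
        tm_k = 1000.0 * dh / denom
        return tm_k - 273.15 + 16.6 * math.log10(self.salt_conc)


@dataclass
class TmProfile:
    """Per-position window Tm values around a TSS.

    ``positions`` are window-start offsets from the TSS on the transcribed
    strand; ``tm`` holds the Tm per window (NaN over N-containing windows).
    """

    positions: np.ndarray
    tm: np.ndarray
    params_id: str
    clipped: bool = False

    def region(self, lo: int, hi: int) -> np.ndarray:
        """Tm values at positions in [lo, hi] inclusive."""
        mask = (self.positions >= lo) & (self.positions <= hi)
        return self.tm[mask]


@dataclass
class PausingScore:
    strength: float        # S, deg C * nt
    background: float      # B, deg C
    high_sum: float
    low_sum: float
    n_missing: int


def _window_tms(seq: str, params: TmParams) -> np.ndarray:
    """Vectorized sliding-window Tm over ``seq`` (window start indexed)."""
    w = params.window
    n = len(seq) - w + 1
    if n <= 0:
        return np.zeros(0)
    codes = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    idx = np.full(len(codes), -1, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        idx[codes == ord(b)] = i
    # per-stack dH/dS lookup tables indexed by 4*first + second
    dh_tab = np.zeros(16)
    ds_tab = np.zeros(16)
    for j, b1 in enumerate("ACGT"):
        for k, b2 in enumerate("ACGT"):
            h, s = params.table[b1 + b2]
            dh_tab[4 * j + k] = h
            ds_tab[4 * j + k] = s
    first, second = idx[:-1], idx[1:]
    ok = (first >= 0) & (second >= 0)
    code = 4 * np.where(ok, first, 0) + np.where(ok, second, 0)
    dh_stack = np.where(ok, dh_tab[code], 0.0)
    ds_stack = np.where(ok, ds_tab[code], 0.0)
    # cumulative sums over the w-1 stacks per window; windows touching an
    # invalid (N-containing) stack become NaN
    dh_cum = np.concatenate([[0.0], np.cumsum(dh_stack)])
    ds_cum = np.concatenate([[0.0], np.cumsum(ds_stack)])
    bad_cum = np.concatenate([[0], np.cumsum(~ok)])
    dh = dh_cum[w - 1 :] - dh_cum[: n]
    ds = ds_cum[w - 1 :] - ds_cum[: n]
    n_bad = bad_cum[w - 1 :] - bad_cum[: n]
    denom = ds - R_GAS * math.log(params.dna_conc / 4.0)
    tm = 1000.0 * dh / denom - 273.15 + 16.6 * math.log10(params.salt_conc)
    tm[n_bad > 0] = np.nan
    return tm


def tm_profile(
    genome: Genome,
    tss: int,
    contig: str,
    strand: str,
    params: TmParams | None = None,
    flank: int = 200,
) -> TmProfile:
    """Tm profile in a window ``[-flank, +flank]`` around a TSS.

    The sequence is taken on the transcribed strand; window Tm values are
    assigned to their start offset relative to the TSS. Windows running off
    the contig are dropped and the profile flagged clipped.
    """
    params = params or TmParams()
    w = params.window
    length = genome.lengths[contig]
    if strand == "+":
        lo = tss - flank
        hi = tss + flank + w  # so the window starting at +flank is complete
        clip_lo, clip_hi = max(lo, 0), min(hi, length)
        seq = extract_sequence(genome, GenomicInterval(contig, clip_lo, clip_hi, "+"))
        first_pos = clip_lo - tss
    elif strand == "-":
        lo = tss - flank - w + 1
        hi = tss + flank + 1
        clip_lo, clip_hi = max(lo, 0), min(hi, length)
        seq = extract_sequence(genome, GenomicInterval(contig, clip_lo, clip_hi, "-"))
        first_pos = tss - (clip_hi - 1)
    else:
        raise ValueError("strand must be + or -")
    clipped = (clip_lo != lo) or (clip_hi != hi)
    tms = _window_tms(seq, params)
    positions = np.arange(first_pos, first_pos + len(tms))
    keep = (positions >= -flank) & (positions <= flank)
    return TmProfile(positions[keep], tms[keep], params.table_id, clipped)


def pausing_strength(
    profile: TmProfile,
    high: tuple[int, int] = (0, 19),
    low: tuple[int, int] = (20, 40),
    flanks: tuple[tuple[int, int], tuple[int, int]] = ((-200, -100), (100, 200)),
    clip: bool = False,
    min_flank_coverage: float = 0.5,
) -> PausingScore:
    """Per-locus pausing strength from a Tm profile.

    S = sum over the high region of (Tm - B) plus sum over the low region of
    (B - Tm), B being the mean Tm over the two flanks. NaN positions are
    omitted from sums (count reported); each flank must have at least
    ``min_flank_coverage`` of its positions defined.
    """
    flank_vals = []
    for lo, hi in flanks:
        vals = profile.region(lo, hi)
        expected = hi - lo + 1
        defined = np.isfinite(vals).sum()
        if defined < min_flank_coverage * expected:
            raise ValueError(
                f"insufficient flank coverage in [{lo},{hi}]: "
                f"{defined}/{expected} defined"
            )
        flank_vals.append(vals[np.isfinite(vals)])
    b = float(np.concatenate(flank_vals).mean())
    high_vals = profile.region(*high)
    low_vals = profile.region(*low)
    n_missing = int(
        (~np.isfinite(high_vals)).sum() + (~np.isfinite(low_vals)).sum()
    )
    hd = high_vals[np.isfinite(high_vals)] - b
    ld = b - low_vals[np.isfinite(low_vals)]
    if clip:
        hd = np.clip(hd, 0, None)
        ld = np.clip(ld, 0, None)
    return PausingScore(
        float(hd.sum() + ld.sum()), b, float(hd.sum()), float(ld.sum()), n_missing
    )


def valley_depth(profile: TmProfile, low: tuple[int, int] = (20, 40)) -> float:
    """Background minus the mean Tm over the low window (deg C); larger =
    deeper valley. The mean is used rather than the minimum because the
    minimum of overlapping windows is dominated by local base-stacking
    arrangement (TA-rich 9-mers melt far below AA-rich ones of identical
    composition), while the mean tracks the composition signal."""
    score = pausing_strength(profile)
    vals = profile.region(*low)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        return float("nan")
    return score.background - float(vals.mean())


# --- BILD -------------------------------------------------------------------

@dataclass
class BILDProfile:
    positions: np.ndarray
    scores: np.ndarray
    baseline: float
    termination_area: float


def bild_columns(
    counts: np.ndarray, background: np.ndarray, alpha0: float = 1.0
) -> np.ndarray:
    """Per-column Bayesian Integral Log-Odds scores.

    For column counts n_b with Dirichlet prior alpha_b = alpha0 * q_b:
    BILD = ln[Gamma(A)/Gamma(A+n) * prod_b Gamma(alpha_b+n_b)/Gamma(alpha_b)]
           - sum_b n_b ln q_b.
    A single-observation column scores exactly 0.
    """
    counts = np.asarray(counts, dtype=float)
    q = np.asarray(background, dtype=float)
    alpha = alpha0 * q
    n = counts.sum(axis=1)
    term = (
        gammaln(alpha0)
        - gammaln(alpha0 + n)
        + (gammaln(alpha[None, :] + counts) - gammaln(alpha[None, :])).sum(axis=1)
    )
    return term - (counts * np.log(q[None, :])).sum(axis=1)


def bild_profile(
    aligned_sequences: list[str],
    background: np.ndarray | list[float],
    alpha0: float = 1.0,
    positions: np.ndarray | None = None,
    flanks: tuple[tuple[int, int], tuple[int, int]] = ((-200, -100), (100, 200)),
    termination_window: tuple[int, int] = (20, 40),
) -> BILDProfile:
    """BILD entropy profile over TSS-aligned sequences.

    ``positions`` gives the TSS-relative offset of each column (defaults to
    0..L-1). Sequences contribute to a column only where they carry an
    unambiguous base. The termination-peak area is the baseline-subtracted
    sum of scores over the low-Tm window, the baseline being the median
    score over the flanks.
    """
    if len(aligned_sequences) < 2:
        raise ValueError("need at least 2 aligned sequences")
    length = len(aligned_sequences[0])
    if any(len(s) != length for s in aligned_sequences):
        raise ValueError("aligned sequences must have equal length")
    q = np.asarray(background, dtype=float)
    counts = np.zeros((length, 4))
    base_index = {b: i for i, b in enumerate("ACGT")}
    for seq in aligned_sequences:
        for i, b in enumerate(seq.upper()):
            if b in base_index:
                counts[i, base_index[b]] += 1
    scores = bild_columns(counts, q, alpha0)
    pos = (
        np.arange(length) if positions is None else np.asarray(positions)
    )
    flank_mask = np.zeros(length, dtype=bool)
    for lo, hi in flanks:
        flank_mask |= (pos >= lo) & (pos <= hi)
    baseline = float(np.median(scores[flank_mask])) if flank_mask.any() else 0.0
    lo, hi = termination_window
    tmask = (pos >= lo) & (pos <= hi)
    area = float((scores[tmask] - baseline).sum())
    return BILDProfile(pos, scores, baseline, area)


# --- cross-species metrics and stratification --------------------------------

def cross_species_range_metric(
    profile: TmProfile,
    high: tuple[int, int] = (0, 19),
    low: tuple[int, int] = (20, 40),
) -> float:
    """Max Tm of the high-GC region minus min Tm of the low-GC region, on a
    species-mean profile. Invariant to adding a constant to all Tm values,
    which removes cross-species GC-background differences."""
    hv = profile.region(*high)
    lv = profile.region(*low)
    hv = hv[np.isfinite(hv)]
    lv = lv[np.isfinite(lv)]
    if len(hv) == 0 or len(lv) == 0:
        raise ValueError("high or low region undefined")
    return float(hv.max() - lv.min())


def mean_profile(profiles: list[TmProfile]) -> TmProfile:
    """Position-wise nanmean of per-locus profiles (species-level profile)."""
    if not profiles:
        raise ValueError("no profiles")
    all_pos = sorted({int(p) for pr in profiles for p in pr.positions})
    pos_index = {p: i for i, p in enumerate(all_pos)}
    acc = np.full((len(profiles), len(all_pos)), np.nan)
    for r, pr in enumerate(profiles):
        for p, t in zip(pr.positions, pr.tm):
            acc[r, pos_index[int(p)]] = t
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(acc, axis=0)
    return TmProfile(np.array(all_pos), mean, profiles[0].params_id)


@dataclass
class ValleyCenter:
    position: int
    flat: bool


def valley_center(
    profile: TmProfile,
    search: tuple[int, int] = (10, 60),
    smooth: int = 5,
) -> ValleyCenter:
    """Center of the low-Tm valley: argmin of the ``smooth``-position moving
    average of Tm within the search window; ties take the smallest position.
    A flat window is flagged and returns the window midpoint."""
    lo, hi = search
    mask = (profile.positions >= lo) & (profile.positions <= hi)
    pos = profile.positions[mask]
    vals = profile.tm[mask]
    if len(pos) == 0:
        raise ValueError("search window undefined")
    half = smooth // 2
    sm = np.full(len(vals), np.nan)
    for i in range(len(vals)):
        window = vals[max(0, i - half) : i + half + 1]
        window = window[np.isfinite(window)]
        if len(window):
            sm[i] = window.mean()
    finite = np.isfinite(sm)
    if not finite.any() or np.nanmax(sm) - np.nanmin(sm) < 1e-9:
        return ValleyCenter(int((lo + hi) // 2), True)
    best = int(pos[np.nanargmin(sm)])
    return ValleyCenter(best, False)


def stratify_by_signal(
    scores: dict[str, float], fraction: float = 0.10
) -> tuple[list[str], list[str]]:
    """Split loci into top and bottom ``fraction`` by pausing strength.

    Deterministic: loci are sorted by (score, locus id); the bottom set is
    the first k and the top set the last k, k = floor(n * fraction), so ties
    at the cut resolve by locus id.
    """
    if len(scores) < 20:
        raise ValueError("need at least 20 loci to stratify")
    k = max(1, int(len(scores) * fraction))
    ordered = sorted(scores, key=lambda lid: (scores[lid], lid))
    return ordered[-k:], ordered[:k]


# --- precursor length statistics ---------------------------------------------

def expand_lengths(length_counts: list[tuple[int, int]]) -> np.ndarray:
    """Expand (length, count) pairs into a flat length vector."""
    out: list[int] = []
    for length, count in length_counts:
        out.extend([length] * count)
    return np.asarray(out, dtype=float)


def precursor_length_test(
    lengths_a, lengths_b, alternative: str = "two-sided"
) -> float:
    """Wilcoxon rank-sum p-value for a difference in precursor lengths."""
    a = np.asarray(lengths_a, dtype=float)
    b = np.asarray(lengths_b, dtype=float)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("need at least 5 lengths per side")
    return rank_sum_test(a, b, alternative=alternative)


@dataclass
class ResamplingResult:
    p_values: np.ndarray
    null_p_values: np.ndarray
    median_p: float
    frac_below_005: float
    n_subsample: int
    n_reps: int
    seed: int


def _weighted_subsample(
    lengths: np.ndarray, counts: np.ndarray, n_sub: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample ``n_sub`` unique precursor sequences without replacement with
    probability proportional to read count; returns their lengths."""
    w = counts / counts.sum()
    idx = rng.choice(len(lengths), size=n_sub, replace=False, p=w)
    return lengths[idx]


def weighted_resampling_test(
    precursors_a: list[tuple[int, int]],
    precursors_b: list[tuple[int, int]],
    n_sub: int = 2500,
    n_reps: int = 1000,
    seed: int = 0,
    alternative: str = "greater",
) -> ResamplingResult:
    """Abundance-weighted subsampling test on precursor lengths.

    Per repetition, ``n_sub`` unique precursor sequences are drawn from each
    side without replacement with probability proportional to read count and
    compared by a one-tailed Wilcoxon rank-sum test (A vs B). The null
    distribution compares two disjoint subsamples drawn from side B alone,
    which controls for the depth-dependence of unique-sequence length
    distributions. When either side has fewer than ``n_sub`` unique
    sequences, n_sub is lowered (with a warning attribute in the result).
    """
    la = np.array([l for l, _ in precursors_a], dtype=float)
    ca = np.array([c for _, c in precursors_a], dtype=float)
    lb = np.array([l for l, _ in precursors_b], dtype=float)
    cb = np.array([c for _, c in precursors_b], dtype=float)
    if len(la) == 0 or len(lb) == 0:
        raise ValueError("empty precursor set")
    n_sub_eff = min(n_sub, len(la), len(lb))
    rng = np.random.default_rng(seed)
    ps = np.empty(n_reps)
    null_ps = np.empty(n_reps)
    for r in range(n_reps):
        sa = _weighted_subsample(la, ca, n_sub_eff, rng)
        sb = _weighted_subsample(lb, cb, n_sub_eff, rng)
        ps[r] = rank_sum_test(sa, sb, alternative=alternative, exact_limit=0)
        # null: two independent subsamples from the same library (B),
        # constructed exactly like the test comparison
        n1 = _weighted_subsample(lb, cb, n_sub_eff, rng)
        n2 = _weighted_subsample(lb, cb, n_sub_eff, rng)
        null_ps[r] = rank_sum_test(n1, n2, alternative=alternative, exact_limit=0)
    return ResamplingResult(
        ps, null_ps, float(np.median(ps)), float((ps < 0.05).mean()),
        n_sub_eff, n_reps, seed,
    )


def rrna_length_control(
    rrna_lengths_a,
    rrna_lengths_b,
    n_a: int,
    n_b: int,
    n_reps: int = 1000,
    seed: int = 0,
    min_length: int = 24,
    alternative: str = "two-sided",
) -> np.ndarray:
    """Null p-value distribution from length-matched rRNA structural reads.

    Samples ``n_a`` and ``n_b`` rRNA fragment lengths (> 23 nt) from each
    library and computes a Wilcoxon rank-sum p-value, repeated ``n_reps``
    times — a size-selection control for precursor-length comparisons.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    a = np.asarray([l for l in rrna_lengths_a if l >= min_length], dtype=float)
    b = np.asarray([l for l in rrna_lengths_b if l >= min_length], dtype=float)
    if len(a) < n_a or len(b) < n_b:
        raise ValueError("insufficient rRNA reads longer than 23 nt")
    rng = np.random.default_rng(seed)
    ps = np.empty(n_reps)
    for r in range(n_reps):
        sa = rng.choice(a, size=n_a, replace=False)
        sb = rng.choice(b, size=n_b, replace=False)
        ps[r] = rank_sum_test(sa, sb, alternative=alternative, exact_limit=0)
    return ps
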