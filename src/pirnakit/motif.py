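"""Position-weight-matrix construction, scanning, and score thresholding.

Nematode piRNA loci are recognized by an upstream promoter element (the Ruby
motif, GTTTC core) whose start lies a characteristic ~42 nt upstream of the
mature 21U 5' end. The workflow here is: build (or import) a PWM, scan
strand-aware upstream windows, and separate true motif instances from
background hits by fitting a two-component Gaussian mixture to the bimodal
score distribution — the threshold is the equal-posterior crossing between
the two components.

Scores are log2 odds (bits) internally; :func:`bits_to_centinats` converts
to the x100 natural-log-odds convention some published thresholds use, so
absolute thresholds quoted on that scale stay representable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: multiply a bits score by this to get x100 natural-log odds ("centinats"),
#: the scale on which published piRNA motif thresholds are usually quoted
BITS_TO_CENTINATS = 100.0 * np.log(2.0)


def bits_to_centinats(score_bits: float) -> float:
    """Convert a log2-odds (bits) score to x100 natural-log odds."""
    return float(score_bits) * BITS_TO_CENTINATS

#: sentinel returned when every window offset overlaps an N
NO_HIT = None


@dataclass
class PWM:
    """Log-odds position weight matrix over A/C/G/T.

    ``log_odds`` has shape (width, 4) in log2 units relative to the
    background frequencies ``background``.
    """

    log_odds: np.ndarray
    background: np.ndarray
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.log_odds.ndim != 2 or self.log_odds.shape[1] != 4:
            raise ValueError("log_odds must be (width, 4)")
        if not np.isclose(self.background.sum(), 1.0) or (self.background <= 0).any():
            raise ValueError("background must be positive and sum to 1")
        if not np.isfinite(self.log_odds).all():
            raise ValueError("log_odds must be finite")

    @property
    def width(self) -> int:
        return self.log_odds.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.log_odds.argmax(axis=1))

    @property
    def max_score(self) -> float:
        """Sum of per-column maxima — the score of the consensus sequence."""
        return float(self.log_odds.max(axis=1).sum())

    def information_content(self) -> float:
        """Total information content in bits (expected score under the PWM's
        implied base probabilities)."""
        probs = self.background[None, :] * np.exp2(self.log_odds)
        probs = probs / probs.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            ic = probs * (np.log2(probs) - np.log2(self.background[None, :]))
        return float(np.nansum(ic))

    def score(self, kmer: str) -> float:
        """Score a single width-length sequence (NaN if it contains N)."""
        if len(kmer) != self.width:
            raise ValueError("kmer length must equal PWM width")
        total = 0.0
        for i, b in enumerate(kmer.upper()):
            if b not in _BASE_INDEX:
                return float("nan")
            total += self.log_odds[i, _BASE_INDEX[b]]
        return total


@dataclass(frozen=True)
class MotifHit:
    """Best-scoring PWM placement inside one scanned window."""

    site_id: str
    score: float
    offset: int  # bp from window start to motif start
    distance_to_site: int | None = None  # motif start -> 21U start, nt


@dataclass
class ThresholdFit:
    """Two-component Gaussian mixture fit to a motif score distribution."""

    threshold: float
    means: tuple[float, float]       # (lower, upper)
    sds: tuple[float, float]
    weights: tuple[float, float]
    separation: float                # |mu2 - mu1| / pooled SD
    unimodal: bool


def build_pwm(
    site_sequences: list[str],
    background: np.ndarray | list[float] | None = None,
    pseudocount: float = 1.0,
) -> PWM:
    """Build a log2-odds PWM from equal-length aligned site sequences.

    log_odds[i][b] = log2( (count_ib + pseudocount*q_b) / (n + pseudocount)
                           / q_b )
    """
    if len(site_sequences) < 2:
        raise ValueError("need at least 2 site sequences")
    width = len(site_sequences[0])
    if any(len(s) != width for s in site_sequences):
        raise ValueError("site sequences must have equal length")
    q = (
        np.full(4, 0.25)
        if background is None
        else np.asarray(background, dtype=float)
    )
    counts = np.zeros((width, 4))
    for seq in site_sequences:
        for i, b in enumerate(seq.upper()):
            if b not in _BASE_INDEX:
                raise ValueError(f"N or non-ACGT base in site sequence: {b!r}")
            counts[i, _BASE_INDEX[b]] += 1
    n = len(site_sequences)
    freqs = (counts + pseudocount * q[None, :]) / (n + pseudocount)
    return PWM(np.log2(freqs / q[None, :]), q, pseudocount)


def scan_window(pwm: PWM, sequence: str, site_id: str = ".") -> MotifHit | None:
    """Return the maximum-scoring PWM placement in ``sequence``.

    Ties are broken by the smallest offset. Offsets whose window overlaps an
    N are skipped; if all are skipped, returns None (no-hit sentinel).
    """
    sequence = sequence.upper()
    w = pwm.width
    if len(sequence) < w:
        raise ValueError("sequence shorter than PWM width")
    codes = np.frombuffer(sequence.encode(), dtype=np.uint8)
    idx = np.full(len(codes), -1, dtype=np.int64)
    for i, b in enumerate(BASES):
        idx[codes == ord(b)] = i
    n_off = len(sequence) - w + 1
    scores = np.zeros(n_off)
    valid = np.ones(n_off, dtype=bool)
    for i in range(w):
        col = idx[i : i + n_off]
        ok = col >= 0
        valid &= ok
        scores += np.where(ok, pwm.log_odds[i, np.where(ok, col, 0)], 0.0)
    if not valid.any():
        return NO_HIT
    scores[~valid] = -np.inf
    best_offset = int(np.argmax(scores))  # argmax takes the first maximum
    return MotifHit(site_id, float(scores[best_offset]), best_offset)


def fit_score_threshold(
    scores: np.ndarray | list[float],
    n_restarts: int = 10,
    seed: int = 0,
    min_separation_sd: float = 1.0,
) -> ThresholdFit:
    """Fit a 2-component Gaussian mixture to motif scores and place the
    classification threshold at the equal-posterior point between the
    component means.

    A fit whose component means differ by less than one pooled SD is flagged
    ``unimodal`` (the score distribution does not separate true motifs from
    background, as happens in species without motif-dependent piRNAs).
    """
    x = np.asarray(scores, dtype=float).reshape(-1, 1)
    if len(x) < 50:
        raise ValueError("need at least 50 scores to fit a threshold")
    gm = GaussianMixture(
        n_components=2, n_init=n_restarts, random_state=seed,
        covariance_type="full", reg_covar=1e-6,
    ).fit(x)
    gm1 = GaussianMixture(
        n_components=1, random_state=seed, covariance_type="full",
        reg_covar=1e-6,
    ).fit(x)
    # a single-component fit explaining the data at least as well (BIC)
    # means the score distribution does not separate into two populations
    bic_prefers_one = gm1.bic(x) <= gm.bic(x)
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    m1, m2 = means[order]
    s1, s2 = sds[order]
    w1, w2 = weights[order]
    pooled = np.sqrt((w1 * s1**2 + w2 * s2**2))
    separation = (m2 - m1) / pooled if pooled > 0 else np.inf
    unimodal = bool(separation < min_separation_sd or bic_prefers_one)

    def posterior_diff(t: float) -> float:
        lo1 = np.log(w1) + norm.logpdf(t, m1, s1)
        lo2 = np.log(w2) + norm.logpdf(t, m2, s2)
        return lo1 - lo2

    if unimodal or m2 - m1 <= 0:
        tau = (m1 + m2) / 2
    else:
        try:
            tau = brentq(posterior_diff, m1, m2)
        except ValueError:
            # no sign change between the means (heavy overlap): midpoint
            tau = (m1 + m2) / 2
    return ThresholdFit(
        float(tau), (float(m1), float(m2)), (float(s1), float(s2)),
        (float(w1), float(w2)), float(separation), bool(unimodal),
    )


@dataclass
class PositionalDistribution:
    histogram: dict[int, int]
    mode: int
    dominant: bool  # max bin >= 2x median bin


def positional_distribution(
    distances: list[int],
) -> PositionalDistribution:
    """Histogram of motif-start -> 21U-start distances and its mode.

    A genuine upstream promoter motif concentrates at a characteristic
    distance (42 nt for the Ruby motif); a flat histogram (max bin < 2x the
    median bin) is flagged as non-dominant.
    """
    if not distances:
        raise ValueError("no distances given")
    hist: dict[int, int] = {}
    for d in distances:
        hist[d] = hist.get(d, 0) + 1
    mode = max(sorted(hist), key=lambda d: hist[d])
    counts = np.array(sorted(hist.values()))
    if len(counts) == 1:
        dominant = True
    else:
        dominant = counts.max() >= 2 * np.median(counts)
    return PositionalDistribution(hist, mode, bool(dominant))


@dataclass(frozen=True)
class AlleleRescore:
    score_ref: float
    score_alt: float
    delta: float
    offset_ref: int
    offset_alt: int


def rescore_with_allele(
    pwm: PWM, window_sequence: str, position: int, ref: str, alt: str,
) -> AlleleRescore:
    """Re-score a scanned window after substituting a SNP allele.

    ``position`` is 0-based within ``window_sequence`` (already on the
    scanned strand). The reference base must match the sequence. When the
    best motif offset is unchanged by the substitution, ``delta`` equals the
    single-column log-odds difference exactly.
    """
    window_sequence = window_sequence.upper()
    ref, alt = ref.upper(), alt.upper()
    if window_sequence[position] != ref:
        raise ValueError(
            f"reference base mismatch at window position {position}: "
            f"sequence has {window_sequence[position]!r}, SNP says {ref!r}"
        )
    hit_ref = scan_window(pwm, window_sequence)
    alt_seq = window_sequence[:position] + alt + window_sequence[position + 1 :]
    hit_alt = scan_window(pwm, alt_seq)
    if hit_ref is None or hit_alt is None:
        raise ValueError("window has no scoreable offsets")
    return AlleleRescore(
        hit_ref.score, hit_alt.score, hit_alt.score - hit_ref.score,
        hit_ref.offset, hit_alt.offset,
    )


def ancestral_kmer_probability(
    site_probs: np.ndarray | list[list[float]], kmer: str
) -> float:
    """Probability of a k-mer under independent per-site marginal base
    probabilities (rows = sites, columns = A/C/G/T)."""
    probs = np.asarray(site_probs, dtype=float)
    if probs.shape != (len(kmer), 4):
        raise ValueError("site_probs must be (len(kmer), 4)")
    p = 1.0
    for i, b in enumerate(kmer.upper()):
        p *= probs[i, _BASE_INDEX[b]]
    return float(p)


def independent_origin_probability(
    p_ancestral: float, p_lineage1: float, p_lineage2: float
) -> float:
    """Probability that a motif arose independently in two lineages rather
    than being inherited: (1 - p_ancestral) * p_lineage1 * p_lineage2."""
    for p in (p_ancestral, p_lineage1, p_lineage2):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    return (1.0 - p_ancestral) * p_lineage1 * p_lineage2


# --- MEME minimal motif format ----------------------------------------------

def write_meme(pwm: PWM, path, name: str = "motif_1") -> None:
    """Write the PWM in MEME minimal motif format (probability matrix)."""
    probs = pwm.background[None, :] * np.exp2(pwm.log_odds)
    probs = probs / probs.sum(axis=1, keepdims=True)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write(
            "Background letter frequencies\n"
            + " ".join(
                f"{b} {q:.6f}" for b, q in zip(BASES, pwm.background)
            )
            + "\n\n"
        )
        fh.write(f"MOTIF {name}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {pwm.width} "
            f"nsites= 20 E= 0\n"
        )
        for row in probs:
            fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")


def read_meme(path) -> PWM:
    """Read the first motif from a MEME minimal-format file."""
    background = np.full(4, 0.25)
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        if line.startswith("Background letter frequencies"):
            toks = lines[i + 1].split()
            background = np.array(
                [float(toks[toks.index(b) + 1]) for b in BASES]
            )
        if line.startswith("letter-probability matrix"):
            for tok in line.split():
                pass
            parts = line.split()
            width = int(parts[parts.index("w=") + 1])
            for row_line in lines[i + 1 : i + 1 + width]:
                rows.append([float(v) for v in row_line.split()[:4]])
            break
    if width is None or len(rows) != width:
        raise ValueError(f"no motif found in MEME file {path}")
    probs = np.asarray(rows)
    probs = np.clip(probs, 1e-9, None)
    probs = probs / probs.sum(axis=1, keepdims=True)
    return PWM(np.log2(probs / background[None, :]), background)
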