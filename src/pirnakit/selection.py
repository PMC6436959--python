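"""Selection on piRNA motifs from strain SNP panels.

Motifs under purifying selection should rarely carry high-frequency
(major, >90% of strains) alleles that lower their score. For each SNP
overlapping a qualifying motif window the motif is rescored under the
alternate allele; disruptive variants (score drop of at least the
species-specific disruption threshold) are classified by the strain
frequency of the LOW-SCORING allele, and the major-allele fraction of
disruptive variants is compared across strata (inside/outside clusters,
active/regulated chromatin, high/low expression) by Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pirnakit.motif import PWM, rescore_with_allele
from pirnakit.stats import FisherResult, fisher_2x2
from pirnakit.core import reverse_complement


@dataclass(frozen=True)
class SNPRecord:
    """One biallelic SNP with its alternate-allele strain frequency."""

    contig: str
    position: int  # 0-based
    ref: str
    alt: str
    frequency: float  # fraction of strains carrying alt

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("frequency must lie in [0, 1]")


def classify_allele(frequency: float) -> str:
    """major (>0.9) / minor (<0.1) / intermediate, by strain frequency."""
    if frequency > 0.9:
        return "major"
    if frequency < 0.1:
        return "minor"
    return "intermediate"


@dataclass
class MotifVariantEffect:
    motif_id: str
    snp: SNPRecord
    score_ref: float
    score_alt: float
    delta: float
    low_score_allele_frequency: float
    allele_class: str      # class of the low-scoring allele
    disruptive: bool


def snp_frequencies_from_genotypes(
    genotypes: np.ndarray,
) -> np.ndarray:
    """Alternate-allele frequencies from a strains x sites genotype matrix
    (0 ref, 1 alt, -1 missing); missing genotypes are excluded from the
    denominator."""
    g = np.asarray(genotypes)
    called = (g >= 0).sum(axis=0)
    alt = (g == 1).sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(called > 0, alt / np.maximum(called, 1), np.nan)


def scaled_disruption_threshold(
    pwm: PWM, reference_threshold: float, reference_ic_bits: float
) -> float:
    """Scale a disruption threshold by PWM information content, for species
    whose motifs carry less information (a fixed score drop means more in a
    low-information motif)."""
    return reference_threshold * pwm.information_content() / reference_ic_bits


def motif_variant_effects(
    motif_windows: list[dict],
    snps: list[SNPRecord],
    pwm: PWM,
    score_floor: float,
    disruption_delta: float,
) -> tuple[list[MotifVariantEffect], int]:
    """Rescore qualifying motif windows under SNP alternate alleles.

    Each window dict carries ``id``, ``contig``, ``strand``, ``start``
    (genomic start of the window on the + strand), and ``sequence`` (the
    window on the + genome strand). Windows whose best motif score is below
    ``score_floor`` are skipped. A variant is disruptive when the absolute
    score change is at least ``disruption_delta`` (classified on the
    low-scoring allele). SNPs whose stated reference base mismatches the
    window sequence are counted and skipped. Returns
    (effects, n_ref_mismatch).
    """
    from pirnakit.motif import scan_window

    by_contig: dict[str, list[SNPRecord]] = {}
    for snp in snps:
        by_contig.setdefault(snp.contig, []).append(snp)
    effects: list[MotifVariantEffect] = []
    n_mismatch = 0
    for win in motif_windows:
        seq_plus = win["sequence"].upper()
        start = win["start"]
        strand = win["strand"]
        scan_seq = (
            seq_plus if strand == "+" else reverse_complement(seq_plus)
        )
        base = scan_window(pwm, scan_seq, win["id"])
        if base is None or base.score < score_floor:
            continue
        for snp in by_contig.get(win["contig"], []):
            if not (start <= snp.position < start + len(seq_plus)):
                continue
            if strand == "+":
                pos = snp.position - start
                ref, alt = snp.ref, snp.alt
            else:
                pos = (start + len(seq_plus) - 1) - snp.position
                ref = reverse_complement(snp.ref)
                alt = reverse_complement(snp.alt)
            if scan_seq[pos] != ref.upper():
                n_mismatch += 1
                continue
            res = rescore_with_allele(pwm, scan_seq, pos, ref, alt)
            # frequency of the LOW-scoring allele: alt has frequency f,
            # ref has 1 - f
            if res.delta < 0:
                low_freq = snp.frequency
            elif res.delta > 0:
                low_freq = 1.0 - snp.frequency
            else:
                low_freq = snp.frequency
            # disruptive: the alternate allele lowers the motif score by at
            # least the species-specific threshold
            disruptive = res.delta < 0 and abs(res.delta) >= disruption_delta
            effects.append(
                MotifVariantEffect(
                    win["id"], snp, res.score_ref, res.score_alt, res.delta,
                    low_freq, classify_allele(low_freq),
                    bool(disruptive),
                )
            )
    return effects, n_mismatch


@dataclass
class StratumFraction:
    stratum: str
    n_major: int
    n_disruptive: int
    fraction_major: float
    ci_low: float
    ci_high: float


@dataclass
class StratifiedResult:
    fractions: list[StratumFraction]
    pairwise_fisher: dict[tuple[str, str], FisherResult]


def stratified_major_fraction(
    effects: list[MotifVariantEffect],
    strata: dict[str, str],
) -> StratifiedResult:
    """Fraction of disruptive variants whose low-scoring allele is major,
    per stratum, with pairwise two-sided Fisher exact tests.

    ``strata`` maps motif id -> stratum label. Intermediate-frequency
    alleles are excluded from the major/minor contrast. Empty strata are
    dropped with a warning.
    """
    import logging
    from statistics import NormalDist

    logger = logging.getLogger(__name__)
    z = NormalDist().inv_cdf(0.975)
    tallies: dict[str, list[int]] = {}
    for eff in effects:
        if not eff.disruptive or eff.allele_class == "intermediate":
            continue
        stratum = strata.get(eff.motif_id)
        if stratum is None:
            continue
        t = tallies.setdefault(stratum, [0, 0])  # [major, minor]
        if eff.allele_class == "major":
            t[0] += 1
        else:
            t[1] += 1
    fractions = []
    for stratum in sorted(strata.values()):
        if stratum not in tallies:
            if not any(f.stratum == stratum for f in fractions):
                logger.warning("stratum %r has no disruptive variants", stratum)
            continue
        major, minor = tallies[stratum]
        if any(f.stratum == stratum for f in fractions):
            continue
        n = major + minor
        p = major / n
        denom = 1 + z**2 / n
        center = (p + z**2 / (2 * n)) / denom
        half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
        fractions.append(
            StratumFraction(stratum, major, n, p, center - half, center + half)
        )
    pairwise: dict[tuple[str, str], FisherResult] = {}
    names = [f.stratum for f in fractions]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = tallies[names[i]]
            c, d = tallies[names[j]]
            pairwise[(names[i], names[j])] = fisher_2x2(a, b, c, d)
    return StratifiedResult(fractions, pairwise)
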