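"""Chromatin-domain context of piRNA loci.

C-type piRNA clusters sit in repressed ("regulated", H3K27me3-type) domains
while P-type loci live in introns of actively transcribed (H3K36me3-type)
genes, so the chromatin environment is diagnostic of the biogenesis mode.
This module measures locus-domain overlap enrichment, assigns genes to
domain states by a 75%-coverage rule, transfers states across species via
1:1 orthologs, scores "genicness" against placement-randomization nulls,
and stratifies genes into expression groups by k-means on log RPKM.

A locus overlapping two domain states is assigned by its TSS position (loci
are 21 bp; the TSS is the biologically operative point).
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from pirnakit.core import Genome, GenomicInterval
from pirnakit.stats import FisherResult, fisher_2x2

logger = logging.getLogger(__name__)

STATES = ("active", "regulated", "other")


class DomainSet:
    """Labeled chromatin-domain intervals with fast point/overlap lookup.

    Overlapping input intervals are resolved at load time (first interval
    wins, the overlap of later ones is trimmed away) with a warning.
    """

    def __init__(self, intervals: list[GenomicInterval]):
        by_contig: dict[str, list[GenomicInterval]] = {}
        n_trimmed = 0
        for iv in sorted(intervals, key=lambda v: (v.contig, v.start, v.end)):
            row = by_contig.setdefault(iv.contig, [])
            start = iv.start
            if row and row[-1].end > start:
                start = row[-1].end
                n_trimmed += 1
            if start < iv.end:
                row.append(GenomicInterval(iv.contig, start, iv.end, ".", iv.name))
        if n_trimmed:
            logger.warning("trimmed %d overlapping domain intervals", n_trimmed)
        self._by_contig = by_contig
        self._starts = {
            c: [iv.start for iv in row] for c, row in by_contig.items()
        }
        self.span_by_state: dict[str, int] = {}
        for row in by_contig.values():
            for iv in row:
                self.span_by_state[iv.name] = (
                    self.span_by_state.get(iv.name, 0) + len(iv)
                )

    @property
    def states(self) -> list[str]:
        return sorted(self.span_by_state)

    def state_at(self, contig: str, position: int) -> str:
        """Domain state at a single position ('other' when uncovered)."""
        row = self._by_contig.get(contig)
        if not row:
            return "other"
        i = bisect_right(self._starts[contig], position) - 1
        if i >= 0 and row[i].start <= position < row[i].end:
            return row[i].name
        return "other"

    def coverage(self, interval: GenomicInterval) -> dict[str, int]:
        """bp of the interval covered by each state."""
        out: dict[str, int] = {}
        row = self._by_contig.get(interval.contig, [])
        starts = self._starts.get(interval.contig, [])
        i = max(bisect_right(starts, interval.start) - 1, 0)
        for iv in row[i:]:
            if iv.start >= interval.end:
                break
            ov = min(iv.end, interval.end) - max(iv.start, interval.start)
            if ov > 0:
                out[iv.name] = out.get(iv.name, 0) + ov
        return out


@dataclass
class StateEnrichment:
    state: str
    observed: int
    expected: float
    fold: float            # observed / expected; < 1 means depletion
    depletion_fold: float  # expected / observed (guarded)
    fisher: FisherResult
    guarded: bool          # zero-observed guard applied


def domain_overlap_enrichment(
    loci_positions: list[tuple[str, int]],
    domains: DomainSet,
    universe_span: int,
) -> list[StateEnrichment]:
    """Per-state observed vs expected locus counts under uniform placement
    across the universe, with a Fisher exact test on the (loci in state vs
    not) x (bp in state vs not) table.

    Loci are assigned to states by TSS position. A zero-observed state gets
    a guarded depletion fold (expected / 1, flagged) rather than infinity.
    """
    n = len(loci_positions)
    counts: dict[str, int] = {}
    for contig, pos in loci_positions:
        st = domains.state_at(contig, pos)
        counts[st] = counts.get(st, 0) + 1
    out = []
    for state in sorted(set(domains.states) | set(counts)):
        span = domains.span_by_state.get(state, 0)
        if state == "other":
            span = max(universe_span - sum(domains.span_by_state.values()), 0)
        if span == 0:
            continue
        expected = n * span / universe_span
        observed = counts.get(state, 0)
        guarded = observed == 0
        fold = observed / expected if expected > 0 else float("nan")
        depletion = expected / max(observed, 1)
        try:
            fisher = fisher_2x2(
                observed, n - observed, span, universe_span - span
            )
        except ValueError:
            # a state covering the whole universe (or holding every locus)
            # leaves the table degenerate: no evidence against uniformity
            fisher = FisherResult(float("nan"), 1.0, True)
        out.append(
            StateEnrichment(
                state, observed, expected, fold, depletion, fisher, guarded
            )
        )
    return out


def assign_gene_state(
    gene: GenomicInterval, domains: DomainSet, min_coverage: float = 0.75
) -> str:
    """Assign a gene to the domain state covering >= ``min_coverage`` of its
    length; 'unassigned' otherwise. Invariant to fragmentation of domains
    into adjacent pieces (coverage is summed per state)."""
    cov = domains.coverage(gene)
    for state, bp in cov.items():
        if bp >= min_coverage * len(gene):
            return state
    return "unassigned"


@dataclass
class OrthologyPrediction:
    predicted: dict[str, str]
    concordance: float | None      # vs direct assignment where both defined
    log2_odds_ratio: float | None  # piRNA association, active vs regulated
    fisher: FisherResult | None
    flagged: bool


def predict_states_by_orthology(
    target_genes: list[str],
    ortholog_table: dict[str, str],
    reference_states: dict[str, str],
    direct_states: dict[str, str] | None = None,
    pirna_genes: set[str] | None = None,
) -> OrthologyPrediction:
    """Transfer chromatin states to target genes from their 1:1 reference
    orthologs; optionally cross-check against direct assignments and compute
    the log2 odds ratio of piRNA-gene association in active vs regulated
    chromatin."""
    predicted = {}
    for gene in target_genes:
        ref = ortholog_table.get(gene)
        if ref is not None and ref in reference_states:
            predicted[gene] = reference_states[ref]
    concordance = None
    if direct_states:
        both = [
            g for g in predicted
            if direct_states.get(g) in ("active", "regulated")
        ]
        if both:
            agree = sum(predicted[g] == direct_states[g] for g in both)
            concordance = agree / len(both)
    log2_or = None
    fisher = None
    flagged = False
    if pirna_genes is not None:
        a = sum(
            1 for g, s in predicted.items() if s == "active" and g in pirna_genes
        )
        b = sum(
            1 for g, s in predicted.items() if s == "active" and g not in pirna_genes
        )
        c = sum(
            1 for g, s in predicted.items() if s == "regulated" and g in pirna_genes
        )
        d = sum(
            1 for g, s in predicted.items()
            if s == "regulated" and g not in pirna_genes
        )
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            # an empty margin leaves the odds ratio undefined
            flagged = True
        else:
            fisher = fisher_2x2(a, b, c, d)
            log2_or = float(np.log2(fisher.odds_ratio))
    return OrthologyPrediction(predicted, concordance, log2_or, fisher, flagged)


# --- genicness ---------------------------------------------------------------

@dataclass
class GenicnessResult:
    observed_ratio: float
    simulated_ratios: np.ndarray
    score: float       # G = log2(observed / median simulated)
    p_value: float     # empirical, +1 corrected
    direction: str     # 'genic' or 'intergenic'


class _GeneIndex:
    def __init__(self, genes: list[GenomicInterval]):
        self._by_contig: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        merged: dict[str, list[tuple[int, int]]] = {}
        for g in sorted(genes, key=lambda v: (v.contig, v.start)):
            row = merged.setdefault(g.contig, [])
            if row and g.start <= row[-1][1]:
                row[-1] = (row[-1][0], max(row[-1][1], g.end))
            else:
                row.append((g.start, g.end))
        for contig, row in merged.items():
            arr = np.array(row)
            self._by_contig[contig] = (arr[:, 0], arr[:, 1])
        self.genic_bp = {
            c: int((e - s).sum()) for c, (s, e) in self._by_contig.items()
        }

    def overlaps(self, contig: str, start: int, end: int) -> bool:
        if contig not in self._by_contig:
            return False
        starts, ends = self._by_contig[contig]
        i = np.searchsorted(starts, end, side="left") - 1
        return i >= 0 and ends[i] > start


def genicness_score(
    loci: list[GenomicInterval],
    genes: list[GenomicInterval],
    genome: Genome,
    n_sim: int = 100,
    scope: str = "genome",
    seed: int = 0,
    pseudocount: float = 0.5,
) -> GenicnessResult:
    """Genicness of locus placement versus a randomization null.

    G = log2( observed genic/intergenic ratio / median simulated ratio )
    over ``n_sim`` random placements preserving locus count and length
    (scope 'contig' re-places each locus within its contig of origin,
    controlling regional composition biases). Empirical p uses the +1
    correction and the side implied by the direction of the effect.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    index = _GeneIndex(genes)
    rng = np.random.default_rng(seed)
    contigs = list(genome)
    lengths = np.array([genome.lengths[c] for c in contigs], dtype=float)
    probs = lengths / lengths.sum()

    def ratio(items: list[tuple[str, int, int]]) -> float:
        genic = sum(index.overlaps(c, s, e) for c, s, e in items)
        inter = len(items) - genic
        return (genic + pseudocount) / (inter + pseudocount)

    observed = ratio([(l.contig, l.start, l.end) for l in loci])
    sims = np.empty(n_sim)
    for s in range(n_sim):
        placed = []
        for locus in loci:
            size = len(locus)
            if scope == "contig":
                contig = locus.contig
            else:
                contig = contigs[rng.choice(len(contigs), p=probs)]
            max_start = genome.lengths[contig] - size
            start = int(rng.integers(0, max(max_start, 0) + 1))
            placed.append((contig, start, start + size))
        sims[s] = ratio(placed)
    med = float(np.median(sims))
    score = float(np.log2(observed / med))
    if score >= 0:
        p = (1 + int((sims >= observed).sum())) / (n_sim + 1)
        direction = "genic"
    else:
        p = (1 + int((sims <= observed).sum())) / (n_sim + 1)
        direction = "intergenic"
    return GenicnessResult(observed, sims, score, float(p), direction)


# --- promoters ---------------------------------------------------------------

@dataclass
class PromoterEnrichment:
    window: int
    observed: int
    expected: float
    fold: float
    n_intergenic_loci: int
    n_skipped_genes: int


def promoter_association(
    loci: list[GenomicInterval],
    genes: list[GenomicInterval],
    genome: Genome,
    windows: tuple[int, ...] = (200, 500, 1000),
) -> list[PromoterEnrichment]:
    """Enrichment of intergenic piRNA loci in promoter windows upstream of
    first exons, relative to non-promoter intergenic space.

    Promoters are ``window`` bp strand-aware upstream of each gene start
    ([start-w, start) for + genes, [end, end+w) for - genes), clipped to the
    contig and to intergenic space. Unstranded genes are skipped and
    counted. Expected counts scale with the promoter share of intergenic bp.
    """
    index = _GeneIndex(genes)
    inter_loci = [
        l for l in loci if not index.overlaps(l.contig, l.start, l.end)
    ]
    out = []
    total_genic = sum(index.genic_bp.get(c, 0) for c in genome)
    intergenic_bp = genome.total_length - total_genic
    for w in windows:
        promoters: list[GenomicInterval] = []
        n_skipped = 0
        for g in genes:
            if g.strand == "+":
                lo, hi = g.start - w, g.start
            elif g.strand == "-":
                lo, hi = g.end, g.end + w
            else:
                n_skipped += 1
                continue
            lo = max(lo, 0)
            hi = min(hi, genome.lengths.get(g.contig, hi))
            if lo < hi:
                promoters.append(GenomicInterval(g.contig, lo, hi, ".", g.name))
        pindex = _GeneIndex(promoters)  # merged promoter intervals
        # promoter bp restricted to intergenic space
        promoter_bp = 0
        for contig, (starts, ends) in pindex._by_contig.items():
            for s, e in zip(starts, ends):
                cov = 0
                if contig in index._by_contig:
                    gs, ge = index._by_contig[contig]
                    for g0, g1 in zip(gs, ge):
                        ov = min(int(e), int(g1)) - max(int(s), int(g0))
                        if ov > 0:
                            cov += ov
                promoter_bp += int(e - s) - cov
        observed = sum(
            pindex.overlaps(l.contig, l.start, l.end) for l in inter_loci
        )
        expected = (
            len(inter_loci) * promoter_bp / intergenic_bp
            if intergenic_bp else float("nan")
        )
        fold = observed / expected if expected > 0 else float("nan")
        out.append(
            PromoterEnrichment(
                w, observed, expected, fold, len(inter_loci), n_skipped
            )
        )
    return out


# --- expression strata -------------------------------------------------------

@dataclass
class ExpressionStrata:
    labels: dict[str, str]   # gene -> {'high', 'low'}
    threshold_rpkm: float


def expression_strata(
    rpkm: dict[str, float], seed: int = 0, n_restarts: int = 10
) -> ExpressionStrata:
    """Split genes into high/low expression groups by k-means (k=2) on
    log2(RPKM + 0.1); the threshold is the midpoint of the cluster centers,
    back-transformed to RPKM."""
    if len(rpkm) < 10:
        raise ValueError("need at least 10 genes")
    names = sorted(rpkm)
    x = np.log2(np.array([rpkm[g] for g in names]) + 0.1).reshape(-1, 1)
    if np.ptp(x) < 1e-12:
        raise ValueError("constant expression input")
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed).fit(x)
    centers = km.cluster_centers_.ravel()
    high_cluster = int(np.argmax(centers))
    mid = centers.mean()
    labels = {
        g: ("high" if km.labels_[i] == high_cluster else "low")
        for i, g in enumerate(names)
    }
    return ExpressionStrata(labels, float(2**mid - 0.1))


@dataclass
class StateFraction:
    state: str
    n_expressed: int
    n_total: int
    fraction: float
    ci_low: float
    ci_high: float


def motif_expression_fraction(
    motif_states: dict[str, str],
    expressed: set[str],
) -> list[StateFraction]:
    """Per chromatin state, the fraction of motif sites with detectable 21U
    expression, with Wilson binomial confidence intervals."""
    from statistics import NormalDist

    z = NormalDist().inv_cdf(0.975)
    by_state: dict[str, list[str]] = {}
    for mid, state in motif_states.items():
        by_state.setdefault(state, []).append(mid)
    out = []
    for state in sorted(by_state):
        ids = by_state[state]
        n = len(ids)
        k = sum(1 for m in ids if m in expressed)
        p = k / n
        denom = 1 + z**2 / n
        center = (p + z**2 / (2 * n)) / denom
        half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
        out.append(StateFraction(state, k, n, p, center - half, center + half))
    return out
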