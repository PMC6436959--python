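"""Genomic clustering statistics for piRNA loci.

Two organizational modes exist in nematodes: C-type species concentrate
piRNA loci in a few large clusters (small span-90), while P-type species
disperse them across the genome (span-90 near genome size). Per-contig
enrichment is measured by an exact one-sided binomial test against uniform
placement; contigs ranked by significance yield a cumulative span curve
whose 90% point (span-90) summarizes clustering. Species are classified by
a two-component mixture of linear regressions of span-90 on locus count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from pirnakit.core import Genome
from pirnakit.stats import FisherResult, fisher_2x2


@dataclass
class ContigStats:
    contig: str
    length: int
    count: int
    expected_proportion: float
    p_value: float

    @property
    def density(self) -> float:
        return self.count / self.length if self.length else 0.0


def contig_enrichment(
    locus_contigs: list[str], genome: Genome
) -> list[ContigStats]:
    """Exact one-sided (greater) binomial p-value per contig for piRNA-count
    enrichment under uniform genome-wide placement."""
    n_total = len(locus_contigs)
    if n_total < 1:
        raise ValueError("need at least one locus")
    counts: dict[str, int] = {}
    for c in locus_contigs:
        counts[c] = counts.get(c, 0) + 1
    total_len = genome.total_length
    out = []
    for contig in genome:
        length = genome.lengths[contig]
        if length == 0:
            continue
        p_i = length / total_len
        k = counts.get(contig, 0)
        # P(K >= k) under Binomial(n_total, p_i)
        p = float(sps.binom.sf(k - 1, n_total, p_i)) if k > 0 else 1.0
        out.append(ContigStats(contig, length, k, p_i, min(p, 1.0)))
    return out


@dataclass
class SpanCurve:
    contigs: list[str]
    cumulative_span: np.ndarray
    cumulative_fraction: np.ndarray
    span90: int
    bh_flags: np.ndarray   # Benjamini-Hochberg significant at 0.05, per contig


def span_curve(stats: list[ContigStats], quantile: float = 0.9) -> SpanCurve:
    """Cumulative piRNA fraction versus cumulative span over contigs ordered
    by enrichment significance.

    Order: ascending p-value, ties broken by descending piRNA density then
    contig name. span90 is the cumulative span at the first contig where the
    cumulative locus fraction reaches ``quantile``.
    """
    if not stats:
        raise ValueError("no contig stats")
    ordered = sorted(stats, key=lambda s: (s.p_value, -s.density, s.contig))
    n_total = sum(s.count for s in ordered)
    spans = np.cumsum([s.length for s in ordered])
    fracs = np.cumsum([s.count for s in ordered]) / max(n_total, 1)
    reach = np.nonzero(fracs >= quantile - 1e-12)[0]
    span90 = int(spans[reach[0]]) if len(reach) else int(spans[-1])
    # BH flags as a user-facing annotation (the ranking itself uses raw p)
    ps = np.array([s.p_value for s in ordered])
    m = len(ps)
    order = np.argsort(ps)
    bh = np.zeros(m, dtype=bool)
    thresh = 0.05 * (np.arange(1, m + 1)) / m
    passing = np.nonzero(np.sort(ps) <= thresh)[0]
    if len(passing):
        bh[order[: passing[-1] + 1]] = True
    return SpanCurve([s.contig for s in ordered], spans, fracs, span90, bh)


@dataclass
class MixRegFit:
    intercepts: np.ndarray
    slopes: np.ndarray
    sigma: float
    weights: np.ndarray
    responsibilities: np.ndarray
    labels: np.ndarray
    log_likelihood: float
    degenerate: bool


def classify_clustering(
    n_pirnas: np.ndarray,
    span90: np.ndarray,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> MixRegFit:
    """Two-component mixture of linear regressions of span-90 on piRNA count
    (EM with random restarts, equal component variances).

    Species whose span-90 grows steeply with locus count (dispersed, P-type
    organization) separate from species on a shallow line (clustered,
    C-type). Assignment is the argmax responsibility. Near-collinear data
    where one component collapses (< 2 expected points) is flagged
    degenerate.
    """
    x = np.asarray(n_pirnas, dtype=float)
    y = np.asarray(span90, dtype=float)
    if len(x) < 6:
        raise ValueError("need at least 6 species points")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        resp = rng.uniform(size=len(x))
        resp = np.column_stack([resp, 1 - resp])
        ll_prev = -np.inf
        params = None
        for _ in range(max_iter):
            # M-step: weighted least squares per component, shared variance
            inter = np.zeros(2)
            slope = np.zeros(2)
            sse = 0.0
            ok = True
            for k in range(2):
                w = resp[:, k]
                sw = w.sum()
                if sw < 1e-8:
                    ok = False
                    break
                xm = (w * x).sum() / sw
                ym = (w * y).sum() / sw
                sxx = (w * (x - xm) ** 2).sum()
                if sxx < 1e-12:
                    slope[k] = 0.0
                else:
                    slope[k] = (w * (x - xm) * (y - ym)).sum() / sxx
                inter[k] = ym - slope[k] * xm
                sse += (w * (y - inter[k] - slope[k] * x) ** 2).sum()
            if not ok:
                break
            sigma2 = max(sse / len(x), 1e-12)
            weights = resp.mean(axis=0)
            # E-step
            logp = np.empty((len(x), 2))
            for k in range(2):
                mu = inter[k] + slope[k] * x
                logp[:, k] = (
                    np.log(max(weights[k], 1e-300))
                    - 0.5 * np.log(2 * np.pi * sigma2)
                    - 0.5 * (y - mu) ** 2 / sigma2
                )
            mx = logp.max(axis=1, keepdims=True)
            lse = mx.ravel() + np.log(np.exp(logp - mx).sum(axis=1))
            ll = float(lse.sum())
            resp = np.exp(logp - lse[:, None])
            params = (inter.copy(), slope.copy(), np.sqrt(sigma2),
                      weights.copy(), resp.copy(), ll)
            if abs(ll - ll_prev) < tol:
                break
            ll_prev = ll
        if params is not None and (best is None or params[5] > best[5]):
            best = params
    if best is None:
        raise RuntimeError("EM failed to fit any restart")
    inter, slope, sigma, weights, resp, ll = best
    labels = resp.argmax(axis=1)
    degenerate = (
        min(weights) * len(x) < 2.0
        or abs(slope[0] - slope[1]) * (x.max() - x.min())
        + abs(inter[0] - inter[1]) < 1e-6 * max(1.0, np.abs(y).max())
    )
    return MixRegFit(inter, slope, sigma, weights, resp, labels, ll, degenerate)


def map_contigs_to_reference(
    pirna_contig_genes: list[str],
    ortholog_table: list[tuple[str, str]],
    reference_gene_positions: dict[str, tuple[str, int]],
    reference_chrom_lengths: dict[str, int],
    bin_bp: int = 100_000,
) -> tuple[dict[str, np.ndarray], int]:
    """Density of reference-genome orthologs of genes on piRNA-enriched
    contigs, in fixed-width bins along each reference chromosome.

    ``ortholog_table`` holds (species_gene, reference_gene) pairs and must
    be strictly 1:1; violating rows are rejected and counted. Returns
    (per-chromosome bin counts, n_rejected).
    """
    from collections import Counter

    left = Counter(g for g, _ in ortholog_table)
    right = Counter(r for _, r in ortholog_table)
    clean = {}
    n_rejected = 0
    for g, r in ortholog_table:
        if left[g] == 1 and right[r] == 1:
            clean[g] = r
        else:
            n_rejected += 1
    tracks = {
        chrom: np.zeros(int(np.ceil(length / bin_bp)), dtype=int)
        for chrom, length in reference_chrom_lengths.items()
    }
    for gene in pirna_contig_genes:
        ref_gene = clean.get(gene)
        if ref_gene is None:
            continue
        pos = reference_gene_positions.get(ref_gene)
        if pos is None:
            continue
        chrom, bp = pos
        if chrom in tracks:
            tracks[chrom][min(bp // bin_bp, len(tracks[chrom]) - 1)] += 1
    return tracks, n_rejected


def x_depletion_test(
    has_pirna: np.ndarray, on_x: np.ndarray
) -> FisherResult:
    """Odds ratio and two-sided Fisher exact p for depletion of
    piRNA-containing genes from the X chromosome.

    Table: (piRNA, X) vs (piRNA, not-X) vs (no piRNA, X) vs (no piRNA,
    not-X); the Haldane +0.5 correction keeps the OR finite on zero cells.
    """
    has_pirna = np.asarray(has_pirna, dtype=bool)
    on_x = np.asarray(on_x, dtype=bool)
    a = int((has_pirna & on_x).sum())
    b = int((has_pirna & ~on_x).sum())
    c = int((~has_pirna & on_x).sum())
    d = int((~has_pirna & ~on_x).sum())
    return fisher_2x2(a, b, c, d)
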