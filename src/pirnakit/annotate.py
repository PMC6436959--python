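"""piRNA locus calling, precursor/cleavage-fragment extraction, and library
size-factor estimation.

A piRNA locus is a 21U read-mapping site whose strand-aware upstream window
contains a motif hit above the species threshold at the expected distance
(42 nt from motif start to 21U start by default, with a +/-5 nt tolerance).
The locus TSS sits 2 nt upstream of the mature 21U 5' end; capped precursor
reads start exactly at the TSS and are longer than 22 nt, while TFIIS-type
3' cleavage fragments map +28..+38 downstream of the TSS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from pirnakit.core import (
    Genome,
    GenomicInterval,
    ReadSite,
    extract_sequence,
    tss_of_21u,
    upstream_window,
)
from pirnakit.motif import PWM, MotifHit, scan_window

logger = logging.getLogger(__name__)


@dataclass
class PiRNALocus:
    """A called piRNA locus: 21U site, strand-aware TSS, and motif evidence."""

    id: str
    site_21u: GenomicInterval
    tss: int
    motif_score: float
    motif_distance: int   # motif start -> 21U start, nt
    chromatin_state: str = "unassigned"
    counts: dict = field(default_factory=dict)

    @property
    def strand(self) -> str:
        return self.site_21u.strand

    @property
    def contig(self) -> str:
        return self.site_21u.contig


@dataclass
class LocusCallResult:
    loci: list[PiRNALocus]
    n_excluded: int        # dropped for overlapping the exclusion set
    n_below_threshold: int
    n_outside_window: int


def _overlaps_any(iv: GenomicInterval, exclusion: list[GenomicInterval]) -> bool:
    for ex in exclusion:
        if ex.contig == iv.contig and iv.start < ex.end and ex.start < iv.end:
            return True
    return False


def scan_upstream_windows(
    sites: list[GenomicInterval],
    genome: Genome,
    pwm: PWM,
    up: int = 110,
    down: int = 30,
) -> list[tuple[GenomicInterval, MotifHit | None, int]]:
    """Scan the (up, down) window around each 21U site's 5' end.

    Returns (site, hit, distance) triples where distance is motif start ->
    21U start in nt on the transcribed strand (hit offset measured from the
    window start, windows clipped at contig edges are handled).
    """
    out = []
    for site in sites:
        win = upstream_window(site, up, down, genome)
        seq = extract_sequence(genome, win.interval)
        if len(seq) < pwm.width:
            out.append((site, None, 0))
            continue
        hit = scan_window(pwm, seq, site.name)
        if hit is None:
            out.append((site, None, 0))
            continue
        # upstream extent actually present after clipping
        if site.strand == "+":
            up_eff = site.start - win.interval.start
        else:
            up_eff = win.interval.end - site.end
        distance = up_eff - hit.offset
        out.append((site, hit, distance))
    return out


def call_pirna_loci(
    scanned: list[tuple[GenomicInterval, MotifHit | None, int]],
    threshold: float,
    offset_center: int = 42,
    offset_tolerance: int = 5,
    exclusion: list[GenomicInterval] | None = None,
) -> LocusCallResult:
    """Call piRNA loci from scanned 21U sites.

    A locus is emitted iff the best motif score reaches ``threshold`` and
    the motif-start -> 21U-start distance lies within ``offset_center +/-
    offset_tolerance``. Loci overlapping the exclusion set (snRNA/snoRNA and
    other non-coding RNA genes) are dropped and counted.
    """
    exclusion = exclusion or []
    loci: list[PiRNALocus] = []
    n_excluded = n_below = n_outside = 0
    for site, hit, distance in sorted(
        scanned, key=lambda t: (t[0].contig, t[0].start, t[0].strand)
    ):
        if hit is None or hit.score < threshold:
            n_below += 1
            continue
        if abs(distance - offset_center) > offset_tolerance:
            n_outside += 1
            continue
        if _overlaps_any(site, exclusion):
            n_excluded += 1
            continue
        loci.append(
            PiRNALocus(
                id=site.name if site.name != "." else
                f"{site.contig}:{site.start}:{site.strand}",
                site_21u=site,
                tss=tss_of_21u(site),
                motif_score=hit.score,
                motif_distance=distance,
            )
        )
    if n_excluded:
        logger.info("removed %d loci overlapping the exclusion set", n_excluded)
    return LocusCallResult(loci, n_excluded, n_below, n_outside)


# --- precursors and cleavage fragments ---------------------------------------

def _read_five_prime(read: ReadSite) -> int:
    return read.interval.five_prime


def extract_precursors(
    capped_reads: list[ReadSite],
    loci: list[PiRNALocus],
    min_length: int = 23,
) -> dict[str, list[tuple[int, int]]]:
    """Capped precursor reads per locus: same strand, 5' end exactly at the
    TSS, length > 22 nt (>= ``min_length``). Returns per-locus
    (length, count) pairs."""
    by_key: dict[tuple[str, str, int], str] = {}
    for locus in loci:
        by_key[(locus.contig, locus.strand, locus.tss)] = locus.id
    out: dict[str, list[tuple[int, int]]] = {locus.id: [] for locus in loci}
    for read in capped_reads:
        if read.length < min_length:
            continue
        key = (read.interval.contig, read.interval.strand, _read_five_prime(read))
        locus_id = by_key.get(key)
        if locus_id is not None:
            out[locus_id].append((read.length, read.count))
    return out


@dataclass
class CleavageCounts:
    per_locus_reads: dict[str, int]
    per_locus_unique: dict[str, int]
    normalized_reads: dict[str, float]    # per million non-structural reads
    normalized_unique: dict[str, float]


def extract_cleavage_fragments(
    monop_reads: list[ReadSite],
    loci: list[PiRNALocus],
    total_nonstructural: int,
    unique_nonstructural: int,
    window: tuple[int, int] = (28, 38),
    min_length: int = 11,
    sequences_21u: set[str] | None = None,
    read_sequences: dict[int, str] | None = None,
) -> CleavageCounts:
    """3' cleavage fragments per locus.

    All 21U reads are removed first (by exact sequence match when sequences
    are supplied, else by the 21-nt-at-21U-site signature); then uniquely
    mapping reads longer than 10 nt whose 5' end lies at TSS+28..TSS+38 are
    counted. Counts are normalized to total non-structural reads, and
    unique-sequence counts to unique non-structural totals (per million).
    """
    for read in monop_reads:
        if read.unique_mapping is None:
            raise ValueError("cleavage extraction requires uniqueness flags")
    site_21u_keys = {
        (l.contig, l.strand, l.site_21u.five_prime) for l in loci
    }
    lo, hi = window
    locus_by_contig: dict[tuple[str, str], list[PiRNALocus]] = {}
    for locus in loci:
        locus_by_contig.setdefault((locus.contig, locus.strand), []).append(locus)
    reads_ct: dict[str, int] = {l.id: 0 for l in loci}
    uniq_ct: dict[str, int] = {l.id: 0 for l in loci}
    seen_unique: dict[str, set] = {l.id: set() for l in loci}
    for i, read in enumerate(monop_reads):
        # remove 21U reads first
        if read_sequences is not None and sequences_21u is not None:
            if read_sequences.get(i) in sequences_21u:
                continue
        elif (
            read.length == 21
            and (read.interval.contig, read.interval.strand,
                 _read_five_prime(read)) in site_21u_keys
        ):
            continue
        if not read.unique_mapping or read.length < min_length:
            continue
        fp = _read_five_prime(read)
        for locus in locus_by_contig.get(
            (read.interval.contig, read.interval.strand), []
        ):
            if locus.strand == "+":
                rel = fp - locus.tss
            else:
                rel = locus.tss - fp
            if lo <= rel <= hi:
                reads_ct[locus.id] += read.count
                sig = (fp, read.length)
                if sig not in seen_unique[locus.id]:
                    seen_unique[locus.id].add(sig)
                    uniq_ct[locus.id] += 1
    scale_r = 1e6 / total_nonstructural if total_nonstructural else 0.0
    scale_u = 1e6 / unique_nonstructural if unique_nonstructural else 0.0
    return CleavageCounts(
        reads_ct,
        uniq_ct,
        {k: v * scale_r for k, v in reads_ct.items()},
        {k: v * scale_u for k, v in uniq_ct.items()},
    )


# --- size factors ------------------------------------------------------------

@dataclass
class SizeFactors:
    factors: np.ndarray
    method: str
    slope_interval: tuple[float, float] | None = None


def size_factors_median_ratios(count_matrix: np.ndarray) -> SizeFactors:
    """Median-of-ratios size factors (the DESeq approach) over reference
    genes (rows = genes, columns = libraries). Genes with a zero in any
    library are excluded from the reference ratios."""
    counts = np.asarray(count_matrix, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("need a genes x libraries matrix with >= 2 libraries")
    nonzero = (counts > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("no gene is nonzero in all libraries")
    ref = counts[nonzero]
    log_geo_mean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geo_mean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return SizeFactors(factors, "median_of_ratios")


def size_factors_slope(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    through_origin: bool = True,
) -> SizeFactors:
    """Slope-based size factor for a library pair from shared reference-gene
    counts: OLS slope of B on A with a +/- 1.96 SE interval."""
    x = np.asarray(counts_a, dtype=float)
    y = np.asarray(counts_b, dtype=float)
    if len(x) != len(y) or len(x) < 10:
        raise ValueError("need >= 10 shared genes")
    if not x.any() or not y.any():
        raise ValueError("degenerate all-zero input")
    if through_origin:
        sxx = float(x @ x)
        slope = float(x @ y) / sxx
        resid = y - slope * x
        dof = len(x) - 1
        se = np.sqrt(float(resid @ resid) / dof / sxx) if dof else 0.0
    else:
        res = sps.linregress(x, y)
        slope, se = float(res.slope), float(res.stderr)
    return SizeFactors(
        np.array([1.0, slope]),
        "slope",
        (slope - 1.96 * se, slope + 1.96 * se),
    )
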