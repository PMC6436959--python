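"""Synthetic species bundles with planted ground truth.

Generates genomes, chromatin domains, gene models, ortholog tables, strain
SNP panels and small-RNA libraries that emulate the two nematode piRNA
organization modes:

* C-type — loci concentrated in large repressed ("regulated") chromatin
  blocks confined to at most two contigs (cluster organization);
* P-type — loci dispersed genome-wide inside introns of genes lying in
  active chromatin.

Every planted locus carries the universal geometry: an upstream promoter
motif whose start lies ``motif_offset`` (42) nt upstream of the mature 21U
5' end, a TSS 2 nt upstream of the 21U, a GC-rich tract over the transcript
body (TSS..+19 in window coordinates) and an AT-rich low-Tm "valley"
downstream whose depth is drawn per-locus from ``tm_valley_depth_range`` —
deeper valleys yield shorter, more abundant capped precursors.

The generator is fully deterministic given (config, seed); the truth table
records every planted property for parameter-recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pirnakit.core import Genome, GenomicInterval, ReadSite, reverse_complement
from pirnakit.motif import PWM, build_pwm
from pirnakit.selection import SNPRecord

RUBY_CONSENSUS = "CGTTACTGTTTCA"  # GTTTC core with a 5' extension

#: transcript-frame geometry relative to the 21U 5' end (u = 0)
TSS_OFFSET = -2           # TSS sits 2 nt upstream of the mature 21U
HIGH_GC_SPAN = (-2, 18)   # GC-rich transcript body (window starts 0..19)
VALLEY_SPAN = (18, 49)    # AT-rich tract: windows starting +20..+40 lie inside


def ruby_like_pwm(
    background: np.ndarray | None = None,
    n_sites: int = 50,
    site_mutation_rate: float = 0.08,
    seed: int = 0,
) -> PWM:
    """A Ruby-motif-like PWM built from near-consensus site sequences.

    Sites carry independent per-position mutations at ``site_mutation_rate``
    so single-mismatch motif instances keep a clearly above-background
    score (real motif columns are informative but not absolute).
    """
    rng = np.random.default_rng(seed)
    q = np.array([0.32, 0.18, 0.18, 0.32]) if background is None else background
    sites = []
    for _ in range(n_sites):
        s = list(RUBY_CONSENSUS)
        for pos in range(len(s)):
            if rng.random() < site_mutation_rate:
                s[pos] = "ACGT"[int(rng.integers(4))]
        sites.append("".join(s))
    return build_pwm(sites, q, pseudocount=1.0)


@dataclass
class SpeciesConfig:
    """Study conditions for one synthetic species."""

    n_contigs: int = 10
    contig_length_bp: int = 1_000_000
    mode: str = "C-type"           # {C-type, P-type, intermediate}
    n_pirna_loci: int = 500
    motif_offset: int = 42         # motif start -> 21U start, nt
    tm_valley_depth_range: tuple[float, float] = (3.0, 18.0)
    valley_shift: int = 0          # extra nt the valley sits downstream
    domain_fraction_regulated: float = 0.6   # of each cluster contig (C-type)
    gene_density_per_mb: float = 60.0
    gc_content: float = 0.36       # nematode-like background
    high_gc_fraction: float = 0.50  # base GC of the transcript body tract
    cluster_fraction: float = 0.95  # C-type loci placed in the clusters
    intronic_fraction: float = 0.90  # P-type loci placed in introns
    mutate_motif_prob: float = 0.20  # chance a planted motif has 1 mismatch
    seed: int = 0


@dataclass
class SpeciesBundle:
    config: SpeciesConfig
    genome: Genome
    domain_intervals: list[GenomicInterval]   # name = state
    genes: list[GenomicInterval]              # name = gene id, stranded
    introns: list[GenomicInterval]            # name = host gene id
    ortholog_pairs: list[tuple[str, str]]     # (species gene, reference gene)
    reference_states: dict[str, str]          # reference gene -> state
    reference_gene_positions: dict[str, tuple[str, int]]
    truth: pd.DataFrame
    pwm: PWM

    @property
    def sites_21u(self) -> list[GenomicInterval]:
        out = []
        for row in self.truth.itertuples():
            if row.strand == "+":
                iv = GenomicInterval(row.contig, row.u_start, row.u_start + 21,
                                     "+", row.locus_id)
            else:
                iv = GenomicInterval(row.contig, row.u_start - 20, row.u_start + 1,
                                     "-", row.locus_id)
            out.append(iv)
        return out


def _random_genome(
    rng: np.random.Generator, n_contigs: int, length: int, gc: float
) -> dict[str, np.ndarray]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return {
        f"contig_{i+1:02d}": rng.choice(
            np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p
        )
        for i in range(n_contigs)
    }


def _plant(
    arr: np.ndarray, pos5: int, strand: str, text: str
) -> None:
    """Write ``text`` into the contig byte array starting at transcript
    position ``pos5`` and extending downstream on ``strand``."""
    enc = text.encode()
    if strand == "+":
        arr[pos5 : pos5 + len(enc)] = np.frombuffer(enc, dtype=np.uint8)
    else:
        rc = reverse_complement(text).encode()
        arr[pos5 - len(enc) + 1 : pos5 + 1] = np.frombuffer(rc, dtype=np.uint8)


def _structured_tract(
    rng: np.random.Generator, length: int, gc: float
) -> str:
    """A tract with ``gc`` G+C content whose G/C bases are evenly spaced,
    so every sliding window sees close to the tract-wide composition (the
    planted Tm signal is a composition signal, not an arrangement signal)."""
    n_gc = int(round(length * gc))
    bases = np.array(
        ["A" if rng.random() < 0.5 else "T" for _ in range(length)]
    )
    if n_gc > 0:
        idx = np.unique(np.round(np.linspace(0, length - 1, n_gc)).astype(int))
        for i in idx:
            bases[i] = "G" if rng.random() < 0.5 else "C"
    return "".join(bases)


def _mutated_consensus(rng: np.random.Generator, prob: float) -> str:
    s = RUBY_CONSENSUS
    if rng.random() < prob:
        pos = int(rng.integers(len(s)))
        choices = [b for b in "ACGT" if b != s[pos]]
        s = s[:pos] + choices[int(rng.integers(3))] + s[pos + 1 :]
    return s


def _slot_positions(
    regions: list[GenomicInterval], n: int, spacing: int,
    margin: int, rng: np.random.Generator, footprint: int = 120,
) -> list[tuple[str, int]]:
    """Deterministically pack ``n`` positions into regions, at least
    ``spacing`` bp apart, ``margin`` bp from region edges, each leaving
    ``footprint`` bp of room inside the region."""
    slots: list[tuple[str, int]] = []
    for region in regions:
        usable = len(region) - 2 * margin - footprint
        if usable < 0:
            continue
        capacity = usable // spacing + 1
        for k in range(capacity):
            slots.append((region.contig, region.start + margin + k * spacing))
    if len(slots) < n:
        raise ValueError(
            f"infeasible packing: {n} loci requested, {len(slots)} slots "
            f"available"
        )
    order = rng.permutation(len(slots))[:n]
    return [slots[i] for i in sorted(order)]


def _depth_fraction(depth: float, depth_range: tuple[float, float]) -> float:
    lo, hi = depth_range
    if hi <= lo:
        return 0.0
    return min(max((depth - lo) / (hi - lo), 0.0), 1.0)


def _valley_tract(rng: np.random.Generator, length: int, t: float) -> str:
    """A pure A/T tract whose duplex stability falls monotonically with
    ``t`` in [0, 1].

    Nearest-neighbor thermodynamics make TA/AT stacks melt far below AA/TT
    runs of identical composition, so the planted valley depth is encoded
    in the alternation probability rather than in base composition: shallow
    valleys are run-rich (near-background stability), deep valleys are
    alternation-rich (strongly destabilized).
    """
    p_alt = 0.05 + 0.95 * t
    bases = ["A" if rng.random() < 0.5 else "T"]
    for _ in range(length - 1):
        prev = bases[-1]
        if rng.random() < p_alt:
            bases.append("T" if prev == "A" else "A")
        else:
            bases.append(prev)
    return "".join(bases)


def _depth_to_high_gc(depth: float, depth_range: tuple[float, float],
                      base: float) -> float:
    """The high-Tm bump over the transcript body scales with the same
    planted signature strength as the valley: one pausing-signal knob."""
    t = _depth_fraction(depth, depth_range)
    return min(base + 0.25 * t, 1.0)


def generate_species(config: SpeciesConfig) -> SpeciesBundle:
    """Generate a full synthetic species bundle with planted ground truth."""
    rng = np.random.default_rng(config.seed)
    contigs = _random_genome(
        rng, config.n_contigs, config.contig_length_bp, config.gc_content
    )
    names = list(contigs)
    L = config.contig_length_bp

    # --- chromatin domains ---------------------------------------------------
    domain_intervals: list[GenomicInterval] = []
    if config.mode == "C-type":
        n_cluster = min(2, config.n_contigs)
        cluster_contigs = names[:n_cluster]
        for c in names:
            if c in cluster_contigs:
                reg_span = int(config.domain_fraction_regulated * L)
                lo = (L - reg_span) // 2
                if lo > 0:
                    domain_intervals.append(GenomicInterval(c, 0, lo, ".", "active"))
                domain_intervals.append(
                    GenomicInterval(c, lo, lo + reg_span, ".", "regulated")
                )
                if lo + reg_span < L:
                    domain_intervals.append(
                        GenomicInterval(c, lo + reg_span, L, ".", "active")
                    )
            else:
                domain_intervals.append(GenomicInterval(c, 0, L, ".", "active"))
    else:
        # P-type / intermediate: alternating blocks, regulated minority
        block = max(L // 10, 1000)
        reg_frac = 0.3 if config.mode == "P-type" else 0.5
        for c in names:
            pos = 0
            i = 0
            while pos < L:
                end = min(pos + block, L)
                state = "regulated" if (i % 10) < int(reg_frac * 10) else "active"
                domain_intervals.append(GenomicInterval(c, pos, end, ".", state))
                pos = end
                i += 1

    def domain_state_at(contig: str, pos: int) -> str:
        for iv in domain_intervals:
            if iv.contig == contig and iv.start <= pos < iv.end:
                return iv.name
        return "other"

    # --- genes (3 exons / 2 introns) inside active domains -------------------
    exon_len, intron_len = 200, 500
    gene_len = 3 * exon_len + 2 * intron_len
    n_genes_target = int(config.gene_density_per_mb * config.n_contigs * L / 1e6)
    if config.mode in ("P-type", "intermediate"):
        # enough host introns (2 per gene) for the intronic loci
        needed = int(np.ceil(config.intronic_fraction * config.n_pirna_loci / 2))
        n_genes_target = max(n_genes_target, needed + 4)
    active_regions = [iv for iv in domain_intervals if iv.name == "active"]
    gene_spacing = max(
        gene_len + 400,
        int(sum(len(r) for r in active_regions) / max(n_genes_target, 1)),
    )
    capacity = sum(
        max((len(r) - 800 - gene_len), -gene_spacing) // gene_spacing + 1
        for r in active_regions
    )
    gene_slots = _slot_positions(
        active_regions, min(n_genes_target, max(capacity, 0)),
        gene_spacing, 400, rng, footprint=gene_len,
    )
    genes: list[GenomicInterval] = []
    introns: list[GenomicInterval] = []
    for gi, (contig, start) in enumerate(gene_slots):
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"g{gi+1:05d}"
        genes.append(GenomicInterval(contig, start, start + gene_len, strand, gid))
        for k in range(2):
            ist = start + exon_len + k * (exon_len + intron_len)
            introns.append(
                GenomicInterval(contig, ist, ist + intron_len, strand, gid)
            )

    # --- piRNA locus placement ----------------------------------------------
    spacing, margin = 160, 260
    placements: list[tuple[str, int, str, bool]] = []  # contig, u_start, strand, intronic
    n = config.n_pirna_loci
    if n > 0:
        if config.mode == "C-type":
            n_in = int(round(config.cluster_fraction * n))
            reg_regions = [
                iv for iv in domain_intervals if iv.name == "regulated"
            ]
            for contig, pos in _slot_positions(reg_regions, n_in, spacing, margin, rng):
                placements.append((contig, pos, "+" if rng.random() < 0.5 else "-", False))
            out_regions = [
                iv for iv in domain_intervals
                if iv.name == "active" and iv.contig not in {r.contig for r in reg_regions}
            ]
            n_out = n - n_in
            if n_out:
                # sparse background loci in intergenic active space
                for contig, pos in _slot_positions(
                    out_regions, n_out, spacing * 40, margin, rng
                ):
                    placements.append(
                        (contig, pos, "+" if rng.random() < 0.5 else "-", False)
                    )
        elif config.mode in ("P-type", "intermediate"):
            n_in = int(round(config.intronic_fraction * n))
            if len(introns) < n_in:
                raise ValueError(
                    f"infeasible packing: {n_in} intronic loci requested but "
                    f"only {len(introns)} introns available"
                )
            chosen = rng.permutation(len(introns))[:n_in]
            for idx in sorted(chosen):
                intron = introns[idx]
                # keep the locus geometry inside the intron
                u = intron.start + intron_len // 2
                placements.append((intron.contig, u, intron.strand, True))
            n_out = n - n_in
            if n_out:
                inter_regions = [
                    GenomicInterval(c, 0, L, ".", "x") for c in names
                ]
                for contig, pos in _slot_positions(
                    inter_regions, n_out, spacing * 50,
                    margin + 5000, rng,
                ):
                    placements.append(
                        (contig, pos, "+" if rng.random() < 0.5 else "-", False)
                    )
        else:
            raise ValueError(f"unknown mode {config.mode!r}")

    # --- plant sequence features and build the truth table -------------------
    depth_lo, depth_hi = config.tm_valley_depth_range
    pwm = ruby_like_pwm(seed=1)
    rows = []
    for li, (contig, u, strand, intronic) in enumerate(placements):
        arr = contigs[contig]
        depth = float(rng.uniform(depth_lo, depth_hi))
        motif_seq = _mutated_consensus(rng, config.mutate_motif_prob)
        sign = 1 if strand == "+" else -1

        def tpos(offset: int) -> int:
            return u + sign * offset

        _plant(arr, tpos(-config.motif_offset), strand, motif_seq)
        # GC-rich transcript body, then the 5' U of the mature 21U
        hi_lo, hi_hi = HIGH_GC_SPAN
        _plant(arr, tpos(hi_lo), strand,
               _structured_tract(
                   rng, hi_hi - hi_lo,
                   _depth_to_high_gc(depth, config.tm_valley_depth_range,
                                     config.high_gc_fraction)))
        _plant(arr, tpos(0), strand, "T")
        v_lo, v_hi = VALLEY_SPAN
        v_lo += config.valley_shift
        v_hi += config.valley_shift
        _plant(arr, tpos(v_lo), strand,
               _valley_tract(
                   rng, v_hi - v_lo,
                   _depth_fraction(depth, config.tm_valley_depth_range)))
        tss = tpos(TSS_OFFSET)
        rows.append({
            "locus_id": f"p{li+1:05d}",
            "contig": contig,
            "u_start": u,
            "strand": strand,
            "tss": tss,
            "planted_motif_score": float(pwm.score(motif_seq)),
            "chromatin_state": domain_state_at(contig, tss),
            "intronic": bool(intronic),
            "valley_depth": depth,
            "mode": config.mode,
            "seed": config.seed,
        })
    truth = pd.DataFrame(
        rows,
        columns=[
            "locus_id", "contig", "u_start", "strand", "tss",
            "planted_motif_score", "chromatin_state", "intronic",
            "valley_depth", "mode", "seed",
        ],
    )

    genome = Genome({c: arr.tobytes().decode() for c, arr in contigs.items()})

    # --- ortholog table to a virtual reference species ------------------------
    ortholog_pairs = [(g.name, f"ceg{gi+1:05d}") for gi, g in enumerate(genes)]
    pirna_tss = truth[["contig", "tss"]].itertuples(index=False)
    reference_states = {}
    reference_gene_positions = {}
    for (gname, ref), gene in zip(ortholog_pairs, genes):
        reference_states[ref] = domain_state_at(gene.contig, gene.start)
        # reference positions laid out on 5 virtual chromosomes
        chrom = f"refchr_{int(ref[3:]) % 5 + 1}"
        reference_gene_positions[ref] = (chrom, (int(ref[3:]) * 7919) % 5_000_000)
    return SpeciesBundle(
        config, genome, domain_intervals, genes, introns,
        ortholog_pairs, reference_states, reference_gene_positions,
        truth, pwm,
    )


# --- small RNA libraries -----------------------------------------------------

@dataclass
class LibraryConfig:
    """Per-library simulation settings for small-RNA read tables."""

    scale: float = 1.0             # library-wide depth factor
    mean_21u_count: float = 50.0
    precursor_rate_range: tuple[float, float] = (3.0, 30.0)  # reads per locus
    geometric_p_range: tuple[float, float] = (0.08, 0.75)
    max_precursor_len: int = 100
    n_mirna_genes: int = 50
    mirna_mean_range: tuple[float, float] = (20.0, 2000.0)
    n_rrna_fragments: int = 3000
    n_noise_21u_sites: int = 100   # 21-nt sites without planted motifs
    seed: int = 0


@dataclass
class SmallRNALibrary:
    reads_21u: list[ReadSite]
    capped: list[ReadSite]
    mirna_counts: dict[str, int]
    rrna_lengths: np.ndarray
    noise_site_ids: set[str]
    config: LibraryConfig


def _depth_fraction(depth: float, rng_range: tuple[float, float]) -> float:
    lo, hi = rng_range
    return 0.0 if hi <= lo else min(max((depth - lo) / (hi - lo), 0.0), 1.0)


def simulate_small_rna_libraries(
    bundle: SpeciesBundle,
    lib_config: LibraryConfig,
    mirna_means: np.ndarray | None = None,
) -> SmallRNALibrary:
    """Simulate one small-RNA library for a species bundle.

    * 21U reads: 21 nt starting at TSS+2 on the transcribed strand (5' U by
      construction), Poisson counts around ``mean_21u_count`` x scale.
    * Capped precursors: 5' end exactly at the TSS; lengths 28 +
      Geometric(p) truncated at ``max_precursor_len``, with p increasing
      and per-locus read number increasing in planted valley depth
      (shallow valley -> longer, rarer precursors).
    * miRNA counts: Poisson around fixed per-gene means times scale.
    * rRNA fragments: lognormal length distribution independent of genotype.
    * Noise 21U sites: background 21-mers with no planted motif, for
      specificity testing.
    """
    cfg = lib_config
    rng = np.random.default_rng(cfg.seed)
    depth_range = bundle.config.tm_valley_depth_range
    reads_21u: list[ReadSite] = []
    capped: list[ReadSite] = []
    p_lo, p_hi = cfg.geometric_p_range
    r_lo, r_hi = cfg.precursor_rate_range
    for row in bundle.truth.itertuples():
        t = _depth_fraction(row.valley_depth, depth_range)
        count = int(rng.poisson(cfg.mean_21u_count * cfg.scale * (0.5 + t)))
        if row.strand == "+":
            iv = GenomicInterval(row.contig, row.u_start, row.u_start + 21,
                                 "+", row.locus_id)
        else:
            iv = GenomicInterval(row.contig, row.u_start - 20, row.u_start + 1,
                                 "-", row.locus_id)
        reads_21u.append(ReadSite(iv, max(count, 1), "monophosphate", True))
        # precursors: deeper valley -> higher release rate, shorter length
        p_geo = p_lo + (p_hi - p_lo) * t
        n_prec = int(rng.poisson((r_lo + (r_hi - r_lo) * t) * cfg.scale))
        lengths = 28 + rng.geometric(p_geo, size=n_prec)
        lengths = np.minimum(lengths, cfg.max_precursor_len)
        for length, ct in zip(*np.unique(lengths, return_counts=True)):
            length = int(length)
            if row.strand == "+":
                piv = GenomicInterval(row.contig, row.tss, row.tss + length,
                                      "+", row.locus_id)
            else:
                piv = GenomicInterval(row.contig, row.tss - length + 1,
                                      row.tss + 1, "-", row.locus_id)
            capped.append(ReadSite(piv, int(ct), "capped", True))
    # background noise 21U sites away from planted loci
    noise_ids: set[str] = set()
    planted = {
        (row.contig, row.u_start) for row in bundle.truth.itertuples()
    }
    names = list(bundle.genome)
    L = bundle.genome.lengths[names[0]]
    attempts = 0
    while len(noise_ids) < cfg.n_noise_21u_sites and attempts < 50 * cfg.n_noise_21u_sites:
        attempts += 1
        contig = names[int(rng.integers(len(names)))]
        pos = int(rng.integers(300, bundle.genome.lengths[contig] - 300))
        if any(
            c == contig and abs(pos - u) < 200 for c, u in planted
        ):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        nid = f"noise{len(noise_ids)+1:05d}"
        noise_ids.add(nid)
        if strand == "+":
            iv = GenomicInterval(contig, pos, pos + 21, "+", nid)
        else:
            iv = GenomicInterval(contig, pos - 20, pos + 1, "-", nid)
        reads_21u.append(ReadSite(iv, int(rng.poisson(3)) + 1, "monophosphate", True))
    # miRNA and rRNA
    if mirna_means is None:
        mean_rng = np.random.default_rng(bundle.config.seed + 977)
        mirna_means = np.exp(
            mean_rng.uniform(
                np.log(cfg.mirna_mean_range[0]), np.log(cfg.mirna_mean_range[1]),
                size=cfg.n_mirna_genes,
            )
        )
    mirna_counts = {
        f"mir-{i+1:03d}": int(rng.poisson(m * cfg.scale))
        for i, m in enumerate(mirna_means)
    }
    rrna_lengths = np.clip(
        np.round(np.exp(rng.normal(np.log(30), 0.25, size=cfg.n_rrna_fragments))),
        18, 80,
    ).astype(int)
    return SmallRNALibrary(
        reads_21u, capped, mirna_counts, rrna_lengths, noise_ids, cfg
    )


# --- strain SNP panels -------------------------------------------------------

def simulate_strain_panel(
    bundle: SpeciesBundle,
    n_strains: int = 40,
    snp_rate: float = 5e-4,
    motif_snp_rate: float = 0.05,
    motif_disruption_bias: float = 0.0,
    constrained_states: tuple[str, ...] = ("regulated",),
    seed: int = 0,
) -> list[SNPRecord]:
    """Simulate a multi-strain SNP panel.

    Background SNPs are placed genome-wide at ``snp_rate`` per bp with
    alternate-allele strain counts uniform over 0..n_strains. Within planted
    motifs, extra SNPs appear at ``motif_snp_rate`` per motif bp; in loci
    whose chromatin state is in ``constrained_states`` the (disruptive)
    alternate allele is pushed to low strain frequency with probability
    ``motif_disruption_bias`` — emulating purifying selection on cluster
    piRNA motifs. ``bias=0`` is an exchangeable null.
    """
    if n_strains < 2:
        raise ValueError("need at least 2 strains")
    rng = np.random.default_rng(seed)
    snps: list[SNPRecord] = []

    def uniform_freq() -> float:
        return int(rng.integers(0, n_strains + 1)) / n_strains

    def low_freq() -> float:
        k_max = max(int(0.1 * n_strains) - 1, 0)
        return int(rng.integers(0, k_max + 1)) / n_strains

    for contig in bundle.genome:
        seq = bundle.genome.sequence(contig)
        n_bg = rng.binomial(len(seq), snp_rate)
        for pos in sorted(rng.integers(0, len(seq), size=n_bg).tolist()):
            ref = seq[pos]
            if ref not in "ACGT":
                continue
            alt = "ACGT"[(("ACGT".index(ref)) + 1 + int(rng.integers(3))) % 4]
            snps.append(SNPRecord(contig, int(pos), ref, alt, uniform_freq()))
    motif_w = len(RUBY_CONSENSUS)
    for row in bundle.truth.itertuples():
        sign = 1 if row.strand == "+" else -1
        seq = bundle.genome.sequence(row.contig)
        constrained = row.chromatin_state in constrained_states
        for k in range(motif_w):
            if rng.random() >= motif_snp_rate:
                continue
            pos = row.u_start + sign * (-bundle.config.motif_offset + k)
            ref = seq[pos]
            if ref not in "ACGT":
                continue
            alt = "ACGT"[(("ACGT".index(ref)) + 1 + int(rng.integers(3))) % 4]
            if constrained and rng.random() < motif_disruption_bias:
                f = low_freq()
            else:
                f = uniform_freq()
            snps.append(SNPRecord(row.contig, int(pos), ref, alt, f))
    return snps
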