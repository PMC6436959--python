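# Methods

This note documents the models, numerical choices and limitations behind
`pirnakit`, in the package's own terms. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Locus model and coordinate conventions

All coordinates are 0-based half-open internally; GFF3 is converted at the
I/O boundary (start − 1). A piRNA locus is anchored at its mature 21U
5′ end `u`; the TSS is `u − 2` strand-aware, and the upstream Ruby-motif
start is expected `42` nt upstream of `u` (motif start → 21U start; the
alternative motif-end convention is exposed via the offset parameter).
Upstream scan windows default to 110 bp upstream / 30 bp downstream of
`u`, extracted on the transcribed strand; windows are never scanned on both
strands. Windows containing N are scored only at N-free offsets; fully
masked windows return a no-hit sentinel and the locus cannot be called.

## Motif scoring and thresholding

PWMs are log2-odds against an explicit background (genome-wide base
frequencies in the pipeline). Construction from aligned sites uses
`log2((count + pc·q_b)/(n + pc)/q_b)` with pseudocount `pc = 1`. Published
nematode piRNA thresholds are quoted in an undefined "log odds" unit
(×100-natural-log-odds-like magnitudes such as 500/1000/1500); because that
scale is not defined anywhere we keep bits internally and treat absolute
thresholds as configuration, never constants.

The annotation threshold τ is fitted, not chosen by eye: a 2-component
Gaussian mixture (EM, 10 restarts, fixed seed) on the scanned score
distribution, with τ at the equal-posterior crossing between the component
means (bisection; midpoint fallback under heavy overlap). Unimodality — the
signature of a species without motif-dependent piRNAs — is flagged when the
component means sit closer than one pooled SD *or* a single-component fit
has the better BIC; the mean-separation criterion alone cannot flag a true
single Gaussian, since a forced 2-component fit of one Gaussian yields
well-separated half-components.

## Locus calling

A 21U site becomes a locus iff its best upstream hit reaches τ and the
motif distance falls in 42 ± 5 nt. The tolerance is a package choice: the
42-nt expectation is fixed by the biology, but no tolerance is published;
±5 nt admits small planted jitter while rejecting background hits (which
are uniform over the ~113 scanned offsets, so the distance filter removes
~90% of them). Loci overlapping a user-supplied exclusion set (snRNA/snoRNA
annotations) are dropped and counted. Precursors are capped reads with 5′
end exactly at the TSS and length > 22 nt (strictly greater, reading the
selection rule literally); 3′ cleavage fragments are unique monophosphate
reads > 10 nt with 5′ ends at TSS+28..+38, counted after removing all 21U
reads, and normalized per million non-structural (non-rRNA/tRNA) reads.

## Clustering statistics

Per-contig enrichment is the exact binomial tail P(K ≥ k) with p_i =
L_i/L_total. Contigs are ranked by raw p-value (ties: descending piRNA
density, then name — the published procedure does not state a tie rule);
the curve is a ranking device, so no multiplicity correction enters the
ranking, though BH flags are emitted for users. Span-90 is read off the
cumulative curve at 90% of loci. Note a finite-sample property: because
ranking favours upward count fluctuations, uniform placement yields span-90
slightly below 0.9 × genome size unless per-contig counts are large
relative to their noise; the calibration tests therefore use ≥50 expected
loci per contig.

Species classification uses a 2-component mixture of linear regressions of
span-90 on locus count, fitted by EM with 20 random restarts (fixed seed)
and equal component variances — with ≤ 20 species points, per-component
variances are under-determined; a flag enables them. Degeneracy (one
component starved below two expected points, or coincident lines) is
reported rather than hidden.

## Chromatin context

Domain states are `active`/`regulated` (the two grouped ChromHMM
super-states) plus implicit `other`. A 21-bp locus is assigned by its TSS
position, not majority overlap — the TSS is the biologically operative
point and the locus is small; results can differ slightly from
any-overlap assignment for loci straddling a boundary. Genes take the state
covering ≥75% of their span, which is invariant to domain fragmentation.
Genicness G = log2(observed genic/intergenic ratio over the median of
placement-randomized ratios); simulations preserve locus count and length,
genome-wide or within the contig of origin; ratios carry a 0.5 pseudocount,
and empirical p-values use the (1 + exceedances)/(n_sim + 1) correction so
p = 0 is never reported. Promoters are 200/500/1000 bp strand-aware
upstream of gene starts, restricted to intergenic space. Expression strata
come from k-means (k = 2, 10 restarts, fixed seed) on log2(RPKM + 0.1); the
threshold is the back-transformed midpoint of the centers.

## Selection on motifs

For motifs above a score floor, each overlapping SNP is rescored under the
alternate allele. "Disruptive" means the alternate allele lowers the score
by at least a species-level threshold (configurable; a helper scales it by
PWM information content, since a fixed drop means more in a low-information
motif). Allele classes are assigned to the frequency of the *low-scoring*
allele (major > 0.9, minor < 0.1 of strains); when the reference itself is
the low-scoring state the complement frequency is used. Frequencies from
genotype matrices exclude missing calls from the denominator. The
stratified contrast — fraction of disruptive variants whose low-scoring
allele is major, inside vs outside clusters (or across chromatin/expression
strata) — uses two-sided Fisher tests with Wilson binomial CIs.

## Tm profiles and pausing strength

Duplex Tm is nearest-neighbor: Tm(K) = 1000·ΣΔH / (ΣΔS − R·ln(C_T/4)) with
a salt term 16.6·log10([Na+]), using the Breslauer 1986 stack table at
C_T = 50 nM DNA and 50 mM Na+ (the classic defaults of sliding-window Tm
tools); the parameter table is pluggable and its id is recorded in every
profile. Windows are 9 nt, shifted 1 nt, values indexed by window *start*,
so "TSS to +19" means windows starting at 0..19. Pausing strength
S = Σ_high (Tm − B) + Σ_low (B − Tm), B = mean Tm over the ±(100..200)
flanks. Deviations are signed, not clipped — the published wording
("positive difference … plus the negative difference") is ambiguous and a
`clip` flag provides the max(·, 0) variant. S is invariant to adding a
constant to all Tm values. The per-locus valley depth statistic is
B − mean(Tm over +20..+40): the *mean*, not the minimum, because the
minimum over overlapping 9-mers is dominated by base-stacking arrangement
(a TA-alternating 9-mer melts ~26 °C below poly-A of identical
composition) rather than by composition. Valley centers are the argmin of a
5-position moving average within +10..+60 (ties → smallest position; flat
windows flagged and returned as the midpoint).

BILD column scores use a Dirichlet prior α_b = α0·q_b with α0 = 1 and the
genome background q; a single-observation column is exactly 0
(analytically), which the tests verify. The termination-peak area is the
flank-median-baseline-subtracted sum over +20..+40; the published "area of
this peak" does not state a baseline or window, so ours is recorded in the
output metadata.

## Precursor-length statistics

Rank-sum tests run an exact full-enumeration path (midranks, so ties are
handled exactly) when the product of sample sizes is ≤ 10,000 *and* the
combination count is enumerable (≤ 2·10⁶); otherwise the tie-corrected
normal approximation with continuity correction. The abundance-weighted
resampling test draws subsamples of unique precursor sequences without
replacement with probability ∝ read count and compares sides by one-tailed
rank-sum tests; its null distribution draws two *independent* subsamples
from the reference library, constructed exactly like the test comparison,
which makes the A = B case exchangeable by design. Requested subsample
sizes exceeding the unique-sequence pool are lowered. The rRNA length
control resamples size-matched structural fragments (> 23 nt) to expose
library-preparation size-selection artifacts.

## Synthetic species generator

The generator is first-class, tested code; its defaults define the study
conditions used by the acceptance checks:

* genomes of 10 × 1 Mb contigs at 36% GC (nematode-like);
* C-type mode: ≥ 95% of loci packed into regulated-chromatin blocks
  confined to two contigs; P-type mode: 90% of loci placed in introns of
  active-domain genes spread over all contigs (3-exon/2-intron gene models,
  ~60 genes/Mb, raised automatically when intronic demand requires);
* every locus carries the full geometry: a 13-nt Ruby-like motif
  (GTTTC core, 20% of instances with one planted mismatch) ending 42 nt
  from the 21U start, TSS at −2 with a 5′ U, a GC tract over the
  transcript body and a downstream low-Tm valley;
* the planted "signature strength" (3–18 °C) drives both the body GC
  fraction (0.50–0.75) and the valley. The valley tract is pure A/T with
  alternation probability 0.05–1.0: encoding depth in the TA/AT stack
  fraction rather than composition gives a clean monotone Tm knob under
  nearest-neighbor thermodynamics (isolated G/C bases in an A/T context
  barely raise — and can lower — window Tm under the Breslauer table);
* precursor lengths are 28 + Geometric(p) truncated at 100 nt with p and
  per-locus read counts increasing in valley depth: strong-signature loci
  release shorter, more abundant precursors;
* libraries include background "noise" 21-mer sites without planted motifs
  (specificity probes), miRNA counts (fixed per-gene means × a library
  scale factor, the normalization ground truth), and genotype-independent
  rRNA fragment lengths;
* strain panels draw alternate-allele counts uniformly over 0..n_strains;
  inside motifs of constrained-stratum loci, a disruption bias pushes
  alternate alleles to < 0.1 frequency with the given probability
  (bias 0 is an exchangeable null by construction).

Everything is deterministic given (config, seed); reruns are
byte-identical.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: sequencing error, adapters, multi-mapping,
ping-pong amplification (absent in nematodes), realistic motif information
content or chromatin-domain geometry, linkage between SNPs, and transposon
content. Recovery rates on this synthetic ground truth measure the
correctness of the statistical machinery, not expected performance on real
libraries.

## Problem sizes

The acceptance checks use 500-locus/10-Mb bundles for locus recovery,
10 species of 8 × 400 kb for clustering classification, 220 loci for
pausing-signal recovery, 1000 uniform loci for the genicness null, 500
resampling repetitions, and 100 seeded strain panels for the selection
null — sizes at which every recovery and calibration statistic is stable
across seeds while the whole suite remains desk-scale.

## Known limitations

* The mixture-of-regressions EM assumes Gaussian residuals and equal
  variances; with very few species points the responsibility boundary can
  be sharp and overconfident.
* Exact rank-sum enumeration is combinatorial; tie-heavy comparisons
  beyond the enumeration guard fall back to the asymptotic approximation.
* The Fisher odds ratio uses the Haldane +0.5 correction on zero cells
  (flagged); the p-value is always the uncorrected exact test.
* EMBOSS-style window Tm values depend on the parameter table; absolute
  temperatures differ across tables even though profile shapes — and all
  statistics built on within-profile contrasts — are robust.
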