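# pirnakit

Comparative analysis of nematode piRNA (21U-RNA) biogenesis: annotation of
piRNA loci from upstream promoter motifs, quantification of their genomic
clustering and chromatin context, selection analysis on motifs from strain
SNP panels, and melting-temperature-based scoring of the RNA polymerase II
pausing signature that shapes piRNA precursors.

## Who this is for

Small-RNA and regulatory-genomics researchers working with nematode piRNAs
(or analogous short Pol II transcription units) who need a reproducible,
testable reimplementation of this analysis stack, exercisable end-to-end on
synthetic genomes with planted ground truth — no sequencing downloads
required.

## The science in brief

Nematode piRNAs are 21-nt, 5′-uracil small RNAs (21U-RNAs). Each locus is a
miniature Pol II transcription unit:

* an upstream **Ruby motif** (GTTTC core) whose start lies ~42 nt upstream
  of the mature 21U 5′ end;
* a **TSS 2 nt upstream** of the 21U 5′ end, where short capped precursors
  (~28 nt) initiate;
* a **thermodynamic pausing signature** downstream: high duplex melting
  temperature (Tm) over the transcript body (TSS..+19) followed by a low-Tm
  "valley" (+20..+40) that promotes early termination and short precursors.

Species organize their loci in two modes: **C-type** (loci concentrated in
a few megabase clusters inside repressed H3K27me3-like chromatin) and
**P-type** (loci dispersed genome-wide in introns of active genes).

Core statistics implemented here:

* PWM log-odds scanning of upstream windows; the annotation threshold τ is
  the equal-posterior point of a 2-component Gaussian mixture fitted to the
  bimodal score distribution.
* Per-contig enrichment by exact one-sided binomial tests; **span-90** (the
  cumulative span of the most enriched contigs holding 90% of loci) as the
  clustering summary; a 2-component mixture of linear regressions (EM) of
  span-90 on locus count classifies species into the two modes.
* Chromatin-domain enrichment (Fisher exact tests on TSS-state overlap), a
  75%-coverage rule for gene-state assignment, orthology-based state
  transfer, and a **genicness score**
  G = log2(observed genic/intergenic ratio / median simulated ratio).
* SNP effects on motifs: rescoring under alternate alleles; the fraction of
  score-lowering (disruptive) variants whose low-scoring allele is a major
  allele (>90% of strains) is compared across strata by Fisher tests —
  purifying selection keeps that fraction low inside clusters.
* Tm profiles (nearest-neighbor thermodynamics, 9-nt window, 1-nt shift),
  pausing strength
  S = Σ_{TSS..+19}(Tm−B) + Σ_{+20..+40}(B−Tm) with background B the mean Tm
  over ±(100..200) nt flanks, Bayesian Integral Log-Odds (BILD) entropy
  profiles for cross-species comparison, and abundance-weighted resampling
  Wilcoxon tests on precursor lengths with rRNA-fragment size controls.

## Worked example

Generate a two-species synthetic demo (one clustered, one dispersed
species, with planted loci, chromatin domains, gene models and small-RNA
libraries) and run the full pipeline:

```sh
cat > demo.yaml <<EOF
seed: 1
species:
  - {name: clustered, mode: C-type, n_pirna_loci: 80, n_contigs: 5, contig_length_bp: 200000}
  - {name: dispersed, mode: P-type, n_pirna_loci: 80, n_contigs: 5, contig_length_bp: 200000, snp_panel: true}
n_sim: 20
EOF
pirnakit run --config demo.yaml --out demo_run
python - <<'PY'
import json
s = json.load(open("demo_run/summary.json"))["species"]
for name, d in s.items():
    print(name, d["n_loci_called"], d["span90"], round(d["genicness"], 2))
PY
```

which prints

```
clustered 80 400000 -1.18
dispersed 80 1000000 6.59
```

Read this as: all 80 planted loci were recovered in each species from their
21U sites and upstream motif scores; the clustered species needs only its
two cluster contigs (400 kb) to hold 90% of its loci while the dispersed
species needs its whole 1-Mb genome; and the genicness score is negative
(intergenic, cluster-resident) for the C-type species but strongly positive
(genic/intronic) for the P-type species. `demo_run/` also contains
per-species TSVs (loci, contig statistics, chromatin enrichment, pausing
scores) and `pirnakit report --run-dir demo_run` assembles panel-style
summary tables.

Individual stages are available as `pirnakit synth | annotate | cluster |
chromatin | selection | pausing` on FASTA/BED/TSV inputs.

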