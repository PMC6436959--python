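"""End-to-end pipeline orchestration.

Runs the three headline analyses over one or more species — locus
annotation plus clustering classification; chromatin/selection context; and
pausing/precursor statistics — from a single structured config, writing
per-stage TSVs and a machine-readable JSON summary stamped with the config
hash and seed. Deterministic stages are byte-identical on rerun.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pirnakit import __version__
from pirnakit.annotate import call_pirna_loci, extract_precursors, scan_upstream_windows
from pirnakit.chromatin import DomainSet, domain_overlap_enrichment, genicness_score
from pirnakit.clustering import classify_clustering, contig_enrichment, span_curve
from pirnakit.core import write_bed, write_fasta
from pirnakit.motif import fit_score_threshold
from pirnakit.pausing import (
    TmParams,
    pausing_strength,
    stratify_by_signal,
    tm_profile,
    valley_depth,
)
from pirnakit.selection import motif_variant_effects, stratified_major_fraction
from pirnakit.synth import (
    LibraryConfig,
    SpeciesConfig,
    generate_species,
    simulate_small_rna_libraries,
    simulate_strain_panel,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "species" not in cfg:
        raise ConfigError("config must be a mapping with a 'species' list")
    if not isinstance(cfg.get("seed", 0), int):
        raise ConfigError("'seed' must be an integer")
    return cfg


def _species_config(block: dict, global_seed: int, index: int) -> SpeciesConfig:
    kwargs = {
        k: v for k, v in block.items()
        if k in SpeciesConfig.__dataclass_fields__
    }
    kwargs.setdefault("seed", global_seed + 101 * index)
    if "tm_valley_depth_range" in kwargs:
        kwargs["tm_valley_depth_range"] = tuple(kwargs["tm_valley_depth_range"])
    return SpeciesConfig(**kwargs)


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run all stages for every species in the config; returns the summary.

    Stages per species: synthesis, annotation (motif scan + threshold +
    locus calling), clustering statistics, chromatin context, optional
    selection analysis, pausing/precursor scoring. A cross-species
    clustering classification runs when >= 6 species are configured.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    config_text = yaml.safe_dump(config, sort_keys=True)
    config_hash = hashlib.sha256(config_text.encode()).hexdigest()[:16]
    (outdir / "config.yaml").write_text(config_text)
    summary: dict = {
        "version": __version__, "seed": seed, "config_hash": config_hash,
        "species": {},
    }
    species_points = []
    for si, block in enumerate(config["species"]):
        name = block.get("name", f"species_{si+1}")
        sdir = outdir / name
        sdir.mkdir(exist_ok=True)
        scfg = _species_config(block, seed, si)
        bundle = generate_species(scfg)
        lib = simulate_small_rna_libraries(
            bundle, LibraryConfig(seed=scfg.seed + 7)
        )
        write_fasta(bundle.genome, sdir / "genome.fa")
        write_bed(bundle.domain_intervals, sdir / "domains.bed")
        bundle.truth.to_csv(sdir / "truth.tsv", sep="\t", index=False)

        # annotation
        sites = [r.interval for r in lib.reads_21u]
        scanned = scan_upstream_windows(sites, bundle.genome, bundle.pwm)
        scores = [h.score for _, h, _ in scanned if h is not None]
        fit = fit_score_threshold(scores, seed=seed)
        result = call_pirna_loci(scanned, fit.threshold)
        loci = result.loci
        pd.DataFrame(
            [
                {
                    "locus_id": l.id, "contig": l.contig,
                    "start": l.site_21u.start, "end": l.site_21u.end,
                    "strand": l.strand, "tss": l.tss,
                    "motif_score": l.motif_score,
                    "motif_distance": l.motif_distance,
                }
                for l in loci
            ]
        ).to_csv(sdir / "loci.tsv", sep="\t", index=False)

        # clustering
        stats = contig_enrichment([l.contig for l in loci], bundle.genome)
        curve = span_curve(stats)
        pd.DataFrame(
            [
                {
                    "contig": s.contig, "length": s.length, "count": s.count,
                    "p_value": s.p_value,
                }
                for s in stats
            ]
        ).to_csv(sdir / "contig_stats.tsv", sep="\t", index=False)
        species_points.append(
            {"name": name, "mode": scfg.mode, "n_loci": len(loci),
             "span90": curve.span90}
        )

        # chromatin
        domains = DomainSet(bundle.domain_intervals)
        enr = domain_overlap_enrichment(
            [(l.contig, l.tss) for l in loci], domains,
            bundle.genome.total_length,
        )
        pd.DataFrame(
            [
                {
                    "state": e.state, "observed": e.observed,
                    "expected": e.expected, "fold": e.fold,
                    "fisher_p": e.fisher.p_value,
                }
                for e in enr
            ]
        ).to_csv(sdir / "chromatin_enrichment.tsv", sep="\t", index=False)
        gres = genicness_score(
            [l.site_21u for l in loci], bundle.genes, bundle.genome,
            n_sim=int(config.get("n_sim", 100)), seed=seed + si,
        )

        # selection (optional)
        sel_summary = None
        if block.get("snp_panel", config.get("snp_panel", False)):
            snps = simulate_strain_panel(
                bundle, motif_disruption_bias=float(
                    block.get("motif_disruption_bias", 0.0)
                ),
                seed=seed + 31 * si,
            )
            windows = []
            for l in loci:
                lo = min(l.tss, l.site_21u.start) - 60
                hi = max(l.tss, l.site_21u.end) + 10
                lo = max(lo, 0)
                hi = min(hi, bundle.genome.lengths[l.contig])
                windows.append(
                    {
                        "id": l.id, "contig": l.contig, "strand": l.strand,
                        "start": lo,
                        "sequence": bundle.genome.sequence(l.contig)[lo:hi],
                    }
                )
            effects, n_mismatch = motif_variant_effects(
                windows, snps, bundle.pwm, score_floor=8.0,
                disruption_delta=2.0,
            )
            strata = {
                l.id: domains.state_at(l.contig, l.tss) for l in loci
            }
            sel = stratified_major_fraction(effects, strata)
            pd.DataFrame(
                [
                    {
                        "stratum": f.stratum, "n_major": f.n_major,
                        "n_disruptive": f.n_disruptive,
                        "fraction_major": f.fraction_major,
                    }
                    for f in sel.fractions
                ]
            ).to_csv(sdir / "selection_fractions.tsv", sep="\t", index=False)
            sel_summary = {
                "n_effects": len(effects), "n_ref_mismatch": n_mismatch,
            }

        # pausing
        params = TmParams()
        rows = []
        strengths = {}
        for l in loci:
            prof = tm_profile(bundle.genome, l.tss, l.contig, l.strand, params)
            try:
                sc = pausing_strength(prof)
            except ValueError:
                continue
            strengths[l.id] = sc.strength
            rows.append(
                {
                    "locus_id": l.id, "strength": sc.strength,
                    "background": sc.background,
                    "valley_depth": valley_depth(prof),
                }
            )
        pd.DataFrame(rows).to_csv(sdir / "pausing.tsv", sep="\t", index=False)
        if len(strengths) >= 20:
            top, bottom = stratify_by_signal(strengths)
            precursors = extract_precursors(lib.capped, loci)
            json.dump(
                {"top_decile": top, "bottom_decile": bottom},
                open(sdir / "strata.json", "w"), indent=1,
            )
        summary["species"][name] = {
            "mode": scfg.mode,
            "n_sites": len(sites),
            "n_loci_called": len(loci),
            "threshold": fit.threshold,
            "span90": curve.span90,
            "genicness": gres.score,
            "selection": sel_summary,
        }
    if len(species_points) >= 6:
        fitmix = classify_clustering(
            np.array([p["n_loci"] for p in species_points], dtype=float),
            np.array([p["span90"] for p in species_points], dtype=float),
            seed=seed,
        )
        for p, lab in zip(species_points, fitmix.labels):
            p["component"] = int(lab)
        summary["clustering_classification"] = {
            "labels": [int(l) for l in fitmix.labels],
            "log_likelihood": fitmix.log_likelihood,
            "degenerate": fitmix.degenerate,
        }
    pd.DataFrame(species_points).to_csv(
        outdir / "species_summary.tsv", sep="\t", index=False
    )
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary


_PANELS = {
    "panel_span_vs_count.tsv": "species_summary.tsv",
}


def make_report(run_dir: str | Path) -> list[Path]:
    """Assemble figure-panel-equivalent TSVs from a completed run directory.

    Emits whatever panels the available stage outputs support; a partial
    run yields the available subset.
    """
    run_dir = Path(run_dir)
    report_dir = run_dir / "report"
    report_dir.mkdir(exist_ok=True)
    written = []
    summary_path = run_dir / "species_summary.tsv"
    if summary_path.exists():
        df = pd.read_csv(summary_path, sep="\t")
        df.to_csv(report_dir / "panel_span_vs_count.tsv", sep="\t", index=False)
        written.append(report_dir / "panel_span_vs_count.tsv")
    for sdir in sorted(run_dir.iterdir()):
        if not sdir.is_dir() or sdir.name == "report":
            continue
        chrom = sdir / "chromatin_enrichment.tsv"
        if chrom.exists():
            out = report_dir / f"panel_chromatin_{sdir.name}.tsv"
            pd.read_csv(chrom, sep="\t").to_csv(out, sep="\t", index=False)
            written.append(out)
        pausing = sdir / "pausing.tsv"
        if pausing.exists():
            out = report_dir / f"panel_pausing_{sdir.name}.tsv"
            pd.read_csv(pausing, sep="\t").to_csv(out, sep="\t", index=False)
            written.append(out)
        sel = sdir / "selection_fractions.tsv"
        if sel.exists():
            out = report_dir / f"panel_selection_{sdir.name}.tsv"
            pd.read_csv(sel, sep="\t").to_csv(out, sep="\t", index=False)
            written.append(out)
    return written
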