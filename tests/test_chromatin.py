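"""Chromatin-domain context: enrichment, state assignment, genicness,
promoters, and expression strata."""

import numpy as np
import pytest

from pirnakit.chromatin import (
    DomainSet,
    assign_gene_state,
    domain_overlap_enrichment,
    expression_strata,
    genicness_score,
    motif_expression_fraction,
    predict_states_by_orthology,
    promoter_association,
)
from pirnakit.core import Genome, GenomicInterval
from tests.test_stats import fisher_two_sided_oracle


def iv(contig, start, end, name=".", strand="."):
    return GenomicInterval(contig, start, end, strand, name)


class TestDomainEnrichment:
    def test_single_state_covering_universe_fold_one(self):
        domains = DomainSet([iv("c", 0, 1000, "active")])
        res = domain_overlap_enrichment(
            [("c", i * 100) for i in range(10)], domains, 1000
        )
        (active,) = [r for r in res if r.state == "active"]
        assert active.fold == pytest.approx(1.0)

    def test_toy_arithmetic_and_fisher_oracle(self):
        # universe 1000 bp, state span 300, N=10, observed 9
        domains = DomainSet([iv("c", 0, 300, "regulated")])
        positions = [("c", 10 + i * 30) for i in range(9)] + [("c", 600)]
        res = domain_overlap_enrichment(positions, domains, 1000)
        reg = [r for r in res if r.state == "regulated"][0]
        assert reg.expected == pytest.approx(3.0)
        assert reg.fold == pytest.approx(9 / 3)
        assert reg.fisher.p_value == pytest.approx(
            fisher_two_sided_oracle(9, 1, 300, 700), abs=1e-12
        )

    def test_zero_observed_guarded(self):
        domains = DomainSet([iv("c", 0, 500, "active"), iv("c", 500, 1000, "regulated")])
        res = domain_overlap_enrichment([("c", 600)] * 10, domains, 1000)
        active = [r for r in res if r.state == "active"][0]
        assert active.guarded
        assert np.isfinite(active.depletion_fold)
        assert active.depletion_fold == pytest.approx(5.0)  # expected/1


class TestAssignGeneState:
    def test_fully_covered_gene(self):
        domains = DomainSet([iv("c", 0, 10_000, "active")])
        assert assign_gene_state(iv("c", 100, 2000), domains) == "active"

    def test_half_split_unassigned(self):
        domains = DomainSet(
            [iv("c", 0, 1000, "active"), iv("c", 1000, 2000, "regulated")]
        )
        assert assign_gene_state(iv("c", 500, 1500), domains) == "unassigned"

    def test_eighty_percent_regulated(self):
        domains = DomainSet(
            [iv("c", 0, 800, "regulated"), iv("c", 800, 1000, "active")]
        )
        assert assign_gene_state(iv("c", 0, 1000), domains) == "regulated"

    def test_invariant_to_domain_fragmentation(self):
        whole = DomainSet([iv("c", 0, 900, "regulated")])
        pieces = DomainSet(
            [iv("c", 0, 300, "regulated"), iv("c", 300, 600, "regulated"),
             iv("c", 600, 900, "regulated")]
        )
        gene = iv("c", 50, 850)
        assert assign_gene_state(gene, whole) == assign_gene_state(gene, pieces)


class TestOrthologyPrediction:
    def test_perfect_transfer_concordance(self):
        genes = [f"g{i}" for i in range(20)]
        orth = {g: f"r{i}" for i, g in enumerate(genes)}
        states = {f"r{i}": ("active" if i % 2 else "regulated") for i in range(20)}
        direct = {g: states[orth[g]] for g in genes}
        res = predict_states_by_orthology(genes, orth, states, direct)
        assert res.concordance == 1.0

    def test_shuffled_table_near_marginal(self, rng):
        genes = [f"g{i}" for i in range(400)]
        perm = rng.permutation(400)
        orth = {g: f"r{perm[i]}" for i, g in enumerate(genes)}
        states = {f"r{i}": ("active" if i < 200 else "regulated") for i in range(400)}
        direct = {f"g{i}": ("active" if i < 200 else "regulated") for i in range(400)}
        res = predict_states_by_orthology(genes, orth, states, direct)
        assert abs(res.concordance - 0.5) < 0.1

    def test_empty_overlap_flagged(self):
        res = predict_states_by_orthology(
            ["g1"], {"g1": "r1"}, {"r1": "active"}, None, pirna_genes=set()
        )
        assert res.flagged


class TestGenicness:
    def _genome_and_genes(self):
        g = Genome({f"c{i}": "A" * 100_000 for i in range(5)})
        genes = [
            iv(f"c{i}", s, s + 2_000, f"c{i}g{k}", "+")
            for i in range(5)
            for k, s in enumerate(range(500, 95_000, 4_000))
        ]
        return g, genes  # ~50% genic

    def test_uniform_placement_score_near_zero(self, rng):
        g, genes = self._genome_and_genes()
        loci = [
            iv(f"c{int(rng.integers(5))}", s, s + 21)
            for s in rng.integers(0, 99_900, size=1000)
        ]
        res = genicness_score(loci, genes, g, n_sim=100, seed=5)
        assert abs(res.score) < 0.2

    def test_all_genic_minimal_p(self):
        g, genes = self._genome_and_genes()
        loci = [iv(genes[i].contig, genes[i].start + 10, genes[i].start + 31)
                for i in range(60)]
        res = genicness_score(loci, genes, g, n_sim=100, seed=1)
        assert res.score > 0
        assert res.p_value == pytest.approx(1 / 101)

    def test_bundle_directions(self, ctype_bundle, ptype_bundle):
        for bundle, check in ((ctype_bundle, lambda s: s <= 0),
                              (ptype_bundle, lambda s: s > 0)):
            res = genicness_score(
                bundle.sites_21u, bundle.genes, bundle.genome,
                n_sim=30, seed=2,
            )
            assert check(res.score), (bundle.config.mode, res.score)


class TestPromoters:
    def test_minus_strand_promoter_is_downstream_interval(self):
        g = Genome({"c": "A" * 10_000})
        gene = iv("c", 2000, 4000, "g1", "-")
        # promoter = [4000, 4200); a locus there must be counted
        loci = [iv("c", 4100, 4121)]
        res = promoter_association(loci, [gene], g, windows=(200,))
        assert res[0].observed == 1
        assert res[0].fold > 1

    def test_promoter_planted_enrichment_all_windows(self):
        g = Genome({"c": "A" * 100_000})
        genes = [iv("c", s, s + 2000, f"g{s}", "+") for s in range(5000, 95_000, 5000)]
        loci = [iv("c", s - 100, s - 79) for s in range(5000, 95_000, 5000)]
        for res in promoter_association(loci, genes, g):
            assert res.fold > 1

    def test_uniform_intergenic_fold_near_one(self, rng):
        g = Genome({"c": "A" * 200_000})
        genes = [iv("c", s, s + 2000, f"g{s}", "+") for s in range(10_000, 190_000, 10_000)]
        # uniform over intergenic space
        loci = []
        while len(loci) < 400:
            s = int(rng.integers(0, 199_900))
            if not any(gene.start <= s < gene.end for gene in genes):
                loci.append(iv("c", s, s + 21))
        res = promoter_association(loci, genes, g, windows=(1000,))
        assert res[0].fold == pytest.approx(1.0, abs=0.35)


class TestExpressionStrata:
    def test_clear_bimodal_split(self):
        rpkm = {f"lo{i}": 0.01 for i in range(20)}
        rpkm.update({f"hi{i}": 100.0 for i in range(20)})
        res = expression_strata(rpkm, seed=0)
        assert all(res.labels[f"lo{i}"] == "low" for i in range(20))
        assert all(res.labels[f"hi{i}"] == "high" for i in range(20))
        assert 0.01 < res.threshold_rpkm < 100

    def test_planted_lognormal_threshold_between_modes(self):
        for seed in range(20):
            r = np.random.default_rng(seed)
            vals = np.concatenate(
                [np.exp(r.normal(np.log(0.1), 0.5, 100)),
                 np.exp(r.normal(np.log(50), 0.5, 100))]
            )
            rpkm = {f"g{i}": float(v) for i, v in enumerate(vals)}
            res = expression_strata(rpkm, seed=seed)
            assert 0.5 < res.threshold_rpkm < 25

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            expression_strata({f"g{i}": float(i) for i in range(5)})

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            expression_strata({f"g{i}": 1.0 for i in range(20)})


class TestMotifExpressionFraction:
    def test_all_and_none_expressed(self):
        states = {"m1": "active", "m2": "active", "m3": "regulated"}
        res = motif_expression_fraction(states, expressed={"m1", "m2", "m3"})
        assert all(f.fraction == 1.0 for f in res)
        res = motif_expression_fraction(states, expressed=set())
        assert all(f.fraction == 0.0 for f in res)

    def test_ctype_bundle_regulated_dominates(self, ctype_bundle):
        # in a clustered species, detectable 21U expression concentrates in
        # regulated chromatin where the loci were planted
        truth = ctype_bundle.truth
        states = dict(zip(truth.locus_id, truth.chromatin_state))
        expressed = set(truth.locus_id[truth.chromatin_state == "regulated"])
        by_state = {f.state: f.fraction for f in
                    motif_expression_fraction(states, expressed)}
        assert by_state["regulated"] > by_state.get("active", 0.0)
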