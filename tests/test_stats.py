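import math

import numpy as np
import pytest
from scipy.stats import hypergeom, kstest

from hgtsieve.core_io import load_fixture
from hgtsieve.records import AnnotationRecord
from hgtsieve.stats import (
    CandidateEvidence,
    TriageRule,
    annotation_similarity,
    composition_fractions,
    gc_amelioration_summary,
    group_transfer_types,
    intron_free_test,
    per_type_values,
    population_sd,
    similarity_enrichment_test,
    triage_contamination,
)


class TestTriage:
    def test_no_evidence_profile_is_suspected(self):
        ev = CandidateEvidence("g", est_count=0, cloned=False, anchored=False,
                               relative_genome_homolog=False, top_hit_identity_pct=69.5)
        res = triage_contamination(ev)
        assert res.status == "suspected_contaminant"
        assert any(f.startswith("high_identity") for f in res.flags)

    def test_est_and_anchoring_keep_gene(self):
        ev = CandidateEvidence("g", est_count=25, anchored=True)
        assert triage_contamination(ev).status == "genuine"

    def test_single_positive_evidence_suffices(self):
        ev = CandidateEvidence("g", est_count=0, cloned=False, anchored=True,
                               relative_genome_homolog=True)
        assert triage_contamination(ev).status == "genuine"

    def test_high_identity_alone_never_decisive(self):
        ev = CandidateEvidence("g", est_count=3, anchored=True, top_hit_identity_pct=96.1)
        res = triage_contamination(ev)
        assert res.status == "genuine"
        assert res.flags  # but the alert is reported


def ann(gene_id, scaffold=None, start=None, end=None, annotation=None, type_group=None):
    return AnnotationRecord(gene_id=gene_id, gc=0.4, scaffold=scaffold, start=start,
                            end=end, annotation=annotation, type_group=type_group)


class TestTypeGrouping:
    def test_published_candidates_form_14_types(self):
        t2 = load_fixture("table2_candidates")
        groups = group_transfer_types(t2, similarity_fn=annotation_similarity)
        assert len(groups) == 14
        by_gene = {g: grp for grp in groups for g in grp}
        assert len(by_gene) == 22
        # grouping matches the packaged type labels exactly
        expected = {}
        for c in t2:
            expected.setdefault(c.type_group, set()).add(c.gene_id)
        assert {frozenset(g) for g in groups} == {frozenset(v) for v in expected.values()}

    def test_singleton(self):
        assert group_transfer_types([ann("only")]) == [["only"]]

    def test_adjacent_same_scaffold_copies_merge(self):
        a = ann("g1", "scafX", 1000, 2000)
        b = ann("g2", "scafX", 5000, 6000)  # 3 kb gap
        assert group_transfer_types([a, b]) == [["g1", "g2"]]

    def test_distant_same_scaffold_copies_stay_apart(self):
        a = ann("g1", "scafX", 1000, 2000)
        b = ann("g2", "scafX", 900_000, 901_000)
        assert group_transfer_types([a, b]) == [["g1"], ["g2"]]

    def test_transitive_closure_of_tandem_chain(self):
        genes = [ann(f"g{i}", "scafX", i * 30_000, i * 30_000 + 1000) for i in range(5)]
        assert group_transfer_types(genes) == [[f"g{i}" for i in range(5)]]


class TestEnrichment:
    def test_observed_statistic_from_published_candidates(self):
        t2 = load_fixture("table2_candidates")
        idents = list(per_type_values(t2, "top_hit_identity_pct").values())
        assert len(idents) == 14
        assert float(np.mean(idents)) == pytest.approx(50.36, abs=0.005)
        assert population_sd(idents) == pytest.approx(10.84, abs=0.005)

    def test_missing_identity_excluded_from_type_mean(self):
        t2 = load_fixture("table2_candidates")
        per_type = per_type_values(t2, "top_hit_identity_pct")
        assert per_type["T011199"] == pytest.approx(40.36, abs=0.005)

    def test_null_sd_matches_finite_population_correction(self):
        rng = np.random.default_rng(42)
        bg = rng.normal(41.02, 9.76, 1176)
        res = similarity_enrichment_test([50.0] * 14, bg, n_reps=10_000, seed=11)
        sigma = float(bg.std())
        fpc = math.sqrt((1176 - 14) / (1176 - 1))
        expected_sd = sigma / math.sqrt(14) * fpc
        assert res.null_sd == pytest.approx(expected_sd, rel=0.05)
        assert res.null_mean == pytest.approx(float(bg.mean()), abs=0.1)

    def test_constant_background_degenerate(self):
        res = similarity_enrichment_test([5.0], [5.0] * 50, k=3, n_reps=100, seed=0)
        assert res.null_sd == 0.0
        assert res.empirical_p in (0.0, 1.0)

    def test_k_larger_than_background_errors(self):
        with pytest.raises(ValueError):
            similarity_enrichment_test([1.0], [1.0, 2.0], k=5, n_reps=10, seed=0)

    def test_seed_reproducibility(self):
        bg = list(range(100))
        r1 = similarity_enrichment_test([60.0], bg, k=5, n_reps=500, seed=3)
        r2 = similarity_enrichment_test([60.0], bg, k=5, n_reps=500, seed=3)
        assert r1.n_extreme == r2.n_extreme

    def test_p_values_uniform_under_null(self):
        """When the observed statistic is itself a null draw, empirical
        p-values must be (discretely) uniform on [0, 1]."""
        rng = np.random.default_rng(2024)
        bg = rng.normal(41.0, 9.8, 500)
        k = 10
        pvals = []
        for i in range(200):
            observed = float(rng.choice(bg, size=k, replace=False).mean())
            res = similarity_enrichment_test([observed], bg, k=k, n_reps=250, seed=1000 + i)
            pvals.append(res.empirical_p)
        stat = kstest(pvals, "uniform").statistic
        # critical value at alpha=0.001 for n=200 is ~0.138 plus 1/250 discreteness
        assert stat < 0.15


class TestIntronFree:
    def test_exact_probability_matches_scipy_hypergeometric(self):
        res = intron_free_test(1176, 116, 14, n_reps=100, seed=0)
        assert res.exact_p == pytest.approx(hypergeom.pmf(14, 1176, 116, 14), rel=1e-9)
        assert res.exact_p < 1e-10

    def test_all_intron_free_background(self):
        res = intron_free_test(50, 50, 10, n_reps=100, seed=0)
        assert res.exact_p == 1.0
        assert res.empirical_p == 1.0

    def test_empirical_converges_to_exact(self):
        # regime with non-negligible success probability
        n, m, k = 60, 40, 5
        exact = hypergeom.pmf(k, n, m, k)
        res = intron_free_test(n, m, k, n_reps=20_000, seed=5)
        mc_se = math.sqrt(exact * (1 - exact) / 20_000)
        assert abs(res.empirical_p - exact) < 3 * mc_se

    def test_invalid_counts_error(self):
        with pytest.raises(ValueError):
            intron_free_test(100, 200, 5, n_reps=10, seed=0)


class TestGcSummary:
    def test_published_per_type_mean(self):
        t2 = load_fixture("table2_candidates")
        gcs = list(per_type_values(t2, "gc", scale=100.0).values())
        summary = gc_amelioration_summary(gcs)
        assert summary.recipient_mean == pytest.approx(43.83, abs=0.005)

    def test_identical_values_sd_zero(self):
        s = gc_amelioration_summary([40.0, 40.0, 40.0])
        assert s.recipient_sd == 0.0

    def test_centralization_verdict(self):
        s = gc_amelioration_summary([40, 44, 48], [30, 50, 66])
        assert s.centralized is True
        assert s.recipient_sd < s.donor_sd

    def test_empty_donor_omits_verdict(self):
        assert gc_amelioration_summary([40.0, 42.0]).centralized is None


class TestCompositionFractions:
    def test_proteobacteria_species_fraction(self):
        panel = load_fixture("panel_composition")
        assert composition_fractions(panel, "Proteobacteria") == 46.3

    def test_entomopathogenic_genera_fraction(self):
        panel = load_fixture("panel_composition")
        assert composition_fractions(panel, "entomopathogenic_genera") == 3.4
        genera = ["Serratia", "Photorhabdus", "Pseudomonas", "Bacillus"]
        assert sum(panel.species(g) for g in genera) == panel.species("entomopathogenic_genera")

    def test_organism_basis(self):
        panel = load_fixture("panel_composition")
        assert composition_fractions(panel, "Proteobacteria", basis="organisms") == 48.9

    def test_unknown_taxon_errors(self):
        panel = load_fixture("panel_composition")
        with pytest.raises(KeyError):
            composition_fractions(panel, "Atlantis")
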