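import numpy as np
import pytest
from scipy.stats import chi2_contingency

from phenosim.cohort import annotation_corpus
from phenosim.simulate import (ControlSpec, DoseResponseEffect,
                               SimulationConfig, generate_cohort,
                               generate_controls, generate_ontology,
                               generate_test_cases, system_members,
                               toy_ontology, variant_labels,
                               variant_profiles)


class TestGenerateOntology:
    def test_minimal_ontology_is_root_plus_children(self):
        g = generate_ontology(3, seed=0)
        assert len(g) == 3
        assert g.children(g.root) == g.terms - {g.root}

    def test_structural_invariants_hold(self):
        # construction itself validates acyclicity/single root; check
        # system branches only meet at the root
        g = generate_ontology(80, max_parents=3, seed=2)
        systems = system_members(g)
        heads = sorted(systems)
        for t in g.terms - {g.root}:
            anc_heads = g.ancestors(t) & set(heads)
            assert len(anc_heads) == 1 or t in heads

    def test_same_seed_identical_edges(self):
        a = generate_ontology(50, seed=7)
        b = generate_ontology(50, seed=7)
        assert a.parents == b.parents
        assert a.parents != generate_ontology(50, seed=8).parents

    def test_toy_ontology_fixed_shape(self):
        g = toy_ontology()
        assert len(g) == 40
        assert g.names[g.root] == "Phenotypic abnormality"
        assert len(g.children(g.root)) == 6
        # the diamond term reaches the root by two routes
        assert g.parents["T:0405"] == {"T:0403", "T:0404"}


class TestGenerateCohort:
    def test_full_sensitivity_no_noise_reproduces_profiles(self):
        g = toy_ontology()
        config = SimulationConfig(seed=3, n_variants=3, profile_size=4,
                                  probands_per_variant=5,
                                  term_sensitivity=1.0, noise_rate=0.0)
        cohort = generate_cohort(config, g)
        profiles = variant_profiles(config, g)
        for p in cohort:
            closure = g.closure(p.hpo_terms)
            assert profiles[p.variants[0]] <= closure

    def test_blood_never_exceeds_muscle(self):
        g = toy_ontology()
        cohort = generate_cohort(
            SimulationConfig(seed=4, n_variants=2, profile_size=4,
                             probands_per_variant=50), g)
        for p in cohort:
            assert p.het_level("blood") <= p.het_level("muscle")

    def test_deterministic_per_seed(self):
        g = toy_ontology()
        cfg = SimulationConfig(seed=11, n_variants=2, profile_size=4,
                               probands_per_variant=10)
        assert generate_cohort(cfg, g).patients == \
            generate_cohort(cfg, g).patients

    def test_generated_cohort_passes_validation(self):
        # CohortTable construction and the corpus builder enforce the
        # relational invariants; annotations must all resolve and be minimal
        g = generate_ontology(150, seed=9)
        config = SimulationConfig(seed=9)
        cohort = generate_cohort(config, g)
        corpus = annotation_corpus(cohort, g)
        for terms in corpus.annotations.values():
            for t in terms:
                assert not any(t != u and t in g.ancestors(u) for u in terms)

    def test_term_frequencies_converge_to_sensitivity(self):
        g = generate_ontology(150, seed=21)
        config = SimulationConfig(seed=21, n_variants=1, profile_size=6,
                                  probands_per_variant=1000,
                                  term_sensitivity=0.7, noise_rate=0.0)
        cohort = generate_cohort(config, g)
        profile = variant_profiles(config, g)[variant_labels(config)[0]]
        # measure on terms with no profile descendant (closure hits equal
        # direct annotation for those)
        leaves = [t for t in profile
                  if not any(t != u and t in g.ancestors(u) for u in profile)]
        for t in leaves:
            freq = np.mean([t in g.closure(p.hpo_terms) for p in cohort])
            assert freq == pytest.approx(0.7, abs=0.05)

    def test_zero_slope_dose_term_independent_of_level(self):
        g = toy_ontology()
        base = SimulationConfig(seed=7, n_variants=1, profile_size=4,
                                probands_per_variant=500,
                                term_sensitivity=0.5, noise_rate=0.0)
        label = variant_labels(base)[0]
        config = SimulationConfig(
            seed=7, n_variants=1, profile_size=4, probands_per_variant=500,
            term_sensitivity=0.5, noise_rate=0.0,
            dose_response=(DoseResponseEffect(label, "T:0603", "muscle",
                                              intercept=0.0, slope=0.0),))
        cohort = generate_cohort(config, g)
        has = np.array(["T:0603" in p.hpo_terms for p in cohort])
        high = np.array([p.het_level("muscle") > 65.0 for p in cohort])
        table = [[np.sum(has & high), np.sum(has & ~high)],
                 [np.sum(~has & high), np.sum(~has & ~high)]]
        assert chi2_contingency(table).pvalue > 0.01

    def test_strong_positive_slope_raises_presence_with_level(self):
        g = toy_ontology()
        base = SimulationConfig(seed=8, n_variants=1, profile_size=4,
                                probands_per_variant=500,
                                term_sensitivity=0.5, noise_rate=0.0)
        label = variant_labels(base)[0]
        config = SimulationConfig(
            seed=8, n_variants=1, profile_size=4, probands_per_variant=500,
            term_sensitivity=0.5, noise_rate=0.0,
            dose_response=(DoseResponseEffect(label, "T:0603", "muscle",
                                              intercept=-7.8, slope=0.12),))
        cohort = generate_cohort(config, g)
        low = [p for p in cohort if p.het_level("muscle") < 50]
        high = [p for p in cohort if p.het_level("muscle") > 80]
        rate = lambda ps: np.mean(["T:0603" in p.hpo_terms for p in ps])
        assert rate(high) > rate(low) + 0.3


class TestControlsAndTestCases:
    def test_zero_overlap_no_noise_is_disjoint_from_case_profiles(self):
        g = generate_ontology(150, seed=5)
        config = SimulationConfig(seed=5, noise_rate=0.0,
                                  controls=ControlSpec(50, 0.0))
        profiles = variant_profiles(config, g)
        all_case_terms = set().union(*profiles.values())
        for _, terms in generate_controls(config, g):
            assert not (terms & all_case_terms)

    def test_full_overlap_draws_from_case_profiles(self):
        g = generate_ontology(150, seed=5)
        config = SimulationConfig(seed=5, noise_rate=0.0,
                                  term_sensitivity=1.0,
                                  controls=ControlSpec(20, 1.0))
        profiles = set(map(frozenset, variant_profiles(config, g).values()))
        for _, terms in generate_controls(config, g):
            # annotation of a full case profile, minimized
            assert any(terms <= frozenset(p) for p in profiles)

    def test_determinism(self):
        g = generate_ontology(150, seed=6)
        config = SimulationConfig(seed=6, controls=ControlSpec(20, 0.3))
        assert generate_controls(config, g) == generate_controls(config, g)
        assert generate_test_cases(config, g, 10) == \
            generate_test_cases(config, g, 10)
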