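import numpy as np
import pytest

from _oracles import brute_lin, random_entangled_dag
from conftest import make_patient
from phenosim.cohort import CohortTable, cohort_information_content
from phenosim.ontology import (AnnotationCorpus, information_content,
                               term_frequencies)
from phenosim.similarity import (SimilarityMatrix, asym_sim, cluster_summary,
                                 cluster_variants, group_sim, lin, sym_sim,
                                 system_profile, variant_similarity_matrix)


def _random_ic(graph, seed, n_individuals=20, terms_per=3):
    rng = np.random.default_rng(seed)
    terms = sorted(graph.terms)
    corpus = AnnotationCorpus({
        f"p{i}": frozenset(terms[j] for j in
                           rng.integers(0, len(terms), size=terms_per))
        for i in range(n_individuals)})
    return information_content(term_frequencies(graph, corpus), n_individuals)


class TestLin:
    def test_self_similarity_is_one(self, small_corpus_ic):
        graph, ic = small_corpus_ic
        assert lin(graph, ic, "d1", "d1") == 1.0

    def test_root_only_common_ancestor_is_zero(self, small_corpus_ic):
        graph, ic = small_corpus_ic
        assert lin(graph, ic, "d1", "c") == 0.0

    def test_sibling_value_matches_hand_calculation(self, small_corpus_ic):
        # 2 ln4 / (ln8 + ln8) = 2/3
        graph, ic = small_corpus_ic
        assert lin(graph, ic, "d1", "d2") == pytest.approx(2 / 3, abs=1e-12)
        assert lin(graph, ic, "d1", "b") == pytest.approx(0.8, abs=1e-12)

    def test_zero_ic_pair_definition(self, small_corpus_ic):
        graph, ic = small_corpus_ic
        assert lin(graph, ic, "root", "root") == 1.0
        assert lin(graph, ic, "root", "b") == 0.0

    def test_matches_brute_force_on_random_dag(self):
        rng = np.random.default_rng(19)
        graph = random_entangled_dag(rng, 30)
        ic = _random_ic(graph, 19)
        for t1 in graph.terms:
            for t2 in graph.terms:
                assert lin(graph, ic, t1, t2) == pytest.approx(
                    brute_lin(graph, ic, t1, t2), abs=1e-12)


class TestSetSimilarity:
    def test_self_and_subset_give_one(self, small_corpus_ic):
        graph, ic = small_corpus_ic
        assert asym_sim(ic, graph, {"d1", "d2"}, {"d1", "d2"}) == 1.0
        assert asym_sim(ic, graph, {"d1"}, {"d1", "d2", "c"}) == 1.0

    def test_best_match_mean(self, small_corpus_ic):
        graph, ic = small_corpus_ic
        # d1 matches b at 0.8, d2 matches b at 0.8 -> mean 0.8
        assert asym_sim(ic, graph, {"d1", "d2"}, {"b"}) == pytest.approx(0.8)
        # symmetric direction: b's best match in {d1, d2} is 0.8
        assert sym_sim(ic, graph, {"d1", "d2"}, {"b"}) == pytest.approx(0.8)

    def test_empty_set_is_error(self, small_corpus_ic):
        graph, ic = small_corpus_ic
        with pytest.raises(ValueError):
            asym_sim(ic, graph, set(), {"b"})

    def test_symmetry_and_range_on_random_sets(self):
        rng = np.random.default_rng(5)
        graph = random_entangled_dag(rng, 35)
        ic = _random_ic(graph, 5)
        terms = sorted(graph.terms)
        for _ in range(100):
            s1 = {terms[i] for i in rng.integers(0, 35, size=4)}
            s2 = {terms[i] for i in rng.integers(0, 35, size=4)}
            v12, v21 = sym_sim(ic, graph, s1, s2), sym_sim(ic, graph, s2, s1)
            assert v12 == pytest.approx(v21, abs=1e-12)
            assert 0.0 <= v12 <= 1.0
            assert sym_sim(ic, graph, s1, s1) == pytest.approx(1.0, abs=1e-12)

    def test_shared_high_ic_term_never_decreases_similarity(self):
        rng = np.random.default_rng(13)
        graph = random_entangled_dag(rng, 35)
        ic = _random_ic(graph, 13)
        terms = sorted(graph.terms)
        rare = max(terms, key=lambda t: ic.ic[t])
        for _ in range(50):
            s1 = {terms[i] for i in rng.integers(0, 35, size=4)}
            s2 = {terms[i] for i in rng.integers(0, 35, size=4)}
            before = sym_sim(ic, graph, s1, s2)
            after = sym_sim(ic, graph, s1 | {rare}, s2 | {rare})
            assert after >= before - 1e-9


class TestGroupSimilarity:
    def test_identical_singletons(self, small_corpus_ic):
        graph, ic = small_corpus_ic
        assert group_sim(ic, graph, [frozenset({"d1"})],
                         [frozenset({"d1"})]) == 1.0

    def test_cross_pair_enumeration(self, small_corpus_ic):
        graph, ic = small_corpus_ic
        g1 = [frozenset({"d1"}), frozenset({"c"})]
        g2 = [frozenset({"d2"}), frozenset({"b"})]
        expected = np.mean([sym_sim(ic, graph, a, b) for a in g1 for b in g2])
        assert group_sim(ic, graph, g1, g2) == pytest.approx(expected)

    def test_empty_individuals_skipped_not_scored(self, small_corpus_ic):
        graph, ic = small_corpus_ic
        value = group_sim(ic, graph, [frozenset({"d1"}), frozenset()],
                          [frozenset({"d1"})])
        assert value == 1.0
        with pytest.raises(ValueError):
            group_sim(ic, graph, [frozenset()], [frozenset({"d1"})])


class TestVariantMatrixAndClustering:
    def test_matrix_matches_direct_group_sim(self, tiny_cohort, toy40):
        ic = cohort_information_content(tiny_cohort, toy40)
        m = variant_similarity_matrix(tiny_cohort, ic, toy40,
                                      ["m.3243A>G", "m.8993T>G"])
        groups = {
            v: [p.hpo_terms for p in tiny_cohort.carriers(v)]
            for v in m.labels}
        direct = group_sim(ic, toy40, groups["m.3243A>G"],
                           groups["m.8993T>G"])
        assert m.values[0, 1] == pytest.approx(direct)
        assert np.allclose(m.values, m.values.T)

    def test_variant_without_phenotyped_probands_is_error(self, toy40):
        cohort = CohortTable([make_patient("P1", "m.3243A>G", {"T:0104"}),
                              make_patient("P2", "m.8993T>G", set())])
        ic = cohort_information_content(cohort, toy40)
        with pytest.raises(ValueError, match="m.8993T>G"):
            variant_similarity_matrix(cohort, ic, toy40,
                                      ["m.3243A>G", "m.8993T>G"])

    def test_block_diagonal_recovery(self):
        labels = [f"v{i}" for i in range(6)]
        values = np.full((6, 6), 0.1)
        values[:3, :3] = 0.9
        values[3:, 3:] = 0.9
        np.fill_diagonal(values, 1.0)
        result = cluster_variants(SimilarityMatrix(labels, values), 2)
        left = {result.labels[l] for l in labels[:3]}
        right = {result.labels[l] for l in labels[3:]}
        assert len(left) == 1 and len(right) == 1 and left != right

    def test_degenerate_cluster_counts(self):
        labels = ["a", "b", "c"]
        values = np.eye(3) * 0.5 + 0.5
        m = SimilarityMatrix(labels, values)
        assert len(set(cluster_variants(m, 3).labels.values())) == 3
        assert len(set(cluster_variants(m, 1).labels.values())) == 1

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(2)
        n = 8
        raw = rng.uniform(0.0, 1.0, (n, n))
        values = (raw + raw.T) / 2
        np.fill_diagonal(values, 1.0)
        labels = [f"v{i}" for i in range(n)]
        base = cluster_variants(SimilarityMatrix(labels, values), 3).labels
        perm = rng.permutation(n)
        shuffled = cluster_variants(
            SimilarityMatrix([labels[i] for i in perm],
                             values[np.ix_(perm, perm)]), 3).labels
        partition = lambda lab: frozenset(
            frozenset(l for l in labels if lab[l] == c)
            for c in set(lab.values()))
        assert partition(base) == partition(shuffled)

    def test_asymmetric_matrix_rejected(self):
        values = np.array([[1.0, 0.2], [0.4, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            SimilarityMatrix(["a", "b"], values)


class TestClusterSummaryAndProfiles:
    def test_shared_single_term(self, toy40):
        cohort = CohortTable([make_patient(f"P{i}", "m.3243A>G", {"T:0104"})
                              for i in range(4)])
        most_common, specific = cluster_summary(cohort, toy40, ["m.3243A>G"])
        assert most_common == "T:0104"
        assert specific == {"T:0104"}

    def test_threshold_excludes_minority_terms(self, toy40):
        patients = [make_patient(f"P{i}", "m.3243A>G", {"T:0104"})
                    for i in range(3)]
        patients.append(make_patient("P4", "m.3243A>G", {"T:0301"}))
        _, specific = cluster_summary(CohortTable(patients), toy40,
                                      ["m.3243A>G"])
        assert "T:0301" not in specific  # present in 25% only

    def test_chain_keeps_most_specific(self, toy40):
        # all probands carry sensorineural hearing impairment, so both it
        # and its parent pass 50%; only the leaf is reported
        cohort = CohortTable([make_patient(f"P{i}", "m.1555A>G", {"T:0502"})
                              for i in range(4)])
        most_common, specific = cluster_summary(cohort, toy40, ["m.1555A>G"])
        assert specific == {"T:0502"}

    def test_system_profile_fractions(self, toy40):
        patients = [make_patient(f"P{i}", "m.3243A>G", {"T:0104"})
                    for i in range(3)]
        patients.append(make_patient("P4", "m.3243A>G", {"T:0301"}))
        profile = system_profile(CohortTable(patients), toy40, "m.3243A>G")
        assert profile["T:0100"] == 0.75   # nervous system via deep term
        assert profile["T:0300"] == 0.25
        assert profile["T:0600"] == 0.0
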