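import math

import numpy as np
import pytest

from mitotriage.ontology import (
    Ontology,
    PhenotypeProfile,
    compute_ic,
)
from mitotriage.similarity import (
    PatientScore,
    ReferenceProfileTable,
    SimilarityScorer,
    lin_sim,
    profile_sim,
    score_patient,
)

from _oracles import brute_lin, brute_profile_sim, random_dag_parents


class TestLinSim:
    def test_self_similarity_is_one(self, diamond_ont, diamond_ic):
        assert lin_sim(diamond_ic, diamond_ont, "C", "C") == pytest.approx(1.0)

    def test_root_similarity_is_zero(self, diamond_ont, diamond_ic):
        assert lin_sim(diamond_ic, diamond_ont, "R", "C") == 0.0

    def test_diamond_hand_value(self, diamond_ont, diamond_ic):
        # MICA(A, C) = A with IC ln2; 2·ln2 / (ln2 + ln4) = 2/3
        assert lin_sim(diamond_ic, diamond_ont, "A", "C") == pytest.approx(
            2 / 3, abs=1e-12)

    def test_symmetric(self, diamond_ont, diamond_ic):
        assert lin_sim(diamond_ic, diamond_ont, "A", "C") == lin_sim(
            diamond_ic, diamond_ont, "C", "A")

    def test_zero_over_zero_is_zero_not_nan(self, diamond_ont):
        corpus = [PhenotypeProfile("p", {"A"})]  # IC(A)=IC(R)=0
        ic = compute_ic(diamond_ont, corpus)
        assert lin_sim(ic, diamond_ont, "A", "A") == 0.0


class TestProfileSim:
    def test_self_similarity_is_one(self, diamond_ont, diamond_ic):
        p = PhenotypeProfile("p", {"A", "C"})
        assert profile_sim(diamond_ic, diamond_ont, p, p) == pytest.approx(1.0)

    def test_root_only_overlap_scores_zero(self, diamond_ont, diamond_ic):
        a = PhenotypeProfile("a", {"A"})
        b = PhenotypeProfile("b", {"B"})
        # MICA(A,B) = R with IC 0
        assert profile_sim(diamond_ic, diamond_ont, a, b) == 0.0

    def test_best_match_average_hand_value(self, diamond_ont, diamond_ic):
        a = PhenotypeProfile("a", {"A"})
        b = PhenotypeProfile("b", {"A", "C"})
        # forward: A matches itself -> 1; backward: (1 + 2/3)/2
        expected = 0.5 * (1.0 + (1.0 + 2 / 3) / 2)
        assert profile_sim(diamond_ic, diamond_ont, a, b) == pytest.approx(
            expected, abs=1e-12)

    def test_symmetry_on_random_draws(self, rng):
        for _ in range(20):
            parents = random_dag_parents(rng, int(rng.integers(4, 25)))
            ont = Ontology.from_edges(parents)
            ids = sorted(parents)
            corpus = [PhenotypeProfile(f"p{i}", set(
                rng.choice(ids, size=int(rng.integers(1, 4)), replace=False)))
                for i in range(5)]
            ic = compute_ic(ont, corpus)
            a = PhenotypeProfile("a", set(
                rng.choice(ids, size=int(rng.integers(1, 5)), replace=False)))
            b = PhenotypeProfile("b", set(
                rng.choice(ids, size=int(rng.integers(1, 5)), replace=False)))
            assert profile_sim(ic, ont, a, b) == pytest.approx(
                profile_sim(ic, ont, b, a), abs=1e-15)


class TestScorePatient:
    def _refs(self, *term_sets):
        profiles = [PhenotypeProfile(f"R{i}", terms)
                    for i, terms in enumerate(term_sets)]
        return ReferenceProfileTable(
            profiles=profiles, labels={p.subject_id: "" for p in profiles})

    def test_identical_reference_scores_one(self, diamond_ont, diamond_ic):
        refs = self._refs({"A", "B"}, {"C"})
        patient = PhenotypeProfile("pat", {"C"})
        s = score_patient(diamond_ic, diamond_ont, patient, refs)
        assert s.score == pytest.approx(1.0)
        assert s.best_match_id == "R1"

    def test_argmax_picks_better_reference(self, diamond_ont, diamond_ic):
        refs = self._refs({"B"}, {"A", "C"})
        patient = PhenotypeProfile("pat", {"A"})
        expected = {
            "R0": profile_sim(diamond_ic, diamond_ont, patient,
                              refs.profiles[0]),
            "R1": profile_sim(diamond_ic, diamond_ont, patient,
                              refs.profiles[1]),
        }
        s = score_patient(diamond_ic, diamond_ont, patient, refs)
        best = max(expected, key=expected.get)
        assert s.best_match_id == best
        assert s.score == pytest.approx(expected[best])

    def test_tie_goes_to_first_reference(self, diamond_ont, diamond_ic):
        refs = self._refs({"C"}, {"C"})
        s = score_patient(diamond_ic, diamond_ont,
                          PhenotypeProfile("pat", {"C"}), refs)
        assert s.best_match_id == "R0"

    def test_reported_counts_use_nonredundant_reduction(self, diamond_ont,
                                                        diamond_ic):
        refs = self._refs({"C"})
        patient = PhenotypeProfile("pat", {"A", "B", "C"})  # reduces to {C}
        s = score_patient(diamond_ic, diamond_ont, patient, refs)
        assert s.n_terms == 1
        assert s.mean_ic == pytest.approx(diamond_ic["C"])

    def test_adding_a_reference_never_decreases_score(self, rng, fixture_ont):
        from mitotriage.synthetic import generate_reference_profiles
        refs = generate_reference_profiles(fixture_ont, 6, (4, 8), seed=3)
        ic = compute_ic(fixture_ont, refs.profiles)
        patient = refs.profiles[0]
        for k in range(1, len(refs.profiles)):
            smaller = ReferenceProfileTable(refs.profiles[:k], dict(refs.labels))
            larger = ReferenceProfileTable(refs.profiles[:k + 1],
                                           dict(refs.labels))
            s1 = score_patient(ic, fixture_ont, patient, smaller).score
            s2 = score_patient(ic, fixture_ont, patient, larger).score
            assert s2 >= s1 - 1e-12


class TestScorerEquivalence:
    def test_matrix_scorer_matches_naive_functions(self, rng):
        for _ in range(15):
            parents = random_dag_parents(rng, int(rng.integers(5, 30)))
            ont = Ontology.from_edges(parents)
            ids = sorted(parents)
            corpus = [PhenotypeProfile(f"p{i}", set(
                rng.choice(ids, size=int(rng.integers(1, 4)), replace=False)))
                for i in range(6)]
            ic = compute_ic(ont, corpus)
            scorer = SimilarityScorer(ont, ic)
            t1, t2 = rng.choice(ids, size=2, replace=True)
            assert scorer.term_sim(t1, t2) == pytest.approx(
                lin_sim(ic, ont, t1, t2), abs=1e-12)
            a = PhenotypeProfile("a", set(
                rng.choice(ids, size=int(rng.integers(1, 6)), replace=False)))
            b = PhenotypeProfile("b", set(
                rng.choice(ids, size=int(rng.integers(1, 6)), replace=False)))
            assert scorer.profile_sim(a, b) == pytest.approx(
                profile_sim(ic, ont, a, b), abs=1e-12)

    def test_pure_noise_terms_do_not_raise_score(self, fixture_ont):
        """Terms sharing only the root with a reference cannot help a patient.

        The musculature branch is disjoint (below the root) from the eye
        branch, so adding eye terms to a muscle-phenotype patient can only
        dilute the best-match mean against a muscle-disease reference.
        """
        ref = PhenotypeProfile("ref", {"FX:0000052", "FX:0000053"})
        corpus = [ref, PhenotypeProfile("p2", {"FX:0000034"}),
                  PhenotypeProfile("p3", {"FX:0000037"})]
        ic = compute_ic(fixture_ont, corpus)
        patient = PhenotypeProfile("pat", {"FX:0000052"})
        base = profile_sim(ic, fixture_ont, patient, ref)
        noisy = PhenotypeProfile("pat", {"FX:0000052", "FX:0000034",
                                         "FX:0000037"})
        assert profile_sim(ic, fixture_ont, noisy, ref) <= base + 1e-12
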