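"""EM consensus: hand-computed steps, objective ascent, silver extraction,
entropy scoring and document selection."""

import math

import numpy as np
import pytest

from gnbench import (
    GnbenchError,
    GoldStandard,
    LabelMatrix,
    LabelObject,
    SourceProfile,
    build_label_matrix,
    e_step,
    extract_silver_standard,
    initialize_probabilities,
    label_entropy,
    m_step,
    make_run,
    run_em,
    score_documents,
    select_documents,
)
from gnbench.em import ConsensusResult, penalized_log_posterior


def matrix_from(delta, docs=None):
    delta = np.asarray(delta)
    n, m = delta.shape
    docs = docs or [f"D{j}" for j in range(n)]
    objects = [LabelObject(docs[j], f"G{j}") for j in range(n)]
    return LabelMatrix(objects, [f"S{i}" for i in range(m)], delta)


class TestSteps:
    def test_initialization_is_label_fraction(self):
        m = matrix_from([[1, 0, 0], [1, 1, 1], [1, 1, 0]])
        assert initialize_probabilities(m).tolist() == [1 / 3, 1.0, 2 / 3]

    def test_m_step_all_zero_probabilities_gives_laplace_half(self):
        m = matrix_from([[1, 0], [0, 1]])
        for prof in m_step(m, np.zeros(2)):
            assert prof.sensitivity == pytest.approx(0.5)

    def test_m_step_hand_computed(self):
        m = matrix_from([[1, 1], [1, 1]])  # one source in two copies: both true
        profs = m_step(m, np.array([1.0, 0.0]))
        assert profs[0].sensitivity == pytest.approx(2 / 3)
        assert profs[0].specificity == pytest.approx(1 / 3)

    def test_m_step_perfect_agreement_approaches_one(self):
        n1 = 60
        delta = np.ones((n1, 1), dtype=np.uint8)
        m = matrix_from(delta)
        prof = m_step(m, np.ones(n1))[0]
        assert prof.sensitivity == pytest.approx((n1 + 1) / (n1 + 2))

    def test_e_step_uninformative_sources_return_prior(self):
        m = matrix_from([[1, 0], [0, 1]])
        profs = [SourceProfile("S0", 0.5, 0.5), SourceProfile("S1", 0.5, 0.5)]
        for prior in (0.1, 0.5, 0.9):
            assert e_step(m, profs, prior) == pytest.approx([prior, prior])

    def test_e_step_two_agreeing_good_sources(self):
        m = matrix_from([[1, 1]])
        profs = [SourceProfile("S0", 0.9, 0.9), SourceProfile("S1", 0.9, 0.9)]
        assert e_step(m, profs, 0.5)[0] == pytest.approx(0.81 / 0.82)

    def test_e_step_symmetric_disagreement_gives_half(self):
        m = matrix_from([[1, 0]])
        profs = [SourceProfile("S0", 0.8, 0.8), SourceProfile("S1", 0.8, 0.8)]
        assert e_step(m, profs, 0.5)[0] == pytest.approx(0.5)

    def test_e_step_matches_direct_product_formula(self):
        rng = np.random.default_rng(0)
        m = matrix_from(rng.integers(0, 2, size=(40, 14)))
        profs = [
            SourceProfile(f"S{i}", rng.uniform(0.55, 0.95), rng.uniform(0.55, 0.95))
            for i in range(14)
        ]
        prior = 0.3
        p = e_step(m, profs, prior)
        for j in range(m.n_objects):
            a = b = 1.0
            for i, pr in enumerate(profs):
                if m.delta[j, i]:
                    a *= pr.sensitivity
                    b *= 1 - pr.specificity
                else:
                    a *= 1 - pr.sensitivity
                    b *= pr.specificity
            direct = prior * a / (prior * a + (1 - prior) * b)
            assert p[j] == pytest.approx(direct, abs=1e-12)

    def test_prior_monotonicity_at_fixed_profiles(self):
        rng = np.random.default_rng(3)
        m = matrix_from(rng.integers(0, 2, size=(30, 5)))
        profs = m_step(m, initialize_probabilities(m))
        p_low = e_step(m, profs, 0.01)
        p_high = e_step(m, profs, 0.5)
        assert (p_low <= p_high + 1e-15).all()


class TestRunEm:
    def test_unanimous_objects_converge_to_confident_truth(self):
        # 10 objects endorsed by all 5 sources, one singleton endorsement
        # per source for contrast (an all-ones matrix has no negatives,
        # hence no specificity signal, and EM settles at the symmetric
        # point 0.5)
        delta = np.vstack([np.ones((10, 5), dtype=np.uint8), np.eye(5, dtype=np.uint8)])
        res = run_em(matrix_from(delta), prior=0.5)
        assert res.converged
        assert (res.p[:10] > 0.9).all()
        assert (res.p[10:] < res.p[:10].min()).all()

    def test_source_permutation_permutes_profiles_not_p(self):
        rng = np.random.default_rng(5)
        delta = rng.integers(0, 2, size=(25, 4))
        m1 = matrix_from(delta)
        m2 = matrix_from(delta[:, ::-1])
        r1, r2 = run_em(m1, 0.4), run_em(m2, 0.4)
        assert r1.p == pytest.approx(r2.p)
        assert [p.sensitivity for p in r1.profiles] == pytest.approx(
            [p.sensitivity for p in r2.profiles][::-1]
        )

    def test_single_object_single_source_fixed_point(self):
        m = matrix_from([[1]])
        res = run_em(m, prior=0.5, tol=1e-12)
        a, b = res.profiles[0].sensitivity, res.profiles[0].specificity
        # converged p must satisfy both the E-step and the M-step equations
        p = res.p[0]
        assert a == pytest.approx((p + 1) / (p + 2), abs=1e-6)
        assert b == pytest.approx(1 / (1 - p + 2), abs=1e-6)
        expected = 0.5 * a / (0.5 * a + 0.5 * (1 - b))
        assert p == pytest.approx(expected, abs=1e-6)

    def test_objective_trace_is_non_decreasing(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            m = matrix_from(rng.integers(0, 2, size=(rng.integers(5, 40), 6)))
            res = run_em(m, prior=float(rng.uniform(0.05, 0.95)))
            diffs = np.diff(res.objective_trace)
            assert (diffs >= -1e-9).all()

    def test_probabilities_interior_after_first_e_step(self):
        m = matrix_from(np.eye(6, dtype=np.uint8))
        res = run_em(m, prior=0.5)
        assert (res.p > 0).all() and (res.p < 1).all()

    def test_identical_profiles_make_p_increasing_in_vote_count(self):
        delta = np.array(
            [[0, 0, 0, 0], [1, 0, 0, 0], [1, 1, 0, 0], [1, 1, 1, 0], [1, 1, 1, 1]]
        )
        m = matrix_from(delta)
        profs = [SourceProfile(f"S{i}", 0.8, 0.7) for i in range(4)]
        p = e_step(m, profs, 0.3)
        assert (np.diff(p) > 0).all()

    def test_non_convergence_warns_not_raises(self):
        rng = np.random.default_rng(1)
        m = matrix_from(rng.integers(0, 2, size=(30, 4)))
        with pytest.warns(RuntimeWarning, match="did not converge"):
            res = run_em(m, prior=0.5, max_iter=1)
        assert not res.converged


class TestSilverAndEntropy:
    def test_threshold_boundary_inclusive(self):
        m = matrix_from([[1], [1]], docs=["D1", "D1"])
        res = ConsensusResult(
            np.array([0.5, 0.5 - 1e-12]), [], 0.5, 1, True, []
        )
        silver = extract_silver_standard(res, m)
        assert silver.annotations == {"D1": {"G0"}}

    def test_all_below_threshold_yields_empty_documents(self):
        m = matrix_from([[1], [1]], docs=["D1", "D2"])
        res = ConsensusResult(np.array([0.1, 0.2]), [], 0.5, 1, True, [])
        silver = extract_silver_standard(res, m)
        assert silver.annotations == {"D1": set(), "D2": set()}

    def test_misaligned_inputs_rejected(self):
        m = matrix_from([[1], [1]])
        res = ConsensusResult(np.array([0.5]), [], 0.5, 1, True, [])
        with pytest.raises(GnbenchError, match="align"):
            extract_silver_standard(res, m)

    @pytest.mark.parametrize(
        "p,expected",
        [(0.5, math.log(2)), (0.0, 0.0), (1.0, 0.0), (0.1, 0.3251)],
    )
    def test_label_entropy_values(self, p, expected):
        assert label_entropy(p) == pytest.approx(expected, abs=1e-4)

    def test_label_entropy_rejects_invalid_probability(self):
        with pytest.raises(GnbenchError):
            label_entropy(1.5)

    def test_document_scores_sum_entropies(self):
        m = matrix_from([[1], [1], [1]], docs=["D1", "D1", "D2"])
        res = ConsensusResult(np.array([0.5, 0.5, 1.0]), [], 0.5, 1, True, [])
        scores = score_documents(res, m)
        assert scores["D1"] == pytest.approx(2 * math.log(2))
        assert scores["D2"] == 0.0


class TestSelectDocuments:
    @staticmethod
    def _teams(seed=0, n_docs=8):
        rng = np.random.default_rng(seed)
        idents = [f"G{i}" for i in range(5)]
        teams = {}
        for t in range(3):
            runs = []
            for r in range(2):
                entries = {}
                for d in range(n_docs):
                    n = int(rng.integers(1, 4))
                    chosen = rng.choice(idents, size=n, replace=False)
                    entries[f"D{d}"] = [
                        (g, float(rng.uniform())) for g in chosen
                    ]
                runs.append(make_run(f"T{t}_R{r}", entries))
            teams[f"T{t}"] = runs
        return teams

    def test_single_run_teams_reduce_to_one_trial(self):
        teams = {k: [v[0]] for k, v in self._teams().items()}
        sel1 = select_documents(teams, n_docs=3, n_trials=1, seed=1)
        sel5 = select_documents(teams, n_docs=3, n_trials=5, seed=2)
        assert sel1.chosen == sel5.chosen
        for doc in sel1.doc_scores:
            assert sel1.doc_scores[doc] == pytest.approx(sel5.doc_scores[doc])

    def test_single_trial_matches_hand_pipeline(self):
        teams = {k: [v[0]] for k, v in self._teams(seed=4).items()}
        runs = [teams[t][0] for t in sorted(teams)]
        matrix = build_label_matrix(runs)
        res = run_em(matrix, prior=0.5)
        expected = score_documents(res, matrix)
        sel = select_documents(teams, n_docs=2, n_trials=1, seed=0)
        for doc, s in expected.items():
            assert sel.doc_scores[doc] == pytest.approx(s)
        ranked = sorted(expected, key=lambda d: (-expected[d], d))
        assert sel.chosen == ranked[:2]

    def test_same_seed_reproduces_selection(self):
        teams = self._teams(seed=9)
        s1 = select_documents(teams, n_docs=4, n_trials=10, seed=42)
        s2 = select_documents(teams, n_docs=4, n_trials=10, seed=42)
        assert s1.chosen == s2.chosen and s1.doc_scores == s2.doc_scores

    def test_requesting_too_many_documents_rejected(self):
        teams = self._teams()
        with pytest.raises(GnbenchError, match="cannot select"):
            select_documents(teams, n_docs=1000, n_trials=1, seed=0)
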