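"""SSQ scoring and the Friedman / Conover scene statistics."""

import math

import numpy as np
import pytest
from scipy import stats

from vreeg.surveys import (
    conover_posthoc,
    friedman_test,
    scene_score_matrix,
    score_ssq,
    score_ssq_table,
    summarize_ssq,
)
from vreeg.synth import QuestionnaireConfig, generate_questionnaires

# ---------------------------------------------------------------------------
# independent oracles, coded naively from the textbook definitions


def oracle_friedman(matrix):
    """Tie-corrected Friedman chi-square via explicit per-block ranking."""
    m = [list(row) for row in matrix]
    n, k = len(m), len(m[0])
    ranks = []
    ties_term = 0.0
    for row in m:
        order = sorted(range(k), key=lambda j: row[j])
        r = [0.0] * k
        j = 0
        while j < k:
            g = [order[j]]
            while j + len(g) < k and row[order[j + len(g)]] == row[order[j]]:
                g.append(order[j + len(g)])
            mid = sum(range(j + 1, j + len(g) + 1)) / len(g)
            for idx in g:
                r[idx] = mid
            ties_term += len(g) ** 3 - len(g)
            j += len(g)
        ranks.append(r)
    col_sums = [sum(ranks[i][j] for i in range(n)) for j in range(k)]
    chi2 = (12.0 / (n * k * (k + 1))) * sum(R * R for R in col_sums) \
        - 3.0 * n * (k + 1)
    correction = 1.0 - ties_term / (n * k * (k * k - 1))
    chi2 /= correction
    p = stats.chi2.sf(chi2, k - 1)
    return chi2, p, ranks, col_sums


def oracle_conover(matrix):
    """Pairwise Conover p-values via the rank-ANOVA LSD, coded with loops."""
    _, _, ranks, col_sums = oracle_friedman(matrix)
    n, k = len(ranks), len(ranks[0])
    a1 = sum(ranks[i][j] ** 2 for i in range(n) for j in range(k))
    b1 = sum(R * R for R in col_sums)
    df = (n - 1) * (k - 1)
    denom = math.sqrt(2.0 * (n * a1 - b1) / df)
    p = [[1.0] * k for _ in range(k)]
    for i in range(k):
        for j in range(k):
            if i != j:
                t = abs(col_sums[i] - col_sums[j]) / denom
                p[i][j] = min(2.0 * stats.t.sf(t, df), 1.0)
    return np.array(p)


# ---------------------------------------------------------------------------


class TestScoreSSQ:
    def test_zero_response(self):
        s = score_ssq([0] * 16)
        assert s.N == s.O == s.D == s.TS == 0

    def test_total_score_formula(self):
        # raw subscale sums (2, 1, 0): one nausea-only item at 2 and one
        # oculomotor-only item at 1 -> TS = 3 x 3.74 = 11.22
        items = [0] * 16
        items[6] = 2   # sweating -> N only
        items[1] = 1   # fatigue -> O only
        s = score_ssq(items)
        assert (s.raw_N, s.raw_O, s.raw_D) == (2, 1, 0)
        assert s.TS == pytest.approx(11.22)

    def test_single_oculomotor_unit(self):
        items = [0] * 16
        items[2] = 1   # headache -> O only
        s = score_ssq(items)
        assert s.O == pytest.approx(7.58)
        assert s.N == 0 and s.D == 0

    def test_overlapping_items_count_in_both_subscales(self):
        items = [0] * 16
        items[7] = 1   # nausea -> N and D
        s = score_ssq(items)
        assert s.raw_N == 1 and s.raw_D == 1
        assert s.N == pytest.approx(9.54)
        assert s.D == pytest.approx(13.92)

    def test_out_of_range_rating_rejected(self):
        with pytest.raises(ValueError):
            score_ssq([4] + [0] * 15)

    def test_table_scoring_and_summary(self):
        cfg = QuestionnaireConfig(seed=3)
        ssq, _, _ = generate_questionnaires(cfg, 8)
        scores = score_ssq_table(ssq)
        assert len(scores) == 8 * 5
        summary = summarize_ssq(scores)
        assert set(summary["scene"]) == set(cfg.ssq_severity)
        assert (summary.filter(like="_mean") >= 0).all().all()


class TestFriedman:
    def test_perfect_ordering_closed_form(self):
        # 3 subjects ranking 3 scenes identically: rank sums 3/6/9 -> chi2=6
        m = [[1, 2, 3], [10, 20, 30], [2, 5, 9]]
        res = friedman_test(m)
        assert res.statistic == pytest.approx(6.0)
        assert res.df == 2

    def test_identical_scores_give_zero(self):
        m = np.ones((4, 3)) * 7.0
        res = friedman_test(m)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(5):
            m = rng.integers(0, 10, size=(4, 3)).astype(float)
            if np.ptp(m, axis=1).max() == 0:
                continue
            res = friedman_test(m)
            chi2, p, _, _ = oracle_friedman(m)
            assert res.statistic == pytest.approx(chi2, abs=1e-10)
            assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_missing_cells_rejected(self):
        m = np.ones((4, 3)); m[0, 0] = np.nan
        with pytest.raises(ValueError):
            friedman_test(m)


class TestConover:
    def test_diagonal_and_symmetry(self, rng):
        m = rng.standard_normal((10, 4))
        ph = conover_posthoc(m)
        p = ph.p_values.to_numpy()
        np.testing.assert_allclose(np.diag(p), 1.0)
        np.testing.assert_allclose(p, p.T)
        assert ((0 <= p) & (p <= 1)).all()

    @pytest.mark.parametrize("shape,seed", [((10, 3), 5), ((12, 5), 17)])
    def test_matches_textbook_oracle(self, shape, seed):
        m = np.random.default_rng(seed).integers(0, 6, size=shape)
        p_pkg = conover_posthoc(m).p_values.to_numpy()
        p_orc = oracle_conover(m)
        np.testing.assert_allclose(p_pkg, p_orc, atol=1e-10)

    def test_degenerate_rank_variance(self):
        m = np.tile([[1.0, 2.0, 3.0]], (5, 1))  # identical rankings, no ties
        with pytest.warns(RuntimeWarning):
            ph = conover_posthoc(m)
        # perfectly consistent rankings leave zero residual rank variance
        off = ~np.eye(3, dtype=bool)
        assert (ph.p_values.to_numpy()[off] == 1.0).all()

    def test_holm_adjustment_monotone(self, rng):
        m = rng.standard_normal((12, 4)) + np.arange(4) * 0.8
        raw = conover_posthoc(m, adjust="none").p_values.to_numpy()
        adj = conover_posthoc(m, adjust="holm").p_values.to_numpy()
        assert (adj >= raw - 1e-12).all()


class TestRankInvariance:
    def test_subject_shift_leaves_tests_unchanged(self, rng):
        m = rng.standard_normal((8, 4))
        shifted = m.copy()
        shifted[3] += 100.0  # constant added to one subject's scores
        assert friedman_test(m).statistic == pytest.approx(
            friedman_test(shifted).statistic, abs=1e-12)
        np.testing.assert_allclose(
            conover_posthoc(m).p_values.to_numpy(),
            conover_posthoc(shifted).p_values.to_numpy(), atol=1e-12)


class TestSceneSeverityPattern:
    def test_synthetic_severity_ordering_detected(self):
        # configured severities order the roller coaster above the calm
        # scene; the omnibus test should detect this at n=32
        hits_sig, hits_cell = 0, 0
        for seed in range(8):
            ssq, _, _ = generate_questionnaires(
                QuestionnaireConfig(seed=seed), 32)
            scores = score_ssq_table(ssq)
            m, scenes = scene_score_matrix(scores, "TS")
            if friedman_test(m).p_value < 0.01:
                hits_sig += 1
            p = conover_posthoc(m, conditions=scenes).p_values
            off = p.where(~np.eye(len(scenes), dtype=bool))
            if off.min().min() == p.loc["TL", "RC"]:
                hits_cell += 1
        assert hits_sig >= 7
        assert hits_cell >= 7
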