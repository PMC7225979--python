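"""Kaplan-Meier and log-rank: hand-checked product limits, agreement with
an independent survival library, invariances, and simulation power."""

import numpy as np
import pytest
from scipy import stats

from oamlseq.model import SurvivalRecord
from oamlseq.recurrence import build_matrix
from oamlseq.simulate import generate_survival
from oamlseq.survival import (
    compare_by_gene,
    km_estimate,
    logrank_test,
    median_survival,
)
from conftest import make_call
from oracles import empirical_survival


def _rec(time, event, pid=None, endpoint="PFS"):
    return SurvivalRecord(patient_id=pid or f"p{time}-{event}", time=time,
                          event=event, endpoint=endpoint)


def _records(times, events, prefix="p"):
    return [SurvivalRecord(patient_id=f"{prefix}{i}", time=t, event=bool(e))
            for i, (t, e) in enumerate(zip(times, events))]


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate(_records([1, 2, 3], [0, 0, 0]))
        assert curve.empty  # no steps: S is identically 1

    def test_no_censoring_equals_empirical_survival(self):
        curve = km_estimate(_records([1, 2, 3], [1, 1, 1]))
        assert list(curve["survival"]) == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_censoring_shrinks_risk_set_without_step(self):
        curve = km_estimate(_records([1, 2, 3], [1, 0, 1]))
        assert list(curve["time"]) == [1.0, 3.0]
        assert list(curve["survival"]) == pytest.approx([2 / 3, 0.0])

    def test_random_uncensored_curves_match_empirical(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            times = rng.exponential(10, size=30).round(1) + 0.1
            curve = km_estimate(_records(times, np.ones_like(times)))
            expected = empirical_survival(times, curve["time"])
            assert np.allclose(curve["survival"], expected, atol=1e-12)

    def test_survival_non_increasing_and_counts_consistent(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(10, size=50) + 0.1
        events = rng.random(50) < 0.6
        curve = km_estimate(_records(times, events))
        assert (np.diff(curve["survival"]) <= 1e-12).all()
        assert curve["n_events"].sum() == events.sum()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([])

    def test_median_survival(self):
        assert median_survival(_records([2, 4, 6, 8], [1, 1, 1, 1])) == 4.0
        assert np.isnan(median_survival(_records([5, 6], [0, 0])))


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        grp = _records([1, 3, 5, 7], [1, 1, 0, 1])
        res = logrank_test(grp, _records([1, 3, 5, 7], [1, 1, 0, 1], "q"))
        assert res.chi_square == 0.0
        assert res.p_value == 1.0

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            logrank_test(_records([1], [0]), _records([2], [0], "q"))

    def test_label_swap_invariance(self):
        a = _records([1, 2, 5, 9], [1, 1, 1, 0], "a")
        b = _records([3, 4, 8], [1, 0, 1], "b")
        r1, r2 = logrank_test(a, b), logrank_test(b, a)
        assert r1.chi_square == pytest.approx(r2.chi_square)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_monotone_time_transform_invariance(self):
        rng = np.random.default_rng(8)
        t_a, t_b = rng.exponential(5, 20) + 0.1, rng.exponential(9, 20) + 0.1
        e_a, e_b = rng.random(20) < 0.7, rng.random(20) < 0.7
        base = logrank_test(_records(t_a, e_a, "a"), _records(t_b, e_b, "b"))
        warped = logrank_test(_records(np.exp(t_a / 10), e_a, "a"),
                              _records(np.exp(t_b / 10), e_b, "b"))
        assert warped.chi_square == pytest.approx(base.chi_square, rel=1e-9)

    def test_matches_independent_library_with_ties(self):
        """Statistic and p agree with lifelines on random tied, censored
        datasets of <= 8 records per group."""
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(12)
        for _ in range(25):
            n_a, n_b = rng.integers(2, 9, size=2)
            t_a = rng.integers(1, 6, size=n_a).astype(float)
            t_b = rng.integers(1, 6, size=n_b).astype(float)
            e_a = rng.random(n_a) < 0.7
            e_b = rng.random(n_b) < 0.7
            if not (e_a.any() or e_b.any()):
                continue
            ours = logrank_test(_records(t_a, e_a, "a"), _records(t_b, e_b, "b"))
            ref = lifelines_stats.logrank_test(t_a, t_b, e_a, e_b)
            assert ours.chi_square == pytest.approx(ref.test_statistic,
                                                    rel=1e-9, abs=1e-12)
            assert ours.p_value == pytest.approx(ref.p_value,
                                                 rel=1e-9, abs=1e-12)

    def test_power_at_hazard_ratio_four(self):
        """HR 4 with 200 uncensored patients per group rejects at
        alpha = 0.01 in >= 95% of 100 replicates."""
        rng = np.random.default_rng(2024)
        rejections = 0
        for _ in range(100):
            t_a = rng.exponential(1.0, 200) + 1e-9
            t_b = rng.exponential(4.0, 200) + 1e-9
            ones = np.ones(200, dtype=bool)
            res = logrank_test(_records(t_a, ones, "a"), _records(t_b, ones, "b"))
            rejections += res.p_value < 0.01
        assert rejections >= 95


class TestCompareByGene:
    def _matrix(self, n_mut, n_wt):
        pats = [f"M{i}" for i in range(n_mut)] + [f"W{i}" for i in range(n_wt)]
        calls = [make_call(patient_id=f"M{i}", sample_id=f"M{i}-S")
                 for i in range(n_mut)]
        return build_matrix(calls, pats, ["JAK3"]), pats

    def test_reports_group_sizes(self):
        """A 6-mutant vs 39-wild-type comparison reports (6, 39)."""
        matrix, pats = self._matrix(6, 39)
        recs = generate_survival(matrix, "JAK3",
                                 {"median_pfs_wt": 60, "hazard_ratio_mut": 4,
                                  "censor_rate": 0.0}, seed=5)
        cmp = compare_by_gene(matrix, recs, "JAK3", "PFS")
        assert (cmp.result.n_a, cmp.result.n_b) == (6, 39)

    def test_single_group_rejected(self):
        matrix, pats = self._matrix(0, 10)
        recs = generate_survival(matrix, "JAK3",
                                 {"censor_rate": 0.0}, seed=1)
        with pytest.raises(ValueError, match="single group"):
            compare_by_gene(matrix, recs, "JAK3")

    def test_absent_gene_rejected(self):
        matrix, _ = self._matrix(3, 3)
        with pytest.raises(KeyError):
            compare_by_gene(matrix, [], "NOPE")

    def test_elevated_hazard_shortens_mutant_median(self):
        matrix, _ = self._matrix(150, 150)
        recs = generate_survival(matrix, "JAK3",
                                 {"median_pfs_wt": 60, "hazard_ratio_mut": 4,
                                  "censor_rate": 0.0}, seed=77)
        cmp = compare_by_gene(matrix, recs, "JAK3", "PFS")
        assert cmp.medians["mutant"] < cmp.medians["wildtype"]

    def test_null_hazard_gives_uniform_p_values(self):
        """With an OS hazard ratio of 1, log-rank p-values over 200
        replicates are uniform (KS not rejecting at alpha = 0.01)."""
        matrix, _ = self._matrix(20, 25)
        pvals = []
        for seed in range(200):
            recs = generate_survival(matrix, "JAK3",
                                     {"median_pfs_wt": 60,
                                      "hazard_ratio_mut": 1.0,
                                      "hazard_ratio_os": 1.0,
                                      "censor_rate": 0.0}, seed=seed)
            cmp = compare_by_gene(matrix, recs, "JAK3", "OS")
            pvals.append(cmp.result.p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
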