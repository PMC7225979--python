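"""Copy-number pipeline: mean-shift normalization, log2 ratios, state
calls, Fisher/BH recurrence enrichment, and planted-event recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from oamlseq.cnv import (
    CnvCallSet,
    call_cnv,
    call_states,
    log2_ratio,
    normalize_pair,
    recurrence_enrichment,
)
from oamlseq.model import CoveragePair
from oamlseq.simulate import CohortConfig, generate_cohort, plant_cnv
from oracles import bh_oracle, fisher_greater_oracle


def _pair(tumor, normal, genes=None, pid="P001"):
    tumor = np.asarray(tumor, dtype=float)
    genes = genes or [f"G{i}" for i in range(len(tumor))]
    return CoveragePair(pid, genes, tumor, np.asarray(normal, dtype=float))


class TestNormalizePair:
    def test_equal_means_unchanged(self):
        p = normalize_pair(_pair([10, 20, 30], [30, 20, 10]))
        assert np.array_equal(p.tumor_cov, [10, 20, 30])
        assert np.array_equal(p.normal_cov, [30, 20, 10])

    def test_lower_mean_sample_shifted_additively(self):
        p = normalize_pair(_pair([30, 30], [20, 20]))
        assert np.array_equal(p.tumor_cov, [30, 30])
        assert np.array_equal(p.normal_cov, [30, 30])

    def test_single_gene_pair_equalizes(self):
        p = normalize_pair(_pair([10], [4]))
        assert p.normal_cov[0] == 10
        assert log2_ratio(p)[0] == 0.0

    def test_all_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalize_pair(_pair([0, 0], [10, 10]))

    @given(st.lists(st.floats(0, 1000), min_size=2, max_size=20),
           st.floats(0.5, 500))
    @settings(max_examples=50, deadline=None)
    def test_means_equal_and_differences_preserved(self, tumor, normal_mean):
        if sum(tumor) == 0:
            return
        normal = np.full(len(tumor), normal_mean)
        p = normalize_pair(_pair(tumor, normal))
        assert abs(p.tumor_cov.mean() - p.normal_cov.mean()) < 1e-9
        before = np.diff(np.asarray(tumor))
        after = np.diff(p.tumor_cov)
        assert np.allclose(before, after, atol=1e-9)


class TestLog2Ratio:
    def test_identical_vectors_all_zero(self):
        p = _pair([10, 25, 40], [10, 25, 40])
        assert np.array_equal(log2_ratio(p), [0.0, 0.0, 0.0])

    def test_zero_tumor_coverage_floored(self):
        p = _pair([0], [100])
        assert log2_ratio(p)[0] == pytest.approx(np.log2(0.5 / 100.5))

    def test_noiseless_planted_fold_recovered(self):
        """A +1 log2 fold planted in one of many genes survives the
        additive mean shift to within 0.05."""
        genes = [f"G{i}" for i in range(200)]
        base = _pair(np.full(200, 30.0), np.full(200, 30.0), genes)
        planted = plant_cnv(base, ["G7"], 1.0)
        ratios = log2_ratio(normalize_pair(planted))
        assert ratios[7] == pytest.approx(1.0, abs=0.05)
        others = np.delete(ratios, 7)
        assert np.abs(others).max() < 0.05


class TestCallStates:
    @pytest.mark.parametrize("ratio,state", [
        (0.0, "neutral"),
        (0.30, "gain"),       # inclusive boundary
        (-0.30, "loss"),
        (-0.58, "loss"),      # one-copy loss at 2/3 tumor purity
        (0.29, "neutral"),
    ])
    def test_thresholds(self, ratio, state):
        assert call_states(np.array([ratio]))[0] == state

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            call_states(np.array([0.0]), gain_thresh=-0.1)

    def test_both_zero_coverage_flagged_nocall(self):
        pair = _pair([0, 30, 30], [0, 30, 30])
        cs = call_cnv(pair)
        assert cs.states[0] == "nocall"
        assert cs.states[1] == "neutral"


class TestBenjaminiHochberg:
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_bh_matches_step_up_oracle(self, pvals):
        ours = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(ours, bh_oracle(pvals), atol=1e-12)


def _callset(pid, genes, states):
    return CnvCallSet(pid, list(genes), np.zeros(len(genes)),
                      np.array(states, dtype=object))


class TestRecurrenceEnrichment:
    def test_all_neutral_nothing_significant(self):
        genes = [f"G{i}" for i in range(10)]
        sets = [_callset(f"P{j}", genes, ["neutral"] * 10) for j in range(4)]
        res = recurrence_enrichment(sets)
        assert (res["p_gain"] == 1.0).all() and (res["p_loss"] == 1.0).all()
        assert not res["significant"].any()

    def test_inconsistent_universe_rejected(self):
        a = _callset("P1", ["G1", "G2"], ["neutral"] * 2)
        b = _callset("P2", ["G1", "G3"], ["neutral"] * 2)
        with pytest.raises(ValueError, match="inconsistent"):
            recurrence_enrichment([a, b])

    def test_universal_gain_over_quiet_background_significant(self):
        """A gene gained in 6/6 patients against a ~1% background gain
        rate over 1000 genes clears the BH threshold."""
        rng = np.random.default_rng(5)
        genes = [f"G{i}" for i in range(1000)]
        sets = []
        for j in range(6):
            states = np.where(rng.random(1000) < 0.01, "gain", "neutral")
            states = states.astype(object)
            states[0] = "gain"
            sets.append(_callset(f"P{j}", genes, states))
        res = recurrence_enrichment(sets).set_index("gene")
        assert res.at["G0", "n_gain"] == 6
        assert res.at["G0", "q_gain"] < 0.05

    def test_fisher_p_matches_enumeration_oracle(self):
        genes = ["G0", "G1", "G2", "G3"]
        sets = [
            _callset("P1", genes, ["gain", "neutral", "neutral", "neutral"]),
            _callset("P2", genes, ["gain", "neutral", "loss", "neutral"]),
            _callset("P3", genes, ["gain", "neutral", "neutral", "neutral"]),
        ]
        res = recurrence_enrichment(sets).set_index("gene")
        # focal G0: 3/3 gains; background (9 cells excluding G0): 0 gains
        assert res.at["G0", "p_gain"] == pytest.approx(
            fisher_greater_oracle(3, 0, 0, 9), rel=1e-9)
        assert res.at["G2", "p_loss"] == pytest.approx(
            fisher_greater_oracle(1, 2, 0, 9), rel=1e-9)


class TestPlantedRecovery:
    def test_recurrent_lesion_counts_match_planting(self):
        """Losses planted at a TNFAIP3-like locus in 3/6 pairs and gains
        at a HES4-like locus in 4/6 are reported at exactly those
        recurrence counts."""
        cfg = CohortConfig(seed=101, coverage_means=(20.0, 20.0),
                           coverage_dispersion=0.05)
        cohort = generate_cohort(cfg)
        callsets = [call_cnv(p) for p in cohort.coverage_pairs]
        res = recurrence_enrichment(callsets).set_index("gene")
        assert res.at["TNFAIP3", "n_loss"] == 3
        assert res.at["HES4", "n_gain"] == 4
        assert res.at["TNFAIP3", "q_loss"] < 0.05
        assert res.at["HES4", "q_gain"] < 0.05

    def test_parameter_recovery_across_seeds(self):
        """Planted |log2 fold| >= 0.5 lesions at depth 20, dispersion
        0.05: per-gene recall >= 0.95 and false gain+loss rate <= 0.05 on
        unplanted genes over 20 seeds."""
        hits = total = false = background = 0
        for seed in range(20):
            cfg = CohortConfig(seed=seed, coverage_means=(20.0, 20.0),
                               coverage_dispersion=0.05,
                               n_background_genes=200)
            cohort = generate_cohort(cfg)
            callsets = {p.patient_id: call_cnv(p)
                        for p in cohort.coverage_pairs}
            planted = set()
            for ev in cohort.truth["cnv"]:
                want = "loss" if ev["log2_fold"] < 0 else "gain"
                for g in ev["genes"]:
                    planted.add((ev["patient_id"], g))
                    cs = callsets[ev["patient_id"]]
                    total += 1
                    hits += cs.states[cs.genes.index(g)] == want
            for pid, cs in callsets.items():
                for i, g in enumerate(cs.genes):
                    if (pid, g) not in planted:
                        background += 1
                        false += cs.states[i] in ("gain", "loss")
        assert hits / total >= 0.95
        assert false / background <= 0.05
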