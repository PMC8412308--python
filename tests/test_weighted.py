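import numpy as np
import pandas as pd
import pytest

from expertpool import (
    Assessment,
    Panel,
    WeightVector,
    aggregate_panel,
    estimate_weights,
    interval_weights,
    metadata_weights,
    shape_weights,
    shift_weights,
    weighted_pool,
    weights_for,
)
from expertpool.weights import ALL_WEIGHTED

from conftest import make_constant_proxy_panel


def panel_from_rows(rows, **kw):
    df = pd.DataFrame(
        rows, columns=["participant_id", "claim_id", "round", "lower", "best", "upper"]
    )
    return Panel(df, **kw)


def weights_of(wvs, claim="c1"):
    return wvs[claim].weights


class TestWeightedPool:
    def test_equal_weights_reduce_to_mean(self):
        a = [Assessment(f"p{i}", "c1", 2, np.nan, b, np.nan)
             for i, b in enumerate([0.70, 0.58, 0.85])]
        wv = WeightVector("c1", {f"p{i}": 1 / 3 for i in range(3)}, "test")
        assert weighted_pool(a, wv).value == pytest.approx(0.71, abs=1e-12)

    def test_degenerate_weight_selects_one_expert(self):
        a = [Assessment("p0", "c1", 2, np.nan, 0.9, np.nan),
             Assessment("p1", "c1", 2, np.nan, 0.2, np.nan)]
        wv = WeightVector("c1", {"p0": 1.0, "p1": 0.0}, "test")
        assert weighted_pool(a, wv).value == 0.9

    def test_convex_combination(self):
        a = [Assessment("p0", "c1", 2, np.nan, 1.0, np.nan),
             Assessment("p1", "c1", 2, np.nan, 0.0, np.nan)]
        wv = WeightVector("c1", {"p0": 0.9, "p1": 0.1}, "test")
        assert weighted_pool(a, wv).value == pytest.approx(0.9)

    def test_support_mismatch_is_an_error(self):
        a = [Assessment("p0", "c1", 2, np.nan, 0.5, np.nan)]
        wv = WeightVector("c1", {"p0": 0.5, "p9": 0.5}, "test")
        with pytest.raises(ValueError, match="does not match"):
            weighted_pool(a, wv)

    def test_weight_vector_rejects_bad_sums(self):
        with pytest.raises(ValueError):
            WeightVector("c1", {"p0": 0.6, "p1": 0.6}, "test")
        with pytest.raises(ValueError):
            WeightVector("c1", {"p0": 1.5, "p1": -0.5}, "test")


class TestIntervalWeights:
    def test_narrower_interval_gets_more_weight_hand_example(self):
        panel = panel_from_rows([
            ("p0", "c1", 2, 0.4, 0.45, 0.5),   # width 0.1
            ("p1", "c1", 2, 0.3, 0.5, 0.7),    # width 0.4
        ])
        w = weights_of(interval_weights(panel, "IntWAgg", eps=0.01))
        raw = np.array([1 / 0.11, 1 / 0.41])
        expect = raw / raw.sum()
        assert w["p0"] == pytest.approx(expect[0], abs=1e-12)
        assert w["p1"] == pytest.approx(expect[1], abs=1e-12)
        assert round(w["p0"], 3) == 0.788

    def test_individual_rescaling_rewards_unusual_precision(self):
        # p0's width on c1 is half their usual; p1 is uniformly wide
        panel = panel_from_rows([
            ("p0", "c1", 2, 0.40, 0.45, 0.50),
            ("p0", "c2", 2, 0.30, 0.40, 0.50),
            ("p1", "c1", 2, 0.30, 0.40, 0.50),
            ("p1", "c2", 2, 0.30, 0.40, 0.50),
        ])
        w = weights_of(interval_weights(panel, "IndIntWAgg", eps=0.01))
        assert w["p0"] > w["p1"]

    def test_variance_variant_single_claim_participant_gets_floor(self):
        panel = panel_from_rows([
            ("p0", "c1", 2, 0.40, 0.45, 0.50),
            ("p0", "c2", 2, 0.10, 0.40, 0.90),
            ("p1", "c1", 2, 0.30, 0.40, 0.50),
        ])
        w = weights_of(interval_weights(panel, "VarIndIntWAgg", eps=0.01))
        assert w["p0"] > w["p1"]  # p0 varies, p1 has a single claim (floor)


class TestShapeWeights:
    @pytest.mark.parametrize(
        "triple,asym",
        [((0.2, 0.5, 0.8), 0.0), ((0.2, 0.8, 0.8), 1.0), ((0.2, 0.2, 0.8), 1.0)],
    )
    def test_asymmetry_endpoints(self, triple, asym):
        lo, b, hi = triple
        panel = panel_from_rows([
            ("p0", "c1", 2, lo, b, hi),
            ("p1", "c1", 2, 0.2, 0.5, 0.8),
        ])
        w = weights_of(shape_weights(panel, "AsymWAgg", eps=0.01))
        expect = np.array([asym + 0.01, 0.01])
        expect = expect / expect.sum()
        assert w["p0"] == pytest.approx(expect[0], abs=1e-12)

    def test_symmetric_vs_maximally_asymmetric_hand_example(self):
        panel = panel_from_rows([
            ("p0", "c1", 2, 0.2, 0.5, 0.8),  # a = 0
            ("p1", "c1", 2, 0.2, 0.8, 0.8),  # a = 1
        ])
        w = weights_of(shape_weights(panel, "AsymWAgg", eps=0.01))
        assert w["p1"] / w["p0"] == pytest.approx(1.01 / 0.01, rel=1e-9)

    def test_composites_multiply_normalised_components(self):
        panel = panel_from_rows([
            ("p0", "c1", 2, 0.40, 0.48, 0.50),
            ("p1", "c1", 2, 0.10, 0.40, 0.90),
            ("p0", "c2", 2, 0.40, 0.45, 0.50),
            ("p1", "c2", 2, 0.20, 0.40, 0.80),
        ])
        wi = weights_of(interval_weights(panel, "IndIntWAgg", eps=0.01))
        wa = weights_of(shape_weights(panel, "AsymWAgg", eps=0.01))
        prod = {p: wi[p] * wa[p] for p in wi}
        total = sum(prod.values())
        w = weights_of(shape_weights(panel, "IndIntAsymWAgg", eps=0.01))
        for p in prod:
            assert w[p] == pytest.approx(prod[p] / total, abs=1e-12)


class TestEstimateWeights:
    def test_distance_to_certainty_limits(self):
        panel = panel_from_rows([
            ("p0", "c1", 2, np.nan, 0.5, np.nan),
            ("p1", "c1", 2, np.nan, 0.99, np.nan),
        ])
        w = weights_of(estimate_weights(panel, "DistLimitWAgg", eps=0.01))
        assert w["p0"] == pytest.approx(0.5 / (0.5 + 0.99), abs=1e-12)

    @pytest.mark.parametrize(
        "bests,frac",
        [([0.63, 0.67], 1.0), ([0.65, 0.70], 0.0), ([0.63, 0.65], 0.5)],
    )
    def test_granularity_fraction(self, bests, frac):
        rows = [("p0", f"c{i}", 2, np.nan, b, np.nan) for i, b in enumerate(bests)]
        rows += [("p1", f"c{i}", 2, np.nan, 0.63, np.nan) for i in range(len(bests))]
        panel = panel_from_rows(rows)
        w = weights_of(estimate_weights(panel, "GranWAgg", eps=0.01), claim="c0")
        expect = np.array([frac + 0.01, 1.0 + 0.01])
        expect = expect / expect.sum()
        assert w["p0"] == pytest.approx(expect[0], abs=1e-12)

    def test_granularity_robust_to_float_representation(self):
        # 0.65 may be stored as 0.6500000000000001; still on the 0.05 grid
        rows = [("p0", "c0", 2, np.nan, 0.65000000000000013, np.nan),
                ("p1", "c0", 2, np.nan, 0.63, np.nan)]
        panel = panel_from_rows(rows)
        w = weights_of(estimate_weights(panel, "GranWAgg", eps=0.01), claim="c0")
        assert w["p0"] == pytest.approx(0.01 / 1.02, abs=1e-12)


class TestShiftWeights:
    def make_two_round_panel(self, b2_p0=0.7, bounds_shift_p0=0.0):
        rows = [
            ("p0", "c1", 1, 0.3, 0.5, 0.7),
            ("p1", "c1", 1, 0.3, 0.5, 0.7),
            ("p0", "c1", 2, 0.3 + bounds_shift_p0, b2_p0, 0.7 + bounds_shift_p0),
            ("p1", "c1", 2, 0.3, 0.5, 0.7),
        ]
        return panel_from_rows(rows)

    def test_no_movement_gives_equal_weights(self):
        panel = self.make_two_round_panel(b2_p0=0.5)
        w = weights_of(shift_weights(panel, eps=0.01))
        assert w["p0"] == pytest.approx(0.5, abs=1e-12)

    def test_mover_gets_more_weight_hand_example(self):
        panel = self.make_two_round_panel(b2_p0=0.7)
        w = weights_of(shift_weights(panel, eps=0.01))
        assert w["p0"] == pytest.approx(0.21 / 0.22, abs=1e-12)

    def test_bound_shifts_count_at_quarter_weight(self):
        moved = self.make_two_round_panel(b2_p0=0.7, bounds_shift_p0=0.2)
        w = weights_of(shift_weights(moved, eps=0.01))
        # raw p0 weight: 0.01 + 0.2 + (0.2 + 0.2)/4 = 0.31
        assert w["p0"] == pytest.approx(0.31 / 0.32, abs=1e-12)

    def test_missing_round_one_falls_back_to_eps(self, caplog):
        rows = [
            ("p0", "c1", 1, 0.3, 0.5, 0.7),
            ("p0", "c1", 2, 0.3, 0.7, 0.8),
            ("p1", "c1", 2, 0.3, 0.5, 0.7),  # never gave a round-1 judgement
        ]
        panel = panel_from_rows(rows)
        with caplog.at_level("WARNING"):
            w = weights_of(shift_weights(panel, eps=0.01))
        # p0 raw: 0.01 + |0.7-0.5| + (0 + |0.8-0.7|)/4 = 0.235; p1 raw: eps
        assert w["p1"] == pytest.approx(0.01 / 0.245, abs=1e-12)


class TestMetadataWeights:
    def make_meta_panel(self, comp=(7, 1), quiz=(3.0, 3.0)):
        rows = [("p0", "c1", 2, 0.3, 0.5, 0.7), ("p1", "c1", 2, 0.3, 0.6, 0.7)]
        claim_meta = pd.DataFrame(
            [["p0", "c1", comp[0], 120, 4, "R01;R02;R03;R04"],
             ["p1", "c1", comp[1], 30, 2, "R01;R05"]],
            columns=["participant_id", "claim_id", "comprehension",
                     "comment_words", "reason_count", "reason_codes"],
        )
        quiz_df = pd.DataFrame({"participant_id": ["p0", "p1"], "score": quiz})
        return panel_from_rows(rows).assessments, claim_meta, quiz_df

    def test_comprehension_scale_endpoints(self):
        df, cm, qz = self.make_meta_panel(comp=(7, 1))
        panel = Panel(df, claim_meta=cm, quiz=qz)
        w = weights_of(metadata_weights(panel, "CompWAgg"))
        assert w["p0"] == pytest.approx(7 / 8, abs=1e-12)
        assert w["p1"] == pytest.approx(1 / 8, abs=1e-12)

    def test_equal_quiz_scores_give_equal_weights(self):
        df, cm, qz = self.make_meta_panel(quiz=(3.0, 3.0))
        panel = Panel(df, claim_meta=cm, quiz=qz)
        w = weights_of(metadata_weights(panel, "QuizWAgg"))
        assert w["p0"] == pytest.approx(0.5, abs=1e-12)

    def test_reason_diversity_scales_reason_weights(self):
        df, cm, qz = self.make_meta_panel()
        panel = Panel(df, claim_meta=cm, quiz=qz)
        w1 = weights_of(metadata_weights(panel, "ReasonWAgg", eps=0.01))
        w2 = weights_of(metadata_weights(panel, "ReasonWAgg2", eps=0.01))
        # codebook = {R01..R05}; D_p0 = 4/5, D_p1 = 2/5
        r = np.array([4.01 * (1 + 0.8), 2.01 * (1 + 0.4)])
        expect = r / r.sum()
        assert w2["p0"] == pytest.approx(expect[0], abs=1e-12)
        assert w2["p0"] > w1["p0"]

    def test_metadata_absent_for_all_assessors_is_an_error(self):
        df, cm, qz = self.make_meta_panel()
        panel = Panel(df, claim_meta=cm.iloc[0:0], quiz=qz)
        with pytest.raises(ValueError, match="EngWAgg"):
            metadata_weights(panel, "EngWAgg")


class TestStructuralInvariants:
    @pytest.mark.parametrize("method", ALL_WEIGHTED)
    def test_weights_normalised_nonnegative_on_assessor_support(
        self, small_panel, method
    ):
        wvs = weights_for(small_panel, method)
        analysis = small_panel.analysis_round()
        for claim, wv in wvs.items():
            vals = np.array(list(wv.weights.values()))
            assert (vals >= 0).all()
            assert vals.sum() == pytest.approx(1.0, abs=1e-12)
            assert set(wv.weights) == set(analysis.assessors(claim))

    @pytest.mark.parametrize("method", ALL_WEIGHTED)
    def test_constant_proxies_collapse_to_ar_mean(self, constant_proxy_panel, method):
        agg = aggregate_panel(constant_proxy_panel, method)
        ref = aggregate_panel(constant_proxy_panel, "ArMean")
        assert np.allclose(agg["value"], ref["value"], atol=1e-12, rtol=0)

    def test_permuting_labels_permutes_weights(self, small_panel):
        relabel = {p: f"z{p}" for p in small_panel.participants}
        df = small_panel.assessments.copy()
        df["participant_id"] = df["participant_id"].map(relabel)
        quiz = small_panel.quiz.copy()
        quiz["participant_id"] = quiz["participant_id"].map(relabel)
        cm = small_panel.claim_meta.copy()
        cm["participant_id"] = cm["participant_id"].map(relabel)
        renamed = Panel(df, outcomes=small_panel.outcomes, quiz=quiz, claim_meta=cm)
        for method in ("IntWAgg", "AsymWAgg", "QuizWAgg"):
            orig = weights_for(small_panel, method)
            new = weights_for(renamed, method)
            for claim in orig:
                for pid, w in orig[claim].weights.items():
                    assert new[claim].weights[relabel[pid]] == pytest.approx(w, abs=1e-12)

    def test_proxy_improvement_never_decreases_weight(self):
        base_rows = [
            ("p0", "c1", 2, 0.30, 0.50, 0.70),
            ("p1", "c1", 2, 0.30, 0.50, 0.70),
        ]
        narrower = [("p0", "c1", 2, 0.40, 0.50, 0.60), base_rows[1]]
        w0 = weights_of(interval_weights(panel_from_rows(base_rows), "IntWAgg"))
        w1 = weights_of(interval_weights(panel_from_rows(narrower), "IntWAgg"))
        assert w1["p0"] >= w0["p0"]
        more_asym = [("p0", "c1", 2, 0.30, 0.65, 0.70), base_rows[1]]
        a0 = weights_of(shape_weights(panel_from_rows(base_rows), "AsymWAgg"))
        a1 = weights_of(shape_weights(panel_from_rows(more_asym), "AsymWAgg"))
        assert a1["p0"] >= a0["p0"]
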