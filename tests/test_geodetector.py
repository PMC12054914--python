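"""q statistic, interaction/risk/ecological detectors, discretisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sandfix import (
    StrataMap,
    discretize,
    ecological_detector,
    interaction_detector,
    q_statistic,
    rank_factors,
    risk_detector,
)
from sandfix.geodetector import DegenerateStrataError, detector_report
from sandfix.synth import plant_driver_response


def brute_force_q(y, labels):
    """Independent oracle: explicit SSW/SST sums with population variances."""
    y = np.asarray(y, float).ravel()
    labels = np.asarray(labels).ravel()
    sst = len(y) * np.var(y)
    ssw = sum(len(y[labels == h]) * np.var(y[labels == h]) for h in np.unique(labels))
    return 1.0 - ssw / sst


def smap(labels):
    return StrataMap.from_categorical(np.asarray(labels))


class TestQStatistic:
    def test_perfect_stratification(self):
        assert q_statistic(np.array([1.0, 1, 2, 2]), smap(["a", "a", "b", "b"])) == 1.0

    def test_orthogonal_stratification(self):
        assert q_statistic(np.array([1.0, 2, 1, 2]), smap(["a", "a", "b", "b"])) == pytest.approx(0.0)

    def test_single_stratum_explains_nothing(self):
        y = np.array([1.0, 2, 3, 4])
        assert q_statistic(y, smap(["a"] * 4)) == pytest.approx(0.0)

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            q_statistic(np.ones(4), smap(["a", "a", "b", "b"]))

    def test_matches_brute_force_on_random_fixtures(self, rng):
        for _ in range(100):
            n = int(rng.integers(20, 200))
            k = int(rng.integers(2, 8))
            labels = rng.integers(1, k + 1, size=n)
            if len(np.unique(labels)) < 2:
                continue
            y = rng.normal(size=n) + 0.5 * labels
            assert q_statistic(y, smap(labels)) == pytest.approx(
                brute_force_q(y, labels), abs=1e-12)

    @given(st.floats(0.1, 10), st.floats(-5, 5), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_invariant_under_affine_y_and_relabeling(self, a, b, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(1, 5, size=50)
        y = rng.normal(size=50) + labels
        q0 = q_statistic(y, smap(labels))
        assert q_statistic(a * y + b, smap(labels)) == pytest.approx(q0, abs=1e-9)
        # permute class ids
        perm = rng.permutation(10)
        assert q_statistic(y, smap(perm[labels])) == pytest.approx(q0, abs=1e-12)


class TestInteraction:
    def test_identical_strata_collapse_to_q1(self, rng):
        labels = rng.integers(1, 4, size=60)
        y = rng.normal(size=60) + labels
        q1 = q_statistic(y, smap(labels))
        q12, _ = interaction_detector(y, smap(labels), smap(labels))
        assert q12 == pytest.approx(q1, abs=1e-12)

    def test_nonlinear_enhancement_hand_example(self):
        y = np.array([0.0, 1, 1, 3])
        q12, cat = interaction_detector(y, smap(["a", "a", "b", "b"]), smap(["c", "d", "c", "d"]))
        q1 = q_statistic(y, smap(["a", "a", "b", "b"]))
        assert q1 == pytest.approx(0.47368, abs=1e-5)
        assert q12 == pytest.approx(1.0)
        assert cat == "nonlinear-enhance"

    def test_refinement_never_explains_less(self, rng):
        """Cross-classification refines both partitions, so q12 >= max(q1,q2)."""
        for _ in range(10):
            la = rng.integers(1, 5, size=200)
            lb = rng.integers(1, 4, size=200)
            y = rng.normal(size=200) + la + 0.5 * lb
            q1 = q_statistic(y, smap(la))
            q2 = q_statistic(y, smap(lb))
            q12, _ = interaction_detector(y, smap(la), smap(lb))
            assert q12 >= max(q1, q2) - 1e-12

    def test_degenerate_second_factor(self, rng):
        la = np.repeat([1, 2, 3, 4], 10)
        y = la.astype(float)  # fully determined by A
        q12, cat = interaction_detector(y + rng.normal(0, 1e-6, 40), smap(la), smap(np.ones(40)))
        q1 = q_statistic(y + 0.0, smap(la))
        assert q12 == pytest.approx(1.0, abs=1e-6)
        # B explains nothing: q12 = q1 = q1 + q2, the additive boundary
        assert cat in ("independent", "univariate-weaken")


class TestRiskDetector:
    def test_identical_groups_not_significant(self):
        y = np.array([1.0, 2, 3, 1, 2, 3])
        out = risk_detector(y, smap([1, 1, 1, 2, 2, 2]))
        assert not out["significant"].loc[1, 2]
        assert out["t"].loc[1, 2] == pytest.approx(0.0, abs=1e-12)

    def test_separated_groups_significant(self):
        y = np.array([0.0, 0, 0, 0, 10, 10, 10, 10.0001])
        out = risk_detector(y, smap([1, 1, 1, 1, 2, 2, 2, 2]))
        assert out["significant"].loc[1, 2]

    def test_means_ordering_preserved(self, rng):
        labels = rng.integers(1, 5, size=200)
        y = rng.normal(size=200) + 3.0 * labels
        out = risk_detector(y, smap(labels))
        raw_means = {h: y[labels == h].mean() for h in np.unique(labels)}
        assert out["means"].idxmax() == max(raw_means, key=raw_means.get)

    def test_tiny_stratum_excluded_with_warning(self):
        y = np.array([1.0, 2, 3, 4, 99.0])
        with pytest.warns(UserWarning, match="excluded"):
            out = risk_detector(y, smap([1, 1, 2, 2, 3]))
        assert 3 not in out["means"].index


class TestEcologicalDetector:
    def test_identical_factors_not_significant(self, rng):
        labels = rng.integers(1, 5, size=100)
        y = rng.normal(size=100) + labels
        assert ecological_detector(y, smap(labels), smap(labels)) is False

    def test_perfect_vs_null_factor_significant(self):
        la = np.repeat([1, 2, 3, 4], 25)
        y = la.astype(float)
        assert ecological_detector(y, smap(la), smap(np.ones(100))) is True

    def test_symmetric_under_factor_exchange(self, rng):
        la = rng.integers(1, 6, size=300)
        lb = rng.integers(1, 4, size=300)
        y = rng.normal(size=300) + 2.0 * la
        assert ecological_detector(y, smap(la), smap(lb)) == \
            ecological_detector(y, smap(lb), smap(la))

    def test_planted_dominant_vs_noise_factor(self):
        """The planted driver beats an unrelated stratification in >=95% of seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            strata = rng.integers(1, 6, size=2000)
            y = plant_driver_response(strata, 0.6, 0.4, seed=seed)
            noise = rng.integers(1, 6, size=2000)
            hits += ecological_detector(y, smap(strata), smap(noise))
        assert hits >= 19


class TestRankFactors:
    def test_descending_dense_ranks(self):
        t = rank_factors({"A": 0.3, "B": 0.1})
        assert list(t.index) == ["A", "B"]
        assert list(t["rank"]) == [1, 2]

    def test_ties_share_rank(self):
        t = rank_factors({"A": 0.3, "POP": 0.019, "GDP": 0.019})
        assert t.loc["POP", "rank"] == t.loc["GDP", "rank"] == 2

    def test_planted_dominant_driver_ranks_first(self, scene):
        from sandfix import build_driver_strata

        y = plant_driver_response(scene.soil_type, 0.37, 0.63, seed=11)
        strata = build_driver_strata(scene)
        q = {name: q_statistic(y, s) for name, s in strata.items()}
        assert rank_factors(q).index[0] == "soil_type"


class TestDiscretize:
    def test_quantile_equal_sizes(self):
        sm = discretize(np.arange(1.0, 11.0), method="quantile", k=5)
        counts = np.bincount(sm.labels.ravel())[1:]
        assert (counts == 2).all() and sm.k == 5

    def test_equal_interval_break_at_midpoint(self):
        sm = discretize(np.arange(1.0, 11.0), method="equal_interval", k=2)
        assert sm.breaks == pytest.approx([5.5])
        assert (sm.labels == np.array([1] * 5 + [2] * 5)).all()

    def test_natural_breaks_separates_clusters(self):
        vals = np.concatenate([np.random.default_rng(0).normal(0, 0.1, 50),
                               np.random.default_rng(1).normal(10, 0.1, 50)])
        sm = discretize(vals, method="natural_breaks", k=2)
        assert sm.k == 2
        assert len(np.unique(sm.labels[:50])) == 1 and len(np.unique(sm.labels[50:])) == 1

    def test_categorical_passthrough_is_identity(self, rng):
        codes = rng.integers(1, 15, size=(20, 20))
        sm = StrataMap.from_categorical(codes)
        assert sm.k == len(np.unique(codes))
        # same partition: q identical for any response
        y = rng.normal(size=(20, 20)) + codes
        assert q_statistic(y, sm) == pytest.approx(brute_force_q(y, codes), abs=1e-12)

    def test_constant_layer_rejected_and_reduced_k_warns(self):
        with pytest.raises(DegenerateStrataError):
            discretize(np.ones(50), k=4)
        with pytest.warns(UserWarning, match="distinct"):
            sm = discretize(np.array([1.0, 2.0] * 25), k=5)
        assert sm.k == 2


def test_detector_report_tables_are_consistent(scene):
    """End-to-end report: symmetric interaction table, q in [0,1], Y/N symmetry."""
    from sandfix import build_driver_strata

    y = plant_driver_response(scene.soil_type, 0.5, 0.5, seed=3)
    strata = build_driver_strata(scene)
    report = detector_report(y, strata)
    q = report.q_table["q"]
    assert ((q >= 0) & (q <= 1)).all()
    iq = report.interaction_q
    pd.testing.assert_frame_equal(iq, iq.T)
    eco = report.ecological
    assert (eco.to_numpy() == eco.T.to_numpy()).all()
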