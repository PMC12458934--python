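import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methylpanel import simulate as sim
from methylpanel.classify import (
    ClassificationError,
    ClassSignature,
    DistanceProfileClassifier,
    binarize,
    binarize_sample,
    build_class_signatures,
    call_tumor_normal,
    decide,
    distance_vector,
    evaluate_panel,
    naive_bayes_scores,
    profile_distance,
    qffit_scores,
)
from methylpanel.io import BetaMatrix
from methylpanel.select import MarkerPanel, PanelProbe


def sig(label, members, profile=None):
    members = np.asarray(members, dtype=float)
    if profile is None:
        med = np.zeros(members.shape[1])
        ok = ~np.isnan(members).all(axis=0)
        med[ok] = np.nanmedian(members[:, ok], axis=0)
        profile = (med > 0.5).astype(float)
    return ClassSignature(label, np.asarray(profile, float), members)


class TestBinarize:
    def test_low_reference_boundaries(self, tiny_panel):
        assert binarize_sample([0.02, 0.5], tiny_panel)[0] == 0  # at ref extreme
        assert binarize_sample([0.95, 0.5], tiny_panel)[0] == 1  # far from ref
        assert binarize_sample([0.30, 0.5], tiny_panel)[0] == 0  # == cutoff: strict

    def test_high_reference_mirrored(self, tiny_panel):
        assert binarize_sample([0.0, 0.98], tiny_panel)[1] == 0
        assert binarize_sample([0.0, 0.10], tiny_panel)[1] == 1
        assert binarize_sample([0.0, 0.70], tiny_panel)[1] == 0  # == cutoff

    def test_missing_is_masked(self, tiny_panel):
        bits = binarize_sample([np.nan, 0.1], tiny_panel)
        assert np.isnan(bits[0]) and bits[1] == 1

    def test_length_mismatch(self, tiny_panel):
        with pytest.raises(ClassificationError, match="panel"):
            binarize_sample([0.1], tiny_panel)


class TestOrRule:
    @pytest.mark.parametrize("bits,expected", [
        ([0] * 8, "normal"),
        ([0, 0, 0, 1, 0, 0, 0, 0], "tumor"),
        ([1] * 8, "tumor"),
        ([np.nan] * 8, "indeterminate"),
        ([np.nan, 0, np.nan], "normal"),
    ])
    def test_call(self, bits, expected):
        assert call_tumor_normal(np.array(bits, float)) == expected


class TestDistances:
    def test_identical_singleton_member_zero(self):
        s = sig("A", [[1, 0, 1, 0]])
        dv = distance_vector(np.array([1., 0., 1., 0.]), [s])
        assert dv["A"] == 0.0

    def test_centroid_hamming_euclid_identity(self):
        s = sig("A", [[0, 0, 0, 0, 0]], profile=[0, 0, 0, 0, 0])
        for k in range(6):
            x = np.zeros(5)
            x[:k] = 1
            dv = distance_vector(x, [s], mode="centroid")
            assert dv["A"] == pytest.approx(np.sqrt(k))

    def test_per_sample_mean_hand_oracle(self):
        # members at Hamming distances 1 and 4 -> (1 + 2) / 2 = 1.5
        members = [[1, 0, 0, 0, 0], [1, 1, 1, 1, 0]]
        s = sig("A", members)
        dv = distance_vector(np.zeros(5), [s])
        assert dv["A"] == pytest.approx((1 + 2) / 2)

    def test_mask_rescaling(self):
        # one masked position of 4: distance on 3 used bits scaled by sqrt(4/3)
        a = np.array([1., np.nan, 0., 0.])
        b = np.array([0., 1., 0., 0.])
        assert profile_distance(a, b, 4) == pytest.approx(np.sqrt(1 * 4 / 3))

    def test_no_overlap_errors(self):
        s = sig("A", [[np.nan, 1.0]])
        with pytest.raises(ClassificationError, match="unmasked"):
            distance_vector(np.array([1.0, np.nan]), [s])

    def test_brute_force_equivalence_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n_classes = rng.integers(2, 6)
            p = rng.integers(3, 12)
            sigs = []
            for c in range(n_classes):
                m = rng.integers(1, 8)
                members = (rng.random((m, p)) < 0.5).astype(float)
                members[rng.random((m, p)) < 0.1] = np.nan
                sigs.append(sig(f"c{c}", members))
            x = (rng.random(p) < 0.5).astype(float)
            dv = distance_vector(x, sigs)
            for s in sigs:
                ds = []
                for mem in s.member_profiles:
                    used = ~np.isnan(x) & ~np.isnan(mem)
                    d = np.sqrt(np.sum((x[used] - mem[used]) ** 2) * p / used.sum())
                    ds.append(d)
                assert dv[s.label] == pytest.approx(np.mean(ds))

    def test_class_permutation_symmetry(self):
        rng = np.random.default_rng(2)
        sigs = [sig(f"c{c}", (rng.random((3, 6)) < 0.5).astype(float))
                for c in range(4)]
        x = (rng.random(6) < 0.5).astype(float)
        dv = distance_vector(x, sigs)
        dv_perm = distance_vector(x, sigs[::-1])
        pd.testing.assert_series_equal(dv.sort_index(), dv_perm.sort_index())


class TestDecide:
    def test_within_range_anchor_best_match(self):
        dv = pd.Series({"c1": 0.1, "c2": 0.2, "c3": 0.3})
        res = decide(dv, delta=0.0)
        assert res.best_match == "c1"
        assert res.within_range == ("c1",)

    def test_min_rank_ties(self):
        dv = pd.Series({"c1": 0.1, "c2": 0.1, "c3": 0.3})
        res = decide(dv)
        assert res.rank_of["c1"] == res.rank_of["c2"] == 1
        assert res.rank_of["c3"] == 3
        # "rank <= 2" counts either tied class as correct
        assert res.rank_of["c2"] <= 2

    def test_large_delta_includes_all(self):
        dv = pd.Series({"c1": 0.1, "c2": 0.2, "c3": 0.3})
        res = decide(dv, delta=0.2)
        assert set(res.within_range) == {"c1", "c2", "c3"}

    def test_sample_anchor_can_be_empty(self):
        dv = pd.Series({"c1": 0.5, "c2": 0.6})
        res = decide(dv, delta=0.2, range_anchor="sample")
        assert res.within_range == ()

    def test_reference_loses_ties(self):
        dv = pd.Series({"reference": 0.1, "liver": 0.1})
        assert decide(dv).best_match == "liver"

    def test_empty_vector_errors(self):
        with pytest.raises(ClassificationError):
            decide(pd.Series(dtype=float))


class TestQFfit:
    def test_training_median_scores_half(self):
        s = sig("A", [[0, 0]])
        s.distance_distribution = np.array([1.0, 2.0, 3.0])
        dv = pd.Series({"A": 2.0})
        assert qffit_scores(dv, [s])["A"] == pytest.approx(0.5)

    def test_below_all_scores_zero(self):
        s = sig("A", [[0, 0]])
        s.distance_distribution = np.array([1.0, 2.0, 3.0])
        assert qffit_scores(pd.Series({"A": 0.5}), [s])["A"] == 0.0

    def test_midpoint_tie_convention(self):
        s = sig("A", [[0, 0]])
        s.distance_distribution = np.array([1.0, 2.0, 2.0, 3.0])
        assert qffit_scores(pd.Series({"A": 2.0}), [s])["A"] == pytest.approx(
            (1 + 2 * 0.5) / 4)

    def test_empty_distribution_errors(self):
        s = sig("A", [[0, 0]])
        s.distance_distribution = np.array([])
        with pytest.raises(ClassificationError, match="empty"):
            qffit_scores(pd.Series({"A": 1.0}), [s])


class TestNaiveBayes:
    def test_identical_classes_symmetric(self):
        members = [[1, 0, 1], [0, 1, 1]]
        sigs = [sig("A", members), sig("B", members)]
        post = naive_bayes_scores(np.array([1., 1., 0.]), sigs)
        assert post["A"] == pytest.approx(0.5)
        assert post["B"] == pytest.approx(0.5)

    def test_matching_deterministic_class_wins(self):
        sigs = [sig("A", np.ones((6, 4))), sig("B", np.zeros((6, 4)))]
        post = naive_bayes_scores(np.ones(4), sigs)
        assert post["A"] > post["B"]
        # direct product oracle with Laplace-smoothed rates (7/8 vs 1/8)
        expected_ratio = (7 / 8) ** 4 / (1 / 8) ** 4
        assert post["A"] / post["B"] == pytest.approx(expected_ratio)

    def test_all_masked_frequency_prior_gives_class_frequencies(self):
        sigs = [sig("A", np.ones((3, 2))), sig("B", np.zeros((1, 2)))]
        post = naive_bayes_scores(np.array([np.nan, np.nan]), sigs,
                                  prior="frequency")
        assert post["A"] == pytest.approx(0.75)
        assert post["B"] == pytest.approx(0.25)


class TestSignatures:
    def _matrix(self):
        panel = MarkerPanel("classification",
                            (PanelProbe("p1", "low", 0.3),
                             PanelProbe("p2", "low", 0.3)))
        samples = ["r1", "r2", "a1", "a2", "a3"]
        groups = ["reference", "reference", "A.T", "A.T", "A.T"]
        vals = pd.DataFrame(
            {"r1": [0.02, 0.02], "r2": [0.03, 0.01],
             "a1": [0.9, 0.29], "a2": [0.9, 0.28], "a3": [0.9, 0.31]},
            index=["p1", "p2"])
        ann = pd.DataFrame({"group": groups},
                           index=pd.Index(samples, name="sample_id"))
        return BetaMatrix(vals), ann, panel

    def test_median_then_binarize(self):
        m, ann, panel = self._matrix()
        sigs = {s.label: s for s in build_class_signatures(m, ann, panel)}
        assert list(sigs["A"].profile) == [1, 0]   # p2 median 0.29 < cutoff 0.3
        assert list(sigs["reference"].profile) == [0, 0]

    def test_empty_class_errors(self):
        m, ann, panel = self._matrix()
        ann2 = ann.copy()
        ann2.loc[["a1", "a2", "a3"], "group"] = "B.T"
        ann2.loc["a1", "group"] = "A.T"
        m2 = BetaMatrix(m.values.drop(columns=["a1"]))
        with pytest.raises(ClassificationError, match="'A'"):
            build_class_signatures(m2, ann2, panel)


class TestEstimatorAndEvaluation:
    def _fit_data(self, seed=0, noise=0.0, n_classes=4, n_members=10, p=12):
        rng = np.random.default_rng(seed)
        protos = (rng.random((n_classes, p)) < 0.5).astype(float)
        X, y = [], []
        for c in range(n_classes):
            for _ in range(n_members):
                bits = protos[c].copy()
                flip = rng.random(p) < noise
                bits[flip] = 1 - bits[flip]
                X.append(bits)
                y.append(f"c{c}")
        return np.array(X), np.array(y)

    def test_noise_free_prediction_is_perfect(self):
        X, y = self._fit_data()
        clf = DistanceProfileClassifier().fit(X, y)
        assert (clf.predict(X) == y).all()

    def test_sklearn_clone_contract(self):
        from sklearn.base import clone
        clf = DistanceProfileClassifier(mode="centroid", delta=0.2)
        c2 = clone(clf)
        assert c2.get_params()["mode"] == "centroid"

    def test_accuracy_degrades_with_noise(self):
        accs = []
        for noise in (0.0, 0.2, 0.45):
            scores = []
            for seed in range(5):
                X, y = self._fit_data(seed=seed, noise=noise)
                Xt, yt = self._fit_data(seed=seed + 100, noise=noise)
                clf = DistanceProfileClassifier().fit(X, y)
                scores.append(np.mean(clf.predict(Xt) == yt))
            accs.append(np.mean(scores))
        assert accs[0] > accs[1] > accs[2] - 0.02

    def test_evaluate_panel_separable_data(self):
        cfg = sim.default_beta_config(seed=12, n_probes=80, n_classes=3)
        m, ann, _ = sim.simulate_beta_matrix(cfg)
        from methylpanel.select import (SelectionParams,
                                        select_classification_candidates,
                                        entropy_panel_search)
        p = SelectionParams()
        cands = select_classification_candidates(m, ann, p)
        panel = entropy_panel_search(m, ann, cands, p=p, seed=0)
        rep = evaluate_panel(m, ann, panel, delta=0.5)
        assert rep.accuracy_best == 1.0
        assert rep.mean_rank_true == 1.0
        assert rep.mean_within_range_size == 1.0
        np.testing.assert_allclose(np.diag(rep.confusion), 100.0)

    def test_criterion_nesting_holds_under_noise(self):
        X, y = self._fit_data(seed=3, noise=0.3)
        Xt, yt = self._fit_data(seed=4, noise=0.3)
        clf = DistanceProfileClassifier(delta=0.8).fit(X, y)
        results = clf.decide_all(Xt)
        best = np.mean([r.best_match == t for r, t in zip(results, yt)])
        rank2 = np.mean([r.rank_of[t] <= 2 for r, t in zip(results, yt)])
        within = np.mean([t in r.within_range for r, t in zip(results, yt)])
        assert best <= rank2 and best <= within


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_or_rule_matches_any_bit_set(seed):
    rng = np.random.default_rng(seed)
    bits = (rng.random(8) < 0.3).astype(float)
    bits[rng.random(8) < 0.2] = np.nan
    call = call_tumor_normal(bits)
    unmasked = bits[~np.isnan(bits)]
    if unmasked.size == 0:
        assert call == "indeterminate"
    else:
        assert call == ("tumor" if unmasked.any() else "normal")
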