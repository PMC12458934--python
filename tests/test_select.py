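import itertools

import numpy as np
import pandas as pd
import pytest

from methylpanel import simulate as sim
from methylpanel.io import BetaMatrix, tumor_types
from methylpanel.select import (
    CandidateProbe,
    SelectionError,
    SelectionParams,
    TumorNormalMarkerSelector,
    ClassificationMarkerSelector,
    assemble_detection_panel,
    entropy_panel_search,
    probe_cutoff,
    select_classification_candidates,
    select_tn_candidates,
    _class_bits,
    _partition_entropy,
)


def oracle_tn_filter(m, ann, p):
    """Independent brute-force application of the four T-N filters."""
    betas = m.values
    ref = betas[ann.index[ann["group"] == "reference"]]
    types = tumor_types(ann)
    keep = {}
    for probe in m.probe_ids:
        rmed = ref.loc[probe].median()
        rsd = ref.loc[probe].std(ddof=1)
        if not (rmed <= p.ref_low_max or rmed >= p.ref_high_min):
            continue
        if rsd > p.ref_sd_max:
            continue
        pos = []
        for t in types:
            tmed = betas.loc[probe, ann.index[ann["group"] == f"{t}.T"]].median()
            if abs(tmed - rmed) >= p.delta_tumor:
                pos.append(t)
        if not pos:
            continue
        ok = True
        for t in types:
            cols = ann.index[ann["group"] == f"{t}.N"]
            if len(cols) == 0:
                continue
            nmed = betas.loc[probe, cols].median()
            if abs(nmed - rmed) > p.eps_normal:
                ok = False
        if ok:
            keep[probe] = tuple(sorted(pos))
    return keep


class TestTnCandidates:
    def test_filters_match_oracle_on_handmade_matrix(self, grouped_beta):
        m, ann = grouped_beta
        p = SelectionParams()
        cands = {c.probe_id: c.positive_types
                 for c in select_tn_candidates(m, ann, p)}
        assert cands == oracle_tn_filter(m, ann, p)
        assert cands["pGood"] == ("A",)
        assert "pNoisy" not in cands          # reference SD ~0.2 > 0.07
        assert "pBadN" not in cands           # deviated normal-tissue group
        assert "pMid" not in cands            # mid-scale reference
        assert "pInter" in cands              # normals fine; B.T at 0.4 irrelevant here

    def test_filters_match_oracle_on_simulated_matrix(self):
        cfg = sim.default_beta_config(seed=2, n_probes=150, n_classes=3)
        m, ann, _ = sim.simulate_beta_matrix(cfg)
        p = SelectionParams()
        cands = {c.probe_id: c.positive_types
                 for c in select_tn_candidates(m, ann, p)}
        assert cands == oracle_tn_filter(m, ann, p)

    def test_no_reference_errors(self, grouped_beta):
        m, ann = grouped_beta
        ann2 = ann[ann["group"] != "reference"]
        with pytest.raises(SelectionError, match="reference"):
            select_tn_candidates(m, ann2, SelectionParams())

    def test_idempotent_on_own_output(self, grouped_beta):
        m, ann = grouped_beta
        p = SelectionParams()
        cands = select_tn_candidates(m, ann, p)
        sub = BetaMatrix(m.values.loc[[c.probe_id for c in cands]])
        again = select_tn_candidates(sub, ann, p)
        assert [c.probe_id for c in again] == [c.probe_id for c in cands]

    @pytest.mark.parametrize("tighten", [
        {"ref_sd_max": 0.05}, {"ref_sd_max": 0.005},
        {"delta_tumor": 0.4}, {"delta_tumor": 0.55},
    ])
    def test_tightening_never_grows_pool(self, tighten):
        cfg = sim.default_beta_config(seed=6, n_probes=120, n_classes=3,
                                      ref_extreme_sd=0.03)
        m, ann, _ = sim.simulate_beta_matrix(cfg)
        base = {c.probe_id for c in select_tn_candidates(m, ann, SelectionParams())}
        tight = {c.probe_id for c in
                 select_tn_candidates(m, ann, SelectionParams(**tighten))}
        assert tight <= base

    def test_missing_value_cap_drops_probe(self, grouped_beta):
        m, ann = grouped_beta
        vals = m.values.copy()
        ref_ids = ann.index[ann["group"] == "reference"]
        vals.loc["pGood", ref_ids[:3]] = np.nan  # 3/9 > 20% missing in reference
        cands = select_tn_candidates(BetaMatrix(vals), ann, SelectionParams())
        assert "pGood" not in {c.probe_id for c in cands}


class TestClassificationCandidates:
    def test_positive_single_type_retained(self, grouped_beta):
        m, ann = grouped_beta
        cands = {c.probe_id: c.positive_types
                 for c in select_classification_candidates(m, ann, SelectionParams())}
        assert cands["pGood"] == ("A",)
        # normal-tissue concordance not required here: pBadN's deviated B.N
        # group does not disqualify it
        assert "pBadN" in cands

    def test_intermediate_negative_class_rejected(self, grouped_beta):
        m, ann = grouped_beta
        cands = select_classification_candidates(m, ann, SelectionParams())
        assert "pInter" not in {c.probe_id for c in cands}  # B.T intermediate

    def test_all_positive_probe_retained(self, grouped_beta):
        m, ann = grouped_beta
        cands = {c.probe_id: c.positive_types
                 for c in select_classification_candidates(m, ann, SelectionParams())}
        assert cands["pAll"] == ("A", "B")

    def test_extreme_band_negative_mode_is_stricter(self, grouped_beta):
        m, ann = grouped_beta
        loose = {c.probe_id for c in select_classification_candidates(
            m, ann, SelectionParams(neg_mode="eps_normal"))}
        strict = {c.probe_id for c in select_classification_candidates(
            m, ann, SelectionParams(neg_mode="extreme_band"))}
        assert strict <= loose


def _cand(pid, types, shift=0.5):
    return CandidateProbe(pid, "low", 0.02, 0.01, tuple(types),
                          {t: 0.02 + shift for t in types})


def oracle_min_cover(cands, types, m):
    """Smallest subset giving every type >= m covering probes (exhaustive)."""
    for size in range(0, len(cands) + 1):
        for sub in itertools.combinations(cands, size):
            if all(sum(1 for c in sub if t in c.positive_types) >= m
                   for t in types):
                return size
    return None


class TestDetectionPanel:
    def test_three_type_example_matches_exhaustive_minimum(self):
        cands = [_cand("c1", ("A", "B")), _cand("c2", ("B", "C")),
                 _cand("c3", ("A", "C"))]
        panel = assemble_detection_panel(cands, ["A", "B", "C"],
                                         SelectionParams(min_probes_per_type=2))
        assert sorted(panel.probe_ids) == ["c1", "c2", "c3"]
        assert oracle_min_cover(cands, ["A", "B", "C"], 2) == 3

    def test_single_covering_candidate_suffices(self):
        cands = [_cand("c1", ("A", "B", "C"))]
        panel = assemble_detection_panel(cands, ["A", "B", "C"],
                                         SelectionParams(min_probes_per_type=1))
        assert panel.probe_ids == ["c1"]

    def test_uncoverable_type_named_in_error(self):
        cands = [_cand("c1", ("A",)), _cand("c2", ("A",))]
        with pytest.raises(SelectionError, match="'D'"):
            assemble_detection_panel(cands, ["A", "D"],
                                     SelectionParams(min_probes_per_type=2))

    def test_max_panel_size_infeasibility(self):
        cands = [_cand(f"c{i}", ("A",)) for i in range(4)]
        with pytest.raises(SelectionError, match="max_panel_size"):
            assemble_detection_panel(
                cands, ["A"],
                SelectionParams(min_probes_per_type=3, max_panel_size=2))

    def test_greedy_coverage_against_exhaustive_oracle_random_pools(self):
        rng = np.random.default_rng(0)
        types = ["A", "B", "C", "D"]
        for trial in range(30):
            n = int(rng.integers(4, 12))
            cands = []
            for i in range(n):
                k = int(rng.integers(1, len(types) + 1))
                ts = tuple(sorted(rng.choice(types, size=k, replace=False)))
                cands.append(_cand(f"c{i:02d}", ts, shift=float(rng.uniform(0.3, 0.9))))
            m = 2
            feasible = oracle_min_cover(cands, types, m) is not None
            p = SelectionParams(min_probes_per_type=m)
            if feasible:
                panel = assemble_detection_panel(cands, types, p)
                by_id = {c.probe_id: c for c in cands}
                for t in types:
                    n_cov = sum(1 for pid in panel.probe_ids
                                if t in by_id[pid].positive_types)
                    assert n_cov >= m
            else:
                with pytest.raises(SelectionError):
                    assemble_detection_panel(cands, types, p)


class TestEntropySearch:
    def _matrix_for(self, class_levels, sd=0.005, n_per=6, n_ref=6, seed=0):
        """Build a matrix whose per-class medians are given per probe.

        class_levels: dict probe -> dict class -> beta level (ref at 0.02).
        """
        rng = np.random.default_rng(seed)
        classes = sorted({c for lv in class_levels.values() for c in lv})
        groups = ["reference"] * n_ref + sum(
            ([f"{c}.T"] * n_per for c in classes), [])
        samples = [f"s{i}" for i in range(len(groups))]
        data = {}
        for probe, levels in class_levels.items():
            v = np.empty(len(groups))
            for i, g in enumerate(groups):
                cls = g[:-2] if g.endswith(".T") else None
                mean = levels.get(cls, 0.02) if cls else 0.02
                v[i] = np.clip(rng.normal(mean, sd), 0, 1)
            data[probe] = v
        m = BetaMatrix(pd.DataFrame(data, index=samples).T)
        ann = pd.DataFrame({"group": groups},
                           index=pd.Index(samples, name="sample_id"))
        return m, ann

    def test_single_perfect_splitter_selected_first(self):
        m, ann = self._matrix_for({"p1": {"A": 0.8, "B": 0.02}})
        cands = select_classification_candidates(m, ann, SelectionParams())
        panel = entropy_panel_search(m, ann, cands, seed=0,
                                     include_reference=False)
        assert panel.probe_ids == ["p1"]

    def test_two_probe_xor_layout_fully_splits_four_classes(self):
        # p1 splits {A,B}|{C,D}; p2 splits {A,C}|{B,D}
        m, ann = self._matrix_for({
            "p1": {"A": 0.8, "B": 0.8},
            "p2": {"A": 0.8, "C": 0.8},
        })
        p = SelectionParams()
        cands = select_classification_candidates(m, ann, p)
        panel = entropy_panel_search(m, ann, cands, seed=1, p=p,
                                     include_reference=False)
        assert sorted(panel.probe_ids) == ["p1", "p2"]
        # enumeration oracle: no single candidate splits all 4 classes
        classes = ["A", "B", "C", "D"]
        meds = {c: m.values[ann.index[ann["group"] == f"{c}.T"]].median(axis=1)
                for c in classes}
        bits = _class_bits(cands, classes, meds, p)
        weights = np.ones(4)
        assert all(_partition_entropy(bits[[i]], weights) > 0
                   for i in range(len(cands)))
        assert _partition_entropy(bits, weights) == 0

    def test_constant_candidates_leave_entropy_unchanged(self, caplog):
        m, ann = self._matrix_for({"p1": {"A": 0.8, "B": 0.8}})
        p = SelectionParams()
        cands = select_classification_candidates(m, ann, p)
        assert {c.probe_id for c in cands} == {"p1"}
        # p1 cannot split A from B: warning + best-effort panel
        with caplog.at_level("WARNING"):
            panel = entropy_panel_search(m, ann, cands, seed=0, p=p,
                                         include_reference=False)
        assert "merged" in caplog.text
        assert len(panel) <= 1

    def test_entropy_non_increasing_along_selection(self):
        cfg = sim.default_beta_config(seed=8, n_probes=100, n_classes=4)
        m, ann, _ = sim.simulate_beta_matrix(cfg)
        p = SelectionParams()
        cands = select_classification_candidates(m, ann, p)
        panel = entropy_panel_search(m, ann, cands, seed=0, p=p)
        classes = tumor_types(ann) + ["reference"]
        meds = {}
        counts = []
        for cls in classes:
            g = "reference" if cls == "reference" else f"{cls}.T"
            cols = ann.index[ann["group"] == g]
            meds[cls] = m.values[cols].median(axis=1)
            counts.append(len(cols))
        by_id = {c.probe_id: c for c in cands}
        chosen = [by_id[pid] for pid in panel.probe_ids]
        bits = _class_bits(chosen, classes, meds, p)
        hs = [_partition_entropy(bits[:k], np.asarray(counts, float))
              for k in range(len(chosen) + 1)]
        assert all(b <= a + 1e-12 for a, b in zip(hs, hs[1:]))
        assert hs[-1] == 0  # planted per-class probes fully split the classes


class TestSklearnSelectors:
    def test_tn_selector_fit_transform(self):
        cfg = sim.default_beta_config(seed=4, n_probes=80, n_classes=2)
        m, ann, truth = sim.simulate_beta_matrix(cfg)
        X = m.samples_by_probes()
        sel = TumorNormalMarkerSelector().fit(X, ann["group"])
        assert set(sel.panel_.probe_ids) <= set(truth["planted_tn"]) | set(
            truth["planted_class"])
        Xt = sel.transform(X)
        assert list(Xt.columns) == sel.panel_.probe_ids

    def test_classification_selector_params_round_trip(self):
        sel = ClassificationMarkerSelector(target_size=5, seed=3, delta_tumor=0.25)
        params = sel.get_params()
        assert params["target_size"] == 5 and params["delta_tumor"] == 0.25
        from sklearn.base import clone
        clone(sel)  # sklearn-compatible constructor contract
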