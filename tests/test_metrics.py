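"""AUROC, stratified bootstrap, and underdiagnosis disparity.

The pairwise brute-force AUROC here is the independent oracle for the
production implementation.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patshortcut.metrics import (BootstrapSummary, DisparitySummary, auroc,
                                 stratified_bootstrap_auroc,
                                 underdiagnosis_disparity)
from patshortcut.sampling import StratumCounts


def brute_force_auroc(scores, labels):
    """P(positive outscores negative), ties half — literal pair enumeration."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _meta(per_stratum=4):
    rows = []
    for sex in "FM":
        for dis in "HD":
            rows += [{"subject_id": f"{sex}{dis}{i}", "sex": sex, "disease": dis}
                     for i in range(per_stratum)]
    return pd.DataFrame(rows)


class TestAuroc:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ((0.9, 0.8, 0.3, 0.2), (1, 1, 0, 0), 1.0),
            ((0.5, 0.5, 0.5, 0.5), (1, 0, 1, 0), 0.5),
            ((0.9, 0.2, 0.8, 0.3), (1, 0, 0, 1), 0.75),
        ],
    )
    def test_known_values(self, scores, labels, expected):
        assert auroc(scores, labels) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.9], [1, 1])

    @settings(deadline=None, derandomize=True, max_examples=150)
    @given(st.lists(
        st.tuples(st.sampled_from([0.0, 0.1, 0.25, 0.5, 0.5, 0.9]),
                  st.integers(0, 1)),
        min_size=2, max_size=12,
    ))
    def test_matches_pair_enumeration(self, pairs):
        scores = [p[0] for p in pairs]
        labels = [p[1] for p in pairs]
        if len(set(labels)) < 2:
            return
        assert auroc(scores, labels) == pytest.approx(brute_force_auroc(scores, labels))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        assert auroc(np.exp(scores), labels) == pytest.approx(auroc(scores, labels))


class TestStratifiedBootstrap:
    def test_perfect_classifier_pins_ci_at_one(self):
        meta = _meta(4)
        scores = {sid: (1.0 if "D" in sid[:2] else 0.0) for sid in meta["subject_id"]}
        s = stratified_bootstrap_auroc(scores, meta, StratumCounts(2, 2, 2, 2),
                                       n_iter=200, seed=0)
        assert (s.mean_auroc, s.ci_low, s.ci_high) == (1.0, 1.0, 1.0)

    def test_constant_scores_give_half(self):
        meta = _meta(4)
        scores = {sid: 0.3 for sid in meta["subject_id"]}
        s = stratified_bootstrap_auroc(scores, meta, StratumCounts(2, 2, 2, 2),
                                       n_iter=100, seed=0)
        assert (s.mean_auroc, s.ci_low, s.ci_high) == (0.5, 0.5, 0.5)

    def test_monte_carlo_stability(self):
        """Doubling n_iter with a fresh seed moves the mean by < 0.01."""
        rng = np.random.default_rng(7)
        meta = _meta(8)
        scores = {sid: rng.normal(loc=1.0 if "D" in sid[:2] else 0.0)
                  for sid in meta["subject_id"]}
        a = stratified_bootstrap_auroc(scores, meta, StratumCounts(6, 6, 6, 6),
                                       n_iter=1000, seed=1)
        b = stratified_bootstrap_auroc(scores, meta, StratumCounts(6, 6, 6, 6),
                                       n_iter=2000, seed=2)
        assert abs(a.mean_auroc - b.mean_auroc) < 0.01

    def test_ci_narrows_with_larger_test_counts(self):
        rng = np.random.default_rng(11)
        meta = _meta(30)
        scores = {sid: rng.normal(loc=1.0 if "D" in sid[:2] else 0.0)
                  for sid in meta["subject_id"]}
        small = stratified_bootstrap_auroc(scores, meta, StratumCounts(6, 6, 6, 6),
                                           n_iter=500, seed=3)
        big = stratified_bootstrap_auroc(scores, meta, StratumCounts(24, 24, 24, 24),
                                         n_iter=500, seed=4)
        assert (big.ci_high - big.ci_low) < (small.ci_high - small.ci_low)

    def test_reproducible_given_seed(self):
        meta = _meta(5)
        rng = np.random.default_rng(0)
        scores = {sid: rng.uniform() for sid in meta["subject_id"]}
        a = stratified_bootstrap_auroc(scores, meta, StratumCounts(3, 3, 3, 3),
                                       n_iter=50, seed=8)
        b = stratified_bootstrap_auroc(scores, meta, StratumCounts(3, 3, 3, 3),
                                       n_iter=50, seed=8)
        assert a == b

    def test_summary_invariants_enforced(self):
        with pytest.raises(ValueError):
            BootstrapSummary(mean_auroc=0.5, ci_low=0.8, ci_high=0.4, n_iter=10)


class TestUnderdiagnosisDisparity:
    def _arrays(self, fn_f, fp_f, fn_m, fp_m, tn=2, tp=2):
        """Build prediction/label arrays realizing the given confusion counts."""
        pred, dis, sex = [], [], []
        for s, fn, fp in (("F", fn_f, fp_f), ("M", fn_m, fp_m)):
            pred += [0] * fn + [1] * fp + [0] * tn + [1] * tp
            dis += [1] * fn + [0] * fp + [0] * tn + [1] * tp
            sex += [s] * (fn + fp + tn + tp)
        return np.array(pred), np.array(dis), np.array(sex)

    def test_hand_computed_value(self):
        pred, dis, sex = self._arrays(fn_f=2, fp_f=1, fn_m=1, fp_m=2)
        assert underdiagnosis_disparity(pred, dis, sex) == pytest.approx(1.5)

    def test_symmetric_confusions_give_zero(self):
        pred, dis, sex = self._arrays(fn_f=3, fp_f=2, fn_m=3, fp_m=2)
        assert underdiagnosis_disparity(pred, dis, sex) == 0.0

    def test_antisymmetric_under_sex_swap(self):
        pred, dis, sex = self._arrays(fn_f=4, fp_f=1, fn_m=2, fp_m=3)
        d = underdiagnosis_disparity(pred, dis, sex)
        swapped = np.where(sex == "F", "M", "F")
        assert underdiagnosis_disparity(pred, dis, swapped) == pytest.approx(-d)

    def test_zero_false_positives_is_undefined(self):
        pred, dis, sex = self._arrays(fn_f=2, fp_f=0, fn_m=1, fp_m=2)
        assert underdiagnosis_disparity(pred, dis, sex) is None

    def test_optional_epsilon_smoothing(self):
        pred, dis, sex = self._arrays(fn_f=2, fp_f=0, fn_m=1, fp_m=2)
        d = underdiagnosis_disparity(pred, dis, sex, epsilon=0.5)
        assert d == pytest.approx((2.5 / 0.5) - (1.5 / 2.5))

    def test_string_disease_labels_accepted(self):
        pred = np.array([0, 1, 0, 1])
        dis = np.array(["D", "H", "D", "H"])
        sex = np.array(["F", "F", "M", "M"])
        assert underdiagnosis_disparity(pred, dis, sex) == 0.0

    def test_missing_sex_stratum_rejected(self):
        with pytest.raises(ValueError):
            underdiagnosis_disparity([0, 1], [1, 0], ["F", "F"])


class TestDisparitySummary:
    def test_mixed_undefined_runs(self):
        s = DisparitySummary.from_runs([1.0, None, 3.0, 2.0])
        assert s.undefined_run_count == 1
        assert s.median == 2.0
        assert s.iqr_low <= s.median <= s.iqr_high

    def test_all_undefined_flagged(self):
        s = DisparitySummary.from_runs([None, None])
        assert s.undefined_run_count == 2
        assert np.isnan(s.median)
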