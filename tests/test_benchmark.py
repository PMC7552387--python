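"""Cross-validation plans, AUROC and the experiment suite / gap report."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from equibench.benchmark import (
    EXPERIMENTS,
    GapReport,
    SuiteResult,
    auroc,
    gap_report,
    minority_batch_size,
    run_suite,
    scheme_gaps,
    stratified_threefold,
)
from equibench.neural import TrainConfig


def _brute_force_auroc(scores, labels):
    pos = np.flatnonzero(np.asarray(labels) > 0)
    neg = np.flatnonzero(np.asarray(labels) <= 0)
    total = 0.0
    for i in pos:
        for j in neg:
            if scores[i] > scores[j]:
                total += 1.0
            elif scores[i] == scores[j]:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_ranking(self):
        assert auroc([0.9, 0.8, 0.3, 0.2], [1, 1, -1, -1]) == 1.0

    def test_hand_counted_pairs(self):
        assert auroc([0.9, 0.6, 0.4, 0.2], [1, -1, 1, -1]) == 0.75

    def test_all_ties_give_half(self):
        assert auroc([0.5] * 6, [1, 1, 1, -1, -1, -1]) == 0.5

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=10_000),
        st.integers(min_value=2, max_value=50),
    )
    def test_matches_bruteforce_on_random_instances(self, seed, n):
        rng = np.random.default_rng(seed)
        scores = rng.choice(np.round(rng.random(5), 2), size=n)  # force ties
        labels = rng.choice([-1, 1], size=n)
        if len(np.unique(labels)) < 2:
            labels[0] *= -1
        assert auroc(scores, labels) == pytest.approx(
            _brute_force_auroc(scores, labels), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(40)
        labels = rng.choice([-1, 1], 40)
        labels[:2] = [-1, 1]
        assert auroc(scores, labels) == pytest.approx(
            auroc(np.exp(5 * scores), labels)
        )

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.random(100)
        labels = rng.choice([-1, 1], 100)
        labels[:2] = [-1, 1]
        assert auroc(scores, labels) == pytest.approx(
            roc_auc_score(labels > 0, scores)
        )


class TestStratifiedThreefold:
    def test_divisible_case_exact_balance(self, rng):
        y = np.tile([-1, -1, -1, 1, 1, 1], 2)
        group = np.r_[np.ones(6, int), np.full(6, 2, int)]
        plan = stratified_threefold(y, group, mode="mixture", rng=rng)
        for key in {(yi, gi) for yi, gi in zip(y, group)}:
            stratum = (y == key[0]) & (group == key[1])
            counts = np.bincount(plan.fold_id[stratum], minlength=3)
            assert (counts == 1).all()

    def test_fold_proportions_within_one_sample_per_stratum(self, rng):
        y = np.r_[np.ones(40, int), -np.ones(30, int), np.ones(20, int), -np.ones(13, int)]
        group = np.r_[np.ones(70, int), np.full(33, 2, int)]
        plan = stratified_threefold(y, group, mode="mixture", rng=rng)
        for yv in (-1, 1):
            for gv in (1, 2):
                stratum = (y == yv) & (group == gv)
                counts = np.bincount(plan.fold_id[stratum], minlength=3)
                assert counts.max() - counts.min() <= 1

    def test_seed_controls_plan(self):
        y = np.r_[np.ones(30, int), -np.ones(30, int)]
        a = stratified_threefold(y, mode="independent", rng=np.random.default_rng(1))
        b = stratified_threefold(y, mode="independent", rng=np.random.default_rng(1))
        c = stratified_threefold(y, mode="independent", rng=np.random.default_rng(2))
        assert np.array_equal(a.fold_id, b.fold_id)
        assert not np.array_equal(a.fold_id, c.fold_id)

    def test_tiny_stratum_warned_and_assigned(self, rng, caplog):
        import logging

        y = np.r_[np.ones(9, int), [-1]]
        with caplog.at_level(logging.WARNING):
            plan = stratified_threefold(y, mode="independent", rng=rng)
        assert "stratum" in caplog.text
        assert set(plan.fold_id) <= {0, 1, 2}

    def test_train_test_masks_partition_samples(self, rng):
        y = np.r_[np.ones(30, int), -np.ones(30, int)]
        plan = stratified_threefold(y, mode="independent", rng=rng)
        seen = np.zeros(60, dtype=int)
        for f in range(3):
            tr, te = plan.train_test(f)
            assert not (tr & te).any() and (tr | te).all()
            seen += te
        assert (seen == 1).all()  # every sample tested exactly once


class TestMinorityBatchSize:
    def test_small_minority_uses_small_batches(self):
        assert minority_batch_size(2184, 320) == 4
        assert minority_batch_size(260, 260) == 20


@pytest.fixture(scope="module")
def tiny_result(tiny_cohort):
    from equibench.neural import SDASpec
    from equibench.transfer import CCSAConfig

    cfg = TrainConfig(max_iter=5, batch_size=10, seed=0)
    return run_suite(
        tiny_cohort,
        n_runs=2,
        seed=3,
        train_cfg=cfg,
        batch_minority=4,
        transfer_kwargs=dict(
            pretrain_cfg=TrainConfig(max_iter=3, batch_size=10, seed=1),
            finetune_cfg=TrainConfig(lr=0.002, batch_size=5, max_iter=3, seed=2),
            sda_spec=SDASpec(input_nodes=tiny_cohort.n_features, code_nodes=8,
                             bottleneck_nodes=4, max_iter=3, seed=3),
            ccsa_cfg=CCSAConfig(max_iter=3, hidden_nodes=8, seed=4),
        ),
    )


class TestRunSuite:
    def test_output_covers_all_experiments_and_runs(self, tiny_result):
        t = tiny_result.table
        assert sorted(t["experiment"].unique()) == sorted(EXPERIMENTS)
        assert set(t["run"]) == {0, 1}
        assert len(t) == 6 * 2

    def test_auroc_values_in_unit_interval(self, tiny_result):
        vals = tiny_result.table["auroc"].dropna()
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_gap_report_from_suite(self, tiny_result):
        rep = gap_report(tiny_result)
        med = tiny_result.medians()
        assert rep.G == pytest.approx(
            (med["Mixture1"] + med["Independent1"]) / 2
            - (med["Mixture2"] + med["Independent2"]) / 2
        )

    def test_suite_deterministic_under_master_seed(self, tiny_cohort):
        cfg = TrainConfig(max_iter=3, batch_size=10, seed=0)
        kw = dict(n_runs=2, seed=9, schemes=("mixture", "independent"), train_cfg=cfg)
        a = run_suite(tiny_cohort, **kw)
        b = run_suite(tiny_cohort, **kw)
        assert a.table.equals(b.table) and a.run_seeds == b.run_seeds

    def test_group_permutation_within_strata_is_identity(self, tiny_cohort):
        # strata are (label, group) pairs, so permuting group labels within a
        # stratum cannot change the group vector at all
        y, group = tiny_cohort.y, tiny_cohort.group.copy()
        rng = np.random.default_rng(0)
        for yv in (-1, 1):
            for gv in (1, 2):
                idx = np.flatnonzero((y == yv) & (group == gv))
                group[rng.permutation(idx)] = group[idx]
        assert np.array_equal(group, tiny_cohort.group)


class TestGapReport:
    def test_worked_example_from_published_medians(self):
        med = {
            "Mixture0": 0.71,
            "Mixture1": 0.71,
            "Mixture2": 0.68,
            "Independent1": 0.70,
            "Independent2": 0.59,
            "Transfer": 0.70,
        }
        rep = gap_report(med)
        assert rep.auroc_bar_majority == pytest.approx(0.705)
        assert rep.auroc_bar_minority == pytest.approx(0.635)
        assert rep.G == pytest.approx(0.07)
        assert rep.G_tilde == pytest.approx(0.005)

    def test_equal_medians_give_zero_gaps(self):
        med = {e: 0.7 for e in EXPERIMENTS}
        rep = gap_report(med)
        assert rep.G == 0.0 and rep.G_tilde == 0.0
        assert rep.mixture_gap_call == "no" and rep.independent_gap_call == "no"

    def test_missing_experiment_raises(self):
        med = {e: 0.7 for e in EXPERIMENTS if e != "Transfer"}
        with pytest.raises(ValueError, match="Transfer"):
            gap_report(med)

    def test_threshold_calls(self):
        med = {e: 0.7 for e in EXPERIMENTS}
        med["Mixture2"] = 0.60
        rep = gap_report(med)
        assert rep.mixture_gap_call == "yes" and rep.independent_gap_call == "no"

    def test_scheme_gaps_match_gap_report(self, tiny_cohort):
        cfg = TrainConfig(max_iter=3, batch_size=10, seed=0)
        res = run_suite(tiny_cohort, n_runs=2, seed=5,
                        schemes=("mixture", "independent"), train_cfg=cfg)
        gaps = scheme_gaps(res)
        med = res.medians()
        assert gaps["mixture_gap"] == pytest.approx(med["Mixture1"] - med["Mixture2"])
        assert gaps["independent_gap"] == pytest.approx(
            med["Independent1"] - med["Independent2"]
        )
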