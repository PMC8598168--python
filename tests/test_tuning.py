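"""Tuning curves, linear difference, partitioning, population matrices,
supra-linearity test."""

import numpy as np
import pandas as pd
import pytest

import combicode as cc
from combicode.responses import ResponseMatrix
from combicode.synth import TrialTable
from combicode.tuning import bootstrap_mean_diff_ci


def matrix_from(values_by_cond, space, trials_pc):
    """ResponseMatrix with given per-condition deterministic values."""
    n_cond = len(space.conditions)
    ids = np.repeat(np.arange(n_cond), trials_pc)
    vals = np.asarray(values_by_cond, float)[:, ids]
    return ResponseMatrix(values=vals, condition_ids=ids, space=space)


class TestTuningCurve:
    def test_flat_responses_give_zero_tuning(self, space5):
        vals = np.full((1, 32), 2.5)
        resp = matrix_from(vals, space5, trials_pc=4)
        tc = cc.tuning_curve(resp, 0, ci=False)
        assert np.allclose(tc.values, 0.0)

    def test_noiseless_ln_neuron_matches_ground_truth(self, space5):
        cfg = cc.SessionConfig(n_neurons=1, trials_per_condition=3, seed=1, trial_noise_sd=0.0)
        pop = cc.sample_population(cfg, mixture=(0.0, 1.0, 0.0), seed=1)
        table, amps = cc.simulate_trials(pop, cfg, seed=2)
        resp = ResponseMatrix(values=amps, condition_ids=table.condition_ids(space5), space=space5)
        tc = cc.tuning_curve(resp, 0, ci=False)
        assert np.allclose(tc.values, pop[0].tuning(space5), atol=1e-9)

    def test_ci_brackets_value(self, space5):
        rng = np.random.default_rng(3)
        ids = np.repeat(np.arange(32), 10)
        vals = rng.normal(size=(1, ids.size))
        resp = ResponseMatrix(values=vals, condition_ids=ids, space=space5)
        tc = cc.tuning_curve(resp, 0, n_boot=300, seed=4)
        assert np.all(tc.ci_low <= tc.values + 1e-9)
        assert np.all(tc.values <= tc.ci_high + 1e-9)

    def test_bootstrap_ci_coverage_on_gaussian_toy(self):
        # percentile bootstrap of mean(cond) - mean(catch), n=50 per group:
        # the 95% interval should cover the true difference in 93-97% of runs
        rng = np.random.default_rng(7)
        true = 0.5
        cover = 0
        n_rep = 1000
        for _ in range(n_rep):
            cond = rng.normal(true, 1.0, size=50)
            catch = rng.normal(0.0, 1.0, size=50)
            lo, hi = bootstrap_mean_diff_ci(cond, catch, n_boot=1000, rng=rng)
            cover += lo <= true <= hi
        assert 0.93 <= cover / n_rep <= 0.97


class TestPreferredStimulus:
    def test_argmax(self, space5):
        values = np.zeros(31)
        j = space5.non_catch.index(cc.Condition(mask=frozenset({0, 2, 3})))
        values[j] = 1.0
        tc = cc.TuningCurve(values=values, space=space5)
        assert cc.preferred_stimulus(tc).mask == frozenset({0, 2, 3})

    def test_tie_breaks_to_smaller_subset_first_in_canonical_order(self, space5):
        tc = cc.TuningCurve(values=np.ones(31), space=space5)
        assert cc.preferred_stimulus(tc) == space5.non_catch[0]  # first singleton

    def test_single_finite_value(self, space5):
        values = np.full(31, np.nan)
        values[17] = 0.2
        tc = cc.TuningCurve(values=values, space=space5)
        assert cc.preferred_stimulus(tc) == space5.non_catch[17]

    def test_all_missing_raises(self, space5):
        with pytest.raises(ValueError):
            cc.preferred_stimulus(cc.TuningCurve(values=np.full(31, np.nan), space=space5))


class TestPrincipalWhisker:
    def test_indicator_neuron(self, space5):
        vals = np.array([[1.0 if 3 in c.mask else 0.0 for c in space5.conditions]])
        resp = matrix_from(vals, space5, trials_pc=2)
        assert cc.principal_whisker(resp, 0) == 3

    def test_additive_neuron_largest_weight_wins(self, space5):
        vals = np.array(
            [[0.2 * (1 in c.mask) + 0.7 * (4 in c.mask) for c in space5.conditions]]
        )
        resp = matrix_from(vals, space5, trials_pc=2)
        assert cc.principal_whisker(resp, 0) == 4

    def test_tie_goes_to_lower_index(self, space5):
        vals = np.array([[0.5 * (0 in c.mask) + 0.5 * (2 in c.mask) for c in space5.conditions]])
        resp = matrix_from(vals, space5, trials_pc=2)
        assert cc.principal_whisker(resp, 0) == 0

    def test_rank_deficiency_names_element(self, space5):
        vals = np.zeros((1, 32))
        resp = matrix_from(vals, space5, trials_pc=2)
        # drop every trial where element 4 is present
        present = np.array(
            [4 in space5.conditions[cid].mask for cid in resp.condition_ids]
        )
        resp.inlier_mask[0, present] = False
        with pytest.raises(ValueError, match="element 4"):
            cc.principal_whisker(resp, 0)


class TestLinearDifference:
    def test_arithmetic_example(self, space5):
        values = np.zeros(31)
        values[space5.non_catch.index(cc.Condition(mask=frozenset({1})))] = 0.3
        values[space5.non_catch.index(cc.Condition(mask=frozenset({2})))] = 0.2
        pair = cc.Condition(mask=frozenset({1, 2}))
        values[space5.non_catch.index(pair)] = 1.0
        ld = cc.linear_difference(cc.TuningCurve(values=values, space=space5))
        assert ld[list(space5.multis).index(pair)] == pytest.approx(0.5)

    def test_linear_neuron_has_zero_ld(self, space5):
        w = np.array([0.4, 0.0, 0.8, 0.1, 0.0])
        values = np.array([sum(w[j] for j in c.mask) for c in space5.non_catch])
        ld = cc.linear_difference(cc.TuningCurve(values=values, space=space5))
        assert np.all(np.abs(ld) < 1e-9)

    def test_threshold_ln_neuron_supralinear_at_preferred(self, space5, design5):
        p = cc.LNParams(w=np.array([1.0, 1.0, 0, 0, 0.0]), h=-1.5, a=1.0)
        values = cc.ln_predict(p, design5)
        tc = cc.TuningCurve(values=values, space=space5)
        ld = cc.linear_difference(tc)
        pair = list(space5.multis).index(cc.Condition(mask=frozenset({0, 1})))
        assert ld[pair] > 0

    def test_ld_is_linear_in_tuning(self, space5):
        rng = np.random.default_rng(5)
        a = cc.TuningCurve(values=rng.normal(size=31), space=space5)
        b = cc.TuningCurve(values=rng.normal(size=31), space=space5)
        s = cc.TuningCurve(values=a.values + b.values, space=space5)
        assert np.allclose(
            cc.linear_difference(s), cc.linear_difference(a) + cc.linear_difference(b)
        )

    def test_missing_singleton_flags_dependent_lds(self, space5):
        values = np.random.default_rng(6).normal(size=31)
        values[0] = np.nan  # first singleton missing
        ld = cc.linear_difference(cc.TuningCurve(values=values, space=space5))
        el = next(iter(space5.non_catch[0].mask))
        for j, c in enumerate(space5.multis):
            assert np.isnan(ld[j]) == (el in c.mask)


class TestPartitioning:
    def _table(self, trials_pc, with_pupil=False, seed=0):
        cfg = cc.SessionConfig(n_neurons=2, trials_per_condition=trials_pc, seed=seed, include_pupil=with_pupil)
        pop = cc.sample_population(cfg, seed=seed)
        table, _ = cc.simulate_trials(pop, cfg, seed=seed + 1)
        return table

    def test_halves_of_twenty(self, space5):
        table = self._table(20)
        labels = cc.partition_trials(table, 2, seed=1)
        ids = table.condition_ids(space5)
        for cid in range(32):
            counts = [np.sum((ids == cid) & (labels == p)) for p in (0, 1)]
            assert counts == [10, 10]

    def test_thirds_of_twenty(self, space5):
        table = self._table(20)
        labels = cc.partition_trials(table, 3, seed=2)
        ids = table.condition_ids(space5)
        for cid in range(32):
            counts = sorted(np.sum((ids == cid) & (labels == p)) for p in (0, 1, 2))
            assert counts == [6, 7, 7]

    def test_covariate_balancing_beats_random_split(self):
        # balanced splits should show smaller between-half covariate
        # differences than the median unbalanced random split
        table = self._table(20, with_pupil=True, seed=3)
        cov = table.df["pupil_diameter"].to_numpy()
        bal = cc.partition_trials(table, 2, balance_keys=("pupil_diameter",), seed=4)
        gap_bal = abs(cov[bal == 0].mean() - cov[bal == 1].mean())
        gaps = []
        for s in range(31):
            lab = cc.partition_trials(table, 2, seed=100 + s)
            gaps.append(abs(cov[lab == 0].mean() - cov[lab == 1].mean()))
        assert gap_bal <= np.median(gaps)

    def test_too_few_trials_raises(self):
        table = self._table(2)
        with pytest.raises(ValueError):
            cc.partition_trials(table, 3, seed=0)


class TestReliability:
    def test_identical_curves(self, space5):
        v = np.random.default_rng(1).normal(size=31)
        a = cc.TuningCurve(values=v, space=space5)
        assert cc.reliability(a, a) == pytest.approx(1.0)

    def test_anticorrelated(self, space5):
        v = np.arange(31.0)
        a = cc.TuningCurve(values=v, space=space5)
        b = cc.TuningCurve(values=-v, space=space5)
        assert cc.reliability(a, b) == pytest.approx(-1.0)

    def test_independent_noise_centers_on_zero(self, space5):
        rng = np.random.default_rng(2)
        rs = [
            cc.reliability(
                cc.TuningCurve(values=rng.normal(size=31), space=space5),
                cc.TuningCurve(values=rng.normal(size=31), space=space5),
            )
            for _ in range(1000)
        ]
        assert abs(np.mean(rs)) < 3 / np.sqrt(31 * 1000)  # ~3 SE

    def test_zero_variance_is_nan(self, space5):
        a = cc.TuningCurve(values=np.ones(31), space=space5)
        b = cc.TuningCurve(values=np.arange(31.0), space=space5)
        assert np.isnan(cc.reliability(a, b))


def comprehensive_population(space, trials_pc=8, noise=0.0, seed=0):
    """One noiseless neuron per condition: responds 1 to it, 0 elsewhere."""
    rng = np.random.default_rng(seed)
    n_cond = len(space.conditions)
    ids = np.repeat(np.arange(n_cond), trials_pc)
    rng.shuffle(ids)
    vals = np.zeros((31, ids.size))
    for i, c in enumerate(space.non_catch):
        vals[i, ids == space.index(c)] = 1.0
    vals += rng.normal(scale=noise, size=vals.shape)
    resp = ResponseMatrix(values=vals, condition_ids=ids, space=space)
    onsets = np.arange(ids.size) * 50 + 10
    df = pd.DataFrame(
        {
            "condition_bits": [space.conditions[i].bitstring(5) for i in ids],
            "is_catch": [space.conditions[i].is_catch for i in ids],
            "onset_frame": onsets,
            "run_speed": np.full(ids.size, 30.0),
        }
    )
    table = TrialTable(df=df, stim_duration_s=1.0, iti_s=2.0)
    return table, resp


class TestPopulationMatrices:
    def test_comprehensive_population_is_block_diagonal(self, space5):
        table, resp = comprehensive_population(space5, noise=1e-6, seed=1)
        labels = cc.partition_trials(table, 2, seed=2)
        pm_t, pm_ld = cc.population_matrices(resp, labels, scheme="halves", seed=2)
        assert pm_t.matrix.shape == (31, 31)
        # every row peaks at its preferred condition; rows cover all 31
        assert sorted(pm_t.row_pref.tolist()) == list(range(31))
        for row in range(31):
            assert np.argmax(pm_t.matrix[row]) == pm_t.row_pref[row]
            assert pm_t.matrix[row].max() == pytest.approx(1.0)

    def test_thirds_display_ignores_training_data(self, space5):
        # poisoning parts 0-1 must not change any displayed row
        table, resp = comprehensive_population(space5, noise=0.05, seed=3)
        labels = cc.partition_trials(table, 3, seed=4)
        pm_t, _ = cc.population_matrices(resp, labels, scheme="thirds", seed=4)
        poisoned = ResponseMatrix(
            values=resp.values + 7.3 * (labels != 2)[None, :],
            condition_ids=resp.condition_ids,
            space=space5,
        )
        pm_p, _ = cc.population_matrices(poisoned, labels, scheme="thirds", seed=4)
        by_neuron = dict(zip(pm_p.row_neurons, pm_p.matrix))
        for neuron, row in zip(pm_t.row_neurons, pm_t.matrix):
            if neuron in by_neuron:
                assert np.allclose(row, by_neuron[neuron], equal_nan=True)

    def test_infinite_threshold_empties_matrix(self, space5):
        table, resp = comprehensive_population(space5, noise=0.01, seed=5)
        labels = cc.partition_trials(table, 2, seed=5)
        with pytest.warns(UserWarning):
            pm_t, pm_ld = cc.population_matrices(resp, labels, r_thresh=np.inf, seed=5)
        assert pm_t.matrix.shape[0] == 0
        assert np.isnan(cc.diagonal_enrichment(pm_ld))

    def test_row_normalization_bounded(self, ln_session):
        cfg, pop, table, resp = ln_session
        labels = cc.partition_trials(table, 2, seed=6)
        pm_t, pm_ld = cc.population_matrices(resp, labels, seed=6)
        for M in (pm_t.matrix, pm_ld.matrix):
            assert np.nanmax(np.abs(M)) <= 1.0 + 1e-12


class TestSortedLinearDifference:
    def test_linear_population_flat_at_zero(self, space5):
        # tabulated neurons with exactly linear multi responses
        rng = np.random.default_rng(8)
        curves = []
        for _ in range(20):
            w = rng.uniform(0.5, 1.5, size=5)
            curves.append([sum(w[j] for j in c.mask) for c in space5.non_catch])
        vals = np.array(curves)
        ids = np.repeat(np.arange(32), 10)
        noise = rng.normal(scale=0.01, size=(20, ids.size))
        full = np.concatenate([vals, np.zeros((20, 1))], axis=1)[:, ids] + noise
        resp = ResponseMatrix(values=full, condition_ids=ids, space=space5)
        onsets = np.arange(ids.size) * 50 + 10
        df = pd.DataFrame(
            {
                "condition_bits": [space5.conditions[i].bitstring(5) for i in ids],
                "is_catch": [space5.conditions[i].is_catch for i in ids],
                "onset_frame": onsets,
                "run_speed": np.full(ids.size, 30.0),
            }
        )
        table = TrialTable(df=df, stim_duration_s=1.0, iti_s=2.0)
        labels = cc.partition_trials(table, 2, seed=9)
        rank_means, n = cc.sorted_linear_difference(resp, labels)
        assert n > 0
        assert np.all(np.abs(rank_means) < 0.05)

    def test_threshold_population_peaks_at_rank_one(self, ln_session):
        cfg, pop, table, resp = ln_session
        labels = cc.partition_trials(table, 2, seed=10)
        rank_means, n = cc.sorted_linear_difference(resp, labels)
        assert n > 10
        assert rank_means[0] > 0
        assert np.mean(rank_means[5:]) < rank_means[0]


class TestSupralinearityTest:
    def test_deterministic_supralinear_neuron(self, space5, design5):
        p = cc.LNParams(w=np.array([1.0, 1.0, 0, 0, 0.0]), h=-1.5, a=1.0)
        values = np.concatenate([cc.ln_predict(p, design5), [0.0]])
        resp = matrix_from(values[None, :], space5, trials_pc=8)
        labels = np.tile([0, 1], resp.n_trials // 2)
        res = cc.supralinearity_test(resp, 0, labels == 0, labels == 1, n_boot=500, seed=0)
        assert res.label == "supra"
        assert res.p_supra == 0.0
        assert res.ld_top > 0

    def test_single_element_preference_is_not_tested(self, space5):
        values = np.zeros(32)
        values[0] = 1.0  # prefers the first singleton
        resp = matrix_from(values[None, :], space5, trials_pc=6)
        labels = np.tile([0, 1], resp.n_trials // 2)
        res = cc.supralinearity_test(resp, 0, labels == 0, labels == 1, n_boot=200, seed=0)
        assert res.label == "ns"
        assert "not multi-element" in res.reason

    def test_null_calibration(self, space5):
        # linear tuning + iid noise: supra flags at two-sided-0.01 should be rare
        rng = np.random.default_rng(11)
        ids = np.repeat(np.arange(32), 20)
        flags = 0
        tested = 0
        for i in range(300):
            w = rng.uniform(0.5, 1.5, size=5)
            mean = np.array(
                [0.0 if c.is_catch else sum(w[j] for j in c.mask) for c in (space5.conditions[k] for k in ids)]
            )
            vals = (mean + rng.normal(scale=0.5, size=ids.size))[None, :]
            resp = ResponseMatrix(values=vals, condition_ids=ids, space=space5)
            labels = np.tile([0, 1], ids.size // 2)
            res = cc.supralinearity_test(resp, 0, labels == 0, labels == 1, n_boot=400, seed=500 + i)
            if not res.reason:
                tested += 1
                flags += res.label == "supra"
        assert tested > 100
        assert flags / tested <= 0.05
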