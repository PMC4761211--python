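"""Median split, probe grid, consensus vote, and the type-I error calculus."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from consig.selection import (
    ConsensusCriteria,
    ConsensusSelector,
    analytic_type1,
    bonferroni_fwer,
    consensus_select,
    median_split,
    monte_carlo_type1,
    probe_cohort_grid,
    probe_cohort_test,
)
from consig.survival import cox_fit, logrank_test
from conftest import random_survival_dataset


class TestMedianSplit:
    @pytest.mark.parametrize(
        "values,expected_high",
        [
            ([1, 2, 3, 4], [False, False, True, True]),
            ([1, 2, 2, 3], [False, False, False, True]),  # ties at the median go low
            ([5, 1, 9, 7], [False, False, True, True]),
        ],
    )
    def test_split_conventions(self, values, expected_high):
        np.testing.assert_array_equal(median_split(values), expected_high)

    def test_odd_n(self):
        np.testing.assert_array_equal(
            median_split([5, 1, 9, 3, 7]), [False, False, True, False, True]
        )

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError, match="impossible"):
            median_split([2.0, 2.0, 2.0, 2.0])

    def test_too_few_values_raises(self):
        with pytest.raises(ValueError, match="at least 4"):
            median_split([1.0, 2.0, 3.0])


class TestProbeCohortTest:
    def test_grid_agrees_with_scalar_fits(self, rng):
        """The vectorized two-group engine must reproduce cox_fit/logrank_test."""
        x, t, e = random_survival_dataset(rng, n=60)
        expr = pd.DataFrame(rng.standard_normal((20, 60)),
                            index=[f"p{i:02d}" for i in range(20)])
        grid = probe_cohort_grid(expr, t, e)
        for _, row in grid.iloc[:8].iterrows():
            v = expr.loc[row["probe_id"]].to_numpy()
            high = v > np.median(v)
            ref = cox_fit(high.astype(float)[:, None], t, e)
            lr = logrank_test(t, e, high.astype(int))
            assert row["coef"] == pytest.approx(ref.coef[0], abs=1e-8)
            assert row["se"] == pytest.approx(ref.se[0], abs=1e-8)
            assert row["p"] == pytest.approx(lr.p, abs=1e-10)
            assert row["direction"] == np.sign(ref.coef[0])

    def test_alignment_invariance_under_joint_permutation(self, rng):
        x, t, e = random_survival_dataset(rng, n=40)
        res = probe_cohort_test(x, t, e)
        perm = rng.permutation(40)
        res2 = probe_cohort_test(x[perm], t[perm], e[perm])
        assert res2.hr == pytest.approx(res.hr, abs=1e-10)
        assert res2.p == pytest.approx(res.p, abs=1e-12)
        assert res2.direction == res.direction

    def test_planted_effect_recovers_direction(self, toy_cohort):
        cfg, expr, clin = toy_cohort
        probe = cfg.prognostic_ids()[0]
        res = probe_cohort_test(
            expr.values.loc[probe].to_numpy(), clin["time"], clin["event"],
            probe_id=probe,
        )
        assert res.hr > 1 and res.direction == 1 and res.p < 0.05

    def test_null_probe_p_is_calibrated(self, rng):
        """Null log-rank p < 0.05 should occur at ~5% over replicates."""
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            x = rng.standard_normal(60)
            t = rng.exponential(30.0, 60)
            e = (rng.random(60) > 0.3).astype(int)
            if probe_cohort_test(x, t, e).p < 0.05:
                hits += 1
        assert hits / n_rep == pytest.approx(0.05, abs=0.025)

    def test_separated_probe_reports_infinite_hr(self):
        # expression perfectly orders early events vs late censorings
        t = np.array([1.0, 2.0, 3.0, 4.0, 50.0, 60.0, 70.0, 80.0])
        e = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        x = np.array([10, 9, 8, 7, 1, 2, 3, 4], dtype=float)
        res = probe_cohort_test(x, t, e)
        assert np.isinf(res.hr) and res.direction == 1
        assert 0 <= res.p <= 1


def make_grid(p_by_probe, dir_by_probe, cohorts):
    rows = []
    for probe, ps in p_by_probe.items():
        for c, p in zip(cohorts, ps):
            rows.append(
                {
                    "probe_id": probe,
                    "cohort_id": c,
                    "hr": np.exp(dir_by_probe[probe][cohorts.index(c)]),
                    "p": p,
                    "direction": int(np.sign(dir_by_probe[probe][cohorts.index(c)])),
                }
            )
    return pd.DataFrame(rows)


class TestConsensusSelect:
    cohorts = [f"c{i}" for i in range(7)]

    def test_six_of_seven_significant_same_direction_selected(self):
        grid = make_grid(
            {"a": [0.01] * 6 + [0.3]}, {"a": [1.0] * 7}, self.cohorts
        )
        assert consensus_select(grid, ConsensusCriteria()) == ["a"]

    def test_direction_veto(self):
        grid = make_grid(
            {"a": [0.01] * 6 + [0.3]}, {"a": [1.0] * 6 + [-1.0]}, self.cohorts
        )
        assert consensus_select(grid, ConsensusCriteria()) == []

    def test_vacuous_criteria_select_everything(self):
        grid = make_grid(
            {"a": [0.9] * 7, "b": [0.9] * 7},
            {"a": [1.0] * 7, "b": [-1.0] * 3 + [1.0] * 4},
            self.cohorts,
        )
        crit = ConsensusCriteria(min_significant=0, require_all_same_direction=False)
        assert consensus_select(grid, crit) == ["a", "b"]

    def test_incomplete_grid_raises(self):
        grid = make_grid({"a": [0.01] * 7}, {"a": [1.0] * 7}, self.cohorts)
        grid = grid.iloc[:-1]
        with pytest.raises(ValueError, match="cohorts"):
            consensus_select(grid, ConsensusCriteria())
        grid2 = pd.concat(
            [make_grid({"a": [0.01] * 7}, {"a": [1.0] * 7}, self.cohorts),
             make_grid({"b": [0.01] * 6}, {"b": [1.0] * 6}, self.cohorts[:6])],
            ignore_index=True,
        )
        with pytest.raises(ValueError, match="missing"):
            consensus_select(grid2, ConsensusCriteria())

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        ps=st.lists(
            st.lists(st.floats(0.001, 0.999), min_size=5, max_size=5),
            min_size=3, max_size=6,
        ),
        alpha_lo=st.floats(0.01, 0.1),
        alpha_hi=st.floats(0.1, 0.5),
        min_sig=st.integers(0, 5),
    )
    def test_monotone_in_alpha_and_min_significant(self, ps, alpha_lo, alpha_hi, min_sig):
        """Lowering alpha or raising min_significant never adds a probe."""
        cohorts = [f"c{i}" for i in range(5)]
        p_by = {f"g{i}": p for i, p in enumerate(ps)}
        d_by = {k: [1.0] * 5 for k in p_by}
        grid = make_grid(p_by, d_by, cohorts)

        def sel(alpha, ms):
            return set(
                consensus_select(
                    grid,
                    ConsensusCriteria(alpha=alpha, min_significant=ms, n_cohorts=5),
                )
            )

        assert sel(alpha_lo, min_sig) <= sel(alpha_hi, min_sig)
        if min_sig < 5:
            assert sel(alpha_hi, min_sig + 1) <= sel(alpha_hi, min_sig)


class TestConsensusSelector:
    def test_sklearn_selector_recovers_planted_probe(self):
        from consig.simulate import SimulationConfig, generate_multi_cohort

        cfg = SimulationConfig(
            cohort_sizes=(150, 150, 150), n_probes=40, prognostic_probe_count=1,
            log_hazard_effects=(np.log(3.0),), intra_signature_correlation=0.0, seed=3,
        )
        cohorts = generate_multi_cohort(cfg)
        X = pd.concat(
            [c.expression.values.T for c in cohorts], axis=0
        )
        y = pd.concat([c.clinical[["time", "event"]] for c in cohorts], axis=0)
        groups = np.concatenate(
            [[c.cohort_id] * len(c.clinical) for c in cohorts]
        )
        sel = ConsensusSelector(min_significant=3).fit(X, y, groups=groups)
        assert sel.selected_ids_ == cfg.prognostic_ids()
        Xt = sel.transform(X)
        assert Xt.shape == (X.shape[0], 1)
        assert sel.get_support().sum() == 1


def enumerate_type1(n, k, alpha):
    """Exhaustive enumeration over all 2^n significance patterns."""
    total = 0.0
    for pattern in itertools.product([0, 1], repeat=n):
        if sum(pattern) >= k:
            total += np.prod([alpha if b else 1 - alpha for b in pattern])
    return total


class TestAnalyticType1:
    @pytest.mark.parametrize(
        "n,k,alpha",
        [(3, 2, 0.2), (5, 4, 0.05), (7, 6, 0.05), (7, 6, 0.2), (10, 8, 0.1), (4, 0, 0.3)],
    )
    def test_matches_exhaustive_enumeration(self, n, k, alpha):
        assert analytic_type1(n, k, alpha) == pytest.approx(
            enumerate_type1(n, k, alpha), rel=1e-12
        )

    def test_three_of_two_at_alpha_point_two(self):
        assert analytic_type1(3, 2, 0.2) == pytest.approx(0.104, abs=1e-12)

    def test_vacuous_threshold_gives_one(self):
        assert analytic_type1(5, 0, 0.01) == 1.0

    def test_direction_requirement_multiplies_sign_probability(self):
        base = analytic_type1(7, 6, 0.05)
        both = analytic_type1(7, 6, 0.05, require_all_same_direction=True)
        assert both == pytest.approx(base * 2.0 ** (1 - 7), rel=1e-12)

    def test_bonferroni_caps_at_one(self):
        assert bonferroni_fwer(1e-7, 22277) == pytest.approx(22277e-7)
        assert bonferroni_fwer(0.5, 10) == 1.0


class TestMonteCarloType1:
    def test_estimate_within_band_of_analytic(self):
        crit = ConsensusCriteria(
            alpha=0.2, min_significant=2, n_cohorts=3, require_all_same_direction=False
        )
        res = monte_carlo_type1(crit, 4000, [50, 50, 50], seed=11)
        band = 2.81 * np.sqrt(0.104 * 0.896 / 4000)  # 99.5% normal band
        assert abs(res.estimate - 0.104) < band
        assert res.ci_low < res.estimate < res.ci_high

    def test_direction_flag_halves_or_more(self):
        crit_off = ConsensusCriteria(
            alpha=0.2, min_significant=2, n_cohorts=3, require_all_same_direction=False
        )
        crit_on = ConsensusCriteria(
            alpha=0.2, min_significant=2, n_cohorts=3, require_all_same_direction=True
        )
        off = monte_carlo_type1(crit_off, 3000, [40, 40, 40], seed=5)
        on = monte_carlo_type1(crit_on, 3000, [40, 40, 40], seed=5)
        assert on.estimate <= off.estimate / 2 + 0.01

    def test_deterministic_under_fixed_seed(self):
        crit = ConsensusCriteria(
            alpha=0.2, min_significant=1, n_cohorts=2, require_all_same_direction=False
        )
        r1 = monte_carlo_type1(crit, 500, [30, 30], seed=42)
        r2 = monte_carlo_type1(crit, 500, [30, 30], seed=42)
        assert r1 == r2

    def test_refuses_unobservable_criteria(self):
        crit = ConsensusCriteria()  # analytic rate ~1e-7
        with pytest.raises(ValueError, match="relax"):
            monte_carlo_type1(crit, 1000, [50] * 7, seed=0)
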