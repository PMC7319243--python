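import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from funcresp.core_model import FRParams
from funcresp.estimation import (
    BootstrapSet,
    _negloglik,
    bootstrap_fr,
    classify_fr,
    compare_bootstrapped_params,
    fit_rogers_mle,
)
from funcresp.synthetic_data import ExperimentDesign, generate_trials
from tests.conftest import ONE_GROUP


class TestClassifyFR:
    def test_type_ii_data_gives_negative_slope(self, type2_trials):
        res = classify_fr(type2_trials)
        assert res.fr_type == "II"
        assert res.linear_coef < 0
        assert res.linear_p < 0.05

    def test_type_iii_data_detected_by_sign_pattern(self):
        # density-dependent attack rate: proportion eaten rises then falls
        design = ExperimentDesign(
            species=("largemouth_bass",),
            pred_sizes=("small",),
            prey_sizes=("small",),
            replicates=10,
        )
        truths = {ONE_GROUP: FRParams(a=0.05, h=0.05, q=1.0, form="hassell_iii")}
        trials = generate_trials(design, truths, seed=7)
        res = classify_fr(trials)
        assert res.fr_type == "III"
        assert res.quadratic_coef < 0 and res.quadratic_p < 0.05

    def test_constant_proportion_is_equivocal_with_aic_table(self):
        trials = pd.DataFrame(
            {"n0": [2, 4, 8, 16, 32] * 3, "ne": [1, 2, 4, 8, 16] * 3, "t_hr": 1.0}
        )
        res = classify_fr(trials)
        assert res.linear_coef == pytest.approx(0.0, abs=1e-6)
        assert res.fr_type == "equivocal"
        assert set(res.aic_table) == {"rogers_ii", "hassell_iii", "generalized"}
        assert res.aic_best_form is not None

    def test_all_zero_consumption_flagged_not_raised(self):
        trials = pd.DataFrame({"n0": [2, 4, 8] * 3, "ne": 0, "t_hr": 1.0})
        res = classify_fr(trials)
        assert res.fr_type == "undeterminable"

    def test_requires_two_densities(self):
        trials = pd.DataFrame({"n0": [8] * 6, "ne": [1, 2, 3, 1, 2, 3], "t_hr": 1.0})
        with pytest.raises(ValueError):
            classify_fr(trials)


class TestFitRogersMLE:
    def test_noise_free_rounded_data_recovers_inputs_within_one_se(self):
        # deterministic expectations rounded to integers, 3 reps per density
        params = FRParams(a=1.0, h=0.01)
        from funcresp.core_model import rogers_expected_eaten

        rows = []
        for n0 in (2, 4, 8, 16, 32, 64):
            ne = int(np.floor(rogers_expected_eaten(n0, params, 1.0) + 0.5))
            rows += [(n0, ne, 1.0)] * 3
        trials = pd.DataFrame(rows, columns=["n0", "ne", "t_hr"])
        fit = fit_rogers_mle(trials)
        assert fit.converged
        assert abs(fit.a - 1.0) <= fit.se_a
        assert abs(fit.h - 0.01) <= fit.se_h

    def test_all_zero_consumption_boundary_fit(self):
        trials = pd.DataFrame({"n0": [2, 4, 8] * 3, "ne": 0, "t_hr": 1.0})
        fit = fit_rogers_mle(trials)
        assert fit.a == 0.0
        assert not fit.converged
        assert np.isnan(fit.se_a)

    def test_parameter_recovery_large_sample(self):
        # 200 binomial trials from (a=0.45, h=0.01): estimate within 3 SE
        design = ExperimentDesign(
            species=("largemouth_bass",),
            pred_sizes=("small",),
            prey_sizes=("small",),
            replicates=34,  # 34 reps x 6 densities = 204 trials
        )
        truths = {ONE_GROUP: FRParams(a=0.45, h=0.01)}
        trials = generate_trials(design, truths, seed=11)
        fit = fit_rogers_mle(trials)
        assert fit.converged
        assert abs(fit.a - 0.45) <= 3 * fit.se_a
        assert abs(fit.h - 0.01) <= 3 * fit.se_h

    def test_optimum_beats_every_multistart_point(self, type2_trials):
        fit = fit_rogers_mle(type2_trials)
        n0 = type2_trials["n0"].to_numpy(float)
        ne = type2_trials["ne"].to_numpy(float)
        t = type2_trials["t_hr"].to_numpy(float)
        for a0, h0 in itertools.product((0.1, 1.0, 5.0), (0.001, 0.05, 0.3)):
            start_nll = _negloglik(np.log([a0, h0]), "rogers_ii", n0, ne, t)
            assert -fit.loglik <= start_nll + 1e-9

    def test_mle_matches_dense_grid_search(self, toy_trials):
        # independent oracle: exhaustive 200x200 grid over (a, h)
        fit = fit_rogers_mle(toy_trials)
        a_grid = np.linspace(0.05, 3.0, 200)
        h_grid = np.linspace(1e-4, 0.2, 200)
        n0 = toy_trials["n0"].to_numpy(float)
        ne = toy_trials["ne"].to_numpy(float)
        t = toy_trials["t_hr"].to_numpy(float)
        nll = np.array(
            [
                [_negloglik(np.log([a, h]), "rogers_ii", n0, ne, t) for h in h_grid]
                for a in a_grid
            ]
        )
        i, j = np.unravel_index(np.argmin(nll), nll.shape)
        assert abs(fit.a - a_grid[i]) <= a_grid[1] - a_grid[0]
        assert abs(fit.h - h_grid[j]) <= h_grid[1] - h_grid[0]

    def test_aic_counts_free_parameters(self, toy_trials):
        fit2 = fit_rogers_mle(toy_trials)
        assert fit2.aic == pytest.approx(2 * 2 - 2 * fit2.loglik)
        fitg = fit_rogers_mle(toy_trials, form="generalized")
        assert fitg.aic == pytest.approx(2 * 3 - 2 * fitg.loglik)


class TestBootstrap:
    def test_draw_count_and_cap(self, type2_trials):
        bs = bootstrap_fr(type2_trials, n=20, seed=3, group=ONE_GROUP)
        assert len(bs.a) == 20 and len(bs.h) == 20
        assert (bs.a >= 0).all() and (bs.h >= 0).all()

    def test_deterministic_under_seed(self, type2_trials):
        b1 = bootstrap_fr(type2_trials, n=5, seed=42)
        b2 = bootstrap_fr(type2_trials, n=5, seed=42)
        np.testing.assert_array_equal(b1.a, b2.a)
        np.testing.assert_array_equal(b1.h, b2.h)

    def test_identical_trials_give_degenerate_draws(self):
        # zero variance within every density stratum: every resample is
        # the same dataset, so every draw equals the point estimate
        trials = pd.DataFrame(
            {"n0": [2, 4, 8, 16, 32] * 3, "ne": [1, 2, 4, 6, 8] * 3, "t_hr": 1.0}
        )
        point = fit_rogers_mle(trials)
        bs = bootstrap_fr(trials, n=10, seed=9)
        np.testing.assert_allclose(bs.a, point.a, rtol=1e-6)
        np.testing.assert_allclose(bs.h, point.h, rtol=1e-6)

    def test_large_bootstrap_mean_near_point_estimate(self, type2_trials):
        # diagnostic mode: 500 draws; bootstrap mean within 10% of the MLE
        point = fit_rogers_mle(type2_trials)
        bs = bootstrap_fr(type2_trials, n=500, seed=21)
        assert abs(bs.a.mean() - point.a) / point.a < 0.10
        assert abs(bs.h.mean() - point.h) / point.h < 0.10

    def test_seed_required(self, type2_trials):
        with pytest.raises(ValueError):
            bootstrap_fr(type2_trials, n=5)


def _gamma_sets(rng, truths):
    """BootstrapSets with gamma-distributed draws around given means."""
    sets = []
    for (sp, ps), (a_mean, h_mean) in truths.items():
        sets.append(
            BootstrapSet(
                group=(sp, ps, "small"),
                a=rng.gamma(30.0, a_mean / 30.0, 20),
                h=rng.gamma(30.0, h_mean / 30.0, 20),
                n=20,
                seed=0,
            )
        )
    return sets


class TestCompareBootstrappedParams:
    def test_single_group_gives_empty_table(self):
        rng = np.random.default_rng(1)
        sets = _gamma_sets(rng, {("largemouth_bass", "small"): (1.0, 0.05)})
        table = compare_bootstrapped_params(sets, "a")
        assert table.empty

    def test_true_difference_in_attack_rate_detected(self):
        rng = np.random.default_rng(5)
        sets = _gamma_sets(
            rng,
            {("largemouth_bass", "small"): (1.0, 0.05), ("bluegill", "small"): (5.0, 0.05)},
        )
        table = compare_bootstrapped_params(sets, "a")
        row = table[table["term"] == "species"]
        assert float(row["p"].iloc[0]) < 0.05

    def test_type_i_error_rate_controlled_under_identical_truths(self):
        # identical truths in a 2x2 species x size layout: the interaction
        # should be non-significant in >= 90% of 100 seeded runs
        n_false = 0
        for run in range(100):
            rng = np.random.default_rng(1000 + run)
            sets = _gamma_sets(
                rng,
                {
                    (sp, ps): (1.0, 0.05)
                    for sp in ("largemouth_bass", "bluegill")
                    for ps in ("small", "large")
                },
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                table = compare_bootstrapped_params(sets, "a")
            interactions = table[table["term"].str.contains(":")]
            if (interactions["p"] < 0.05).any():
                n_false += 1
        assert n_false <= 10

    def test_zero_only_group_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        sets = _gamma_sets(
            rng,
            {("largemouth_bass", "small"): (1.0, 0.05), ("bluegill", "small"): (2.0, 0.05)},
        )
        sets.append(
            BootstrapSet(
                group=("bluegill", "large", "small"),
                a=np.zeros(20),
                h=np.zeros(20),
                n=20,
                seed=0,
            )
        )
        with pytest.warns(UserWarning, match="all-zero"):
            table = compare_bootstrapped_params(sets, "a")
        assert not table.empty
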