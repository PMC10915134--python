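import numpy as np
import pandas as pd
import pytest

from pbmscore.survival import (
    _cox_loglik_breslow,
    cox_fit,
    cv_compare_models,
    harrell_c,
    km_logrank,
    median_split,
    stage_iss,
    stage_r2_iss,
    stage_r_iss,
)


class TestMedianSplit:
    def test_even_split(self):
        g = median_split(pd.Series([1, 2, 3, 4], index=list("abcd")))
        assert set(g[g == "high"].index) == {"c", "d"}

    def test_median_value_goes_low(self):
        g = median_split(pd.Series([1, 2, 3], index=list("abc")))
        assert set(g[g == "high"].index) == {"c"}

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            median_split(pd.Series([5, 5, 5]))


class TestKMLogrank:
    def test_identical_groups_chi_square_zero(self):
        res = km_logrank([1, 2, 3, 1, 2, 3], [1, 0, 1, 1, 0, 1], list("AAABBB"))
        assert res.chi_square == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_chi_square(self):
        # A events at 1,2; B events at 3,4: O-E = 2 - 5/6, variance 17/36
        res = km_logrank([1, 2, 3, 4], [1, 1, 1, 1], list("AABB"))
        assert res.chi_square == pytest.approx(2.88235, abs=1e-4)

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            km_logrank([1, 2, 3, 4], [0, 0, 0, 0], list("AABB"))

    def test_curves_are_product_limit(self):
        res = km_logrank([1, 2, 3, 4], [1, 1, 1, 1], list("AABB"))
        s_a = res.curves["A"].iloc[:, 0]
        assert s_a.loc[1.0] == pytest.approx(0.5)
        assert s_a.loc[2.0] == pytest.approx(0.0)


def brute_force_cox_beta(times, events, x):
    """Grid + golden-section maximisation of the one-covariate Breslow
    partial likelihood, independent of the Newton path."""
    from scipy.optimize import minimize_scalar

    X = np.asarray(x, float).reshape(-1, 1)

    def neg_ll(b):
        return -_cox_loglik_breslow(np.array([b]), np.asarray(times, float),
                                    np.asarray(events, int), X)[0]

    res = minimize_scalar(neg_ll, bounds=(-5, 5), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


def naive_breslow_loglik(beta, times, events, x):
    """Direct risk-set double loop (independent of the vectorised path)."""
    ll = 0.0
    for i in range(len(times)):
        if events[i]:
            risk = [j for j in range(len(times)) if times[j] >= times[i]]
            ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


class TestCox:
    def test_mirrored_dataset_gives_null_coefficient(self):
        times = [3, 5, 7, 9, 3, 5, 7, 9]
        events = [1, 1, 0, 1, 1, 1, 0, 1]
        x = [0, 0, 1, 1, 1, 1, 0, 0]
        for ties in ("efron", "breslow"):
            res = cox_fit(times, events, pd.DataFrame({"x": x}), ties=ties)
            assert res.coef("x") == pytest.approx(0.0, abs=1e-6)
            assert res.hr("x") == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_matches_brute_force_likelihood_oracle(self, rng, ties):
        """Estimated coefficient maximises the partial likelihood (checked
        against bounded scalar optimisation on tie-free data, where Efron
        and Breslow coincide)."""
        for _ in range(15):
            n = 8
            times = rng.permutation(np.arange(1.0, n + 1))  # no ties
            events = rng.integers(0, 2, size=n)
            if events.sum() < 2:
                events[:2] = 1
            x = rng.normal(size=n)
            beta_hat = cox_fit(
                times, events, pd.DataFrame({"x": x}), ties=ties
            ).coef("x")
            if abs(beta_hat) > 4.5:  # near-separation: oracle bound region
                continue
            assert beta_hat == pytest.approx(
                brute_force_cox_beta(times, events, x), abs=1e-4
            )

    def test_internal_likelihood_matches_naive_risk_set_loop(self, rng):
        times = rng.permutation(np.arange(1.0, 11))
        events = rng.integers(0, 2, size=10)
        x = rng.normal(size=10)
        for beta in (-1.0, 0.0, 0.7):
            ll = _cox_loglik_breslow(
                np.array([beta]), times, events, x.reshape(-1, 1)
            )[0]
            assert ll == pytest.approx(naive_breslow_loglik(beta, times, events, x))

    def test_separation_flagged_not_raised(self):
        # binary covariate perfectly ordering event times
        times = [1, 2, 3, 4, 5, 6]
        events = [1, 1, 1, 1, 1, 1]
        x = [1, 1, 1, 0, 0, 0]
        res = cox_fit(times, events, pd.DataFrame({"x": x}))
        assert not res.converged
        assert np.isinf(res.summary.loc["x", "coef"])

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit([1, 2], [1, 1], pd.DataFrame({"x": [1.0, 1.0]}))

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            cox_fit([1, 2], [0, 0], pd.DataFrame({"x": [1.0, 2.0]}))


def pairwise_c_oracle(times, events, risk):
    conc = disc = ties = 0
    n = len(times)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = (i, j) if times[i] < times[j] else (j, i)
            if times[i] == times[j]:
                continue  # neither both-event equal-time nor usable ordering here
            if not events[a]:
                continue
            if risk[a] > risk[b]:
                conc += 1
            elif risk[a] < risk[b]:
                disc += 1
            else:
                ties += 1
    return (conc + 0.5 * ties) / (conc + disc + ties)


class TestHarrellC:
    def test_perfect_concordance(self):
        assert harrell_c([1, 2, 3], [1, 1, 1], [3, 2, 1]) == 1.0

    def test_perfect_discordance_with_censoring(self):
        assert harrell_c([1, 2, 3], [1, 0, 1], [1, 3, 2]) == 0.0

    def test_all_risk_ties_give_half(self):
        assert harrell_c([1, 2, 3], [1, 1, 1], [5, 5, 5]) == 0.5

    def test_no_usable_pairs_rejected(self):
        with pytest.raises(ValueError):
            harrell_c([1, 2], [0, 0], [1, 2])

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 31))
            times = rng.permutation(np.arange(1.0, n + 1))  # distinct times
            events = rng.integers(0, 2, size=n)
            if events.sum() == 0:
                events[0] = 1
            risk = rng.integers(0, 5, size=n).astype(float)  # ties in risk
            assert harrell_c(times, events, risk) == pytest.approx(
                pairwise_c_oracle(times, events, risk)
            )


def _cv_data(rng, n=150):
    lam = rng.uniform(size=n)
    iss = rng.integers(1, 4, size=n).astype(float)
    rate = 0.02 * np.exp(np.log(2.2) * lam + 0.3 * (iss - 1))
    t = rng.exponential(1 / rate)
    c = rng.uniform(0, np.quantile(t, 0.9), size=n)
    return pd.DataFrame(
        {
            "os_time": np.minimum(t, c),
            "os_event": (t <= c).astype(int),
            "iss": iss,
            "score": lam + rng.normal(0, 0.1, size=n),
        },
        index=[f"S{i}" for i in range(n)],
    )


class TestCVCompare:
    def test_model_against_itself_p_one(self, rng):
        data = _cv_data(rng)
        res = cv_compare_models(
            data, {"a": ["iss"], "b": ["iss"]}, repeats=3, folds=3, seed=4
        )
        assert np.array_equal(res.c_indexes["a"], res.c_indexes["b"])
        assert res.pairwise_p.loc["a", "b"] == 1.0

    def test_informative_score_improves_mean_c(self, rng):
        data = _cv_data(rng, n=250)
        res = cv_compare_models(
            data,
            {"iss": ["iss"], "iss+score": ["iss", "score"]},
            repeats=5,
            folds=5,
            seed=11,
        )
        assert res.mean_c["iss+score"] > res.mean_c["iss"]

    def test_deterministic_and_order_invariant(self, rng):
        data = _cv_data(rng)
        shuffled = data.sample(frac=1.0, random_state=3)
        a = cv_compare_models(data, {"m": ["score"]}, repeats=2, folds=3, seed=5)
        b = cv_compare_models(shuffled, {"m": ["score"]}, repeats=2, folds=3, seed=5)
        assert np.array_equal(a.c_indexes["m"], b.c_indexes["m"])

    def test_insufficient_complete_cases_rejected(self, rng):
        data = _cv_data(rng, n=15)
        with pytest.raises(ValueError, match="complete cases"):
            cv_compare_models(data, {"m": ["iss", "score"]}, repeats=1, folds=3, seed=1)


class TestStaging:
    @pytest.mark.parametrize(
        "b2m, alb, expected",
        [(6.0, 4.0, 3), (3.0, 3.6, 1), (4.0, 4.0, 2), (3.0, 3.0, 2), (5.5, 4.0, 3)],
    )
    def test_iss(self, b2m, alb, expected):
        assert stage_iss([b2m], [alb]).iloc[0] == expected

    def test_iss_missing_propagates(self):
        assert np.isnan(stage_iss([np.nan], [4.0]).iloc[0])

    @pytest.mark.parametrize(
        "iss, ca, ldh, expected",
        [(1, False, False, 1), (3, True, False, 3), (3, False, False, 2),
         (2, True, True, 2), (1, True, False, 2)],
    )
    def test_r_iss(self, iss, ca, ldh, expected):
        assert stage_r_iss([iss], [ca], [ldh]).iloc[0] == expected

    @pytest.mark.parametrize(
        "iss, d17, t414, g1q, ldh, score, group",
        [
            (1, False, False, False, False, 0.0, "Low"),
            (3, True, False, False, True, 3.5, "High"),
            (2, False, False, True, False, 1.5, "Int-High"),
            (1, False, False, True, False, 0.5, "Low-Int"),
        ],
    )
    def test_r2_iss(self, iss, d17, t414, g1q, ldh, score, group):
        out = stage_r2_iss([iss], [d17], [t414], [g1q], [ldh])
        assert out["r2_iss_score"].iloc[0] == score
        assert out["r2_iss_group"].iloc[0] == group
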