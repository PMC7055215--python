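"""Questionnaire scoring: indifference points, consistency maximisation."""

import numpy as np
import pytest
from scipy.stats import spearmanr
from sklearn.base import clone

from kirbyhorizon.instrument import MCQ27, MAGNITUDE_BINS, DiscountItem
from kirbyhorizon.kirby import (
    K_CEIL,
    K_FLOOR,
    DiscountProfile,
    KirbyScorer,
    hyperbolic_value,
    indifference_k,
    score_bin,
    score_subject,
    score_table,
)
from kirbyhorizon.model import LogisticParams
from kirbyhorizon.simulate import LatentSubject, gen_kirby_responses, simulate_kirby_table

NEUTRAL = LogisticParams(info_bonus=0.0, side_bias=0.0, noise=1.0)


def deterministic_profile(true_k: float, sid: str = "d") -> DiscountProfile:
    """Noiseless responder: today exactly when true k exceeds the item's k."""
    return DiscountProfile(
        sid,
        {
            it.index: "today" if true_k > indifference_k(it) else "later"
            for it in MCQ27
        },
    )


class TestInstrument:
    def test_packaged_ladder_shape_and_ranges(self):
        assert len(MCQ27) == 27
        for b in MAGNITUDE_BINS:
            assert sum(it.magnitude_bin == b for it in MCQ27) == 9
        assert all(11 <= it.immediate_amount <= 80 for it in MCQ27)
        assert all(25 <= it.delayed_amount <= 85 for it in MCQ27)
        assert all(7 <= it.delay <= 186 for it in MCQ27)

    def test_ladder_endpoints_match_floor_and_ceiling(self):
        ks = [indifference_k(it) for it in MCQ27]
        assert min(ks) == K_FLOOR
        assert max(ks) == K_CEIL == 0.25

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(index=1, immediate_amount=30, delayed_amount=20, delay=10,
                 magnitude_bin="small"),
            dict(index=1, immediate_amount=10, delayed_amount=20, delay=0,
                 magnitude_bin="small"),
            dict(index=1, immediate_amount=10, delayed_amount=20, delay=10,
                 magnitude_bin="tiny"),
        ],
    )
    def test_invalid_items_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DiscountItem(**kwargs)


class TestHyperbolicValue:
    @pytest.mark.parametrize(
        "A, D, k, expected, tol",
        [
            # printed discount rates are rounded, hence the loose-but-tiny tols
            (75, 61, 0.00596125, 55.0, 5e-6),
            (35, 13, 0.102564103, 15.0, 5e-7),
            (100, 0, 0.5, 100.0, 0),
            (100, 30, 0.0, 100.0, 0),
        ],
    )
    def test_worked_values(self, A, D, k, expected, tol):
        assert hyperbolic_value(A, D, k) == pytest.approx(expected, abs=tol)

    def test_monotone_decreasing_in_rate_and_delay(self):
        vals_k = [hyperbolic_value(80, 30, k) for k in np.linspace(0, 0.3, 7)]
        vals_d = [hyperbolic_value(80, d, 0.05) for d in np.linspace(0, 180, 7)]
        assert np.all(np.diff(vals_k) < 0)
        assert np.all(np.diff(vals_d) < 0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            hyperbolic_value(-5, 10, 0.1)
        with pytest.raises(ValueError):
            hyperbolic_value(5, -1, 0.1)
        with pytest.raises(ValueError):
            hyperbolic_value(5, 10, -0.1)


class TestIndifferenceK:
    def test_worked_examples_match_printed_digits(self):
        by_idx = {it.index: it for it in MCQ27}
        assert indifference_k(by_idx[2]) == pytest.approx(0.00596125, abs=5e-9)
        assert indifference_k(by_idx[7]) == pytest.approx(0.102564103, abs=5e-10)

    def test_solves_value_equation(self):
        for it in MCQ27:
            k = indifference_k(it)
            assert hyperbolic_value(it.delayed_amount, it.delay, k) == (
                pytest.approx(it.immediate_amount, rel=1e-12)
            )


def _grid_consistency(items, profile, k_grid):
    """Independent oracle: consistency of each grid k by direct counting."""
    ks = np.array([indifference_k(it) for it in items])
    today = np.array([profile.responses[it.index] == "today" for it in items])
    ok = np.where(today[None, :], k_grid[:, None] >= ks[None, :],
                  k_grid[:, None] <= ks[None, :])
    return ok.mean(axis=1)


class TestScoreBin:
    def test_uniform_responders_hit_ladder_endpoints(self):
        all_later = DiscountProfile("p", {it.index: "later" for it in MCQ27})
        all_today = DiscountProfile("q", {it.index: "today" for it in MCQ27})
        k, c = score_bin(MCQ27, all_later)
        assert k == pytest.approx(K_FLOOR, rel=1e-9) and c == 1.0
        k, c = score_bin(MCQ27, all_today)
        assert k == pytest.approx(K_CEIL, rel=1e-9) and c == 1.0

    def test_deterministic_responder_bracketed(self):
        true_k = 0.02
        prof = deterministic_profile(true_k)
        k, c = score_bin(MCQ27, prof)
        ks = sorted(indifference_k(it) for it in MCQ27)
        lo = max(x for x in ks if x < true_k)
        hi = min(x for x in ks if x > true_k)
        assert lo < k < hi
        assert c == 1.0

    def test_assigned_k_attains_grid_maximum(self, rng):
        """The returned candidate is a global consistency maximiser."""
        grid = np.exp(np.linspace(np.log(K_FLOOR), np.log(K_CEIL), 10_000))
        for trial in range(20):
            resp = {
                it.index: ("today" if rng.random() < 0.5 else "later")
                for it in MCQ27
            }
            prof = DiscountProfile(f"r{trial}", resp)
            for items in (MCQ27, [it for it in MCQ27 if it.magnitude_bin == "small"]):
                k, c = score_bin(items, prof)
                assert c >= _grid_consistency(items, prof, grid).max() - 1e-12

    def test_item_order_irrelevant(self, rng):
        prof = deterministic_profile(0.009)
        shuffled = list(MCQ27)
        rng.shuffle(shuffled)
        assert score_bin(MCQ27, prof) == score_bin(shuffled, prof)

    def test_missing_items_named(self):
        resp = {it.index: "later" for it in MCQ27 if it.index not in (3, 19)}
        with pytest.raises(ValueError, match=r"\[3, 19\]"):
            score_bin(MCQ27, DiscountProfile("m", resp))


class TestScoreSubject:
    def test_uniform_profiles(self):
        later = score_subject(
            DiscountProfile("p", {it.index: "later" for it in MCQ27})
        )
        today = score_subject(
            DiscountProfile("q", {it.index: "today" for it in MCQ27})
        )
        assert later.n_today == 0 and today.n_today == 27
        for s, target in ((later, K_FLOOR), (today, K_CEIL)):
            for k in (s.k_overall, s.k_small, s.k_medium, s.k_large):
                assert k == pytest.approx(target, rel=1e-9)

    def test_geomean_identity_and_prop_today(self):
        s = score_subject(deterministic_profile(0.013))
        expected = np.exp(np.mean(np.log([s.k_small, s.k_medium, s.k_large])))
        assert s.k_geomean == pytest.approx(expected, rel=1e-12)
        assert s.prop_today == pytest.approx(s.n_today / 27)

    def test_flipping_to_today_never_lowers_k(self):
        """Monotonicity for perfectly consistent profiles."""
        for true_k in (0.001, 0.0123, 0.07):
            base = score_subject(deterministic_profile(true_k)).k_overall
            prof = deterministic_profile(true_k)
            for it in MCQ27:
                if prof.responses[it.index] == "later":
                    resp = dict(prof.responses)
                    resp[it.index] = "today"
                    flipped = score_subject(DiscountProfile("f", resp))
                    assert flipped.k_overall >= base - 1e-15

    def test_recovery_of_simulated_true_rates(self, rng):
        true_k = np.exp(rng.uniform(np.log(K_FLOOR), np.log(K_CEIL), 120))
        assigned = []
        for i, k in enumerate(true_k):
            s = LatentSubject(f"s{i}", float(k), NEUTRAL, NEUTRAL)
            prof = gen_kirby_responses(s, MCQ27, 0.0, rng)
            assigned.append(score_subject(prof).k_overall)
        rho = spearmanr(true_k, assigned).statistic
        assert rho > 0.95

    def test_partial_profile_modes(self):
        resp = {it.index: "later" for it in MCQ27 if it.index > 5}
        prof = DiscountProfile("p", resp)
        with pytest.raises(ValueError, match="missing responses"):
            score_subject(prof)
        scored = score_subject(prof, allow_partial=True)
        assert not scored.complete and scored.n_answered == 22


class TestKirbyScorer:
    def test_transform_matches_function(self, rng):
        subs = [
            LatentSubject(f"s{i}", k, NEUTRAL, NEUTRAL)
            for i, k in enumerate((0.002, 0.02, 0.2))
        ]
        table = simulate_kirby_table(subs, MCQ27, 0.0, rng)
        est = KirbyScorer().fit()
        out = est.transform(table)
        direct = score_table(table)
        assert out.equals(direct)
        assert est.n_items_ == 27

    def test_sklearn_protocol(self):
        est = KirbyScorer(allow_partial=True)
        assert clone(est).get_params()["allow_partial"] is True
        est.set_params(allow_partial=False)
        assert est.get_params()["allow_partial"] is False
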