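"""Logistic model of the first free choice in the Horizon Task.

The probability of choosing the right-hand arm is a softmax of the decision
variable built from three subject-level parameters per horizon:

    p(right) = 1 / (1 + exp(-(dR + A * dI + b) / sigma))

where dR is the observed forced-trial mean reward difference (right minus
left, points), dI in {-1, 0, +1} flags whether the right arm is the
once-played (more informative) one, A is the information bonus (points added
to the informative arm), b a spatial bias toward the right arm, and sigma > 0
the decision noise (softmax temperature in points). A and sigma are the
model-based counterparts of the model-free p(high info) and p(low mean)
measures.

Fitting is maximum likelihood over first free choices of one horizon, with
bounded multi-start optimisation over (A, b, log sigma).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, log_expit
from scipy.stats import qmc
from sklearn.base import BaseEstimator

from .horizon import HorizonGame

__all__ = [
    "LogisticParams",
    "ChoicePredictors",
    "choice_prob",
    "neg_log_lik",
    "predictors_from_games",
    "fit_subject",
    "fit_table",
    "HorizonChoiceModel",
    "BOUNDS",
    "FIT_COLUMNS",
]

#: Parameter box: info bonus and side bias in points, noise in points.
BOUNDS = {
    "info_bonus": (-80.0, 80.0),
    "side_bias": (-80.0, 80.0),
    "noise": (0.1, 200.0),
}


@dataclass(frozen=True)
class LogisticParams:
    """Subject-by-horizon parameters of the first-free-choice model."""

    info_bonus: float   # points credited to the once-played arm
    side_bias: float    # points credited to the right arm
    noise: float        # softmax temperature, points; > 0
    horizon: int | None = None

    def __post_init__(self) -> None:
        if not self.noise > 0:
            raise ValueError(f"decision noise must be positive, got {self.noise}")
        for name in ("info_bonus", "side_bias", "noise"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class ChoicePredictors:
    """Per-game predictors: reward difference and information flag."""

    dR: float  # observed forced-mean reward, right minus left (points)
    dI: int    # +1 right once-played, -1 left once-played, 0 in [2 2]

    def __post_init__(self) -> None:
        if self.dI not in (-1, 0, 1):
            raise ValueError(f"dI must be -1, 0 or +1, got {self.dI}")


def choice_prob(params: LogisticParams, pred: ChoicePredictors) -> float:
    """Probability that the first free choice is the right-hand arm."""
    z = (pred.dR + params.info_bonus * pred.dI + params.side_bias) / params.noise
    return float(expit(z))


def predictors_from_games(
    games: Sequence[HorizonGame],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(dR, dI, chose_right) arrays over games' first free choices."""
    dR = np.empty(len(games))
    dI = np.zeros(len(games), dtype=int)
    y = np.empty(len(games), dtype=bool)
    for i, g in enumerate(games):
        if not g.free_choices:
            raise ValueError(f"game {g.game_id} has no free choices")
        dR[i] = g.forced_mean("right") - g.forced_mean("left")
        if g.info_condition == "unequal_13":
            dI[i] = 1 if g.high_info_side == "right" else -1
        y[i] = g.free_choices[0][0] == "right"
    return dR, dI, y


def _nll(theta: np.ndarray, dR: np.ndarray, dI: np.ndarray, y: np.ndarray) -> float:
    info_bonus, side_bias, log_noise = theta
    z = (dR + info_bonus * dI + side_bias) / np.exp(log_noise)
    # log p(observed): log_expit(z) for right choices, log_expit(-z) for left
    return float(-np.sum(log_expit(np.where(y, z, -z))))


def neg_log_lik(
    params: LogisticParams, games: Sequence[HorizonGame]
) -> float:
    """Bernoulli negative log-likelihood of observed first free choices."""
    dR, dI, y = predictors_from_games(games)
    return _nll(
        np.array([params.info_bonus, params.side_bias, np.log(params.noise)]),
        dR, dI, y,
    )


@dataclass(frozen=True)
class SubjectFit:
    """Maximum-likelihood parameters plus fit diagnostics."""

    params: LogisticParams
    nll: float
    converged: bool
    n_games: int
    boundary: bool          # any estimate at its bound, or degenerate choices


def _fit_arrays(
    dR: np.ndarray,
    dI: np.ndarray,
    y: np.ndarray,
    *,
    horizon: int | None,
    n_starts: int,
    rng: np.random.Generator,
) -> SubjectFit:
    lo = np.array([BOUNDS["info_bonus"][0], BOUNDS["side_bias"][0],
                   np.log(BOUNDS["noise"][0])])
    hi = np.array([BOUNDS["info_bonus"][1], BOUNDS["side_bias"][1],
                   np.log(BOUNDS["noise"][1])])
    sampler = qmc.LatinHypercube(d=3, seed=rng)
    starts = lo + sampler.random(n_starts) * (hi - lo)
    # anchor one start at a neutral, moderate-noise point
    starts[0] = np.array([0.0, 0.0, np.log(8.0)])
    best = None
    for x0 in starts:
        res = minimize(
            _nll, x0, args=(dR, dI, y), method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
        )
        if best is None:
            best = res
        elif res.fun < best.fun - 1e-9 or (
            abs(res.fun - best.fun) <= 1e-9
            and abs(res.x[0]) < abs(best.x[0])
        ):
            best = res
    theta = best.x
    params = LogisticParams(
        info_bonus=float(theta[0]),
        side_bias=float(theta[1]),
        noise=float(np.exp(theta[2])),
        horizon=horizon,
    )
    at_bound = bool(np.any(np.isclose(theta, lo)) or np.any(np.isclose(theta, hi)))
    degenerate = bool(y.all() or (~y).all())
    return SubjectFit(
        params=params,
        nll=float(best.fun),
        converged=bool(best.success),
        n_games=len(y),
        boundary=at_bound or degenerate,
    )


def fit_subject(
    games: Sequence[HorizonGame],
    horizon: int | None = None,
    *,
    n_starts: int = 10,
    min_games: int = 20,
    random_state: int | np.random.Generator | None = 0,
) -> SubjectFit:
    """Fit the logistic model to one subject's games of one horizon.

    ``games`` may mix horizons only if ``horizon`` is given, in which case
    the other horizon is dropped. Requires at least ``min_games`` first free
    choices; multi-start L-BFGS-B over (info_bonus, side_bias, log noise)
    within :data:`BOUNDS`, likelihood ties resolved toward the smaller
    absolute information bonus.
    """
    games = list(games)
    if horizon is not None:
        games = [g for g in games if g.horizon == horizon]
    else:
        horizons = {g.horizon for g in games}
        if len(horizons) > 1:
            raise ValueError("games span multiple horizons; pass horizon=")
        horizon = horizons.pop() if horizons else None
    if len(games) < min_games:
        raise ValueError(
            f"need >= {min_games} games to fit, got {len(games)}"
        )
    dR, dI, y = predictors_from_games(games)
    rng = np.random.default_rng(random_state)
    return _fit_arrays(
        dR, dI, y, horizon=horizon, n_starts=n_starts, rng=rng
    )


FIT_COLUMNS = [
    "subject_id",
    "horizon",
    "info_bonus",
    "side_bias",
    "noise",
    "nll",
    "n_games",
    "converged",
]


def fit_table(
    games_by_subject: dict[str, list[HorizonGame]],
    *,
    n_starts: int = 10,
    min_games: int = 20,
    random_state: int = 0,
) -> pd.DataFrame:
    """Fit every subject and horizon; one output row per subject-horizon."""
    rows = []
    for sid in sorted(games_by_subject):
        for h in (1, 6):
            fit = fit_subject(
                games_by_subject[sid], h,
                n_starts=n_starts, min_games=min_games,
                random_state=random_state,
            )
            rows.append({
                "subject_id": sid,
                "horizon": h,
                "info_bonus": fit.params.info_bonus,
                "side_bias": fit.params.side_bias,
                "noise": fit.params.noise,
                "nll": fit.nll,
                "n_games": fit.n_games,
                "converged": fit.converged,
            })
    return pd.DataFrame(rows, columns=FIT_COLUMNS)


class HorizonChoiceModel(BaseEstimator):
    """sklearn-style estimator for the first-free-choice logistic model.

    ``X`` is an (n, 2) array of predictors ``[dR, dI]`` (or a list of
    :class:`HorizonGame`, from which predictors and choices are extracted)
    and ``y`` a boolean vector of right-arm choices.

    Attributes (after ``fit``): ``info_bonus_``, ``side_bias_``, ``noise_``,
    ``nll_``, ``converged_``, ``n_obs_``, ``boundary_``.
    """

    def __init__(self, n_starts: int = 10, min_games: int = 20,
                 random_state: int | None = 0):
        self.n_starts = n_starts
        self.min_games = min_games
        self.random_state = random_state

    def _validate(self, X) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n, 2): columns dR, dI")
        if not np.isin(X[:, 1], (-1, 0, 1)).all():
            raise ValueError("dI column must be in {-1, 0, +1}")
        return X[:, 0], X[:, 1].astype(int)

    def fit(self, X, y=None) -> "HorizonChoiceModel":
        if y is None and len(X) and isinstance(X[0], HorizonGame):
            dR, dI, y = predictors_from_games(X)
        else:
            dR, dI = self._validate(X)
            y = np.asarray(y, dtype=bool)
        if len(y) < self.min_games:
            raise ValueError(
                f"need >= {self.min_games} observations, got {len(y)}"
            )
        rng = np.random.default_rng(self.random_state)
        fit = _fit_arrays(
            dR, dI, y, horizon=None, n_starts=self.n_starts, rng=rng
        )
        self.info_bonus_ = fit.params.info_bonus
        self.side_bias_ = fit.params.side_bias
        self.noise_ = fit.params.noise
        self.nll_ = fit.nll
        self.converged_ = fit.converged
        self.n_obs_ = fit.n_games
        self.boundary_ = fit.boundary
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Column-stacked [p(left), p(right)] for each row of X."""
        dR, dI = self._validate(X)
        z = (dR + self.info_bonus_ * dI + self.side_bias_) / self.noise_
        p_right = expit(z)
        return np.column_stack([1.0 - p_right, p_right])

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1] >= 0.5

    def score(self, X, y) -> float:
        """Mean log-likelihood per choice (higher is better)."""
        p = self.predict_proba(X)[:, 1]
        y = np.asarray(y, dtype=bool)
        return float(np.mean(np.log(np.where(y, p, 1.0 - p))))
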