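"""Synthetic cohorts: latent traits, questionnaire responses, task logs.

Subjects carry five latent traits — log discount rate, information bonus at
each horizon, and log decision noise at each horizon — drawn from a
multivariate Gaussian (a Gaussian copula: correlations are imposed on the
latent scale because discount rate and noise are log-normal-like).
Questionnaire responses follow a softmax comparison of the immediate amount
against the hyperbolically discounted delayed amount; Horizon Task games are
two-armed Gaussian bandits (SD 8 points) with four forced trials per game
and free choices sampled from the logistic first-free-choice model (later
free choices in horizon 6 reapply the same rule to the running observed
means; no learning model).

Default trait means and dispersions are calibrated so that a simulated
cohort reproduces the group-level first-free-choice summary statistics and
cross-trait correlations typically reported for this task battery; see
docs/methods.md for the calibration targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .instrument import MCQ27, DiscountItem
from .kirby import K_CEIL, K_FLOOR, DiscountProfile, hyperbolic_value
from .horizon import TRIAL_COLUMNS, HorizonGame, games_from_frame
from .model import LogisticParams

from scipy.special import expit

__all__ = [
    "TRAIT_NAMES",
    "PopulationConfig",
    "LatentSubject",
    "default_trait_corr",
    "gen_population",
    "gen_kirby_responses",
    "gen_horizon_games",
    "simulate_kirby_table",
    "simulate_trial_log",
    "truth_table",
    "simulate_study",
]

#: Order of the latent trait vector.
TRAIT_NAMES = ("log_k", "info_h1", "info_h6", "log_noise_h1", "log_noise_h6")


def default_trait_corr() -> np.ndarray:
    """Default latent correlation matrix.

    Discount rate vs exploration traits follow the reported trait
    correlations (log k with the horizon-1 information bonus +0.35, with the
    horizon-6 bonus -0.01, with log noise +0.22 / +0.27); the within-pair
    correlations (bonus h1-h6 0.487, log noise h1-h6 0.219) are chosen so
    that, at the default trait dispersions, the implied latent correlation
    of log k with the bonus difference is -0.30 and with the log-noise
    difference +0.04.
    """
    c = np.eye(5)
    pairs = {
        (0, 1): 0.35,   # log_k, info_h1
        (0, 2): -0.01,  # log_k, info_h6
        (0, 3): 0.22,   # log_k, log_noise_h1
        (0, 4): 0.27,   # log_k, log_noise_h6
        (1, 2): 0.487,  # info_h1, info_h6
        (3, 4): 0.219,  # log_noise_h1, log_noise_h6
    }
    for (i, j), r in pairs.items():
        c[i, j] = c[j, i] = r
    return c


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given natural-scale moments."""
    if mean <= 0 or sd < 0:
        raise ValueError("log-normal moments need mean > 0, sd >= 0")
    sigma2 = np.log1p((sd / mean) ** 2)
    return float(np.log(mean) - sigma2 / 2.0), float(np.sqrt(sigma2))


@dataclass
class PopulationConfig:
    """Generative settings for a synthetic cohort.

    Amount-scale quantities (information bonus, decision noise, side bias)
    are in reward points; the discount rate k is per day; the questionnaire
    choice noise is in dollars. ``trait_corr`` is the 5x5 latent correlation
    matrix over :data:`TRAIT_NAMES`.
    """

    n_subjects: int = 82
    # discount rate: natural-log normal
    log_k_mean: float = -4.157
    log_k_sd: float = 1.150
    # information bonus: Gaussian per horizon (points)
    info_bonus_mean_h1: float = 1.6
    info_bonus_sd_h1: float = 12.3
    info_bonus_mean_h6: float = 6.3
    info_bonus_sd_h6: float = 16.3
    # decision noise: log-normal per horizon, given as natural-scale moments
    noise_mean_h1: float = 20.0
    noise_sd_h1: float = 20.0
    noise_mean_h6: float = 38.0
    noise_sd_h6: float = 38.0
    side_bias_sd: float = 3.0
    trait_corr: np.ndarray = field(default_factory=default_trait_corr)
    # questionnaire softmax temperature (dollars); 0 = deterministic
    kirby_choice_noise: float = 2.0
    games_per_cell: int = 32
    mean_range: tuple[float, float] = (40.0, 60.0)
    mean_gaps: tuple[float, ...] = (4.0, 8.0, 12.0, 20.0, 30.0)
    reward_sd: float = 8.0
    rt_log_mean: float = np.log(0.8)   # seconds; nuisance only
    rt_log_sd: float = 0.4
    seed: int | None = None

    def validate(self) -> "PopulationConfig":
        if self.n_subjects <= 0 or self.games_per_cell <= 0:
            raise ValueError("counts must be positive")
        c = np.asarray(self.trait_corr, dtype=float)
        if c.shape != (5, 5):
            raise ValueError("trait_corr must be 5x5")
        if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
            raise ValueError("trait_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ValueError("trait_corr must be positive semidefinite")
        for name in ("log_k_sd", "info_bonus_sd_h1", "info_bonus_sd_h6",
                     "noise_sd_h1", "noise_sd_h6", "side_bias_sd",
                     "kirby_choice_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        return self

    def implied_exploration_correlations(self) -> dict[str, float]:
        """Latent correlations of log k with the horizon trait differences.

        directed: corr(log k, info_h6 - info_h1); random: corr(log k,
        log_noise_h6 - log_noise_h1). These are the generative counterparts
        of the directed/random exploration measures.
        """
        c = np.asarray(self.trait_corr, dtype=float)
        _, s1_mu = 0.0, self.info_bonus_sd_h1
        out = {}
        s1, s6 = self.info_bonus_sd_h1, self.info_bonus_sd_h6
        cov = c[0, 2] * s6 - c[0, 1] * s1
        var = s1 ** 2 + s6 ** 2 - 2 * c[1, 2] * s1 * s6
        out["directed"] = float(cov / np.sqrt(var)) if var > 0 else np.nan
        t1 = _lognormal_params(self.noise_mean_h1, self.noise_sd_h1)[1]
        t6 = _lognormal_params(self.noise_mean_h6, self.noise_sd_h6)[1]
        cov = c[0, 4] * t6 - c[0, 3] * t1
        var = t1 ** 2 + t6 ** 2 - 2 * c[3, 4] * t1 * t6
        out["random"] = float(cov / np.sqrt(var)) if var > 0 else np.nan
        out["p_high_info_h1"] = float(c[0, 1])
        return out


@dataclass(frozen=True)
class LatentSubject:
    """One simulated subject's true traits."""

    subject_id: str
    true_k: float
    params_h1: LogisticParams
    params_h6: LogisticParams
    latent: tuple[float, ...] = ()   # raw latent trait vector (TRAIT_NAMES)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_population(
    config: PopulationConfig,
    rng: np.random.Generator | int | None = None,
) -> list[LatentSubject]:
    """Draw a cohort of latent subjects from the trait copula."""
    config.validate()
    rng = _as_rng(config.seed if rng is None else rng)
    n = config.n_subjects
    chol = np.linalg.cholesky(
        np.asarray(config.trait_corr, dtype=float)
        + 1e-12 * np.eye(5)
    )
    z = rng.standard_normal((n, 5)) @ chol.T
    log_k = config.log_k_mean + config.log_k_sd * z[:, 0]
    info1 = config.info_bonus_mean_h1 + config.info_bonus_sd_h1 * z[:, 1]
    info6 = config.info_bonus_mean_h6 + config.info_bonus_sd_h6 * z[:, 2]
    mu1, t1 = _lognormal_params(config.noise_mean_h1, config.noise_sd_h1)
    mu6, t6 = _lognormal_params(config.noise_mean_h6, config.noise_sd_h6)
    noise1 = np.exp(mu1 + t1 * z[:, 3])
    noise6 = np.exp(mu6 + t6 * z[:, 4])
    bias = rng.normal(0.0, config.side_bias_sd, size=n)
    k = np.clip(np.exp(log_k), K_FLOOR, K_CEIL)
    width = len(str(n - 1))
    subjects = []
    for i in range(n):
        sid = f"s{i:0{width}d}"
        subjects.append(
            LatentSubject(
                subject_id=sid,
                true_k=float(k[i]),
                params_h1=LogisticParams(
                    info_bonus=float(info1[i]), side_bias=float(bias[i]),
                    noise=float(noise1[i]), horizon=1,
                ),
                params_h6=LogisticParams(
                    info_bonus=float(info6[i]), side_bias=float(bias[i]),
                    noise=float(noise6[i]), horizon=6,
                ),
                latent=tuple(float(v) for v in z[i]),
            )
        )
    return subjects


# ---------------------------------------------------------------------------
# Questionnaire responses

def gen_kirby_responses(
    subject: LatentSubject,
    instrument: Sequence[DiscountItem] | None = None,
    choice_noise: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> DiscountProfile:
    """Simulate one subject's questionnaire choices.

    p(today) is a softmax of (immediate - discounted delayed value) with
    temperature ``choice_noise`` (dollars); at zero noise the subject
    deterministically takes "today" exactly when its value is higher.
    """
    instrument = MCQ27 if instrument is None else list(instrument)
    rng = _as_rng(rng)
    responses = {}
    for it in instrument:
        dv = it.immediate_amount - hyperbolic_value(
            it.delayed_amount, it.delay, subject.true_k
        )
        if choice_noise == 0:
            # ties (exact indifference) resolve to the immediate offer
            today = dv >= 0
        else:
            today = rng.random() < expit(dv / choice_noise)
        responses[it.index] = "today" if today else "later"
    return DiscountProfile(subject_id=subject.subject_id, responses=responses)


def simulate_kirby_table(
    subjects: Sequence[LatentSubject],
    instrument: Sequence[DiscountItem] | None = None,
    choice_noise: float | None = None,
    rng: np.random.Generator | int | None = None,
    config: PopulationConfig | None = None,
) -> pd.DataFrame:
    """Long response table (subject_id, item_index, choice) for a cohort."""
    if choice_noise is None:
        choice_noise = (config or PopulationConfig()).kirby_choice_noise
    rng = _as_rng(rng)
    frames = []
    for s in subjects:
        prof = gen_kirby_responses(s, instrument, choice_noise, rng)
        idx = sorted(prof.responses)
        frames.append(pd.DataFrame({
            "subject_id": prof.subject_id,
            "item_index": idx,
            "choice": [prof.responses[i] for i in idx],
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Horizon Task games

def _subject_trial_arrays(
    subject: LatentSubject, config: PopulationConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """All trials for one subject, as flat per-trial column arrays."""
    g = config.games_per_cell
    n_games = 4 * g
    horizon = np.repeat([1, 1, 6, 6], g)
    unequal = np.tile([True, False], 2).repeat(g)

    lo, hi = config.mean_range
    base = rng.uniform(lo, hi, n_games)
    gap = rng.choice(config.mean_gaps, n_games) * rng.choice([-1.0, 1.0], n_games)
    other = base + gap
    left_is_base = rng.random(n_games) < 0.5
    mean_left = np.where(left_is_base, base, other)
    mean_right = np.where(left_is_base, other, base)

    # forced sides: rows of {0=left, 1=right}; [1 3] games balanced between
    # once-played-left and once-played-right, order shuffled within game
    sides = np.zeros((n_games, 4), dtype=int)
    once_right = np.zeros(n_games, dtype=bool)
    once_right[unequal] = rng.random(unequal.sum()) < 0.5
    sides[unequal & once_right] = [1, 0, 0, 0]
    sides[unequal & ~once_right] = [0, 1, 1, 1]
    sides[~unequal] = [0, 0, 1, 1]
    sides = rng.permuted(sides, axis=1)

    mean_mat = np.where(sides == 1, mean_right[:, None], mean_left[:, None])
    forced_rewards = rng.normal(mean_mat, config.reward_sd)

    n_right = sides.sum(axis=1)
    sum_right = np.where(sides == 1, forced_rewards, 0.0).sum(axis=1)
    sum_left = forced_rewards.sum(axis=1) - sum_right
    count_r = n_right.astype(float)
    count_l = 4.0 - count_r
    dR = sum_right / count_r - sum_left / count_l
    dI = np.where(unequal, np.where(n_right == 1, 1, -1), 0)

    A = np.where(horizon == 1, subject.params_h1.info_bonus,
                 subject.params_h6.info_bonus)
    noise = np.where(horizon == 1, subject.params_h1.noise,
                     subject.params_h6.noise)
    bias = subject.params_h1.side_bias

    n_free = np.where(horizon == 1, 1, 6)
    max_free = 6
    free_side = np.full((n_games, max_free), -1, dtype=int)
    free_reward = np.full((n_games, max_free), np.nan)
    sum_side = np.stack([sum_left, sum_right], axis=1)
    cnt_side = np.stack([count_l, count_r], axis=1)
    for t in range(max_free):
        active = n_free > t
        obs_dR = sum_side[:, 1] / cnt_side[:, 1] - sum_side[:, 0] / cnt_side[:, 0]
        cur_dI = np.sign(cnt_side[:, 0] - cnt_side[:, 1]).astype(int) if t else dI
        p_right = expit((obs_dR + A * cur_dI + bias) / noise)
        chose_right = rng.random(n_games) < p_right
        mean_chosen = np.where(chose_right, mean_right, mean_left)
        reward = rng.normal(mean_chosen, config.reward_sd)
        idx = chose_right.astype(int)
        rows = np.arange(n_games)
        sum_side[rows, idx] += np.where(active, reward, 0.0)
        cnt_side[rows, idx] += np.where(active, 1.0, 0.0)
        free_side[active, t] = chose_right[active].astype(int)
        free_reward[active, t] = reward[active]

    n_trials = 4 + n_free
    total = int(n_trials.sum())
    rt = np.exp(rng.normal(config.rt_log_mean, config.rt_log_sd, total))

    game_ids = np.array(
        [f"{subject.subject_id}-g{i:03d}" for i in range(n_games)]
    )
    cond = np.where(unequal, "unequal_13", "equal_22")
    side_name = np.array(["left", "right"])

    # flatten game-major: per-game matrices masked to each game's length
    keep = np.arange(10)[None, :] < n_trials[:, None]
    side_mat = np.concatenate([sides, free_side], axis=1)
    reward_mat = np.concatenate([forced_rewards, free_reward], axis=1)
    trial_index = (np.tile(np.arange(1, 11), (n_games, 1)))[keep]
    return {
        "subject_id": np.repeat(subject.subject_id, total),
        "game_id": np.repeat(game_ids, n_trials),
        "horizon": np.repeat(horizon, n_trials),
        "info_condition": np.repeat(cond, n_trials),
        "trial_index": trial_index,
        "forced": (trial_index <= 4).astype(int),
        "side": side_name[side_mat[keep]],
        "reward": reward_mat[keep],
        "rt": rt,
        "mean_left": np.repeat(mean_left, n_trials),
        "mean_right": np.repeat(mean_right, n_trials),
    }


def simulate_trial_log(
    subjects: Sequence[LatentSubject],
    config: PopulationConfig,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Full trial log for a cohort, one row per trial."""
    config.validate()
    rng = _as_rng(config.seed if rng is None else rng)
    chunks = [_subject_trial_arrays(s, config, rng) for s in subjects]
    data = {
        c: np.concatenate([ch[c] for ch in chunks]) for c in TRIAL_COLUMNS
    }
    return pd.DataFrame(data, columns=TRIAL_COLUMNS)


def gen_horizon_games(
    subject: LatentSubject,
    config: PopulationConfig,
    rng: np.random.Generator | int | None = None,
) -> list[HorizonGame]:
    """Game objects for one subject (wrapper over the trial-log generator)."""
    df = simulate_trial_log([subject], config, rng)
    return games_from_frame(df)[subject.subject_id]


def truth_table(subjects: Sequence[LatentSubject]) -> pd.DataFrame:
    """Latent traits as a DataFrame (one row per subject)."""
    rows = []
    for s in subjects:
        rows.append({
            "subject_id": s.subject_id,
            "true_k": s.true_k,
            "info_bonus_h1": s.params_h1.info_bonus,
            "info_bonus_h6": s.params_h6.info_bonus,
            "noise_h1": s.params_h1.noise,
            "noise_h6": s.params_h6.noise,
            "side_bias": s.params_h1.side_bias,
            **{f"latent_{n}": v for n, v in zip(TRAIT_NAMES, s.latent)},
        })
    return pd.DataFrame(rows)


def simulate_study(
    config: PopulationConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a full study: (truth, questionnaire responses, trial log)."""
    rng = _as_rng(config.seed if rng is None else rng)
    subjects = gen_population(config, rng)
    responses = simulate_kirby_table(
        subjects, choice_noise=config.kirby_choice_noise, rng=rng
    )
    trials = simulate_trial_log(subjects, config, rng)
    return truth_table(subjects), responses, trials
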