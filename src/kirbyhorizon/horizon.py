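"""Model-free Horizon Task measures.

Each game of the task is a two-armed Gaussian bandit (reward SD 8 points)
opened by four forced choices that set up one of two information conditions:
unequal ([1 3]: one arm shown once, the other three times) or equal ([2 2]).
Games then allow 1 (horizon 1) or 6 (horizon 6) free choices. All model-free
measures are computed from the first free choice:

- p(high info): probability of picking the once-played arm in [1 3] games —
  uncertainty/information seeking.
- p(low mean): probability of picking the generatively worse arm in [2 2]
  games — behavioural variability.
- accuracy: probability of picking the generatively better arm.

Directed exploration is the horizon-6 minus horizon-1 change in p(high info);
random exploration is the corresponding change in p(low mean).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "HorizonGame",
    "FirstFreeFlags",
    "SubjectMetrics",
    "classify_first_free",
    "subject_metrics",
    "metrics_table",
    "games_from_frame",
    "HorizonMetrics",
    "TRIAL_COLUMNS",
    "METRIC_COLUMNS",
]

SIDES = ("left", "right")
HORIZONS = (1, 6)
CONDITIONS = ("unequal_13", "equal_22")

TRIAL_COLUMNS = [
    "subject_id",
    "game_id",
    "horizon",
    "info_condition",
    "trial_index",
    "forced",
    "side",
    "reward",
    "rt",
    "mean_left",
    "mean_right",
]


@dataclass(frozen=True)
class HorizonGame:
    """One game: generative means, 4 forced trials, then free choices."""

    game_id: str
    horizon: int                      # 1 or 6 free choices
    info_condition: str               # "unequal_13" or "equal_22"
    mean_left: float                  # generative mean, left arm (points)
    mean_right: float
    forced_sides: tuple[str, ...]     # 4 entries in {"left","right"}
    forced_rewards: tuple[float, ...]
    free_choices: tuple[tuple[str, float, float], ...]  # (side, reward, rt)

    def __post_init__(self) -> None:
        if self.horizon not in HORIZONS:
            raise ValueError(f"horizon must be 1 or 6, got {self.horizon}")
        if self.info_condition not in CONDITIONS:
            raise ValueError(f"unknown info condition {self.info_condition!r}")
        if len(self.forced_sides) != 4 or len(self.forced_rewards) != 4:
            raise ValueError("games must have exactly 4 forced trials")
        bad = set(self.forced_sides) - set(SIDES)
        if bad:
            raise ValueError(f"invalid forced sides {bad}")
        n_right = sum(s == "right" for s in self.forced_sides)
        if self.info_condition == "unequal_13" and n_right not in (1, 3):
            raise ValueError(
                f"game {self.game_id}: [1 3] games need forced counts 1/3, "
                f"got {4 - n_right}/{n_right}"
            )
        if self.info_condition == "equal_22" and n_right != 2:
            raise ValueError(
                f"game {self.game_id}: [2 2] games need forced counts 2/2, "
                f"got {4 - n_right}/{n_right}"
            )

    @property
    def high_info_side(self) -> str | None:
        """The once-played (more informative) arm; None in [2 2] games."""
        if self.info_condition != "unequal_13":
            return None
        n_right = sum(s == "right" for s in self.forced_sides)
        return "right" if n_right == 1 else "left"

    def forced_mean(self, side: str) -> float:
        vals = [r for s, r in zip(self.forced_sides, self.forced_rewards) if s == side]
        return float(np.mean(vals))


@dataclass(frozen=True)
class FirstFreeFlags:
    """First-free-choice classification for one game."""

    chose_high_info: bool | None   # defined only in [1 3] games
    chose_low_mean: bool | None    # defined only when generative means differ
    correct: bool | None           # high-generative-mean choice; None on ties
    rt: float


def classify_first_free(game: HorizonGame) -> FirstFreeFlags:
    """Classify a game's first free choice.

    Information status is judged against the forced-trial counts; low-mean
    and correctness against the generative means (games with tied means are
    excluded from those denominators).
    """
    if not game.free_choices:
        raise ValueError(f"game {game.game_id} has no free choices")
    side, _reward, rt = game.free_choices[0]
    if side not in SIDES:
        raise ValueError(f"invalid free-choice side {side!r}")
    chose_high_info = None
    if game.info_condition == "unequal_13":
        chose_high_info = side == game.high_info_side
    chose_low_mean = None
    correct = None
    if game.mean_left != game.mean_right:
        low = "left" if game.mean_left < game.mean_right else "right"
        chosen_low = side == low
        if game.info_condition == "equal_22":
            chose_low_mean = chosen_low
        correct = not chosen_low
    return FirstFreeFlags(
        chose_high_info=chose_high_info,
        chose_low_mean=chose_low_mean,
        correct=correct,
        rt=rt,
    )


@dataclass(frozen=True)
class SubjectMetrics:
    """One subject's ten model-free task quantities plus cell counts."""

    subject_id: str
    p_high_info_h1: float
    p_high_info_h6: float
    p_low_mean_h1: float
    p_low_mean_h6: float
    accuracy_h1: float
    accuracy_h6: float
    rt_h1: float
    rt_h6: float
    directed: float   # p_high_info_h6 - p_high_info_h1
    random: float     # p_low_mean_h6 - p_low_mean_h1
    game_counts: Mapping[tuple[int, str], int]


def _frac(flags: Sequence[bool]) -> float:
    return float(np.mean(flags)) if flags else float("nan")


def subject_metrics(
    games: Iterable[HorizonGame], subject_id: str = ""
) -> SubjectMetrics:
    """Aggregate first-free-choice flags over a subject's games.

    Games without free choices are dropped (with a logged count); empty
    horizon-condition cells leave the affected fields NaN with a warning.
    """
    games = list(games)
    playable = [g for g in games if g.free_choices]
    if len(playable) < len(games):
        logger.warning(
            "subject %s: dropped %d game(s) with no free choices",
            subject_id, len(games) - len(playable),
        )
    counts = {(h, c): 0 for h in HORIZONS for c in CONDITIONS}
    hi: dict[int, list[bool]] = {1: [], 6: []}
    lo: dict[int, list[bool]] = {1: [], 6: []}
    acc: dict[int, list[bool]] = {1: [], 6: []}
    rts: dict[int, list[float]] = {1: [], 6: []}
    for g in playable:
        counts[(g.horizon, g.info_condition)] += 1
        flags = classify_first_free(g)
        if flags.chose_high_info is not None:
            hi[g.horizon].append(flags.chose_high_info)
        if flags.chose_low_mean is not None:
            lo[g.horizon].append(flags.chose_low_mean)
        if flags.correct is not None:
            acc[g.horizon].append(flags.correct)
        rts[g.horizon].append(flags.rt)
    for (h, c), n in counts.items():
        if n == 0:
            logger.warning(
                "subject %s: no games in horizon %d, %s; affected metrics NaN",
                subject_id, h, c,
            )
    p_hi = {h: _frac(hi[h]) for h in HORIZONS}
    p_lo = {h: _frac(lo[h]) for h in HORIZONS}
    return SubjectMetrics(
        subject_id=subject_id,
        p_high_info_h1=p_hi[1],
        p_high_info_h6=p_hi[6],
        p_low_mean_h1=p_lo[1],
        p_low_mean_h6=p_lo[6],
        accuracy_h1=_frac(acc[1]),
        accuracy_h6=_frac(acc[6]),
        rt_h1=float(np.mean(rts[1])) if rts[1] else float("nan"),
        rt_h6=float(np.mean(rts[6])) if rts[6] else float("nan"),
        directed=p_hi[6] - p_hi[1],
        random=p_lo[6] - p_lo[1],
        game_counts=counts,
    )


# ---------------------------------------------------------------------------
# Trial-log (long table) interface

def _require_columns(df: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"trial log missing columns: {sorted(missing)}")


def games_from_frame(trials: pd.DataFrame) -> dict[str, list[HorizonGame]]:
    """Reconstruct per-subject game objects from a long trial log."""
    _require_columns(trials, TRIAL_COLUMNS)
    out: dict[str, list[HorizonGame]] = {}
    for (sid, gid), grp in trials.groupby(["subject_id", "game_id"], sort=True):
        grp = grp.sort_values("trial_index")
        forced = grp[grp["forced"] == 1]
        free = grp[grp["forced"] == 0]
        game = HorizonGame(
            game_id=str(gid),
            horizon=int(grp["horizon"].iloc[0]),
            info_condition=str(grp["info_condition"].iloc[0]),
            mean_left=float(grp["mean_left"].iloc[0]),
            mean_right=float(grp["mean_right"].iloc[0]),
            forced_sides=tuple(forced["side"]),
            forced_rewards=tuple(float(r) for r in forced["reward"]),
            free_choices=tuple(
                (str(s), float(r), float(t))
                for s, r, t in zip(free["side"], free["reward"], free["rt"])
            ),
        )
        out.setdefault(str(sid), []).append(game)
    return out


METRIC_COLUMNS = [
    "subject_id",
    "p_high_info_h1",
    "p_high_info_h6",
    "p_low_mean_h1",
    "p_low_mean_h6",
    "accuracy_h1",
    "accuracy_h6",
    "rt_h1",
    "rt_h6",
    "directed",
    "random",
    "n_games",
]


def metrics_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject model-free measures from a long trial log (vectorised).

    Equivalent to :func:`subject_metrics` applied per subject; implemented
    on the flat table so cohorts of millions of trials stay fast.
    """
    _require_columns(trials, TRIAL_COLUMNS)
    forced = trials[trials["forced"] == 1]
    n_right = (
        (forced["side"] == "right")
        .groupby([forced["subject_id"], forced["game_id"]])
        .sum()
        .rename("n_forced_right")
    )
    free = trials[trials["forced"] == 0].sort_values("trial_index")
    first = free.groupby(["subject_id", "game_id"], as_index=False).first()
    first = first.join(
        n_right, on=["subject_id", "game_id"]
    )
    unequal = first["info_condition"] == "unequal_13"
    high_side = np.where(first["n_forced_right"] == 1, "right", "left")
    first["chose_high_info"] = np.where(
        unequal, first["side"] == high_side, np.nan
    )
    ties = first["mean_left"] == first["mean_right"]
    low_side = np.where(first["mean_left"] < first["mean_right"], "left", "right")
    chose_low = first["side"] == low_side
    first["chose_low_mean"] = np.where(
        (~ties) & (first["info_condition"] == "equal_22"), chose_low, np.nan
    )
    first["correct"] = np.where(~ties, ~chose_low, np.nan)

    rows = []
    for sid, grp in first.groupby("subject_id", sort=True):
        by_h = {h: grp[grp["horizon"] == h] for h in HORIZONS}
        vals = {"subject_id": sid}
        for h in HORIZONS:
            g = by_h[h]
            vals[f"p_high_info_h{h}"] = g["chose_high_info"].mean()
            vals[f"p_low_mean_h{h}"] = g["chose_low_mean"].mean()
            vals[f"accuracy_h{h}"] = g["correct"].mean()
            vals[f"rt_h{h}"] = g["rt"].mean()
        vals["directed"] = vals["p_high_info_h6"] - vals["p_high_info_h1"]
        vals["random"] = vals["p_low_mean_h6"] - vals["p_low_mean_h1"]
        vals["n_games"] = len(grp)
        rows.append(vals)
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


class HorizonMetrics(BaseEstimator, TransformerMixin):
    """Transformer mapping trial logs to per-subject model-free measures."""

    def fit(self, X: pd.DataFrame | None = None, y=None) -> "HorizonMetrics":
        self.n_features_in_ = len(TRIAL_COLUMNS)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return metrics_table(X)
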