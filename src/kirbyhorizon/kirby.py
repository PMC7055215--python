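"""Scoring of the 27-item delay-discounting questionnaire.

A subject's choices between immediate and delayed rewards are summarised by
hyperbolic discount rates. Each item defines an indifference rate k at which
the immediate amount equals the hyperbolically discounted delayed amount,
V = A / (1 + k D). A respondent with discount rate k should take the
immediate ("today") offer exactly when their k exceeds the item's
indifference rate, so the pattern of today/later switches brackets the
subject's k. The assigned k for a set of items is the candidate that is
consistent with the largest fraction of observed choices, candidates being
the geometric means of adjacent item indifference rates plus the ladder
endpoints.

Six measures result per subject: overall k (all 27 items), small/medium/
large-bin ks (9 items each), their geometric mean, and the count of "today"
choices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .instrument import MCQ27, MAGNITUDE_BINS, DiscountItem

__all__ = [
    "K_FLOOR",
    "K_CEIL",
    "CHOICES",
    "DiscountProfile",
    "KirbyScores",
    "hyperbolic_value",
    "indifference_k",
    "score_bin",
    "score_subject",
    "score_table",
    "KirbyScorer",
]

CHOICES = ("today", "later")

#: Assignable discount-rate range: the exact endpoints of the packaged
#: instrument's indifference-rate ladder, ((35/34)-1)/186 and ((55/20)-1)/7.
#: Conventionally printed rounded as 0.00016 and 0.25 per day.
K_FLOOR = (35.0 / 34.0 - 1.0) / 186.0
K_CEIL = (55.0 / 20.0 - 1.0) / 7.0


@dataclass(frozen=True)
class DiscountProfile:
    """One subject's questionnaire responses (item index -> choice)."""

    subject_id: str
    responses: Mapping[int, str]

    def __post_init__(self) -> None:
        bad = {i: c for i, c in self.responses.items() if c not in CHOICES}
        if bad:
            raise ValueError(f"invalid choices (must be in {CHOICES}): {bad}")


@dataclass(frozen=True)
class KirbyScores:
    """The six discounting measures (rates in 1/day) plus consistencies."""

    subject_id: str
    k_overall: float
    k_small: float
    k_medium: float
    k_large: float
    k_geomean: float
    n_today: int
    prop_today: float
    consistency_overall: float
    consistency_small: float
    consistency_medium: float
    consistency_large: float
    complete: bool = True
    n_answered: int = 27


def hyperbolic_value(A: float, D: float, k: float) -> float:
    """Present value of amount ``A`` delayed ``D`` days at discount rate ``k``.

    V = A / (1 + k D); equals A when D = 0 or k = 0.
    """
    if A <= 0:
        raise ValueError(f"amount must be positive, got {A}")
    if D < 0 or k < 0:
        raise ValueError(f"delay and rate must be nonnegative, got D={D}, k={k}")
    return A / (1.0 + k * D)


def indifference_k(item: DiscountItem) -> float:
    """Discount rate at which the item's two offers have equal value.

    Solves immediate = delayed / (1 + k * delay), i.e.
    k = (delayed/immediate - 1) / delay.
    """
    return (item.delayed_amount / item.immediate_amount - 1.0) / item.delay


def _check_answered(
    items: Sequence[DiscountItem], responses: Mapping[int, str]
) -> list[int]:
    return sorted(it.index for it in items if it.index not in responses)


def _consistency_counts(
    candidates: np.ndarray, item_ks: np.ndarray, today: np.ndarray
) -> np.ndarray:
    """Consistent-item counts for each candidate k.

    A "today" response is consistent with candidate c when c >= item k, a
    "later" response when c <= item k; at exact equality either response
    counts as consistent.
    """
    c = candidates[:, None]
    k = item_ks[None, :]
    ok = np.where(today[None, :], c >= k, c <= k)
    return ok.sum(axis=1)


def score_bin(
    items: Sequence[DiscountItem],
    profile: DiscountProfile,
    *,
    allow_partial: bool = False,
) -> tuple[float, float]:
    """Assign a discount rate to one item set by maximum consistency.

    Candidates are K_FLOOR, K_CEIL and the geometric means of adjacent
    distinct item indifference rates; ties between equally consistent
    candidates are resolved by their geometric mean. Returns
    ``(k, consistency)`` where consistency is the maximised fraction of
    choices matched.
    """
    missing = _check_answered(items, profile.responses)
    if missing:
        if not allow_partial:
            raise ValueError(
                f"subject {profile.subject_id}: missing responses for items {missing}"
            )
        items = [it for it in items if it.index in profile.responses]
        if not items:
            return math.nan, math.nan
    item_ks = np.array([indifference_k(it) for it in items])
    today = np.array(
        [profile.responses[it.index] == "today" for it in items], dtype=bool
    )
    uniq = np.unique(item_ks)
    candidates = np.concatenate(
        [[K_FLOOR], np.sqrt(uniq[:-1] * uniq[1:]), [K_CEIL]]
    )
    counts = _consistency_counts(candidates, item_ks, today)
    best = counts.max()
    winners = candidates[counts == best]
    k = float(np.exp(np.mean(np.log(winners))))
    return k, float(best) / len(items)


def score_subject(
    profile: DiscountProfile,
    instrument: Sequence[DiscountItem] | None = None,
    *,
    allow_partial: bool = False,
) -> KirbyScores:
    """Score one subject into the six discounting measures."""
    instrument = MCQ27 if instrument is None else list(instrument)
    missing = _check_answered(instrument, profile.responses)
    if missing and not allow_partial:
        raise ValueError(
            f"subject {profile.subject_id}: missing responses for items {missing}"
        )
    per_bin: dict[str, tuple[float, float]] = {}
    for b in MAGNITUDE_BINS:
        bin_items = [it for it in instrument if it.magnitude_bin == b]
        per_bin[b] = score_bin(bin_items, profile, allow_partial=allow_partial)
    k_overall, cons_overall = score_bin(
        instrument, profile, allow_partial=allow_partial
    )
    bin_ks = [per_bin[b][0] for b in MAGNITUDE_BINS]
    k_geomean = float(np.exp(np.mean(np.log(bin_ks))))
    answered = [it for it in instrument if it.index in profile.responses]
    n_today = sum(profile.responses[it.index] == "today" for it in answered)
    return KirbyScores(
        subject_id=profile.subject_id,
        k_overall=k_overall,
        k_small=per_bin["small"][0],
        k_medium=per_bin["medium"][0],
        k_large=per_bin["large"][0],
        k_geomean=k_geomean,
        n_today=int(n_today),
        prop_today=n_today / len(instrument),
        consistency_overall=cons_overall,
        consistency_small=per_bin["small"][1],
        consistency_medium=per_bin["medium"][1],
        consistency_large=per_bin["large"][1],
        complete=not missing,
        n_answered=len(answered),
    )


SCORE_COLUMNS = [
    "subject_id",
    "k_overall",
    "k_small",
    "k_medium",
    "k_large",
    "k_geomean",
    "n_today",
    "prop_today",
    "consistency_overall",
    "consistency_small",
    "consistency_medium",
    "consistency_large",
    "complete",
    "n_answered",
]


def profiles_from_frame(responses: pd.DataFrame) -> list[DiscountProfile]:
    """Build profiles from a long table (subject_id, item_index, choice)."""
    needed = {"subject_id", "item_index", "choice"}
    missing = needed - set(responses.columns)
    if missing:
        raise ValueError(f"responses table missing columns: {sorted(missing)}")
    profiles = []
    for sid, grp in responses.groupby("subject_id", sort=True):
        profiles.append(
            DiscountProfile(
                subject_id=str(sid),
                responses={
                    int(i): str(c)
                    for i, c in zip(grp["item_index"], grp["choice"])
                },
            )
        )
    return profiles


def score_table(
    responses: pd.DataFrame,
    instrument: Sequence[DiscountItem] | None = None,
    *,
    allow_partial: bool = False,
) -> pd.DataFrame:
    """Score a long response table into one row of measures per subject."""
    rows = [
        score_subject(p, instrument, allow_partial=allow_partial).__dict__
        for p in profiles_from_frame(responses)
    ]
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


class KirbyScorer(BaseEstimator, TransformerMixin):
    """Transformer mapping long response tables to per-subject measures.

    Parameters
    ----------
    instrument : sequence of DiscountItem, optional
        Item table; the packaged 27-item ladder when omitted.
    allow_partial : bool, default False
        Score incomplete profiles on answered items only (flagged in the
        output) instead of raising.
    """

    def __init__(self, instrument=None, allow_partial: bool = False):
        self.instrument = instrument
        self.allow_partial = allow_partial

    def fit(self, X: pd.DataFrame | None = None, y=None) -> "KirbyScorer":
        items = MCQ27 if self.instrument is None else list(self.instrument)
        for b in MAGNITUDE_BINS:
            n = sum(it.magnitude_bin == b for it in items)
            if n == 0:
                raise ValueError(f"instrument has no items in bin {b!r}")
        self.instrument_ = items
        self.n_items_ = len(items)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "instrument_"):
            self.fit()
        return score_table(
            X, self.instrument_, allow_partial=self.allow_partial
        )
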