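"""The 27-item monetary choice questionnaire instrument.

Each item offers a smaller immediate reward against a larger delayed one.
Items fall into three 9-item magnitude bins (small/medium/large) defined by
the delayed amount ($25-35, $50-60, $75-85). The packaged item table is the
canonical ladder for this instrument; a different table can be loaded from
CSV with :func:`load_instrument`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

MAGNITUDE_BINS = ("small", "medium", "large")

#: Columns of an instrument CSV.
INSTRUMENT_COLUMNS = ["index", "immediate", "delayed", "delay_days", "bin"]


@dataclass(frozen=True)
class DiscountItem:
    """One questionnaire item: immediate vs delayed monetary offer."""

    index: int
    immediate_amount: float  # dollars, paid today
    delayed_amount: float    # dollars, paid after the delay
    delay: float             # days
    magnitude_bin: str

    def __post_init__(self) -> None:
        if not self.delayed_amount > self.immediate_amount > 0:
            raise ValueError(
                f"item {self.index}: need delayed > immediate > 0, got "
                f"immediate={self.immediate_amount}, delayed={self.delayed_amount}"
            )
        if self.delay <= 0:
            raise ValueError(f"item {self.index}: delay must be positive")
        if self.magnitude_bin not in MAGNITUDE_BINS:
            raise ValueError(
                f"item {self.index}: bin must be one of {MAGNITUDE_BINS}, "
                f"got {self.magnitude_bin!r}"
            )


def _items_from_frame(df: pd.DataFrame) -> list[DiscountItem]:
    missing = set(INSTRUMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"instrument table missing columns: {sorted(missing)}")
    items = [
        DiscountItem(
            index=int(r["index"]),
            immediate_amount=float(r["immediate"]),
            delayed_amount=float(r["delayed"]),
            delay=float(r["delay_days"]),
            magnitude_bin=str(r["bin"]),
        )
        for _, r in df.iterrows()
    ]
    return sorted(items, key=lambda it: it.index)


def load_instrument(path: str | Path | None = None) -> list[DiscountItem]:
    """Load an instrument table; the packaged 27-item ladder by default."""
    if path is None:
        source = resources.files("kirbyhorizon.data") / "mcq27.csv"
        with resources.as_file(source) as p:
            df = pd.read_csv(p, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    return _items_from_frame(df)


def instrument_frame(items: Iterable[DiscountItem]) -> pd.DataFrame:
    """Instrument as a DataFrame with the canonical CSV columns."""
    return pd.DataFrame(
        [
            {
                "index": it.index,
                "immediate": it.immediate_amount,
                "delayed": it.delayed_amount,
                "delay_days": it.delay,
                "bin": it.magnitude_bin,
            }
            for it in items
        ],
        columns=INSTRUMENT_COLUMNS,
    )


#: The packaged 27-item instrument, loaded once at import.
MCQ27: list[DiscountItem] = load_instrument()
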