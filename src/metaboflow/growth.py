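"""Growth-performance metrics for the feeding trial.

Specific growth rate (SGR) uses the standard aquaculture definition,
100 * (ln w_final - ln w_initial) / days, in percent body weight per day.
Feed efficiency (FE) is wet-weight gain divided by dry feed given (uneaten
feed is not quantified). The ration schedule models biweekly feeding at a
fixed fraction of group biomass (default 3 % per day), re-adjusted at each
14-day weighing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

GROWTH_COLUMNS = ["fish_id", "group", "day", "weight_g", "length_cm"]


def sgr(w_initial: float, w_final: float, days: float) -> float:
    """Specific growth rate in percent per day."""
    if w_initial <= 0 or w_final <= 0:
        raise ValueError("weights must be positive")
    if days <= 0:
        raise ValueError("days must be positive")
    return 100.0 * (math.log(w_final) - math.log(w_initial)) / days


def feed_efficiency(weight_gain: float, feed_given: float) -> float:
    """Wet-weight gain divided by feed given."""
    if feed_given <= 0:
        raise ValueError("feed_given must be positive")
    return weight_gain / feed_given


@dataclass(frozen=True)
class RationPeriod:
    start_day: int
    end_day: int
    daily_feed: float

    @property
    def total(self) -> float:
        return self.daily_feed * (self.end_day - self.start_day)


def validate_series(series: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GROWTH_COLUMNS if c not in series.columns]
    if missing:
        raise ValueError(f"growth series lacks columns {missing}")
    if (series["weight_g"] <= 0).any() or (series["length_cm"] <= 0).any():
        raise ValueError("weights and lengths must be positive")
    for fish, sub in series.groupby("fish_id"):
        days = sub["day"].to_numpy()
        if days[0] != 0 or (np.diff(days) <= 0).any():
            raise ValueError(
                f"fish {fish!r}: days must strictly increase from 0"
            )
    return series


def ration_schedule(
    series: pd.DataFrame, rate: float = 0.03, interval: int = 14
) -> list[RationPeriod]:
    """Biweekly ration periods for one group's series.

    For each ``interval``-day period the daily feed is ``rate`` x group
    biomass at the period's first observation. Every period start must have
    an observation for every fish.
    """
    validate_series(series)
    days = sorted(series["day"].unique())
    last = max(days)
    periods = []
    n_fish = series["fish_id"].nunique()
    for start in range(0, last, interval):
        at_start = series[series["day"] == start]
        if len(at_start) != n_fish:
            raise ValueError(f"missing observation at period start day {start}")
        biomass = at_start["weight_g"].sum()
        periods.append(RationPeriod(start, min(start + interval, last),
                                    rate * biomass))
    return periods


def total_feed(periods: list[RationPeriod]) -> float:
    return sum(p.total for p in periods)


def group_summary(series: pd.DataFrame, rate: float = 0.03) -> pd.DataFrame:
    """Per-group growth performance table.

    Columns: n fish, mean initial/final weight and length, per-fish SGR
    mean +/- sd, group feed efficiency (total gain over total ration feed).
    """
    validate_series(series)
    rows = []
    for group, sub in series.groupby("group"):
        first_day, last_day = sub["day"].min(), sub["day"].max()
        w0 = sub.loc[sub["day"] == first_day].set_index("fish_id")["weight_g"]
        w1 = sub.loc[sub["day"] == last_day].set_index("fish_id")["weight_g"]
        l0 = sub.loc[sub["day"] == first_day].set_index("fish_id")["length_cm"]
        l1 = sub.loc[sub["day"] == last_day].set_index("fish_id")["length_cm"]
        per_fish_sgr = [
            sgr(w0[f], w1[f], last_day - first_day) for f in w0.index
        ]
        feed = total_feed(ration_schedule(sub, rate=rate))
        gain = float(w1.sum() - w0.sum())
        rows.append(
            {
                "group": group,
                "n": len(w0),
                "initial_weight_g": float(w0.mean()),
                "final_weight_g": float(w1.mean()),
                "initial_length_cm": float(l0.mean()),
                "final_length_cm": float(l1.mean()),
                "sgr_mean": float(np.mean(per_fish_sgr)),
                "sgr_sd": float(np.std(per_fish_sgr, ddof=1)),
                "weight_gain_g": gain,
                "feed_given_g": feed,
                "feed_efficiency": feed_efficiency(gain, feed),
            }
        )
    return pd.DataFrame(rows).set_index("group")
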