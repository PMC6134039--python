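"""Per-metabolite group comparison: Pro/Con ratios, Welch tests, data-derived
thresholds, composite UP/SAME/DOWN classification, and the whole-metabolome
distribution-shift test.

The Pro/Con ratio of a metabolite is the mean normalized abundance in the
probiotic-fed group divided by that in the control group; ND cells are
excluded from the means. A metabolite detected only in the probiotic group
has no finite ratio and carries the ``pro_only`` state (the "1<" notation of
the study tables); the symmetric case is ``con_only``; metabolites
undetected in both groups are ``both_nd`` and excluded from classification.

Classification is a composite of significance and fold change: a metabolite
is UP when it is significantly higher (Welch p < 0.05) with ratio at or
above the upper threshold, or at least 1.5-fold higher with p < 0.1, or
detected only in the probiotic group; DOWN is the mirrored rule. The upper
and lower thresholds default to 1.20 and 0.8 but are normally re-derived
from the data as the extreme ratios among the significantly changed
metabolites (e.g. a maximum significant ratio of 1.202 yields the 1.20
threshold, a minimum of 0.830 yields 0.8).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

# classification labels
UP, SAME, DOWN, UNDETECTED = "UP", "SAME", "DOWN", "UNDETECTED"

# ratio states
FINITE, PRO_ONLY, CON_ONLY, BOTH_ND = "finite", "pro_only", "con_only", "both_nd"


@dataclass(frozen=True)
class RatioValue:
    state: str
    value: float | None = None

    def __post_init__(self):
        if self.state not in (FINITE, PRO_ONLY, CON_ONLY, BOTH_ND):
            raise ValueError(f"unknown ratio state {self.state!r}")
        if (self.state == FINITE) != (self.value is not None):
            raise ValueError("value must be present iff state is finite")
        if self.value is not None and self.value <= 0:
            raise ValueError("finite ratio must be positive")


@dataclass(frozen=True)
class Thresholds:
    """Fold-change and significance cut-offs for the composite rule.

    With the default cut-offs ``fold_loose >= upper`` (1.5 vs 1.20), so the
    loose clause relaxes only the p-value. Data-derived uppers can exceed
    ``fold_loose``; the loose 1.5-fold clause then dominates the strict one
    over the intermediate ratio range, which is intended.
    """

    upper: float = 1.20
    lower: float = 0.8
    p_strict: float = 0.05
    p_loose: float = 0.1
    fold_loose: float = 1.5

    def __post_init__(self):
        if not (self.lower < 1 < self.upper):
            raise ValueError("need lower < 1 < upper")
        if not self.p_strict < self.p_loose:
            raise ValueError("need p_strict < p_loose")


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if (arr < 0).any():
        raise ValueError("negative abundance values")
    return arr


def pro_con_ratio(pro, con) -> RatioValue:
    """Ratio of group means, with ND-aware degenerate states.

    ``pro``/``con`` are replicate vectors of normalized areas with NaN for
    ND. Returns a finite ratio mean(pro)/mean(con) when both groups have at
    least one detected replicate and positive means; ``pro_only`` when the
    control group is entirely ND but the probiotic group is detected;
    ``con_only`` symmetrically; ``both_nd`` when every cell is ND.
    """
    p, c = _clean(pro), _clean(con)
    if p.size == 0 and c.size == 0:
        return RatioValue(BOTH_ND)
    if c.size == 0:
        return RatioValue(PRO_ONLY)
    if p.size == 0:
        return RatioValue(CON_ONLY)
    mp, mc = p.mean(), c.mean()
    if mc == 0:
        return RatioValue(PRO_ONLY) if mp > 0 else RatioValue(BOTH_ND)
    if mp == 0:
        return RatioValue(CON_ONLY)
    return RatioValue(FINITE, mp / mc)


def welch_test(pro, con) -> float | None:
    """Two-sided Welch (unequal-variance) t-test p-value.

    Returns None when either group has fewer than two detected replicates
    (the test is undefined, not "not significant"). Zero pooled variance is
    handled by the limit convention: p = 1 for equal means, p = 0 otherwise.
    """
    p, c = _clean(pro), _clean(con)
    if p.size < 2 or c.size < 2:
        return None
    # zero variance up to float rounding (reachable with cv = 0 fixtures)
    scale = max(abs(p.mean()), abs(c.mean()), 1e-300)
    tol = (1e-9 * scale) ** 2
    if p.var(ddof=1) <= tol and c.var(ddof=1) <= tol:
        return 1.0 if abs(p.mean() - c.mean()) <= 1e-9 * scale else 0.0
    return float(stats.ttest_ind(p, c, equal_var=False).pvalue)


def _floor(x: float, decimals: int) -> float:
    scale = 10 ** decimals
    return math.floor(x * scale + 1e-9) / scale


def derive_thresholds(
    results: pd.DataFrame,
    p_strict: float = 0.05,
    upper_decimals: int = 2,
    lower_decimals: int = 1,
) -> Thresholds:
    """Derive fold-change cut-offs from the significant extremes.

    Provisional significance is p < ``p_strict`` with the ratio giving the
    direction. The upper threshold is the maximum finite ratio among
    significantly higher metabolites, rounded down to ``upper_decimals``;
    the lower threshold is the minimum finite ratio among significantly
    lower metabolites, rounded down to ``lower_decimals`` (the asymmetric
    printing 1.202 -> 1.20, 0.830 -> 0.8). A side with no significant
    members falls back to the 1.20 / 0.8 defaults.
    """
    finite = results[(results["ratio_state"] == FINITE) & results["p"].notna()]
    sig = finite[finite["p"] < p_strict]
    up_side = sig.loc[sig["ratio"] > 1, "ratio"]
    down_side = sig.loc[sig["ratio"] < 1, "ratio"]
    upper = _floor(up_side.max(), upper_decimals) if len(up_side) else 1.20
    lower = _floor(down_side.min(), lower_decimals) if len(down_side) else 0.8
    # floor rounding can collapse a near-unity extreme onto 1; fall back
    if upper <= 1:
        upper = 1.20
    if lower >= 1:
        lower = 0.8
    return Thresholds(upper=upper, lower=lower, p_strict=p_strict)


def classify(ratio: RatioValue, p: float | None,
             thresholds: Thresholds = Thresholds()) -> str:
    """Composite UP/SAME/DOWN call for one metabolite."""
    t = thresholds
    if ratio.state == BOTH_ND:
        return UNDETECTED
    if ratio.state == PRO_ONLY:
        return UP
    if ratio.state == CON_ONLY:
        return DOWN
    r = ratio.value
    if p is not None:
        if (p < t.p_strict and r >= t.upper) or (r >= t.fold_loose and p < t.p_loose):
            return UP
        if (p < t.p_strict and r < t.lower) or (r <= 1 / t.fold_loose and p < t.p_loose):
            return DOWN
    return SAME


# ---------------------------------------------------------------------------
# Table-level drivers
# ---------------------------------------------------------------------------

def differential_table(bundle, compartment: str) -> pd.DataFrame:
    """Ratio + Welch p for every metabolite of one compartment.

    ``bundle`` must already be normalized. Returns a frame indexed by
    canonical metabolite id with columns ``metabolite``, ``mode``,
    ``compartment``, ``ratio_state``, ``ratio``, ``p``.
    """
    frame = bundle.compartment_frame(compartment)
    pro_cols = [c for c in frame.columns[2:] if "_probiotic_" in c]
    con_cols = [c for c in frame.columns[2:] if "_control_" in c]
    records = []
    for key, row in frame.iterrows():
        ratio = pro_con_ratio(row[pro_cols], row[con_cols])
        p = welch_test(row[pro_cols], row[con_cols])
        records.append(
            {
                "metabolite": row["metabolite"],
                "mode": row["mode"],
                "compartment": compartment,
                "ratio_state": ratio.state,
                "ratio": ratio.value if ratio.state == FINITE else np.nan,
                "p": np.nan if p is None else p,
            }
        )
    return pd.DataFrame(records, index=frame.index.copy())


def classify_table(
    diff: pd.DataFrame,
    thresholds: Thresholds | None = None,
    fdr: bool = False,
) -> tuple[pd.DataFrame, Thresholds]:
    """Attach class labels to a differential table.

    With ``thresholds=None`` the cut-offs are derived from the table itself.
    ``fdr=True`` applies Benjamini-Hochberg to the p-values before
    classification (off by default; the study design reports raw p-values).
    """
    out = diff.copy()
    if fdr:
        mask = out["p"].notna()
        out.loc[mask, "p"] = stats.false_discovery_control(
            out.loc[mask, "p"].to_numpy(), method="bh"
        )
    if thresholds is None:
        thresholds = derive_thresholds(out)
    labels = []
    for _, row in out.iterrows():
        if row["ratio_state"] == FINITE:
            ratio = RatioValue(FINITE, row["ratio"])
        else:
            ratio = RatioValue(row["ratio_state"])
        p = None if pd.isna(row["p"]) else float(row["p"])
        labels.append(classify(ratio, p, thresholds))
    out["class"] = labels
    return out, thresholds


def class_counts(diff: pd.DataFrame) -> dict[str, int]:
    counts = diff["class"].value_counts().to_dict()
    return {label: int(counts.get(label, 0)) for label in (UP, SAME, DOWN, UNDETECTED)}


# ---------------------------------------------------------------------------
# Whole-metabolome distribution shift
# ---------------------------------------------------------------------------

def distribution_shift_test(
    con_levels, pro_levels, alternative: str = "two_sided"
) -> float:
    """Wilcoxon-Mann-Whitney test on paired metabolite level panels.

    Compares the distribution of per-metabolite levels (typically group
    means) between the control and probiotic panels. ``alternative`` is
    ``two_sided`` or ``con_less`` (H1: control levels stochastically smaller
    than probiotic levels, the right-skew direction). Uses exact enumeration
    for combined n <= 12 without ties, the tie-corrected normal
    approximation otherwise.
    """
    con = np.asarray(con_levels, dtype=float)
    pro = np.asarray(pro_levels, dtype=float)
    if con.size == 0 or pro.size == 0:
        raise ValueError("empty input panel")
    alt = {"two_sided": "two-sided", "con_less": "less"}[alternative]
    pooled = np.concatenate([con, pro])
    exact = con.size + pro.size <= 12 and np.unique(pooled).size == pooled.size
    method = "exact" if exact else "asymptotic"
    return float(stats.mannwhitneyu(con, pro, alternative=alt, method=method).pvalue)
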