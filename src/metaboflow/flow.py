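"""Set-theoretic classification of metabolites across feed pellet, intestine
and serum: pellet/intestine groups a-e, intestine/serum transport categories
i-iii, and the three-compartment Venn bookkeeping.

Groups (joint pellet x intestinal-class):

* a - intestinal UP, not detected in the pellet (likely produced by the
  host or intestinal microbiota);
* b - intestinal UP, detected in the pellet (feed-derived, uplifted);
* c - intestinal SAME, not in the pellet;
* d - intestinal SAME, in the pellet;
* e - compounds detected only in the pellet.

Intestinal DOWN metabolites fall outside this enumeration and are emitted in
a dedicated ``down`` bucket rather than silently merged.

Transport categories (shared intestine/serum metabolites):

* i  - concordant Pro/Con ratios in intestine and serum (transported to the
  systemic circulation independent of gateways);
* ii - discordant ratios (influenced by gateways such as enterocyte
  transport or first-pass metabolism), including shared metabolites whose
  ratio is non-finite in either compartment;
* iii - intestine-only metabolites (not transported, or consumed);
* serum-only metabolites are flagged separately (derived from metabolism in
  internal organs).

Concordance is |log ratio difference|-symmetric: two finite ratios are
concordant when max/min <= factor (default 1.3, which places the study's
worked citrulline pair 1.64/2.04 in category i).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import canonical_name
from .differential import DOWN, FINITE, SAME, UP


@dataclass(frozen=True)
class ConcordanceRule:
    """Maximum fold discrepancy between compartment ratios for category i."""

    factor: float = 1.3

    def __post_init__(self):
        if not np.isfinite(self.factor) or self.factor <= 1:
            raise ValueError("concordance factor must be finite and > 1")

    def concordant(self, r1: float, r2: float) -> bool:
        hi, lo = max(r1, r2), min(r1, r2)
        return hi / lo <= self.factor


class ConsistencyError(ValueError):
    pass


def assign_pellet_groups(
    diff_intestine: pd.DataFrame, pellet_members: set[str]
) -> pd.DataFrame:
    """Label every intestinal metabolite (and pellet-only compound) a-e.

    ``diff_intestine`` is a classified differential table indexed by
    canonical id; ``pellet_members`` is the set of canonical names detected
    in the pellet panels. Returns a frame with columns ``metabolite``,
    ``in_pellet``, ``intestine_class``, ``pellet_group``.
    """
    pellet_members = {canonical_name(m) for m in pellet_members}
    records = []
    for key, row in diff_intestine.iterrows():
        in_pellet = key in pellet_members
        cls = row["class"]
        if cls == UP:
            group = "b" if in_pellet else "a"
        elif cls == SAME:
            group = "d" if in_pellet else "c"
        elif cls == DOWN:
            group = "down"
        else:  # UNDETECTED: in the table but in no compartment
            raise ConsistencyError(
                f"metabolite {row['metabolite']!r} undetected in every sample"
            )
        records.append(
            {
                "metabolite": row["metabolite"],
                "in_pellet": in_pellet,
                "intestine_class": cls,
                "pellet_group": group,
            }
        )
    index = list(diff_intestine.index)
    for name in sorted(pellet_members - set(index)):
        records.append(
            {
                "metabolite": name,
                "in_pellet": True,
                "intestine_class": "none",
                "pellet_group": "e",
            }
        )
        index.append(name)
    return pd.DataFrame(records, index=pd.Index(index, name="id"))


def assign_transport_categories(
    diff_intestine: pd.DataFrame,
    diff_serum: pd.DataFrame,
    rule: ConcordanceRule = ConcordanceRule(),
) -> pd.DataFrame:
    """Label metabolites i / ii / iii / serum_only by ratio concordance.

    Shared metabolites with two finite ratios are category i when the
    ratios agree within ``rule.factor`` (a symmetric max/min test, so the
    assignment does not depend on which compartment is taken first), else
    ii; shared metabolites with any non-finite ratio state are ii;
    intestine-only metabolites are iii; serum-only are flagged
    ``serum_only``.
    """
    shared = diff_intestine.index.intersection(diff_serum.index)
    records, index = [], []
    for key, row in diff_intestine.iterrows():
        if key in shared:
            srow = diff_serum.loc[key]
            if row["ratio_state"] == FINITE and srow["ratio_state"] == FINITE:
                cat = "i" if rule.concordant(row["ratio"], srow["ratio"]) else "ii"
            else:
                cat = "ii"
            r_ser = srow["ratio"]
            s_cls = srow.get("class", "none")
        else:
            cat, r_ser, s_cls = "iii", np.nan, "none"
        records.append(
            {
                "metabolite": row["metabolite"],
                "ratio_intestine": row["ratio"],
                "ratio_serum": r_ser,
                "intestine_class": row.get("class", "none"),
                "serum_class": s_cls,
                "transport_category": cat,
            }
        )
        index.append(key)
    for key, srow in diff_serum.iterrows():
        if key in shared:
            continue
        records.append(
            {
                "metabolite": srow["metabolite"],
                "ratio_intestine": np.nan,
                "ratio_serum": srow["ratio"],
                "intestine_class": "none",
                "serum_class": srow.get("class", "none"),
                "transport_category": "serum_only",
            }
        )
        index.append(key)
    return pd.DataFrame(records, index=pd.Index(index, name="id"))


def venn_counts(members: dict[str, set[str]]) -> dict:
    """Three-compartment membership bookkeeping.

    ``members`` maps compartment name -> set of canonical metabolite names
    detected there (>= 1 non-ND cell). Percentages are shares of the serum
    panel, reported at 1 decimal.
    """
    intestine = {canonical_name(m) for m in members.get("intestine", set())}
    serum = {canonical_name(m) for m in members.get("serum", set())}
    pellet = {canonical_name(m) for m in members.get("pellet", set())}
    shared = intestine & serum
    counts = {
        "intestine": len(intestine),
        "serum": len(serum),
        "pellet": len(pellet),
        "intestine_serum_shared": len(shared),
        "intestine_only": len(intestine - serum),
        "serum_only": len(serum - intestine),
        "intestine_pellet_shared": len(intestine & pellet),
        "pellet_only": len(pellet - intestine),
    }
    if serum:
        counts["serum_shared_pct"] = round(100 * len(shared) / len(serum), 1)
        counts["serum_only_pct"] = round(
            100 * len(serum - intestine) / len(serum), 1
        )
    else:
        counts["serum_shared_pct"] = counts["serum_only_pct"] = 0.0
    return counts


def flow_table(
    diff_intestine: pd.DataFrame,
    diff_serum: pd.DataFrame,
    pellet_members: set[str],
    rule: ConcordanceRule = ConcordanceRule(),
) -> pd.DataFrame:
    """Full per-metabolite flow assignment across the three compartments."""
    groups = assign_pellet_groups(diff_intestine, pellet_members)
    cats = assign_transport_categories(diff_intestine, diff_serum, rule)
    idx = groups.index.union(cats.index, sort=False)
    out = pd.DataFrame(index=idx)
    out["metabolite"] = groups["metabolite"].combine_first(cats["metabolite"])
    out["in_pellet"] = groups["in_pellet"].reindex(idx, fill_value=False).astype(bool)
    out["in_intestine"] = out.index.isin(diff_intestine.index)
    out["in_serum"] = out.index.isin(diff_serum.index)
    out["intestine_class"] = (
        groups["intestine_class"].reindex(idx).fillna("none")
    )
    out["serum_class"] = cats["serum_class"].reindex(idx).fillna("none")
    out["pellet_group"] = groups["pellet_group"].reindex(idx).fillna("none")
    out["transport_category"] = (
        cats["transport_category"].reindex(idx).fillna("none")
    )
    return out


def group_counts(flow: pd.DataFrame) -> dict[str, int]:
    counts = flow["pellet_group"].value_counts().to_dict()
    return {g: int(counts.get(g, 0)) for g in ("a", "b", "c", "d", "e", "down")}


def category_counts(flow: pd.DataFrame) -> dict[str, int]:
    counts = flow["transport_category"].value_counts().to_dict()
    return {c: int(counts.get(c, 0)) for c in ("i", "ii", "iii", "serum_only")}
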