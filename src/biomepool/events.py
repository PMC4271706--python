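"""Dated range-expansion/restriction events, dispersal rates, and inflection.

An *expansion* is a branch on which a lineage's range gains the focal area
(absent in the parent's range, present in the child's); a *restriction* is a
branch on which the range collapses to exactly the focal area.  Events are
dated at the stem (parent) node by default.  Dispersal rate is events per Myr
over the [oldest event, youngest event] window.  The inflection stage fits the
cumulative event-count curve with geometric estimators (extremum-distance and
extremum-surface, as in sigmoid regression-free inflection detection) to date
a change in dispersal rate, then re-computes the rate on either side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .trees import DatedTree

__all__ = [
    "RateEstimate",
    "InflectionResult",
    "EnsembleSummary",
    "extract_events",
    "extract_events_from_states",
    "dispersal_rate",
    "find_inflection",
    "inflection_from_curve",
    "split_rates",
    "summarize_ensemble",
    "assign_introductions",
]

AGE_CONVENTIONS = ("stem", "crown", "midpoint")

EVENT_COLUMNS = ["type", "parent", "child", "stem_age", "crown_age",
                 "parent_range", "child_range", "event_age"]


def _event_age(stem: float, crown: float, convention: str) -> float:
    if convention == "stem":
        return stem
    if convention == "crown":
        return crown
    if convention == "midpoint":
        return 0.5 * (stem + crown)
    raise ValueError(f"age convention must be one of {AGE_CONVENTIONS}")


def extract_events_from_states(tree: DatedTree, masks, focal_index: int,
                               areas: Sequence[str],
                               age_convention: str = "stem") -> pd.DataFrame:
    """Scan every branch of ``tree`` for focal-area transitions.

    ``masks`` gives the range bitmask at each node (index-aligned).  Expansion:
    focal absent in parent, present in child.  Restriction: child range equals
    exactly the focal singleton and the parent's does not.  A branch whose
    parent lacks the focal area and whose child is exactly the focal singleton
    emits both.  If the root's range includes the focal area one expansion is
    emitted with stem age = crown age = root age.
    """
    masks = np.asarray(masks, dtype=int)
    focal_bit = 1 << focal_index

    def fmt(mask):
        return "+".join(a for i, a in enumerate(areas) if mask >> i & 1) or "extinct"

    rows = []
    root = tree.root
    if masks[root] & focal_bit:
        ra = float(tree.ages[root])
        rows.append(("expansion", -1, root, ra, ra, fmt(masks[root]),
                     fmt(masks[root]), ra))
    for node in tree.preorder():
        if node == root:
            continue
        parent = int(tree.parent[node])
        pm, cm = int(masks[parent]), int(masks[node])
        stem, crown = float(tree.ages[parent]), float(tree.ages[node])
        ev_age = _event_age(stem, crown, age_convention)
        if not pm & focal_bit and cm & focal_bit:
            rows.append(("expansion", parent, node, stem, crown, fmt(pm),
                         fmt(cm), ev_age))
        if cm == focal_bit and pm != focal_bit:
            rows.append(("restriction", parent, node, stem, crown, fmt(pm),
                         fmt(cm), ev_age))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def extract_events(tree: DatedTree, ancestral_table: pd.DataFrame,
                   focal_area: str, areas: Sequence[str],
                   age_convention: str = "stem") -> pd.DataFrame:
    """Events from a most-probable-state ancestral range table (as produced by
    :func:`biomepool.biogeo.ancestral_ranges`; tips use observed states)."""
    if focal_area not in areas:
        raise ValueError(f"focal area {focal_area!r} not in area list {areas}")
    masks = np.zeros(tree.n_nodes, dtype=int)
    for _, row in ancestral_table.iterrows():
        masks[int(row["node"])] = int(row["map_mask"])
    return extract_events_from_states(tree, masks, list(areas).index(focal_area),
                                      areas, age_convention)


@dataclass
class RateEstimate:
    """Events per Myr over the [oldest, youngest] event-age window."""

    n_events: int
    window: tuple
    rate: float | None

    @property
    def defined(self) -> bool:
        return self.rate is not None


def dispersal_rate(event_ages: Sequence[float]) -> RateEstimate:
    """Average number of events per Myr across the observed event-age window."""
    ages = np.asarray(list(event_ages), dtype=float)
    n = ages.size
    if n < 2:
        return RateEstimate(n, (float(ages.max()), float(ages.min())) if n else
                            (np.nan, np.nan), None)
    oldest, youngest = float(ages.max()), float(ages.min())
    if oldest <= youngest:
        return RateEstimate(n, (oldest, youngest), None)
    return RateEstimate(n, (oldest, youngest), n / (oldest - youngest))


@dataclass
class InflectionResult:
    t_star: float | None
    method: str
    rate_before: float | None = None
    rate_after: float | None = None
    fold_change: float | None = None
    degenerate: bool = False
    t_ede: float | None = None
    t_ese: float | None = None


def _area_balance(x: np.ndarray, d: np.ndarray) -> float:
    """x at which the cumulative trapezoidal area of |d| reaches half its total."""
    a = np.concatenate([[0.0], np.cumsum(0.5 * (np.abs(d[1:]) + np.abs(d[:-1]))
                                         * np.diff(x))])
    half = a[-1] / 2.0
    i = int(np.searchsorted(a, half))
    i = min(max(i, 1), len(x) - 1)
    if a[i] == a[i - 1]:
        return float(x[i])
    frac = (half - a[i - 1]) / (a[i] - a[i - 1])
    return float(x[i - 1] + frac * (x[i] - x[i - 1]))


def inflection_from_curve(x, y, degenerate_tol: float = 0.05,
                          both_signs_frac: float = 0.25) -> dict:
    """Geometric inflection estimates for a monotone curve ``y(x)``.

    The deviation of the curve from the chord joining its endpoints drives two
    estimators.  EDE (extremum distance): the x of the extremal deviation; for
    sigmoid-like curves whose deviation changes sign, the midpoint of the two
    opposite-sign extrema.  ESE (extremum surface): the x balancing the
    trapezoidal area between curve and chord; for sign-changing deviations the
    midpoint of the per-sign balance points.  Curves whose maximal relative
    deviation falls below ``degenerate_tol`` are flagged degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need at least 5 curve points")
    order = np.argsort(x)
    x, y = x[order], y[order]
    span = y[-1] - y[0]
    if span == 0:
        return {"ede": None, "ese": None, "degenerate": True}
    chord = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
    d = y - chord
    pos_max, neg_max = d.max(), -d.min()
    scale = max(pos_max, neg_max)
    if scale / abs(span) < degenerate_tol:
        return {"ede": None, "ese": None, "degenerate": True}
    sigmoid = min(pos_max, neg_max) > both_signs_frac * scale
    if sigmoid:
        i_pos, i_neg = int(np.argmax(d)), int(np.argmin(d))
        ede = 0.5 * (x[i_pos] + x[i_neg])
        lo, hi = sorted((i_pos, i_neg))
        # zero crossing of the deviation between the two extrema
        seg = slice(lo, hi + 1)
        zc = lo
        for i in range(lo, hi):
            if d[i] == 0 or d[i] * d[i + 1] < 0:
                zc = i
                break
        left = slice(0, zc + 2)
        right = slice(zc, len(x))
        ese = 0.5 * (_area_balance(x[left], d[left])
                     + _area_balance(x[right], d[right]))
    else:
        ede = float(x[int(np.argmax(np.abs(d)))])
        ese = _area_balance(x, d)
    return {"ede": float(ede), "ese": float(ese), "degenerate": False}


def find_inflection(event_ages: Sequence[float], method: str = "consensus",
                    degenerate_tol: float = 0.05) -> InflectionResult:
    """Date a change in event rate from the cumulative event-count curve.

    Builds the cumulative count over calendar time (x = -age so time runs
    toward the present), applies the EDE/ESE estimators, converts the result
    back to an age, and re-computes the before/after rates at the estimate.
    """
    ages = np.sort(np.asarray(list(event_ages), dtype=float))[::-1]
    if ages.size < 5:
        raise ValueError("inflection detection needs at least 5 events")
    x = -ages
    y = np.arange(1, ages.size + 1, dtype=float)
    est = inflection_from_curve(x, y, degenerate_tol=degenerate_tol)
    if est["degenerate"]:
        return InflectionResult(None, method, degenerate=True)
    t_ede, t_ese = -est["ede"], -est["ese"]
    if method == "EDE":
        t_star = t_ede
    elif method == "ESE":
        t_star = t_ese
    elif method == "consensus":
        t_star = 0.5 * (t_ede + t_ese)
    else:
        raise ValueError("method must be EDE, ESE or consensus")
    oldest, youngest = float(ages.max()), float(ages.min())
    result = InflectionResult(float(t_star), method, t_ede=float(t_ede),
                              t_ese=float(t_ese))
    if youngest < t_star < oldest:
        before, after, fold = split_rates(ages, t_star)
        result.rate_before, result.rate_after = before, after
        result.fold_change = fold
    return result


def split_rates(event_ages: Sequence[float], t_star: float) -> tuple:
    """Event rates on either side of ``t_star``.

    ``rate_before = #(age > t_star) / (oldest - t_star)``;
    ``rate_after = #(age <= t_star) / (t_star - youngest)``;
    fold change = after / before (None when the before side is empty).
    """
    ages = np.asarray(list(event_ages), dtype=float)
    oldest, youngest = float(ages.max()), float(ages.min())
    if not youngest < t_star < oldest:
        raise ValueError("t_star must lie strictly inside the event window")
    n_before = int((ages > t_star).sum())
    n_after = int((ages <= t_star).sum())
    rate_before = n_before / (oldest - t_star) if n_before else None
    rate_after = n_after / (t_star - youngest) if n_after else None
    if not n_before or not n_after:
        return rate_before, rate_after, None
    return rate_before, rate_after, rate_after / rate_before


@dataclass
class EnsembleSummary:
    """Mean and empirical 95% quantile band of a per-tree statistic."""

    values: np.ndarray
    mean: float
    q025: float
    q975: float
    skewed: bool


def summarize_ensemble(values: Sequence[float]) -> EnsembleSummary:
    """Arithmetic mean and 2.5/97.5 empirical percentiles (linear
    interpolation) of per-tree values."""
    vals = np.asarray([v for v in values], dtype=float)
    if vals.size == 0:
        raise ValueError("cannot summarize an empty ensemble")
    mean = float(vals.mean())
    q025, q975 = (float(np.percentile(vals, q, method="linear"))
                  for q in (2.5, 97.5))
    return EnsembleSummary(vals, mean, q025, q975,
                           skewed=not (q025 <= mean <= q975))


def assign_introductions(tree: DatedTree, events: pd.DataFrame,
                         focal_tips: Sequence[str]) -> dict:
    """Map each focal tip to its introduction: the youngest expansion branch on
    the tip's root path.  Tips under no expansion branch are left unassigned."""
    expansions = events[events["type"] == "expansion"]
    by_child = {int(r["child"]): i for i, (_, r) in enumerate(expansions.iterrows())}
    out = {}
    for label in focal_tips:
        node = tree.node_of(label)
        for anc in tree.path_to_root(node):
            if anc in by_child:
                out[label] = by_child[anc]
                break
    return out
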