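"""Synthetic data with known ground truth for every pipeline stage.

Generates birth-death trees, discrete range histories simulated under the same
dispersal-extinction-cladogenesis (+founder-event) kernels the likelihood uses
(exact event-driven Gillespie stepping, epoch-aware), Brownian-motion climate
traits with optional clade shifts, noisy per-species occurrence records, and
jittered tree ensembles emulating bootstrap age uncertainty.  All generators
are pure functions of (configuration, seed).

Defaults mirror the study conditions of the motivating system: 7 areas with a
maximum observed range of 4, the four-epoch 70/45/30/5/0 Myr connectivity
schedule, ~395 species, and GBIF-like occurrence sampling (median 8 records
per species).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .biogeo import (
    BiogeoParams,
    EpochSchedule,
    RangeStateSpace,
    build_state_space,
    cladogenesis_distribution,
    example_epoch_schedule,
    areas_from_mask,
    DEFAULT_AREAS,
)
from .trees import DatedTree, TreeEnsemble

__all__ = [
    "SimulationError",
    "SimulationConfig",
    "TrueHistory",
    "simulate_bd_tree",
    "simulate_range_history",
    "simulate_bm_traits",
    "simulate_occurrences",
    "make_tree_ensemble",
]


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Generator settings; defaults are the study conditions.

    Rates are per Myr; ``bm_sigma2``/``bm_root`` map trait name to the BM
    variance rate (units^2 Myr^-1) and root value; ``occurrence_noise_sd``
    maps trait name to the within-species record standard deviation.
    """

    n_tips: int = 395
    birth_rate: float = 0.2
    death_rate: float = 0.1
    biogeo_params: BiogeoParams = field(
        default_factory=lambda: BiogeoParams(0.02, 0.01, 0.1, "DEC"))
    epoch_schedule: EpochSchedule = field(default_factory=example_epoch_schedule)
    max_range: int = 4
    root_area: str = "SA"
    focal_area: str = "Me"
    bm_sigma2: dict = field(default_factory=lambda: {"bio12": 5000.0, "bio17": 120.0})
    bm_root: dict = field(default_factory=lambda: {"bio12": 2200.0, "bio17": 250.0})
    occurrence_k: int = 8
    occurrence_noise_sd: dict = field(
        default_factory=lambda: {"bio12": 300.0, "bio17": 50.0})
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.birth_rate <= 0 or self.death_rate < 0:
            raise ValueError("need birth_rate > 0 and death_rate >= 0")
        if self.occurrence_k < 1:
            raise ValueError("occurrence_k must be >= 1")
        for name, s2 in self.bm_sigma2.items():
            if s2 <= 0:
                raise ValueError(f"bm_sigma2[{name!r}] must be > 0")


# ---------------------------------------------------------------------------
# Birth-death trees


def simulate_bd_tree(birth_rate: float, death_rate: float, n_tips: int,
                     seed: int, max_tries: int = 1000) -> DatedTree:
    """Simulate a reconstructed birth-death tree conditioned on ``n_tips``
    extant survivors.

    Forward Gillespie simulation from a crown pair; when the extant count first
    reaches ``n_tips`` the process is stopped at a uniform point of the waiting
    interval to the next event (avoiding zero-length youngest branches), and
    extinct lineages are pruned.  Replicates that go extinct, or whose pruned
    tree has fewer than ``n_tips`` survivors, are retried up to ``max_tries``.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    if death_rate < 0:
        raise ValueError("death_rate must be >= 0")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        tree = _try_bd(birth_rate, death_rate, n_tips, rng)
        if tree is not None:
            return tree
    raise SimulationError(
        f"no surviving tree with {n_tips} tips in {max_tries} tries "
        f"(birth={birth_rate}, death={death_rate})")


def _try_bd(lam, mu, n_tips, rng):
    # nodes: parent list, time-of-node (from crown origin), children later
    parent = [-1, 0, 0]
    node_time = [0.0, None, None]  # internal event times; tips filled at stop
    active = [1, 2]
    t = 0.0
    while True:
        n = len(active)
        if n == 0:
            return None
        total = n * (lam + mu)
        dt = rng.exponential(1.0 / total)
        if n == n_tips:
            t_stop = t + rng.uniform(0.0, dt)
            break
        t += dt
        i = rng.integers(n)
        node = active[i]
        if rng.random() < lam / (lam + mu):
            node_time[node] = t
            c1, c2 = len(parent), len(parent) + 1
            parent.extend([node, node])
            node_time.extend([None, None])
            active[i] = c1
            active.append(c2)
        else:
            node_time[node] = t  # death: tip at time t
            active.pop(i)
    labels: list = [None] * len(parent)
    extinct = []
    k = 0
    for node in active:
        node_time[node] = t_stop
        k += 1
        labels[node] = f"t{k}"
    xk = 0
    for node in range(len(parent)):
        if node_time[node] is None:
            return None  # should not happen
    # identify extinct tips: nodes that are not internal (no children) and not active
    has_child = [False] * len(parent)
    for node in range(1, len(parent)):
        has_child[parent[node]] = True
    for node in range(len(parent)):
        if not has_child[node] and labels[node] is None:
            xk += 1
            labels[node] = f"x{xk}"
            extinct.append(f"x{xk}")
    lengths = np.zeros(len(parent))
    for node in range(1, len(parent)):
        lengths[node] = node_time[node] - node_time[parent[node]]
    tree = DatedTree(np.asarray(parent), lengths, labels)
    if extinct:
        try:
            tree = tree.prune_tips(extinct)
        except Exception:
            return None
    if tree.n_tips != n_tips:
        return None
    return tree


# ---------------------------------------------------------------------------
# Range histories


@dataclass
class TrueHistory:
    """Ground-truth log of a simulated range history.

    ``node_masks[i]`` is the range bitmask at node ``i`` (after anagenesis on
    its branch, before its own cladogenesis); ``clado_outcomes[i]`` the ordered
    daughter ranges drawn at internal node ``i``; ``branch_events`` the dated
    anagenetic events ``(parent, child, kind, area, age)`` with kind in
    {"gain", "loss"}.
    """

    areas: tuple
    root_mask: int
    node_masks: np.ndarray
    clado_outcomes: dict
    branch_events: list
    tip_ranges: dict
    extinct_tips: list

    def replay(self, tree: DatedTree) -> dict:
        """Re-derive tip ranges by replaying the event log from the root."""
        masks = np.zeros(tree.n_nodes, dtype=int)
        masks[tree.root] = self.root_mask
        ev_by_branch: dict = {}
        for parent, child, kind, area, age in self.branch_events:
            ev_by_branch.setdefault(child, []).append((age, kind, area))
        for node in tree.preorder():
            if tree.is_tip(node):
                continue
            left, right = tree.children[node]
            lm, rm = self.clado_outcomes[node]
            for child, top in ((left, lm), (right, rm)):
                mask = top
                for age, kind, area in sorted(ev_by_branch.get(child, []),
                                              reverse=True):
                    if kind == "gain":
                        mask |= 1 << area
                    else:
                        mask &= ~(1 << area)
                masks[child] = mask
        return {tree.labels[i]: int(masks[i]) for i in tree.tip_indices}

    def true_events(self, tree: DatedTree, focal_area: str) -> pd.DataFrame:
        """Expansion/restriction events implied by the true node states, using
        the same stem/crown conventions as the inference stage."""
        from .events import extract_events_from_states
        return extract_events_from_states(
            tree, self.node_masks, self.areas.index(focal_area), self.areas)

    def events_on_pruned(self, pruned_tree: DatedTree,
                         focal_area: str) -> pd.DataFrame:
        """True events restricted to a pruned (observable) tree: node states
        are carried over via the pruned tree's ``orig_index`` map, so counts
        are comparable with what inference on the pruned tree can recover."""
        from .events import extract_events_from_states
        idx = getattr(pruned_tree, "orig_index", None)
        masks = self.node_masks if idx is None else self.node_masks[idx]
        return extract_events_from_states(
            pruned_tree, masks, self.areas.index(focal_area), self.areas)

    def to_json(self) -> str:
        return json.dumps({
            "areas": list(self.areas),
            "root_mask": int(self.root_mask),
            "node_masks": [int(m) for m in self.node_masks],
            "clado_outcomes": {str(k): [int(a), int(b)]
                               for k, (a, b) in self.clado_outcomes.items()},
            "branch_events": [[int(p), int(c), k, int(a), float(t)]
                              for p, c, k, a, t in self.branch_events],
            "tip_ranges": {k: int(v) for k, v in self.tip_ranges.items()},
            "extinct_tips": list(self.extinct_tips),
        }, indent=1)


def _gain_rates(mask, d, m_k, n_areas, max_range):
    occupied = [b for b in range(n_areas) if mask >> b & 1]
    out = {}
    if len(occupied) < max_range:
        for a in range(n_areas):
            if mask >> a & 1:
                continue
            r = d * sum(m_k[b, a] for b in occupied)
            if r > 0:
                out[a] = r
    return out, occupied


def simulate_range_history(tree: DatedTree, biogeo_params: BiogeoParams,
                           epoch_schedule: EpochSchedule, root_range,
                           seed: int, space: RangeStateSpace | None = None,
                           max_range: int | None = None) -> tuple:
    """Simulate discrete range evolution along a dated tree.

    Anagenesis is exact event-driven (Gillespie) per branch with epoch-aware
    dispersal kernels identical to the likelihood's rate matrix; one
    cladogenetic outcome is drawn at each node from the cladogenesis
    distribution applied to the node's post-anagenesis range.  A lineage whose
    range empties is flagged extinct (absorbing).  Returns
    ``(tip_ranges, TrueHistory)``.
    """
    if space is None:
        mr = max_range if max_range is not None else epoch_schedule.n_areas
        areas = (DEFAULT_AREAS[:epoch_schedule.n_areas]
                 if epoch_schedule.n_areas <= len(DEFAULT_AREAS)
                 else tuple(f"A{i}" for i in range(epoch_schedule.n_areas)))
        space = RangeStateSpace(areas, mr)
    if isinstance(root_range, (int, np.integer)):
        root_mask = int(root_range)
    else:
        from .biogeo import mask_from_areas
        root_mask = mask_from_areas(root_range, space.areas)
    if root_mask == 0:
        raise ValueError("root range must be non-empty")
    space.state_index(root_mask)  # enforces max-range constraint
    rng = np.random.default_rng(seed)
    d, e = biogeo_params.d, biogeo_params.e
    n_areas, mr = space.n_areas, space.max_range
    bounds = sorted(epoch_schedule.boundaries, reverse=True)

    node_masks = np.zeros(tree.n_nodes, dtype=int)
    node_masks[tree.root] = root_mask
    clado_outcomes: dict = {}
    branch_events: list = []
    for node in tree.preorder():
        if tree.is_tip(node):
            continue
        mask = int(node_masks[node])
        if mask == 0:
            lm = rm = 0
        else:
            dist = cladogenesis_distribution(mask, biogeo_params, space)
            pairs = list(dist.keys())
            probs = np.array([dist[p] for p in pairs])
            lm, rm = pairs[rng.choice(len(pairs), p=probs / probs.sum())]
        clado_outcomes[node] = (lm, rm)
        for child, top in zip(tree.children[node], (lm, rm)):
            a0, a1 = float(tree.ages[node]), float(tree.ages[child])
            mask_c = top
            age = a0
            while age > a1 + 1e-12 and mask_c != 0:
                k = epoch_schedule.epoch_index(age - 1e-9)
                m_k = epoch_schedule.matrices[k]
                gains, occupied = _gain_rates(mask_c, d, m_k, n_areas, mr)
                rates = list(gains.items()) + [(-(a + 1), e) for a in occupied]
                total = sum(r for _, r in rates)
                next_bound = max((b for b in bounds if a1 < b < age - 1e-12),
                                 default=a1)
                if total <= 0:
                    age = next_bound
                    continue
                wait = rng.exponential(1.0 / total)
                if age - wait < next_bound:
                    age = next_bound
                    continue
                age -= wait
                pick = rng.random() * total
                acc = 0.0
                for code, r in rates:
                    acc += r
                    if pick <= acc:
                        if code >= 0:
                            mask_c |= 1 << code
                            branch_events.append((node, child, "gain", code, age))
                        else:
                            area = -code - 1
                            mask_c &= ~(1 << area)
                            branch_events.append((node, child, "loss", area, age))
                        break
            node_masks[child] = mask_c
    tip_ranges = {tree.labels[i]: int(node_masks[i]) for i in tree.tip_indices}
    extinct = [lab for lab, m in tip_ranges.items() if m == 0]
    hist = TrueHistory(space.areas, root_mask, node_masks, clado_outcomes,
                       branch_events, tip_ranges, extinct)
    return tip_ranges, hist


# ---------------------------------------------------------------------------
# Continuous traits and occurrences


def simulate_bm_traits(tree: DatedTree, sigma2: float, root_value: float,
                       seed: int, shifts: Mapping[int, float] | None = None
                       ) -> np.ndarray:
    """Brownian-motion trait values at all nodes and tips.

    ``value(child) ~ Normal(value(parent) + shift(child), sigma2 * branch
    length)`` where ``shifts`` maps a node index to an additive mean shift
    applied on the branch leading to that node (and hence inherited by its
    whole clade).
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    rng = np.random.default_rng(seed)
    shifts = dict(shifts or {})
    values = np.zeros(tree.n_nodes)
    values[tree.root] = root_value
    for node in tree.preorder():
        if node == tree.root:
            continue
        bl = tree.lengths[node]
        drift = shifts.get(int(node), 0.0)
        values[node] = (values[tree.parent[node]] + drift
                        + rng.normal(0.0, np.sqrt(sigma2 * bl)))
    return values


def simulate_occurrences(tip_values, k: int, noise_sd, seed: int) -> pd.DataFrame:
    """Noisy occurrence records: ``k`` records per species, each trait value
    drawn Normal(tip value, noise_sd^2).

    ``tip_values`` is a DataFrame (index species, one column per trait) or a
    mapping species -> value for a single trait named "trait"; ``noise_sd`` is
    a scalar or a per-trait mapping.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not isinstance(tip_values, pd.DataFrame):
        tip_values = pd.DataFrame({"trait": pd.Series(dict(tip_values))})
    rng = np.random.default_rng(seed)
    rows = []
    for species, row in tip_values.iterrows():
        for _ in range(k):
            rec = {"species": species}
            for trait, val in row.items():
                sd = noise_sd[trait] if isinstance(noise_sd, Mapping) else noise_sd
                rec[trait] = val + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ensembles


def make_tree_ensemble(tree: DatedTree, n_trees: int, age_jitter_sd: float,
                       seed: int) -> TreeEnsemble:
    """Emulate bootstrap age uncertainty: each member perturbs internal node
    ages multiplicatively (factor Normal(1, sd)), preserving parent-older-than-
    child monotonicity by resampling violating draws.  Tip ages are fixed."""
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    rng = np.random.default_rng(seed)
    members = []
    tip_set = set(tree.tip_indices)
    for _ in range(n_trees):
        ages = tree.ages.copy()
        if age_jitter_sd > 0:
            max_tip_below = np.zeros(tree.n_nodes)
            for node in tree.postorder():
                if node in tip_set:
                    max_tip_below[node] = tree.ages[node]
                else:
                    max_tip_below[node] = max(max_tip_below[c]
                                              for c in tree.children[node])
            for node in tree.preorder():
                if node in tip_set:
                    continue
                upper = ages[tree.parent[node]] if node != tree.root else np.inf
                lower = max_tip_below[node]
                base = tree.ages[node]
                new = None
                for _ in range(100):
                    cand = base * rng.normal(1.0, age_jitter_sd)
                    if lower < cand < upper:
                        new = cand
                        break
                ages[node] = new if new is not None else 0.5 * (
                    lower + min(upper, base * (1 + 3 * age_jitter_sd)))
        lengths = np.zeros(tree.n_nodes)
        for node in range(tree.n_nodes):
            if node != tree.root:
                lengths[node] = ages[tree.parent[node]] - ages[node]
        members.append(DatedTree(tree.parent.copy(), lengths,
                                 list(tree.labels), ages))
    return TreeEnsemble(members)
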