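"""Climate profiles, PGLS contrasts, BM ancestral climate, and evolutionary lag.

Species climate profiles are per-species means of occurrence-record values for
two precipitation traits (total annual precipitation, mm yr^-1, and
precipitation of the driest quarter, mm qtr^-1).  Group contrasts between
endemic, widespread, and non-focal species use phylogenetic generalized least
squares with the Brownian-motion covariance (shared root-to-MRCA path length).
Ancestral climate values are reconstructed under Brownian motion by ML (GLS
conditional expectations) or by Gibbs-sampled Bayesian MCMC.  A lineage
"reaches" a dry-biome condition the first (oldest) time its reconstructed
root-to-tip trajectory drops to or below a threshold; the evolutionary lag of
a geographic restriction is the crossing age minus the restriction age
(positive = pre-adapted, negative = in-situ adaptation, same-branch =
concurrent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .trees import DatedTree, TreeError

__all__ = [
    "ThresholdSpec",
    "BMFit",
    "CrossingRecord",
    "LagRecord",
    "PGLSResult",
    "species_climate_means",
    "assign_groups",
    "pgls_group_test",
    "bm_ancestral_ml",
    "bm_ancestral_bayes",
    "threshold_crossing_age",
    "lag_time",
    "lag_table",
]

GROUPS = ("non_focal", "endemic", "widespread")

#: Biome-defining minimum thresholds: traditional and stricter total annual
#: precipitation (mm yr^-1), and severe / moderate dry-quarter precipitation
#: (mm qtr^-1).
DEFAULT_THRESHOLDS = {
    "bio12": (1800.0, 1600.0),
    "bio17": (50.0, 100.0),
}


@dataclass(frozen=True)
class ThresholdSpec:
    """A biome condition is reached when the trait value is <= ``threshold``."""

    trait: str
    threshold: float

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")


def species_climate_means(occurrences: pd.DataFrame,
                          traits: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-species arithmetic means of occurrence records.

    Non-numeric trait entries reject the whole record with a logged warning;
    species with no valid records are excluded.  Returns a DataFrame indexed
    by species with one column per trait plus ``n_records``.
    """
    if "species" not in occurrences.columns:
        raise ValueError("occurrence table must have a 'species' column")
    if traits is None:
        traits = [c for c in occurrences.columns if c != "species"]
    df = occurrences[["species", *traits]].copy()
    for t in traits:
        df[t] = pd.to_numeric(df[t], errors="coerce")
    bad = df[traits].isna().any(axis=1)
    if bad.any():
        warnings.warn(f"rejected {int(bad.sum())} occurrence record(s) with "
                      "non-numeric trait values")
        df = df[~bad]
    grouped = df.groupby("species")
    out = grouped[list(traits)].mean()
    out["n_records"] = grouped.size()
    return out


def assign_groups(region_table: pd.DataFrame, focal_area: str) -> pd.Series:
    """Label each species endemic (range == {focal}), widespread (focal plus
    others), or non_focal, from a 0/1 species-by-region table."""
    if focal_area not in region_table.columns:
        raise ValueError(f"focal area {focal_area!r} not a region column")
    vals = region_table.astype(int)
    totals = vals.sum(axis=1)
    if (totals == 0).any():
        empty = totals[totals == 0].index.tolist()
        raise ValueError(f"species with all-zero range: {empty}")
    labels = []
    for sp, row in vals.iterrows():
        if row[focal_area]:
            labels.append("endemic" if row.sum() == 1 else "widespread")
        else:
            labels.append("non_focal")
    return pd.Series(labels, index=vals.index, name="group")


@dataclass
class PGLSResult:
    trait: str
    coefficients: pd.DataFrame
    contrasts: pd.DataFrame
    sigma2: float
    n: int


def pgls_group_test(tree: DatedTree, profile: pd.DataFrame, labels: pd.Series,
                    trait: str) -> PGLSResult:
    """Phylogenetic GLS of a climate trait on the 3-level group factor.

    The covariance is the BM structure C[i,j] = shared root-to-MRCA path
    length; ``non_focal`` is the reference level.  Returns the coefficient
    table and all pairwise group contrasts with t statistics and p values.
    """
    species = [s for s in profile.index if s in labels.index
               and s in tree._label_to_node]
    labs = labels.loc[species]
    present = set(labs)
    compared = [g for g in GROUPS if g in present]
    counts = labs.value_counts()
    if len(compared) < 2 or (counts < 3).any():
        raise ValueError("need >= 3 species in each of >= 2 groups; got "
                         f"{counts.to_dict()}")
    y = profile.loc[species, trait].to_numpy(dtype=float)
    tips = [tree.node_of(s) for s in species]
    C = tree.shared_depth_matrix(tips)
    X = np.column_stack([np.ones(len(species))]
                        + [(labs == g).to_numpy(dtype=float)
                           for g in compared if g != "non_focal"])
    names = ["intercept"] + [g for g in compared if g != "non_focal"]
    model = sm.GLS(y, X, sigma=C)
    res = model.fit()
    coef = pd.DataFrame({"coef": res.params, "se": res.bse, "t": res.tvalues,
                         "p": res.pvalues}, index=names)
    # pairwise contrasts via linear combinations of the fitted coefficients
    level_vec = {g: np.zeros(len(names)) for g in compared}
    for g in compared:
        level_vec[g][0] = 1.0
        if g != "non_focal":
            level_vec[g][names.index(g)] = 1.0
    cov = res.cov_params()
    dof = len(species) - len(names)
    rows = []
    for i, ga in enumerate(compared):
        for gb in compared[i + 1:]:
            lvec = level_vec[ga] - level_vec[gb]
            est = float(lvec @ res.params)
            se = float(np.sqrt(lvec @ cov @ lvec))
            tval = est / se
            rows.append({"group_a": ga, "group_b": gb, "estimate": est,
                         "se": se, "t": tval,
                         "p": 2 * stats.t.sf(abs(tval), dof)})
    sigma2 = float(res.scale)
    return PGLSResult(trait, coef, pd.DataFrame(rows), sigma2, len(species))


# ---------------------------------------------------------------------------
# Brownian-motion ancestral reconstruction


@dataclass
class BMFit:
    """ML Brownian-motion fit: variance rate ``sigma2`` (units^2 Myr^-1), root
    state, per-node ancestral estimates (tips keep observed values), logL."""

    sigma2: float
    root_state: float
    node_values: np.ndarray
    loglik: float


def _tip_vector(tree: DatedTree, tip_values: Mapping) -> tuple:
    tips = tree.tip_indices
    try:
        y = np.array([float(tip_values[tree.labels[i]]) for i in tips])
    except KeyError as exc:
        raise TreeError(f"tip {exc.args[0]!r} has no trait value") from None
    return tips, y


def _descendant_sets(tree: DatedTree):
    below = {}
    for node in tree.postorder():
        if tree.is_tip(node):
            below[node] = {node}
        else:
            s = set()
            for c in tree.children[node]:
                s |= below[c]
            below[node] = s
    return below


def bm_ancestral_ml(tree: DatedTree, tip_values: Mapping) -> BMFit:
    """Joint ML reconstruction of ancestral states under Brownian motion.

    The root state is the GLS mean (1'C^-1 y)/(1'C^-1 1); internal states are
    the GLS conditional expectations given the tips, which jointly maximize
    the BM likelihood; sigma2 is the ML variance rate.
    """
    if tree.n_tips < 2:
        raise ValueError("need at least 2 tips")
    tips, y = _tip_vector(tree, tip_values)
    C = tree.shared_depth_matrix(tips)
    n = len(tips)
    try:
        cho = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        raise TreeError(
            "singular BM covariance (duplicate zero-length tips with "
            "conflicting values?)") from None
    Cinv_y = np.linalg.solve(C, y)
    Cinv_1 = np.linalg.solve(C, np.ones(n))
    root = float(np.ones(n) @ Cinv_y / (np.ones(n) @ Cinv_1))
    r = y - root
    Cinv_r = np.linalg.solve(C, r)
    sigma2 = float(r @ Cinv_r / n)
    logdet = 2.0 * np.log(np.diag(cho)).sum()
    if sigma2 > 0:
        loglik = float(-0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n))
    else:
        loglik = np.inf  # degenerate: all tips identical
    values = np.zeros(tree.n_nodes)
    for i, t in enumerate(tips):
        values[t] = y[i]
    below = _descendant_sets(tree)
    pos = {t: k for k, t in enumerate(tips)}
    S = C  # shared-depth matrix doubles as tip-tip covariance shape
    for node in range(tree.n_nodes):
        if tree.is_tip(node):
            continue
        desc = below[node]
        rep = pos[next(iter(desc))]
        depth_node = tree.root_age - tree.ages[node]
        c = S[rep].copy()
        for t in desc:
            c[pos[t]] = depth_node
        values[node] = root + float(c @ Cinv_r)
    return BMFit(sigma2, root, values, loglik)


def bm_ancestral_bayes(tree: DatedTree, tip_values: Mapping,
                       n_iter: int = 10000, seed: int = 0,
                       burn_frac: float = 0.2) -> dict:
    """Bayesian BM reconstruction by Gibbs sampling with flat priors.

    Internal states have normal full conditionals given their neighbors;
    sigma2 has an inverse-gamma full conditional, so every update is a direct
    draw (the reported acceptance rate is 1 by construction).  Returns
    posterior means/SDs per node and the sigma2 posterior summary.
    """
    if n_iter < 10:
        raise ValueError("n_iter too small")
    tips, y = _tip_vector(tree, tip_values)
    rng = np.random.default_rng(seed)
    ml = bm_ancestral_ml(tree, tip_values)
    values = ml.node_values.copy()
    sigma2 = max(ml.sigma2, 1e-12)
    tip_set = set(tips)
    internal = [n for n in range(tree.n_nodes) if n not in tip_set]
    lengths = np.maximum(tree.lengths, 1e-8)
    n_branches = tree.n_nodes - 1
    keep_from = int(burn_frac * n_iter)
    sums = np.zeros(tree.n_nodes)
    sqs = np.zeros(tree.n_nodes)
    s2_samples = []
    kept = 0
    for it in range(n_iter):
        for node in internal:
            prec, mean_num = 0.0, 0.0
            if node != tree.root:
                w = 1.0 / (sigma2 * lengths[node])
                prec += w
                mean_num += w * values[tree.parent[node]]
            for c in tree.children[node]:
                w = 1.0 / (sigma2 * lengths[c])
                prec += w
                mean_num += w * values[c]
            mu = mean_num / prec
            values[node] = rng.normal(mu, np.sqrt(1.0 / prec))
        ss = 0.0
        for node in range(tree.n_nodes):
            if node == tree.root:
                continue
            diff = values[node] - values[tree.parent[node]]
            ss += diff * diff / lengths[node]
        shape = 0.5 * n_branches - 1.0
        if shape <= 0:
            shape = 0.5
        # floor keeps the chain alive for (near-)constant tip data
        sigma2 = max((0.5 * ss) / rng.gamma(shape), 1e-30)
        if it >= keep_from:
            kept += 1
            sums += values
            sqs += values ** 2
            s2_samples.append(sigma2)
    means = sums / kept
    sds = np.sqrt(np.maximum(sqs / kept - means ** 2, 0.0))
    s2 = np.asarray(s2_samples)
    return {
        "node_means": means,
        "node_sds": sds,
        "sigma2_mean": float(s2.mean()),
        "sigma2_sd": float(s2.std()),
        "acceptance_rate": 1.0,
        "n_kept": kept,
    }


# ---------------------------------------------------------------------------
# Threshold crossings and lag


@dataclass
class CrossingRecord:
    """First (oldest) point on the root-to-target path at which the
    reconstructed trait drops to or below the threshold."""

    target: int
    threshold: ThresholdSpec
    crossing_age: float | None
    branch: tuple | None  # (parent, child) node ids; None at the root
    n_recrossings: int = 0


def threshold_crossing_age(tree: DatedTree, node_values, target,
                           spec: ThresholdSpec) -> CrossingRecord:
    """Walk from the root toward ``target``; the first branch whose values pass
    from above to at-or-below the threshold dates the crossing by linear
    interpolation.  A root already at or below the threshold crosses at the
    root age; a path never reaching it yields no crossing.  Later re-crossings
    above the threshold are counted but do not move the (oldest) crossing.
    """
    node = tree.node_of(target) if isinstance(target, str) else int(target)
    if not 0 <= node < tree.n_nodes:
        raise TreeError(f"node {target!r} not in tree")
    values = np.asarray(node_values, dtype=float)
    path = tree.path_to_root(node)[::-1]  # root ... target
    theta = spec.threshold
    crossing_age, branch = None, None
    n_re = 0
    below = values[path[0]] <= theta
    if below:
        crossing_age = float(tree.ages[path[0]])
    for p, c in zip(path[:-1], path[1:]):
        vp, vc = values[p], values[c]
        if not below and vp > theta >= vc:
            a_p, a_c = tree.ages[p], tree.ages[c]
            age = a_p - (a_p - a_c) * (vp - theta) / (vp - vc)
            if crossing_age is None:
                crossing_age = float(age)
                branch = (int(p), int(c))
            else:
                n_re += 1
            below = True
        elif below and vc > theta:
            below = False
    return CrossingRecord(node, spec, crossing_age, branch, n_re)


@dataclass
class LagRecord:
    """Evolutionary lag of one geographic restriction under one threshold:
    lag = crossing age - restriction age; class pre_adapted / concurrent /
    in_situ."""

    restriction_branch: tuple
    threshold: ThresholdSpec
    crossing_age: float | None
    restriction_age: float
    lag: float | None
    klass: str


def lag_time(restriction, crossing: CrossingRecord,
             concurrency_rule: str = "same_branch") -> LagRecord:
    """Classify one restriction event against one threshold crossing.

    ``concurrent`` when the crossing lies on the restriction's own branch;
    otherwise ``pre_adapted`` for positive lag and ``in_situ`` for
    non-positive lag or no crossing at all (lag flagged undefined).
    """
    if concurrency_rule != "same_branch":
        raise ValueError("only the same_branch concurrency rule is implemented")
    rbranch = (int(restriction["parent"]), int(restriction["child"]))
    if rbranch[1] != crossing.target:
        raise ValueError("restriction child and crossing target differ: "
                         f"{rbranch[1]} vs {crossing.target}")
    r_age = float(restriction["event_age"])
    if crossing.crossing_age is None:
        return LagRecord(rbranch, crossing.threshold, None, r_age, None, "in_situ")
    lag = crossing.crossing_age - r_age
    if crossing.branch == rbranch:
        klass = "concurrent"
    elif lag > 0:
        klass = "pre_adapted"
    else:
        klass = "in_situ"
    return LagRecord(rbranch, crossing.threshold, crossing.crossing_age,
                     r_age, lag, klass)


def lag_table(tree: DatedTree, node_values, restrictions: pd.DataFrame,
              spec: ThresholdSpec) -> pd.DataFrame:
    """Lag records for every restriction event against one threshold."""
    rows = []
    for _, ev in restrictions.iterrows():
        if int(ev["child"]) < 0:
            continue
        crossing = threshold_crossing_age(tree, node_values, int(ev["child"]),
                                          spec)
        rec = lag_time(ev, crossing)
        rows.append({
            "parent": rec.restriction_branch[0],
            "child": rec.restriction_branch[1],
            "trait": spec.trait,
            "threshold": spec.threshold,
            "crossing_age": rec.crossing_age,
            "restriction_age": rec.restriction_age,
            "lag": rec.lag,
            "class": rec.klass,
        })
    return pd.DataFrame(rows, columns=["parent", "child", "trait", "threshold",
                                       "crossing_age", "restriction_age",
                                       "lag", "class"])
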