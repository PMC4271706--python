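"""Independent reference computations used by the test suite.

These deliberately avoid the library's pruning/propagation code paths: the
biogeographic likelihood oracle enumerates every internal-state assignment and
cladogenetic outcome explicitly; the birth-death oracles use closed forms or a
discrete-time simulation.
"""

import itertools
from math import lgamma

import numpy as np

from biomepool.biogeo import (
    branch_transition_probs,
    cladogenesis_distribution,
)


def brute_force_loglik(tree, tip_masks, params, schedule, space):
    """Exhaustive sum over internal-node states and cladogenetic outcomes."""
    internal = [n for n in range(tree.n_nodes) if not tree.is_tip(n)]
    P = {
        n: branch_transition_probs(space, params, schedule,
                                   tree.ages[tree.parent[n]], tree.ages[n])
        for n in range(tree.n_nodes) if n != tree.root
    }
    tipstate = {i: space.state_index(tip_masks[tree.labels[i]])
                for i in tree.tip_indices}
    total = 0.0
    for assign in itertools.product(range(space.n_nonextinct),
                                    repeat=len(internal)):
        st = dict(zip(internal, assign))
        st.update(tipstate)
        p = 1.0 / space.n_nonextinct
        for n in internal:
            dist = cladogenesis_distribution(space.masks[st[n]], params, space)
            kids = tree.children[n]
            sub = 0.0
            for (lm, rm), w in dist.items():
                li, ri = space.index[lm], space.index[rm]
                sub += w * P[kids[0]][li, st[kids[0]]] * P[kids[1]][ri, st[kids[1]]]
            p *= sub
            if p == 0.0:
                break
        total += p
    return np.log(total)


def brute_force_marginals(tree, tip_masks, params, schedule, space):
    """Posterior state probabilities at internal nodes by enumeration."""
    internal = [n for n in range(tree.n_nodes) if not tree.is_tip(n)]
    P = {
        n: branch_transition_probs(space, params, schedule,
                                   tree.ages[tree.parent[n]], tree.ages[n])
        for n in range(tree.n_nodes) if n != tree.root
    }
    tipstate = {i: space.state_index(tip_masks[tree.labels[i]])
                for i in tree.tip_indices}
    marg = {n: np.zeros(space.n_states) for n in internal}
    for assign in itertools.product(range(space.n_nonextinct),
                                    repeat=len(internal)):
        st = dict(zip(internal, assign))
        st.update(tipstate)
        p = 1.0 / space.n_nonextinct
        for n in internal:
            dist = cladogenesis_distribution(space.masks[st[n]], params, space)
            kids = tree.children[n]
            sub = 0.0
            for (lm, rm), w in dist.items():
                li, ri = space.index[lm], space.index[rm]
                sub += w * P[kids[0]][li, st[kids[0]]] * P[kids[1]][ri, st[kids[1]]]
            p *= sub
            if p == 0.0:
                break
        for n in internal:
            marg[n][st[n]] += p
    for n in internal:
        marg[n] /= marg[n].sum()
    return marg


def yule_loglik_from_node_ages(tree, lam):
    """Closed-form pure-birth log-likelihood from the internal node ages,
    conditioned on the crown age (Nee-style reconstructed process)."""
    n = tree.n_tips
    ages = sorted((tree.ages[i] for i in range(tree.n_nodes)
                   if not tree.is_tip(i)), reverse=True)
    x1, others = ages[0], ages[1:]
    return lgamma(n) + (n - 2) * np.log(lam) - lam * sum(others) - 2 * lam * x1


def discrete_time_crown_age(lam, mu, n_tips, rng, dt=0.01, max_steps=200000):
    """Crown age of one surviving discrete-time birth-death replicate with
    n_tips extant survivors, or None if the replicate fails."""
    # Bernoulli-per-step approximation of the continuous-time process
    n_alive = 2
    t = 0.0
    for _ in range(max_steps):
        if n_alive == 0:
            return None
        if n_alive >= n_tips:
            return t
        births = rng.binomial(n_alive, min(lam * dt, 1.0))
        deaths = rng.binomial(n_alive, min(mu * dt, 1.0))
        n_alive += births - deaths
        t += dt
    return None


def expected_gain_count(space, params, schedule, root_mask, t_total,
                        n_steps=4000):
    """Expected number of anagenetic gain events along one branch of duration
    ``t_total`` starting (at age t_total) from ``root_mask``, by numerically
    integrating the state distribution against the per-state gain rates."""
    from biomepool.biogeo import build_rate_matrix
    from scipy.linalg import expm

    pi = np.zeros(space.n_states)
    pi[space.state_index(root_mask)] = 1.0
    dt = t_total / n_steps
    total = 0.0
    age = t_total
    step_cache = {}
    for _ in range(n_steps):
        k = schedule.epoch_index(age - 0.5 * dt)
        Q = step_cache.get(("Q", k))
        if Q is None:
            Q = build_rate_matrix(space, params.d, params.e,
                                  schedule.matrices[k])
            step_cache[("Q", k)] = Q
            gain = np.zeros(space.n_states)
            for i, mask in enumerate(space.masks):
                if mask == 0:
                    continue
                for jdx, m2 in enumerate(space.masks):
                    if m2 and bin(m2).count("1") == bin(mask).count("1") + 1 \
                            and (mask & m2) == mask:
                        gain[i] += Q[i, jdx]
            step_cache[("g", k)] = gain
            step_cache[("P", k)] = expm(Q * dt)
        gain = step_cache[("g", k)]
        total += float(pi @ gain) * dt
        pi = pi @ step_cache[("P", k)]
        age -= dt
    return total
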