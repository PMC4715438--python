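"""Minimal discrete-lineage coalescent machinery.

Shared by the synthetic-sequence generator and by the simulation-based
p-values of the neutrality tests and the mismatch-distribution bootstrap.
Trees are stored as flat parent/time arrays: nodes ``0..n-1`` are leaves,
``n..2n-2`` internal, node ``2n-2`` the root.  Times increase into the past.

Scales used by callers:

* :func:`sim_kingman` — time in units of N generations (haploid); a pair of
  lineages coalesces at rate 1.  With per-locus scaled diversity
  ``theta = 2*N*u`` mutations are dropped at rate ``theta/2`` per lineage
  per unit time, so E[pairwise differences] = theta.
* :func:`sim_two_epoch` — time in mutational units (tau = 2*u*t); a pair
  coalesces at rate ``1/theta`` within an epoch and every lineage mutates
  at rate 1/2 per unit time.
* :func:`sim_structured` — explicit generations with per-population sizes,
  a backward migration matrix, and a merge of all demes at the split time.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "sim_kingman",
    "sim_two_epoch",
    "sim_structured",
    "branch_lengths",
    "leaf_indicator",
    "pair_difference_matrix",
    "segregating_and_pi_conditional",
]


def _merge(active: list[int], rng: np.random.Generator) -> tuple[int, int]:
    """Pick two distinct active lineages uniformly at random."""
    i, j = rng.choice(len(active), size=2, replace=False)
    a, b = active[int(i)], active[int(j)]
    # remove higher index first
    for idx in sorted((int(i), int(j)), reverse=True):
        active.pop(idx)
    return a, b


def sim_kingman(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a constant-size Kingman genealogy for ``n`` samples.

    Returns ``(parent, time)`` arrays of length ``2n-1``; the root's parent
    is ``-1``.  Time is in coalescent units (pairwise rate 1).
    """
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes, dtype=float)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        a, b = _merge(active, rng)
        parent[a] = nxt
        parent[b] = nxt
        time[nxt] = t
        active.append(nxt)
        nxt += 1
    return parent, time


def sim_two_epoch(
    n: int,
    tau_switch: float,
    theta0: float,
    theta1: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Genealogy under a sudden size change, in mutational time units.

    Recent epoch (tau < ``tau_switch``) has scaled size ``theta1``, the
    ancestral epoch ``theta0``; a lineage pair coalesces at rate
    ``1/theta`` within an epoch.
    """
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes, dtype=float)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        theta = theta1 if t < tau_switch else theta0
        rate = k * (k - 1) / 2.0 / theta
        wait = rng.exponential(1.0 / rate)
        if t < tau_switch and t + wait > tau_switch:
            # re-draw in the ancestral epoch (memorylessness)
            t = tau_switch
            continue
        t += wait
        a, b = _merge(active, rng)
        parent[a] = nxt
        parent[b] = nxt
        time[nxt] = t
        active.append(nxt)
        nxt += 1
    return parent, time


def sim_structured(
    pop_of_sample: np.ndarray,
    pop_sizes: np.ndarray,
    migration: np.ndarray,
    split_generations: float,
    rng: np.random.Generator,
    ancestral_size: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Structured coalescent: island model collapsing to one ancestral deme.

    ``pop_of_sample`` gives each sample's deme; ``migration[i, j]`` is the
    per-generation backward rate at which a lineage in deme ``i`` traces to
    deme ``j``.  At ``split_generations`` before present every lineage is
    moved into a single ancestral deme (size ``ancestral_size``, default
    the mean deme size).  Time is in generations.
    """
    n = len(pop_of_sample)
    n_pops = len(pop_sizes)
    if ancestral_size is None:
        ancestral_size = float(np.mean(pop_sizes))
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes, dtype=float)
    active = list(range(n))
    deme = {i: int(pop_of_sample[i]) for i in range(n)}
    t = 0.0
    nxt = n
    merged = split_generations <= 0
    if merged:
        for a in active:
            deme[a] = 0
    mig_out = migration.sum(axis=1)
    while len(active) > 1:
        counts = np.zeros(n_pops, dtype=np.int64)
        for a in active:
            counts[deme[a]] += 1
        if merged:
            coal_rates = np.zeros(n_pops)
            coal_rates[0] = counts[0] * (counts[0] - 1) / 2.0 / ancestral_size
            mig_rate = 0.0
        else:
            sizes = np.asarray(pop_sizes, dtype=float)
            coal_rates = counts * (counts - 1) / 2.0 / sizes
            mig_rate = float(np.dot(counts, mig_out))
        total = float(coal_rates.sum()) + mig_rate
        if total <= 0:
            # isolated singleton lineages: jump to the split time
            t = max(t, split_generations)
            merged = True
            for a in active:
                deme[a] = 0
            continue
        wait = rng.exponential(1.0 / total)
        if not merged and t + wait > split_generations:
            t = split_generations
            merged = True
            for a in active:
                deme[a] = 0
            continue
        t += wait
        u = rng.uniform(0, total)
        if u < coal_rates.sum():
            # coalescence in the deme selected proportionally to its rate
            p = int(np.searchsorted(np.cumsum(coal_rates), u))
            members = [a for a in active if deme[a] == p]
            i, j = rng.choice(len(members), size=2, replace=False)
            a, b = members[int(i)], members[int(j)]
            active.remove(a)
            active.remove(b)
            parent[a] = nxt
            parent[b] = nxt
            time[nxt] = t
            deme[nxt] = p
            active.append(nxt)
            nxt += 1
        else:
            # migration event: pick lineage weighted by its outward rate
            weights = np.array([mig_out[deme[a]] for a in active])
            a = active[int(rng.choice(len(active), p=weights / weights.sum()))]
            row = migration[deme[a]]
            dest = int(rng.choice(n_pops, p=row / row.sum()))
            deme[a] = dest
    return parent, time


def branch_lengths(parent: np.ndarray, time: np.ndarray) -> np.ndarray:
    """Branch length above each non-root node (0 for the root)."""
    lens = np.zeros(len(parent))
    nz = parent >= 0
    lens[nz] = time[parent[nz]] - time[nz]
    return lens


def leaf_indicator(parent: np.ndarray, n: int) -> np.ndarray:
    """Boolean matrix (n_nodes, n): which leaves descend from each node.

    Relies on child indices being smaller than parent indices, which the
    simulators guarantee.
    """
    n_nodes = len(parent)
    ind = np.zeros((n_nodes, n), dtype=bool)
    ind[np.arange(n), np.arange(n)] = True
    for node in range(n_nodes):
        p = parent[node]
        if p >= 0:
            ind[p] |= ind[node]
    return ind


def pair_difference_matrix(
    mut_counts: np.ndarray, indicator: np.ndarray
) -> np.ndarray:
    """Pairwise difference matrix implied by per-branch mutation counts."""
    n = indicator.shape[1]
    d = np.zeros((n, n))
    for node in np.nonzero(mut_counts)[0]:
        a = indicator[node].astype(float)
        d += mut_counts[node] * np.not_equal.outer(a, a)
    return d


def segregating_and_pi_conditional(
    n: int, s: int, rng: np.random.Generator
) -> float:
    """Mean pairwise differences from ``s`` mutations dropped on a neutral
    genealogy with branches weighted by length (Hudson's fixed-S scheme)."""
    parent, time = sim_kingman(n, rng)
    lens = branch_lengths(parent, time)
    probs = lens / lens.sum()
    muts = rng.multinomial(s, probs)
    ind = leaf_indicator(parent, n)
    counts = ind.sum(axis=1)
    pairs = counts * (n - counts)
    total = float(np.dot(muts, pairs))
    return total / (n * (n - 1) / 2.0)


def haplotype_count_and_pi(
    n: int, theta: float, rng: np.random.Generator
) -> tuple[int, float]:
    """Number of distinct haplotypes and mean pairwise differences under the
    infinite-sites coalescent with per-locus ``theta`` (E[pair diff]=theta)."""
    parent, time = sim_kingman(n, rng)
    lens = branch_lengths(parent, time)
    total_len = float(lens.sum())
    n_mut = rng.poisson(theta / 2.0 * total_len)
    ind = leaf_indicator(parent, n)
    if n_mut == 0:
        return 1, 0.0
    branches = rng.choice(len(lens), size=n_mut, p=lens / lens.sum())
    muts = np.bincount(branches, minlength=len(lens))
    counts = ind.sum(axis=1)
    pairs = counts * (n - counts)
    pi = float(np.dot(muts, pairs)) / (n * (n - 1) / 2.0)
    # haplotype identity = the set of mutated branches above each leaf
    carriers = ind[muts > 0]  # (n_mutated_branches, n)
    k = len(np.unique(np.ascontiguousarray(carriers.T), axis=0))
    return k, pi


def total_tree_length(n: int, rng: np.random.Generator) -> float:
    parent, time = sim_kingman(n, rng)
    return float(branch_lengths(parent, time).sum())


def harmonic(n: int) -> float:
    """a_n = sum_{i=1}^{n} 1/i."""
    return float(sum(1.0 / i for i in range(1, n + 1)))


def harmonic2(n: int) -> float:
    return float(sum(1.0 / i**2 for i in range(1, n + 1)))


def log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
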