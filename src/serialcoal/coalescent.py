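"""Backward-in-time serial coalescent conditioned on the forward demography.

Lineages enter the genealogy at their sampling ages (heterochronous sampling),
coalesce within demes at the recorded local density, and trace parent demes
using the recorded forward migrant flows.  Before the expansion onset, all
surviving lineages coalesce in a constant-size ancestral population of N0
haploids at the origin deme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernel import STATUS_OK, simulate_tree_kernel
from .demography import ForwardDemography, SimulationError
from .world import ScenarioConfig

__all__ = [
    "GeneGenealogy",
    "CoalTimes",
    "backward_move_probs",
    "coalesce_in_deme",
    "simulate_genealogy",
    "mean_coal_times",
]


@dataclass
class GeneGenealogy:
    """Binary genealogy over serially sampled lineages.

    Nodes 0..n_leaves-1 are leaves; internal nodes follow in order of
    creation (children always have smaller ids than their parent).  Times are
    in generations before present; branch lengths are parent time minus child
    time.

    Attributes
    ----------
    n_leaves : int
    parent : ndarray of int, shape (2n-1,)
        Parent node id; -1 for the root (the last node).
    time : ndarray of int, shape (2n-1,)
        Node times in generations BP.
    deme : ndarray of int, shape (2n-1,)
        Land-deme index of each node (for internal nodes, the deme where the
        merging lineages were co-located; origin during the ancestral phase).
    leaf_labels : ndarray of str, shape (n,)
        Sample label ('modern'/'ancient') per leaf.
    positions : ndarray, shape (D, 2)
        (row, col) per land deme, for reporting.
    """

    n_leaves: int
    parent: np.ndarray = field(repr=False)
    time: np.ndarray = field(repr=False)
    deme: np.ndarray = field(repr=False)
    leaf_labels: np.ndarray = field(repr=False)
    positions: np.ndarray = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def leaf_ages(self) -> np.ndarray:
        return self.time[: self.n_leaves]

    def branch_length(self, node: int) -> int:
        p = self.parent[node]
        if p < 0:
            return 0
        return int(self.time[p] - self.time[node])

    def total_branch_length(self) -> float:
        nodes = np.arange(self.n_nodes - 1)
        return float((self.time[self.parent[nodes]] - self.time[nodes]).sum())

    def validate(self) -> None:
        """Check the structural tree invariants; raises on violation."""
        if self.parent[self.root] != -1:
            raise ValueError("root must have no parent")
        if (self.parent[: self.root] <= np.arange(self.root)).any():
            raise ValueError("every parent id must exceed its child's id")
        ptimes = self.time[self.parent[: self.root]]
        if (ptimes <= self.time[: self.root]).any():
            raise ValueError("parent times BP must strictly exceed child times")
        counts = np.bincount(self.parent[: self.root], minlength=self.n_nodes)
        if (counts[self.n_leaves :] != 2).any() or counts[: self.n_leaves].any():
            raise ValueError("internal nodes must have exactly two children")

    def pairwise_tmrca(self) -> np.ndarray:
        """Dense (n, n) matrix of pair MRCA times BP (0 on the diagonal)."""
        n = self.n_leaves
        # leaf sets per node, built bottom-up (children precede parents)
        below: list[list[int] | None] = [[i] for i in range(n)]
        below += [None] * (self.n_nodes - n)
        out = np.zeros((n, n), dtype=np.int64)
        pending: list[list[list[int]]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes):
            if v >= n:
                left, right = pending[v]
                for i in left:
                    for j in right:
                        out[i, j] = out[j, i] = self.time[v]
                below[v] = left + right
            p = self.parent[v]
            if p >= 0:
                pending[p].append(below[v])
        return out

    def to_newick(self, include_demes: bool = True) -> str:
        """Newick string with branch lengths in generations.

        Leaf names encode index, label and age; node comments carry deme
        coordinates when ``include_demes`` is set.
        """
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes - 1):
            children[self.parent[v]].append(v)

        def comment(v: int) -> str:
            if not include_demes:
                return ""
            r, c = self.positions[self.deme[v]]
            return f"[&deme={r}_{c}]"

        # iterative post-order assembly (trees are small, but avoid recursion)
        parts: dict[int, str] = {}
        stack = [(self.root, False)]
        while stack:
            v, done = stack.pop()
            if v < self.n_leaves:
                name = f"L{v}_{self.leaf_labels[v]}_{self.time[v]}"
                parts[v] = f"{name}{comment(v)}:{self.branch_length(v)}"
                continue
            if not done:
                stack.append((v, True))
                for c in children[v]:
                    stack.append((c, False))
            else:
                inner = ",".join(parts[c] for c in children[v])
                bl = f":{self.branch_length(v)}" if self.parent[v] >= 0 else ""
                parts[v] = f"({inner}){comment(v)}{bl}"
        return parts[self.root] + ";"


def backward_move_probs(
    demography: ForwardDemography, deme: int, t: int
) -> dict[int | str, float]:
    """Parent-deme distribution for a lineage in ``deme`` at forward generation t.

    Returns a mapping from source deme id (plus the key ``"stay"``) to
    probability.  P(source = neighbor i) = M(i->j, t) / N(j, t); the stay
    probability is the complement.  If the deme was uncolonized at t-1, the
    lineage must leave and probabilities over incoming neighbors are
    renormalized.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    world = demography.world
    j = int(deme)
    Nj = demography.densities[t, j]
    grown = demography.grown(t)
    m_t = float(demography.m_gen[t])
    w: dict[int | str, float] = {}
    wstay = (1.0 - m_t) * grown[j]
    total = wstay
    for k in range(4):
        i = int(world.neighbors[j, k])
        if i >= 0:
            wi = m_t * grown[i] / world.degree[i]
            if wi > 0.0:
                w[i] = wi
                total += wi
    if total <= 0.0:
        raise SimulationError(
            f"lineage stranded in deme {j} at generation {t}: no incoming "
            "migrants and zero density at the parent generation"
        )
    if Nj <= 0.0:
        raise SimulationError(f"deme {j} has zero density at generation {t}")
    probs: dict[int | str, float] = {i: wi / total for i, wi in w.items()}
    probs["stay"] = wstay / total
    return probs


def coalesce_in_deme(
    lineages: list[int], N: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Single-generation Wright-Fisher merges among co-located lineages.

    The number of merging pairs is Binomial(k*(k-1)/2, 1/N), truncated at
    floor(k/2); pairs are disjoint and chosen uniformly.
    """
    k = len(lineages)
    if N < 1:
        raise ValueError("N must be >= 1")
    if k < 2:
        return []
    npairs = min(int(rng.binomial(k * (k - 1) // 2, 1.0 / N)), k // 2)
    if npairs == 0:
        return []
    perm = rng.permutation(k)
    return [
        (lineages[perm[2 * p]], lineages[perm[2 * p + 1]]) for p in range(npairs)
    ]


def _leaf_arrays(scenario: ScenarioConfig):
    """Flatten the sampling scheme into per-leaf deme/age/label arrays."""
    world = scenario.world
    demes, ages, labels = [], [], []
    for g in scenario.sampling.groups:
        d = world.id_of(g.deme)
        demes += [d] * g.count
        ages += [g.age] * g.count
        labels += [g.label] * g.count
    return (
        np.asarray(demes, dtype=np.int64),
        np.asarray(ages, dtype=np.int64),
        np.asarray(labels),
    )


def simulate_genealogy(
    demography: ForwardDemography, scenario: ScenarioConfig, seed: int
) -> GeneGenealogy:
    """Simulate one genealogy of the sampled lineages.

    Iterates backward from the most recent sampling age; per generation,
    lineages whose age is reached are activated, co-located lineages coalesce
    at the local size max(1, round(N(d, t))), and survivors trace their parent
    demes.  Reaching forward generation 0 starts the ancestral phase: a
    constant-size panmictic population of N0 haploids at the origin.
    """
    leaf_deme, leaf_age, leaf_labels = _leaf_arrays(scenario)
    if leaf_deme.size < 2:
        raise ValueError("need at least two sampled lineages")
    ct = demography.colonization_time
    for d, a in zip(leaf_deme, leaf_age):
        t_samp = scenario.T - int(a)
        if ct[d] < 0 or ct[d] > t_samp:
            r, c = demography.world.positions[d]
            raise SimulationError(
                f"sampling deme ({r}, {c}) is not colonized at {a} generations BP"
            )
    status, parent, node_time, node_deme = simulate_tree_kernel(
        int(seed) & 0x7FFFFFFF,
        scenario.T,
        demography.densities,
        demography.world.neighbors,
        demography.world.degree,
        float(scenario.r),
        demography.K_gen,
        demography.m_gen,
        np.int64(demography.world.origin_id),
        np.int64(scenario.N0),
        leaf_deme,
        leaf_age,
    )
    if status != STATUS_OK:
        raise SimulationError("lineage stranded before colonization")
    return GeneGenealogy(
        n_leaves=leaf_deme.size,
        parent=parent,
        time=node_time,
        deme=node_deme,
        leaf_labels=leaf_labels,
        positions=demography.world.positions,
    )


@dataclass(frozen=True)
class CoalTimes:
    """Mean pairwise coalescent times, in generations BP.

    t1 averages over between-label pairs; t0_mod / t0_anc over within-label
    pairs; t0 pools all within-label pairs.  Within-times are None when a
    label has fewer than two leaves.
    """

    t0_mod: float | None
    t0_anc: float | None
    t0: float | None
    t1: float


def mean_coal_times(
    genealogy: GeneGenealogy, labels: tuple[str, str] = ("modern", "ancient")
) -> CoalTimes:
    """Average TMRCA within and between the two sample labels."""
    lab = genealogy.leaf_labels
    mod_label, anc_label = labels
    is_mod = (lab == mod_label).astype(np.int64)
    is_anc = (lab == anc_label).astype(np.int64)
    if is_mod.sum() + is_anc.sum() != genealogy.n_leaves:
        raise ValueError("every leaf must carry one of the two labels")
    if is_mod.sum() == 0 or is_anc.sum() == 0:
        raise ValueError("both labels must be present")

    n_nodes = genealogy.n_nodes
    cmod = np.zeros(n_nodes, dtype=np.int64)
    canc = np.zeros(n_nodes, dtype=np.int64)
    cmod[: genealogy.n_leaves] = is_mod
    canc[: genealogy.n_leaves] = is_anc
    s1 = s0m = s0a = 0.0
    n1 = n0m = n0a = 0
    # push each node's label counts into its parent; the cross products with
    # the counts already accumulated there are exactly the pairs whose MRCA
    # is that parent (children always precede parents in id order)
    for v in range(n_nodes - 1):
        p = genealogy.parent[v]
        tp = float(genealogy.time[p])
        cross_mm = cmod[v] * cmod[p]
        cross_aa = canc[v] * canc[p]
        cross_ma = cmod[v] * canc[p] + canc[v] * cmod[p]
        s0m += tp * cross_mm
        n0m += cross_mm
        s0a += tp * cross_aa
        n0a += cross_aa
        s1 += tp * cross_ma
        n1 += cross_ma
        cmod[p] += cmod[v]
        canc[p] += canc[v]
    t0_mod = s0m / n0m if n0m else None
    t0_anc = s0a / n0a if n0a else None
    t0 = (s0m + s0a) / (n0m + n0a) if (n0m + n0a) else None
    return CoalTimes(t0_mod=t0_mod, t0_anc=t0_anc, t0=t0, t1=s1 / n1)
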