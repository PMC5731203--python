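"""Numba kernel for the backward serial-coalescent simulation.

The kernel walks backward one generation at a time.  Lineages sitting at
forward generation t coalesce within their deme (Wright-Fisher single
generation rule at the local size), then each picks its parent deme with
probabilities proportional to the forward flows into its deme: weight
(1-m)*G(j) to stay and m*G(i)/deg(i) per incoming neighbor i, where G is the
post-growth density at t-1.  These weights sum to N(j, t) exactly, so the
normalized probabilities equal M(i->j, t)/N(j, t).  Once forward generation 0
is reached, all surviving lineages coalesce in a constant-size panmictic
population of N0 haploids at the origin.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_STRANDED = 1


@njit(cache=True)
def simulate_tree_kernel(
    seed,
    T,
    dens,  # (T+1, D) float64 post-migration densities
    nbrs,  # (D, 4) int32, -1 padded
    deg,  # (D,) int32
    r,  # float64 logistic growth rate
    K_gen,  # (T+1,) float64
    m_gen,  # (T+1,) float64
    origin,  # int64 origin deme id
    N0,  # int64 ancestral haploid size
    leaf_deme,  # (n,) int64 deme ids
    leaf_age,  # (n,) int64 ages in generations BP (all < T)
):
    np.random.seed(seed)
    n = leaf_deme.shape[0]
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, np.int64)
    node_time = np.zeros(n_nodes, np.int64)
    node_deme = np.full(n_nodes, -1, np.int64)
    for i in range(n):
        node_time[i] = leaf_age[i]
        node_deme[i] = leaf_deme[i]
    next_node = n

    act_node = np.empty(n, np.int64)
    act_deme = np.empty(n, np.int64)
    n_act = 0
    order = np.argsort(leaf_age)
    ptr = 0

    memb = np.empty(n, np.int64)
    wn = np.empty(4, np.float64)
    processed = np.empty(n, np.uint8)

    for b in range(T):
        t = T - b  # forward generation of the active lineages
        while ptr < n and leaf_age[order[ptr]] == b:
            i = order[ptr]
            act_node[n_act] = i
            act_deme[n_act] = leaf_deme[i]
            n_act += 1
            ptr += 1
        if n_act == 0:
            continue
        if ptr >= n and n_act == 1:
            break  # root found before the expansion onset

        # ---- coalescence within demes at local size max(1, round(N(d, t)))
        if n_act >= 2:
            for a in range(n_act):
                processed[a] = 0
            for a in range(n_act):
                if processed[a] == 1:
                    continue
                d0 = act_deme[a]
                mcount = 0
                for a2 in range(a, n_act):
                    if processed[a2] == 0 and act_deme[a2] == d0:
                        memb[mcount] = a2
                        mcount += 1
                        processed[a2] = 1
                if mcount < 2:
                    continue
                Ni = int(dens[t, d0] + 0.5)  # round; densities are >= 0
                if Ni < 1:
                    Ni = 1
                npairs = np.random.binomial(mcount * (mcount - 1) // 2, 1.0 / Ni)
                if npairs > mcount // 2:
                    npairs = mcount // 2
                if npairs == 0:
                    continue
                # uniform disjoint pairs: Fisher-Yates shuffle, pair prefix
                for s in range(mcount - 1, 0, -1):
                    j3 = np.random.randint(0, s + 1)
                    tmp = memb[s]
                    memb[s] = memb[j3]
                    memb[j3] = tmp
                for p in range(npairs):
                    sa = memb[2 * p]
                    sb = memb[2 * p + 1]
                    nid = next_node
                    next_node += 1
                    parent[act_node[sa]] = nid
                    parent[act_node[sb]] = nid
                    node_time[nid] = b + 1  # parent generation, in BP
                    node_deme[nid] = d0
                    act_node[sa] = nid
                    act_node[sb] = -1
            # compact dead slots
            w = 0
            for a in range(n_act):
                if act_node[a] >= 0:
                    act_node[w] = act_node[a]
                    act_deme[w] = act_deme[a]
                    w += 1
            n_act = w
            if ptr >= n and n_act == 1:
                break

        # ---- backward moves to generation t-1
        m_t = m_gen[t]
        K_t = K_gen[t]
        for a in range(n_act):
            j = act_deme[a]
            Njm1 = dens[t - 1, j]
            Gj = Njm1 + r * Njm1 * (1.0 - Njm1 / K_t)
            if Gj < 0.0:
                Gj = 0.0
            wstay = (1.0 - m_t) * Gj
            total = wstay
            for k in range(4):
                ii = nbrs[j, k]
                if ii >= 0 and deg[ii] > 0:
                    Nim1 = dens[t - 1, ii]
                    Gi = Nim1 + r * Nim1 * (1.0 - Nim1 / K_t)
                    if Gi < 0.0:
                        Gi = 0.0
                    wn[k] = m_t * Gi / deg[ii]
                else:
                    wn[k] = 0.0
                total += wn[k]
            if total <= 0.0:
                return STATUS_STRANDED, parent, node_time, node_deme
            u = np.random.random() * total
            acc = wstay
            if u < acc:
                continue
            for k in range(4):
                acc += wn[k]
                if u < acc:
                    act_deme[a] = nbrs[j, k]
                    break

    # ---- ancestral phase: constant-size N0 panmictic population at the origin
    b = T
    while n_act > 1 or ptr < n:
        while ptr < n and leaf_age[order[ptr]] <= b:
            i = order[ptr]
            act_node[n_act] = i
            act_deme[n_act] = origin
            n_act += 1
            ptr += 1
        if n_act >= 2:
            npairs = np.random.binomial(n_act * (n_act - 1) // 2, 1.0 / N0)
            if npairs > n_act // 2:
                npairs = n_act // 2
            if npairs > 0:
                for s in range(n_act - 1, 0, -1):
                    j3 = np.random.randint(0, s + 1)
                    tmp = act_node[s]
                    act_node[s] = act_node[j3]
                    act_node[j3] = tmp
                for p in range(npairs):
                    sa = 2 * p
                    sb = 2 * p + 1
                    nid = next_node
                    next_node += 1
                    parent[act_node[sa]] = nid
                    parent[act_node[sb]] = nid
                    node_time[nid] = b + 1
                    node_deme[nid] = origin
                    act_node[sa] = nid
                    act_node[sb] = -1
                w = 0
                for a in range(n_act):
                    if act_node[a] >= 0:
                        act_node[w] = act_node[a]
                        w += 1
                n_act = w
        b += 1

    return STATUS_OK, parent, node_time, node_deme
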