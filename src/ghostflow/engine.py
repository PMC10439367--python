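"""Compiled single-site structured-coalescent engine.

Simulates unlinked biallelic SNPs one independent genealogy at a time:
a standard exponential-rates (Gillespie) structured coalescent over the
four scheduled populations, with one mutation per genealogy placed
uniformly along total branch length (Hudson's fixed-segregating-sites
convention) and rejection of realizations below the ascertainment MAF.

The whole per-dataset loop runs inside numba-compiled code; msprime,
driven from the identical event schedule, serves as the distributional
cross-check in the test suite (see tests).  Times are generations,
sizes diploid, so the pairwise coalescence rate within a population of
size N is 1/(2N) per generation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["simulate_dataset_haplotypes", "simulate_branch_stats"]

# status codes returned by the kernels
OK = 0
ASCERTAINMENT_FAILURE = 1

_N_POPS = 4


@njit(cache=True)
def _sim_genealogy(sizes0, mig0, ev_time, ev_kind, ev_i, ev_j, ev_val,
                   pop0, node_time, node_parent, sizes, mig, act_node,
                   act_pop, kpop):
    """One genealogy; fills node_time/node_parent, returns node count."""
    n_hap = pop0.shape[0]
    for i in range(_N_POPS):
        sizes[i] = sizes0[i]
        for j in range(_N_POPS):
            mig[i, j] = mig0[i, j]
        kpop[i] = 0
    for s in range(n_hap):
        act_node[s] = s
        act_pop[s] = pop0[s]
        kpop[pop0[s]] += 1
        node_time[s] = 0.0
        node_parent[s] = -1
    n_act = n_hap
    next_node = n_hap
    t = 0.0
    ev_ptr = 0
    n_ev = ev_time.shape[0]

    while n_act > 1:
        # total coalescence and migration rates in the current state
        coal = 0.0
        for p in range(_N_POPS):
            k = kpop[p]
            if k > 1:
                coal += k * (k - 1) * 0.25 / sizes[p]  # C(k,2)/(2N)
        migr = 0.0
        for p in range(_N_POPS):
            if kpop[p] > 0:
                mo = 0.0
                for q in range(_N_POPS):
                    mo += mig[p, q]
                migr += kpop[p] * mo
        tot = coal + migr
        t_ev = ev_time[ev_ptr] if ev_ptr < n_ev else np.inf
        if tot == 0.0 and ev_ptr >= n_ev:
            return -1  # lineages can never meet: malformed schedule
        if tot > 0.0:
            dt = np.random.exponential(1.0) / tot
        else:
            dt = np.inf
        if t + dt >= t_ev:
            # apply every scheduled event at this time, in schedule order
            t = t_ev
            while ev_ptr < n_ev and ev_time[ev_ptr] == t_ev:
                kind = ev_kind[ev_ptr]
                i = ev_i[ev_ptr]
                j = ev_j[ev_ptr]
                if kind == 0:  # size change
                    sizes[i] = ev_val[ev_ptr]
                elif kind == 1:  # migration rate change
                    mig[i, j] = ev_val[ev_ptr]
                elif kind == 2:  # move all lineages i -> j
                    for a in range(n_act):
                        if act_pop[a] == i:
                            act_pop[a] = j
                            kpop[i] -= 1
                            kpop[j] += 1
                else:  # admixture pulse i -> j with prob val
                    frac = ev_val[ev_ptr]
                    for a in range(n_act):
                        if act_pop[a] == i and np.random.random() < frac:
                            act_pop[a] = j
                            kpop[i] -= 1
                            kpop[j] += 1
                ev_ptr += 1
            continue
        t += dt
        u = np.random.random() * tot
        if u < coal:
            # choose population proportional to its coalescence rate
            acc = 0.0
            cp = _N_POPS - 1
            for p in range(_N_POPS):
                k = kpop[p]
                if k > 1:
                    acc += k * (k - 1) * 0.25 / sizes[p]
                    if u < acc:
                        cp = p
                        break
            # two distinct uniformly chosen lineages of cp
            k = kpop[cp]
            r1 = int(np.random.random() * k)
            r2 = int(np.random.random() * (k - 1))
            if r2 >= r1:
                r2 += 1
            a1 = -1
            a2 = -1
            seen = 0
            for a in range(n_act):
                if act_pop[a] == cp:
                    if seen == r1:
                        a1 = a
                    if seen == r2:
                        a2 = a
                    seen += 1
            node_time[next_node] = t
            node_parent[act_node[a1]] = next_node
            node_parent[act_node[a2]] = next_node
            node_parent[next_node] = -1
            # replace a1 with parent; swap-delete a2
            act_node[a1] = next_node
            lo = a2
            act_node[lo] = act_node[n_act - 1]
            act_pop[lo] = act_pop[n_act - 1]
            n_act -= 1
            kpop[cp] -= 1
            next_node += 1
        else:
            u -= coal
            acc = 0.0
            sp = _N_POPS - 1
            for p in range(_N_POPS):
                if kpop[p] > 0:
                    mo = 0.0
                    for q in range(_N_POPS):
                        mo += mig[p, q]
                    acc += kpop[p] * mo
                    if u < acc:
                        sp = p
                        break
            # destination proportional to the row of the migration matrix
            mo = 0.0
            for q in range(_N_POPS):
                mo += mig[sp, q]
            v = np.random.random() * mo
            acc = 0.0
            dq = _N_POPS - 1
            for q in range(_N_POPS):
                acc += mig[sp, q]
                if v < acc:
                    dq = q
                    break
            r = int(np.random.random() * kpop[sp])
            seen = 0
            for a in range(n_act):
                if act_pop[a] == sp:
                    if seen == r:
                        act_pop[a] = dq
                        kpop[sp] -= 1
                        kpop[dq] += 1
                        break
                    seen += 1
    return next_node


@njit(cache=True)
def simulate_dataset_haplotypes(sizes0, mig0, ev_time, ev_kind, ev_i, ev_j,
                                ev_val, pop0, n_snps, min_minor, max_tries,
                                seed):
    """Simulate ``n_snps`` ascertained unlinked SNPs as 0/1 haplotypes.

    Each SNP is one independent genealogy carrying a single mutation
    placed uniformly along total branch length; realizations whose minor
    allele count among the sampled haplotypes is below ``min_minor`` are
    rejected and redrawn.  Returns ``(haplotypes, tries, status)`` with
    ``haplotypes`` of shape ``(n_hap, n_snps)``.
    """
    np.random.seed(seed)
    n_hap = pop0.shape[0]
    n_nodes = 2 * n_hap - 1
    node_time = np.empty(n_nodes, dtype=np.float64)
    node_parent = np.empty(n_nodes, dtype=np.int64)
    sizes = np.empty(_N_POPS, dtype=np.float64)
    mig = np.empty((_N_POPS, _N_POPS), dtype=np.float64)
    act_node = np.empty(n_hap, dtype=np.int64)
    act_pop = np.empty(n_hap, dtype=np.int64)
    kpop = np.empty(_N_POPS, dtype=np.int64)
    anc = np.empty(n_nodes, dtype=np.uint8)
    haps = np.zeros((n_hap, n_snps), dtype=np.int8)

    tries = 0
    got = 0
    while got < n_snps:
        tries += 1
        if tries > max_tries:
            return haps, tries, 1  # ascertainment failure
        nn = _sim_genealogy(sizes0, mig0, ev_time, ev_kind, ev_i, ev_j,
                            ev_val, pop0, node_time, node_parent, sizes,
                            mig, act_node, act_pop, kpop)
        if nn < 0:
            return haps, tries, 2  # malformed schedule
        # total branch length; root is node nn-1
        tot_len = 0.0
        for i in range(nn - 1):
            tot_len += node_time[node_parent[i]] - node_time[i]
        target = np.random.random() * tot_len
        acc = 0.0
        chosen = nn - 2
        for i in range(nn - 1):
            acc += node_time[node_parent[i]] - node_time[i]
            if target < acc:
                chosen = i
                break
        # mark the subtree below the mutated branch (parents have larger ids)
        for i in range(nn):
            anc[i] = 0
        anc[chosen] = 1
        for i in range(nn - 2, -1, -1):
            if i != chosen and node_parent[i] >= 0 and anc[node_parent[i]] == 1:
                anc[i] = 1
        k = 0
        for s in range(n_hap):
            k += anc[s]
        minor = k if k <= n_hap - k else n_hap - k
        if minor >= min_minor:
            for s in range(n_hap):
                haps[s, got] = anc[s]
            got += 1
    return haps, tries, 0


@njit(cache=True)
def simulate_ddrad_haplotypes(sizes0, mig0, ev_time, ev_kind, ev_i, ev_j,
                              ev_val, pop0, n_loci, mu_locus, min_minor,
                              seed):
    """Simulate a ddRAD-style panel: ``n_loci`` loci at fixed mutation rate.

    Each locus is an independent genealogy; the locus carries mutations
    with count Poisson(mu_locus * total branch length).  Polymorphic
    loci contribute one SNP (a uniformly chosen mutation, i.e. placed
    branch-length-weighted); SNPs below the ascertainment minor-allele
    count are dropped.  The number of returned SNPs is random — it
    carries the absolute-scale (theta) information of the panel.
    Returns ``(haplotypes buffer (n_hap, n_loci), n_kept, status)``.
    """
    np.random.seed(seed)
    n_hap = pop0.shape[0]
    n_nodes = 2 * n_hap - 1
    node_time = np.empty(n_nodes, dtype=np.float64)
    node_parent = np.empty(n_nodes, dtype=np.int64)
    sizes = np.empty(_N_POPS, dtype=np.float64)
    mig = np.empty((_N_POPS, _N_POPS), dtype=np.float64)
    act_node = np.empty(n_hap, dtype=np.int64)
    act_pop = np.empty(n_hap, dtype=np.int64)
    kpop = np.empty(_N_POPS, dtype=np.int64)
    anc = np.empty(n_nodes, dtype=np.uint8)
    haps = np.zeros((n_hap, n_loci), dtype=np.int8)

    kept = 0
    for _ in range(n_loci):
        nn = _sim_genealogy(sizes0, mig0, ev_time, ev_kind, ev_i, ev_j,
                            ev_val, pop0, node_time, node_parent, sizes,
                            mig, act_node, act_pop, kpop)
        if nn < 0:
            return haps, kept, 2  # malformed schedule
        tot_len = 0.0
        for i in range(nn - 1):
            tot_len += node_time[node_parent[i]] - node_time[i]
        n_mut = np.random.poisson(mu_locus * tot_len)
        if n_mut < 1:
            continue
        target = np.random.random() * tot_len
        acc = 0.0
        chosen = nn - 2
        for i in range(nn - 1):
            acc += node_time[node_parent[i]] - node_time[i]
            if target < acc:
                chosen = i
                break
        for i in range(nn):
            anc[i] = 0
        anc[chosen] = 1
        for i in range(nn - 2, -1, -1):
            if i != chosen and node_parent[i] >= 0 and anc[node_parent[i]] == 1:
                anc[i] = 1
        k = 0
        for s in range(n_hap):
            k += anc[s]
        minor = k if k <= n_hap - k else n_hap - k
        if minor >= min_minor:
            for s in range(n_hap):
                haps[s, kept] = anc[s]
            kept += 1
    return haps, kept, 0


@njit(cache=True)
def simulate_branch_stats(sizes0, mig0, ev_time, ev_kind, ev_i, ev_j, ev_val,
                          pop0, n_loci, seed):
    """Total branch length and TMRCA per independent genealogy.

    Used for mutation-count oracles: with per-locus mutation rate mu the
    segregating-site count of a locus is Poisson(mu * total_length).
    """
    np.random.seed(seed)
    n_hap = pop0.shape[0]
    n_nodes = 2 * n_hap - 1
    node_time = np.empty(n_nodes, dtype=np.float64)
    node_parent = np.empty(n_nodes, dtype=np.int64)
    sizes = np.empty(_N_POPS, dtype=np.float64)
    mig = np.empty((_N_POPS, _N_POPS), dtype=np.float64)
    act_node = np.empty(n_hap, dtype=np.int64)
    act_pop = np.empty(n_hap, dtype=np.int64)
    kpop = np.empty(_N_POPS, dtype=np.int64)
    total_len = np.empty(n_loci, dtype=np.float64)
    tmrca = np.empty(n_loci, dtype=np.float64)
    for rep in range(n_loci):
        nn = _sim_genealogy(sizes0, mig0, ev_time, ev_kind, ev_i, ev_j,
                            ev_val, pop0, node_time, node_parent, sizes,
                            mig, act_node, act_pop, kpop)
        if nn < 0:
            total_len[rep] = np.nan
            tmrca[rep] = np.nan
            continue
        s = 0.0
        for i in range(nn - 1):
            s += node_time[node_parent[i]] - node_time[i]
        total_len[rep] = s
        tmrca[rep] = node_time[nn - 1]
    return total_len, tmrca
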