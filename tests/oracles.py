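"""Independent reference implementations used only to check the package.

Everything here is deliberately written from first principles with a
different algorithmic approach than the implementation under test:
bitmask subset enumeration instead of pruned combination search, union-find
instead of graph traversal, and a generic phase-enumeration EM instead of
the closed-form double-heterozygote split.
"""

from itertools import product

import numpy as np


# -- graph oracles ----------------------------------------------------------


def union_find_components(nodes, edges):
    """Connected components via union-find; returns a set of frozensets."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return {frozenset(g) for g in groups.values()}


def min_dominating_set_size(nodes, edges):
    """Minimum dominating set cardinality by bitmask enumeration (<= ~16 nodes)."""
    nodes = sorted(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    m = len(nodes)
    nbr = [1 << i for i in range(m)]
    for a, b in edges:
        nbr[idx[a]] |= 1 << idx[b]
        nbr[idx[b]] |= 1 << idx[a]
    full = (1 << m) - 1
    best = m
    for mask in range(1, 1 << m):
        cov = 0
        s = mask
        while s:
            low = s & -s
            cov |= nbr[low.bit_length() - 1]
            s ^= low
        if cov == full:
            best = min(best, bin(mask).count("1"))
    return best


def is_dominating(members, edges, chosen):
    adj = {m: {m} for m in members}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    covered = set()
    for c in chosen:
        covered |= adj[c]
    return covered == set(members)


# -- LD oracles -------------------------------------------------------------


def pearson_r2(x, y):
    """Squared Pearson correlation of two allele columns."""
    r = np.corrcoef(np.asarray(x, float), np.asarray(y, float))[0, 1]
    return float(r * r)


def em_reference(tab, iters=5000):
    """Two-locus haplotype-frequency EM by explicit phase enumeration.

    State: frequency vector over haplotypes (0,0),(0,1),(1,0),(1,1).
    E step enumerates, for every genotype-pair class, all ordered pairs of
    haplotypes consistent with it and splits the class count by the current
    product frequencies.  Initialization at linkage equilibrium.
    """
    tab = np.asarray(tab, dtype=float)
    n = tab.sum()
    haps = [(0, 0), (0, 1), (1, 0), (1, 1)]
    # allele frequencies
    g1 = tab.sum(axis=1) @ np.array([0, 1, 2]) / (2 * n)
    g2 = tab.sum(axis=0) @ np.array([0, 1, 2]) / (2 * n)
    f = np.array([(1 - g1) * (1 - g2), (1 - g1) * g2, g1 * (1 - g2), g1 * g2])
    for _ in range(iters):
        expected = np.zeros(4)
        for a in range(3):
            for b in range(3):
                if tab[a, b] == 0:
                    continue
                weights = {}
                total = 0.0
                for h1, h2 in product(range(4), repeat=2):
                    if (
                        haps[h1][0] + haps[h2][0] == a
                        and haps[h1][1] + haps[h2][1] == b
                    ):
                        w = f[h1] * f[h2]
                        weights[(h1, h2)] = w
                        total += w
                if total == 0:
                    continue
                for (h1, h2), w in weights.items():
                    expected[h1] += tab[a, b] * w / total
                    expected[h2] += tab[a, b] * w / total
        f = expected / (2 * n)
    return f


def genotype_pair_loglik(tab, f):
    """Observed-data log-likelihood of a genotype-pair table under haplotype
    frequencies f (HWE random union of gametes)."""
    haps = [(0, 0), (0, 1), (1, 0), (1, 1)]
    ll = 0.0
    for a in range(3):
        for b in range(3):
            if tab[a][b] == 0:
                continue
            p = 0.0
            for h1, h2 in product(range(4), repeat=2):
                if haps[h1][0] + haps[h2][0] == a and haps[h1][1] + haps[h2][1] == b:
                    p += f[h1] * f[h2]
            ll += tab[a][b] * np.log(max(p, 1e-300))
    return ll


def brute_force_best_r2(target_col, panel_cols):
    """Max squared correlation of a target allele column against panel columns."""
    best = 0.0
    for c in panel_cols:
        if np.ptp(c) == 0:
            continue
        best = max(best, pearson_r2(target_col, c))
    return best


def linear_scan_min_floor(mafs, must, capacity, base, step):
    """Smallest floor (scanned upward) with <= capacity retained tags."""
    floor = base
    while True:
        kept = [m for m, mi in zip(mafs, must) if mi or m >= floor - 1e-12]
        if len(kept) <= capacity:
            return floor, len(kept)
        floor = round(floor + step, 12)
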