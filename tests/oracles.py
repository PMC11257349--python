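"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately written as plain loops over the definitions,
independent of the vectorized implementations under test.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import factorial

import numpy as np

HOM_REF, HET, HOM_ALT, HALF_CALL, MISSING = 0, 1, 2, 3, -1


# ---------------------------------------------------------------------------
# candidate-site criteria
# ---------------------------------------------------------------------------


def brute_candidate_mask(gt, species_members):
    """Per-site pass mask for the three fusion criteria, evaluated per species.

    ``species_members``: species -> (male column indices, female column
    indices).  A site passes when every species has zero heterozygous males,
    at least one heterozygous female, at most one homozygous female and at
    most one half-called female.
    """
    n_sites = gt.shape[0]
    out = np.zeros(n_sites, dtype=bool)
    for i in range(n_sites):
        ok = True
        for sp, (males, females) in species_members.items():
            het_m = sum(1 for j in males if gt[i, j] == HET)
            het_f = sum(1 for j in females if gt[i, j] == HET)
            hom_f = sum(1 for j in females if gt[i, j] in (HOM_REF, HOM_ALT))
            half_f = sum(1 for j in females if gt[i, j] == HALF_CALL)
            if het_m != 0 or het_f < 1 or hom_f > 1 or half_f > 1:
                ok = False
                break
        out[i] = ok
    return out


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (heterozygote-excess tail), exact rationals
# ---------------------------------------------------------------------------


def hwe_exact_excess_p_fraction(n_hom_ref: int, n_het: int, n_hom_alt: int) -> Fraction:
    """P(het >= observed) under the exact conditional HW distribution."""
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return Fraction(1)
    n_alt = 2 * n_hom_alt + n_het
    n_rare = min(n_alt, 2 * n - n_alt)
    n_common = 2 * n - n_rare
    if n_rare == 0:
        return Fraction(1)

    def prob(h: int) -> Fraction:
        a = (n_rare - h) // 2
        b = n - h - a
        num = Fraction(2**h) * factorial(n) * factorial(n_rare) * factorial(n_common)
        den = factorial(a) * factorial(h) * factorial(b) * factorial(2 * n)
        return num / den

    hs = range(n_rare % 2, n_rare + 1, 2)
    total = sum(prob(h) for h in hs)
    tail = sum(prob(h) for h in hs if h >= n_het)
    return tail / total


# ---------------------------------------------------------------------------
# windowed FST / dxy / pi
# ---------------------------------------------------------------------------


def brute_window_stats(gt_a, gt_b):
    """Window FST/dxy/pi by per-site loops over the definitions.

    Returns (fst, dxy, pi_a, pi_b, n_used) as plain floats, or NaNs when no
    site is usable.  Matches the documented estimator: per-site unbiased pi
    and dxy, window values are means over used sites, FST is the ratio of
    window means.
    """

    def counts(row):
        n = 0
        alt = 0
        for g in row:
            if g in (HOM_REF, HET, HOM_ALT):
                n += 2
                alt += {HOM_REF: 0, HET: 1, HOM_ALT: 2}[g]
        return n, alt

    pis_a, pis_b, dxys = [], [], []
    for i in range(gt_a.shape[0]):
        na, xa = counts(gt_a[i])
        nb, xb = counts(gt_b[i])
        if na < 2 or nb < 2:
            continue
        if (xa + xb) == 0 or (xa + xb) == (na + nb):
            continue
        pis_a.append(2 * xa * (na - xa) / (na * (na - 1)))
        pis_b.append(2 * xb * (nb - xb) / (nb * (nb - 1)))
        pa, pb = xa / na, xb / nb
        dxys.append(pa * (1 - pb) + pb * (1 - pa))
    if not dxys:
        return np.nan, np.nan, np.nan, np.nan, 0
    pi_a = sum(pis_a) / len(pis_a)
    pi_b = sum(pis_b) / len(pis_b)
    dxy = sum(dxys) / len(dxys)
    fst = 1 - 0.5 * (pi_a + pi_b) / dxy if dxy > 0 else np.nan
    return fst, dxy, pi_a, pi_b, len(dxys)


def hudson_fst_over_sites(hap_a, hap_b):
    """Plain Hudson FST over all sites from two haplotype matrices (sites x haps)."""
    na, nb = hap_a.shape[1], hap_b.shape[1]
    xa = hap_a.sum(axis=1)
    xb = hap_b.sum(axis=1)
    variable = (xa + xb > 0) & (xa + xb < na + nb)
    xa, xb = xa[variable], xb[variable]
    pi_a = 2 * xa * (na - xa) / (na * (na - 1))
    pi_b = 2 * xb * (nb - xb) / (nb * (nb - 1))
    pa, pb = xa / na, xb / nb
    dxy = pa * (1 - pb) + pb * (1 - pa)
    return 1 - 0.5 * (pi_a.mean() + pi_b.mean()) / dxy.mean()


# ---------------------------------------------------------------------------
# exhaustive minimum-evolution tree search
# ---------------------------------------------------------------------------


def _all_topologies(n_leaves: int):
    """All unrooted binary topologies as frozensets of leaf-set bipartitions.

    Built by sequential leaf insertion into every edge (1*3*5*... trees).
    Each topology is represented by its set of non-trivial splits, each split
    being the frozenset of leaf indices on one (canonical) side.
    """

    def edges_of(tree):
        return list(tree)

    # tree = list of edges; nodes: leaves 0..n-1, internal node ids >= HUB
    HUB = 1_000_000
    start = [(0, HUB), (1, HUB), (2, HUB)]
    trees = [start]
    for leaf in range(3, n_leaves):
        new_trees = []
        for t in trees:
            for e_idx, (u, v) in enumerate(edges_of(t)):
                node = HUB + 1000 * leaf + e_idx  # unique internal node id
                nt = [e for i, e in enumerate(t) if i != e_idx]
                nt += [(u, node), (v, node), (leaf, node)]
                new_trees.append(nt)
        trees = new_trees
    return trees


def _splits(tree, n_leaves):
    """Non-trivial leaf bipartitions of an edge-list tree (canonical sides)."""
    from collections import defaultdict

    adj = defaultdict(list)
    for u, v in tree:
        adj[u].append(v)
        adj[v].append(u)

    def side(u, v):
        seen = {v, u}
        stack = [u]
        leaves = set()
        while stack:
            x = stack.pop()
            if x < n_leaves:
                leaves.add(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return leaves

    out = set()
    for u, v in tree:
        s = side(u, v)
        if 2 <= len(s) <= n_leaves - 2:
            canon = frozenset(s) if 0 in s else frozenset(set(range(n_leaves)) - s)
            out.add(canon)
    return frozenset(out)


def min_evolution_topology(dist: np.ndarray):
    """Exhaustive OLS minimum-evolution search; returns the best topology's splits."""
    n = dist.shape[0]
    pairs = list(combinations(range(n), 2))
    d = np.array([dist[i, j] for i, j in pairs])
    best = None
    best_len = np.inf
    for tree in _all_topologies(n):
        edges = list(tree)
        from collections import defaultdict

        adj = defaultdict(list)
        for u, v in edges:
            adj[u].append(v)
            adj[v].append(u)

        def path_edges(a, b):
            prev = {a: None}
            stack = [a]
            while stack:
                x = stack.pop()
                if x == b:
                    break
                for y in adj[x]:
                    if y not in prev:
                        prev[y] = x
                        stack.append(y)
            out = []
            x = b
            while prev[x] is not None:
                out.append(frozenset((x, prev[x])))
                x = prev[x]
            return out

        edge_ids = {frozenset(e): k for k, e in enumerate(edges)}
        X = np.zeros((len(pairs), len(edges)))
        for r, (i, j) in enumerate(pairs):
            for e in path_edges(i, j):
                X[r, edge_ids[e]] = 1.0
        coef, *_ = np.linalg.lstsq(X, d, rcond=None)
        tree_len = coef.sum()
        if tree_len < best_len - 1e-12:
            best_len = tree_len
            best = _splits(tree, n)
    return best
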