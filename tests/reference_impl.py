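"""Independent brute-force reference implementations used as test oracles.

Everything here is written directly from the mathematical definitions
with plain Python loops, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math
from fractions import Fraction


def bh_step_up(p_values):
    """Benjamini-Hochberg adjusted p-values by literal step-up enumeration."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        candidate = min(1.0, p_values[i] * m / rank_from_top)
        running_min = min(running_min, candidate)
        adjusted[i] = running_min
    return adjusted


def hypergeom_sf_exact(k, n_draws, big_k, big_n):
    """P(X >= k) by exact rational summation of the hypergeometric pmf."""
    if k <= 0:
        return 1.0
    total = Fraction(0)
    denom = math.comb(big_n, n_draws)
    for x in range(k, min(n_draws, big_k) + 1):
        if n_draws - x > big_n - big_k:
            continue
        total += Fraction(math.comb(big_k, x) * math.comb(big_n - big_k, n_draws - x), denom)
    return float(total)


def gsea_es_brute(metrics, is_hit, weight_p=1.0):
    """Enrichment score by walking the ranked list index by index."""
    n = len(metrics)
    n_hits = sum(is_hit)
    total_w = sum(abs(m) ** weight_p for m, h in zip(metrics, is_hit) if h)
    running = 0.0
    best = 0.0
    for m, h in zip(metrics, is_hit):
        if h:
            running += (abs(m) ** weight_p / total_w) if total_w > 0 else 1.0 / n_hits
        else:
            running -= 1.0 / (n - n_hits)
        if abs(running) > abs(best):
            best = running
    return best


def mcl_reference(nodes, edges, inflation=1.5, evalue_cutoff=1e-5, prune=1e-6,
                  tol=1e-8, max_iter=200):
    """Dense-matrix Markov clustering with explicit loops.

    ``edges`` is an iterable of (node_a, node_b, e_value). Returns the
    partition as a set of frozensets.
    """
    nodes = sorted(set(nodes))
    idx = {n: i for i, n in enumerate(nodes)}
    k = len(nodes)
    w = [[0.0] * k for _ in range(k)]
    for a, b, ev in edges:
        if ev > evalue_cutoff or a == b:
            continue
        weight = min(-math.log10(max(ev, 1e-300)), 200.0)
        i, j = idx[a], idx[b]
        w[i][j] = max(w[i][j], weight)
        w[j][i] = max(w[j][i], weight)
    for i in range(k):
        incident = max(w[i][j] for j in range(k)) if k else 0.0
        w[i][i] = incident if incident > 0 else 1.0
    # column-stochastic start
    m = [[0.0] * k for _ in range(k)]
    for j in range(k):
        colsum = sum(w[i][j] for i in range(k))
        for i in range(k):
            m[i][j] = w[i][j] / colsum
    for _ in range(max_iter):
        sq = [[sum(m[i][l] * m[l][j] for l in range(k)) for j in range(k)] for i in range(k)]
        infl = [[sq[i][j] ** inflation for j in range(k)] for i in range(k)]
        for i in range(k):
            for j in range(k):
                if infl[i][j] < prune:
                    infl[i][j] = 0.0
        for j in range(k):
            colsum = sum(infl[i][j] for i in range(k))
            if colsum == 0.0:
                infl[j][j] = 1.0
                colsum = 1.0
            for i in range(k):
                infl[i][j] /= colsum
        diff = max(abs(infl[i][j] - m[i][j]) for i in range(k) for j in range(k))
        m = infl
        if diff < tol:
            break
    # connected components of the (symmetrized) support
    seen = [False] * k
    clusters = set()
    for start in range(k):
        if seen[start]:
            continue
        stack = [start]
        comp = []
        seen[start] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in range(k):
                if not seen[v] and (m[u][v] > prune or m[v][u] > prune):
                    seen[v] = True
                    stack.append(v)
        clusters.add(frozenset(nodes[i] for i in comp))
    return clusters
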