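"""Independent brute-force reference implementations used only by tests.

Each oracle is written from the definition, not from the package code, so a
disagreement localizes a defect in the implementation under test.
"""

from collections import deque
from itertools import combinations

import numpy as np


def triangles_through_edge(net, u, v):
    """Count triangles containing edge (u, v) by scanning all third nodes."""
    return sum(1 for w in net.nodes() if w not in (u, v)
               and net.has_edge(u, w) and net.has_edge(v, w))


def ecc_bruteforce(net, u, v):
    z = triangles_through_edge(net, u, v)
    denom = min(net.degree(u) - 1, net.degree(v) - 1)
    return 0.0 if denom <= 0 else (z + 1) / denom


def enumerate_shortest_paths(net, source, target):
    """All shortest paths source -> target via BFS predecessor expansion."""
    if source == target:
        return [[source]]
    dist = {source: 0}
    preds = {source: []}
    queue = deque([source])
    while queue:
        node = queue.popleft()
        for nbr in net[node]:
            if nbr not in dist:
                dist[nbr] = dist[node] + 1
                preds[nbr] = [node]
                queue.append(nbr)
            elif dist[nbr] == dist[node] + 1:
                preds[nbr].append(node)
    if target not in dist:
        return []
    paths = []

    def backtrack(node, suffix):
        if node == source:
            paths.append([source] + suffix)
            return
        for pred in preds[node]:
            backtrack(pred, [node] + suffix)

    backtrack(target, [])
    return paths


def betweenness_bruteforce(net):
    """BC(u) = sum over unordered pairs i != u != j of (paths through u) / paths."""
    scores = {n: 0.0 for n in net.nodes()}
    for i, j in combinations(net.nodes(), 2):
        paths = enumerate_shortest_paths(net, i, j)
        if not paths:
            continue
        for u in net.nodes():
            if u in (i, j):
                continue
            through = sum(1 for p in paths if u in p)
            scores[u] += through / len(paths)
    return scores


def harmonic_closeness_bruteforce(net):
    """CC(u) = sum of 1/d(u, v) by per-source BFS."""
    scores = {}
    for u in net.nodes():
        dist = {u: 0}
        queue = deque([u])
        while queue:
            node = queue.popleft()
            for nbr in net[node]:
                if nbr not in dist:
                    dist[nbr] = dist[node] + 1
                    queue.append(nbr)
        scores[u] = sum(1.0 / d for v, d in dist.items() if v != u)
    return scores


def expm_diag_taylor(adj, terms=60):
    """Diagonal of exp(A) by truncated power series sum_k A^k / k!."""
    n = adj.shape[0]
    total = np.eye(n)
    power = np.eye(n)
    fact = 1.0
    for k in range(1, terms + 1):
        power = power @ adj
        fact *= k
        total = total + power / fact
    return np.diag(total)


def dcor_bruteforce(x, y):
    """Distance correlation by explicit O(m^2) loops over the definition."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    m = len(x)

    def centered(v):
        d = np.empty((m, m))
        for i in range(m):
            for j in range(m):
                d[i, j] = abs(v[i] - v[j])
        row = d.mean(axis=1)
        col = d.mean(axis=0)
        grand = d.mean()
        c = np.empty((m, m))
        for i in range(m):
            for j in range(m):
                c[i, j] = d[i, j] - row[i] - col[j] + grand
        return c

    ax, ay = centered(x), centered(y)
    dcov2 = (ax * ay).mean()
    dvx = (ax * ax).mean()
    dvy = (ay * ay).mean()
    if dvx <= 0 or dvy <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvx * dvy)))


def auc_pair_counting(scores, labels):
    """Mann-Whitney AUC: fraction of positive-negative pairs ranked correctly (ties 1/2)."""
    pos = [scores[n] for n in scores if labels[n] == 1]
    neg = [scores[n] for n in scores if labels[n] == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
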