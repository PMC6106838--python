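"""Independent brute-force oracles used to cross-check the implementation.

Kept deliberately naive: path enumeration by BFS layering + DFS, and matchings
by exhaustive recursion.  They never call the code paths they verify.
"""

from collections import deque


def brute_betweenness(net):
    """Betweenness by explicit enumeration of all shortest paths.

    Each unordered pair {s, t} contributes the fraction of its shortest paths
    passing through v; disconnected pairs contribute nothing.
    """
    adj = {v: sorted(net.neighbors(v)) for v in net.nodes}
    nodes = sorted(adj)
    b = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        dist = {s: 0}
        q = deque([s])
        while q:
            u = q.popleft()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        for t in nodes[i + 1 :]:
            if t not in dist:
                continue
            paths = []

            def dfs(u, path):
                if u == t:
                    paths.append(path)
                    return
                for v in adj[u]:
                    if dist.get(v) == dist[u] + 1 and dist[v] <= dist[t]:
                        dfs(v, path + [v])

            dfs(s, [s])
            for p in paths:
                for v in p[1:-1]:
                    b[v] += 1.0 / len(paths)
    return b


def brute_max_weight_matching(weights):
    """Maximum-weight one-to-one matching by exhaustive recursion.

    *weights* is a 2-D array-like; entries <= 0 are unmatchable.
    """
    n = len(weights)
    m = len(weights[0]) if n else 0

    best = 0.0

    def rec(i, used, total):
        nonlocal best
        if total > best:
            best = total
        if i == n:
            return
        rec(i + 1, used, total)  # leave row i unmatched
        for j in range(m):
            if j not in used and weights[i][j] > 0:
                rec(i + 1, used | {j}, total + weights[i][j])

    rec(0, frozenset(), 0.0)
    return best


def naive_dedupe_filter(candidates, min_size):
    """Set deduplication (first occurrence wins) followed by the size filter."""
    seen = []
    for c in candidates:
        fc = frozenset(c)
        if fc and fc not in seen:
            seen.append(fc)
    return {c for c in seen if len(c) >= min_size}
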