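"""Independent brute-force oracles used across the test suite.

Everything here is written as straight-line / nested-loop numpy with no
imports from the package's model code, so layer implementations are
checked against genuinely independent computations.
"""

import numpy as np


def lrelu(x, slope=1.0 / 3.0):
    return np.where(np.asarray(x, float) >= 0, x, slope * np.asarray(x, float))


def sig(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, float)))


def e2e_oracle(f, r, c, slope=1.0 / 3.0):
    """Quadruple-nested-loop edge-to-edge convolution.

    f: (d_in, n, n); r, c: (d_in, n, d_out) -> (d_out, n, n)
    """
    d_in, n, _ = f.shape
    d_out = r.shape[2]
    out = np.zeros((d_out, n, n))
    for b in range(d_out):
        for i in range(n):
            for j in range(n):
                acc = 0.0
                for a in range(d_in):
                    for k in range(n):
                        acc += r[a, k, b] * f[a, i, k] + c[a, k, b] * f[a, k, j]
                out[b, i, j] = lrelu(acc, slope)
    return out


def e2n_oracle(f, w, slope=1.0 / 3.0):
    """Triple-loop edge-to-node aggregation: (d_in, n, n) -> (n, d_out)."""
    d_in, n, _ = f.shape
    d_out = w.shape[2]
    out = np.zeros((n, d_out))
    for b in range(d_out):
        for i in range(n):
            acc = 0.0
            for a in range(d_in):
                for k in range(n):
                    acc += w[a, k, b] * f[a, i, k]
            out[i, b] = lrelu(acc, slope)
    return out


def gcn_oracle(x, a, w):
    """Dense matrix-product GCN: D̃^{-1/2} Ã D̃^{-1/2} X W."""
    n = a.shape[0]
    a_t = a + np.eye(n)
    d = np.diag(a_t.sum(axis=1) ** -0.5)
    return d @ a_t @ d @ x @ w


def attention_oracle(x, a, w0, w1, slope=1.0 / 3.0):
    return sig(gcn_oracle(lrelu(gcn_oracle(x, a, w0), slope), a, w1)).ravel()


def topk_oracle(scores, ratio):
    """Full-sort top-k selection; ties broken by lowest index."""
    n = len(scores)
    k = int(np.ceil(ratio * n))
    ranked = sorted(range(n), key=lambda i: (-scores[i], i))[:k]
    return np.array(sorted(ranked))


def readout_oracle(states):
    """states: list of (n_l, m) arrays -> sum_l [mean || max]."""
    z = None
    for x in states:
        part = np.concatenate([x.mean(axis=0), x.max(axis=0)])
        z = part if z is None else z + part
    return z


def model_oracle(g, params, n, d, slope=1.0 / 3.0, ratio=0.5, l_att=2,
                 n_e2e=2):
    """Monolithic straight-line forward pass (identity adjacency)."""
    f = g[np.newaxis]  # (1, n, n)
    for l in range(1, n_e2e + 1):
        f = e2e_oracle(f, params[f"e2e{l}_r"], params[f"e2e{l}_c"], slope)
    x = e2n_oracle(f, params["e2n_w"], slope)
    a = (sig(g) >= 0.5).astype(float)
    a = np.maximum(a, a.T)
    states = []
    for l in range(1, l_att + 1):
        s = attention_oracle(x, a, params[f"att{l}_W0"], params[f"att{l}_W1"], slope)
        keep = topk_oracle(s, ratio)
        x = x[keep] * (1.0 + s[keep])[:, None]
        a = a[np.ix_(keep, keep)]
        states.append(x)
    z = readout_oracle(states)
    h = z
    n_mlp = sum(1 for k in params if k.startswith("mlp") and k.endswith("_W"))
    for i in range(1, n_mlp + 1):
        h = h @ params[f"mlp{i}_W"] + params[f"mlp{i}_b"]
        if i < n_mlp:
            h = lrelu(h, slope)
    return float(h[0])


# -- graph-measure oracles ---------------------------------------------------

def all_shortest_paths_brute(b):
    """All geodesics per unordered pair by breadth-limited enumeration."""
    import itertools
    n = b.shape[0]
    # Floyd-Warshall distances
    dist = np.where(b > 0, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
    return dist


def betweenness_oracle(b):
    """Raw betweenness: fractional geodesic counts, each pair once (n <= 8)."""
    n = b.shape[0]
    dist = all_shortest_paths_brute(b)

    def count_paths(s, t):
        """(number of geodesics s->t, count passing through each node)."""
        if not np.isfinite(dist[s, t]):
            return 0, np.zeros(n)
        paths = []
        stack = [(s, [s])]
        target_len = int(dist[s, t])
        while stack:
            node, path = stack.pop()
            if node == t and len(path) - 1 == target_len:
                paths.append(path)
                continue
            if len(path) - 1 >= target_len:
                continue
            for nxt in range(n):
                if b[node, nxt] > 0 and dist[s, nxt] == len(path) and \
                        dist[s, nxt] + dist[nxt, t] == dist[s, t]:
                    stack.append((nxt, path + [nxt]))
        through = np.zeros(n)
        for p in paths:
            for v in p[1:-1]:
                through[v] += 1
        return len(paths), through

    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            total, through = count_paths(s, t)
            if total:
                bc += through / total
    return bc


def kcore_oracle(b):
    """Iterative pruning: repeatedly remove nodes of degree < k."""
    n = b.shape[0]
    core = np.zeros(n, dtype=int)
    for k in range(1, n + 1):
        alive = np.ones(n, dtype=bool)
        changed = True
        while changed:
            changed = False
            deg = (b[np.ix_(alive, alive)]).sum(axis=1)
            idx = np.flatnonzero(alive)
            for pos, node in enumerate(idx):
                if deg[pos] < k:
                    alive[node] = False
                    changed = True
        core[alive] = k
        if not alive.any():
            break
    return core


def subgraph_oracle(b, terms=30):
    """Truncated power series sum_m (B^m)_ii / m!."""
    n = b.shape[0]
    acc = np.eye(n)
    power = np.eye(n)
    fact = 1.0
    for m in range(1, terms + 1):
        power = power @ b
        fact *= m
        acc = acc + power / fact
    return np.diag(acc)
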