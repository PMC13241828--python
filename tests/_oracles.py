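"""Independent brute-force implementations of the graph metrics.

Deliberately naive (triple loops, hand-rolled Floyd-Warshall) so they share
no code path with the package implementations they check.
"""

import numpy as np


def clustering_bf(w):
    """Onnela clustering by explicit triple enumeration."""
    n = w.shape[0]
    wmax = w.max()
    out = np.zeros(n)
    if wmax <= 0:
        return out
    wn = w / wmax
    for i in range(n):
        k = int((w[i] > 0).sum())
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                total += (wn[i, j] * wn[j, h] * wn[h, i]) ** (1.0 / 3.0)
        out[i] = total / (k * (k - 1))
    return out


def _floyd_warshall(lengths):
    n = lengths.shape[0]
    d = np.where(lengths > 0, lengths, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def local_efficiency_bf(w):
    """Weighted local efficiency via neighbor-subgraph Floyd-Warshall."""
    n = w.shape[0]
    wmax = w.max()
    out = np.zeros(n)
    if wmax <= 0:
        return out
    wn = w / wmax
    for i in range(n):
        nbrs = np.flatnonzero(wn[i] > 0)
        m = nbrs.size
        if m < 2:
            continue
        sub = wn[np.ix_(nbrs, nbrs)]
        lengths = np.where(sub > 0, 1.0 / np.where(sub > 0, sub, 1.0), 0.0)
        d = _floyd_warshall(lengths)
        total = 0.0
        for a in range(m):
            for b in range(m):
                if a != b and np.isfinite(d[a, b]) and d[a, b] > 0:
                    total += 1.0 / d[a, b]
        out[i] = total / (m * (m - 1))
    return out


def participation_bf(w, modules):
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        k = w[i].sum()
        if k <= 0:
            continue
        s = 0.0
        for m in np.unique(modules):
            kim = w[i, modules == m].sum()
            s += (kim / k) ** 2
        out[i] = 1.0 - s
    return out
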