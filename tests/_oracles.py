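"""Independent brute-force oracles shared by the unit and acceptance
suites; deliberately written from the definitions, not from the
implementations they check."""

import numpy as np


def brute_force_waves(wf, windows, min_height, min_distance_ms):
    """Exhaustive peak scoring: strict local maxima above the height
    bound, greedy distance pruning from the tallest down, then the
    tallest survivor per latency window (earliest on ties)."""
    v, t = wf.values, wf.times_ms
    cand = [i for i in range(1, v.size - 1)
            if v[i] > v[i - 1] and v[i] > v[i + 1] and v[i] >= min_height]
    kept = []
    dt = t[1] - t[0]
    dist = max(1, int(round(min_distance_ms / dt)))
    for i in sorted(cand, key=lambda i: -v[i]):
        if all(abs(i - j) >= dist for j in kept):
            kept.append(i)
    out = {}
    for name, (lo, hi) in windows.items():
        inside = [i for i in kept if lo <= t[i] <= hi]
        pick = None if not inside else max(inside, key=lambda i: (v[i], -t[i]))
        out[name] = None if pick is None else (t[pick], v[pick])
    return out


def holm_brute(p):
    """Holm step-down from the definition: adj_(i) = max_{j<=i}
    min(1, (m-j+1) p_(j)) over the ascending order."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adj[idx] = running
    return adj


def bh_brute(p):
    """Benjamini–Hochberg step-up from the definition: adj_(i) =
    min_{j>=i} min(1, m p_(j) / j) over the ascending order."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, min(1.0, m * p[idx] / (rank + 1)))
        adj[idx] = running
    return adj
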