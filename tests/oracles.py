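"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's own code paths: run-length scans in
plain Python, BH from its textbook definition, path length by explicit
pairwise distances, hypergeometric tails by full enumeration.
"""

from __future__ import annotations

import itertools
import math


def bolt_runs_oracle(v, dt, theta, min_duration_s, merge_gap_s):
    """Run-length scan: returns [(start_idx, end_idx_exclusive), ...]."""
    n = len(v)
    runs = []
    i = 0
    while i < n:
        if v[i] > theta:
            j = i
            while j < n and v[j] > theta:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    merged = []
    for a, b in runs:
        if merged and (a - merged[-1][1]) * dt <= merge_gap_s + 1e-9:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged if (b - a) * dt >= min_duration_s - 1e-12]


def bh_oracle(p):
    """q_i = min_{j: p_j >= p_i} p_j * m / rank(p_j), capped at 1 — computed
    naively from the step-up definition."""
    m = len(p)
    indexed = sorted(range(m), key=lambda i: p[i])
    out = [0.0] * m
    running = math.inf
    for rank in range(m, 0, -1):
        i = indexed[rank - 1]
        running = min(running, p[i] * m / rank)
        out[i] = min(running, 1.0)
    return out


def path_length_oracle(x, y):
    """Total path length by explicit pairwise Euclidean distances."""
    total = 0.0
    for i in range(len(x) - 1):
        total += math.sqrt((x[i + 1] - x[i]) ** 2 + (y[i + 1] - y[i]) ** 2)
    return total


def hypergeom_tail_oracle(k, K, n, N):
    """P[X >= k] by enumerating all C(N, n) draws (tiny N only)."""
    universe = list(range(N))
    special = set(range(K))
    hits = 0
    total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(special.intersection(draw)) >= k:
            hits += 1
    return hits / total
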