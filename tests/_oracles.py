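"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle re-derives the expected result with explicit python loops or an
exhaustive search, deliberately sharing no code with the implementation path
it checks.
"""

import numpy as np


def naive_saccade_scan(velocity, acceleration, moving, t_ms, pad_ms=5, merge_ms=10):
    """Per-sample threshold scan + run merging + padding, all explicit loops."""
    n = t_ms.size
    flags = []
    for i in range(n):
        speed = (velocity[i, 0] ** 2 + velocity[i, 1] ** 2) ** 0.5
        acc = (acceleration[i, 0] ** 2 + acceleration[i, 1] ** 2) ** 0.5
        hit = acc > 1000.0
        if moving[i]:
            hit = hit or speed > 50.0
        else:
            hit = hit or speed > 15.0
        flags.append(hit)
    runs = []
    i = 0
    while i < n:
        if flags[i]:
            j = i
            while j + 1 < n and flags[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    merged = []
    for r in runs:
        if merged and (r[0] - merged[-1][1] - 1) < merge_ms:
            merged[-1][1] = r[1]
        else:
            merged.append(list(r))
    padded = [[max(0, s - pad_ms), min(n - 1, e + pad_ms)] for s, e in merged]
    final = []
    for r in padded:
        if final and r[0] <= final[-1][1] + 1:
            final[-1][1] = max(final[-1][1], r[1])
        else:
            final.append(list(r))
    return [(int(t_ms[s]), int(t_ms[e])) for s, e in final]


def bruteforce_masked_mean(values, valid):
    """Per-sample mean/SEM over valid entries with explicit loops."""
    n_trials, n_samples = values.shape
    mean = np.full(n_samples, np.nan)
    sem = np.full(n_samples, np.nan)
    for j in range(n_samples):
        col = [values[i, j] for i in range(n_trials) if valid[i, j]]
        if col:
            mean[j] = sum(col) / len(col)
        if len(col) >= 2:
            m = mean[j]
            var = sum((x - m) ** 2 for x in col) / (len(col) - 1)
            sem[j] = (var / len(col)) ** 0.5
    return mean, sem


def grid_search_oracle(T, y, n_grid=6):
    """Coarse exhaustive tau-grid search with nonnegative amplitudes solved by
    NNLS (the free baseline enters as a +/- column pair)."""
    from scipy.optimize import nnls

    taus = np.logspace(-3, 3, n_grid)
    best = np.inf
    for t1 in taus:
        for t2 in taus:
            if t1 > t2:
                continue
            M = np.column_stack(
                [1 - np.exp(-T / t1), 1 - np.exp(-T / t2), np.ones_like(T), -np.ones_like(T)]
            )
            coef, _ = nnls(M, y)
            sse = float(np.sum((M @ coef - y) ** 2))
            best = min(best, sse)
    return best
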