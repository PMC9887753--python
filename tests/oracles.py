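"""Independent reference implementations used only as test oracles.

These deliberately avoid the code paths (and scipy routines) they check.
"""

import numpy as np


def brute_force_peaks(values, prominence, distance):
    """From-definition peak scan: strict local maxima, height-priority distance
    pruning, then topographic prominence (walk each side to the first strictly
    higher sample; the key col is the minimum en route)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    maxima = [i for i in range(1, n - 1)
              if values[i] > values[i - 1] and values[i] > values[i + 1]]

    keep = []
    for i in sorted(maxima, key=lambda i: (-values[i], i)):
        if all(abs(i - k) >= distance for k in keep):
            keep.append(i)

    def prom(i):
        left_min = values[i]
        j = i - 1
        while j >= 0 and values[j] <= values[i]:
            left_min = min(left_min, values[j])
            j -= 1
        right_min = values[i]
        j = i + 1
        while j < n and values[j] <= values[i]:
            right_min = min(right_min, values[j])
            j += 1
        return values[i] - max(left_min, right_min)

    return sorted(i for i in keep if prom(i) >= prominence)


def sse_oracle_fit_k(t, y, k_lo=0.05, k_hi=50.0):
    """Exponential-decay rate by dense grid search + golden-section refinement,
    profiling (A, C) out by linear least squares at each k."""
    t = np.asarray(t) - t[0]
    y = np.asarray(y, dtype=float)

    def sse(k):
        X = np.column_stack([np.exp(-k * t), np.ones_like(t)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    grid = np.geomspace(k_lo, k_hi, 400)
    errs = [sse(k) for k in grid]
    i = int(np.argmin(errs))
    a, b = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    phi = (np.sqrt(5) - 1) / 2
    c, d = b - phi * (b - a), a + phi * (b - a)
    for _ in range(80):
        if sse(c) < sse(d):
            b, d = d, c
            c = b - phi * (b - a)
        else:
            a, c = c, d
            d = a + phi * (b - a)
    return (a + b) / 2
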