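"""Independent brute-force reference implementations used as test oracles.

Everything here is written with explicit loops and first-principles formulas,
deliberately sharing no code with the package's vectorized implementations.
"""

import math

import numpy as np


def brute_pearson(y_true, y_pred):
    t = [float(a) for a in y_true]
    p = [float(b) for b in y_pred]
    pairs = [(a, b) for a, b in zip(t, p)
             if not (math.isnan(a) or math.isnan(b))]
    if len(pairs) < 3:
        return float("nan")
    mt = sum(a for a, _ in pairs) / len(pairs)
    mp = sum(b for _, b in pairs) / len(pairs)
    num = sum((a - mt) * (b - mp) for a, b in pairs)
    dt = sum((a - mt) ** 2 for a, _ in pairs)
    dp = sum((b - mp) ** 2 for _, b in pairs)
    if dt == 0 or dp == 0:
        return float("nan")
    return num / math.sqrt(dt * dp)


def brute_nrmse(y_true, y_pred):
    pairs = [(float(a), float(b)) for a, b in zip(y_true, y_pred)
             if not (math.isnan(float(a)) or math.isnan(float(b)))]
    if not pairs:
        return float("nan")
    mse = sum((a - b) ** 2 for a, b in pairs) / len(pairs)
    lo = min(a for a, _ in pairs)
    hi = max(a for a, _ in pairs)
    if hi == lo:
        return float("nan")
    return math.sqrt(mse) / (hi - lo)


def brute_median(values):
    vals = sorted(float(v) for v in values)
    n = len(vals)
    if n == 0:
        return float("nan")
    mid = n // 2
    return vals[mid] if n % 2 else 0.5 * (vals[mid - 1] + vals[mid])


def brute_ranks(values):
    """Average ranks (1-based) with midrank ties."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_spearman(x, y):
    pairs = [(float(a), float(b)) for a, b in zip(x, y)
             if not (math.isnan(float(a)) or math.isnan(float(b)))]
    if len(pairs) < 3:
        return float("nan")
    rx = brute_ranks([a for a, _ in pairs])
    ry = brute_ranks([b for _, b in pairs])
    return brute_pearson(rx, ry)


def brute_ols(X, y):
    """Normal equations: beta = (X'X)^-1 X'y with a prepended intercept."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    A = np.hstack([np.ones((len(y), 1)), X])
    return np.linalg.solve(A.T @ A, A.T @ y)


def brute_aracne(mi, eps=0.0):
    """DPI triple scan over a dense MI matrix; returns kept edge index pairs.

    Marks, for every triple with all three edges present, the edge with
    strictly the smallest MI; removes all marked edges at the end.
    """
    k = mi.shape[0]
    present = set()
    for i in range(k):
        for j in range(i + 1, k):
            present.add((i, j))
    marked = set()
    for a in range(k):
        for b in range(a + 1, k):
            for c in range(b + 1, k):
                tri = [(a, b), (b, c), (a, c)]
                if not all(e in present for e in tri):
                    continue
                vals = [mi[e] for e in tri]
                smallest = min(range(3), key=lambda t: vals[t])
                others = [vals[t] for t in range(3) if t != smallest]
                if vals[smallest] < min(others) - eps:
                    marked.add(tri[smallest])
    return present - marked


def brute_nrd0(values):
    vals = [float(v) for v in values]
    n = len(vals)
    mean = sum(vals) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1)) if n > 1 else 0.0
    q75, q25 = np.percentile(vals, [75, 25])
    lo = min(sd, (q75 - q25) / 1.34)
    if lo == 0:
        lo = sd if sd > 0 else (abs(vals[0]) if vals[0] != 0 else 1.0)
    return 0.9 * lo * n ** (-0.2)


def brute_kde(values, grid):
    h = brute_nrd0(values)
    out = []
    for g in grid:
        total = 0.0
        for v in values:
            z = (g - v) / h
            total += math.exp(-0.5 * z * z)
        out.append(total / (len(values) * h * math.sqrt(2 * math.pi)))
    return out


def brute_fuzzy_predict(transcript_vectors, protein_train, test_values,
                        tau, alpha, min_window_samples=10, step_sd=0.1):
    """Explicit-loop fuzzy prediction for one test sample.

    transcript_vectors: list of (transcript training vector) in selection
    order; test_values: the matching transcript values of the test sample.
    Returns (value, status).
    """
    y_all = [float(v) for v in protein_train if not math.isnan(float(v))]
    train_mean = sum(y_all) / len(y_all)
    n = len(y_all)
    mean = sum(y_all) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in y_all) / (n - 1))
    if sd == 0:
        grid = [y_all[0]]
    else:
        step = step_sd * sd
        span = max(y_all) - min(y_all)
        n_cells = max(1, math.ceil(span / step - 1e-12))
        grid = [min(y_all) + step * (i + 0.5) for i in range(n_cells)]
    densities = []
    for x_vec, q in zip(transcript_vectors, test_values):
        if math.isnan(float(q)):
            continue
        pairs = [(float(x), float(y)) for x, y in zip(x_vec, protein_train)
                 if not (math.isnan(float(x)) or math.isnan(float(y)))]
        if len(pairs) < 2:
            continue
        xs = [x for x, _ in pairs]
        mx = sum(xs) / len(xs)
        sx = math.sqrt(sum((x - mx) ** 2 for x in xs) / (len(xs) - 1))
        if sx == 0:
            continue
        window = [y for x, y in pairs if abs(x - float(q)) <= tau * sx]
        if len(window) < min_window_samples:
            continue
        densities.append(brute_kde(window, grid))
    if not densities:
        return train_mean, "fallback_mean"
    lo, hi = 0, len(grid) - 1
    for dens in densities:
        above = [i for i, d in enumerate(dens) if d > alpha]
        if not above:
            return train_mean, "fallback_mean"
        lo = max(lo, above[0])
        hi = min(hi, above[-1])
    if lo > hi:
        return train_mean, "fallback_mean"
    best_i, best_m = None, -1.0
    for i in range(lo, hi + 1):
        m = min(dens[i] for dens in densities)
        if m > best_m:  # strict: ties keep the smallest grid value
            best_i, best_m = i, m
    return grid[best_i], "ok"
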