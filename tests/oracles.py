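"""Independent brute-force oracles used to cross-check the implementation.

Each function here recomputes a quantity by the most direct method available
— exhaustive scans, double loops, textbook formulas — sharing no code with
the package's own implementations.
"""

import numpy as np


def brute_force_peaks(times, values, min_height, min_prominence, min_separation):
    """Every sample higher than both neighbours, then filter by height,
    prominence and greedy tallest-first separation."""
    candidates = [
        i
        for i in range(1, len(values) - 1)
        if values[i] > values[i - 1] and values[i] > values[i + 1]
    ]

    def prominence(i):
        # on each side: lowest point between the peak and the nearest
        # higher sample (or the signal edge); base = the higher of the two
        left_min = values[i]
        base_left = None
        for j in range(i - 1, -1, -1):
            if values[j] > values[i]:
                break
            left_min = min(left_min, values[j])
        base_left = left_min
        right_min = values[i]
        for j in range(i + 1, len(values)):
            if values[j] > values[i]:
                break
            right_min = min(right_min, values[j])
        base_right = right_min
        return values[i] - max(base_left, base_right)

    kept = [
        i
        for i in candidates
        if values[i] >= min_height and prominence(i) >= min_prominence
    ]
    # greedy suppression, tallest first (earlier time wins ties)
    order = sorted(kept, key=lambda i: (-values[i], times[i]))
    selected = []
    for i in order:
        if all(abs(times[i] - times[j]) >= min_separation for j in selected):
            selected.append(i)
    return sorted(selected)


def brute_force_single_linkage(times, gap):
    """Exhaustive single-linkage: merge the two closest clusters while the
    minimum inter-cluster distance is <= gap."""
    clusters = [[t] for t in sorted(times)]
    while len(clusters) > 1:
        dists = [
            (min(abs(a - b) for a in clusters[i] for b in clusters[i + 1]), i)
            for i in range(len(clusters) - 1)
        ]
        d, i = min(dists)
        if d > gap:
            break
        clusters[i] = sorted(clusters[i] + clusters[i + 1])
        del clusters[i + 1]
    return [tuple(c) for c in clusters]


def brute_force_bray_curtis(x, y):
    """1 - 2a/(2a+b+c) on binary vectors, counted element by element."""
    a = b = c = 0
    for xi, yi in zip(x, y):
        if xi == 1 and yi == 1:
            a += 1
        elif xi == 1:
            b += 1
        elif yi == 1:
            c += 1
    if 2 * a + b + c == 0:
        raise ZeroDivisionError("both profiles empty")
    return 1.0 - 2.0 * a / (2 * a + b + c)


def pava(y):
    """Pool-adjacent-violators for non-decreasing isotonic regression,
    implemented with explicit block lists."""
    blocks = [[v] for v in y]
    means = [float(v) for v in y]
    i = 0
    while i < len(blocks) - 1:
        if means[i] > means[i + 1] + 1e-15:
            blocks[i] = blocks[i] + blocks[i + 1]
            means[i] = sum(blocks[i]) / len(blocks[i])
            del blocks[i + 1], means[i + 1]
            if i > 0:
                i -= 1
        else:
            i += 1
    out = []
    for block, mean in zip(blocks, means):
        out.extend([mean] * len(block))
    return np.array(out)


def normal_equations_r2(X, y):
    """Multiple-regression r^2 via an explicit normal-equations solve."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ yc)
    rss = float(np.sum((yc - Xc @ beta) ** 2))
    tss = float(yc @ yc)
    return 1.0 - rss / tss, beta


def kruskal_stress_oracle(d, D):
    """Stress-1 with its own PAVA, for cross-checking the minimiser."""
    order = np.lexsort((D, d))
    dhat = np.empty_like(D)
    dhat[order] = pava(D[order])
    denom = np.sum(D**2)
    return float(np.sqrt(np.sum((D - dhat) ** 2) / denom)) if denom > 0 else 0.0
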