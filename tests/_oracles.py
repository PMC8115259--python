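"""Independent brute-force / closed-form oracles used by the tests.

These deliberately avoid the package's optimized code paths: the MIC oracle
enumerates every admissible grid directly, the prediction oracle is a triple
loop, the prevalence oracle a per-ASV counting loop, and the BH oracle the
hand step-up rule.
"""

from itertools import combinations

import numpy as np
import scipy.stats


def brute_force_mic(x, y, alpha_exponent: float = 0.6) -> float:
    """Exhaustive MIC: every (rows x cols) grid with rows*cols <= B, both >= 2.

    Partitions are placed at gaps between distinct values; points sharing a
    value are inseparable (as in the package implementation).
    """
    x = scipy.stats.rankdata(np.asarray(x, float), method="average")
    y = scipy.stats.rankdata(np.asarray(y, float), method="average")
    n = len(x)
    b = max(n**alpha_exponent, 4.0)
    xo = np.argsort(x, kind="mergesort")
    yo = np.argsort(y, kind="mergesort")
    xs, ys = x[xo], y[yo]
    xgaps = [i for i in range(1, n) if xs[i] != xs[i - 1]]
    ygaps = [i for i in range(1, n) if ys[i] != ys[i - 1]]

    def labels(order, cuts):
        lab = np.empty(n, dtype=int)
        start = 0
        for r, c in enumerate((*cuts, n)):
            lab[order[start:c]] = r
            start = c
        return lab

    best = 0.0
    k = 2
    while 2 * k <= b:
        l_max = int(b / k)
        for ycuts in combinations(ygaps, k - 1):
            row_lab = labels(yo, ycuts)
            for l in range(2, l_max + 1):
                for xcuts in combinations(xgaps, l - 1):
                    col_lab = labels(xo, xcuts)
                    cont = np.zeros((k, l))
                    np.add.at(cont, (row_lab, col_lab), 1)
                    p = cont / n
                    pr = p.sum(axis=1, keepdims=True)
                    pc = p.sum(axis=0, keepdims=True)
                    nz = p > 0
                    mi = float((p[nz] * np.log2(p[nz] / (pr @ pc)[nz])).sum())
                    val = mi / np.log2(min(k, l))
                    if val > best:
                        best = val
        k += 1
    return min(best, 1.0)


def loop_prevalence(counts: np.ndarray) -> np.ndarray:
    """Per-ASV presence fraction by explicit counting."""
    n_asvs, n_samples = counts.shape
    out = np.zeros(n_asvs)
    for i in range(n_asvs):
        present = 0
        for j in range(n_samples):
            if counts[i, j] > 0:
                present += 1
        out[i] = present / n_samples
    return out


def loop_predict_metagenome(counts, ko_copies, ssu, normalize=True):
    """Triple-nested-loop KO prediction."""
    n_asvs, n_samples = counts.shape
    n_kos = ko_copies.shape[1]
    out = np.zeros((n_kos, n_samples))
    for k in range(n_kos):
        for j in range(n_samples):
            for a in range(n_asvs):
                c = counts[a, j]
                if normalize:
                    c = c / ssu[a]
                out[k, j] += c * ko_copies[a, k]
    return out


def stepup_bh(pvals):
    """Hand Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
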