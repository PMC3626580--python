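"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity from first principles (enumeration,
direct formula evaluation, closed forms) without calling the package
code paths it checks.
"""

from __future__ import annotations

import math

import numpy as np

_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


def duplex_score(a: str, b: str, pairs: list[tuple[int, int]], params) -> float:
    """Score one explicit pairing under the bundled parameter rules."""
    e = params.init
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        ga, gb = i2 - i1 - 1, j1 - j2 - 1
        if ga == 0 and gb == 0:
            e += params.stacks[((a[i1], b[j1]), (a[i2], b[j2]))]
        else:
            e += params.loop_penalty[ga + gb]
    return e


def brute_force_duplex(a: str, b: str, params) -> float | None:
    """Minimum duplex energy by exhaustive enumeration of every valid
    non-crossing antiparallel pairing (consecutive-gap cap included)."""
    n, m = len(a), len(b)
    max_loop = max(params.loop_penalty)
    starts = [(i, j) for i in range(n) for j in range(m) if (a[i], b[j]) in _PAIRS]
    if not starts:
        return None
    best = math.inf

    def extend(pairs: list[tuple[int, int]], energy: float) -> None:
        nonlocal best
        best = min(best, energy)
        i0, j0 = pairs[-1]
        for i in range(i0 + 1, min(n, i0 + max_loop + 2)):
            for j in range(max(0, j0 - max_loop - 1), j0):
                if (a[i], b[j]) not in _PAIRS:
                    continue
                ga, gb = i - i0 - 1, j0 - j - 1
                if ga == 0 and gb == 0:
                    step = params.stacks[((a[i0], b[j0]), (a[i], b[j]))]
                elif ga + gb <= max_loop:
                    step = params.loop_penalty[ga + gb]
                else:
                    continue
                extend(pairs + [(i, j)], energy + step)

    for start in starts:
        extend([start], params.init)
    return best


def sam_d_oracle(x_a: np.ndarray, x_b: np.ndarray, s0: float) -> tuple[float, float]:
    """Direct evaluation of the moderated two-sample statistic for one
    probe, written independently of the package's vectorized path."""
    na, nb = len(x_a), len(x_b)
    mean_a, mean_b = float(np.mean(x_a)), float(np.mean(x_b))
    ss = float(((x_a - mean_a) ** 2).sum() + ((x_b - mean_b) ** 2).sum())
    s = math.sqrt((1.0 / na + 1.0 / nb) * ss / (na + nb - 2))
    return (mean_b - mean_a) / (s + s0), s


def nearest_centroid_oracle(X_train, y_train, X_test, s0: float):
    """Plain standardized nearest-centroid classifier with empirical
    priors: argmin_k sum_i (x_i - xbar_ki)^2/(s_i+s0)^2 - 2 log pi_k."""
    classes = np.unique(y_train)
    n, p = X_train.shape
    cents = np.vstack([X_train[y_train == c].mean(axis=0) for c in classes])
    ss = np.zeros(p)
    for ci, c in enumerate(classes):
        ss += ((X_train[y_train == c] - cents[ci]) ** 2).sum(axis=0)
    s = np.sqrt(ss / (n - len(classes)))
    priors = np.array([(y_train == c).mean() for c in classes])
    out = []
    for x in X_test:
        scores = [
            (((x - cents[ci]) ** 2) / (s + s0) ** 2).sum() - 2 * math.log(priors[ci])
            for ci in range(len(classes))
        ]
        out.append(classes[int(np.argmin(scores))])
    return np.array(out)


def hypergeom_tail_oracle(k: int, M: int, K: int, N: int) -> float:
    """P[X >= k] for a hypergeometric(M, K, N) by direct summation."""
    total = 0.0
    for x in range(k, min(K, N) + 1):
        total += math.comb(K, x) * math.comb(M - K, N - x) / math.comb(M, N)
    return total


def enumerate_structures(seq: str, min_hairpin: int = 3):
    """All valid secondary structures (nested, canonical pairs, hairpin
    >= min_hairpin) of a short sequence, as sets of pairs."""

    def rec(i: int, j: int) -> list[frozenset]:
        if j - i <= min_hairpin:
            return [frozenset()]
        out = list(rec(i, j - 1))
        for k in range(i, j - min_hairpin):
            if (seq[k], seq[j]) in _PAIRS:
                for left in rec(i, k - 1) if k > i else [frozenset()]:
                    for inner in rec(k + 1, j - 1):
                        out.append(left | inner | {(k, j)})
        return out

    return rec(0, len(seq) - 1)
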