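"""Deliberately naive reference implementations used only as test oracles.

Every function here is a literal transcription of the defining formula,
written with plain Python loops, independent of the production code paths it
checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

ONE_SECOND_MIN = 1.0 / 60.0


def naive_proportion(n_count: int, n_words: int) -> float:
    return n_count / n_words


def naive_mean(values) -> float:
    total = 0.0
    for v in values:
        total += v
    return total / len(values)


def naive_isd(values, ddof: int = 1) -> float:
    m = naive_mean(values)
    acc = 0.0
    for v in values:
        acc += (v - m) ** 2
    return math.sqrt(acc / (len(values) - ddof))


def naive_mssd(values) -> float:
    acc = 0.0
    for i in range(len(values) - 1):
        acc += (values[i + 1] - values[i]) ** 2
    return acc / (len(values) - 1)


def naive_tamssd(values, times) -> float:
    gaps = []
    for i in range(len(times) - 1):
        gaps.append(max(times[i + 1] - times[i], ONE_SECOND_MIN))
    med = float(np.median(gaps))
    acc = 0.0
    for i in range(len(values) - 1):
        acc += (med / gaps[i]) * (values[i + 1] - values[i]) ** 2
    return acc / (len(values) - 1)


def spearman_d2(x, y) -> float:
    """Classic 1 - 6*sum(d^2)/(n(n^2-1)) formula; valid only without ties."""
    n = len(x)
    rx = {v: r for r, v in enumerate(sorted(x), start=1)}
    ry = {v: r for r, v in enumerate(sorted(y), start=1)}
    d2 = sum((rx[a] - ry[b]) ** 2 for a, b in zip(x, y))
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))


def partial_corr_matrix_inversion(x, y, controls) -> float:
    """Partial correlation of x, y given controls via the precision matrix."""
    data = np.column_stack([x, y, np.atleast_2d(controls).reshape(len(x), -1)])
    corr = np.corrcoef(data, rowvar=False)
    prec = np.linalg.inv(corr)
    return float(-prec[0, 1] / math.sqrt(prec[0, 0] * prec[1, 1]))


def mwu_exact_enumeration(a, b) -> tuple[float, float]:
    """(U1, two-tailed exact p) for untied samples, by full enumeration."""
    pooled = sorted(list(a) + list(b))
    assert len(set(pooled)) == len(pooled), "oracle requires untied data"
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    n1, n2 = len(a), len(b)
    mu = n1 * n2 / 2.0

    def u_of(ranks):
        return sum(ranks) - n1 * (n1 + 1) / 2.0

    u_obs = u_of([rank[v] for v in a])
    dev = abs(u_obs - mu)
    all_ranks = list(range(1, n1 + n2 + 1))
    hits = total = 0
    for combo in combinations(all_ranks, n1):
        total += 1
        if abs(u_of(combo) - mu) >= dev - 1e-12:
            hits += 1
    return u_obs, hits / total


def simulate_ar1(n: int, phi: float, sigma: float, rng: np.random.Generator):
    """Stationary AR(1), marginal SD sigma, lag-1 correlation phi."""
    z = np.empty(n)
    z[0] = rng.normal(0, sigma)
    innov = rng.normal(0, sigma * math.sqrt(1 - phi * phi), size=n - 1)
    for i in range(1, n):
        z[i] = phi * z[i - 1] + innov[i - 1]
    return z
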