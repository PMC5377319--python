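"""Independent brute-force oracles used by the test suite.

Deliberately written with plain Python loops, ``math`` and
``statistics`` — no shared code with the package implementation — so that
agreement between the two routes is evidence, not tautology.
"""

from __future__ import annotations

import itertools
import math
import statistics


def log2(x: float) -> float:
    return math.log(x, 2)


def brute_pair_sd(rq: dict[str, list[float]], a: str, b: str) -> float:
    """Sample SD of log2 ratios for one gene pair, direct loops."""
    ratios = [log2(x / y) for x, y in zip(rq[a], rq[b])]
    return statistics.stdev(ratios)


def brute_m_values(rq: dict[str, list[float]], genes: list[str]) -> dict[str, float]:
    out = {}
    for j in genes:
        sds = [brute_pair_sd(rq, j, k) for k in genes if k != j]
        out[j] = sum(sds) / len(sds)
    return out


def brute_stepwise(rq: dict[str, list[float]], genes: list[str]):
    """Stepwise exclusion with the documented tie rule (latest input order).

    Returns (ranking, m_trace, excluded).
    """
    remaining = list(genes)
    trace, excluded = [], []
    while len(remaining) > 2:
        ms = brute_m_values(rq, remaining)
        trace.append(dict(ms))
        worst = max(ms.values())
        tied = [g for g in remaining if worst - ms[g] <= 1e-12]
        drop = tied[-1]  # remaining preserves input order
        excluded.append(drop)
        remaining.remove(drop)
    trace.append(brute_m_values(rq, remaining))
    ranking = list(remaining) + list(reversed(excluded))
    return ranking, trace, excluded


def brute_nf(rq: dict[str, list[float]], genes: list[str], n: int) -> list[float]:
    """NF_n per sample as explicit product**(1/n)."""
    n_samples = len(next(iter(rq.values())))
    out = []
    for j in range(n_samples):
        prod = 1.0
        for g in genes[:n]:
            prod *= rq[g][j]
        out.append(prod ** (1.0 / n))
    return out


def brute_v_series(rq: dict[str, list[float]], ranking: list[str]):
    series = []
    for n in range(2, len(ranking)):
        nf_n = brute_nf(rq, ranking, n)
        nf_n1 = brute_nf(rq, ranking, n + 1)
        ratios = [log2(a / b) for a, b in zip(nf_n, nf_n1)]
        series.append((n, statistics.stdev(ratios)))
    return series


def brute_normfinder(y: dict[str, list[float]]) -> dict[str, float]:
    """Variance unmixing by explicit loops on the log2 matrix ``y``."""
    genes = list(y)
    G = len(genes)
    N = len(y[genes[0]])
    sample_means = [sum(y[g][j] for g in genes) / G for j in range(N)]
    s2 = {}
    for g in genes:
        centered = [y[g][j] - sample_means[j] for j in range(N)]
        s2[g] = statistics.variance(centered)
    total = G / (G - 1) * sum(s2.values())
    out = {}
    for g in genes:
        sigma2 = (s2[g] - total / G**2) * G / (G - 2)
        out[g] = math.sqrt(max(sigma2, 0.0))
    return out


def enumerate_overlap_probability(n: int, k_top: int, k_spec: int) -> float:
    """P(k_spec given items all inside a random k_top subset), by listing
    every subset."""
    items = list(range(n))
    wanted = set(range(k_spec))
    hits = total = 0
    for subset in itertools.combinations(items, k_top):
        total += 1
        if wanted <= set(subset):
            hits += 1
    return hits / total


def spearman_of_orders(order_a: list[str], order_b: list[str]) -> float:
    """Spearman rho between two rankings given as ordered lists."""
    rank_a = {g: i for i, g in enumerate(order_a)}
    rank_b = {g: i for i, g in enumerate(order_b)}
    genes = list(order_a)
    n = len(genes)
    d2 = sum((rank_a[g] - rank_b[g]) ** 2 for g in genes)
    return 1.0 - 6.0 * d2 / (n * (n**2 - 1))
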