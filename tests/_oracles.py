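"""Independent brute-force oracles shared by the test modules.

These deliberately avoid the library code paths (and scipy's ranking): ranks
are computed by explicit enumeration and the guarding optimum by a dense
argmax over the documented payoff formula.
"""

import math

import numpy as np


def brute_ranks(values):
    """Midranks by explicit pairwise counting."""
    values = list(values)
    ranks = []
    for v in values:
        below = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        ranks.append(below + (equal + 1) / 2.0)
    return ranks


def brute_kruskal_h(groups):
    """Kruskal-Wallis H from the rank-sum definition with tie correction."""
    flat = [v for g in groups for v in g]
    n = len(flat)
    ranks = brute_ranks(flat)
    idx = 0
    h = 0.0
    for g in groups:
        r = sum(ranks[idx : idx + len(g)])
        idx += len(g)
        h += r * r / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    ties = 0.0
    for v in set(flat):
        t = flat.count(v)
        ties += t**3 - t
    correction = 1.0 - ties / (n**3 - n)
    return h / correction if correction > 0 else 0.0


def brute_dunn_z(groups, i, j):
    """Dunn z statistic for one pair from explicit joint ranking."""
    flat = [v for g in groups for v in g]
    n = len(flat)
    ranks = brute_ranks(flat)
    bounds = np.cumsum([0] + [len(g) for g in groups])
    mean_i = np.mean(ranks[bounds[i] : bounds[i + 1]])
    mean_j = np.mean(ranks[bounds[j] : bounds[j + 1]])
    ties = sum(flat.count(v) ** 3 - flat.count(v) for v in set(flat))
    var = (n * (n + 1) / 12.0 - ties / (12.0 * (n - 1))) * (
        1.0 / len(groups[i]) + 1.0 / len(groups[j])
    )
    return (mean_i - mean_j) / math.sqrt(var)


def brute_force_optimum(params, n=200_001):
    """Dense-grid argmax of the documented payoff B(t) - C(t)."""
    t = np.linspace(0.0, params.t_max, n)
    net = (1.0 / params.alpha) * (1.0 - np.exp(-params.beta * t)) - (
        params.gamma / math.e
    ) * t
    return float(t[np.argmax(net)])
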