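"""Independent brute-force oracles used by unit and acceptance tests."""

import itertools

import numpy as np


def brute_force_link_cost(xy_a: np.ndarray, xy_b: np.ndarray,
                          max_dist: float) -> float:
    """Minimum of sum(d^2 over links) + max_dist^2 per unmatched point,
    over ALL partial one-to-one matchings with links <= max_dist.

    Exhaustive enumeration; only feasible for small point sets.
    """
    xy_a = np.asarray(xy_a, dtype=float).reshape(-1, 2)
    xy_b = np.asarray(xy_b, dtype=float).reshape(-1, 2)
    n, m = len(xy_a), len(xy_b)
    penalty = max_dist ** 2
    d2 = ((xy_a[:, None, :] - xy_b[None, :, :]) ** 2).sum(axis=2)
    best = (n + m) * penalty  # nothing linked
    a_indices = list(range(n))
    b_indices = list(range(m))
    for k in range(1, min(n, m) + 1):
        for a_sub in itertools.combinations(a_indices, k):
            for b_perm in itertools.permutations(b_indices, k):
                if any(d2[i, j] > penalty for i, j in zip(a_sub, b_perm)):
                    continue
                cost = sum(d2[i, j] for i, j in zip(a_sub, b_perm))
                cost += penalty * (n - k) + penalty * (m - k)
                best = min(best, cost)
    return best


def link_cost(xy_a: np.ndarray, xy_b: np.ndarray,
              links: list[tuple[int, int]], max_dist: float) -> float:
    """Objective value of a given link set under the same cost model."""
    xy_a = np.asarray(xy_a, dtype=float).reshape(-1, 2)
    xy_b = np.asarray(xy_b, dtype=float).reshape(-1, 2)
    penalty = max_dist ** 2
    cost = 0.0
    for i, j in links:
        cost += float(((xy_a[i] - xy_b[j]) ** 2).sum())
    cost += penalty * (len(xy_a) - len(links))
    cost += penalty * (len(xy_b) - len(links))
    return cost
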