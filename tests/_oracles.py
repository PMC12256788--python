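"""Independent brute-force oracles used by unit and acceptance tests.

Everything here is implemented directly from definitions (BFS closures,
exhaustive enumeration) without calling the package's query machinery, so the
tests compare two genuinely distinct computational routes.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def bfs_ancestors(parents: dict[str, set[str]], term: str) -> frozenset[str]:
    """Reflexive ancestor closure by breadth-first traversal of parent edges."""
    seen = {term}
    queue = deque([term])
    while queue:
        for p in parents[queue.popleft()]:
            if p not in seen:
                seen.add(p)
                queue.append(p)
    return frozenset(seen)


def brute_lin(parents: dict[str, set[str]], ic: dict[str, float],
              t1: str, t2: str) -> float:
    """Lin similarity via full common-ancestor enumeration."""
    common = bfs_ancestors(parents, t1) & bfs_ancestors(parents, t2)
    denom = ic[t1] + ic[t2]
    if denom <= 0:
        return 0.0
    return 2.0 * max(ic[t] for t in common) / denom


def brute_profile_sim(parents: dict[str, set[str]], ic: dict[str, float],
                      a: set[str], b: set[str]) -> float:
    """Symmetric best-match average via the full pairwise score matrix."""
    a_list, b_list = sorted(a), sorted(b)
    matrix = [[brute_lin(parents, ic, x, y) for y in b_list] for x in a_list]
    forward = sum(max(row) for row in matrix) / len(a_list)
    backward = sum(max(matrix[i][j] for i in range(len(a_list)))
                   for j in range(len(b_list))) / len(b_list)
    return 0.5 * (forward + backward)


def brute_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Pair-counting AUC: concordant pairs + half the ties."""
    wins = sum(1.0 for p in pos for q in neg if p > q)
    ties = sum(1.0 for p in pos for q in neg if p == q)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def exhaustive_youden(pos: np.ndarray, neg: np.ndarray,
                      thresholds: np.ndarray) -> tuple[float, float]:
    """Best (threshold, J) by direct evaluation at every candidate threshold,
    smallest threshold winning ties."""
    best_t, best_j = None, -np.inf
    for t in thresholds:
        sens = float((pos >= t).mean())
        spec = float((neg < t).mean())
        j = sens + spec - 1.0
        if j > best_j + 1e-9:
            best_t, best_j = t, j
    return float(best_t), float(best_j)


def random_dag_parents(rng: np.random.Generator, n_terms: int,
                       max_parents: int = 3) -> dict[str, set[str]]:
    """A random rooted DAG as a child -> parents map (edges to earlier nodes)."""
    ids = [f"T{i:03d}" for i in range(n_terms)]
    parents: dict[str, set[str]] = {ids[0]: set()}
    for i in range(1, n_terms):
        k = int(rng.integers(1, max_parents + 1))
        chosen = rng.choice(i, size=min(k, i), replace=False)
        parents[ids[i]] = {ids[int(j)] for j in chosen}
    return parents
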