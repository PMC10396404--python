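"""Independent oracles used by the test suite.

These are deliberately naive: an exhaustive path-enumeration d-separation
check (exponential but exact) and a closed-form covariance calculator for
linear-Gaussian structural models.  They share no code with the package
implementations they verify.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_dags(n: int):
    """All labelled DAGs on nodes 0..n-1.

    Each unordered pair independently gets: no edge, i->j, or j->i; cyclic
    orientations are discarded.
    """
    pairs = list(itertools.combinations(range(n), 2))
    for choice in itertools.product((0, 1, 2), repeat=len(pairs)):
        edges = []
        for (i, j), c in zip(pairs, choice):
            if c == 1:
                edges.append((i, j))
            elif c == 2:
                edges.append((j, i))
        if _is_acyclic(n, edges):
            yield edges


def _is_acyclic(n: int, edges) -> bool:
    children = {i: [] for i in range(n)}
    indeg = {i: 0 for i in range(n)}
    for u, v in edges:
        children[u].append(v)
        indeg[v] += 1
    stack = [i for i in range(n) if indeg[i] == 0]
    seen = 0
    while stack:
        u = stack.pop()
        seen += 1
        for v in children[u]:
            indeg[v] -= 1
            if indeg[v] == 0:
                stack.append(v)
    return seen == n


def random_dag(n: int, rng: np.random.Generator, p: float = 0.4):
    """A random DAG: random order, each forward pair an edge with prob p."""
    order = rng.permutation(n)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append((int(order[i]), int(order[j])))
    return edges


def dsep_path_oracle(n_nodes, edges, a, b, z) -> bool:
    """Brute-force d-separation: enumerate every simple undirected path from a
    to b and check each for blocking under the standard rules."""
    z = set(z)
    parents = {i: set() for i in range(n_nodes)}
    children = {i: set() for i in range(n_nodes)}
    for u, v in edges:
        children[u].add(v)
        parents[v].add(u)

    def descendants(x):
        out, stack = set(), [x]
        while stack:
            u = stack.pop()
            for v in children[u]:
                if v not in out:
                    out.add(v)
                    stack.append(v)
        return out

    desc = {i: descendants(i) for i in range(n_nodes)}

    def path_open(path) -> bool:
        for k in range(1, len(path) - 1):
            prev, mid, nxt = path[k - 1], path[k], path[k + 1]
            into_from_prev = mid in children[prev]
            into_from_next = mid in children[nxt]
            if into_from_prev and into_from_next:  # collider
                if mid not in z and not (desc[mid] & z):
                    return False
            else:  # chain or fork
                if mid in z:
                    return False
        return True

    # DFS over simple paths in the skeleton
    neighbors = {i: parents[i] | children[i] for i in range(n_nodes)}
    stack = [(a, [a])]
    while stack:
        node, path = stack.pop()
        if node == b:
            if path_open(path):
                return False
            continue
        for nb in neighbors[node]:
            if nb not in path:
                stack.append((nb, path + [nb]))
    return True


def implied_covariance(order, coefs, noise_vars) -> np.ndarray:
    """Closed-form covariance of a linear-Gaussian structural model.

    ``order`` is a topological node order; ``coefs[child][parent]`` the path
    coefficient; ``noise_vars[node]`` the residual variance.  Solves
    Sigma = (I - B)^-1 D (I - B)^-T.
    """
    idx = {v: i for i, v in enumerate(order)}
    k = len(order)
    B = np.zeros((k, k))
    D = np.zeros((k, k))
    for child, ps in coefs.items():
        for parent, c in ps.items():
            B[idx[child], idx[parent]] = c
    for v, s2 in noise_vars.items():
        D[idx[v], idx[v]] = s2
    ainv = np.linalg.inv(np.eye(k) - B)
    return ainv @ D @ ainv.T
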