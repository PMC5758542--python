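"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own code paths: the
modularity oracle counts edges directly from the edge list, the
partition enumerator generates restricted-growth strings, and the
Pearson oracle uses the textbook sum-of-products formula.
"""

from __future__ import annotations

import numpy as np
import pytest

from modgain.connectome import BinaryGraph


def edge_count_modularity(adj: np.ndarray, labels) -> float:
    """Brute-force Q: count edges within modules, endpoints per module."""
    labels = np.asarray(labels)
    iu, ju = np.nonzero(np.triu(adj, k=1))
    m = len(iu)
    if m == 0:
        raise ValueError("no edges")
    q = 0.0
    for mod in np.unique(labels):
        within = sum(1 for a, b in zip(iu, ju) if labels[a] == mod and labels[b] == mod)
        endpoints = sum(
            int(labels[a] == mod) + int(labels[b] == mod) for a, b in zip(iu, ju)
        )
        e_ii = within / m
        a_i = endpoints / (2 * m)
        q += e_ii - a_i**2
    return q


def all_set_partitions(n: int) -> np.ndarray:
    """All partitions of n items as restricted-growth label strings."""
    out: list[list[int]] = []

    def rec(prefix: list[int], mx: int) -> None:
        if len(prefix) == n:
            out.append(list(prefix))
            return
        for lab in range(mx + 2):
            rec(prefix + [lab], max(mx, lab))

    rec([], -1)
    return np.array(out)


def exhaustive_max_q(adj: np.ndarray, partitions: np.ndarray) -> float:
    """Maximum Q over every set partition, evaluated from the modularity matrix."""
    m = adj.sum() / 2
    k = adj.sum(axis=1)
    b = adj - np.outer(k, k) / (2 * m)
    same = partitions[:, :, None] == partitions[:, None, :]
    return float(((b[None] * same).sum(axis=(1, 2)) / (2 * m)).max())


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook sum-of-products Pearson correlation."""
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxy = (x * y).sum()
    sxx, syy = (x * x).sum(), (y * y).sum()
    return (n * sxy - sx * sy) / np.sqrt((n * sxx - sx**2) * (n * syy - sy**2))


def two_cliques_graph(clique_size: int = 3) -> tuple[BinaryGraph, np.ndarray]:
    """Two disconnected equal cliques; component labels returned alongside."""
    k = clique_size
    adj = np.zeros((2 * k, 2 * k), dtype=int)
    adj[:k, :k] = 1
    adj[k:, k:] = 1
    np.fill_diagonal(adj, 0)
    labels = np.repeat([0, 1], k)
    return BinaryGraph(adjacency=adj, cost=1.0), labels


@pytest.fixture(scope="session")
def small_partitions() -> dict[int, np.ndarray]:
    return {n: all_set_partitions(n) for n in range(2, 9)}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
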