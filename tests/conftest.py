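"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from meltforms import PeptideQuantMatrix
from meltforms.detect import SimilarityGraph


def set_partitions(items):
    """Yield every partition of *items* as a list of lists (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def modularity_oracle(weights: np.ndarray, partition: list[list[int]]) -> float:
    """Newman-Girvan weighted modularity computed directly from its formula.

    ``weights`` is a symmetric matrix of edge weights (diagonal ignored,
    NaN = absent edge).  Independent of igraph.
    """
    w = np.array(weights, dtype=float)
    np.fill_diagonal(w, 0.0)
    w = np.nan_to_num(w)
    two_m = w.sum()  # counts each edge twice
    strength = w.sum(axis=1)
    q = 0.0
    for block in partition:
        idx = np.array(block)
        e_c = w[np.ix_(idx, idx)].sum() / 2.0
        a_c = strength[idx].sum() / two_m
        q += e_c / (two_m / 2.0) - a_c**2
    return q


def best_partition_oracle(weights: np.ndarray) -> tuple[float, list[list[int]]]:
    """Exhaustive best-modularity partition for graphs with few vertices."""
    n = len(weights)
    assert n <= 8, "exhaustive enumeration only sensible for tiny graphs"
    best_q, best_p = -np.inf, None
    for part in set_partitions(range(n)):
        q = modularity_oracle(weights, part)
        if q > best_q:
            best_q, best_p = q, part
    return best_q, best_p


def graph_from_weights(weights: np.ndarray, gene: str = "G") -> SimilarityGraph:
    """Wrap a symmetric similarity matrix as a SimilarityGraph."""
    w = np.array(weights, dtype=float)
    n = len(w)
    np.fill_diagonal(w, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 / w - 1.0
    np.fill_diagonal(d, 0.0)
    return SimilarityGraph(
        gene=gene,
        peptide_ids=[f"{gene}_pep{i}" for i in range(n)],
        similarity=w,
        distance=d,
        n_valid=np.full((n, n), 1, dtype=int),
    )


def two_block_weights(sizes=(3, 3), intra=0.9, inter=0.1) -> np.ndarray:
    n = sum(sizes)
    w = np.full((n, n), inter)
    start = 0
    for s in sizes:
        w[start:start + s, start:start + s] = intra
        start += s
    np.fill_diagonal(w, 1.0)
    return w


@pytest.fixture
def paper_temps():
    return np.array([41.0, 44.0, 47.0, 50.0, 53.0, 56.0, 59.0, 63.0])


@pytest.fixture
def small_matrix():
    """3 peptides x 2 cell lines x 3 temperatures with one masked series."""
    temps = np.array([41.0, 50.0, 59.0])
    intensity = np.array(
        [
            [[200.0, 100.0, 50.0], [400.0, 200.0, 100.0]],
            [[40.0, 40.0, 40.0], [np.nan, 30.0, 20.0]],
            [[100.0, 60.0, 30.0], [90.0, 50.0, 25.0]],
        ]
    )
    return PeptideQuantMatrix(
        peptide_ids=["PEPA", "PEPB", "PEPC"],
        gene_symbols=[frozenset({"G1"}), frozenset({"G1"}), frozenset({"G1", "G2"})],
        intensity=intensity,
        temperatures=temps,
        cell_lines=["CL01", "CL02"],
    )


def make_gene_tensor(curves: dict[str, np.ndarray], temperatures, cell_lines=None,
                     gene: str = "G"):
    """FoldChangeTensor from per-peptide (N, K) curve arrays of one gene."""
    from meltforms import FoldChangeTensor

    ids = sorted(curves)
    x = np.stack([np.atleast_2d(curves[i]) for i in ids]).astype(float)
    n = x.shape[1]
    return FoldChangeTensor(
        ids=ids,
        x=x,
        temperatures=np.asarray(temperatures, dtype=float),
        cell_lines=cell_lines or [f"CL{i + 1:02d}" for i in range(n)],
        gene_symbols=[frozenset({gene}) for _ in ids],
    )
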