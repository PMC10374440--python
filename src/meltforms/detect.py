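"""Graph-based detection of functional proteoform groups.

The detector exploits that peptides arising from distinct proteoforms of one
gene (splice variants, cleavage products, PTM or interaction states) can melt
differently.  For every gene symbol a complete weighted graph is built over
its peptides; edge weights are similarities

    S_ij = 1 / (1 + d_ij)

derived from a weighted Euclidean distance between the two peptides' melting
curves across all cell lines,

    d_ij = sqrt( sum over valid (n, k) of (x_i - x_j)^2 * v / (N*K) ),

where v is the number of grid positions at which both peptides are
quantified.  Communities are found with the Leiden algorithm under the
modularity objective; a gene's communities are accepted as proteoform groups
only if the gene met the analysis criteria (>= 10 peptides, >= 2 peptides in
every covered cell line, peptide ambiguity ratio < 0.5), the partition
modularity exceeds Q > 1e-13 and each community is supported by >= 3
peptides.  Genes failing any gate keep a single unresolved group "<gene>_0".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np

from .data import (
    FoldChangeTensor,
    PeptideQuantMatrix,
    gene_ambiguity_ratio,
    normalize_per_temperature,
    to_fold_changes,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionParams",
    "SimilarityGraph",
    "ProteoformAssignment",
    "weighted_distance",
    "similarity",
    "build_gene_graph",
    "detect_communities",
    "partition_modularity",
    "meets_analysis_criteria",
    "assign_proteoform_groups",
    "detect_proteoforms",
    "summarize_proteoform_profiles",
    "assignments_to_frame",
]


@dataclass
class DetectionParams:
    """Acceptance thresholds and graph options for the detector.

    Defaults are the published operating point of the method.
    """

    min_gene_peptides: int = 10
    min_peptides_per_sample: int = 2
    min_group_peptides: int = 3
    q_threshold: float = 1e-13
    max_ambiguity: float = 0.5
    #: 'as_published' multiplies the summed squared differences by v/(N*K)
    #: (sparse overlaps shrink distances); 'unbiased' multiplies by (N*K)/v,
    #: completing the partial sum to the full grid.
    distance_scaling: str = "as_published"
    resolution: float = 1.0


@dataclass
class SimilarityGraph:
    """Complete weighted peptide graph for one gene."""

    gene: str
    peptide_ids: list[str]
    similarity: np.ndarray  # S_ij in (0, 1]; NaN where no valid comparison
    distance: np.ndarray  # d_ij >= 0
    n_valid: np.ndarray  # v_ij: valid paired comparisons

    @property
    def n_vertices(self) -> int:
        return len(self.peptide_ids)

    def to_igraph(self) -> ig.Graph:
        """Undirected igraph with a 'weight' attribute; NaN edges omitted."""
        n = self.n_vertices
        edges, weights = [], []
        for i in range(n):
            for j in range(i + 1, n):
                w = self.similarity[i, j]
                if np.isfinite(w):
                    edges.append((i, j))
                    weights.append(float(w))
        g = ig.Graph(n=n, edges=edges)
        g.es["weight"] = weights
        g.vs["name"] = self.peptide_ids
        return g


@dataclass
class ProteoformAssignment:
    """Accepted proteoform groups for one gene."""

    gene: str
    groups: list[tuple[str, frozenset[str]]]  # (proteoform_id, member peptides)
    modularity_q: float  # NaN when no community detection was run
    analyzed: bool
    unassigned_peptides: frozenset[str] = field(default_factory=frozenset)
    community_sizes: tuple[int, ...] = ()

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_of(self, peptide: str) -> str | None:
        for pid, members in self.groups:
            if peptide in members:
                return pid
        return None


# ---------------------------------------------------------------------------
# similarity graph construction
# ---------------------------------------------------------------------------

def weighted_distance(
    x_i: np.ndarray,
    x_j: np.ndarray,
    scaling: str = "as_published",
) -> float:
    """Weighted Euclidean distance between two melting profiles.

    Both arrays have shape (cell lines, temperatures) with NaN for missing.
    Returns NaN when the pair shares no valid position (v = 0).
    """
    xi = np.asarray(x_i, dtype=float)
    xj = np.asarray(x_j, dtype=float)
    if xi.shape != xj.shape:
        raise ValueError("profiles must share the same (cell line, temperature) grid")
    valid = np.isfinite(xi) & np.isfinite(xj)
    v = int(valid.sum())
    if v == 0:
        return float("nan")
    ss = float(np.sum((xi[valid] - xj[valid]) ** 2))
    nk = xi.size
    factor = v / nk if scaling == "as_published" else nk / v
    return float(np.sqrt(ss * factor))


def similarity(d: float) -> float:
    """Similarity S = 1 / (1 + d) of a non-negative curve distance."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    return 1.0 / (1.0 + d)


def _pairwise_distances(X: np.ndarray, scaling: str) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pairwise distances for X of shape (peptides, N*K).

    Returns (d, v) square matrices; d is NaN where v = 0.
    """
    V = np.isfinite(X)
    Xf = np.where(V, X, 0.0)
    Vf = V.astype(float)
    sq = Xf**2
    # sum over joint-valid t of (x_i - x_j)^2
    ss = sq @ Vf.T + Vf @ sq.T - 2.0 * (Xf @ Xf.T)
    np.clip(ss, 0.0, None, out=ss)
    v = Vf @ Vf.T
    nk = X.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        factor = v / nk if scaling == "as_published" else nk / v
        d = np.sqrt(ss * factor)
    d[v == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    return d, v.astype(int)


def build_gene_graph(
    gene: str,
    t: FoldChangeTensor,
    scaling: str = "as_published",
) -> SimilarityGraph:
    """Complete similarity graph over all of a gene's peptides."""
    idx = [i for i, g in enumerate(t.gene_symbols) if gene in g]
    if len(idx) < 2:
        raise ValueError(f"gene {gene!r} has fewer than 2 peptides; not graphable")
    X = t.x[idx].reshape(len(idx), -1)
    d, v = _pairwise_distances(X, scaling)
    if np.isnan(d[np.triu_indices(len(idx), k=1)]).any():
        logger.warning("gene %s: some peptide pairs share no valid values", gene)
    with np.errstate(invalid="ignore"):
        s = 1.0 / (1.0 + d)
    np.fill_diagonal(s, 1.0)
    return SimilarityGraph(
        gene=gene,
        peptide_ids=[t.ids[i] for i in idx],
        similarity=s,
        distance=d,
        n_valid=v,
    )


# ---------------------------------------------------------------------------
# community detection and acceptance
# ---------------------------------------------------------------------------

def detect_communities(
    g: SimilarityGraph,
    seed: int,
    resolution: float = 1.0,
) -> list[int]:
    """Leiden partition (modularity objective) of the similarity graph.

    Deterministic for a fixed seed; returns the community label of every
    vertex in graph order.
    """
    graph = g.to_igraph()
    part = leidenalg.find_partition(
        graph,
        leidenalg.ModularityVertexPartition
        if resolution == 1.0
        else leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        seed=int(seed),
        n_iterations=-1,  # iterate to convergence: stable and reproducible
        **({} if resolution == 1.0 else {"resolution_parameter": resolution}),
    )
    return list(part.membership)


def partition_modularity(g: SimilarityGraph, partition: list[int]) -> float:
    """Newman-Girvan weighted modularity Q of a vertex partition."""
    if len(partition) != g.n_vertices:
        raise ValueError("partition must cover every vertex of the graph")
    graph = g.to_igraph()
    return float(graph.modularity(partition, weights="weight"))


def meets_analysis_criteria(
    gene: str,
    t: FoldChangeTensor,
    params: DetectionParams | None = None,
) -> bool:
    """Gene-level gate for community detection.

    Requires >= ``min_gene_peptides`` peptides, >= ``min_peptides_per_sample``
    quantified peptides in every cell line where the gene is quantified at
    all, and a peptide ambiguity ratio below ``max_ambiguity``.
    """
    params = params or DetectionParams()
    idx = [i for i, g in enumerate(t.gene_symbols) if gene in g]
    if not idx:
        raise KeyError(f"gene symbol not found: {gene!r}")
    if len(idx) < params.min_gene_peptides:
        return False
    per_line = t.valid_mask[idx].any(axis=2).sum(axis=0)  # peptides per cell line
    covered = per_line > 0
    if not covered.any() or np.any(per_line[covered] < params.min_peptides_per_sample):
        return False
    if gene_ambiguity_ratio(gene, t) >= params.max_ambiguity:
        return False
    return True


def assign_proteoform_groups(
    gene: str,
    g: SimilarityGraph | None,
    partition: list[int] | None,
    analyzed: bool,
    params: DetectionParams | None = None,
    peptide_ids: list[str] | None = None,
) -> ProteoformAssignment:
    """Turn a community partition into named proteoform groups.

    A gene that was not analyzed (failed the gates) or whose partition
    modularity Q <= ``q_threshold`` keeps one unresolved group ``<gene>_0``
    containing all peptides.  Otherwise communities with >=
    ``min_group_peptides`` members become ``<gene>_1``, ``<gene>_2``, ...
    ordered by decreasing size (ties broken by lexicographically smallest
    member peptide); peptides of smaller communities are left unassigned and
    excluded from downstream profiles.
    """
    params = params or DetectionParams()
    if g is not None:
        peptide_ids = g.peptide_ids
    if peptide_ids is None:
        raise ValueError("need a graph or an explicit peptide list")

    if not analyzed or g is None or partition is None:
        return ProteoformAssignment(
            gene=gene,
            groups=[(f"{gene}_0", frozenset(peptide_ids))],
            modularity_q=float("nan"),
            analyzed=False,
        )

    q = partition_modularity(g, partition)
    comms: dict[int, list[str]] = {}
    for pep, c in zip(peptide_ids, partition):
        comms.setdefault(c, []).append(pep)
    sizes = tuple(sorted((len(m) for m in comms.values()), reverse=True))

    if q <= params.q_threshold:
        return ProteoformAssignment(
            gene=gene,
            groups=[(f"{gene}_0", frozenset(peptide_ids))],
            modularity_q=q,
            analyzed=True,
            community_sizes=sizes,
        )

    accepted = [m for m in comms.values() if len(m) >= params.min_group_peptides]
    accepted.sort(key=lambda m: (-len(m), min(m)))
    groups = [(f"{gene}_{r}", frozenset(m)) for r, m in enumerate(accepted, start=1)]
    assigned = set().union(*(m for _, m in groups)) if groups else set()
    return ProteoformAssignment(
        gene=gene,
        groups=groups,
        modularity_q=q,
        analyzed=True,
        unassigned_peptides=frozenset(set(peptide_ids) - assigned),
        community_sizes=sizes,
    )


def detect_proteoforms(
    t: FoldChangeTensor,
    seed: int,
    params: DetectionParams | None = None,
) -> dict[str, ProteoformAssignment]:
    """Run the full detector over every gene in the tensor."""
    params = params or DetectionParams()
    out: dict[str, ProteoformAssignment] = {}
    for gene in t.genes():
        idx = [i for i, g in enumerate(t.gene_symbols) if gene in g]
        peptide_ids = [t.ids[i] for i in idx]
        analyzed = len(idx) >= 2 and meets_analysis_criteria(gene, t, params)
        if not analyzed:
            out[gene] = assign_proteoform_groups(
                gene, None, None, analyzed=False, params=params,
                peptide_ids=peptide_ids,
            )
            continue
        graph = build_gene_graph(gene, t, scaling=params.distance_scaling)
        membership = detect_communities(graph, seed=seed, resolution=params.resolution)
        out[gene] = assign_proteoform_groups(
            gene, graph, membership, analyzed=True, params=params
        )
    return out


def summarize_proteoform_profiles(
    assignments: dict[str, ProteoformAssignment] | ProteoformAssignment,
    raw: PeptideQuantMatrix,
    normalize: bool = True,
) -> FoldChangeTensor:
    """Summarize member peptides into proteoform-level melting profiles.

    Per group, the *non-normalized raw* member intensities are summed per
    (cell line, temperature); the summed signal is then normalized per
    temperature (optional) and converted to fold changes relative to the
    lowest temperature.  Channels where every member is missing stay masked.
    """
    if isinstance(assignments, ProteoformAssignment):
        assignments = {assignments.gene: assignments}
    pep_index = {p: i for i, p in enumerate(raw.peptide_ids)}
    ids: list[str] = []
    genes: list[frozenset[str]] = []
    rows: list[np.ndarray] = []
    for gene in sorted(assignments):
        for pid, members in assignments[gene].groups:
            idx = []
            for m in sorted(members):
                if m not in pep_index:
                    raise KeyError(f"group {pid}: member peptide {m!r} not in raw matrix")
                idx.append(pep_index[m])
            block = raw.intensity[idx]
            all_missing = np.isnan(block).all(axis=0)
            summed = np.nansum(block, axis=0)
            summed[all_missing] = np.nan
            ids.append(pid)
            genes.append(frozenset({gene}))
            rows.append(summed)
    if not rows:
        raise ValueError("no proteoform groups to summarize")
    pf_matrix = PeptideQuantMatrix(
        peptide_ids=ids,
        gene_symbols=genes,
        intensity=np.stack(rows),
        temperatures=raw.temperatures.copy(),
        cell_lines=list(raw.cell_lines),
    )
    if normalize:
        pf_matrix = normalize_per_temperature(pf_matrix)
    return to_fold_changes(pf_matrix)


def assignments_to_frame(assignments: dict[str, ProteoformAssignment]):
    """Long table (gene, proteoform_id, peptide, modularity_Q, analyzed)."""
    import pandas as pd

    recs = []
    for gene in sorted(assignments):
        a = assignments[gene]
        for pid, members in a.groups:
            for pep in sorted(members):
                recs.append((gene, pid, pep, a.modularity_q, a.analyzed))
        for pep in sorted(a.unassigned_peptides):
            recs.append((gene, "", pep, a.modularity_q, a.analyzed))
    return pd.DataFrame(
        recs, columns=["gene", "proteoform_id", "peptide", "modularity_Q", "analyzed"]
    )
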