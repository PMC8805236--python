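"""Random walk with restart on a weighted graph.

The walk iterates ``p <- (1 - alpha) W p + alpha q`` from ``p0 = q`` until
the L1 step difference drops to the tolerance. ``W`` is the column-stochastic
transfer matrix obtained by normalising the weighted adjacency column-wise
(column j is node j's outgoing distribution); isolated nodes get a self-loop
column so stochasticity holds everywhere. ``q`` is uniform over a document's
seed nodes — its MeSH terms and retained concepts — and the convergent
distribution over all nodes is the document's feature vector.

``alpha`` is the restart probability: the chance per step of jumping back to
the seeds. Larger alpha keeps mass near the seeds; smaller alpha lets the
walk diffuse further through the term network. A symmetric-Laplacian
normalisation (D^{-1/2} A D^{-1/2}) is available as an alternative to the
stochastic column normalisation; it does not conserve probability mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp

COLUMN = "column"
LAPLACIAN = "laplacian"


class ConvergenceError(RuntimeError):
    """Iteration cap reached before the residual dropped below tolerance."""


@dataclass(frozen=True)
class RWRConfig:
    """Restart probability, convergence tolerance (L1), iteration cap,
    and adjacency normalisation."""

    alpha: float = 0.6
    tol: float = 1e-10
    max_iter: int = 10_000
    norm: str = COLUMN

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.norm not in (COLUMN, LAPLACIAN):
            raise ValueError(f"unknown normalisation {self.norm!r}")


@dataclass
class TransferMatrix:
    """Square transfer matrix with the node order it is expressed in."""

    matrix: sp.csr_matrix
    nodes: list[str]

    @property
    def index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}


def build_transfer_matrix(g: nx.Graph, norm: str = COLUMN) -> TransferMatrix:
    """Normalise the weighted adjacency of ``g``.

    Column normalisation gives W[i, j] = w(j, i) / strength(j), a
    column-stochastic walk matrix; isolated nodes become self-loops.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    nodes = sorted(g.nodes)
    adj = nx.to_scipy_sparse_array(g, nodelist=nodes, weight="weight", format="csc")
    if adj.nnz and adj.min() < 0:
        raise ValueError("negative edge weight")
    strength = np.asarray(adj.sum(axis=0)).ravel()
    isolated = np.where(strength == 0)[0]
    if isolated.size:
        loops = sp.csc_array(
            (np.ones(isolated.size), (isolated, isolated)), shape=adj.shape
        )
        adj = adj + loops
        strength = np.asarray(adj.sum(axis=0)).ravel()
    if norm == COLUMN:
        w = adj @ sp.diags(1.0 / strength)
    elif norm == LAPLACIAN:
        inv_sqrt = sp.diags(1.0 / np.sqrt(strength))
        w = inv_sqrt @ adj @ inv_sqrt
    else:
        raise ValueError(f"unknown normalisation {norm!r}")
    return TransferMatrix(matrix=sp.csr_matrix(w), nodes=nodes)


def restart_vector(seeds, tm: TransferMatrix) -> np.ndarray:
    """Uniform distribution over the seed nodes (1/|seeds| each)."""
    seeds = sorted(set(seeds))
    if not seeds:
        raise ValueError("seed set is empty")
    index = tm.index
    q = np.zeros(len(tm.nodes))
    for seed in seeds:
        if seed not in index:
            raise KeyError(f"seed {seed!r} not in graph")
        q[index[seed]] = 1.0
    return q / q.sum()


def rwr_iterate(tm: TransferMatrix, q: np.ndarray, config: RWRConfig = RWRConfig()) -> np.ndarray:
    """Power iteration of p <- (1 - alpha) W p + alpha q from p0 = q."""
    w = tm.matrix
    alpha = config.alpha
    p = q.copy()
    for _ in range(config.max_iter):
        p_next = (1.0 - alpha) * (w @ p) + alpha * q
        residual = np.abs(p_next - p).sum()
        p = p_next
        if residual <= config.tol:
            return p
    raise ConvergenceError(
        f"no convergence after {config.max_iter} iterations (residual {residual:.3e})"
    )


def rwr_closed_form(tm: TransferMatrix, q: np.ndarray, alpha: float) -> np.ndarray:
    """Direct fixed point p = alpha (I - (1 - alpha) W)^-1 q.

    Dense solve; the verification oracle for the iterative walk on small
    graphs (the system is nonsingular for stochastic W and alpha > 0).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    n = len(tm.nodes)
    system = np.eye(n) - (1.0 - alpha) * tm.matrix.toarray()
    return alpha * np.linalg.solve(system, q)


def document_feature_vectors(
    g: nx.Graph,
    seeds_by_document: dict[str, set[str]],
    config: RWRConfig = RWRConfig(),
) -> tuple[np.ndarray, list[str], list[str]]:
    """Run one restart walk per document; all walks share the node order.

    ``seeds_by_document`` maps pmid -> seed node labels (MeSH terms, and
    concepts for the MeSH-concept graph). Documents with no seed present in
    the graph are skipped with a warning. All columns are iterated together
    until every walk's L1 residual is below tolerance.

    Returns ``(features, pmids, nodes)`` where ``features[i]`` is the
    convergent distribution for ``pmids[i]`` over ``nodes``.
    """
    import logging

    logger = logging.getLogger(__name__)
    tm = build_transfer_matrix(g, norm=config.norm)
    pmids: list[str] = []
    columns: list[np.ndarray] = []
    for pmid in seeds_by_document:
        in_graph = {s for s in seeds_by_document[pmid] if s in tm.index}
        if not in_graph:
            logger.warning("document %s has no seeds in the graph; skipped", pmid)
            continue
        pmids.append(pmid)
        columns.append(restart_vector(in_graph, tm))
    if not pmids:
        raise ValueError("no document has seeds in the graph")
    q = np.column_stack(columns)
    w = tm.matrix
    alpha = config.alpha
    p = q.copy()
    for _ in range(config.max_iter):
        p_next = (1.0 - alpha) * (w @ p) + alpha * q
        residual = np.abs(p_next - p).sum(axis=0).max()
        p = p_next
        if residual <= config.tol:
            break
    else:
        raise ConvergenceError(
            f"no convergence after {config.max_iter} iterations (residual {residual:.3e})"
        )
    return p.T.copy(), pmids, tm.nodes
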