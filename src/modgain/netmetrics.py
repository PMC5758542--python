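"""Network modularity and segregation metrics.

Modularity of a partition of an unweighted, undirected graph is

    Q = sum_i (e_ii - a_i**2)

where ``e_ii`` is the fraction of all edges that join two nodes inside
module *i* and ``a_i`` is the fraction of edge endpoints attached to
module *i*. Q compares the observed within-module connectivity to the
expectation under a degree-preserving random rewiring; Q = 0 for the
trivial single-module partition, and high Q marks a segregated
("modular") network.

Two partition sources are supported:

* :func:`spectral_partition` — Newman's leading-eigenvector bisection of
  the modularity matrix with Kernighan–Lin-style node-swap refinement,
  maximizing Q per subject and per density threshold;
* :func:`canonical_partition` — a fixed node-to-system assignment table
  (e.g. the 13 functional systems of the Power parcellation), shared
  across subjects.

:func:`module_segregation` is the weighted companion metric
``(Zw - Zb)/Zw`` computed on the full Fisher-z matrix: it retains the
weights of all connections rather than the thresholded edge set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .connectome import BinaryGraph, ConnectivityMatrix

__all__ = [
    "Partition",
    "ModularityResult",
    "SegregationResult",
    "modularity_q",
    "spectral_partition",
    "canonical_partition",
    "read_partition_table",
    "subnetwork_modularity",
    "module_segregation",
    "ASSOCIATION_MODULES",
    "SENSORY_MOTOR_MODULES",
    "UNASSIGNED_MODULE",
]

# Canonical system names for the 13-module cortical partition.
ASSOCIATION_MODULES = ("dmn", "fp", "co", "sal", "dan", "van")
SENSORY_MOTOR_MODULES = ("aud", "vis", "sm_hand", "sm_mouth")
UNASSIGNED_MODULE = "unassigned"


@dataclass(frozen=True)
class Partition:
    """Node -> module assignment aligned with a graph's ROI ordering."""

    labels: tuple
    roi_ids: tuple[str, ...]
    source: str = "spectral"
    q: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "roi_ids", tuple(self.roi_ids))
        if len(self.labels) != len(self.roi_ids):
            raise ValueError("one module label per node required")
        if self.source not in ("spectral", "canonical"):
            raise ValueError(f"unknown partition source {self.source!r}")

    @property
    def m(self) -> int:
        """Number of modules."""
        return len(set(self.labels))

    @property
    def module_labels(self) -> tuple:
        seen: dict = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return tuple(seen)

    def codes(self) -> np.ndarray:
        """Integer codes, numbered by first occurrence."""
        mapping = {lab: i for i, lab in enumerate(self.module_labels)}
        return np.array([mapping[lab] for lab in self.labels], dtype=int)

    def as_mapping(self) -> dict:
        return dict(zip(self.roi_ids, self.labels))


@dataclass(frozen=True)
class ModularityResult:
    q: float
    per_module_terms: dict
    e_within: dict
    a_totals: dict
    cost: float
    partition: Partition


@dataclass(frozen=True)
class SegregationResult:
    segregation: float
    zw: float
    zb: float
    scope: str


def _check_alignment(g: BinaryGraph, p: Partition) -> None:
    if p.roi_ids != g.roi_ids:
        raise ValueError("partition ROI ordering does not match the graph")


def modularity_q(g: BinaryGraph, p: Partition) -> ModularityResult:
    """Newman–Girvan modularity ``Q = sum_i (e_ii - a_i**2)`` of a partition.

    ``e_ii`` counts within-module edges as a fraction of all edges;
    ``a_i`` counts module-i endpoints as a fraction of all endpoints.
    Undefined (raises) on an edgeless graph.
    """
    _check_alignment(g, p)
    adj = g.adjacency
    m_edges = adj.sum() / 2.0
    if m_edges == 0:
        raise ValueError("modularity is undefined on an edgeless graph")
    codes = p.codes()
    n_mod = codes.max() + 1
    onehot = np.zeros((len(codes), n_mod))
    onehot[np.arange(len(codes)), codes] = 1.0
    block = onehot.T @ adj @ onehot  # degree-sum between module pairs
    e_within = np.diag(block) / 2.0 / m_edges
    a_totals = block.sum(axis=1) / (2.0 * m_edges)
    terms = e_within - a_totals**2
    labels = p.module_labels
    return ModularityResult(
        q=float(terms.sum()),
        per_module_terms={lab: float(t) for lab, t in zip(labels, terms)},
        e_within={lab: float(e) for lab, e in zip(labels, e_within)},
        a_totals={lab: float(a) for lab, a in zip(labels, a_totals)},
        cost=g.cost,
        partition=p,
    )


# -- spectral maximization --------------------------------------------------

def _kl_refine(bg: np.ndarray, s: np.ndarray, tol: float, max_passes: int = 50) -> np.ndarray:
    """Kernighan–Lin node-swap refinement of a bisection sign vector.

    Each pass tentatively flips every node once in order of steepest gain
    in s'Bs (negative interim gains allowed), then rolls back to the best
    prefix; passes repeat while the best prefix improves. Deterministic:
    ties in the gain vector resolve to the lowest node index.
    """
    s = s.copy()
    n = s.size
    diag = np.diag(bg).copy()
    for _ in range(max_passes):
        bs = bg @ s
        s_work = s.copy()
        free = np.ones(n, dtype=bool)
        flips = np.empty(n, dtype=int)
        cum = np.empty(n)
        total = 0.0
        for step in range(n):
            delta = -4.0 * s_work * bs + 4.0 * diag
            delta[~free] = -np.inf
            i = int(np.argmax(delta))
            total += delta[i]
            s_work[i] = -s_work[i]
            bs += 2.0 * s_work[i] * bg[:, i]
            free[i] = False
            flips[step] = i
            cum[step] = total
        best = int(np.argmax(cum))
        if cum[best] > tol:
            for i in flips[: best + 1]:
                s[i] = -s[i]
        else:
            break
    return s


def _module_block(adj: np.ndarray, codes: np.ndarray) -> np.ndarray:
    n_mod = codes.max() + 1
    onehot = np.zeros((len(codes), n_mod))
    onehot[np.arange(len(codes)), codes] = 1.0
    return onehot.T @ adj @ onehot


def _greedy_moves(adj: np.ndarray, codes: np.ndarray, m_edges: float, tol: float,
                  max_sweeps: int = 100) -> np.ndarray:
    """Move single nodes between modules (or to a new singleton) while Q improves."""
    codes = codes.copy()
    k = adj.sum(axis=1)
    for _ in range(max_sweeps):
        n_mod = codes.max() + 1
        big_k = np.bincount(codes, weights=k, minlength=n_mod)
        improved = False
        for v in range(len(codes)):
            c = codes[v]
            k_to = np.bincount(codes, weights=adj[v], minlength=n_mod)
            kv = k[v]
            # candidate destinations: every existing module plus a fresh one
            k_to_ext = np.append(k_to, 0.0)
            big_k_ext = np.append(big_k, 0.0)
            dq = (k_to_ext - k_to[c]) / m_edges - kv * (
                big_k_ext - big_k[c] + kv
            ) / (2.0 * m_edges**2)
            dq[c] = 0.0
            d = int(np.argmax(dq))
            if dq[d] > tol:
                codes[v] = d
                big_k_ext[c] -= kv
                big_k_ext[d] += kv
                big_k = big_k_ext if d == n_mod else big_k_ext[:-1]
                if d == n_mod:
                    n_mod += 1
                improved = True
        if not improved:
            break
        codes = _relabel(codes)
    return _relabel(codes)


def _greedy_merges(adj: np.ndarray, codes: np.ndarray, m_edges: float, tol: float) -> np.ndarray:
    """Merge module pairs while the merge increases Q."""
    codes = codes.copy()
    while True:
        codes = _relabel(codes)
        n_mod = codes.max() + 1
        if n_mod < 2:
            return codes
        block = _module_block(adj, codes)
        a = block.sum(axis=1) / (2.0 * m_edges)
        # dQ of merging (c, d): e_cd/m - 2 a_c a_d, block[c,d] = c-d edge count
        dq = block / m_edges - 2.0 * np.outer(a, a)
        np.fill_diagonal(dq, -np.inf)
        c, d = np.unravel_index(np.argmax(dq), dq.shape)
        if dq[c, d] <= tol:
            return codes
        codes[codes == max(c, d)] = min(c, d)


def _kl_moves(adj: np.ndarray, codes: np.ndarray, m_edges: float, tol: float,
              max_passes: int = 10) -> np.ndarray:
    """Multiway Kernighan–Lin refinement over module assignments.

    Each pass tentatively relocates every node once (to any module,
    including a fresh singleton), always taking the steepest move even
    when its immediate gain is negative, then rolls back to the best
    prefix of the move sequence. Escapes local optima that single-node
    hill climbing cannot leave.
    """
    codes = _relabel(codes)
    n = len(codes)
    k_deg = adj.sum(axis=1)
    idx = np.arange(n)
    for _ in range(max_passes):
        work = codes.copy()
        n_mod = work.max() + 1
        k_to = np.zeros((n, n_mod + 1))
        for mod in range(n_mod):
            k_to[:, mod] = adj[:, work == mod].sum(axis=1)
        big_k = np.append(np.bincount(work, weights=k_deg, minlength=n_mod), 0.0)
        free = np.ones(n, dtype=bool)
        moves: list[tuple[int, int]] = []
        cum: list[float] = []
        total = 0.0
        while free.any():
            kc = k_to[idx, work]
            dq = (k_to - kc[:, None]) / m_edges - k_deg[:, None] * (
                big_k[None, :] - big_k[work][:, None] + k_deg[:, None]
            ) / (2.0 * m_edges**2)
            dq[idx, work] = -np.inf
            dq[~free] = -np.inf
            v, d = np.unravel_index(np.argmax(dq), dq.shape)
            if not np.isfinite(dq[v, d]):
                break
            c = work[v]
            total += dq[v, d]
            work[v] = d
            big_k[c] -= k_deg[v]
            big_k[d] += k_deg[v]
            k_to[:, c] -= adj[:, v]
            k_to[:, d] += adj[:, v]
            free[v] = False
            if d == n_mod:  # opened the fresh module; provision a new empty one
                n_mod += 1
                k_to = np.hstack([k_to, np.zeros((n, 1))])
                big_k = np.append(big_k, 0.0)
            moves.append((v, d))
            cum.append(total)
        if not cum:
            break
        best = int(np.argmax(cum))
        if cum[best] > tol:
            for v, d in moves[: best + 1]:
                codes[v] = d
            codes = _relabel(codes)
        else:
            break
    return codes


def _q_codes(adj: np.ndarray, codes: np.ndarray, m_edges: float) -> float:
    block = _module_block(adj, codes)
    e_within = np.diag(block) / 2.0 / m_edges
    a = block.sum(axis=1) / (2.0 * m_edges)
    return float((e_within - a**2).sum())


def _local_search(adj: np.ndarray, codes: np.ndarray, m_edges: float,
                  tol: float) -> np.ndarray:
    codes = _greedy_moves(adj, codes, m_edges, tol)
    codes = _greedy_merges(adj, codes, m_edges, tol)
    codes = _kl_moves(adj, codes, m_edges, tol)
    codes = _greedy_merges(adj, codes, m_edges, tol)
    codes = _greedy_moves(adj, codes, m_edges, tol)
    return codes


def _relabel(codes: np.ndarray) -> np.ndarray:
    """Renumber module codes contiguously by first occurrence."""
    mapping: dict[int, int] = {}
    out = np.empty_like(codes)
    for i, c in enumerate(codes):
        if c not in mapping:
            mapping[c] = len(mapping)
        out[i] = mapping[c]
    return out


def spectral_partition(g: BinaryGraph, seed: int | None = None, tol: float = 1e-10,
                       n_restarts: int = 4, ils_rounds: int | None = None) -> Partition:
    """Maximize Q by recursive leading-eigenvector bisection with refinement.

    Each connected component is recursively bisected along the sign
    pattern of the leading eigenvector of its (generalized) modularity
    matrix, refined by Kernighan–Lin node swaps; ``n_restarts`` additional
    KL runs from random sign vectors guard against local optima of the
    refinement, and the recursion stops when no split raises Q. The final
    labels then pass through multiway local search (single-node moves,
    module merges, a multiway KL pass) plus ``ils_rounds`` rounds of
    iterated local search (perturb a fifth of the nodes, reoptimize, keep
    the best Q). Edgeless components become singleton modules. The
    procedure is deterministic for a fixed ``seed`` (the seed only feeds
    restart and perturbation draws; ``None`` behaves as 0).
    """
    adj = g.adjacency.astype(float)
    n = g.n_nodes
    m_edges = adj.sum() / 2.0
    codes = np.full(n, -1, dtype=int)
    if m_edges == 0:
        codes = np.arange(n)
        return Partition(labels=tuple(codes.tolist()), roi_ids=g.roi_ids,
                         source="spectral", q=None)
    k = adj.sum(axis=1)
    b_full = adj - np.outer(k, k) / (2.0 * m_edges)
    rng = np.random.default_rng(0 if seed is None else seed)

    next_label = 0
    n_comp, comp = connected_components(adj, directed=False)
    for ci in range(n_comp):
        stack = [np.nonzero(comp == ci)[0]]
        while stack:
            grp = stack.pop()
            if grp.size == 1:
                codes[grp] = next_label
                next_label += 1
                continue
            bg = b_full[np.ix_(grp, grp)]
            bg = bg - np.diag(bg.sum(axis=1))
            evals, evecs = np.linalg.eigh(bg)
            if evals[-1] <= tol:
                codes[grp] = next_label
                next_label += 1
                continue
            starts = [np.where(evecs[:, -1] >= 0, 1.0, -1.0)]
            starts += [np.where(rng.random(grp.size) < 0.5, 1.0, -1.0)
                       for _ in range(n_restarts)]
            best_s, best_val = None, -np.inf
            for s0 in starts:
                s = _kl_refine(bg, s0, tol)
                val = float(s @ bg @ s)
                if val > best_val + tol:
                    best_s, best_val = s, val
            s = best_s
            if np.all(s == s[0]) or best_val <= tol:
                codes[grp] = next_label
                next_label += 1
                continue
            stack.append(grp[s > 0])
            stack.append(grp[s < 0])

    codes = _local_search(adj, _relabel(codes), m_edges, tol)
    best_q = _q_codes(adj, codes, m_edges)
    # iterated local search: deterministic perturb-and-reoptimize rounds
    # rescue the rare configurations where recursive bisection commits to
    # a split incompatible with the global optimum; small graphs are cheap
    # enough to search hard
    if ils_rounds is None:
        ils_rounds = 24 if n <= 100 else 6
    for r in range(ils_rounds):
        pert = codes.copy()
        frac = 5 if r % 2 == 0 else 2  # alternate weak/strong kicks
        n_move = max(1, n // frac)
        moved = rng.choice(n, size=n_move, replace=False)
        pert[moved] = rng.integers(0, pert.max() + 2, size=n_move)
        pert = _local_search(adj, _relabel(pert), m_edges, tol)
        q = _q_codes(adj, pert, m_edges)
        if q > best_q + tol:
            codes, best_q = pert, q
    part = Partition(labels=tuple(int(c) for c in codes), roi_ids=g.roi_ids,
                     source="spectral")
    q = modularity_q(g, part).q
    return Partition(labels=part.labels, roi_ids=g.roi_ids, source="spectral", q=q)


# -- canonical partitions ---------------------------------------------------

def canonical_partition(assignment: Mapping[str, object] | pd.DataFrame,
                        roi_ids: Sequence[str]) -> Partition:
    """Build a Partition from a fixed node-to-system assignment table.

    ``assignment`` maps ROI id -> module label (a mapping, or a two-column
    DataFrame of roi_id, module_label). Every retained ROI must appear
    exactly once; unassigned nodes should carry the ``"unassigned"`` label
    explicitly.
    """
    if isinstance(assignment, pd.DataFrame):
        if assignment.shape[1] < 2:
            raise ValueError("assignment table needs (roi_id, module_label) columns")
        ids = assignment.iloc[:, 0].astype(str)
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate ROI in assignment table: {dup}")
        mapping = dict(zip(ids, assignment.iloc[:, 1]))
    else:
        mapping = dict(assignment)
    missing = [rid for rid in roi_ids if rid not in mapping]
    if missing:
        raise KeyError(f"ROI(s) missing from assignment table: {missing[:5]}")
    labels = tuple(mapping[rid] for rid in roi_ids)
    return Partition(labels=labels, roi_ids=tuple(roi_ids), source="canonical")


def read_partition_table(path: str | Path, roi_ids: Sequence[str]) -> Partition:
    """Read a two-column TSV (roi_id, module_label) into a canonical Partition."""
    df = pd.read_csv(path, sep="\t", header=None, names=["roi_id", "module"],
                     dtype=str, comment="#")
    return canonical_partition(df, roi_ids)


def subnetwork_modularity(g: BinaryGraph, p: Partition,
                          class_modules: Iterable,
                          method: str = "contribution") -> float:
    """Modularity attributable to a class of modules (e.g. association systems).

    ``method="contribution"`` (default) sums the per-module terms
    ``q_i = e_ii - a_i**2`` over the class, evaluated on the whole-brain
    graph; the class contributions then sum exactly to whole-brain Q.
    ``method="subgraph"`` instead computes Q of the induced subgraph on the
    class's nodes under the restricted partition.
    """
    class_modules = list(class_modules)
    known = set(p.module_labels)
    unknown = [lab for lab in class_modules if lab not in known]
    if unknown:
        raise KeyError(f"unknown module label(s): {unknown}")
    if method == "contribution":
        if not class_modules:
            return 0.0
        result = modularity_q(g, p)
        return float(sum(result.per_module_terms[lab] for lab in class_modules))
    if method == "subgraph":
        mask = np.array([lab in set(class_modules) for lab in p.labels])
        if not mask.any():
            return 0.0
        sub_adj = g.adjacency[np.ix_(mask.nonzero()[0], mask.nonzero()[0])]
        sub_ids = tuple(rid for rid, keep in zip(p.roi_ids, mask) if keep)
        sub_labels = tuple(lab for lab, keep in zip(p.labels, mask) if keep)
        sub_g = BinaryGraph(adjacency=sub_adj, cost=g.cost, roi_ids=sub_ids)
        sub_p = Partition(labels=sub_labels, roi_ids=sub_ids, source=p.source)
        return modularity_q(sub_g, sub_p).q
    raise ValueError(f"unknown method {method!r}")


def module_segregation(zm: ConnectivityMatrix, p: Partition,
                       scope: Iterable | str = "whole_brain") -> SegregationResult:
    """Weighted module segregation ``(Zw - Zb)/Zw`` on the full z-matrix.

    ``Zw`` is the mean Fisher-z over node pairs inside the same scope
    module; ``Zb`` the mean over pairs joining a scope-module node to a
    node of any *other* module. ``scope`` is ``"whole_brain"`` or an
    iterable of module labels (e.g. the association systems).
    """
    if zm.scale != "fisher_z":
        raise ValueError("segregation is computed on the Fisher-z matrix")
    if p.roi_ids != zm.roi_ids:
        raise ValueError("partition ROI ordering does not match the matrix")
    codes = p.codes()
    labels = p.module_labels
    if isinstance(scope, str) and scope == "whole_brain":
        scope_codes = set(range(len(labels)))
        scope_name = "whole_brain"
    else:
        scope_list = list(scope)
        unknown = [lab for lab in scope_list if lab not in set(labels)]
        if unknown:
            raise KeyError(f"unknown module label(s): {unknown}")
        code_of = {lab: i for i, lab in enumerate(labels)}
        scope_codes = {code_of[lab] for lab in scope_list}
        scope_name = ",".join(str(lab) for lab in scope_list)

    n = zm.n_rois
    iu, ju = np.triu_indices(n, k=1)
    ci, cj = codes[iu], codes[ju]
    w = zm.values[iu, ju]
    in_scope_i = np.isin(ci, list(scope_codes))
    in_scope_j = np.isin(cj, list(scope_codes))
    within = (ci == cj) & in_scope_i
    between = (ci != cj) & (in_scope_i | in_scope_j)
    if not within.any():
        raise ValueError("scope contains no within-module pairs")
    zw = float(w[within].mean())
    zb = float(w[between].mean()) if between.any() else 0.0
    if zw == 0:
        raise ValueError("Zw = 0: segregation undefined")
    return SegregationResult(segregation=(zw - zb) / zw, zw=zw, zb=zb,
                             scope=scope_name)
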