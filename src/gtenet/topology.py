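"""Ground-truth network ensembles and directed-graph statistics.

Networks model dissociated neuronal cultures grown on a square substrate:
``N`` neurons at random positions inside an ``area_side`` x ``area_side``
square (mm), connected by a sparse boolean adjacency matrix with entry
``(i, j)`` meaning a directed excitatory link i -> j.  Two ensembles are
provided:

* a *non-local* ensemble, where an Erdos-Renyi draw is rewired by
  degree-preserving "crossing" moves until the mean full (directed)
  clustering coefficient reaches a target value, independently of the
  neuron positions; and
* a *local* ensemble, where the connection probability decays with the
  Euclidean distance between somata as a Gaussian kernel
  ``exp(-d^2 / lambda^2)``, rescaled so the expected link count matches a
  prescribed connection density.

Clustering is measured with the full clustering coefficient for directed
graphs (Fagiolo's definition), which counts all directed triangle motifs
through a node:

    C_i = [(A + A^T)^3]_ii / [2 (d_i^tot (d_i^tot - 1) - 2 d_i^bidir)]
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .errors import ConvergenceError, StructuralError

__all__ = [
    "DirectedNetwork",
    "GraphStats",
    "full_clustering",
    "graph_stats",
    "generate_nonlocal",
    "generate_local",
    "randomize_full",
    "randomize_partial",
    "connection_distances",
]

DEFAULT_N = 100
DEFAULT_P = 0.12
DEFAULT_AREA_SIDE = 0.5  # mm


@dataclass
class DirectedNetwork:
    """Boolean directed adjacency plus 2-D neuron positions in mm.

    ``adjacency[i, j]`` is True for a link i -> j; the diagonal is always
    False (autaptic links are excluded).  ``meta`` records how the network
    was generated (ensemble tag, target parameter, connection probability,
    seed, realized link count).
    """

    adjacency: np.ndarray
    positions: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise StructuralError(f"adjacency must be square, got {a.shape}")
        self.adjacency = a.astype(bool)
        if np.any(np.diag(self.adjacency)):
            raise StructuralError("adjacency contains diagonal (autaptic) entries")
        if self.positions is not None:
            pos = np.asarray(self.positions, dtype=float)
            if pos.shape != (a.shape[0], 2):
                raise StructuralError(
                    f"positions must be (N, 2), got {pos.shape} for N={a.shape[0]}"
                )
            self.positions = pos
        self.meta.setdefault("n_links", int(self.adjacency.sum()))

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_links(self) -> int:
        return int(self.adjacency.sum())


@dataclass
class GraphStats:
    """Per-node degree/clustering statistics and per-link distances."""

    clustering: np.ndarray
    in_degree: np.ndarray
    out_degree: np.ndarray
    total_degree: np.ndarray
    bidirectional: np.ndarray
    distances: np.ndarray  # one entry per true link (mm); empty if no positions
    mean_clustering: float
    mean_distance: float


def full_clustering(net: DirectedNetwork | np.ndarray) -> np.ndarray:
    """Per-node full clustering coefficient of a directed graph.

    Counts all directed triangles through each node via ``(A + A^T)^3`` and
    normalizes by the number of possible triangles given the node's total
    degree and its number of bidirectional links.  Nodes whose denominator
    is zero (degree < 2, or all links concentrated in reciprocal pairs)
    return 0 by convention.
    """
    a = net.adjacency if isinstance(net, DirectedNetwork) else np.asarray(net)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise StructuralError(f"adjacency must be square, got {a.shape}")
    A = a.astype(np.float64)
    B = A + A.T
    num = np.einsum("ij,ji->i", B @ B, B)
    d_tot = (A.sum(0) + A.sum(1)).astype(np.int64)
    d_bidir = np.diag(A @ A).astype(np.int64)
    den = 2.0 * (d_tot * (d_tot - 1) - 2 * d_bidir)
    out = np.zeros(a.shape[0])
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def graph_stats(net: DirectedNetwork) -> GraphStats:
    """Bundle of the standard topology observables for one network."""
    A = net.adjacency.astype(np.int64)
    cc = full_clustering(net)
    d_in = A.sum(0)
    d_out = A.sum(1)
    d_bi = np.diag(A @ A)
    dist = (
        connection_distances(net)
        if net.positions is not None
        else np.empty(0)
    )
    return GraphStats(
        clustering=cc,
        in_degree=d_in,
        out_degree=d_out,
        total_degree=d_in + d_out,
        bidirectional=d_bi,
        distances=dist,
        mean_clustering=float(cc.mean()),
        mean_distance=float(dist.mean()) if dist.size else float("nan"),
    )


# ---------------------------------------------------------------------------
# non-local ensemble: degree-preserving rewiring toward a target clustering


@njit(cache=True)
def _triangles_through(B, i):
    """(B^3)_ii computed sparsely: sum over neighbors j of B_ij (B^2)_ji."""
    N = B.shape[0]
    total = 0.0
    for j in range(N):
        bij = B[i, j]
        if bij == 0:
            continue
        inner = 0.0
        for k in range(N):
            inner += B[j, k] * B[k, i]
        total += bij * inner
    return total


@njit(cache=True)
def _mean_cc(T, den):
    N = T.shape[0]
    s = 0.0
    for i in range(N):
        if den[i] > 0:
            s += T[i] / den[i]
    return s / N


@njit(cache=True)
def _rewire_kernel(A, target, max_iter, seed):
    """Crossing-move hill climb toward a target mean full clustering.

    Picks two random directed links (a->b, c->d) and crosses them into
    (a->d, c->b); every node's in- and out-degree is conserved by
    construction.  A move is accepted only if it strictly reduces the
    distance of the mean clustering coefficient from the target.  Returns
    (achieved_cc, n_accepted, n_iter, converged_flag).
    """
    N = A.shape[0]
    np.random.seed(seed)
    B = A.astype(np.int64) + A.T.astype(np.int64)
    # edge list
    E = 0
    for i in range(N):
        for j in range(N):
            if A[i, j]:
                E += 1
    src = np.empty(E, np.int64)
    dst = np.empty(E, np.int64)
    m = 0
    for i in range(N):
        for j in range(N):
            if A[i, j]:
                src[m] = i
                dst[m] = j
                m += 1
    d_tot = np.zeros(N, np.int64)
    bidir = np.zeros(N, np.int64)
    for i in range(N):
        for j in range(N):
            if A[i, j]:
                d_tot[i] += 1
                d_tot[j] += 1
                if A[j, i]:
                    bidir[i] += 1
    den = 2.0 * (d_tot * (d_tot - 1) - 2 * bidir)
    T = np.zeros(N)
    for i in range(N):
        T[i] = _triangles_through(B, i)
    cc = _mean_cc(T, den)
    direction = 1.0 if target >= cc else -1.0
    accepted = 0
    it = 0
    nodes = np.empty(4, np.int64)
    dT_special = np.empty(4)
    den_new = np.empty(4)
    while it < max_iter:
        it += 1
        if abs(cc - target) <= 1e-3 * max(abs(target), 1e-12) or (
            (cc - target) * direction >= 0.0
        ):
            return cc, accepted, it, 1
        e1 = np.random.randint(E)
        e2 = np.random.randint(E)
        if e1 == e2:
            continue
        a, b = src[e1], dst[e1]
        c, d = src[e2], dst[e2]
        # crossing (a->b, c->d) -> (a->d, c->b); all four nodes must be
        # distinct (equalities either change nothing or create self-links)
        if a == c or b == d or a == d or c == b:
            continue
        if A[a, d] or A[c, b]:
            continue
        nodes[0], nodes[1], nodes[2], nodes[3] = a, b, c, d
        # contribution of nodes outside {a,b,c,d}: the only change to their
        # triangle count comes from the changed opposite edges, giving
        # dT_i = 2 (B_ia - B_ic)(B_id - B_ib)
        dcc = 0.0
        for i in range(N):
            if i == a or i == b or i == c or i == d:
                continue
            if den[i] <= 0:
                continue
            dT = 2.0 * (B[i, a] - B[i, c]) * (B[i, d] - B[i, b])
            if dT != 0.0:
                dcc += dT / den[i]
        # apply the move
        A[a, b] = False
        A[c, d] = False
        A[a, d] = True
        A[c, b] = True
        B[a, b] -= 1
        B[b, a] -= 1
        B[c, d] -= 1
        B[d, c] -= 1
        B[a, d] += 1
        B[d, a] += 1
        B[c, b] += 1
        B[b, c] += 1
        for m4 in range(4):
            i = nodes[m4]
            bd = 0
            for j in range(N):
                if A[i, j] and A[j, i]:
                    bd += 1
            den_new[m4] = 2.0 * (d_tot[i] * (d_tot[i] - 1) - 2 * bd)
            Tnew = _triangles_through(B, i)
            dT_special[m4] = Tnew
            old = T[i] / den[i] if den[i] > 0 else 0.0
            new = Tnew / den_new[m4] if den_new[m4] > 0 else 0.0
            dcc += new - old
        cc_new = cc + dcc / N
        if abs(cc_new - target) < abs(cc - target):
            # keep: refresh cached statistics
            for i in range(N):
                if i == a or i == b or i == c or i == d:
                    continue
                T[i] += 2.0 * (B[i, a] - B[i, c]) * (B[i, d] - B[i, b])
            for m4 in range(4):
                T[nodes[m4]] = dT_special[m4]
                den[nodes[m4]] = den_new[m4]
            src[e1], dst[e1] = a, d
            src[e2], dst[e2] = c, b
            cc = cc_new
            accepted += 1
        else:
            # revert
            A[a, b] = True
            A[c, d] = True
            A[a, d] = False
            A[c, b] = False
            B[a, b] += 1
            B[b, a] += 1
            B[c, d] += 1
            B[d, c] += 1
            B[a, d] -= 1
            B[d, a] -= 1
            B[c, b] -= 1
            B[b, c] -= 1
    done = 1 if abs(cc - target) <= 1e-3 * max(abs(target), 1e-12) or (
        (cc - target) * direction >= 0.0
    ) else 0
    return cc, accepted, it, done


def _er_adjacency(N: int, p: float, rng: np.random.Generator) -> np.ndarray:
    A = rng.random((N, N)) < p
    np.fill_diagonal(A, False)
    return A


def generate_nonlocal(
    N: int = DEFAULT_N,
    p: float = DEFAULT_P,
    target_cc: float = 0.5,
    seed: int = 0,
    area_side: float = DEFAULT_AREA_SIDE,
    max_iter: int = 10_000_000,
) -> DirectedNetwork:
    """Non-locally clustered network with a prescribed mean full clustering.

    Starts from an Erdos-Renyi digraph (connection probability ``p``) and
    applies crossing moves -- swapping the targets of two randomly chosen
    links -- accepted only when they move the mean full clustering
    coefficient toward ``target_cc``.  Every node's in- and out-degree is
    left exactly as in the initial draw.  Positions are uniform in the
    square (this ensemble is spatially random by construction).

    Raises :class:`ConvergenceError` if the target is not reached within
    ``max_iter`` attempted moves; ``best`` on the exception carries the
    network at the best clustering achieved.
    """
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    rng = np.random.default_rng(seed)
    A = _er_adjacency(N, p, rng)
    positions = rng.random((N, 2)) * area_side
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    cc, accepted, iters, done = _rewire_kernel(A, float(target_cc), int(max_iter), kernel_seed)
    meta = {
        "ensemble": "nonlocal",
        "target_cc": float(target_cc),
        "achieved_cc": float(cc),
        "p": float(p),
        "seed": int(seed),
        "area_side": float(area_side),
        "rewire_accepted": int(accepted),
        "rewire_iterations": int(iters),
    }
    net = DirectedNetwork(A, positions, meta)
    if not done:
        raise ConvergenceError(
            f"rewiring stopped at CC={cc:.4f} (target {target_cc}) "
            f"after {iters} iterations",
            best=net,
        )
    return net


# ---------------------------------------------------------------------------
# local ensemble: Gaussian distance kernel with two-pass rescaling


def generate_local(
    N: int = DEFAULT_N,
    p: float = DEFAULT_P,
    lambda_mm: float = 0.5,
    area_side: float = DEFAULT_AREA_SIDE,
    seed: int = 0,
) -> DirectedNetwork:
    """Locally clustered network from a Gaussian distance kernel.

    Connection probability between neurons at Euclidean distance ``d`` is
    proportional to ``exp(-d^2 / lambda_mm^2)`` (non-periodic boundaries).
    The kernel is rescaled in a second pass so the expected link count
    matches ``p * N * (N - 1)``: a first network is drawn from the unscaled
    kernel, its realized link count fixes the rescaling prefactor, and the
    returned network is drawn from the rescaled kernel.  Probabilities that
    would exceed 1 are clamped (with a warning).
    """
    if lambda_mm <= 0:
        raise ValueError("lambda_mm must be positive")
    rng = np.random.default_rng(seed)
    positions = rng.random((N, 2)) * area_side
    diff = positions[:, None, :] - positions[None, :, :]
    d2 = (diff**2).sum(-1)
    kernel = np.exp(-d2 / lambda_mm**2)
    np.fill_diagonal(kernel, 0.0)
    first = rng.random((N, N)) < kernel
    np.fill_diagonal(first, False)
    n0 = first.sum()
    target_links = p * N * (N - 1)
    factor = target_links / max(n0, 1)
    probs = factor * kernel
    if np.any(probs > 1.0):
        warnings.warn(
            "rescaled Gaussian kernel clipped at probability 1 for "
            f"{int((probs > 1).sum())} pairs (lambda={lambda_mm} mm)",
            stacklevel=2,
        )
        probs = np.clip(probs, 0.0, 1.0)
    A = rng.random((N, N)) < probs
    np.fill_diagonal(A, False)
    meta = {
        "ensemble": "local",
        "lambda_mm": float(lambda_mm),
        "p": float(p),
        "seed": int(seed),
        "area_side": float(area_side),
        "rescale_factor": float(factor),
    }
    return DirectedNetwork(A, positions, meta)


# ---------------------------------------------------------------------------
# randomized controls


def randomize_full(net: DirectedNetwork, seed: int = 0) -> DirectedNetwork:
    """Complete randomization preserving only the total link count.

    All off-diagonal slots are equally likely; used as an Erdos-Renyi
    control for reconstructed cultures.
    """
    N = net.n_nodes
    rng = np.random.default_rng(seed)
    n_links = net.n_links
    slots = rng.choice(N * (N - 1), size=n_links, replace=False)
    A = np.zeros((N, N), dtype=bool)
    row, rem = np.divmod(slots, N - 1)
    col = rem + (rem >= row)  # skip the diagonal slot in each row
    A[row, col] = True
    meta = {"ensemble": "randomized_full", "seed": int(seed), "parent": net.meta.get("ensemble")}
    return DirectedNetwork(A, None if net.positions is None else net.positions.copy(), meta)


def randomize_partial(net: DirectedNetwork, seed: int = 0) -> DirectedNetwork:
    """Row-internal shuffle preserving each node's out-degree exactly.

    The targets of every node are redrawn uniformly among the other
    ``N - 1`` nodes (diagonal disallowed); the out-degree sequence, and
    hence the total link count, is unchanged.
    """
    N = net.n_nodes
    rng = np.random.default_rng(seed)
    A = np.zeros((N, N), dtype=bool)
    others = np.arange(N)
    for i in range(N):
        k = int(net.adjacency[i].sum())
        if k == 0:
            continue
        choices = np.delete(others, i)
        A[i, rng.choice(choices, size=k, replace=False)] = True
    meta = {"ensemble": "randomized_partial", "seed": int(seed), "parent": net.meta.get("ensemble")}
    return DirectedNetwork(A, None if net.positions is None else net.positions.copy(), meta)


def connection_distances(net: DirectedNetwork) -> np.ndarray:
    """Euclidean distance (mm) of every true link, in row-major link order."""
    if net.positions is None:
        raise StructuralError("network has no positions")
    src, dst = np.nonzero(net.adjacency)
    d = net.positions[src] - net.positions[dst]
    return np.hypot(d[:, 0], d[:, 1])
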