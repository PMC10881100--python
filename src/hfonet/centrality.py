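"""Channel ranking by network centrality.

Two centralities are used on the HFO networks: eigenvector centrality on the
undirected networks (FCN, uLAN), which scores a channel by the importance of
its neighbours, and Wasserman-Faust outcloseness on the directed forward
lag-asymmetry network (fLAN), which scores how far "upstream" a channel sits.
Raw centrality values (and raw HFO counts) are converted to a shared
normalized ordinal rank in [0, 1] by :func:`ordinal_rank_normalize`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import dijkstra

#: the four per-channel measures used downstream
MEASURES = ("fLAN-OUT", "uLAN-EIG", "FCN-EIG", "HFO-RATE")


@dataclass
class ChannelRanking:
    """Per-channel raw values and normalized ordinal ranks for one measure.

    ``rank01`` assigns rank 0 to the channel with the lowest raw value and
    rank N-1 to the highest, divided by N-1 so ranks span [0, 1]. Ties are
    broken deterministically by channel-label order.
    """

    measure: str
    labels: list[str]
    raw: np.ndarray
    rank01: np.ndarray

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.rank01 = np.asarray(self.rank01, dtype=float)
        n = len(self.labels)
        if not (len(self.raw) == len(self.rank01) == n):
            raise ValueError("labels, raw and rank01 must have equal length")

    def rank_of(self, label: str) -> float:
        return float(self.rank01[self.labels.index(label)])

    @classmethod
    def from_raw(cls, measure: str, labels: list[str], raw: np.ndarray) -> "ChannelRanking":
        return cls(measure, list(labels), np.asarray(raw, float),
                   ordinal_rank_normalize(raw, labels))


def eigenvector_centrality(
    weights: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Principal-eigenvector scores of a symmetric nonnegative network.

    Power iteration on ``W + c I`` (the identity shift guarantees a strictly
    dominant eigenvalue on bipartite-like graphs without changing the
    eigenvectors), run to relative tolerance `tol`. Scores are nonnegative
    with unit 2-norm.

    An all-zero network has no preferred direction: uniform scores are
    returned with a warning. Non-convergence raises with the iteration count.
    """
    W = np.asarray(weights, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weights must be a square matrix")
    if np.any(W < 0):
        raise ValueError("weights must be nonnegative")
    if not np.allclose(W, W.T):
        raise ValueError("eigenvector centrality requires a symmetric network")
    n = W.shape[0]
    if not np.any(W):
        warnings.warn("all-zero network: returning uniform centrality scores")
        return np.full(n, 1.0 / np.sqrt(n))

    shift = W.sum(axis=1).max()  # |lambda_i| <= max row sum, so W + shift*I is PSD-dominant
    v = np.full(n, 1.0 / np.sqrt(n))
    for it in range(max_iter):
        w = W @ v + shift * v
        nrm = np.linalg.norm(w)
        if nrm == 0:
            warnings.warn("network annihilates the uniform vector: uniform scores")
            return np.full(n, 1.0 / np.sqrt(n))
        w /= nrm
        if np.linalg.norm(w - v) <= tol * np.linalg.norm(w):
            return np.abs(w)
        v = w
    raise RuntimeError(f"power iteration did not converge in {max_iter} iterations")


def outcloseness_centrality(weights: np.ndarray) -> np.ndarray:
    """Wasserman-Faust outcloseness of a directed weighted network.

    Edge weights are converted to distances ``d = 1/w`` (strong connections
    are short); a node's score is ``(r / (N-1)) * (r / sum_d)`` where ``r``
    counts the nodes reachable along directed paths and ``sum_d`` is the sum
    of shortest out-distances to them. Nodes that reach nothing score 0, so
    the measure stays bounded on disconnected networks.
    """
    W = np.asarray(weights, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weights must be a square matrix")
    if np.any(W < 0):
        raise ValueError("weights must be nonnegative")
    n = W.shape[0]
    if n < 2:
        return np.zeros(n)
    with np.errstate(divide="ignore"):
        dist = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), 0.0)
    np.fill_diagonal(dist, 0.0)
    # csgraph treats 0 as "no edge"
    D = dijkstra(dist, directed=True)
    scores = np.zeros(n)
    for i in range(n):
        d = np.delete(D[i], i)
        finite = np.isfinite(d)
        r = int(finite.sum())
        if r == 0:
            continue
        total = d[finite].sum()
        if total == 0:
            continue
        scores[i] = (r / (n - 1)) * (r / total)
    return scores


def ordinal_rank_normalize(
    values: np.ndarray,
    labels: list[str] | None = None,
) -> np.ndarray:
    """Normalized ascending ordinal ranks.

    The lowest value maps to 0, the highest to N-1, divided by N-1 so ranks
    span [0, 1]. Ties are broken by channel-label order (lexicographic),
    making the ranking deterministic and permutation-equivariant.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("ordinal rank normalization requires at least 2 channels")
    if labels is None:
        order = np.argsort(v, kind="stable")
    else:
        if len(labels) != n:
            raise ValueError("labels must match values in length")
        # lexsort: last key is primary; labels break ties among equal values
        order = np.lexsort((np.asarray(labels, dtype=object), v))
    ranks = np.empty(n)
    ranks[order] = np.arange(n, dtype=float)
    return ranks / (n - 1)
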