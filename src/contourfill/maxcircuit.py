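"""Recurrent MAX microcircuit.

A network of excitatory nodes whose recurrent collaterals land on distinct
dendritic branches.  Each branch is gated by dendritic inhibition carrying the
node's own activity, so a collateral influences the soma only while it is
stronger than the node's momentary activity.  At steady state every node that
is allowed to relay converges to the maximum feedforward drive of its
connected component; nodes outside the relay support keep their own drive.

Two solvers are provided: a leaky continuous-time integration
(:func:`relax_dynamics`) that tells the mechanistic story, and a synchronous
fixed-point iteration (:func:`relax_fixed_point`) used by the downstream
boundary and filling-in stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MaxNetwork", "MaxState", "relax_dynamics", "relax_fixed_point"]


@dataclass
class MaxNetwork:
    """A directed graph of excitatory nodes with per-node relay support.

    Parameters
    ----------
    feedforward:
        Nonnegative drive delivered to each node, shape ``(n,)``.
    edges:
        Integer array of shape ``(m, 2)``; row ``(j, i)`` means node ``i``
        receives a recurrent collateral from node ``j``.
    support:
        Boolean mask, shape ``(n,)``.  Nodes outside the support neither relay
        recurrent activity nor accept it; they hold their feedforward value.
        Defaults to all-true.
    """

    feedforward: np.ndarray
    edges: np.ndarray
    support: np.ndarray | None = None

    n_nodes: int = field(init=False)

    def __post_init__(self) -> None:
        self.feedforward = np.asarray(self.feedforward, dtype=np.float64).ravel()
        if np.any(self.feedforward < 0):
            raise ValueError("feedforward drive must be nonnegative")
        self.n_nodes = self.feedforward.size
        self.edges = np.asarray(self.edges, dtype=np.intp).reshape(-1, 2)
        if self.edges.size and (
            self.edges.min() < 0 or self.edges.max() >= self.n_nodes
        ):
            raise ValueError("edge endpoint out of range")
        if self.support is None:
            self.support = np.ones(self.n_nodes, dtype=bool)
        else:
            self.support = np.asarray(self.support, dtype=bool).ravel()
            if self.support.size != self.n_nodes:
                raise ValueError("support mask size mismatch")

    @classmethod
    def from_pairs(
        cls,
        feedforward,
        pairs,
        support=None,
        mutual: bool = True,
    ) -> "MaxNetwork":
        """Build a network from undirected node pairs.

        With ``mutual=True`` (the model's default wiring) every pair produces
        collaterals in both directions.
        """
        pairs = np.asarray(pairs, dtype=np.intp).reshape(-1, 2)
        if mutual and pairs.size:
            pairs = np.vstack([pairs, pairs[:, ::-1]])
        return cls(feedforward, pairs, support)

    def active_edges(self) -> tuple[np.ndarray, np.ndarray]:
        """Edges whose source and target may both take part in relaying."""
        if not self.edges.size:
            empty = np.empty(0, dtype=np.intp)
            return empty, empty
        src, dst = self.edges[:, 0], self.edges[:, 1]
        keep = self.support[src] & self.support[dst]
        return src[keep], dst[keep]


@dataclass
class MaxState:
    """Solver result: per-node activity plus convergence bookkeeping."""

    activity: np.ndarray
    iterations: int
    converged: bool
    residual: float = 0.0


def relax_fixed_point(
    net: MaxNetwork, tol: float = 1e-9, max_iter: int = 100_000
) -> MaxState:
    """Synchronous iteration to the unique monotone-reachable fixed point.

    Supported nodes update as ``x_i <- max(ff_i, max_j x_j)`` over supported
    in-neighbours ``j``; unsupported nodes are pinned at their feedforward
    drive.  The iteration is monotone nondecreasing from ``x = ff`` and halts
    once no activity changes by more than ``tol``.
    """
    ff = net.feedforward
    x = ff.copy()
    src, dst = net.active_edges()
    if src.size == 0:
        return MaxState(activity=x, iterations=0, converged=True)
    neigh = np.zeros_like(x)
    for it in range(1, max_iter + 1):
        neigh[:] = 0.0
        np.maximum.at(neigh, dst, x[src])
        x_new = np.maximum(ff, neigh)
        x_new[~net.support] = ff[~net.support]
        resid = float(np.max(np.abs(x_new - x)))
        x = x_new
        if resid <= tol:
            return MaxState(activity=x, iterations=it, converged=True, residual=resid)
    # Unreachable for finite graphs under monotone updates, reported anyway.
    return MaxState(activity=x, iterations=max_iter, converged=False, residual=resid)


def relax_dynamics(
    net: MaxNetwork,
    dt: float = 0.1,
    t_max: float = 500.0,
    tol: float = 1e-9,
    leak: float = 1.0,
) -> MaxState:
    """Integrate the leaky dendritic-gating dynamics of the microcircuit.

    Each dendritic branch passes its collateral only in excess of the node's
    own activity (the interneuron subtracts the somatic level at every
    branch), so the soma is driven by ``max(ff_i, x_i + max_j [x_j - x_i]_+)``
    and decays toward that drive with rate ``leak``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    ff = net.feedforward
    x = ff.copy()
    src, dst = net.active_edges()
    n_steps = int(np.ceil(t_max / dt))
    gated = np.zeros_like(x)
    for it in range(1, n_steps + 1):
        if src.size:
            gated[:] = 0.0
            # [x_j - x_i]_+ on each branch; soma sees its own level plus the
            # strongest surviving branch, i.e. max(x_i, max_j x_j) when any
            # branch survives.
            np.maximum.at(gated, dst, np.maximum(x[src] - x[dst], 0.0))
            drive = np.maximum(ff, x + gated)
        else:
            drive = ff
        drive = np.where(net.support, drive, ff)
        dx = dt * leak * (drive - x)
        x = x + dx
        resid = float(np.max(np.abs(dx)))
        if resid <= tol:
            return MaxState(activity=x, iterations=it, converged=True, residual=resid)
    return MaxState(activity=x, iterations=n_steps, converged=False, residual=resid)
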