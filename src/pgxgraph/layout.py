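"""Deterministic force-directed layout.

A seeded spring embedder in the Fruchterman–Reingold family: every node pair
repels with an inverse-square force ``k³/d²`` and every edge attracts with
``d²/k``, where ``k`` is the ideal edge length (canvas units are abstract;
the renderer scales to the viewport). The corresponding energy

    E = Σ_edges |d|³ / (3k)  +  k³ Σ_pairs 1 / |d|

is non-negative and is what ``final_stress`` reports. Positions are updated
by force descent with an adaptive step and a candidate move is accepted only
if it does not increase E, so the recorded stress is non-increasing across
cooling epochs and the result for a fixed (graph, seed, max_iter) is
bit-identical between runs. For an isolated connected pair the equilibrium
separation solves d²/k = k³/d², i.e. d = k exactly.
"""

from __future__ import annotations

import math

import numpy as np
from pydantic import BaseModel, Field

from .graph_builder import AnnotatedGraph

__all__ = ["LayoutResult", "force_layout", "two_node_equilibrium_distance"]

_EPS = 1e-9


class LayoutResult(BaseModel):
    positions: dict[str, tuple[float, float]]
    iterations_run: int
    final_stress: float
    seed: int
    stress_history: list[float] = Field(default_factory=list)


def two_node_equilibrium_distance(k: float) -> float:
    """Closed-form rest distance of a single connected pair: d = k."""
    return k


def _energy(pos: np.ndarray, edge_idx: np.ndarray, k: float) -> float:
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    iu = np.triu_indices(len(pos), 1)
    rep = k**3 * (1.0 / np.maximum(dist[iu], _EPS)).sum()
    att = 0.0
    if len(edge_idx):
        d = dist[edge_idx[:, 0], edge_idx[:, 1]]
        att = float((d**3).sum()) / (3.0 * k)
    return float(att + rep)


def _forces(pos: np.ndarray, edge_idx: np.ndarray, k: float) -> np.ndarray:
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.maximum(np.sqrt((diff**2).sum(-1)), _EPS)
    np.fill_diagonal(dist, np.inf)
    # repulsion k^3/d^2, directed away from the other node
    f = (k**3 / dist**3)[:, :, None] * diff
    force = f.sum(axis=1)
    if len(edge_idx):
        i, j = edge_idx[:, 0], edge_idx[:, 1]
        d = dist[i, j][:, None]
        pull = (d / k) * (pos[j] - pos[i])  # magnitude d^2/k toward neighbor
        np.add.at(force, i, pull)
        np.add.at(force, j, -pull)
    return force


def force_layout(
    g: AnnotatedGraph,
    seed: int,
    max_iter: int = 300,
    k: float = 1.0,
) -> LayoutResult:
    """Lay out an annotated graph; a pure function of (g, seed, max_iter, k).

    Raises ``ValueError`` for ``max_iter < 1`` or an empty graph.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    ids = [n.node_id for n in g.nodes]
    if not ids:
        raise ValueError("cannot lay out an empty graph")
    index = {nid: i for i, nid in enumerate(ids)}
    edge_idx = np.array(
        sorted({(index[e.from_id], index[e.to_id]) for e in g.edges}), dtype=int
    ).reshape(-1, 2)

    rng = np.random.default_rng(seed)
    span = k * max(1.0, math.sqrt(len(ids)))
    pos = rng.uniform(0.0, span, size=(len(ids), 2))
    if len(ids) == 1:
        return LayoutResult(
            positions={ids[0]: (float(pos[0, 0]), float(pos[0, 1]))},
            iterations_run=0,
            final_stress=0.0,
            seed=seed,
            stress_history=[0.0],
        )

    energy = _energy(pos, edge_idx, k)
    history = [energy]
    lr = 0.1  # damped force step; stable for the pair stiffness E''(k) = 4
    temp = 0.2 * span  # cooling cap on per-epoch displacement
    iterations = 0
    for _ in range(max_iter):
        iterations += 1
        force = _forces(pos, edge_idx, k)
        norm = np.maximum(np.sqrt((force**2).sum(-1, keepdims=True)), _EPS)
        disp = force * lr
        disp *= np.minimum(1.0, temp / np.maximum(norm * lr, _EPS))
        accepted = False
        for _try in range(30):
            cand = pos + disp
            cand_e = _energy(cand, edge_idx, k)
            if cand_e <= energy:
                pos, energy, accepted = cand, cand_e, True
                break
            disp *= 0.5
        history.append(energy)
        if not accepted:
            break  # no strictly non-worsening move at any scale: converged
        temp *= 0.98  # cooling

    return LayoutResult(
        positions={nid: (float(pos[i, 0]), float(pos[i, 1])) for nid, i in index.items()},
        iterations_run=iterations,
        final_stress=energy,
        seed=seed,
        stress_history=history,
    )
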