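"""Globally optimal tile placement via per-direction minimum spanning trees.

Pairwise displacements are redundant (the grid graph has cycles), so
absolute tile coordinates are fixed by a minimum spanning tree of the tile
mesh, with edge weight the inverse of the displacement reliability
(reliability 0 -> infinite weight).  The MST keeps, for each direction
independently, the most reliable consistent subset of displacements;
infinite edges enter the tree only when connectivity demands (isolated
stitchable regions), in which case those edges contribute the plain stage
displacement.  Coordinates are accumulated from the anchor tile (0, 0)
along the tree and finally translated so the minimum per direction is 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx

from .volume_model import (
    DIRECTIONS,
    PairDisplacement,
    StitchState,
    grid_pairs,
)

__all__ = ["TileGraph", "build_graph", "minimum_spanning_tree", "solve_placement"]


@dataclass
class TileGraph:
    """The tile mesh for one direction: inverse-reliability weights plus
    signed offsets (corrections relative to nominal, from the
    lower-index to the higher-index tile of each edge)."""

    direction: str
    graph: nx.Graph


def build_graph(state: StitchState, direction: str) -> TileGraph:
    """Build the weighted tile mesh for one of V, H, D.

    Every grid adjacency is present; pairs missing from the state (e.g.
    after a preview-restricted alignment) behave like nonstitchable ones:
    reliability 0, offset 0 (the stage default), infinite weight.
    """
    state.require_stage("thresholded", "placed")
    i = DIRECTIONS.index(direction)
    g = nx.Graph()
    vol = state.volume
    for r in range(vol.n_rows):
        for c in range(vol.n_cols):
            g.add_node((r, c))
    for key in grid_pairs(vol.n_rows, vol.n_cols):  # lexicographic insertion
        entry = state.pair_displacements.get(key)
        if entry is None:
            rel, off = 0.0, 0
        else:
            pd: PairDisplacement = entry  # single record after thresholding
            rel, off = pd.reliabilities[i], pd.offsets[i]
        if rel == 0:
            off = 0  # zero reliability means: fall back to stage coordinates
        weight = (1.0 / rel) if rel > 0 else math.inf
        g.add_edge(key[0], key[1], weight=weight, offset=int(off))
    return TileGraph(direction=direction, graph=g)


def minimum_spanning_tree(tile_graph: TileGraph) -> list[tuple]:
    """Kruskal MST of the tile mesh; deterministic under ties.

    Edges were inserted in lexicographic endpoint order and Kruskal's sort
    is stable, so equal weights are broken lexicographically.  Infinite
    edges sort last and are taken only when no finite edge can complete the
    spanning tree.
    """
    g = tile_graph.graph
    edges = [
        tuple(sorted((u, v)))
        for u, v, _ in nx.minimum_spanning_edges(g, algorithm="kruskal", data=True)
    ]
    assert len(edges) == g.number_of_nodes() - 1
    return sorted(edges)


def solve_placement(state: StitchState) -> StitchState:
    """Compute absolute per-tile (V, H, D) voxel coordinates; stage 'placed'.

    For each direction: build the graph, take the MST, root it at tile
    (0, 0) and accumulate, along every tree edge, the nominal stage offset
    plus the computed correction (sign flipped when the edge is traversed
    from the higher-index to the lower-index tile).  The three directions
    are solved independently; finally each direction is translated so its
    minimum coordinate is 0.
    """
    state.require_stage("thresholded")
    vol = state.volume
    coords: dict[tuple[int, int], list[int]] = {
        node: [0, 0, 0] for node in vol.tiles
    }
    for i, direction in enumerate(DIRECTIONS):
        tg = build_graph(state, direction)
        tree = nx.Graph()
        tree.add_nodes_from(tg.graph.nodes)
        for u, v in minimum_spanning_tree(tg):
            tree.add_edge(u, v, offset=tg.graph.edges[u, v]["offset"])
        pos: dict[tuple[int, int], int] = {(0, 0): 0}
        for parent, child in nx.bfs_edges(tree, (0, 0)):
            a, b = sorted((parent, child))
            nominal = _nominal(vol, b, i) - _nominal(vol, a, i)
            step = nominal + tree.edges[a, b]["offset"]
            pos[child] = pos[parent] + (step if child == b else -step)
        lo = min(pos.values())
        for node in pos:
            coords[node][i] = pos[node] - lo
    return StitchState(
        stage="placed",
        volume=vol,
        pair_displacements=dict(state.pair_displacements),
        placements={node: tuple(c) for node, c in coords.items()},  # type: ignore[misc]
    )


def _nominal(vol, node: tuple[int, int], axis: int) -> int:
    t = vol.tile(*node)
    return (t.nominal_v, t.nominal_h, t.nominal_d)[axis]
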