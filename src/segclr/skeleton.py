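"""Skeleton graphs with path-length queries.

A skeleton is a 1-D graph summarizing a segment's centerline: nodes carry
physical coordinates in nanometers (and optionally a local radius), edges
are weighted by their Euclidean length. Path length between two nodes is
the length of the shortest edge path; it drives positive-pair sampling,
inference-time node spacing, and radius-window embedding aggregation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np


@dataclass(frozen=True)
class RadiusWindow:
    """Nodes within path-length radius ``R`` of a center node.

    ``r_max`` is the path distance to the furthest collected node; it is
    used downstream to flag fragments too short to aggregate meaningfully.
    """

    center_node_id: int
    collected_node_ids: frozenset[int]
    r_nm: float
    r_max_nm: float
    distances: dict[int, float] = field(compare=False, default_factory=dict)


class Skeleton:
    """Per-segment node/edge graph in nm with a path-length metric."""

    def __init__(self, segment_id: int, nodes: dict[int, tuple[float, float, float]],
                 edges: list[tuple[int, int]],
                 radii: dict[int, float] | None = None):
        if len(set(nodes)) != len(nodes):
            raise ValueError("node ids must be unique")
        self.segment_id = int(segment_id)
        self.graph = nx.Graph()
        for nid, xyz in nodes.items():
            self.graph.add_node(int(nid), xyz=np.asarray(xyz, dtype=float))
        for a, b in edges:
            if a not in nodes or b not in nodes:
                raise ValueError(f"edge ({a}, {b}) references unknown node")
            length = float(np.linalg.norm(np.asarray(nodes[a], float)
                                          - np.asarray(nodes[b], float)))
            if length <= 0:
                raise ValueError(f"edge ({a}, {b}) has non-positive length")
            self.graph.add_edge(int(a), int(b), weight=length)
        self.radii = {int(k): float(v) for k, v in (radii or {}).items()}

    # -- basics ------------------------------------------------------------
    @property
    def node_ids(self) -> list[int]:
        return sorted(self.graph.nodes)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def coords(self, node_id: int) -> np.ndarray:
        return self.graph.nodes[node_id]["xyz"]

    def coords_array(self, node_ids=None) -> np.ndarray:
        ids = self.node_ids if node_ids is None else list(node_ids)
        return np.array([self.coords(i) for i in ids], dtype=float)

    def total_path_length(self) -> float:
        return float(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))

    # -- path-length queries ----------------------------------------------
    def path_length(self, node_a: int, node_b: int) -> float:
        """Shortest-path arc length in nm; +inf across components."""
        for n in (node_a, node_b):
            if n not in self.graph:
                raise KeyError(f"unknown node id {n}")
        if node_a == node_b:
            return 0.0
        try:
            return float(nx.dijkstra_path_length(self.graph, node_a, node_b))
        except nx.NetworkXNoPath:
            return math.inf

    def distances_from(self, source: int, cutoff: float | None = None) -> dict[int, float]:
        if source not in self.graph:
            raise KeyError(f"unknown node id {source}")
        return {int(k): float(v) for k, v in
                nx.single_source_dijkstra_path_length(
                    self.graph, source, cutoff=cutoff).items()}

    def nodes_within_radius(self, center: int, r_nm: float) -> RadiusWindow:
        """All nodes with path length <= r_nm from ``center``."""
        if r_nm < 0:
            raise ValueError("radius must be non-negative")
        dists = self.distances_from(center, cutoff=r_nm)
        r_max = max(dists.values()) if dists else 0.0
        return RadiusWindow(center_node_id=center,
                            collected_node_ids=frozenset(dists),
                            r_nm=float(r_nm), r_max_nm=float(r_max),
                            distances=dists)

    # -- resampling --------------------------------------------------------
    def components(self) -> list[set[int]]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def resample_nodes(self, spacing_nm: float = 1500.0) -> list[int]:
        """Greedy traversal emitting nodes ~``spacing_nm`` apart along paths.

        Each connected component is walked depth-first from its lowest node
        id; a node is emitted whenever the cumulative path length since the
        last emitted node on the walk reaches ``spacing_nm``. The root of
        every component is always emitted.
        """
        if spacing_nm <= 0:
            raise ValueError("spacing must be positive")
        emitted: list[int] = []
        for comp in sorted(self.components(), key=min):
            root = min(comp)
            emitted.append(root)
            seen = {root}
            # stack entries: (node, distance since last emission)
            stack: list[tuple[int, float]] = [(root, 0.0)]
            while stack:
                node, since = stack.pop()
                for nb in sorted(self.graph.neighbors(node), reverse=True):
                    if nb in seen:
                        continue
                    seen.add(nb)
                    d = since + self.graph.edges[node, nb]["weight"]
                    if d >= spacing_nm:
                        emitted.append(nb)
                        d = 0.0
                    stack.append((nb, d))
        return emitted

    # -- SWC io ------------------------------------------------------------
    def to_swc(self, path: str | Path) -> None:
        """Write SWC (node_id, type, x, y, z, radius, parent_id); roots get -1."""
        lines = ["# segment_id %d" % self.segment_id,
                 "# id type x y z radius parent"]
        parent: dict[int, int] = {}
        for comp in sorted(self.components(), key=min):
            root = min(comp)
            parent[root] = -1
            for a, b in nx.bfs_edges(self.graph, root):
                parent[b] = a
        for nid in self.node_ids:
            x, y, z = self.coords(nid)
            r = self.radii.get(nid, 0.0)
            lines.append(f"{nid} 0 {x:.3f} {y:.3f} {z:.3f} {r:.3f} {parent[nid]}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_swc(cls, path: str | Path, segment_id: int | None = None) -> "Skeleton":
        nodes: dict[int, tuple[float, float, float]] = {}
        radii: dict[int, float] = {}
        edges: list[tuple[int, int]] = []
        seg = segment_id
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if line.startswith("#"):
                if line.startswith("# segment_id") and seg is None:
                    seg = int(line.split()[-1])
                continue
            if not line:
                continue
            parts = line.split()
            nid, parent = int(parts[0]), int(parts[6])
            nodes[nid] = (float(parts[2]), float(parts[3]), float(parts[4]))
            radii[nid] = float(parts[5])
            if parent != -1:
                edges.append((parent, nid))
        return cls(seg if seg is not None else 0, nodes, edges, radii)


def polyline_skeleton(segment_id: int, points_nm: np.ndarray,
                      radii_nm=None) -> Skeleton:
    """Build a chain skeleton from an ordered polyline of nm coordinates."""
    pts = np.asarray(points_nm, dtype=float)
    nodes = {i: tuple(p) for i, p in enumerate(pts)}
    edges = [(i, i + 1) for i in range(len(pts) - 1)]
    radii = None
    if radii_nm is not None:
        radii = {i: float(r) for i, r in enumerate(radii_nm)}
    return Skeleton(segment_id, nodes, edges, radii)
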