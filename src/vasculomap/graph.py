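"""Spatial vessel graphs.

A :class:`VesselGraph` is a spatial multigraph: nodes are branch points,
endpoints, or control-volume boundary cuts, each with a 3D position in μm;
edges ("segments") carry an ordered polyline of μm points and a per-point
radius.  Parallel segments and self-loops (anatomical loops) are allowed,
hence the multigraph.

Segment polylines are oriented: ``data["u"]`` records the node at
``polyline[0]``.  Lengths are Euclidean polyline lengths, never voxel
counts.
"""

from __future__ import annotations

from typing import Iterator

import networkx as nx
import numpy as np

BRANCH = "branch"
ENDPOINT = "endpoint"
BOUNDARY = "boundary"


def polyline_length(points: np.ndarray) -> float:
    """Sum of consecutive point-to-point Euclidean distances, in μm."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


class VesselGraph:
    """Multigraph of vessel nodes and polyline segments (all geometry μm)."""

    def __init__(self) -> None:
        self.g = nx.MultiGraph()
        self._next_node = 0
        self._next_segment = 0

    # ------------------------------------------------------------------ nodes

    def add_node(self, pos, kind: str | None = None) -> int:
        nid = self._next_node
        self._next_node += 1
        self.g.add_node(nid, pos=np.asarray(pos, dtype=float), kind=kind)
        return nid

    def node_pos(self, nid: int) -> np.ndarray:
        return self.g.nodes[nid]["pos"]

    def node_kind(self, nid: int) -> str:
        """Node kind; inferred from degree when not set explicitly."""
        kind = self.g.nodes[nid].get("kind")
        if kind is not None:
            return kind
        return ENDPOINT if self.g.degree(nid) <= 1 else BRANCH

    def endpoint_nodes(self) -> list[int]:
        return [n for n in self.g.nodes if self.g.degree(n) == 1]

    def branch_nodes(self) -> list[int]:
        return [n for n in self.g.nodes if self.g.degree(n) >= 3]

    # --------------------------------------------------------------- segments

    def add_segment(self, u: int, v: int, polyline, radii) -> int:
        """Add a segment oriented from ``u`` to ``v``.

        ``polyline`` must run from u's position to v's position; ``radii``
        gives one μm radius per polyline point.
        """
        polyline = np.asarray(polyline, dtype=float).reshape(-1, 3)
        radii = np.asarray(radii, dtype=float).ravel()
        if len(radii) != len(polyline):
            raise ValueError("radii and polyline length mismatch")
        if len(polyline) < 2:
            raise ValueError("segment polyline needs at least 2 points")
        sid = self._next_segment
        self._next_segment += 1
        self.g.add_edge(
            u,
            v,
            key=sid,
            u=u,
            polyline=polyline,
            radii=radii,
            length=polyline_length(polyline),
            mean_radius=float(radii.mean()),
        )
        return sid

    def segments(self) -> Iterator[tuple[int, int, int, dict]]:
        """Yield ``(u, v, key, data)`` with u/v in polyline orientation."""
        for a, b, key, data in self.g.edges(keys=True, data=True):
            u = data["u"]
            v = b if u == a else a
            yield u, v, key, data

    def oriented_polyline(self, a: int, b: int, key: int) -> tuple[np.ndarray, np.ndarray]:
        """Polyline and radii oriented from ``a`` to ``b``."""
        data = self.g.edges[a, b, key]
        if data["u"] == a and not (a == b):
            return data["polyline"], data["radii"]
        if a == b:  # self-loop: orientation is arbitrary
            return data["polyline"], data["radii"]
        return data["polyline"][::-1], data["radii"][::-1]

    def remove_segment(self, a: int, b: int, key: int, drop_isolated: bool = True) -> None:
        self.g.remove_edge(a, b, key)
        if drop_isolated:
            for n in {a, b}:
                if n in self.g and self.g.degree(n) == 0:
                    self.g.remove_node(n)

    # ------------------------------------------------------------- summaries

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_segments(self) -> int:
        return self.g.number_of_edges()

    def total_length(self) -> float:
        return float(sum(d["length"] for _, _, d in self.g.edges(data=True)))

    def n_components(self) -> int:
        return nx.number_connected_components(self.g)

    def component_labels(self) -> dict[int, int]:
        labels: dict[int, int] = {}
        for i, comp in enumerate(nx.connected_components(self.g)):
            for n in comp:
                labels[n] = i
        return labels

    def copy(self) -> "VesselGraph":
        out = VesselGraph()
        out.g = self.g.copy()
        # deep-copy mutable per-edge arrays so edits don't alias
        for a, b, key, data in out.g.edges(keys=True, data=True):
            data["polyline"] = data["polyline"].copy()
            data["radii"] = data["radii"].copy()
        out._next_node = self._next_node
        out._next_segment = self._next_segment
        return out

    # ------------------------------------------------------------ operations

    def collapse_node(self, n: int) -> bool:
        """Splice out a degree-2 node, merging its two segments into one.

        Returns False (no-op) for self-loop anchors or non-degree-2 nodes.
        """
        if n not in self.g or self.g.degree(n) != 2:
            return False
        incident = list(self.g.edges(n, keys=True))
        if len(incident) == 1:  # single self-loop: keep the anchor node
            return False
        (_, a, k1), (_, b, k2) = incident
        p1, r1 = self.oriented_polyline(a, n, k1)
        p2, r2 = self.oriented_polyline(n, b, k2)
        merged_p = np.vstack([p1, p2[1:]])
        merged_r = np.concatenate([r1, r2[1:]])
        self.g.remove_edge(a, n, k1)
        self.g.remove_edge(n, b, k2)
        self.g.remove_node(n)
        self.add_segment(a, b, merged_p, merged_r)
        return True

    def collapse_degree2_nodes(self, keep: set[int] | None = None) -> int:
        """Splice out every degree-2 interior node; returns number removed."""
        keep = keep or set()
        removed = 0
        changed = True
        while changed:
            changed = False
            for n in list(self.g.nodes):
                if n in keep or n not in self.g:
                    continue
                if self.g.nodes[n].get("kind") == BOUNDARY:
                    continue
                if self.collapse_node(n):
                    removed += 1
                    changed = True
        return removed

    def merge_nodes(self, u: int, v: int, new_pos=None) -> int:
        """Merge node ``v`` into ``u``, re-anchoring v's segments at u.

        Re-attached polylines get u's (possibly updated) position appended
        so the segment still terminates at its node.  Used to contract
        spurious short inter-node segments.
        """
        if new_pos is None:
            new_pos = 0.5 * (self.node_pos(u) + self.node_pos(v))
        new_pos = np.asarray(new_pos, dtype=float)
        self.g.nodes[u]["pos"] = new_pos
        for _, other, key in list(self.g.edges(v, keys=True)):
            p, r = self.oriented_polyline(v, other, key)
            self.g.remove_edge(v, other, key)
            if other == v:  # self-loop transfers wholesale
                self.add_segment(u, u, np.vstack([new_pos, p[1:-1], new_pos]),
                                 np.concatenate([[r[0]], r[1:-1], [r[-1]]]))
                continue
            self.add_segment(u, other, np.vstack([[new_pos], p]),
                             np.concatenate([[r[0]], r]))
        self.g.remove_node(v)
        # also re-anchor u's own pre-existing segments at the new position
        for _, other, key in list(self.g.edges(u, keys=True)):
            p, r = self.oriented_polyline(u, other, key)
            if not np.allclose(p[0], new_pos):
                self.g.remove_edge(u, other, key)
                if other == u:
                    self.add_segment(u, u, p, r)
                else:
                    self.add_segment(u, other, np.vstack([[new_pos], p]),
                                     np.concatenate([[r[0]], r]))
        return u

    # ---------------------------------------------------------------- tables

    def nodes_table(self):
        import pandas as pd

        rows = []
        for n in self.g.nodes:
            x, y, z = self.node_pos(n)
            rows.append(
                dict(id=n, x_um=x, y_um=y, z_um=z,
                     kind=self.node_kind(n), degree=self.g.degree(n))
            )
        return pd.DataFrame(rows, columns=["id", "x_um", "y_um", "z_um", "kind", "degree"])

    def segments_table(self):
        import pandas as pd

        rows = []
        for u, v, key, data in self.segments():
            rows.append(
                dict(id=key, node_a=u, node_b=v,
                     length_um=data["length"], mean_radius_um=data["mean_radius"])
            )
        return pd.DataFrame(
            rows, columns=["id", "node_a", "node_b", "length_um", "mean_radius_um"]
        )
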