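"""Semi-metric topological experience map with loop-closure relaxation.

Vertices store positions decoded from the grid network (mutable under
relaxation) together with the odometric displacement from the previous
vertex (immutable).  A loop closure adds a link between the current vertex
and a re-recognised one; graph relaxation then moves vertex positions to
minimise the disagreement between stored relative displacements and the
absolute positions:

    E = sum over links |p_to - p_from - rel|^2.

Relaxation performs Gauss-Seidel sweeps: each vertex moves a fraction
min(alpha, 1/degree) of the way toward the average position its incident
links suggest.  Each single-vertex move is an under-relaxed minimisation of
the (convex, quadratic) local energy, so E is non-increasing sweep by
sweep.  The root vertex is held fixed to pin the translation gauge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "ExperienceVertex",
    "ExperienceLink",
    "ExperienceGraph",
    "maybe_create_vertex",
    "close_loop",
    "relax_graph",
]


@dataclass
class ExperienceVertex:
    id: int
    position: np.ndarray                 # (x, y) metres, mutable under relaxation
    odometry_from_prev: np.ndarray       # (dx, dy) metres at creation, immutable
    view_id: int | None = None


@dataclass
class ExperienceLink:
    from_id: int
    to_id: int
    rel: np.ndarray                      # stored relative displacement (dx, dy)


@dataclass
class ExperienceGraph:
    creation_threshold: float = 5.0      # metres between consecutive vertices
    relax_rate: float = 0.25             # alpha of the relaxation update
    relax_iters: int = 20                # sweeps per loop closure
    vertices: dict[int, ExperienceVertex] = field(default_factory=dict)
    links: list[ExperienceLink] = field(default_factory=list)
    current_id: int | None = None

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def current(self) -> ExperienceVertex | None:
        return None if self.current_id is None else self.vertices[self.current_id]

    def energy(self) -> float:
        """Total disagreement between link displacements and vertex positions."""
        e = 0.0
        for link in self.links:
            d = (
                self.vertices[link.to_id].position
                - self.vertices[link.from_id].position
                - link.rel
            )
            e += float(d @ d)
        return e

    # -- export -------------------------------------------------------------

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for v in self.vertices.values():
            g.add_node(v.id, x=float(v.position[0]), y=float(v.position[1]),
                       view_id=-1 if v.view_id is None else int(v.view_id))
        for link in self.links:
            g.add_edge(link.from_id, link.to_id,
                       dx=float(link.rel[0]), dy=float(link.rel[1]))
        return g

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))

    def to_json(self, path: str | Path) -> None:
        data = {
            "vertices": [
                {
                    "id": v.id,
                    "position": v.position.tolist(),
                    "odometry_from_prev": v.odometry_from_prev.tolist(),
                    "view_id": v.view_id,
                }
                for v in self.vertices.values()
            ],
            "links": [
                {"from": l.from_id, "to": l.to_id, "rel": l.rel.tolist()}
                for l in self.links
            ],
        }
        Path(path).write_text(json.dumps(data))


def maybe_create_vertex(
    graph: ExperienceGraph,
    decoded_xy,
    active_view=None,
) -> tuple[ExperienceVertex | None, ExperienceLink | None]:
    """Create a vertex when the decoded position moved far enough.

    An empty graph gets a root vertex at the decoded position.  Otherwise a
    new vertex (plus a link carrying the decoded displacement) is created
    once the displacement from the current vertex reaches the creation
    threshold.
    """
    p = np.asarray(decoded_xy, dtype=float)
    view_id = None if active_view is None else active_view.id
    if graph.current_id is None:
        v = ExperienceVertex(0, p.copy(), np.zeros(2), view_id)
        graph.vertices[0] = v
        graph.current_id = 0
        return v, None
    cur = graph.current
    rel = p - cur.position
    if float(np.hypot(*rel)) < graph.creation_threshold:
        return None, None
    vid = max(graph.vertices) + 1
    v = ExperienceVertex(vid, p.copy(), rel.copy(), view_id)
    graph.vertices[vid] = v
    link = ExperienceLink(cur.id, vid, rel.copy())
    graph.links.append(link)
    graph.current_id = vid
    return v, link


def close_loop(
    graph: ExperienceGraph,
    current_vertex: int,
    matched_view_vertex: int,
    measured_rel,
    relax: bool = True,
) -> ExperienceLink | None:
    """Add a loop-closure link and relax the graph.

    ``measured_rel`` is the odometrically measured displacement from the
    current vertex to the matched one.  A self-closure is a no-op.
    """
    if current_vertex == matched_view_vertex:
        return None
    link = ExperienceLink(
        current_vertex, matched_view_vertex, np.asarray(measured_rel, dtype=float)
    )
    graph.links.append(link)
    if relax:
        relax_graph(graph)
    return link


def relax_graph(
    graph: ExperienceGraph,
    alpha: float | None = None,
    iters: int | None = None,
) -> ExperienceGraph:
    """Gauss-Seidel relaxation of vertex positions against link constraints.

    Sweeps the vertices in id order; vertex i moves by
    min(alpha, 1/deg_i) * sum over incident links of (suggested - current),
    where an outgoing link (i -> j) suggests p_j - rel and an incoming link
    (j -> i) suggests p_j + rel.  The root vertex stays fixed.  The energy
    is non-increasing across sweeps.
    """
    alpha = graph.relax_rate if alpha is None else alpha
    iters = graph.relax_iters if iters is None else iters
    if not graph.vertices:
        return graph
    root = min(graph.vertices)
    incident: dict[int, list[tuple[int, np.ndarray]]] = {
        vid: [] for vid in graph.vertices
    }
    for link in graph.links:
        incident[link.from_id].append((link.to_id, -link.rel))
        incident[link.to_id].append((link.from_id, link.rel))
    order = sorted(graph.vertices)
    for _ in range(iters):
        for vid in order:
            if vid == root:
                continue
            nbrs = incident[vid]
            if not nbrs:
                continue
            rate = min(alpha, 1.0 / len(nbrs))
            p = graph.vertices[vid].position
            delta = np.zeros(2)
            for other, rel in nbrs:
                delta += graph.vertices[other].position + rel - p
            graph.vertices[vid].position = p + rate * delta
    return graph
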