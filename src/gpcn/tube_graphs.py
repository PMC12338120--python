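"""Offset-tube and grid graphs, Laplacians, and the microtubule lattice geometry.

An offset tube ``GTube(n, k, p)`` is the graph of a helical lattice with ``n``
rings of ``k`` monomers each: node ``(r, j)`` (ring ``r``, protofilament ``j``)
connects longitudinally to ``(r+1, j)``, laterally to ``(r, j+1)``, and the tube
is closed by *seam* edges joining ``(r, k-1)`` to ``(r+p, 0)``, where ``p`` is
the seam offset (helical pitch, in monomer units).  A 13-protofilament
microtubule of 48 monomer rings with pitch 3 is ``GTube(48, 13, 3)``.

The structure matrix used throughout is the Laplacian in the ``A - D``
convention, ``L = A - diag(A 1)``; its spectrum is non-positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable
import warnings

import numpy as np
import scipy.sparse as sp

__all__ = [
    "TubeSpec",
    "Graph",
    "LatticeGeometry",
    "RESTING_LENGTHS",
    "RESTING_ANGLES",
    "build_tube_graph",
    "build_grid_graph",
    "laplacian",
    "build_lattice_geometry",
    "write_edgelist_tsv",
    "read_edgelist_tsv",
]

# Resting lengths (nm) and angles (degrees) of the five microtubule interaction
# types.  These are authoritative constants of the model, not derived from the
# helix coordinates below.
RESTING_LENGTHS: dict[str, float] = {
    "LatAssoc": 5.15639,
    "LongAssoc": 5.0,
}
RESTING_ANGLES: dict[str, float] = {
    "LatAngle": 153.023,
    "LongAngle": 180.0,
    "QuadAcute": 77.0694,
    "QuadObtuse": 102.931,
}

#: strength-parameter name for each geometric interaction type
STRENGTH_OF_TYPE: dict[str, str] = {
    "LatAssoc": "LatAssoc",
    "LongAssoc": "LongAssoc",
    "LatAngle": "LatAngle",
    "LongAngle": "LongAngle",
    "QuadAcute": "QuadAngles",
    "QuadObtuse": "QuadAngles",
}


class InvalidSpecError(ValueError):
    """Raised when a tube/grid specification violates its invariants."""


@dataclass(frozen=True)
class TubeSpec:
    """Parameters (n, k, p) of an offset tube graph, plus the seam edge weight."""

    n_rings: int
    k_per_turn: int
    offset: int = 0
    seam_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.n_rings < 1 or self.k_per_turn < 3:
            raise InvalidSpecError(
                f"need n_rings >= 1 and k_per_turn >= 3, got {self.n_rings}, {self.k_per_turn}"
            )
        if not 0 <= self.offset < self.n_rings:
            raise InvalidSpecError(
                f"offset must satisfy 0 <= offset < n_rings, got {self.offset} vs {self.n_rings}"
            )
        if self.seam_weight <= 0:
            raise InvalidSpecError("seam_weight must be positive")

    @property
    def node_count(self) -> int:
        return self.n_rings * self.k_per_turn

    def node_id(self, ring: int, pf: int) -> int:
        return ring * self.k_per_turn + pf


@dataclass
class Graph:
    """Undirected weighted graph with 0-based contiguous node ids.

    Edges are stored canonically as ``(i, j, weight)`` with ``i < j``; no
    self-loops or duplicates.
    """

    node_count: int
    edges: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        canon = []
        seen = set()
        for i, j, w in self.edges:
            if i == j:
                raise ValueError(f"self-loop at node {i}")
            if not (0 <= i < self.node_count and 0 <= j < self.node_count):
                raise ValueError(f"edge ({i},{j}) out of range")
            if w <= 0:
                raise ValueError(f"non-positive weight on edge ({i},{j})")
            a, b = (i, j) if i < j else (j, i)
            if (a, b) in seen:
                raise ValueError(f"duplicate edge ({a},{b})")
            seen.add((a, b))
            canon.append((a, b, float(w)))
        self.edges = sorted(canon)

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    def adjacency(self) -> sp.csr_array:
        """Symmetric weighted adjacency matrix (CSR)."""
        n = self.node_count
        if not self.edges:
            return sp.csr_array((n, n))
        ii, jj, ww = zip(*self.edges)
        ii, jj, ww = np.array(ii), np.array(jj), np.array(ww)
        a = sp.coo_array(
            (np.concatenate([ww, ww]), (np.concatenate([ii, jj]), np.concatenate([jj, ii]))),
            shape=(n, n),
        )
        return a.tocsr()

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.node_count))
        g.add_weighted_edges_from(self.edges)
        return g

    def is_connected(self) -> bool:
        n_comp = sp.csgraph.connected_components(self.adjacency(), directed=False)[0]
        return n_comp == 1


def build_tube_graph(spec: TubeSpec) -> Graph:
    """Construct the offset tube graph GTube(n_rings, k_per_turn, offset).

    Longitudinal and lateral edges have unit weight; seam edges carry
    ``spec.seam_weight``.
    """
    n, k, p = spec.n_rings, spec.k_per_turn, spec.offset
    edges: list[tuple[int, int, float]] = []
    for r in range(n):
        for j in range(k):
            u = spec.node_id(r, j)
            if r + 1 < n:  # longitudinal
                edges.append((u, spec.node_id(r + 1, j), 1.0))
            if j + 1 < k:  # lateral within the turn
                edges.append((u, spec.node_id(r, j + 1), 1.0))
        if 0 <= r + p < n:  # seam closure, shifted by the pitch
            edges.append((spec.node_id(r, k - 1), spec.node_id(r + p, 0), spec.seam_weight))
    return Graph(node_count=n * k, edges=edges)


def build_grid_graph(rows: int, cols: int) -> Graph:
    """Rectangular 4-neighbour grid graph, no wraparound, unit weights."""
    if rows < 1 or cols < 1:
        raise InvalidSpecError(f"grid dimensions must be positive, got {rows}x{cols}")
    edges = []
    for r in range(rows):
        for c in range(cols):
            u = r * cols + c
            if c + 1 < cols:
                edges.append((u, u + 1, 1.0))
            if r + 1 < rows:
                edges.append((u, u + cols, 1.0))
    return Graph(node_count=rows * cols, edges=edges)


def laplacian(g: Graph, dense: bool = False):
    """Graph Laplacian ``L = A - diag(A 1)`` (non-positive spectrum).

    Note the sign: this is the negative of the more common ``D - A`` form.  All
    spectral code in this package uses this convention consistently.
    """
    a = g.adjacency()
    deg = np.asarray(a.sum(axis=1)).ravel()
    lap = (a - sp.diags_array(deg)).tocsr()
    return lap.toarray() if dense else lap


# ---------------------------------------------------------------------------
# lattice geometry
# ---------------------------------------------------------------------------


@dataclass
class LatticeGeometry:
    """3D helical lattice with typed harmonic bond and angle interactions.

    ``bonds`` are ``(i, j, bond_type)``; ``angles`` are ``(i, j, k, angle_type)``
    with ``j`` the vertex.  Resting lengths are nm, resting angles degrees.
    """

    coordinates: np.ndarray  # (n, 3) nm
    bonds: list[tuple[int, int, str]]
    angles: list[tuple[int, int, int, str]]
    resting_lengths: dict[str, float]
    resting_angles: dict[str, float]
    spec: TubeSpec | None = None

    @property
    def node_count(self) -> int:
        return self.coordinates.shape[0]

    def bond_graph(self) -> Graph:
        """Graph induced by the association (bond) list, unit weights."""
        edges = {}
        for i, j, _ in self.bonds:
            a, b = (i, j) if i < j else (j, i)
            edges[(a, b)] = 1.0
        return Graph(self.node_count, [(a, b, w) for (a, b), w in edges.items()])


def _lateral_pairs(spec: TubeSpec) -> list[tuple[int, int]]:
    """Ordered lateral neighbour pairs ((r,j) -> next around the turn), seam included."""
    pairs = []
    n, k, p = spec.n_rings, spec.k_per_turn, spec.offset
    for r in range(n):
        for j in range(k - 1):
            pairs.append((spec.node_id(r, j), spec.node_id(r, j + 1)))
        if 0 <= r + p < n:
            pairs.append((spec.node_id(r, k - 1), spec.node_id(r + p, 0)))
    return pairs


def build_lattice_geometry(
    spec: TubeSpec,
    radius_nm: float = 13.0,
    axial_spacing_nm: float = 5.0,
) -> LatticeGeometry:
    """Place monomers on a helix and enumerate typed bonds/angles.

    Node ``(r, j)`` sits at azimuth ``2*pi*j/k`` and height
    ``r*spacing + j*offset*spacing/k`` (the helical rise per lateral step).
    Interactions are enumerated by pattern-matching templates over the lattice:

    * ``LongAssoc`` bonds between axial neighbours, ``LatAssoc`` bonds between
      lateral neighbours (seam included);
    * ``LongAngle`` at each interior node of a protofilament;
    * ``LatAngle`` (pitch angle) at each node with lateral neighbours on both
      sides;
    * the four angles of every lattice quadrilateral cell, two acute
      (``QuadAcute``) and two obtuse (``QuadObtuse``).

    Resting lengths/angles are the model's tabulated constants, never measured
    from the coordinates.
    """
    if spec.k_per_turn != 13:
        warnings.warn(
            f"spec has k_per_turn={spec.k_per_turn}; geometry templates were designed "
            "for the 13-protofilament microtubule lattice",
            stacklevel=2,
        )
    n, k, p = spec.n_rings, spec.k_per_turn, spec.offset
    rise = p * axial_spacing_nm / k  # helical rise per lateral step
    coords = np.zeros((n * k, 3))
    for r in range(n):
        for j in range(k):
            theta = 2.0 * np.pi * j / k
            coords[spec.node_id(r, j)] = (
                radius_nm * np.cos(theta),
                radius_nm * np.sin(theta),
                r * axial_spacing_nm + j * rise,
            )

    bonds: list[tuple[int, int, str]] = []
    for r in range(n - 1):
        for j in range(k):
            bonds.append((spec.node_id(r, j), spec.node_id(r + 1, j), "LongAssoc"))
    lat = _lateral_pairs(spec)
    bonds.extend((i, j, "LatAssoc") for i, j in lat)

    angles: list[tuple[int, int, int, str]] = []
    # straight angle along each protofilament
    for r in range(1, n - 1):
        for j in range(k):
            angles.append(
                (spec.node_id(r - 1, j), spec.node_id(r, j), spec.node_id(r + 1, j), "LongAngle")
            )
    # pitch angle: two consecutive lateral steps sharing their middle node
    succ = dict(lat)  # i -> lateral successor of i
    for i, j in lat:
        if j in succ:
            angles.append((i, j, succ[j], "LatAngle"))
    # quadrilateral cells: lateral pair (a -> b) with both longitudinal
    # successors present; corners a,b (lower) and c,d (upper)
    long_succ = {
        spec.node_id(r, j): spec.node_id(r + 1, j) for r in range(n - 1) for j in range(k)
    }
    for a, b in lat:
        if a in long_succ and b in long_succ:
            c, d = long_succ[a], long_succ[b]
            # acute corners at the leading-lower and trailing-upper vertices,
            # obtuse at the other two (opposite corners of the parallelogram equal)
            angles.append((b, a, c, "QuadAcute"))
            angles.append((a, d, c, "QuadAcute"))
            angles.append((a, b, d, "QuadObtuse"))
            angles.append((b, c, d, "QuadObtuse"))
    return LatticeGeometry(
        coordinates=coords,
        bonds=bonds,
        angles=angles,
        resting_lengths=dict(RESTING_LENGTHS),
        resting_angles=dict(RESTING_ANGLES),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_edgelist_tsv(g: Graph, path: str | Path) -> None:
    """Write a graph as 0-based TSV lines ``i<TAB>j<TAB>weight``."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# nodes\t{g.node_count}\n")
        for i, j, w in g.edges:
            fh.write(f"{i}\t{j}\t{w:.17g}\n")


def read_edgelist_tsv(path: str | Path) -> Graph:
    path = Path(path)
    node_count = 0
    edges: list[tuple[int, int, float]] = []
    explicit_n = None
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if parts and parts[0] == "nodes":
                explicit_n = int(parts[1])
            continue
        i_s, j_s, w_s = line.split("\t")
        i, j, w = int(i_s), int(j_s), float(w_s)
        node_count = max(node_count, i + 1, j + 1)
        edges.append((i, j, w))
    return Graph(explicit_n if explicit_n is not None else node_count, edges)
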