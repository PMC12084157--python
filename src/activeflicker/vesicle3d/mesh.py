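"""Triangulated closed membrane meshes (icosphere construction + topology).

The mesh is stored as flat arrays suited to the Monte Carlo kernels:

* ``verts`` (N, 3) float64 positions in um
* ``tris``  (F, 3) int32, counterclockwise seen from outside
* ``e_v``   (E, 2) int32 edge endpoints
* ``e_t``   (E, 2) int32 the two triangles sharing each edge
* ``tri_edge`` (F, 3) int32: edge id between tris[f, k] and tris[f, (k+1)%3]
* ``nbr``/``nnbr``: vertex adjacency lists (fixed-width, MAX_DEGREE)
* ``v_tri``/``nvt``: vertex -> incident triangle lists

A closed spherical mesh satisfies Euler's relation N - E + F = 2; bond
flips preserve it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MAX_DEGREE = 16


@dataclass
class MembraneMesh:
    verts: np.ndarray
    tris: np.ndarray
    e_v: np.ndarray
    e_t: np.ndarray
    tri_edge: np.ndarray
    nbr: np.ndarray
    nnbr: np.ndarray
    v_tri: np.ndarray
    nvt: np.ndarray
    l_min: float
    l_max: float
    area_target: float = 0.0
    volume_target: float = 0.0

    @property
    def n_vertices(self) -> int:
        return self.verts.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.tris.shape[0]

    @property
    def n_edges(self) -> int:
        return self.e_v.shape[0]

    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + self.n_triangles

    def copy(self) -> "MembraneMesh":
        return MembraneMesh(
            verts=self.verts.copy(), tris=self.tris.copy(),
            e_v=self.e_v.copy(), e_t=self.e_t.copy(),
            tri_edge=self.tri_edge.copy(), nbr=self.nbr.copy(),
            nnbr=self.nnbr.copy(), v_tri=self.v_tri.copy(),
            nvt=self.nvt.copy(), l_min=self.l_min, l_max=self.l_max,
            area_target=self.area_target, volume_target=self.volume_target)


def triangle_areas(verts: np.ndarray, tris: np.ndarray) -> np.ndarray:
    a = verts[tris[:, 1]] - verts[tris[:, 0]]
    b = verts[tris[:, 2]] - verts[tris[:, 0]]
    return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)


def total_area(verts: np.ndarray, tris: np.ndarray) -> float:
    return float(triangle_areas(verts, tris).sum())


def total_volume(verts: np.ndarray, tris: np.ndarray) -> float:
    """Enclosed volume from signed tetrahedra against the origin."""
    v0 = verts[tris[:, 0]]
    v1 = verts[tris[:, 1]]
    v2 = verts[tris[:, 2]]
    return float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)


def _icosahedron():
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
        [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
        [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1]], dtype=float)
    verts /= np.linalg.norm(verts[0])
    tris = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1]], dtype=np.int32)
    return verts, tris


def _subdivide(verts, tris):
    verts = list(map(tuple, verts))
    cache = {}

    def midpoint(i, j):
        key = (min(i, j), max(i, j))
        if key not in cache:
            v = 0.5 * (np.array(verts[i]) + np.array(verts[j]))
            v /= np.linalg.norm(v)
            cache[key] = len(verts)
            verts.append(tuple(v))
        return cache[key]

    new_tris = []
    for a, b, c in tris:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_tris += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
    return np.array(verts), np.array(new_tris, dtype=np.int32)


def _build_topology(verts, tris):
    n = verts.shape[0]
    edge_map = {}
    e_v, e_t = [], []
    tri_edge = np.full((tris.shape[0], 3), -1, dtype=np.int32)
    for f, tri in enumerate(tris):
        for k in range(3):
            a, b = int(tri[k]), int(tri[(k + 1) % 3])
            key = (min(a, b), max(a, b))
            if key not in edge_map:
                edge_map[key] = len(e_v)
                e_v.append([a, b])
                e_t.append([f, -1])
            else:
                e_t[edge_map[key]][1] = f
            tri_edge[f, k] = edge_map[key]
    e_v = np.asarray(e_v, dtype=np.int32)
    e_t = np.asarray(e_t, dtype=np.int32)
    if np.any(e_t < 0):
        raise ValueError("mesh is not closed")
    nbr = np.full((n, MAX_DEGREE), -1, dtype=np.int32)
    nnbr = np.zeros(n, dtype=np.int32)
    for a, b in e_v:
        nbr[a, nnbr[a]] = b
        nnbr[a] += 1
        nbr[b, nnbr[b]] = a
        nnbr[b] += 1
    v_tri = np.full((n, MAX_DEGREE), -1, dtype=np.int32)
    nvt = np.zeros(n, dtype=np.int32)
    for f, tri in enumerate(tris):
        for v in tri:
            v_tri[v, nvt[v]] = f
            nvt[v] += 1
    return e_v, e_t, tri_edge, nbr, nnbr, v_tri, nvt


def build_vesicle(n_vertices: int = 642, diameter: float = 40.0,
                  reduced_volume: float = 1.0, seed: int = 0,
                  tether_ratio: float = 1.45) -> MembraneMesh:
    """Near-uniform triangulated sphere at the target diameter.

    ``n_vertices`` must be one of the icosphere sizes 162, 642, 2562
    (2, 3 or 4 subdivisions); smaller meshes cannot resolve the mode
    range of interest and are rejected.  The area target is the initial
    sphere's area; the volume target is ``reduced_volume`` times the
    initial enclosed volume, so values < 1 grant excess area for
    deformations.  Construction is deterministic (``seed`` kept for
    interface symmetry).
    """
    sizes = {162: 2, 642: 3, 2562: 4}
    if n_vertices not in sizes:
        if n_vertices < 162:
            raise ValueError("n_vertices must be >= 162 (refined icosahedron)")
        raise ValueError(f"n_vertices must be one of {sorted(sizes)}")
    verts, tris = _icosahedron()
    for _ in range(sizes[n_vertices]):
        verts, tris = _subdivide(verts, tris)
    verts = verts * (diameter / 2.0)
    e_v, e_t, tri_edge, nbr, nnbr, v_tri, nvt = _build_topology(verts, tris)
    lengths = np.linalg.norm(verts[e_v[:, 0]] - verts[e_v[:, 1]], axis=1)
    l0 = float(lengths.mean())
    mesh = MembraneMesh(
        verts=verts, tris=tris, e_v=e_v, e_t=e_t, tri_edge=tri_edge,
        nbr=nbr, nnbr=nnbr, v_tri=v_tri, nvt=nvt,
        l_min=l0 / tether_ratio, l_max=l0 * tether_ratio)
    mesh.area_target = total_area(verts, tris)
    mesh.volume_target = reduced_volume * total_volume(verts, tris)
    lo, hi = lengths.min(), lengths.max()
    if lo < mesh.l_min or hi > mesh.l_max:
        raise ValueError("initial bonds violate tether limits")
    return mesh


def mean_bond_length(mesh: MembraneMesh) -> float:
    d = mesh.verts[mesh.e_v[:, 0]] - mesh.verts[mesh.e_v[:, 1]]
    return float(np.linalg.norm(d, axis=1).mean())
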