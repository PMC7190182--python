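"""Planar cross-sections of triangle meshes.

Slicing a closed, consistently wound surface with a plane yields one or more
closed intersection loops. Each crossing triangle contributes one segment;
orienting every segment along ``plane_normal x face_normal`` makes the
winding consistent within a loop, so loop area and centroid follow from
segment-wise shoelace sums without ordering the polygon first. Loops are
separated by connecting triangles that share a crossed mesh edge.

This module is deliberately array-based: the morphometry stage slices a
canal mesh at hundreds of divisions, so the per-plane cost must stay in the
tens of microseconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SectionLoop", "slice_loops"]


def _cross3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


def _union_find_components(n: int, pairs_a: np.ndarray, pairs_b: np.ndarray):
    """Connected components of n nodes given edge lists (plain union-find;
    the per-plane graphs are tiny, so this beats sparse-matrix machinery)."""
    parent = list(range(n))

    def find(x):
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for a, b in zip(pairs_a.tolist(), pairs_b.tolist()):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    roots = [find(i) for i in range(n)]
    uniq = {}
    comp = np.empty(n, dtype=np.int64)
    for i, r in enumerate(roots):
        comp[i] = uniq.setdefault(r, len(uniq))
    return len(uniq), comp

_EDGE_NEXT = np.array([1, 2, 0])


@dataclass
class SectionLoop:
    """One closed intersection loop of a mesh-plane cut."""

    area: float
    centroid: np.ndarray
    normal: np.ndarray
    points: np.ndarray | None = None  # ordered boundary points (K, 3)


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = normal / np.linalg.norm(normal)
    a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(n, a)
    u /= np.linalg.norm(u)
    return u, np.cross(n, u)


def slice_loops(
    vertices: np.ndarray,
    faces: np.ndarray,
    origin: np.ndarray,
    normal: np.ndarray,
    return_polygons: bool = False,
) -> list[SectionLoop]:
    """Intersect a triangle mesh with the plane through ``origin`` with
    ``normal``; return one :class:`SectionLoop` per closed loop.

    ``return_polygons=True`` additionally orders each loop's boundary
    points (slower; the area/centroid do not need it).
    """
    V = np.asarray(vertices, dtype=float)
    F = np.asarray(faces, dtype=np.int64)
    origin = np.asarray(origin, dtype=float).reshape(3)
    n = np.asarray(normal, dtype=float).reshape(3)
    n = n / np.linalg.norm(n)

    s = V @ n - origin @ n
    # perturb vertices lying exactly on the plane to keep crossings generic
    eps = 1e-9 * max(1.0, np.abs(s).max())
    s = np.where(np.abs(s) < eps, eps, s)

    sf = s[F]
    crossing = (sf.min(axis=1) < 0) & (sf.max(axis=1) > 0)
    if not crossing.any():
        return []
    cf = F[crossing]
    sfc = sf[crossing]

    pos = sfc > 0
    edge_cross = pos != pos[:, _EDGE_NEXT]  # (K, 3), exactly two True per row
    fi, ei = np.nonzero(edge_cross)  # 2K entries, row-major: pairs per face
    a_idx = cf[fi, ei]
    b_idx = cf[fi, _EDGE_NEXT[ei]]
    sa = s[a_idx]
    sb = s[b_idx]
    t = sa / (sa - sb)
    pts = V[a_idx] + t[:, None] * (V[b_idx] - V[a_idx])  # (2K, 3)

    K = len(cf)
    p0 = pts[0::2]
    p1 = pts[1::2]

    # consistent winding: segment runs along plane_normal x face_normal
    v0 = V[cf[:, 0]]
    fn = _cross3(V[cf[:, 1]] - v0, V[cf[:, 2]] - v0)
    tangent = _cross3(np.broadcast_to(n, fn.shape).copy(), fn)
    flip = np.einsum("ij,ij->i", p1 - p0, tangent) < 0
    p0f = np.where(flip[:, None], p1, p0)
    p1f = np.where(flip[:, None], p0, p1)

    # group crossing faces into loops via shared crossed mesh edges
    keys = np.minimum(a_idx, b_idx) * len(V) + np.maximum(a_idx, b_idx)
    uniq, inv, counts = np.unique(keys, return_inverse=True, return_counts=True)
    face_of_entry = fi  # 2K entries -> crossing-face index
    shared = counts == 2
    order = np.argsort(inv, kind="stable")
    # entries sorted by edge key: paired entries are adjacent for shared edges
    sorted_faces = face_of_entry[order]
    sorted_inv = inv[order]
    firsts = np.searchsorted(sorted_inv, np.nonzero(shared)[0], side="left")
    fa = sorted_faces[firsts]
    fb = sorted_faces[firsts + 1]
    n_comp, comp = _union_find_components(K, fa, fb)

    u2, v2 = _plane_basis(n)
    a2 = np.stack([(p0f - origin) @ u2, (p0f - origin) @ v2], axis=1)
    b2 = np.stack([(p1f - origin) @ u2, (p1f - origin) @ v2], axis=1)
    cross2 = a2[:, 0] * b2[:, 1] - a2[:, 1] * b2[:, 0]
    area_c = 0.5 * np.bincount(comp, weights=cross2, minlength=n_comp)
    with np.errstate(divide="ignore", invalid="ignore"):
        cx = np.bincount(comp, weights=(a2[:, 0] + b2[:, 0]) * cross2,
                         minlength=n_comp) / (6 * area_c)
        cy = np.bincount(comp, weights=(a2[:, 1] + b2[:, 1]) * cross2,
                         minlength=n_comp) / (6 * area_c)

    loops: list[SectionLoop] = []
    for c in range(n_comp):
        A = area_c[c]
        if not np.isfinite(cx[c]) or abs(A) < 1e-12:
            continue
        centroid = origin + cx[c] * u2 + cy[c] * v2
        poly = None
        if return_polygons:
            poly = _order_loop(comp, c, fi, keys, pts)
        loops.append(SectionLoop(abs(float(A)), centroid, n.copy(), poly))
    return loops


def _order_loop(comp, c, fi, keys, pts) -> np.ndarray:
    """Order one loop's boundary points by walking faces across shared
    crossed edges. Stops early for open curves (non-watertight meshes)."""
    members = np.nonzero(comp == c)[0]
    # per crossing face: its two edge entries; per edge: point and faces
    face_edges: dict[int, list[int]] = {}
    for entry, face in enumerate(fi):
        if comp[face] == c:
            face_edges.setdefault(int(face), []).append(entry)
    edge_points: dict[int, np.ndarray] = {}
    edge_faces: dict[int, list[int]] = {}
    for face, entries in face_edges.items():
        for e in entries:
            k = int(keys[e])
            edge_points[k] = pts[e]
            edge_faces.setdefault(k, []).append(face)

    start = int(members[0])
    pts = []
    face = start
    prev_key = int(keys[face_edges[face][0]])
    for _ in range(len(members)):
        k1, k2 = (int(keys[e]) for e in face_edges[face][:2])
        exit_key = k2 if k1 == prev_key else k1
        pts.append(edge_points[exit_key])
        nxt = [f for f in edge_faces.get(exit_key, []) if f != face]
        if not nxt:
            break
        face = nxt[0]
        prev_key = exit_key
    return np.asarray(pts)
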