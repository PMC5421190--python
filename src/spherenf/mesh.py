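"""Icosphere meshes with spherical quadrature weights.

The sphere is triangulated by recursive quadrisection of the icosahedron with
vertex projection to the unit sphere, giving ``F = 20 * 4^level`` triangles
and ``V = 10 * 4^level + 2`` vertices.  Integration over the sphere is
approximated by vertex weights: each vertex receives one third of the
spherical (solid-angle) area of its incident triangles, rescaled so the
weights sum to ``4 pi`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

__all__ = ["SphereMesh", "build_icosphere", "quadrature_weights"]

_MAX_LEVEL = 7


@dataclass
class SphereMesh:
    vertices: np.ndarray  # (V, 3) unit vectors
    triangles: np.ndarray  # (F, 3) vertex indices
    weights: np.ndarray  # (V,) quadrature weights, sum = 4 pi
    subdivision_level: int
    _harmonics: dict = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def euler_characteristic(self) -> int:
        edges = set()
        for tri in self.triangles:
            for a, b in ((0, 1), (1, 2), (2, 0)):
                edges.add(frozenset((int(tri[a]), int(tri[b]))))
        return len(self.vertices) - len(edges) + len(self.triangles)

    def harmonic_basis(self, n_max: int):
        """Cached per-degree (2n+1, V) arrays of Y_n^m at the vertices."""
        from .harmonics import harmonic_matrix

        if n_max not in self._harmonics:
            self._harmonics[n_max] = harmonic_matrix(self.vertices, n_max)
        return self._harmonics[n_max]

    def angles(self) -> tuple[np.ndarray, np.ndarray]:
        """Polar and azimuthal angles of the vertices."""
        v = self.vertices
        theta = np.arccos(np.clip(v[:, 2], -1.0, 1.0))
        phi = np.mod(np.arctan2(v[:, 1], v[:, 0]), 2.0 * np.pi)
        return theta, phi


def _solid_angles(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Spherical triangle areas via the van Oosterom-Strackee formula."""
    num = np.abs(np.einsum("ij,ij->i", a, np.cross(b, c)))
    den = (
        1.0
        + np.einsum("ij,ij->i", a, b)
        + np.einsum("ij,ij->i", b, c)
        + np.einsum("ij,ij->i", a, c)
    )
    return 2.0 * np.arctan2(num, den)


def quadrature_weights(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Vertex quadrature weights from spherical triangle areas.

    One third of each triangle's solid angle goes to each of its corners;
    the result is rescaled so the total is exactly ``4 pi``.
    """
    v, t = np.asarray(vertices, float), np.asarray(triangles)
    areas = _solid_angles(v[t[:, 0]], v[t[:, 1]], v[t[:, 2]])
    if np.any(areas <= 0):
        raise ValueError("degenerate triangle in mesh")
    w = np.zeros(len(v))
    for k in range(3):
        np.add.at(w, t[:, k], areas / 3.0)
    return w * (4.0 * np.pi / w.sum())


def build_icosphere(level: int = 3) -> SphereMesh:
    """Subdivided icosahedron projected to the unit sphere."""
    if level < 0 or level > _MAX_LEVEL:
        raise ValueError(f"subdivision level must be in [0, {_MAX_LEVEL}]")
    m = trimesh.creation.icosphere(subdivisions=level, radius=1.0)
    verts = np.asarray(m.vertices, dtype=float)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    tris = np.asarray(m.faces, dtype=np.int64)
    return SphereMesh(
        vertices=verts,
        triangles=tris,
        weights=quadrature_weights(verts, tris),
        subdivision_level=level,
    )
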