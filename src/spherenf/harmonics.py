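"""Spherical harmonics, Legendre polynomials and Funk-Hecke transforms.

A rotationally invariant kernel ``g(r . r')`` acts diagonally on the
spherical-harmonic basis; its eigenvalue on degree ``n`` is the Funk-Hecke
coefficient ``G_n = 2 pi int_{-1}^{1} g(s) P_n(s) ds``.  This module provides
that transform (by adaptive Gauss-Legendre quadrature), the harmonics
themselves (orthonormal, complex, Condon-Shortley phase) and the discrete
projection of a field sampled on a quadrature mesh onto harmonic degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import eval_legendre, roots_legendre, sph_harm_y

__all__ = [
    "legendre_polynomial",
    "spherical_harmonic",
    "funk_hecke",
    "project_degrees",
    "DegreeSpectrum",
]


@lru_cache(maxsize=32)
def gauss_legendre(order: int):
    """Cached Gauss-Legendre nodes/weights on [-1, 1]."""
    return roots_legendre(order)


def legendre_polynomial(n: int, s):
    """Legendre polynomial P_n with the P_n(1) = 1 normalization."""
    if n < 0:
        raise ValueError("degree n must be nonnegative")
    return eval_legendre(n, s)


def spherical_harmonic(n: int, m: int, theta, phi):
    """Orthonormal complex spherical harmonic Y_n^m(theta, phi).

    ``theta`` is the polar angle in [0, pi], ``phi`` the azimuth in [0, 2 pi).
    Condon-Shortley phase; Y_0^0 = 1/sqrt(4 pi).
    """
    if abs(m) > n:
        raise ValueError("order must satisfy |m| <= n")
    return sph_harm_y(n, m, theta, phi)


def funk_hecke(
    g,
    n: int,
    quad_order: int = 64,
    rtol: float = 1e-10,
    max_order: int = 2**14,
):
    """Funk-Hecke coefficient ``2 pi int_{-1}^{1} g(s) P_n(s) ds``.

    The integral is evaluated in the polar-angle variable ``s = cos(theta)``,
    where kernels built from the great-circle distance ``arccos(s)`` are
    analytic (in ``s`` they have square-root endpoint singularities in their
    derivatives, which stalls quadrature).  Gauss-Legendre order is doubled
    until successive estimates agree to relative tolerance ``rtol``.  ``g``
    may return complex values (e.g. ``w(s) exp(-lambda tau(s))``).
    """
    if n < 0:
        raise ValueError("degree n must be nonnegative")
    if quad_order < 2:
        raise ValueError("quad_order must be at least 2")

    def estimate(order: int):
        x, w = gauss_legendre(order)
        th = 0.5 * np.pi * (x + 1.0)
        s = np.cos(th)
        wt = 0.5 * np.pi * w * np.sin(th)
        return 2.0 * np.pi * np.sum(wt * np.asarray(g(s)) * eval_legendre(n, s))

    prev = estimate(quad_order)
    order = quad_order
    while order <= max_order:
        order *= 2
        cur = estimate(order)
        scale = max(abs(cur), 1e-300)
        if abs(cur - prev) <= rtol * scale + 1e-14:
            return cur
        prev = cur
    raise RuntimeError(
        f"Funk-Hecke quadrature did not converge by order {max_order}"
    )


@dataclass
class DegreeSpectrum:
    """Harmonic coefficients ``v_nm`` up to ``n_max`` with per-degree power.

    ``coefficients[n]`` is a complex array of length ``2n+1`` ordered
    ``m = -n .. n``; ``power[n] = sum_m |v_nm|^2``.
    """

    n_max: int
    coefficients: list = field(default_factory=list)

    def __post_init__(self):
        if not self.coefficients:
            self.coefficients = [
                np.zeros(2 * n + 1, dtype=complex) for n in range(self.n_max + 1)
            ]

    def __getitem__(self, nm: tuple[int, int]) -> complex:
        n, m = nm
        return self.coefficients[n][m + n]

    def __setitem__(self, nm: tuple[int, int], value: complex) -> None:
        n, m = nm
        self.coefficients[n][m + n] = value

    @property
    def power(self) -> np.ndarray:
        return np.array(
            [float(np.sum(np.abs(c) ** 2)) for c in self.coefficients]
        )

    def map(self, fn) -> "DegreeSpectrum":
        """New spectrum with ``fn(n, coeff_array)`` applied per degree."""
        out = DegreeSpectrum(self.n_max)
        out.coefficients = [
            np.asarray(fn(n, c), dtype=complex)
            for n, c in enumerate(self.coefficients)
        ]
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for n, c in enumerate(self.coefficients):
            p = float(np.sum(np.abs(c) ** 2))
            for m in range(-n, n + 1):
                v = c[m + n]
                rows.append((n, m, v.real, v.imag, p))
        return pd.DataFrame(rows, columns=["n", "m", "re", "im", "degree_power"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def harmonic_matrix(vertices: np.ndarray, n_max: int) -> list[np.ndarray]:
    """Y_n^m evaluated at unit vectors; one (2n+1, N) array per degree."""
    v = np.asarray(vertices, dtype=float)
    theta = np.arccos(np.clip(v[:, 2], -1.0, 1.0))
    phi = np.mod(np.arctan2(v[:, 1], v[:, 0]), 2.0 * np.pi)
    out = []
    for n in range(n_max + 1):
        block = np.empty((2 * n + 1, len(v)), dtype=complex)
        for m in range(-n, n + 1):
            block[m + n] = sph_harm_y(n, m, theta, phi)
        out.append(block)
    return out


def project_degrees(field_values, mesh, n_max: int) -> DegreeSpectrum:
    """Project a mesh field onto harmonic degrees via quadrature.

    ``v_nm = sum_i weight_i field_i conj(Y_n^m(r_i))``.
    """
    u = np.asarray(field_values)
    if u.shape[-1] != len(mesh.vertices):
        raise ValueError("field length must equal mesh vertex count")
    if n_max < 0:
        raise ValueError("n_max must be nonnegative")
    Y = mesh.harmonic_basis(n_max)
    spec = DegreeSpectrum(n_max)
    wu = mesh.weights * u
    for n in range(n_max + 1):
        spec.coefficients[n] = Y[n].conj() @ wu
    return spec
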