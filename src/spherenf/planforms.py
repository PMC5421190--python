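"""Equivariant Hopf planforms on the sphere.

When a degree-``nc`` eigenvalue pair crosses the imaginary axis, the
equivariant Hopf theorem guarantees one branch of periodic solutions for each
C-axial isotropy subgroup of O(3) x S1 acting on the critical eigenspace.
The catalog of those subgroups for ``1 <= nc <= 6`` is classical and embedded
here as static data; for ``nc = 4`` the representative fixed-point vectors
are included, so the ten guaranteed patterns (six standing waves, four
travelling waves) can be synthesized as explicit space-time fields

    u(t, r) = sum_m  v_m z e^{i omega t} Y_nc^m(r)  +  complex conjugate.

A spatiotemporal symmetry ``(gamma, psi)`` of such a field satisfies
``u(t, gamma^{-1} r) = u(t + psi, r)``; each branch stores concrete
generators (rotation matrices, optionally the inversion) with their phase
shifts, which are verified numerically by :func:`check_spatiotemporal_symmetry`.

The octahedral and tetrahedral fixed vectors restore square-root ratios that
are lost in some typeset reproductions of the catalog; the symmetry check
distinguishes the two candidate readings unambiguously (see the tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .harmonics import spherical_harmonic

__all__ = [
    "IsotropyBranch",
    "branches_for_degree",
    "synthesize",
    "field_function",
    "check_spatiotemporal_symmetry",
    "rotation_about",
    "INVERSION",
]

SQ5, SQ7, SQ10, SQ12, SQ14 = (np.sqrt(v) for v in (5.0, 7.0, 10.0, 12.0, 14.0))

INVERSION = -np.eye(3)


def rotation_about(axis, angle: float) -> np.ndarray:
    """Rotation matrix about an arbitrary axis (Rodrigues)."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


@dataclass(frozen=True)
class IsotropyBranch:
    """One C-axial branch: subgroup labels, wave type and (optionally) a
    representative fixed-point vector with verified symmetry generators.

    ``generators`` is a tuple of ``(matrix, phase_fraction)`` pairs: each
    group element, applied spatially, equals a time shift by
    ``phase_fraction`` of the period.
    """

    nc: int
    name: str
    J_name: str
    K_name: str
    theta_image: str
    fix_vector: tuple | None = None  # length 2nc+1, m = -nc..nc
    generators: tuple = ()

    @property
    def wave_type(self) -> str:
        return "travelling" if self.theta_image == "S1" else "standing"


def _row(nc, name, J, K, theta, fix=None, gens=()):
    return IsotropyBranch(nc, name, J, K, theta, fix, gens)


_RZ = rotation_about([0, 0, 1], 1.0)  # placeholder; real ones built below


def _gens_so2(m_abs: int, nc: int):
    """Travelling-wave generators: a generic z-rotation paired with the
    matching phase, plus the inversion (spatial for even nc)."""
    ang = 0.9
    gens = [(rotation_about([0, 0, 1], ang), m_abs * ang / (2.0 * np.pi))]
    if nc % 2 == 0:
        gens.append((INVERSION, 0.0))
    return tuple(gens)


def _catalog_nc4() -> list[IsotropyBranch]:
    Rz = lambda a: rotation_about([0, 0, 1], a)
    Rx_pi = rotation_about([1, 0, 0], np.pi)
    R111 = rotation_about([1, 1, 1], 2.0 * np.pi / 3.0)
    rows = [
        _row(
            4, "O(2)~", "O(2)", "O(2)xZ2c", "1",
            fix=(0, 0, 0, 0, 1, 0, 0, 0, 0),
            gens=((Rz(0.7), 0.0), (Rx_pi, 0.0), (INVERSION, 0.0)),
        ),
        _row(
            4, "O~", "O", "OxZ2c", "1",
            fix=(SQ5, 0, 0, 0, SQ14, 0, 0, 0, SQ5),
            gens=((Rz(np.pi / 2), 0.0), (R111, 0.0), (Rx_pi, 0.0),
                  (INVERSION, 0.0)),
        ),
        _row(
            4, "T~", "T", "D2xZ2c", "Z3",
            fix=(SQ7, 0, SQ12 * 1j, 0, -SQ10, 0, SQ12 * 1j, 0, SQ7),
            gens=((Rz(np.pi), 0.0), (Rx_pi, 0.0), (INVERSION, 0.0),
                  (R111, 2.0 / 3.0)),
        ),
        _row(
            4, "D8~", "D8", "D4xZ2c", "Z2",
            fix=(1, 0, 0, 0, 0, 0, 0, 0, 1),
            gens=((Rz(np.pi / 2), 0.0), (Rx_pi, 0.0), (INVERSION, 0.0),
                  (Rz(np.pi / 4), 0.5)),
        ),
        _row(
            4, "D6~", "D6", "D3xZ2c", "Z2",
            fix=(0, 1, 0, 0, 0, 0, 0, 1, 0),
            gens=((Rz(2 * np.pi / 3), 0.0), (Rx_pi, 0.0), (INVERSION, 0.0),
                  (Rz(np.pi / 3), 0.5)),
        ),
        _row(
            4, "D4~", "D4", "D2xZ2c", "Z2",
            fix=(0, 0, 1, 0, 0, 0, 1, 0, 0),
            gens=((Rz(np.pi), 0.0), (Rx_pi, 0.0), (INVERSION, 0.0),
                  (Rz(np.pi / 2), 0.5)),
        ),
        _row(4, "SO(2)4~", "SO(2)", "Z4xZ2c", "S1",
             fix=(1, 0, 0, 0, 0, 0, 0, 0, 0), gens=_gens_so2(4, 4)),
        _row(4, "SO(2)3~", "SO(2)", "Z3xZ2c", "S1",
             fix=(0, 1, 0, 0, 0, 0, 0, 0, 0), gens=_gens_so2(3, 4)),
        _row(4, "SO(2)2~", "SO(2)", "Z2xZ2c", "S1",
             fix=(0, 0, 1, 0, 0, 0, 0, 0, 0), gens=_gens_so2(2, 4)),
        _row(4, "SO(2)1~", "SO(2)", "Z2c", "S1",
             fix=(0, 0, 0, 1, 0, 0, 0, 0, 0), gens=_gens_so2(1, 4)),
    ]
    return rows


def _so2_rows(nc: int, K_fmt: str) -> list[IsotropyBranch]:
    return [
        _row(nc, f"SO(2){m}~", "SO(2)", K_fmt.format(n=m), "S1")
        for m in range(nc, 0, -1)
    ]


_CATALOG: dict[int, list[IsotropyBranch]] = {
    1: [
        _row(1, "O(2)~", "O(2)", "O(2)-", "Z2"),
        _row(1, "SO(2)1~", "SO(2)", "Z2-", "S1"),
    ],
    2: [
        _row(2, "O(2)~", "O(2)", "O(2)xZ2c", "1"),
        *_so2_rows(2, "Z{n}xZ2c"),
        _row(2, "T~", "T", "D2xZ2c", "Z3"),
        _row(2, "D4~", "D4", "D2xZ2c", "Z2"),
    ],
    3: [
        _row(3, "O(2)~", "O(2)", "O(2)-", "Z2"),
        *_so2_rows(3, "Z2{n}-"),
        _row(3, "O~", "O", "O-", "Z2"),
        _row(3, "D6~", "D6", "D6d", "Z2"),
    ],
    4: _catalog_nc4(),
    5: [
        _row(5, "O(2)~", "O(2)", "O(2)-", "Z2"),
        *_so2_rows(5, "Z2{n}-"),
        _row(5, "T~", "T", "D2", "Z6"),
        _row(5, "D10~", "D10", "D10d", "Z2"),
        _row(5, "D8~", "D8", "D8d", "Z2"),
        _row(5, "D6~", "D6", "D6d", "Z2"),
        _row(5, "D4~", "D4", "D4d", "Z2"),
    ],
    6: [
        _row(6, "O(2)~", "O(2)", "O(2)xZ2c", "1"),
        *_so2_rows(6, "Z{n}xZ2c"),
        _row(6, "I~", "I", "IxZ2c", "1"),
        _row(6, "O~", "O", "OxZ2c", "1"),
        _row(6, "O/T~", "O", "TxZ2c", "Z2"),
        _row(6, "T~", "T", "D2xZ2c", "Z3"),
        _row(6, "D12~", "D12", "D6xZ2c", "Z2"),
        _row(6, "D10~", "D10", "D5xZ2c", "Z2"),
        _row(6, "D8~", "D8", "D4xZ2c", "Z2"),
        _row(6, "D6~", "D6", "D3xZ2c", "Z2"),
    ],
}


def branches_for_degree(nc: int) -> list[IsotropyBranch]:
    """The C-axial branch catalog for critical degree ``nc`` in [1, 6]."""
    if nc not in _CATALOG:
        raise ValueError("catalog covers critical degrees 1..6")
    return list(_CATALOG[nc])


def _eval_modes(nc: int, coeffs, points) -> np.ndarray:
    """Real field  sum_m c_m Y_nc^m + cc  at unit vectors ``points``."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    theta = np.arccos(np.clip(pts[:, 2], -1.0, 1.0))
    phi = np.mod(np.arctan2(pts[:, 1], pts[:, 0]), 2 * np.pi)
    total = np.zeros(len(pts), dtype=complex)
    for m in range(-nc, nc + 1):
        c = coeffs[m + nc]
        if c != 0:
            total += c * spherical_harmonic(nc, m, theta, phi)
    return 2.0 * np.real(total)


def field_function(branch: IsotropyBranch, z: complex, omega: float):
    """Closure ``u(t, points)`` for a synthesized branch field."""
    if branch.fix_vector is None:
        raise ValueError(
            f"branch {branch.name} has no stored fixed-point vector; "
            "supply one explicitly via synthesize()"
        )
    v = np.asarray(branch.fix_vector, dtype=complex) * z

    def u(t, points):
        coeffs = v * np.exp(1j * omega * t)
        return _eval_modes(branch.nc, coeffs, points)

    return u


def synthesize(
    branch: IsotropyBranch,
    z: complex,
    omega: float,
    t: float,
    points,
    fix_vector=None,
) -> np.ndarray:
    """Real planform field values at time ``t`` on the given unit vectors."""
    if fix_vector is not None:
        v = np.asarray(fix_vector, dtype=complex) * z
        return _eval_modes(branch.nc, v * np.exp(1j * omega * t), points)
    return field_function(branch, z, omega)(t, points)


def check_spatiotemporal_symmetry(
    field_fn,
    transform: np.ndarray,
    phase_shift: float,
    period: float,
    n_points: int = 60,
    n_times: int = 5,
    seed: int = 7,
) -> float:
    """Sup-norm residual of ``u(t, gamma^{-1} r) - u(t + psi, r)``.

    ``transform`` is the orthogonal matrix of ``gamma`` (inversion allowed);
    ``phase_shift`` is the time shift ``psi`` in time units.  The residual is
    evaluated at Sobol-free random unit vectors and times spanning a period.
    """
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n_points, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    times = rng.uniform(0.0, period, size=n_times)
    resid = 0.0
    for t in times:
        lhs = field_fn(t, pts @ transform)  # row-vector form of gamma^{-1} r
        rhs = field_fn(t + phase_shift, pts)
        resid = max(resid, float(np.max(np.abs(lhs - rhs))))
    return resid


def verify_branch(branch: IsotropyBranch, omega: float = 1.3,
                  z: complex = 0.8 - 0.3j) -> dict[str, float]:
    """Residuals of all stored generators for a synthesized branch field."""
    period = 2.0 * np.pi / omega
    u = field_function(branch, z, omega)
    out = {}
    for i, (mat, frac) in enumerate(branch.generators):
        out[f"gen{i}"] = check_spatiotemporal_symmetry(
            u, mat, frac * period, period
        )
    return out
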