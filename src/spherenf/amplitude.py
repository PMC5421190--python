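"""Amplitude equations near the non-resonant 0:1 double Hopf bifurcation.

The critical modes are one complex amplitude ``w`` for the homogeneous
(degree-0) oscillation and a complex triple ``z = (z_-1, z_0, z_1)`` for the
degree-1 modes.  Equivariance under O(3) x S1 restricts the cubic truncation
of the normal form to

    w'   = (rho0 + i omega0) w + a1 w |w|^2 + a2 w |z|^2
    z_m' = (rho1 + i omega1) z_m + b1 z_m |z|^2
           + b2 zhat_m (z_0^2 - 2 z_-1 z_1) + b3 z_m |w|^2

with ``zhat = (-conj z_1, conj z_0, -conj z_-1)``.  The real quantities
``(x1, x2, x3) = (|w|^2, |z_0^2 - 2 z_-1 z_1|, |z|^2)`` obey a closed cubic
ODE system involving only the real parts of the coefficients; its first-octant
equilibria classify the competing patterns (bulk oscillation, travelling wave,
standing wave, mixtures) via their isotropy types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

__all__ = [
    "DoubleHopfCoefficients",
    "AmplitudeState",
    "ReducedState",
    "OctantEquilibrium",
    "normal_form_rhs",
    "reduce_state",
    "reduced_rhs",
    "reduced_jacobian",
    "octant_equilibria",
    "classify_stability",
    "isotropy_classify",
    "integrate_normal_form",
    "integrate_reduced",
    "ISOTROPY_TABLE",
]


@dataclass(frozen=True)
class DoubleHopfCoefficients:
    """Unfolding parameters, frequencies and cubic coefficients.

    The truncated (cubic) analysis is valid in the 'simple' case
    ``Re(a1) Re(b1) > 0``; ``simple_case`` flags it.
    """

    rho0: float
    rho1: float
    omega0: float
    omega1: float
    a1: complex
    a2: complex
    b1: complex
    b2: complex
    b3: complex

    @property
    def simple_case(self) -> bool:
        return self.a1.real * self.b1.real > 0

    @property
    def real_parts(self) -> tuple[float, float, float, float, float]:
        return (
            self.a1.real,
            self.a2.real,
            self.b1.real,
            self.b2.real,
            self.b3.real,
        )


@dataclass
class AmplitudeState:
    w: complex
    z: np.ndarray  # (z_-1, z_0, z_1)

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=complex)
        if self.z.shape != (3,):
            raise ValueError("z must be a complex triple")

    @property
    def z_hat(self) -> np.ndarray:
        zm1, z0, zp1 = self.z
        return np.array([-np.conj(zp1), np.conj(z0), -np.conj(zm1)])

    @property
    def z_norm2(self) -> float:
        return float(np.sum(np.abs(self.z) ** 2))

    @property
    def z_invariant(self) -> complex:
        """The O(3)-equivariant quadratic ``z_0^2 - 2 z_-1 z_1``."""
        zm1, z0, zp1 = self.z
        return z0 * z0 - 2.0 * zm1 * zp1

    def to_vector(self) -> np.ndarray:
        return np.concatenate([[self.w], self.z])

    @classmethod
    def from_vector(cls, v) -> "AmplitudeState":
        v = np.asarray(v, dtype=complex)
        return cls(w=complex(v[0]), z=v[1:4])


@dataclass(frozen=True)
class ReducedState:
    x1: float
    x2: float
    x3: float

    def __post_init__(self):
        if min(self.x1, self.x2, self.x3) < -1e-12:
            raise ValueError("reduced coordinates must be nonnegative")

    def to_array(self) -> np.ndarray:
        return np.array([self.x1, self.x2, self.x3])


@dataclass
class OctantEquilibrium:
    x: np.ndarray
    label: str  # "i".."vi"
    jacobian_eigenvalues: np.ndarray
    stability: str  # "stable" | "unstable" | "degenerate"
    isotropy_row: int | None
    isotropy_name: str


def normal_form_rhs(s: AmplitudeState, c: DoubleHopfCoefficients) -> AmplitudeState:
    """Right-hand side of the cubic O(3) x S1 equivariant normal form."""
    w, z = s.w, s.z
    z2 = s.z_norm2
    w2 = abs(w) ** 2
    dw = (c.rho0 + 1j * c.omega0) * w + c.a1 * w * w2 + c.a2 * w * z2
    dz = (
        (c.rho1 + 1j * c.omega1) * z
        + c.b1 * z * z2
        + c.b2 * s.z_hat * s.z_invariant
        + c.b3 * z * w2
    )
    return AmplitudeState(w=complex(dw), z=dz)


def reduce_state(s: AmplitudeState) -> ReducedState:
    """Map to the decoupling coordinates (|w|^2, |z0^2-2 z-1 z1|, |z|^2)."""
    return ReducedState(
        x1=float(abs(s.w) ** 2),
        x2=float(abs(s.z_invariant)),
        x3=s.z_norm2,
    )


def reduced_rhs(x, c: DoubleHopfCoefficients) -> np.ndarray:
    """Closed cubic system for the reduced coordinates (first octant)."""
    a1, a2, b1, b2, b3 = c.real_parts
    x1, x2, x3 = np.asarray(x, dtype=float)
    return np.array(
        [
            2.0 * x1 * (c.rho0 + a1 * x1 + a2 * x3),
            2.0 * x2 * (c.rho1 + (b1 + b2) * x3 + b3 * x1),
            2.0 * x3 * (c.rho1 + b1 * x3 + b3 * x1) + 2.0 * b2 * x2 * x2,
        ]
    )


def reduced_jacobian(x, c: DoubleHopfCoefficients) -> np.ndarray:
    a1, a2, b1, b2, b3 = c.real_parts
    x1, x2, x3 = np.asarray(x, dtype=float)
    return np.array(
        [
            [2.0 * (c.rho0 + 2.0 * a1 * x1 + a2 * x3), 0.0, 2.0 * a2 * x1],
            [
                2.0 * b3 * x2,
                2.0 * (c.rho1 + (b1 + b2) * x3 + b3 * x1),
                2.0 * (b1 + b2) * x2,
            ],
            [
                2.0 * b3 * x3,
                4.0 * b2 * x2,
                2.0 * (c.rho1 + 2.0 * b1 * x3 + b3 * x1),
            ],
        ]
    )


_LABELS = ("i", "ii", "iii", "iv", "v", "vi")


def octant_equilibria(
    c: DoubleHopfCoefficients,
    tol: float = 1e-10,
    degeneracy_tol: float = 1e-10,
) -> list[OctantEquilibrium]:
    """Closed-form enumeration of all first-octant equilibria.

    Candidates: the origin (i); the pure degree-0 mode (ii); the pure
    degree-1 mode with ``x2 = 0`` (iii); the mixed point with ``x2 = 0``
    (iv); and the two branches on the invariant surface ``x2 = x3``
    (v: ``x1 = 0``; vi: interior).  Each candidate is kept when it lies in
    the closed octant; there are therefore at most six equilibria.
    """
    a1, a2, b1, b2, b3 = c.real_parts
    rho0, rho1 = c.rho0, c.rho1
    cands: list[tuple[str, np.ndarray]] = [("i", np.zeros(3))]

    if abs(a1) > degeneracy_tol:
        cands.append(("ii", np.array([-rho0 / a1, 0.0, 0.0])))
    if abs(b1) > degeneracy_tol:
        cands.append(("iii", np.array([0.0, 0.0, -rho1 / b1])))
    det_iv = a1 * b1 - a2 * b3
    if abs(det_iv) > degeneracy_tol:
        x1 = (-rho0 * b1 + rho1 * a2) / det_iv
        x3 = (-rho1 * a1 + rho0 * b3) / det_iv
        cands.append(("iv", np.array([x1, 0.0, x3])))
    if abs(b1 + b2) > degeneracy_tol:
        x3 = -rho1 / (b1 + b2)
        cands.append(("v", np.array([0.0, x3, x3])))
    det_vi = a1 * (b1 + b2) - a2 * b3
    if abs(det_vi) > degeneracy_tol:
        x1 = (-rho0 * (b1 + b2) + rho1 * a2) / det_vi
        x3 = (-rho1 * a1 + rho0 * b3) / det_vi
        cands.append(("vi", np.array([x1, x3, x3])))

    out: list[OctantEquilibrium] = []
    seen: list[np.ndarray] = []
    for label, x in cands:
        if np.min(x) < -1e-12:
            continue
        x = np.maximum(x, 0.0)
        if np.max(np.abs(reduced_rhs(x, c))) > tol * (1.0 + np.max(np.abs(x))):
            continue
        if any(np.linalg.norm(x - s) < 1e-9 * (1.0 + np.linalg.norm(x)) for s in seen):
            continue
        seen.append(x)
        eigvals = np.linalg.eigvals(reduced_jacobian(x, c))
        out.append(_finalize(x, label, eigvals))
    return out


def _finalize(x, label, eigvals) -> OctantEquilibrium:
    re = np.real(eigvals)
    if np.min(np.abs(re)) < 1e-8:
        verdict = "degenerate"
    else:
        verdict = "stable" if np.max(re) < 0 else "unstable"
    row, name = isotropy_classify(x)
    return OctantEquilibrium(
        x=x,
        label=label,
        jacobian_eigenvalues=eigvals,
        stability=verdict,
        isotropy_row=row,
        isotropy_name=name,
    )


def classify_stability(eq: OctantEquilibrium, c: DoubleHopfCoefficients) -> str:
    """Stability verdict from the reduced-system Jacobian.

    Negative real parts of all Jacobian eigenvalues give asymptotic stability
    within the reduced coordinates; phase directions of the full normal form
    are neutral (group orbits) and do not affect orbital stability.
    """
    eigvals = np.linalg.eigvals(reduced_jacobian(eq.x, c))
    re = np.real(eigvals)
    if np.min(np.abs(re)) < 1e-8:
        return "degenerate"
    return "stable" if np.max(re) < 0 else "unstable"


# rows of the isotropy-type catalog for the (V0+V0)+(V1+V1) representation:
# (row, name, fixed-point pattern description)
ISOTROPY_TABLE = {
    1: ("O(3)~", "bulk oscillation"),
    2: ("SO(2)~", "travelling wave"),
    3: ("O(2)~", "standing wave"),
    4: ("Z2~", "two 1-modes, equal amplitudes"),
    5: ("1~", "generic mixture of 1-modes"),
    6: ("O(2)-", "bulk + standing wave"),
    7: ("Z2-", "bulk + two 1-modes"),
    8: ("1", "no symmetry"),
}


def isotropy_classify(
    x, tol: float = 1e-9
) -> tuple[int | None, str]:
    """Map the sign pattern of (x1, x2, x3) onto an isotropy-type row.

    Equality of ``x2`` and ``x3`` selects the standing-wave (degree-1) or
    bulk+standing classes; patterns that the reduced coordinates cannot
    disambiguate are mapped to the most symmetric compatible row.  Unknown
    patterns give ``(None, 'unclassified')``.
    """
    x1, x2, x3 = (float(v) for v in np.asarray(x))
    scale = max(x1, x2, x3, 1.0)
    pos = [v > tol * scale for v in (x1, x2, x3)]
    eq23 = abs(x2 - x3) <= tol * scale
    if not any(pos):
        return 0, "trivial (homogeneous steady state)"
    if pos[0] and not pos[1] and not pos[2]:
        return 1, ISOTROPY_TABLE[1][0] + " " + ISOTROPY_TABLE[1][1]
    if not pos[0] and not pos[1] and pos[2]:
        return 2, ISOTROPY_TABLE[2][0] + " " + ISOTROPY_TABLE[2][1]
    if not pos[0] and pos[1] and pos[2]:
        row = 3 if eq23 else 4
        return row, ISOTROPY_TABLE[row][0] + " " + ISOTROPY_TABLE[row][1]
    if pos[0] and not pos[1] and pos[2]:
        return 8, ISOTROPY_TABLE[8][0] + " " + ISOTROPY_TABLE[8][1]
    if all(pos):
        row = 6 if eq23 else 8
        return row, ISOTROPY_TABLE[row][0] + " " + ISOTROPY_TABLE[row][1]
    return None, "unclassified"


def integrate_normal_form(
    s0: AmplitudeState,
    c: DoubleHopfCoefficients,
    t_span: tuple[float, float],
    t_eval=None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
):
    """Adaptive Runge-Kutta integration of the full normal form."""

    def rhs(t, v):
        s = AmplitudeState.from_vector(v[:4] + 1j * v[4:])
        d = normal_form_rhs(s, c).to_vector()
        return np.concatenate([d.real, d.imag])

    v0 = s0.to_vector()
    y0 = np.concatenate([v0.real, v0.imag])
    sol = solve_ivp(rhs, t_span, y0, t_eval=t_eval, rtol=rtol, atol=atol,
                    method="RK45")
    states = sol.y[:4] + 1j * sol.y[4:]
    return sol.t, states


def integrate_reduced(
    x0,
    c: DoubleHopfCoefficients,
    t_span: tuple[float, float],
    t_eval=None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
):
    sol = solve_ivp(
        lambda t, x: reduced_rhs(x, c),
        t_span,
        np.asarray(x0, dtype=float),
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        method="RK45",
    )
    return sol.t, sol.y


def multistart_equilibria(
    c: DoubleHopfCoefficients,
    n_starts: int = 200,
    seed: int = 0,
    box: float | None = None,
    tol: float = 1e-9,
) -> list[np.ndarray]:
    """Independent numerical enumeration by multistart root search."""
    rng = np.random.default_rng(seed)
    if box is None:
        a1, a2, b1, b2, b3 = c.real_parts
        denom = min(abs(v) for v in (a1, b1) if abs(v) > 1e-12)
        box = 3.0 * max(abs(c.rho0), abs(c.rho1), 1e-3) / denom
    # the components x1 and x2 of the vector field vanish identically on
    # their own zero faces, so Newton iterates started in the interior never
    # land on the boundary; seed the origin, the invariant axes and faces
    # explicitly in addition to interior starts
    n_bdry = max(n_starts // 8, 8)
    starts = [np.zeros(3)]
    for _ in range(n_bdry):
        u, v = rng.uniform(0.0, box, size=2)
        starts += [
            np.array([u, 0.0, 0.0]),   # bulk-mode axis
            np.array([0.0, 0.0, u]),   # pure-wave axis
            np.array([0.0, u, v]),     # x1 = 0 face
            np.array([u, 0.0, v]),     # x2 = 0 face
        ]
    starts += [rng.uniform(0.0, box, size=3) for _ in range(n_starts)]
    found: list[np.ndarray] = []
    for x0 in starts:
        sol, info, ier, _ = fsolve(
            lambda x: reduced_rhs(x, c), x0, full_output=True, xtol=1e-13
        )
        if ier != 1:
            continue
        if np.min(sol) < -1e-9:
            continue
        sol = np.maximum(sol, 0.0)
        if np.max(np.abs(reduced_rhs(sol, c))) > tol:
            continue
        if not any(np.linalg.norm(sol - f) < 1e-6 * (1 + np.linalg.norm(sol))
                   for f in found):
            found.append(sol)
    return found
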