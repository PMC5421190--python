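"""Characteristic equations, eigenvalues and resolvent of the linearization.

Linearizing the delayed field equation about a homogeneous steady state and
separating in spherical harmonics leaves one transcendental characteristic
equation per degree::

    E_n(lambda) = lambda + 1 - kappa G_n(lambda) = 0,

where ``G_n(lambda)`` is the Funk-Hecke coefficient of the delay-weighted
kernel ``s -> w(s) exp(-lambda tau(s))``.  Each root is an eigenvalue with
multiplicity ``2n+1``; the essential spectrum is the single point ``-1``
contributed by the local decay term.  Roots are located by Newton iteration
from a seed grid and certified by an argument-principle count over the search
box boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import eval_legendre

from .harmonics import gauss_legendre, DegreeSpectrum
from .model_core import Equilibrium, ModelParams

__all__ = [
    "LinearizationContext",
    "Eigenvalue",
    "Spectrum",
    "G_n",
    "G_n_prime",
    "E_n",
    "E_n_prime",
    "Q_n",
    "solve_modes",
    "rightmost_eigenvalue",
    "resolvent_coefficients",
    "argument_principle_count",
]

_SINGULAR_TOL = 1e-8


@dataclass
class LinearizationContext:
    """Parameters + equilibrium + quadrature tables for spectral work."""

    params: ModelParams
    equilibrium: Equilibrium
    n_max: int = 10
    quad_order: int = 256
    _tables: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_lumped_gains(
        cls,
        kJ1: float,
        kJ2: float,
        sigmas: tuple[float, float],
        delay,
        n_max: int = 10,
    ) -> "LinearizationContext":
        """Context for pure linear analysis parametrized by lumped gains.

        The spectrum depends on ``(kappa J1, kappa J2)`` only, so for linear
        work we may take ``kappa = 1`` and raw couplings equal to the lumped
        gains.  (The placeholder equilibrium is not meaningful and the context
        must not be used for normal-form computations.)
        """
        from .model_core import ConnectivityParams, DelayParams, FiringParams

        if not isinstance(delay, DelayParams):
            delay = DelayParams(*delay)
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            conn = ConnectivityParams(kJ1, kJ2, sigmas[0], sigmas[1])
        params = ModelParams(FiringParams(1.0, 1.0, 0.0), conn, delay)
        eq = Equilibrium(u_hat=0.0, kappa=1.0, w0=np.nan)
        return cls(params, eq, n_max=n_max)

    @property
    def kappa(self) -> float:
        return self.equilibrium.kappa

    @property
    def kJ1(self) -> float:
        return self.kappa * self.params.connectivity.J1

    @property
    def kJ2(self) -> float:
        return self.kappa * self.params.connectivity.J2

    def _table(self):
        """Quadrature nodes with kernel and delay samples (cached)."""
        key = self.quad_order
        if key not in self._tables:
            # quadrature in the polar angle theta (s = cos theta), where the
            # distance-based kernel and delay profiles are analytic
            x, w = gauss_legendre(self.quad_order)
            th = 0.5 * np.pi * (x + 1.0)
            conn, dly = self.params.connectivity, self.params.delay
            self._tables[key] = {
                "x": np.cos(th),
                "glw": 0.5 * np.pi * w * np.sin(th),
                "kernel": conn.J1 * np.exp(-th / conn.sigma1)
                + conn.J2 * np.exp(-th / conn.sigma2),
                "delay": dly.tau0 + th / dly.c,
                "legendre": {},
            }
        return self._tables[key]

    def _legendre(self, n: int):
        t = self._table()
        if n not in t["legendre"]:
            t["legendre"][n] = eval_legendre(n, t["x"])
        return t["legendre"][n]


@dataclass(frozen=True)
class Eigenvalue:
    """Root of E_n tagged with its harmonic degree (multiplicity 2n+1)."""

    n: int
    lam: complex
    residual: float


@dataclass
class Spectrum:
    eigenvalues: list
    search_box: tuple  # (re_min, re_max, im_min, im_max)
    essential_point: complex = -1.0 + 0.0j

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.n, e.lam.real, e.lam.imag, e.residual) for e in self.eigenvalues],
            columns=["n", "re", "im", "residual"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def G_n(n: int, lam, ctx: LinearizationContext, der: int = 0):
    """Funk-Hecke coefficient of ``w(s) exp(-lambda tau(s))`` (or its
    ``der``-th derivative in lambda, which inserts ``(-tau)^der``)."""
    if n < 0:
        raise ValueError("degree n must be nonnegative")
    t = ctx._table()
    lam = np.asarray(lam, dtype=complex)
    scalar = lam.ndim == 0
    integ = t["kernel"] * ctx._legendre(n) * t["glw"]
    if der:
        integ = integ * (-t["delay"]) ** der
    vals = 2.0 * np.pi * np.exp(
        -np.multiply.outer(np.atleast_1d(lam), t["delay"])
    ) @ integ
    return vals[0] if scalar else vals.reshape(lam.shape)


def G_n_prime(n: int, lam, ctx: LinearizationContext):
    """d G_n / d lambda."""
    return G_n(n, lam, ctx, der=1)


def E_n(n: int, lam, ctx: LinearizationContext):
    """Characteristic function ``lambda + 1 - kappa G_n(lambda)``."""
    return np.asarray(lam, dtype=complex) + 1.0 - ctx.kappa * G_n(n, lam, ctx)


def E_n_prime(n: int, lam, ctx: LinearizationContext):
    return 1.0 - ctx.kappa * G_n_prime(n, lam, ctx)


def Q_n(n: int, mu, ctx: LinearizationContext):
    """Resolvent gain ``G_n(mu) / (mu + 1 - kappa G_n(mu))``.

    Appears in the cubic normal-form coefficient; ``mu`` must be a regular
    value of the characteristic equation for degree ``n``.
    """
    g = G_n(n, mu, ctx)
    den = np.asarray(mu, dtype=complex) + 1.0 - ctx.kappa * g
    if np.any(np.abs(den) < _SINGULAR_TOL):
        raise ValueError("mu is within 1e-8 of the point spectrum")
    return g / den


def resolvent_coefficients(
    y: DegreeSpectrum, mu: complex, ctx: LinearizationContext
) -> DegreeSpectrum:
    """Solve ``Delta(mu) q = y`` degree-wise: ``q_nm = y_nm / E_n(mu)``."""
    dens = [E_n(n, mu, ctx) for n in range(y.n_max + 1)]
    if any(abs(d) < _SINGULAR_TOL for d in dens):
        raise ValueError("mu is within 1e-8 of the point spectrum")
    return y.map(lambda n, c: c / dens[n])


_DEFAULT_GRID = 25


def solve_modes(
    n: int,
    ctx: LinearizationContext,
    box: tuple[float, float, float, float] | None = None,
    grid: int = _DEFAULT_GRID,
    residual_tol: float = 1e-9,
    verify_count: bool = False,
) -> list[Eigenvalue]:
    """All roots of ``E_n`` inside a complex box.

    Newton iterations are started from a ``grid x grid`` seed lattice over the
    upper half of the box; converged roots are deduplicated (pairwise distance
    > 1e-6) and completed with complex conjugates.  With ``verify_count`` the
    number of roots is checked against the argument-principle winding number
    over the box boundary.
    """
    if box is None:
        box = default_box(ctx)
    re0, re1, im0, im1 = box
    if re1 <= re0 or im1 < im0:
        raise ValueError("box must have positive area")
    seeds_im0 = max(im0, 0.0)
    L = (
        np.linspace(re0, re1, grid)[:, None]
        + 1j * np.linspace(seeds_im0, max(im1, seeds_im0 + 1e-6), grid)[None, :]
    ).ravel()
    # Diverging seeds overflow exp(-lambda tau) harmlessly before being
    # discarded by the residual filter; silence those warnings.
    with np.errstate(over="ignore", invalid="ignore"):
        for _ in range(60):
            e = E_n(n, L, ctx)
            d = E_n_prime(n, L, ctx)
            step = np.where(
                np.abs(d) > 1e-14, e / np.where(d == 0, 1, d), 0.0
            )
            L = L - step
            L = np.where(np.isfinite(L), L, np.inf)
        e = np.abs(E_n(n, L, ctx))
    ok = np.isfinite(L) & (e < residual_tol)
    if not np.any(ok):
        count = argument_principle_count(n, ctx, box)
        if count == 0:
            return []
        raise RuntimeError(
            f"Newton failed to converge for degree {n} although the "
            f"argument principle counts {count} roots in the box"
        )
    roots: list[complex] = []
    for lam in L[ok]:
        lam = complex(lam)
        if lam.imag < 0:
            lam = lam.conjugate()
        if not (re0 <= lam.real <= re1):
            continue
        if not any(abs(lam - r) < 1e-6 for r in roots):
            roots.append(lam)
    out = []
    for lam in roots:
        if abs(lam.imag) < 1e-9:
            lam = complex(lam.real, 0.0)
            if im0 <= 0.0 <= im1:
                out.append(lam)
        else:
            if im0 <= lam.imag <= im1:
                out.append(lam)
            if im0 <= -lam.imag <= im1:
                out.append(lam.conjugate())
    eigs = [
        Eigenvalue(n=n, lam=lam, residual=float(abs(E_n(n, lam, ctx))))
        for lam in out
    ]
    eigs.sort(key=lambda e: (-e.lam.real, abs(e.lam.imag)))
    if verify_count:
        count = argument_principle_count(n, ctx, box)
        if count != len(eigs):
            warnings.warn(
                f"degree {n}: Newton found {len(eigs)} roots but the "
                f"argument principle counts {count}",
                stacklevel=2,
            )
    return eigs


def argument_principle_count(
    n: int,
    ctx: LinearizationContext,
    box: tuple[float, float, float, float],
    samples_per_side: int = 2048,
) -> int:
    """Number of zeros of E_n inside the box by boundary winding number."""
    re0, re1, im0, im1 = box
    t = np.linspace(0.0, 1.0, samples_per_side, endpoint=False)
    sides = [
        re0 + t * (re1 - re0) + 1j * im0,
        re1 + 1j * (im0 + t * (im1 - im0)),
        re1 - t * (re1 - re0) + 1j * im1,
        re0 + 1j * (im1 - t * (im1 - im0)),
    ]
    z = np.concatenate(sides)
    vals = E_n(n, z, ctx)
    ang = np.angle(vals)
    d = np.diff(np.concatenate([ang, ang[:1]]))
    d = np.mod(d + np.pi, 2.0 * np.pi) - np.pi
    winding = d.sum() / (2.0 * np.pi)
    return int(round(winding))


def default_box(ctx: LinearizationContext) -> tuple[float, float, float, float]:
    """Search box covering the stability-governing right-most root branches."""
    h = ctx.params.delay.max_delay
    return (-6.0, 2.0, 0.0, 2.0 * np.pi / h + 10.0)


def compute_spectrum(
    ctx: LinearizationContext,
    box: tuple[float, float, float, float] | None = None,
    n_values=None,
) -> Spectrum:
    if box is None:
        b = default_box(ctx)
        box = (b[0], b[1], -b[3], b[3])
    if n_values is None:
        n_values = range(ctx.n_max + 1)
    eigs = []
    for n in n_values:
        eigs.extend(solve_modes(n, ctx, box))
    return Spectrum(eigenvalues=eigs, search_box=box)


def rightmost_eigenvalue(
    ctx: LinearizationContext,
    box: tuple[float, float, float, float] | None = None,
) -> Eigenvalue:
    """Eigenvalue of maximal real part over degrees ``n <= n_max``.

    Ties are broken by smaller degree, then smaller ``|Im|``.
    """
    spec = compute_spectrum(ctx, box=box)
    if not spec.eigenvalues:
        raise RuntimeError("no eigenvalues found in the search box")
    return min(
        spec.eigenvalues,
        key=lambda e: (-e.lam.real, e.n, abs(e.lam.imag)),
    )
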