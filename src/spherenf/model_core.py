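"""Model parameters, constitutive functions and homogeneous equilibria.

The neural field on the unit sphere is specified by three ingredients:

* a sigmoidal firing rate ``f(u) = alpha / (1 + exp(-beta (u - delta)))``,
* a rotationally invariant connectivity kernel
  ``w(s) = J1 exp(-arccos(s)/sigma1) + J2 exp(-arccos(s)/sigma2)`` where
  ``s = r . r'`` is the cosine of the angular separation of two points,
* a distance-dependent transmission delay
  ``tau(s) = tau0 + arccos(s)/c`` combining an offset delay ``tau0`` with a
  finite propagation speed ``c``.

A spatially homogeneous steady state satisfies ``u = w0 f(u)`` with
``w0 = 2 pi * int_{-1}^{1} w(s) ds`` the total kernel mass.  The linearization
about a steady state only involves the lumped gains ``kappa J1`` and
``kappa J2`` with ``kappa = f'(u)``, which is why stability diagrams are drawn
in the ``(kappa J1, kappa J2)`` plane and a calibration step is needed to
recover raw couplings for simulation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .harmonics import funk_hecke

__all__ = [
    "FiringParams",
    "ConnectivityParams",
    "DelayParams",
    "ModelParams",
    "Equilibrium",
    "firing_rate",
    "firing_rate_derivative",
    "kernel_profile",
    "delay_profile",
    "find_equilibria",
    "calibrate_couplings",
]

_CLAMP = 1e-12


@dataclass(frozen=True)
class FiringParams:
    """Sigmoid firing rate: maximal rate ``alpha``, steepness ``beta``,
    threshold ``delta``."""

    alpha: float
    beta: float
    delta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass(frozen=True)
class ConnectivityParams:
    """Sum-of-exponentials kernel in great-circle distance."""

    J1: float
    J2: float
    sigma1: float
    sigma2: float

    def __post_init__(self) -> None:
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("decay scales must be positive")
        if not self.sigma1 > self.sigma2:
            warnings.warn(
                "expected sigma1 > sigma2 (broad component first)",
                stacklevel=2,
            )

    @property
    def shape(self) -> str:
        """``'wizard-hat'`` for J1+J2>0, ``'inverted'`` for J1+J2<0."""
        s = self.J1 + self.J2
        if s > 0:
            return "wizard-hat"
        if s < 0:
            return "inverted"
        return "degenerate"


@dataclass(frozen=True)
class DelayParams:
    """Offset delay ``tau0`` plus great-circle distance over speed ``c``."""

    tau0: float
    c: float

    def __post_init__(self) -> None:
        if self.tau0 < 0:
            raise ValueError("tau0 must be nonnegative")
        if self.c <= 0:
            raise ValueError("propagation speed c must be positive")

    @property
    def max_delay(self) -> float:
        """Largest delay ``h = tau0 + pi/c`` (antipodal points)."""
        return self.tau0 + np.pi / self.c


@dataclass(frozen=True)
class ModelParams:
    firing: FiringParams
    connectivity: ConnectivityParams
    delay: DelayParams

    def to_json(self) -> str:
        f, w, d = self.firing, self.connectivity, self.delay
        return json.dumps(
            {
                "alpha": f.alpha,
                "beta": f.beta,
                "delta": f.delta,
                "J1": w.J1,
                "J2": w.J2,
                "sigma1": w.sigma1,
                "sigma2": w.sigma2,
                "tau0": d.tau0,
                "c": d.c,
            }
        )

    @classmethod
    def from_json(cls, doc: str) -> "ModelParams":
        d = json.loads(doc)
        return cls(
            FiringParams(d["alpha"], d["beta"], d["delta"]),
            ConnectivityParams(d["J1"], d["J2"], d["sigma1"], d["sigma2"]),
            DelayParams(d["tau0"], d["c"]),
        )


@dataclass(frozen=True)
class Equilibrium:
    """Homogeneous steady state with the linearization gain attached.

    ``kappa = f'(u_hat)`` and ``w0`` is the total kernel mass, so the lumped
    gains of the linear problem are ``kappa * J1`` and ``kappa * J2``.
    """

    u_hat: float
    kappa: float
    w0: float
    residual: float = 0.0
    fold_suspect: bool = False


def firing_rate(u, p: FiringParams):
    """Sigmoid firing rate; overflow-safe for large ``|beta (u - delta)|``."""
    return p.alpha * expit(p.beta * (np.asarray(u, dtype=float) - p.delta))


def firing_rate_derivative(u, p: FiringParams, order: int = 1):
    """Analytic derivative of the sigmoid of order 1, 2 or 3.

    With ``g = expit(beta (u - delta))``:

    * f'   = alpha beta g (1-g)
    * f''  = alpha beta^2 g (1-g) (1-2g)
    * f''' = alpha beta^3 g (1-g) (1-6g+6g^2)
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    g = expit(p.beta * (np.asarray(u, dtype=float) - p.delta))
    base = p.alpha * p.beta**order * g * (1.0 - g)
    if order == 1:
        return base
    if order == 2:
        return base * (1.0 - 2.0 * g)
    return base * (1.0 - 6.0 * g + 6.0 * g * g)


def _clamp_s(s):
    s = np.asarray(s, dtype=float)
    if np.any(s < -1.0 - _CLAMP) or np.any(s > 1.0 + _CLAMP):
        raise ValueError("argument s outside [-1, 1]")
    return np.clip(s, -1.0, 1.0)


def kernel_profile(s, p: ConnectivityParams):
    """Connectivity as a function of the cosine of angular separation."""
    th = np.arccos(_clamp_s(s))
    return p.J1 * np.exp(-th / p.sigma1) + p.J2 * np.exp(-th / p.sigma2)


def delay_profile(s, p: DelayParams):
    """Transmission delay as a function of the cosine of angular separation."""
    th = np.arccos(_clamp_s(s))
    return p.tau0 + th / p.c


def kernel_mass(p: ConnectivityParams) -> float:
    """Total kernel mass ``w0 = 2 pi int w(s) ds`` (Funk-Hecke degree 0)."""
    return float(np.real(funk_hecke(lambda s: kernel_profile(s, p), 0)))


def find_equilibria(p: ModelParams, n_grid: int = 2048) -> list[Equilibrium]:
    """All homogeneous steady states ``u = w0 f(u)``.

    The right-hand side is bounded by ``|w0| alpha`` so every root lies in
    ``[-|w0| alpha - 1, |w0| alpha + 1]``; that interval is scanned in
    ``n_grid`` sub-intervals and every sign change is bisected.  Near-zero
    minima of the residual without a sign change (tangency / fold candidates)
    are reported with ``fold_suspect=True``.
    """
    w0 = kernel_mass(p.connectivity)
    f = p.firing

    def resid(u: float) -> float:
        return u - w0 * firing_rate(u, f)

    bound = abs(w0) * f.alpha + 1.0
    grid = np.linspace(-bound, bound, n_grid + 1)
    vals = resid(grid)
    roots: list[Equilibrium] = []

    def make(u: float, fold: bool = False) -> Equilibrium:
        return Equilibrium(
            u_hat=u,
            kappa=float(firing_rate_derivative(u, f, 1)),
            w0=w0,
            residual=abs(resid(u)),
            fold_suspect=fold,
        )

    for a, b, va, vb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if va == 0.0:
            roots.append(make(float(a)))
        elif va * vb < 0:
            u = brentq(resid, a, b, xtol=1e-14, rtol=4.0e-15)
            roots.append(make(float(u)))
    if vals[-1] == 0.0:
        roots.append(make(float(grid[-1])))

    # tangency detection: interior near-zero local minima of |resid|
    absv = np.abs(vals)
    for i in range(1, n_grid):
        if absv[i] < 1e-8 and absv[i] <= absv[i - 1] and absv[i] <= absv[i + 1]:
            u = float(grid[i])
            if not any(abs(u - r.u_hat) < 4.0 * bound / n_grid for r in roots):
                roots.append(make(u, fold=True))

    roots.sort(key=lambda r: r.u_hat)
    return roots


def calibrate_couplings(
    target_kJ1: float,
    target_kJ2: float,
    firing: FiringParams,
    sigmas: tuple[float, float],
    delay: DelayParams,
    select: str = "all",
):
    """Recover raw couplings (J1, J2) and the equilibrium from lumped gains.

    Stability diagrams are parametrized by the lumped gains
    ``kappa J1, kappa J2`` but the nonlinear model needs raw ``J1, J2``.
    Given targets, the triple (J1, J2, u_hat) must jointly satisfy
    ``kappa(u_hat) J_i = target_i`` and ``u_hat = w0(J1, J2) f(u_hat)``.
    Eliminating J_i reduces this to a scalar root problem in ``u_hat``.

    Returns a list of ``(ConnectivityParams, Equilibrium)`` pairs, one per
    consistent ``u_hat`` branch (sorted by ``u_hat``).  With
    ``select='leading'`` the branch whose n=0 spectrum is closest to the
    imaginary axis is returned alone (the destabilizing branch used by the
    bifurcation studies).
    """
    if target_kJ1 == 0.0 and target_kJ2 == 0.0:
        raise ValueError("targets must not both be zero")
    s1, s2 = sigmas
    h1 = float(
        np.real(funk_hecke(lambda s: np.exp(-np.arccos(_clamp_s(s)) / s1), 0))
    )
    h2 = float(
        np.real(funk_hecke(lambda s: np.exp(-np.arccos(_clamp_s(s)) / s2), 0))
    )
    kw0 = target_kJ1 * h1 + target_kJ2 * h2  # kappa * w0, fixed by the targets

    def resid(u: float) -> float:
        kap = float(firing_rate_derivative(u, firing, 1))
        return kap * u - kw0 * float(firing_rate(u, firing))

    # kappa*u is unbounded in u while kappa*w0*f is bounded, so all roots lie
    # in a modest interval; scan densely and bisect sign changes.
    bound = abs(kw0) * firing.alpha + abs(firing.delta) + 10.0 / firing.beta + 1.0
    grid = np.linspace(-bound, bound, 4097)
    vals = np.array([resid(u) for u in grid])
    sols = []
    for a, b, va, vb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if va * vb < 0 or va == 0.0:
            u = brentq(resid, a, b, xtol=1e-14, rtol=4.0e-15) if va != 0 else a
            kap = float(firing_rate_derivative(u, firing, 1))
            conn = ConnectivityParams(target_kJ1 / kap, target_kJ2 / kap, s1, s2)
            w0 = conn.J1 * h1 + conn.J2 * h2
            eq = Equilibrium(
                u_hat=float(u),
                kappa=kap,
                w0=w0,
                residual=abs(u - w0 * float(firing_rate(u, firing))),
            )
            if eq.residual > 1e-10:
                continue
            sols.append((conn, eq))
    if not sols:
        raise RuntimeError("coupling calibration did not converge to any branch")
    sols.sort(key=lambda ce: ce[1].u_hat)
    if select == "all" or len(sols) == 1 and select == "leading":
        return sols if select == "all" else sols[0]
    if select == "leading":
        # defer to the spectral module for the branch closest to instability
        from .spectral import LinearizationContext, rightmost_eigenvalue

        def closeness(ce):
            conn, eq = ce
            ctx = LinearizationContext(
                ModelParams(firing, conn, delay), eq, n_max=5
            )
            return abs(rightmost_eigenvalue(ctx).lam.real)

        return min(sols, key=closeness)
    raise ValueError(f"unknown select policy {select!r}")
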