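"""Bifurcation curves, Hopf normal form and codimension-2 point location.

In the plane of lumped coupling gains ``(kappa J1, kappa J2)``:

* fold/transcritical candidates of degree ``n`` lie on the line
  ``kappa J1 h_n(0; sigma1) + kappa J2 h_n(0; sigma2) = 1`` (a real root
  ``lambda = 0`` of the characteristic equation),
* Hopf candidates of degree ``n`` form curves parametrized by the critical
  frequency ``omega``, obtained by splitting
  ``kappa J1 h_n(i omega; sigma1) + kappa J2 h_n(i omega; sigma2) = 1 + i omega``
  into real and imaginary parts and solving the 2x2 linear system.

Here ``h_n(lambda; sigma)`` is the Funk-Hecke coefficient of one exponential
kernel component weighted by the delay factor ``exp(-lambda tau(s))``.

The criticality of the n=0 Hopf bifurcation is decided by the first Lyapunov
coefficient ``l1 = Re(g21)/omega0`` with the cubic normal-form coefficient

    g21 = (1 + i omega0) / (8 pi kappa (1 - kappa G0'(i omega0)))
          * ( f'''(u) + f''(u)^2 [ Q0(2 i omega0) + 2 Q0(0) ] ).

Two codimension-2 organizing centres are located along the balanced-kernel
convention (``w0 = 0``, hence ``u = 0``): the generalized (Bautin) Hopf point
where ``l1`` changes sign under variation of the firing threshold, and the
double Hopf point where the degree-0 and degree-1 eigenvalue pairs cross the
imaginary axis simultaneously.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, root

from .harmonics import gauss_legendre
from .model_core import (
    ConnectivityParams,
    DelayParams,
    Equilibrium,
    FiringParams,
    ModelParams,
    firing_rate,
    firing_rate_derivative,
)
from .spectral import E_n, G_n, G_n_prime, LinearizationContext, Q_n

__all__ = [
    "AnalysisTemplate",
    "HopfPoint",
    "NormalFormResult",
    "Codim2Point",
    "fold_line",
    "hopf_curve",
    "balanced_hopf_point",
    "stability_mask",
    "lyapunov_coefficient",
    "find_generalized_hopf",
    "find_double_hopf",
]


@dataclass(frozen=True)
class AnalysisTemplate:
    """Everything but the couplings: kernel scales, delay, optional firing."""

    sigma1: float
    sigma2: float
    delay: DelayParams
    firing: FiringParams | None = None
    quad_order: int = 512

    def h(self, n: int, lam, sigma: float, der: int = 0):
        """Funk-Hecke coefficient of one delay-weighted kernel component."""
        # quadrature in the polar angle, where the integrand is analytic
        x, w = gauss_legendre(self.quad_order)
        th = 0.5 * np.pi * (x + 1.0)
        from scipy.special import eval_legendre

        dly = self.delay.tau0 + th / self.delay.c
        lam = np.asarray(lam, dtype=complex)
        integ = (
            0.5 * np.pi * np.sin(th) * np.exp(-th / sigma)
            * eval_legendre(n, np.cos(th)) * w
        )
        if der:
            integ = integ * (-dly) ** der
        vals = 2.0 * np.pi * np.exp(
            -np.multiply.outer(np.atleast_1d(lam), dly)
        ) @ integ
        return vals[0] if np.asarray(lam).ndim == 0 else vals


@dataclass
class HopfPoint:
    """Certified point on a degree-n Hopf curve in lumped-gain coordinates."""

    n: int
    omega: float
    kJ1: float
    kJ2: float
    context: LinearizationContext | None = None
    residual: float = np.nan


@dataclass
class NormalFormResult:
    g21: complex
    l1: float
    omega0: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def criticality(self) -> str:
        return "supercritical" if self.l1 < 0 else "subcritical"


@dataclass
class Codim2Point:
    kind: str  # "generalized_hopf" | "double_hopf"
    params: ModelParams
    omegas: tuple
    certificates: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


def fold_line(n: int, template: AnalysisTemplate) -> tuple[float, float]:
    """Coefficients (a, b) of the degree-n fold line a*kJ1 + b*kJ2 = 1."""
    a = float(np.real(template.h(n, 0.0, template.sigma1)))
    b = float(np.real(template.h(n, 0.0, template.sigma2)))
    if abs(a) < 1e-14 and abs(b) < 1e-14:
        raise ValueError(f"degenerate fold line for degree {n}")
    return a, b


def _hopf_gains(n: int, omega: float, template: AnalysisTemplate):
    v1 = template.h(n, 1j * omega, template.sigma1)
    v2 = template.h(n, 1j * omega, template.sigma2)
    A = np.array([[v1.real, v2.real], [v1.imag, v2.imag]])
    cond = np.linalg.cond(A)
    kJ = np.linalg.solve(A, np.array([1.0, omega]))
    return kJ, cond


def hopf_curve(
    n: int,
    omega_grid,
    template: AnalysisTemplate,
    max_condition: float = 1e10,
    certify_tol: float = 1e-9,
) -> list[HopfPoint]:
    """Degree-n Hopf curve sampled at the given critical frequencies.

    Each point carries the residual of the characteristic equation at
    ``i omega`` as a certificate; frequencies at which the 2x2 system is
    numerically singular are skipped.
    """
    pts = []
    for om in np.asarray(omega_grid, dtype=float):
        if om <= 0:
            raise ValueError("omega values must be positive")
        kJ, cond = _hopf_gains(n, om, template)
        if cond > max_condition:
            continue
        ctx = LinearizationContext.from_lumped_gains(
            kJ[0], kJ[1], (template.sigma1, template.sigma2), template.delay
        )
        res = abs(E_n(n, 1j * om, ctx))
        if res > certify_tol:
            continue
        pts.append(
            HopfPoint(n=n, omega=om, kJ1=kJ[0], kJ2=kJ[1], context=ctx, residual=res)
        )
    return pts


def balanced_line_ratio(template: AnalysisTemplate) -> float:
    """Slope kJ2/kJ1 of the balanced-kernel line ``w0 = 0``."""
    a, b = fold_line(0, template)
    return -a / b


def balanced_hopf_point(
    n: int,
    template: AnalysisTemplate,
    omega_bracket: tuple[float, float] = (0.05, 3.0),
    n_scan: int = 120,
) -> HopfPoint:
    """Intersection of the degree-n Hopf curve with the balanced line.

    A balanced kernel (``w0 = 0``) forces the zero steady state, making the
    linearization gain explicit; the normal-form analyses in this package
    sit on this line.  Among the intersections in the bracket, the one closest to the
    origin of the gain plane with ``kJ1 > 0`` is returned (the first
    bifurcation reached from the stable origin along the wizard-hat
    direction).
    """
    a0, b0 = fold_line(0, template)

    def resid(om: float) -> float:
        kJ, _ = _hopf_gains(n, om, template)
        return kJ[0] * a0 + kJ[1] * b0

    oms = np.linspace(*omega_bracket, n_scan)
    vals = [resid(o) for o in oms]
    hits = []
    for lo, hi, vlo, vhi in zip(oms[:-1], oms[1:], vals[:-1], vals[1:]):
        if vlo * vhi < 0:
            om = brentq(resid, lo, hi, xtol=1e-13)
            kJ, _ = _hopf_gains(n, om, template)
            hits.append((om, kJ))
    hits = [(om, kJ) for om, kJ in hits if kJ[0] > 0]
    if not hits:
        raise RuntimeError("no balanced Hopf intersection in the bracket")
    om, kJ = min(hits, key=lambda h: float(np.hypot(*h[1])))
    ctx = LinearizationContext.from_lumped_gains(
        kJ[0], kJ[1], (template.sigma1, template.sigma2), template.delay
    )
    return HopfPoint(
        n=n,
        omega=float(om),
        kJ1=float(kJ[0]),
        kJ2=float(kJ[1]),
        context=ctx,
        residual=float(abs(E_n(n, 1j * om, ctx))),
    )


def stability_mask(
    kJ1_values,
    kJ2_values,
    template: AnalysisTemplate,
    n_max: int = 5,
    grid: int = 12,
) -> np.ndarray:
    """Boolean stability verdict over a lumped-gain grid.

    ``True`` where the rightmost eigenvalue over degrees ``n <= n_max`` has
    negative real part; ``None``-like cells (spectral failure) are marked
    unstable=False-with-NaN via a masked array is avoided for simplicity --
    failures raise instead, as they indicate a defective search box.
    """
    from .spectral import rightmost_eigenvalue

    kJ1_values = np.asarray(kJ1_values, float)
    kJ2_values = np.asarray(kJ2_values, float)
    mask = np.zeros((len(kJ1_values), len(kJ2_values)), dtype=bool)
    for i, kj1 in enumerate(kJ1_values):
        for j, kj2 in enumerate(kJ2_values):
            if kj1 == 0.0 and kj2 == 0.0:
                mask[i, j] = True  # pure decay
                continue
            ctx = LinearizationContext.from_lumped_gains(
                kj1, kj2, (template.sigma1, template.sigma2), template.delay,
                n_max=n_max,
            )
            lead = rightmost_eigenvalue(ctx)
            mask[i, j] = lead.lam.real < 0
    return mask


def _context_on_balanced_line(
    hp: HopfPoint, firing: FiringParams, template: AnalysisTemplate
) -> LinearizationContext:
    """Full nonlinear context for a balanced Hopf point (u = 0)."""
    kappa = float(firing_rate_derivative(0.0, firing, 1))
    conn = ConnectivityParams(
        hp.kJ1 / kappa, hp.kJ2 / kappa, template.sigma1, template.sigma2
    )
    a0, b0 = fold_line(0, template)
    w0 = conn.J1 * a0 + conn.J2 * b0
    eq = Equilibrium(u_hat=0.0, kappa=kappa, w0=w0, residual=abs(w0) * float(
        firing_rate(0.0, firing)))
    return LinearizationContext(
        ModelParams(firing, conn, template.delay), eq, n_max=10,
        quad_order=template.quad_order,
    )


def lyapunov_coefficient(hp: HopfPoint, n_check: int = 8) -> NormalFormResult:
    """First Lyapunov coefficient of a degree-0 Hopf point.

    Requires a context with a genuine equilibrium (``hp.context`` built from
    calibrated raw couplings).  The non-resonance condition -- ``i omega0``
    simple and no other characteristic root on the imaginary axis -- is
    checked for degrees up to ``n_check``.
    """
    if hp.n != 0:
        raise ValueError("the scalar Hopf normal form applies to degree 0")
    ctx = hp.context
    if ctx is None or not np.isfinite(ctx.equilibrium.w0):
        raise ValueError("HopfPoint must carry a full nonlinear context")
    from .spectral import E_n_prime

    # Re-polish the critical root inside this context's own quadrature so the
    # normal form is evaluated at an exact root of its discretized E_0.
    lam = 1j * hp.omega
    for _ in range(50):
        e = E_n(0, lam, ctx)
        if abs(e) < 1e-13:
            break
        lam = lam - e / E_n_prime(0, lam, ctx)
    if abs(lam - 1j * hp.omega) > 1e-4 or abs(lam.real) > 1e-6:
        raise ValueError("context inconsistent with the Hopf certificate")
    om0 = float(lam.imag)
    iw = 1j * om0

    if abs(E_n_prime(0, iw, ctx)) < 1e-10:
        raise ValueError("i omega0 is not a simple root of E0")
    for n in range(1, n_check + 1):
        r = _nearest_imaginary_root(n, ctx, om_guess=om0)
        if r is not None and abs(r.real) < 1e-8:
            raise ValueError(f"resonant critical pair at degree {n}")
    u = ctx.equilibrium.u_hat
    f = ctx.params.firing
    f2 = float(firing_rate_derivative(u, f, 2))
    f3 = float(firing_rate_derivative(u, f, 3))
    kap = ctx.kappa
    g0p = G_n_prime(0, iw, ctx)
    q2 = Q_n(0, 2j * om0, ctx)
    q0 = Q_n(0, 0.0 + 0.0j, ctx)
    g21 = (
        (1.0 + iw)
        / (8.0 * np.pi * kap * (1.0 - kap * g0p))
        * (f3 + f2**2 * (q2 + 2.0 * q0))
    )
    return NormalFormResult(
        g21=complex(g21),
        l1=float(g21.real / om0),
        omega0=om0,
        diagnostics={
            "Q0_0": complex(q0),
            "Q0_2iw0": complex(q2),
            "G0_prime_iw0": complex(g0p),
            "kappa": kap,
            "u_hat": u,
        },
    )


def _nearest_imaginary_root(n, ctx, om_guess, tries=(1.0, 0.5, 1.5, 2.0)):
    """Newton polish of the degree-n root nearest the imaginary axis."""
    from .spectral import E_n_prime

    best = None
    for fac in tries:
        lam = 1j * om_guess * fac
        for _ in range(80):
            e = E_n(n, lam, ctx)
            d = E_n_prime(n, lam, ctx)
            if abs(d) < 1e-14:
                break
            lam = lam - e / d
        if abs(E_n(n, lam, ctx)) < 1e-10:
            if best is None or abs(lam.real) < abs(best.real):
                best = complex(lam)
    return best


def find_generalized_hopf(
    template: AnalysisTemplate,
    delta_range: tuple[float, float],
    alpha: float = 1.0,
    beta: float | None = None,
    tol: float = 1e-8,
) -> Codim2Point:
    """Bautin point: the threshold delta* at which l1 vanishes.

    Along the balanced-kernel line the n=0 Hopf point in lumped coordinates is
    independent of the firing threshold, while the normal-form coefficient
    depends on it through the sigmoid derivatives; the sign change of ``l1``
    is bisected to ``|l1| <= tol``.
    """
    if beta is None:
        if template.firing is None:
            raise ValueError("supply beta or a firing template")
        beta = template.firing.beta

    hp = balanced_hopf_point(0, template)

    def l1_of(delta: float) -> float:
        firing = FiringParams(alpha, beta, delta)
        ctx = _context_on_balanced_line(hp, firing, template)
        nf = lyapunov_coefficient(
            HopfPoint(0, hp.omega, hp.kJ1, hp.kJ2, context=ctx), n_check=0
        )
        return nf.l1

    lo, hi = delta_range
    vlo, vhi = l1_of(lo), l1_of(hi)
    if vlo * vhi > 0:
        raise ValueError("l1 does not change sign over the delta interval")
    delta_star = brentq(l1_of, lo, hi, xtol=1e-12)
    firing = FiringParams(alpha, beta, float(delta_star))
    ctx = _context_on_balanced_line(hp, firing, template)
    l1_star = l1_of(float(delta_star))
    return Codim2Point(
        kind="generalized_hopf",
        params=ctx.params,
        omegas=(hp.omega,),
        certificates={
            "l1": l1_star,
            "hopf_residual": hp.residual,
            "E0_residual": float(abs(E_n(0, 1j * hp.omega, ctx))),
        },
        extras={"delta_star": float(delta_star), "kJ1": hp.kJ1, "kJ2": hp.kJ2},
    )


def find_double_hopf(
    template: AnalysisTemplate,
    firing: FiringParams,
    seed: dict | None = None,
    tol: float = 1e-10,
) -> Codim2Point:
    """Double Hopf point with simultaneous degree-0 and degree-1 pairs.

    Unknowns are (J1, J2, tau0, omega0, omega1); the four real conditions
    Re/Im E_0(i omega0) = Re/Im E_1(i omega1) = 0 are closed by the balanced
    kernel constraint w0 = 0, under which the equilibrium is u = 0 and
    kappa = f'(0).  A damped Newton (scipy hybr) is seeded from the balanced
    n=0 Hopf point at the template's offset delay.
    """
    s1, s2 = template.sigma1, template.sigma2
    kappa = float(firing_rate_derivative(0.0, firing, 1))

    if seed is None:
        hp = balanced_hopf_point(0, template)
        seed = {
            "J1": hp.kJ1 / kappa,
            "J2": hp.kJ2 / kappa,
            "tau0": template.delay.tau0,
            "omega0": hp.omega,
            "omega1": 0.7 * hp.omega,
        }

    def h(n, lam, sigma, tau0):
        t = AnalysisTemplate(s1, s2, DelayParams(tau0, template.delay.c),
                             quad_order=template.quad_order)
        return t.h(n, lam, sigma)

    def F(v):
        J1, J2, tau0, om0, om1 = v
        e0 = (
            1j * om0 + 1.0
            - kappa * (J1 * h(0, 1j * om0, s1, tau0) + J2 * h(0, 1j * om0, s2, tau0))
        )
        e1 = (
            1j * om1 + 1.0
            - kappa * (J1 * h(1, 1j * om1, s1, tau0) + J2 * h(1, 1j * om1, s2, tau0))
        )
        bal = J1 * float(np.real(h(0, 0.0, s1, tau0))) + J2 * float(
            np.real(h(0, 0.0, s2, tau0))
        )
        return [e0.real, e0.imag, e1.real, e1.imag, bal]

    x0 = [seed[k] for k in ("J1", "J2", "tau0", "omega0", "omega1")]
    sol = root(F, x0, method="hybr", tol=1e-13)
    if not sol.success or np.max(np.abs(F(sol.x))) > tol:
        raise RuntimeError(f"double-Hopf Newton did not converge: {sol.message}")
    J1, J2, tau0, om0, om1 = (float(v) for v in sol.x)
    # non-resonance: k omega0 != l omega1 for k + l <= 5
    for k in range(1, 5):
        for l in range(1, 5):
            if k + l <= 5 and abs(k * om0 - l * om1) < 1e-6 * max(om0, om1):
                raise RuntimeError(f"resonance {k}:{l} between omega0 and omega1")
    params = ModelParams(
        firing, ConnectivityParams(J1, J2, s1, s2), DelayParams(tau0, template.delay.c)
    )
    res = np.abs(F(sol.x))
    return Codim2Point(
        kind="double_hopf",
        params=params,
        omegas=(om0, om1),
        certificates={
            "E0_residual": float(np.hypot(res[0], res[1])),
            "E1_residual": float(np.hypot(res[2], res[3])),
            "balance_residual": float(res[4]),
        },
        extras={"kappa": kappa},
    )


def curve_frame(points: list[HopfPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.n, p.omega, p.kJ1, p.kJ2) for p in points],
        columns=["n", "omega", "kJ1", "kJ2"],
    )
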