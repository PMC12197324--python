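"""Deterministic model of exogenous retrovirus (XRV) dynamics and virulence evolution.

The model is an SI-type compartment system with logistic births.  Uninfected
hosts (density ``N0``) are born at per-capita rate ``b0`` and die at rate
``v0``.  A viral strain is characterised by its virus production rate ``x``
(which sets both the horizontal transmission rate ``alpha * x`` and the
infected death rate ``v0 * exp(x)``) and its maternal transmission
probability ``m``.  When many strains compete on a grid of ``x`` values with
``m = 1 - exp(-M * x)``, numerical integration of the competition equations
selects the evolutionarily favoured virulence / maternal-transmission pair.

All rates are in model time units; densities may be expressed per carrying
capacity ``K`` (the deterministic system is scale-free in ``K``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "HostDemography",
    "XRVStrain",
    "StrainGrid",
    "SteadyStateSummary",
    "maternal_rate",
    "infected_death_rate",
    "uninfected_density",
    "reproductive_ratio",
    "invasion_exponent",
    "ode_rhs_single",
    "ode_rhs_multistrain",
    "rk4_integrate",
    "steady_state_single",
    "relative_fitness",
    "evolve_competition",
    "critical_alpha",
]


@dataclass(frozen=True)
class HostDemography:
    """Demographic parameters of the uninfected host population.

    Parameters
    ----------
    b0 : float
        Per-capita birth rate (per unit time).  In the sexual, individual-based
        interpretation the rate per female is ``2 * b0``; the two conventions
        give identical population dynamics.
    v0 : float
        Death rate of uninfected hosts (per unit time).  The mean uninfected
        lifespan is ``1 / v0``.
    K : float
        Carrying capacity.  The deterministic dynamics are scale-free in ``K``:
        all steady-state densities scale proportionally.
    """

    b0: float = 1.0
    v0: float = 0.2
    K: float = 1e6

    def __post_init__(self) -> None:
        if self.b0 <= 0 or self.v0 <= 0:
            raise ValueError("b0 and v0 must be positive")
        if self.v0 >= self.b0:
            warnings.warn(
                "v0 >= b0: the uninfected population is not viable", stacklevel=2
            )
        if self.K < 1:
            raise ValueError("K must be >= 1")

    @property
    def p_uninf(self) -> float:
        """Equilibrium density of a virus-free population, ``1 - v0/b0``."""
        return uninfected_density(self.b0, self.v0)


def maternal_rate(x: float, M: float) -> float:
    """Maternal transmission probability ``m = 1 - exp(-M * x)``.

    ``M`` measures how easily maternal transmission occurs: strains with
    ``x >> 1/M`` transmit maternally with probability close to one, while
    ``M = 0`` switches maternal transmission off entirely.
    """
    x = np.asarray(x, dtype=float) if np.ndim(x) else float(x)
    if np.any(np.asarray(x) < 0) or M < 0:
        raise ValueError("x and M must be non-negative")
    return -np.expm1(-M * x) if np.ndim(x) else -math.expm1(-M * x)


def infected_death_rate(x: float, v0: float) -> float:
    """Death rate ``v0 * exp(x)`` of a host infected by a strain of virulence x."""
    if np.any(np.asarray(x) < 0) or v0 <= 0:
        raise ValueError("require x >= 0 and v0 > 0")
    return v0 * np.exp(x)


def uninfected_density(b0: float, v0: float) -> float:
    """Equilibrium population density ``1 - v0/b0`` with no virus present.

    Returns 0 (with a warning) when ``v0 >= b0``, i.e. when the population
    cannot sustain itself.
    """
    if b0 <= 0 or v0 <= 0:
        raise ValueError("b0 and v0 must be positive")
    if v0 >= b0:
        if v0 > b0:
            warnings.warn("v0 > b0: population not viable", stacklevel=2)
        return 0.0
    return 1.0 - v0 / b0


@dataclass(frozen=True)
class XRVStrain:
    """A single XRV strain: production rate ``x`` and maternal transmission ``m``."""

    x: float
    m: float = 0.0

    def __post_init__(self) -> None:
        if self.x < 0:
            raise ValueError("x must be >= 0")
        if not 0.0 <= self.m <= 1.0:
            raise ValueError("m must lie in [0, 1]")

    @classmethod
    def from_tradeoff(cls, x: float, M: float) -> "XRVStrain":
        """Strain on the trade-off curve ``m = 1 - exp(-M x)``."""
        return cls(x=x, m=maternal_rate(x, M))

    def death_rate(self, v0: float) -> float:
        return infected_death_rate(self.x, v0)


@dataclass(frozen=True)
class StrainGrid:
    """Discretised strain space ``x_i = delta * i`` for ``i = 1..n``.

    Maternal transmission follows the trade-off ``m_i = 1 - exp(-M x_i)``.
    The default grid (delta = 0.001, n = 1100) spans x in (0, 1.1].
    """

    M: float = 0.0
    alpha: float = 1.0
    delta: float = 0.001
    n: int = 1100
    x: np.ndarray = field(init=False, repr=False)
    m: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.M < 0 or self.alpha < 0 or self.delta <= 0 or self.n < 1:
            raise ValueError("invalid strain grid parameters")
        x = self.delta * np.arange(1, self.n + 1)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "m", np.asarray(-np.expm1(-self.M * x)))


@dataclass
class SteadyStateSummary:
    """Long-time summary of the multi-strain competition.

    ``mean_x`` and ``mean_m`` are population-weighted means over the infected
    classes (NaN when the virus goes extinct).  ``p0`` and ``pX`` are
    uninfected / infected densities per carrying capacity; ``w0`` and ``wX``
    are fitnesses of uninfected / infected individuals relative to the
    population mean death rate.
    """

    mean_x: float
    mean_m: float
    p0: float
    pX: float
    w0: float
    wX: float
    converged: bool
    t_end: float


def reproductive_ratio(
    strain: XRVStrain, demog: HostDemography, alpha: float
) -> float:
    """Reproductive ratio R of a strain invading the uninfected equilibrium.

    ``R = b0 * m * (1 - p_uninf) / vX + alpha * x * p_uninf / vX``: the first
    term counts maternally infected offspring, the second horizontally
    infected contacts, both over the infected lifespan ``1/vX``.  The strain
    invades iff ``R > 1``.
    """
    p = demog.p_uninf
    vX = infected_death_rate(strain.x, demog.v0)
    return (demog.b0 * strain.m * (1.0 - p) + alpha * strain.x * p) / vX


def invasion_exponent(
    strain: XRVStrain, demog: HostDemography, alpha: float
) -> float:
    """Initial exponential growth rate of a rare strain at the uninfected equilibrium.

    ``lambda = b0*m*(1-p_uninf) - vX + alpha*x*p_uninf``; same sign as R - 1.
    """
    p = demog.p_uninf
    vX = infected_death_rate(strain.x, demog.v0)
    return demog.b0 * strain.m * (1.0 - p) - vX + alpha * strain.x * p


def ode_rhs_single(
    state, strain: XRVStrain, demog: HostDemography, alpha: float
):
    """Right-hand side of the two-compartment (uninfected, infected) system.

    dN0/dt = b0*N0*(1-Ntot/K) + b0*(1-m)*NX*(1-Ntot/K) - v0*N0 - alpha*x*N0*NX/K
    dNX/dt = b0*m*NX*(1-Ntot/K) - vX*NX + alpha*x*N0*NX/K
    """
    N0, NX = state
    b0, v0, K = demog.b0, demog.v0, demog.K
    x, m = strain.x, strain.m
    vX = v0 * math.exp(x)
    logistic = 1.0 - (N0 + NX) / K
    infection = alpha * x * N0 * NX / K
    dN0 = b0 * N0 * logistic + b0 * (1.0 - m) * NX * logistic - v0 * N0 - infection
    dNX = b0 * m * NX * logistic - vX * NX + infection
    return np.array([dN0, dNX])


def ode_rhs_multistrain(N0: float, N, grid: StrainGrid, demog: HostDemography):
    """Right-hand side of the multi-strain competition system.

    dNi/dt = b0*mi*Ni*(1-Ntot/K) - vi*Ni + alpha*xi*N0*Ni/K
    dN0/dt = (b0*N0 + sum_i b0*(1-mi)*Ni)*(1-Ntot/K) - v0*N0
             - (alpha*N0/K) * sum_i xi*Ni

    Hosts carry at most one strain and never recover.
    """
    N = np.asarray(N, dtype=float)
    b0, v0, K = demog.b0, demog.v0, demog.K
    x, m, alpha = grid.x, grid.m, grid.alpha
    v = v0 * np.exp(x)
    Ntot = N0 + N.sum()
    logistic = 1.0 - Ntot / K
    xN = x * N
    dN = b0 * m * N * logistic - v * N + alpha * N0 * xN / K
    dN0 = (
        (b0 * N0 + b0 * np.sum((1.0 - m) * N)) * logistic
        - v0 * N0
        - alpha * N0 * xN.sum() / K
    )
    return dN0, dN


def rk4_integrate(rhs, y0, h: float, t_end: float, sample_every: int = 0):
    """Fixed-step classic fourth-order Runge-Kutta integration.

    Negative densities produced by truncation error are clipped to zero after
    each step.  If ``sample_every`` > 0, the state is recorded every that many
    steps (plus the final state); otherwise only the final state is returned.

    Returns ``(t, y)`` where ``t`` is the array of sample times and ``y`` the
    corresponding states (final state only when ``sample_every`` == 0).
    """
    if h <= 0 or t_end <= 0:
        raise ValueError("h and t_end must be positive")
    y = np.array(y0, dtype=float)
    n_steps = int(round(t_end / h))
    ts, ys = [0.0], [y.copy()]
    t = 0.0
    for step in range(1, n_steps + 1):
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * h * k1)
        k3 = rhs(y + 0.5 * h * k2)
        k4 = rhs(y + h * k3)
        y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        np.clip(y, 0.0, None, out=y)
        if not np.all(np.isfinite(y)):
            raise FloatingPointError(f"non-finite state at t={step * h:g}")
        t = step * h
        if sample_every and step % sample_every == 0:
            ts.append(t)
            ys.append(y.copy())
    if not sample_every or ts[-1] != t:
        ts.append(t)
        ys.append(y.copy())
    return np.array(ts), np.array(ys)


def steady_state_single(
    strain: XRVStrain,
    demog: HostDemography,
    alpha: float,
    h: float = 0.01,
    t_max: float = 1e5,
    residual_tol: float = 1e-10,
):
    """Stationary densities ``(p0, pX)`` of the two-compartment system.

    When the strain cannot invade (R <= 1) the virus-free equilibrium
    ``(p_uninf, 0)`` is returned.  Otherwise the ODEs are integrated to
    convergence and the result is verified by requiring the RHS residual
    (per carrying capacity) to fall below ``residual_tol``.
    """
    p = demog.p_uninf
    if reproductive_ratio(strain, demog, alpha) <= 1.0 or strain.x == 0 and strain.m == 0:
        return p, 0.0
    K = demog.K
    y = np.array([p * K, 1e-3 * K])

    def rhs(state):
        return ode_rhs_single(state, strain, demog, alpha)

    t, block = 0.0, 50.0
    while t < t_max:
        _, ys = rk4_integrate(rhs, y, h, block)
        y = ys[-1]
        t += block
        if np.max(np.abs(rhs(y))) / K < residual_tol:
            break
    residual = np.max(np.abs(rhs(y))) / K
    if residual > residual_tol:
        warnings.warn(
            f"steady_state_single: residual {residual:.2e} above tolerance",
            stacklevel=2,
        )
    return float(y[0] / K), float(y[1] / K)


def relative_fitness(p0: float, pX: float, x: float, v0: float = 0.2):
    """Relative fitness (w0, wX) of uninfected and infected individuals.

    Fitness is inversely proportional to the death rate, so with the mean
    death rate ``v_mean = (v0*p0 + vX*pX) / (p0 + pX)`` the relative fitness
    of an uninfected individual is ``w0 = v_mean / v0`` and of an infected
    one ``wX = v_mean / vX``.  When no one is infected, both are 1.
    """
    if p0 + pX <= 0:
        raise ValueError("p0 + pX must be positive")
    vX = infected_death_rate(x, v0)
    if pX == 0:
        return 1.0, 1.0
    v_mean = (v0 * p0 + vX * pX) / (p0 + pX)
    return v_mean / v0, v_mean / vX


@njit(cache=True)
def _competition_kernel(
    x, m, v, b0, v0, K, alpha, N0_init, Ni_init, h, t_max, window, tol
):  # pragma: no cover - exercised through evolve_competition
    n = x.shape[0]
    N = Ni_init.copy()
    N0 = N0_init
    steps_per_window = int(round(window / h))
    max_windows = int(round(t_max / window))
    prev_mx = np.nan
    prev_mm = np.nan
    converged = False
    t = 0.0
    dN = np.empty(n)
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    Ntmp = np.empty(n)
    mx = np.nan
    mm = np.nan
    for w in range(max_windows):
        for s in range(steps_per_window):
            # classic RK4 on (N0, N)
            d01 = _rhs_multi(x, m, v, b0, v0, K, alpha, N0, N, k1)
            d02 = _rhs_multi(x, m, v, b0, v0, K, alpha, N0 + 0.5 * h * d01,
                             _axpy(N, k1, 0.5 * h, Ntmp), k2)
            d03 = _rhs_multi(x, m, v, b0, v0, K, alpha, N0 + 0.5 * h * d02,
                             _axpy(N, k2, 0.5 * h, Ntmp), k3)
            d04 = _rhs_multi(x, m, v, b0, v0, K, alpha, N0 + h * d03,
                             _axpy(N, k3, h, Ntmp), k4)
            N0 = N0 + (h / 6.0) * (d01 + 2.0 * d02 + 2.0 * d03 + d04)
            if N0 < 0.0:
                N0 = 0.0
            for i in range(n):
                N[i] += (h / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
                # clip undershoot; flush vanishing densities to zero so that
                # exponentially decaying strains cannot reach subnormal range
                if N[i] < 1e-250:
                    N[i] = 0.0
        t = (w + 1) * window
        Ninf = N.sum()
        if Ninf <= 0.0:
            return N0, N, t, np.nan, np.nan, True
        mx = 0.0
        mm = 0.0
        for i in range(n):
            mx += x[i] * N[i]
            mm += m[i] * N[i]
        mx /= Ninf
        mm /= Ninf
        if w > 0 and abs(mx - prev_mx) < tol and abs(mm - prev_mm) < tol:
            converged = True
            break
        prev_mx = mx
        prev_mm = mm
    return N0, N, t, mx, mm, converged


@njit(cache=True, inline="always")
def _axpy(N, k, a, out):  # pragma: no cover
    for i in range(N.shape[0]):
        out[i] = N[i] + a * k[i]
    return out


@njit(cache=True, inline="always")
def _rhs_multi(x, m, v, b0, v0, K, alpha, N0, N, dN):  # pragma: no cover
    n = x.shape[0]
    Ntot = N0
    sxN = 0.0
    s1mN = 0.0
    for i in range(n):
        Ntot += N[i]
        sxN += x[i] * N[i]
        s1mN += (1.0 - m[i]) * N[i]
    logistic = 1.0 - Ntot / K
    for i in range(n):
        dN[i] = b0 * m[i] * N[i] * logistic - v[i] * N[i] + alpha * x[i] * N0 * N[i] / K
    dN0 = (b0 * N0 + b0 * s1mN) * logistic - v0 * N0 - alpha * N0 * sxN / K
    return dN0


def evolve_competition(
    grid: StrainGrid,
    demog: HostDemography = HostDemography(),
    h: float = 0.01,
    t_max: float = 1e5,
    window: float = 100.0,
    tol: float = 1e-6,
) -> SteadyStateSummary:
    """Integrate the multi-strain competition to its evolutionary steady state.

    Starts from ``N0 = p_uninf * K`` uninfected hosts and one individual of
    every strain, and integrates with fixed-step RK4 until the
    population-weighted mean virulence and maternal transmission each change
    by less than ``tol`` over a ``window`` of model time (or ``t_max`` is
    reached, in which case ``converged`` is False).

    The winning strain maximises long-term competitive success given the
    trade-off ``m = 1 - exp(-M x)``; with ``M = 0`` this reduces to
    maximising ``R`` and selects ``x = 1``.
    """
    v = demog.v0 * np.exp(grid.x)
    N0_init = demog.p_uninf * demog.K
    Ni_init = np.ones_like(grid.x)
    N0, N, t_end, mx, mm, converged = _competition_kernel(
        grid.x,
        np.asarray(grid.m, dtype=float),
        v,
        demog.b0,
        demog.v0,
        demog.K,
        grid.alpha,
        N0_init,
        Ni_init,
        h,
        t_max,
        window,
        tol,
    )
    Ninf = float(N.sum())
    p0 = float(N0 / demog.K)
    pX = Ninf / demog.K
    if pX < 1e-12:
        # virus effectively extinct (far below one individual at any
        # realistic K); the means of a vanishing population are undefined
        Ninf = 0.0
        mx = mm = float("nan")
    if Ninf > 0:
        v_inf = float(np.sum(v * N) / Ninf)
        v_mean = (demog.v0 * p0 + v_inf * pX) / (p0 + pX)
        w0, wX = v_mean / demog.v0, v_mean / v_inf
    else:
        w0, wX = 1.0, float("nan")
    return SteadyStateSummary(
        mean_x=float(mx),
        mean_m=float(mm),
        p0=p0,
        pX=pX,
        w0=w0,
        wX=wX,
        converged=bool(converged),
        t_end=float(t_end),
    )


def critical_alpha(
    M: float,
    demog: HostDemography = HostDemography(),
    grid: StrainGrid | None = None,
    tol: float = 1e-4,
) -> float:
    """Critical contact rate below which no strain on the grid can invade.

    Found by bisection on ``max_i R_i(alpha) = 1``.  Survival of a rare virus
    at the uninfected equilibrium is governed by the reproductive ratio, so
    this threshold coincides with the one obtained by re-running the full
    competition at each alpha (the slow scan retained in
    :func:`critical_alpha_scan`).
    """
    if M < 0:
        raise ValueError("M must be >= 0")
    grid = grid if grid is not None else StrainGrid(M=M, alpha=1.0)

    def max_R(alpha: float) -> float:
        p = demog.p_uninf
        vX = demog.v0 * np.exp(grid.x)
        R = (demog.b0 * np.asarray(grid.m) * (1.0 - p) + alpha * grid.x * p) / vX
        return float(R.max())

    lo, hi = 0.0, 1.0
    while max_R(hi) < 1.0:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("failed to bracket the invasion threshold")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if max_R(mid) >= 1.0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def critical_alpha_scan(
    M: float,
    demog: HostDemography = HostDemography(),
    alphas=None,
    grid_kwargs: dict | None = None,
    t_max: float = 2000.0,
    survival_density: float = 1e-9,
) -> float:
    """Competition-based cross-check of :func:`critical_alpha`.

    Runs the multi-strain competition at each alpha in ``alphas`` and reports
    the smallest alpha at which the virus survives (infected density above
    ``survival_density`` per K at ``t_max``).  Orders of magnitude slower
    than the bisection; intended for validation at coarse alpha grids.
    """
    if alphas is None:
        alphas = np.arange(0.5, 1.01, 0.05)
    kwargs = dict(delta=0.01, n=110)
    kwargs.update(grid_kwargs or {})
    for alpha in np.sort(np.asarray(alphas, dtype=float)):
        grid = StrainGrid(M=M, alpha=float(alpha), **kwargs)
        # tol=0 forces the full horizon: near the threshold the strain mix
        # stabilises long before the (slowly decaying) total density does
        out = evolve_competition(grid, demog, t_max=t_max, tol=0.0)
        if out.pX > survival_density:
            return float(alpha)
    raise RuntimeError("virus did not survive at any alpha in the scan")
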