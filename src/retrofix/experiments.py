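"""Batch drivers: outcome-probability estimation and parameter sweeps.

Every sweep runs independent Gillespie replicates per grid point (replicate
``i`` of point ``j`` uses seed ``base_seed + j * n_repeats + i``, so results
do not depend on execution order) and tabulates the full outcome
decomposition — fixation, loss, clearance, extinction, censoring — together
with binomial uncertainty on the fixation and clearance probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from retrofix.gillespie import (
    CENSORED,
    CLEARANCE,
    EXTINCT,
    FIXATION,
    LOSS,
    StochasticParams,
    run_replicate,
    run_replicates,
)
from retrofix import xrv_ode

__all__ = [
    "SweepSpec",
    "OutcomeEstimate",
    "estimate_outcomes",
    "sweep_y",
    "sweep_L",
    "sweep_x_locus",
    "xrv_locus",
    "reproduce_figure",
    "estimates_to_frame",
]


@dataclass(frozen=True)
class SweepSpec:
    """One-dimensional parameter sweep over the stochastic model.

    ``vary`` names a :class:`StochasticParams` field varied over ``grid``
    (``None`` runs the base parameter set once).  ``p0``/``pX`` fix the
    initial densities; left as None they are derived from the deterministic
    model (XRV present) or the virus-free equilibrium.
    """

    params: StochasticParams
    n_repeats: int = 2000
    base_seed: int = 0
    xrv_present: bool = False
    vary: Optional[str] = None
    grid: Sequence = ()
    p0: Optional[float] = None
    pX: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.vary is not None and len(self.grid) == 0:
            raise ValueError("a varied parameter needs a non-empty grid")


@dataclass
class OutcomeEstimate:
    """Outcome tallies and probability estimates at one parameter value.

    ``p_fix`` (and ``p_clear``) use the definition
    ``fixations / (n_repeats - extinct - censored)``; ``ci_lo``/``ci_hi``
    are exact (Clopper-Pearson) 95% bounds and ``se`` the Wald standard
    error for ``p_fix``.
    """

    value: float
    n_repeats: int
    n_fix: int
    n_loss: int
    n_clear: int
    n_extinct: int
    n_censored: int

    @property
    def n_effective(self) -> int:
        return self.n_repeats - self.n_extinct - self.n_censored

    @property
    def p_fix(self) -> float:
        return self.n_fix / self.n_effective if self.n_effective else float("nan")

    @property
    def p_clear(self) -> float:
        return self.n_clear / self.n_effective if self.n_effective else float("nan")

    @property
    def se(self) -> float:
        n, p = self.n_effective, self.p_fix
        return math.sqrt(p * (1.0 - p) / n) if n else float("nan")

    @property
    def ci(self) -> tuple:
        return _clopper_pearson(self.n_fix, self.n_effective)

    @property
    def ci_clear(self) -> tuple:
        return _clopper_pearson(self.n_clear, self.n_effective)


def _clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple:
    if n == 0:
        return (float("nan"), float("nan"))
    a = (1.0 - level) / 2.0
    lo = 0.0 if k == 0 else stats.beta.ppf(a, k, n - k + 1)
    hi = 1.0 if k == n else stats.beta.ppf(1.0 - a, k + 1, n - k)
    return (float(lo), float(hi))


def _estimate_point(
    params: StochasticParams,
    xrv_present: bool,
    n_repeats: int,
    base_seed: int,
    value: float,
    p0: Optional[float],
    pX: Optional[float],
) -> OutcomeEstimate:
    codes = run_replicates(params, xrv_present, n_repeats, base_seed, p0, pX)
    counts = np.bincount(codes, minlength=5)
    return OutcomeEstimate(
        value=value,
        n_repeats=n_repeats,
        n_fix=int(counts[FIXATION]),
        n_loss=int(counts[LOSS]),
        n_clear=int(counts[CLEARANCE]),
        n_extinct=int(counts[EXTINCT]),
        n_censored=int(counts[CENSORED]),
    )


def estimate_outcomes(spec: SweepSpec) -> list[OutcomeEstimate]:
    """Run the sweep and return one :class:`OutcomeEstimate` per grid point."""
    if spec.vary is None:
        return [
            _estimate_point(
                spec.params, spec.xrv_present, spec.n_repeats, spec.base_seed,
                float("nan"), spec.p0, spec.pX,
            )
        ]
    out = []
    for j, val in enumerate(spec.grid):
        params = replace(spec.params, **{spec.vary: val})
        out.append(
            _estimate_point(
                params, spec.xrv_present, spec.n_repeats,
                spec.base_seed + j * spec.n_repeats, float(val),
                spec.p0, spec.pX,
            )
        )
    return out


def estimates_to_frame(estimates: list[OutcomeEstimate], param_name: str = "param") -> pd.DataFrame:
    """Tabulate estimates with the fixed CSV schema used by the CLI."""
    rows = []
    for e in estimates:
        lo, hi = e.ci
        clo, chi = e.ci_clear
        rows.append(
            {
                param_name: e.value,
                "n_reps": e.n_repeats,
                "n_fix": e.n_fix,
                "n_loss": e.n_loss,
                "n_clear": e.n_clear,
                "n_extinct": e.n_extinct,
                "n_censored": e.n_censored,
                "p_fix": e.p_fix,
                "ci_lo": lo,
                "ci_hi": hi,
                "p_clear": e.p_clear,
                "p_clear_ci_lo": clo,
                "p_clear_ci_hi": chi,
            }
        )
    return pd.DataFrame(rows)


def sweep_y(
    y_grid: Sequence,
    r: float = 0.1,
    L: int = 10,
    beta: float = 1.0,
    xrv: Optional[tuple] = None,
    n_repeats: int = 2000,
    base_seed: int = 0,
    **param_overrides,
) -> list[OutcomeEstimate]:
    """Fixation probability as a function of the ERV's deleterious effect y.

    ``xrv=(x, m)`` switches on the XRV with those parameters (initial
    densities from the deterministic stationary state); ``xrv=None`` runs the
    insertion alone in a virus-free population.
    """
    x, m = xrv if xrv is not None else (0.0, 0.0)
    params = StochasticParams(
        x=x, m=m, r=r, L=L, beta=beta, **param_overrides
    )
    spec = SweepSpec(
        params=params, n_repeats=n_repeats, base_seed=base_seed,
        xrv_present=xrv is not None, vary="y", grid=list(y_grid),
    )
    return estimate_outcomes(spec)


def sweep_L(
    L_grid: Sequence = (1, 2, 10, 50, 250),
    r: float = 0.1,
    y: float = 0.0,
    n_repeats: int = 2000,
    base_seed: int = 0,
    **param_overrides,
) -> list[OutcomeEstimate]:
    """Effect of the number of insertable loci L on the fixation probability
    (virus-free population)."""
    params = StochasticParams(x=0.0, m=0.0, r=r, y=y, **param_overrides)
    spec = SweepSpec(
        params=params, n_repeats=n_repeats, base_seed=base_seed,
        xrv_present=False, vary="L", grid=list(L_grid),
    )
    return estimate_outcomes(spec)


def xrv_locus(
    M_grid: Sequence = (0.0, 0.4, 1.0, 4.0, 40.0, 400.0),
    alpha: float = 1.0,
    demog: Optional[xrv_ode.HostDemography] = None,
    grid_kwargs: Optional[dict] = None,
    **competition_kwargs,
) -> pd.DataFrame:
    """Evolved (x, m) pairs along the virulence / maternal-transmission
    trade-off, one per value of the ease-of-transmission parameter M.

    Runs the multi-strain competition for each M and records the winning
    mean x and m together with the single-strain stationary densities and
    relative fitnesses.  This is the locus from which XRV parameters for the
    stochastic model are drawn.
    """
    demog = demog or xrv_ode.HostDemography()
    rows = []
    for M in M_grid:
        grid = xrv_ode.StrainGrid(M=M, alpha=alpha, **(grid_kwargs or {}))
        summary = xrv_ode.evolve_competition(grid, demog, **competition_kwargs)
        if np.isnan(summary.mean_x):
            rows.append({"M": M, "x": np.nan, "m": np.nan, "p0": summary.p0,
                         "pX": 0.0, "w0": 1.0, "wX": np.nan,
                         "converged": summary.converged})
            continue
        strain = xrv_ode.XRVStrain(x=summary.mean_x, m=summary.mean_m)
        p0, pX = xrv_ode.steady_state_single(strain, demog, alpha)
        w0, wX = xrv_ode.relative_fitness(p0, pX, strain.x, demog.v0)
        rows.append({"M": M, "x": summary.mean_x, "m": summary.mean_m,
                     "p0": p0, "pX": pX, "w0": w0, "wX": wX,
                     "converged": summary.converged})
    return pd.DataFrame(rows)


def sweep_x_locus(
    pairs: Sequence,
    y: str | float = 0.0,
    r: float = 0.1,
    beta: float = 1.0,
    n_repeats: int = 2000,
    base_seed: int = 0,
    **param_overrides,
) -> list[OutcomeEstimate]:
    """Fixation probability across evolved XRV (x, m) pairs.

    ``pairs`` is a sequence of ``(x, m)`` tuples (typically from
    :func:`xrv_locus`).  ``y`` may be a number or ``"equal"`` to set the
    insertion's virulence equal to the XRV's (y = x).  When the XRV cannot
    persist at a pair (reproductive ratio <= 1, e.g. x = 0), the replicate
    runs virus-free, matching the limit in which the XRV has no effect.
    """
    demog = xrv_ode.HostDemography()
    out = []
    for j, (x, m) in enumerate(pairs):
        y_val = float(x) if y == "equal" else float(y)
        params = StochasticParams(
            x=float(x), m=float(m), y=y_val, r=r, beta=min(beta, param_overrides.get("alpha", 1.0)),
            **param_overrides,
        )
        strain = xrv_ode.XRVStrain(x=params.x, m=params.m)
        R = xrv_ode.reproductive_ratio(strain, demog, params.alpha)
        if R > 1.0:
            p0, pX = xrv_ode.steady_state_single(strain, demog, params.alpha)
            xrv_present = pX > 0
        else:
            p0, pX = demog.p_uninf, 0.0
            xrv_present = False
        est = _estimate_point(
            params, xrv_present, n_repeats,
            base_seed + j * n_repeats, float(x), p0, pX,
        )
        out.append(est)
    return out


def reproduce_figure(
    figure: int,
    scale: float = 1.0,
    base_seed: int = 0,
    n_repeats: int = 10000,
    locus: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Regenerate one of the numbered reference analyses of the model family.

    ``scale`` multiplies the replicate count (deterministic figures 1-3
    ignore it).  Returns a tidy DataFrame; plotting is left to the caller.
    Figures 8 and 9 need the evolved (x, m) locus; pass ``locus`` (from
    :func:`xrv_locus`) to avoid recomputing it.
    """
    reps = max(1, int(round(n_repeats * scale)))
    demog = xrv_ode.HostDemography()
    if figure == 1:
        return xrv_locus(M_grid=(0.0, 0.4, 1.0, 4.0, 40.0, 400.0))
    if figure == 2:
        return locus if locus is not None else xrv_locus()
    if figure == 3:
        rows = []
        for M in (0.0, 0.4, 4.0, 40.0, 400.0):
            for alpha in np.arange(0.2, 2.01, 0.2):
                grid = xrv_ode.StrainGrid(M=M, alpha=float(alpha), delta=0.01, n=110)
                s = xrv_ode.evolve_competition(grid, demog)
                rows.append({"M": M, "alpha": float(alpha), "x": s.mean_x,
                             "m": s.mean_m, "N_inf": s.pX})
        return pd.DataFrame(rows)
    if figure == 4:
        frames = []
        for r in (0.01, 0.1, 1.0):
            ests = sweep_y(np.arange(0.0, 0.75, 0.1), r=r,
                           n_repeats=reps, base_seed=base_seed)
            f = estimates_to_frame(ests, "y")
            f.insert(0, "r", r)
            f.insert(0, "panel", "a")
            frames.append(f)
        for L in (1, 2, 10, 50, 250):
            ests = sweep_y(np.arange(0.0, 0.45, 0.1), r=0.1, L=L,
                           n_repeats=reps, base_seed=base_seed + 7919)
            f = estimates_to_frame(ests, "y")
            f.insert(0, "L", L)
            f.insert(0, "panel", "b")
            frames.append(f)
        return pd.concat(frames, ignore_index=True)
    if figure == 5:
        cases = [
            dict(y=0.0, r=0.1, beta=1.0),
            dict(y=0.0, r=0.01, beta=0.0),
            dict(y=0.1, r=0.01, beta=1.0),
        ]
        frames = []
        for k, case in enumerate(cases):
            params = StochasticParams(x=1.0, m=0.0, **case)
            # fixed per-case seed; the interesting outcomes are stochastic,
            # so scan seeds until the narrative outcome appears
            want = "clearance" if case["y"] > 0 else "fixation"
            for s in range(200):
                out = run_replicate(params, xrv_present=True,
                                    seed=base_seed + 1000 * k + s, sample_dt=1.0)
                if out.outcome == want:
                    break
            tr = pd.DataFrame(out.trajectory,
                              columns=["t", "N0", "NX", "NE", "NEX", "g"])
            tr.insert(0, "case", chr(ord("a") + k))
            tr["outcome"] = out.outcome
            frames.append(tr)
        return pd.concat(frames, ignore_index=True)
    if figure in (6, 7):
        frames = []
        y_grid = np.arange(0.0, 0.65, 0.1)
        r_values = (0.1, 0.01) if figure == 6 else (0.01, 0.0)
        betas = (1.0, 0.0) if figure == 6 else (0.0,)
        for r in r_values:
            for beta in betas:
                ests = sweep_y(y_grid, r=r, beta=beta, xrv=(1.0, 0.0),
                               n_repeats=reps, base_seed=base_seed)
                f = estimates_to_frame(ests, "y")
                f.insert(0, "beta", beta)
                f.insert(0, "r", r)
                frames.append(f)
            if figure == 6:
                ests = sweep_y(y_grid, r=r, n_repeats=reps, base_seed=base_seed)
                f = estimates_to_frame(ests, "y")
                f.insert(0, "beta", np.nan)
                f.insert(0, "r", r)
                frames.append(f)
        return pd.concat(frames, ignore_index=True)
    if figure in (8, 9):
        loc = locus if locus is not None else xrv_locus()
        pairs = [(row.x, row.m) for row in loc.itertuples() if not np.isnan(row.x)]
        pairs = [(0.0, 0.0)] + pairs
        y = 0.0 if figure == 8 else "equal"
        r_values = (0.1, 0.0) if figure == 8 else (0.1, 0.01)
        frames = []
        for r in r_values:
            for beta in (1.0, 0.0):
                ests = sweep_x_locus(pairs, y=y, r=r, beta=beta,
                                     n_repeats=reps, base_seed=base_seed)
                f = estimates_to_frame(ests, "x")
                f.insert(0, "beta", beta)
                f.insert(0, "r", r)
                frames.append(f)
            if figure == 9:
                for x, _ in pairs:
                    params = StochasticParams(x=0.0, m=0.0, y=float(x), r=r)
                    est = _estimate_point(params, False, reps, base_seed,
                                          float(x), None, None)
                    f = estimates_to_frame([est], "x")
                    f.insert(0, "beta", np.nan)
                    f.insert(0, "r", r)
                    frames.append(f)
        return pd.concat(frames, ignore_index=True)
    raise ValueError(f"unknown figure id: {figure!r}")
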