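"""Exact stochastic simulation of ERV spread in a finite diploid host population.

Each of ``K`` population slots is either empty or holds one individual with a
sex, an XRV infection flag, and a diploid genome of ``L`` unlinked loci whose
alleles are 0 (absent) or E (an endogenous retrovirus insertion).  Individuals
fall into four types: 0 (no insertion, uninfected), X (infected, no
insertion), E (carrier, uninfected) and EX (carrier, infected).

Events follow the Gillespie stochastic simulation algorithm:

* birth at rate ``2*b0*(1 - Ntot/K)`` per female (a random male fathers the
  offspring; Mendelian inheritance at L unlinked loci; maternal XRV
  transmission with probability ``m`` for non-carrier offspring and
  ``m*beta/alpha`` for carrier offspring of an infected mother),
* death at rate ``v0``, ``v0*e^x``, ``v0*e^y`` or ``max(v0*e^x, v0*e^y)``
  for types 0, X, E, EX respectively,
* horizontal infection at per-capita rate ``alpha*x*(NX+NEX)/K`` for
  non-carriers and ``beta*x*(NX+NEX)/K`` for carriers (receptor
  interference: ``beta < alpha`` means the insertion confers resistance),
* transposition at rate ``r*l*(1 - l/2L)`` for an individual carrying ``l``
  insertions, duplicating one insertion into a random unoccupied slot of the
  same genome.

A replicate runs until the insertion fixes (no individual without a copy),
is lost, the population goes extinct, or a censoring horizon is reached.

The event loop and event primitives are numba-compiled; all randomness flows
through numba's internal RNG, seeded once per replicate, so replicates are
reproducible and embarrassingly parallel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from numba import njit

__all__ = [
    "StochasticParams",
    "Population",
    "SimOutcome",
    "OUTCOME_NAMES",
    "init_population",
    "run_replicate",
    "run_replicates",
    "seed_event_rng",
    "compute_rates",
]

OUTCOME_NAMES = ("loss", "fixation", "clearance", "extinct", "censored")
LOSS, FIXATION, CLEARANCE, EXTINCT, CENSORED = range(5)

# individual types; E-carrier types have bit 1 set, infected types bit 0
TYPE_0, TYPE_X, TYPE_E, TYPE_EX = 0, 1, 2, 3


@dataclass(frozen=True)
class StochasticParams:
    """Parameter set for the stochastic model.

    Defaults follow the reference configuration: ``K=1000``, ``b0=1``,
    ``v0=0.2``, ``L=10``, contact rate ``alpha=1``.  ``x`` and ``m`` describe
    the XRV (ignored when no XRV is present), ``y`` and ``r`` the ERV's
    virulence and transposition rate, and ``beta`` the contact rate
    experienced by ERV carriers (``beta=0``: full resistance;
    ``beta=alpha``: no protection).
    """

    K: int = 1000
    b0: float = 1.0
    v0: float = 0.2
    x: float = 1.0
    m: float = 0.0
    y: float = 0.0
    r: float = 0.1
    alpha: float = 1.0
    beta: float = 1.0
    L: int = 10
    t_max: float = 1e5

    def __post_init__(self) -> None:
        if self.K < 1 or self.L < 1:
            raise ValueError("K and L must be >= 1")
        if min(self.b0, self.v0, self.x, self.y, self.r, self.alpha) < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.m <= 1.0:
            raise ValueError("m must lie in [0, 1]")
        if not 0.0 <= self.beta <= self.alpha:
            raise ValueError("beta must lie in [0, alpha]")
        if self.m > 0 and self.alpha == 0:
            raise ValueError("m > 0 requires alpha > 0 (m*beta/alpha undefined)")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")

    @property
    def vX(self) -> float:
        return self.v0 * math.exp(self.x)

    @property
    def vE(self) -> float:
        return self.v0 * math.exp(self.y)

    @property
    def vEX(self) -> float:
        return max(self.vX, self.vE)


@dataclass
class SimOutcome:
    """Terminal record of one stochastic replicate.

    ``outcome`` is one of ``loss`` (insertion lost while the XRV was never
    eliminated first), ``fixation`` (every individual carries at least one
    copy), ``clearance`` (the XRV was eliminated while carriers were present
    and the insertion was subsequently lost), ``extinct`` (whole population
    died) or ``censored`` (horizon reached).  ``trajectory`` holds sampled
    rows ``(t, N0, NX, NE, NEX, g)`` where ``g`` is the mean occupied-locus
    fraction ``C / (2L * Ntot)``.
    """

    outcome: str
    t_end: float
    t_xrv_eliminated: Optional[float]
    t_all_carry: Optional[float]
    seed: int
    n_initial: int
    trajectory: Optional[np.ndarray] = None
    init_retries: int = 0
    mean_lifetime: float = float("nan")
    n_lifetimes: int = 0
    final_population: Optional["Population"] = None


# ---------------------------------------------------------------------------
# numba primitives
# ---------------------------------------------------------------------------


@njit(cache=True)
def seed_event_rng(seed):  # pragma: no cover - trivial
    """Seed numba's internal RNG (separate state from Python-level numpy)."""
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _lst_add(row, pos, cnt, ci, ind):  # pragma: no cover
    row[cnt[ci]] = ind
    pos[ind] = cnt[ci]
    cnt[ci] += 1


@njit(cache=True, inline="always")
def _lst_remove(row, pos, cnt, ci, ind):  # pragma: no cover
    c = cnt[ci] - 1
    last = row[c]
    p = pos[ind]
    row[p] = last
    pos[last] = p
    cnt[ci] = c


@njit(cache=True, inline="always")
def _type_of(lc, infected):  # pragma: no cover
    t = 0
    if infected:
        t += 1
    if lc > 0:
        t += 2
    return t


@njit(cache=True)
def _compute_rates(cnt_type, cnt_sex, S, K, L2, b0, v0, vX, vE, vEX, x, r,
                   alpha, beta, out):  # pragma: no cover
    """Fill ``out`` with the eight event-class rates and return their sum.

    Layout: [birth, death-0, death-X, death-E, death-EX, infect-noncarrier,
    infect-carrier, transposition].
    """
    n0, nX, nE, nEX = cnt_type[0], cnt_type[1], cnt_type[2], cnt_type[3]
    ntot = n0 + nX + nE + nEX
    nF = cnt_sex[1]
    nM = cnt_sex[0]
    if nM > 0 and ntot < K:
        out[0] = 2.0 * b0 * nF * (1.0 - ntot / K)
    else:
        out[0] = 0.0
    out[1] = v0 * n0
    out[2] = vX * nX
    out[3] = vE * nE
    out[4] = vEX * nEX
    force = x * (nX + nEX) / K
    out[5] = alpha * force * n0
    out[6] = beta * force * nE
    out[7] = r * (S[0] - S[1] / L2)
    total = 0.0
    for i in range(8):
        total += out[i]
    return total


@njit(cache=True)
def _birth_event(t, genome, l, sex, inf, alive, tb,
                 by_type, pos_type, cnt_type,
                 by_sex, pos_sex, cnt_sex,
                 empty_lst, pos_empty, cnt_empty,
                 S, L, m, alpha, beta):  # pragma: no cover
    """One birth: uniform mother among females, uniform father among males,
    Mendelian inheritance, maternal XRV transmission, uniform empty slot."""
    mom = by_sex[1][np.random.randint(cnt_sex[1])]
    dad = by_sex[0][np.random.randint(cnt_sex[0])]
    slot = empty_lst[np.random.randint(cnt_empty[0])]
    lc = 0
    for j in range(L):
        a = genome[mom, 2 * j + (1 if np.random.random() < 0.5 else 0)]
        b = genome[dad, 2 * j + (1 if np.random.random() < 0.5 else 0)]
        genome[slot, 2 * j] = a
        genome[slot, 2 * j + 1] = b
        lc += a + b
    child_inf = np.uint8(0)
    if inf[mom] == 1 and m > 0.0:
        p = m if lc == 0 else m * beta / alpha
        if np.random.random() < p:
            child_inf = np.uint8(1)
    sx = np.uint8(1) if np.random.random() < 0.5 else np.uint8(0)
    alive[slot] = 1
    sex[slot] = sx
    inf[slot] = child_inf
    l[slot] = lc
    tb[slot] = t
    S[0] += lc
    S[1] += lc * lc
    _lst_remove(empty_lst, pos_empty, cnt_empty, 0, slot)
    _lst_add(by_sex[sx], pos_sex, cnt_sex, sx, slot)
    ty = _type_of(lc, child_inf == 1)
    _lst_add(by_type[ty], pos_type, cnt_type, ty, slot)
    return slot


@njit(cache=True)
def _death_event(ty, genome, l, sex, inf, alive,
                 by_type, pos_type, cnt_type,
                 by_sex, pos_sex, cnt_sex,
                 empty_lst, pos_empty, cnt_empty, S):  # pragma: no cover
    """Remove a uniformly chosen individual of type ``ty``."""
    victim = by_type[ty][np.random.randint(cnt_type[ty])]
    lc = l[victim]
    S[0] -= lc
    S[1] -= lc * lc
    alive[victim] = 0
    _lst_remove(by_type[ty], pos_type, cnt_type, ty, victim)
    sx = sex[victim]
    _lst_remove(by_sex[sx], pos_sex, cnt_sex, sx, victim)
    _lst_add(empty_lst, pos_empty, cnt_empty, 0, victim)
    return victim


@njit(cache=True)
def _infection_event(ty_from, inf, by_type, pos_type, cnt_type):  # pragma: no cover
    """Infect a uniformly chosen member of class ``ty_from`` (type 0 or E)."""
    victim = by_type[ty_from][np.random.randint(cnt_type[ty_from])]
    inf[victim] = 1
    _lst_remove(by_type[ty_from], pos_type, cnt_type, ty_from, victim)
    ty_to = ty_from + 1
    _lst_add(by_type[ty_to], pos_type, cnt_type, ty_to, victim)
    return victim


@njit(cache=True)
def _transposition_event(genome, l, by_type, cnt_type, S, L2):  # pragma: no cover
    """Duplicate one insertion: individual chosen with weight l*(1 - l/2L),
    then a uniformly chosen unoccupied allele slot flips to E."""
    w_tot = S[0] - S[1] / L2
    target = np.random.random() * w_tot
    acc = 0.0
    chosen = -1
    for ty in (TYPE_E, TYPE_EX):
        for k in range(cnt_type[ty]):
            ind = by_type[ty][k]
            li = l[ind]
            acc += li * (1.0 - li / L2)
            # strict inequality: saturated (l=2L) individuals add zero weight
            # and must be unselectable even when target == 0
            if acc > target:
                chosen = ind
                break
        if chosen >= 0:
            break
    if chosen < 0:
        # float round-off fallback: last carrier with an open slot
        for ty in (TYPE_EX, TYPE_E):
            for k in range(cnt_type[ty] - 1, -1, -1):
                ind = by_type[ty][k]
                if l[ind] < int(L2):
                    chosen = ind
                    break
            if chosen >= 0:
                break
    li = l[chosen]
    kth = np.random.randint(int(L2) - li)
    seen = 0
    for a in range(int(L2)):
        if genome[chosen, a] == 0:
            if seen == kth:
                genome[chosen, a] = 1
                break
            seen += 1
    l[chosen] = li + 1
    S[0] += 1
    S[1] += 2 * li + 1
    return chosen


@njit(cache=True)
def _run_kernel(seed, t_max,
                genome, l, sex, inf, alive, tb,
                by_type, pos_type, cnt_type,
                by_sex, pos_sex, cnt_sex,
                empty_lst, pos_empty, cnt_empty, S,
                K, L, b0, v0, x, m, y, r, alpha, beta,
                xrv_present,
                sample_dt, traj_t, traj_n,
                collect_lifetimes, birth_cutoff):  # pragma: no cover
    """Gillespie event loop from a prepared population to an absorbing state.

    Returns ``(code, t_end, t_xrv_elim, t_fix, n_samples, age_sum, age_n)``
    with times < 0 meaning "never happened".
    """
    np.random.seed(seed)
    L2 = 2.0 * L
    vX = v0 * math.exp(x)
    vE = v0 * math.exp(y)
    vEX = max(vX, vE)
    rates = np.empty(8)
    t = 0.0
    t_xrv = -1.0
    t_fix = -1.0
    age_sum = 0.0
    age_n = 0
    erv_present = cnt_type[TYPE_E] + cnt_type[TYPE_EX] > 0
    next_sample = 0.0
    n_samples = 0
    code = CENSORED
    while True:
        n0 = cnt_type[TYPE_0]
        nX = cnt_type[TYPE_X]
        nE = cnt_type[TYPE_E]
        nEX = cnt_type[TYPE_EX]
        ntot = n0 + nX + nE + nEX
        if ntot == 0:
            code = EXTINCT
            break
        if erv_present:
            if nE + nEX == 0:
                code = CLEARANCE if (xrv_present and t_xrv >= 0.0) else LOSS
                break
            if n0 + nX == 0:
                code = FIXATION
                t_fix = t
                break
        if xrv_present and t_xrv < 0.0 and nX + nEX == 0:
            t_xrv = t
        r_tot = _compute_rates(cnt_type, cnt_sex, S, K, L2, b0, v0, vX, vE,
                               vEX, x, r, alpha, beta, rates)
        if r_tot <= 0.0:
            code = CENSORED
            t = t_max
            break
        t_new = t + np.random.exponential(1.0 / r_tot)
        if sample_dt > 0.0:
            lim = t_new if t_new < t_max else t_max
            C = S[0]
            while next_sample <= lim and n_samples < traj_t.shape[0]:
                traj_t[n_samples] = next_sample
                traj_n[n_samples, 0] = n0
                traj_n[n_samples, 1] = nX
                traj_n[n_samples, 2] = nE
                traj_n[n_samples, 3] = nEX
                traj_n[n_samples, 4] = C
                n_samples += 1
                next_sample += sample_dt
        if t_new >= t_max:
            code = CENSORED
            t = t_max
            break
        t = t_new
        u = np.random.random() * r_tot
        if u < rates[0]:
            _birth_event(t, genome, l, sex, inf, alive, tb,
                         by_type, pos_type, cnt_type,
                         by_sex, pos_sex, cnt_sex,
                         empty_lst, pos_empty, cnt_empty,
                         S, L, m, alpha, beta)
        else:
            u -= rates[0]
            done = False
            for ty in range(4):
                if u < rates[1 + ty]:
                    victim = _death_event(ty, genome, l, sex, inf, alive,
                                          by_type, pos_type, cnt_type,
                                          by_sex, pos_sex, cnt_sex,
                                          empty_lst, pos_empty, cnt_empty, S)
                    if (collect_lifetimes and ty == TYPE_0
                            and tb[victim] >= 0.0
                            and tb[victim] <= birth_cutoff):
                        age_sum += t - tb[victim]
                        age_n += 1
                    done = True
                    break
                u -= rates[1 + ty]
            if not done:
                if u < rates[5]:
                    _infection_event(TYPE_0, inf, by_type, pos_type, cnt_type)
                elif u - rates[5] < rates[6]:
                    _infection_event(TYPE_E, inf, by_type, pos_type, cnt_type)
                else:
                    _transposition_event(genome, l, by_type, cnt_type, S, L2)
    return code, t, t_xrv, t_fix, n_samples, age_sum, age_n


# ---------------------------------------------------------------------------
# Python-level state container and drivers
# ---------------------------------------------------------------------------


@dataclass
class Population:
    """Array-of-slots population state with incremental tallies.

    ``genome`` is ``(K, 2L)`` with entries 0/1; ``l`` caches the insertion
    count per individual.  ``by_type`` / ``by_sex`` / ``empty`` are
    swap-remove index lists giving O(1) uniform sampling within a class.
    """

    K: int
    L: int
    genome: np.ndarray
    l: np.ndarray
    sex: np.ndarray
    inf: np.ndarray
    alive: np.ndarray
    tb: np.ndarray
    by_type: np.ndarray = field(repr=False, default=None)
    pos_type: np.ndarray = field(repr=False, default=None)
    cnt_type: np.ndarray = field(repr=False, default=None)
    by_sex: np.ndarray = field(repr=False, default=None)
    pos_sex: np.ndarray = field(repr=False, default=None)
    cnt_sex: np.ndarray = field(repr=False, default=None)
    empty_lst: np.ndarray = field(repr=False, default=None)
    pos_empty: np.ndarray = field(repr=False, default=None)
    cnt_empty: np.ndarray = field(repr=False, default=None)
    S: np.ndarray = field(repr=False, default=None)

    @classmethod
    def empty(cls, K: int, L: int) -> "Population":
        return cls(
            K=K,
            L=L,
            genome=np.zeros((K, 2 * L), dtype=np.uint8),
            l=np.zeros(K, dtype=np.int64),
            sex=np.zeros(K, dtype=np.uint8),
            inf=np.zeros(K, dtype=np.uint8),
            alive=np.zeros(K, dtype=np.uint8),
            tb=np.full(K, -1.0),
        )

    def add(self, slot: int, sex: int, infected: bool = False,
            genome_row=None) -> None:
        """Place an individual into ``slot`` (python-side setup helper)."""
        if self.alive[slot]:
            raise ValueError(f"slot {slot} already occupied")
        self.alive[slot] = 1
        self.sex[slot] = sex
        self.inf[slot] = 1 if infected else 0
        if genome_row is not None:
            self.genome[slot] = np.asarray(genome_row, dtype=np.uint8)
        else:
            self.genome[slot] = 0
        self.l[slot] = int(self.genome[slot].sum())

    def type_of(self, slot: int) -> int:
        return (2 if self.l[slot] > 0 else 0) + (1 if self.inf[slot] else 0)

    def rebuild_lists(self) -> None:
        """(Re)derive all index lists and tallies from the slot arrays."""
        K = self.K
        self.by_type = np.zeros((4, K), dtype=np.int32)
        self.pos_type = np.zeros(K, dtype=np.int32)
        self.cnt_type = np.zeros(4, dtype=np.int64)
        self.by_sex = np.zeros((2, K), dtype=np.int32)
        self.pos_sex = np.zeros(K, dtype=np.int32)
        self.cnt_sex = np.zeros(2, dtype=np.int64)
        self.empty_lst = np.zeros(K, dtype=np.int32)
        self.pos_empty = np.zeros(K, dtype=np.int32)
        self.cnt_empty = np.zeros(1, dtype=np.int64)
        self.S = np.zeros(2, dtype=np.int64)
        self.l[:] = self.genome.sum(axis=1, dtype=np.int64)
        alive = self.alive.astype(bool)
        types = (self.l > 0) * 2 + self.inf
        for ty in range(4):
            idx = np.flatnonzero(alive & (types == ty))
            self.by_type[ty, : idx.size] = idx
            self.pos_type[idx] = np.arange(idx.size, dtype=np.int32)
            self.cnt_type[ty] = idx.size
        for sx in range(2):
            idx = np.flatnonzero(alive & (self.sex == sx))
            self.by_sex[sx, : idx.size] = idx
            self.pos_sex[idx] = np.arange(idx.size, dtype=np.int32)
            self.cnt_sex[sx] = idx.size
        idx = np.flatnonzero(~alive)
        self.empty_lst[: idx.size] = idx
        self.pos_empty[idx] = np.arange(idx.size, dtype=np.int32)
        self.cnt_empty[0] = idx.size
        la = self.l[alive]
        self.S[0] = la.sum()
        self.S[1] = (la * la).sum()

    def counts(self) -> dict:
        """Current tallies (N0, NX, NE, NEX, NM, NF, Ntot, C)."""
        n = self.cnt_type
        return {
            "N0": int(n[0]), "NX": int(n[1]), "NE": int(n[2]), "NEX": int(n[3]),
            "NM": int(self.cnt_sex[0]), "NF": int(self.cnt_sex[1]),
            "Ntot": int(n.sum()), "C": int(self.S[0]),
        }

    def audit(self) -> None:
        """Debug check: recount everything from the slot arrays and compare."""
        n_type = np.zeros(4, dtype=np.int64)
        n_sex = np.zeros(2, dtype=np.int64)
        S0 = S1 = 0
        for i in range(self.K):
            if self.alive[i]:
                li = int(self.genome[i].sum())
                assert li == self.l[i], f"cached l mismatch at slot {i}"
                n_type[self.type_of(i)] += 1
                n_sex[self.sex[i]] += 1
                S0 += li
                S1 += li * li
        assert np.array_equal(n_type, self.cnt_type), "type tallies drifted"
        assert np.array_equal(n_sex, self.cnt_sex), "sex tallies drifted"
        assert self.cnt_empty[0] == self.K - n_type.sum(), "empty count drifted"
        assert S0 == self.S[0] and S1 == self.S[1], "copy-number sums drifted"


def init_population(
    params: StochasticParams,
    xrv_present: bool,
    rng: np.random.Generator,
    p0: float,
    pX: float = 0.0,
    max_retries: int = 1000,
):
    """Random initial population plus a single seeded ERV copy.

    Each slot independently holds an uninfected individual with probability
    ``p0``, an infected one with probability ``pX``, or stays empty.  Sexes
    are assigned with probability 1/2.  Then exactly one E allele is added at
    a uniformly chosen locus copy of a uniformly chosen type-X individual
    (when the XRV is present) or type-0 individual (otherwise).  If no
    individual of the required type exists, the draw is repeated
    (``retries`` counts the redraws).
    """
    if p0 < 0 or pX < 0 or p0 + pX > 1:
        raise ValueError("need p0 >= 0, pX >= 0, p0 + pX <= 1")
    for retry in range(max_retries):
        pop = Population.empty(params.K, params.L)
        u = rng.random(params.K)
        occupied = u < p0 + pX
        infected = u >= p0
        pop.alive[occupied] = 1
        pop.inf[occupied & infected] = 1
        pop.sex[occupied] = (rng.random(params.K) < 0.5)[occupied]
        want_infected = 1 if xrv_present else 0
        candidates = np.flatnonzero(occupied & (pop.inf == want_infected))
        if candidates.size == 0:
            continue
        seed_ind = int(rng.choice(candidates))
        pop.genome[seed_ind, rng.integers(2 * params.L)] = 1
        pop.rebuild_lists()
        return pop, retry
    raise RuntimeError(
        f"no individual of the required type after {max_retries} draws"
    )


def compute_rates(pop: Population, params: StochasticParams) -> np.ndarray:
    """Event-class rates [birth, death-0/X/E/EX, infect-noncarrier,
    infect-carrier, transposition] for the current population state."""
    out = np.empty(8)
    _compute_rates(
        pop.cnt_type, pop.cnt_sex, pop.S, params.K, 2.0 * params.L,
        params.b0, params.v0, params.vX, params.vE, params.vEX,
        params.x, params.r, params.alpha, params.beta, out,
    )
    return out

def _resolve_initial_densities(params, xrv_present, p0, pX):
    if p0 is None:
        from retrofix import xrv_ode

        demog = xrv_ode.HostDemography(b0=params.b0, v0=params.v0, K=float(params.K))
        if xrv_present:
            strain = xrv_ode.XRVStrain(x=params.x, m=params.m)
            p0, pX = xrv_ode.steady_state_single(strain, demog, params.alpha)
        else:
            p0, pX = demog.p_uninf, 0.0
    return p0, (pX or 0.0)


def run_replicate(
    params: StochasticParams,
    xrv_present: bool = False,
    seed: int = 0,
    p0: float | None = None,
    pX: float | None = None,
    population: Population | None = None,
    sample_dt: float = 0.0,
    collect_lifetimes: bool = False,
    lifetime_birth_cutoff: float | None = None,
) -> SimOutcome:
    """Run a single stochastic replicate to an absorbing outcome.

    Initial densities default to the virus-free equilibrium (no XRV) or the
    stationary state of the deterministic two-compartment model (XRV
    present); pass ``p0``/``pX`` to override, or ``population`` for a fully
    explicit start (the array is copied).  ``sample_dt > 0`` records a
    trajectory at that interval.  ``collect_lifetimes`` additionally returns
    the mean age at death of uninfected individuals born before
    ``lifetime_birth_cutoff`` (stored on the returned outcome as
    ``mean_lifetime`` / ``n_lifetimes``).
    """
    rng = np.random.default_rng(seed)
    retries = 0
    if population is None:
        p0, pX = _resolve_initial_densities(params, xrv_present, p0, pX)
        pop, retries = init_population(params, xrv_present, rng, p0, pX)
    else:
        pop = replace(
            population,
            genome=population.genome.copy(),
            l=population.l.copy(),
            sex=population.sex.copy(),
            inf=population.inf.copy(),
            alive=population.alive.copy(),
            tb=population.tb.copy(),
        )
        pop.rebuild_lists()
    n_initial = int(pop.cnt_type.sum())
    if sample_dt > 0:
        cap = int(params.t_max / sample_dt) + 2
        traj_t = np.empty(cap)
        traj_n = np.empty((cap, 5))
    else:
        traj_t = np.empty(0)
        traj_n = np.empty((0, 5))
    cutoff = (
        lifetime_birth_cutoff
        if lifetime_birth_cutoff is not None
        else params.t_max
    )
    kernel_seed = int(rng.integers(2**31 - 1))
    code, t_end, t_xrv, t_fix, n_samp, age_sum, age_n = _run_kernel(
        kernel_seed, params.t_max,
        pop.genome, pop.l, pop.sex, pop.inf, pop.alive, pop.tb,
        pop.by_type, pop.pos_type, pop.cnt_type,
        pop.by_sex, pop.pos_sex, pop.cnt_sex,
        pop.empty_lst, pop.pos_empty, pop.cnt_empty, pop.S,
        params.K, params.L, params.b0, params.v0, params.x, params.m,
        params.y, params.r, params.alpha, params.beta,
        xrv_present,
        sample_dt, traj_t, traj_n,
        collect_lifetimes, cutoff,
    )
    trajectory = None
    if sample_dt > 0 and n_samp > 0:
        ntot = traj_n[:n_samp, :4].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            g = traj_n[:n_samp, 4] / (2 * params.L * ntot)
        trajectory = np.column_stack([traj_t[:n_samp], traj_n[:n_samp, :4], g])
    out = SimOutcome(
        outcome=OUTCOME_NAMES[code],
        t_end=float(t_end),
        t_xrv_eliminated=float(t_xrv) if t_xrv >= 0 else None,
        t_all_carry=float(t_fix) if t_fix >= 0 else None,
        seed=seed,
        n_initial=n_initial,
        trajectory=trajectory,
        init_retries=retries,
    )
    if collect_lifetimes:
        out.mean_lifetime = age_sum / age_n if age_n else float("nan")
        out.n_lifetimes = age_n
    out.final_population = pop
    return out


def run_replicates(
    params: StochasticParams,
    xrv_present: bool,
    n_replicates: int,
    base_seed: int,
    p0: float | None = None,
    pX: float | None = None,
) -> np.ndarray:
    """Outcome codes of ``n_replicates`` independent replicates.

    Replicate ``i`` is seeded with ``base_seed + i``; results are independent
    of execution order.  Returns an int array of outcome codes indexed as in
    :data:`OUTCOME_NAMES`.
    """
    p0, pX = _resolve_initial_densities(params, xrv_present, p0, pX)
    codes = np.empty(n_replicates, dtype=np.int64)
    empty_t = np.empty(0)
    empty_n = np.empty((0, 5))
    for i in range(n_replicates):
        rng = np.random.default_rng(base_seed + i)
        pop, _ = init_population(params, xrv_present, rng, p0, pX)
        kernel_seed = int(rng.integers(2**31 - 1))
        code, *_ = _run_kernel(
            kernel_seed, params.t_max,
            pop.genome, pop.l, pop.sex, pop.inf, pop.alive, pop.tb,
            pop.by_type, pop.pos_type, pop.cnt_type,
            pop.by_sex, pop.pos_sex, pop.cnt_sex,
            pop.empty_lst, pop.pos_empty, pop.cnt_empty, pop.S,
            params.K, params.L, params.b0, params.v0, params.x, params.m,
            params.y, params.r, params.alpha, params.beta,
            xrv_present,
            0.0, empty_t, empty_n,
            False, 0.0,
        )
        codes[i] = code
    return codes
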