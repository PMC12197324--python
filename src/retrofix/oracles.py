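"""Independent reference calculations used to validate the simulation engines.

Nothing here shares code with :mod:`retrofix.gillespie` or
:mod:`retrofix.xrv_ode`: the rates and transition laws are re-derived from
the model description, so agreement between an oracle and an engine is
evidence of correctness rather than a tautology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

import numpy as np

__all__ = [
    "neutral_fixation_probability",
    "invasion_threshold_closed_form",
    "TinyChainSpec",
    "tiny_chain_absorption",
]


def neutral_fixation_probability(n_tot: int) -> float:
    """Fixation probability ``1 / (2 * N)`` of a neutral allele present as a
    single copy in a diploid population of census size ``N``."""
    if n_tot < 1:
        raise ValueError("population size must be >= 1")
    return 1.0 / (2.0 * n_tot)


def invasion_threshold_closed_form(b0: float = 1.0, v0: float = 0.2) -> float:
    """Critical contact rate for a purely horizontally transmitted virus.

    With ``m = 0`` the reproductive ratio of a strain with production rate
    ``x`` is ``R = alpha * x * p_uninf / (v0 * e^x)``.  ``x * e^{-x}`` is
    maximised at ``x = 1``, so the most invasive strain crosses ``R = 1`` at
    ``alpha_c = v0 * e / p_uninf``.
    """
    p_uninf = 1.0 - v0 / b0
    if p_uninf <= 0:
        raise ValueError("population not viable (v0 >= b0)")
    return v0 * math.e / p_uninf


# ---------------------------------------------------------------------------
# Exact continuous-time Markov chain for tiny populations
# ---------------------------------------------------------------------------

# genotype at the single locus: 0 = no insertion, 1 = heterozygous, 2 = homozygous
_N_CLASS = 6  # (male, female) x (genotype 0, 1, 2)


@dataclass(frozen=True)
class TinyChainSpec:
    """A tiny-population model instance solvable by exact enumeration.

    Restricted to one insertable locus (L=1), no transposition (r=0) and no
    XRV, so the population state is fully described by the counts of
    individuals in the six (sex x genotype) classes.  ``initial`` lists those
    counts in the order (m/geno0, m/geno1, m/geno2, f/geno0, f/geno1,
    f/geno2).
    """

    K: int
    initial: tuple
    b0: float = 1.0
    v0: float = 0.2
    y: float = 0.0

    def __post_init__(self) -> None:
        if self.K > 12:
            raise ValueError("state space too large for exact enumeration")
        if len(self.initial) != _N_CLASS:
            raise ValueError("initial must have six class counts")
        if sum(self.initial) > self.K:
            raise ValueError("initial population exceeds K")


def _mendel(gm: int, gf: int) -> list[float]:
    """Offspring genotype distribution given parental genotypes (copy counts).

    Each parent transmits an insertion-bearing allele with probability g/2.
    """
    pm, pf = gm / 2.0, gf / 2.0
    return [
        (1 - pm) * (1 - pf),
        pm * (1 - pf) + (1 - pm) * pf,
        pm * pf,
    ]


def _classify(state: tuple) -> str | None:
    n = sum(state)
    carriers = state[1] + state[2] + state[4] + state[5]
    if n == 0:
        return "extinct"
    if carriers == 0:
        return "loss"
    if state[0] + state[3] == 0:
        return "fixation"
    return None


def _transitions(state: tuple, spec: TinyChainSpec):
    """All outgoing (next_state, rate) pairs of a transient state."""
    out = []
    n = sum(state)
    nM = state[0] + state[1] + state[2]
    nF = state[3] + state[4] + state[5]
    v_geno = (spec.v0, spec.v0 * math.exp(spec.y), spec.v0 * math.exp(spec.y))
    # deaths
    for c in range(_N_CLASS):
        if state[c] > 0:
            rate = v_geno[c % 3] * state[c]
            nxt = list(state)
            nxt[c] -= 1
            out.append((tuple(nxt), rate))
    # births
    if nM > 0 and nF > 0 and n < spec.K:
        birth_total = 2.0 * spec.b0 * nF * (1.0 - n / spec.K)
        for gm, gf in product(range(3), range(3)):
            w = (state[3 + gm] / nF) * (state[gf] / nM)
            if w == 0:
                continue
            for go, p_go in enumerate(_mendel(gm, gf)):
                if p_go == 0:
                    continue
                for sx in (0, 1):
                    nxt = list(state)
                    nxt[3 * sx + go] += 1
                    out.append((tuple(nxt), birth_total * w * p_go * 0.5))
    return out


def tiny_chain_absorption(spec: TinyChainSpec) -> dict:
    """Exact absorption probabilities of the tiny-population birth-death chain.

    Enumerates all states reachable from ``spec.initial``, builds the
    embedded jump chain, and solves the linear system for the probability of
    absorbing into each of {loss, fixation, extinct}.
    """
    initial = tuple(spec.initial)
    absorbed = _classify(initial)
    if absorbed is not None:
        return {k: float(k == absorbed) for k in ("loss", "fixation", "extinct")}

    # breadth-first enumeration of the reachable transient states
    index: dict[tuple, int] = {initial: 0}
    transient: list[tuple] = [initial]
    rows: list[list] = []
    frontier = [initial]
    while frontier:
        nxt_frontier = []
        for s in frontier:
            trans = _transitions(s, spec)
            total = sum(rate for _, rate in trans)
            row = []
            for s2, rate in trans:
                cls = _classify(s2)
                if cls is None and s2 not in index:
                    index[s2] = len(transient)
                    transient.append(s2)
                    nxt_frontier.append(s2)
                row.append((s2, cls, rate / total))
            rows.append(row)
        frontier = nxt_frontier

    n = len(transient)
    P = np.zeros((n, n))
    B = np.zeros((n, 3))  # columns: loss, fixation, extinct
    names = ("loss", "fixation", "extinct")
    for i, row in enumerate(rows):
        for s2, cls, p in row:
            if cls is None:
                P[i, index[s2]] += p
            else:
                B[i, names.index(cls)] += p
    h = np.linalg.solve(np.eye(n) - P, B)
    return dict(zip(names, h[0]))
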