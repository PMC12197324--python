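import numpy as np
import pytest

from retrofix import gillespie, xrv_ode


@pytest.fixture(scope="session")
def demog():
    return xrv_ode.HostDemography()


@pytest.fixture(scope="session")
def steady_x1(demog):
    """Stationary (p0, pX) for the maximally virulent horizontal strain
    (x=1, m=0) at contact rate alpha=1."""
    strain = xrv_ode.XRVStrain(x=1.0, m=0.0)
    return xrv_ode.steady_state_single(strain, demog, 1.0)


def evolved_pair(M, demog, delta=0.01, n=110):
    """Evolved (x, m, p0, pX) at ease-of-transmission M, on a coarse strain
    grid (10x the reference spacing) to keep test runtimes short."""
    grid = xrv_ode.StrainGrid(M=M, alpha=1.0, delta=delta, n=n)
    s = xrv_ode.evolve_competition(grid, demog)
    strain = xrv_ode.XRVStrain(x=s.mean_x, m=s.mean_m)
    p0, pX = xrv_ode.steady_state_single(strain, demog, 1.0)
    return s.mean_x, s.mean_m, p0, pX


@pytest.fixture(scope="session")
def locus_m4(demog):
    return evolved_pair(4.0, demog)


@pytest.fixture(scope="session")
def locus_m40(demog):
    return evolved_pair(40.0, demog)


def make_population(K, L, members):
    """Build an explicit population: ``members`` is a list of dicts with keys
    sex (0 male / 1 female), infected (bool), genome (length-2L 0/1 row)."""
    pop = gillespie.Population.empty(K, L)
    for slot, spec in enumerate(members):
        pop.add(
            slot,
            sex=spec.get("sex", 0),
            infected=spec.get("infected", False),
            genome_row=spec.get("genome"),
        )
    pop.rebuild_lists()
    return pop
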