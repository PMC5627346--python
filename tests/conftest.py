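import dataclasses

import pytest

from bc1dimer import Conditions, default_parameters


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def covian_conditions():
    """Antimycin-titration assay conditions: decylubiquinone analog pool of
    50 uM at the fitted initial redox state (2.59% oxidized), 50 uM fully
    oxidized cytochrome c, aerobic, de-energized."""
    return Conditions.from_pools(
        q_total=50e-6,
        q_reduced_fraction=1.0 - 0.0259,
        c_total=50e-6,
        c_reduced_fraction=0.0,
        delta_psi=0.0,
        O2=250e-6,
        O2m=100e-12,
        species="DQ",
    )


@pytest.fixture(scope="session")
def midredox_conditions():
    """Half-reduced analog pool, convenient generic turnover condition."""
    return Conditions.from_pools(
        q_total=50e-6,
        q_reduced_fraction=0.5,
        c_total=50e-6,
        c_reduced_fraction=0.10,
        delta_psi=0.0,
        O2=250e-6,
        O2m=100e-12,
        species="DQ",
    )


@pytest.fixture(scope="session")
def equilibrium_setup(params):
    """Parameters and conditions under which every edge's full free energy
    (standard part plus concentration terms) vanishes: all pool midpoint
    potentials zero, symmetric binding constants, equal reactant/product
    concentrations.  The steady state must then be the Boltzmann
    distribution over the ensemble free energies."""
    kd = dict(params.kd)
    kd.update(
        {
            "KQ10H2Qp": 1e-3,
            "KQ10Qp": 1e-3,
            "KQ10Qn": 1e-4,
            "KQ10H2Qn": 1e-4,
            "Kc2+": kd["Kc3+"],
        }
    )
    fixed = dataclasses.replace(
        params.fixed,
        Em_c=0.0,
        Em_O2=0.0,
        Em_pool={s: 0.0 for s in params.fixed.Em_pool},
    )
    p = params.replace(kd=kd, fixed=fixed, K_SQ10=1.0)
    cond = Conditions(
        delta_psi=0.0,
        QH2=20e-6,
        Q=20e-6,
        c2=10e-6,
        c3=10e-6,
        O2=30e-6,
        O2m=30e-6,
        species="Q10",
    )
    return p, cond
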