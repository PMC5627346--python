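"""Scenario runners: pharmacological condition panels, membrane-potential
and Q-redox scans, antimycin titrations of the dimer population, and the
Q-pool redox inversion with the Complex I reaction-energy check.

The reconstituted-vesicle panel mirrors classical liposome assays: a
control with both a membrane potential and a pH gradient, FCCP collapsing
both, nigericin converting the pH gradient into extra membrane potential,
valinomycin collapsing only the membrane potential, and antimycin A
blocking both Q_n sites so turnover proceeds only through the superoxide
bypass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .binding import antimycin_class_fractions
from .constants import FARADAY, RT, T_DEFAULT
from .kinetics import FluxResult, StateDistribution, steady_state
from .params import Conditions, ParameterSet, default_parameters

SCENARIOS = (
    "control",
    "FCCP",
    "nigericin",
    "valinomycin",
    "antimycinA",
    "anoxic_resting",
)


def _z_mV(temperature: float) -> float:
    """2.3 RT/F in mV (~59.2 mV per pH unit at room temperature)."""
    return 1000.0 * RT(temperature) * math.log(10.0) / FARADAY


@dataclass(frozen=True)
class Scenario:
    """A named, fully resolvable simulation setup."""

    name: str
    conditions: Conditions
    antimycin_ratio: float = 0.0
    superoxide_reduces_c: bool = False


@dataclass(frozen=True)
class ScenarioResult:
    scenario: Scenario
    states: StateDistribution
    flux: FluxResult

    @property
    def measured_Jc(self) -> float:
        return self.flux.measured_Jc(self.scenario.superoxide_reduces_c)


@dataclass(frozen=True)
class ScanResult:
    """Tidy table of a one-variable steady-state scan."""

    variable: str
    table: pd.DataFrame

    @property
    def argmax_superoxide(self) -> float:
        idx = self.table["J_SO"].to_numpy().argmax()
        return float(self.table[self.variable].iloc[idx])


def _reconstitution_conditions(
    p: ParameterSet,
    *,
    delta_psi: float,
    dpH_mV: float,
    temperature: float = T_DEFAULT,
) -> Conditions:
    """Reconstituted-vesicle assay conditions: ubiquinol-2 analog pool of
    50 uM at the fitted initial redox state, 50 uM fully oxidized
    cytochrome c, air-saturated buffer, trace superoxide.  The pH gradient
    is specified through its (2.3RT/F)*dpH millivolt equivalent with the
    p side held at pH 7."""
    pct_ox = p.initial_percent_oxidized["rottenberg"]
    return Conditions.from_pools(
        q_total=50e-6,
        q_reduced_fraction=1.0 - pct_ox / 100.0,
        c_total=50e-6,
        c_reduced_fraction=0.0,
        delta_psi=delta_psi,
        pH_p=7.0,
        pH_n=7.0 + dpH_mV / _z_mV(temperature),
        temperature=temperature,
        O2=250e-6,
        O2m=100e-12,
        species="Q2",
    )


def make_scenario(name: str, p: ParameterSet | None = None) -> Scenario:
    p = p if p is not None else default_parameters()
    if name == "control":
        return Scenario(name, _reconstitution_conditions(p, delta_psi=200.0, dpH_mV=15.0))
    if name == "FCCP":
        return Scenario(name, _reconstitution_conditions(p, delta_psi=0.0, dpH_mV=0.0))
    if name == "nigericin":
        return Scenario(name, _reconstitution_conditions(p, delta_psi=215.0, dpH_mV=0.0))
    if name == "valinomycin":
        return Scenario(name, _reconstitution_conditions(p, delta_psi=0.0, dpH_mV=15.0))
    if name == "antimycinA":
        return Scenario(
            name,
            _reconstitution_conditions(p, delta_psi=200.0, dpH_mV=15.0),
            antimycin_ratio=1.0,
            superoxide_reduces_c=True,
        )
    if name == "anoxic_resting":
        # anoxic, de-energized, no cytochrome c: pure state-space conditions
        return Scenario(
            name,
            Conditions.from_pools(
                q_total=20e-3,
                q_reduced_fraction=0.10,
                c_total=0.0,
                delta_psi=0.0,
                O2=0.0,
                O2m=0.0,
                species="Q10",
            ),
        )
    raise ValueError(f"unknown scenario name {name!r}")


def run_scenario(
    name: str, p: ParameterSet | None = None
) -> ScenarioResult:
    """Run one named scenario to steady state."""
    p = p if p is not None else default_parameters()
    sc = make_scenario(name, p)
    states, flux = population_state_and_rates(sc.conditions, p, sc.antimycin_ratio)
    return ScenarioResult(sc, states, flux)


# ---------------------------------------------------------------------------
# antimycin population mixing


def class_fluxes(
    cond: Conditions, p: ParameterSet
) -> dict[str, tuple[StateDistribution, FluxResult]]:
    """Steady states of the three antimycin dimer classes under one
    condition (they do not depend on the titration ratio)."""
    return {
        inh: steady_state(cond, p, inh)
        for inh in ("none", "single_AA", "double_AA")
    }


def population_rates(
    cond: Conditions,
    p: ParameterSet,
    antimycin_ratio: float,
    _classes: dict | None = None,
) -> FluxResult:
    """Population-averaged fluxes under independent binomial antimycin
    binding: f0*Flux(none) + f1*Flux(single) + f2*Flux(double)."""
    classes = _classes if _classes is not None else class_fluxes(cond, p)
    f = antimycin_class_fractions(antimycin_ratio)
    return (
        classes["none"][1].scaled(f.f0)
        + classes["single_AA"][1].scaled(f.f1)
        + classes["double_AA"][1].scaled(f.f2)
    )


def population_state_and_rates(
    cond: Conditions, p: ParameterSet, antimycin_ratio: float
) -> tuple[StateDistribution, FluxResult]:
    if antimycin_ratio == 0.0:
        return steady_state(cond, p, "none")
    if antimycin_ratio >= 1.0:
        return steady_state(cond, p, "double_AA")
    classes = class_fluxes(cond, p)
    f = antimycin_class_fractions(antimycin_ratio)
    probs = (
        f.f0 * classes["none"][0].probabilities
        + f.f1 * classes["single_AA"][0].probabilities
        + f.f2 * classes["double_AA"][0].probabilities
    )
    return StateDistribution(probs), population_rates(cond, p, antimycin_ratio, classes)


def antimycin_titration(
    cond: Conditions,
    p: ParameterSet,
    ratios: np.ndarray | None = None,
    superoxide_reduces_c: bool = False,
) -> pd.DataFrame:
    """Population cytochrome c reduction and superoxide rates across an
    antimycin/monomer titration."""
    ratios = np.linspace(0.0, 1.0, 101) if ratios is None else np.asarray(ratios, float)
    classes = class_fluxes(cond, p)
    rows = []
    for r in ratios:
        fl = population_rates(cond, p, float(r), classes)
        rows.append(
            {
                "aa_ratio": float(r),
                "J_c": fl.measured_Jc(superoxide_reduces_c),
                "J_SO": fl.J_SO,
                "J_SO_sr": fl.J_SO_sr,
                "J_SO_sf": fl.J_SO_sf,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scans


def scan(
    variable: str,
    grid: np.ndarray,
    cond: Conditions,
    p: ParameterSet,
    inhibition: str = "none",
) -> ScanResult:
    """Steady-state scan over a strictly monotone grid of either the
    membrane potential ('delta_psi', mV) or the Q-pool reduced fraction
    ('q_reduced', using the condition's total pool)."""
    grid = np.asarray(grid, float)
    if not (np.all(np.diff(grid) > 0) or np.all(np.diff(grid) < 0)):
        raise ValueError("scan grid must be strictly monotone")
    q_tot = cond.QH2 + cond.Q
    rows = []
    for v in grid:
        if variable == "delta_psi":
            c = cond.replace(delta_psi=float(v))
        elif variable == "q_reduced":
            c = cond.replace(QH2=float(v) * q_tot, Q=(1.0 - float(v)) * q_tot)
        else:
            raise ValueError(f"unknown scan variable {variable!r}")
        states, flux = steady_state(c, p, inhibition)
        row = {
            variable: float(v),
            "J_c": flux.J_c,
            "J_SO": flux.J_SO,
            "J_SO_sr": flux.J_SO_sr,
            "J_SO_sf": flux.J_SO_sf,
            "J_Qn": flux.J_Qn,
        }
        row.update({f"E{k}": states[k] for k in range(6)})
        rows.append(row)
    return ScanResult(variable, pd.DataFrame(rows))


def physiology_conditions(p: ParameterSet | None = None) -> Conditions:
    """Native-quinone physiological baseline: 20 mM Q pool, cytochrome c
    pool (50 uM) 20% reduced, pH 7 on both sides, 30 uM O2, 100 pM
    superoxide."""
    return Conditions.from_pools(
        q_total=20e-3,
        q_reduced_fraction=0.5,
        c_total=50e-6,
        c_reduced_fraction=0.20,
        delta_psi=0.0,
        O2=30e-6,
        O2m=100e-12,
        species="Q10",
    )


def physiology_grid(
    p: ParameterSet | None = None,
    dpsi_grid: np.ndarray | None = None,
    qred_grid: np.ndarray | None = None,
    inhibition: str = "none",
) -> pd.DataFrame:
    """Steady-state surface over membrane potential x Q-pool redox under
    the native-quinone physiological baseline."""
    p = p if p is not None else default_parameters()
    dpsi_grid = np.linspace(0.0, 215.0, 11) if dpsi_grid is None else dpsi_grid
    qred_grid = np.linspace(0.02, 0.98, 13) if qred_grid is None else qred_grid
    base = physiology_conditions(p)
    frames = []
    for dpsi in dpsi_grid:
        res = scan("q_reduced", qred_grid, base.replace(delta_psi=float(dpsi)), p, inhibition)
        t = res.table.copy()
        t.insert(0, "delta_psi", float(dpsi))
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Q-redox inversion and Complex I energetics


@dataclass(frozen=True)
class InversionResult:
    found: bool
    q_reduced: float | None
    side: str
    target: float


def invert_q_redox(
    target: float,
    cond: Conditions,
    side: str,
    p: ParameterSet,
    inhibition: str = "none",
    flux: str = "J_c",
    n_grid: int = 101,
    xtol: float = 1e-8,
) -> InversionResult:
    """Solve the biphasic flux-vs-redox curve for the pool reduced
    fraction that yields a target flux, bracketing from the oxidized or
    the reduced side of the curve maximum.

    Returns a no-solution result (found=False) when the target exceeds
    the branch maximum instead of raising.
    """
    if side not in ("oxidized", "reduced"):
        raise ValueError("side must be 'oxidized' or 'reduced'")
    if target < 0:
        raise ValueError("target flux must be >= 0")
    q_tot = cond.QH2 + cond.Q
    grid = np.linspace(1e-3, 1.0 - 1e-3, n_grid)

    def f(qred: float) -> float:
        c = cond.replace(QH2=qred * q_tot, Q=(1.0 - qred) * q_tot)
        _, fl = steady_state(c, p, inhibition)
        return getattr(fl, flux)

    ys = np.array([f(q) for q in grid])
    imax = int(ys.argmax())
    if side == "oxidized":
        branch = slice(0, imax + 1)
    else:
        branch = slice(imax, n_grid)
    xs_b, ys_b = grid[branch], ys[branch]
    resid = ys_b - target
    sign_change = np.nonzero(np.diff(np.sign(resid)) != 0)[0]
    if len(sign_change) == 0:
        return InversionResult(False, None, side, target)
    # take the bracket nearest the requested side of the curve
    j = sign_change[0] if side == "oxidized" else sign_change[-1]
    root = brentq(lambda q: f(q) - target, xs_b[j], xs_b[j + 1], xtol=xtol)
    return InversionResult(True, float(root), side, target)


def complex_one_energy(
    nadh_fraction: float,
    q_reduced_fraction: float,
    delta_psi: float,
    delta_pH: float,
    temperature: float = T_DEFAULT,
    dG0: float = -74.3,
) -> float:
    """Reaction free energy (kJ/mol) of Complex I
    (NADH + Q + 5 H+_n -> NAD+ + QH2 + 4 H+_p translocated):

        dG = dG0' + RT ln([NAD+][QH2] / ([NADH][Q])) + 4 F dp,
        dp = dpsi + (RT ln10 / F) dpH   (volts; dpH = pH_n - pH_p)

    Positive values flag reverse electron transport.
    """
    for name, frac in (
        ("nadh_fraction", nadh_fraction),
        ("q_reduced_fraction", q_reduced_fraction),
    ):
        if not 0.0 < frac < 1.0:
            raise ValueError(f"{name} must lie strictly in (0, 1)")
    rt = RT(temperature)
    ratio = ((1.0 - nadh_fraction) / nadh_fraction) * (
        q_reduced_fraction / (1.0 - q_reduced_fraction)
    )
    dp_V = delta_psi / 1000.0 + rt * math.log(10.0) / FARADAY * delta_pH
    return dG0 + rt * math.log(ratio) + 4.0 * FARADAY * dp_V
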