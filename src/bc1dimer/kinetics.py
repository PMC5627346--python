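"""Thermodynamically reversible six-state kinetics of the bc1 dimer.

The enzyme population is described by six electronic states E0..E5 (number
of electrons residing on the dimer).  State transitions are:

* quinol oxidation at the Q_p site, E_i -> E_{i+1} for i = 0..4 — a lumped
  two-electron step in which the first electron reduces cytochrome c and
  the second is deposited on the complex;
* quinone reduction at the Q_n site, E_i -> E_{i-2} for i = 2..5 — removal
  of two electrons (requires the SQn/bH substate on an uninhibited
  monomer) forming quinol on the n side, electrogenic;
* superoxide formation, E_i -> E_{i-1} for i = 1..5 — a Q_p-site
  semiquinone electron reduces O2.  From states E1..E4 the semiquinone was
  formed by reverse electron flow from reduced heme bL (the "semireverse"
  mode); from E5, where the low-potential chain is full, the semiquinone
  left behind by quinol oxidation has no internal acceptor and its electron
  leaves as superoxide (the "semiforward" mode).

Every reversible edge obeys forward/reverse = exp(-dG_total/RT), where
dG_total combines the standard edge free energy (built from ensemble free
energies, pool/cytochrome/oxygen midpoint potentials, the two-sided pH and
the membrane potential) with the concentration terms carried by the
binding-polynomial fractions and the explicit [O2]/[O2-] factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .binding import site_occupancy
from .constants import FARADAY, RT
from .params import Conditions, ParameterSet
from .statespace import ElectronEnsemble

N_STATES = 6
EDGE_KINDS = ("Qp_ox", "Qn_red", "SO_semireverse", "SO_semiforward")
INHIBITION_CLASSES = ("none", "single_AA", "double_AA")

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class EdgeRate:
    """One reversible transition of the state network.

    ``kf``/``kr`` are the forward/reverse propensities (s^-1) including all
    binding-fraction and concentration factors; ``dG`` is the standard edge
    free energy (kJ/mol), excluding those concentration terms.
    """

    kind: str
    i: int
    j: int
    kf: float
    kr: float
    dG: float


@dataclass(frozen=True)
class StateDistribution:
    """Steady-state probabilities of the electronic states E0..E5."""

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.probabilities, float)
        if x.shape != (N_STATES,):
            raise ValueError("expected 6 state probabilities")
        if (x < -1e-12).any():
            raise ValueError("negative state probability")
        if abs(x.sum() - 1.0) > 1e-9:
            raise ValueError("state probabilities do not sum to 1")

    def __getitem__(self, k: int) -> float:
        return float(self.probabilities[k])


@dataclass(frozen=True)
class FluxResult:
    """Net per-dimer turnover rates (s^-1).

    J_c counts chemical cytochrome c reduction events — one per Q_p
    oxidation edge event, since the lumped two-electron quinol oxidation
    sends its first electron to cytochrome c.  J_QH2_Qp counts quinol
    molecules oxidized at the Q_p site; J_Qn quinol molecules formed at
    the Q_n site.  At steady state the deposited electrons balance:
    J_c = 2 J_Qn + J_SO_sr + J_SO_sf.
    """

    J_c: float
    J_SO_sr: float
    J_SO_sf: float
    J_QH2_Qp: float
    J_Qn: float

    @property
    def J_SO(self) -> float:
        """Total superoxide production rate."""
        return self.J_SO_sr + self.J_SO_sf

    @property
    def J_deposition(self) -> float:
        """Net electron deposition rate through the Q_p oxidation edges."""
        return self.J_c

    def measured_Jc(self, superoxide_reduces_c: bool = False) -> float:
        """Cytochrome c reduction rate as an assay would report it; with
        ``superoxide_reduces_c`` each superoxide molecule subsequently
        reduces one additional cytochrome c."""
        return self.J_c + (self.J_SO if superoxide_reduces_c else 0.0)

    def scaled(self, w: float) -> "FluxResult":
        return FluxResult(*(w * v for v in _as_tuple(self)))

    def __add__(self, other: "FluxResult") -> "FluxResult":
        return FluxResult(
            *(a + b for a, b in zip(_as_tuple(self), _as_tuple(other)))
        )


def _as_tuple(f: FluxResult) -> tuple[float, ...]:
    return (f.J_c, f.J_SO_sr, f.J_SO_sf, f.J_QH2_Qp, f.J_Qn)


# ---------------------------------------------------------------------------
# edge free energies


def edge_free_energy(
    kind: str,
    i: int,
    cond: Conditions,
    p: ParameterSet,
    ensemble: ElectronEnsemble | None = None,
) -> float:
    """Standard free energy (kJ/mol) of one state-transition edge.

    The ensemble free energies G_ens(k) carry the on-complex energetics
    (midpoints, Coulomb terms, membrane-potential depth terms); the
    remaining terms account for the redox chemistry of the pools at their
    pH-7 standard states, the scalar proton releases/uptakes, and the two
    charges translocated per Q_n-site reduction.
    """
    ens = ensemble if ensemble is not None else ElectronEnsemble(p, cond)
    rt = ens.rt
    fx = p.fixed
    em_pool = fx.Em_pool[cond.species] / 1000.0
    em_c = fx.Em_c / 1000.0
    em_o2 = fx.Em_O2 / 1000.0
    dpsi = cond.delta_psi / 1000.0

    if kind == "Qp_ox":
        if not 0 <= i <= 4:
            raise ValueError(f"no Qp_ox edge from state {i}")
        return (
            ens.ensemble_free_energy(i + 1)
            - ens.ensemble_free_energy(i)
            + 2.0 * FARADAY * em_pool
            - 2.0 * rt * _LN10 * (cond.pH_p - 7.0)
            - FARADAY * em_c
        )
    if kind == "Qn_red":
        if not 2 <= i <= 5:
            raise ValueError(f"no Qn_red edge from state {i}")
        return (
            ens.ensemble_free_energy(i - 2)
            - ens.ensemble_free_energy(i)
            - 2.0 * FARADAY * em_pool
            + 2.0 * rt * _LN10 * (cond.pH_n - 7.0)
            + 2.0 * FARADAY * dpsi
        )
    if kind in ("SO_semireverse", "SO_semiforward"):
        lo = 1 if kind == "SO_semireverse" else 5
        hi = 4 if kind == "SO_semireverse" else 5
        if not lo <= i <= hi:
            raise ValueError(f"no {kind} edge from state {i}")
        return (
            ens.ensemble_free_energy(i - 1)
            - ens.ensemble_free_energy(i)
            - FARADAY * em_o2
        )
    raise ValueError(f"unknown edge kind {kind!r}")


# ---------------------------------------------------------------------------
# generator construction


def build_generator(
    cond: Conditions,
    p: ParameterSet,
    inhibition: str = "none",
) -> list[EdgeRate]:
    """Assemble all state-transition edges for one condition.

    ``inhibition`` selects the dimer class: 'none' (one operational Q_p
    site per turnover, both Q_n monomers active), 'single_AA' (one Q_n
    monomer blocked, both Q_p sites operational), or 'double_AA' (no Q_n
    edges; Q_p oxidation rate constants reduced by the antimycin
    inhibition factors, bypass-only turnover).
    """
    if inhibition not in INHIBITION_CLASSES:
        raise ValueError(f"unknown inhibition class {inhibition!r}")
    ens = ElectronEnsemble(p, cond)
    rt = ens.rt
    fx = p.fixed

    occ_qp = site_occupancy("Qp", cond, p)
    occ_qn = site_occupancy("Qn", cond, p)
    occ_c = site_occupancy("c", cond, p)
    b_qh2_p, b_q_p = occ_qp["QH2"], occ_qp["Q"]
    b_q_n, b_qh2_n = occ_qn["Q"], occ_qn["QH2"]
    b_c3, b_c2 = occ_c["c3"], occ_c["c2"]

    n_qp = 2.0 if inhibition == "single_AA" else 1.0
    active_monomers = ("A",) if inhibition == "single_AA" else ("A", "B")

    isp = 1.0
    if fx.isp_factor_enabled:
        isp = 1.0 / (1.0 + 10.0 ** (cond.pH_p - fx.isp_pK))

    edges: list[EdgeRate] = []

    # Q_p oxidation edges
    for i in range(5):
        k = p.kf_qp[i]
        if inhibition == "double_AA":
            k = k / (p.beta_aa_f if i == 4 else p.beta_aa_r)
        dg = edge_free_energy("Qp_ox", i, cond, p, ens)
        base = n_qp * k * isp
        kf = base * b_qh2_p * b_c3
        kr = base * b_q_p * b_c2 * math.exp(dg / rt)
        edges.append(EdgeRate("Qp_ox", i, i + 1, kf, kr, dg))

    # Q_n reduction edges
    if inhibition != "double_AA":
        for i in range(2, 6):
            s_i = sum(ens.sqn_bh_pair_prob(i, m) for m in active_monomers)
            dg = edge_free_energy("Qn_red", i, cond, p, ens)
            base = p.kf_qn[i] * s_i
            kf = base * b_q_n
            kr = base * b_qh2_n * math.exp(dg / rt)
            edges.append(EdgeRate("Qn_red", i, i - 2, kf, kr, dg))

    # superoxide edges: semireverse from E1..E4, semiforward from E5
    for i in range(1, 6):
        kind = "SO_semiforward" if i == 5 else "SO_semireverse"
        amp = ens.sqp_occupancy(i) * b_q_p
        dg = edge_free_energy(kind, i, cond, p, ens)
        kf = fx.k_O2 * cond.O2 * amp
        kr = fx.k_O2 * cond.O2m * amp * math.exp(dg / rt)
        edges.append(EdgeRate(kind, i, i - 1, kf, kr, dg))

    return edges


# ---------------------------------------------------------------------------
# steady-state solve


class SteadyStateError(RuntimeError):
    pass


def _assemble_matrix(edges: list[EdgeRate]) -> np.ndarray:
    m = np.zeros((N_STATES, N_STATES))
    for e in edges:
        if e.i == e.j:
            continue
        m[e.j, e.i] += e.kf
        m[e.i, e.i] -= e.kf
        m[e.i, e.j] += e.kr
        m[e.j, e.j] -= e.kr
    return m


def solve_steady_state(edges: list[EdgeRate]) -> StateDistribution:
    """Stationary distribution of the six-state rate generator.

    Solves M x = 0 with sum(x) = 1 on the connected component containing
    E0 (states unreachable from E0 carry zero probability).  Raises
    :class:`SteadyStateError` naming unreachable states if the restricted
    system is degenerate.
    """
    m = _assemble_matrix(edges)
    # undirected connectivity over edges with any positive propensity
    adj = (np.abs(m) > 0) | (np.abs(m.T) > 0)
    reach = {0}
    frontier = [0]
    while frontier:
        i = frontier.pop()
        for j in np.nonzero(adj[i])[0]:
            if j != i and j not in reach:
                reach.add(int(j))
                frontier.append(int(j))
    comp = sorted(reach)
    x = np.zeros(N_STATES)
    if len(comp) == 1:
        x[0] = 1.0
        return StateDistribution(x)

    sub = m[np.ix_(comp, comp)]
    scale = np.abs(sub).max()
    _, s, vt = np.linalg.svd(sub / scale)
    if len(s) > 1 and s[-2] < 1e-12 * s[0]:
        missing = sorted(set(range(N_STATES)) - reach)
        raise SteadyStateError(
            "degenerate steady-state system (multiple stationary "
            f"distributions); states outside the E0 component: {missing}"
        )
    v = vt[-1]
    total = v.sum()
    if total == 0:
        raise SteadyStateError("null-space vector sums to zero")
    v = v / total
    v = np.where(np.abs(v) < 1e-14, 0.0, v)
    if (v < -1e-9).any():
        raise SteadyStateError("stationary vector has negative entries")
    v = np.clip(v, 0.0, None)
    v = v / v.sum()
    resid = np.abs(sub @ v).max()
    if resid > 1e-8 * scale:
        raise SteadyStateError(f"steady-state residual too large: {resid:g}")
    x[comp] = v
    return StateDistribution(x)


def steady_fluxes(x: StateDistribution, edges: list[EdgeRate]) -> FluxResult:
    """Net per-dimer fluxes at a stationary distribution."""
    j_dep = j_qn = j_sr = j_sf = 0.0
    for e in edges:
        net = e.kf * x[e.i] - e.kr * x[e.j]
        if e.kind == "Qp_ox":
            j_dep += net
        elif e.kind == "Qn_red":
            j_qn += net
        elif e.kind == "SO_semireverse":
            j_sr += net
        elif e.kind == "SO_semiforward":
            j_sf += net
    return FluxResult(
        J_c=j_dep,
        J_SO_sr=j_sr,
        J_SO_sf=j_sf,
        J_QH2_Qp=j_dep,
        J_Qn=j_qn,
    )


def steady_state(
    cond: Conditions, p: ParameterSet, inhibition: str = "none"
) -> tuple[StateDistribution, FluxResult]:
    """Convenience wrapper: build the generator, solve it and return the
    state distribution with the resulting fluxes."""
    edges = build_generator(cond, p, inhibition)
    x = solve_steady_state(edges)
    return x, steady_fluxes(x, edges)
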