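import math

import numpy as np
import pytest
from scipy.linalg import null_space

from bc1dimer import Conditions
from bc1dimer.binding import site_occupancy
from bc1dimer.constants import FARADAY, RT
from bc1dimer.kinetics import (
    EdgeRate,
    StateDistribution,
    build_generator,
    edge_free_energy,
    solve_steady_state,
    steady_fluxes,
    steady_state,
)
from bc1dimer.statespace import ElectronEnsemble


def edge(i, j, kf, kr, kind="Qp_ox"):
    return EdgeRate(kind, i, j, kf, kr, 0.0)


class TestEdgeFreeEnergy:
    def test_qp_edge_assembles_ensemble_and_chemistry_terms(self, params, covian_conditions):
        cond = covian_conditions
        ens = ElectronEnsemble(params, cond)
        rt = RT(cond.temperature)
        em_pool = params.fixed.Em_pool["DQ"] / 1000.0
        expected = (
            ens.ensemble_free_energy(1)
            - ens.ensemble_free_energy(0)
            + 2 * FARADAY * em_pool
            - FARADAY * params.fixed.Em_c / 1000.0
        )
        assert edge_free_energy("Qp_ox", 0, cond, params) == pytest.approx(expected)
        # p-side pH releases two protons per quinol
        acid = cond.replace(pH_p=8.0)
        assert edge_free_energy("Qp_ox", 0, acid, params) - edge_free_energy(
            "Qp_ox", 0, cond, params
        ) == pytest.approx(-2 * rt * math.log(10.0), rel=1e-6)

    def test_qn_edge_carries_two_charges(self, params, covian_conditions):
        cond0 = covian_conditions
        cond = cond0.replace(delta_psi=150.0)
        ens0 = ElectronEnsemble(params, cond0)
        ens = ElectronEnsemble(params, cond)
        dg0 = edge_free_energy("Qn_red", 2, cond0, params)
        dg = edge_free_energy("Qn_red", 2, cond, params)
        ens_shift = (
            ens.ensemble_free_energy(0)
            - ens.ensemble_free_energy(2)
            - ens0.ensemble_free_energy(0)
            + ens0.ensemble_free_energy(2)
        )
        assert dg - dg0 - ens_shift == pytest.approx(2 * FARADAY * 0.150, rel=1e-9)

    def test_invalid_edges_rejected(self, params):
        cond = Conditions()
        with pytest.raises(ValueError):
            edge_free_energy("Qp_ox", 5, cond, params)
        with pytest.raises(ValueError):
            edge_free_energy("Qn_red", 1, cond, params)
        with pytest.raises(ValueError):
            edge_free_energy("SO_semireverse", 5, cond, params)
        with pytest.raises(ValueError):
            edge_free_energy("SO_semiforward", 3, cond, params)


class TestGeneratorContracts:
    def test_edge_ratio_obeys_thermodynamics(self, params, midredox_conditions):
        """For every reversible edge, kf/kr = exp(-(dG + RT ln Q_conc)/RT)
        where the concentration terms are the binding-fraction and
        [O2-]/[O2] ratios, computed here independently of the generator."""
        cond = midredox_conditions
        rt = RT(cond.temperature)
        qp = site_occupancy("Qp", cond, params)
        qn = site_occupancy("Qn", cond, params)
        cc = site_occupancy("c", cond, params)
        conc_ratio = {
            "Qp_ox": (qp["Q"] * cc["c2"]) / (qp["QH2"] * cc["c3"]),
            "Qn_red": qn["QH2"] / qn["Q"],
            "SO_semireverse": cond.O2m / cond.O2,
            "SO_semiforward": cond.O2m / cond.O2,
        }
        for e in build_generator(cond, params, "none"):
            if e.kf == 0 or e.kr == 0:
                continue
            lhs = e.kf / e.kr
            rhs = math.exp(-e.dG / rt) / conc_ratio[e.kind]
            assert lhs == pytest.approx(rhs, rel=1e-9), e.kind

    def test_anoxia_silences_superoxide(self, params):
        cond = Conditions.from_pools(
            q_total=20e-3, q_reduced_fraction=0.10, c_total=0.0,
            O2=0.0, O2m=0.0, species="Q10",
        )
        for e in build_generator(cond, params, "none"):
            if e.kind.startswith("SO_"):
                assert e.kf == 0.0
                assert e.kr == 0.0

    def test_double_antimycin_removes_qn_edges(self, params, covian_conditions):
        kinds = {e.kind for e in build_generator(covian_conditions, params, "double_AA")}
        assert "Qn_red" not in kinds

    def test_single_antimycin_doubles_qp_throughput(self, params, covian_conditions):
        e_none = build_generator(covian_conditions, params, "none")
        e_single = build_generator(covian_conditions, params, "single_AA")
        qp_none = {e.i: e.kf for e in e_none if e.kind == "Qp_ox"}
        qp_single = {e.i: e.kf for e in e_single if e.kind == "Qp_ox"}
        for i in range(5):
            assert qp_single[i] == pytest.approx(2 * qp_none[i], rel=1e-12)

    def test_double_antimycin_slows_quinol_oxidation(self, params, covian_conditions):
        e_none = {e.i: e.kf for e in build_generator(covian_conditions, params, "none")
                  if e.kind == "Qp_ox"}
        e_aa = {e.i: e.kf for e in build_generator(covian_conditions, params, "double_AA")
                if e.kind == "Qp_ox"}
        for i in range(4):
            assert e_aa[i] == pytest.approx(e_none[i] / params.beta_aa_r, rel=1e-12)
        assert e_aa[4] == pytest.approx(e_none[4] / params.beta_aa_f, rel=1e-12)

    def test_unknown_inhibition_class_rejected(self, params, covian_conditions):
        with pytest.raises(ValueError):
            build_generator(covian_conditions, params, "triple_AA")


class TestSolver:
    def test_symmetric_two_state(self):
        x = solve_steady_state([edge(0, 1, 3.0, 3.0)])
        assert x[0] == pytest.approx(0.5)
        assert x[1] == pytest.approx(0.5)

    def test_irreversible_cycle_uniform(self):
        edges = [edge(0, 1, 5.0, 0.0), edge(1, 2, 5.0, 0.0), edge(2, 0, 5.0, 0.0)]
        x = solve_steady_state(edges)
        assert x.probabilities[:3] == pytest.approx(np.full(3, 1 / 3), abs=1e-12)
        assert x.probabilities[3:] == pytest.approx(np.zeros(3))

    def test_three_state_analytic_null_space(self):
        """Birth-death chain E0<->E1<->E2: stationary distribution is
        proportional to (b*d, a*d, a*c) — hand-derived null space."""
        a, b, c, d = 2.0, 7.0, 3.0, 5.0
        x = solve_steady_state([edge(0, 1, a, b), edge(1, 2, c, d)])
        expected = np.array([b * d, a * d, a * c])
        expected = expected / expected.sum()
        assert x.probabilities[:3] == pytest.approx(expected, abs=1e-12)

    def test_against_brute_force_null_space(self, params, midredox_conditions):
        edges = build_generator(midredox_conditions, params, "none")
        x = solve_steady_state(edges)
        m = np.zeros((6, 6))
        for e in edges:
            if e.i == e.j:
                continue
            m[e.j, e.i] += e.kf
            m[e.i, e.i] -= e.kf
            m[e.i, e.j] += e.kr
            m[e.j, e.j] -= e.kr
        ns = null_space(m, rcond=1e-13)
        assert ns.shape[1] == 1
        ref = ns[:, 0] / ns[:, 0].sum()
        assert x.probabilities == pytest.approx(ref, abs=1e-10)
        max_prop = max(max(e.kf, e.kr) for e in edges)
        assert np.abs(m @ x.probabilities).max() <= 1e-10 * max_prop

    def test_against_markov_jump_simulation(self):
        """Long-run occupancy of a seeded Gillespie simulation on a
        three-state chain matches the algebraic steady state."""
        a, b, c, d = 4.0, 2.0, 1.5, 3.0
        x = solve_steady_state([edge(0, 1, a, b), edge(1, 2, c, d)]).probabilities[:3]
        rates = {0: [(1, a)], 1: [(0, b), (2, c)], 2: [(1, d)]}
        rng = np.random.default_rng(1234)
        state, t_occ = 0, np.zeros(3)
        for _ in range(200_000):
            targets, ks = zip(*rates[state])
            total = sum(ks)
            t_occ[state] += rng.exponential(1.0 / total)
            state = rng.choice(targets, p=np.array(ks) / total)
        emp = t_occ / t_occ.sum()
        assert emp == pytest.approx(x, abs=0.01)

    def test_unreachable_states_carry_zero_probability(self):
        # only E0<->E1 connected: E2..E5 must get exactly zero
        x = solve_steady_state([edge(0, 1, 1.0, 2.0)])
        assert x.probabilities[2:] == pytest.approx(np.zeros(4))
        assert x.probabilities.sum() == pytest.approx(1.0)

    def test_state_distribution_validation(self):
        with pytest.raises(ValueError):
            StateDistribution(np.array([0.5, 0.6, 0, 0, 0, 0]))
        with pytest.raises(ValueError):
            StateDistribution(np.array([1.5, -0.5, 0, 0, 0, 0]))


class TestThermodynamicConsistency:
    def test_equilibrium_detailed_balance(self, equilibrium_setup):
        """When every edge's total free energy vanishes, all net fluxes are
        zero and the state distribution is Boltzmann over the ensemble
        free energies."""
        p, cond = equilibrium_setup
        edges = build_generator(cond, p, "none")
        x = solve_steady_state(edges)
        fl = steady_fluxes(x, edges)
        scale = max(max(e.kf, e.kr) for e in edges)
        for flux in (fl.J_c, fl.J_SO_sr, fl.J_SO_sf, fl.J_Qn):
            assert abs(flux) <= 1e-9 * scale
        ens = ElectronEnsemble(p, cond)
        rt = RT(cond.temperature)
        w = np.array([math.exp(-ens.ensemble_free_energy(k) / rt) for k in range(6)])
        assert x.probabilities == pytest.approx(w / w.sum(), abs=1e-9)

    def test_cycle_free_energy_closure(self, params, midredox_conditions):
        """Around the closed cycle (two Q_p oxidations + one Q_n reduction)
        the product of forward/reverse ratios equals exp(-dG_cycle/RT)
        with dG_cycle built independently from the net-reaction
        stoichiometry (the ensemble terms telescope out)."""
        cond = midredox_conditions.replace(delta_psi=120.0, pH_p=7.3, pH_n=7.6)
        rt = RT(cond.temperature)
        edges = {(e.kind, e.i): e for e in build_generator(cond, params, "none")}
        prod = (
            (edges[("Qp_ox", 0)].kf / edges[("Qp_ox", 0)].kr)
            * (edges[("Qp_ox", 1)].kf / edges[("Qp_ox", 1)].kr)
            * (edges[("Qn_red", 2)].kf / edges[("Qn_red", 2)].kr)
        )
        em_pool = params.fixed.Em_pool[cond.species] / 1000.0
        em_c = params.fixed.Em_c / 1000.0
        dg_standard = (
            2 * FARADAY * em_pool
            - 2 * FARADAY * em_c
            - 4 * rt * math.log(10.0) * (cond.pH_p - 7.0)
            + 2 * rt * math.log(10.0) * (cond.pH_n - 7.0)
            + 2 * FARADAY * cond.delta_psi / 1000.0
        )
        qp = site_occupancy("Qp", cond, params)
        qn = site_occupancy("Qn", cond, params)
        cc = site_occupancy("c", cond, params)
        ln_conc = 2 * math.log(qp["Q"] * cc["c2"] / (qp["QH2"] * cc["c3"])) + math.log(
            qn["QH2"] / qn["Q"]
        )
        assert math.log(prod) == pytest.approx(
            -(dg_standard / rt + ln_conc), rel=1e-9
        )


class TestSteadyFluxes:
    @pytest.mark.parametrize("inhibition", ["none", "single_AA", "double_AA"])
    def test_electron_conservation(self, params, covian_conditions, inhibition):
        _, fl = steady_state(covian_conditions, params, inhibition)
        scale = max(abs(fl.J_c), abs(fl.J_Qn), abs(fl.J_SO), 1e-30)
        assert abs(fl.J_c - 2 * fl.J_Qn - fl.J_SO_sr - fl.J_SO_sf) <= 1e-9 * scale

    def test_bypass_only_turnover_under_double_antimycin(self, params, covian_conditions):
        _, fl = steady_state(covian_conditions, params, "double_AA")
        assert fl.J_Qn == 0.0
        assert fl.J_c == pytest.approx(fl.J_SO, rel=1e-9)
        assert fl.measured_Jc(True) == pytest.approx(2 * fl.J_SO, rel=1e-9)

    def test_flux_linearity_helpers(self, params, covian_conditions):
        _, fl = steady_state(covian_conditions, params, "none")
        doubled = fl.scaled(2.0)
        assert doubled.J_c == pytest.approx(2 * fl.J_c)
        summed = fl + fl
        assert summed.J_SO == pytest.approx(2 * fl.J_SO)
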