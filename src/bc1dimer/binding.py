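"""Rapid-equilibrium binding polynomials and semiquinone energetics.

Substrate binding and release are assumed fast relative to electron
transfer, so each site (Q_p, Q_n, cytochrome c) is described by a
competitive single-site binding polynomial over its mutually exclusive
ligation states.  The dissociation constants are apparent constants with
respect to the aqueous phase.  Antimycin A occupancy of the two Q_n sites
of a dimer is treated at the population level as independent binomial
binding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .constants import FARADAY, RT
from .params import Conditions, ParameterError, ParameterSet

SITES = ("Qp", "Qn", "c")
REACTIONS = ("Qp_oxidation", "Qn_reduction", "SO_semiforward", "SO_semireverse")


@dataclass(frozen=True)
class SiteOccupancy:
    """Fractional ligation states of one binding site (sum to 1)."""

    fractions: Mapping[str, float]

    def __getitem__(self, state: str) -> float:
        return self.fractions[state]


def site_occupancy(site: str, cond: Conditions, p: ParameterSet) -> SiteOccupancy:
    """Competitive rapid-equilibrium occupancy of one site.

    Quinone sites have states empty / Q / QH2; the cytochrome c site has
    empty / c3+ / c2+.  fraction(X) = ([X]/K_X) / (1 + sum_Y [Y]/K_Y).
    """
    if site in ("Qp", "Qn"):
        k_qh2_p, k_q_p, k_q_n, k_qh2_n = p.quinone_kd(cond.species)
        if site == "Qp":
            r_qh2, r_q = cond.QH2 / k_qh2_p, cond.Q / k_q_p
        else:
            r_qh2, r_q = cond.QH2 / k_qh2_n, cond.Q / k_q_n
        z = 1.0 + r_qh2 + r_q
        return SiteOccupancy(
            {"empty": 1.0 / z, "Q": r_q / z, "QH2": r_qh2 / z}
        )
    if site == "c":
        k3, k2 = p.cytc_kd(cond.magnesium)
        r3, r2 = cond.c3 / k3, cond.c2 / k2
        z = 1.0 + r3 + r2
        return SiteOccupancy({"empty": 1.0 / z, "c3": r3 / z, "c2": r2 / z})
    raise ParameterError(f"unknown site tag {site!r}")


def semiquinone_potentials(
    em_pool_mV: float, k_stab: float, temperature: float
) -> tuple[float, float]:
    """One-electron couple potentials (mV) from the two-electron pool
    midpoint and the semiquinone stability constant
    K_stab = [SQ]^2 / ([Q][QH2]):

        E1(Q/SQ)   = Em_pool + (RT/2F) ln K_stab
        E2(SQ/QH2) = Em_pool - (RT/2F) ln K_stab

    so E1 + E2 = 2 Em_pool always.
    """
    if k_stab <= 0:
        raise ValueError(f"stability constant must be > 0, got {k_stab}")
    shift = 1000.0 * RT(temperature) / (2.0 * FARADAY) * np.log(k_stab)
    return em_pool_mV + shift, em_pool_mV - shift


@dataclass(frozen=True)
class DimerClassFractions:
    """Fractions of dimers with 0, 1 or 2 antimycin-blocked Q_n sites."""

    f0: float
    f1: float
    f2: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.f0, self.f1, self.f2)


def antimycin_class_fractions(
    ratio: float, kd: float | None = None, enzyme: float = 1.0
) -> DimerClassFractions:
    """Dimer-class fractions at an antimycin A / monomer titration ratio.

    Default mode is tight stoichiometric binding, p = min(ratio, 1); the
    inhibitor binds each Q_n site independently, so the dimer classes are
    binomial: f0 = (1-p)^2, f1 = 2p(1-p), f2 = p^2.  Passing ``kd`` (M)
    with an enzyme-site concentration switches to a mass-action isotherm
    (single-site occupancy from the quadratic binding equation).
    """
    if ratio < 0:
        raise ValueError(f"antimycin ratio must be >= 0, got {ratio}")
    if kd is None:
        occ = min(ratio, 1.0)
    else:
        # total inhibitor = ratio * enzyme monomer sites; solve the
        # single-site quadratic for bound fraction
        total = ratio * enzyme
        b = enzyme + total + kd
        bound = (b - np.sqrt(b * b - 4.0 * enzyme * total)) / 2.0
        occ = bound / enzyme
    return DimerClassFractions(
        (1.0 - occ) ** 2, 2.0 * occ * (1.0 - occ), occ**2
    )


def catalytic_complex_fraction(
    reaction: str, cond: Conditions, p: ParameterSet
) -> float:
    """Fraction of enzyme in the substrate-ligation state required by a
    partial reaction (product of the required site fractions)."""
    if reaction not in REACTIONS:
        raise ParameterError(f"unknown reaction tag {reaction!r}")
    if reaction in ("Qp_oxidation", "SO_semiforward"):
        return site_occupancy("Qp", cond, p)["QH2"] * site_occupancy("c", cond, p)["c3"]
    if reaction == "Qn_reduction":
        return site_occupancy("Qn", cond, p)["Q"]
    # semireverse: requires quinone bound at the Q_p site
    return site_occupancy("Qp", cond, p)["Q"]
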