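"""Electron configurations of the bc1 dimer and their Boltzmann statistics.

The dimer carries eight one-electron redox centers — per monomer a Q_p-site
semiquinone (SQp), heme bL, heme bH and a Q_n-site semiquinone (SQn).  An
electronic state E_k is the ensemble of all C(8, k) configurations placing
k electrons on these centers.  Within a state the electrons are assumed to
equilibrate rapidly (through the bL-bL "bus bar"), so configuration
probabilities follow the Boltzmann distribution over configuration free
energies.  A configuration energy is the sum of per-center terms
(-F*Em + F*delta*dpsi for each occupied center) plus Coulombic repulsion
for bH/bL co-occupancy within a monomer and bL/bL co-occupancy across the
dimer interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .constants import FARADAY, RT
from .params import Conditions, ParameterSet

#: canonical center ordering; monomer A then monomer B
CENTER_IDS = (
    "SQp_A", "bL_A", "bH_A", "SQn_A",
    "SQp_B", "bL_B", "bH_B", "SQn_B",
)
N_CENTERS = 8

_IDX = {name: i for i, name in enumerate(CENTER_IDS)}

# all 256 occupancy patterns as boolean rows, grouped by electron count;
# within a count the rows are ordered by ascending bitmask, which fixes a
# deterministic canonical configuration order
_ALL_MASKS = np.arange(256, dtype=np.uint16)
_ALL_OCC = ((_ALL_MASKS[:, None] >> np.arange(N_CENTERS)) & 1).astype(bool)
_BY_K: dict[int, np.ndarray] = {
    k: _ALL_OCC[_ALL_OCC.sum(axis=1) == k] for k in range(N_CENTERS + 1)
}


@dataclass(frozen=True)
class Configuration:
    """An assignment of electrons to the eight redox centers."""

    occupancy: Mapping[str, bool]

    def __post_init__(self) -> None:
        extra = set(self.occupancy) - set(CENTER_IDS)
        if extra:
            raise ValueError(f"unknown center ids {sorted(extra)}")

    @property
    def electron_count(self) -> int:
        return sum(bool(self.occupancy.get(c, False)) for c in CENTER_IDS)

    def as_array(self) -> np.ndarray:
        return np.array(
            [bool(self.occupancy.get(c, False)) for c in CENTER_IDS], bool
        )

    @classmethod
    def from_array(cls, occ: np.ndarray) -> "Configuration":
        return cls({c: bool(occ[i]) for i, c in enumerate(CENTER_IDS)})


def enumerate_configurations(k: int) -> list[Configuration]:
    """All C(8, k) distinct configurations with exactly k electrons, in
    canonical (ascending-bitmask) order."""
    if not 0 <= k <= N_CENTERS:
        raise ValueError(f"electron count {k} outside 0..{N_CENTERS}")
    return [Configuration.from_array(row) for row in _BY_K[k]]


def _center_potentials_mV(p: ParameterSet, cond: Conditions) -> np.ndarray:
    """Per-center one-electron midpoint potentials (mV) in canonical order.
    The SQp potential is the Q/SQ couple derived from the pool two-electron
    midpoint and the site stability constant."""
    from .binding import semiquinone_potentials  # local import, no cycle

    em_pool = p.fixed.Em_pool[cond.species]
    e_sqp, _ = semiquinone_potentials(
        em_pool, p.stability_constant(cond.species), cond.temperature
    )
    per_monomer = [e_sqp, p.fixed.Em_bL, p.fixed.Em_bH, p.fixed.Em_SQn]
    return np.array(per_monomer * 2)


class ElectronEnsemble:
    """Boltzmann statistics of the dimer's electron configurations for one
    (parameters, conditions) pair.  All per-k quantities are vectorized and
    cached."""

    def __init__(self, p: ParameterSet, cond: Conditions):
        self.p = p
        self.cond = cond
        self.rt = RT(cond.temperature)
        depths = np.array(
            [p.fixed.depth_SQp, p.fixed.depth_bL, p.fixed.depth_bH,
             p.fixed.depth_SQn] * 2
        )
        em_V = _center_potentials_mV(p, cond) / 1000.0
        dpsi_V = cond.delta_psi / 1000.0
        # per-center free energy of placing one electron, kJ/mol
        self._g_center = -FARADAY * em_V + FARADAY * depths * dpsi_V
        self._cache: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}

    # -- internals ------------------------------------------------------
    def _level(self, k: int) -> tuple[np.ndarray, np.ndarray, float]:
        """(energies, probabilities, ensemble free energy) for state E_k."""
        if not 0 <= k <= N_CENTERS:
            raise ValueError(f"electron count {k} outside 0..{N_CENTERS}")
        if k not in self._cache:
            occ = _BY_K[k]
            g = occ @ self._g_center
            both_A = occ[:, _IDX["bL_A"]] & occ[:, _IDX["bH_A"]]
            both_B = occ[:, _IDX["bL_B"]] & occ[:, _IDX["bH_B"]]
            bLbL = occ[:, _IDX["bL_A"]] & occ[:, _IDX["bL_B"]]
            g = g + self.p.dG_bHbL * (both_A + both_B) + self.p.dG_bLbL * bLbL
            # max-shift stabilization of the Boltzmann weights
            gmin = g.min()
            w = np.exp(-(g - gmin) / self.rt)
            z = w.sum()
            g_ens = gmin - self.rt * np.log(z)
            self._cache[k] = (g, w / z, g_ens)
        return self._cache[k]

    def occupancy_matrix(self, k: int) -> np.ndarray:
        return _BY_K[k]

    # -- public surface -------------------------------------------------
    def configuration_energies(self, k: int) -> np.ndarray:
        """Free energies (kJ/mol) of the C(8, k) configurations, canonical
        order, referenced to the empty configuration at 0."""
        return self._level(k)[0]

    def distribution(self, k: int) -> np.ndarray:
        """Boltzmann probabilities of the k-electron configurations."""
        return self._level(k)[1]

    def ensemble_free_energy(self, k: int) -> float:
        """G_ens(k) = -RT ln sum_c exp(-G(c)/RT), kJ/mol."""
        return self._level(k)[2]

    def center_occupancy(self, k: int) -> np.ndarray:
        """Marginal probability of each center being occupied in E_k; the
        marginals sum to k."""
        return self.distribution(k) @ _BY_K[k].astype(float)

    def fraction(self, k: int, mask_fn: Callable[[np.ndarray], np.ndarray]) -> float:
        """Probability mass of the configurations whose occupancy rows
        satisfy ``mask_fn`` (a vectorized predicate on the (n, 8) boolean
        occupancy matrix)."""
        sel = np.asarray(mask_fn(_BY_K[k]), bool)
        return float(self.distribution(k)[sel].sum())

    def sqn_bh_pair_prob(self, k: int, monomer: str) -> float:
        """P(SQn and bH both occupied on the given monomer | E_k): the
        substate required for quinol formation at that monomer's Q_n site."""
        i_sqn = _IDX[f"SQn_{monomer}"]
        i_bh = _IDX[f"bH_{monomer}"]
        return self.fraction(k, lambda occ: occ[:, i_sqn] & occ[:, i_bh])

    def sqp_occupancy(self, k: int) -> float:
        """Expected number of occupied Q_p-site semiquinones in E_k
        (sum of the two monomers' SQp marginals)."""
        m = self.center_occupancy(k)
        return float(m[_IDX["SQp_A"]] + m[_IDX["SQp_B"]])


# -- functional API matching the module surface -----------------------------

def configuration_energy(
    c: Configuration, p: ParameterSet, cond: Conditions
) -> float:
    """Free energy (kJ/mol) of a single configuration."""
    ens = ElectronEnsemble(p, cond)
    occ = c.as_array()
    g = float(occ @ ens._g_center)
    for mono in "AB":
        if occ[_IDX[f"bL_{mono}"]] and occ[_IDX[f"bH_{mono}"]]:
            g += p.dG_bHbL
    if occ[_IDX["bL_A"]] and occ[_IDX["bL_B"]]:
        g += p.dG_bLbL
    return g


def substate_distribution(
    k: int, p: ParameterSet, cond: Conditions
) -> np.ndarray:
    return ElectronEnsemble(p, cond).distribution(k)


def ensemble_free_energy(k: int, p: ParameterSet, cond: Conditions) -> float:
    return ElectronEnsemble(p, cond).ensemble_free_energy(k)


def center_occupancy(
    k: int, p: ParameterSet, cond: Conditions
) -> dict[str, float]:
    occ = ElectronEnsemble(p, cond).center_occupancy(k)
    return {name: float(occ[i]) for i, name in enumerate(CENTER_IDS)}


def substate_fraction(
    k: int,
    predicate: Callable[[Configuration], bool],
    p: ParameterSet,
    cond: Conditions,
) -> float:
    """Probability that E_k satisfies a pure boolean predicate on the
    configuration."""
    ens = ElectronEnsemble(p, cond)
    probs = ens.distribution(k)
    total = 0.0
    for prob, row in zip(probs, _BY_K[k]):
        if predicate(Configuration.from_array(row)):
            total += prob
    return float(total)
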