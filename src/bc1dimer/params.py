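"""Model parameters and simulation conditions.

The adjustable block mirrors the fitted parameter table of the model
(site-specific rate constants, apparent dissociation constants, Coulombic
interaction energies, semiquinone stability constants, and per-dataset
initial Q-pool redox states).  The fixed block carries midpoint potentials,
electrical depths and physical constants.  A bundled JSON file supplies the
default values; every entry can be overridden from a user file.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

from .constants import T_DEFAULT

QUINONE_SPECIES = ("Q10", "DQ", "Q2", "NB", "mix")

#: dissociation-constant table keys per quinone species, in the order
#: (QH2 at Qp, Q at Qp, Q at Qn, QH2 at Qn)
_SPECIES_KEYS = {
    "DQ": ("KDQH2Qp", "KDQQp", "KDQQn", "KDQH2Qn"),
    "Q2": ("KQ2H2Qp", "KQ2Qp", "KQ2Qn", "KQ2H2Qn"),
    "NB": ("KNBHQp", "KNBQp", "KNBQn", "KNBHQn"),
    "mix": ("KQH2mixQp", "KQmixQp", "KQmixQn", "KQH2mixQn"),
    "Q10": ("KQ10H2Qp", "KQ10Qp", "KQ10Qn", "KQ10H2Qn"),
}

_EXPECTED_UNITS = {
    "rate_constants": {"1/s", "1"},
    "binding_constants": {"M"},
    "thermodynamic": {"kJ/mol", "1"},
    "initial_percent_oxidized": {"%"},
    "fixed": {"mV", "1/M/s", "1"},
}


class ParameterError(ValueError):
    """Raised on a missing, mis-typed or out-of-range parameter entry."""


@dataclass(frozen=True)
class FixedParameters:
    """Literature-fixed block: midpoint potentials (mV vs SHE, pH 7),
    electrical depths (fraction of the membrane dielectric measured from
    the p side) and the superoxide formation rate constant."""

    Em_bL: float = -60.0
    Em_bH: float = 80.0
    Em_SQn: float = 90.0
    Em_c: float = 260.0
    Em_O2: float = -160.0
    Em_pool: Mapping[str, float] = field(
        default_factory=lambda: {s: 90.0 for s in QUINONE_SPECIES}
    )
    k_O2: float = 1.0e14  # M^-1 s^-1, apparent; see docs/methods.md
    depth_SQp: float = 0.0
    depth_bL: float = 0.0
    depth_bH: float = 0.5
    depth_SQn: float = 1.0
    #: optional Rieske-protonation factor on the high-potential chain,
    #: 1/(1+10**(pH_p - pK)); disabled by default
    isp_pK: float = 7.6
    isp_factor_enabled: bool = False


@dataclass(frozen=True)
class ParameterSet:
    """All adjustable model parameters plus the fixed block.

    ``kf_qp[i]`` is the quinol-oxidation rate constant for the transition
    E_i -> E_{i+1}; ``kf_qn[i]`` the quinone-reduction rate constant for
    E_i -> E_{i-2}.  ``kd`` holds the apparent dissociation constants keyed
    by their table row names.
    """

    kf_qp: tuple[float, float, float, float, float]
    kf_qn: Mapping[int, float]
    beta_aa_r: float
    beta_aa_f: float
    kd: Mapping[str, float]
    dG_bHbL: float
    dG_bLbL: float
    K_SQ10: float
    K_SQanalog: float
    initial_percent_oxidized: Mapping[str, float]
    fixed: FixedParameters = field(default_factory=FixedParameters)

    def __post_init__(self) -> None:
        for i, k in enumerate(self.kf_qp):
            if not k > 0:
                raise ParameterError(f"kfQp{i},{i + 1} must be > 0, got {k}")
        for i, k in self.kf_qn.items():
            if not k > 0:
                raise ParameterError(f"kfQn{i},{i - 2} must be > 0, got {k}")
        for name, k in self.kd.items():
            if not k > 0:
                raise ParameterError(
                    f"dissociation constant {name} must be > 0, got {k}"
                )
        if self.dG_bHbL < 0 or self.dG_bLbL < 0:
            raise ParameterError("Coulomb repulsion energies must be >= 0")
        for name, k in (("KSQ10", self.K_SQ10), ("KSQanalog", self.K_SQanalog)):
            if not (0 < k <= 1):
                raise ParameterError(f"{name} must lie in (0, 1], got {k}")

    # -- species-resolved accessors -------------------------------------
    def quinone_kd(self, species: str) -> tuple[float, float, float, float]:
        """(K_QH2@Qp, K_Q@Qp, K_Q@Qn, K_QH2@Qn) for a quinone species."""
        try:
            keys = _SPECIES_KEYS[species]
        except KeyError:
            raise ParameterError(f"unknown quinone species tag {species!r}")
        return tuple(self.kd[k] for k in keys)  # type: ignore[return-value]

    def cytc_kd(self, magnesium: bool) -> tuple[float, float]:
        """(K_c3+, K_c2+), selecting the Mg2+ constants when requested."""
        if magnesium:
            return self.kd["Kc3+Mg2+"], self.kd["Kc2+Mg2+"]
        return self.kd["Kc3+"], self.kd["Kc2+"]

    def stability_constant(self, species: str) -> float:
        """Q_p-site semiquinone stability constant for a species."""
        if species not in QUINONE_SPECIES:
            raise ParameterError(f"unknown quinone species tag {species!r}")
        return self.K_SQ10 if species == "Q10" else self.K_SQanalog

    def replace(self, **changes) -> "ParameterSet":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class Conditions:
    """Thermodynamic and chemical environment of one steady-state solve.

    ``delta_psi`` is the membrane potential in mV, p side positive.
    Concentrations are molar with respect to the aqueous phase (the
    dissociation constants are apparent constants on the same scale).
    """

    delta_psi: float = 0.0
    pH_p: float = 7.0
    pH_n: float = 7.0
    temperature: float = T_DEFAULT
    QH2: float = 0.0
    Q: float = 0.0
    c2: float = 0.0
    c3: float = 0.0
    O2: float = 0.0
    O2m: float = 0.0
    species: str = "Q10"
    magnesium: bool = False

    def __post_init__(self) -> None:
        for name in ("QH2", "Q", "c2", "c3", "O2", "O2m"):
            if getattr(self, name) < 0:
                raise ValueError(f"concentration {name} must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        for name in ("pH_p", "pH_n"):
            if not 0 <= getattr(self, name) <= 14:
                raise ValueError(f"{name} outside [0, 14]")
        if self.species not in QUINONE_SPECIES:
            raise ValueError(f"unknown quinone species tag {self.species!r}")

    @classmethod
    def from_pools(
        cls,
        *,
        q_total: float,
        q_reduced_fraction: float,
        c_total: float = 0.0,
        c_reduced_fraction: float = 0.0,
        **kwargs,
    ) -> "Conditions":
        """Build conditions from total pools and reduced fractions:
        [QH2] = f_red * Q_tot, [Q] = (1 - f_red) * Q_tot, and likewise for
        the cytochrome c pool."""
        if not 0.0 <= q_reduced_fraction <= 1.0:
            raise ValueError("q_reduced_fraction outside [0, 1]")
        if not 0.0 <= c_reduced_fraction <= 1.0:
            raise ValueError("c_reduced_fraction outside [0, 1]")
        return cls(
            QH2=q_reduced_fraction * q_total,
            Q=(1.0 - q_reduced_fraction) * q_total,
            c2=c_reduced_fraction * c_total,
            c3=(1.0 - c_reduced_fraction) * c_total,
            **kwargs,
        )

    def replace(self, **changes) -> "Conditions":
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# parameter file I/O


def _load_raw(path: str | Path | None) -> dict:
    if path is None:
        ref = resources.files("bc1dimer.data").joinpath("default_parameters.json")
        return json.loads(ref.read_text())
    text = Path(path).read_text()
    return json.loads(text)


def _coerce(section: str, name: str, entry) -> float:
    if isinstance(entry, dict):
        unit = entry.get("unit")
        allowed = _EXPECTED_UNITS[section]
        if unit is not None and unit not in allowed:
            raise ParameterError(
                f"row {name!r}: unit {unit!r} not among {sorted(allowed)}"
            )
        entry = entry["value"]
    try:
        # Table-dialect scientific notation ("9.19E+09") parses as float
        return float(entry)
    except (TypeError, ValueError):
        raise ParameterError(f"row {name!r}: cannot parse value {entry!r}")


def read_parameters(path: str | Path | None = None) -> ParameterSet:
    """Load a ParameterSet from a JSON parameter table.

    ``path=None`` loads the bundled default table.  A user file only needs
    the entries it overrides; everything else falls back to the defaults.
    Raises :class:`ParameterError` naming the offending row on a missing
    key, bad unit, or non-positive constant.
    """
    raw = _load_raw(None)
    if path is not None:
        user = _load_raw(path)
        for section, entries in user.items():
            if section not in raw:
                raise ParameterError(f"unknown parameter section {section!r}")
            raw[section].update(entries)

    def sec(section: str) -> dict[str, float]:
        return {
            name: _coerce(section, name, entry)
            for name, entry in raw[section].items()
        }

    rates = sec("rate_constants")
    kds = sec("binding_constants")
    thermo = sec("thermodynamic")
    pct = sec("initial_percent_oxidized")
    fx = sec("fixed")

    try:
        kf_qp = tuple(rates[f"kfQp{i},{i + 1}"] for i in range(5))
        kf_qn = {i: rates[f"kfQn{i},{i - 2}"] for i in range(2, 6)}
        fixed = FixedParameters(
            Em_bL=fx["Em_bL"],
            Em_bH=fx["Em_bH"],
            Em_SQn=fx["Em_SQn"],
            Em_c=fx["Em_c"],
            Em_O2=fx["Em_O2"],
            Em_pool={s: fx[f"Em_pool_{s}"] for s in QUINONE_SPECIES},
            k_O2=fx["k_O2"],
            depth_SQp=fx["depth_SQp"],
            depth_bL=fx["depth_bL"],
            depth_bH=fx["depth_bH"],
            depth_SQn=fx["depth_SQn"],
        )
        return ParameterSet(
            kf_qp=kf_qp,  # type: ignore[arg-type]
            kf_qn=kf_qn,
            beta_aa_r=rates["bAAr"],
            beta_aa_f=rates["bAAf"],
            kd=kds,
            dG_bHbL=thermo["dGbHbLCoulomb"],
            dG_bLbL=thermo["dGbLbLCoulomb"],
            K_SQ10=thermo["KSQ10"],
            K_SQanalog=thermo["KSQanalog"],
            initial_percent_oxidized=pct,
            fixed=fixed,
        )
    except KeyError as exc:
        raise ParameterError(f"missing required parameter row {exc.args[0]!r}")


def default_parameters() -> ParameterSet:
    """The bundled fitted parameter set."""
    return read_parameters(None)
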