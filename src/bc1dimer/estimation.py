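"""Sensitivity analysis, calibration cost function, fitting harness and the
synthetic-data generator.

The generator emulates the shapes of the calibration data classes used to
parameterize the model — substrate titrations of cytochrome c reduction,
superoxide production versus membrane potential, superoxide versus Q-pool
redox state in the antimycin-saturated enzyme, and an antimycin titration
of the dimer population — with multiplicative log-normal noise.  Local
sensitivities are normalized elasticities |(p/J) dJ/dp| averaged over the
nonzero model outputs at the data abscissae.  Fitting runs a seeded
simulated-annealing global search in log10 parameter space followed by
bounded local refinement.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .binding import antimycin_class_fractions
from .experiments import class_fluxes
from .kinetics import steady_state
from .params import Conditions, ParameterSet, default_parameters

log = logging.getLogger(__name__)

DATASET_TYPES = ("cytc_titration", "SO_vs_dpsi", "SO_vs_qredox", "aa_titration")


@dataclass(frozen=True)
class DatasetSpec:
    """One calibration dataset: a condition template, an x grid, observed
    values and their relative noise scale."""

    name: str
    kind: str
    conditions: Conditions
    x: np.ndarray
    y: np.ndarray
    noise_scale: float
    percent_ox_key: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in DATASET_TYPES:
            raise ValueError(f"unknown dataset type {self.kind!r}")
        if len(self.x) != len(self.y):
            raise ValueError("x and y must have equal length")
        if not self.noise_scale > 0:
            raise ValueError("noise scale must be > 0")


@dataclass(frozen=True)
class SensitivityTable:
    """Normalized local sensitivity coefficients with descending ranks."""

    table: pd.DataFrame  # columns: parameter, coefficient, rank

    def coefficient(self, name: str) -> float:
        row = self.table[self.table["parameter"] == name]
        return float(row["coefficient"].iloc[0])

    def rank(self, name: str) -> int:
        row = self.table[self.table["parameter"] == name]
        return int(row["rank"].iloc[0])

    def top(self, n: int) -> list[str]:
        return list(self.table.sort_values("rank")["parameter"].head(n))


# ---------------------------------------------------------------------------
# named-parameter access (fit/sensitivity vector interface)


def _qp_name(i: int) -> str:
    return f"kfQp{i},{i + 1}"


def _qn_name(i: int) -> str:
    return f"kfQn{i},{i - 2}"


def parameter_names(p: ParameterSet) -> list[str]:
    """All adjustable parameter names, in table order."""
    names = [_qp_name(i) for i in range(5)]
    names += ["bAAr", "bAAf"]
    names += [_qn_name(i) for i in range(2, 6)]
    names += list(p.kd)
    names += ["dGbHbLCoulomb", "dGbLbLCoulomb", "KSQ10", "KSQanalog"]
    names += [f"pctox:{k}" for k in p.initial_percent_oxidized]
    return names


def get_param(p: ParameterSet, name: str) -> float:
    for i in range(5):
        if name == _qp_name(i):
            return p.kf_qp[i]
    for i in range(2, 6):
        if name == _qn_name(i):
            return p.kf_qn[i]
    if name == "bAAr":
        return p.beta_aa_r
    if name == "bAAf":
        return p.beta_aa_f
    if name in p.kd:
        return p.kd[name]
    simple = {
        "dGbHbLCoulomb": p.dG_bHbL,
        "dGbLbLCoulomb": p.dG_bLbL,
        "KSQ10": p.K_SQ10,
        "KSQanalog": p.K_SQanalog,
    }
    if name in simple:
        return simple[name]
    if name.startswith("pctox:"):
        return p.initial_percent_oxidized[name.split(":", 1)[1]]
    raise KeyError(name)


def set_param(p: ParameterSet, name: str, value: float) -> ParameterSet:
    for i in range(5):
        if name == _qp_name(i):
            kf = list(p.kf_qp)
            kf[i] = value
            return p.replace(kf_qp=tuple(kf))
    for i in range(2, 6):
        if name == _qn_name(i):
            kn = dict(p.kf_qn)
            kn[i] = value
            return p.replace(kf_qn=kn)
    if name == "bAAr":
        return p.replace(beta_aa_r=value)
    if name == "bAAf":
        return p.replace(beta_aa_f=value)
    if name in p.kd:
        kd = dict(p.kd)
        kd[name] = value
        return p.replace(kd=kd)
    if name == "dGbHbLCoulomb":
        return p.replace(dG_bHbL=value)
    if name == "dGbLbLCoulomb":
        return p.replace(dG_bLbL=value)
    if name == "KSQ10":
        return p.replace(K_SQ10=value)
    if name == "KSQanalog":
        return p.replace(K_SQanalog=value)
    if name.startswith("pctox:"):
        key = name.split(":", 1)[1]
        pct = dict(p.initial_percent_oxidized)
        pct[key] = value
        return p.replace(initial_percent_oxidized=pct)
    raise KeyError(name)


# ---------------------------------------------------------------------------
# forward model over a dataset


def _apply_pctox(ds: DatasetSpec, p: ParameterSet, cond: Conditions) -> Conditions:
    """Re-derive the pool split from the (possibly refitted) per-dataset
    initial percent-oxidized parameter."""
    if ds.percent_ox_key is None:
        return cond
    pct = p.initial_percent_oxidized[ds.percent_ox_key]
    q_tot = cond.QH2 + cond.Q
    fr = 1.0 - pct / 100.0
    return cond.replace(QH2=fr * q_tot, Q=(1.0 - fr) * q_tot)


def predict(p: ParameterSet, ds: DatasetSpec) -> np.ndarray:
    """Model curve for one dataset at its x grid."""
    cond = _apply_pctox(ds, p, ds.conditions)
    out = np.empty(len(ds.x))
    if ds.kind == "cytc_titration":
        fr = cond.QH2 / (cond.QH2 + cond.Q)
        for i, q_tot in enumerate(ds.x):
            c = cond.replace(QH2=fr * q_tot, Q=(1.0 - fr) * q_tot)
            out[i] = steady_state(c, p, "none")[1].J_c
    elif ds.kind == "SO_vs_dpsi":
        for i, dpsi in enumerate(ds.x):
            out[i] = steady_state(cond.replace(delta_psi=dpsi), p, "none")[1].J_SO
    elif ds.kind == "SO_vs_qredox":
        q_tot = cond.QH2 + cond.Q
        for i, pct_ox in enumerate(ds.x):
            fr = 1.0 - pct_ox / 100.0
            c = cond.replace(QH2=fr * q_tot, Q=(1.0 - fr) * q_tot)
            out[i] = steady_state(c, p, "double_AA")[1].J_SO
    elif ds.kind == "aa_titration":
        classes = class_fluxes(cond, p)
        flux = {k: v[1] for k, v in classes.items()}
        for i, ratio in enumerate(ds.x):
            f = antimycin_class_fractions(float(ratio))
            out[i] = (
                f.f0 * flux["none"].J_c
                + f.f1 * flux["single_AA"].J_c
                + f.f2 * flux["double_AA"].measured_Jc(True)
            )
    else:  # pragma: no cover - guarded by DatasetSpec
        raise ValueError(ds.kind)
    return out


# ---------------------------------------------------------------------------
# synthetic data


def generate_synthetic_datasets(
    p: ParameterSet | None = None,
    noise_fraction: float = 0.05,
    seed: int = 0,
    n_points: int = 8,
) -> list[DatasetSpec]:
    """Synthetic stand-ins for the calibration data classes, generated from
    the model itself with multiplicative log-normal noise
    (y = model * exp(sigma * z), sigma = noise_fraction).  ``noise_fraction
    = 0`` returns the noiseless model curves."""
    if noise_fraction < 0:
        raise ValueError("noise fraction must be >= 0")
    p = p if p is not None else default_parameters()
    rng = np.random.default_rng(seed)

    analog_assay = Conditions.from_pools(
        q_total=50e-6, q_reduced_fraction=0.5, c_total=50e-6,
        c_reduced_fraction=0.0, delta_psi=0.0, O2=250e-6, O2m=100e-12,
        species="DQ",
    )
    energized = Conditions.from_pools(
        q_total=50e-6, q_reduced_fraction=0.5, c_total=50e-6,
        c_reduced_fraction=0.0, delta_psi=0.0, O2=250e-6, O2m=100e-12,
        species="Q2",
    )

    specs = [
        DatasetSpec(
            "cytc_vs_substrate", "cytc_titration", analog_assay,
            np.linspace(5e-6, 100e-6, n_points), np.empty(n_points),
            max(noise_fraction, 1e-6), percent_ox_key="speck_margoliash",
        ),
        DatasetSpec(
            "SO_vs_membrane_potential", "SO_vs_dpsi", energized,
            np.linspace(0.0, 200.0, n_points), np.empty(n_points),
            max(noise_fraction, 1e-6), percent_ox_key="rottenberg",
        ),
        DatasetSpec(
            "SO_vs_qredox_antimycin", "SO_vs_qredox", analog_assay,
            np.linspace(10.0, 90.0, n_points), np.empty(n_points),
            max(noise_fraction, 1e-6),
        ),
        DatasetSpec(
            "aa_titration", "aa_titration", analog_assay,
            np.linspace(0.0, 1.0, n_points), np.empty(n_points),
            max(noise_fraction, 1e-6), percent_ox_key="covian_trumpower",
        ),
    ]
    out = []
    for ds in specs:
        y = predict(p, ds)
        if noise_fraction > 0:
            y = y * np.exp(noise_fraction * rng.standard_normal(len(y)))
        out.append(replace(ds, y=y))
    return out


# ---------------------------------------------------------------------------
# cost function


def cost(
    p: ParameterSet,
    datasets: list[DatasetSpec],
    penalty_weight: float = 1e-3,
) -> float:
    """Weighted sum-of-squares over all datasets plus the rate-constant
    difference penalty:

        sum_d (1/n_d) sum_i (model_i - y_i)^2 / sigma_i^2
        + lambda * [Var(ln kfQp) + Var(ln kfQn)]

    The variance penalty keeps the per-state Q_p and Q_n rate constants
    similar to each other during estimation.  Evaluation failures yield
    +inf (logged) so an optimizer can continue.
    """
    total = 0.0
    for ds in datasets:
        try:
            model = predict(p, ds)
        except Exception as exc:  # noqa: BLE001 - optimizer robustness
            log.warning("dataset %s evaluation failed: %s", ds.name, exc)
            return math.inf
        if not np.all(np.isfinite(model)):
            log.warning("dataset %s produced non-finite outputs", ds.name)
            return math.inf
        sigma = ds.noise_scale * np.maximum(np.abs(ds.y), 1e-12)
        total += float(np.mean(((model - ds.y) / sigma) ** 2))
    lnqp = np.log(p.kf_qp)
    lnqn = np.log(list(p.kf_qn.values()))
    penalty = float(np.var(lnqp) + np.var(lnqn))
    return total + penalty_weight * penalty


# ---------------------------------------------------------------------------
# local sensitivities


def local_sensitivities(
    p: ParameterSet,
    datasets: list[DatasetSpec],
    rel_step: float = 0.01,
    names: list[str] | None = None,
) -> SensitivityTable:
    """Normalized local sensitivity coefficients |(p/J) dJ/dp| by central
    finite differences, averaged over the nonzero model outputs at the
    dataset abscissae, ranked descending."""
    if not 0 < rel_step <= 0.1:
        raise ValueError("relative step must lie in (0, 0.1]")
    names = names if names is not None else parameter_names(p)
    base = np.concatenate([predict(p, ds) for ds in datasets])
    rows = []
    for name in names:
        v = get_param(p, name)
        up = np.concatenate(
            [predict(set_param(p, name, v * (1 + rel_step)), ds) for ds in datasets]
        )
        dn = np.concatenate(
            [predict(set_param(p, name, v * (1 - rel_step)), ds) for ds in datasets]
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            elast = (up - dn) / (2.0 * rel_step * base)
        ok = np.isfinite(elast) & (np.abs(base) > 0)
        nonzero = np.abs(elast[ok])
        nonzero = nonzero[nonzero > 0]
        coeff = float(nonzero.mean()) if nonzero.size else 0.0
        rows.append({"parameter": name, "coefficient": coeff})
    df = pd.DataFrame(rows)
    df["rank"] = (
        df["coefficient"].rank(ascending=False, method="first").astype(int)
    )
    return SensitivityTable(df)


# ---------------------------------------------------------------------------
# fitting


@dataclass(frozen=True)
class FitSettings:
    seed: int = 0
    sa_steps: int = 200
    sa_initial_temp: float = 2.0
    sa_cooling: float = 0.98
    sa_step_decades: float = 0.15
    local_maxiter: int = 60
    penalty_weight: float = 1e-3


@dataclass(frozen=True)
class FitResult:
    params: ParameterSet
    names: list[str]
    values: np.ndarray
    best_cost: float
    trace: list[float] = field(repr=False)
    settings: FitSettings = field(repr=False, default_factory=FitSettings)


def fit(
    datasets: list[DatasetSpec],
    names: list[str],
    p0: ParameterSet | None = None,
    bounds_decades: float = 1.0,
    settings: FitSettings | None = None,
) -> FitResult:
    """Fit the named parameters to the datasets.

    The search works in log10 space (the adjustable parameters span many
    orders of magnitude) inside +/- ``bounds_decades`` around the starting
    values: a seeded Metropolis simulated-annealing pass with geometric
    cooling, then L-BFGS-B refinement.  The same seed reproduces the same
    trajectory and result bit for bit.
    """
    if not datasets:
        raise ValueError("no datasets supplied")
    p0 = p0 if p0 is not None else default_parameters()
    settings = settings if settings is not None else FitSettings()
    rng = np.random.default_rng(settings.seed)

    x0 = np.array([math.log10(get_param(p0, n)) for n in names])
    lo, hi = x0 - bounds_decades, x0 + bounds_decades

    def build(x: np.ndarray) -> ParameterSet:
        p = p0
        for n, v in zip(names, x):
            p = set_param(p, n, 10.0**v)
        return p

    def f(x: np.ndarray) -> float:
        try:
            return cost(build(x), datasets, settings.penalty_weight)
        except Exception:  # noqa: BLE001 - bad region of parameter space
            return math.inf

    x, fx = x0.copy(), f(x0)
    best_x, best_f = x.copy(), fx
    trace = [fx]
    temp = settings.sa_initial_temp
    for _ in range(settings.sa_steps):
        prop = np.clip(
            x + settings.sa_step_decades * rng.standard_normal(len(x)), lo, hi
        )
        fp = f(prop)
        if fp < fx or rng.random() < math.exp(-(fp - fx) / max(temp, 1e-12)):
            x, fx = prop, fp
            if fx < best_f:
                best_x, best_f = x.copy(), fx
        trace.append(best_f)
        temp *= settings.sa_cooling

    res = minimize(
        f,
        best_x,
        method="L-BFGS-B",
        bounds=list(zip(lo, hi)),
        options={"maxiter": settings.local_maxiter},
    )
    if res.fun <= best_f:
        best_x, best_f = res.x, float(res.fun)
    trace.append(best_f)
    return FitResult(
        params=build(best_x),
        names=list(names),
        values=10.0**best_x,
        best_cost=best_f,
        trace=trace,
        settings=settings,
    )
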