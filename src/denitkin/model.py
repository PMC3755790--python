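"""Modified activated-sludge kinetics for anoxic nitrate reduction.

The model describes heterotrophic denitrifiers growing on a set of soluble
organic-carbon pools (electron donors) with nitrate as the sole electron
acceptor, following the anoxic-growth structure of the activated sludge
models (ASM1 and its TOC-based variant ASM3C) with three modifications:

* donors are split into degradability categories (glucose, cement
  super-plasticizer extract, organics released from dead cells, humic acids),
  each with its own maximum rate constant ``k3`` and half-saturation
  constant;
* a fraction ``f_recycle`` of dead-biomass carbon re-enters solution
  directly as a soluble ``biomass_derived`` donor pool, short-circuiting the
  usual particulate-hydrolysis step — important where easily degradable
  carbon is scarce;
* nitrate is reduced straight to N2 (intermediates are not tracked), so the
  cumulative N2-nitrogen pool closes the nitrogen balance.

State variables are carbon- and nitrogen-mass based (g-C/dm3, g-N/dm3).
For every pool *i*,

    growth_i      = k3_i * sS_i/(KsS_i + sS_i) * sNO3/(KsNO3 + sNO3) * xB
    consumption_i = growth_i / x_yield
    dxB/dt        = sum_i growth_i - bH * xB
    dsS_i/dt      = -consumption_i  (+ f_recycle * bH * xB for biomass_derived)
    dsNO3/dt      = -z_nc * sum_i consumption_i      dcumN2/dt = -dsNO3/dt

with the non-assimilated carbon fraction (1 - x_yield) of consumption
booked to ``cumCO2`` and the non-recycled death flux to inert solids ``xI``,
so that total carbon and total nitrogen are conserved exactly by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import ConfigurationError, IntegrationError, InvalidParameterError

__all__ = [
    "DONOR_CATEGORIES",
    "DEFAULT_K3",
    "DEFAULT_KS_S",
    "DEFAULT_KS_NO3",
    "C_MOLAR_MASS",
    "N_MOLAR_MASS",
    "KineticParams",
    "OrganicsPool",
    "SystemState",
    "monod_factor",
    "growth_rate",
    "substrate_rates",
    "nitrate_rate",
    "derivatives",
    "simulate",
    "trajectory_frame",
]

#: Donor categories in decreasing order of microbial usability.
DONOR_CATEGORIES = ("glucose", "plasticizer", "biomass_derived", "humic")

#: Default maximum anoxic growth-rate constants [1/d] per donor category.
#: The plasticizer value is the in-situ calibration result; glucose sits at
#: the low end of the typical ASM range for readily degradable substrate;
#: the dead-cell and humic pools are ranked below plasticizer per the
#: observed degradability ordering.
DEFAULT_K3 = {
    "glucose": 1.0,
    "plasticizer": 0.1,
    "biomass_derived": 0.02,
    "humic": 0.001,
}

DEFAULT_KS_S = 0.01  # g-C/dm3, half-saturation of soluble organics
DEFAULT_KS_NO3 = 0.001  # g-N/dm3, half-saturation of nitrate

C_MOLAR_MASS = 12.011  # g/mol
N_MOLAR_MASS = 14.007  # g/mol


def monod_factor(s: float, K: float) -> float:
    """Monod saturation fraction ``s / (K + s)``.

    Parameters
    ----------
    s : substrate concentration, >= 0.
    K : half-saturation concentration, > 0 (same units as ``s``).
    """
    if K <= 0:
        raise InvalidParameterError(f"half-saturation constant must be > 0, got {K}")
    if s < 0:
        raise InvalidParameterError(f"substrate concentration must be >= 0, got {s}")
    return s / (K + s)


@dataclass(frozen=True)
class KineticParams:
    """All rate and stoichiometry constants of the denitrification model.

    Attributes
    ----------
    k3_per_pool : maximum anoxic growth-rate constant [1/d] per donor label.
    bH : first-order death-rate constant [1/d].
    KsS_per_pool : half-saturation of soluble organics [g-C/dm3] per label;
        labels not listed fall back to ``DEFAULT_KS_S``.
    KsNO3 : half-saturation of nitrate [g-N/dm3].
    x_yield : fraction of consumed organic carbon incorporated into biomass
        (dimensionless, (0, 1]); the remainder is mineralized.
    z_nc : nitrate-N reduced per organic-C consumed [g-N/g-C].
    f_recycle : fraction of dead-biomass carbon released directly as soluble
        organics into the ``biomass_derived`` pool (dimensionless, [0, 1]).
    """

    k3_per_pool: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_K3))
    bH: float = 0.005
    KsS_per_pool: Mapping[str, float] = field(default_factory=dict)
    KsNO3: float = DEFAULT_KS_NO3
    x_yield: float = 0.5
    z_nc: float = 1.0
    f_recycle: float = 0.5

    def __post_init__(self) -> None:
        for label, k in self.k3_per_pool.items():
            if k < 0:
                raise InvalidParameterError(f"k3[{label}] must be >= 0, got {k}")
        for label, K in self.KsS_per_pool.items():
            if K <= 0:
                raise InvalidParameterError(f"KsS[{label}] must be > 0, got {K}")
        if self.bH < 0:
            raise InvalidParameterError(f"bH must be >= 0, got {self.bH}")
        if self.KsNO3 <= 0:
            raise InvalidParameterError(f"KsNO3 must be > 0, got {self.KsNO3}")
        if not 0 < self.x_yield <= 1:
            raise InvalidParameterError(f"x_yield must be in (0, 1], got {self.x_yield}")
        if not 0 <= self.f_recycle <= 1:
            raise InvalidParameterError(f"f_recycle must be in [0, 1], got {self.f_recycle}")
        if self.z_nc < 0:
            raise InvalidParameterError(f"z_nc must be >= 0, got {self.z_nc}")

    def k3(self, label: str) -> float:
        try:
            return self.k3_per_pool[label]
        except KeyError:
            raise ConfigurationError(f"no k3 configured for donor pool {label!r}") from None

    def KsS(self, label: str) -> float:
        return self.KsS_per_pool.get(label, DEFAULT_KS_S)

    def with_updates(self, **kwargs) -> "KineticParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class OrganicsPool:
    """One electron-donor category: label plus its soluble-carbon concentration."""

    label: str
    sS: float  # g-C/dm3

    def __post_init__(self) -> None:
        if self.sS < 0:
            raise InvalidParameterError(f"sS[{self.label}] must be >= 0, got {self.sS}")


@dataclass(frozen=True)
class SystemState:
    """Instantaneous model state.

    ``cumN2`` (cumulative N2-nitrogen, g-N/dm3) and ``cumCO2`` / ``xI``
    (mineralized and inert dead-biomass carbon, g-C/dm3) are bookkeeping
    pools that make the nitrogen and carbon balances closed quantities.
    """

    t: float
    pools: tuple[OrganicsPool, ...]
    sNO3: float
    xB: float
    cumN2: float = 0.0
    cumCO2: float = 0.0
    xI: float = 0.0

    def __post_init__(self) -> None:
        labels = [p.label for p in self.pools]
        if len(set(labels)) != len(labels):
            raise InvalidParameterError(f"duplicate pool labels: {labels}")
        for name in ("sNO3", "xB", "cumN2", "cumCO2", "xI"):
            v = getattr(self, name)
            if v < 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {v}")
        object.__setattr__(self, "pools", tuple(self.pools))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(p.label for p in self.pools)

    def pool(self, label: str) -> OrganicsPool:
        for p in self.pools:
            if p.label == label:
                return p
        raise KeyError(label)

    @property
    def total_soluble_carbon(self) -> float:
        return sum(p.sS for p in self.pools)

    @property
    def total_carbon(self) -> float:
        """Closed carbon inventory: donors + biomass + inerts + mineralized."""
        return self.total_soluble_carbon + self.xB + self.xI + self.cumCO2

    @property
    def total_nitrogen(self) -> float:
        """Closed nitrogen inventory: nitrate-N + cumulative N2-N."""
        return self.sNO3 + self.cumN2


# ---------------------------------------------------------------------------
# rate expressions


def _check_recycle_sink(labels: Sequence[str], p: KineticParams) -> None:
    if p.f_recycle > 0 and "biomass_derived" not in labels:
        raise ConfigurationError(
            "f_recycle > 0 requires a 'biomass_derived' pool to receive the "
            "dead-biomass carbon flux"
        )


def _gross_growth(state: SystemState, p: KineticParams) -> dict[str, float]:
    """Gross growth flux [g-C/dm3/d] contributed by each pool."""
    mn = monod_factor(state.sNO3, p.KsNO3)
    return {
        pool.label: p.k3(pool.label) * monod_factor(pool.sS, p.KsS(pool.label)) * mn * state.xB
        for pool in state.pools
    }


def growth_rate(state: SystemState, p: KineticParams) -> float:
    """Net biomass rate dxB/dt [g-C/dm3/d]: summed pool growth minus death."""
    return sum(_gross_growth(state, p).values()) - p.bH * state.xB


def substrate_rates(state: SystemState, p: KineticParams) -> dict[str, float]:
    """Per-pool rate dsS_i/dt [g-C/dm3/d].

    Consumption of each pool is gross growth divided by the yield
    ``x_yield``; the ``biomass_derived`` pool additionally receives the
    direct death-recycle input ``f_recycle * bH * xB``.
    """
    _check_recycle_sink(state.labels, p)
    growth = _gross_growth(state, p)
    rates = {label: -g / p.x_yield for label, g in growth.items()}
    if p.f_recycle > 0:
        rates["biomass_derived"] += p.f_recycle * p.bH * state.xB
    return rates


def nitrate_rate(substrate_consumption_total: float, p: KineticParams) -> tuple[float, float]:
    """(dsNO3/dt, dcumN2/dt) from the total respiration-driven carbon flux.

    ``substrate_consumption_total`` is the summed donor-oxidation flux
    (negative by convention, g-C/dm3/d), excluding the recycle input, which
    is not an oxidation and reduces no nitrate.
    """
    dno3 = p.z_nc * substrate_consumption_total
    return dno3, -dno3


def derivatives(state: SystemState, p: KineticParams) -> dict[str, float | dict[str, float]]:
    """Full state rate vector as a mapping mirroring SystemState fields.

    Carbon from gross consumption splits x_yield -> xB and (1 - x_yield) ->
    cumCO2; the death flux bH*xB splits f_recycle -> biomass_derived pool and
    (1 - f_recycle) -> xI, so the carbon derivatives sum to zero exactly.
    """
    _check_recycle_sink(state.labels, p)
    growth = _gross_growth(state, p)
    consumption = {label: g / p.x_yield for label, g in growth.items()}
    total_cons = sum(consumption.values())

    ds = {label: -c for label, c in consumption.items()}
    if p.f_recycle > 0:
        ds["biomass_derived"] += p.f_recycle * p.bH * state.xB

    dno3, dn2 = nitrate_rate(-total_cons, p)
    return {
        "sS": ds,
        "sNO3": dno3,
        "xB": sum(growth.values()) - p.bH * state.xB,
        "cumN2": dn2,
        "cumCO2": (1.0 - p.x_yield) * total_cons,
        "xI": (1.0 - p.f_recycle) * p.bH * state.xB,
    }


# ---------------------------------------------------------------------------
# integration


def _pack(state: SystemState) -> np.ndarray:
    return np.array(
        [p.sS for p in state.pools]
        + [state.sNO3, state.xB, state.cumN2, state.cumCO2, state.xI],
        dtype=float,
    )


def _unpack(t: float, y: np.ndarray, labels: Sequence[str]) -> SystemState:
    n = len(labels)
    return SystemState(
        t=float(t),
        pools=tuple(OrganicsPool(lab, float(y[i])) for i, lab in enumerate(labels)),
        sNO3=float(y[n]),
        xB=float(y[n + 1]),
        cumN2=float(y[n + 2]),
        cumCO2=float(y[n + 3]),
        xI=float(y[n + 4]),
    )


def _make_rhs(labels: Sequence[str], p: KineticParams):
    n = len(labels)
    k3 = np.array([p.k3(lab) for lab in labels])
    KsS = np.array([p.KsS(lab) for lab in labels])
    i_bd = labels.index("biomass_derived") if "biomass_derived" in labels else -1

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        # Monod rates vanish at zero, so clipping the evaluation state at the
        # physical floor is consistent with the dynamics.
        yc = np.maximum(y, 0.0)
        sS = yc[:n]
        sNO3, xB = yc[n], yc[n + 1]
        mn = sNO3 / (p.KsNO3 + sNO3)
        growth = k3 * sS / (KsS + sS) * mn * xB
        cons = growth / p.x_yield
        total_cons = cons.sum()
        dy = np.empty_like(y)
        dy[:n] = -cons
        if i_bd >= 0:
            dy[i_bd] += p.f_recycle * p.bH * xB
        dy[n] = -p.z_nc * total_cons
        dy[n + 1] = growth.sum() - p.bH * xB
        dy[n + 2] = p.z_nc * total_cons
        dy[n + 3] = (1.0 - p.x_yield) * total_cons
        dy[n + 4] = (1.0 - p.f_recycle) * p.bH * xB
        return dy

    return rhs


def simulate(
    initial: SystemState,
    p: KineticParams,
    t_grid: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "LSODA",
) -> list[SystemState]:
    """Integrate the model and return states at the requested times.

    ``t_grid`` must be strictly increasing and start at ``initial.t``.
    States are clipped at the physical floor of zero; if the integrator
    undershoots zero by more than the error the tolerances allow, an
    :class:`IntegrationError` is raised rather than silently repaired.
    """
    _check_recycle_sink(initial.labels, p)
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 1:
        raise InvalidParameterError("t_grid must be a non-empty 1-D sequence")
    if not math.isclose(t[0], initial.t, rel_tol=0, abs_tol=1e-12):
        raise InvalidParameterError(
            f"t_grid must start at initial.t = {initial.t}, got {t[0]}"
        )
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise InvalidParameterError("t_grid must be strictly increasing")
    if len(t) == 1:
        return [initial]

    y0 = _pack(initial)
    rhs = _make_rhs(list(initial.labels), p)
    sol = solve_ivp(
        rhs, (t[0], t[-1]), y0, t_eval=t, method=method, rtol=rtol, atol=atol
    )
    if not sol.success:
        t_last = float(sol.t[-1]) if sol.t.size else float(t[0])
        raise IntegrationError(f"integration failed: {sol.message}", t_last=t_last)

    scale = max(float(np.max(np.abs(sol.y))), 1e-30)
    floor = -(100.0 * atol + 10.0 * rtol * scale)
    if float(sol.y.min()) < floor:
        raise IntegrationError(
            f"state undershot zero beyond tolerance (min {sol.y.min():.3e})",
            t_last=float(sol.t[-1]),
        )
    y = np.maximum(sol.y, 0.0)
    return [_unpack(t[j], y[:, j], initial.labels) for j in range(len(t))]


def trajectory_frame(states: Sequence[SystemState]) -> pd.DataFrame:
    """Tabulate a trajectory: columns t, sS.<label>..., sNO3, xB, cumN2, cumCO2, xI."""
    labels = states[0].labels
    rows = []
    for s in states:
        if s.labels != labels:
            raise InvalidParameterError("inconsistent pool labels along trajectory")
        row = {"t": s.t}
        row.update({f"sS.{p.label}": p.sS for p in s.pools})
        row.update(
            {"sNO3": s.sNO3, "xB": s.xB, "cumN2": s.cumN2, "cumCO2": s.cumCO2, "xI": s.xI}
        )
        rows.append(row)
    return pd.DataFrame(rows)
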