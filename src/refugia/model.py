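"""Deterministic refuge model: logistic growth under joint nutrient supply,
abiotic stress, and mixing.

The population density ``N`` obeys

    dN/dt = N [ (R + mu) (1 - N/q) - s (1 + mu) ]

where ``R`` is the nutrient-driven growth rate, ``s`` the stressor-induced
mortality rate, ``q`` the intraspecific-competition (capacity) scale, and
``mu`` the mixing rate. Mixing has a dual effect: it circulates nutrients
(adding to growth) but also destroys spatial refuges (amplifying stressor
exposure). After rearrangement this is a logistic equation with intrinsic
rate ``r = R + mu - s(1 + mu)`` and carrying capacity ``K = q r / (R + mu)``,
so the system has exactly two candidate states — extinction (N = 0) and an
interior equilibrium N* = K — with mutually exclusive stability governed by
the sign of the low-density eigenvalue ``r``. The persistence boundary in the
(s, R) plane is ``R = mu (s - 1) + s``.

Mixing a population can therefore either rescue it (low stress, where the
nutrient boost dominates) or extinguish it (high stress, where increased
exposure dominates); :func:`phase_diagram` maps those regions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "ModelParams",
    "EquilibriumReport",
    "PhaseDiagram",
    "Trajectory",
    "VariantParams",
    "UndefinedEquilibriumError",
    "SolverError",
    "growth_rate",
    "interior_equilibrium",
    "eigenvalue_extinct",
    "eigenvalue_interior",
    "equilibrium_report",
    "critical_nutrient",
    "classify_outcome",
    "mixing_effect",
    "logistic_rate_capacity",
    "integrate_ode",
    "phase_diagram",
    "variant_growth_rate",
    "variant_persistence_threshold",
]

PERSIST = "persist"
EXTINCT = "extinct"

MIXING_LABELS = (
    "persist_both",
    "extinct_both",
    "rescued_by_mixing",
    "extinguished_by_mixing",
)

VARIANTS = ("baseline", "capacity_mixing", "growth_stressor")


class UndefinedEquilibriumError(ValueError):
    """Raised when R + mu = 0 and the interior equilibrium is undefined."""


class SolverError(RuntimeError):
    """ODE integration failed; carries the solver's diagnostic message."""


@dataclass(frozen=True)
class ModelParams:
    """Parameter vector (R, s, mu, q) of the refuge model.

    Parameters
    ----------
    R : float
        Nutrient-driven growth rate (per unit time, >= 0).
    s : float
        Stressor-induced mortality rate (per unit time, >= 0).
    mu : float
        Mixing rate (dimensionless, >= 0). 0 = static, 1 = fully mixed.
    q : float
        Competition/capacity scale (population units, > 0).
    """

    R: float
    s: float
    mu: float = 0.0
    q: float = 1.0

    def __post_init__(self) -> None:
        for name in ("R", "s", "mu", "q"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.R < 0 or self.s < 0 or self.mu < 0:
            raise ValueError("R, s and mu must be nonnegative")
        if self.q <= 0:
            raise ValueError("q must be strictly positive")


@dataclass(frozen=True)
class EquilibriumReport:
    """Equilibria and their stability for one parameter set."""

    params: ModelParams
    N_star: float
    lambda_extinct: float
    lambda_interior: float
    stable_state: Literal["extinction", "persistence"]


@dataclass(frozen=True)
class Trajectory:
    """Time series produced by :func:`integrate_ode`."""

    t: np.ndarray
    N: np.ndarray
    params: ModelParams

    @property
    def final(self) -> float:
        return float(self.N[-1])


def growth_rate(params: ModelParams, N: float | np.ndarray) -> float | np.ndarray:
    """Instantaneous rate of change dN/dt at density ``N``.

    Accepts scalars or arrays; negative densities are rejected.
    """
    N_arr = np.asarray(N, dtype=float)
    if np.any(N_arr < 0):
        raise ValueError("density N must be nonnegative")
    p = params
    out = N_arr * ((p.R + p.mu) * (1.0 - N_arr / p.q) - p.s * (1.0 + p.mu))
    return float(out) if np.isscalar(N) or out.ndim == 0 else out


def logistic_rate_capacity(params: ModelParams) -> tuple[float, float]:
    """Return (r, K): the model rewritten in logistic form.

    r = R + mu - s(1 + mu) is the low-density growth rate; K = q r/(R + mu)
    is the interior equilibrium (may be <= 0, in which case only extinction
    is stable). Raises :class:`UndefinedEquilibriumError` when R + mu = 0.
    """
    p = params
    if p.R + p.mu == 0:
        raise UndefinedEquilibriumError("interior equilibrium undefined for R + mu = 0")
    r = eigenvalue_extinct(p)
    return r, p.q * r / (p.R + p.mu)


def interior_equilibrium(params: ModelParams) -> float:
    """Non-trivial equilibrium N* = q (R + mu - s(1 + mu)) / (R + mu).

    A nonpositive return value means the interior state is biologically
    void (only N = 0 is feasible); callers should check the sign or use
    :func:`equilibrium_report`.
    """
    return logistic_rate_capacity(params)[1]


def eigenvalue_extinct(params: ModelParams) -> float:
    """Eigenvalue of the linearization at N = 0: R + mu - s(1 + mu)."""
    p = params
    return p.R + p.mu - p.s * (1.0 + p.mu)


def eigenvalue_interior(params: ModelParams) -> float:
    """Eigenvalue at N = N*; exactly the negation of the extinct-state one."""
    return -eigenvalue_extinct(params)


def equilibrium_report(params: ModelParams) -> EquilibriumReport:
    lam0 = eigenvalue_extinct(params)
    n_star = interior_equilibrium(params)
    # Boundary convention: lam0 = 0 has no stable interior state -> extinction.
    state = "persistence" if lam0 > 0 else "extinction"
    return EquilibriumReport(
        params=params,
        N_star=n_star,
        lambda_extinct=lam0,
        lambda_interior=-lam0,
        stable_state=state,
    )


def critical_nutrient(s: float, mu: float) -> float:
    """Persistence boundary in R: populations with R > mu(s-1)+s persist."""
    if s < 0 or mu < 0:
        raise ValueError("s and mu must be nonnegative")
    return mu * (s - 1.0) + s


def classify_outcome(params: ModelParams) -> str:
    """Long-run fate: ``"persist"`` iff the extinct state is unstable.

    The exact boundary (eigenvalue 0) is classified extinct: the neutral
    case has no stable interior equilibrium.
    """
    return PERSIST if eigenvalue_extinct(params) > 0 else EXTINCT


def mixing_effect(
    R: float,
    s: float,
    mu_static: float = 0.0,
    mu_mixed: float = 1.0,
    q: float = 1.0,
) -> str:
    """Compare fates of the static and mixed cases at one (R, s) point.

    Returns one of ``persist_both``, ``extinct_both``, ``rescued_by_mixing``
    (extinct static but persisting mixed — mixing supplies nutrients), or
    ``extinguished_by_mixing`` (persisting static but extinct mixed — mixing
    amplifies stressor exposure).
    """
    static = classify_outcome(ModelParams(R=R, s=s, mu=mu_static, q=q))
    mixed = classify_outcome(ModelParams(R=R, s=s, mu=mu_mixed, q=q))
    if static == PERSIST and mixed == PERSIST:
        return "persist_both"
    if static == EXTINCT and mixed == EXTINCT:
        return "extinct_both"
    if static == EXTINCT:
        return "rescued_by_mixing"
    return "extinguished_by_mixing"


def integrate_ode(
    params: ModelParams,
    n0: float,
    t_end: float,
    t_eval: Sequence[float] | None = None,
    rtol: float = 1e-8,
    atol: float | None = None,
    method: str = "RK45",
) -> Trajectory:
    """Numerically integrate the model from density ``n0`` to time ``t_end``.

    Adaptive Runge-Kutta with relative tolerance 1e-8 and absolute tolerance
    1e-12 * q by default. Tiny negative excursions from the solver are
    clipped to zero with a warning. Raises :class:`SolverError` on failure.
    """
    if n0 < 0:
        raise ValueError("initial density must be nonnegative")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if atol is None:
        atol = 1e-12 * params.q

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        n = max(y[0], 0.0)
        return np.array(
            [n * ((params.R + params.mu) * (1.0 - n / params.q)
                  - params.s * (1.0 + params.mu))]
        )

    sol = solve_ivp(
        rhs,
        (0.0, float(t_end)),
        [float(n0)],
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        method=method,
    )
    if not sol.success:
        raise SolverError(f"ODE integration failed: {sol.message}")
    N = sol.y[0]
    if np.any(N < 0):
        if np.any(N < -10 * atol):
            warnings.warn(
                "integrator produced negative densities beyond tolerance; clipping",
                RuntimeWarning,
                stacklevel=2,
            )
        N = np.clip(N, 0.0, None)
    return Trajectory(t=sol.t, N=N, params=params)


@dataclass(frozen=True)
class PhaseDiagram:
    """Grid classification of mixing effects over the (R, s) plane.

    ``region[i, j]`` is the label at ``(R_axis[i], s_axis[j])``.
    """

    R_axis: np.ndarray
    s_axis: np.ndarray
    mu_static: float
    mu_mixed: float
    region: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view with columns R, s, region."""
        rr, ss = np.meshgrid(self.R_axis, self.s_axis, indexing="ij")
        return pd.DataFrame(
            {"R": rr.ravel(), "s": ss.ravel(), "region": self.region.ravel()}
        )


def phase_diagram(
    R_axis: Sequence[float],
    s_axis: Sequence[float],
    mu_static: float = 0.0,
    mu_mixed: float = 1.0,
) -> PhaseDiagram:
    """Label every grid point by :func:`mixing_effect`.

    Axes must be sorted, nonnegative and non-empty. Points exactly on a
    persistence boundary take the extinct-side label (boundary convention).
    """
    R_arr = np.asarray(R_axis, dtype=float)
    s_arr = np.asarray(s_axis, dtype=float)
    if R_arr.size == 0 or s_arr.size == 0:
        raise ValueError("axes must be non-empty")
    if np.any(R_arr < 0) or np.any(s_arr < 0):
        raise ValueError("axes must be nonnegative")
    if np.any(np.diff(R_arr) < 0) or np.any(np.diff(s_arr) < 0):
        raise ValueError("axes must be sorted ascending")
    # Vectorized classification: persistence iff R + mu - s(1+mu) > 0.
    rr, ss = np.meshgrid(R_arr, s_arr, indexing="ij")
    persist_static = rr + mu_static - ss * (1.0 + mu_static) > 0
    persist_mixed = rr + mu_mixed - ss * (1.0 + mu_mixed) > 0
    region = np.where(
        persist_static & persist_mixed,
        "persist_both",
        np.where(
            ~persist_static & ~persist_mixed,
            "extinct_both",
            np.where(persist_mixed, "rescued_by_mixing", "extinguished_by_mixing"),
        ),
    )
    return PhaseDiagram(
        R_axis=R_arr, s_axis=s_arr, mu_static=mu_static, mu_mixed=mu_mixed,
        region=region,
    )


# --------------------------------------------------------------------------
# Supplementary model variants
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantParams:
    """A structural variant of the refuge model.

    ``baseline`` is the model itself. ``capacity_mixing`` lets nutrients and
    mixing scale the capacity term instead of the growth term:

        dN/dt = N [ R (1 - N/(q (1 + mu))) - s (1 + mu) ].

    ``growth_stressor`` lets the stressor scale growth down instead of adding
    mortality, with an optional baseline turnover ``delta``:

        dN/dt = N (R + mu)(1 - N/q) / (1 + s (1 + mu)) - delta N.

    Both alternative forms are reconstructions of the verbal robustness
    argument, clearly labelled as such; they preserve the two-state,
    mutually-exclusive-stability structure.
    """

    variant: str
    base: ModelParams
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )


def variant_growth_rate(vp: VariantParams, N: float) -> float:
    """dN/dt for a model variant at density ``N``."""
    if N < 0:
        raise ValueError("density N must be nonnegative")
    p = vp.base
    if vp.variant == "baseline":
        return float(growth_rate(p, N))
    if vp.variant == "capacity_mixing":
        return N * (p.R * (1.0 - N / (p.q * (1.0 + p.mu))) - p.s * (1.0 + p.mu))
    # growth_stressor
    delta = float(vp.extra.get("delta", 0.0))
    return (
        N * (p.R + p.mu) * (1.0 - N / p.q) / (1.0 + p.s * (1.0 + p.mu))
        - delta * N
    )


def _variant_lambda0(variant: str, R: float, s: float, mu: float, q: float,
                     extra: dict) -> float:
    """Low-density per-capita growth rate of a variant (sign decides fate)."""
    eps = q * 1e-9
    vp = VariantParams(variant, ModelParams(R=R, s=s, mu=mu, q=q), extra)
    return variant_growth_rate(vp, eps) / eps


def variant_persistence_threshold(
    variant: str,
    R: float,
    mu: float,
    q: float = 1.0,
    extra: dict | None = None,
    s_max: float = 50.0,
) -> float:
    """Critical stressor lethality s* for a variant, by bisection.

    Finds the unique sign change of the low-density per-capita growth rate
    along ``s`` in [0, s_max]. Raises ``ValueError`` if the growth rate does
    not change sign on that interval (e.g. growth_stressor with delta = 0,
    which persists for every s).
    """
    from scipy.optimize import brentq

    extra = extra or {}
    f = lambda s: _variant_lambda0(variant, R, s, mu, q, extra)
    f0, f1 = f(0.0), f(s_max)
    if f0 <= 0:
        raise ValueError("population does not persist even without the stressor")
    if f1 > 0:
        raise ValueError(f"no extinction threshold in s on [0, {s_max}]")
    return float(brentq(f, 0.0, s_max, xtol=1e-12, rtol=1e-12))
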