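"""Source–sink model of density-dependent growth.

A population of ``n`` identical sinks (fruit cells, seeds, fruits, or whole
plants) imports sugars from a common source through the phloem.  Flow is
Münch-style: proportional to the source–sink concentration gradient with a
conductance that scales with population size as ``k = kappa * n**alpha``.
Unloading into sink tissue follows Michaelis–Menten kinetics.  Assuming no
phloem storage, flow equals unloading at every instant, which fixes the sink
phloem concentration ``Cf`` as the positive root of a quadratic; individual
dry mass then grows by forward Euler at an hourly step.

Units: time h, mass g, concentration g cm^-3, conductance cm^6 g^-1 h^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


__all__ = [
    "InvalidParameterError",
    "IntegrationError",
    "DDMParameters",
    "SourceModel",
    "SimulationConfig",
    "GrowthTrajectory",
    "conductance",
    "source_concentration",
    "sink_concentration",
    "flow",
    "unloading",
    "simulate_growth",
]

# Threshold above which n**alpha is evaluated in log space; n spans eight
# orders of magnitude (cells to plots) and exp(alpha*log(n)) is stable there.
_LOG_SPACE_N = 1.0e6


class InvalidParameterError(ValueError):
    """A physiological parameter or simulation setting is out of range."""


class IntegrationError(RuntimeError):
    """The Euler integration produced a non-finite state.

    Attributes
    ----------
    step : int
        Index of the first step whose state is non-finite.
    """

    def __init__(self, message: str, step: int):
        super().__init__(message)
        self.step = step


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DDMParameters:
    """Physiological constants of the source–sink model.

    Parameters
    ----------
    kappa : float
        Phloem conductance for a population of a single individual,
        cm^6 g^-1 h^-1.  A scaling factor tied to the organisation level.
    alpha : float
        Exponent of the conductance–population-size relationship,
        dimensionless.  ``alpha = 1`` makes conductance proportional to
        population size (no density dependence); ``alpha = 0`` makes it
        independent of it.
    Vm : float
        Maximal unloading rate per unit sink dry mass,
        g sugar (g DM)^-1 h^-1.  High ``Vm`` means strong potential demand.
    Km : float
        Michaelis constant of unloading, g cm^-3.  Low ``Km`` means carriers
        saturate even at low sink phloem concentration.
    r : float
        Fraction of unloaded sugar respired rather than incorporated,
        dimensionless.  Default 0.16.
    DMC : float
        Dry matter content of sink tissue (dry mass / fresh mass),
        dimensionless.  Default 0.16, inside the observed 0.06–0.24 range.
    """

    kappa: float
    alpha: float
    Vm: float
    Km: float
    r: float = 0.16
    DMC: float = 0.16

    def __post_init__(self):
        if not (self.kappa > 0):
            raise InvalidParameterError(f"kappa must be > 0, got {self.kappa}")
        if not (self.alpha >= 0):
            raise InvalidParameterError(f"alpha must be >= 0, got {self.alpha}")
        if not (self.Vm > 0):
            raise InvalidParameterError(f"Vm must be > 0, got {self.Vm}")
        if not (self.Km > 0):
            raise InvalidParameterError(f"Km must be > 0, got {self.Km}")
        if not (0 <= self.r < 1):
            raise InvalidParameterError(f"r must be in [0, 1), got {self.r}")
        if not (0 < self.DMC <= 1):
            raise InvalidParameterError(f"DMC must be in (0, 1], got {self.DMC}")


@dataclass(frozen=True)
class SourceModel:
    """Source phloem sugar concentration, constant or declining with density.

    ``constant`` mode returns ``C0`` for every population size (the sub-plant
    default, 0.1 g cm^-3).  ``logistic`` mode models competition for light
    among plants: ``C(n) = C0 / (1 + exp(b*(n - d)))``, which equals ``C0/2``
    at ``n = d`` (the density at the maximal rate of decrease) and stays in
    (0, C0).
    """

    mode: str = "constant"
    C0: float = 0.1
    b: float = 0.0
    d: float = 0.0

    def __post_init__(self):
        if self.mode not in ("constant", "logistic"):
            raise InvalidParameterError(f"unknown source mode {self.mode!r}")
        if not (self.C0 > 0):
            raise InvalidParameterError(f"C0 must be > 0, got {self.C0}")

    def concentration(self, n: float) -> float:
        return source_concentration(self, n)


@dataclass(frozen=True)
class SimulationConfig:
    """Scenario settings for one growth simulation.

    ``n`` is accepted as a positive real, not an integer: observed population
    sizes are often means (e.g. 5.7e6 cells) and the model is continuous in
    ``n``.  ``t0`` is the hour at which population size becomes fixed (end of
    cell division / thinning); it only offsets the time axis.  ``duration``
    must be a whole number of steps of length ``dt`` (default 1 h).
    """

    n: float
    s0: float
    duration: float
    t0: float = 0.0
    dt: float = 1.0

    def __post_init__(self):
        if not (self.n >= 1):
            raise InvalidParameterError(f"n must be >= 1, got {self.n}")
        if not (self.s0 > 0):
            raise InvalidParameterError(f"s0 must be > 0, got {self.s0}")
        if not (self.duration > 0):
            raise InvalidParameterError(f"duration must be > 0, got {self.duration}")
        if not (self.dt > 0):
            raise InvalidParameterError(f"dt must be > 0, got {self.dt}")
        steps = self.duration / self.dt
        if abs(steps - round(steps)) > 1e-9 * max(1.0, steps):
            raise InvalidParameterError(
                f"duration {self.duration} is not a whole number of steps of dt={self.dt}"
            )

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def with_n(self, n: float) -> "SimulationConfig":
        return replace(self, n=n)


@dataclass
class GrowthTrajectory:
    """Hourly state series of one simulated population.

    Arrays all have length ``n_steps + 1`` and share the time grid ``times``
    (hours, starting at ``t0``).  ``M = s / DMC`` and ``TM = n * M`` hold
    element-wise by construction.
    """

    times: np.ndarray
    s: np.ndarray
    Cf: np.ndarray
    U: np.ndarray
    M: np.ndarray
    TM: np.ndarray
    n: float
    dt: float
    r: float
    DMC: float
    C: float = field(default=np.nan)

    @property
    def final_dry_mass(self) -> float:
        return float(self.s[-1])

    @property
    def final_fresh_mass(self) -> float:
        return float(self.M[-1])

    def mass_balance_gap(self) -> float:
        """Growth minus same-order accumulated unloading; 0.0 bit-exactly.

        Recomputes ``s_end - s0`` by accumulating ``dt*(1-r)*U/n`` in the
        integration order, so the comparison is exact in floating point, not
        merely close.
        """
        acc = self.s[0]
        dt, r, n = self.dt, self.r, self.n
        for u in self.U[:-1]:
            acc = acc + dt * (1.0 - r) * u / n
        return float(self.s[-1] - acc)

    def total_unloaded(self) -> float:
        """Sum of U*dt over the integration steps, g of sugar."""
        acc = 0.0
        for u in self.U[:-1]:
            acc = acc + u * self.dt
        return acc


# ---------------------------------------------------------------------------
# Elementary model relations
# ---------------------------------------------------------------------------


def conductance(kappa: float, alpha: float, n: float) -> float:
    """Pathway conductance for a population of size n: ``kappa * n**alpha``."""
    if not (kappa > 0):
        raise InvalidParameterError(f"kappa must be > 0, got {kappa}")
    if not (n >= 1):
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    if not (alpha >= 0):
        raise InvalidParameterError(f"alpha must be >= 0, got {alpha}")
    if n > _LOG_SPACE_N:
        return kappa * math.exp(alpha * math.log(n))
    return kappa * n**alpha


def source_concentration(model: SourceModel, n: float) -> float:
    """Source phloem concentration for population size n, g cm^-3."""
    if not (n >= 1):
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    if model.mode == "constant":
        return model.C0
    # logistic decline with density; exp can overflow for extreme b*(n-d)
    z = model.b * (n - model.d)
    if z > 700.0:
        return model.C0 * math.exp(-z)  # underflow-safe tail, still > 0
    return model.C0 / (1.0 + math.exp(z))


def flow(C: float, Cf: float, k: float) -> float:
    """Münch flow from source to sink, g h^-1: ``k * C * (C - Cf)``."""
    return k * C * (C - Cf)


def unloading(n: float, s: float, Cf: float, Vm: float, Km: float) -> float:
    """Michaelis–Menten unloading of the whole population, g h^-1."""
    return n * s * Vm * Cf / (Km + Cf)


def sink_concentration(C: float, n: float, s: float, params: DDMParameters) -> float:
    """Sink phloem concentration balancing flow against unloading.

    Setting flow equal to unloading gives the quadratic

        A*Cf**2 + (A*(Km - C) + n*s*Vm)*Cf - A*C*Km = 0,   A = kappa*n**alpha*C,

    whose unique positive root is returned.  The root is computed with the
    cancellation-stable q-formula: with demand ``n*s*Vm`` up to ~15 orders of
    magnitude larger than supply ``A*C``, the textbook formula subtracts
    nearly equal terms and loses every significant digit.
    """
    if not (C > 0):
        raise InvalidParameterError(f"C must be > 0, got {C}")
    if not (s > 0):
        raise InvalidParameterError(f"s must be > 0, got {s}")
    k = conductance(params.kappa, params.alpha, n)
    A = k * C
    if A == 0.0:
        raise InvalidParameterError("degenerate quadratic: kappa*C underflowed to 0")
    return _positive_root(A, C, n, s, params.Vm, params.Km)


@njit(cache=True)
def _positive_root(A: float, C: float, n: float, s: float, Vm: float, Km: float) -> float:
    b = A * (Km - C) + n * s * Vm
    c = -A * C * Km
    disc = math.sqrt(b * b - 4.0 * A * c)
    if b >= 0.0:
        q = -0.5 * (b + disc)
        return c / q
    q = -0.5 * (b - disc)
    return q / A


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


@njit(cache=True)
def _euler_kernel(
    n: float,
    s0: float,
    C: float,
    dt: float,
    steps: int,
    kappa: float,
    alpha: float,
    Vm: float,
    Km: float,
    r: float,
):
    """Forward-Euler march of individual dry mass; returns (s, Cf, U) series."""
    s = np.empty(steps + 1)
    Cf = np.empty(steps + 1)
    U = np.empty(steps + 1)
    if n > _LOG_SPACE_N:
        k = kappa * math.exp(alpha * math.log(n))
    else:
        k = kappa * n**alpha
    A = k * C
    si = s0
    for i in range(steps + 1):
        cf = _positive_root(A, C, n, si, Vm, Km)
        u = n * si * Vm * cf / (Km + cf)
        s[i] = si
        Cf[i] = cf
        U[i] = u
        if i < steps:
            si = si + dt * (1.0 - r) * u / n
    return s, Cf, U


@njit(cache=True)
def _euler_sample_kernel(
    ns: np.ndarray,
    Cs: np.ndarray,
    s0: float,
    dt: float,
    steps: int,
    sample_idx: np.ndarray,
    kappa: float,
    alpha: float,
    Vm: float,
    Km: float,
    r: float,
):
    """Dry mass at selected step indices for a batch of population sizes.

    Same arithmetic, step by step, as `_euler_kernel`; only the bookkeeping
    differs (states are sampled at ``sample_idx`` instead of stored densely),
    so results agree bit-for-bit.  Used by the estimation hot path.
    """
    out = np.empty((ns.size, sample_idx.size))
    for i in range(ns.size):
        n = ns[i]
        C = Cs[i]
        if n > _LOG_SPACE_N:
            k = kappa * math.exp(alpha * math.log(n))
        else:
            k = kappa * n**alpha
        A = k * C
        si = s0
        j = 0
        for step in range(steps + 1):
            if j < sample_idx.size and sample_idx[j] == step:
                out[i, j] = si
                j += 1
            if j >= sample_idx.size:
                break
            if step < steps:
                cf = _positive_root(A, C, n, si, Vm, Km)
                u = n * si * Vm * cf / (Km + cf)
                si = si + dt * (1.0 - r) * u / n
    return out


def simulate_growth(
    params: DDMParameters, source: SourceModel, config: SimulationConfig
) -> GrowthTrajectory:
    """Integrate individual dry mass over the season at fixed population size.

    At every hourly step the sink phloem concentration is recomputed from the
    flow/unloading balance and the net assimilation ``(1-r)*U/n`` is added to
    the individual dry mass (explicit first-order scheme at ``dt`` = 1 h by
    default).  The source concentration depends on ``n`` (through the source
    model) but not on time.

    Raises
    ------
    IntegrationError
        If any state becomes non-finite; the exception carries the step index.
    """
    n = config.n
    C = source_concentration(source, n)
    if not (C > 0):
        raise InvalidParameterError(f"source concentration must be > 0, got {C}")
    steps = config.n_steps
    s, Cf, U = _euler_kernel(
        n, config.s0, C, config.dt, steps,
        params.kappa, params.alpha, params.Vm, params.Km, params.r,
    )
    finite = np.isfinite(s) & np.isfinite(Cf) & np.isfinite(U)
    if not finite.all():
        step = int(np.argmin(finite))
        raise IntegrationError(f"non-finite state at step {step}", step)
    times = config.t0 + config.dt * np.arange(steps + 1)
    M = s / params.DMC
    TM = n * M
    return GrowthTrajectory(
        times=times, s=s, Cf=Cf, U=U, M=M, TM=TM,
        n=n, dt=config.dt, r=params.r, DMC=params.DMC, C=C,
    )
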