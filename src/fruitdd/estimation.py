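"""Parameter estimation: SSE objective, real-coded GA, multi-restart fits.

The free parameters are (Vm, Km, kappa, alpha), plus (b, d) of the logistic
source when plant-level density feedback is fitted.  The objective is the sum
of squared errors between predicted and observed individual fresh masses —
either along the season (time-series designs) or at maturity across
population sizes (cross-section designs).  kappa, Vm and Km are searched in
log10 space (each spans three or more decades across organisation levels);
alpha, b and d are searched linearly.

The optimiser is a real-coded genetic algorithm (tournament selection, blend
crossover, per-gene Gaussian mutation, elitism), run at least 15 times from
independent seeds with the best-by-SSE solution retained.  Goodness of fit is
reported as the relative root-mean-square error

    RRMSE = (1 / X_bar) * sqrt( sum_i (Y_i - X_i)^2 / nb )

with X the observations, Y the predictions and X_bar the observed mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    DDMParameters,
    IntegrationError,
    InvalidParameterError,
    SimulationConfig,
    SourceModel,
    source_concentration,
    _euler_sample_kernel,
)

__all__ = [
    "ObservationSet",
    "FitResult",
    "GASettings",
    "DEFAULT_BOUNDS",
    "LOG_SCALE_PARAMS",
    "rrmse",
    "predict_masses",
    "sse_objective",
    "fit_ga",
    "multi_start_fit",
]

# Default search boxes mirror the ranges estimated across all organisation
# levels: alpha in [1e-4, 1], kappa 1e-7..1e4 cm^6 g^-1 h^-1, Vm 1e-5..1e-2
# h^-1, Km 1e-6..0.1 g cm^-3.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (1e-4, 1.0),
    "kappa": (1e-7, 1e4),
    "Vm": (1e-5, 1e-2),
    "Km": (1e-6, 0.1),
}
LOG_SCALE_PARAMS = frozenset({"kappa", "Vm", "Km"})

# Finite penalty returned when a candidate makes the integration blow up;
# dominates any plausible SSE without poisoning the GA with infinities.
INTEGRATION_PENALTY = 1e12

VALID_LEVELS = ("cell", "seed", "fruit_in_cluster", "fruit_in_plant", "plant")


@dataclass
class ObservationSet:
    """Observed masses for one dataset, plus the scenario constants.

    ``data`` holds one row per observation with columns ``n``, ``time_h``
    (NaN for maturity designs), ``individual_mass_g`` and optionally
    ``population_mass_g``.  Scenario constants that are measured rather than
    fitted (``s0``, ``t0``, ``DMC``, ``duration``) ride along as metadata.
    """

    design: str
    data: pd.DataFrame
    level: str
    species: str
    s0: float
    t0: float
    DMC: float
    duration: float
    dt: float = 1.0
    dataset_id: str = ""

    def __post_init__(self):
        if self.design not in ("time_series", "maturity_cross_section"):
            raise InvalidParameterError(f"unknown design {self.design!r}")
        if self.level not in VALID_LEVELS:
            raise InvalidParameterError(f"unknown level {self.level!r}")
        required = {"n", "individual_mass_g"}
        missing = required - set(self.data.columns)
        if missing:
            raise InvalidParameterError(f"observation table missing columns {sorted(missing)}")
        if "time_h" not in self.data.columns:
            self.data = self.data.assign(time_h=np.nan)
        if "population_mass_g" not in self.data.columns:
            self.data = self.data.assign(population_mass_g=np.nan)
        if not (self.data["individual_mass_g"] > 0).all():
            raise InvalidParameterError("all individual masses must be positive")
        pop = self.data["population_mass_g"].dropna()
        if not (pop > 0).all():
            raise InvalidParameterError("all population masses must be positive")
        if self.design == "maturity_cross_section":
            if self.data["n"].nunique() < 2:
                raise InvalidParameterError(
                    "maturity_cross_section needs at least 2 distinct population sizes"
                )
        else:
            t = self.data["time_h"]
            if t.isna().any():
                raise InvalidParameterError("time_series design requires time_h on every row")
            if ((t < self.t0 - 1e-9) | (t > self.t0 + self.duration + 1e-9)).any():
                raise InvalidParameterError("observation times outside [t0, t0+duration]")

    @property
    def n_values(self) -> np.ndarray:
        return np.sort(self.data["n"].unique())

    def config_for(self, n: float) -> SimulationConfig:
        return SimulationConfig(n=n, s0=self.s0, duration=self.duration, t0=self.t0, dt=self.dt)


@dataclass
class FitResult:
    """One GA solution: fitted parameters and its quality/provenance."""

    params: dict[str, float]
    sse: float
    rrmse: float
    seed: int
    restart_index: int
    n_evaluations: int
    best_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        return {
            "params": dict(self.params),
            "sse": self.sse,
            "rrmse": self.rrmse,
            "seed": int(self.seed),
            "restart_index": int(self.restart_index),
            "n_evaluations": int(self.n_evaluations),
        }


def rrmse(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Relative RMSE: RMSE of (predicted - observed) over the observed mean."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or observed.size == 0:
        raise InvalidParameterError("predicted and observed must have equal nonzero length")
    xbar = observed.mean()
    if xbar <= 0:
        raise InvalidParameterError("observed mean must be positive")
    return float(np.sqrt(np.mean((predicted - observed) ** 2)) / xbar)


def _source_from_theta(theta: Mapping[str, float], C0: float) -> SourceModel:
    if "b" in theta or "d" in theta:
        return SourceModel(mode="logistic", C0=C0, b=float(theta["b"]), d=float(theta["d"]))
    return SourceModel(mode="constant", C0=C0)


class _ObsCache:
    """Precomputed design arrays for fast repeated objective evaluation."""

    def __init__(self, obs: ObservationSet):
        n_col = obs.data["n"].to_numpy(dtype=float)
        self.unique_n, row_to_n = np.unique(n_col, return_inverse=True)
        self.row_to_n = row_to_n
        n_steps = int(round(obs.duration / obs.dt))
        if obs.design == "time_series":
            steps = np.rint((obs.data["time_h"].to_numpy() - obs.t0) / obs.dt).astype(np.int64)
            steps = np.clip(steps, 0, n_steps)
        else:
            steps = np.full(len(obs.data), n_steps, dtype=np.int64)
        self.sample_idx, row_to_step = np.unique(steps, return_inverse=True)
        self.row_to_step = row_to_step
        self.n_steps = n_steps
        self.obs_M = obs.data["individual_mass_g"].to_numpy(dtype=float)
        tm = obs.data["population_mass_g"].to_numpy(dtype=float)
        self.tm_mask = np.isfinite(tm)
        self.obs_TM = tm
        self.n_col = n_col


def _cache_for(obs: ObservationSet) -> _ObsCache:
    cache = getattr(obs, "_cache", None)
    if cache is None:
        cache = _ObsCache(obs)
        object.__setattr__(obs, "_cache", cache)
    return cache


def _predict_rows(
    theta: Mapping[str, float], obs: ObservationSet, C0: float, r: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-row predicted individual and population fresh masses, g."""
    cache = _cache_for(obs)
    source = _source_from_theta(theta, C0)
    Cs = np.array([source_concentration(source, n) for n in cache.unique_n])
    S = _euler_sample_kernel(
        cache.unique_n,
        Cs,
        obs.s0,
        obs.dt,
        cache.n_steps,
        cache.sample_idx,
        float(theta["kappa"]),
        float(theta["alpha"]),
        float(theta["Vm"]),
        float(theta["Km"]),
        r,
    )
    M = S / obs.DMC
    pred_M = M[cache.row_to_n, cache.row_to_step]
    pred_TM = cache.n_col * pred_M
    return pred_M, pred_TM


def predict_masses(
    theta: Mapping[str, float],
    obs: ObservationSet,
    C0: float = 0.1,
    r: float = 0.16,
) -> pd.DataFrame:
    """Model predictions aligned row-by-row with ``obs.data``.

    Simulates once per distinct population size; time-series rows are read
    off the trajectory at the nearest step, maturity rows at the final step.
    Returns a frame with ``individual_mass_g`` and ``population_mass_g``.
    """
    # parameter validation (and its error signals) come from the dataclass
    DDMParameters(
        kappa=float(theta["kappa"]),
        alpha=float(theta["alpha"]),
        Vm=float(theta["Vm"]),
        Km=float(theta["Km"]),
        r=r,
        DMC=obs.DMC,
    )
    pred_M, pred_TM = _predict_rows(theta, obs, C0, r)
    return pd.DataFrame(
        {"individual_mass_g": pred_M, "population_mass_g": pred_TM}, index=obs.data.index
    )


def sse_objective(
    theta: Mapping[str, float],
    obs: ObservationSet,
    C0: float = 0.1,
    r: float = 0.16,
    include_population: bool = True,
    population_weight: float = 1.0,
) -> float:
    """Sum of squared errors of individual fresh masses, g^2.

    Population-mass observations, when present, enter as residuals rescaled
    to the per-individual scale, ``(TM_pred - TM_obs)/n``, weighted by
    ``population_weight`` — so both mass columns contribute in comparable
    units.  Integration failures return a large finite penalty (1e12 g^2)
    rather than raising, so a stochastic search can continue.
    """
    try:
        pred_M, pred_TM = _predict_rows(theta, obs, C0, r)
    except (IntegrationError, InvalidParameterError, OverflowError, FloatingPointError):
        return INTEGRATION_PENALTY
    cache = _cache_for(obs)
    res = pred_M - cache.obs_M
    sse = float(np.dot(res, res))
    if include_population and cache.tm_mask.any():
        mask = cache.tm_mask
        res_tm = (pred_TM[mask] - cache.obs_TM[mask]) / cache.n_col[mask]
        sse += population_weight * float(np.dot(res_tm, res_tm))
    if not np.isfinite(sse):
        return INTEGRATION_PENALTY
    return sse


# ---------------------------------------------------------------------------
# Real-coded genetic algorithm
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GASettings:
    """Hyperparameters of the real-coded GA (small-dimension defaults)."""

    population_size: int = 50
    generations: int = 300
    mutation_prob: float = 0.05
    mutation_sigma: float = 0.1  # as a fraction of the search-space width
    elitism: int = 2
    tournament_size: int = 2
    crossover_prob: float = 0.9
    blend_alpha: float = 0.5


def _validate_bounds(bounds: Mapping[str, tuple[float, float]]) -> list[str]:
    if not bounds:
        raise InvalidParameterError("empty parameter bounds")
    names = list(bounds)
    for name in names:
        lo, hi = bounds[name]
        if not (np.isfinite(lo) and np.isfinite(hi)) or not (lo < hi):
            raise InvalidParameterError(f"invalid bounds for {name}: ({lo}, {hi})")
        if name in LOG_SCALE_PARAMS and lo <= 0:
            raise InvalidParameterError(f"{name} is log-scaled and needs positive bounds")
    return names


def _encode_bounds(names, bounds):
    lo = np.array(
        [np.log10(bounds[p][0]) if p in LOG_SCALE_PARAMS else bounds[p][0] for p in names]
    )
    hi = np.array(
        [np.log10(bounds[p][1]) if p in LOG_SCALE_PARAMS else bounds[p][1] for p in names]
    )
    return lo, hi


def _decode(z: np.ndarray, names) -> dict[str, float]:
    return {
        p: float(10.0 ** z[i]) if p in LOG_SCALE_PARAMS else float(z[i])
        for i, p in enumerate(names)
    }


def fit_ga(
    obs: ObservationSet,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    settings: GASettings | None = None,
    seed: int = 0,
    restart_index: int = 0,
    **objective_kwargs,
) -> FitResult:
    """Minimise the SSE objective with a seeded real-coded GA.

    Each generation: the ``elitism`` best genomes survive unchanged, and the
    rest of the next population is produced by binary-tournament selection,
    blend (BLX-alpha) crossover, and per-gene Gaussian mutation with standard
    deviation ``mutation_sigma`` times the search-space width, clipped to the
    bounds.  Fully reproducible given ``seed``.
    """
    if bounds is None:
        bounds = DEFAULT_BOUNDS
    if settings is None:
        settings = GASettings()
    names = _validate_bounds(bounds)
    lo, hi = _encode_bounds(names, bounds)
    width = hi - lo
    rng = np.random.default_rng(seed)
    npop, dim = settings.population_size, len(names)

    pop = lo + rng.random((npop, dim)) * width
    n_evaluations = 0

    def evaluate(population: np.ndarray) -> np.ndarray:
        nonlocal n_evaluations
        n_evaluations += len(population)
        return np.array(
            [sse_objective(_decode(z, names), obs, **objective_kwargs) for z in population]
        )

    fitness = evaluate(pop)
    order = np.argsort(fitness, kind="stable")
    pop, fitness = pop[order], fitness[order]
    best_history = [fitness[0]]

    for _ in range(settings.generations):
        children = np.empty_like(pop)
        children[: settings.elitism] = pop[: settings.elitism]
        for i in range(settings.elitism, npop):
            p1 = _tournament(rng, fitness, settings.tournament_size)
            p2 = _tournament(rng, fitness, settings.tournament_size)
            child = pop[p1].copy()
            if rng.random() < settings.crossover_prob:
                a = settings.blend_alpha
                low = np.minimum(pop[p1], pop[p2])
                high = np.maximum(pop[p1], pop[p2])
                span = high - low
                child = rng.uniform(low - a * span, high + a * span)
            mutate = rng.random(dim) < settings.mutation_prob
            if mutate.any():
                child = child + mutate * rng.normal(0.0, settings.mutation_sigma * width)
            children[i] = np.clip(child, lo, hi)
        new_fitness = np.concatenate(
            [fitness[: settings.elitism], evaluate(children[settings.elitism :])]
        )
        order = np.argsort(new_fitness, kind="stable")
        pop, fitness = children[order], new_fitness[order]
        best_history.append(fitness[0])

    theta = _decode(pop[0], names)
    pred = predict_masses(theta, obs, **{
        k: v for k, v in objective_kwargs.items() if k in ("C0", "r")
    })
    fit_rrmse = rrmse(
        pred["individual_mass_g"].to_numpy(), obs.data["individual_mass_g"].to_numpy()
    )
    return FitResult(
        params=theta,
        sse=float(fitness[0]),
        rrmse=fit_rrmse,
        seed=int(seed),
        restart_index=int(restart_index),
        n_evaluations=n_evaluations,
        best_history=np.asarray(best_history),
    )


def _tournament(rng: np.random.Generator, fitness: np.ndarray, size: int) -> int:
    contenders = rng.integers(0, len(fitness), size=size)
    return int(contenders[np.argmin(fitness[contenders])])


def derive_restart_seeds(master_seed: int, n_restarts: int) -> np.ndarray:
    """Distinct per-restart seeds below 2^31, derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    seeds = ss.generate_state(n_restarts, dtype=np.uint64) % np.uint64(2**31)
    # generate_state collisions are vanishingly rare; resolve them anyway
    seen: set[int] = set()
    out = []
    for s in seeds.astype(int):
        while s in seen:
            s = (s + 1) % 2**31
        seen.add(s)
        out.append(s)
    return np.array(out, dtype=np.int64)


def multi_start_fit(
    obs: ObservationSet,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    settings: GASettings | None = None,
    n_restarts: int = 15,
    master_seed: int = 0,
    **objective_kwargs,
) -> tuple[list[FitResult], FitResult]:
    """Independent seeded GA runs; returns (all results, best by SSE)."""
    if n_restarts < 1:
        raise InvalidParameterError("n_restarts must be >= 1")
    seeds = derive_restart_seeds(master_seed, n_restarts)
    results = [
        fit_ga(
            obs,
            bounds=bounds,
            settings=settings,
            seed=int(seeds[i]),
            restart_index=i,
            **objective_kwargs,
        )
        for i in range(n_restarts)
    ]
    best = min(results, key=lambda fr: fr.sse)
    return results, best
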