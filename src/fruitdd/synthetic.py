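"""Synthetic observation sets mirroring the field data the analysis expects.

Real calibration data for this kind of study span five organisation levels —
cells within a fruit (10^6–10^8 individuals), seeds plus associated flesh
(1–10^3), fruits within a cluster (10^1–10^2), fruits within a plant
(10^2–10^4) and plants within an orchard plot (400–2000 trees/ha).  None of
the original tables are deposited, so this module generates structurally
faithful stand-ins: the growth model is simulated at documented "true"
parameters for each level and multiplicative lognormal noise (default CV
0.10 — masses are positive and errors scale with size) is applied to the
masses.  Every generated set carries an audit record of its truth and seed.

The twelve fixtures emulate the designs of the original datasets: tomato
pericarp-cell time series (three truss positions; two cultivars with
manipulated fruit load), peach mesocarp-cell maturity cross-sections at two
fruit loads, seed cross-sections (apple, sarsaparilla), cluster
cross-sections (grape; dogwood generated at alpha = 1, hence
density-independent), fruit-per-plant cross-sections (peach, apple) and a
peach orchard plant-density cross-section with a logistic source decline.
All fixture truths are synthetic choices inside the per-level fitted
parameter ranges, not published estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .estimation import ObservationSet
from .model import (
    DDMParameters,
    InvalidParameterError,
    SimulationConfig,
    SourceModel,
    simulate_growth,
)

__all__ = [
    "LevelPreset",
    "NoiseModel",
    "LEVEL_PRESETS",
    "FIXTURE_DEFS",
    "generate_observations",
    "make_fixture_suite",
]


@dataclass(frozen=True)
class LevelPreset:
    """Typical scales of one organisation level (used as generator defaults)."""

    level: str
    n_range: tuple[float, float]
    s0: float  # g dry mass at t0
    DMC: float
    design: str
    duration: float  # h
    t0: float = 0.0


# Population-size ranges follow the printed field ranges: apple fruits hold
# 30e6-120e6 cells, kiwifruit 100-1400 seeds, St. Lucie's cherry bears
# 700-30000 fruits per plant, peach orchards run 400-2000 trees/ha.
LEVEL_PRESETS: dict[str, LevelPreset] = {
    "cell": LevelPreset("cell", (5e6, 120e6), 3e-8, 0.10, "time_series", 960.0, 240.0),
    "seed": LevelPreset("seed", (1.0, 1400.0), 0.08, 0.15, "maturity_cross_section", 3000.0),
    "fruit_in_cluster": LevelPreset(
        "fruit_in_cluster", (10.0, 200.0), 0.02, 0.20, "maturity_cross_section", 1800.0
    ),
    "fruit_in_plant": LevelPreset(
        "fruit_in_plant", (100.0, 30000.0), 0.4, 0.13, "maturity_cross_section", 2400.0
    ),
    "plant": LevelPreset("plant", (400.0, 2000.0), 300.0, 0.13, "maturity_cross_section", 2400.0),
}


@dataclass(frozen=True)
class NoiseModel:
    """Observation noise: none, or multiplicative lognormal with given CV."""

    kind: str = "lognormal_multiplicative"
    cv: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("none", "lognormal_multiplicative"):
            raise InvalidParameterError(f"unknown noise kind {self.kind!r}")
        if self.cv < 0:
            raise InvalidParameterError(f"cv must be >= 0, got {self.cv}")

    def apply(self, masses: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none" or self.cv == 0.0:
            return np.asarray(masses, dtype=float).copy()
        sigma = math.sqrt(math.log1p(self.cv**2))
        mu = -0.5 * sigma**2  # unit-mean multiplier
        factors = rng.lognormal(mean=mu, sigma=sigma, size=np.shape(masses))
        return np.asarray(masses, dtype=float) * factors


def generate_observations(
    true_params: DDMParameters,
    source: SourceModel,
    level: str,
    n_values: Sequence[float],
    noise: NoiseModel | None = None,
    design: str | None = None,
    obs_times: Sequence[float] | None = None,
    s0: float | None = None,
    t0: float | None = None,
    DMC: float | None = None,
    duration: float | None = None,
    include_population: bool = True,
    species: str = "synthetic",
    dataset_id: str = "synthetic",
) -> tuple[ObservationSet, dict]:
    """Simulate the model on a design and wrap the (noisy) masses as data.

    Scenario constants default to the level preset; ``obs_times`` (absolute
    hours) are required for time-series designs.  Returns the observation set
    together with an audit record of the generating truth and seed.
    """
    preset = LEVEL_PRESETS[level]
    design = design or preset.design
    s0 = preset.s0 if s0 is None else s0
    t0 = preset.t0 if t0 is None else t0
    DMC = preset.DMC if DMC is None else DMC
    duration = preset.duration if duration is None else duration
    noise = noise or NoiseModel(kind="none", cv=0.0)
    if design == "time_series" and obs_times is None:
        raise InvalidParameterError("time_series design requires obs_times")
    params = DDMParameters(
        kappa=true_params.kappa,
        alpha=true_params.alpha,
        Vm=true_params.Vm,
        Km=true_params.Km,
        r=true_params.r,
        DMC=DMC,
    )
    rng = np.random.default_rng(noise.seed)
    rows = []
    for n in n_values:
        traj = simulate_growth(
            params, source, SimulationConfig(n=float(n), s0=s0, duration=duration, t0=t0)
        )
        if design == "time_series":
            steps = np.rint((np.asarray(obs_times) - t0) / 1.0).astype(int)
            for t_abs, step in zip(obs_times, steps):
                rows.append((float(n), float(t_abs), traj.M[step], traj.TM[step]))
        else:
            rows.append((float(n), np.nan, traj.M[-1], traj.TM[-1]))
    frame = pd.DataFrame(rows, columns=["n", "time_h", "individual_mass_g", "population_mass_g"])
    frame["individual_mass_g"] = noise.apply(frame["individual_mass_g"].to_numpy(), rng)
    if include_population:
        frame["population_mass_g"] = noise.apply(frame["population_mass_g"].to_numpy(), rng)
    else:
        frame["population_mass_g"] = np.nan
    obs = ObservationSet(
        design=design,
        data=frame,
        level=level,
        species=species,
        s0=s0,
        t0=t0,
        DMC=DMC,
        duration=duration,
        dataset_id=dataset_id,
    )
    truth = {
        "dataset_id": dataset_id,
        "level": level,
        "species": species,
        "design": design,
        "params": {
            "kappa": params.kappa,
            "alpha": params.alpha,
            "Vm": params.Vm,
            "Km": params.Km,
            "r": params.r,
            "DMC": params.DMC,
        },
        "source": asdict(source),
        "scenario": {"s0": s0, "t0": t0, "duration": duration, "DMC": DMC},
        "n_values": [float(n) for n in n_values],
        "noise": asdict(noise),
    }
    return obs, truth


def _ts_times(t0: float, duration: float, k: int = 10) -> list[float]:
    step = duration / k
    return [t0 + step * i for i in range(1, k + 1)]


# Twelve synthetic dataset definitions.  Truth parameters sit inside the
# per-level fitted ranges; scenario constants are plausible field values
# (documented synthetic stand-ins, not measurements).
FIXTURE_DEFS: list[dict] = [
    dict(
        dataset_id="tomato_raissa_cells",
        level="cell",
        species="tomato cv. Raissa",
        design="time_series",
        n_values=[5.7e6, 6.4e6, 7.2e6],
        s0=2.5e-8,
        t0=240.0,
        DMC=0.07,
        duration=960.0,
        truth=dict(kappa=8e-5, alpha=0.65, Vm=5e-3, Km=0.02),
        source=dict(mode="constant", C0=0.1),
    ),
    dict(
        dataset_id="tomato_cervil_cells",
        level="cell",
        species="tomato cv. Cervil",
        design="time_series",
        n_values=[8e6, 3e7],
        s0=1.5e-8,
        t0=240.0,
        DMC=0.10,
        duration=960.0,
        truth=dict(kappa=6e-5, alpha=0.68, Vm=6e-3, Km=0.03),
        source=dict(mode="constant", C0=0.1),
    ),
    dict(
        dataset_id="tomato_levovil_cells",
        level="cell",
        species="tomato cv. Levovil",
        design="time_series",
        n_values=[1.7e7, 4.3e7],
        s0=3e-8,
        t0=240.0,
        DMC=0.06,
        duration=1104.0,
        truth=dict(kappa=1.2e-4, alpha=0.66, Vm=5e-3, Km=0.02),
        source=dict(mode="constant", C0=0.1),
    ),
    dict(
        dataset_id="peach_cells_load1",
        level="cell",
        species="peach cv. Alexandra, 1 fruit/shoot",
        design="maturity_cross_section",
        n_values=[3.0e7, 3.6e7, 4.2e7, 4.8e7, 5.4e7, 6.0e7],
        s0=1e-8,
        t0=0.0,
        DMC=0.12,
        duration=2400.0,
        truth=dict(kappa=3e-5, alpha=0.70, Vm=3e-3, Km=0.01),
        source=dict(mode="constant", C0=0.1),
    ),
    dict(
        dataset_id="peach_cells_load6",
        level="cell",
        species="peach cv. Alexandra, 6 fruits/shoot",
        design="maturity_cross_section",
        n_values=[4.0e7, 5.0e7, 6.0e7, 7.0e7, 8.0e7, 9.0e7],
        s0=1e-8,
        t0=0.0,
        DMC=0.12,
        duration=2400.0,
        truth=dict(kappa=8e-6, alpha=0.65, Vm=3e-3, Km=0.02),
        source=dict(mode="constant", C0=0.1),
    ),
    dict(
        dataset_id="apple_seeds",
        level="seed",
        species="apple cv. Royal Gala",
        design="maturity_cross_section",
        n_values=[2.0, 4.0, 6.0, 8.0, 10.0, 12.0],
        s0=0.08,
        t0=0.0,
        DMC=0.15,
        duration=3000.0,
        truth=dict(kappa=1.5, alpha=0.01, Vm=7e-3, Km=5e-4),
        source=dict(mode="constant", C0=0.1),
    ),
    dict(
        dataset_id="sarsaparilla_seeds",
        level="seed",
        species="sarsaparilla",
        design="maturity_cross_section",
        n_values=[1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        s0=1.5e-3,
        t0=0.0,
        DMC=0.20,
        duration=2400.0,
        truth=dict(kappa=0.012, alpha=0.05, Vm=8e-3, Km=1e-3),
        source=dict(mode="constant", C0=0.1),
    ),
    dict(
        dataset_id="grape_cluster",
        level="fruit_in_cluster",
        species="grape cv. Muscat",
        design="maturity_cross_section",
        n_values=[40.0, 70.0, 100.0, 130.0, 160.0, 200.0],
        s0=0.02,
        t0=0.0,
        DMC=0.20,
        duration=1800.0,
        truth=dict(kappa=0.2, alpha=0.85, Vm=2e-3, Km=5e-3),
        source=dict(mode="constant", C0=0.1),
    ),
    dict(
        dataset_id="dogwood_cluster",
        level="fruit_in_cluster",
        species="common dogwood",
        design="maturity_cross_section",
        n_values=[10.0, 15.0, 20.0, 25.0, 30.0, 40.0],
        s0=3e-3,
        t0=0.0,
        DMC=0.20,
        duration=1500.0,
        truth=dict(kappa=0.02, alpha=1.0, Vm=2e-3, Km=5e-3),
        source=dict(mode="constant", C0=0.1),
    ),
    dict(
        dataset_id="peach_fruits_per_plant",
        level="fruit_in_plant",
        species="peach cv. Suncrest",
        design="maturity_cross_section",
        n_values=[100.0, 200.0, 350.0, 500.0, 750.0, 1000.0],
        s0=0.4,
        t0=0.0,
        DMC=0.13,
        duration=2400.0,
        truth=dict(kappa=10.0, alpha=0.75, Vm=1.5e-3, Km=0.01),
        source=dict(mode="constant", C0=0.1),
    ),
    dict(
        dataset_id="apple_fruits_per_plant",
        level="fruit_in_plant",
        species="apple cv. Summerred",
        design="maturity_cross_section",
        n_values=[200.0, 400.0, 700.0, 1100.0, 1600.0, 2200.0],
        s0=0.5,
        t0=0.0,
        DMC=0.15,
        duration=3000.0,
        truth=dict(kappa=8.0, alpha=0.80, Vm=1.2e-3, Km=0.01),
        source=dict(mode="constant", C0=0.1),
    ),
    dict(
        dataset_id="peach_orchard_plants",
        level="plant",
        species="peach cv. Yanco queen",
        design="maturity_cross_section",
        n_values=[400.0, 600.0, 800.0, 1000.0, 1200.0, 1400.0, 1600.0, 1800.0, 2000.0],
        s0=300.0,
        t0=0.0,
        DMC=0.13,
        duration=2400.0,
        truth=dict(kappa=1500.0, alpha=0.95, Vm=1.5e-3, Km=0.01),
        source=dict(mode="logistic", C0=0.1, b=0.004, d=1300.0),
    ),
]


def make_fixture_suite(
    master_seed: int, noise_cv: float = 0.10
) -> dict[str, tuple[ObservationSet, dict]]:
    """Generate the twelve-level fixture suite with per-fixture derived seeds.

    One master seed; fixture ``i`` uses the ``i``-th state of the master
    ``SeedSequence``, so fixtures are independent and the whole suite is
    reproducible.  ``noise_cv=0`` yields noiseless sets for round-trip tests.
    """
    ss = np.random.SeedSequence(master_seed)
    child_seeds = ss.generate_state(len(FIXTURE_DEFS), dtype=np.uint64) % np.uint64(2**31)
    suite: dict[str, tuple[ObservationSet, dict]] = {}
    for i, defn in enumerate(FIXTURE_DEFS):
        truth_params = DDMParameters(**defn["truth"], DMC=defn["DMC"])
        source = SourceModel(**defn["source"])
        kind = "none" if noise_cv == 0 else "lognormal_multiplicative"
        noise = NoiseModel(kind=kind, cv=noise_cv, seed=int(child_seeds[i]))
        obs_times = (
            _ts_times(defn["t0"], defn["duration"]) if defn["design"] == "time_series" else None
        )
        obs, truth = generate_observations(
            truth_params,
            source,
            level=defn["level"],
            n_values=defn["n_values"],
            noise=noise,
            design=defn["design"],
            obs_times=obs_times,
            s0=defn["s0"],
            t0=defn["t0"],
            DMC=defn["DMC"],
            duration=defn["duration"],
            species=defn["species"],
            dataset_id=defn["dataset_id"],
        )
        suite[defn["dataset_id"]] = (obs, truth)
    return suite
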