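"""Density-response curves, the density-dependence index, and compensation.

The density-dependence (DD) index quantifies how strongly individual mass at
maturity declines as population size grows from ``n_min`` to ``n_max``::

    DD = -[(M(n_min) - M(n_max)) / M_bar] * [n_bar / (n_min - n_max)]

with ``M_bar`` and ``n_bar`` means of the endpoints (the default here; grid
means are available as an option).  DD is positive when individual mass
decreases with density, and zero when mass is density-independent — which the
model guarantees at ``alpha = 1`` (sink phloem concentration then cancels
``n`` exactly) and approaches whenever ``Km`` is negligible against ``Cf``.

Compensation describes the population total: *under* if total mass still
rises with density, *exact* if it stays constant within a tolerance, *over*
if competition makes it fall.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    DDMParameters,
    InvalidParameterError,
    SimulationConfig,
    SourceModel,
    simulate_growth,
)

__all__ = [
    "DensityResponse",
    "REFERENCE_SCENARIO",
    "REFERENCE_PARAMS",
    "density_response",
    "dd_index",
    "classify_compensation",
    "dd_sensitivity_grid",
]

# Reference sensitivity scenario: populations of 1-20 individuals grown for
# 50 days (1200 h) from s0 = 3 g at C = 0.1 g cm^-3 and DMC = 0.16.
REFERENCE_SCENARIO = SimulationConfig(n=1.0, s0=3.0, duration=1200.0, t0=0.0, dt=1.0)
REFERENCE_N_GRID = np.arange(1.0, 21.0)
# Representative physiology for that scenario, inside the fitted ranges:
# moderate conductance, weakly size-dependent, intermediate sink demand.
REFERENCE_PARAMS = DDMParameters(kappa=0.5, alpha=0.2, Vm=2e-3, Km=0.01)


@dataclass
class DensityResponse:
    """Maturity masses across a population-size grid plus the DD summary."""

    n_grid: np.ndarray
    M_maturity: np.ndarray
    TM_maturity: np.ndarray
    dd_index: float
    compensation: str


def dd_index(
    M_min: float,
    M_max: float,
    n_min: float,
    n_max: float,
    mean: str = "endpoint",
    M_mean: float | None = None,
    n_mean: float | None = None,
) -> float:
    """Density-dependence index from the endpoint masses.

    ``mean='endpoint'`` (default) normalises by the endpoint means; callers
    holding a full grid may pass precomputed grid means via ``mean='grid'``
    with ``M_mean``/``n_mean``.
    """
    if n_min == n_max:
        raise InvalidParameterError("dd_index undefined for n_min == n_max")
    if n_min > n_max:
        raise InvalidParameterError("n_min must be < n_max")
    if not (M_min > 0 and M_max > 0):
        raise InvalidParameterError("masses must be positive")
    if mean == "endpoint":
        M_bar = 0.5 * (M_min + M_max)
        n_bar = 0.5 * (n_min + n_max)
    elif mean == "grid":
        if M_mean is None or n_mean is None:
            raise InvalidParameterError("grid means require M_mean and n_mean")
        M_bar, n_bar = M_mean, n_mean
    else:
        raise InvalidParameterError(f"unknown mean convention {mean!r}")
    return -((M_min - M_max) / M_bar) * (n_bar / (n_min - n_max))


def classify_compensation(TM_min: float, TM_max: float, rel_tol: float = 0.05) -> str:
    """Classify the population-mass response between two densities.

    under / exact / over as ``TM_max`` is above, within, or below the
    ``rel_tol`` band around ``TM_min``.
    """
    if not (TM_min > 0 and TM_max > 0):
        raise InvalidParameterError("masses must be positive")
    if not (0 < rel_tol < 1):
        raise InvalidParameterError(f"rel_tol must be in (0, 1), got {rel_tol}")
    if TM_max > TM_min * (1.0 + rel_tol):
        return "under"
    if TM_max < TM_min * (1.0 - rel_tol):
        return "over"
    return "exact"


def density_response(
    params: DDMParameters,
    source: SourceModel,
    base_config: SimulationConfig,
    n_grid: Sequence[float],
    rel_tol: float = 0.05,
    mean: str = "endpoint",
) -> DensityResponse:
    """Simulate maturity masses over a population-size grid.

    One growth simulation per grid point, identical ``s0``/``t0``/``duration``
    throughout; "maturity" is the state at the final integration step.
    Integration failures propagate with the offending ``n`` attached.
    """
    n_grid = np.asarray(n_grid, dtype=float)
    if n_grid.ndim != 1 or n_grid.size < 2:
        raise InvalidParameterError("n_grid must be 1-D with at least 2 sizes")
    if not np.all(np.diff(n_grid) > 0):
        raise InvalidParameterError("n_grid must be sorted strictly ascending")
    M = np.empty_like(n_grid)
    for i, n in enumerate(n_grid):
        try:
            traj = simulate_growth(params, source, base_config.with_n(n))
        except Exception as err:
            raise type(err)(f"{err} (at n={n})", *getattr(err, "args", [])[1:]) from err
        M[i] = traj.final_fresh_mass
    TM = n_grid * M
    if mean == "grid":
        dd = dd_index(
            M[0], M[-1], n_grid[0], n_grid[-1],
            mean="grid", M_mean=float(M.mean()), n_mean=float(n_grid.mean()),
        )
    else:
        dd = dd_index(M[0], M[-1], n_grid[0], n_grid[-1])
    comp = classify_compensation(TM[0], TM[-1], rel_tol)
    return DensityResponse(
        n_grid=n_grid, M_maturity=M, TM_maturity=TM, dd_index=dd, compensation=comp
    )


def dd_sensitivity_grid(
    alphas: Iterable[float],
    kappas: Iterable[float],
    Vms: Iterable[float],
    Kms: Iterable[float],
    config: SimulationConfig = REFERENCE_SCENARIO,
    n_min: float = 1.0,
    n_max: float = 20.0,
    C0: float = 0.1,
    DMC: float = 0.16,
    r: float = 0.16,
) -> pd.DataFrame:
    """DD index over a factorial grid of (alpha, kappa, Vm, Km).

    Only the endpoint populations ``n_min`` and ``n_max`` are simulated (the
    endpoint-mean DD index needs nothing else), so large factorial grids stay
    cheap.  Returns a tidy DataFrame with one row per parameter combination.
    """
    source = SourceModel(mode="constant", C0=C0)
    rows = []
    for alpha in alphas:
        for kappa in kappas:
            for Vm in Vms:
                for Km in Kms:
                    p = DDMParameters(kappa=kappa, alpha=alpha, Vm=Vm, Km=Km, r=r, DMC=DMC)
                    M_lo = simulate_growth(p, source, config.with_n(n_min)).final_fresh_mass
                    M_hi = simulate_growth(p, source, config.with_n(n_max)).final_fresh_mass
                    rows.append(
                        {
                            "alpha": alpha,
                            "kappa": kappa,
                            "Vm": Vm,
                            "Km": Km,
                            "M_nmin": M_lo,
                            "M_nmax": M_hi,
                            "dd": dd_index(M_lo, M_hi, n_min, n_max),
                        }
                    )
    return pd.DataFrame(rows)
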