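"""Reading and writing the tabular/JSON interchange formats.

Observation tables travel as UTF-8 CSV with a mandatory header and columns
``level, dataset_id, n, time_h, individual_mass_g, population_mass_g``
(``time_h`` blank for maturity designs, ``population_mass_g`` optional).
Scenario constants (design, species, s0, t0, DMC, duration) go in a JSON
sidecar or are passed explicitly.  Fit results are written as JSON (all
restarts plus the best) and as a flat CSV parameter table.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .estimation import FitResult, ObservationSet
from .model import InvalidParameterError

__all__ = [
    "read_observations",
    "write_observations",
    "read_observations_csv",
    "write_fit_results",
]

OBS_COLUMNS = ["level", "dataset_id", "n", "time_h", "individual_mass_g", "population_mass_g"]
_META_KEYS = ["design", "level", "species", "s0", "t0", "DMC", "duration", "dataset_id"]


def write_observations(obs: ObservationSet, csv_path, meta_path=None) -> None:
    """Write one observation set as CSV plus a JSON metadata sidecar."""
    csv_path = Path(csv_path)
    frame = obs.data.copy()
    frame.insert(0, "dataset_id", obs.dataset_id)
    frame.insert(0, "level", obs.level)
    frame[OBS_COLUMNS].to_csv(csv_path, index=False)
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".meta.json")
    meta = {k: getattr(obs, k) for k in _META_KEYS}
    meta_path.write_text(json.dumps(meta, indent=2) + "\n")


def read_observations_csv(csv_path) -> pd.DataFrame:
    """Read and schema-check the raw observation table.

    Raises with the missing column names, and names offending row numbers
    for non-positive masses.
    """
    frame = pd.read_csv(csv_path)
    missing = [c for c in ("level", "dataset_id", "n", "individual_mass_g") if c not in frame.columns]
    if missing:
        raise InvalidParameterError(f"observations file missing column(s): {', '.join(missing)}")
    bad = frame.index[~(frame["individual_mass_g"] > 0)].tolist()
    if bad:
        rows = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
        raise InvalidParameterError(f"non-positive individual_mass_g at row(s) {rows}")
    return frame


def read_observations(csv_path, meta_path=None, **meta_overrides) -> ObservationSet:
    """Load an observation set from CSV (+ JSON sidecar or explicit metadata)."""
    csv_path = Path(csv_path)
    frame = read_observations_csv(csv_path)
    meta: dict = {}
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".meta.json")
    if meta_path.exists():
        meta.update(json.loads(meta_path.read_text()))
    meta.update(meta_overrides)
    needed = {"design", "s0", "t0", "DMC", "duration"}
    missing = needed - set(meta)
    if missing:
        raise InvalidParameterError(
            f"observation metadata missing {sorted(missing)}; provide a sidecar or overrides"
        )
    keep = [c for c in ("n", "time_h", "individual_mass_g", "population_mass_g")
            if c in frame.columns]
    return ObservationSet(
        design=meta["design"],
        data=frame[keep].copy(),
        level=meta.get("level", frame["level"].iloc[0]),
        species=meta.get("species", ""),
        s0=float(meta["s0"]),
        t0=float(meta["t0"]),
        DMC=float(meta["DMC"]),
        duration=float(meta["duration"]),
        dataset_id=meta.get("dataset_id", str(frame["dataset_id"].iloc[0])),
    )


def write_fit_results(results: Sequence[FitResult], best: FitResult, json_path, csv_path) -> None:
    """Write all restarts + the best as JSON, and a flat CSV parameter table."""
    payload = {
        "restarts": [fr.to_dict() for fr in results],
        "best": best.to_dict(),
    }
    Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
    rows = []
    for fr in results:
        row = {"restart_index": fr.restart_index, "seed": fr.seed,
               "sse": fr.sse, "rrmse": fr.rrmse,
               "is_best": fr.restart_index == best.restart_index}
        row.update(fr.params)
        rows.append(row)
    pd.DataFrame(rows).to_csv(csv_path, index=False)
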