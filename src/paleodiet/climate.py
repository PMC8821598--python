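"""Gridded climate time-series container and long-CSV round trip.

Holds coarse general-circulation-model style output: four annual variables
(mean temperature °C, temperature seasonality sd°C×100, precipitation
mm/day, precipitation seasonality sd mm/day×100) on a regular lat/lon cell
grid at a uniform time step in calendar years BP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CLIMATE_VARIABLES", "ClimateFieldSet", "read_climate", "write_climate"]

CLIMATE_VARIABLES = ("temp", "temp_seasonality", "precip", "precip_seasonality")


@dataclass
class ClimateFieldSet:
    """Complete cell × step matrix for each climate variable.

    ``values[var]`` has shape (n_cells, n_steps); ``steps`` is a uniformly
    spaced grid of years BP (ascending).
    """

    cell_ids: np.ndarray        # (n_cells,)
    lats: np.ndarray            # (n_cells,)
    lons: np.ndarray            # (n_cells,)
    steps: np.ndarray           # (n_steps,) yBP ascending
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids)
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.steps = np.asarray(self.steps, dtype=float)
        n_cells, n_steps = len(self.cell_ids), len(self.steps)
        if n_cells == 0 or n_steps == 0:
            raise ValueError("climate grid must be non-empty")
        diffs = np.diff(self.steps)
        if n_steps > 1 and not np.allclose(diffs, diffs[0]):
            raise ValueError("steps must be uniformly spaced")
        for var in CLIMATE_VARIABLES:
            if var not in self.values:
                raise ValueError(f"missing climate variable {var!r}")
            arr = np.asarray(self.values[var], dtype=float)
            if arr.shape != (n_cells, n_steps):
                raise ValueError(
                    f"{var}: expected shape {(n_cells, n_steps)}, got {arr.shape}"
                )
            if np.any(~np.isfinite(arr)):
                raise ValueError(f"{var}: non-finite values")
            self.values[var] = arr

    @property
    def step_size(self) -> float:
        return float(self.steps[1] - self.steps[0]) if len(self.steps) > 1 else 0.0

    def nearest_cell(self, lat: float, lon: float) -> int:
        """Index of the nearest cell center (simple Euclidean in degrees).

        Raises if the point is outside the grid's bounding box padded by half
        a cell spacing.
        """
        d2 = (self.lats - lat) ** 2 + (self.lons - lon) ** 2
        idx = int(np.argmin(d2))
        pad_lat = _half_spacing(self.lats)
        pad_lon = _half_spacing(self.lons)
        if not (self.lats.min() - pad_lat <= lat <= self.lats.max() + pad_lat
                and self.lons.min() - pad_lon <= lon <= self.lons.max() + pad_lon):
            raise ValueError(
                f"({lat}, {lon}) outside climate grid bounds "
                f"lat [{self.lats.min()}, {self.lats.max()}], "
                f"lon [{self.lons.min()}, {self.lons.max()}]"
            )
        return idx

    def nearest_step(self, year: float) -> int:
        """Index of the nearest time step; ties go to the younger step."""
        pos = np.searchsorted(self.steps, year)
        if pos == 0:
            return 0
        if pos == len(self.steps):
            return len(self.steps) - 1
        lo, hi = self.steps[pos - 1], self.steps[pos]
        # steps ascend in yBP so the younger step is the smaller value
        return pos - 1 if (year - lo) <= (hi - year) else pos

    def at(self, lat: float, lon: float, year: float) -> dict[str, float]:
        ci = self.nearest_cell(lat, lon)
        si = self.nearest_step(year)
        return {v: float(self.values[v][ci, si]) for v in CLIMATE_VARIABLES}


def _half_spacing(coords: np.ndarray) -> float:
    uniq = np.unique(coords)
    if len(uniq) < 2:
        return 1.25  # half of a 2.5-degree cell
    return float(np.min(np.diff(uniq))) / 2.0


def write_climate(fields: ClimateFieldSet, path) -> None:
    """Write in long form: cell_id, lat, lon, year_bp, variable, value."""
    n_cells, n_steps = len(fields.cell_ids), len(fields.steps)
    frames = []
    for var in CLIMATE_VARIABLES:
        frames.append(pd.DataFrame({
            "cell_id": np.repeat(fields.cell_ids, n_steps),
            "lat": np.repeat(fields.lats, n_steps),
            "lon": np.repeat(fields.lons, n_steps),
            "year_bp": np.tile(fields.steps, n_cells),
            "variable": var,
            "value": fields.values[var].ravel(),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_climate(path) -> ClimateFieldSet:
    df = pd.read_csv(path)
    cells = (df[["cell_id", "lat", "lon"]].drop_duplicates()
             .sort_values("cell_id").reset_index(drop=True))
    steps = np.sort(df["year_bp"].unique())
    values = {}
    for var in CLIMATE_VARIABLES:
        sub = df[df["variable"] == var].pivot_table(
            index="cell_id", columns="year_bp", values="value")
        sub = sub.reindex(index=cells["cell_id"], columns=steps)
        values[var] = sub.to_numpy()
    return ClimateFieldSet(
        cell_ids=cells["cell_id"].to_numpy(),
        lats=cells["lat"].to_numpy(),
        lons=cells["lon"].to_numpy(),
        steps=steps.astype(float),
        values=values,
    )
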