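"""Gridded palaeoclimate container.

A :class:`ClimateCube` holds time slices (years BP, descending) of the five
niche covariates used throughout the package — leaf area index (``lai``),
temperature annual range (``bio07``, °C), mean temperature of the wettest
quarter (``bio08``, °C), mean temperature of the warmest quarter (``bio10``,
°C) and precipitation of the wettest quarter (``bio16``, mm) — together with
a static land mask, a per-cell per-slice biome identifier and a mapping from
biome identifiers to the three coarse biome classes (forest, savannah,
desert).

The cube is a thin wrapper around an :class:`xarray.Dataset` with dimensions
``(time, lat, lon)``; cell coordinates refer to cell centres and sea cells
are missing-valued (NaN) in every covariate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

#: Covariates every cube must carry, in canonical order.
COVARIATES = ("lai", "bio07", "bio08", "bio10", "bio16")

#: The three coarse biome classes, in the fixed tie-break order
#: (drier classes first).
BIOME_CLASSES = ("desert", "savannah", "forest")


class CubeError(ValueError):
    """Structural problem with a climate cube."""


@dataclass
class ClimateCube:
    """Gridded time series of niche covariates plus land mask and biomes.

    Parameters
    ----------
    data
        Dataset with dims ``(time, lat, lon)``; data variables are the five
        covariates (float, NaN over sea), ``biome_id`` (int, ``time, lat,
        lon``) and ``land_mask`` (bool/byte, ``lat, lon``). ``time`` is in
        years BP, strictly descending (oldest first).
    biome_class_map
        Mapping ``biome_id -> class`` with classes drawn from
        :data:`BIOME_CLASSES`. May be empty for cubes without biome labels.
    """

    data: xr.Dataset
    biome_class_map: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in COVARIATES:
            if name not in self.data:
                raise CubeError(f"cube is missing covariate {name!r}")
        if "land_mask" not in self.data:
            raise CubeError("cube is missing land_mask")
        t = self.times
        if len(t) > 1 and not np.all(np.diff(t) < 0):
            raise CubeError("time axis must be strictly descending (years BP)")
        for cls in self.biome_class_map.values():
            if cls not in BIOME_CLASSES:
                raise CubeError(f"unknown biome class {cls!r}")

    # -- axes ---------------------------------------------------------------

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.data["time"].values, dtype=float)

    @property
    def lons(self) -> np.ndarray:
        return np.asarray(self.data["lon"].values, dtype=float)

    @property
    def lats(self) -> np.ndarray:
        return np.asarray(self.data["lat"].values, dtype=float)

    @property
    def land_mask(self) -> np.ndarray:
        return np.asarray(self.data["land_mask"].values).astype(bool)

    @property
    def cell_size(self) -> float:
        lons = self.lons
        return float(lons[1] - lons[0]) if len(lons) > 1 else float(
            self.lats[1] - self.lats[0]
        )

    @property
    def n_land_cells(self) -> int:
        return int(self.land_mask.sum())

    # -- lookups ------------------------------------------------------------

    def nearest_slice(self, time_bp: float) -> tuple[int, float]:
        """Index and value of the slice nearest ``time_bp``.

        Ties (time exactly midway between two slices) break toward the more
        recent slice, i.e. the smaller years-BP value.
        """
        t = self.times
        dist = np.abs(t - float(time_bp))
        best = dist.min()
        candidates = np.flatnonzero(dist == best)
        # descending axis: the last candidate is the most recent
        idx = int(candidates[-1])
        return idx, float(t[idx])

    def cell_index(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the grid cell whose centre is nearest the point.

        Points must lie within half a cell of the grid extent.
        """
        lons, lats = self.lons, self.lats
        half = self.cell_size / 2.0
        if not (lons[0] - half <= lon <= lons[-1] + half):
            raise CubeError(f"longitude {lon} outside grid extent")
        if not (lats[0] - half <= lat <= lats[-1] + half):
            raise CubeError(f"latitude {lat} outside grid extent")
        col = int(np.argmin(np.abs(lons - lon)))
        row = int(np.argmin(np.abs(lats - lat)))
        return row, col

    def slice_frame(self, time_index: int, land_only: bool = True) -> pd.DataFrame:
        """Covariates of one slice as a tidy frame (one row per cell)."""
        ds = self.data.isel(time=time_index)
        lon2d, lat2d = np.meshgrid(self.lons, self.lats)
        rows, cols = np.meshgrid(
            np.arange(len(self.lats)), np.arange(len(self.lons)), indexing="ij"
        )
        out = {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "lon": lon2d.ravel(),
            "lat": lat2d.ravel(),
        }
        for name in COVARIATES:
            out[name] = np.asarray(ds[name].values, dtype=float).ravel()
        if "biome_id" in ds:
            out["biome_id"] = np.asarray(ds["biome_id"].values).ravel()
        frame = pd.DataFrame(out)
        frame["slice_time_bp"] = float(self.times[time_index])
        if land_only:
            frame = frame[self.land_mask.ravel()].reset_index(drop=True)
        return frame

    # -- I/O ----------------------------------------------------------------

    def to_netcdf(self, path) -> None:
        """Write the cube (NETCDF3 via the scipy backend)."""
        ds = self.data.copy()
        ds.attrs["biome_class_map"] = json.dumps(
            {str(k): v for k, v in self.biome_class_map.items()}
        )
        enc = {}
        if "land_mask" in ds:
            ds["land_mask"] = ds["land_mask"].astype(np.int8)
        if "biome_id" in ds:
            ds["biome_id"] = ds["biome_id"].astype(np.int32)
        ds.to_netcdf(path, engine="scipy", encoding=enc)

    @classmethod
    def from_netcdf(cls, path) -> "ClimateCube":
        ds = xr.load_dataset(path, engine="scipy")
        raw = ds.attrs.pop("biome_class_map", "{}")
        cmap = {int(k): v for k, v in json.loads(raw).items()}
        return cls(ds, cmap)


def write_biome_class_map(path, class_map: dict[int, str]) -> None:
    """Persist a biome-id-to-class map as a 2-column CSV."""
    pd.DataFrame(
        {"biome_id": list(class_map), "class": list(class_map.values())}
    ).to_csv(path, index=False)


def read_biome_class_map(path) -> dict[int, str]:
    df = pd.read_csv(path)
    missing = {"biome_id", "class"} - set(df.columns)
    if missing:
        raise CubeError(f"biome class map missing columns: {sorted(missing)}")
    return {int(r.biome_id): str(r["class"]) for _, r in df.iterrows()}
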