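"""Synthetic worlds: climate cubes, biome labels and dated occurrences.

This module generates inputs with the same statistical structure the
pipeline expects of real palaeoclimate reconstructions and radiometrically
dated archaeological occurrence databases, but with a *known* ground-truth
niche, so every downstream stage can be tested end to end.

Climate fields are low-order sinusoidal harmonics in space (so they carry
genuine spatial autocorrelation, which the residual diagnostics need) plus a
configurable linear temporal trend and white noise. Occurrences are drawn
per time slice with probability proportional to a Gaussian niche suitability
whose optima may drift linearly through time; reported ages receive Gaussian
dating error. Ground-truth columns (``true_*``) are carried alongside but
are never read by pipeline stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .cube import BIOME_CLASSES, COVARIATES, ClimateCube, CubeError


class SyntheticSpecError(ValueError):
    """Invalid synthetic world specification."""


@dataclass
class VariableParams:
    """Spatio-temporal behaviour of one covariate field.

    ``trend_amplitude`` is the total change of the slice mean over the full
    time range (units of the variable); ``spatial_amplitude`` scales the
    harmonic spatial pattern; ``noise_sd`` is i.i.d. per cell-slice noise.
    """

    mean: float
    spatial_amplitude: float = 1.0
    trend_amplitude: float = 0.0
    noise_sd: float = 0.0
    n_harmonics: int = 2


@dataclass
class NicheDimension:
    """Gaussian niche response along one covariate.

    Suitability along this axis is ``exp(-(x - opt(t))^2 / (2 tol^2))``
    where ``opt(t) = optimum + optimum_drift * progress(t)`` and progress
    runs 0 → 1 from the oldest to the youngest slice. A fixed niche has
    ``optimum_drift = 0``.
    """

    optimum: float
    tolerance: float
    optimum_drift: float = 0.0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise SyntheticSpecError("niche tolerance must be > 0")

    def optimum_at(self, progress: float) -> float:
        return self.optimum + self.optimum_drift * progress


@dataclass
class SyntheticWorldSpec:
    """Full description of a synthetic study system.

    Defaults follow the study design the pipeline targets: a 120 ka → 14 ka
    window in 2,000-year slices (54 slices), five covariates, and a mostly
    land grid with some sea.
    """

    lon_min: float = 0.0
    lon_max: float = 40.0
    lat_min: float = -20.0
    lat_max: float = 20.0
    cell_size: float = 2.0
    time_start: float = 120_000.0
    time_end: float = 14_000.0
    time_step: float = 2_000.0
    sea_fraction: float = 0.15
    variable_params: dict[str, VariableParams] = field(default_factory=dict)
    niche_spec: dict[str, NicheDimension] = field(default_factory=dict)
    n_occurrences_per_slice: int | list[int] = 6
    dating_error_sd: float = 1_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.time_start <= self.time_end:
            raise SyntheticSpecError(
                "time_start must be > time_end (years BP count down)"
            )
        if self.cell_size <= 0:
            raise SyntheticSpecError("cell_size must be > 0")
        if self.time_step <= 0:
            raise SyntheticSpecError("time_step must be > 0")
        if not self.variable_params:
            self.variable_params = default_variable_params()
        for name, vp in self.variable_params.items():
            if vp.noise_sd < 0:
                raise SyntheticSpecError(f"noise sd for {name} must be >= 0")
        if not self.niche_spec:
            self.niche_spec = default_niche_spec()

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.time_start, self.time_end - 1e-9, -self.time_step)

    @property
    def lons(self) -> np.ndarray:
        half = self.cell_size / 2
        return np.arange(self.lon_min + half, self.lon_max, self.cell_size)

    @property
    def lats(self) -> np.ndarray:
        half = self.cell_size / 2
        return np.arange(self.lat_min + half, self.lat_max, self.cell_size)


def default_variable_params() -> dict[str, VariableParams]:
    """Covariate fields on roughly realistic tropical-African scales."""
    return {
        "lai": VariableParams(mean=2.5, spatial_amplitude=1.5, noise_sd=0.1),
        "bio07": VariableParams(mean=18.0, spatial_amplitude=6.0, noise_sd=0.3),
        "bio08": VariableParams(mean=24.0, spatial_amplitude=4.0, noise_sd=0.3),
        "bio10": VariableParams(mean=28.0, spatial_amplitude=5.0, noise_sd=0.3),
        "bio16": VariableParams(mean=450.0, spatial_amplitude=300.0, noise_sd=15.0),
    }


def default_niche_spec(drift: float = 0.0) -> dict[str, NicheDimension]:
    """A fixed niche centred inside the default covariate ranges.

    ``drift`` shifts the bio10 optimum linearly across the time range; the
    default 0 gives a fixed niche, while e.g. ``drift=4.0`` (°C over the
    full window) gives a clearly changing niche.
    """
    return {
        "bio10": NicheDimension(optimum=28.0, tolerance=2.5, optimum_drift=drift),
        "bio16": NicheDimension(optimum=450.0, tolerance=200.0),
        "lai": NicheDimension(optimum=2.5, tolerance=1.2),
    }


# ---------------------------------------------------------------------------
# climate cube generation
# ---------------------------------------------------------------------------

def _harmonic_field(
    rng: np.random.Generator, xg: np.ndarray, yg: np.ndarray, n_harmonics: int
) -> np.ndarray:
    """Smooth random field from a few sinusoidal harmonics, sd ~ 1."""
    out = np.zeros_like(xg)
    for i in range(1, n_harmonics + 1):
        for j in range(1, n_harmonics + 1):
            amp = rng.normal(0.0, 1.0 / (i * j))
            phx, phy = rng.uniform(0, 2 * math.pi, size=2)
            out += amp * np.sin(2 * math.pi * i * xg + phx) * np.sin(
                2 * math.pi * j * yg + phy
            )
    sd = out.std()
    return out / sd if sd > 0 else out


def generate_climate_cube(spec: SyntheticWorldSpec) -> ClimateCube:
    """Build a deterministic synthetic climate cube from ``spec``.

    Each covariate is ``mean + spatial_amplitude * harmonics(lon, lat)
    + trend_amplitude * progress(t) + noise``; progress runs 0 at
    ``time_start`` to 1 at ``time_end``, so the slice-mean trend is exactly
    linear in elapsed time when noise is zero.
    """
    lons, lats, times = spec.lons, spec.lats, spec.times
    if len(lons) < 2 or len(lats) < 2 or len(times) < 2:
        raise SyntheticSpecError("grid or time axis degenerate (need >= 2 steps)")

    root = np.random.SeedSequence(spec.seed)
    keys = {}
    for name, child in zip(
        ["mask", *COVARIATES], root.spawn(1 + len(COVARIATES))
    ):
        keys[name] = np.random.default_rng(child)

    # normalized coordinates in [0, 1] for the harmonic basis
    xg, yg = np.meshgrid(
        (lons - lons[0]) / max(lons[-1] - lons[0], 1e-9),
        (lats - lats[0]) / max(lats[-1] - lats[0], 1e-9),
    )

    mask_field = _harmonic_field(keys["mask"], xg, yg, 3)
    cut = np.quantile(mask_field, spec.sea_fraction)
    land = mask_field >= cut
    if land.sum() < 16:
        raise SyntheticSpecError(
            f"only {int(land.sum())} land cells; need at least a 4x4-cell "
            "land area — enlarge the grid or lower sea_fraction"
        )

    progress = (spec.time_start - times) / (spec.time_start - spec.time_end)
    data_vars = {}
    for name in COVARIATES:
        vp = spec.variable_params[name]
        rng = keys[name]
        base = vp.mean + vp.spatial_amplitude * _harmonic_field(
            rng, xg, yg, vp.n_harmonics
        )
        arr = base[None, :, :] + vp.trend_amplitude * progress[:, None, None]
        if vp.noise_sd > 0:
            arr = arr + rng.normal(0.0, vp.noise_sd, size=arr.shape)
        else:
            arr = arr + np.zeros_like(arr)
        arr = np.where(land[None, :, :], arr, np.nan)
        data_vars[name] = (("time", "lat", "lon"), arr)

    data_vars["land_mask"] = (("lat", "lon"), land)
    ds = xr.Dataset(
        data_vars,
        coords={"time": times.astype(float), "lat": lats, "lon": lons},
    )
    return ClimateCube(ds)


# ---------------------------------------------------------------------------
# biome labelling
# ---------------------------------------------------------------------------

@dataclass
class ThresholdBiomeRules:
    """Exhaustive covariate-threshold mapping onto the 3 biome classes.

    The default mirrors a vegetation-density classification on leaf area
    index: dense canopy → forest, sparse vegetation → desert, everything in
    between → savannah.
    """

    variable: str = "lai"
    forest_min: float = 3.0
    desert_max: float = 0.5

    def __post_init__(self) -> None:
        if self.desert_max > self.forest_min:
            raise SyntheticSpecError(
                "rules not exhaustive: desert_max > forest_min leaves the "
                f"interval [{self.forest_min}, {self.desert_max}) doubly "
                "mapped and none uncovered — thresholds must satisfy "
                "desert_max <= forest_min"
            )

    def classify(self, values: np.ndarray) -> np.ndarray:
        """Class index per cell (0=desert, 1=savannah, 2=forest); NaN → -1."""
        out = np.full(values.shape, -1, dtype=np.int32)
        ok = np.isfinite(values)
        out[ok & (values >= self.forest_min)] = 2
        out[ok & (values < self.desert_max)] = 0
        out[ok & (values >= self.desert_max) & (values < self.forest_min)] = 1
        uncovered = ok & (out == -1)
        if uncovered.any():
            vals = np.unique(values[uncovered])[:5]
            raise SyntheticSpecError(
                f"biome rules leave covariate values uncovered: {vals}"
            )
        return out


def generate_biome_labels(
    cube: ClimateCube, rules: ThresholdBiomeRules | None = None
) -> ClimateCube:
    """Attach a ``biome_id`` layer and class map to ``cube`` (new object).

    Biome ids are 0/1/2 mapped to desert/savannah/forest; sea cells get -1
    and no class.
    """
    rules = rules or ThresholdBiomeRules()
    if rules.variable not in cube.data:
        raise CubeError(f"rules reference unknown covariate {rules.variable!r}")
    vals = np.asarray(cube.data[rules.variable].values, dtype=float)
    ids = rules.classify(vals)
    ids[:, ~cube.land_mask] = -1
    ds = cube.data.copy()
    ds["biome_id"] = (("time", "lat", "lon"), ids)
    class_map = {i: cls for i, cls in enumerate(BIOME_CLASSES)}
    return ClimateCube(ds, class_map)


# ---------------------------------------------------------------------------
# occurrence simulation
# ---------------------------------------------------------------------------

def niche_suitability(
    frame: pd.DataFrame, niche_spec: dict[str, NicheDimension], progress: float
) -> np.ndarray:
    """Gaussian product suitability for cells of one slice."""
    logsuit = np.zeros(len(frame))
    for var, dim in niche_spec.items():
        opt = dim.optimum_at(progress)
        z = (frame[var].to_numpy(dtype=float) - opt) / dim.tolerance
        logsuit -= 0.5 * z**2
    return np.exp(logsuit)


def simulate_occurrences(
    cube: ClimateCube,
    niche_spec: dict[str, NicheDimension] | None = None,
    n_per_slice: int | list[int] = 6,
    dating_error_sd: float = 1_000.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw dated occurrences from a known niche over the cube.

    For each slice, cells are drawn (with replacement) with probability
    proportional to suitability over land cells. The reported age is the
    true slice time plus Gaussian error of sd ``dating_error_sd``, truncated
    to the cube's time range; the reported half-range (``age_uncertainty``)
    is ``2 * dating_error_sd``, i.e. the generator reports its own error
    honestly on the plus/minus-as-2σ convention.

    The output uses the occurrence-database CSV schema plus ground-truth
    columns ``true_slice_time_bp``, ``true_row``, ``true_col`` that pipeline
    stages never read.
    """
    niche_spec = niche_spec or default_niche_spec()
    times = cube.times
    if np.isscalar(n_per_slice):
        n_per = [int(n_per_slice)] * len(times)
    else:
        n_per = list(n_per_slice)
        if len(n_per) != len(times):
            raise SyntheticSpecError(
                f"n_per_slice has {len(n_per)} entries for {len(times)} slices"
            )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    t_hi, t_lo = float(times[0]), float(times[-1])

    rows = []
    counter = 0
    for i, t in enumerate(times):
        n = n_per[i]
        if n == 0:
            continue
        frame = cube.slice_frame(i)
        progress = (t_hi - t) / (t_hi - t_lo)
        suit = niche_suitability(frame, niche_spec, progress)
        total = suit.sum()
        if total <= 0:
            raise SyntheticSpecError(
                f"suitability identically zero at slice {t} BP with {n} "
                "occurrences requested"
            )
        picks = rng.choice(len(frame), size=n, replace=True, p=suit / total)
        ages = t + rng.normal(0.0, dating_error_sd, size=n)
        ages = np.clip(ages, t_lo, t_hi)
        for j, cell in enumerate(picks):
            rec = frame.iloc[cell]
            counter += 1
            rows.append(
                {
                    "site_id": f"syn{counter:05d}",
                    "layer_id": "L1",
                    "lon": float(rec.lon),
                    "lat": float(rec.lat),
                    "method_class": "other_radiometric",
                    "age_mean": float(ages[j]),
                    "age_uncertainty": 2.0 * dating_error_sd,
                    "raw_14c_age": np.nan,
                    "raw_14c_error": np.nan,
                    "true_slice_time_bp": float(t),
                    "true_row": int(rec.row),
                    "true_col": int(rec.col),
                }
            )
    return pd.DataFrame(rows)


def generate_world(
    spec: SyntheticWorldSpec,
) -> tuple[ClimateCube, pd.DataFrame]:
    """Convenience: cube with biome labels plus an occurrence table."""
    cube = generate_biome_labels(generate_climate_cube(spec))
    occ = simulate_occurrences(
        cube,
        spec.niche_spec,
        spec.n_occurrences_per_slice,
        spec.dating_error_sd,
        seed=spec.seed + 1,
    )
    return cube, occ
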