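"""Ensembles, minimum-predicted-area zones, period aggregation and
niche-breadth series.

Accepted repeats (ΔAIC > 2 supporting the changing niche, Boyce index >
0.7) are averaged cell-wise into a mean or median ensemble. The ensemble is
binarized into nested zones by minimum-predicted-area (MPA) thresholds: the
smallest suitability cutoffs whose suprathreshold regions still contain
90% (core), 95% (peripheral) and 99% (total) of the occurrences, computed
with no rounding on the pooled occurrence set. Downstream series quantify,
per time slice and coarse biome class, the suitable (core + peripheral)
area in km² and the climatic niche breadth as the area of the 99% 2D kernel
of suitable cells in the space of the first two principal components of the
standardized covariates (PCA pooled over all land cells of all slices).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .climate import biome_class_grid
from .cube import BIOME_CLASSES, COVARIATES, ClimateCube

EARTH_RADIUS_KM = 6371.0

#: Marine-isotope-stage subdivision of the 120–14 ka window
#: (name, older bound, younger bound; years BP). Bounds follow benthic δ¹⁸O
#: peaks and lows; each slice t belongs to the period with
#: younger < t <= older (the oldest slice is included in the first period).
DEFAULT_MIS_PERIODS: tuple[tuple[str, float, float], ...] = (
    ("MIS 5e", 120_000, 116_000),
    ("MIS 5d", 116_000, 104_000),
    ("MIS 5c", 104_000, 94_000),
    ("MIS 5b", 94_000, 85_000),
    ("MIS 5a", 85_000, 71_000),
    ("early MIS 4", 71_000, 64_000),
    ("late MIS 4", 64_000, 57_000),
    ("early MIS 3", 57_000, 47_000),
    ("mid MIS 3", 47_000, 39_000),
    ("late MIS 3", 39_000, 29_000),
    ("early MIS 2", 29_000, 23_000),
    ("late MIS 2", 23_000, 14_000),
)


class GateError(ValueError):
    """No ensemble member passes the acceptance gates."""


class PeriodError(ValueError):
    pass


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsemblePrediction:
    method: str
    member_ids: list[int]
    suitability: xr.DataArray  # (time, lat, lon)
    gates: dict[str, float]
    member_boyce: dict[int, float] = field(default_factory=dict)

    @property
    def summary_boyce(self) -> float:
        vals = list(self.member_boyce.values())
        if not vals:
            return float("nan")
        return float(np.mean(vals) if self.method == "mean" else np.median(vals))


def build_ensemble(
    predictions: dict[int, xr.DataArray],
    delta_aic: dict[int, float],
    boyce: dict[int, float],
    method: str = "mean",
    daic_gate: float = 2.0,
    boyce_gate: float = 0.7,
    fixed_variant: bool = False,
) -> EnsemblePrediction:
    """Aggregate accepted member predictions cell-wise.

    The changing-niche ensemble keeps repeats with ``delta_aic > daic_gate``
    and ``boyce > boyce_gate``. The fixed-niche (null) variant uses the
    complementary gate ``delta_aic < daic_gate`` only, providing the
    climate-fluctuation-only baseline.
    """
    if method not in ("mean", "median"):
        raise ValueError(f"unknown ensemble method {method!r}")
    if fixed_variant:
        accepted = [r for r in predictions if delta_aic[r] < daic_gate]
    else:
        accepted = [
            r
            for r in predictions
            if delta_aic[r] > daic_gate and boyce.get(r, -np.inf) > boyce_gate
        ]
    if not accepted:
        n_daic = sum(1 for r in predictions if delta_aic[r] > daic_gate)
        n_boyce = sum(
            1 for r in predictions if boyce.get(r, -np.inf) > boyce_gate
        )
        raise GateError(
            f"zero accepted members out of {len(predictions)} "
            f"(delta_aic gate passes {n_daic}, boyce gate passes {n_boyce})"
        )
    stack = xr.concat([predictions[r] for r in accepted], dim="member")
    agg = stack.mean("member") if method == "mean" else stack.median("member")
    return EnsemblePrediction(
        method=method,
        member_ids=sorted(accepted),
        suitability=agg,
        gates={
            "daic_gate": daic_gate,
            "boyce_gate": boyce_gate,
            "fixed_variant": float(fixed_variant),
        },
        member_boyce={r: boyce[r] for r in accepted if r in boyce},
    )


# ---------------------------------------------------------------------------
# minimum predicted area
# ---------------------------------------------------------------------------

def mpa_threshold(values: np.ndarray, coverage: float) -> float:
    """Minimum-predicted-area threshold at the given occurrence coverage.

    The threshold is the k-th smallest suitability with
    ``k = n - ceil(coverage * n) + 1``: the fraction of values at or above
    it is at least ``coverage`` and no larger threshold achieves that. No
    rounding is applied to values or threshold.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n == 0:
        raise ValueError("empty suitability vector")
    if not (0 < coverage <= 1):
        raise ValueError(f"coverage must be in (0, 1], got {coverage}")
    k = n - math.ceil(coverage * n) + 1
    return float(v[k - 1])


#: Zone codes in the binarized cube.
ZONE_UNSUITABLE, ZONE_TOTAL, ZONE_PERIPHERAL, ZONE_CORE = 0, 1, 2, 3


@dataclass
class ZoneCube:
    zones: xr.DataArray  # int8 codes; -1 over sea
    thresholds: dict[str, float]  # t90 >= t95 >= t99

    def suitable_mask(self) -> xr.DataArray:
        """Core + peripheral cells — the 'suitable habitat' region."""
        return self.zones >= ZONE_PERIPHERAL


def extract_ensemble_at_occurrences(
    ensemble: EnsemblePrediction, presences: pd.DataFrame
) -> np.ndarray:
    """Ensemble suitability at each occurrence's cell and slice."""
    suit = ensemble.suitability
    times = np.asarray(suit["time"].values, dtype=float)
    out = np.empty(len(presences))
    rows = presences["cell_row"].to_numpy(dtype=int)
    cols = presences["cell_col"].to_numpy(dtype=int)
    ts = presences["slice_time_bp"].to_numpy(dtype=float)
    arr = np.asarray(suit.values)
    for i in range(len(presences)):
        ti = int(np.argmin(np.abs(times - ts[i])))
        out[i] = arr[ti, rows[i], cols[i]]
    return out


def binarize_zones(
    ensemble: EnsemblePrediction,
    occurrence_suitabilities: np.ndarray,
    coverages: tuple[float, float, float] = (0.90, 0.95, 0.99),
) -> ZoneCube:
    """Label every cell-slice with its nested suitability zone.

    Thresholds are computed once from the occurrence suitabilities pooled
    over all slices; a cell's zone is the highest whose threshold its
    suitability meets (core ⊆ peripheral ⊆ total by construction).
    """
    c_core, c_peri, c_total = sorted(coverages)
    t90 = mpa_threshold(occurrence_suitabilities, c_core)
    t95 = mpa_threshold(occurrence_suitabilities, c_peri)
    t99 = mpa_threshold(occurrence_suitabilities, c_total)
    suit = ensemble.suitability
    arr = np.asarray(suit.values)
    zones = np.full(arr.shape, -1, dtype=np.int8)
    landish = np.isfinite(arr)
    zones[landish] = ZONE_UNSUITABLE
    zones[landish & (arr >= t99)] = ZONE_TOTAL
    zones[landish & (arr >= t95)] = ZONE_PERIPHERAL
    zones[landish & (arr >= t90)] = ZONE_CORE
    return ZoneCube(
        zones=xr.DataArray(zones, coords=suit.coords, dims=suit.dims,
                           name="zone"),
        thresholds={"t90": t90, "t95": t95, "t99": t99},
    )


# ---------------------------------------------------------------------------
# period aggregation
# ---------------------------------------------------------------------------

def assign_periods(
    times: np.ndarray,
    periods: tuple[tuple[str, float, float], ...] = DEFAULT_MIS_PERIODS,
) -> list[str]:
    """Period label per slice; errors listing any orphan slices."""
    labels, orphans = [], []
    oldest = max(p[1] for p in periods)
    youngest = min(p[2] for p in periods)
    for t in np.asarray(times, dtype=float):
        hit = None
        for name, older, younger in periods:
            # half-open (younger, older] bins; both end slices included
            if (
                (younger < t <= older)
                or (t == oldest and older == oldest)
                or (t == youngest and younger == youngest)
            ):
                hit = name
                break
        if hit is None:
            orphans.append(t)
            labels.append("")
        else:
            labels.append(hit)
    if orphans:
        raise PeriodError(f"slices outside all periods: {orphans}")
    return labels


def aggregate_by_period(
    da: xr.DataArray,
    periods: tuple[tuple[str, float, float], ...] = DEFAULT_MIS_PERIODS,
) -> xr.DataArray:
    """Per-cell mean over the slices of each period (dim 'period')."""
    labels = assign_periods(np.asarray(da["time"].values, dtype=float), periods)
    order = [p[0] for p in periods if p[0] in set(labels)]
    grids = [
        da.isel(time=[i for i, l in enumerate(labels) if l == name]).mean("time")
        for name in order
    ]
    out = xr.concat(grids, dim="period")
    out = out.assign_coords(period=order)
    return out


def modal_biome_by_period(
    cube: ClimateCube,
    periods: tuple[tuple[str, float, float], ...] = DEFAULT_MIS_PERIODS,
) -> tuple[xr.DataArray, xr.DataArray]:
    """Most common biome class per cell per period.

    Ties break by the fixed class order desert < savannah < forest (the
    drier class wins); tied cells are flagged in the second return value.
    """
    labels = assign_periods(cube.times, periods)
    order = [p[0] for p in periods if p[0] in set(labels)]
    class_stack = np.stack(
        [biome_class_grid(cube, i) for i in range(len(cube.times))]
    )
    n_classes = len(BIOME_CLASSES)
    modal, ties = [], []
    for name in order:
        idx = [i for i, l in enumerate(labels) if l == name]
        sub = class_stack[idx]  # (slices, lat, lon)
        counts = np.stack(
            [(sub == c).sum(axis=0) for c in range(n_classes)]
        )  # (class, lat, lon)
        best = counts.max(axis=0)
        mode = np.argmax(counts, axis=0).astype(np.int8)  # first max = driest
        tie = (counts == best[None]).sum(axis=0) > 1
        mode[~cube.land_mask] = -1
        tie[~cube.land_mask] = False
        modal.append(mode)
        ties.append(tie)
    coords = {"period": order, "lat": cube.lats, "lon": cube.lons}
    dims = ("period", "lat", "lon")
    return (
        xr.DataArray(np.stack(modal), coords=coords, dims=dims, name="biome"),
        xr.DataArray(np.stack(ties), coords=coords, dims=dims, name="tie"),
    )


# ---------------------------------------------------------------------------
# area and niche-breadth series
# ---------------------------------------------------------------------------

def cell_area_grid(cube: ClimateCube, radius_km: float = EARTH_RADIUS_KM) -> np.ndarray:
    """km² per cell on the regular grid, cosine-latitude weighted."""
    step = math.radians(cube.cell_size)
    areas = (radius_km**2) * step * step * np.cos(np.radians(cube.lats))
    return np.broadcast_to(areas[:, None], cube.land_mask.shape).copy()


def biome_area_series(
    zones: ZoneCube, cube: ClimateCube, radius_km: float = EARTH_RADIUS_KM
) -> pd.DataFrame:
    """Suitable-habitat area per slice per biome class (km²)."""
    areas = cell_area_grid(cube, radius_km)
    suitable = np.asarray(zones.suitable_mask().values)
    rows = []
    for i, t in enumerate(cube.times):
        classes = biome_class_grid(cube, i)
        for c, cname in enumerate(BIOME_CLASSES):
            sel = suitable[i] & (classes == c)
            rows.append(
                {
                    "slice_time_bp": float(t),
                    "biome_class": cname,
                    "n_cells": int(sel.sum()),
                    "area_km2": float(areas[sel].sum()),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PCADefinition:
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray  # (5, 2), orthonormal columns
    explained_variance: np.ndarray

    def project(self, frame: pd.DataFrame) -> np.ndarray:
        x = frame[list(COVARIATES)].to_numpy(dtype=float)
        z = (x - self.means) / self.sds
        return z @ self.loadings


def fit_climate_pca(cube: ClimateCube) -> PCADefinition:
    """PCA of the standardized covariates over all land cells, all slices."""
    frames = [cube.slice_frame(i) for i in range(len(cube.times))]
    x = pd.concat(frames)[list(COVARIATES)].to_numpy(dtype=float)
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    if np.any(sds <= 0) or not np.all(np.isfinite(sds)):
        bad = [c for c, s in zip(COVARIATES, sds) if not (s > 0)]
        raise ValueError(f"degenerate covariates for PCA: {bad}")
    z = (x - means) / sds
    cov = np.cov(z, rowvar=False)
    cond = np.linalg.cond(cov)
    if cond > 1e10:
        raise ValueError(
            f"covariates nearly collinear (condition number {cond:.3g})"
        )
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return PCADefinition(
        means=means,
        sds=sds,
        loadings=evecs[:, order[:2]],
        explained_variance=evals[order],
    )


def kernel_area_2d(points: np.ndarray, coverage: float = 0.99,
                   grid_size: int = 256) -> float:
    """Area of the region enclosing ``coverage`` of a 2D kernel density.

    A Gaussian kernel with normal-reference (plug-in) bandwidth is fitted to
    the points; the density is thresholded at the ``1 - coverage`` quantile
    of its values at the data points and the suprathreshold area integrated
    on a ``grid_size``² grid padded by 3 bandwidths.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points for a 2D kernel")
    try:
        kde = stats.gaussian_kde(pts.T)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"degenerate point cloud for kernel: {exc}") from exc
    dens_at_points = kde(pts.T)
    level = np.quantile(dens_at_points, 1.0 - coverage)
    bw = np.sqrt(np.diag(kde.covariance))
    lo = pts.min(axis=0) - 3 * bw
    hi = pts.max(axis=0) + 3 * bw
    gx = np.linspace(lo[0], hi[0], grid_size)
    gy = np.linspace(lo[1], hi[1], grid_size)
    xx, yy = np.meshgrid(gx, gy)
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    cell = (gx[1] - gx[0]) * (gy[1] - gy[0])
    return float((dens >= level).sum() * cell)


def niche_kernel_area_series(
    cube: ClimateCube,
    zones: ZoneCube,
    pca: PCADefinition | None = None,
    coverage: float = 0.99,
) -> tuple[pd.DataFrame, PCADefinition]:
    """99% kernel area per slice per biome class in PC1–PC2 space.

    Class-slices with fewer than 3 suitable cells get area 0 with
    ``degenerate=True``.
    """
    pca = pca or fit_climate_pca(cube)
    suitable = np.asarray(zones.suitable_mask().values)
    rows = []
    for i, t in enumerate(cube.times):
        frame = cube.slice_frame(i)
        classes = biome_class_grid(cube, i)
        cls_flat = classes[frame["row"].to_numpy(), frame["col"].to_numpy()]
        suit_flat = suitable[i, frame["row"].to_numpy(), frame["col"].to_numpy()]
        pcs = pca.project(frame)
        for c, cname in enumerate(BIOME_CLASSES):
            sel = suit_flat & (cls_flat == c)
            n = int(sel.sum())
            if n < 3:
                rows.append(
                    {
                        "slice_time_bp": float(t),
                        "biome_class": cname,
                        "n_cells": n,
                        "kernel_area": 0.0,
                        "degenerate": True,
                    }
                )
                continue
            try:
                area = kernel_area_2d(pcs[sel], coverage=coverage)
                degenerate = False
            except ValueError:
                area, degenerate = 0.0, True
            rows.append(
                {
                    "slice_time_bp": float(t),
                    "biome_class": cname,
                    "n_cells": n,
                    "kernel_area": float(area),
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows), pca
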