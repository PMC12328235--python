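"""Covariate extraction, biome class lookup and the variable-selection screen."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cube import COVARIATES, ClimateCube, CubeError


@dataclass
class Extraction:
    """Covariates at one point-time, with the snapped slice time."""

    values: dict[str, float]
    slice_time_bp: float
    slice_index: int
    row: int
    col: int
    is_sea: bool


def extract_at(
    cube: ClimateCube, lon: float, lat: float, time_bp: float
) -> Extraction:
    """Covariates of the cell containing the point, at the nearest slice.

    Time snaps to the nearest slice; an exact midpoint snaps toward the more
    recent slice. A sea cell yields ``is_sea=True`` with NaN values — the
    caller decides whether to reassign or drop. The cube is never mutated.
    """
    idx, t = cube.nearest_slice(time_bp)
    row, col = cube.cell_index(lon, lat)
    if not cube.land_mask[row, col]:
        return Extraction(
            {name: float("nan") for name in COVARIATES}, t, idx, row, col, True
        )
    values = {
        name: float(cube.data[name].values[idx, row, col]) for name in COVARIATES
    }
    return Extraction(values, t, idx, row, col, False)


def nearest_land_cell(
    cube: ClimateCube, row: int, col: int
) -> tuple[int, int] | None:
    """Nearest land cell within one cell's distance (8-neighbourhood)."""
    best = None
    best_d = np.inf
    nrow, ncol = cube.land_mask.shape
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            r, c = row + dr, col + dc
            if 0 <= r < nrow and 0 <= c < ncol and cube.land_mask[r, c]:
                d = np.hypot(dr, dc)
                if d < best_d:
                    best, best_d = (r, c), d
    return best


def extract_for_occurrences(
    cube: ClimateCube, table: pd.DataFrame, time_column: str = "age_mean"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach covariates to each occurrence row.

    Occurrences falling on sea cells are reassigned to the nearest land cell
    within one cell's distance; otherwise they are excluded with a log
    entry. Returns (annotated table, exclusion log).
    """
    records, dropped = [], []
    for i in table.index:
        ext = extract_at(
            cube,
            float(table.at[i, "lon"]),
            float(table.at[i, "lat"]),
            float(table.at[i, time_column]),
        )
        row, col = ext.row, ext.col
        if ext.is_sea:
            near = nearest_land_cell(cube, row, col)
            if near is None:
                dropped.append((i, "sea cell with no land within one cell"))
                continue
            row, col = near
            ext = Extraction(
                {
                    name: float(cube.data[name].values[ext.slice_index, row, col])
                    for name in COVARIATES
                },
                ext.slice_time_bp,
                ext.slice_index,
                row,
                col,
                False,
            )
        rec = dict(table.loc[i])
        rec.update(ext.values)
        rec["slice_time_bp"] = ext.slice_time_bp
        rec["cell_row"], rec["cell_col"] = row, col
        records.append(rec)
    log = pd.DataFrame(dropped, columns=["row_index", "reason"])
    return pd.DataFrame(records).reset_index(drop=True), log


def biome_class_of(cube: ClimateCube, row: int, col: int, time_bp: float) -> str:
    """Coarse biome class (forest/savannah/desert) of a land cell."""
    if "biome_id" not in cube.data:
        raise CubeError("cube carries no biome_id layer")
    if not cube.land_mask[row, col]:
        raise CubeError(f"cell ({row}, {col}) is sea")
    idx, _ = cube.nearest_slice(time_bp)
    bid = int(cube.data["biome_id"].values[idx, row, col])
    if bid not in cube.biome_class_map:
        raise CubeError(f"biome id {bid} missing from class map")
    return cube.biome_class_map[bid]


def biome_class_grid(cube: ClimateCube, time_index: int) -> np.ndarray:
    """Class index grid for one slice (-1 sea, else index into BIOME_CLASSES)."""
    from .cube import BIOME_CLASSES

    if "biome_id" not in cube.data:
        raise CubeError("cube carries no biome_id layer")
    ids = np.asarray(cube.data["biome_id"].values[time_index])
    out = np.full(ids.shape, -1, dtype=np.int32)
    land = cube.land_mask
    for bid in np.unique(ids[land]):
        bid = int(bid)
        if bid not in cube.biome_class_map:
            raise CubeError(f"biome id {bid} missing from class map")
        out[land & (ids == bid)] = BIOME_CLASSES.index(cube.biome_class_map[bid])
    return out


# ---------------------------------------------------------------------------
# variable selection
# ---------------------------------------------------------------------------

def informativeness_scores(
    presences: pd.DataFrame, background: pd.DataFrame, candidates: list[str]
) -> dict[str, float]:
    """Standardized absolute presence-vs-background mean difference.

    ``|mean_presence - mean_background| / sd_background`` per candidate; a
    zero-variance candidate scores 0 with a warning.
    """
    scores = {}
    for var in candidates:
        p = presences[var].to_numpy(dtype=float)
        b = background[var].to_numpy(dtype=float)
        sd = b.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"variable {var!r} has zero background variance",
                          stacklevel=2)
            scores[var] = 0.0
        else:
            scores[var] = float(abs(p.mean() - b.mean()) / sd)
    return scores


def select_variables(
    presences: pd.DataFrame,
    background: pd.DataFrame,
    candidates: list[str] | None = None,
    corr_threshold: float = 0.8,
) -> list[str]:
    """Greedy informativeness-ranked selection under a correlation cap.

    Candidates are scored by the standardized presence-vs-background mean
    difference, ranked, and accepted greedily when their absolute Pearson
    correlation (on the background sample) with every already-accepted
    variable is strictly below ``corr_threshold``.
    """
    candidates = list(candidates or COVARIATES)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate variables")
    if len(presences) == 0 or len(background) == 0:
        raise ValueError("presence and background tables must be non-empty")
    scores = informativeness_scores(presences, background, candidates)
    if all(s == 0.0 for s in scores.values()):
        warnings.warn(
            "no candidate separates presences from background; "
            "selection is rank-arbitrary", stacklevel=2,
        )
    ranked = sorted(candidates, key=lambda v: (-scores[v], candidates.index(v)))
    corr = background[candidates].corr(method="pearson")
    selected: list[str] = []
    for var in ranked:
        if scores[var] == 0.0:
            continue
        if all(abs(corr.loc[var, s]) < corr_threshold for s in selected):
            selected.append(var)
    return selected
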