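"""Occurrence database I/O, radiocarbon calibration and chronological filters.

Records are archaeological occupation layers with published coordinates and
radiometric ages. Uncalibrated radiocarbon ages are calibrated against a
hemisphere-appropriate calibration curve (northern curve for latitude >= 0,
southern otherwise); layers dated by radiocarbon *and* other radiometric
methods get a combined chronology (arithmetic mean of method means, and a
half-range spanning the union of the 1σ bounds). Layers are then filtered to
radiometric-only dating, a full age range of at most 20,000 years, and a
mean age within 14–120 ka.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

MANDATORY_COLUMNS = (
    "site_id",
    "layer_id",
    "lon",
    "lat",
    "method_class",
    "age_mean",
    "age_uncertainty",
)
OPTIONAL_COLUMNS = ("raw_14c_age", "raw_14c_error")
METHOD_CLASSES = (
    "radiocarbon",
    "other_radiometric",
    "non_radiometric",
    "undated",
)


class SchemaError(ValueError):
    """Occurrence CSV does not match the documented schema."""


class ValidationError(ValueError):
    """Row-level validation failures, with row numbers."""


class CalibrationRangeError(ValueError):
    """Radiocarbon age outside the calibration curve's support."""


def load_occurrence_database(path) -> pd.DataFrame:
    """Read and validate an occurrence CSV.

    Tolerates UTF-8 BOMs and Windows line endings. All malformed rows are
    reported at once (1-based data row numbers); nothing is silently
    dropped.
    """
    df = pd.read_csv(path, encoding="utf-8-sig")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan

    problems = []
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    unc = pd.to_numeric(df["age_uncertainty"], errors="coerce")
    for i in df.index:
        row = i + 1
        if not np.isfinite(lon[i]) or not (-180 <= lon[i] <= 180):
            problems.append(f"row {row}: lon={df['lon'][i]!r} outside [-180, 180]")
        if not np.isfinite(lat[i]) or not (-90 <= lat[i] <= 90):
            problems.append(f"row {row}: lat={df['lat'][i]!r} outside [-90, 90]")
        if df["method_class"][i] not in METHOD_CLASSES:
            problems.append(
                f"row {row}: method_class={df['method_class'][i]!r} not one of "
                f"{METHOD_CLASSES}"
            )
        if np.isfinite(unc[i]) and unc[i] < 0:
            problems.append(f"row {row}: age_uncertainty={unc[i]} < 0")
    if problems:
        raise ValidationError("; ".join(problems))

    df = df.copy()
    df["lon"], df["lat"], df["age_uncertainty"] = lon, lat, unc
    df["age_mean"] = pd.to_numeric(df["age_mean"], errors="coerce")
    df["hemisphere"] = np.where(df["lat"] >= 0, "north", "south")
    return df


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationCurve:
    """Radiocarbon calibration curve on a calendar-age grid.

    ``cal_bp`` is strictly monotone; ``c14_age`` is the curve's conventional
    radiocarbon age at each calendar age and ``curve_sigma`` its 1σ
    uncertainty (all in years). Standard curve files (IntCal20/SHCal20
    ``.14c``) carry these in their first three columns.
    """

    cal_bp: np.ndarray
    c14_age: np.ndarray
    curve_sigma: np.ndarray
    curve_name: str = "custom"

    def __post_init__(self) -> None:
        self.cal_bp = np.asarray(self.cal_bp, dtype=float)
        self.c14_age = np.asarray(self.c14_age, dtype=float)
        self.curve_sigma = np.asarray(self.curve_sigma, dtype=float)
        order = np.argsort(self.cal_bp)
        self.cal_bp = self.cal_bp[order]
        self.c14_age = self.c14_age[order]
        self.curve_sigma = self.curve_sigma[order]
        if np.any(np.diff(self.cal_bp) <= 0):
            raise ValueError("cal_bp grid must be strictly monotone")
        if np.any(self.curve_sigma <= 0):
            raise ValueError("curve_sigma must be > 0 everywhere")

    @classmethod
    def from_file(cls, path, curve_name: str | None = None) -> "CalibrationCurve":
        """Read the standard comma-separated curve format (first 3 columns:
        cal BP, ¹⁴C age, σ); header lines starting with ``#`` are skipped."""
        df = pd.read_csv(path, comment="#", header=None)
        if df.iloc[0].astype(str).str.contains("[A-Za-z]").any():
            df = df.iloc[1:].reset_index(drop=True)
        arr = df.iloc[:, :3].astype(float).to_numpy()
        name = curve_name or str(path)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], curve_name=name)


@dataclass
class CalibratedDate:
    """Posterior calendar-age summary of one radiocarbon determination."""

    mean_cal_bp: float
    sigma: float
    grid_cal_bp: np.ndarray
    density: np.ndarray
    interval_half_width: float  # 68.3% central-interval half-width

    def mass(self) -> float:
        return float(np.trapezoid(self.density, self.grid_cal_bp))


def calibrate_14c(
    age: float, error: float, curve: CalibrationCurve
) -> CalibratedDate:
    """Basic (non-Bayesian-sequence) calibration of one ¹⁴C age.

    The posterior over calendar age is proportional to
    ``Normal(age; mu_curve(cal_bp), sqrt(error^2 + sigma_curve(cal_bp)^2))``
    evaluated on the curve's native grid and normalized by the trapezoid
    rule. Summaries are the posterior mean and, by default, the posterior
    standard deviation (a 68.3% central-interval half-width is also
    carried).
    """
    if error <= 0:
        raise ValueError("measurement error must be > 0")
    lo = float(np.min(curve.c14_age) - 3 * np.max(curve.curve_sigma))
    hi = float(np.max(curve.c14_age) + 3 * np.max(curve.curve_sigma))
    if not (lo - 3 * error <= age <= hi + 3 * error):
        raise CalibrationRangeError(
            f"age {age} BP outside the support of curve {curve.curve_name}"
        )
    grid = curve.cal_bp
    mu = curve.c14_age
    sd = np.sqrt(error**2 + curve.curve_sigma**2)
    # log-density for numerical safety at old ages
    logd = -0.5 * ((age - mu) / sd) ** 2 - np.log(sd)
    logd -= logd.max()
    dens = np.exp(logd)
    mass = np.trapezoid(dens, grid)
    if mass <= 0 or not np.isfinite(mass):
        raise CalibrationRangeError(
            f"age {age} BP has no posterior mass on curve {curve.curve_name}"
        )
    dens = dens / mass
    mean = float(np.trapezoid(grid * dens, grid))
    var = float(np.trapezoid((grid - mean) ** 2 * dens, grid))
    cdf = np.concatenate(
        [[0.0], np.cumsum(np.diff(grid) * 0.5 * (dens[1:] + dens[:-1]))]
    )
    cdf = cdf / cdf[-1]
    q16, q84 = np.interp([0.1585, 0.8415], cdf, grid)
    return CalibratedDate(
        mean_cal_bp=mean,
        sigma=float(np.sqrt(var)),
        grid_cal_bp=grid,
        density=dens,
        interval_half_width=float((q84 - q16) / 2),
    )


def combine_age_estimates(
    cal_mean: float,
    cal_sigma: float,
    other_mean: float | None = None,
    other_half_range: float | None = None,
) -> tuple[float, float]:
    """Combine a calibrated ¹⁴C age with another radiometric estimate.

    Combined mean is the arithmetic mean of the method means; the combined
    half-range spans from the lowest lower bound to the highest upper bound
    across methods (bounds at mean ± 1σ or ± stated half-range). With only
    one estimate present this is a pass-through.
    """
    if other_mean is None:
        return float(cal_mean), float(cal_sigma)
    mean = (cal_mean + other_mean) / 2.0
    lo = min(cal_mean - cal_sigma, other_mean - other_half_range)
    hi = max(cal_mean + cal_sigma, other_mean + other_half_range)
    return float(mean), float((hi - lo) / 2.0)


def standardize_chronology(
    table: pd.DataFrame,
    north_curve: CalibrationCurve,
    south_curve: CalibrationCurve,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Calibrate all radiocarbon rows and combine with other estimates.

    Rows with ``method_class == 'radiocarbon'`` must carry ``raw_14c_age`` /
    ``raw_14c_error``; their ``age_mean`` / ``age_uncertainty``, when also
    present, are treated as the other-method estimate to combine with.
    Hemisphere routing is by latitude (>= 0 → northern curve; a record on
    the equator uses the northern curve). Radiocarbon ages beyond curve
    support are excluded with a logged reason, never extrapolated.

    Returns the standardized table and an exclusion log frame.
    """
    out = table.copy()
    excluded = []
    for i in out.index:
        if out.at[i, "method_class"] != "radiocarbon":
            continue
        raw_age = out.at[i, "raw_14c_age"]
        raw_err = out.at[i, "raw_14c_error"]
        if not np.isfinite(raw_age) or not np.isfinite(raw_err):
            excluded.append((i, "radiocarbon row missing raw_14c_age/error"))
            continue
        curve = north_curve if out.at[i, "lat"] >= 0 else south_curve
        try:
            cal = calibrate_14c(float(raw_age), float(raw_err), curve)
        except CalibrationRangeError as exc:
            excluded.append((i, str(exc)))
            continue
        other_mean = out.at[i, "age_mean"]
        other_half = out.at[i, "age_uncertainty"]
        if np.isfinite(other_mean) and np.isfinite(other_half):
            mean, half = combine_age_estimates(
                cal.mean_cal_bp, cal.sigma, float(other_mean), float(other_half)
            )
        else:
            mean, half = cal.mean_cal_bp, cal.sigma
        out.at[i, "age_mean"] = mean
        out.at[i, "age_uncertainty"] = half
    if excluded:
        idx = [i for i, _ in excluded]
        out = out.drop(index=idx)
    log = pd.DataFrame(excluded, columns=["row_index", "reason"])
    return out.reset_index(drop=True), log


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_occurrences(
    table: pd.DataFrame,
    min_age: float = 14_000.0,
    max_age: float = 120_000.0,
    max_uncertainty: float = 20_000.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the inclusion rules for modelled occurrences.

    Retains records that (1) are dated by a radiometric method (radiocarbon
    or other), (2) have a full age range — maximum minus minimum age, i.e.
    twice the half-range — of at most ``max_uncertainty`` years (the rule is
    ``<=``), and (3) have a mean age within ``[min_age, max_age]``. Returns
    the filtered table and a per-rule exclusion tally. Idempotent and
    order-independent; an empty result is legal.
    """
    tally = {
        "non_radiometric": 0,
        "undated": 0,
        "range_gt_max": 0,
        "age_outside_window": 0,
        "retained": 0,
    }
    keep = np.zeros(len(table), dtype=bool)
    mc = table["method_class"].to_numpy()
    mean = table["age_mean"].to_numpy(dtype=float)
    half = table["age_uncertainty"].to_numpy(dtype=float)
    for j in range(len(table)):
        if mc[j] == "undated":
            tally["undated"] += 1
        elif mc[j] not in ("radiocarbon", "other_radiometric"):
            tally["non_radiometric"] += 1
        elif not np.isfinite(half[j]) or 2.0 * half[j] > max_uncertainty:
            tally["range_gt_max"] += 1
        elif not np.isfinite(mean[j]) or not (min_age <= mean[j] <= max_age):
            tally["age_outside_window"] += 1
        else:
            keep[j] = True
            tally["retained"] += 1
    out = table.loc[keep].reset_index(drop=True)
    if len(out) == 0:
        warnings.warn("all occurrences excluded by the filters", stacklevel=2)
    return out, tally
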