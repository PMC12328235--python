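"""Fixed- and changing-niche models, statsmodels-style.

A model object is built from a presence-background frame (``obs`` 0/1, the
five covariates, ``time_bp`` in years BP); ``fit()`` returns a
:class:`NicheGAMResults` carrying AIC, effective degrees of freedom,
deviance, predictions, partial effects and a text ``summary()``.

* :class:`FixedNicheGAM` — one univariate smooth per covariate, no time
  terms: the niche is constant, so predictions at two times with identical
  covariates are identical.
* :class:`ChangingNicheGAM` — additionally a univariate time smooth and one
  time x covariate tensor-interaction smooth per covariate, each marginal
  capped at ``k = 4`` basis functions. Time is affinely rescaled to [0, 1]
  internally for conditioning; the map is recorded in the fit.

The AIC contrast between the two (``delta_aic = aic_fixed - aic_changing``,
support when ``> 2``) is the test for niche change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cube import COVARIATES, ClimateCube
from .gam import (
    PenalizedGAMFit,
    data_digest,
    fit_from_dict,
    fit_penalized_gam,
    fit_to_dict,
    make_smooth_term,
)

MODEL_COLUMNS = (*COVARIATES, "time_bp")


class ComparisonError(ValueError):
    pass


def _check_frame(data: pd.DataFrame, covariates: tuple[str, ...]) -> pd.DataFrame:
    need = {"obs", *covariates}
    missing = need - set(data.columns)
    if missing:
        raise ValueError(f"model frame missing columns: {sorted(missing)}")
    vals = data[list(covariates)].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("covariates must be finite (handle sea cells upstream)")
    return data


@dataclass
class NicheGAMResults:
    """Results of a fitted fixed- or changing-niche model."""

    kind: str  # "fixed" | "changing"
    fit: PenalizedGAMFit
    covariates: tuple[str, ...]
    k: int
    time_offset: float
    time_scale: float
    repeat_id: int | None = None

    @property
    def aic(self) -> float:
        return self.fit.aic

    @property
    def deviance(self) -> float:
        return self.fit.deviance

    @property
    def edf(self) -> float:
        return self.fit.edf_total

    @property
    def edf_by_term(self) -> dict[str, float]:
        return self.fit.edf_by_term

    @property
    def data_hash(self) -> str:
        return self.fit.data_hash

    def _internal_frame(self, data: pd.DataFrame) -> pd.DataFrame:
        out = data.copy()
        if "time_bp" in out.columns:
            out["time_s"] = (out["time_bp"] - self.time_offset) / self.time_scale
        return out

    def predict(self, data: pd.DataFrame, link: bool = False) -> np.ndarray:
        """Occurrence probability (or log-odds with ``link=True``)."""
        return self.fit.predict(self._internal_frame(data), link=link)

    def partial_effect(self, term: str, data: pd.DataFrame) -> np.ndarray:
        """Centred log-odds contribution of one smooth term."""
        return self.fit.term_effect(term, self._internal_frame(data))

    def summary(self) -> str:
        head = (
            f"{self.kind.capitalize()}-niche additive logistic model "
            f"(k = {self.k} per margin)\n"
        )
        return head + self.fit.summary()

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "covariates": list(self.covariates),
            "k": self.k,
            "time_offset": self.time_offset,
            "time_scale": self.time_scale,
            "repeat_id": self.repeat_id,
            "fit": fit_to_dict(self.fit),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NicheGAMResults":
        return cls(
            kind=d["kind"],
            fit=fit_from_dict(d["fit"]),
            covariates=tuple(d["covariates"]),
            k=d["k"],
            time_offset=d["time_offset"],
            time_scale=d["time_scale"],
            repeat_id=d["repeat_id"],
        )


class _BaseNicheGAM:
    kind = "base"

    def __init__(
        self,
        data: pd.DataFrame,
        covariates: tuple[str, ...] = COVARIATES,
        k: int = 4,
        repeat_id: int | None = None,
    ) -> None:
        self.covariates = tuple(covariates)
        self.k = int(k)
        self.repeat_id = repeat_id
        self.data = _check_frame(data, self.covariates)
        t = data["time_bp"].to_numpy(dtype=float) if "time_bp" in data else None
        if t is not None and np.ptp(t) > 0:
            self.time_offset = float(t.min())
            self.time_scale = float(np.ptp(t))
        else:
            self.time_offset, self.time_scale = 0.0, 1.0

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "_BaseNicheGAM":
        return cls(data, **kwargs)

    def _terms(self, frame: pd.DataFrame):
        raise NotImplementedError

    def fit(self, **fit_kwargs) -> NicheGAMResults:
        frame = self.data.copy()
        if "time_bp" in frame.columns:
            frame["time_s"] = (
                frame["time_bp"] - self.time_offset
            ) / self.time_scale
        y = frame["obs"].to_numpy(dtype=float)
        terms = self._terms(frame)
        fit = fit_penalized_gam(frame, y, terms, **fit_kwargs)
        fit.data_hash = data_digest(
            self.data[[c for c in MODEL_COLUMNS if c in self.data.columns]
                      + ["obs"]]
        )
        return NicheGAMResults(
            kind=self.kind,
            fit=fit,
            covariates=self.covariates,
            k=self.k,
            time_offset=self.time_offset,
            time_scale=self.time_scale,
            repeat_id=self.repeat_id,
        )


class FixedNicheGAM(_BaseNicheGAM):
    """Additive logistic model with time-constant covariate effects."""

    kind = "fixed"

    def _terms(self, frame: pd.DataFrame):
        return [
            make_smooth_term(f"s({v})", (v,), frame, k=self.k)
            for v in self.covariates
        ]


class ChangingNicheGAM(_BaseNicheGAM):
    """Adds a time smooth and time x covariate tensor interactions."""

    kind = "changing"

    def __init__(self, data, covariates=COVARIATES, k=4, repeat_id=None):
        super().__init__(data, covariates=covariates, k=k, repeat_id=repeat_id)
        if "time_bp" not in data.columns:
            raise ValueError("changing-niche model requires a time_bp column")

    def _terms(self, frame: pd.DataFrame):
        terms = [
            make_smooth_term(f"s({v})", (v,), frame, k=self.k)
            for v in self.covariates
        ]
        terms.append(make_smooth_term("s(time_bp)", ("time_s",), frame, k=self.k))
        for v in self.covariates:
            terms.append(
                make_smooth_term(f"ti(time_bp,{v})", ("time_s", v), frame,
                                 k=self.k)
            )
        return terms


# ---------------------------------------------------------------------------
# comparison and projection
# ---------------------------------------------------------------------------

@dataclass
class ModelComparison:
    """AIC contrast of the two niche hypotheses on one repeat."""

    aic_fixed: float
    aic_changing: float

    @property
    def delta_aic(self) -> float:
        return self.aic_fixed - self.aic_changing

    @property
    def supported(self) -> bool:
        """True when the changing-niche model is substantially supported
        (``delta_aic`` strictly greater than 2)."""
        return self.delta_aic > 2.0


def compare_models(
    fixed: NicheGAMResults, changing: NicheGAMResults
) -> ModelComparison:
    """ΔAIC = AIC(fixed) − AIC(changing); both fits must share the data."""
    if fixed.kind != "fixed" or changing.kind != "changing":
        raise ComparisonError(
            f"expected (fixed, changing), got ({fixed.kind}, {changing.kind})"
        )
    if fixed.data_hash and changing.data_hash and (
        fixed.data_hash != changing.data_hash
    ):
        raise ComparisonError("models were fitted on different data")
    return ModelComparison(aic_fixed=fixed.aic, aic_changing=changing.aic)


def predict_suitability(
    results: NicheGAMResults,
    cube: ClimateCube,
    times: np.ndarray | None = None,
    extrapolation_warn: float = 0.2,
):
    """Per-land-cell suitability grids for the requested slices.

    Returns an ``xarray.DataArray`` (time, lat, lon) with NaN over sea.
    Covariates outside the training hull are still predicted (the spline
    basis extends flat beyond its range); a warning reports any slice whose
    extrapolation fraction exceeds ``extrapolation_warn``.
    """
    import xarray as xr

    cube_times = cube.times
    if times is None:
        times = cube_times
    grids = []
    high_extrap = []
    for t in np.asarray(times, dtype=float):
        idx, snapped = cube.nearest_slice(t)
        frame = cube.slice_frame(idx)
        frame = frame.rename(columns={"slice_time_bp": "time_bp"})
        frac = results.fit.extrapolation_fraction(
            results._internal_frame(frame)
        )
        if frac > extrapolation_warn:
            high_extrap.append((snapped, frac))
        p = results.predict(frame)
        grid = np.full(cube.land_mask.shape, np.nan)
        grid[frame["row"].to_numpy(), frame["col"].to_numpy()] = p
        grids.append(grid)
    if high_extrap:
        worst = max(f for _, f in high_extrap)
        warnings.warn(
            f"{len(high_extrap)} slices have > {extrapolation_warn:.0%} of "
            f"cells outside the training covariate range (max {worst:.0%})",
            stacklevel=2,
        )
    return xr.DataArray(
        np.stack(grids),
        coords={
            "time": np.asarray(times, dtype=float),
            "lat": cube.lats,
            "lon": cube.lons,
        },
        dims=("time", "lat", "lon"),
        name="suitability",
    )


@dataclass
class EffectSurface:
    """Mean partial-effect surface of a time x covariate interaction."""

    variable: str
    times: np.ndarray
    values: np.ndarray
    surface: np.ndarray  # (len(times), len(values)), log-odds scale
    n_fits: int


def partial_effect_surface(
    fits: list[NicheGAMResults],
    variable: str,
    times: np.ndarray | None = None,
    values: np.ndarray | None = None,
    n_grid: int = 41,
) -> EffectSurface:
    """Across-fit mean of the time x variable interaction's partial effect.

    The effect is evaluated on a (time x variable-value) grid on the
    log-odds scale with all other terms at their (centred-out) means; red
    regions of the usual heat map are positive values here, blue negative.
    """
    if not fits:
        raise ValueError("need at least one accepted fit")
    term = f"ti(time_bp,{variable})"
    for f in fits:
        if term not in f.fit.edf_by_term:
            raise KeyError(f"variable {variable!r} has no interaction term in "
                           f"fit (kind={f.kind})")
    f0 = fits[0]
    t_term = next(t for t in f0.fit.terms if t.name == term)
    if times is None:
        lo, hi = t_term.bases[0].lo, t_term.bases[0].hi
        times = (np.linspace(lo, hi, n_grid) * f0.time_scale) + f0.time_offset
    if values is None:
        values = np.linspace(t_term.bases[1].lo, t_term.bases[1].hi, n_grid)
    tg, vg = np.meshgrid(times, values, indexing="ij")
    frame = pd.DataFrame({"time_bp": tg.ravel(), variable: vg.ravel()})
    surfaces = [
        f.partial_effect(term, frame).reshape(len(times), len(values))
        for f in fits
    ]
    return EffectSurface(
        variable=variable,
        times=np.asarray(times, dtype=float),
        values=np.asarray(values, dtype=float),
        surface=np.mean(surfaces, axis=0),
        n_fits=len(fits),
    )
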