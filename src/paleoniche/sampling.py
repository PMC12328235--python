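"""Repeat-dataset construction: date resampling, constant sampling effort,
and time-matched background draws.

Chronological uncertainty is resolved by drawing, for every occurrence, one
age from a truncated normal whose mean is the published mean age and whose
σ is half the published plus/minus (the half-range is read as 2σ), truncated
to mean ± half-range. Temporal sampling bias is removed by subsampling each
time slice younger than a boundary (78 ka by default) down to the occurrence
count of a randomly chosen pre-boundary slice. Each retained presence is
then matched with 200 background locations drawn uniformly from the land
cells of its time slice. Composing the three steps with independent
sub-seeds yields exchangeable, individually reproducible repeats.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .climate import extract_for_occurrences
from .cube import COVARIATES, ClimateCube


class SamplingError(ValueError):
    pass


@dataclass
class RepeatDataset:
    """One resampled realization of the presence-background design."""

    repeat_id: int
    presences: pd.DataFrame
    backgrounds: pd.DataFrame
    seed: int
    provenance: dict[str, int] = field(default_factory=dict)

    def model_frame(self) -> pd.DataFrame:
        """Stacked observations for model fitting (obs 1 = presence)."""
        cols = list(COVARIATES) + ["slice_time_bp"]
        p = self.presences[cols].copy()
        p["obs"] = 1
        b = self.backgrounds[cols].copy()
        b["obs"] = 0
        out = pd.concat([p, b], ignore_index=True)
        out = out.rename(columns={"slice_time_bp": "time_bp"})
        return out

    def validate(self, backgrounds_per_occurrence: int = 200) -> None:
        if len(self.backgrounds) != backgrounds_per_occurrence * len(self.presences):
            raise SamplingError(
                f"repeat {self.repeat_id}: {len(self.backgrounds)} backgrounds "
                f"for {len(self.presences)} presences (expected ratio "
                f"{backgrounds_per_occurrence})"
            )
        for frame in (self.presences, self.backgrounds):
            if frame[list(COVARIATES)].isna().any().any():
                raise SamplingError(
                    f"repeat {self.repeat_id}: missing covariates present"
                )

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.presences.to_csv(directory / "presences.csv", index=False)
        self.backgrounds.to_csv(directory / "backgrounds.csv", index=False)
        sidecar = {
            "repeat_id": self.repeat_id,
            "seed": self.seed,
            "provenance": self.provenance,
        }
        (directory / "provenance.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def read(cls, directory) -> "RepeatDataset":
        directory = Path(directory)
        sidecar = json.loads((directory / "provenance.json").read_text())
        return cls(
            repeat_id=sidecar["repeat_id"],
            presences=pd.read_csv(directory / "presences.csv"),
            backgrounds=pd.read_csv(directory / "backgrounds.csv"),
            seed=sidecar["seed"],
            provenance=sidecar["provenance"],
        )


def resample_dates(
    table: pd.DataFrame,
    time_axis: np.ndarray,
    seed: int | np.random.SeedSequence,
) -> pd.DataFrame:
    """Draw one age per occurrence and snap it to the climate time axis.

    The draw is Normal(mean, (half_range/2)^2) truncated to
    [mean - half_range, mean + half_range]; a zero half-range degenerates
    exactly to the mean. Sampled ages that fall off the time axis after
    truncation snap to the nearest end slice (counted in the output's
    ``clamped`` attribute).
    """
    rng = np.random.default_rng(seed)
    time_axis = np.asarray(time_axis, dtype=float)
    mean = table["age_mean"].to_numpy(dtype=float)
    half = table["age_uncertainty"].to_numpy(dtype=float)
    sampled = np.empty(len(table))
    degenerate = half <= 0
    sampled[degenerate] = mean[degenerate]
    n_rand = int((~degenerate).sum())
    if n_rand:
        m, h = mean[~degenerate], half[~degenerate]
        draws = stats.truncnorm.rvs(
            -2.0, 2.0, loc=m, scale=h / 2.0, size=n_rand, random_state=rng
        )
        sampled[~degenerate] = draws
    # nearest slice; ties toward the more recent (smaller BP) slice
    dist = np.abs(sampled[:, None] - time_axis[None, :])
    # argmax of reversed equality trick: pick last minimal index (descending
    # axis => most recent among ties)
    idx = dist.shape[1] - 1 - np.argmin(dist[:, ::-1], axis=1)
    out = table.copy()
    out["sampled_time_bp"] = sampled
    out["slice_time_bp"] = time_axis[idx]
    out.attrs["clamped"] = int(
        ((sampled > time_axis[0]) | (sampled < time_axis[-1])).sum()
    )
    return out


def subsample_constant_effort(
    presences: pd.DataFrame,
    time_axis: np.ndarray,
    boundary: float = 78_000.0,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Equalize sampling effort across time.

    Slices at or older than ``boundary`` are kept intact. For each younger
    slice, one pre-boundary slice is drawn uniformly (including empty ones)
    and the young slice is uniformly subsampled down to that slice's count
    (kept whole if already at or below it).
    """
    rng = np.random.default_rng(seed)
    time_axis = np.asarray(time_axis, dtype=float)
    old_slices = time_axis[time_axis >= boundary]
    if len(old_slices) == 0:
        raise SamplingError(
            f"no slices at or older than the {boundary} BP boundary"
        )
    counts = presences.groupby("slice_time_bp").size()
    old_counts = np.array([counts.get(t, 0) for t in old_slices])
    if old_counts.max() == 0:
        raise SamplingError(
            "no pre-boundary slice has any occurrence; the constant-effort "
            "correction is impossible — widen the age range or move the "
            "boundary"
        )
    pieces = []
    for t, grp in presences.groupby("slice_time_bp", sort=False):
        if t >= boundary:
            pieces.append(grp)
            continue
        target = int(old_counts[rng.integers(len(old_slices))])
        if len(grp) <= target:
            pieces.append(grp)
        elif target > 0:
            take = rng.choice(len(grp), size=target, replace=False)
            pieces.append(grp.iloc[np.sort(take)])
    if not pieces:
        return presences.iloc[0:0].copy()
    return pd.concat(pieces, ignore_index=True)


def sample_background(
    presences: pd.DataFrame,
    cube: ClimateCube,
    n_per_occurrence: int = 200,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Uniform background draws from land cells, time-matched per presence.

    For each presence, ``n_per_occurrence`` cells are drawn uniformly at
    random with replacement from the land cells of the presence's slice;
    background cells may coincide with presence cells.
    """
    rng = np.random.default_rng(seed)
    rows = []
    frames = {}
    for t, grp in presences.groupby("slice_time_bp", sort=False):
        idx, _ = cube.nearest_slice(float(t))
        if idx not in frames:
            frames[idx] = cube.slice_frame(idx)
        frame = frames[idx]
        if len(frame) == 0:
            raise SamplingError(f"slice {t} BP has zero land cells")
        n = len(grp) * n_per_occurrence
        picks = rng.integers(0, len(frame), size=n)
        sub = frame.iloc[picks].copy()
        rows.append(sub)
    if not rows:
        return pd.DataFrame(
            columns=["lon", "lat", "slice_time_bp", *COVARIATES]
        )
    return pd.concat(rows, ignore_index=True)


def build_repeats(
    table: pd.DataFrame,
    cube: ClimateCube,
    n_repeats: int = 100,
    n_background: int = 200,
    effort_boundary: float = 78_000.0,
    seed: int = 0,
) -> list[RepeatDataset]:
    """Compose resampling, constant effort and backgrounds into repeats.

    The master seed spawns one child per repeat and each repeat spawns one
    sub-seed per stage, so any repeat can be reproduced in isolation.
    """
    time_axis = cube.times
    master = np.random.SeedSequence(seed)
    out = []
    for rid, child in enumerate(master.spawn(n_repeats)):
        s_dates, s_effort, s_bg = child.spawn(3)
        dated = resample_dates(table, time_axis, s_dates)
        n_dated = len(dated)
        effort = subsample_constant_effort(
            dated, time_axis, boundary=effort_boundary, seed=s_effort
        )
        pres, drop_log = extract_for_occurrences(
            cube, effort, time_column="slice_time_bp"
        )
        bg = sample_background(pres, cube, n_per_occurrence=n_background, seed=s_bg)
        rep = RepeatDataset(
            repeat_id=rid,
            presences=pres,
            backgrounds=bg,
            seed=int(child.generate_state(1)[0] % (2**31)),
            provenance={
                "input": len(table),
                "dated": n_dated,
                "after_effort": len(effort),
                "sea_dropped": len(drop_log),
                "presences": len(pres),
                "backgrounds": len(bg),
            },
        )
        rep.validate(n_background)
        out.append(rep)
    return out
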