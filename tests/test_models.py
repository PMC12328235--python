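"""Fixed- and changing-niche model behaviour: shrinkage, recovery, nesting,
prediction and partial-effect surfaces."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from paleoniche.gam import fit_penalized_gam, load_fit, make_smooth_term, save_fit
from paleoniche.models import (
    ChangingNicheGAM,
    ComparisonError,
    FixedNicheGAM,
    ModelComparison,
    compare_models,
    partial_effect_surface,
    predict_suitability,
)
from paleoniche.sampling import build_repeats
from paleoniche.synthetic import (
    SyntheticWorldSpec,
    default_niche_spec,
    generate_world,
)

from conftest import small_spec

RNG = np.random.default_rng(20_240)


def noise_frame(n=4000, n_pres=200, seed=0):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {
            "lai": rng.normal(2.5, 1.0, n),
            "bio07": rng.normal(18, 4, n),
            "bio08": rng.normal(24, 3, n),
            "bio10": rng.normal(28, 3, n),
            "bio16": rng.normal(450, 120, n),
            "time_bp": rng.uniform(14_000, 120_000, n),
        }
    )
    obs = np.zeros(n)
    obs[rng.choice(n, n_pres, replace=False)] = 1
    frame["obs"] = obs
    return frame


@pytest.fixture(scope="module")
def drift_frame(drift_world):
    cube, occ = drift_world
    return build_repeats(occ, cube, n_repeats=1, seed=17)[0].model_frame()


class TestFixedNiche:
    def test_pure_noise_smooths_shrink(self):
        res = FixedNicheGAM(noise_frame(seed=1)).fit()
        for term, edf in res.edf_by_term.items():
            assert edf <= 1.5, f"{term} kept edf {edf:.2f} on pure noise"

    def test_logistic_linear_signal_recovered_monotone(self):
        rng = np.random.default_rng(2)
        frame = noise_frame(n=6000, n_pres=0, seed=2)
        eta = -3.0 + 0.01 * (frame["bio16"] - 450)
        frame["obs"] = rng.binomial(1, expit(eta))
        res = FixedNicheGAM(frame).fit()
        lo, hi = np.quantile(frame["bio16"], [0.05, 0.95])
        grid = pd.DataFrame({"bio16": np.linspace(lo, hi, 60)})
        eff = res.partial_effect("s(bio16)", grid)
        assert np.all(np.diff(eff) > -1e-8)

    def test_row_duplication_sufficiency(self):
        # at fixed smoothing, doubling every row while doubling the penalty
        # leaves the penalized-likelihood optimum unchanged
        frame = noise_frame(n=1500, n_pres=150, seed=3)
        dup = pd.concat([frame, frame], ignore_index=True)
        r1 = FixedNicheGAM(frame).fit(max_outer=0, lambda_init=10.0)
        r2 = FixedNicheGAM(dup).fit(max_outer=0, lambda_init=20.0)
        np.testing.assert_allclose(r1.fit.coef, r2.fit.coef, rtol=1e-5,
                                   atol=1e-8)

    def test_predictions_in_unit_interval_and_time_invariant(self):
        frame = noise_frame(seed=4)
        res = FixedNicheGAM(frame).fit()
        new = frame.head(50).copy()
        p1 = res.predict(new)
        new["time_bp"] = new["time_bp"] / 2 + 10_000
        p2 = res.predict(new)
        assert np.all((p1 >= 0) & (p1 <= 1))
        np.testing.assert_array_equal(p1, p2)


class TestChangingNiche:
    def test_fixed_niche_data_interactions_penalized_out(self, labelled_world):
        cube, occ = labelled_world
        rep = build_repeats(occ, cube, n_repeats=1, seed=8)[0]
        res = ChangingNicheGAM(rep.model_frame()).fit()
        inter = sum(
            v for k, v in res.edf_by_term.items() if k.startswith("ti(")
        )
        assert inter < 1.5

    def test_drifting_optimum_lands_on_right_interaction(self):
        wins = 0
        for seed in range(5):
            spec = SyntheticWorldSpec(
                seed=seed, niche_spec=default_niche_spec(drift=4.0)
            )
            cube, occ = generate_world(spec)
            rep = build_repeats(occ, cube, n_repeats=1, seed=seed)[0]
            res = ChangingNicheGAM(rep.model_frame()).fit()
            inter = {
                k: v for k, v in res.edf_by_term.items() if k.startswith("ti(")
            }
            if max(inter, key=inter.get) == "ti(time_bp,bio10)":
                wins += 1
        assert wins >= 4

    def test_nesting_deviance(self, drift_frame):
        fx = FixedNicheGAM(drift_frame).fit()
        ch = ChangingNicheGAM(drift_frame).fit()
        assert ch.deviance <= fx.deviance + 1e-6

    def test_requires_time_column(self):
        frame = noise_frame(seed=5).drop(columns=["time_bp"])
        with pytest.raises(ValueError, match="time_bp"):
            ChangingNicheGAM(frame)

    def test_serialization_roundtrip(self, drift_frame, tmp_path):
        res = ChangingNicheGAM(drift_frame).fit()
        import json

        path = tmp_path / "fit.json"
        path.write_text(json.dumps(res.to_dict()))
        back = type(res).from_dict(json.loads(path.read_text()))
        new = drift_frame.head(200)
        np.testing.assert_allclose(res.predict(new), back.predict(new))
        assert back.aic == res.aic

    def test_summary_mentions_terms(self, drift_frame):
        res = ChangingNicheGAM(drift_frame).fit()
        text = res.summary()
        assert "ti(time_bp,bio10)" in text and "AIC" in text


class TestComparison:
    def test_delta_and_support(self):
        c = ModelComparison(aic_fixed=1000.0, aic_changing=990.0)
        assert c.delta_aic == 10.0 and c.supported

    def test_boundary_exactly_two_not_supported(self):
        c = ModelComparison(aic_fixed=1000.0, aic_changing=998.0)
        assert c.delta_aic == 2.0 and not c.supported

    def test_mismatched_data_rejected(self, drift_frame):
        fx = FixedNicheGAM(drift_frame).fit()
        other = drift_frame.copy()
        other["bio10"] = other["bio10"] + 1.0
        ch = ChangingNicheGAM(other).fit()
        with pytest.raises(ComparisonError, match="different data"):
            compare_models(fx, ch)

    def test_kind_ordering_enforced(self, drift_frame):
        fx = FixedNicheGAM(drift_frame).fit()
        with pytest.raises(ComparisonError):
            compare_models(fx, fx)


class TestPrediction:
    def test_constant_cube_fixed_fit_identical_maps(self, quiet_cube):
        frame = noise_frame(seed=6)
        res = FixedNicheGAM(frame).fit()
        suit = predict_suitability(res, quiet_cube)
        arr = suit.values
        for i in range(1, arr.shape[0]):
            np.testing.assert_array_equal(arr[0], arr[i])

    def test_grid_matches_per_point_loop(self, quiet_cube):
        frame = noise_frame(seed=7)
        res = FixedNicheGAM(frame).fit()
        suit = predict_suitability(res, quiet_cube, times=quiet_cube.times[:2])
        cells = quiet_cube.slice_frame(0)
        for _, rec in cells.head(40).iterrows():
            single = pd.DataFrame([rec]).rename(
                columns={"slice_time_bp": "time_bp"}
            )
            want = res.predict(single)[0]
            got = suit.values[0, int(rec.row), int(rec.col)]
            assert got == pytest.approx(want, abs=1e-12)

    def test_values_bounded_and_sea_missing(self, quiet_cube):
        frame = noise_frame(seed=8)
        res = FixedNicheGAM(frame).fit()
        suit = predict_suitability(res, quiet_cube)
        arr = suit.values
        land = quiet_cube.land_mask
        assert np.all(np.isnan(arr[:, ~land]))
        assert np.nanmin(arr) >= 0 and np.nanmax(arr) <= 1


class TestPartialEffectSurface:
    def test_single_fit_mean_equals_that_fit(self, drift_frame):
        res = ChangingNicheGAM(drift_frame).fit()
        surf = partial_effect_surface([res], "bio10", n_grid=15)
        tg, vg = np.meshgrid(surf.times, surf.values, indexing="ij")
        frame = pd.DataFrame({"time_bp": tg.ravel(), "bio10": vg.ravel()})
        direct = res.partial_effect("ti(time_bp,bio10)", frame).reshape(15, 15)
        np.testing.assert_allclose(surf.surface, direct)

    def test_null_surface_near_zero(self, labelled_world):
        cube, occ = labelled_world
        rep = build_repeats(occ, cube, n_repeats=1, seed=13)[0]
        res = ChangingNicheGAM(rep.model_frame()).fit()
        surf = partial_effect_surface([res], "bio16", n_grid=21)
        frac_small = np.mean(np.abs(surf.surface) < 0.5)
        assert frac_small >= 0.95

    def test_drift_ridge_moves_with_time(self, drift_world):
        cube, occ = drift_world
        reps = build_repeats(occ, cube, n_repeats=3, seed=23)
        fits = [ChangingNicheGAM(r.model_frame()).fit() for r in reps]
        surf = partial_effect_surface(fits, "bio10", n_grid=25)
        # the preferred bio10 (surface argmax per time row) drifts downward
        # through time as the optimum moves: rank-correlate with time
        ridge = surf.values[np.argmax(surf.surface, axis=1)]
        from scipy import stats

        rho = stats.spearmanr(surf.times, ridge).statistic
        assert abs(rho) > 0.6

    def test_unknown_variable_rejected(self, drift_frame):
        res = ChangingNicheGAM(drift_frame).fit()
        with pytest.raises(KeyError):
            partial_effect_surface([res], "elevation")

    def test_empty_fit_list_rejected(self):
        with pytest.raises(ValueError):
            partial_effect_surface([], "bio10")


class TestAgainstReferenceSmoother:
    def test_univariate_binomial_smooth_matches_mgcv(self, tmp_path):
        """Independent oracle: the same univariate binomial smooth fitted by
        mgcv produces near-identical probability predictions."""
        rng = np.random.default_rng(99)
        n = 3000
        x = rng.uniform(-2, 2, n)
        p = expit(np.sin(1.5 * x) * 1.2 - 0.5)
        y = rng.binomial(1, p)
        frame = pd.DataFrame({"x": x, "obs": y.astype(float)})
        term = make_smooth_term("s(x)", ("x",), frame, k=4)
        fit = fit_penalized_gam(frame, frame["obs"].to_numpy(), [term])
        grid = pd.DataFrame({"x": np.linspace(-1.9, 1.9, 101)})
        ours = fit.predict(grid)

        csv = tmp_path / "d.csv"
        frame.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            textwrap.dedent(
                f"""
                library(mgcv)
                d <- read.csv("{csv}")
                m <- gam(obs ~ s(x, k = 4), data = d, family = binomial)
                g <- data.frame(x = seq(-1.9, 1.9, length.out = 101))
                cat(predict(m, g, type = "response"), sep = "\\n")
                """
            )
        )
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script)],
            capture_output=True, text=True, timeout=300,
        )
        if proc.returncode != 0:
            pytest.fail(f"reference fit failed: {proc.stderr[-500:]}")
        theirs = np.array([float(v) for v in proc.stdout.split()])
        r = np.corrcoef(ours, theirs)[0, 1]
        assert r > 0.98
        assert np.max(np.abs(ours - theirs)) < 0.1
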