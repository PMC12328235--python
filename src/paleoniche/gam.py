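"""Penalized-spline additive logistic models with tensor interactions.

This is the fitting engine behind the fixed- and changing-niche models: a
binomial GAM with

* univariate smooths built from cubic B-spline bases with ``k`` basis
  functions per term,
* tensor-product interaction smooths built as row-wise Kronecker products
  of *centred* marginal bases (so an interaction term excludes the marginal
  main effects, in the spirit of an ANOVA decomposition),
* first-order difference penalties, which — once the sum-to-zero centring
  removes the constant — are full rank, so smoothing can shrink any term's
  effective degrees of freedom towards zero,
* penalized IRLS for the coefficients and Fellner–Schall updates for the
  smoothing parameters (one per term; a tensor term's penalty is the sum of
  its two marginal Kronecker penalties under a single parameter).

Effective degrees of freedom per term are block sums of the influence-matrix
trace ``tr(F)``; the AIC penalty uses the model-comparison dof
``tr(2F - F^2)``, which is never smaller than ``tr(F)`` and compensates for
the optimism introduced by selecting the smoothing parameters on the same
data (the plain conditional AIC is known to favour the more flexible model
too often).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.interpolate import BSpline
from scipy.special import expit


class FitError(RuntimeError):
    """Non-convergence or numerically degenerate fit."""


# ---------------------------------------------------------------------------
# bases
# ---------------------------------------------------------------------------

@dataclass
class SplineBasis1D:
    """Cubic B-spline basis on the training range with ``k`` functions.

    Evaluation clamps inputs to the training range (flat extrapolation of
    the basis; callers flag the extrapolation fraction separately).
    """

    knots: np.ndarray
    k: int
    degree: int = 3

    @classmethod
    def from_data(cls, x: np.ndarray, k: int = 4, degree: int = 3) -> "SplineBasis1D":
        x = np.asarray(x, dtype=float)
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            hi = lo + 1.0  # constant covariate: degenerate but well defined
        n_interior = k - degree - 1
        if n_interior > 0:
            qs = np.linspace(0, 1, n_interior + 2)[1:-1]
            interior = np.quantile(x, qs)
        else:
            interior = np.array([])
        knots = np.concatenate(
            [[lo] * (degree + 1), interior, [hi] * (degree + 1)]
        )
        return cls(knots=knots, k=k, degree=degree)

    @property
    def lo(self) -> float:
        return float(self.knots[0])

    @property
    def hi(self) -> float:
        return float(self.knots[-1])

    def design(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.lo, self.hi)
        return BSpline.design_matrix(
            x, self.knots, self.degree, extrapolate=False
        ).toarray()

    def penalty(self) -> np.ndarray:
        d = np.diff(np.eye(self.k), axis=0)
        return d.T @ d


def _null_space_transform(col_means: np.ndarray) -> np.ndarray:
    """Orthonormal basis Z of the space orthogonal to the constraint row."""
    c = np.atleast_2d(col_means)
    return linalg.null_space(c)


# ---------------------------------------------------------------------------
# terms
# ---------------------------------------------------------------------------

@dataclass
class SmoothTerm:
    """One penalized model term (univariate or tensor interaction)."""

    name: str
    variables: tuple[str, ...]
    bases: list[SplineBasis1D]
    transforms: list[tuple[float, float]]  # per variable: (offset, scale)
    z_mats: list[np.ndarray]  # centring transforms per marginal
    penalty_mat: np.ndarray  # in the constrained parameterization
    rank: int

    @property
    def ncols(self) -> int:
        return self.penalty_mat.shape[0]

    def _marginal(self, j: int, values: np.ndarray) -> np.ndarray:
        off, scale = self.transforms[j]
        b = self.bases[j].design((values - off) / scale)
        return b @ self.z_mats[j]

    def design(self, frame: pd.DataFrame) -> np.ndarray:
        mats = [
            self._marginal(j, frame[v].to_numpy(dtype=float))
            for j, v in enumerate(self.variables)
        ]
        if len(mats) == 1:
            return mats[0]
        a, b = mats
        # row-wise Kronecker product
        return (a[:, :, None] * b[:, None, :]).reshape(len(a), -1)

    def extrapolation_fraction(self, frame: pd.DataFrame) -> float:
        out = np.zeros(len(frame), dtype=bool)
        for j, v in enumerate(self.variables):
            off, scale = self.transforms[j]
            x = (frame[v].to_numpy(dtype=float) - off) / scale
            out |= (x < self.bases[j].lo) | (x > self.bases[j].hi)
        return float(out.mean()) if len(frame) else 0.0


def make_smooth_term(
    name: str,
    variables: tuple[str, ...],
    frame: pd.DataFrame,
    k: int = 4,
    transforms: dict[str, tuple[float, float]] | None = None,
) -> SmoothTerm:
    """Build a centred, penalized term from training data."""
    transforms = transforms or {}
    bases, tfs, zs, pens = [], [], [], []
    for v in variables:
        off, scale = transforms.get(v, (0.0, 1.0))
        x = (frame[v].to_numpy(dtype=float) - off) / scale
        basis = SplineBasis1D.from_data(x, k=k)
        b = basis.design(x)
        z = _null_space_transform(b.mean(axis=0))
        if z.shape[1] == 0:
            raise FitError(f"term {name}: constraint removed all columns")
        bases.append(basis)
        tfs.append((off, scale))
        zs.append(z)
        pens.append(z.T @ basis.penalty() @ z)
    if len(variables) == 1:
        pen = pens[0]
    else:
        i0 = np.eye(pens[1].shape[0])
        i1 = np.eye(pens[0].shape[0])
        pen = np.kron(pens[0], i0) + np.kron(i1, pens[1])
    rank = int(np.linalg.matrix_rank(pen))
    return SmoothTerm(
        name=name,
        variables=variables,
        bases=bases,
        transforms=tfs,
        z_mats=zs,
        penalty_mat=pen,
        rank=rank,
    )


# ---------------------------------------------------------------------------
# model fit
# ---------------------------------------------------------------------------

def _binomial_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


@dataclass
class PenalizedGAMFit:
    """Fitted penalized additive logistic model."""

    terms: list[SmoothTerm]
    coef: np.ndarray
    lambdas: np.ndarray
    edf_by_term: dict[str, float]
    edf_total: float
    edf_comparison: float
    deviance: float
    null_deviance: float
    aic: float
    n_obs: int
    data_hash: str
    n_iter: int
    converged: bool
    cov_unscaled: np.ndarray = dc_field(repr=False, default=None)

    # -- design helpers -----------------------------------------------------

    def _blocks(self) -> list[tuple[int, int]]:
        out, start = [], 1
        for t in self.terms:
            out.append((start, start + t.ncols))
            start += t.ncols
        return out

    def design_matrix(self, frame: pd.DataFrame) -> np.ndarray:
        mats = [np.ones((len(frame), 1))]
        mats += [t.design(frame) for t in self.terms]
        return np.hstack(mats)

    def predict(self, frame: pd.DataFrame, link: bool = False) -> np.ndarray:
        eta = self.design_matrix(frame) @ self.coef
        return eta if link else expit(eta)

    def term_effect(self, term_name: str, frame: pd.DataFrame) -> np.ndarray:
        """Centred partial effect of one term on the log-odds scale."""
        for t, (a, b) in zip(self.terms, self._blocks()):
            if t.name == term_name:
                return t.design(frame) @ self.coef[a:b]
        raise KeyError(f"no term named {term_name!r}; have "
                       f"{[t.name for t in self.terms]}")

    def extrapolation_fraction(self, frame: pd.DataFrame) -> float:
        return max(t.extrapolation_fraction(frame) for t in self.terms)

    def summary(self) -> str:
        lines = [
            "Penalized additive logistic model",
            f"  n = {self.n_obs}, deviance = {self.deviance:.2f}, "
            f"null deviance = {self.null_deviance:.2f}",
            f"  total edf = {self.edf_total:.2f} "
            f"(comparison dof {self.edf_comparison:.2f}), AIC = {self.aic:.2f}",
            f"  {'term':<22}{'cols':>5}{'edf':>8}{'lambda':>12}",
        ]
        for t, lam in zip(self.terms, self.lambdas):
            lines.append(
                f"  {t.name:<22}{t.ncols:>5}{self.edf_by_term[t.name]:>8.2f}"
                f"{lam:>12.3g}"
            )
        return "\n".join(lines)


def data_digest(frame: pd.DataFrame) -> str:
    arr = np.ascontiguousarray(
        frame.to_numpy(dtype=float)
    )
    return hashlib.sha1(arr.tobytes()).hexdigest()


def fit_penalized_gam(
    frame: pd.DataFrame,
    y: np.ndarray,
    terms: list[SmoothTerm],
    max_outer: int = 25,
    max_pirls: int = 60,
    tol: float = 1e-7,
    lambda_tol: float = 0.02,
    lambda_init: float = 1.0,
) -> PenalizedGAMFit:
    """Penalized IRLS with Fellner–Schall smoothing-parameter updates."""
    y = np.asarray(y, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("response must be 0/1")
    if y.sum() < 1 or (1 - y).sum() < 1:
        raise ValueError("need at least one presence and one background")

    X = np.hstack([np.ones((len(frame), 1))] + [t.design(frame) for t in terms])
    n, p = X.shape
    blocks, start = [], 1
    for t in terms:
        blocks.append((start, start + t.ncols))
        start += t.ncols

    def total_penalty(lams: np.ndarray) -> np.ndarray:
        S = np.zeros((p, p))
        for lam, t, (a, b) in zip(lams, terms, blocks):
            S[a:b, a:b] = lam * t.penalty_mat
        return S

    lams = np.full(len(terms), float(lambda_init))
    beta = np.zeros(p)
    pbar = np.clip(y.mean(), 1e-6, 1 - 1e-6)
    beta[0] = np.log(pbar / (1 - pbar))
    null_dev = _binomial_deviance(y, np.full(n, pbar))

    XtWX = None
    n_iter = 0
    converged = False

    def pirls(beta: np.ndarray, S: np.ndarray):
        nonlocal n_iter
        eta = X @ beta
        mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
        pdev = _binomial_deviance(y, mu) + float(beta @ S @ beta)
        for _ in range(max_pirls):
            n_iter += 1
            w = mu * (1 - mu)
            z = eta + (y - mu) / w
            XtWX = X.T @ (X * w[:, None])
            rhs = X.T @ (w * z)
            A = XtWX + S
            try:
                c, low = linalg.cho_factor(A, check_finite=False)
            except linalg.LinAlgError:
                A = A + 1e-8 * np.eye(p)
                c, low = linalg.cho_factor(A, check_finite=False)
            beta_new = linalg.cho_solve((c, low), rhs, check_finite=False)
            # step halving on the penalized deviance
            step = beta_new - beta
            for _half in range(30):
                trial = beta + step
                eta_t = X @ trial
                mu_t = np.clip(expit(eta_t), 1e-10, 1 - 1e-10)
                pdev_t = _binomial_deviance(y, mu_t) + float(trial @ S @ trial)
                if pdev_t <= pdev + 1e-10:
                    break
                step = step / 2
            else:
                raise FitError(
                    f"penalized IRLS diverged after {n_iter} iterations "
                    f"(penalized deviance {pdev:.3f})"
                )
            moved = np.abs(pdev_t - pdev) <= tol * (np.abs(pdev) + 1.0)
            beta, eta, mu, pdev = trial, eta_t, mu_t, pdev_t
            if moved:
                break
        w = mu * (1 - mu)
        XtWX = X.T @ (X * w[:, None])
        return beta, mu, XtWX, pdev

    for outer in range(max_outer):
        S = total_penalty(lams)
        beta, mu, XtWX, _ = pirls(beta, S)
        A_inv = linalg.inv(XtWX + S + 1e-12 * np.eye(p))
        new_lams = lams.copy()
        for j, (t, (a, b)) in enumerate(zip(terms, blocks)):
            Sj = t.penalty_mat
            tr_A = float(np.sum(A_inv[a:b, a:b] * Sj.T))
            num = t.rank / lams[j] - tr_A
            den = float(beta[a:b] @ Sj @ beta[a:b])
            num = max(num, 1e-10)
            den = max(den, 1e-12)
            new_lams[j] = np.clip(lams[j] * num / den, 1e-4, 1e9)
        delta = np.max(np.abs(np.log(new_lams) - np.log(lams)))
        lams = new_lams
        if delta < lambda_tol:
            converged = True
            break

    S = total_penalty(lams)
    beta, mu, XtWX, _ = pirls(beta, S)
    A_inv = linalg.inv(XtWX + S + 1e-12 * np.eye(p))
    F = A_inv @ XtWX
    diag_f = np.diag(F)
    edf_by_term = {
        t.name: float(diag_f[a:b].sum()) for t, (a, b) in zip(terms, blocks)
    }
    edf_total = float(diag_f.sum())
    # model-comparison dof: tr(2F - F^2) >= tr(F); the plain influence trace
    # understates the cost of flexibility when smoothing parameters are
    # themselves selected, making the naive conditional AIC anti-conservative
    edf_comparison = float(2.0 * edf_total - np.sum(F * F.T))
    dev = _binomial_deviance(y, mu)
    fit = PenalizedGAMFit(
        terms=terms,
        coef=beta,
        lambdas=lams,
        edf_by_term=edf_by_term,
        edf_total=edf_total,
        edf_comparison=edf_comparison,
        deviance=dev,
        null_deviance=null_dev,
        aic=dev + 2.0 * edf_comparison,
        n_obs=n,
        data_hash="",
        n_iter=n_iter,
        converged=converged,
        cov_unscaled=A_inv,
    )
    return fit


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def fit_to_dict(fit: PenalizedGAMFit) -> dict:
    terms = []
    for t in fit.terms:
        terms.append(
            {
                "name": t.name,
                "variables": list(t.variables),
                "k": t.bases[0].k,
                "knots": [b.knots.tolist() for b in t.bases],
                "degree": t.bases[0].degree,
                "transforms": [list(tf) for tf in t.transforms],
                "z_mats": [z.tolist() for z in t.z_mats],
                "penalty": t.penalty_mat.tolist(),
                "rank": t.rank,
            }
        )
    return {
        "terms": terms,
        "coef": fit.coef.tolist(),
        "lambdas": fit.lambdas.tolist(),
        "edf_by_term": fit.edf_by_term,
        "edf_total": fit.edf_total,
        "edf_comparison": fit.edf_comparison,
        "deviance": fit.deviance,
        "null_deviance": fit.null_deviance,
        "aic": fit.aic,
        "n_obs": fit.n_obs,
        "data_hash": fit.data_hash,
        "n_iter": fit.n_iter,
        "converged": fit.converged,
    }


def fit_from_dict(d: dict) -> PenalizedGAMFit:
    terms = []
    for td in d["terms"]:
        bases = [
            SplineBasis1D(
                knots=np.asarray(kn, dtype=float), k=td["k"], degree=td["degree"]
            )
            for kn in td["knots"]
        ]
        terms.append(
            SmoothTerm(
                name=td["name"],
                variables=tuple(td["variables"]),
                bases=bases,
                transforms=[tuple(tf) for tf in td["transforms"]],
                z_mats=[np.asarray(z, dtype=float) for z in td["z_mats"]],
                penalty_mat=np.asarray(td["penalty"], dtype=float),
                rank=td["rank"],
            )
        )
    return PenalizedGAMFit(
        terms=terms,
        coef=np.asarray(d["coef"], dtype=float),
        lambdas=np.asarray(d["lambdas"], dtype=float),
        edf_by_term=dict(d["edf_by_term"]),
        edf_total=d["edf_total"],
        edf_comparison=d["edf_comparison"],
        deviance=d["deviance"],
        null_deviance=d["null_deviance"],
        aic=d["aic"],
        n_obs=d["n_obs"],
        data_hash=d["data_hash"],
        n_iter=d["n_iter"],
        converged=d["converged"],
        cov_unscaled=None,
    )


def save_fit(fit: PenalizedGAMFit, path) -> None:
    with open(path, "w") as fh:
        json.dump(fit_to_dict(fit), fh)


def load_fit(path) -> PenalizedGAMFit:
    with open(path) as fh:
        return fit_from_dict(json.load(fh))
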