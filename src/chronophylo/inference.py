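"""Diversity -> biomass inference layer.

Three complementary analyses relate plot-level evolutionary diversity to
aboveground biomass (AGB):

* a linear mixed model with recovery stage as a random intercept (Gaussian
  response on possibly transformed AGB), reporting per-predictor t-values,
  AIC, and Nakagawa's marginal / conditional R²;
* variance partitioning (VPA) of AGB between two predictor sets via adjusted
  R² (unique and shared fractions, reported unclipped);
* partial least squares path modeling (PLS-PM, mode A outer model, path
  inner weighting scheme) over latent blocks, with the goodness of fit
  GOF = sqrt(mean communality x mean R² of endogenous blocks) and a
  bootstrap for path significance.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "MixedModelResult",
    "VPAResult",
    "PathModelResult",
    "fit_mixed",
    "r2_nakagawa",
    "variance_partition",
    "PLSPathModel",
    "fit_plspm",
]

logger = logging.getLogger(__name__)


def _zscore(x: np.ndarray) -> np.ndarray:
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("cannot standardize a constant column")
    return (x - x.mean()) / s


# ---------------------------------------------------------------------------
# Mixed model
# ---------------------------------------------------------------------------


@dataclass
class MixedModelResult:
    """Random-intercept mixed model summary for one analysis level."""

    level: str
    coefficients: dict[str, float]
    t_values: dict[str, float]
    significant: dict[str, bool]
    aic: float
    r2_marginal: float
    r2_conditional: float
    sigma2_stage: float
    sigma2_resid: float
    boundary_fit: bool

    def to_series(self) -> pd.Series:
        s = {"level": self.level, "AIC": self.aic, "R2m": self.r2_marginal,
             "R2c": self.r2_conditional}
        for k, t in self.t_values.items():
            s[k] = t
        return pd.Series(s)


def r2_nakagawa(
    fixed_predictor: np.ndarray, sigma2_group: float, sigma2_resid: float
) -> tuple[float, float]:
    """Marginal and conditional R² for a Gaussian random-intercept model.

    ``R2m = s2_f / (s2_f + s2_group + s2_e)`` with ``s2_f`` the variance of
    the fixed-effect linear predictor, and ``R2c`` adds the random-intercept
    variance to the numerator.
    """
    s2f = float(np.var(np.asarray(fixed_predictor, dtype=float)))
    denom = s2f + sigma2_group + sigma2_resid
    if denom <= 0:
        logger.warning("all variance components zero: R2m/R2c undefined")
        return float("nan"), float("nan")
    return s2f / denom, (s2f + sigma2_group) / denom


def fit_mixed(
    data: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    group: str = "stage_years",
    level: str = "total",
    standardize: bool = True,
    t_threshold: float = 2.0,
) -> MixedModelResult:
    """Random-intercept linear mixed model of ``response`` on ``predictors``.

    Predictors are z-scored by default so t-values are comparable across
    levels.  Variance components come from the REML fit; AIC from a maximum
    likelihood refit so models with different fixed effects are comparable.
    A vanishing stage variance is returned as a flagged boundary fit rather
    than an error.
    """
    cols = [response, group, *predictors]
    d = data[cols].dropna()
    if len(d) < 10:
        raise ValueError(f"mixed model needs >= 10 complete rows, got {len(d)}")
    if d[group].nunique() < 2:
        raise ValueError("mixed model needs at least 2 groups")
    y = d[response].to_numpy(dtype=float)
    X = np.column_stack([
        _zscore(d[p].to_numpy(dtype=float)) if standardize
        else d[p].to_numpy(dtype=float)
        for p in predictors
    ])
    exog = sm.add_constant(X)
    groups = d[group].to_numpy()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, exog, groups=groups)
        fit = model.fit(reml=True)
        fit_ml = MixedLM(y, exog, groups=groups).fit(reml=False)

    sigma2_stage = float(np.asarray(fit.cov_re).ravel()[0])
    sigma2_resid = float(fit.scale)
    boundary = sigma2_stage < 1e-8 * max(sigma2_resid, 1.0)
    fixed_pred = exog @ fit.fe_params
    r2m, r2c = r2_nakagawa(fixed_pred, sigma2_stage, sigma2_resid)

    names = ["const", *predictors]
    coefs = dict(zip(names, map(float, fit.fe_params)))
    tvals = dict(zip(names, map(float, fit.tvalues[: len(names)])))
    coefs.pop("const")
    tvals.pop("const")
    return MixedModelResult(
        level=level,
        coefficients=coefs,
        t_values=tvals,
        significant={k: abs(t) > t_threshold for k, t in tvals.items()},
        aic=float(fit_ml.aic),
        r2_marginal=r2m,
        r2_conditional=r2c,
        sigma2_stage=sigma2_stage,
        sigma2_resid=sigma2_resid,
        boundary_fit=bool(boundary),
    )


# ---------------------------------------------------------------------------
# Variance partitioning
# ---------------------------------------------------------------------------


@dataclass
class VPAResult:
    """Adjusted-R² variance partition between two predictor sets."""

    unique1: float
    unique2: float
    shared: float
    residual: float
    adj_r2_full: float
    set1: tuple[str, ...]
    set2: tuple[str, ...]

    def clipped(self) -> "VPAResult":
        """Display variant with small negative adjusted-R² artifacts set to 0."""
        u1, u2, sh = (max(v, 0.0) for v in (self.unique1, self.unique2, self.shared))
        return VPAResult(u1, u2, sh, self.residual, self.adj_r2_full,
                         self.set1, self.set2)


def _adj_r2(y: np.ndarray, X: np.ndarray, names: Sequence[str]) -> float:
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        corr = np.corrcoef(X, rowvar=False) if p > 1 else np.ones((1, 1))
        bad = sorted({names[i] for i in range(p) for j in range(i)
                      if abs(corr[i, j]) > 1 - 1e-10})
        raise ValueError(
            f"singular design; collinear columns involve {bad or list(names)}"
        )
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    return float(fit.rsquared_adj)


def variance_partition(
    data: pd.DataFrame, response: str,
    set1: Sequence[str], set2: Sequence[str],
) -> VPAResult:
    """Partition the adjusted R² of ``response`` between two predictor sets.

    unique1 = adjR²(both) - adjR²(set2); unique2 symmetric; shared =
    adjR²(set1) + adjR²(set2) - adjR²(both); residual = 1 - adjR²(both).
    The three fractions sum to adjR²(both) exactly; negative values (an
    adjusted-R² artifact) are reported as-is.
    """
    d = data[[response, *set1, *set2]].dropna()
    n = len(d)
    if n <= len(set1) + len(set2) + 2:
        raise ValueError("too few rows for the requested predictor sets")
    y = d[response].to_numpy(dtype=float)
    X1 = d[list(set1)].to_numpy(dtype=float)
    X2 = d[list(set2)].to_numpy(dtype=float)
    both = np.column_stack([X1, X2])
    r_full = _adj_r2(y, both, [*set1, *set2])
    r1 = _adj_r2(y, X1, list(set1))
    r2 = _adj_r2(y, X2, list(set2))
    return VPAResult(
        unique1=r_full - r2,
        unique2=r_full - r1,
        shared=r1 + r2 - r_full,
        residual=1.0 - r_full,
        adj_r2_full=r_full,
        set1=tuple(set1),
        set2=tuple(set2),
    )


# ---------------------------------------------------------------------------
# PLS path modeling
# ---------------------------------------------------------------------------


@dataclass
class PathModelResult:
    """Inner paths, outer loadings, block communalities, R², and GOF."""

    path_coefficients: pd.DataFrame  # rows: target, cols: source (nan if no path)
    loadings: dict[str, dict[str, float]]
    communalities: dict[str, float]
    r2: dict[str, float]
    gof: float
    scores: pd.DataFrame = field(repr=False)
    n_iter: int = 0
    boot_se: pd.DataFrame | None = field(default=None, repr=False)
    boot_p: pd.DataFrame | None = field(default=None, repr=False)


class PLSPathModel:
    """Partial least squares path model (mode A, path weighting scheme).

    Parameters
    ----------
    blocks:
        Mapping latent-variable name -> list of manifest indicator columns.
    paths:
        Directed inner model as (source, target) latent pairs; must be
        recursive (acyclic).
    tol, max_iter:
        Outer-weight convergence threshold (max absolute change) and
        iteration cap.

    After :meth:`fit`: ``path_coefficients_``, ``loadings_``,
    ``communalities_``, ``r2_``, ``gof_``, ``scores_``, ``n_iter_``.
    """

    def __init__(
        self,
        blocks: Mapping[str, Sequence[str]],
        paths: Sequence[tuple[str, str]],
        tol: float = 1e-6,
        max_iter: int = 300,
    ):
        self.blocks = {k: list(v) for k, v in blocks.items()}
        self.paths = [tuple(p) for p in paths]
        self.tol = tol
        self.max_iter = max_iter
        names = list(self.blocks)
        for s, t in self.paths:
            if s not in names or t not in names:
                raise ValueError(f"path {s}->{t} references unknown block")
        self._order = self._topological_order()

    def _topological_order(self) -> list[str]:
        names = list(self.blocks)
        preds = {n: {s for s, t in self.paths if t == n} for n in names}
        order, done = [], set()
        while len(order) < len(names):
            ready = [n for n in names if n not in done and preds[n] <= done]
            if not ready:
                raise ValueError("inner path model contains a cycle")
            order.extend(ready)
            done.update(ready)
        return order

    # -- estimation --------------------------------------------------------

    def _standardized_blocks(self, data: pd.DataFrame) -> dict[str, np.ndarray]:
        out = {}
        for name, cols in self.blocks.items():
            X = data[cols].to_numpy(dtype=float)
            out[name] = np.column_stack([_zscore(X[:, j]) for j in range(X.shape[1])])
        return out

    def _iterate_weights(self, Xb: dict[str, np.ndarray]) -> tuple[dict, int]:
        names = list(self.blocks)
        n = next(iter(Xb.values())).shape[0]
        adj_in = {t: [s for s, tt in self.paths if tt == t] for t in names}
        adj_out = {s: [t for ss, t in self.paths if ss == s] for s in names}
        w = {b: np.ones(Xb[b].shape[1]) for b in names}

        def score(b, wb):
            y = Xb[b] @ wb
            return y / y.std(ddof=1)

        Y = {b: score(b, w[b]) for b in names}
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            Z = {}
            for b in names:
                z = np.zeros(n)
                preds = adj_in[b]
                if preds:  # path scheme: regression weights on predecessors
                    P = np.column_stack([Y[p] for p in preds])
                    beta, *_ = np.linalg.lstsq(P, Y[b], rcond=None)
                    z = z + P @ beta
                for succ in adj_out[b]:  # successors: correlation weights
                    r = float(np.corrcoef(Y[b], Y[succ])[0, 1])
                    z = z + r * Y[succ]
                if not preds and not adj_out[b]:
                    raise ValueError(f"latent block {b!r} is isolated")
                Z[b] = z / z.std(ddof=1)
            w_new = {}
            for b in names:  # mode A: outer weights are indicator covariances
                w_new[b] = Xb[b].T @ Z[b] / (n - 1)
                # fix sign so the score correlates positively with its indicators
                if w_new[b].sum() < 0:
                    w_new[b] = -w_new[b]
            delta = max(
                float(np.max(np.abs(np.abs(w_new[b]) - np.abs(w[b]))))
                for b in names
            )
            w = w_new
            Y = {b: score(b, w[b]) for b in names}
            if delta < self.tol:
                break
        else:
            raise RuntimeError(
                f"PLS-PM outer weights did not converge in {self.max_iter} "
                f"iterations (last change {delta:.2e})"
            )
        return {b: Y[b] for b in names}, n_iter

    def _inner_paths(self, Y: dict[str, np.ndarray]) -> tuple[pd.DataFrame, dict]:
        names = list(self.blocks)
        coefs = pd.DataFrame(np.nan, index=names, columns=names)
        r2: dict[str, float] = {}
        for t in names:
            preds = [s for s, tt in self.paths if tt == t]
            if not preds:
                continue
            P = np.column_stack([Y[p] for p in preds])
            beta, *_ = np.linalg.lstsq(P, Y[t], rcond=None)
            fittedv = P @ beta
            r2[t] = float(1.0 - np.var(Y[t] - fittedv) / np.var(Y[t]))
            for p, b in zip(preds, beta):
                coefs.loc[t, p] = float(b)
        return coefs, r2

    def fit(self, data: pd.DataFrame) -> "PLSPathModel":
        """Estimate the model on ``data`` (rows = plots)."""
        Xb = self._standardized_blocks(data)
        Y, n_iter = self._iterate_weights(Xb)
        coefs, r2 = self._inner_paths(Y)
        loadings = {
            b: {
                col: float(np.corrcoef(Xb[b][:, j], Y[b])[0, 1])
                for j, col in enumerate(self.blocks[b])
            }
            for b in self.blocks
        }
        comm = {b: float(np.mean([l * l for l in loadings[b].values()]))
                for b in self.blocks}
        mean_comm = float(np.mean(list(comm.values())))
        mean_r2 = float(np.mean(list(r2.values()))) if r2 else float("nan")
        self.path_coefficients_ = coefs
        self.loadings_ = loadings
        self.communalities_ = comm
        self.r2_ = r2
        self.gof_ = float(np.sqrt(mean_comm * mean_r2))
        self.scores_ = pd.DataFrame(Y, index=data.index)
        self.n_iter_ = n_iter
        self._data = data
        return self

    def bootstrap(self, n_boot: int = 500, seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Bootstrap standard errors and two-sided p-values for inner paths."""
        if not hasattr(self, "path_coefficients_"):
            raise RuntimeError("fit the model before bootstrapping")
        rng = np.random.default_rng(seed)
        n = len(self._data)
        draws = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            sample = self._data.iloc[idx]
            try:
                m = PLSPathModel(self.blocks, self.paths, self.tol, self.max_iter)
                m.fit(sample)
                draws.append(m.path_coefficients_.to_numpy())
            except (ValueError, RuntimeError):
                continue
        arr = np.array(draws)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sd = np.nanstd(arr, axis=0, ddof=1)
        se = pd.DataFrame(
            sd,
            index=self.path_coefficients_.index,
            columns=self.path_coefficients_.columns,
        )
        t = self.path_coefficients_ / se
        from scipy import stats as sps
        p = pd.DataFrame(
            2 * sps.t.sf(np.abs(t.to_numpy()), df=max(n - 1, 1)),
            index=se.index, columns=se.columns,
        )
        self.boot_se_, self.boot_p_ = se, p
        return se, p

    def result(self) -> PathModelResult:
        return PathModelResult(
            path_coefficients=self.path_coefficients_,
            loadings=self.loadings_,
            communalities=self.communalities_,
            r2=self.r2_,
            gof=self.gof_,
            scores=self.scores_,
            n_iter=self.n_iter_,
            boot_se=getattr(self, "boot_se_", None),
            boot_p=getattr(self, "boot_p_", None),
        )

    # sklearn-style parameter access
    def get_params(self, deep: bool = True) -> dict:
        return {"blocks": self.blocks, "paths": self.paths,
                "tol": self.tol, "max_iter": self.max_iter}

    def set_params(self, **params) -> "PLSPathModel":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self


def fit_plspm(
    data: pd.DataFrame,
    blocks: Mapping[str, Sequence[str]],
    paths: Sequence[tuple[str, str]],
    n_boot: int = 500,
    seed: int | None = None,
) -> PathModelResult:
    """One-call PLS-PM fit with bootstrap path significance."""
    model = PLSPathModel(blocks, paths).fit(data)
    if n_boot:
        model.bootstrap(n_boot=n_boot, seed=seed)
    return model.result()
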