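"""Hierarchical learning-curve models for arcsine-transformed success rates.

The full model for bee *n*'s arcsine success y at visit count x is

    y_nx = i + l·ln(x) + T·s_t + T·ln(x)·c_t + C·s_c + C·ln(x)·c_c
           + b_n + r_n·ln(x) + e_nx

where T and C are Boolean group indicators (T = 1 for the circle/cross
reward group, C = 1 for the control group; the bar reward group is the
baseline), b_n ~ N(0, sigma_b^2) and r_n ~ N(0, sigma_r^2) are independent
per-bee random intercepts and slopes, and e ~ N(0, sigma^2).

Fitting is by maximum likelihood on the Gaussian marginal: the per-bee
covariance is sigma^2 (I + g_b 11' + g_r zz') with variance ratios
g = sigma_b^2/sigma^2 etc.; fixed effects and the residual variance are
profiled out and the ratios optimised on the log scale (floored at 1e-10).
ML rather than REML is used throughout so that AIC is comparable across
fixed-effect structures.  AIC = deviance + 2k with deviance = -2 log L and
k = #fixed effects + #active variance components + 1 (residual).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "ModelSpec",
    "Design",
    "LearningCurveModel",
    "LearningCurveResults",
    "build_design",
    "information_criteria",
]

_LOG_FLOOR = math.log(1e-10)  # variance-ratio floor on the log scale
_GROUP_TC = {"bar_rewarded": (0, 0), "circle_rewarded": (1, 0), "control": (0, 1)}


@dataclass(frozen=True)
class ModelSpec:
    """Which terms of the full model are active.

    The term hierarchy is enforced: group-by-experience interactions require
    both the learning slope and the group intercepts.
    """

    include_learning: bool = True
    include_group_intercepts: bool = True
    include_group_slopes: bool = True
    include_bee_intercepts: bool = True
    include_bee_slopes: bool = True
    predictor_transform: str = "ln"

    def __post_init__(self) -> None:
        if self.include_group_slopes and not (
            self.include_learning and self.include_group_intercepts
        ):
            raise ValueError(
                "group-by-experience slopes require include_learning and "
                "include_group_intercepts"
            )
        if self.predictor_transform not in ("ln", "identity"):
            raise ValueError(f"unknown predictor_transform {self.predictor_transform!r}")

    @classmethod
    def full(cls) -> "ModelSpec":
        return cls()

    @classmethod
    def intercept_only(cls) -> "ModelSpec":
        return cls(
            include_learning=False,
            include_group_intercepts=False,
            include_group_slopes=False,
            include_bee_intercepts=False,
            include_bee_slopes=False,
        )

    @classmethod
    def per_group(cls) -> "ModelSpec":
        """The single-group model y = i + l·ln(x) + b_n."""
        return cls(
            include_group_intercepts=False,
            include_group_slopes=False,
            include_bee_slopes=False,
        )

    def drop(self, **kwargs) -> "ModelSpec":
        """Copy of this spec with the named include_* switches turned off."""
        updates = {}
        for name in kwargs:
            if not name.startswith("include_") or not hasattr(self, name):
                raise ValueError(f"unknown term switch {name!r}")
            updates[name] = False
        return ModelSpec(**{**self.__dict__, **updates})

    @property
    def fixed_terms(self) -> tuple:
        terms = ["intercept"]
        if self.include_learning:
            terms.append("l")
        if self.include_group_intercepts:
            terms += ["s_t", "s_c"]
        if self.include_group_slopes:
            terms += ["c_t", "c_c"]
        return tuple(terms)

    @property
    def n_fixed(self) -> int:
        return len(self.fixed_terms)

    @property
    def n_variance_components(self) -> int:
        return int(self.include_bee_intercepts) + int(self.include_bee_slopes)

    @property
    def k(self) -> int:
        """Parameter count entering AIC (fixed + variance comps + residual)."""
        return self.n_fixed + self.n_variance_components + 1

    @property
    def term_set(self) -> frozenset:
        return frozenset(
            name
            for name in (
                "include_learning",
                "include_group_intercepts",
                "include_group_slopes",
                "include_bee_intercepts",
                "include_bee_slopes",
            )
            if getattr(self, name)
        )

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return self.term_set <= other.term_set


@dataclass
class Design:
    """Assembled regression problem: response, fixed-effect matrix, bee grouping."""

    y: np.ndarray
    X: np.ndarray
    z: np.ndarray  # random-slope covariate (transformed x), one entry per row
    bee_index: np.ndarray  # dense 0..n_bees-1 codes, rows sorted by bee
    bee_ids: np.ndarray
    colnames: tuple
    spec: ModelSpec

    @property
    def n_bees(self) -> int:
        return len(self.bee_ids)


def _transform_x(x: np.ndarray, spec: ModelSpec) -> np.ndarray:
    return np.log(x) if spec.predictor_transform == "ln" else x.astype(float)


def build_design(series: pd.DataFrame, spec: ModelSpec) -> Design:
    """Build the fixed-effect matrix and random-effect layout for a success series.

    ``series`` must have columns bee_id, group, x, theta.  Groups map to the
    Boolean indicators (T, C): bar_rewarded -> (0,0), circle_rewarded ->
    (1,0), control -> (0,1).
    """
    unknown = set(series["group"].unique()) - set(_GROUP_TC)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    df = series.sort_values(["bee_id", "x"], kind="mergesort").reset_index(drop=True)
    x = df["x"].to_numpy(dtype=float)
    if np.any(x < 1):
        raise ValueError("visit counts must be >= 1")
    z = _transform_x(x, spec)
    tc = np.array([_GROUP_TC[g] for g in df["group"]], dtype=float)
    cols = [np.ones(len(df))]
    names = ["intercept"]
    if spec.include_learning:
        cols.append(z)
        names.append("l")
    if spec.include_group_intercepts:
        cols += [tc[:, 0], tc[:, 1]]
        names += ["s_t", "s_c"]
    if spec.include_group_slopes:
        cols += [tc[:, 0] * z, tc[:, 1] * z]
        names += ["c_t", "c_c"]
    X = np.column_stack(cols)
    bee_ids, bee_index = np.unique(df["bee_id"].to_numpy(), return_inverse=True)
    return Design(
        y=df["theta"].to_numpy(dtype=float),
        X=X,
        z=z,
        bee_index=bee_index,
        bee_ids=bee_ids,
        colnames=tuple(names),
        spec=spec,
    )


def _bee_blocks(design: Design) -> list:
    """Batched per-bee blocks, grouped by shared random-slope pattern.

    Bees whose transformed-x vectors coincide (the balanced canonical design)
    share one marginal covariance, so their whitening solves are batched:
    each entry is (z, B) with z the shared pattern (length ni) and B the
    stacked [X | y] array of shape (m_bees, ni, p + 1).
    """
    order = np.argsort(design.bee_index, kind="mergesort")
    bounds = np.searchsorted(design.bee_index[order], np.arange(design.n_bees + 1))
    p = design.X.shape[1]
    groups: dict = {}
    for i in range(design.n_bees):
        rows = order[bounds[i] : bounds[i + 1]]
        z = design.z[rows]
        key = (z.size, z.tobytes())
        groups.setdefault(key, (z, []))[1].append(
            np.column_stack([design.X[rows], design.y[rows]])
        )
    return [(z, np.stack(mats)) for z, mats in groups.values()]


def _profiled_nll_parts(blocks, n: int, p: int, g_b: float, g_r: float):
    """Profiled -2 log-likelihood pieces given variance ratios.

    Returns (deviance, beta, sigma2, XtWiX_inv).  W_i = I + g_b 11' + g_r zz'
    per bee; beta is the GLS estimate, sigma2 the profiled residual variance.
    """
    from scipy.linalg import solve_triangular

    XtWX = np.zeros((p, p))
    XtWy = np.zeros(p)
    logdet = 0.0
    whitened = []
    for z, B in blocks:
        ni = z.size
        m = B.shape[0]
        W = np.eye(ni) + g_b + g_r * np.outer(z, z)
        cW = np.linalg.cholesky(W)
        logdet += 2.0 * m * np.log(np.diag(cW)).sum()
        # whiten all m bees of this pattern in one triangular solve
        flat = B.transpose(1, 0, 2).reshape(ni, m * (p + 1))
        A = solve_triangular(cW, flat, lower=True).reshape(ni, m, p + 1).transpose(1, 0, 2)
        whitened.append(A)
        Ax = A[:, :, :p].reshape(m * ni, p)
        Ay = A[:, :, p].reshape(m * ni)
        XtWX += Ax.T @ Ax
        XtWy += Ax.T @ Ay
    try:
        XtWX_inv = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular fixed-effect design") from exc
    beta = XtWX_inv @ XtWy
    rss = 0.0
    for A in whitened:
        resid = A[:, :, p] - A[:, :, :p] @ beta
        rss += float((resid * resid).sum())
    sigma2 = max(rss / n, 1e-12)  # floor keeps perfect fits comparable
    deviance = n * math.log(2.0 * math.pi * sigma2) + logdet + n
    return deviance, beta, sigma2, XtWX_inv


@dataclass
class LearningCurveResults:
    """ML fit of one learning-curve model.

    Carries the fixed-effect estimates with standard errors, the variance
    components, log-likelihood, deviance (-2 log L), parameter count k and
    AIC = deviance + 2k, plus a statsmodels-flavoured ``summary()``.
    """

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    sigma2: float
    sigma2_bee_intercept: float
    sigma2_bee_slope: float
    llf: float
    nobs: int
    n_bees: int
    design: Design = field(repr=False)

    @property
    def deviance(self) -> float:
        return -2.0 * self.llf

    @property
    def k(self) -> int:
        return self.spec.k

    @property
    def aic(self) -> float:
        return self.deviance + 2.0 * self.k

    def predict(self, group: str, xs) -> pd.DataFrame:
        """Population-level curve (bee deviations at zero) for one group.

        Returns theta and probability = sin^2(theta) at each visit count.
        """
        xs = np.asarray(xs, dtype=float)
        if np.any(xs < 1):
            raise ValueError("visit counts must be >= 1")
        z = np.log(xs) if self.spec.predictor_transform == "ln" else xs
        T, C = _GROUP_TC[group]
        beta = self.params
        theta = np.full(xs.shape, beta["intercept"], dtype=float)
        if self.spec.include_learning:
            theta = theta + beta["l"] * z
        if self.spec.include_group_intercepts:
            theta = theta + beta["s_t"] * T + beta["s_c"] * C
        if self.spec.include_group_slopes:
            theta = theta + (beta["c_t"] * T + beta["c_c"] * C) * z
        return pd.DataFrame(
            {"x": xs, "theta": theta, "probability": np.sin(theta) ** 2}
        )

    def summary(self) -> str:
        lines = [
            "Learning-curve model (Gaussian ML)",
            "=" * 46,
            f"observations: {self.nobs}    bees: {self.n_bees}",
            f"fixed terms:  {', '.join(self.spec.fixed_terms)}",
            "-" * 46,
            f"{'term':<12}{'estimate':>12}{'std err':>12}",
        ]
        for name in self.params.index:
            lines.append(f"{name:<12}{self.params[name]:>12.4f}{self.bse[name]:>12.4f}")
        lines.append("-" * 46)
        if self.spec.include_bee_intercepts:
            lines.append(f"sigma2_bee_intercept  {self.sigma2_bee_intercept:.6f}")
        if self.spec.include_bee_slopes:
            lines.append(f"sigma2_bee_slope      {self.sigma2_bee_slope:.6f}")
        lines.append(f"sigma2_residual       {self.sigma2:.6f}")
        lines.append(
            f"loglik {self.llf:.3f}  deviance {self.deviance:.3f}  "
            f"k {self.k}  AIC {self.aic:.3f}"
        )
        return "\n".join(lines)

    def to_report(self) -> str:
        """Flat key-value text report (one `name value` pair per line)."""
        pairs = [(name, self.params[name]) for name in self.params.index]
        pairs += [
            ("sigma2_bee_intercept", self.sigma2_bee_intercept),
            ("sigma2_bee_slope", self.sigma2_bee_slope),
            ("sigma2_residual", self.sigma2),
            ("loglik", self.llf),
            ("deviance", self.deviance),
            ("k", self.k),
            ("AIC", self.aic),
        ]
        return "\n".join(f"{name} {value:.10g}" for name, value in pairs)


class LearningCurveModel:
    """Hierarchical learning-curve model bound to a success series.

    Parameters
    ----------
    series:
        Per-bee windowed success table with columns bee_id, group, x, theta
        (the output of :func:`thermoflor.scoring.success_series`).
    spec:
        Which model terms are active; defaults to the full model.
    """

    def __init__(self, series: pd.DataFrame, spec: ModelSpec | None = None):
        self.spec = spec or ModelSpec.full()
        self.design = build_design(series, self.spec)
        if self.design.y.size < self.spec.k:
            raise ValueError("fewer observations than parameters")
        self._check_rank()

    @classmethod
    def from_dataframe(cls, series: pd.DataFrame, spec: ModelSpec | None = None):
        return cls(series, spec=spec)

    def _check_rank(self) -> None:
        X = self.design.X
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # name the offending columns for the error message
            _, r = np.linalg.qr(X)
            bad = [
                self.design.colnames[j]
                for j in range(X.shape[1])
                if abs(r[j, j]) < 1e-8 * max(1.0, abs(r[0, 0]))
            ]
            raise ValueError(f"singular design; collinear columns: {bad}")

    def fit(self) -> LearningCurveResults:
        """Maximise the Gaussian marginal likelihood.

        Variance ratios are optimised on the log scale from a fixed grid of
        starting points (deterministic), with the floor 1e-10 treated as an
        exact zero; with no random effects the fit reduces to OLS with its
        closed-form ML variance.
        """
        design = self.design
        spec = self.spec
        blocks = _bee_blocks(design)
        n = design.y.size
        p = design.X.shape[1]

        has_b = spec.include_bee_intercepts
        has_r = spec.include_bee_slopes
        ndim = int(has_b) + int(has_r)

        def unpack(v):
            vals = iter(v)
            g_b = math.exp(next(vals)) if has_b else 0.0
            g_r = math.exp(next(vals)) if has_r else 0.0
            return max(g_b, 0.0), max(g_r, 0.0)

        def nll(v):
            g_b, g_r = unpack(np.clip(v, _LOG_FLOOR, 12.0))
            return _profiled_nll_parts(blocks, n, p, g_b, g_r)[0]

        if ndim == 0:
            g_b = g_r = 0.0
        else:
            # coarse deterministic grid, then Nelder-Mead polish from the
            # best two grid points
            grid = [math.log(s) for s in (1e-9, 1e-3, 0.05, 0.3, 1.0, 4.0, 20.0)]
            if ndim == 1:
                candidates = [np.array([s]) for s in grid]
            else:
                candidates = [np.array([a, b]) for a in grid for b in grid]
            scored = sorted(candidates, key=nll)
            best_v, best_f = None, np.inf
            for v0 in scored[:2]:
                res = optimize.minimize(
                    nll,
                    v0,
                    method="Nelder-Mead",
                    options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 1000},
                )
                if res.fun < best_f - 1e-12:
                    best_f, best_v = res.fun, np.clip(res.x, _LOG_FLOOR, 12.0)
            g_b, g_r = unpack(best_v)
            # snap near-floor ratios to exactly zero when that costs nothing
            g_b0 = 0.0 if g_b < 1e-8 else g_b
            g_r0 = 0.0 if g_r < 1e-8 else g_r
            if (g_b0, g_r0) != (g_b, g_r):
                if _profiled_nll_parts(blocks, n, p, g_b0, g_r0)[0] <= best_f + 1e-9:
                    g_b, g_r = g_b0, g_r0

        deviance, beta, sigma2, XtWX_inv = _profiled_nll_parts(blocks, n, p, g_b, g_r)
        cov = sigma2 * XtWX_inv
        names = list(design.colnames)
        params = pd.Series(beta, index=names)
        bse = pd.Series(np.sqrt(np.diag(cov)), index=names)
        return LearningCurveResults(
            spec=spec,
            params=params,
            bse=bse,
            cov_params=pd.DataFrame(cov, index=names, columns=names),
            sigma2=sigma2,
            sigma2_bee_intercept=g_b * sigma2,
            sigma2_bee_slope=g_r * sigma2,
            llf=-deviance / 2.0,
            nobs=design.y.size,
            n_bees=design.n_bees,
            design=design,
        )


def information_criteria(fit: LearningCurveResults) -> tuple:
    """(deviance, k, AIC) of a fit; AIC = deviance + 2k exactly."""
    return fit.deviance, fit.k, fit.deviance + 2 * fit.k
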