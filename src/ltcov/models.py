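"""Hierarchy and connectivity models.

Asymmetry-based hierarchy from directed connectivity; exponential
distance models of edge values; logistic models of structural-connection
likelihood; windowed connection-probability curves; and edge-table
utilities over the lower triangle of parcel matrices.

The regression stages are scikit-learn style estimators
(`ExponentialDecayModel`, `ConnectionProbabilityModel`); thin functions
wrap them for one-shot use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit
from scipy.stats import pearsonr, spearmanr
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "asymmetry_hierarchy",
    "edge_table",
    "ExponentialDecayModel",
    "ConnectionProbabilityModel",
    "exponential_distance_fit",
    "residualize_distance",
    "sc_likelihood_model",
    "window_probability_curve",
    "edge_correlation",
    "subset_long_range",
    "FitResult",
]


@dataclass
class FitResult:
    """A fitted edge model with its goodness-of-fit and provenance."""

    model: str
    coefficients: dict[str, float]
    gof: float
    gof_name: str
    n_edges: int
    p_value: float | None = None
    extra: dict = field(default_factory=dict)


def asymmetry_hierarchy(weights) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted unsigned out-degree minus in-degree per region.

    h_i = sum_j |A_ij| - sum_j |A_ji| with the diagonal excluded; returns
    (hierarchy, out_degree, in_degree). The scores sum to zero exactly.
    """
    A = np.abs(np.asarray(getattr(weights, "weights", weights), dtype=float))
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("connectivity matrix must be square")
    np.fill_diagonal(A, 0.0)
    out_deg = A.sum(axis=1)
    in_deg = A.sum(axis=0)
    return out_deg - in_deg, out_deg, in_deg


def edge_table(parcels: np.ndarray | None = None, **matrices) -> pd.DataFrame:
    """Lower-triangle edge table of one or more aligned parcel matrices.

    Keyword arguments are P x P matrices; the result has one row per
    unordered pair (i > j) restricted to ``parcels`` if given, with a
    column per matrix. NaN entries mark undefined edges.
    """
    if not matrices:
        raise ValueError("at least one matrix required")
    mats = {k: np.asarray(v, dtype=float) for k, v in matrices.items()}
    P = next(iter(mats.values())).shape[0]
    for k, v in mats.items():
        if v.shape != (P, P):
            raise ValueError(f"matrix {k!r} is not aligned")
    if parcels is None:
        parcels = np.arange(P)
    parcels = np.asarray(parcels)
    ii, jj = np.tril_indices(len(parcels), k=-1)
    gi, gj = parcels[ii], parcels[jj]
    data = {"i": gi, "j": gj}
    for k, v in mats.items():
        data[k] = v[gi, gj]
    return pd.DataFrame(data)


def _exp_model(d, a, lam, c):
    return a * np.exp(-d / lam) + c


class ExponentialDecayModel(BaseEstimator, RegressorMixin):
    """Nonlinear least-squares fit of y = a * exp(-d / lambda) + c.

    Initialization a = range(y), lambda = median(d), c = min(y), with a
    few jittered restarts on non-convergence. ``score`` and ``r2_`` are
    1 - SS_res / SS_tot on the original scale.
    """

    def __init__(self, max_restarts: int = 5, random_state: int = 0):
        self.max_restarts = max_restarts
        self.random_state = random_state

    def fit(self, d, y):
        d = np.asarray(d, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        ok = np.isfinite(d) & np.isfinite(y)
        d, y = d[ok], y[ok]
        if len(y) < 10:
            raise ValueError("need at least 10 defined edges")
        if (d <= 0).any():
            raise ValueError("distances must be positive")
        if np.ptp(y) == 0:
            raise ValueError("degenerate fit: response is constant")
        p0 = np.array([np.ptp(y), np.median(d), y.min()])
        rng = np.random.default_rng(self.random_state)
        last_err = None
        for attempt in range(self.max_restarts):
            start = p0 if attempt == 0 else p0 * rng.uniform(0.5, 2.0, size=3)
            try:
                popt, _ = curve_fit(
                    _exp_model, d, y, p0=start,
                    bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
                    maxfev=20000,
                )
                break
            except RuntimeError as err:  # pragma: no cover - rare
                last_err = err
        else:  # pragma: no cover
            raise RuntimeError(f"exponential fit failed after {self.max_restarts} restarts: {last_err}")
        self.a_, self.lambda_, self.c_ = (float(v) for v in popt)
        resid = y - _exp_model(d, *popt)
        ss_tot = ((y - y.mean()) ** 2).sum()
        self.r2_ = float(1.0 - (resid**2).sum() / ss_tot)
        self.n_edges_ = len(y)
        return self

    def predict(self, d):
        check_is_fitted(self, "lambda_")
        return _exp_model(np.asarray(d, dtype=float), self.a_, self.lambda_, self.c_)

    def result(self) -> FitResult:
        check_is_fitted(self, "lambda_")
        return FitResult(
            model="exponential_decay",
            coefficients={"a": self.a_, "lambda": self.lambda_, "c": self.c_},
            gof=self.r2_, gof_name="r2", n_edges=self.n_edges_,
        )


class ConnectionProbabilityModel(BaseEstimator):
    """Logistic regression of binary connection status on edge predictors.

    Predictors are standardized internally; the fit is maximum-likelihood
    (statsmodels Logit) with an intercept. ``pseudo_r2_`` is McFadden's
    1 - l_model / l_null by default (Cox-Snell selectable).
    """

    def __init__(self, pseudo_r2: str = "mcfadden"):
        self.pseudo_r2 = pseudo_r2

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float).ravel()
        ok = np.isfinite(X).all(axis=1) & np.isfinite(y)
        X, y = X[ok], y[ok]
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("outcome has a single class; logistic fit undefined")
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (X - mu) / sd
        design = sm.add_constant(Xs)
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except Exception as err:
            raise RuntimeError(
                "logistic fit failed (possibly complete separation); consider a "
                f"regularized fit: {err}"
            ) from err
        if not res.mle_retvals.get("converged", True):
            raise RuntimeError("logistic fit did not converge (possible complete separation); "
                               "consider a regularized fit")
        params = np.asarray(res.params, dtype=float)
        self.intercept_ = float(params[0])
        self.coef_ = params[1:]
        if self.pseudo_r2 == "mcfadden":
            self.pseudo_r2_ = float(1.0 - res.llf / res.llnull)
        elif self.pseudo_r2 == "cox-snell":
            n = len(y)
            self.pseudo_r2_ = float(1.0 - np.exp(2.0 * (res.llnull - res.llf) / n))
        else:
            raise ValueError(f"unknown pseudo_r2 {self.pseudo_r2!r}")
        self.n_edges_ = len(y)
        self._scale = (mu, sd)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        mu, sd = self._scale
        eta = self.intercept_ + ((X - mu) / sd) @ self.coef_
        p = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1 - p, p])

    def result(self) -> FitResult:
        check_is_fitted(self, "coef_")
        coefs = {"intercept": self.intercept_}
        coefs.update({f"beta_{k}": float(b) for k, b in enumerate(self.coef_)})
        return FitResult(
            model="logistic", coefficients=coefs,
            gof=self.pseudo_r2_, gof_name=f"pseudo_r2_{self.pseudo_r2}",
            n_edges=self.n_edges_,
        )


def exponential_distance_fit(y, gd) -> ExponentialDecayModel:
    """One-shot exponential decay fit of edge values on distances."""
    return ExponentialDecayModel().fit(gd, y)


def residualize_distance(matrix, gd) -> "CovarianceMatrix":
    """Regress the exponential distance trend out of a covariance matrix.

    Fits y = a exp(-d / lambda) + c over defined lower-triangle edges and
    places the residuals back into a symmetric matrix; undefined entries
    stay undefined.
    """
    from .covariance import CovarianceMatrix

    vals = np.asarray(getattr(matrix, "values", matrix), dtype=float)
    dmat = np.asarray(getattr(gd, "distances", gd), dtype=float)
    i, j = np.tril_indices(vals.shape[0], k=-1)
    y, d = vals[i, j], dmat[i, j]
    ok = np.isfinite(y) & np.isfinite(d) & (d > 0)
    model = ExponentialDecayModel().fit(d[ok], y[ok])
    resid = np.full_like(vals, np.nan)
    r = y[ok] - model.predict(d[ok])
    resid[i[ok], j[ok]] = r
    resid[j[ok], i[ok]] = r
    kind = getattr(matrix, "kind", "residual")
    return CovarianceMatrix(resid, kind=f"{kind}-residual",
                            fisher_z=getattr(matrix, "fisher_z", False),
                            parcel_ids=getattr(matrix, "parcel_ids", None))


def sc_likelihood_model(sc_binary, *predictors) -> ConnectionProbabilityModel:
    """One-shot logistic model of connection likelihood on edge predictors."""
    X = np.column_stack([np.asarray(p, dtype=float).ravel() for p in predictors])
    return ConnectionProbabilityModel().fit(X, sc_binary)


def window_probability_curve(sc_binary, predictor, n_windows: int = 200) -> pd.DataFrame:
    """Connection probability in contiguous windows of edges sorted by predictor.

    Edges are sorted by the predictor and split into ``n_windows``
    near-equal windows (sizes differ by at most 1); each row reports the
    window's mean predictor value, connection probability, and edge count.
    """
    sc = np.asarray(sc_binary, dtype=float).ravel()
    x = np.asarray(predictor, dtype=float).ravel()
    ok = np.isfinite(sc) & np.isfinite(x)
    sc, x = sc[ok], x[ok]
    n = len(sc)
    if n < n_windows:
        raise ValueError(f"need at least {n_windows} edges, got {n}")
    order = np.argsort(x, kind="stable")
    splits = np.array_split(order, n_windows)
    rows = [
        {"predictor_mean": float(x[s].mean()),
         "probability": float(sc[s].mean()),
         "n_edges": len(s)}
        for s in splits
    ]
    return pd.DataFrame(rows)


def edge_correlation(x_edges, y_edges, method: str = "pearson") -> FitResult:
    """Correlation of two edge (or point) vectors over mutually defined entries."""
    x = np.asarray(x_edges, dtype=float).ravel()
    y = np.asarray(y_edges, dtype=float).ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 defined points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; correlation undefined")
    if method == "pearson":
        r, p = pearsonr(x, y)
    elif method == "spearman":
        r, p = spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return FitResult(model=f"{method}_correlation", coefficients={"r": float(r)},
                     gof=float(r) ** 2, gof_name="r2", n_edges=len(x),
                     extra={"parametric_p": float(p)})


def subset_long_range(edges: pd.DataFrame, threshold_mm: float | None = None,
                      quantile: float | None = None, gd_column: str = "gd") -> pd.DataFrame:
    """Edges with geodesic distance above an absolute or quantile threshold.

    Default: upper tercile (quantile = 2/3) when neither is given.
    """
    if gd_column not in edges:
        raise ValueError(f"edge table lacks column {gd_column!r}")
    gd = edges[gd_column].to_numpy(dtype=float)
    if threshold_mm is None:
        q = 2.0 / 3.0 if quantile is None else quantile
        threshold_mm = float(np.nanquantile(gd, q))
        out = edges[gd > threshold_mm] if q > 0 else edges
    else:
        out = edges[gd > threshold_mm] if threshold_mm > 0 else edges
    if len(out) == 0:
        raise ValueError("long-range subset is empty")
    return out.reset_index(drop=True)
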