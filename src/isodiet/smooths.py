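"""Cyclic penalized regression splines and seasonal (H)GAMs.

The seasonal models treat day-of-year as a circular covariate: a
fitted curve and its first two derivatives must match at the ends of
the year so that late March joins smoothly onto early April.  The
basis is a cyclic cubic regression spline parameterized by the
function values at k knots spread over [1, 366], with the k-th knot
identified with the first.  Writing beta for the k-1 free knot values
and gamma for the second derivatives at the knots, the natural-spline
continuity conditions give a cyclic tridiagonal system B gamma =
D beta, the curve between knots is the usual cubic Hermite form in
(beta, gamma), and the curvature penalty is

    integral f''(x)^2 dx = beta' D' B^{-1} D beta.

The penalty's null space is the constant function, so heavy smoothing
collapses a fit to a flat line rather than to zero.

Fitting is penalized IRLS (binomial-logit or Gaussian identity), with
the smoothing parameter chosen by grid-search GCV; an approximate REML
criterion is available for Gaussian fits.  Hierarchical fits give each
group its own smooth and its own smoothing parameter ("model I" of the
hierarchical-GAM taxonomy), capturing group-specific seasonal shape
and wiggliness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CyclicSplineBasis",
    "build_cyclic_basis",
    "GamFit",
    "fit_gam",
    "HGamFit",
    "fit_hgam",
    "occurrence_curves",
]

PERIOD_DOMAIN = (1.0, 366.0)
DEFAULT_LAMBDA_GRID = np.logspace(-5, 9, 43)


@dataclass
class CyclicSplineBasis:
    """Cyclic cubic regression spline basis over a periodic domain."""

    knots: np.ndarray          # k knots; knots[-1] identified with knots[0]
    penalty: np.ndarray        # (k-1) x (k-1) PSD curvature penalty
    _binv_d: np.ndarray = field(repr=False, default=None)

    @property
    def k(self) -> int:
        return len(self.knots)

    @property
    def n_coef(self) -> int:
        return self.k - 1

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.knots[0]), float(self.knots[-1])

    def wrap(self, x) -> np.ndarray:
        lo, hi = self.domain
        period = hi - lo
        return (np.asarray(x, dtype=float) - lo) % period + lo

    def design_matrix(self, x) -> np.ndarray:
        """Rows of basis-function values at x (wrapped into the domain)."""
        x = np.atleast_1d(self.wrap(x))
        t = self.knots
        n = self.n_coef
        h = np.diff(t)
        j = np.clip(np.searchsorted(t, x, side="right") - 1, 0, self.k - 2)
        a = (t[j + 1] - x) / h[j]
        b = (x - t[j]) / h[j]
        A_beta = np.zeros((len(x), n))
        A_gamma = np.zeros((len(x), n))
        jn = j % n
        j1 = (j + 1) % n
        rows = np.arange(len(x))
        A_beta[rows, jn] += a
        A_beta[rows, j1] += b
        A_gamma[rows, jn] += (a ** 3 - a) * h[j] ** 2 / 6.0
        A_gamma[rows, j1] += (b ** 3 - b) * h[j] ** 2 / 6.0
        return A_beta + A_gamma @ self._binv_d


def build_cyclic_basis(
    k: int, domain: tuple[float, float] = PERIOD_DOMAIN
) -> CyclicSplineBasis:
    """Construct a cyclic cubic spline basis with k evenly spaced knots.

    k counts the knots including the wrap knot; there are k-1 free
    coefficients.  Requires k >= 4 for a sensible cubic fit.
    """
    if k < 4:
        raise ValueError("cyclic cubic basis needs k >= 4")
    lo, hi = domain
    t = np.linspace(lo, hi, k)
    h = np.diff(t)                      # k-1 interval widths
    n = k - 1
    # cyclic interval width "before" knot i (interval n-1 precedes knot 0)
    h_prev = np.roll(h, 1)
    B = np.zeros((n, n))
    D = np.zeros((n, n))
    for i in range(n):
        ip = (i + 1) % n
        im = (i - 1) % n
        B[i, i] = (h_prev[i] + h[i]) / 3.0
        B[i, ip] += h[i] / 6.0
        B[i, im] += h_prev[i] / 6.0
        D[i, i] = -(1.0 / h_prev[i] + 1.0 / h[i])
        D[i, ip] += 1.0 / h[i]
        D[i, im] += 1.0 / h_prev[i]
    binv_d = np.linalg.solve(B, D)
    S = D.T @ binv_d
    S = (S + S.T) / 2.0                 # symmetrize against round-off
    # normalize to unit spectral norm so lambda is scale-interpretable
    S = S / np.linalg.eigvalsh(S).max()
    return CyclicSplineBasis(knots=t, penalty=S, _binv_d=binv_d)


# ---------------------------------------------------------------------------
# penalized IRLS
# ---------------------------------------------------------------------------

class GamConvergenceError(RuntimeError):
    def __init__(self, message, trace):
        super().__init__(message)
        self.trace = trace


def _link(family):
    if family == "binomial":
        inv = lambda eta: 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        var = lambda mu: mu * (1.0 - mu)

        def dev(y, mu):
            mu = np.clip(mu, 1e-12, 1 - 1e-12)
            with np.errstate(divide="ignore", invalid="ignore"):
                t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
                t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
            return 2.0 * np.sum(t1 + t2)

        return inv, var, dev
    if family == "gaussian":
        inv = lambda eta: eta
        var = lambda mu: np.ones_like(mu)
        dev = lambda y, mu: float(np.sum((y - mu) ** 2))
        return inv, var, dev
    raise ValueError(f"unknown family {family!r}")


def _pirls(X, y, S, lam, family, max_iter=100, tol=1e-9):
    """Penalized IRLS at fixed lambda.  Returns beta, edf, deviance, W."""
    inv_link, var_fun, dev_fun = _link(family)
    n, p = X.shape
    if family == "gaussian":
        A = X.T @ X + lam * S
        beta = np.linalg.solve(A, X.T @ y)
        mu = X @ beta
        edf = float(np.trace(np.linalg.solve(A, X.T @ X)))
        return beta, edf, dev_fun(y, mu), np.ones(n)
    # binomial-logit
    beta = np.zeros(p)
    ybar = np.clip(np.mean(y), 1e-3, 1 - 1e-3)
    eta = np.full(n, np.log(ybar / (1 - ybar)))
    dev_old = np.inf
    trace = []
    for it in range(max_iter):
        mu = inv_link(eta)
        w = np.clip(var_fun(mu), 1e-10, None)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        A = X.T @ Xw + lam * S
        beta = np.linalg.solve(A, X.T @ (w * z))
        eta = X @ beta
        dev = dev_fun(y, inv_link(eta))
        trace.append(dev)
        if abs(dev_old - dev) < tol * (abs(dev) + 1e-8):
            break
        dev_old = dev
    else:
        raise GamConvergenceError(
            f"penalized IRLS failed to converge in {max_iter} iterations", trace
        )
    mu = inv_link(eta)
    w = np.clip(var_fun(mu), 1e-10, None)
    A = X.T @ (X * w[:, None]) + lam * S
    edf = float(np.trace(np.linalg.solve(A, X.T @ (X * w[:, None]))))
    return beta, edf, dev_fun(y, mu), w


def _gcv(n, deviance, edf):
    return n * deviance / max(n - edf, 1e-8) ** 2


def _reml_gaussian(X, y, S, lam, beta, edf):
    """Approximate (profiled) restricted-likelihood score; lower is better."""
    n = len(y)
    rss = float(np.sum((y - X @ beta) ** 2))
    pen = float(lam * beta @ S @ beta)
    m0 = 1  # penalty null-space dimension (constants)
    sigma2 = (rss + pen) / max(n - m0, 1)
    evals = np.linalg.eigvalsh(S)
    pos = evals[evals > 1e-10 * evals.max()]
    _, logdet_a = np.linalg.slogdet(X.T @ X + lam * S)
    logdet_lam_s = float(np.sum(np.log(lam * pos)))
    return (
        (rss + pen) / sigma2
        + (n - m0) * np.log(2 * np.pi * sigma2)
        + logdet_a
        - logdet_lam_s
    )


@dataclass
class GamFit:
    """A fitted penalized cyclic-spline smooth for one response."""

    basis: CyclicSplineBasis
    family: str
    coefficients: np.ndarray
    lam: float
    edf: float
    deviance: float
    p_value: float
    n_obs: int

    def predict_link(self, x) -> np.ndarray:
        return self.basis.design_matrix(x) @ self.coefficients

    def predict(self, x) -> np.ndarray:
        eta = self.predict_link(x)
        if self.family == "binomial":
            return 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        return eta


def _smooth_p_value(X, S, lam, beta, w, edf, family, deviance, n):
    """Wald-type test of the smooth against a constant.

    The statistic contrasts the fitted coefficients with their mean
    (removing the penalty null space) using the frequentist sandwich
    covariance, referred to a chi-square with edf-matched degrees of
    freedom (F for Gaussian, with the scale estimated from deviance).
    """
    p = len(beta)
    Xw = X * w[:, None]
    A = np.linalg.inv(X.T @ Xw + lam * S)
    V = A @ (X.T @ Xw) @ A  # frequentist covariance (unit scale)
    L = np.eye(p) - np.ones((p, p)) / p
    c = L @ beta
    Vc = L @ V @ L.T
    stat = float(c @ np.linalg.pinv(Vc, rcond=1e-10) @ c)
    df = max(edf - 1.0, 0.5)
    if family == "gaussian":
        scale = deviance / max(n - edf, 1.0)
        return float(stats.f.sf(stat / scale / df, df, max(n - edf, 1.0)))
    return float(stats.chi2.sf(stat, df))


def fit_gam(
    x,
    y,
    family: str = "gaussian",
    k: int = 8,
    basis: CyclicSplineBasis | None = None,
    lambda_grid=None,
    criterion: str = "gcv",
) -> GamFit:
    """Fit a cyclic-spline GAM of y on a periodic covariate x.

    The smoothing parameter is selected from ``lambda_grid`` by GCV
    (default) or, for Gaussian fits, an approximate REML score.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y lengths differ")
    if len(x) < 10:
        raise ValueError("need at least 10 observations")
    if family == "binomial" and not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binomial response must be 0/1")
    basis = basis or build_cyclic_basis(k)
    if basis.n_coef > len(np.unique(x)):
        raise ValueError("basis dimension exceeds number of unique x values")
    X = basis.design_matrix(x)
    S = basis.penalty
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid)

    best = None
    for lam in grid:
        beta, edf, dev, w = _pirls(X, y, S, lam, family)
        if criterion == "gcv" or family != "gaussian":
            score = _gcv(len(y), dev, edf)
        elif criterion == "reml":
            score = _reml_gaussian(X, y, S, lam, beta, edf)
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        if best is None or score < best[0]:
            best = (score, lam, beta, edf, dev, w)

    _, lam, beta, edf, dev, w = best
    pval = _smooth_p_value(X, S, lam, beta, w, edf, family, dev, len(y))
    return GamFit(
        basis=basis, family=family, coefficients=beta, lam=float(lam),
        edf=edf, deviance=dev, p_value=pval, n_obs=len(y),
    )


# ---------------------------------------------------------------------------
# hierarchical fits
# ---------------------------------------------------------------------------

@dataclass
class HGamFit:
    """Group-wise cyclic smooths with independent shape and wiggliness.

    Each group gets its own smooth (own smoothing parameter) plus an
    intercept defined as the mean of the fitted curve over the periodic
    domain, so group-level offsets are directly comparable.
    """

    fits: dict[str, GamFit]
    intercepts: dict[str, float]

    def predict(self, x, group) -> np.ndarray:
        return self.fits[group].predict(x)

    def groups(self):
        return list(self.fits)


def fit_hgam(
    x, y, groups, family: str = "gaussian", k: int = 8,
    lambda_grid=None, criterion: str = "gcv",
) -> HGamFit:
    """Fit one cyclic smooth per group (hierarchical "model I")."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("hierarchical fit needs at least 2 groups")
    fits, intercepts = {}, {}
    grid_days = np.linspace(*PERIOD_DOMAIN, 200)
    for g in uniq:
        mask = labels == g
        if mask.sum() < 10:
            raise ValueError(f"group {g!r} has fewer than 10 observations")
        fit = fit_gam(
            x[mask], y[mask], family=family, k=k,
            lambda_grid=lambda_grid, criterion=criterion,
        )
        fits[g] = fit
        intercepts[g] = float(np.mean(fit.predict_link(grid_days)))
    return HGamFit(fits=fits, intercepts=intercepts)


# ---------------------------------------------------------------------------
# prey occurrence curves
# ---------------------------------------------------------------------------

def occurrence_curves(
    prey: pd.DataFrame,
    stomachs: pd.DataFrame,
    taxa: list[str] | None = None,
    k: int = 6,
    min_stomachs: int = 5,
    rank: str = "family",
) -> pd.DataFrame:
    """Seasonal probability-of-occurrence curve per prey taxon.

    For each taxon present in at least ``min_stomachs`` stomachs, a
    binomial cyclic-spline GAM models presence/absence against
    day-of-year.  Returns one row per taxon with the fit, its peak day
    (argmax of the fitted curve over days 1-366) and a ``degenerate``
    flag for all-present/all-absent taxa (which are not fitted).
    """
    from .diet_metrics import aggregation_key

    work = prey.assign(_taxon=aggregation_key(prey, rank))
    doy = stomachs.set_index("stomach_id")["day_of_year"]
    all_ids = doy.index
    if taxa is None:
        counts = work.groupby("_taxon")["stomach_id"].nunique()
        taxa = list(counts[counts >= min_stomachs].index)

    days = np.arange(1, 367, dtype=float)
    rows = []
    for taxon in taxa:
        present_ids = set(work.loc[work["_taxon"] == taxon, "stomach_id"])
        y = np.asarray(all_ids.isin(present_ids), dtype=float)
        n_present = int(y.sum())
        if n_present < min_stomachs:
            continue
        if n_present == 0 or n_present == len(y):
            rows.append(
                {"taxon": taxon, "degenerate": True, "fit": None,
                 "peak_day": np.nan, "p_value": np.nan}
            )
            continue
        fit = fit_gam(doy.to_numpy(dtype=float), y, family="binomial", k=k)
        curve = fit.predict(days)
        rows.append(
            {"taxon": taxon, "degenerate": False, "fit": fit,
             "peak_day": int(days[np.argmax(curve)]), "p_value": fit.p_value}
        )
    return pd.DataFrame(rows)
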