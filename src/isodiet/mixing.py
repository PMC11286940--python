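"""Bayesian stable-isotope mixing model with diet-informed priors.

Estimates the proportional contribution p (a point on the simplex) of
K prey source groups to a consumer's diet from tracer measurements
(d13C, d15N, optionally d34S), accounting for:

* trophic discrimination factors (TDFs) — per-tracer enrichment
  Delta_j between diet and consumer tissue, with uncertainty;
* elemental concentration dependence — a source's contribution to a
  tracer is weighted by its elemental concentration of that element:

      mean_j    = sum_k p_k c_kj (mu_kj + Delta_j) / sum_k p_k c_kj
      procvar_j = sum_k (p_k c_kj)^2 (sigma_kj^2 + tau_j^2)
                  / (sum_k p_k c_kj)^2

* residual and process error — the consumer-level variance is the
  process variance scaled by a per-tracer multiplicative residual
  factor xi_j with a weakly informative Lognormal(0, 1) prior;
* an informative Dirichlet prior on p built from stomach-content data:
  alpha_k = K * (mean diet share of source k), so the alpha vector
  always sums to the number of sources and equal shares recover the
  uninformative Dirichlet(1, ..., 1).

Sampling is adaptive random-walk Metropolis in unconstrained space
(additive log-ratio coordinates for p, log coordinates for xi), with
step-size adaptation frozen after burn-in.  Convergence is monitored
with the split-chain Gelman-Rubin statistic; candidate tracer sets are
compared by PSIS-LOO (WAIC fallback) on the pointwise log-likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "SourceSet",
    "TDF",
    "DirichletPrior",
    "MCMCSettings",
    "MixingPosterior",
    "build_prior",
    "mixture_moments",
    "log_likelihood",
    "pointwise_log_likelihood",
    "sample_posterior",
    "gelman_rubin",
    "compare_tracer_sets",
    "apply_time_lag",
]

DEFAULT_SOURCES = ("coastal_nekton", "oceanic_nekton", "oceanic_plankton")
DEFAULT_TRACERS = ("d13C", "d15N")

#: white-muscle trophic discrimination factors for tuna (per-mil)
TDF_D13C = (0.82, 1.13)
TDF_D15N = (2.1, 1.0)

SEASON_CYCLE = ("spring", "summer", "fall", "winter")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SourceSet:
    """Tracer means, SDs and elemental concentrations for K sources."""

    names: list[str]
    tracers: list[str]
    mu: np.ndarray      # (K, J) per-mil
    sigma: np.ndarray   # (K, J) per-mil, >= 0
    conc: np.ndarray    # (K, J) elemental concentration, > 0

    def __post_init__(self):
        K, J = len(self.names), len(self.tracers)
        for name, arr in (("mu", self.mu), ("sigma", self.sigma), ("conc", self.conc)):
            arr = np.asarray(arr, dtype=float)
            setattr(self, name, arr)
            if arr.shape != (K, J):
                raise ValueError(f"{name} must have shape ({K}, {J})")
        if (self.sigma < 0).any():
            raise ValueError("source SDs must be non-negative")
        if (self.conc <= 0).any():
            raise ValueError("concentrations must be positive")

    @property
    def n_sources(self) -> int:
        return len(self.names)

    def subset(self, tracers) -> "SourceSet":
        idx = [self.tracers.index(t) for t in tracers]
        return SourceSet(
            self.names, list(tracers),
            self.mu[:, idx], self.sigma[:, idx], self.conc[:, idx],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SourceSet":
        """Build from a long table with columns name, tracer, mu, sigma, conc."""
        names = list(dict.fromkeys(df["name"]))
        tracers = list(dict.fromkeys(df["tracer"]))
        piv = df.set_index(["name", "tracer"])
        mu = np.array([[piv.loc[(n, t), "mu"] for t in tracers] for n in names])
        sigma = np.array([[piv.loc[(n, t), "sigma"] for t in tracers] for n in names])
        conc = np.array([[piv.loc[(n, t), "conc"] for t in tracers] for n in names])
        return cls(names, tracers, mu, sigma, conc)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, n in enumerate(self.names):
            for j, t in enumerate(self.tracers):
                rows.append({"name": n, "tracer": t, "mu": self.mu[i, j],
                             "sigma": self.sigma[i, j], "conc": self.conc[i, j]})
        return pd.DataFrame(rows)


@dataclass
class TDF:
    """Per-tracer trophic discrimination: mean enrichment and SD."""

    tracers: list[str]
    delta_mu: np.ndarray
    delta_sigma: np.ndarray

    def __post_init__(self):
        self.delta_mu = np.asarray(self.delta_mu, dtype=float)
        self.delta_sigma = np.asarray(self.delta_sigma, dtype=float)
        if (self.delta_sigma < 0).any():
            raise ValueError("TDF SDs must be non-negative")

    def subset(self, tracers) -> "TDF":
        idx = [self.tracers.index(t) for t in tracers]
        return TDF(list(tracers), self.delta_mu[idx], self.delta_sigma[idx])

    @classmethod
    def tuna_default(cls) -> "TDF":
        return cls(
            list(DEFAULT_TRACERS),
            np.array([TDF_D13C[0], TDF_D15N[0]]),
            np.array([TDF_D13C[1], TDF_D15N[1]]),
        )


@dataclass
class DirichletPrior:
    alpha: np.ndarray

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        if (self.alpha <= 0).any():
            raise ValueError("Dirichlet alpha must be positive")

    @property
    def mean(self) -> np.ndarray:
        return self.alpha / self.alpha.sum()


def build_prior(diet_shares, n_sources: int | None = None,
                floor: float = 0.01) -> DirichletPrior:
    """Informative Dirichlet prior from mean diet shares.

    alpha_k = K * share_k, where the shares are the season-averaged
    %NW proportions of each source group (summing to 1).  Zero shares
    are floored at ``floor`` and the vector renormalized so that the
    alpha components always sum exactly to the number of sources;
    equal shares give the uninformative Dirichlet(1, ..., 1).
    """
    shares = np.asarray(diet_shares, dtype=float)
    if (shares < 0).any():
        raise ValueError("diet shares must be non-negative")
    total = shares.sum()
    if total <= 0:
        raise ValueError("diet shares are all zero")
    shares = shares / total
    K = len(shares) if n_sources is None else int(n_sources)
    if K != len(shares):
        raise ValueError("n_sources does not match number of shares")
    shares = np.maximum(shares, floor)
    shares = shares / shares.sum()
    return DirichletPrior(K * shares)


# ---------------------------------------------------------------------------
# model mathematics
# ---------------------------------------------------------------------------

def mixture_moments(p, sources: SourceSet, tdf: TDF):
    """Concentration-weighted mixture mean and process variance per tracer.

    Accepts a single simplex vector (K,) or a batch (..., K); returns
    arrays broadcast to (..., J).
    """
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    p2 = np.atleast_2d(p)
    if not np.allclose(p2.sum(axis=-1), 1.0, atol=1e-8):
        raise ValueError("p must lie on the simplex")
    pc = p2[..., :, None] * sources.conc[None, :, :]          # (..., K, J)
    denom = pc.sum(axis=-2)                                    # (..., J)
    assert (denom > 0).all(), "zero concentration denominator"
    mean = (pc * (sources.mu + tdf.delta_mu)[None]).sum(axis=-2) / denom
    var = ((pc ** 2) * (sources.sigma ** 2 + tdf.delta_sigma ** 2)[None]).sum(
        axis=-2
    ) / denom ** 2
    if single:
        return mean[0], var[0]
    return mean, var


def log_likelihood(consumers, p, sources: SourceSet, tdf: TDF, residual_mult=1.0):
    """Gaussian tracer log-likelihood of consumer data.

    Variance per tracer is the process variance of the mixture scaled
    by a residual multiplier xi_j (scalar or length-J vector).
    """
    c = np.atleast_2d(np.asarray(consumers, dtype=float))
    if not np.isfinite(c).all():
        raise ValueError("consumer values must be finite")
    mean, procvar = mixture_moments(p, sources, tdf)
    var = np.asarray(residual_mult, dtype=float) * procvar
    if (var <= 0).any():
        raise ValueError("non-positive likelihood variance")
    z2 = (c - mean) ** 2 / var
    return float(-0.5 * np.sum(z2 + np.log(2 * np.pi * var)))


def pointwise_log_likelihood(consumers, p, sources, tdf, residual_mult=1.0):
    """Per-consumer log-likelihood (summed over tracers)."""
    c = np.atleast_2d(np.asarray(consumers, dtype=float))
    mean, procvar = mixture_moments(p, sources, tdf)
    var = np.asarray(residual_mult, dtype=float) * procvar
    return -0.5 * ((c - mean) ** 2 / var + np.log(2 * np.pi * var)).sum(axis=1)


def _alr_to_simplex(z):
    """Additive log-ratio inverse: z in R^{K-1} -> p on the simplex."""
    z = np.asarray(z, dtype=float)
    e = np.exp(z - z.max(axis=-1, keepdims=True).clip(min=0.0))
    # append the reference coordinate exp(0 - shift)
    ref = np.exp(-z.max(axis=-1, keepdims=True).clip(min=0.0))
    full = np.concatenate([e, ref], axis=-1)
    return full / full.sum(axis=-1, keepdims=True)


def _log_prior(p, u, alpha):
    """Dirichlet prior on p (with ALR Jacobian) + N(0,1) on u = log xi."""
    logp = np.log(p)
    dirich = (
        gammaln(alpha.sum()) - gammaln(alpha).sum() + ((alpha - 1.0) * logp).sum(-1)
    )
    jac = logp.sum(-1)  # |d p / d z| for the ALR transform
    normal_u = -0.5 * (u ** 2 + np.log(2 * np.pi)).sum(-1)
    return dirich + jac + normal_u


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

@dataclass
class MCMCSettings:
    n_iter: int = 20_000
    n_burn: int = 10_000
    thin: int = 10
    n_chains: int = 4
    seed: int = 0
    target_accept: float = 0.3

    def __post_init__(self):
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        if self.n_burn >= self.n_iter:
            raise ValueError("burn-in must be shorter than the run")


@dataclass
class MixingPosterior:
    """Retained MCMC draws with convergence diagnostics."""

    source_names: list[str]
    tracers: list[str]
    p_draws: np.ndarray        # (chains, draws, K) on the simplex
    xi_draws: np.ndarray       # (chains, draws, J) residual multipliers
    rhat: dict[str, float]
    accept_rate: np.ndarray
    converged: bool = field(init=False)
    rhat_threshold: float = 1.1

    def __post_init__(self):
        self.converged = max(self.rhat.values()) < self.rhat_threshold
        if not self.converged:
            warnings.warn(
                f"max Gelman-Rubin statistic {max(self.rhat.values()):.3f} "
                f">= {self.rhat_threshold}; chains may not have converged",
                stacklevel=2,
            )

    @property
    def flat_p(self) -> np.ndarray:
        return self.p_draws.reshape(-1, self.p_draws.shape[-1])

    def summary(self, ci: float = 0.95) -> pd.DataFrame:
        """Median and central credible interval per source."""
        lo, hi = 50 * (1 - ci), 50 * (1 + ci)
        flat = self.flat_p
        return pd.DataFrame(
            {
                "source": self.source_names,
                "median": np.median(flat, axis=0),
                "ci_low": np.percentile(flat, lo, axis=0),
                "ci_high": np.percentile(flat, hi, axis=0),
            }
        )

    def diagnostics(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"parameter": list(self.rhat), "rhat": list(self.rhat.values())}
        )


def sample_posterior(
    consumers,
    sources: SourceSet,
    tdf: TDF,
    prior: DirichletPrior | None = None,
    mcmc: MCMCSettings | None = None,
) -> MixingPosterior:
    """Sample the posterior of source proportions by adaptive RW Metropolis.

    Proposals act on the unconstrained state (ALR coordinates of p,
    log residual multipliers), all chains advanced in lockstep with
    per-chain step sizes adapted toward the target acceptance rate
    during burn-in and frozen afterwards.  ``consumers`` may be an
    empty array, in which case the posterior equals the prior.
    """
    mcmc = mcmc or MCMCSettings()
    K = sources.n_sources
    J = len(sources.tracers)
    prior = prior or DirichletPrior(np.ones(K))
    alpha = prior.alpha
    c = np.asarray(consumers, dtype=float).reshape(-1, J)
    n = len(c)
    # sufficient statistics: sum and sum of squares per tracer
    s1 = c.sum(axis=0)
    s2 = (c ** 2).sum(axis=0)

    C = mcmc.n_chains
    dim = (K - 1) + J
    rng = np.random.default_rng(mcmc.seed)
    state = np.concatenate(
        [rng.normal(0.0, 2.0, size=(C, K - 1)), rng.normal(0.0, 0.5, size=(C, J))],
        axis=1,
    )
    step = np.full(C, 0.3)

    def log_post(Z):
        z, u = Z[:, : K - 1], Z[:, K - 1:]
        p = _alr_to_simplex(z)                                   # (C, K)
        xi = np.exp(u)                                           # (C, J)
        mean, procvar = mixture_moments(p, sources, tdf)         # (C, J)
        lp = _log_prior(p, u, alpha)
        if n > 0:
            var = xi * procvar
            ss = s2 - 2.0 * mean * s1 + n * mean ** 2
            lp = lp - 0.5 * (ss / var + n * np.log(2 * np.pi * var)).sum(axis=1)
        return lp, p, xi

    lp, p_cur, xi_cur = log_post(state)
    n_keep = (mcmc.n_iter - mcmc.n_burn) // mcmc.thin
    p_draws = np.empty((C, n_keep, K))
    xi_draws = np.empty((C, n_keep, J))
    accepted = np.zeros(C)
    window_acc = np.zeros(C)
    kept = 0
    # per-dimension proposal scales, preconditioned mid-burn-in from the
    # pooled within-chain spread and frozen before sampling starts
    scale_vec = np.ones(dim)
    history = np.empty((C, mcmc.n_burn, dim)) if mcmc.n_burn else None

    for it in range(mcmc.n_iter):
        prop = state + (step[:, None] * scale_vec) * rng.standard_normal((C, dim))
        lp_prop, p_prop, xi_prop = log_post(prop)
        accept = np.log(rng.random(C)) < lp_prop - lp
        state[accept] = prop[accept]
        lp[accept] = lp_prop[accept]
        p_cur[accept] = p_prop[accept]
        xi_cur[accept] = xi_prop[accept]
        window_acc += accept
        if it < mcmc.n_burn:
            history[:, it] = state
            if (it + 1) % 100 == 0:  # adapt only during burn-in
                rate = window_acc / 100.0
                step *= np.exp(0.5 * (rate - mcmc.target_accept))
                window_acc[:] = 0.0
            if it > 200 and (it + 1) in (mcmc.n_burn // 2, 9 * mcmc.n_burn // 10):
                recent = history[:, (it + 1) // 2: it + 1]
                scale_vec = recent.std(axis=(0, 1)).clip(min=0.05)
                scale_vec = scale_vec / scale_vec.mean()
        else:
            accepted += accept
            if (it - mcmc.n_burn) % mcmc.thin == mcmc.thin - 1 and kept < n_keep:
                p_draws[:, kept] = p_cur
                xi_draws[:, kept] = xi_cur
                kept += 1

    rhat: dict[str, float] = {}
    for k in range(K):
        rhat[f"p[{sources.names[k]}]"] = gelman_rubin(p_draws[:, :, k])
    for j in range(J):
        rhat[f"xi[{sources.tracers[j]}]"] = gelman_rubin(xi_draws[:, :, j])

    return MixingPosterior(
        source_names=list(sources.names),
        tracers=list(sources.tracers),
        p_draws=p_draws,
        xi_draws=xi_draws,
        rhat=rhat,
        accept_rate=accepted / max(mcmc.n_iter - mcmc.n_burn, 1),
    )


def gelman_rubin(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one parameter.

    ``chains`` has shape (n_chains, n_draws).  Each chain is split in
    half, doubling the chain count, and the classic between/within
    variance ratio is computed.  Zero within-chain variance across all
    chains (a constant parameter) is defined as 1.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 10:
        raise ValueError("need >= 2 chains with >= 10 draws each")
    half = x.shape[1] // 2
    split = np.concatenate([x[:, :half], x[:, half: 2 * half]], axis=0)
    m, L = split.shape
    within = split.var(axis=1, ddof=1)
    W = within.mean()
    if W == 0:
        return 1.0
    B = L * split.mean(axis=1).var(ddof=1)
    var_plus = (L - 1) / L * W + B / L
    return float(np.sqrt(var_plus / W))


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def compare_tracer_sets(
    consumers: pd.DataFrame,
    sources: SourceSet,
    tdf: TDF,
    prior: DirichletPrior | None = None,
    tracer_sets: list[tuple[str, ...]] | None = None,
    mcmc: MCMCSettings | None = None,
    pareto_k_threshold: float = 0.7,
) -> pd.DataFrame:
    """Rank candidate tracer sets by leave-one-out information criterion.

    Each candidate model is fitted with the corresponding subset of
    tracers; the pointwise log-likelihood matrix over retained draws
    feeds PSIS-LOO.  If more than 10% of Pareto-k diagnostics exceed
    the threshold the model falls back to WAIC (flagged in the output).
    Lower LOOic means higher relative support; ties in content (the
    same set twice) score equally within Monte-Carlo error.
    """
    import arviz as az

    if tracer_sets is None:
        tracer_sets = [tuple(sources.tracers)]
    if len(tracer_sets) < 2:
        raise ValueError("need at least two candidate tracer sets")
    rows = []
    for ts in tracer_sets:
        sub_sources = sources.subset(ts)
        sub_tdf = tdf.subset(ts)
        c = consumers[list(ts)].to_numpy(dtype=float)
        post = sample_posterior(c, sub_sources, sub_tdf, prior, mcmc)
        C, D, _ = post.p_draws.shape
        ll = np.empty((C, D, len(c)))
        for ci in range(C):
            for di in range(D):
                ll[ci, di] = pointwise_log_likelihood(
                    c, post.p_draws[ci, di], sub_sources, sub_tdf,
                    post.xi_draws[ci, di],
                )
        idata = az.from_dict(
            posterior={"p": post.p_draws}, log_likelihood={"y": ll}
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            loo = az.loo(idata, pointwise=True)
            k = np.asarray(loo.pareto_k)
            used_waic = bool(np.mean(k > pareto_k_threshold) > 0.10)
            if used_waic:
                ic = az.waic(idata)
                elpd = float(ic.elpd_waic)
            else:
                elpd = float(loo.elpd_loo)
        rows.append(
            {"tracers": "+".join(ts), "looic": -2.0 * elpd,
             "elpd": elpd, "method": "waic" if used_waic else "psis_loo",
             "max_rhat": max(post.rhat.values())}
        )
    out = pd.DataFrame(rows).sort_values("looic", ignore_index=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# turnover alignment
# ---------------------------------------------------------------------------

TIME_LAG_MONTHS = {"sub_adult": 6, "adult": 9}


def apply_time_lag(seasons, size_class: str,
                   lag_months: int | None = None) -> list[str] | str:
    """Map tissue seasons to the diet windows they integrate.

    Muscle tissue turns over slowly, so isotope values lag diet: 6
    months for sub-adults, 9 for adults.  A tissue sampled in a given
    season therefore reflects the diet ``lag`` months earlier, cyclic
    over the year (a 12-month lag is the identity).
    """
    if lag_months is None:
        lag_months = TIME_LAG_MONTHS[size_class]
    if lag_months % 3 != 0:
        raise ValueError("lag must be a whole number of seasons (3-month units)")
    shift = (lag_months // 3) % 4
    single = isinstance(seasons, str)
    items = [seasons] if single else list(seasons)
    out = []
    for s in items:
        idx = SEASON_CYCLE.index(s)
        out.append(SEASON_CYCLE[(idx - shift) % 4])
    return out[0] if single else out
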