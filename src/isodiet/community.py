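"""Permutational community analysis of diet composition.

Native implementations of the dissimilarity-based machinery used to
compare prey assemblages across seasons: Bray-Curtis dissimilarity,
one-way PERMANOVA with permutation p-values, pairwise contrasts with
optional multiplicity adjustment, SIMPER decomposition of between-group
dissimilarity into per-taxon contributions, species accumulation
curves, and hierarchical (Ward) clustering of prey isotope values into
source groups.

All permutation procedures take an explicit seed and include the
observed statistic in the null set, so a reported p-value is never 0:

    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import gammaln

__all__ = [
    "DissimilarityMatrix",
    "PermanovaResult",
    "bray_curtis",
    "permanova",
    "pairwise_permanova",
    "simper",
    "species_accumulation",
    "cluster_sources",
]


@dataclass
class DissimilarityMatrix:
    ids: list
    d: np.ndarray
    metric: str = "bray_curtis"

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")


@dataclass
class PermanovaResult:
    pseudo_F: float
    df_between: int
    df_within: int
    n_permutations: int
    p_value: float
    permuted_F: np.ndarray


def bray_curtis(matrix: pd.DataFrame | np.ndarray, ids=None) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis dissimilarity of a sample x taxon table.

    d_ij = sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk), in [0, 1] for
    non-negative data.  All-zero rows are rejected (their dissimilarity
    is undefined).
    """
    if isinstance(matrix, pd.DataFrame):
        ids = list(matrix.index) if ids is None else list(ids)
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        ids = list(range(len(x))) if ids is None else list(ids)
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires non-negative data")
    zero = x.sum(axis=1) == 0
    if zero.any():
        raise ValueError(f"all-zero row for sample {ids[int(np.argmax(zero))]!r}")
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    d = num / den
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(ids, d)


def _ss_within(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    ss = 0.0
    for g in groups:
        mask = labels == g
        n_g = int(mask.sum())
        ss += d2[np.ix_(mask, mask)].sum() / (2.0 * n_g)
    return ss


def permanova(
    d: DissimilarityMatrix,
    groups,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> PermanovaResult:
    """One-way PERMANOVA on a dissimilarity matrix.

    Squared dissimilarities are partitioned: total SS is
    sum_{i<j} d_ij^2 / n, within-group SS sums the same quantity inside
    each group, and between = total - within.  Significance comes from
    unrestricted random relabeling of samples.
    """
    labels = np.asarray(groups)
    if len(labels) != len(d.ids):
        raise ValueError("group labels do not match matrix ids")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if counts.min() < 2:
        small = uniq[counts.argmin()]
        raise ValueError(f"group {small!r} has fewer than 2 samples")

    n = len(labels)
    a = len(uniq)
    d2 = d.d ** 2
    ss_total = d2.sum() / (2.0 * n)

    def pseudo_f(lab: np.ndarray) -> float:
        ss_w = _ss_within(d2, lab, uniq)
        ss_b = ss_total - ss_w
        return (ss_b / (a - 1)) / (ss_w / (n - a))

    f_obs = pseudo_f(labels)
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_perm)
    for i in range(n_perm):
        permuted[i] = pseudo_f(rng.permutation(labels))
    p = (1.0 + np.sum(permuted >= f_obs)) / (1.0 + n_perm)
    return PermanovaResult(
        pseudo_F=float(f_obs),
        df_between=a - 1,
        df_within=n - a,
        n_permutations=n_perm,
        p_value=float(p),
        permuted_F=permuted,
    )


def _adjust(pvals: np.ndarray, method: str) -> np.ndarray:
    m = len(pvals)
    if method == "none":
        return pvals.copy()
    if method == "bonferroni":
        return np.minimum(pvals * m, 1.0)
    if method == "holm":
        order = np.argsort(pvals)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pvals[idx])
            adj[idx] = min(running, 1.0)
        return adj
    raise ValueError(f"unknown adjustment {method!r}")


def pairwise_permanova(
    d: DissimilarityMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
    adjust: str = "none",
) -> pd.DataFrame:
    """PERMANOVA on every unordered pair of groups.

    Each contrast re-runs the one-way test on the sub-matrix of the two
    groups, with its own permutation stream derived from ``seed``.
    Adjustment: ``none`` (default), ``bonferroni`` or ``holm``.
    """
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    rng = np.random.default_rng(seed)
    rows = []
    for g1, g2 in combinations(uniq, 2):
        mask = (labels == g1) | (labels == g2)
        idx = np.flatnonzero(mask)
        sub = DissimilarityMatrix(
            [d.ids[i] for i in idx], d.d[np.ix_(idx, idx)], d.metric
        )
        res = permanova(sub, labels[mask], n_perm=n_perm, seed=rng)
        rows.append(
            {"group_a": g1, "group_b": g2, "pseudo_F": res.pseudo_F,
             "p_value": res.p_value}
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = _adjust(out["p_value"].to_numpy(), adjust)
    return out


def simper(matrix: pd.DataFrame, groups) -> dict[tuple, pd.DataFrame]:
    """SIMPER decomposition of between-group Bray-Curtis dissimilarity.

    For each pair of samples (i in A, j in B) the taxon-k share of
    their dissimilarity is delta_k(i,j) = |x_ik - x_jk| / sum_m (x_im +
    x_jm); its average over all between-group pairs is the taxon's
    contribution, and contributions sum to the mean between-group
    dissimilarity.  Returns one table per unordered group pair with
    columns ``taxon``, ``contribution`` and ``pct_contribution`` (the
    latter summing to 100).
    """
    x = matrix.to_numpy(dtype=float)
    taxa = list(matrix.columns)
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("SIMPER needs at least two groups")
    results: dict[tuple, pd.DataFrame] = {}
    for g1, g2 in combinations(uniq, 2):
        xa = x[labels == g1]
        xb = x[labels == g2]
        # delta[i, j, k] for every between-group pair, vectorized
        num = np.abs(xa[:, None, :] - xb[None, :, :])
        den = (xa[:, None, :] + xb[None, :, :]).sum(axis=2, keepdims=True)
        delta = (num / den).mean(axis=(0, 1))
        total = delta.sum()
        results[(g1, g2)] = pd.DataFrame(
            {"taxon": taxa, "contribution": delta,
             "pct_contribution": 100.0 * delta / total}
        ).sort_values("contribution", ascending=False, ignore_index=True)
    return results


def species_accumulation(
    incidence: pd.DataFrame | np.ndarray,
    n_perm: int = 100,
    seed: int = 0,
    method: str = "permutation",
) -> pd.DataFrame:
    """Species accumulation curve over stomachs.

    ``incidence`` is a stomach x taxon presence table (any positive
    value counts as presence).  ``method="permutation"`` averages the
    cumulative richness over random stomach orderings;
    ``method="exact"`` evaluates the closed-form expectation

        E[S(m)] = sum_t [1 - C(n - n_t, m) / C(n, m)]

    where n_t is the number of stomachs containing taxon t.  Both
    curves are monotone non-decreasing.
    """
    x = (np.asarray(incidence, dtype=float) > 0)
    n, _ = x.shape
    if n < 1:
        raise ValueError("need at least one stomach")
    if method == "exact":
        n_t = x.sum(axis=0)
        m = np.arange(1, n + 1)[:, None]

        def log_choose(a, b):
            with np.errstate(invalid="ignore"):
                return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

        # P(taxon absent from a random subset of size m) = C(n-n_t, m)/C(n, m)
        avail = (n - n_t)[None, :]
        log_p_absent = np.where(
            m <= avail, log_choose(avail, m) - log_choose(n, m), -np.inf
        )
        richness = (1.0 - np.exp(log_p_absent)).sum(axis=1)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        acc = np.zeros(n)
        for _ in range(n_perm):
            order = rng.permutation(n)
            seen = np.cumsum(x[order], axis=0) > 0
            acc += seen.sum(axis=1)
        richness = acc / n_perm
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame({"n_stomachs": np.arange(1, n + 1), "richness": richness})


def cluster_sources(
    prey_isotopes: pd.DataFrame,
    n_groups: int = 3,
    tracers: tuple[str, ...] = ("d13C", "d15N", "d34S"),
) -> pd.Series:
    """Split prey taxa into source groups by their isotope values.

    Agglomerative clustering with Ward linkage on the Euclidean
    distance of z-scored per-taxon tracer means, cut at ``n_groups``.
    ``prey_isotopes`` is indexed (or keyed by a ``taxon`` column) with
    one row per taxon.  Returns integer group labels per taxon.
    """
    df = prey_isotopes.copy()
    if "taxon" in df.columns:
        df = df.set_index("taxon")
    cols = [t for t in tracers if t in df.columns]
    if not cols:
        raise ValueError("no tracer columns found")
    vals = df[cols].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("tracer values must be complete (no NaN)")
    if len(df) < n_groups:
        raise ValueError(f"need at least {n_groups} taxa, got {len(df)}")
    sd = vals.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (vals - vals.mean(axis=0)) / sd
    tree = linkage(z, method="ward")
    labels = fcluster(tree, t=n_groups, criterion="maxclust")
    return pd.Series(labels, index=df.index, name="source_group")
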