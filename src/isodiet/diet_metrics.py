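"""Prey-importance indices and per-stomach composition matrices.

Three classic stomach-content metrics per taxon within a stratum:

* ``%N``  — percent of all prey items by count,
* ``%W``  — percent of total prey wet weight,
* ``%FO`` — percent of stomachs in which the taxon occurs.

These combine into the index of relative importance

    IRI  = (%N + %W) x %FO,        %IRI = 100 * IRI / sum(IRI)

and, per individual stomach, into the weighted composition metric

    %NW = (%N + %W) / 2

whose stomach x taxon matrix feeds the dissimilarity analysis and the
mixing-model priors.  Aggregation defaults to family level (order
Stomatopoda counts as an honorary family); the lowest identifiable rank
is available via ``rank="taxon"``.
"""

from __future__ import annotations

import pandas as pd

from .core_io import Stratum

__all__ = [
    "aggregation_key",
    "percent_composition",
    "iri",
    "composition_table",
    "nw_matrix",
    "heat_matrix",
]


class EmptyStratumError(ValueError):
    """No stomachs fall in the requested stratum."""


def aggregation_key(prey: pd.DataFrame, rank: str = "family") -> pd.Series:
    """Grouping label per prey row: ``family`` (default) or ``taxon``.

    Family-level aggregation uses the ``family`` column, falling back on
    the taxon name where the family is blank (e.g. Stomatopoda entered
    as an order-level group).
    """
    if rank == "taxon":
        return prey["taxon_name"].astype(str)
    if rank != "family":
        raise ValueError(f"unknown aggregation rank {rank!r}")
    fam = prey["family"].astype(str).str.strip()
    return fam.where(fam != "", prey["taxon_name"].astype(str))


def percent_composition(
    prey: pd.DataFrame, rank: str = "family"
) -> pd.DataFrame:
    """%N, %W and %FO per taxon over a set of (already filtered) rows.

    The %FO denominator is the number of distinct stomachs present in
    ``prey`` (the post-filter count).  Taxa absent from the stratum are
    not emitted.  Raises :class:`EmptyStratumError` on an empty input.
    """
    if len(prey) == 0:
        raise EmptyStratumError("no prey rows in stratum")
    key = aggregation_key(prey, rank)
    work = prey.assign(_taxon=key)
    n_stomachs = work["stomach_id"].nunique()
    total_count = work["count"].sum()
    total_weight = work["wet_weight_g"].sum()

    g = work.groupby("_taxon", sort=True)
    counts = g["count"].sum()
    weights = g["wet_weight_g"].sum()
    occ = g["stomach_id"].nunique()

    pct_N = 100.0 * counts / total_count
    if total_weight > 0:
        pct_W = 100.0 * weights / total_weight
    else:
        # degenerate stratum: every item weighed to 0.0 g
        pct_W = pd.Series(0.0, index=counts.index)
    pct_FO = 100.0 * occ / n_stomachs

    out = pd.DataFrame(
        {"taxon": counts.index, "pct_N": pct_N.values,
         "pct_W": pct_W.values, "pct_FO": pct_FO.values}
    ).reset_index(drop=True)
    return out


def iri(composition: pd.DataFrame) -> pd.DataFrame:
    """Attach IRI and %IRI columns to a composition table."""
    out = composition.copy()
    out["IRI"] = (out["pct_N"] + out["pct_W"]) * out["pct_FO"]
    total = out["IRI"].sum()
    if total <= 0:
        raise ValueError("degenerate stratum: all IRI values are zero")
    out["pct_IRI"] = 100.0 * out["IRI"] / total
    return out


def composition_table(
    prey: pd.DataFrame,
    stomachs: pd.DataFrame,
    stratum: Stratum,
    rank: str = "family",
) -> pd.DataFrame:
    """Full composition + IRI table for one season x size-class stratum.

    ``stomachs`` must carry ``season`` and ``size_class`` columns (see
    :func:`isodiet.core_io.stratify`).
    """
    ids = stomachs.loc[
        (stomachs["season"] == stratum.season)
        & (stomachs["size_class"] == stratum.size_class),
        "stomach_id",
    ]
    sub = prey[prey["stomach_id"].isin(set(ids))]
    if len(sub) == 0:
        raise EmptyStratumError(f"no prey rows in stratum {stratum}")
    table = iri(percent_composition(sub, rank))
    table.insert(0, "season", stratum.season)
    table.insert(0, "size_class", stratum.size_class)
    return table


def nw_matrix(prey: pd.DataFrame, rank: str = "family") -> pd.DataFrame:
    """Stomach x taxon matrix of %NW = (%N + %W)/2 computed per stomach.

    Within each stomach, %N and %W are taken over that stomach's own
    items; absent taxa get 0, and every row sums to 100.  A stomach
    whose items all weigh 0.0 g (possible at 0.1-g resolution) has its
    %W term dropped and %NW renormalized from %N alone.
    """
    if len(prey) == 0:
        return pd.DataFrame()
    key = aggregation_key(prey, rank)
    work = prey.assign(_taxon=key)

    counts = work.pivot_table(
        index="stomach_id", columns="_taxon", values="count",
        aggfunc="sum", fill_value=0,
    ).astype(float)
    weights = work.pivot_table(
        index="stomach_id", columns="_taxon", values="wet_weight_g",
        aggfunc="sum", fill_value=0.0,
    ).astype(float)

    pct_n = 100.0 * counts.div(counts.sum(axis=1), axis=0)
    wsum = weights.sum(axis=1)
    nonzero = wsum > 0
    pct_w = pd.DataFrame(0.0, index=weights.index, columns=weights.columns)
    pct_w.loc[nonzero] = 100.0 * weights.loc[nonzero].div(wsum[nonzero], axis=0)
    # zero-total-weight stomachs: %NW reduces to %N (renormalized)
    nw = (pct_n + pct_w) / 2.0
    nw.loc[~nonzero] = pct_n.loc[~nonzero]
    nw.index.name = "stomach_id"
    nw.columns.name = "taxon"
    return nw


def heat_matrix(
    composition_tables: list[pd.DataFrame], threshold_pct_IRI: float = 1.0
) -> pd.DataFrame:
    """Season x taxon table of %IRI for one size class.

    A taxon is retained if its %IRI reaches ``threshold_pct_IRI``
    (inclusive) in at least one season; cells are 0 where the taxon is
    absent from a season.
    """
    frames = []
    for tab in composition_tables:
        frames.append(tab[["season", "taxon", "pct_IRI"]])
    long = pd.concat(frames, ignore_index=True)
    wide = long.pivot_table(
        index="season", columns="taxon", values="pct_IRI", fill_value=0.0
    )
    keep = wide.columns[(wide >= threshold_pct_IRI).any(axis=0)]
    out = wide[keep]
    # seasons in study-cycle order
    order = [s for s in ("spring", "summer", "fall", "winter") if s in out.index]
    return out.loc[order]
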