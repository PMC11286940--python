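"""Seeded synthetic-data generators for the full analysis chain.

The generators emulate the statistical structure the analyses assume
rather than any particular dataset: seasonally shifting multinomial
prey assemblages across two predator size classes (squids and
flyingfishes in spring, juvenile carangids in summer, coastal fishes
in fall, planktonic crustaceans in winter), and consumer isotope
values drawn from the mixing model's own generative process at known
source proportions, discrimination factors and error terms — so every
estimator in the package can be checked against a known truth.

All generators are pure functions of (scenario, seed).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mixing import TDF, SourceSet, mixture_moments

__all__ = [
    "TaxonProfile",
    "DietScenario",
    "IsotopeScenario",
    "generate_stomachs",
    "generate_consumers",
    "generate_prey_isotopes",
    "default_source_set",
    "default_tdf",
]

SEASONS = ("spring", "summer", "fall", "winter")
SEASON_MONTHS = {
    "spring": (4, 5, 6), "summer": (7, 8, 9),
    "fall": (10, 11, 12), "winter": (1, 2, 3),
}


@dataclass(frozen=True)
class TaxonProfile:
    """Sampling profile for one prey taxon."""

    name: str
    family: str
    source_group: str
    mean_count: float = 3.0       # zero-truncated Poisson mean
    weight_g: float = 20.0        # lognormal median wet weight
    weight_cv: float = 0.6


# the nine dissimilarity-driving taxa plus a coastal fish, with
# availability profiles shaped like the seasonal assemblages they mimic
DEFAULT_TAXA: tuple[TaxonProfile, ...] = (
    TaxonProfile("Caranx crysos", "Carangidae", "oceanic_nekton", 4.0, 15.0),
    TaxonProfile("Coryphaena hippurus", "Coryphaenidae", "oceanic_nekton", 1.5, 40.0),
    TaxonProfile("Exocoetus obtusirostris", "Exocoetidae", "oceanic_nekton", 2.0, 30.0),
    TaxonProfile("Cubiceps pauciradiatus", "Nomeidae", "oceanic_nekton", 2.0, 10.0),
    TaxonProfile("Ommastrephes bartramii", "Ommastrephidae", "oceanic_nekton", 2.5, 35.0),
    TaxonProfile("Phrosina semilunata", "Phrosinidae", "oceanic_plankton", 8.0, 0.4),
    TaxonProfile("Euthynnus alletteratus", "Scombridae", "oceanic_nekton", 1.5, 50.0),
    TaxonProfile("Epinephelus sp.", "Serranidae", "oceanic_nekton", 2.0, 8.0),
    TaxonProfile("Stomatopoda", "", "oceanic_plankton", 5.0, 0.8),
    TaxonProfile("Mugil cephalus", "Mugilidae", "coastal_nekton", 1.5, 60.0),
)

_T = [t.name for t in DEFAULT_TAXA]

# per-season availability over DEFAULT_TAXA order (rows sum to 1)
DEFAULT_AVAILABILITY: dict[str, tuple[float, ...]] = {
    #        Car   Cor   Exo   Nom   Omm   Phr   Sco   Ser   Sto   Mug
    "spring": (0.08, 0.02, 0.25, 0.02, 0.35, 0.05, 0.02, 0.15, 0.04, 0.02),
    "summer": (0.50, 0.02, 0.05, 0.02, 0.05, 0.05, 0.15, 0.05, 0.10, 0.01),
    "fall":   (0.25, 0.02, 0.15, 0.03, 0.10, 0.10, 0.05, 0.03, 0.07, 0.20),
    "winter": (0.08, 0.10, 0.10, 0.10, 0.05, 0.45, 0.02, 0.02, 0.06, 0.02),
}

# size-class tilts on availability (renormalized after applying)
DEFAULT_CLASS_MULTIPLIERS = {
    "sub_adult": (1.0, 0.5, 1.0, 1.0, 1.0, 1.5, 0.8, 1.2, 1.2, 0.5),
    "adult":     (1.0, 1.5, 1.0, 1.0, 1.2, 0.6, 1.3, 0.8, 0.8, 1.8),
}


@dataclass
class DietScenario:
    """Configuration for stomach-content generation."""

    taxa: tuple[TaxonProfile, ...] = DEFAULT_TAXA
    availability: dict = field(default_factory=lambda: dict(DEFAULT_AVAILABILITY))
    class_multipliers: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MULTIPLIERS)
    )
    n_stomachs: dict = field(
        default_factory=lambda: {"sub_adult": 78, "adult": 44}  # per season
    )
    mean_taxa_per_stomach: float = 2.0
    contamination_rate: float = 0.10
    empty_rate: float = 0.15
    cycle_start_year: int = 2019
    seed: int = 0

    def __post_init__(self):
        for season, avail in self.availability.items():
            a = np.asarray(avail, dtype=float)
            if (a < 0).any() or not np.isclose(a.sum(), 1.0):
                raise ValueError(f"{season} availability is not a simplex vector")
        for rate in (self.contamination_rate, self.empty_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


_FORK_LENGTH = {
    # (mean, sd, lower, upper): truncated to the observed size range
    "sub_adult": (82.0, 8.0, 64.5, 99.5),
    "adult": (130.0, 15.0, 100.0, 183.5),
}


def _season_dates(season: str, year0: int, n: int, rng) -> list[_dt.date]:
    months = SEASON_MONTHS[season]
    year = year0 if months[0] >= 4 else year0 + 1
    start = _dt.date(year, months[0], 1)
    if months[-1] == 12:
        end = _dt.date(year, 12, 31)
    else:
        end = _dt.date(year, months[-1] + 1, 1) - _dt.timedelta(days=1)
    span = (end - start).days + 1
    return [start + _dt.timedelta(days=int(d)) for d in rng.integers(0, span, n)]


def _zt_poisson(mean: float, size: int, rng) -> np.ndarray:
    """Zero-truncated Poisson via inverse-CDF on the conditional."""
    lam = max(mean, 1e-6)
    u = rng.random(size)
    p0 = np.exp(-lam)
    return stats.poisson.ppf(p0 + u * (1.0 - p0), lam).astype(int).clip(min=1)


def generate_stomachs(scenario: DietScenario | None = None,
                      seed: int | None = None):
    """Generate stomach and prey tables for one April->March study cycle.

    Returns ``(stomachs, prey)`` DataFrames matching the core schemas.
    Bait rows are injected at the contamination rate and empty stomachs
    at the empty rate, so the tables exercise the full filtering path.
    """
    scenario = scenario or DietScenario()
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    taxa = scenario.taxa
    stomach_rows, prey_rows = [], []
    sid = 0
    for size_class in ("sub_adult", "adult"):
        n_per_season = scenario.n_stomachs[size_class]
        mults = np.asarray(scenario.class_multipliers[size_class], dtype=float)
        mu, sd, lo, hi = _FORK_LENGTH[size_class]
        for season in SEASONS:
            avail = np.asarray(scenario.availability[season], dtype=float) * mults
            avail = avail / avail.sum()
            dates = _season_dates(season, scenario.cycle_start_year, n_per_season, rng)
            a, b = (lo - mu) / sd, (hi - mu) / sd
            lengths = stats.truncnorm.rvs(
                a, b, loc=mu, scale=sd, size=n_per_season, random_state=rng
            )
            for i in range(n_per_season):
                sid += 1
                stomach_id = f"S{sid:04d}"
                bait = rng.random() < scenario.contamination_rate
                stomach_rows.append(
                    {
                        "stomach_id": stomach_id,
                        "capture_date": dates[i],
                        "fork_length_cm": round(lengths[i] * 2) / 2,  # 0.5 cm
                        "sex": rng.choice(["M", "F", "unknown"]),
                        "bait_used": bait,
                        "chum_used": False,
                    }
                )
                if rng.random() < scenario.empty_rate:
                    continue  # empty stomach: no prey rows
                n_taxa = 1 + rng.poisson(scenario.mean_taxa_per_stomach - 1)
                n_taxa = min(n_taxa, int((avail > 0).sum()))
                chosen = rng.choice(len(taxa), size=n_taxa, replace=False, p=avail)
                for t_idx in chosen:
                    prof = taxa[t_idx]
                    count = int(_zt_poisson(prof.mean_count, 1, rng)[0])
                    sigma = np.sqrt(np.log1p(prof.weight_cv ** 2))
                    w = float(
                        count * prof.weight_g * rng.lognormal(-sigma ** 2 / 2, sigma)
                    )
                    prey_rows.append(
                        {
                            "stomach_id": stomach_id,
                            "taxon_name": prof.name,
                            "taxon_rank": "order" if prof.name == "Stomatopoda"
                                          else "species",
                            "family": prof.family,
                            "count": count,
                            "wet_weight_g": max(round(w, 1), 0.1),
                            "life_stage": "juvenile",
                            "is_bait": False,
                            "is_chum": False,
                            "source_group": prof.source_group,
                        }
                    )
                if bait:
                    prey_rows.append(
                        {
                            "stomach_id": stomach_id,
                            "taxon_name": "Brevoortia patronus",
                            "taxon_rank": "species",
                            "family": "Clupeidae",
                            "count": 1,
                            "wet_weight_g": round(float(rng.uniform(5, 30)), 1),
                            "life_stage": "adult",
                            "is_bait": True,
                            "is_chum": False,
                            "source_group": "unassigned",
                        }
                    )
    stomachs = pd.DataFrame(stomach_rows)
    prey = pd.DataFrame(prey_rows)
    return stomachs, prey


# ---------------------------------------------------------------------------
# isotope generation
# ---------------------------------------------------------------------------

# stand-in source-group tracer parameters (means/SDs in per-mil;
# concentrations as dry-weight fractions: C ~ 0.45, N ~ 0.12, S ~ 0.01)
_SOURCE_PARAMS = {
    #                      d13C            d15N           d34S
    "coastal_nekton": {"mu": (-17.0, 14.5, 12.0), "sigma": (0.5, 0.8, 1.0),
                       "conc": (0.46, 0.13, 0.010)},
    "oceanic_nekton": {"mu": (-18.5, 9.5, 18.5), "sigma": (0.5, 1.0, 0.8),
                       "conc": (0.45, 0.12, 0.010)},
    "oceanic_plankton": {"mu": (-20.0, 6.5, 19.5), "sigma": (0.6, 0.8, 0.7),
                         "conc": (0.40, 0.09, 0.012)},
}
_ALL_TRACERS = ("d13C", "d15N", "d34S")


def default_tdf(tracers=("d13C", "d15N")) -> TDF:
    """Tuna white-muscle TDFs; tracers without a literature value
    (d34S) get a zero-mean, 0.5 per-mil-SD stand-in."""
    base = TDF.tuna_default()
    mu, sd = [], []
    for t in tracers:
        if t in base.tracers:
            j = base.tracers.index(t)
            mu.append(base.delta_mu[j])
            sd.append(base.delta_sigma[j])
        else:
            mu.append(0.0)
            sd.append(0.5)
    return TDF(list(tracers), np.array(mu), np.array(sd))


def default_source_set(tracers=("d13C", "d15N")) -> SourceSet:
    """Three-source SourceSet with the stand-in synthetic parameters."""
    names = list(_SOURCE_PARAMS)
    idx = [_ALL_TRACERS.index(t) for t in tracers]
    mu = np.array([[_SOURCE_PARAMS[n]["mu"][j] for j in idx] for n in names])
    sigma = np.array([[_SOURCE_PARAMS[n]["sigma"][j] for j in idx] for n in names])
    conc = np.array([[_SOURCE_PARAMS[n]["conc"][j] for j in idx] for n in names])
    return SourceSet(names, list(tracers), mu, sigma, conc)


@dataclass
class IsotopeScenario:
    """Configuration for consumer isotope generation.

    ``true_p`` is the known simplex of source proportions the mixing
    model should recover; the default TDFs are the tuna white-muscle
    values (0.82 +/- 1.13 for d13C, 2.1 +/- 1.0 for d15N).
    """

    true_p: tuple[float, ...] = (0.2, 0.5, 0.3)
    tracers: tuple[str, ...] = ("d13C", "d15N")
    sources: SourceSet | None = None
    tdf: TDF | None = None
    residual_mult: float | tuple[float, ...] = 1.0
    n_consumers: int = 30
    cn_mean: float = 3.3
    cn_sd: float = 0.25
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.true_p, dtype=float)
        if (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise ValueError("true_p must lie on the simplex")
        if self.n_consumers < 1:
            raise ValueError("need at least one consumer")
        if self.sources is None:
            self.sources = default_source_set(self.tracers)
        if self.tdf is None:
            self.tdf = default_tdf(self.tracers)


def generate_consumers(scenario: IsotopeScenario | None = None,
                       seed: int | None = None):
    """Draw consumer tracer values from the mixing model's own process.

    Consumers are Normal(mixture mean, process variance x residual
    multiplier) at the scenario's true proportions.  Returns
    ``(consumers, sources, tdf)`` where ``consumers`` is a DataFrame
    with one row per individual and ``sources``/``tdf`` are the model
    input objects (also exportable via ``SourceSet.to_frame``).
    """
    scenario = scenario or IsotopeScenario()
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    p = np.asarray(scenario.true_p, dtype=float)
    mean, procvar = mixture_moments(p, scenario.sources, scenario.tdf)
    var = np.asarray(scenario.residual_mult, dtype=float) * procvar
    n = scenario.n_consumers
    values = mean + np.sqrt(var) * rng.standard_normal((n, len(mean)))
    cn = rng.normal(scenario.cn_mean, scenario.cn_sd, n).clip(min=2.8)
    df = pd.DataFrame(values, columns=list(scenario.tracers))
    df.insert(0, "sample_id", [f"C{i + 1:03d}" for i in range(n)])
    df["CN_ratio"] = np.round(cn, 2)
    df["role"] = "consumer"
    return df, scenario.sources, scenario.tdf


def generate_prey_isotopes(
    n_taxa: int = 12,
    centroids: np.ndarray | None = None,
    sd: float = 0.3,
    tracers=("d13C", "d15N", "d34S"),
    seed: int = 0,
) -> pd.DataFrame:
    """Prey taxa scattered around planted tracer centroids.

    Taxa are assigned to the three planted groups as evenly as
    possible; the ``true_group`` column carries the ground truth for
    partition-recovery checks.
    """
    rng = np.random.default_rng(seed)
    if centroids is None:
        src = default_source_set(tracers)
        centroids = src.mu
    centroids = np.asarray(centroids, dtype=float)
    n_groups = len(centroids)
    if n_groups < 3:
        raise ValueError("need at least 3 planted centroids")
    groups = np.arange(n_taxa) % n_groups
    vals = centroids[groups] + sd * rng.standard_normal((n_taxa, centroids.shape[1]))
    df = pd.DataFrame(vals, columns=list(tracers))
    df.insert(0, "taxon", [f"taxon_{i + 1:02d}" for i in range(n_taxa)])
    df["true_group"] = groups + 1
    return df
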