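"""End-to-end orchestration: validate/load -> filter -> indices ->
community -> smooths -> mixing, from one configuration.

Each stage writes its outputs to the run directory and records status,
wall-clock time and emitted files in a JSON manifest.  A stage failure
halts everything downstream; missing inputs fail pre-flight before any
stage runs.  Given fixed seeds the whole chain is deterministic, so
re-running an unchanged config overwrites outputs identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, community, core_io, diet_metrics, mixing, smooths
from .core_io import Stratum

logger = logging.getLogger("isodiet")

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    stomachs_csv: str = ""
    prey_csv: str = ""
    consumers_csv: str = ""
    sources_csv: str = ""
    tdf_csv: str = ""
    out_dir: str = "isodiet_run"
    rank: str = "family"
    heat_threshold: float = 1.0
    n_permutations: int = 999
    permutation_seed: int = 42
    k_occurrence: int = 6
    k_isotope: int = 8
    tracers: tuple = ("d13C", "d15N")
    mcmc_iter: int = 20_000
    mcmc_burn: int = 10_000
    mcmc_thin: int = 10
    mcmc_chains: int = 4
    mcmc_seed: int = 7
    synthetic: bool = False
    synthetic_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        if isinstance(cfg.tracers, list):
            cfg.tracers = tuple(cfg.tracers)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["tracers"] = list(self.tracers)
        return d

    def digest(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str = __version__
    stages: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def record(self, stage: str, status: str, seconds: float, files=()):
        self.stages[stage] = {"status": status, "seconds": round(seconds, 3)}
        self.outputs.extend(str(f) for f in files)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"config_hash": self.config_hash, "version": self.version,
                 "stages": self.stages, "outputs": self.outputs},
                fh, indent=2,
            )

    @property
    def ok(self) -> bool:
        return bool(self.stages) and all(
            s["status"] == "ok" for s in self.stages.values()
        )


def _preflight(cfg: RunConfig) -> None:
    if cfg.synthetic:
        return
    if not cfg.stomachs_csv or not cfg.prey_csv:
        raise FileNotFoundError("stomachs_csv and prey_csv are required")
    missing = [
        p for p in (cfg.stomachs_csv, cfg.prey_csv, cfg.consumers_csv,
                    cfg.sources_csv, cfg.tdf_csv)
        if p and not Path(p).exists()
    ]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Run the full analysis chain and return its manifest."""
    _preflight(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=cfg.digest())
    ctx: dict = {}

    stages = [
        ("load", _stage_load),
        ("filter", _stage_filter),
        ("indices", _stage_indices),
        ("community", _stage_community),
        ("smooths", _stage_smooths),
        ("mixing", _stage_mixing),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            files = fn(cfg, ctx, out) or ()
        except Exception as exc:
            manifest.record(name, f"failed: {exc}", time.perf_counter() - t0)
            logger.error("stage %s failed: %s", name, exc)
            break
        manifest.record(name, "ok", time.perf_counter() - t0, files)
        logger.info("stage %s ok (%.2fs)", name, time.perf_counter() - t0)

    manifest.write(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_load(cfg, ctx, out):
    if cfg.synthetic:
        from .synthetic import (DietScenario, IsotopeScenario,
                                generate_consumers, generate_stomachs)

        stomachs, prey = generate_stomachs(DietScenario(seed=cfg.synthetic_seed))
        consumers, sources, tdf = generate_consumers(
            IsotopeScenario(tracers=tuple(cfg.tracers), seed=cfg.synthetic_seed)
        )
    else:
        stomachs = core_io.read_stomach_table(cfg.stomachs_csv)
        prey = core_io.read_prey_table(cfg.prey_csv)
        consumers = pd.read_csv(cfg.consumers_csv) if cfg.consumers_csv else None
        sources = (
            mixing.SourceSet.from_frame(pd.read_csv(cfg.sources_csv))
            if cfg.sources_csv else None
        )
        if cfg.tdf_csv:
            tdf_df = pd.read_csv(cfg.tdf_csv)
            tdf = mixing.TDF(
                list(tdf_df["tracer"]),
                tdf_df["delta_mu"].to_numpy(float),
                tdf_df["delta_sigma"].to_numpy(float),
            )
        else:
            tdf = mixing.TDF.tuna_default()
    ctx.update(stomachs=stomachs, prey=prey, consumers=consumers,
               sources=sources, tdf=tdf)
    return []


def _stage_filter(cfg, ctx, out):
    res = core_io.filter_stomachs(ctx["stomachs"], ctx["prey"])
    ctx["filtered"] = res
    ctx["stomachs_strat"] = core_io.stratify(res.stomachs)
    files = [out / "stomachs_retained.csv", out / "prey_retained.csv",
             out / "exclusion_log.csv"]
    core_io.write_table(res.stomachs, files[0])
    core_io.write_table(res.prey, files[1])
    core_io.write_table(res.exclusion_log, files[2])
    return files


def _stage_indices(cfg, ctx, out):
    files = []
    res = ctx["filtered"]
    strat = ctx["stomachs_strat"]
    for sc in core_io.SIZE_CLASSES:
        tables = []
        for season in core_io.SEASONS:
            try:
                tab = diet_metrics.composition_table(
                    res.prey, strat, Stratum(season, sc), rank=cfg.rank
                )
            except diet_metrics.EmptyStratumError:
                continue
            f = out / f"composition_{sc}_{season}.csv"
            core_io.write_table(tab, f)
            files.append(f)
            tables.append(tab)
        if tables:
            hm = diet_metrics.heat_matrix(tables, cfg.heat_threshold)
            f = out / f"heat_matrix_{sc}.csv"
            hm.to_csv(f)
            files.append(f)
    nw = diet_metrics.nw_matrix(res.prey, rank=cfg.rank)
    ctx["nw"] = nw
    f = out / "diet_matrix.csv"
    nw.to_csv(f)
    files.append(f)
    return files


def _stage_community(cfg, ctx, out):
    files = []
    nw = ctx["nw"]
    strat = ctx["stomachs_strat"].set_index("stomach_id")
    seasons = strat.loc[nw.index, "season"].to_numpy()
    d = community.bray_curtis(nw)
    res = community.permanova(
        d, seasons, n_perm=cfg.n_permutations, seed=cfg.permutation_seed
    )
    f = out / "permanova_result.csv"
    pd.DataFrame(
        [{"pseudo_F": res.pseudo_F, "df_between": res.df_between,
          "df_within": res.df_within, "p_value": res.p_value,
          "n_permutations": res.n_permutations}]
    ).to_csv(f, index=False)
    files.append(f)
    pw = community.pairwise_permanova(
        d, seasons, n_perm=cfg.n_permutations, seed=cfg.permutation_seed
    )
    f = out / "pairwise_permanova.csv"
    pw.to_csv(f, index=False)
    files.append(f)
    for (a, b), tab in community.simper(nw, seasons).items():
        f = out / f"simper_{a}_{b}.csv"
        tab.to_csv(f, index=False)
        files.append(f)
    acc = community.species_accumulation(nw, seed=cfg.permutation_seed)
    f = out / "accumulation_all.csv"
    acc.to_csv(f, index=False)
    files.append(f)
    return files


def _stage_smooths(cfg, ctx, out):
    files = []
    curves = smooths.occurrence_curves(
        ctx["filtered"].prey, ctx["stomachs_strat"], k=cfg.k_occurrence,
        rank=cfg.rank,
    )
    days = np.arange(1, 367)
    for _, row in curves.iterrows():
        if row["degenerate"]:
            continue
        f = out / f"occurrence_{str(row['taxon']).replace(' ', '_')}.csv"
        pd.DataFrame(
            {"day": days, "probability": row["fit"].predict(days)}
        ).to_csv(f, index=False)
        files.append(f)
    ctx["occurrence"] = curves
    return files


def _stage_mixing(cfg, ctx, out):
    consumers = ctx.get("consumers")
    sources = ctx.get("sources")
    if consumers is None or sources is None:
        return []
    tracers = [t for t in cfg.tracers if t in consumers.columns]
    sub = sources.subset(tracers)
    tdf = ctx["tdf"].subset(tracers)
    shares = source_group_shares(ctx["nw"], ctx["filtered"].prey, sub.names,
                                 rank=cfg.rank)
    prior = mixing.build_prior(shares)
    logger.info("diet-informed prior alpha = %s", np.round(prior.alpha, 3))
    settings = mixing.MCMCSettings(
        n_iter=cfg.mcmc_iter, n_burn=cfg.mcmc_burn, thin=cfg.mcmc_thin,
        n_chains=cfg.mcmc_chains, seed=cfg.mcmc_seed,
    )
    post = mixing.sample_posterior(
        consumers[tracers].to_numpy(float), sub, tdf, prior, settings
    )
    files = [out / "posterior_summary.csv", out / "diagnostics.csv",
             out / "prior.csv", out / "posterior_draws.csv"]
    post.summary().to_csv(files[0], index=False)
    post.diagnostics().to_csv(files[1], index=False)
    pd.DataFrame({"source": sub.names, "alpha": prior.alpha}).to_csv(
        files[2], index=False
    )
    pd.DataFrame(post.flat_p, columns=sub.names).to_csv(files[3], index=False)
    ctx["posterior"] = post
    return files


def source_group_shares(nw: pd.DataFrame, prey: pd.DataFrame,
                        source_names, rank: str = "family") -> np.ndarray:
    """Mean per-stomach %NW share of each source group (sums to 1).

    The quantity the diet-informed Dirichlet prior is built from:
    average the stomach x taxon %NW matrix over stomachs, then pool
    taxa by their source-group label.
    """
    from .diet_metrics import aggregation_key

    key = aggregation_key(prey, rank)
    group_map = (
        prey.assign(_taxon=key)
        .drop_duplicates("_taxon")
        .set_index("_taxon")["source_group"]
    )
    mean_nw = nw.mean(axis=0)
    shares = np.zeros(len(source_names))
    for i, name in enumerate(source_names):
        taxa = [t for t in mean_nw.index if group_map.get(t, "") == name]
        shares[i] = mean_nw[taxa].sum()
    total = shares.sum()
    if total <= 0:
        raise ValueError("no %NW mass maps onto the source groups")
    return shares / total
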