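"""End-to-end orchestration: simulate -> fit -> decode -> infer network.

One `RunConfig` (serializable as JSON) drives the whole analysis: synthetic
tables are generated (or user tables loaded), lifespan and expression are
fitted hierarchically, food/temperature decoding powers are computed with
posterior uncertainty, the regulatory network is inferred per environmental
condition, and temperature-dependent edge rewiring is tested by column
shuffling.  A single global seed is fanned out deterministically to named
per-stage substreams, so any stage can be rerun in isolation and two runs
with the same config are identical.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .config import (
    Genotype,
    McmcSettings,
    OptimizerSettings,
    StudyConfig,
    default_conditions,
    stage_seed,
)
from . import decoding as dec
from . import expression as ex
from . import network as nw
from . import survival as sv
from . import synthetic as syn

__all__ = [
    "DecodeSettings",
    "NetworkSettings",
    "RunConfig",
    "ReportBundle",
    "PipelineError",
    "run_pipeline",
    "validate_tables",
]

logger = logging.getLogger(__name__)


class DecodeSettings(BaseModel):
    axis: Literal["food", "temperature"] = "food"
    n_draws: int = Field(default=30, ge=2)
    n_per_stimulus: int = Field(default=200, ge=10)


class NetworkSettings(BaseModel):
    strength_threshold: float = Field(default=2.0, gt=1)
    optimizer: OptimizerSettings = Field(default_factory=OptimizerSettings)
    n_shuffles: int = Field(default=20_000, ge=1)
    min_edges: int = Field(default=4, ge=1)


def _default_study() -> StudyConfig:
    return StudyConfig(conditions=default_conditions())


class RunConfig(BaseModel):
    study: StudyConfig = Field(default_factory=_default_study)
    # the 18-condition hierarchical survival fits need longer chains than the
    # single-condition default to clear the convergence threshold
    mcmc: McmcSettings = Field(default_factory=lambda: McmcSettings(n_iter=2500))
    decode: DecodeSettings = Field(default_factory=DecodeSettings)
    network: NetworkSettings = Field(default_factory=NetworkSettings)
    #: genotypes whose lifespan/expression posteriors are fitted (network
    #: inference always uses all genotypes through the paired ratios)
    fit_genotypes: list[Genotype] = Field(
        default_factory=lambda: [Genotype.wild_type]
    )
    outdir: str = "wormdecode_run"
    seed: int = 0


@dataclass
class ReportBundle:
    outdir: Path
    outputs: dict = field(default_factory=dict)
    summaries: dict = field(default_factory=dict)
    manifest_path: Optional[Path] = None


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _write(bundle: ReportBundle, name: str, df: pd.DataFrame) -> Path:
    path = bundle.outdir / f"{name}.csv"
    df.to_csv(path, index=True)
    bundle.outputs[name] = str(path)
    return path


def _weibull_model_sets(post, conditions, stimuli_of, n_draws, rng):
    """Point-estimate model set plus per-draw model sets for one decoding
    axis slice (conditions share the axis value being decoded)."""
    keys = [(c, stimuli_of(c)) for c in conditions]
    point = dec.ResponseModelSet(
        tuple(s for _, s in keys),
        tuple(
            dec.WeibullResponse(
                scale=post.flat(f"{c.label()}|wild_type|scale").mean(),
                shape=post.flat(f"{c.label()}|wild_type|shape").mean(),
            )
            for c, _ in keys
        ),
    )
    n_total = post.flat(f"{keys[0][0].label()}|wild_type|scale").size
    idx = rng.choice(n_total, size=n_draws, replace=False)
    draw_sets = []
    for i in idx:
        draw_sets.append(
            dec.ResponseModelSet(
                tuple(s for _, s in keys),
                tuple(
                    dec.WeibullResponse(
                        scale=post.flat(f"{c.label()}|wild_type|scale")[i],
                        shape=post.flat(f"{c.label()}|wild_type|shape")[i],
                    )
                    for c, _ in keys
                ),
            )
        )
    return point, draw_sets


def run_pipeline(
    config: RunConfig, truth: Optional[syn.GroundTruth] = None
) -> ReportBundle:
    """Execute every stage on the configured synthetic study and write the
    report artifacts (CSV/JSON) plus a reproduction manifest.

    ``truth`` optionally pins the ground-truth parameter store (Weibull
    scales, network matrices, expression means); by default the study-level
    defaults are generated."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(outdir=outdir)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.model_dump(mode="json"),
        "stages": {},
    }

    def stage(name):
        manifest["stages"][name] = {"seed": stage_seed(config.seed, name)}
        logger.info("stage %s (seed %d)", name, manifest["stages"][name]["seed"])
        return np.random.default_rng(stage_seed(config.seed, name))

    def fail(name, exc):
        manifest["stages"][name]["failed"] = str(exc)
        bundle.manifest_path = outdir / "manifest.json"
        with open(bundle.manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise PipelineError(name, exc) from exc

    # --- simulate -----------------------------------------------------
    rng = stage("simulate")
    try:
        study = config.study.model_copy(
            update={"seed": stage_seed(config.seed, "simulate")}
        )
        lifespans, truth = syn.generate_lifespans(study, truth)
        expr, beads, truth = syn.generate_expression(study, truth)
        lifespans.to_csv(outdir / "lifespans.csv", index=False)
        expr.to_csv(outdir / "expression.csv", index=False)
        beads.to_csv(outdir / "beads.csv", index=False)
        truth.save(outdir / "ground_truth.json")
        for name in ("lifespans", "expression", "beads"):
            bundle.outputs[name] = str(outdir / f"{name}.csv")
        bundle.outputs["ground_truth"] = str(outdir / "ground_truth.json")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail("simulate", exc)

    # --- survival ------------------------------------------------------
    stage("survival")
    try:
        fit_genos = {Genotype(g).value for g in config.fit_genotypes}
        sub = lifespans[lifespans["genotype"].isin(fit_genos)]
        mcmc = config.mcmc.model_copy(
            update={"seed": stage_seed(config.seed, "survival")}
        )
        surv_post = sv.fit_hierarchical_weibull(
            sub,
            mcmc,
            day_resolution=1.0 if study.record_whole_days else None,
        )
        _write(bundle, "survival_posterior_summary", sv.posterior_summary(surv_post))
        rows = []
        for c in study.conditions:
            ml = sv.mean_lifespan_posterior(surv_post, c)
            rows.append(
                dict(
                    food=c.food,
                    temperature=c.temperature,
                    mean_lifespan=ml.mean(),
                    sd=ml.std(ddof=1),
                    q05=np.percentile(ml, 5),
                    q95=np.percentile(ml, 95),
                )
            )
        mean_life = pd.DataFrame(rows)
        _write(bundle, "mean_lifespans", mean_life)
        dr_rows = []
        for t in study.temperatures:
            means = {
                c.food: sv.mean_lifespan_posterior(surv_post, c)
                for c in study.conditions
                if c.temperature == t
            }
            dr = sv.dynamic_range_posterior(means)
            dr_rows.append(
                dict(
                    temperature=t,
                    dynamic_range=dr.mean(),
                    q05=np.percentile(dr, 5),
                    q95=np.percentile(dr, 95),
                )
            )
        _write(bundle, "lifespan_dynamic_range", pd.DataFrame(dr_rows))
        bundle.summaries["max_rhat_survival"] = surv_post.meta["max_rhat"]
    except Exception as exc:
        fail("survival", exc)

    # --- lifespan decoding --------------------------------------------
    rng = stage("decode_lifespan")
    try:
        axis = config.decode.axis
        slices = (
            study.temperatures if axis == "food" else study.foods
        )
        power_rows = []
        for sl in slices:
            if axis == "food":
                conds = [c for c in study.conditions if c.temperature == sl]
                stim_of = lambda c: c.food  # noqa: E731
                dat = lifespans[
                    (lifespans["temperature"] == sl)
                    & (~lifespans["censored"])
                    & (lifespans["genotype"] == Genotype.wild_type.value)
                ]
                labels = dat["food"].to_numpy()
            else:
                conds = [c for c in study.conditions if c.food == sl]
                stim_of = lambda c: c.temperature  # noqa: E731
                dat = lifespans[
                    (lifespans["food"] == sl)
                    & (~lifespans["censored"])
                    & (lifespans["genotype"] == Genotype.wild_type.value)
                ]
                labels = dat["temperature"].to_numpy()
            point, draw_sets = _weibull_model_sets(
                surv_post, conds, stim_of, config.decode.n_draws, rng
            )
            conf = dec.confusion_matrix(dat["day"].to_numpy(float), labels, point, rng)
            _write(bundle, f"confusion_lifespan_{axis}_{sl:g}", conf)
            powers = dec.decoding_power_distribution(
                draw_sets, n_per_stimulus=config.decode.n_per_stimulus, rng=rng
            )
            power_rows.append(
                {
                    "slice": sl,
                    "power": dec.decoding_power(conf),
                    "power_mean": powers.mean(),
                    "power_q05": np.percentile(powers, 5),
                    "power_q95": np.percentile(powers, 95),
                    "chance": 1.0 / point.K,
                }
            )
        _write(bundle, f"decoding_power_lifespan_{axis}", pd.DataFrame(power_rows))
    except Exception as exc:
        fail("decode_lifespan", exc)

    # --- expression ----------------------------------------------------
    stage("expression")
    try:
        cal = {
            ch: ex.fit_bead_regression(
                beads, ch, seed=stage_seed(config.seed, f"beads|{ch}")
            )
            for ch in sorted(beads["channel"].unique())
        }
        norm = ex.normalize_expression(expr, cal)
        emcmc = config.mcmc.model_copy(
            update={
                "seed": stage_seed(config.seed, "expression"),
                "n_iter": min(config.mcmc.n_iter, 800),
            }
        )
        expr_post = ex.fit_hierarchical_expression(
            norm, emcmc, genotypes=config.fit_genotypes
        )
        _write(
            bundle,
            "expression_posterior_summary",
            sv.posterior_summary(expr_post),
        )
        bundle.summaries["max_rhat_expression_mu"] = expr_post.meta["max_rhat_mu"]
    except Exception as exc:
        fail("expression", exc)

    # --- expression decoding ------------------------------------------
    rng = stage("decode_expression")
    try:
        power_rows = []
        wt = norm[norm["genotype"] == Genotype.wild_type.value]
        for t in study.temperatures:
            conds = [c for c in study.conditions if c.temperature == t]
            models = dec.ResponseModelSet(
                tuple(c.food for c in conds),
                tuple(ex.response_distribution(expr_post, c) for c in conds),
            )
            dat = wt[wt["temperature"] == t]
            resp = dat[list(syn.EXPRESSION_COLUMNS)].to_numpy(float)
            conf = dec.confusion_matrix(resp, dat["food"].to_numpy(), models, rng)
            _write(bundle, f"confusion_expression_food_{t:g}", conf)
            power_rows.append(
                dict(
                    temperature=t,
                    power=dec.decoding_power(conf),
                    chance=1.0 / models.K,
                )
            )
        _write(bundle, "decoding_power_expression_food", pd.DataFrame(power_rows))
    except Exception as exc:
        fail("decode_expression", exc)

    # --- network inference --------------------------------------------
    rng = stage("network")
    try:
        fits = {}
        for c in study.conditions:
            cexpr = norm[
                (norm["food"] == c.food) & (norm["temperature"] == c.temperature)
            ]
            obs = nw.observed_ratios(cexpr)
            fits[(c.food, c.temperature)] = nw.fit_network(
                obs,
                opt=config.network.optimizer,
                rng=np.random.default_rng(
                    stage_seed(config.seed, f"netfit|{c.label()}")
                ),
                condition=c.label(),
            )
        table = nw.edge_sign_table(fits)
        _write(bundle, "edge_signs", table)
        cat_rows = []
        for (food, t), fit in fits.items():
            cats = nw.classify_edges(
                fit.w_hat, config.network.strength_threshold
            ).reset_index()
            cats["food"] = food
            cats["temperature"] = t
            cats["cost"] = fit.cost
            cat_rows.append(cats)
        _write(bundle, "edge_categories", pd.concat(cat_rows, ignore_index=True))
        shuffle = nw.shuffle_significance(
            table,
            n_shuffles=config.network.n_shuffles,
            min_edges=config.network.min_edges,
            seed=stage_seed(config.seed, "shuffle"),
        )
        with open(outdir / "shuffle_significance.json", "w") as fh:
            json.dump(shuffle.__dict__, fh, indent=1)
        bundle.outputs["shuffle_significance"] = str(
            outdir / "shuffle_significance.json"
        )
        bundle.summaries["edge_flips_observed"] = shuffle.observed_statistic
        bundle.summaries["shuffle_p_hat"] = shuffle.p_hat
    except Exception as exc:
        fail("network", exc)

    bundle.manifest_path = outdir / "manifest.json"
    manifest["outputs"] = bundle.outputs
    manifest["summaries"] = {
        k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
        for k, v in bundle.summaries.items()
    }
    with open(bundle.manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return bundle


_LIFESPAN_COLUMNS = {
    "animal_id",
    "batch",
    "food",
    "temperature",
    "genotype",
    "day",
    "censored",
}
_EXPRESSION_REQUIRED = {
    "animal_id",
    "batch",
    "tau",
    "food",
    "temperature",
    "genotype",
    "f_nsm",
    "f_adf",
    "f_asi",
}
_BEAD_COLUMNS = {"channel", "tau", "fluorescence"}
_KNOWN_GENOTYPES = {g.value for g in Genotype}


@dataclass
class ValidationReport:
    issues: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, table, row, message):
        self.issues.append({"table": table, "row": row, "message": message})


def validate_tables(
    lifespan_path=None, expression_path=None, beads_path=None
) -> ValidationReport:
    """Schema and range checks for the CSV dialects the pipeline consumes.

    Row-level problems (non-positive days, unknown genotypes, non-positive
    fluorescence) are reported with their row indices; malformed CSV raises
    a parse error naming the line."""
    report = ValidationReport()

    def load(path, name):
        try:
            return pd.read_csv(path)
        except pd.errors.ParserError as exc:
            raise ValueError(f"malformed CSV in {name} table: {exc}") from exc

    if lifespan_path is not None:
        df = load(lifespan_path, "lifespan")
        missing = _LIFESPAN_COLUMNS - set(df.columns)
        if missing:
            report.add("lifespan", None, f"missing columns: {sorted(missing)}")
        else:
            for i in df.index[df["day"] <= 0]:
                report.add("lifespan", int(i), "non-positive day")
            bad = df.index[~df["genotype"].isin(_KNOWN_GENOTYPES)]
            for i in bad:
                report.add(
                    "lifespan",
                    int(i),
                    f"unknown genotype {df.loc[i, 'genotype']!r}; "
                    f"allowed: {sorted(_KNOWN_GENOTYPES)}",
                )
            for i in df.index[df["food"] < 0]:
                report.add("lifespan", int(i), "negative food concentration")
    if expression_path is not None:
        df = load(expression_path, "expression")
        missing = _EXPRESSION_REQUIRED - set(df.columns)
        if missing:
            report.add("expression", None, f"missing columns: {sorted(missing)}")
        else:
            for col in ("f_nsm", "f_adf", "f_asi"):
                for i in df.index[df[col] <= 0]:
                    report.add("expression", int(i), f"non-positive {col}")
            bad = df.index[~df["genotype"].isin(_KNOWN_GENOTYPES)]
            for i in bad:
                report.add(
                    "expression",
                    int(i),
                    f"unknown genotype {df.loc[i, 'genotype']!r}; "
                    f"allowed: {sorted(_KNOWN_GENOTYPES)}",
                )
    if beads_path is not None:
        df = load(beads_path, "beads")
        missing = _BEAD_COLUMNS - set(df.columns)
        if missing:
            report.add("beads", None, f"missing columns: {sorted(missing)}")
        else:
            for i in df.index[df["fluorescence"] <= 0]:
                report.add("beads", int(i), "non-positive fluorescence")
    return report
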