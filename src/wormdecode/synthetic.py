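"""Seeded synthetic datasets with the statistical structure of the worm study.

Three generators emulate the three data modalities the downstream analyses
consume:

* lifespans — Weibull with batch-perturbed scale/shape and right-censoring
  at the end of the observation schedule;
* 3-cell gene expression (tph-1 in NSM and ADF, daf-7 in ASI) — a
  condition -> batch -> animal hierarchy of multivariate normals, recorded
  through a multiplicative LED-drift factor linear in imaging time, together
  with the bead-standard series used to estimate that drift;
* mutant/wild-type expression ratios — generated from a ground-truth
  regulatory matrix through the Master-equation model.

The generators mimic only the structural form of the real data (batch
structure, censoring, drift, knockout logic), not its empirical
distributions.  Everything is bit-reproducible from `StudyConfig.seed`.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    EnvironmentCondition,
    Genotype,
    StudyConfig,
    stage_seed,
)
from .network import RegulatoryMatrix, RatioObservations, predicted_ratios

__all__ = [
    "GroundTruth",
    "default_weibull_truth",
    "default_network_truth",
    "default_expression_truth",
    "generate_lifespans",
    "generate_expression",
    "simulate_ratio_observations",
    "REPORTER_CHANNELS",
    "EXPRESSION_COLUMNS",
]

#: Expression-table fluorescence columns and the imaging channel of each
#: reporter (tph-1 reporters in the green channel, daf-7 in the red).
EXPRESSION_COLUMNS = ("f_nsm", "f_adf", "f_asi")
REPORTER_CHANNELS = {"f_nsm": "green", "f_adf": "green", "f_asi": "red"}

#: Food-responsiveness of each genotype: knockouts attenuate the food
#: dependence of lifespan, the double mutant most severely.
_FOOD_RESPONSIVENESS = {
    Genotype.wild_type: 1.0,
    Genotype.tph1_minus: 0.5,
    Genotype.daf7_minus: 0.5,
    Genotype.double_minus: 0.15,
}


@dataclass
class GroundTruth:
    """True parameters behind a synthetic study, kept for recovery tests.

    ``weibull_params`` maps (condition, genotype) -> (scale, shape);
    ``network_w`` maps condition -> regulatory matrix;
    ``expression_means`` maps (condition, genotype) -> wild-type-scale
    3-vector in column order (f_nsm, f_adf, f_asi)."""

    weibull_params: dict = field(default_factory=dict)
    network_w: dict = field(default_factory=dict)
    expression_means: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "weibull_params": {
                f"{c.label()}|{g.value}": list(v)
                for (c, g), v in self.weibull_params.items()
            },
            "network_w": {
                c.label(): w.to_dict() for c, w in self.network_w.items()
            },
            "expression_means": {
                f"{c.label()}|{g.value}": np.asarray(v).tolist()
                for (c, g), v in self.expression_means.items()
            },
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)


def _interp_temperature(temp: float, lo=(15.0, 24.0), mid=(20.0, 17.0), hi=(25.0, 12.0)):
    xs = np.array([lo[0], mid[0], hi[0]])
    ys = np.array([lo[1], mid[1], hi[1]])
    return float(np.interp(temp, xs, ys))


def default_weibull_truth(
    conditions: list[EnvironmentCondition],
    genotypes: list[Genotype],
    shape: float = 2.0,
) -> dict:
    """Condition x genotype -> (scale, shape) days.

    Scale drops steeply with temperature (about 24 d at 15C to 12 d at 25C)
    and declines with food level (dietary restriction extends lifespan);
    knockouts flatten the food dependence."""
    foods = sorted({c.food for c in conditions})
    if len(foods) > 1:
        mult = np.geomspace(1.2, 0.78, len(foods))
    else:
        mult = np.array([1.0])
    food_mult = dict(zip(foods, mult))
    out = {}
    for c in conditions:
        base = _interp_temperature(c.temperature)
        for g in genotypes:
            resp = _FOOD_RESPONSIVENESS[Genotype(g)]
            out[(c, Genotype(g))] = (base * food_mult[c.food] ** resp, shape)
    return out


#: Edges of the ground-truth network that converge on ASI (column y of w):
#: wxy (t2), wyy (t5), wzy (t8).
ASI_CONVERGING_EDGES = ("t2", "t5", "t8")

_CORE_EDGES = {  # fixed across all conditions
    "t1": 2.5,  # wxx  negative self-regulation of ADF
    "t3": 0.45,  # wxz positive ADF -> NSM
    "t4": 2.2,  # wyx  negative ASI -> ADF
    "t6": 0.4,  # wyz  positive ASI -> NSM
    "t7": 2.8,  # wzx  negative NSM -> ADF
    "t9": 0.5,  # wzz  positive self-regulation of NSM
}
_ASI_EDGES_COLD = {"t2": 3.0, "t5": 2.5, "t8": 0.35}
_ASI_EDGES_WARM = {"t2": 1 / 3.0, "t5": 0.4, "t8": 2.8}


def default_network_truth(conditions: list[EnvironmentCondition]) -> dict:
    """Condition -> regulatory matrix.

    The three edges converging on ASI flip sign between the coldest and
    warmest temperature (the warm variant applies above the midpoint of the
    temperature range); the six other edges are identical everywhere."""
    temps = sorted({c.temperature for c in conditions})
    midpoint = 0.5 * (temps[0] + temps[-1])
    out = {}
    for c in conditions:
        asi = _ASI_EDGES_WARM if c.temperature > midpoint else _ASI_EDGES_COLD
        t = {**_CORE_EDGES, **asi}
        out[c] = RegulatoryMatrix.from_flat([t[f"t{i}"] for i in range(1, 10)])
    return out


def default_expression_truth(
    conditions: list[EnvironmentCondition],
    genotypes: list[Genotype],
    network_w: dict,
) -> dict:
    """(condition, genotype) -> mean fluorescence (f_nsm, f_adf, f_asi).

    Wild-type means rise with food for the tph-1 reporters and fall for
    daf-7@ASI, with the food modulation amplitude growing with temperature
    (the warm network has the larger dynamic range).  Mutant means are the
    wild-type means times the mutant/wild-type marginal ratios predicted by
    the condition's ground-truth network."""
    base = np.array([120.0, 180.0, 250.0])  # (nsm, adf, asi), a.u.
    foods = sorted({c.food for c in conditions})
    temps = sorted({c.temperature for c in conditions})
    out = {}
    for c in conditions:
        frank = foods.index(c.food) / max(len(foods) - 1, 1)
        trank = (
            temps.index(c.temperature) / max(len(temps) - 1, 1)
            if len(temps) > 1
            else 1.0
        )
        amp = 0.25 + 0.45 * trank
        mod = np.array(
            [
                1.0 + amp * (frank - 0.5),
                1.0 + amp * (frank - 0.5),
                1.0 - amp * (frank - 0.5),
            ]
        )
        wt = base * mod
        ratios = predicted_ratios(network_w[c])  # rows daf7, tph1, double; cols ADF,ASI,NSM
        # reorder cells (ADF, ASI, NSM) -> columns (NSM, ADF, ASI)
        reorder = [2, 0, 1]
        per_genotype = {
            Genotype.wild_type: np.ones(3),
            Genotype.daf7_minus: ratios[0][reorder],
            Genotype.tph1_minus: ratios[1][reorder],
            Genotype.double_minus: ratios[2][reorder],
        }
        for g in genotypes:
            out[(c, Genotype(g))] = wt * per_genotype[Genotype(g)]
    return out


def generate_lifespans(
    config: StudyConfig, truth: GroundTruth | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-animal lifespan table.

    For every condition x genotype x batch the cell's (scale, shape) is
    perturbed log-normally to give batch parameters; individual lifespans are
    Weibull draws; animals alive past the last day of the observation
    schedule are right-censored there.  Death days are recorded as whole days
    (deaths are scored at transfers) unless ``record_whole_days`` is off.
    """
    truth = truth or GroundTruth()
    if not truth.weibull_params:
        truth.weibull_params = default_weibull_truth(
            config.conditions, config.genotypes
        )
    rng = np.random.default_rng(stage_seed(config.seed, "lifespans"))
    last_day = config.censoring_day_schedule[-1]
    rows = []
    aid = 0
    for c in config.conditions:
        for g in config.genotypes:
            lam, k = truth.weibull_params[(c, Genotype(g))]
            for b in range(config.n_batches):
                lam_b = lam * np.exp(rng.normal(0, config.batch_sd_log_scale))
                k_b = k * np.exp(rng.normal(0, config.batch_sd_log_shape))
                t = lam_b * rng.weibull(k_b, size=config.n_animals_per_cell)
                if config.record_whole_days:
                    day = np.maximum(np.ceil(t), 1.0)
                else:
                    day = t
                censored = day > last_day
                day = np.where(censored, last_day, day)
                for d, cen in zip(day, censored):
                    rows.append(
                        dict(
                            animal_id=f"a{aid:06d}",
                            batch=b,
                            food=c.food,
                            temperature=c.temperature,
                            genotype=Genotype(g).value,
                            day=float(d),
                            censored=bool(cen),
                        )
                    )
                    aid += 1
    return pd.DataFrame(rows), truth


def _check_psd(m: np.ndarray, what: str) -> None:
    if np.min(np.linalg.eigvalsh(m)) < -1e-8:
        raise ValueError(f"{what} covariance is not positive semidefinite")


def generate_expression(
    config: StudyConfig, truth: GroundTruth | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Per-animal 3-cell expression table plus the bead-calibration series.

    True per-condition means come from the ground truth (mutants through the
    Master-equation ratios); batch means and animals add the two Gaussian
    noise layers; the recorded raw fluorescence is the true value times the
    channel's drift factor C1 + C2*tau at the batch's imaging time.  Beads
    report the drift factor directly with small i.i.d. noise (bead brightness
    normalized to 1 at zero drift)."""
    truth = truth or GroundTruth()
    if not truth.network_w:
        truth.network_w = default_network_truth(config.conditions)
    if not truth.expression_means:
        truth.expression_means = default_expression_truth(
            config.conditions, config.genotypes, truth.network_w
        )
    rng = np.random.default_rng(stage_seed(config.seed, "expression"))
    taus = np.arange(config.n_batches) * 7.0
    c1, c2 = config.drift_intercept, config.drift_slope_per_day
    if np.any(c1 + c2 * taus <= 0):
        raise ValueError("drift factor C1 + C2*tau must stay positive")
    rows = []
    aid = 0
    for c in config.conditions:
        for g in config.genotypes:
            mu = np.asarray(truth.expression_means[(c, Genotype(g))], float)
            cov_b, cov_p = config.expression_noise.covariances(mu)
            _check_psd(cov_b, "batch")
            _check_psd(cov_p, "population")
            for b in range(config.n_batches):
                m_b = rng.multivariate_normal(mu, cov_b)
                vals = rng.multivariate_normal(
                    m_b, cov_p, size=config.n_animals_per_cell
                )
                vals = np.maximum(vals, 1e-3)
                factor = c1 + c2 * taus[b]
                raw = vals * factor
                for v in raw:
                    rows.append(
                        dict(
                            animal_id=f"e{aid:06d}",
                            batch=b,
                            tau=taus[b],
                            food=c.food,
                            temperature=c.temperature,
                            genotype=Genotype(g).value,
                            f_nsm=v[0],
                            f_adf=v[1],
                            f_asi=v[2],
                            channel="dual",
                        )
                    )
                    aid += 1
    expr = pd.DataFrame(rows)
    bead_rows = []
    bead_taus = np.linspace(0.0, max(taus[-1], 1.0), max(3 * config.n_batches, 4))
    for channel in ("green", "red"):
        f = (c1 + c2 * bead_taus) * (1.0 + rng.normal(0, 0.005, bead_taus.size))
        for t, v in zip(bead_taus, f):
            bead_rows.append(dict(channel=channel, tau=float(t), fluorescence=float(v)))
    beads = pd.DataFrame(bead_rows)
    return expr, beads, truth


def simulate_ratio_observations(
    w_true: RegulatoryMatrix, noise_cv: float, n_pairs: int, seed: int
) -> RatioObservations:
    """Noisy replicates of the mutant/wild-type expression ratios implied by
    a ground-truth network.

    Each of the 9 (mutant, cell) entries gets ``n_pairs`` multiplicative
    log-normal replicates with unit mean and coefficient of variation
    ``noise_cv``; the summary is their mean and standard deviation, matching
    how paired mutant/control experiments are reduced."""
    if n_pairs < 2:
        raise ValueError("need at least 2 pairs (SD undefined otherwise)")
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    true = predicted_ratios(w_true)
    if noise_cv == 0:
        return RatioObservations(R=true, sigma=np.zeros((3, 3)), n_pairs=n_pairs)
    rng = np.random.default_rng(seed)
    slog = np.sqrt(np.log1p(noise_cv**2))
    reps = true[None] * np.exp(
        rng.normal(-0.5 * slog**2, slog, size=(n_pairs, 3, 3))
    )
    return RatioObservations(
        R=reps.mean(axis=0), sigma=reps.std(axis=0, ddof=1), n_pairs=n_pairs
    )
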