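"""Configuration objects shared across the pipeline.

All study-level knobs live in pydantic models so that a run can be fully
specified by one JSON document and validated before any compute starts.
"""
from __future__ import annotations

import enum

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator


class Genotype(str, enum.Enum):
    """The four genetic backgrounds assayed: wild type, single knockouts of
    the serotonin-synthesis gene *tph-1* (expressed in NSM and ADF) and the
    TGF-beta ligand *daf-7* (expressed in ASI), and the double knockout."""

    wild_type = "wild_type"
    tph1_minus = "tph1_minus"
    daf7_minus = "daf7_minus"
    double_minus = "double_minus"


class EnvironmentCondition(BaseModel):
    """One cell of the environment grid: bacterial food concentration
    (cells/mL) crossed with cultivation temperature (degrees C)."""

    model_config = {"frozen": True}

    food: float = Field(ge=0)
    temperature: float

    def label(self) -> str:
        return f"food={self.food:g},T={self.temperature:g}"


class ExpressionNoise(BaseModel):
    """Covariance specification for the two stochastic layers of the
    expression model, parameterized as coefficients of variation relative to
    the condition mean plus a common inter-cell correlation."""

    batch_cv: float = Field(default=0.08, ge=0)
    population_cv: float = Field(default=0.20, ge=0)
    correlation: float = Field(default=0.3, gt=-1, lt=1)

    def covariances(self, mean: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (batch, population) 3x3 covariance matrices scaled to
        ``mean``. Both are of the form D R D with R the equicorrelation
        matrix, hence positive semidefinite by construction."""
        mean = np.asarray(mean, float)
        d = mean.size
        corr = np.full((d, d), self.correlation)
        np.fill_diagonal(corr, 1.0)
        batch = np.outer(mean, mean) * corr * self.batch_cv**2
        pop = np.outer(mean, mean) * corr * self.population_cv**2
        return batch, pop


class StudyConfig(BaseModel):
    """Design of a synthetic study: which environment grid, which genotypes,
    how many animals and batches, and the noise/censoring structure."""

    conditions: list[EnvironmentCondition]
    genotypes: list[Genotype] = Field(default_factory=lambda: list(Genotype))
    n_animals_per_cell: int = Field(default=50, ge=1)
    n_batches: int = Field(default=3, ge=1)
    censoring_day_schedule: list[float] = Field(
        default_factory=lambda: [float(d) for d in range(2, 62, 2)]
    )
    batch_sd_log_scale: float = Field(default=0.05, ge=0)
    batch_sd_log_shape: float = Field(default=0.05, ge=0)
    expression_noise: ExpressionNoise = Field(default_factory=ExpressionNoise)
    drift_slope_per_day: float = -0.01
    drift_intercept: float = 1.2
    record_whole_days: bool = True
    seed: int = 0

    @field_validator("conditions")
    @classmethod
    def _nonempty_conditions(cls, v):
        if not v:
            raise ValueError("condition list must not be empty")
        return v

    @field_validator("censoring_day_schedule")
    @classmethod
    def _sorted_schedule(cls, v):
        if not v:
            raise ValueError("censoring schedule must contain at least one day")
        if any(d <= 0 for d in v):
            raise ValueError("schedule days must be positive")
        return sorted(v)

    @property
    def foods(self) -> list[float]:
        return sorted({c.food for c in self.conditions})

    @property
    def temperatures(self) -> list[float]:
        return sorted({c.temperature for c in self.conditions})


#: Food levels used by default, bracketing the levels the decoder resolves
#: best in worms (2e7 and 6e8 cells/mL) with starvation and dilutions.
DEFAULT_FOODS = [0.0, 2e6, 2e7, 2e8, 6e8, 2e9]
DEFAULT_TEMPERATURES = [15.0, 20.0, 25.0]


def default_conditions(
    foods=None, temperatures=None
) -> list[EnvironmentCondition]:
    foods = DEFAULT_FOODS if foods is None else foods
    temperatures = DEFAULT_TEMPERATURES if temperatures is None else temperatures
    return [
        EnvironmentCondition(food=f, temperature=t)
        for t in temperatures
        for f in foods
    ]


class McmcSettings(BaseModel):
    """Sampler settings shared by the survival and expression fitters."""

    n_chains: int = Field(default=8, ge=2)
    n_iter: int = Field(default=1500, ge=10)
    burn_frac: float = Field(default=0.5, gt=0, lt=1)
    seed: int = 0
    rhat_threshold: float = Field(default=1.05, gt=1)


class OptimizerSettings(BaseModel):
    """Multi-restart greedy stochastic descent settings for network fits.

    Proposals are Gaussian steps in log-regulatory-parameter space; a step is
    accepted only if it lowers the cost, so each restart's accepted-cost
    trajectory is non-increasing.
    """

    n_restarts: int = Field(default=20, ge=1)
    n_iter: int = Field(default=600, ge=1)
    step_sigma: float = Field(default=0.1, gt=0)
    start_log_range: float = Field(default=float(np.log(10.0)), gt=0)
    max_abs_log_w: float = Field(default=float(np.log(100.0)), gt=0)
    #: deterministic Powell refinement of the n_polish best restarts
    #: (0 disables); the fixed-step descent alone stalls short of the minimum
    n_polish: int = Field(default=3, ge=0)
    polish_maxiter: int = Field(default=300, ge=1)
    seed: int = 0

    @model_validator(mode="after")
    def _range_inside_box(self):
        if self.start_log_range > self.max_abs_log_w:
            raise ValueError("start range must lie inside the log-w box")
        return self


def stage_seed(seed: int, stage: str) -> int:
    """Deterministically derive a per-stage child seed (< 2**31) from a
    global seed, so stages can be rerun in isolation."""
    import zlib

    return (int(seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31 - 1)
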