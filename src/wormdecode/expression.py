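"""Bead-based drift normalization and hierarchical expression estimation.

LED illumination drifts slowly over an imaging campaign, so recorded
fluorescence F relates to the biological signal f through a channel-specific
linear factor, F = f * (C1 + C2 * tau), estimated by Bayesian linear
regression of periodically imaged bead standards on time.  Normalized
per-animal 3-cell expression (tph-1 in NSM and ADF, daf-7 in ASI) is then
modeled per environmental condition with a two-layer multivariate normal
hierarchy — batch means scatter around a global condition mean with a batch
covariance, animals scatter around their batch mean with a population
covariance — sampled by a conjugate Gibbs sampler (normal / inverse-Wishart
updates).  For decoding, each condition's response distribution is the
multivariate normal with the posterior global mean and the element-wise sum
of the batch and population covariances (variance layers add quadratically).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import EnvironmentCondition, Genotype, McmcSettings, stage_seed
from .decoding import GaussianResponse
from .survival import PosteriorSamples, dynamic_range_posterior
from .synthetic import EXPRESSION_COLUMNS, REPORTER_CHANNELS

__all__ = [
    "BeadCalibration",
    "fit_bead_regression",
    "normalize_expression",
    "fit_hierarchical_expression",
    "response_distribution",
    "expression_dynamic_range",
]

logger = logging.getLogger(__name__)

#: Shared implementation: the dynamic range of expression across foods is
#: the same per-draw max-minus-min statistic used for lifespan.
expression_dynamic_range = dynamic_range_posterior


@dataclass
class BeadCalibration:
    """Posterior of the drift-regression coefficients for one channel.

    With flat priors on (C1, C2, log sigma2) the posterior is the standard
    normal-inverse-chi-square form: sigma2 ~ RSS / chi2_nu and
    (C1, C2) | sigma2 ~ N(beta_hat, sigma2 (X'X)^-1); ``draws`` holds joint
    samples (C1, C2, sigma2)."""

    channel: str
    c1: float
    c2: float
    sigma2: float
    draws: np.ndarray
    tau_range: tuple

    def factor(self, tau) -> np.ndarray:
        """Posterior-mean drift factor C1 + C2 * tau."""
        return self.c1 + self.c2 * np.asarray(tau, float)


def fit_bead_regression(
    beads: pd.DataFrame,
    channel: str,
    n_draws: int = 2000,
    seed: int = 0,
) -> BeadCalibration:
    """Bayesian linear regression of bead fluorescence on imaging time."""
    sub = beads[beads["channel"] == channel]
    tau = sub["tau"].to_numpy(float)
    y = sub["fluorescence"].to_numpy(float)
    if np.unique(tau).size < 2:
        raise ValueError(
            f"bead regression for channel {channel!r} is rank-deficient: "
            "need measurements at >=2 distinct timestamps"
        )
    if len(sub) < 3:
        raise ValueError("need at least 3 bead measurements per channel")
    X = np.column_stack([np.ones_like(tau), tau])
    beta_hat, rss_arr, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_hat
    rss = float(resid @ resid)
    nu = len(y) - 2
    xtx_inv = np.linalg.inv(X.T @ X)
    rng = np.random.default_rng(seed)
    if rss < 1e-12:  # exact line: posterior collapses to the OLS point
        sig2 = np.zeros(n_draws)
        betas = np.tile(beta_hat, (n_draws, 1))
    else:
        sig2 = rss / rng.chisquare(nu, size=n_draws)
        L = np.linalg.cholesky(xtx_inv)
        betas = beta_hat + np.sqrt(sig2)[:, None] * (
            rng.standard_normal((n_draws, 2)) @ L.T
        )
    tr = (float(tau.min()), float(tau.max()))
    cal = BeadCalibration(
        channel=channel,
        c1=float(beta_hat[0]),
        c2=float(beta_hat[1]),
        sigma2=rss / nu if nu > 0 else 0.0,
        draws=np.column_stack([betas, sig2]),
        tau_range=tr,
    )
    if np.any(cal.factor(np.array(tr)) <= 0):
        raise ValueError("fitted drift factor non-positive over the observed range")
    return cal


def normalize_expression(
    expr: pd.DataFrame, calibrations: dict
) -> pd.DataFrame:
    """Divide raw fluorescence by the posterior-mean drift factor of each
    reporter's channel at the batch imaging time; the input is not modified.

    Normalization uses the point (posterior-mean) factor; drift uncertainty
    is small next to batch and population variability, and full posterior
    propagation can be emulated by normalizing once per calibration draw."""
    out = expr.copy()
    tau = expr["tau"].to_numpy(float)
    for col in EXPRESSION_COLUMNS:
        cal = calibrations.get(REPORTER_CHANNELS[col])
        if cal is None:
            raise KeyError(f"no calibration for channel {REPORTER_CHANNELS[col]!r}")
        factor = cal.factor(tau)
        if np.any(factor <= 0):
            raise ValueError("drift factor non-positive at some imaging time")
        out[col] = expr[col].to_numpy(float) / factor
    return out


def _group_key(condition: EnvironmentCondition, genotype: Genotype) -> str:
    return f"{condition.label()}|{Genotype(genotype).value}"


_COV_NAMES = [(i, j) for i in range(3) for j in range(i, 3)]


def _gibbs_group(
    y: np.ndarray,
    batch_idx: np.ndarray,
    n_batches: int,
    mcmc: McmcSettings,
    seed: int,
):
    """Conjugate Gibbs sampler for one condition x genotype group.

    y: (n, 3) normalized expression; returns draws (chain, draw) for the
    global mean, batch covariance and population covariance entries.  The
    inverse-Wishart prior scale follows the data variance so the model is
    exactly equivariant under global rescaling of the fluorescence units."""
    n, d = y.shape
    rng = np.random.default_rng(seed)
    ybar = y.mean(axis=0)
    svar = y.var(axis=0, ddof=1) + 1e-12
    nu0 = d + 2
    psi0 = 1e-3 * np.diag(svar)
    hierarchical = n_batches > 1
    n_keep = mcmc.n_iter - int(mcmc.burn_frac * mcmc.n_iter)
    out = {
        name: np.empty((mcmc.n_chains, n_keep))
        for name in (
            [f"mu[{i}]" for i in range(d)]
            + [f"cov_batch[{i},{j}]" for i, j in _COV_NAMES]
            + [f"cov_pop[{i},{j}]" for i, j in _COV_NAMES]
        )
    }
    counts = np.bincount(batch_idx, minlength=n_batches)
    ymeans = np.stack(
        [y[batch_idx == b].mean(axis=0) for b in range(n_batches)]
    )
    for chain in range(mcmc.n_chains):
        # dispersed initialization around the empirical moments
        mu = ybar * np.exp(rng.normal(0, 0.05, d))
        sig_p = np.cov(y.T) * np.exp(rng.normal(0, 0.2))
        sig_b = np.diag(svar) * 0.1 * np.exp(rng.normal(0, 0.2))
        m = ymeans.copy()
        keep = 0
        for it in range(mcmc.n_iter):
            sp_inv = np.linalg.inv(sig_p)
            if hierarchical:
                sb_inv = np.linalg.inv(sig_b)
                for b in range(n_batches):
                    prec = counts[b] * sp_inv + sb_inv
                    cov = np.linalg.inv(prec)
                    mean = cov @ (counts[b] * sp_inv @ ymeans[b] + sb_inv @ mu)
                    m[b] = rng.multivariate_normal(mean, cov)
                mu = rng.multivariate_normal(m.mean(axis=0), sig_b / n_batches)
                # interweaved (non-centered) re-update of mu: holding the
                # batch offsets e_b = m_b - mu fixed removes the slow
                # mu <-> batch-mean random walk of the centered sampler
                e = m - mu
                mu = rng.multivariate_normal((y - e[batch_idx]).mean(axis=0), sig_p / n)
                m = e + mu
                S_b = (m - mu).T @ (m - mu)
                sig_b = stats.invwishart.rvs(
                    df=nu0 + n_batches, scale=psi0 + S_b, random_state=rng
                )
            else:
                m[0] = rng.multivariate_normal(ybar, sig_p / n)
                mu = m[0]
            resid = y - m[batch_idx]
            S_p = resid.T @ resid
            sig_p = stats.invwishart.rvs(
                df=nu0 + n, scale=psi0 + S_p, random_state=rng
            )
            if it >= mcmc.n_iter - n_keep:
                for i in range(d):
                    out[f"mu[{i}]"][chain, keep] = mu[i]
                for i, j in _COV_NAMES:
                    out[f"cov_batch[{i},{j}]"][chain, keep] = (
                        sig_b[i, j] if hierarchical else 0.0
                    )
                    out[f"cov_pop[{i},{j}]"][chain, keep] = sig_p[i, j]
                keep += 1
    return out


def fit_hierarchical_expression(
    expr: pd.DataFrame,
    mcmc: Optional[McmcSettings] = None,
    genotypes: Optional[list] = None,
) -> PosteriorSamples:
    """Fit the two-layer multivariate-normal hierarchy to every condition x
    genotype group of a (normalized) expression table.

    Needs columns food, temperature, genotype, batch and the three
    fluorescence columns.  With a single batch in a group the batch
    covariance is not identifiable and is fixed at zero (logged)."""
    mcmc = mcmc or McmcSettings(n_iter=600)
    draws = {}
    if genotypes is not None:
        allowed = {Genotype(g).value for g in genotypes}
        expr = expr[expr["genotype"].isin(allowed)]
    for (food, temp, geno), grp in expr.groupby(
        ["food", "temperature", "genotype"], observed=True
    ):
        cond = EnvironmentCondition(food=food, temperature=temp)
        key = _group_key(cond, Genotype(geno))
        y = grp[list(EXPRESSION_COLUMNS)].to_numpy(float)
        if np.any(y <= 0):
            raise ValueError(f"non-positive fluorescence in group {key}")
        batches = grp["batch"].to_numpy()
        uniq = np.unique(batches)
        if uniq.size == 1:
            logger.warning(
                "group %s has a single batch; batch covariance fixed to 0", key
            )
        batch_idx = np.searchsorted(uniq, batches)
        seed = stage_seed(mcmc.seed, f"expression|{key}")
        for name, arr in _gibbs_group(y, batch_idx, uniq.size, mcmc, seed).items():
            draws[f"{key}|{name}"] = arr
    post = PosteriorSamples(
        draws=draws,
        meta={
            "n_chains": mcmc.n_chains,
            "n_iter": mcmc.n_iter,
            "seed": mcmc.seed,
            "model": "hierarchical_expression",
        },
    )
    post.meta["rhat"] = {n: post.rhat(n) for n in post.names()}
    post.meta["max_rhat"] = float(np.nanmax(list(post.meta["rhat"].values())))
    # Covariance entries are weakly identified with few batches and have
    # heavy-tailed posteriors; the mean parameters are the decodable
    # quantities and their convergence is tracked separately.
    post.meta["max_rhat_mu"] = max(
        v for n, v in post.meta["rhat"].items() if "|mu[" in n
    )
    if post.meta["max_rhat_mu"] > mcmc.rhat_threshold:
        logger.warning(
            "mean-parameter convergence above threshold: %.4f",
            post.meta["max_rhat_mu"],
        )
    return post


def _mean_cov(post: PosteriorSamples, key: str):
    mu = np.array([post.flat(f"{key}|mu[{i}]").mean() for i in range(3)])
    cb = np.zeros((3, 3))
    cp = np.zeros((3, 3))
    for i, j in _COV_NAMES:
        cb[i, j] = cb[j, i] = post.flat(f"{key}|cov_batch[{i},{j}]").mean()
        cp[i, j] = cp[j, i] = post.flat(f"{key}|cov_pop[{i},{j}]").mean()
    return mu, cb, cp


def response_distribution(
    post: PosteriorSamples,
    condition: EnvironmentCondition,
    genotype: Genotype = Genotype.wild_type,
    ridge_frac: float = 1e-8,
) -> GaussianResponse:
    """Multivariate-normal response model for decoding: posterior global mean
    and the element-wise sum of the batch and population covariances, plus a
    small trace-scaled ridge so the density is always full rank."""
    key = _group_key(condition, genotype)
    try:
        mu, cb, cp = _mean_cov(post, key)
    except KeyError as exc:
        raise KeyError(f"condition {key!r} was not fitted") from exc
    total = cb + cp
    tr = np.trace(total)
    if tr <= 0:
        raise ValueError(
            f"degenerate (zero-variance) response distribution for {key}"
        )
    return GaussianResponse(mean=mu, cov=total + ridge_frac * tr * np.eye(3))
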