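"""Maximum-likelihood decoding of environmental stimuli from responses.

A decoder is given, for each candidate stimulus (food level or temperature),
the response distribution estimated under that stimulus — Weibull for
lifespan, multivariate normal for 3-cell expression.  Each observed response
is attributed to the stimulus maximizing its likelihood; ties are broken
uniformly at random with a seeded generator so that identical distributions
give exactly chance-level performance in expectation.  Tallying decoded
against actual stimuli gives the row-stochastic confusion matrix, and the
unweighted mean of its diagonal is the decoding power (1 = perfect
discrimination, 1/K = chance among K stimuli).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WeibullResponse",
    "GaussianResponse",
    "ResponseModelSet",
    "ml_decode",
    "confusion_matrix",
    "decoding_power",
    "decoding_power_distribution",
    "leave_one_out_decoding",
    "plot_confusion",
]


@dataclass(frozen=True)
class WeibullResponse:
    """Weibull lifespan response distribution (scale in days, shape)."""

    scale: float
    shape: float

    def __post_init__(self):
        if self.scale <= 0 or self.shape <= 0:
            raise ValueError("Weibull scale and shape must be positive")

    def logpdf(self, x) -> np.ndarray:
        return stats.weibull_min.logpdf(x, self.shape, scale=self.scale)

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.scale * rng.weibull(self.shape, size=n)


@dataclass(frozen=True)
class GaussianResponse:
    """Multivariate normal response distribution (e.g. 3-cell expression)."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        mean = np.atleast_1d(np.asarray(self.mean, float))
        cov = np.atleast_2d(np.asarray(self.cov, float))
        if cov.shape != (mean.size, mean.size):
            raise ValueError("covariance shape does not match the mean")
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)

    def logpdf(self, x) -> np.ndarray:
        return stats.multivariate_normal.logpdf(x, mean=self.mean, cov=self.cov)

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.multivariate_normal(self.mean, self.cov, size=n)


@dataclass(frozen=True)
class ResponseModelSet:
    """Ordered stimuli with one response density per stimulus."""

    stimuli: tuple
    models: tuple

    def __post_init__(self):
        object.__setattr__(self, "stimuli", tuple(self.stimuli))
        object.__setattr__(self, "models", tuple(self.models))
        if len(self.stimuli) != len(self.models):
            raise ValueError("one model per stimulus required")
        if len(self.stimuli) < 2:
            raise ValueError("need at least two stimuli to decode")

    @property
    def K(self) -> int:
        return len(self.stimuli)

    def drop(self, stimulus) -> "ResponseModelSet":
        keep = [i for i, s in enumerate(self.stimuli) if s != stimulus]
        if len(keep) == len(self.stimuli):
            raise KeyError(f"unknown stimulus {stimulus!r}")
        return ResponseModelSet(
            tuple(self.stimuli[i] for i in keep),
            tuple(self.models[i] for i in keep),
        )

    def loglik_matrix(self, responses) -> np.ndarray:
        responses = np.asarray(responses, float)
        n = responses.shape[0]
        L = np.empty((n, self.K))
        for k, m in enumerate(self.models):
            L[:, k] = m.logpdf(responses)
        return L


def ml_decode(
    responses,
    models: ResponseModelSet,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Decoded stimulus index for each response: argmax over stimuli of the
    response density, ties broken uniformly at random."""
    rng = rng if rng is not None else np.random.default_rng(0)
    L = models.loglik_matrix(responses)
    if np.any(np.all(np.isinf(L) & (L < 0), axis=1)):
        raise ValueError("response has zero density under every stimulus")
    is_max = L == L.max(axis=1, keepdims=True)
    # random argmax among tied maxima
    u = rng.random(L.shape)
    return np.argmax(np.where(is_max, u, -1.0), axis=1)


def confusion_matrix(
    responses,
    labels,
    models: ResponseModelSet,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Row-stochastic matrix of decoded-vs-actual stimulus frequencies.

    ``labels`` holds each response's true stimulus (values from
    ``models.stimuli``); every stimulus must contribute at least one
    response."""
    labels = np.asarray(labels)
    decoded = ml_decode(responses, models, rng)
    K = models.K
    stim_index = {s: i for i, s in enumerate(models.stimuli)}
    counts = np.zeros((K, K))
    for lab, d in zip(labels, decoded):
        counts[stim_index[lab], d] += 1
    row_n = counts.sum(axis=1)
    missing = [models.stimuli[i] for i in np.where(row_n == 0)[0]]
    if missing:
        raise ValueError(f"no responses for stimulus {missing[0]!r}")
    freq = counts / row_n[:, None]
    return pd.DataFrame(freq, index=list(models.stimuli), columns=list(models.stimuli))


def decoding_power(confusion: pd.DataFrame, weights=None) -> float:
    """Average frequency of correct inference: the unweighted mean of the
    confusion-matrix diagonal (optionally weighted per stimulus)."""
    diag = np.diag(np.asarray(confusion, float))
    if weights is None:
        return float(diag.mean())
    weights = np.asarray(weights, float)
    return float(diag @ weights / weights.sum())


def decoding_power_distribution(
    model_sets: Sequence[ResponseModelSet],
    data=None,
    labels=None,
    n_per_stimulus: int = 200,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Posterior distribution of decoding power.

    Each element of ``model_sets`` is the response-model set rebuilt from
    one posterior parameter draw.  By default, fresh responses are simulated
    from that draw's models (``n_per_stimulus`` each) and decoded; passing
    ``data``/``labels`` decodes the fixed observed set instead."""
    if len(model_sets) < 2:
        raise ValueError("need at least two posterior draws")
    rng = rng if rng is not None else np.random.default_rng(0)
    powers = np.empty(len(model_sets))
    for i, ms in enumerate(model_sets):
        if data is None:
            resp, labs = [], []
            for s, m in zip(ms.stimuli, ms.models):
                r = np.asarray(m.rvs(n_per_stimulus, rng), float)
                resp.append(r.reshape(n_per_stimulus, -1))
                labs.extend([s] * n_per_stimulus)
            stacked = np.concatenate(resp)
            if stacked.shape[1] == 1:
                stacked = stacked[:, 0]
            conf = confusion_matrix(stacked, labs, ms, rng)
        else:
            conf = confusion_matrix(data, labels, ms, rng)
        powers[i] = decoding_power(conf)
    return powers


def leave_one_out_decoding(
    responses,
    labels,
    models: ResponseModelSet,
    rng: Optional[np.random.Generator] = None,
) -> dict:
    """Decoding power recomputed with each stimulus left out in turn.

    Guards against the power estimate hinging on a single informative
    stimulus; requires at least 3 stimuli so the reduced problem is still a
    discrimination task."""
    if models.K < 3:
        raise ValueError("leave-one-out needs at least 3 stimuli")
    labels = np.asarray(labels)
    responses = np.asarray(responses, float)
    out = {}
    for s in models.stimuli:
        keep = labels != s
        sub = models.drop(s)
        conf = confusion_matrix(responses[keep], labels[keep], sub, rng)
        out[s] = decoding_power(conf)
    return out


def plot_confusion(confusion: pd.DataFrame, path, title: str = "") -> None:
    """Render a confusion matrix as a heatmap image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(np.asarray(confusion, float), vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(confusion.columns)))
    ax.set_xticklabels([f"{c:g}" if isinstance(c, float) else str(c) for c in confusion.columns], rotation=45)
    ax.set_yticks(range(len(confusion.index)))
    ax.set_yticklabels([f"{c:g}" if isinstance(c, float) else str(c) for c in confusion.index])
    ax.set_xlabel("inferred stimulus")
    ax.set_ylabel("actual stimulus")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
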