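"""Eight-state Master-equation model of the ADF/ASI/NSM regulatory network.

The three food-sensing neuron classes are reduced to binary activity
variables (s_x, s_y, s_z) for ADF (x), ASI (y) and NSM (z).  The joint state
lives on the 8 corners of a cube; allowed transitions flip one neuron at a
time.  Every ON switch occurs at a uniform reference rate ``kon``; an OFF
switch of neuron beta is modulated by a positive 3x3 regulatory matrix ``w``:

    rate(beta OFF from state s) = w[beta,beta] * prod_{alpha active, alpha!=beta} w[alpha,beta]

so an entry w[alpha,beta] > 1 speeds up switch-off of beta when alpha is
active (negative regulation) and an entry < 1 slows it down (positive
regulation); w == 1 means no interaction.  The steady state of the Master
equation gives each neuron's marginal probability of being active,
Q = (Q_x, Q_y, Q_z), and knocking a gene out deletes all regulatory edges
arising from the cells that express it (its promoter, hence its readout,
remains).  Mutant/wild-type ratios of these marginals are fitted against the
corresponding measured expression ratios by weighted least squares over the
9-parameter space, optionally constrained to one of the 2^9 = 512 sign
assignments of the edges.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .config import Genotype, OptimizerSettings

__all__ = [
    "N_STATES",
    "N_EDGES",
    "N_SIGN_MODELS",
    "EDGE_NAMES",
    "CELLS",
    "MUTANT_ORDER",
    "RegulatoryMatrix",
    "RatioObservations",
    "SignModel",
    "NetworkFit",
    "ShuffleResult",
    "build_rate_matrix",
    "steady_state",
    "marginals",
    "apply_mutant",
    "predicted_ratios",
    "observed_ratios",
    "cost",
    "fit_network",
    "enumerate_sign_models",
    "classify_edges",
    "edge_sign_table",
    "aggregate_models",
    "shuffle_significance",
]

N_STATES = 8
N_EDGES = 9
N_SIGN_MODELS = 2**N_EDGES

#: Edge names t1..t9 in row-major order of w: rows = regulating neuron,
#: columns = regulated neuron, axis order (x=ADF, y=ASI, z=NSM).
EDGE_NAMES = ("t1", "t2", "t3", "t4", "t5", "t6", "t7", "t8", "t9")
CELLS = ("ADF", "ASI", "NSM")  # x, y, z

#: Mutant rows of the ratio matrices, in the order f = 1, 2, 3.
MUTANT_ORDER = (Genotype.daf7_minus, Genotype.tph1_minus, Genotype.double_minus)

# State index i (0-based) has neuron bits: x = bit0, y = bit1, z = bit2, so
# state 1 = (0,0,0), 2 = (1,0,0), 3 = (0,1,0), 4 = (1,1,0), 5 = (0,0,1), ...
_BITS = np.array(
    [[(i >> n) & 1 for n in range(3)] for i in range(N_STATES)], dtype=int
)
#: (8, 3) membership matrix: column n selects the states where neuron n is ON.
STATE_MEMBERSHIP = _BITS.astype(float)


def _off_transitions():
    """Enumerate single-neuron OFF transitions.

    Returns (i_idx, j_idx, expo) where transition j -> i switches one neuron
    off and its rate is exp(expo @ log w.ravel())."""
    i_idx, j_idx, expos = [], [], []
    for j in range(N_STATES):
        for beta in range(3):
            if not _BITS[j, beta]:
                continue
            i = j & ~(1 << beta)
            e = np.zeros((3, 3))
            e[beta, beta] += 1.0
            for alpha in range(3):
                if alpha != beta and _BITS[j, alpha]:
                    e[alpha, beta] += 1.0
            i_idx.append(i)
            j_idx.append(j)
            expos.append(e.ravel())
    return np.array(i_idx), np.array(j_idx), np.array(expos)


_OFF_I, _OFF_J, _OFF_EXPO = _off_transitions()

_ON_I, _ON_J = [], []
for j in range(N_STATES):
    for beta in range(3):
        if not _BITS[j, beta]:
            _ON_I.append(j | (1 << beta))
            _ON_J.append(j)
_ON_I = np.array(_ON_I)
_ON_J = np.array(_ON_J)

# Gene knockouts delete all edges arising from the cells expressing the gene:
# daf-7 is made by ASI (row y -> t4,t5,t6), tph-1 by ADF and NSM (rows x and z).
_MUTANT_KEEP = {
    Genotype.wild_type: np.ones(9),
    Genotype.daf7_minus: np.array([1, 1, 1, 0, 0, 0, 1, 1, 1], dtype=float),
    Genotype.tph1_minus: np.array([0, 0, 0, 1, 1, 1, 0, 0, 0], dtype=float),
    Genotype.double_minus: np.zeros(9),
}


@dataclass(frozen=True)
class RegulatoryMatrix:
    """Positive 3x3 regulatory matrix plus the reference ON rate.

    Entry [alpha, beta] scales the OFF rate of neuron beta when alpha is
    active; 1 means no regulation. Flattened row-major the entries are the
    nine parameters t1..t9.
    """

    w: np.ndarray
    kon: float = 1.0

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        if w.shape != (3, 3):
            raise ValueError(f"w must be 3x3, got {w.shape}")
        if not np.all(w > 0):
            raise ValueError("all regulatory entries must be positive")
        if not self.kon > 0:
            raise ValueError("kon must be positive")
        object.__setattr__(self, "w", w)

    @classmethod
    def from_flat(cls, t: Iterable[float], kon: float = 1.0) -> "RegulatoryMatrix":
        t = np.asarray(list(t), dtype=float)
        if t.size != 9:
            raise ValueError("need exactly 9 entries t1..t9")
        return cls(w=t.reshape(3, 3), kon=kon)

    @classmethod
    def ones(cls, kon: float = 1.0) -> "RegulatoryMatrix":
        return cls(w=np.ones((3, 3)), kon=kon)

    @property
    def flat(self) -> np.ndarray:
        return self.w.ravel()

    def to_dict(self) -> dict:
        return {"kon": self.kon, **dict(zip(EDGE_NAMES, self.flat.tolist()))}


def build_rate_matrix(w: RegulatoryMatrix) -> np.ndarray:
    """8x8 transition-rate matrix W with W[i, j] = rate of j -> i.

    Only single-neuron flips have nonzero rates; the diagonal is zero (the
    outflow terms are carried by the Master-equation generator, see
    :func:`steady_state`)."""
    W = np.zeros((N_STATES, N_STATES))
    logw = np.log(w.w.ravel())
    W[_OFF_I, _OFF_J] = np.exp(_OFF_EXPO @ logw)
    W[_ON_I, _ON_J] = w.kon
    return W


def _generator(W: np.ndarray) -> np.ndarray:
    """Master-equation generator A with dp/dt = A p."""
    A = W.copy()
    np.fill_diagonal(A, 0.0)
    A[np.diag_indices_from(A)] = -A.sum(axis=0)
    return A


def steady_state(W: np.ndarray) -> np.ndarray:
    """Stationary distribution of the Master equation for rate matrix W.

    Solves the balance equations sum_j (W_ij p_j - W_ji p_i) = 0 with the
    normalization sum_i p_i = 1 by replacing one balance row with the
    normalization constraint."""
    A = _generator(np.asarray(W, dtype=float))
    M = A.copy()
    M[-1, :] = 1.0
    b = np.zeros(N_STATES)
    b[-1] = 1.0
    p = np.linalg.solve(M, b)
    resid = np.abs(A @ p).max()
    if resid > 1e-10 or np.any(p < -1e-12):
        raise np.linalg.LinAlgError(
            f"steady-state solve failed (residual {resid:.2e})"
        )
    return np.clip(p, 0.0, None)


def _steady_state_batch(logw: np.ndarray, kon: float) -> np.ndarray:
    """Stationary distributions for a batch of log-regulatory matrices.

    logw has shape (m, 9); returns (m, 8). One stacked linear solve."""
    m = logw.shape[0]
    rates_off = np.exp(logw @ _OFF_EXPO.T)  # (m, n_off)
    A = np.zeros((m, N_STATES, N_STATES))
    A[:, _OFF_I, _OFF_J] = rates_off
    A[:, _ON_I, _ON_J] = kon
    colsum = A.sum(axis=1)
    idx = np.arange(N_STATES)
    A[:, idx, idx] = -colsum
    A[:, -1, :] = 1.0
    b = np.zeros((m, N_STATES, 1))
    b[:, -1, 0] = 1.0
    return np.linalg.solve(A, b)[..., 0]


def marginals(p: np.ndarray) -> np.ndarray:
    """(Q_x, Q_y, Q_z): probability of each neuron being active, summing the
    stationary probabilities of the states where it is ON."""
    p = np.asarray(p, dtype=float)
    return p @ STATE_MEMBERSHIP


def apply_mutant(w: RegulatoryMatrix, genotype: Genotype) -> RegulatoryMatrix:
    """Network of a knockout: every edge arising from the deleted gene's
    cells is reset to 1 (no regulation); incoming edges onto its promoter
    are kept because the reporter is still present."""
    genotype = Genotype(genotype)
    keep = _MUTANT_KEEP[genotype]
    flat = np.where(keep > 0, w.flat, 1.0)
    return RegulatoryMatrix.from_flat(flat, kon=w.kon)


def _predicted_ratios_batch(logw: np.ndarray, kon: float) -> np.ndarray:
    """Predicted mutant/wild-type marginal ratios for a batch of networks.

    logw (m, 9) -> (m, 3 mutants, 3 cells), mutant rows in MUTANT_ORDER."""
    m = logw.shape[0]
    keep = np.stack([_MUTANT_KEEP[g] for g in (Genotype.wild_type,) + MUTANT_ORDER])
    stacked = (logw[:, None, :] * keep[None, :, :]).reshape(4 * m, 9)
    p = _steady_state_batch(stacked, kon)
    Q = (p @ STATE_MEMBERSHIP).reshape(m, 4, 3)
    return Q[:, 1:, :] / Q[:, :1, :]


def predicted_ratios(w: RegulatoryMatrix) -> np.ndarray:
    """3x3 matrix of predicted expression ratios: rows are the mutants
    (daf-7(-), tph-1(-), double) and columns the cells (ADF, ASI, NSM); each
    entry is Q_n(mutant network) / Q_n(wild-type network)."""
    return _predicted_ratios_batch(np.log(w.flat)[None, :], w.kon)[0]


@dataclass(frozen=True)
class RatioObservations:
    """Observed mutant/wild-type expression ratios.

    R and sigma are 3x3 (mutants in MUTANT_ORDER x cells in CELLS): the mean
    and standard deviation of the per-pair ratios across paired
    mutant/wild-type experiments."""

    R: np.ndarray
    sigma: np.ndarray
    n_pairs: int

    def __post_init__(self):
        R = np.asarray(self.R, dtype=float)
        s = np.asarray(self.sigma, dtype=float)
        if R.shape != (3, 3) or s.shape != (3, 3):
            raise ValueError("R and sigma must be 3x3")
        if not np.all(R > 0):
            raise ValueError("ratios must be positive")
        if np.any(s < 0):
            raise ValueError("sigma must be nonnegative")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "sigma", s)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f, g in enumerate(MUTANT_ORDER):
            for n, cell in enumerate(CELLS):
                rows.append(
                    dict(
                        mutant=g.value,
                        cell=cell,
                        R=self.R[f, n],
                        sigma=self.sigma[f, n],
                        n_pairs=self.n_pairs,
                    )
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RatioObservations":
        R = np.empty((3, 3))
        s = np.empty((3, 3))
        for f, g in enumerate(MUTANT_ORDER):
            for n, cell in enumerate(CELLS):
                row = df[(df["mutant"] == g.value) & (df["cell"] == cell)]
                if len(row) != 1:
                    raise ValueError(f"missing or duplicated entry {g.value}/{cell}")
                R[f, n] = row["R"].iloc[0]
                s[f, n] = row["sigma"].iloc[0]
        return cls(R=R, sigma=s, n_pairs=int(df["n_pairs"].iloc[0]))


# Expression-table columns carrying each cell's readout, in (x, y, z) order.
_CELL_COLUMNS = {"ADF": "f_adf", "ASI": "f_asi", "NSM": "f_nsm"}


def observed_ratios(expr: pd.DataFrame, min_pairs: int = 2) -> RatioObservations:
    """Estimate mutant/wild-type expression ratios from paired batches.

    ``expr`` holds per-animal (normalized) fluorescence for one environmental
    condition with columns batch, genotype, f_nsm, f_adf, f_asi. Mutant
    batches are paired with the wild-type data of the same batch (the
    same-day control); the per-pair ratio of batch mean expression is
    averaged across pairs.
    """
    cols = [_CELL_COLUMNS[c] for c in CELLS]
    means = expr.groupby(["batch", "genotype"], observed=True)[cols].mean()
    R = np.empty((3, 3))
    sig = np.empty((3, 3))
    n_min = None
    for f, g in enumerate(MUTANT_ORDER):
        ratios = []
        for batch in means.index.get_level_values("batch").unique():
            try:
                wt = means.loc[(batch, Genotype.wild_type.value)]
                mu = means.loc[(batch, g.value)]
            except KeyError:
                continue
            if np.any(wt.to_numpy() <= 0):
                raise ValueError(f"non-positive wild-type mean in batch {batch}")
            ratios.append(mu.to_numpy() / wt.to_numpy())
        if len(ratios) < min_pairs:
            raise ValueError(
                f"need >= {min_pairs} paired batches for {g.value}, got {len(ratios)}"
            )
        arr = np.asarray(ratios)
        R[f] = arr.mean(axis=0)
        sig[f] = arr.std(axis=0, ddof=1)
        n_min = len(ratios) if n_min is None else min(n_min, len(ratios))
    return RatioObservations(R=R, sigma=sig, n_pairs=n_min)


def cost(w: RegulatoryMatrix, obs: RatioObservations) -> float:
    """Weighted least-squares cost H: sum over the 9 mutant/cell entries of
    ((predicted ratio - observed ratio) / sigma)^2.

    A zero sigma with a matching prediction contributes 0 (a hard, satisfied
    constraint); a zero sigma with a mismatch is infeasible and raises."""
    pred = predicted_ratios(w)
    resid = pred - obs.R
    out = np.zeros((3, 3))
    zero = obs.sigma == 0
    if np.any(zero & (np.abs(resid) > 1e-12)):
        raise ValueError("zero sigma with nonzero residual: infinite cost")
    ok = ~zero
    out[ok] = (resid[ok] / obs.sigma[ok]) ** 2
    return float(out.sum())


def _cost_batch(logw: np.ndarray, obs: RatioObservations, kon: float) -> np.ndarray:
    pred = _predicted_ratios_batch(logw, kon)
    resid = pred - obs.R[None]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = resid / obs.sigma[None]
    z = np.where(obs.sigma[None] == 0, np.where(np.abs(resid) > 1e-12, np.inf, 0.0), z)
    return (z * z).sum(axis=(1, 2))


@dataclass(frozen=True)
class SignModel:
    """Assignment of each of the 9 edges to positive (w < 1) or negative
    (w > 1) regulation; one of the 512 candidate architectures."""

    signs: tuple

    def __post_init__(self):
        if len(self.signs) != 9 or any(
            s not in ("positive", "negative") for s in self.signs
        ):
            raise ValueError("sign model needs 9 entries in {positive, negative}")

    @classmethod
    def from_log_sign(cls, s: np.ndarray) -> "SignModel":
        return cls(tuple("negative" if v > 0 else "positive" for v in s))

    def log_bounds(self, max_abs_log_w: float) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) box in log-w space consistent with the signs."""
        s = np.array([1.0 if x == "negative" else -1.0 for x in self.signs])
        lo = np.where(s > 0, 0.0, -max_abs_log_w)
        hi = np.where(s > 0, max_abs_log_w, 0.0)
        return lo, hi

    @classmethod
    def enumerate_all(cls):
        for combo in itertools.product(("positive", "negative"), repeat=9):
            yield cls(combo)


@dataclass
class NetworkFit:
    """Result of fitting the regulatory matrix to ratio observations."""

    w_hat: RegulatoryMatrix
    cost: float
    sign_model: SignModel
    n_restarts: int
    n_iter: int
    n_accepted: int
    restart_costs: np.ndarray
    converged: bool = True
    condition: Optional[str] = None


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Reflect proposals into the box [lo, hi] (steps are small relative to
    the box, one folding pass suffices; clip guards the pathological tail)."""
    span = hi - lo
    y = np.abs(np.mod(x - lo, 2 * span))
    y = np.where(y > span, 2 * span - y, y)
    return np.clip(lo + y, lo, hi)


def _descend(
    x: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    obs: RatioObservations,
    kon: float,
    n_iter: int,
    step_sigma: float,
    rng: np.random.Generator,
    return_trace: bool = False,
):
    """Vectorized greedy stochastic descent: every row of ``x`` is an
    independent restart; Gaussian proposals are accepted only when they lower
    the cost."""
    costs = _cost_batch(x, obs, kon)
    n_accepted = np.zeros(x.shape[0], dtype=int)
    trace = [costs.copy()] if return_trace else None
    for _ in range(n_iter):
        prop = _reflect(x + rng.normal(0.0, step_sigma, size=x.shape), lo, hi)
        prop_costs = _cost_batch(prop, obs, kon)
        better = prop_costs < costs
        x[better] = prop[better]
        costs[better] = prop_costs[better]
        n_accepted += better
        if return_trace:
            trace.append(costs.copy())
    return x, costs, n_accepted, (np.array(trace) if return_trace else None)


def _polish(x, costs, lo, hi, obs, kon, n_polish, maxiter):
    """Deterministic local refinement of the lowest-cost restarts.

    The fixed-step stochastic descent stalls short of the minimum inside
    narrow curved valleys of H; a bounded derivative-free line-search
    (Powell) started from the best restarts closes that gap."""
    from scipy.optimize import minimize

    order = np.argsort(costs)[:n_polish]
    best_c = np.inf
    best_x = x[order[0]]
    for i in order:
        f = lambda v: float(  # noqa: E731
            _cost_batch(np.clip(v, lo[i], hi[i])[None, :], obs, kon)[0]
        )
        res = minimize(
            f,
            x[i],
            method="Powell",
            options=dict(maxiter=maxiter, xtol=1e-6, ftol=1e-9),
        )
        if res.fun < best_c:
            best_c = float(res.fun)
            best_x = np.clip(res.x, lo[i], hi[i])
    return best_x, best_c


def fit_network(
    obs: RatioObservations,
    sign_model: Optional[SignModel] = None,
    opt: Optional[OptimizerSettings] = None,
    kon: float = 1.0,
    rng: Optional[np.random.Generator] = None,
    condition: Optional[str] = None,
) -> NetworkFit:
    """Fit the 9 regulatory parameters by multi-restart stochastic descent
    on the weighted least-squares cost, in log-w space, followed by a
    deterministic local polish of the best restarts.

    With a sign model, each entry is confined by reflection to its side of
    w = 1; without one, the full box is searched and the fitted signs are
    read off the estimate."""
    opt = opt or OptimizerSettings()
    rng = rng if rng is not None else np.random.default_rng(opt.seed)
    R = opt.n_restarts
    if sign_model is None:
        lo = np.full((R, 9), -opt.max_abs_log_w)
        hi = np.full((R, 9), opt.max_abs_log_w)
    else:
        l, h = sign_model.log_bounds(opt.max_abs_log_w)
        lo = np.tile(l, (R, 1))
        hi = np.tile(h, (R, 1))
    x0 = rng.uniform(
        np.maximum(lo, -opt.start_log_range), np.minimum(hi, opt.start_log_range)
    )
    x, costs, n_acc, _ = _descend(
        x0, lo, hi, obs, kon, opt.n_iter, opt.step_sigma, rng
    )
    best = int(np.argmin(costs))
    best_x, best_c = x[best], float(costs[best])
    if opt.n_polish > 0:
        px, pc = _polish(
            x, costs, lo, hi, obs, kon, opt.n_polish, opt.polish_maxiter
        )
        if pc <= best_c:
            best_x, best_c = px, pc
    w_hat = RegulatoryMatrix.from_flat(np.exp(best_x), kon=kon)
    fitted_sign = sign_model or SignModel.from_log_sign(best_x)
    return NetworkFit(
        w_hat=w_hat,
        cost=best_c,
        sign_model=fitted_sign,
        n_restarts=R,
        n_iter=opt.n_iter,
        n_accepted=int(n_acc.sum()),
        restart_costs=np.sort(costs),
        converged=bool(n_acc[best] > 0),
        condition=condition,
    )


def enumerate_sign_models(
    obs: RatioObservations,
    opt: Optional[OptimizerSettings] = None,
    kon: float = 1.0,
    rng: Optional[np.random.Generator] = None,
    condition: Optional[str] = None,
) -> list[NetworkFit]:
    """Fit all 512 sign-constrained architectures and return the fits sorted
    by cost (best first).

    All models and restarts are packed into a single vectorized descent, so
    the full scan costs one batched linear solve per iteration."""
    opt = opt or OptimizerSettings()
    rng = rng if rng is not None else np.random.default_rng(opt.seed)
    models = list(SignModel.enumerate_all())
    R = opt.n_restarts
    los, his = zip(*(m.log_bounds(opt.max_abs_log_w) for m in models))
    lo = np.repeat(np.stack(los), R, axis=0)
    hi = np.repeat(np.stack(his), R, axis=0)
    x0 = rng.uniform(
        np.maximum(lo, -opt.start_log_range), np.minimum(hi, opt.start_log_range)
    )
    x, costs, n_acc, _ = _descend(
        x0, lo, hi, obs, kon, opt.n_iter, opt.step_sigma, rng
    )
    fits = []
    for k, m in enumerate(models):
        block = slice(k * R, (k + 1) * R)
        bc = costs[block]
        best = int(np.argmin(bc)) + k * R
        fits.append(
            NetworkFit(
                w_hat=RegulatoryMatrix.from_flat(np.exp(x[best]), kon=kon),
                cost=float(costs[best]),
                sign_model=m,
                n_restarts=R,
                n_iter=opt.n_iter,
                n_accepted=int(n_acc[block].sum()),
                restart_costs=np.sort(bc),
                converged=True,
                condition=condition,
            )
        )
    fits.sort(key=lambda f: f.cost)
    if opt.n_polish > 0:
        # polish only the winning model: the scan ranks architectures, the
        # refined parameters matter for the best fit alone
        top = fits[0]
        l, h = top.sign_model.log_bounds(opt.max_abs_log_w)
        px, pc = _polish(
            np.log(top.w_hat.flat)[None, :],
            np.array([top.cost]),
            l[None, :],
            h[None, :],
            obs,
            kon,
            1,
            opt.polish_maxiter,
        )
        if pc <= top.cost:
            top.w_hat = RegulatoryMatrix.from_flat(np.exp(px), kon=kon)
            top.cost = pc
            fits.sort(key=lambda f: f.cost)
    return fits


def classify_edges(
    w: RegulatoryMatrix, strength_threshold: float = 2.0, tol: float = 1e-9
) -> pd.DataFrame:
    """Categorize each edge by sign (negative if w > 1, positive if w < 1,
    neutral at 1) and strength (strong if the fold effect max(w, 1/w)
    reaches the threshold)."""
    if not strength_threshold > 1:
        raise ValueError("strength threshold must exceed 1")
    rows = []
    for name, v in zip(EDGE_NAMES, w.flat):
        if abs(v - 1.0) <= tol:
            sign = "neutral"
        else:
            sign = "negative" if v > 1 else "positive"
        fold = max(v, 1.0 / v)
        rows.append(
            dict(
                edge=name,
                w=v,
                sign=sign,
                strength="strong" if fold >= strength_threshold else "weak",
            )
        )
    return pd.DataFrame(rows).set_index("edge")


def edge_sign_table(fits: dict) -> pd.DataFrame:
    """Edge-category table: rows t1..t9, one column per environmental
    condition keyed by (food, temperature), values the fitted edge sign."""
    cols = {}
    for (food, temperature), fit in fits.items():
        cols[(food, temperature)] = classify_edges(fit.w_hat)["sign"]
    table = pd.DataFrame(cols)
    table.columns = pd.MultiIndex.from_tuples(
        table.columns, names=["food", "temperature"]
    )
    return table


def aggregate_models(
    fits: Sequence[NetworkFit],
    scheme: Literal["best", "gof_weighted_geomean", "top_likelihood_set"] = "best",
    likelihood_cutoff: float = 0.95,
) -> RegulatoryMatrix:
    """Combine a grid of fitted models into one regulatory matrix.

    ``best`` takes the minimum-cost model; ``gof_weighted_geomean`` takes the
    geometric mean of the parameters weighted by exp(-H/2);
    ``top_likelihood_set`` averages (geometrically, unweighted) the models
    whose likelihood relative to the best, exp(-(H - Hmin)/2), reaches the
    cutoff."""
    if not fits:
        raise ValueError("empty model grid")
    H = np.array([f.cost for f in fits])
    logw = np.log(np.stack([f.w_hat.flat for f in fits]))
    kon = fits[0].w_hat.kon
    if scheme == "best":
        return fits[int(np.argmin(H))].w_hat
    if scheme == "gof_weighted_geomean":
        wts = np.exp(-(H - H.min()) / 2.0)
        wts /= wts.sum()
        return RegulatoryMatrix.from_flat(np.exp(wts @ logw), kon=kon)
    if scheme == "top_likelihood_set":
        keep = np.exp(-(H - H.min()) / 2.0) >= likelihood_cutoff
        return RegulatoryMatrix.from_flat(np.exp(logw[keep].mean(axis=0)), kon=kon)
    raise ValueError(f"unknown aggregation scheme {scheme!r}")


@dataclass(frozen=True)
class ShuffleResult:
    observed_statistic: int
    threshold: int
    n_passing: int
    n_shuffles: int
    p_hat: float


_SIGN_CODE = {"positive": 1, "negative": -1, "neutral": 0}


def shuffle_significance(
    table: pd.DataFrame,
    n_shuffles: int = 100_000,
    min_edges: int = 4,
    seed: int = 0,
    chunk: int = 20_000,
) -> ShuffleResult:
    """Permutation test for temperature-dependent edge rewiring.

    The statistic counts edges whose per-temperature consensus sign (majority
    over the food columns at each temperature, ties neutral) flips between
    the temperature extremes — opposite nonzero signs at the lowest and
    highest temperature — moving monotonically through the intermediate
    temperatures. Shuffling permutes the condition columns uniformly while
    the (food, temperature) labels stay in place; p_hat is the fraction of
    shuffles whose statistic reaches min(observed, min_edges) (at least 1,
    so a table with no observed flip is never trivially matched)."""
    if not isinstance(table.columns, pd.MultiIndex):
        raise ValueError("table columns must be a (food, temperature) MultiIndex")
    temps = sorted(table.columns.get_level_values("temperature").unique())
    if len(temps) < 2:
        raise ValueError("need at least two temperatures")
    data = table.to_numpy()
    enc = np.vectorize(_SIGN_CODE.__getitem__)(data).astype(np.int64)
    C = enc.shape[1]
    G = np.zeros((C, len(temps)))
    col_t = table.columns.get_level_values("temperature").to_numpy()
    for k, t in enumerate(temps):
        G[col_t == t, k] = 1.0

    def statistic(block: np.ndarray) -> np.ndarray:
        # block: (..., 9, C) -> count of monotonically flipping edges (...)
        sums = block @ G  # (..., 9, T)
        cons = np.sign(sums)
        d = np.diff(cons, axis=-1)
        mono = np.all(d >= 0, axis=-1) | np.all(d <= 0, axis=-1)
        flipped = cons[..., 0] * cons[..., -1] == -1
        return (mono & flipped).sum(axis=-1)

    observed = int(statistic(enc))
    threshold = max(1, min(observed, min_edges))
    rng = np.random.default_rng(seed)
    n_passing = 0
    done = 0
    base = np.arange(C)
    while done < n_shuffles:
        s = min(chunk, n_shuffles - done)
        perms = rng.permuted(np.broadcast_to(base, (s, C)).copy(), axis=1)
        shuffled = enc[:, perms].transpose(1, 0, 2)  # (s, 9, C)
        stats = statistic(shuffled)
        n_passing += int((stats >= threshold).sum())
        done += s
    return ShuffleResult(
        observed_statistic=observed,
        threshold=threshold,
        n_passing=n_passing,
        n_shuffles=n_shuffles,
        p_hat=n_passing / n_shuffles,
    )
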