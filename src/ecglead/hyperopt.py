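"""Gaussian-process Bayesian optimization of training hyperparameters.

The objective f(x) is the final validation RMSE of a network trained
with hyperparameters x.  A GP surrogate with an ARD Matérn 5/2 kernel

    k(xi, xj) = σf² (1 + √5 r + (5/3) r²) exp(−√5 r),
    r² = Σ_m (x_im − x_jm)² / σm²

models f over a transformed, bounded space (log10 for the learning
rate and the Adam coefficients, linear otherwise; integers and the
schedule category are relaxed to continuous values for the GP and
rounded/thresholded at decode).  Kernel amplitude, per-dimension
length scales and observation noise are refit each iteration by
marginal-likelihood maximization with random restarts.

Acquisition is expected improvement against the lowest posterior mean,
with an exploration constraint: a candidate is admissible only when
its posterior standard deviation is at least 0.8 times the fitted
noise standard deviation, discouraging over-granular re-sampling
inside a basin already mapped to the noise floor.  If no candidate
passes, the constraint is dropped for that iteration with a warning.

The search starts from 4 uniform random points and runs until the
evaluation budget (default 50) is exhausted.  The number of LSTM
layers is not a search dimension; independent searches are run per
layer count.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize
from scipy.stats import norm

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Search space

@dataclass(frozen=True)
class Dimension:
    """One hyperparameter axis: bounds, type, and sampling transform."""

    name: str
    bounds: tuple[float, float]
    kind: str = "real"          # "real" | "integer" | "categorical"
    transform: str = "linear"   # "linear" | "log"
    categories: tuple = ()

    def __post_init__(self):
        lo, hi = self.bounds
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
            raise ValueError(f"{self.name}: bounds must be finite and ordered")
        if self.transform == "log" and lo <= 0:
            raise ValueError(f"{self.name}: log transform needs positive bounds")

    # transformed coordinates are what the GP sees
    def to_unit(self, value: float) -> float:
        lo, hi = self.bounds
        if self.transform == "log":
            return (math.log10(value) - math.log10(lo)) / (math.log10(hi) - math.log10(lo))
        return (value - lo) / (hi - lo)

    def from_unit(self, u: float) -> float:
        u = min(max(u, 0.0), 1.0)
        lo, hi = self.bounds
        if self.transform == "log":
            return 10 ** (math.log10(lo) + u * (math.log10(hi) - math.log10(lo)))
        return lo + u * (hi - lo)

    def decode(self, u: float):
        v = self.from_unit(u)
        if self.kind == "integer":
            lo, hi = self.bounds
            return int(min(max(round(v), lo), hi))
        if self.kind == "categorical":
            # categories occupy equal sub-intervals of [0, 1]
            idx = min(int(u * len(self.categories)), len(self.categories) - 1)
            return self.categories[idx]
        return v


@dataclass(frozen=True)
class SearchSpace:
    dimensions: tuple[Dimension, ...]

    def __post_init__(self):
        object.__setattr__(self, "dimensions", tuple(self.dimensions))

    @property
    def d(self) -> int:
        return len(self.dimensions)

    def decode(self, u: np.ndarray) -> dict:
        return {dim.name: dim.decode(ui)
                for dim, ui in zip(self.dimensions, u)}

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform in the transformed unit cube (log dims are log-uniform)."""
        return rng.uniform(0.0, 1.0, size=(n, self.d))


def default_search_space(num_layers: int) -> SearchSpace:
    """The tuning space: per-layer hidden units, minibatch, schedule,
    learning rate and Adam coefficients (log-scaled where noted)."""
    dims = [Dimension(f"hidden_units_{l + 1}", (10, 50), kind="integer")
            for l in range(num_layers)]
    dims += [
        Dimension("minibatch", (16, 32), kind="integer"),
        Dimension("schedule", (0, 1), kind="categorical",
                  categories=("none", "piecewise")),
        Dimension("learning_rate", (1e-3, 1e-1), transform="log"),
        Dimension("beta1", (0.9, 0.999), transform="log"),
        Dimension("beta2", (0.9, 1.0), transform="log"),
    ]
    return SearchSpace(tuple(dims))


@dataclass
class HyperPoint:
    """A point in the transformed unit cube plus its decoded record."""

    u: np.ndarray
    decoded: dict

    @classmethod
    def from_unit(cls, space: SearchSpace, u: np.ndarray) -> "HyperPoint":
        u = np.asarray(u, dtype=np.float64)
        return cls(u=u, decoded=space.decode(u))


def sample_initial(space: SearchSpace, n: int = 4,
                   seed: int = 0) -> list[HyperPoint]:
    """Draw the initial design: n uniform points in the transformed cube."""
    if n < 1:
        raise ValueError("need at least one initial point")
    rng = np.random.default_rng(seed)
    return [HyperPoint.from_unit(space, u) for u in space.sample(n, rng)]


# ---------------------------------------------------------------------------
# GP regression with ARD Matérn 5/2

def matern52(xi: np.ndarray, xj: np.ndarray, sigma_f: float,
             length_scales: np.ndarray) -> float:
    """ARD Matérn 5/2 covariance between two points."""
    length_scales = np.asarray(length_scales, dtype=np.float64)
    if np.any(length_scales <= 0):
        raise ValueError("length scales must be positive")
    xi = np.atleast_1d(np.asarray(xi, dtype=np.float64))
    xj = np.atleast_1d(np.asarray(xj, dtype=np.float64))
    if xi.shape != xj.shape:
        raise ValueError("points must share a dimension")
    r = math.sqrt(float(np.sum((xi - xj) ** 2 / length_scales ** 2)))
    s5r = math.sqrt(5.0) * r
    return sigma_f ** 2 * (1.0 + s5r + (5.0 / 3.0) * r ** 2) * math.exp(-s5r)


def _kernel_matrix(X: np.ndarray, Z: np.ndarray, sigma_f: float,
                   ls: np.ndarray) -> np.ndarray:
    d2 = np.sum(((X[:, None, :] - Z[None, :, :]) / ls) ** 2, axis=2)
    r = np.sqrt(np.maximum(d2, 0.0))
    s5r = math.sqrt(5.0) * r
    return sigma_f ** 2 * (1.0 + s5r + (5.0 / 3.0) * r ** 2) * np.exp(-s5r)


@dataclass
class GPState:
    """Fitted surrogate: data, kernel hyperparameters, cached factors."""

    X: np.ndarray                 # (n, d) transformed coordinates
    y: np.ndarray                 # (n,) objective values
    sigma_f: float
    length_scales: np.ndarray     # (d,)
    noise_sd: float
    y_mean: float = 0.0
    _cho: tuple = field(default=None, repr=False)
    _alpha: np.ndarray = field(default=None, repr=False)

    def factorize(self) -> None:
        n = len(self.y)
        K = _kernel_matrix(self.X, self.X, self.sigma_f, self.length_scales)
        K[np.diag_indices(n)] += self.noise_sd ** 2 + 1e-10
        try:
            self._cho = cho_factor(K, lower=True)
        except np.linalg.LinAlgError:
            K[np.diag_indices(n)] += 1e-6
            try:
                self._cho = cho_factor(K, lower=True)
            except np.linalg.LinAlgError as exc:
                raise RuntimeError("kernel matrix is degenerate even "
                                   "after jitter") from exc
        self._alpha = cho_solve(self._cho, self.y - self.y_mean)

    def posterior(self, Xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and standard deviation of the latent f at Xs."""
        Xs = np.atleast_2d(np.asarray(Xs, dtype=np.float64))
        if self._alpha is None:
            self.factorize()
        Ks = _kernel_matrix(Xs, self.X, self.sigma_f, self.length_scales)
        mean = self.y_mean + Ks @ self._alpha
        v = solve_triangular(self._cho[0], Ks.T, lower=True)
        var = self.sigma_f ** 2 - np.sum(v ** 2, axis=0)
        return mean, np.sqrt(np.maximum(var, 0.0))


def _neg_log_marginal(log_params: np.ndarray, X: np.ndarray,
                      yc: np.ndarray) -> float:
    d = X.shape[1]
    sigma_f = math.exp(log_params[0])
    ls = np.exp(log_params[1:1 + d])
    noise = math.exp(log_params[-1])
    n = len(yc)
    K = _kernel_matrix(X, X, sigma_f, ls)
    K[np.diag_indices(n)] += noise ** 2 + 1e-10
    try:
        c = cho_factor(K, lower=True)
    except np.linalg.LinAlgError:
        return 1e12
    alpha = cho_solve(c, yc)
    return float(0.5 * yc @ alpha + np.sum(np.log(np.diag(c[0])))
                 + 0.5 * n * math.log(2 * math.pi))


def gp_fit(X: np.ndarray, y: np.ndarray, seed: int = 0,
           n_restarts: int = 3) -> GPState:
    """Fit the surrogate by maximizing the log marginal likelihood.

    Kernel amplitude, ARD length scales and the observation-noise SD
    are optimized jointly in log space (L-BFGS-B, ``n_restarts``
    random restarts).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    if len(y) < 2:
        raise ValueError("need at least 2 observations to fit the GP")
    d = X.shape[1]
    y_mean = float(np.mean(y))
    yc = y - y_mean
    y_sd = float(np.std(yc)) or 1.0

    rng = np.random.default_rng(seed)
    starts = [np.concatenate(([math.log(y_sd)], np.zeros(d),
                              [math.log(max(0.1 * y_sd, 1e-4))]))]
    for _ in range(n_restarts - 1):
        starts.append(np.concatenate((
            [math.log(y_sd) + rng.normal(0, 1)],
            rng.normal(0, 1, size=d),
            [math.log(y_sd) + rng.normal(-2, 1)],
        )))
    lb = np.concatenate(([math.log(y_sd) - 6], np.full(d, math.log(1e-2)),
                         [math.log(y_sd) - 9]))
    ub = np.concatenate(([math.log(y_sd) + 6], np.full(d, math.log(1e2)),
                         [math.log(y_sd) + 2]))
    best, best_val = None, np.inf
    for x0 in starts:
        res = minimize(_neg_log_marginal, np.clip(x0, lb, ub),
                       args=(X, yc), method="L-BFGS-B",
                       bounds=list(zip(lb, ub)))
        if res.fun < best_val:
            best, best_val = res.x, res.fun
    state = GPState(X=X, y=y, sigma_f=math.exp(best[0]),
                    length_scales=np.exp(best[1:1 + d]),
                    noise_sd=math.exp(best[-1]), y_mean=y_mean)
    state.factorize()
    return state


def expected_improvement(state: GPState, Xs: np.ndarray,
                         incumbent: float | None = None) -> np.ndarray:
    """Closed-form EI for minimization: E[max(0, incumbent − f(x))].

    ``incumbent`` defaults to the lowest posterior mean over the
    observed points.
    """
    if incumbent is None:
        mu_obs, _ = state.posterior(state.X)
        incumbent = float(np.min(mu_obs))
    mu, sd = state.posterior(Xs)
    ei = np.zeros_like(mu)
    pos = sd > 0
    z = (incumbent - mu[pos]) / sd[pos]
    ei[pos] = (incumbent - mu[pos]) * norm.cdf(z) + sd[pos] * norm.pdf(z)
    ei[~pos] = np.maximum(incumbent - mu[~pos], 0.0)
    return np.maximum(ei, 0.0)


def propose_next(state: GPState, space: SearchSpace, seed: int = 0,
                 n_candidates: int = 2000, std_factor: float = 0.8,
                 n_polish: int = 10) -> HyperPoint:
    """EI argmax over random candidates, under the exploration constraint.

    Candidates with posterior std below ``std_factor`` times the fitted
    noise SD are filtered out; coordinate-wise local polish refines the
    best survivors.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    cands = space.sample(n_candidates, rng)
    mu_obs, _ = state.posterior(state.X)
    incumbent = float(np.min(mu_obs))
    _, sd = state.posterior(cands)
    admissible = sd >= std_factor * state.noise_sd
    if not np.any(admissible):
        logger.warning("no candidate meets the posterior-std exploration "
                       "criterion; dropping it for this iteration")
        admissible = np.ones(len(cands), dtype=bool)
    cands = cands[admissible]
    ei = expected_improvement(state, cands, incumbent)
    top = np.argsort(ei)[::-1][:n_polish]

    def constrained_ei(points: np.ndarray) -> np.ndarray:
        vals = expected_improvement(state, points, incumbent)
        _, sd_p = state.posterior(points)
        vals[sd_p < std_factor * state.noise_sd] = -np.inf
        return vals

    best_u, best_val = cands[top[0]].copy(), float(ei[top[0]])
    for idx in top:
        u = cands[idx].copy()
        u_val = float(ei[idx])
        width = 0.1
        for _sweep in range(3):          # coordinate-wise local polish
            for m in range(space.d):
                grid = np.clip(u[m] + np.linspace(-width, width, 21), 0, 1)
                pts = np.tile(u, (len(grid), 1))
                pts[:, m] = grid
                vals = constrained_ei(pts)
                k = int(np.argmax(vals))
                if vals[k] > u_val:
                    u, u_val = pts[k], float(vals[k])
            width /= 4.0
        if u_val > best_val:
            best_u, best_val = u, u_val
    return HyperPoint.from_unit(space, best_u)


# ---------------------------------------------------------------------------
# The optimization loop

@dataclass
class BOptTrace:
    """Ordered evaluation history of one search."""

    points: list[HyperPoint] = field(default_factory=list)
    values: list[float] = field(default_factory=list)
    failures: list[tuple[HyperPoint, str]] = field(default_factory=list)
    diagnostics: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def incumbent_index(self) -> int:
        return int(np.argmin(self.values))

    @property
    def incumbent(self) -> tuple[HyperPoint, float]:
        i = self.incumbent_index
        return self.points[i], self.values[i]

    def incumbent_values(self) -> np.ndarray:
        """Running best objective along the trace (non-increasing)."""
        return np.minimum.accumulate(np.asarray(self.values))

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for p, v in zip(self.points, self.values):
                fh.write(json.dumps({"hyperparameters": p.decoded,
                                     "objective": v,
                                     "u": p.u.tolist()}) + "\n")


def run_bopt(space: SearchSpace, objective, budget: int = 50,
             seed: int = 0, n_initial: int = 4,
             std_factor: float = 0.8) -> BOptTrace:
    """Bayesian optimization: initial design, then fit → propose → evaluate.

    ``objective`` maps a HyperPoint to a scalar (final validation RMSE);
    evaluations that raise are recorded as failures and excluded from
    the GP.  Returns the full trace; the incumbent is the evaluation
    with the lowest objective.
    """
    if budget < n_initial:
        raise ValueError("budget must cover the initial design")
    trace = BOptTrace()

    def evaluate(point: HyperPoint) -> None:
        try:
            val = float(objective(point))
        except Exception as exc:   # noqa: BLE001 — failed trainings are data
            logger.warning("objective failed at %s: %s", point.decoded, exc)
            trace.failures.append((point, str(exc)))
            return
        trace.points.append(point)
        trace.values.append(val)

    for point in sample_initial(space, n=n_initial, seed=seed):
        evaluate(point)

    it = 0
    while len(trace) + len(trace.failures) < budget:
        it += 1
        if len(trace) >= 2:
            state = gp_fit(np.stack([p.u for p in trace.points]),
                           np.asarray(trace.values), seed=seed + it)
            point = propose_next(state, space, seed=seed + 1000 + it,
                                 std_factor=std_factor)
            trace.diagnostics.append({
                "iteration": it, "noise_sd": state.noise_sd,
                "sigma_f": state.sigma_f,
            })
        else:   # not enough successes to fit: fall back to random
            rng = np.random.default_rng(seed + 2000 + it)
            point = HyperPoint.from_unit(space, space.sample(1, rng)[0])
        evaluate(point)
    return trace


class BayesianOptimizer:
    """Thin object interface over :func:`run_bopt` (sklearn-searchCV flavour).

    Parameters mirror ``run_bopt``; after ``optimize(objective)`` the
    fitted attributes ``trace_``, ``best_params_`` and ``best_score_``
    are available.
    """

    def __init__(self, space: SearchSpace, budget: int = 50, seed: int = 0,
                 n_initial: int = 4, std_factor: float = 0.8):
        self.space = space
        self.budget = budget
        self.seed = seed
        self.n_initial = n_initial
        self.std_factor = std_factor

    def optimize(self, objective) -> "BayesianOptimizer":
        self.trace_ = run_bopt(self.space, objective, budget=self.budget,
                               seed=self.seed, n_initial=self.n_initial,
                               std_factor=self.std_factor)
        best_point, self.best_score_ = self.trace_.incumbent
        self.best_params_ = best_point.decoded
        return self
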