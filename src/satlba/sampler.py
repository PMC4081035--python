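"""Posterior sampling via Markov chain Monte Carlo with
differential-evolution proposals, plus diagnostics and summaries.

Each chain proposes ``x* = x_i + gamma * (x_j - x_k) + jitter`` with
``j != k != i`` drawn from the current population, followed by a
Metropolis accept/reject step.  A small fraction of proposals use
``gamma = 1`` to allow mode jumping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr

from . import model
from .model import LikelihoodEvaluator, SatParameters, params_from_vector, vector_names

__all__ = [
    "UniformPrior",
    "TruncNormalPrior",
    "PriorSpec",
    "default_priors",
    "PosteriorSamples",
    "ConvergenceError",
    "log_posterior",
    "make_log_posterior",
    "run_demc",
    "rhat",
    "summarize",
    "fit_sat_model",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


class ConvergenceError(RuntimeError):
    """The sampler failed a convergence/health check."""


class UniformPrior:
    """Uniform density on [low, high]."""

    def __init__(self, low: float, high: float):
        if not high > low:
            raise ValueError("require high > low")
        self.low, self.high = float(low), float(high)
        self._logdens = -math.log(self.high - self.low)

    def logpdf(self, x: float) -> float:
        return self._logdens if self.low <= x <= self.high else -math.inf

    def rvs(self, rng: np.random.Generator, size=None):
        return rng.uniform(self.low, self.high, size)

    def __repr__(self):
        return f"UniformPrior({self.low}, {self.high})"


class TruncNormalPrior:
    """Normal(loc, scale**2) truncated to [low, high]."""

    def __init__(self, loc: float, scale: float, low: float = -math.inf, high: float = math.inf):
        if scale <= 0:
            raise ValueError("scale must be > 0")
        self.loc, self.scale = float(loc), float(scale)
        self.low, self.high = float(low), float(high)
        mass = float(ndtr((self.high - loc) / scale) - ndtr((self.low - loc) / scale))
        if mass <= 0:
            raise ValueError("truncation interval has no mass")
        self._log_mass = math.log(mass)
        self._log_scale = math.log(self.scale)

    def logpdf(self, x: float) -> float:
        if not self.low <= x <= self.high:
            return -math.inf
        z = (x - self.loc) / self.scale
        return -0.5 * z * z - self._log_scale - _LOG_SQRT_2PI - self._log_mass

    def rvs(self, rng: np.random.Generator, size=None):
        # rejection sampling; truncation regions used here are mild
        n = 1 if size is None else int(size)
        out = np.empty(n)
        filled = 0
        for _ in range(10_000):
            draw = rng.normal(self.loc, self.scale, max(n - filled, 1))
            keep = draw[(draw >= self.low) & (draw <= self.high)]
            take = min(len(keep), n - filled)
            out[filled : filled + take] = keep[:take]
            filled += take
            if filled == n:
                return float(out[0]) if size is None else out
        raise RuntimeError("truncated-normal rejection sampling failed")

    def __repr__(self):
        return f"TruncNormalPrior({self.loc}, {self.scale}, [{self.low}, {self.high}])"


@dataclass(frozen=True)
class PriorSpec:
    """Ordered per-parameter priors (evaluable, finite on their support)."""

    priors: dict

    @property
    def names(self) -> tuple:
        return tuple(self.priors)

    @property
    def ndim(self) -> int:
        return len(self.priors)

    def logpdf(self, theta) -> float:
        total = 0.0
        for name, x in zip(self.priors, theta):
            lp = self.priors[name].logpdf(float(x))
            if lp == -math.inf:
                return -math.inf
            total += lp
        return total

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return np.array([d.rvs(rng) for d in self.priors.values()])


def default_priors(over_constrained: bool = False) -> PriorSpec:
    """Weakly informative defaults on the scale fixed by the speed-setting
    drift SD of 1.  All overridable; these are modelling decisions, not
    estimated quantities.
    """
    table = {
        "t0": UniformPrior(0.0, 0.5),
        "b_acc": TruncNormalPrior(0.5, 0.5, low=1e-6),
        "v_t_acc": TruncNormalPrior(1.0, 2.0, low=-3.0, high=8.0),
        "v_d_acc": TruncNormalPrior(1.0, 2.0, low=-3.0, high=8.0),
        "v_t_spd": TruncNormalPrior(1.0, 2.0, low=-3.0, high=8.0),
        "v_d_spd": TruncNormalPrior(1.0, 2.0, low=-3.0, high=8.0),
        "s_acc": TruncNormalPrior(0.5, 0.5, low=1e-6),
        "p": UniformPrior(0.0, 1.0),
    }
    names = vector_names(over_constrained)
    return PriorSpec({n: table[n] for n in names})


@dataclass
class PosteriorSamples:
    """MCMC output: chains x iterations x parameters plus diagnostics."""

    chains: np.ndarray  # (n_chains, n_iter, ndim)
    log_post: np.ndarray  # (n_chains, n_iter)
    param_names: tuple
    burn_in: int
    acceptance_rate: np.ndarray = field(default=None)  # per chain

    def __post_init__(self):
        c, i, d = self.chains.shape
        if self.log_post.shape != (c, i):
            raise ValueError("log_post shape does not match chains")
        if len(self.param_names) != d:
            raise ValueError("param_names length does not match chains")
        if not 0 <= self.burn_in < i:
            raise ValueError("burn_in out of range")

    @property
    def n_chains(self) -> int:
        return self.chains.shape[0]

    @property
    def posterior(self) -> np.ndarray:
        """Post-burn-in samples, shape (n_chains, n_kept, ndim)."""
        return self.chains[:, self.burn_in :, :]

    def flat(self) -> np.ndarray:
        """Post-burn-in samples pooled over chains, shape (N, ndim)."""
        return self.posterior.reshape(-1, self.chains.shape[2])

    def to_frame(self) -> pd.DataFrame:
        c, i, d = self.chains.shape
        df = pd.DataFrame(self.chains.reshape(-1, d), columns=list(self.param_names))
        df.insert(0, "iteration", np.tile(np.arange(i), c))
        df.insert(0, "chain", np.repeat(np.arange(c), i))
        df["log_posterior"] = self.log_post.reshape(-1)
        return df

    def save(self, path) -> None:
        """Write as delimited text with '#'-prefixed metadata lines."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            fh.write(f"# burn_in={self.burn_in}\n")
            fh.write(f"# n_chains={self.n_chains}\n")
            acc = ",".join(f"{a:.6g}" for a in np.atleast_1d(self.acceptance_rate))
            fh.write(f"# acceptance_rate={acc}\n")
            self.to_frame().to_csv(fh, index=False, float_format="%.10g")

    @classmethod
    def load(cls, path) -> "PosteriorSamples":
        meta = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val
        df = pd.read_csv(path, comment="#")
        names = tuple(c for c in df.columns if c not in ("chain", "iteration", "log_posterior"))
        n_chains = int(meta["n_chains"])
        n_iter = len(df) // n_chains
        chains = df[list(names)].to_numpy().reshape(n_chains, n_iter, len(names))
        log_post = df["log_posterior"].to_numpy().reshape(n_chains, n_iter)
        acc = np.array([float(x) for x in meta["acceptance_rate"].split(",")])
        return cls(chains, log_post, names, int(meta["burn_in"]), acc)


def log_posterior(params: SatParameters, trials, priors: PriorSpec,
                  over_constrained: bool = False) -> float:
    """Dataset log-likelihood plus summed log prior densities
    (``-inf`` outside the prior support)."""
    theta = model.params_to_vector(params, over_constrained)
    lp = priors.logpdf(theta)
    if lp == -math.inf:
        return -math.inf
    return lp + model.dataset_loglik(params, trials)


def make_log_posterior(trials, priors: PriorSpec, A: float = 0.0,
                       over_constrained: bool = False, floor: float = model.LIKELIHOOD_FLOOR):
    """Closure mapping a flat parameter vector to the log posterior,
    with the likelihood evaluator built once."""
    evaluator = LikelihoodEvaluator(trials, floor=floor)

    def logpost(theta: np.ndarray) -> float:
        lp = priors.logpdf(theta)
        if lp == -math.inf:
            return -math.inf
        try:
            params = params_from_vector(theta, over_constrained=over_constrained, A=A)
        except Exception:
            return -math.inf
        return lp + evaluator(params)

    return logpost


def run_demc(
    target_density,
    priors: PriorSpec,
    n_chains: int,
    n_iter: int,
    burn_in: int,
    gamma: float | None = None,
    jitter: float = 1e-3,
    seed=None,
    gamma1_prob: float = 0.1,
    stuck_window: int = 200,
    migrate_prob: float = 0.1,
) -> PosteriorSamples:
    """Differential-evolution MCMC.

    Chains are initialized from the priors (overdispersed by
    construction).  ``gamma`` defaults to ``2.38 / sqrt(2 d)``;
    ``gamma1_prob`` of steps use ``gamma = 1`` for mode jumping; the
    additive jitter is uniform on ``[-jitter, jitter]`` per coordinate.

    During burn-in, with probability ``migrate_prob`` per iteration, a
    Metropolis-accepted cyclic migration of states among a random chain
    subset is attempted; this rescues chains initialized in flat,
    floored-likelihood regions, where difference-vector proposals mix
    very slowly.  Migration is disabled after burn-in, so retained
    samples come from the plain DE kernel.

    Raises :class:`ConvergenceError` if no chain accepts any proposal
    over a ``stuck_window``-iteration window.
    """
    if n_chains < 4:
        raise ValueError(f"need n_chains >= 4, got {n_chains}")
    if not 0 <= burn_in < n_iter:
        raise ValueError(f"need 0 <= burn_in < n_iter, got {burn_in}, {n_iter}")
    rng = np.random.default_rng(seed)
    d = priors.ndim
    if gamma is None:
        gamma = 2.38 / math.sqrt(2.0 * d)

    x = np.array([priors.sample(rng) for _ in range(n_chains)])
    lp = np.array([target_density(xi) for xi in x], dtype=float)

    chains = np.empty((n_chains, n_iter, d))
    log_post = np.empty((n_chains, n_iter))
    chains[:, 0, :] = x
    log_post[:, 0] = lp
    accepts = np.zeros(n_chains, dtype=np.int64)
    window_accepts = 0

    for it in range(1, n_iter):
        if it < burn_in and rng.random() < migrate_prob:
            k = int(rng.integers(2, n_chains + 1))
            idx = rng.choice(n_chains, size=k, replace=False)
            x_snap, lp_snap = x[idx].copy(), lp[idx].copy()
            for m in range(k):
                src, dst = m - 1, idx[m]  # cyclic: dst adopts src's state
                if lp_snap[src] == -math.inf:
                    continue
                if lp[dst] == -math.inf or math.log(rng.random()) < lp_snap[src] - lp[dst]:
                    x[dst] = x_snap[src]
                    lp[dst] = lp_snap[src]
        for i in range(n_chains):
            j = k = i
            while j == i:
                j = int(rng.integers(n_chains))
            while k == i or k == j:
                k = int(rng.integers(n_chains))
            g = 1.0 if rng.random() < gamma1_prob else gamma
            prop = x[i] + g * (x[j] - x[k]) + rng.uniform(-jitter, jitter, d)
            lp_prop = target_density(prop)
            if lp_prop > -math.inf and math.log(rng.random()) < lp_prop - lp[i]:
                x[i] = prop
                lp[i] = lp_prop
                accepts[i] += 1
                window_accepts += 1
        chains[:, it, :] = x
        log_post[:, it] = lp
        if it % stuck_window == 0:
            if window_accepts == 0:
                raise ConvergenceError(
                    f"no chain accepted any proposal in iterations "
                    f"{it - stuck_window + 1}..{it}; sampler is stuck"
                )
            window_accepts = 0

    return PosteriorSamples(
        chains=chains,
        log_post=log_post,
        param_names=priors.names,
        burn_in=burn_in,
        acceptance_rate=accepts / (n_iter - 1),
    )


def _chains_array(samples) -> tuple[np.ndarray, tuple]:
    if isinstance(samples, PosteriorSamples):
        return samples.posterior, samples.param_names
    arr = np.asarray(samples, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    return arr, tuple(f"p{i}" for i in range(arr.shape[2]))


def rhat(samples) -> pd.Series:
    """Gelman-Rubin potential scale reduction factor per parameter.

    ``sqrt(((n-1)/n * W + B/n) / W)`` with ``W`` the mean within-chain
    variance and ``B`` the between-chain variance of the chain means.
    Requires at least 2 chains.
    """
    arr, names = _chains_array(samples)
    m, n, d = arr.shape
    if m < 2:
        raise ValueError("rhat requires at least 2 chains")
    if n < 2:
        raise ValueError("rhat requires at least 2 iterations per chain")
    chain_means = arr.mean(axis=1)  # (m, d)
    W = arr.var(axis=1, ddof=1).mean(axis=0)  # (d,)
    B = n * chain_means.var(axis=0, ddof=1)  # (d,)
    var_plus = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(var_plus / W)
    out = np.where(W == 0, 1.0, out)  # constant chains: no dispersion to shrink
    return pd.Series(out, index=list(names), name="rhat")


def summarize(samples) -> pd.DataFrame:
    """Posterior mean, median and central 95% interval per parameter."""
    arr, names = _chains_array(samples)
    flat = arr.reshape(-1, arr.shape[2])
    if flat.shape[0] == 0:
        raise ValueError("no post-burn-in samples to summarize")
    return pd.DataFrame(
        {
            "mean": flat.mean(axis=0),
            "median": np.median(flat, axis=0),
            "lo95": np.quantile(flat, 0.025, axis=0),
            "hi95": np.quantile(flat, 0.975, axis=0),
        },
        index=list(names),
    )


def fit_sat_model(
    trials,
    priors: PriorSpec | None = None,
    n_chains: int | None = None,
    n_iter: int = 15_000,
    burn_in: int = 10_000,
    seed=None,
    A: float = 0.0,
    over_constrained: bool = False,
    gamma: float | None = None,
    jitter: float = 1e-3,
    gamma1_prob: float = 0.1,
) -> PosteriorSamples:
    """Fit the constrained mixture model to a trial table.

    Defaults: 3 chains per free parameter (24 for the 8-parameter
    model), 15000 iterations with the first 10000 discarded as burn-in.
    """
    if priors is None:
        priors = default_priors(over_constrained)
    if n_chains is None:
        n_chains = 3 * priors.ndim
    logpost = make_log_posterior(trials, priors, A=A, over_constrained=over_constrained)
    return run_demc(
        logpost,
        priors,
        n_chains=n_chains,
        n_iter=n_iter,
        burn_in=burn_in,
        gamma=gamma,
        jitter=jitter,
        seed=seed,
        gamma1_prob=gamma1_prob,
    )
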