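"""Posterior predictive checks.

Predictive joint distributions over response time and choice per
emphasis condition, discrepancy reports against an observed table, and
accumulation-trajectory panels aligned on stimulus onset or on response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lba import TARGET, DISTRACTOR, RaceSpec, TrajectorySample, simulate_trials, simulate_trajectories
from .model import (
    ACCURACY,
    ACCURACY_SETTING,
    CONDITIONS,
    NEUTRAL,
    RESPONSES,
    SPEED,
    SPEED_SETTING,
    SatParameters,
    build_race,
    params_from_vector,
    trial_density,
    validate_trials,
)
from .sampler import PosteriorSamples

__all__ = [
    "RT_QUANTILES",
    "PredictiveSummary",
    "AlignedTrajectories",
    "posterior_predict",
    "fit_report",
    "trajectory_panels",
    "plot_predictive",
    "plot_trajectories",
]

RT_QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass(frozen=True)
class PredictiveSummary:
    """Per (condition, response): defective density curve on an RT grid,
    predictive choice probability, and RT quantiles.

    Density curves are posterior-averaged analytic defective densities
    (so per condition they integrate, numerically, to the choice
    probabilities); quantiles come from the pooled simulated trials.
    """

    rt_grid: np.ndarray = field(repr=False)
    density: dict = field(repr=False)  # (condition, response) -> ndarray
    choice_prob: dict  # (condition, response) -> float
    quantiles: dict  # (condition, response) -> ndarray over RT_QUANTILES
    n_draws: int = 0
    n_trials_per_draw: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (cond, resp), q in self.quantiles.items():
            row = {"condition": cond, "response": resp, "choice_prob": self.choice_prob[(cond, resp)]}
            row.update({f"q{int(100 * p)}": val for p, val in zip(RT_QUANTILES, q)})
            rows.append(row)
        return pd.DataFrame(rows)

    def density_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"rt": self.rt_grid})
        for (cond, resp), dens in self.density.items():
            df[f"{cond}_{resp}"] = dens
        return df


def _simulate_condition(params: SatParameters, condition: str, n: int, rng):
    """One condition's trials under the mixture generative process."""
    speed_race = build_race(params, SPEED_SETTING)
    if condition in (SPEED, NEUTRAL):
        return simulate_trials(speed_race, n, rng)
    n_neg = int(rng.binomial(n, params.p))
    parts_w, parts_rt = [], []
    if n_neg:
        sim = simulate_trials(speed_race, n_neg, rng)
        parts_w.append(sim.winner)
        parts_rt.append(sim.rt)
    if n - n_neg:
        sim = simulate_trials(build_race(params, ACCURACY_SETTING), n - n_neg, rng)
        parts_w.append(sim.winner)
        parts_rt.append(sim.rt)
    return np.concatenate(parts_w), np.concatenate(parts_rt)


def _default_grid(pooled: dict, draws: list) -> np.ndarray:
    """Dense grid over the bulk plus a log-spaced tail.

    The race RT density has a ``1/t**2`` tail, so a uniform grid over the
    observed range would either miss tail mass or under-resolve the peak.
    The tail horizon is extended until the truncated race mass is below
    1e-4, keeping grid-integrated choice probabilities accurate.
    """
    from .lba import _upper_time_bound

    all_rt = np.concatenate([v for v in pooled.values() if v.size])
    t_dense = 1.25 * float(np.quantile(all_rt, 0.999))
    horizon = t_dense
    for params in draws[: min(len(draws), 8)]:
        for setting in (SPEED_SETTING, ACCURACY_SETTING):
            race = build_race(params, setting)
            horizon = max(horizon, race.t0 + _upper_time_bound(race, tol=1e-4))
    dense = np.linspace(0.0, t_dense, 1600)
    tail = np.geomspace(t_dense, min(horizon, 1e5), 400)[1:]
    return np.concatenate([dense, tail])


def posterior_predict(
    samples: PosteriorSamples,
    n_draws: int = 100,
    n_trials_per_draw: int = 1000,
    seed=None,
    rt_grid: np.ndarray | None = None,
    A: float = 0.0,
    over_constrained: bool = False,
) -> PredictiveSummary:
    """Posterior predictive summary.

    ``n_draws`` parameter vectors are drawn uniformly, with replacement,
    from the post-burn-in pool (replacement means the call is defined
    even when ``n_draws`` exceeds the pool size); each simulates
    ``n_trials_per_draw`` trials per condition.
    """
    pool = samples.flat()
    if pool.shape[0] == 0:
        raise ValueError("no post-burn-in samples available")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, pool.shape[0], size=n_draws)
    draws = [params_from_vector(pool[i], over_constrained=over_constrained, A=A) for i in idx]

    pooled = {(c, r): [] for c in CONDITIONS for r in RESPONSES}
    for params in draws:
        for cond in CONDITIONS:
            winner, rt = _simulate_condition(params, cond, n_trials_per_draw, rng)
            for resp in RESPONSES:
                pooled[(cond, resp)].append(rt[winner == resp])
    pooled = {key: np.concatenate(parts) if parts else np.array([]) for key, parts in pooled.items()}

    if rt_grid is None:
        rt_grid = _default_grid(pooled, draws)
    rt_grid = np.asarray(rt_grid, dtype=float)

    density = {}
    for cond in CONDITIONS:
        for resp in RESPONSES:
            curves = np.zeros_like(rt_grid)
            for params in draws:
                curves += trial_density(params, cond, resp, rt_grid)
            density[(cond, resp)] = curves / n_draws

    choice_prob = {key: float(np.trapezoid(dens, rt_grid)) for key, dens in density.items()}
    quantiles = {
        key: (np.quantile(v, RT_QUANTILES) if v.size else np.full(len(RT_QUANTILES), np.nan))
        for key, v in pooled.items()
    }
    return PredictiveSummary(
        rt_grid=rt_grid,
        density=density,
        choice_prob=choice_prob,
        quantiles=quantiles,
        n_draws=n_draws,
        n_trials_per_draw=n_trials_per_draw,
    )


def fit_report(observed: pd.DataFrame, predictive: PredictiveSummary) -> pd.DataFrame:
    """Observed-vs-predicted discrepancies per (condition, response).

    Reports choice-probability differences and RT-quantile differences;
    cells absent from the observed table are flagged, not fatal.
    """
    validate_trials(observed)
    obs_conditions = set(observed["condition"].unique()) & set(CONDITIONS)
    if not obs_conditions:
        raise ValueError("observed table shares no conditions with the predictive summary")
    rows = []
    for cond in CONDITIONS:
        in_cond = observed[observed["condition"] == cond]
        for resp in RESPONSES:
            key = (cond, resp)
            cell = in_cond[in_cond["response"] == resp]
            row = {"condition": cond, "response": resp, "n_observed": len(cell)}
            row["pred_choice_prob"] = predictive.choice_prob[key]
            if len(in_cond) == 0:
                row["missing"] = True
                rows.append(row)
                continue
            row["missing"] = len(cell) == 0
            row["obs_choice_prob"] = len(cell) / len(in_cond)
            row["choice_prob_diff"] = row["obs_choice_prob"] - row["pred_choice_prob"]
            if len(cell):
                obs_q = np.quantile(cell["rt"].to_numpy(), RT_QUANTILES)
                for pq, oq, sq in zip(RT_QUANTILES, obs_q, predictive.quantiles[key]):
                    row[f"q{int(100 * pq)}_diff"] = oq - sq
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trajectory panels
# ---------------------------------------------------------------------------

STIMULUS_ONSET = "stimulus_onset"
RESPONSE = "response"


@dataclass(frozen=True)
class AlignedTrajectories:
    """Per-setting sample paths with pointwise mean paths on a common grid.

    Stimulus-aligned means clamp finished paths at threshold (the path
    has terminated; evidence does not retreat), which keeps the mean
    nondecreasing.  Response-aligned means average only paths that have
    already started, at grid times where at least ``min_active`` of them
    exist, and terminate exactly at threshold at time 0.
    """

    alignment: str
    settings: tuple
    paths: dict = field(repr=False)  # setting -> list[TrajectorySample]
    grid: dict = field(repr=False)  # setting -> ndarray of times
    mean_path: dict = field(repr=False)  # setting -> ndarray of evidence


def _setting_threshold(params: SatParameters, setting: str) -> float:
    return build_race(params, setting).target.b


def trajectory_panels(
    params: SatParameters,
    setting_list=(SPEED_SETTING, ACCURACY_SETTING),
    align: str = STIMULUS_ONSET,
    n_paths: int = 50,
    seed=None,
    dt: float = 0.001,
    min_active: int = 10,
) -> AlignedTrajectories:
    """Correct-decision target-accumulator trajectories with mean paths.

    "Correct" means the target accumulator wins.  ``align`` is
    ``'stimulus_onset'`` (paths share t=0 at onset) or ``'response'``
    (paths shifted so each crosses threshold at t=0).
    """
    if align not in (STIMULUS_ONSET, RESPONSE):
        raise ValueError(f"unknown alignment {align!r}")
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    rng = np.random.default_rng(seed)
    paths: dict = {}
    grid: dict = {}
    mean_path: dict = {}
    active_floor = min(min_active, n_paths)
    for setting in setting_list:
        race = build_race(params, setting)
        b = race.target.b
        trajs = simulate_trajectories(race, n_paths, dt=dt, winner_filter=TARGET, rng=rng)
        paths[setting] = trajs
        cross = np.array([tr.crossing_time for tr in trajs])
        start = np.array([tr.start for tr in trajs])
        drift = np.array([tr.drift for tr in trajs])
        t_max = cross.max()
        if align == STIMULUS_ONSET:
            g = np.arange(0.0, t_max + dt, dt)
            evid = start[:, None] + drift[:, None] * g[None, :]
            evid = np.minimum(evid, b)  # clamp finished paths at threshold
            mean_path[setting] = evid.mean(axis=0)
            grid[setting] = g
        else:
            g = -np.arange(0.0, t_max + dt, dt)[::-1]  # ends exactly at 0
            evid = b + drift[:, None] * g[None, :]
            active = g[None, :] >= -cross[:, None]
            counts = active.sum(axis=0)
            keep = counts >= active_floor
            with np.errstate(invalid="ignore"):
                mean = np.where(
                    keep, np.sum(np.where(active, evid, 0.0), axis=0) / np.maximum(counts, 1), np.nan
                )
            grid[setting] = g[keep]
            mean_path[setting] = mean[keep]
    return AlignedTrajectories(
        alignment=align, settings=tuple(setting_list), paths=paths, grid=grid, mean_path=mean_path
    )


# ---------------------------------------------------------------------------
# Optional plots
# ---------------------------------------------------------------------------

def plot_predictive(predictive: PredictiveSummary, observed: pd.DataFrame | None = None, path=None):
    """Density overlays per condition (observed histograms optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(CONDITIONS), figsize=(12, 3.5), sharex=True)
    for ax, cond in zip(np.atleast_1d(axes), CONDITIONS):
        if observed is not None:
            sub = observed[observed["condition"] == cond]
            for resp, alpha in ((TARGET, 0.4), (DISTRACTOR, 0.7)):
                cell = sub[sub["response"] == resp]
                if len(cell) and len(sub):
                    ax.hist(
                        cell["rt"],
                        bins=40,
                        density=True,
                        weights=np.full(len(cell), len(cell) / len(sub) / len(cell)),
                        alpha=alpha,
                        label=f"obs {resp}",
                    )
        for resp, style in ((TARGET, "-"), (DISTRACTOR, "--")):
            ax.plot(predictive.rt_grid, predictive.density[(cond, resp)], style, label=f"pred {resp}")
        ax.set_title(cond)
        ax.set_xlabel("RT (s)")
    axes[0].set_ylabel("defective density (1/s)")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_trajectories(aligned: AlignedTrajectories, path=None):
    """Sample paths (thin) with mean paths (heavy) per setting."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {}
    for i, setting in enumerate(aligned.settings):
        color = f"C{i}"
        colors[setting] = color
        for tr in aligned.paths[setting][:30]:
            if aligned.alignment == STIMULUS_ONSET:
                ax.plot(tr.times, tr.evidence, color=color, alpha=0.15, lw=0.6)
            else:
                ax.plot(tr.times - tr.crossing_time, tr.evidence, color=color, alpha=0.15, lw=0.6)
        ax.plot(aligned.grid[setting], aligned.mean_path[setting], color=color, lw=2.5, label=setting)
    ax.set_xlabel("time (s)" if aligned.alignment == STIMULUS_ONSET else "time to response (s)")
    ax.set_ylabel("evidence")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
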