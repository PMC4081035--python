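"""Synthetic trial-table generation.

Stands in for the (unreleased) monkey behavioral data: three emphasis
conditions with far fewer neutral trials, speed/neutral trials drawn from
the speed-setting race, and accuracy trials drawn as a cue-neglect
mixture.  Per-trial neglect labels are kept in a sidecar so recovery
tests can audit them without exposing them to the fitting path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .lba import simulate_trials
from .model import (
    ACCURACY,
    ACCURACY_SETTING,
    NEUTRAL,
    SPEED,
    SPEED_SETTING,
    SatParameters,
    build_race,
    validate_trials,
    write_trials,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "generate_dataset",
    "neglect_fraction",
    "write_dataset",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Generating truth plus per-condition trial counts and a seed.

    The neutral default is far smaller than the other conditions,
    mirroring the design imbalance the analysis must cope with.
    """

    params: SatParameters
    n_speed: int = 2000
    n_neutral: int = 400
    n_accuracy: int = 2000
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_speed", "n_neutral", "n_accuracy"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_speed + self.n_neutral + self.n_accuracy == 0:
            raise ValueError("total trial count must be > 0")


@dataclass(frozen=True)
class SyntheticDataset:
    """Public trial table plus the private per-trial neglect sidecar."""

    trials: pd.DataFrame
    neglect: pd.DataFrame = field(repr=False)  # columns: trial_id, neglect_flag


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Generate a seeded trial table with the mixture structure.

    Speed and neutral trials come from the speed-setting race.  Each
    accuracy trial is a cue-neglect (speed-setting) trial with
    probability ``p``, else an accuracy-setting trial.  Trial order is
    shuffled within condition; output is fully determined by the seed.
    """
    rng = np.random.default_rng(config.seed)
    params = config.params
    speed_race = build_race(params, SPEED_SETTING)
    acc_race = build_race(params, ACCURACY_SETTING)

    frames = []
    flags = []
    for condition, n in ((SPEED, config.n_speed), (NEUTRAL, config.n_neutral)):
        if n == 0:
            continue
        sim = simulate_trials(speed_race, n, rng)
        frames.append(
            pd.DataFrame({"condition": condition, "response": sim.winner, "rt": sim.rt})
        )
        flags.append(np.zeros(n, dtype=bool))

    if config.n_accuracy > 0:
        n = config.n_accuracy
        neglect = rng.random(n) < params.p
        resp = np.empty(n, dtype="<U10")
        rt = np.empty(n)
        n_neg = int(neglect.sum())
        if n_neg:
            sim = simulate_trials(speed_race, n_neg, rng)
            resp[neglect], rt[neglect] = sim.winner, sim.rt
        if n - n_neg:
            sim = simulate_trials(acc_race, n - n_neg, rng)
            resp[~neglect], rt[~neglect] = sim.winner, sim.rt
        order = rng.permutation(n)  # shuffle within condition
        frames.append(
            pd.DataFrame({"condition": ACCURACY, "response": resp[order], "rt": rt[order]})
        )
        flags.append(neglect[order])

    trials = pd.concat(frames, ignore_index=True)
    trials.index.name = "trial_id"
    sidecar = pd.DataFrame(
        {"trial_id": np.arange(len(trials)), "neglect_flag": np.concatenate(flags).astype(int)}
    )
    validate_trials(trials)
    return SyntheticDataset(trials=trials, neglect=sidecar)


def neglect_fraction(dataset: SyntheticDataset) -> float:
    """Realized fraction of accuracy-condition trials generated under the
    speed setting (cue neglect).  Requires the generator's sidecar labels."""
    if dataset.neglect is None or "neglect_flag" not in getattr(dataset.neglect, "columns", ()):
        raise ValueError("neglect labels are not available for this dataset")
    is_acc = (dataset.trials["condition"] == ACCURACY).to_numpy()
    if not is_acc.any():
        return 0.0
    flags = dataset.neglect["neglect_flag"].to_numpy()[is_acc]
    return float(flags.mean())


def write_dataset(dataset: SyntheticDataset, trials_path, sidecar_path=None) -> None:
    """Write the public table, and optionally the neglect sidecar."""
    write_trials(dataset.trials, trials_path)
    if sidecar_path is not None:
        Path(sidecar_path).parent.mkdir(parents=True, exist_ok=True)
        dataset.neglect.to_csv(sidecar_path, index=False)
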