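"""Constrained speed/accuracy parameterization and mixture likelihood.

Maps 7 free parameters plus a cue-neglect mixture proportion ``p`` to
per-setting two-accumulator races and to a dataset log-likelihood.

Built-in constraints:

* the speed-setting threshold is exactly 1.2x the accuracy-setting
  threshold (a 20% increase, from the neural firing-rate constraint);
* the speed-setting drift SD is fixed to 1 (scaling constraint);
* speed and neutral emphasis conditions share identical predictions;
* accuracy-condition trials are a mixture: with probability ``p`` the
  cue is neglected and the trial behaves as a speed-setting trial.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .lba import (
    DISTRACTOR,
    TARGET,
    Accumulator,
    ParameterError,
    RaceSpec,
    _cdf_raw,
    _pdf_raw,
    defective_pdf,
    rt_cdf,
)

__all__ = [
    "SPEED",
    "NEUTRAL",
    "ACCURACY",
    "CONDITIONS",
    "RESPONSES",
    "SPEED_SETTING",
    "ACCURACY_SETTING",
    "THRESHOLD_RATIO",
    "SPEED_DRIFT_SD",
    "LIKELIHOOD_FLOOR",
    "SatParameters",
    "free_parameter_names",
    "vector_names",
    "params_from_vector",
    "params_to_vector",
    "build_race",
    "trial_density",
    "condition_rt_cdf",
    "dataset_loglik",
    "LikelihoodEvaluator",
    "over_constrained_variant",
    "read_trials",
    "write_trials",
    "validate_trials",
]

SPEED = "speed"
NEUTRAL = "neutral"
ACCURACY = "accuracy"
CONDITIONS = (SPEED, NEUTRAL, ACCURACY)
RESPONSES = (TARGET, DISTRACTOR)

SPEED_SETTING = "speed_setting"
ACCURACY_SETTING = "accuracy_setting"

#: Speed-setting threshold is this multiple of the accuracy-setting one.
THRESHOLD_RATIO = 1.2
#: Drift SD fixed in the speed setting to satisfy the scaling property.
SPEED_DRIFT_SD = 1.0
#: Sum that the speed-setting mean drift rates are pinned to when the
#: redundant second scaling constraint is switched on.
DRIFT_SUM_CONSTANT = 1.0
#: Per-trial density floor applied before taking logs.
LIKELIHOOD_FLOOR = 1e-29

_CORE_NAMES = ("t0", "b_acc", "v_t_acc", "v_d_acc", "v_t_spd", "v_d_spd", "s_acc")
_MIXTURE_NAME = "p"


@dataclass(frozen=True)
class SatParameters:
    """Full parameter set: 7 core free parameters + mixture proportion.

    ``A`` is the start-point range, held at a fixed configured constant
    (default 0, the exact no-start-noise limit) rather than estimated.
    Derived quantities: ``b_spd = 1.2 * b_acc`` and ``s_spd = 1``.
    """

    t0: float
    p: float
    b_acc: float
    v_t_acc: float
    v_d_acc: float
    v_t_spd: float
    v_d_spd: float
    s_acc: float
    A: float = 0.0

    def __post_init__(self) -> None:
        for name in ("t0", "p", "b_acc", "v_t_acc", "v_d_acc", "v_t_spd", "v_d_spd", "s_acc", "A"):
            val = getattr(self, name)
            if not np.isfinite(val):
                raise ParameterError(f"{name} must be finite, got {val!r}")
            object.__setattr__(self, name, float(val))
        if self.t0 < 0:
            raise ParameterError(f"t0 must be >= 0, got {self.t0}")
        if not 0.0 <= self.p <= 1.0:
            raise ParameterError(f"p must be in [0, 1], got {self.p}")
        if self.b_acc <= 0:
            raise ParameterError(f"b_acc must be > 0, got {self.b_acc}")
        if self.s_acc <= 0:
            raise ParameterError(f"s_acc must be > 0, got {self.s_acc}")
        if self.A < 0 or self.A >= self.b_acc:
            raise ParameterError(f"A must satisfy 0 <= A < b_acc, got A={self.A}")

    @property
    def b_spd(self) -> float:
        return THRESHOLD_RATIO * self.b_acc

    @property
    def s_spd(self) -> float:
        return SPEED_DRIFT_SD


def free_parameter_names(include_mixture: bool = True, over_constrained: bool = False):
    """Ordered names of the free parameters.

    The 7 core names come first; the mixture proportion ``p`` is appended
    last when ``include_mixture`` (it is the cue-neglect addition, not
    part of the core accumulation model).  Under the over-constrained
    variant ``v_d_spd`` becomes derived and is dropped.
    """
    core = tuple(n for n in _CORE_NAMES if not (over_constrained and n == "v_d_spd"))
    return core + ((_MIXTURE_NAME,) if include_mixture else ())


def vector_names(over_constrained: bool = False):
    """Parameter ordering used by sampling vectors (core names + 'p')."""
    return free_parameter_names(include_mixture=True, over_constrained=over_constrained)


def params_from_vector(theta, over_constrained: bool = False, A: float = 0.0) -> SatParameters:
    """Build :class:`SatParameters` from a flat vector in ``vector_names`` order."""
    names = vector_names(over_constrained)
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (len(names),):
        raise ParameterError(f"expected vector of length {len(names)}, got shape {theta.shape}")
    kw = dict(zip(names, theta))
    if over_constrained:
        kw["v_d_spd"] = DRIFT_SUM_CONSTANT - kw["v_t_spd"]
    return SatParameters(A=A, **kw)


def params_to_vector(params: SatParameters, over_constrained: bool = False) -> np.ndarray:
    names = vector_names(over_constrained)
    return np.array([getattr(params, n) for n in names], dtype=float)


def build_race(params: SatParameters, setting: str) -> RaceSpec:
    """Per-setting race: both accumulators share b, A and s within a setting."""
    if setting == SPEED_SETTING:
        b, vt, vd, s = params.b_spd, params.v_t_spd, params.v_d_spd, params.s_spd
    elif setting == ACCURACY_SETTING:
        b, vt, vd, s = params.b_acc, params.v_t_acc, params.v_d_acc, params.s_acc
    else:
        raise ParameterError(f"unknown setting {setting!r}")
    return RaceSpec(
        target=Accumulator(b=b, A=params.A, v=vt, s=s),
        distractor=Accumulator(b=b, A=params.A, v=vd, s=s),
        t0=params.t0,
    )


def trial_density(params: SatParameters, condition: str, response: str, rt: float) -> float:
    """Density of one observed trial under the mixture model.

    Speed and neutral conditions use the speed-setting race; the accuracy
    condition is a ``(1 - p)`` / ``p`` mixture of the accuracy-setting
    and speed-setting (cue-neglect) races.
    """
    if response not in RESPONSES:
        raise ValueError(f"unknown response {response!r}")
    if condition in (SPEED, NEUTRAL):
        return defective_pdf(build_race(params, SPEED_SETTING), response, rt)
    if condition == ACCURACY:
        acc = defective_pdf(build_race(params, ACCURACY_SETTING), response, rt)
        spd = defective_pdf(build_race(params, SPEED_SETTING), response, rt)
        return (1.0 - params.p) * acc + params.p * spd
    raise ValueError(f"unknown condition {condition!r}")


def condition_rt_cdf(params: SatParameters, condition: str, t):
    """RT CDF pooled over responses for one condition (mixture-weighted)."""
    if condition in (SPEED, NEUTRAL):
        return rt_cdf(build_race(params, SPEED_SETTING), t)
    if condition == ACCURACY:
        acc = rt_cdf(build_race(params, ACCURACY_SETTING), t)
        spd = rt_cdf(build_race(params, SPEED_SETTING), t)
        return (1.0 - params.p) * acc + params.p * spd
    raise ValueError(f"unknown condition {condition!r}")


def over_constrained_variant(params: SatParameters, enable: bool = True) -> SatParameters:
    """Apply the redundant second scaling constraint on top of the fixed
    speed-setting drift SD: pin the speed-setting mean drift rates to sum
    to :data:`DRIFT_SUM_CONSTANT`.

    With ``enable=False`` the parameters are returned unchanged
    (round-trips to the main model).
    """
    if not enable:
        return params
    return replace(params, v_d_spd=DRIFT_SUM_CONSTANT - params.v_t_spd)


# ---------------------------------------------------------------------------
# Trial tables
# ---------------------------------------------------------------------------

_TRIAL_COLUMNS = ("condition", "response", "rt")


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    if trials is None or len(trials) == 0:
        raise ValueError("trial table is empty")
    missing = [c for c in _TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    bad_cond = set(trials["condition"].unique()) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(f"unknown condition labels: {sorted(bad_cond)}")
    bad_resp = set(trials["response"].unique()) - set(RESPONSES)
    if bad_resp:
        raise ValueError(f"unknown response labels: {sorted(bad_resp)}")
    rt = trials["rt"].to_numpy(dtype=float)
    if not np.all(np.isfinite(rt)) or np.any(rt <= 0):
        raise ValueError("all RTs must be finite and > 0")
    return trials


def read_trials(path) -> pd.DataFrame:
    """Read a ``condition,response,rt`` delimited trial table."""
    trials = pd.read_csv(path)
    return validate_trials(trials)


def write_trials(trials: pd.DataFrame, path) -> None:
    validate_trials(trials)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    trials.to_csv(path, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _winner_density(dt, b, A, v_win, v_lose, s):
    """f_win(dt) * (1 - F_lose(dt)) with zero density at dt <= 0."""
    out = np.zeros_like(dt)
    m = dt > 0
    if np.any(m):
        d = dt[m]
        out[m] = _pdf_raw(d, b, A, v_win, s) * (1.0 - _cdf_raw(d, b, A, v_lose, s))
    return out


def _finish_prob(v_t, v_d, s):
    from scipy.special import ndtr

    return 1.0 - float(ndtr(-v_t / s) * ndtr(-v_d / s))


class LikelihoodEvaluator:
    """Vectorized dataset log-likelihood, reusable across parameter values.

    Trial RTs are split once by (setting-relevant) condition and response;
    each call then evaluates the closed-form race densities on those
    arrays.  Used by the MCMC sampler, where the same table is evaluated
    tens of thousands of times.
    """

    def __init__(self, trials: pd.DataFrame, floor: float = LIKELIHOOD_FLOOR):
        validate_trials(trials)
        self.floor = float(floor)
        cond = trials["condition"].to_numpy()
        resp = trials["response"].to_numpy()
        rt = trials["rt"].to_numpy(dtype=float)
        speedlike = (cond == SPEED) | (cond == NEUTRAL)
        self._spd_t = rt[speedlike & (resp == TARGET)]
        self._spd_d = rt[speedlike & (resp == DISTRACTOR)]
        self._acc_t = rt[(cond == ACCURACY) & (resp == TARGET)]
        self._acc_d = rt[(cond == ACCURACY) & (resp == DISTRACTOR)]
        self.n_trials = len(trials)

    def _setting_densities(self, rts_by_resp, b, vt, vd, s, A, t0):
        pf = _finish_prob(vt, vd, s)
        if pf <= 0.0:
            return [np.zeros_like(r) for r in rts_by_resp]
        out = []
        for rts, (vw, vl) in zip(rts_by_resp, ((vt, vd), (vd, vt))):
            out.append(_winner_density(rts - t0, b, A, vw, vl, s) / pf)
        return out

    def __call__(self, params: SatParameters) -> float:
        t0, A = params.t0, params.A
        spd = self._setting_densities(
            (self._spd_t, self._spd_d),
            params.b_spd, params.v_t_spd, params.v_d_spd, params.s_spd, A, t0,
        )
        acc_under_acc = self._setting_densities(
            (self._acc_t, self._acc_d),
            params.b_acc, params.v_t_acc, params.v_d_acc, params.s_acc, A, t0,
        )
        acc_under_spd = self._setting_densities(
            (self._acc_t, self._acc_d),
            params.b_spd, params.v_t_spd, params.v_d_spd, params.s_spd, A, t0,
        )
        p = params.p
        total = 0.0
        for dens in spd:
            total += float(np.log(np.maximum(dens, self.floor)).sum())
        for da, ds in zip(acc_under_acc, acc_under_spd):
            total += float(np.log(np.maximum((1.0 - p) * da + p * ds, self.floor)).sum())
        return total


def dataset_loglik(params: SatParameters, trials: pd.DataFrame, floor: float = LIKELIHOOD_FLOOR) -> float:
    """Sum over trials of ``log(max(trial density, floor))``.

    Finite for any valid parameter set; raises ``ValueError`` on an empty
    or malformed table.
    """
    return LikelihoodEvaluator(trials, floor=floor)(params)
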