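"""Linear ballistic accumulator primitives.

Closed-form first-passage densities for a single linear ballistic
accumulator (including the exact zero start-point-variability limit),
defective densities for a two-accumulator race, and seeded simulation of
trials and of evidence-accumulation trajectories.

Conventions
-----------
* Evidence is in arbitrary units; drift rates are evidence units per
  second; all times are seconds.
* A trial's drift rate is drawn once, per accumulator, from a normal
  distribution; within a trial accumulation is noiseless and linear.
* An accumulator whose sampled drift is non-positive never reaches
  threshold.  Race densities are therefore renormalized by the race's
  finish probability, and simulation redraws non-terminating trials, so
  the analytic densities and the simulator describe the same process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.integrate import quad
from scipy.special import ndtr

__all__ = [
    "TARGET",
    "DISTRACTOR",
    "Accumulator",
    "RaceSpec",
    "TrajectorySample",
    "SimulatedTrials",
    "ParameterError",
    "NumericalError",
    "SimulationError",
    "fpt_pdf",
    "fpt_cdf",
    "defective_pdf",
    "rt_cdf",
    "choice_prob",
    "simulate_trials",
    "simulate_trajectories",
]

TARGET = "target"
DISTRACTOR = "distractor"

_SQRT_2PI = math.sqrt(2.0 * math.pi)


class ParameterError(ValueError):
    """Invalid accumulator/race parameters or evaluation points."""


class NumericalError(RuntimeError):
    """A numerical routine failed to reach its accuracy target."""


class SimulationError(RuntimeError):
    """Simulation could not produce the requested trials."""


def _npdf(x: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * x * x) / _SQRT_2PI


@dataclass(frozen=True)
class Accumulator:
    """One racer: threshold ``b``, start-point range ``A``, drift mean ``v``
    and across-trial drift standard deviation ``s``.

    The start point is uniform on ``[0, A]`` and must lie strictly below
    threshold (``A < b``).  ``A = 0`` selects the exact no-start-noise
    limit, in which the crossing time is ``b`` divided by the sampled
    drift.
    """

    b: float
    A: float = 0.0
    v: float = 1.0
    s: float = 1.0

    def __post_init__(self) -> None:
        for name in ("b", "A", "v", "s"):
            val = getattr(self, name)
            if not np.isfinite(val):
                raise ParameterError(f"{name} must be finite, got {val!r}")
            object.__setattr__(self, name, float(val))
        if self.b <= 0:
            raise ParameterError(f"threshold b must be > 0, got {self.b}")
        if self.A < 0:
            raise ParameterError(f"start-point range A must be >= 0, got {self.A}")
        if self.A >= self.b:
            raise ParameterError(f"A must be < b, got A={self.A}, b={self.b}")
        if self.s <= 0:
            raise ParameterError(f"drift SD s must be > 0, got {self.s}")

    @property
    def finish_prob(self) -> float:
        """Probability that this accumulator ever crosses threshold.

        Only trials whose sampled drift is positive ever finish, so this
        equals ``Phi(v / s)`` regardless of ``A`` (the start point is
        strictly below threshold).
        """
        return float(ndtr(self.v / self.s))


@dataclass(frozen=True)
class RaceSpec:
    """A two-accumulator race plus shared non-decision time."""

    target: Accumulator
    distractor: Accumulator
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.t0) or self.t0 < 0:
            raise ParameterError(f"t0 must be finite and >= 0, got {self.t0}")
        object.__setattr__(self, "t0", float(self.t0))
        if self.finish_prob <= 0.0:
            raise ParameterError("race has zero finish probability")

    @property
    def finish_prob(self) -> float:
        """Probability that at least one accumulator finishes."""
        pt = self.target.finish_prob
        pd = self.distractor.finish_prob
        return 1.0 - (1.0 - pt) * (1.0 - pd)

    def accumulator(self, which: str) -> Accumulator:
        if which == TARGET:
            return self.target
        if which == DISTRACTOR:
            return self.distractor
        raise ParameterError(f"unknown accumulator label {which!r}")


# ---------------------------------------------------------------------------
# First-passage densities (raw: decision-time axis, strictly positive t)
# ---------------------------------------------------------------------------

# below this start-point range (relative to threshold) the A > 0 closed
# form loses precision to cancellation; the exact A -> 0 limit differs by
# O(A/b) and is used instead
_A_NEGLIGIBLE = 1e-6


def _pdf_raw(t, b, A, v, s):
    """Unnormalized first-passage density at decision times t > 0."""
    t = np.asarray(t, dtype=float)
    if A < _A_NEGLIGIBLE * b:
        # crossing time is b / drift for positive drift
        z = (b / t - v) / s
        return (b / (t * t)) * _npdf(z) / s
    g = t * s
    z1 = (b - A - t * v) / g
    z2 = (b - t * v) / g
    out = (-v * ndtr(z1) + s * _npdf(z1) + v * ndtr(z2) - s * _npdf(z2)) / A
    return np.maximum(out, 0.0)


def _cdf_raw(t, b, A, v, s):
    """P(crossing time <= t) for decision times t > 0 (defective: limit
    as t -> inf is Phi(v/s))."""
    t = np.asarray(t, dtype=float)
    if A < _A_NEGLIGIBLE * b:
        return ndtr((v - b / t) / s)
    g = t * s
    z1 = (b - A - t * v) / g
    z2 = (b - t * v) / g
    out = (
        1.0
        + ((b - A - t * v) / A) * ndtr(z1)
        - ((b - t * v) / A) * ndtr(z2)
        + (g / A) * (_npdf(z1) - _npdf(z2))
    )
    return np.clip(out, 0.0, 1.0)


def _check_times(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ParameterError("evaluation times must be finite")
    return t


def fpt_pdf(acc: Accumulator, t):
    """First-passage-time density of a single accumulator.

    Parameters
    ----------
    acc : Accumulator
    t : float or array_like
        Decision time(s), strictly positive, in seconds.

    Returns
    -------
    float or ndarray
        Density (1/seconds).  Defective for accumulators that may never
        finish: it integrates to ``acc.finish_prob``, not 1.
    """
    t = _check_times(t)
    if np.any(t <= 0):
        raise ParameterError("fpt_pdf requires t > 0")
    out = _pdf_raw(t, acc.b, acc.A, acc.v, acc.s)
    return float(out) if out.ndim == 0 else out


def fpt_cdf(acc: Accumulator, t):
    """P(crossing time <= t) for a single accumulator; see :func:`fpt_pdf`."""
    t = _check_times(t)
    if np.any(t <= 0):
        raise ParameterError("fpt_cdf requires t > 0")
    out = _cdf_raw(t, acc.b, acc.A, acc.v, acc.s)
    return float(out) if out.ndim == 0 else out


def defective_pdf(race: RaceSpec, winner: str, t):
    """Joint density that ``winner`` finishes first at observed RT ``t``.

    Computed as ``f_winner(t - t0) * (1 - F_loser(t - t0))`` and
    renormalized by the race's finish probability, so the two winners'
    densities together integrate to exactly 1.  Zero for ``t <= t0``.
    """
    w = race.accumulator(winner)
    l = race.distractor if winner == TARGET else race.target
    t = _check_times(t)
    dt = t - race.t0
    out = np.zeros_like(dt)
    m = dt > 0
    if np.any(m):
        dm = dt[m] if dt.ndim else dt
        val = _pdf_raw(dm, w.b, w.A, w.v, w.s) * (
            1.0 - _cdf_raw(dm, l.b, l.A, l.v, l.s)
        )
        if dt.ndim:
            out[m] = val
        else:
            out = val
    out = out / race.finish_prob
    return float(out) if out.ndim == 0 else out


def rt_cdf(race: RaceSpec, t):
    """CDF of the observed RT, pooled over winners (renormalized).

    ``P(min crossing <= t - t0 | race finishes)``; closed form
    ``(1 - (1 - F_t)(1 - F_d)) / P(finish)``.
    """
    tgt, dis = race.target, race.distractor
    t = _check_times(t)
    dt = t - race.t0
    out = np.zeros_like(dt)
    m = dt > 0
    if np.any(m):
        dm = dt[m] if dt.ndim else dt
        ft = _cdf_raw(dm, tgt.b, tgt.A, tgt.v, tgt.s)
        fd = _cdf_raw(dm, dis.b, dis.A, dis.v, dis.s)
        val = 1.0 - (1.0 - ft) * (1.0 - fd)
        if dt.ndim:
            out[m] = val
        else:
            out = val
    out = out / race.finish_prob
    return float(out) if out.ndim == 0 else out


def _upper_time_bound(race: RaceSpec, tol: float = 1e-8) -> float:
    """Decision-time horizon beyond which the truncated race mass < tol."""
    tgt, dis = race.target, race.distractor
    T = 1.0
    for _ in range(80):
        resid = (tgt.finish_prob - float(_cdf_raw(T, tgt.b, tgt.A, tgt.v, tgt.s))) + (
            dis.finish_prob - float(_cdf_raw(T, dis.b, dis.A, dis.v, dis.s))
        )
        if resid < tol:
            return T
        T *= 2.0
    return T


def choice_prob(race: RaceSpec, winner: str) -> float:
    """Probability that ``winner`` wins the (renormalized) race.

    Numerical integral of the defective density over decision time; the
    two winners' probabilities sum to 1.

    The decision-time density has a ``1/t**2`` tail (near-zero sampled
    drifts cross arbitrarily late), so the integral is evaluated after
    the substitution ``u = 1/t``, which makes the integrand smooth with
    Gaussian decay at large ``u`` and a finite limit at ``u = 0``.
    """
    w = race.accumulator(winner)
    l = race.distractor if winner == TARGET else race.target

    def integrand(u):
        t = 1.0 / u
        return float(
            _pdf_raw(t, w.b, w.A, w.v, w.s) * (1.0 - _cdf_raw(t, l.b, l.A, l.v, l.s))
        ) / (u * u)

    # winning drifts above v + 12 s carry ~1e-33 mass; crossing cannot be
    # faster than (b - A) / drift
    u_max = (abs(w.v) + 12.0 * w.s) / max(w.b - w.A, 1e-12)
    points = sorted(
        {p for p in (w.v / w.b, w.v / max(w.b - w.A, 1e-12)) if 0.0 < p < u_max}
    )
    try:
        val, err = quad(integrand, 0.0, u_max, limit=500, points=points or None)
    except Exception as exc:  # pragma: no cover - scipy-internal failures
        raise NumericalError(f"choice_prob quadrature failed: {exc}") from exc
    if not np.isfinite(val) or err > 1e-6:
        raise NumericalError(
            f"choice_prob quadrature unreliable (value={val}, abserr={err})"
        )
    return val / race.finish_prob


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

class SimulatedTrials(NamedTuple):
    """Winner labels ('target'/'distractor') and observed RTs (seconds)."""

    winner: np.ndarray
    rt: np.ndarray


class _RaceDraw(NamedTuple):
    ct_target: np.ndarray  # crossing times (decision axis), inf if never
    ct_distractor: np.ndarray
    start_target: np.ndarray
    drift_target: np.ndarray


def _draw_race(race: RaceSpec, m: int, rng: np.random.Generator) -> _RaceDraw:
    tgt, dis = race.target, race.distractor
    start_t = rng.uniform(0.0, tgt.A, m) if tgt.A > 0 else np.zeros(m)
    start_d = rng.uniform(0.0, dis.A, m) if dis.A > 0 else np.zeros(m)
    drift_t = rng.normal(tgt.v, tgt.s, m)
    drift_d = rng.normal(dis.v, dis.s, m)
    with np.errstate(divide="ignore"):
        ct_t = np.where(drift_t > 0, (tgt.b - start_t) / drift_t, np.inf)
        ct_d = np.where(drift_d > 0, (dis.b - start_d) / drift_d, np.inf)
    return _RaceDraw(ct_t, ct_d, start_t, drift_t)


def simulate_trials(race: RaceSpec, n: int, rng=None, max_rounds: int = 10_000) -> SimulatedTrials:
    """Simulate ``n`` race trials.

    Start points are uniform on ``[0, A]`` and drifts normal, drawn
    independently per accumulator; trials in which neither accumulator
    finishes are redrawn (bounded by ``max_rounds`` redraw rounds).
    ``rng`` is an integer seed or a ``numpy.random.Generator``.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(rng)
    winner = np.empty(n, dtype="<U10")
    rt = np.empty(n, dtype=float)
    pending = np.arange(n)
    for _ in range(max_rounds):
        if pending.size == 0:
            break
        d = _draw_race(race, pending.size, rng)
        tmin = np.minimum(d.ct_target, d.ct_distractor)
        ok = np.isfinite(tmin)
        done = pending[ok]
        rt[done] = tmin[ok] + race.t0
        winner[done] = np.where(d.ct_target[ok] <= d.ct_distractor[ok], TARGET, DISTRACTOR)
        pending = pending[~ok]
    if pending.size:
        raise SimulationError(
            f"{pending.size} trials failed to terminate after {max_rounds} redraw "
            f"rounds (race finish probability {race.finish_prob:.3g})"
        )
    return SimulatedTrials(winner, rt)


@dataclass(frozen=True)
class TrajectorySample:
    """One ballistic evidence path of the target accumulator.

    ``evidence(t) = start + drift * t`` on a fixed time grid, truncated at
    the threshold crossing; the final grid point is the exact crossing.
    Times are on the decision axis (exclude non-decision time).
    """

    start: float
    drift: float
    crossing_time: float
    times: np.ndarray = field(repr=False)
    evidence: np.ndarray = field(repr=False)

    @property
    def path(self) -> np.ndarray:
        """(k, 2) array of (time, evidence) pairs."""
        return np.column_stack([self.times, self.evidence])


def simulate_trajectories(
    race: RaceSpec,
    n: int,
    dt: float = 0.001,
    winner_filter: str = TARGET,
    rng=None,
    max_rounds: int = 1000,
) -> list[TrajectorySample]:
    """Simulate target-accumulator trajectories for trials won by
    ``winner_filter``.

    Each path is sampled on the grid ``0, dt, 2*dt, ...`` up to that
    trial's own threshold crossing; the crossing point ``(T, b)`` is
    appended exactly.  If the target never crosses (possible only when
    filtering on distractor wins) the path is truncated at the race's
    decision time instead.
    """
    if dt <= 0:
        raise ParameterError(f"dt must be > 0, got {dt}")
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if winner_filter not in (TARGET, DISTRACTOR):
        raise ParameterError(f"unknown winner_filter {winner_filter!r}")
    rng = np.random.default_rng(rng)
    b = race.target.b
    out: list[TrajectorySample] = []
    batch = max(4 * n, 256)
    for _ in range(max_rounds):
        d = _draw_race(race, batch, rng)
        tmin = np.minimum(d.ct_target, d.ct_distractor)
        won_by_target = np.isfinite(tmin) & (d.ct_target <= d.ct_distractor)
        keep = won_by_target if winner_filter == TARGET else (np.isfinite(tmin) & ~won_by_target)
        for i in np.flatnonzero(keep):
            cross = d.ct_target[i] if np.isfinite(d.ct_target[i]) else tmin[i]
            times = np.arange(0.0, cross, dt)
            evid = d.start_target[i] + d.drift_target[i] * times
            end_val = d.start_target[i] + d.drift_target[i] * cross
            times = np.append(times, cross)
            evid = np.append(evid, min(end_val, b))
            out.append(
                TrajectorySample(
                    start=float(d.start_target[i]),
                    drift=float(d.drift_target[i]),
                    crossing_time=float(cross),
                    times=times,
                    evidence=evid,
                )
            )
            if len(out) == n:
                return out
    raise SimulationError(
        f"collected only {len(out)}/{n} '{winner_filter}'-win trajectories "
        f"after {max_rounds} simulation rounds"
    )
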