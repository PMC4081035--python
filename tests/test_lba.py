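"""Unit and property tests for the accumulator-race primitives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import kstest, norm

from satlba.lba import (
    DISTRACTOR,
    TARGET,
    Accumulator,
    ParameterError,
    RaceSpec,
    SimulationError,
    choice_prob,
    defective_pdf,
    fpt_cdf,
    fpt_pdf,
    rt_cdf,
    simulate_trials,
    simulate_trajectories,
)


def make_race(b=0.3, v_t=2.0, v_d=1.0, s=1.0, t0=0.1, A=0.0):
    return RaceSpec(
        target=Accumulator(b=b, A=A, v=v_t, s=s),
        distractor=Accumulator(b=b, A=A, v=v_d, s=s),
        t0=t0,
    )


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"b": 0.0},
            {"b": -1.0},
            {"b": 1.0, "A": -0.1},
            {"b": 1.0, "A": 1.0},  # A must be < b
            {"b": 1.0, "s": 0.0},
            {"b": np.nan},
            {"b": 1.0, "v": np.inf},
        ],
    )
    def test_bad_accumulator(self, kwargs):
        with pytest.raises(ParameterError):
            Accumulator(**kwargs)

    def test_negative_t0(self):
        with pytest.raises(ParameterError):
            make_race(t0=-0.1)

    def test_zero_finish_probability(self):
        with pytest.raises(ParameterError):
            make_race(v_t=-60.0, v_d=-60.0, s=1.0)

    def test_nonfinite_time(self):
        acc = Accumulator(b=1.0, v=1.0, s=0.5)
        with pytest.raises(ParameterError):
            fpt_pdf(acc, np.nan)
        with pytest.raises(ParameterError):
            fpt_cdf(acc, np.inf)
        with pytest.raises(ParameterError):
            fpt_pdf(acc, -1.0)


class TestFptPdf:
    def test_degenerate_ballistic(self):
        # with vanishing drift noise the crossing time concentrates at b/v
        acc = Accumulator(b=1.0, A=0.0, v=1.0, s=1e-5)
        eps = 1e-3
        mass = fpt_cdf(acc, 1.0 + eps) - fpt_cdf(acc, 1.0 - eps)
        assert mass > 1.0 - 1e-8

    def test_matches_simulated_histogram(self):
        # independent oracle: crossing time is b / drift for positive drift
        b, v, s = 0.24, 0.66, 0.10
        acc = Accumulator(b=b, A=0.0, v=v, s=s)
        rng = np.random.default_rng(5)
        drift = rng.normal(v, s, 10**6)
        times = b / drift[drift > 0]
        edges = np.linspace(0.25, 0.55, 61)
        counts, _ = np.histogram(times, bins=edges)
        width = edges[1] - edges[0]
        dens = counts / (len(drift) * width)
        se = np.sqrt(counts.clip(1)) / (len(drift) * width)
        mid = 0.5 * (edges[:-1] + edges[1:])
        assert np.max(np.abs(fpt_pdf(acc, mid) - dens) / np.maximum(se, 1e-12)) < 3.0

    @pytest.mark.parametrize(
        "acc",
        [
            Accumulator(b=0.24, A=0.0, v=0.66, s=0.10),
            Accumulator(b=1.0, A=0.0, v=-0.5, s=1.0),
            Accumulator(b=0.5, A=0.2, v=1.5, s=0.8),
        ],
    )
    def test_integrates_to_finish_prob(self, acc):
        # u = 1/t substitution tames the 1/t**2 tail
        u_max = (abs(acc.v) + 12 * acc.s) / max(acc.b - acc.A, 1e-12)
        val, err = quad(
            lambda u: fpt_pdf(acc, 1.0 / u) / u**2, 0.0, u_max, limit=400,
            points=[min(max(acc.v, 1e-6) / acc.b, 0.99 * u_max)],
        )
        assert val == pytest.approx(acc.finish_prob, abs=1e-6)


class TestFptCdf:
    def test_zero_at_origin(self):
        acc = Accumulator(b=0.24, v=0.66, s=0.10)
        assert fpt_cdf(acc, 1e-12) == pytest.approx(0.0, abs=1e-300)

    def test_matches_empirical_cdf(self):
        b, v, s = 0.24, 0.66, 0.10
        acc = Accumulator(b=b, A=0.0, v=v, s=s)
        rng = np.random.default_rng(6)
        drift = rng.normal(v, s, 10**6)
        emp = np.mean((drift > 0) & (b / np.where(drift > 0, drift, np.inf) <= 0.4))
        assert fpt_cdf(acc, 0.4) == pytest.approx(emp, abs=0.005)

    @pytest.mark.parametrize("A", [0.0, 0.15])
    def test_derivative_matches_pdf(self, A):
        acc = Accumulator(b=0.3, A=A, v=1.2, s=0.6)
        t = np.linspace(0.05, 2.0, 100)
        h = 1e-6
        fd = (fpt_cdf(acc, t + h) - fpt_cdf(acc, t - h)) / (2 * h)
        assert np.max(np.abs(fd - fpt_pdf(acc, t))) < 1e-4

    @settings(max_examples=40, deadline=None)
    @given(
        b=st.floats(0.1, 3.0),
        frac=st.floats(0.0, 0.9),
        v=st.floats(-2.0, 4.0),
        s=st.floats(0.05, 2.0),
    )
    def test_cdf_properties(self, b, frac, v, s):
        acc = Accumulator(b=b, A=frac * b, v=v, s=s)
        t = np.geomspace(1e-3, 50.0, 60)
        c = fpt_cdf(acc, t)
        assert np.all(c >= 0) and np.all(c <= 1)
        assert np.all(np.diff(c) >= -1e-9)  # allows closed-form roundoff
        assert c[-1] <= acc.finish_prob + 1e-9
        assert np.all(fpt_pdf(acc, t) >= 0)


def _numeric_integral(race, winner):
    """Trapezoid integral of the defective density on a dense+tail grid."""
    grid = np.concatenate(
        [np.linspace(race.t0, race.t0 + 5.0, 4000), np.geomspace(race.t0 + 5.0, 5e4, 3000)]
    )
    return np.trapezoid(defective_pdf(race, winner, grid), grid)


class TestDefectivePdf:
    def test_zero_at_and_before_t0(self):
        race = make_race(t0=0.1)
        assert defective_pdf(race, TARGET, 0.1) == 0.0
        assert defective_pdf(race, TARGET, 0.05) == 0.0

    def test_symmetric_race_integrates_to_half(self):
        race = make_race(v_t=1.3, v_d=1.3, s=0.7)
        assert _numeric_integral(race, TARGET) == pytest.approx(0.5, abs=2e-3)

    def test_matches_winner_separated_histogram(self, monkey_q):
        from satlba.model import SPEED_SETTING, build_race

        race = build_race(monkey_q, SPEED_SETTING)
        sim = simulate_trials(race, 10**6, rng=13)
        n = len(sim.rt)
        edges = np.linspace(0.1, 0.8, 71)
        for winner in (TARGET, DISTRACTOR):
            counts, _ = np.histogram(sim.rt[sim.winner == winner], bins=edges)
            # expected bin mass: fine-grid integral of the analytic density
            expected = np.empty(len(edges) - 1)
            for i in range(len(edges) - 1):
                grid = np.linspace(edges[i], edges[i + 1], 40)
                expected[i] = np.trapezoid(defective_pdf(race, winner, grid), grid)
            se = np.sqrt(expected * (1 - expected) / n)
            z = (counts / n - expected) / np.maximum(se, 1e-12)
            assert np.max(np.abs(z)) < 4.5

    def test_nonnegative(self):
        race = make_race(A=0.1, v_t=0.5, v_d=-0.5)
        t = np.linspace(0.0, 10.0, 500)
        assert np.all(defective_pdf(race, TARGET, t) >= 0)


class TestChoiceProb:
    def test_symmetric(self):
        race = make_race(v_t=1.5, v_d=1.5, s=0.9)
        assert choice_prob(race, TARGET) == pytest.approx(0.5, abs=1e-8)

    def test_normalization(self):
        race = make_race(v_t=1.7, v_d=0.4, s=0.8, A=0.1)
        total = choice_prob(race, TARGET) + choice_prob(race, DISTRACTOR)
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_dominant_racer(self):
        race = make_race(v_t=3.0, v_d=0.5, s=0.05)
        assert choice_prob(race, TARGET) > 0.999

    def test_matches_simulation_monkey_s_accuracy(self, monkey_s):
        from satlba.model import ACCURACY_SETTING, build_race

        race = build_race(monkey_s, ACCURACY_SETTING)
        sim = simulate_trials(race, 10**6, rng=17)
        emp = float(np.mean(sim.winner == TARGET))
        assert choice_prob(race, TARGET) == pytest.approx(emp, abs=0.005)

    def test_increases_with_target_drift(self):
        probs = [choice_prob(make_race(v_t=v), TARGET) for v in (0.5, 1.0, 2.0, 3.0)]
        assert np.all(np.diff(probs) > 0)


class TestScalingProperty:
    def test_common_rescaling_is_invariant(self):
        # multiplying all evidence-dimension parameters by a constant
        # leaves the race's predictions unchanged (why one SD is fixed)
        t = np.linspace(0.12, 2.0, 50)
        base = make_race(b=0.3, v_t=2.0, v_d=1.0, s=0.7, t0=0.1, A=0.05)
        for c in (0.5, 3.0):
            scaled = RaceSpec(
                target=Accumulator(b=0.3 * c, A=0.05 * c, v=2.0 * c, s=0.7 * c),
                distractor=Accumulator(b=0.3 * c, A=0.05 * c, v=1.0 * c, s=0.7 * c),
                t0=0.1,
            )
            np.testing.assert_allclose(
                defective_pdf(scaled, TARGET, t), defective_pdf(base, TARGET, t), rtol=1e-9
            )


class TestSimulateTrials:
    def test_degenerate_all_target(self):
        race = make_race(b=0.4, v_t=2.0, v_d=1.0, s=1e-7, t0=0.15)
        sim = simulate_trials(race, 500, rng=0)
        assert np.all(sim.winner == TARGET)
        np.testing.assert_allclose(sim.rt, 0.4 / 2.0 + 0.15, rtol=1e-5)

    def test_winner_frequency_matches_choice_prob(self):
        race = make_race(b=0.3, v_t=2.0, v_d=1.2, s=0.9)
        n = 10**5
        sim = simulate_trials(race, n, rng=3)
        p = choice_prob(race, TARGET)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(np.mean(sim.winner == TARGET) - p) < 4 * se

    def test_deterministic(self):
        race = make_race()
        a = simulate_trials(race, 1000, rng=99)
        b = simulate_trials(race, 1000, rng=99)
        assert np.array_equal(a.winner, b.winner)
        assert np.array_equal(a.rt, b.rt)

    def test_bad_n(self):
        with pytest.raises(ParameterError):
            simulate_trials(make_race(), 0)

    def test_nonterminating_race_errors(self):
        race = make_race(v_t=-7.5, v_d=-7.5, s=1.0)  # finish prob ~ 1e-13
        with pytest.raises(SimulationError):
            simulate_trials(race, 10, rng=0, max_rounds=5)

    def test_rt_distribution_matches_analytic_cdf(self):
        race = make_race(b=0.29, v_t=2.3, v_d=1.41, s=1.0, t0=0.1)
        sim = simulate_trials(race, 10**5, rng=8)
        assert kstest(sim.rt, lambda t: rt_cdf(race, t)).statistic < 0.01

    def test_mean_rt_increases_with_threshold(self):
        # paired by seed: identical drift draws, larger threshold
        lo = simulate_trials(make_race(b=0.3, s=0.5), 5000, rng=42)
        hi = simulate_trials(make_race(b=0.45, s=0.5), 5000, rng=42)
        assert np.all(hi.rt > lo.rt)
        assert hi.rt.mean() > lo.rt.mean()


class TestSimulateTrajectories:
    def test_paths_are_exactly_linear(self):
        race = make_race(A=0.1)
        for tr in simulate_trajectories(race, 20, dt=0.002, rng=1):
            np.testing.assert_allclose(tr.evidence[:-1], tr.start + tr.drift * tr.times[:-1], rtol=1e-12)
            assert tr.path.shape == (len(tr.times), 2)

    def test_paths_end_at_threshold(self):
        race = make_race(b=0.35)
        dt = 0.001
        for tr in simulate_trajectories(race, 50, dt=dt, rng=2):
            assert tr.evidence[-1] == pytest.approx(race.target.b, abs=abs(tr.drift) * dt)
            assert tr.times[-1] == pytest.approx(tr.crossing_time)

    def test_mean_crossing_matches_trials(self):
        race = make_race(b=0.3, v_t=2.5, v_d=1.5, s=0.3, t0=0.1)
        trajs = simulate_trajectories(race, 3000, dt=0.005, rng=4)
        cross = np.array([tr.crossing_time for tr in trajs])
        sim = simulate_trials(race, 30000, rng=5)
        dec = sim.rt[sim.winner == TARGET] - race.t0
        sem = np.sqrt(cross.var() / len(cross) + dec.var() / len(dec))
        assert abs(cross.mean() - dec.mean()) < 4 * sem

    def test_filter_never_satisfied(self):
        race = make_race(v_t=5.0, v_d=-5.0, s=0.5)  # distractor essentially never wins
        with pytest.raises(SimulationError):
            simulate_trajectories(race, 5, winner_filter=DISTRACTOR, rng=0, max_rounds=3)

    def test_bad_args(self):
        with pytest.raises(ParameterError):
            simulate_trajectories(make_race(), 10, dt=0.0)
        with pytest.raises(ParameterError):
            simulate_trajectories(make_race(), 10, winner_filter="nobody")
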