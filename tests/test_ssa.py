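"""Unit tests of the delayed-SSA engine: channel bookkeeping, waiting-time
statistics, delayed-event interleaving and sampling."""

import numpy as np
import pytest
from scipy import stats as sps

from prokexpress.ssa import (BufferedRNG, DelayedSSA, ReactionChannel,
                             truncated_normal_delay)


class Counts(dict):
    """Tiny mutable species-count state for functional channels."""


def make_channel(cid, species, k, effect):
    return ReactionChannel(
        cid,
        propensity_fn=lambda s, sp=species, k=k: k * s.get(sp, 0),
        effect_fn=effect,
    )


def test_channel_addition_and_removal_update_the_propensity_sum():
    eng = DelayedSSA(0, state=Counts(A=1))
    assert eng.total_propensity == 0.0
    h = eng.add_channel(make_channel("a2b", "A", 1.0, lambda s: None))
    assert eng.total_propensity == pytest.approx(1.0)
    # zero-reactant channel contributes nothing
    eng.add_channel(make_channel("c2d", "C", 5.0, lambda s: None))
    assert eng.total_propensity == pytest.approx(1.0)
    assert eng.remove_channels([h]) == 1
    assert eng.total_propensity == pytest.approx(0.0)
    assert eng.remove_channels([]) == 0


def test_duplicate_and_unknown_handles_are_rejected_by_name():
    eng = DelayedSSA(0, state=Counts(A=1))
    eng.add_channel(make_channel("x", "A", 1.0, lambda s: None))
    with pytest.raises(ValueError, match="duplicate"):
        eng.add_channel(make_channel("x", "A", 1.0, lambda s: None))
    with pytest.raises(KeyError, match="nope"):
        eng.remove_channels(["nope"])


def test_exhausted_engine_reports_termination_not_exception():
    eng = DelayedSSA(0, state=Counts(A=1))
    h = eng.add_channel(make_channel("only", "A", 2.0, lambda s: None))
    eng.remove_channels([h])
    assert eng.step() is None


def test_single_channel_waiting_times_are_exponential():
    state = Counts(A=2)
    eng = DelayedSSA(123, state=state)
    eng.add_channel(make_channel("a", "A", 1.5, lambda s: None))  # rate 3.0
    n = 20000
    waits = np.empty(n)
    prev = 0.0
    for i in range(n):
        ev = eng.step()
        waits[i] = ev.time - prev
        prev = ev.time
    rate = 3.0
    se = (1 / rate) / np.sqrt(n)
    assert abs(waits.mean() - 1 / rate) < 3 * se
    # distribution shape: KS against the true exponential
    assert sps.kstest(waits, "expon", args=(0, 1 / rate)).pvalue > 0.01


def test_kolmogorov_smirnov_passes_in_most_repeated_runs():
    # exactness of the waiting-time law, checked over repeated seeds
    passes = 0
    for seed in range(20):
        eng = DelayedSSA(seed, state=Counts(A=1))
        eng.add_channel(make_channel("a", "A", 2.0, lambda s: None))
        waits = []
        prev = 0.0
        for _ in range(500):
            ev = eng.step()
            waits.append(ev.time - prev)
            prev = ev.time
        if sps.kstest(waits, "expon", args=(0, 0.5)).pvalue > 0.01:
            passes += 1
    assert passes >= 18


def test_competing_channels_fire_proportionally_to_propensity():
    eng = DelayedSSA(7, state=Counts(A=1))
    eng.add_channel(make_channel("fast", "A", 3.0, lambda s: None))
    eng.add_channel(make_channel("slow", "A", 1.0, lambda s: None))
    n = 100_000
    fast = sum(eng.step().channel_id == "fast" for _ in range(n))
    se = np.sqrt(0.75 * 0.25 / n)
    assert abs(fast / n - 0.75) < 3 * se


def test_delayed_release_dominates_when_propensity_is_zero():
    eng = DelayedSSA(0, state=Counts())
    fired = []
    eng.schedule_delayed(lambda: fired.append("x"), 40.0)
    ev = eng.step()
    assert ev.kind == "delayed"
    assert ev.time == pytest.approx(40.0)
    assert fired == ["x"]
    assert eng.step() is None


def test_delayed_releases_come_out_in_time_order_fifo_on_ties():
    eng = DelayedSSA(0, state=Counts())
    order = []
    eng.schedule_delayed(lambda: order.append(5), 5.0)
    eng.schedule_delayed(lambda: order.append(3), 3.0)
    eng.schedule_delayed(lambda: order.append("tie1"), 3.0)
    while eng.step() is not None:
        pass
    assert order == [3, "tie1", 5]


def test_zero_delay_applies_before_any_positive_waiting_time():
    state = Counts(A=1)
    eng = DelayedSSA(1, state=state)
    seen = []
    eng.add_channel(make_channel("a", "A", 100.0, lambda s: seen.append("rxn")))
    eng.schedule_delayed(lambda: seen.append("delayed"), 0.0)
    eng.step()
    assert seen[0] == "delayed"
    with pytest.raises(ValueError, match="negative delay"):
        eng.schedule_delayed(lambda: None, -1.0)


def test_truncated_normal_delay_matches_requested_moments():
    rng = BufferedRNG(5)
    sampler = truncated_normal_delay(40.0, 4.0)
    draws = np.array([sampler(rng) for _ in range(10_000)])
    assert abs(draws.mean() - 40.0) < 3 * 4.0 / np.sqrt(draws.size)
    assert abs(draws.std(ddof=1) - 4.0) < 0.2
    assert draws.min() > 0.0


def test_delayed_product_never_appears_before_its_minimum_delay():
    # species B produced only through a fixed 2 s delayed reaction
    state = Counts(A=5, B=0)
    eng = DelayedSSA(11, state=state)

    def consume(s):
        s["A"] -= 1

    birth_times = []

    def born(s):
        s["B"] += 1
        birth_times.append(eng.time)

    ch = ReactionChannel("delayed_birth",
                         propensity_fn=lambda s: 10.0 * s["A"],
                         effect_fn=born, delay=2.0)
    eng.add_channel(ReactionChannel("consume",
                                    propensity_fn=lambda s: 0.0,
                                    effect_fn=lambda s: None))
    eng.add_channel(ch)
    fire_times = []
    while state["A"] > 0 or eng.n_pending_delays:
        ev = eng.step()
        if ev.kind == "reaction":
            fire_times.append(ev.time)
            state["A"] -= 1
            eng.recompute_all()
    assert len(birth_times) == 5
    for t_fire, t_born in zip(fire_times, birth_times):
        assert t_born >= t_fire + 2.0 - 1e-12


def test_run_with_no_channels_yields_a_flat_series():
    eng = DelayedSSA(0, state=Counts(A=4))
    series = eng.run(10.0, 1.0, observe=lambda: {"A": eng.state["A"]})
    assert (series["A"] == 4).all()
    assert len(series) == 11


def test_birth_death_reaches_the_closed_form_stationary_mean():
    state = Counts(N=0)
    eng = DelayedSSA(21, state=state)

    def birth(s):
        s["N"] += 1

    def death(s):
        s["N"] -= 1

    eng.add_channel(ReactionChannel("birth", propensity_fn=lambda s: 5.0,
                                    effect_fn=birth))
    eng.add_channel(ReactionChannel("death", propensity_fn=lambda s: 0.5 * s["N"],
                                    effect_fn=death))
    series = eng.run(2000.0, 1.0, observe=lambda: {"N": state["N"]})
    steady = series[series["time_s"] > 50.0]["N"]
    # stationary mean k_birth/k_death = 10 (Poisson), sampling error via
    # effective sample size ~ T * k_death
    n_eff = (2000 - 50) * 0.5
    assert abs(steady.mean() - 10.0) < 3 * np.sqrt(10.0 / n_eff)


def test_identical_seeds_reproduce_the_event_sequence_exactly():
    def trace(seed):
        state = Counts(N=1)
        eng = DelayedSSA(seed, state=state)
        eng.add_channel(ReactionChannel("b", propensity_fn=lambda s: 2.0,
                                        effect_fn=lambda s: s.__setitem__("N", s["N"] + 1)))
        eng.add_channel(ReactionChannel("d", propensity_fn=lambda s: 0.3 * s["N"],
                                        effect_fn=lambda s: s.__setitem__("N", s["N"] - 1)))
        out = []
        for _ in range(2000):
            ev = eng.step()
            out.append((ev.time, ev.channel_id))
        return out

    assert trace(42) == trace(42)
    assert trace(42) != trace(43)
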