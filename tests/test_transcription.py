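"""Transcription model: phase-dependent reaction availability, footprint
exclusion, collision rules, and analytic oracles for initiation timing,
lone-RNAp transit and premature termination."""

import numpy as np
import pytest

from prokexpress import (GeneSequence, KineticParameters, Simulation,
                         annotate_site, generate_random_gene)
from prokexpress.transcription import (ACTIVATED, ARRESTED, PAUSED, STEPPING,
                                       RnapState)
from prokexpress.translation import RibosomeState, TranslationParameters


def quiet_params(**over):
    """Side-reaction-free transcription, translation switched off."""
    p = KineticParameters().without_elongation_side_reactions()
    return p.with_overrides(
        translation=TranslationParameters(k_trans_init=0.0), **over
    )


def engage(sim, position=None):
    """Force one RNAp through binding + clearance, optionally repositioning it."""
    rnap = RnapState(sim._next_rnap_id)
    sim._next_rnap_id += 1
    sim.free_rnap -= 1
    sim.n_oc_pending += 1
    sim.waiting_rnap = rnap
    sim.dna.promoter_free = False
    sim.engine.recompute("clearance")
    sim.engine.channel("clearance").fire()
    placed = sim.rnap_tail
    if position is not None:
        placed.position = position
        placed.compartment.advance_front(position)
    sim.engine.recompute_all()
    return placed


def rate_tags(sim, rnap):
    ch = sim.engine.channel(rnap.channel_id)
    return dict((tag, rate) for rate, tag in ch._rates())


def test_activation_is_slow_in_the_promoter_proximal_region(short_gene):
    sim = Simulation(short_gene, quiet_params(), seed=0)
    r = engage(sim, position=10)
    r.phase = STEPPING
    assert rate_tags(sim, r) == {"activate": 30.0}
    r.position = 11
    assert rate_tags(sim, r) == {"activate": 114.0}


def test_elongation_requires_a_free_footprint_ahead(short_gene):
    sim = Simulation(short_gene, quiet_params(), seed=0)
    leader = engage(sim, position=56)
    trailer = engage(sim, position=30)
    leader.phase = ACTIVATED
    trailer.phase = ACTIVATED
    sim.engine.recompute_all()
    # target 31, leader at 56: gap 25 => allowed, exactly at the footprint
    assert "elongate" in rate_tags(sim, trailer)
    leader.position = 55
    sim.engine.recompute_all()
    assert "elongate" not in rate_tags(sim, trailer)
    sim.validate()


def test_promoter_clearance_blocked_until_start_region_is_free(short_gene):
    sim = Simulation(short_gene, quiet_params(), seed=0)
    first = engage(sim)
    assert first.position == 1
    # stage a second RNAp waiting at the promoter
    waiting = RnapState(99)
    sim.free_rnap -= 1
    sim.n_oc_pending += 1
    sim.waiting_rnap = waiting
    sim.dna.promoter_free = False
    sim.engine.recompute_all()
    clearance = sim.engine.channel("clearance")
    assert clearance.propensity() == 0.0
    first.position = 25
    sim.engine.recompute_all()
    assert clearance.propensity() == 0.0
    first.position = 26
    first.compartment.advance_front(26)
    sim.engine.recompute_all()
    assert clearance.propensity() == pytest.approx(114.0)


def test_collision_rules_need_abutting_footprints(short_gene):
    params = KineticParameters().with_overrides(
        translation=TranslationParameters(k_trans_init=0.0))
    sim = Simulation(short_gene, params, seed=0)
    leader = engage(sim, position=60)
    trailer = engage(sim, position=35)  # 35 + 25 == 60: abutting
    leader.phase = PAUSED
    leader.release_rate = 1.0 / 3.0
    leader.collision_releasable = True
    leader.resume_phase = ACTIVATED
    trailer.phase = ACTIVATED
    sim.engine.recompute_all()
    assert rate_tags(sim, leader)["collision_release"] == pytest.approx(114.0)
    assert rate_tags(sim, trailer)["collision_pause"] == pytest.approx(114.0)
    # separate them: both collision channels vanish
    trailer.position = 34
    trailer.compartment.advance_front(34)
    sim.engine.recompute_all()
    assert "collision_release" not in rate_tags(sim, leader)
    assert "collision_pause" not in rate_tags(sim, trailer)


def test_three_rnap_chain_propagates_collision_pausing(short_gene):
    params = KineticParameters().with_overrides(
        translation=TranslationParameters(k_trans_init=0.0))
    sim = Simulation(short_gene, params, seed=0)
    head = engage(sim, position=80)
    middle = engage(sim, position=55)
    tail = engage(sim, position=30)
    head.phase = PAUSED
    head.release_rate = 1.0 / 3.0
    head.collision_releasable = True
    head.resume_phase = ACTIVATED
    middle.phase = ACTIVATED
    tail.phase = ACTIVATED
    sim.engine.recompute_all()
    assert "collision_pause" in rate_tags(sim, middle)
    # middle gets collision-paused; the tail can now be collision-paused too
    ch_middle = sim.engine.channel(middle.channel_id)
    ch_middle._do_collision_pause()
    assert middle.phase == PAUSED
    assert "collision_pause" in rate_tags(sim, tail)
    # once the head releases and steps away, the middle one can be
    # collision-released by the still-active tail
    head.phase = ACTIVATED
    head.position = 81
    head.compartment.advance_front(81)
    sim.engine.recompute_all()
    assert rate_tags(sim, middle)["collision_release"] == pytest.approx(114.0)
    sim.validate()


def test_arrests_are_not_released_by_collisions(short_gene):
    sim = Simulation(short_gene, quiet_params(), seed=0)
    leader = engage(sim, position=60)
    trailer = engage(sim, position=35)
    leader.phase = ARRESTED
    leader.release_rate = 1.0 / 100.0
    leader.collision_releasable = False
    trailer.phase = ACTIVATED
    sim.engine.recompute_all()
    tags = rate_tags(sim, leader)
    assert tags == {"release": pytest.approx(0.01)}
    # the arrested leader blocks the trailer completely
    assert "elongate" not in rate_tags(sim, trailer)


def test_pyrophosphorolysis_boundaries_and_ribosome_block(short_gene):
    params = KineticParameters(k_p=0, k_ar=0, k_ec=0, k_pre=0,
                               translation=TranslationParameters(k_trans_init=0.0))
    sim = Simulation(short_gene, params, seed=0)
    r = engage(sim, position=1)
    r.phase = ACTIVATED
    sim.engine.recompute_all()
    assert "pyro" not in rate_tags(sim, r)  # nucleotide 1: nowhere to go back
    r.position = 50
    comp = r.compartment
    comp.advance_front(50)  # front = 37
    sim.engine.recompute_all()
    assert "pyro" in rate_tags(sim, r)
    # park a ribosome on the ribonucleotide that retraction would remove
    rib = RibosomeState(0, comp)
    rib.position = comp.front - 10  # footprint reaches front
    comp.rib_head = comp.rib_tail = rib
    comp.n_bound = 1
    assert "pyro" not in rate_tags(sim, r)
    rib.position = comp.front - 16  # footprint clear of the front
    assert "pyro" in rate_tags(sim, r)
    # blocked as well when the trailing footprint would overlap another RNAp
    trailer = engage(sim, position=26)
    r.position = 51
    comp.advance_front(51)
    comp.rib_head = comp.rib_tail = None
    comp.n_bound = 0
    r.phase = ACTIVATED
    sim.engine.recompute_all()
    assert "pyro" not in rate_tags(sim, r)  # 50 - 26 < 25


def test_mean_initiation_interval_is_binding_plus_open_complex(short_gene):
    sim = Simulation(short_gene, quiet_params(), seed=5)
    _, log = sim.run(500 * 43.0, sample_interval=1000.0)
    times = log.times_of("transcription_initiation")
    assert times.size > 400
    intervals = np.diff(times)
    expected = 1.0 / (0.015 * 28) + 40.0 + 1.0 / 114.0
    se = intervals.std(ddof=1) / np.sqrt(intervals.size)
    # small bias: engaged RNAps deplete the free pool slightly
    assert abs(intervals.mean() - expected) < 3 * se + 0.3


def test_lone_rnap_transit_matches_the_two_stage_analytic_sum():
    gene = generate_random_gene(100, seed=17)
    p = quiet_params()
    sim = Simulation(gene, p, seed=8)
    _, log = sim.run(320 * 43.0, sample_interval=2000.0)
    starts = {}
    transits = []
    for t, e, c in zip(log.times, log.event_types, log.compartment_ids):
        if e == "transcription_initiation":
            starts[c] = t
        elif e == "transcription_completion":
            transits.append(t - starts.pop(c))
    transits = np.array(transits)
    assert transits.size >= 280
    L = gene.length
    ka = np.where(np.arange(1, L + 1) <= 10, p.k_a_near, p.k_a_far)
    rates = np.concatenate([ka, np.full(L - 1, p.k_m), [p.k_f]])
    mean = (1 / rates).sum()
    var = (1 / rates**2).sum()
    mu4 = 3 * var**2 + (6 / rates**4).sum()
    n = transits.size
    assert abs(transits.mean() - mean) < 3 * np.sqrt(var / n)
    se_var = np.sqrt((mu4 - var**2) / n)
    assert abs(transits.var(ddof=1) - var) < 3 * se_var


def test_premature_termination_frequency_matches_the_stage_competition():
    gene = generate_random_gene(100, seed=18)
    p = quiet_params(k_pre=0.01)
    sim = Simulation(gene, p, seed=12)
    _, log = sim.run(800 * 43.0, sample_interval=2000.0)
    n_init = log.count("transcription_initiation")
    n_pre = log.count("premature_termination")
    n_done = log.count("transcription_completion")
    assert n_init >= 700
    # exact competition: survive each activated stage against k_pre
    L = gene.length
    p_survive = (114.0 / (114.0 + 0.01)) ** (L - 1) * (2.0 / (2.0 + 0.01))
    expected = 1.0 - p_survive
    finished = n_pre + n_done
    frac = n_pre / finished
    se = np.sqrt(expected * (1 - expected) / finished)
    assert abs(frac - expected) < 3 * se


def test_annotated_site_triggers_with_its_probability(short_gene):
    annotate_site(short_gene, 45, "long_pause", 0.7, 5.0)
    sim = Simulation(short_gene, quiet_params(), seed=3, k_eff_multiplier=2.0,
                     log_types=frozenset({"site_arrival", "site_pause"}))
    sim.run(600 * 45.0, sample_interval=2000.0)
    arrivals = sim.log.count("site_arrival")
    pauses = sim.log.count("site_pause")
    assert arrivals >= 500
    se = np.sqrt(0.7 * 0.3 / arrivals)
    assert abs(pauses / arrivals - 0.7) < 3 * se


def test_probability_zero_site_never_triggers(short_gene):
    annotate_site(short_gene, 45, "long_pause", 0.0, 500.0)
    sim = Simulation(short_gene, quiet_params(), seed=3,
                     log_types=frozenset({"site_arrival", "site_pause"}))
    sim.run(5000.0, sample_interval=1000.0)
    assert sim.log.count("site_arrival") > 50
    assert sim.log.count("site_pause") == 0
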