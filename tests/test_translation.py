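"""Translation model: RBS gating, lone-ribosome transit oracle,
back-translocation slowdown, drop-off and trans-translation bookkeeping."""

import numpy as np
import pytest

from prokexpress import (GeneSequence, KineticParameters, Simulation)
from prokexpress.transcription import ACTIVATED
from prokexpress.translation import TranslationParameters
from conftest import drain
from test_transcription import engage


def fast_params(**tp_over):
    """Quiet transcription, uniform-fast translation without rescue paths."""
    tp = TranslationParameters(k_bt=0.0, k_drop=0.0, k_tt=0.0, **tp_over)
    return KineticParameters(k_dr=0.0).without_elongation_side_reactions() \
        .with_overrides(translation=tp)


def completed_transits(log, t_min=0.0):
    starts = {}
    transits = []
    for t, e, c, d in zip(log.times, log.event_types, log.compartment_ids,
                          log.details):
        if e == "translation_initiation":
            starts[(c, d)] = t
        elif e == "translation_completion" and (c, d) in starts:
            t0 = starts.pop((c, d))
            if t0 >= t_min:
                transits.append(t - t0)
    return np.array(transits)


def single_strand_sim(gene, params, seed):
    """One complete, immortal mRNA strand; no further transcription."""
    sim = Simulation(gene, params, seed=seed, k_eff_multiplier=0.0)
    rnap = engage(sim)
    rnap.position = gene.length
    rnap.phase = ACTIVATED
    sim.engine.recompute_all()
    sim.engine.channel(rnap.channel_id)._do_complete()
    return sim


def test_lone_ribosome_transit_matches_the_stage_sum_oracle(fast_gene):
    p = fast_params(k_trans_init=0.1)
    sim = single_strand_sim(fast_gene, p, seed=20)
    _, log = sim.run(4200.0, sample_interval=2000.0)
    transits = completed_transits(log, t_min=30.0)
    assert transits.size >= 330
    n_act = fast_gene.n_codons - 1
    mean = n_act * (1 / 35.0 + 3 / 1000.0) + 0.5
    var = n_act * (1 / 35.0**2 + 3 / 1000.0**2) + 0.25
    assert abs(transits.mean() - mean) < 3 * np.sqrt(var / transits.size)
    mu4 = 3 * var**2 + n_act * (6 / 35.0**4 + 3 * 6 / 1000.0**4) + 6 / 2.0**4
    se_var = np.sqrt((mu4 - var**2) / transits.size)
    assert abs(transits.var(ddof=1) - var) < 3 * se_var


@pytest.mark.parametrize("k_bt_values", [(0.0, 1.5, 15.0)])
def test_back_translocation_slows_net_elongation(fast_gene, k_bt_values):
    means = []
    for k_bt in k_bt_values:
        p = fast_params(k_trans_init=0.05)
        p = p.with_overrides(translation=p.translation.with_overrides(k_bt=k_bt))
        sim = single_strand_sim(fast_gene, p, seed=21)
        _, log = sim.run(5000.0, sample_interval=2500.0)
        transits = completed_transits(log, t_min=30.0)
        assert transits.size > 150
        means.append(transits.mean())
    no_bt_mean = (fast_gene.n_codons - 1) * (1 / 35.0 + 3 / 1000.0) + 0.5
    assert means[0] < means[1] < means[2]
    assert means[2] > 1.5 * no_bt_mean


def test_rbs_occlusion_gates_the_next_initiation(fast_gene):
    sim = Simulation(fast_gene, fast_params(k_trans_init=0.33), seed=1)
    rnap = engage(sim)
    rnap.position = fast_gene.length
    rnap.phase = ACTIVATED
    comp = rnap.compartment
    sim.engine.recompute_all()
    sim.engine.channel(rnap.channel_id)._do_complete()
    assert comp.competent and comp.front == fast_gene.length
    comp_ch = sim.engine.channel(comp.channel_id)
    tags = dict((tag, r) for r, tag in comp_ch._rates())
    assert tags.get("initiate") == pytest.approx(0.33)
    comp_ch._do_initiate()
    rib = comp.rib_tail
    assert rib.position == 3
    # a ribosome covering any ribonucleotide of the RBS blocks initiation
    tags = dict((tag, r) for r, tag in comp_ch._rates())
    assert "initiate" not in tags
    rib.position = 46  # footprint 31..61 still touches the RBS edge
    tags = dict((tag, r) for r, tag in comp_ch._rates())
    assert "initiate" not in tags
    rib.position = 47  # footprint 32..62: RBS free again
    tags = dict((tag, r) for r, tag in comp_ch._rates())
    assert tags.get("initiate") == pytest.approx(0.33)


def test_ribosomes_stall_at_the_exposure_front(fast_gene):
    sim = Simulation(fast_gene, fast_params(k_trans_init=0.33), seed=2)
    rnap = engage(sim, position=50)
    comp = rnap.compartment
    assert comp.front == 37
    assert comp.competent
    comp_ch = sim.engine.channel(comp.channel_id)
    comp_ch._do_initiate()
    rib = comp.rib_tail
    rib.position = comp.front  # at the front: next ribonucleotide untranscribed
    rib.phase = 1  # TRANSLOCATING
    rib.tloc_remaining = 2
    sim.engine.recompute_all()
    rib_ch = sim.engine.channel(rib.channel_id)
    assert rib_ch.propensity() == 0.0  # only drop-off would apply, but k_drop=0
    comp.advance_front(51)
    assert rib_ch.propensity() == pytest.approx(1000.0)


def test_drop_off_frequency_matches_the_continuous_hazard(fast_gene):
    p = fast_params(k_trans_init=0.2)
    p = p.with_overrides(translation=p.translation.with_overrides(k_drop=0.02))
    sim = single_strand_sim(fast_gene, p, seed=23)
    _, log = sim.run(5000.0, sample_interval=2500.0)
    n_init = log.count("translation_initiation")
    n_drop = log.count("ribosome_dropoff")
    n_done = log.count("translation_completion")
    assert n_init >= 800
    n_act = fast_gene.n_codons - 1
    log_survive = (n_act * np.log(35.0 / 35.02)
                   + 3 * n_act * np.log(1000.0 / 1000.02)
                   + np.log(2.0 / 2.02))
    expected = 1.0 - np.exp(log_survive)
    finished = n_drop + n_done
    se = np.sqrt(expected * (1 - expected) / finished)
    assert abs(n_drop / finished - expected) < 3 * se


def test_trans_translation_releases_every_bound_ribosome_at_once(short_gene):
    p = KineticParameters().with_overrides(
        translation=TranslationParameters(k_tt=0.02))
    sim = Simulation(short_gene, p, seed=3, n_ribosomes=60)
    series, log = sim.run(4000.0, sample_interval=50.0, validate_every=4)
    tt_events = [(t, int(d)) for t, e, d in
                 zip(log.times, log.event_types, log.details)
                 if e == "trans_translation"]
    assert len(tt_events) >= 3
    destroyed = set(log.times_of("compartment_destroyed"))
    for t, n in tt_events:
        assert n >= 1
        assert t in destroyed  # the strand dies at the same instant
    sim.validate()


def test_every_initiation_is_matched_by_exactly_one_outcome(short_gene):
    sim = Simulation(short_gene, seed=4, n_ribosomes=80)
    _, log = sim.run(6000.0, sample_interval=100.0)
    n_init = log.count("translation_initiation")
    n_done = log.count("translation_completion")
    n_drop = log.count("ribosome_dropoff")
    n_tt = sum(int(d) for e, d in zip(log.event_types, log.details)
               if e == "trans_translation")
    assert n_init > 500
    assert n_init == n_done + n_drop + n_tt + sim.total_bound


def test_stalled_ribosomes_on_dead_strands_are_eventually_cleared():
    from prokexpress import generate_random_gene

    gene = generate_random_gene(60, seed=30)
    p = KineticParameters(k_pre=0.05).with_overrides(
        translation=TranslationParameters(k_drop=0.002, k_tt=0.002))
    sim = Simulation(gene, p, seed=31, n_ribosomes=100)
    sim.run(20_000.0, sample_interval=500.0, validate_every=5)
    assert sim.log.count("premature_termination") > 10
    drain(sim)
    assert len(sim.compartments) == 0
    assert sim.total_bound == 0
    assert sim.free_rib == 100
    sim.validate()
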