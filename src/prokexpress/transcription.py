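"""Nucleotide-level transcription: initiation with open-complex formation,
promoter clearance, stepwise elongation/activation, ubiquitous and
collision-induced pausing, arrests, editing, premature termination,
pyrophosphorolysis, completion, and first-order functional-mRNA degradation.

The DNA template is a 1-based nucleotide lattice.  Each RNA polymerase
(RNAp) occupies ``2*delta_rnap + 1 = 25`` nucleotides around its active site;
footprints never overlap, which is what forbids overtaking.  An RNAp cycles
between a post-move "stepping" state and an "activated" state (the activation
rate is slower over the first 10 promoter-proximal nucleotides); only an
activated RNAp can elongate, pause, arrest, edit, terminate prematurely or
slide backwards by pyrophosphorolysis.

Transcription initiation is a two-stage event: a bimolecular RNAp-promoter
binding (propensity ``k_eff_multiplier * k_init * [free RNAp]``) followed by a
normally distributed open-complex delay (40 +/- 4 s, truncated at zero), after
which the RNAp waits at nucleotide 1 for the start region to be free and
clears the promoter at rate ``k_m``, freeing it for the next initiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .ssa import Channel
from .translation import TranslationParameters

__all__ = [
    "KineticParameters",
    "DnaTemplate",
    "RnapState",
    "PromoterChannel",
    "ClearanceChannel",
    "RnapChannel",
    "STEPPING",
    "ACTIVATED",
    "PAUSED",
    "ARRESTED",
    "EDITING",
]

STEPPING = 0    # just moved; must activate before anything else
ACTIVATED = 1
PAUSED = 2
ARRESTED = 3
EDITING = 4

PHASE_NAMES = {STEPPING: "stepping", ACTIVATED: "activated", PAUSED: "paused",
               ARRESTED: "arrested", EDITING: "editing"}


@dataclass(frozen=True)
class KineticParameters:
    """All rate constants and delays of the transcription reactions, the RNAp
    footprint half-width, and the nested translation parameters.

    Rates are in 1/s, delays and mean dwell times in seconds.
    """

    k_init: float = 0.015          # RNAp-promoter binding, per free RNAp
    tau_oc_mean: float = 40.0      # open-complex formation delay, normal
    tau_oc_sd: float = 4.0
    k_m: float = 114.0             # clearance, elongation, collision reactions
    k_a_far: float = 114.0         # activation beyond the promoter-proximal region
    k_a_near: float = 30.0         # activation at nucleotides 1..10 (inclusive)
    slow_activation_boundary: int = 10
    k_p: float = 0.55              # ubiquitous pausing
    tau_p: float = 3.0             # mean ubiquitous pause dwell
    k_ar: float = 0.00028          # arrest
    tau_ar: float = 100.0          # mean arrest dwell
    k_ec: float = 0.008            # editing
    tau_c: float = 5.0             # mean editing dwell
    k_pre: float = 0.00019         # premature termination
    k_pyro: float = 0.75           # pyrophosphorolysis (one nt backwards)
    k_f: float = 2.0               # completion / RNAp release at the last nt
    k_dr: float = 0.011            # functional mRNA degradation
    delta_rnap: int = 12
    translation: TranslationParameters = field(default_factory=TranslationParameters)

    def __post_init__(self):
        for name in ("k_init", "k_m", "k_a_far", "k_a_near", "k_p", "k_ar",
                     "k_ec", "k_pre", "k_pyro", "k_f", "k_dr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("tau_p", "tau_ar", "tau_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.delta_rnap < 0:
            raise ValueError("delta_rnap must be non-negative")

    @property
    def footprint(self) -> int:
        """Nucleotides occupied by one RNAp (2*delta_rnap + 1)."""
        return 2 * self.delta_rnap + 1

    def with_overrides(self, **kwargs) -> "KineticParameters":
        """Copy with named rates replaced; translation rates via ``translation=``."""
        return replace(self, **kwargs)

    def without_elongation_side_reactions(self) -> "KineticParameters":
        """Pure two-stage elongation: pausing, arrests, editing, premature
        termination and pyrophosphorolysis switched off.  Used for analytic
        transit-time oracles."""
        return replace(self, k_p=0.0, k_ar=0.0, k_ec=0.0, k_pre=0.0, k_pyro=0.0)


class DnaTemplate:
    """The nucleotide lattice of one gene plus the promoter state."""

    __slots__ = ("length", "annotations", "promoter_free")

    def __init__(self, gene):
        self.length = gene.length
        self.annotations = gene.annotations
        self.promoter_free = True


class RnapState:
    """One RNA polymerase engaged on the template.

    ``ahead`` / ``behind`` link the RNAps in template order (ahead = closer to
    the 3' end); exclusion plus these links make overtaking impossible.
    ``release_rate`` holds the memoryless escape rate of the current halted
    phase (pause, arrest or editing); ``collision_releasable`` distinguishes
    ubiquitous pauses (released by a trailing collision) from
    sequence-specific long pauses and arrests (spontaneous release only).
    """

    __slots__ = ("id", "position", "phase", "release_rate", "collision_releasable",
                 "resume_phase", "compartment", "ahead", "behind", "channel_id")

    def __init__(self, rnap_id: int):
        self.id = rnap_id
        self.position = 1
        self.phase = STEPPING
        self.release_rate = 0.0
        self.collision_releasable = True
        self.resume_phase = ACTIVATED
        self.compartment = None
        self.ahead = None
        self.behind = None
        self.channel_id = None


class PromoterChannel(Channel):
    """Reaction (1): RNAp-promoter binding followed by the open-complex delay."""

    __slots__ = ("sim",)

    id = "promoter"

    def __init__(self, sim):
        self.sim = sim

    def propensity(self) -> float:
        sim = self.sim
        if not sim.dna.promoter_free:
            return 0.0
        return sim.k_eff_multiplier * sim.params.k_init * sim.free_rnap

    def fire(self) -> None:
        sim = self.sim
        sim.free_rnap -= 1
        sim.n_oc_pending += 1
        sim.dna.promoter_free = False
        sim.log.append(sim.engine.time, "rnap_bind")
        tau = sim.sample_tau_oc()
        sim.engine.schedule_delayed(sim._open_complex_done, tau)
        sim.engine.recompute(self.id)


class ClearanceChannel(Channel):
    """Reaction (2): promoter clearance once the start region is unobstructed."""

    __slots__ = ("sim",)

    id = "clearance"

    def __init__(self, sim):
        self.sim = sim

    def propensity(self) -> float:
        sim = self.sim
        if sim.waiting_rnap is None:
            return 0.0
        tail = sim.rnap_tail
        if tail is not None and tail.position < 1 + sim.params.footprint:
            return 0.0  # previous RNAp footprint still covers the start region
        return sim.params.k_m

    def fire(self) -> None:
        sim = self.sim
        rnap = sim.waiting_rnap
        sim.waiting_rnap = None
        sim.n_oc_pending -= 1
        sim.dna.promoter_free = True  # the next initiation binding may begin
        rnap.position = 1
        rnap.phase = STEPPING
        tail = sim.rnap_tail
        rnap.ahead = tail
        if tail is not None:
            tail.behind = rnap
        sim.rnap_tail = rnap
        sim.rnaps[rnap.id] = rnap
        sim._create_compartment(rnap)
        channel = RnapChannel(sim, rnap)
        rnap.channel_id = sim.engine.add_channel(channel)
        sim.log.append(sim.engine.time, "transcription_initiation", rnap.compartment.id, 1)
        sim._maybe_trigger_site(rnap)
        eng = sim.engine
        eng.recompute(self.id)
        eng.recompute(PromoterChannel.id)
        if rnap.ahead is not None:
            eng.recompute(rnap.ahead.channel_id)


class RnapChannel(Channel):
    """Grouped reaction channel of one engaged RNAp (reactions 3-12).

    As with ribosomes, the mutually exclusive sub-reactions available in the
    current phase are summed into one propensity and disambiguated on firing.
    """

    __slots__ = ("sim", "rnap")

    def __init__(self, sim, rnap: RnapState):
        self.id = ("rnap", rnap.id)
        self.sim = sim
        self.rnap = rnap

    # -------------------------------------------------------------- gating
    def _abuts_ahead(self) -> bool:
        r = self.rnap
        return (r.ahead is not None and
                r.position + self.sim.params.footprint == r.ahead.position)

    def _abutted_by_active_trailer(self) -> bool:
        r = self.rnap
        return (r.behind is not None and
                r.behind.position + self.sim.params.footprint == r.position and
                r.behind.phase == ACTIVATED)

    def _forward_clear(self) -> bool:
        r = self.rnap
        return (r.ahead is None or
                r.ahead.position - (r.position + 1) >= self.sim.params.footprint)

    def _backward_clear(self) -> bool:
        r = self.rnap
        sim = self.sim
        if r.position <= 1:
            return False
        if (r.behind is not None and
                (r.position - 1) - r.behind.position < sim.params.footprint):
            return False
        # Retracting the trailing ribonucleotide is forbidden while a ribosome
        # occupies it; in that case the backward move is blocked outright.
        comp = r.compartment
        front = comp.front
        if front > 0 and front == r.position - sim.params.delta_rnap - 1:
            head = comp.rib_head
            if head is not None and head.position + sim.tp.delta_rib >= front:
                return False
        return True

    def _rates(self):
        r = self.rnap
        p = self.sim.params
        phase = r.phase
        out = []
        if phase == STEPPING:
            k_a = p.k_a_near if r.position <= p.slow_activation_boundary else p.k_a_far
            out.append((k_a, "activate"))
        elif phase == ACTIVATED:
            if r.position < self.sim.dna.length:
                if self._forward_clear():
                    out.append((p.k_m, "elongate"))
            else:
                out.append((p.k_f, "complete"))
            if p.k_p > 0.0:
                out.append((p.k_p, "pause"))
            if self._abuts_ahead() and r.ahead.phase == PAUSED:
                out.append((p.k_m, "collision_pause"))
            if p.k_ar > 0.0:
                out.append((p.k_ar, "arrest"))
            if p.k_ec > 0.0:
                out.append((p.k_ec, "edit"))
            if p.k_pre > 0.0:
                out.append((p.k_pre, "premature"))
            if p.k_pyro > 0.0 and self._backward_clear():
                out.append((p.k_pyro, "pyro"))
        elif phase == PAUSED:
            out.append((r.release_rate, "release"))
            if r.collision_releasable and self._abutted_by_active_trailer():
                out.append((p.k_m, "collision_release"))
        else:  # ARRESTED or EDITING: spontaneous release only
            out.append((r.release_rate, "release"))
        return out

    def propensity(self) -> float:
        return sum(rate for rate, _ in self._rates())

    def fire(self) -> None:
        rates = self._rates()
        total = sum(rate for rate, _ in rates)
        u = self.sim.rng.uniform() * total
        acc = 0.0
        tag = rates[-1][1]
        for rate, t in rates:
            acc += rate
            if u <= acc:
                tag = t
                break
        getattr(self, "_do_" + tag)()

    # -------------------------------------------------------------- helpers
    def _refresh_neighbours(self, clearance: bool = False) -> None:
        eng = self.sim.engine
        r = self.rnap
        eng.recompute(self.id)
        if r.ahead is not None:
            eng.recompute(r.ahead.channel_id)
        if r.behind is not None:
            eng.recompute(r.behind.channel_id)
        if clearance and r.behind is None:
            eng.recompute(ClearanceChannel.id)

    def _halt(self, phase: int, release_rate: float, releasable: bool,
              resume: int) -> None:
        r = self.rnap
        r.phase = phase
        r.release_rate = release_rate
        r.collision_releasable = releasable
        r.resume_phase = resume

    # -------------------------------------------------------------- effects
    def _do_activate(self) -> None:
        self.rnap.phase = ACTIVATED
        self._refresh_neighbours()

    def _do_elongate(self) -> None:
        sim = self.sim
        r = self.rnap
        r.position += 1
        r.phase = STEPPING
        if sim.log.wants("rnap_move"):
            sim.log.append(sim.engine.time, "rnap_move", r.compartment.id,
                           r.position, str(r.id))
        r.compartment.advance_front(r.position)
        sim._maybe_trigger_site(r)
        self._refresh_neighbours(clearance=True)

    def _do_pause(self) -> None:
        sim = self.sim
        self._halt(PAUSED, 1.0 / sim.params.tau_p, True, ACTIVATED)
        if sim.log.wants("pause"):
            sim.log.append(sim.engine.time, "pause", self.rnap.compartment.id,
                           self.rnap.position)
        self._refresh_neighbours()

    def _do_collision_pause(self) -> None:
        sim = self.sim
        self._halt(PAUSED, 1.0 / sim.params.tau_p, True, ACTIVATED)
        if sim.log.wants("pause"):
            sim.log.append(sim.engine.time, "pause", self.rnap.compartment.id,
                           self.rnap.position, "collision")
        self._refresh_neighbours()

    def _do_release(self) -> None:
        r = self.rnap
        sim = self.sim
        if sim.log.wants("halt_release"):
            sim.log.append(sim.engine.time, "halt_release", r.compartment.id,
                           r.position, PHASE_NAMES[r.phase])
        r.phase = r.resume_phase
        r.release_rate = 0.0
        self._refresh_neighbours()

    def _do_collision_release(self) -> None:
        self._do_release()

    def _do_arrest(self) -> None:
        sim = self.sim
        self._halt(ARRESTED, 1.0 / sim.params.tau_ar, False, ACTIVATED)
        if sim.log.wants("arrest"):
            sim.log.append(sim.engine.time, "arrest", self.rnap.compartment.id,
                           self.rnap.position)
        self._refresh_neighbours()

    def _do_edit(self) -> None:
        sim = self.sim
        self._halt(EDITING, 1.0 / sim.params.tau_c, False, ACTIVATED)
        if sim.log.wants("edit"):
            sim.log.append(sim.engine.time, "edit", self.rnap.compartment.id,
                           self.rnap.position)
        self._refresh_neighbours()

    def _do_pyro(self) -> None:
        sim = self.sim
        r = self.rnap
        comp = r.compartment
        old_front_pos = r.position - sim.params.delta_rnap - 1
        r.position -= 1
        r.phase = STEPPING
        if comp.front > 0 and comp.front == old_front_pos:
            comp.retract_front()
        if sim.log.wants("pyrophosphorolysis"):
            sim.log.append(sim.engine.time, "pyrophosphorolysis", comp.id, r.position)
        self._refresh_neighbours(clearance=True)

    def _do_premature(self) -> None:
        sim = self.sim
        r = self.rnap
        comp = r.compartment
        sim.log.append(sim.engine.time, "premature_termination", comp.id, r.position)
        sim._detach_rnap(r)
        comp.transcription_ended(premature=True)
        comp.maybe_destroy()

    def _do_complete(self) -> None:
        sim = self.sim
        r = self.rnap
        comp = r.compartment
        sim.log.append(sim.engine.time, "transcription_completion", comp.id, r.position)
        sim._detach_rnap(r)
        comp.transcription_ended(premature=False)
        comp.maybe_destroy()
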