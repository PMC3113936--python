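"""The transcription-translation bridge.

Every RNAp that clears the promoter drags a nascent RNA with it; here that
RNA is an :class:`RnaCompartment` — a private reaction compartment created at
run time, holding the strand's exposure front, its bound ribosomes and its
own copies of the translation reaction channels.  The compartment is
destroyed (its channels removed from the engine) when the strand is gone:
after degradation or premature termination once the last ribosome leaves, or
immediately on trans-translation.

Exposure front
    Ribonucleotide ``rnap_position - delta_rnap - 1`` is the highest one free
    of the RNAp's footprint; the front advances with the RNAp (retreating at
    most one nucleotide under pyrophosphorolysis, and only when no ribosome
    sits on the retracted ribonucleotide).  Translation initiation becomes
    possible once the ribosome binding site — the first ``2*delta_rib + 1``
    ribonucleotides — is fully exposed.

mRNA observable
    The mRNA count reported in time series is the number of
    translation-competent strands: RBS exposed and not degradation-marked.
    It increments when the front first clears the RBS and decrements when
    degradation (or premature termination, which destroys the RBS region, or
    trans-translation) strikes; ribosomes finishing their run on a marked
    strand do not count towards it.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .sequences import GeneSequence
from .ssa import BufferedRNG, Channel, DelayedSSA, EventLog
from .transcription import (ACTIVATED, ARRESTED, EDITING, PAUSED, STEPPING,
                            ClearanceChannel, DnaTemplate, KineticParameters,
                            PromoterChannel, RnapChannel, RnapState)
from .translation import (AWAITING_ACTIVATION, ProteinPoolChannel,
                          RibosomeChannel, RibosomeState, TranslationParameters)

__all__ = ["RnaCompartment", "CompartmentChannel", "Simulation", "DEFAULT_LOG_TYPES"]

ELONGATING = "elongating"
COMPLETE = "complete"
PREMATURE = "prematurely_terminated"

#: Event types recorded by default: per-molecule lifecycle events, cheap and
#: informative.  Per-nucleotide movement, per-codon activation and protein
#: pool events must be requested explicitly.
DEFAULT_LOG_TYPES = frozenset({
    "rnap_bind", "transcription_initiation", "transcription_completion",
    "premature_termination", "translation_initiation", "translation_completion",
    "ribosome_dropoff", "trans_translation", "mrna_birth",
    "mrna_degradation_marked", "compartment_destroyed",
    "site_arrival", "site_pause", "site_arrest",
})


class RnaCompartment:
    """One nascent/complete RNA strand and its private translation machinery."""

    __slots__ = ("id", "sim", "gene", "front", "status", "degradation_marked",
                 "competent", "rib_head", "rib_tail", "n_bound", "channel_id",
                 "proteins_completed", "destroyed", "created_time", "rnap",
                 "activation_rates", "rbs_end", "rib_footprint")

    def __init__(self, comp_id: int, sim: "Simulation", rnap: RnapState):
        self.id = comp_id
        self.sim = sim
        self.gene = sim.gene
        self.front = 0
        self.status = ELONGATING
        self.degradation_marked = False
        self.competent = False
        self.rib_head = None   # ribosome furthest from the RBS (highest position)
        self.rib_tail = None   # ribosome nearest the RBS
        self.n_bound = 0
        self.proteins_completed = 0
        self.destroyed = False
        self.created_time = sim.engine.time
        self.rnap = rnap
        self.activation_rates = sim.activation_rates
        self.rbs_end = sim.tp.footprint          # ribonucleotide 31 by default
        self.rib_footprint = sim.tp.footprint
        self.channel_id = sim.engine.add_channel(CompartmentChannel(sim, self))

    # ------------------------------------------------------------ front
    def advance_front(self, rnap_position: int) -> None:
        new_front = rnap_position - self.sim.params.delta_rnap - 1
        if new_front <= self.front:
            return
        old_front = self.front
        self.front = new_front
        self._front_changed(old_front)

    def set_front(self, value: int) -> None:
        old = self.front
        self.front = value
        if value > old:
            self._front_changed(old)

    def retract_front(self) -> None:
        """Single-ribonucleotide retraction under pyrophosphorolysis; the
        caller has already verified the retracted position is ribosome-free."""
        self.front -= 1
        head = self.rib_head
        if head is not None:
            self.sim.engine.recompute(head.channel_id)

    def _front_changed(self, old_front: int) -> None:
        sim = self.sim
        head = self.rib_head
        # unblock a ribosome stalled at the old front
        if head is not None and head.position >= old_front:
            sim.engine.recompute(head.channel_id)
        if (not self.competent and not self.degradation_marked
                and self.front >= self.rbs_end):
            self.competent = True
            sim.mrna_count += 1
            sim.log.append(sim.engine.time, "mrna_birth", self.id, self.front)
            sim.engine.recompute(self.channel_id)

    # ------------------------------------------------------------ lifecycle
    def transcription_ended(self, premature: bool) -> None:
        self.rnap = None
        if premature:
            self.status = PREMATURE
            # The frozen strand can never complete its RBS-to-stop message;
            # treat its RBS region as destroyed so no new ribosome binds and
            # the compartment drains and dies.
            self.mark_degraded()
        else:
            self.status = COMPLETE
            self.set_front(self.gene.length)
            self.sim.engine.recompute(self.channel_id)

    def mark_degraded(self) -> None:
        if self.degradation_marked:
            return
        self.degradation_marked = True
        sim = self.sim
        if self.competent:
            self.competent = False
            sim.mrna_count -= 1
        sim.engine.recompute(self.channel_id)
        # the trailing ribosome loses its back-translocation headroom
        if self.rib_tail is not None:
            sim.engine.recompute(self.rib_tail.channel_id)

    def release_ribosome(self, rib: RibosomeState) -> None:
        """Unbind one ribosome (completion, drop-off or trans-translation)."""
        sim = self.sim
        if rib.behind is not None:
            rib.behind.ahead = rib.ahead
        else:
            self.rib_tail = rib.ahead
        if rib.ahead is not None:
            rib.ahead.behind = rib.behind
        else:
            self.rib_head = rib.behind
        sim.engine.remove_channels([rib.channel_id])
        self.n_bound -= 1
        sim.total_bound -= 1
        if sim.free_rib is not None:
            sim.free_rib += 1
        eng = sim.engine
        if rib.behind is not None:
            eng.recompute(rib.behind.channel_id)
        if rib.ahead is not None:
            eng.recompute(rib.ahead.channel_id)
        eng.recompute(self.channel_id)
        # losing the lead ribosome can re-enable the RNAp's backward move
        if (rib.ahead is None and self.rnap is not None
                and rib.position + sim.tp.delta_rib >= self.front - 1):
            eng.recompute(self.rnap.channel_id)

    def maybe_destroy(self) -> None:
        if (not self.destroyed and self.degradation_marked
                and self.n_bound == 0 and self.status != ELONGATING):
            self.destroy()

    def destroy(self) -> None:
        if self.n_bound != 0:
            raise RuntimeError(
                f"compartment {self.id} destroyed with {self.n_bound} bound ribosomes"
            )
        sim = self.sim
        sim.engine.remove_channels([self.channel_id])
        del sim.compartments[self.id]
        self.destroyed = True
        sim.log.append(sim.engine.time, "compartment_destroyed", self.id)

    # ------------------------------------------------------------ queries
    def ribosomes(self) -> list[RibosomeState]:
        """Bound ribosomes ordered from the RBS towards the 3' end."""
        out = []
        rib = self.rib_tail
        while rib is not None:
            out.append(rib)
            rib = rib.ahead
        return out

    def rbs_clear(self) -> bool:
        tail = self.rib_tail
        return tail is None or tail.position - self.sim.tp.delta_rib > self.rbs_end


class CompartmentChannel(Channel):
    """Per-strand channel grouping translation initiation, functional-mRNA
    degradation, and the trans-translation hazard (rate per bound ribosome)."""

    __slots__ = ("sim", "comp")

    def __init__(self, sim: "Simulation", comp: RnaCompartment):
        self.id = ("comp", comp.id)
        self.sim = sim
        self.comp = comp

    def _rates(self):
        sim = self.sim
        comp = self.comp
        tp = sim.tp
        out = []
        if comp.competent:
            if sim.params.k_dr > 0.0:
                out.append((sim.params.k_dr, "degrade"))
            if (tp.k_trans_init > 0.0 and comp.rbs_clear()
                    and (sim.free_rib is None or sim.free_rib > 0)):
                out.append((tp.k_trans_init, "initiate"))
        if comp.n_bound > 0 and tp.k_tt > 0.0:
            out.append((tp.k_tt * comp.n_bound, "trans_translate"))
        return out

    def propensity(self) -> float:
        return sum(r for r, _ in self._rates())

    def fire(self) -> None:
        rates = self._rates()
        total = sum(r for r, _ in rates)
        u = self.sim.rng.uniform() * total
        acc = 0.0
        tag = rates[-1][1]
        for r, t in rates:
            acc += r
            if u <= acc:
                tag = t
                break
        getattr(self, "_do_" + tag)()

    def _do_initiate(self) -> None:
        sim = self.sim
        comp = self.comp
        rib = RibosomeState(sim._next_rib_id, comp)
        sim._next_rib_id += 1
        rib.ahead = comp.rib_tail
        if comp.rib_tail is not None:
            comp.rib_tail.behind = rib
        else:
            comp.rib_head = rib
        comp.rib_tail = rib
        comp.n_bound += 1
        sim.total_bound += 1
        if sim.free_rib is not None:
            sim.free_rib -= 1
        rib.channel_id = sim.engine.add_channel(RibosomeChannel(sim, rib))
        sim.log.append(sim.engine.time, "translation_initiation", comp.id,
                       rib.position, str(rib.id))
        sim.engine.recompute(self.id)

    def _do_degrade(self) -> None:
        sim = self.sim
        comp = self.comp
        sim.log.append(sim.engine.time, "mrna_degradation_marked", comp.id)
        comp.mark_degraded()
        comp.maybe_destroy()

    def _do_trans_translate(self) -> None:
        sim = self.sim
        comp = self.comp
        n = comp.n_bound
        sim.log.append(sim.engine.time, "trans_translation", comp.id, detail=str(n))
        rib = comp.rib_tail
        while rib is not None:
            sim.engine.remove_channels([rib.channel_id])
            rib = rib.ahead
        comp.rib_tail = comp.rib_head = None
        comp.n_bound = 0
        sim.total_bound -= n
        if sim.free_rib is not None:
            sim.free_rib += n
        if comp.status == ELONGATING:
            # the strand is destroyed under the polymerase: it detaches
            rnap = comp.rnap
            sim.log.append(sim.engine.time, "premature_termination", comp.id,
                           rnap.position, "trans_translation")
            sim._detach_rnap(rnap)
            comp.status = PREMATURE
            comp.rnap = None
        comp.mark_degraded()
        comp.maybe_destroy()


class Simulation:
    """Coupled stochastic transcription + translation of one gene.

    Parameters
    ----------
    gene:
        The :class:`~prokexpress.sequences.GeneSequence` to express.
    params:
        :class:`~prokexpress.transcription.KineticParameters`; defaults are
        the calibrated constants listed in the module docs.
    seed:
        Seed of the simulation's single random stream.
    n_rnap:
        Total RNAp pool (28 by default); free RNAp sets the binding propensity.
    n_ribosomes:
        Total ribosome pool; ``None`` (default) treats the pool as
        non-limiting, with translation initiation pseudo-first-order.
    k_eff / k_eff_multiplier:
        Effective transcription-initiation control.  ``k_eff_multiplier``
        scales the binding propensity directly (an effective repression
        level); ``k_eff`` instead sets the target binding rate in 1/s when the
        whole pool is free, i.e. multiplier = k_eff / (k_init * n_rnap).
    log_types:
        Event types to record (``None`` = record everything emitted); see
        :data:`DEFAULT_LOG_TYPES`.
    """

    def __init__(
        self,
        gene: GeneSequence,
        params: Optional[KineticParameters] = None,
        *,
        seed: int = 0,
        n_rnap: int = 28,
        n_ribosomes: Optional[int] = None,
        k_eff: Optional[float] = None,
        k_eff_multiplier: float = 1.0,
        log_types=DEFAULT_LOG_TYPES,
    ):
        self.gene = gene
        self.params = params if params is not None else KineticParameters()
        self.tp: TranslationParameters = self.params.translation
        self.n_rnap = int(n_rnap)
        if k_eff is not None:
            if self.params.k_init <= 0 or self.n_rnap <= 0:
                raise ValueError("k_eff requires positive k_init and n_rnap")
            k_eff_multiplier = k_eff / (self.params.k_init * self.n_rnap)
        self.k_eff_multiplier = float(k_eff_multiplier)
        self.engine = DelayedSSA(BufferedRNG(seed), state=self, auto_recompute=False)
        self.rng = self.engine.rng
        self.log = EventLog(log_types)
        self.dna = DnaTemplate(gene)
        self.activation_rates = gene.activation_rates(self.tp)

        self.free_rnap = self.n_rnap
        self.n_oc_pending = 0
        self.waiting_rnap: Optional[RnapState] = None
        self.rnap_tail: Optional[RnapState] = None
        self.rnaps: dict[int, RnapState] = {}
        self.compartments: dict[int, RnaCompartment] = {}
        self.mrna_count = 0
        self.p_prem = 0
        self.protein = 0
        self.free_rib = None if n_ribosomes is None else int(n_ribosomes)
        self.n_ribosomes = n_ribosomes
        self.total_bound = 0
        self._next_rnap_id = 0
        self._next_comp_id = 0
        self._next_rib_id = 0

        self.engine.add_channel(PromoterChannel(self))
        self.engine.add_channel(ClearanceChannel(self))
        self.protein_channel_id = self.engine.add_channel(ProteinPoolChannel(self))
        self.base_channel_count = self.engine.n_channels

    # ------------------------------------------------------------ plumbing
    def sample_tau_oc(self) -> float:
        """Open-complex delay: normal(tau_oc_mean, tau_oc_sd), re-sampled on
        the (vanishingly rare) negative draw."""
        p = self.params
        while True:
            v = self.rng.normal(p.tau_oc_mean, p.tau_oc_sd)
            if v >= 0.0:
                return v

    def _open_complex_done(self) -> None:
        rnap = RnapState(self._next_rnap_id)
        self._next_rnap_id += 1
        self.waiting_rnap = rnap
        if self.log.wants("oc_complete"):
            self.log.append(self.engine.time, "oc_complete")
        self.engine.recompute(ClearanceChannel.id)

    def _create_compartment(self, rnap: RnapState) -> RnaCompartment:
        comp = RnaCompartment(self._next_comp_id, self, rnap)
        self._next_comp_id += 1
        rnap.compartment = comp
        self.compartments[comp.id] = comp
        return comp

    def _detach_rnap(self, rnap: RnapState) -> None:
        """Remove an RNAp from the lattice and return it to the free pool."""
        if rnap.behind is not None:
            rnap.behind.ahead = rnap.ahead
        else:
            if self.rnap_tail is rnap:
                self.rnap_tail = rnap.ahead
        if rnap.ahead is not None:
            rnap.ahead.behind = rnap.behind
        del self.rnaps[rnap.id]
        self.engine.remove_channels([rnap.channel_id])
        self.free_rnap += 1
        eng = self.engine
        eng.recompute(PromoterChannel.id)
        eng.recompute(ClearanceChannel.id)
        if rnap.ahead is not None:
            eng.recompute(rnap.ahead.channel_id)
        if rnap.behind is not None:
            eng.recompute(rnap.behind.channel_id)

    def _maybe_trigger_site(self, rnap: RnapState) -> None:
        ann = self.dna.annotations.get(rnap.position)
        if ann is None:
            return
        log = self.log
        comp_id = rnap.compartment.id if rnap.compartment else -1
        log.append(self.engine.time, "site_arrival", comp_id, rnap.position, ann.kind)
        if ann.probability <= 0.0 or self.rng.uniform() >= ann.probability:
            return
        rate = 1.0 / ann.mean_duration_s
        if ann.kind == "long_pause":
            rnap.phase = PAUSED
            rnap.collision_releasable = False
            log.append(self.engine.time, "site_pause", comp_id, rnap.position)
        else:
            rnap.phase = ARRESTED
            rnap.collision_releasable = False
            log.append(self.engine.time, "site_arrest", comp_id, rnap.position)
        rnap.release_rate = rate
        rnap.resume_phase = STEPPING

    # ------------------------------------------------------------ observation
    def observe(self) -> dict:
        return {
            "mrna": self.mrna_count,
            "protein": self.protein,
            "p_prem": self.p_prem,
            "free_rnap": self.free_rnap,
            "rnap_on_template": len(self.rnaps),
            "bound_ribosomes": self.total_bound,
            "compartments": len(self.compartments),
        }

    def run(self, t_end: float, sample_interval: float = 1.0,
            validate_every: Optional[int] = None) -> tuple[pd.DataFrame, EventLog]:
        """Simulate to ``t_end``, sampling species counts on a fixed grid.

        ``validate_every`` runs the full structural-invariant check every that
        many samples (used by the test suite; it is O(molecules) per call).
        """
        callback = None
        if validate_every:
            def callback(i: int) -> None:
                if i % validate_every == 0:
                    self.validate()
        series = self.engine.run(t_end, sample_interval, observe=self.observe,
                                 callback=callback)
        return series, self.log

    # ------------------------------------------------------------ invariants
    def validate(self) -> None:
        """Assert every structural invariant of the coupled model.

        Checks RNAp ordering and footprint exclusion, ribosome ordering,
        footprints and the exposure-front bound, RNAp/ribosome conservation,
        the mRNA observable ledger, non-negative counts, and agreement of all
        cached propensities with fresh evaluations.
        """
        p = self.params
        # RNAp lattice: walk inward->outward, positions strictly increasing
        seen = 0
        r = self.rnap_tail
        prev = None
        while r is not None:
            seen += 1
            if not 1 <= r.position <= self.dna.length:
                raise AssertionError(f"RNAp {r.id} off template at {r.position}")
            if prev is not None and r.position - prev.position < p.footprint:
                raise AssertionError(
                    f"RNAp footprints overlap: {prev.id}@{prev.position} vs {r.id}@{r.position}"
                )
            prev = r
            r = r.ahead
        if seen != len(self.rnaps):
            raise AssertionError("RNAp linked list inconsistent with registry")
        if self.free_rnap + len(self.rnaps) + self.n_oc_pending != self.n_rnap:
            raise AssertionError("RNAp conservation violated")
        if self.free_rnap < 0:
            raise AssertionError("negative free RNAp")
        # per-compartment ribosome checks
        n_bound = 0
        n_competent = 0
        for comp in self.compartments.values():
            if comp.competent:
                n_competent += 1
            prev_rib = None
            rib = comp.rib_tail
            count = 0
            while rib is not None:
                count += 1
                if rib.position > comp.front:
                    raise AssertionError(
                        f"ribosome {rib.id} at {rib.position} beyond front {comp.front}"
                    )
                if rib.position < 3:
                    raise AssertionError(f"ribosome {rib.id} before the first codon")
                if (prev_rib is not None and
                        rib.position - prev_rib.position < comp.rib_footprint):
                    raise AssertionError("ribosome footprints overlap")
                prev_rib = rib
                rib = rib.ahead
            if count != comp.n_bound:
                raise AssertionError("ribosome list inconsistent with count")
            n_bound += count
        if n_bound != self.total_bound:
            raise AssertionError("bound-ribosome ledger violated")
        if self.free_rib is not None and self.free_rib + self.total_bound != self.n_ribosomes:
            raise AssertionError("ribosome conservation violated")
        if n_competent != self.mrna_count:
            raise AssertionError("mRNA observable out of sync with competent strands")
        if self.p_prem < 0 or self.protein < 0:
            raise AssertionError("negative protein count")
        self.engine.validate_propensities()
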