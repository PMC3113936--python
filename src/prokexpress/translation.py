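"""Codon-level translation: initiation, stepwise translocation, codon-specific
activation, back-translocation, drop-off, trans-translation, completion, and
first-order protein folding/degradation.

Each nascent RNA strand carries its own set of these reactions (see
:mod:`prokexpress.coupling`); this module defines the per-ribosome state and
reaction channels plus the shared protein pool channel.

Kinetics (defaults, all in 1/s):

===============  =========  =====================================================
initiation       0.33       ribosome binds the exposed, unoccupied RBS
translocation    1000 (x3)  three sub-steps, one ribonucleotide each
activation       35/8/4.5   classes A/B/C; peptide bond formation, codon specific
back-transloc.   1.5        one codon backwards when the bond has not locked
drop-off         0.000114   spontaneous dissociation, no protein produced
trans-transl.    0.000052   per bound ribosome; rescues the strand, destroys it
completion       2          at the stop codon; releases ribosome, yields P_prem
folding          0.0024     P_prem -> P (GFP-like maturation)
protein decay    0.0017     P -> nothing
===============  =========  =====================================================

A ribosome's footprint covers ``2*delta_rib + 1 = 31`` ribonucleotides around
its active site; footprints on one strand never overlap and a ribosome never
advances past the transcription exposure front.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .ssa import Channel

__all__ = [
    "TranslationParameters",
    "RibosomeState",
    "RibosomeChannel",
    "ProteinPoolChannel",
    "AWAITING_ACTIVATION",
    "TRANSLOCATING",
]

AWAITING_ACTIVATION = 0
TRANSLOCATING = 1


@dataclass(frozen=True)
class TranslationParameters:
    """Rate constants of the translation reactions (Table defaults above)."""

    k_trans_init: float = 0.33
    k_tm: float = 1000.0
    k_transA: float = 35.0
    k_transB: float = 8.0
    k_transC: float = 4.5
    specific_codon_rates: dict = field(default_factory=dict)
    k_bt: float = 1.5
    k_drop: float = 0.000114
    k_tt: float = 0.000052
    k_trans_f: float = 2.0
    k_fold: float = 0.0024
    k_dec: float = 0.0017
    delta_rib: int = 15

    def __post_init__(self):
        for name in ("k_trans_init", "k_tm", "k_transA", "k_transB", "k_transC",
                     "k_bt", "k_drop", "k_tt", "k_trans_f", "k_fold", "k_dec"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.delta_rib < 0:
            raise ValueError("delta_rib must be non-negative")

    @property
    def footprint(self) -> int:
        """Ribonucleotides occupied by one ribosome (2*delta_rib + 1)."""
        return 2 * self.delta_rib + 1

    def with_overrides(self, **kwargs) -> "TranslationParameters":
        return replace(self, **kwargs)


class RibosomeState:
    """One translating ribosome on one RNA strand.

    ``position`` is the ribonucleotide index of the active site; at a codon
    boundary (a multiple of 3) the ribosome awaits the activation reaction for
    codon ``position/3``.  ``max_activated`` tracks the furthest codon whose
    activation has fired so that re-activation after back-translocation does
    not double-count peptide bonds.
    """

    __slots__ = ("id", "position", "phase", "tloc_remaining", "max_activated",
                 "peptide_length", "compartment", "ahead", "behind", "channel_id")

    def __init__(self, rib_id: int, compartment):
        self.id = rib_id
        self.position = 3  # active site at the first codon boundary
        self.phase = AWAITING_ACTIVATION
        self.tloc_remaining = 0
        self.max_activated = 0
        self.peptide_length = 0
        self.compartment = compartment
        self.ahead = None   # ribosome closer to the 3' end (higher position)
        self.behind = None  # ribosome closer to the RBS
        self.channel_id = None

    @property
    def codon(self) -> int:
        """1-based codon index of the active site (meaningful at boundaries)."""
        return self.position // 3

    def footprint_interval(self, delta_rib: int) -> tuple[int, int]:
        return (max(1, self.position - delta_rib), self.position + delta_rib)


class RibosomeChannel(Channel):
    """Grouped reaction channel of one ribosome.

    The ribosome's mutually exclusive sub-reactions (activation or completion,
    back-translocation, drop-off while awaiting activation; one translocation
    sub-step or drop-off while translocating) are exposed to the SSA core as a
    single channel whose propensity is the sum of the applicable rates; on
    firing the sub-reaction is chosen proportionally.  This is statistically
    identical to registering the reactions individually and keeps the channel
    registry (and its update cost) proportional to the number of molecules,
    not reactions.
    """

    __slots__ = ("sim", "rib")

    def __init__(self, sim, rib: RibosomeState):
        self.id = ("rib", rib.id)
        self.sim = sim
        self.rib = rib

    # -------------------------------------------------------------- gating
    def _forward_clear(self) -> bool:
        rib = self.rib
        comp = rib.compartment
        target = rib.position + 1
        if target > comp.front:
            return False  # stalled at the transcription exposure front
        if target > 3 * comp.gene.n_codons:
            return False
        ahead = rib.ahead
        if ahead is not None and ahead.position - target < comp.rib_footprint:
            return False
        return True

    def _back_clear(self) -> bool:
        rib = self.rib
        comp = rib.compartment
        if rib.position - 3 < 3:
            return False  # codon 1 has no previous codon
        behind = rib.behind
        if behind is None:
            # Trailing ribonucleotides of the last ribosome are destroyed on a
            # degradation-marked strand, so there is nothing to move back onto.
            return not comp.degradation_marked
        return rib.position - 3 - behind.position >= comp.rib_footprint

    def _rates(self):
        rib = self.rib
        tp = self.sim.tp
        comp = rib.compartment
        out = []
        if rib.phase == AWAITING_ACTIVATION:
            c = rib.position // 3
            if c == comp.gene.n_codons:
                out.append((tp.k_trans_f, "complete"))
            else:
                out.append((comp.activation_rates[c - 1], "activate"))
            if tp.k_bt > 0.0 and self._back_clear():
                out.append((tp.k_bt, "back"))
        else:
            if self._forward_clear():
                out.append((tp.k_tm, "step"))
        if tp.k_drop > 0.0:
            out.append((tp.k_drop, "drop"))
        return out

    def propensity(self) -> float:
        return sum(r for r, _ in self._rates())

    # -------------------------------------------------------------- firing
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

    def _do_activate(self) -> None:
        sim = self.sim
        rib = self.rib
        comp = rib.compartment
        c = rib.position // 3
        if c > rib.max_activated:
            rib.max_activated = c
            rib.peptide_length += 1
            log = sim.log
            if log.wants("codon_activation"):
                log.append(sim.engine.time, "codon_activation", comp.id, c)
            if comp.gene.codons[c - 1] == "ATG" and log.wants("met_activation"):
                log.append(sim.engine.time, "met_activation", comp.id, c, str(rib.id))
        rib.phase = TRANSLOCATING
        rib.tloc_remaining = 3
        sim.engine.recompute(self.id)

    def _do_step(self) -> None:
        sim = self.sim
        rib = self.rib
        rib.position += 1
        rib.tloc_remaining -= 1
        if rib.tloc_remaining == 0:
            rib.phase = AWAITING_ACTIVATION
        if sim.log.wants("ribosome_move"):
            sim.log.append(sim.engine.time, "ribosome_move", rib.compartment.id,
                           rib.position, str(rib.id))
        eng = sim.engine
        eng.recompute(self.id)
        if rib.behind is not None:
            eng.recompute(rib.behind.channel_id)
        if rib.ahead is not None:
            eng.recompute(rib.ahead.channel_id)
        comp = rib.compartment
        if rib.behind is None and rib.position <= comp.rbs_end + comp.rib_footprint + 3:
            eng.recompute(comp.channel_id)
        # approaching the exposure front flips the RNAp's backward-move gate
        if (rib.ahead is None and comp.rnap is not None
                and rib.position + sim.tp.delta_rib >= comp.front - 1):
            eng.recompute(comp.rnap.channel_id)

    def _do_back(self) -> None:
        sim = self.sim
        rib = self.rib
        rib.position -= 3
        if sim.log.wants("back_translocation"):
            sim.log.append(sim.engine.time, "back_translocation", rib.compartment.id,
                           rib.position, str(rib.id))
        eng = sim.engine
        eng.recompute(self.id)
        if rib.behind is not None:
            eng.recompute(rib.behind.channel_id)
        if rib.ahead is not None:
            eng.recompute(rib.ahead.channel_id)
        comp = rib.compartment
        if rib.behind is None:
            eng.recompute(comp.channel_id)
        if (rib.ahead is None and comp.rnap is not None
                and rib.position + sim.tp.delta_rib >= comp.front - 4):
            eng.recompute(comp.rnap.channel_id)

    def _do_drop(self) -> None:
        sim = self.sim
        rib = self.rib
        comp = rib.compartment
        sim.log.append(sim.engine.time, "ribosome_dropoff", comp.id, rib.position,
                       str(rib.id))
        comp.release_ribosome(rib)
        comp.maybe_destroy()

    def _do_complete(self) -> None:
        sim = self.sim
        rib = self.rib
        comp = rib.compartment
        sim.p_prem += 1
        comp.proteins_completed += 1
        sim.log.append(sim.engine.time, "translation_completion", comp.id,
                       rib.position, str(rib.id))
        comp.release_ribosome(rib)
        sim.engine.recompute(sim.protein_channel_id)
        comp.maybe_destroy()


class ProteinPoolChannel(Channel):
    """First-order folding (P_prem -> P) and protein degradation (P -> 0)."""

    __slots__ = ("sim",)

    id = "protein_pool"

    def __init__(self, sim):
        self.sim = sim

    def propensity(self) -> float:
        tp = self.sim.tp
        return tp.k_fold * self.sim.p_prem + tp.k_dec * self.sim.protein

    def fire(self) -> None:
        sim = self.sim
        tp = sim.tp
        a_fold = tp.k_fold * sim.p_prem
        total = a_fold + tp.k_dec * sim.protein
        if sim.rng.uniform() * total <= a_fold:
            sim.p_prem -= 1
            sim.protein += 1
            if sim.log.wants("protein_folded"):
                sim.log.append(sim.engine.time, "protein_folded")
        else:
            sim.protein -= 1
            if sim.log.wants("protein_degraded"):
                sim.log.append(sim.engine.time, "protein_degraded")
        sim.engine.recompute(self.id)
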