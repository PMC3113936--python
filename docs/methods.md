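# Methods

## Scope and model

`prokexpress` simulates the expression of one prokaryotic gene at
single-nucleotide and single-codon resolution, with transcription and
translation dynamically coupled: ribosomes translate the nascent mRNA while
the RNA polymerase (RNAp) is still elongating it.  The dynamics follow the
delayed stochastic simulation algorithm (delayed SSA): a direct-method SSA
whose reactions may deposit their products on a wait list, to appear a
sampled delay after firing.  When a sampled waiting time would cross the
next queued release, the release is applied first and the waiting time is
re-drawn; for memoryless channels this interleaving is exact.

### Transcription (per nucleotide)

The DNA template is a 1-based lattice.  Each RNAp occupies
`2*delta_rnap + 1 = 25` nucleotides around its active site; footprints never
overlap, so RNAps queue and never overtake.  Reactions and defaults (rates
in 1/s, dwell times in s):

| event | constants |
|---|---|
| initiation (binding + open complex) | `k_init = 0.015` per free RNAp; delay `tau_oc ~ N(40, 4)` |
| promoter clearance | `k_m = 114`, gated on a free start region |
| elongation | `k_m = 114` per step, then activation `k_a = 114` (`30` for nucleotides 1–10) |
| ubiquitous pausing | `k_p = 0.55`, mean dwell `tau_p = 3` |
| pause release / induction by collision | `k_m = 114` between abutting RNAps |
| arrest | `k_ar = 2.8e-4`, mean dwell `tau_ar = 100`, never collision-released |
| editing | `k_ec = 8e-3`, mean dwell `tau_c = 5` |
| premature termination | `k_pre = 1.9e-4` |
| pyrophosphorolysis | `k_pyro = 0.75`, one nucleotide backwards |
| completion | `k_f = 2` at the last nucleotide |
| functional-mRNA degradation | `k_dr = 0.011` per competent strand |

Halted states (pause, arrest, editing) are implemented as memoryless release
channels at rate `1/tau` rather than fixed delays, so that a paused RNAp
remains interruptible by a trailing collision; the means match the table.

Sequence-specific sites are per-nucleotide annotations `(kind, probability,
mean duration)`.  On each forward arrival at the annotated nucleotide the
event triggers with its probability; a triggered RNAp halts with memoryless
mean dwell equal to the site's duration and resumes its stepping cycle on
release.  Site-triggered long pauses, like arrests, are released only
spontaneously: the long pauses these sites model (his-pause-like elements,
hundreds of seconds) persist under traffic in the measurements they come
from, and making them collision-releasable would truncate every long pause
to roughly one initiation interval whenever the promoter is busy, erasing
the difference between a 100 s and a 500 s site.  The ubiquitous pause stays
collision-releasable.

The effective transcription-initiation rate `k_eff` is exposed as a scalar on
the binding propensity (`k_eff_multiplier`), or as a target binding rate with
the whole pool free (`k_eff`); repressors are not modelled explicitly — in
the source experiments they are only the means of tuning this rate.

### Coupling: per-RNA compartments and the exposure front

Each RNAp that clears the promoter creates an `RnaCompartment` — a reaction
compartment registered at run time with its own translation channels.
Ribonucleotide `position - delta_rnap - 1` is the highest one clear of the
RNAp footprint; this *exposure front* advances with the RNAp, jumps to the
gene end on completion, and retreats by one under pyrophosphorolysis (the
backward move is blocked outright if a ribosome sits on the ribonucleotide
that would be retracted).  Translation initiation becomes possible once the
ribosome binding site (RBS), the first `2*delta_rib + 1 = 31`
ribonucleotides, is fully exposed — first reached when the RNAp active site
is at nucleotide 44 under the default footprints.  Competence is latched: a
later 1-nt retraction at the far front does not un-form the RBS.

The mRNA observable reported in time series counts translation-competent
strands (RBS exposed, not degradation-marked).  Degradation (13) marks the
RBS destroyed; bound ribosomes finish their runs and the strand is
physically removed when the last one leaves.  Degradation never aborts an
RNAp still transcribing; a marked, still-elongating strand is removed only
after transcription ends and the last ribosome leaves.  Premature
termination freezes the front and likewise marks the RBS destroyed, so the
compartment drains and dies; trans-translation destroys the strand
instantly, releasing all bound ribosomes and detaching a still-elongating
RNAp.

### Translation (per codon)

Each ribosome occupies `2*delta_rib + 1 = 31` ribonucleotides around its
active site; a binding ribosome sits with its active site at ribonucleotide
3, awaiting activation of codon 1.  Defaults:

| event | constants |
|---|---|
| initiation | `k_trans_init = 0.33` per competent strand with a clear RBS |
| translocation | `k_tm = 1000`, three sub-steps of one ribonucleotide |
| activation (codon-specific) | `k_transA = 35`, `k_transB = 8`, `k_transC = 4.5` |
| back-translocation | `k_bt = 1.5`, one codon backwards |
| drop-off | `k_drop = 1.14e-4` per bound ribosome (continuous hazard) |
| trans-translation | `k_tt = 5.2e-5` per bound ribosome |
| completion | `k_trans_f = 2` at the stop codon |
| folding / activation | `k_fold = 2.4e-3` (GFP-like maturation) |
| protein degradation | `k_dec = 1.7e-3` |

Initiation is pseudo-first-order (the ribosome pool is non-limiting by
default but can be made finite, in which case conservation is enforced and
checked).  Codon classes ship as an editable TSV covering all 64 codons;
individual codons may instead carry explicit rates.  The bundled class
assignment is derived from relative E. coli codon usage (frequent → A,
rare → C), with GAG placed in class C because it is the slow codon the
engineered slow-stretch constructs use; the class boundaries are a bundled
default, not a measured table, and should be replaced when a calibrated one
is available.  Back-translocation forces re-activation of the previous codon
but peptide bonds are counted once (first activation of each codon), so
peptide length equals protein length at completion.  The stop codon is the
final codon of the sequence; release factors are not modelled.

### The SSA core

The engine is a direct-method SSA over a dynamic channel set with a
delayed-event heap (FIFO on ties, for reproducibility).  Each molecule
(RNAp, ribosome, compartment, the promoter, the protein pool) registers one
grouped channel whose propensity is the sum of its currently available
reactions; on firing the sub-reaction is chosen proportionally.  This is
statistically identical to one channel per reaction and keeps the registry
small.  Propensities are cached and recomputed only for the channels a
firing can affect (the molecule itself, its lattice neighbours, its
compartment, and cross-dependencies such as the lead ribosome gating the
RNAp's backward move); a validation mode re-evaluates every cached
propensity from scratch and is exercised throughout the test suite, along
with footprint, ordering, conservation and ledger invariants.  The running
propensity total is maintained incrementally and re-summed every 4096
updates to bound float drift.  One seeded generator drives each simulation;
replicate r of a batch uses `base_seed + r`, and matched arms of a
comparison reuse the same replicate seeds (common random numbers).

The open-complex delay sampler re-draws on negative values; at 40 ± 4 s the
truncation mass (~1e-23) is irrelevant, but the rule keeps the sampler
well-defined for any parameterisation.

## Statistics

Noise is `CV² = Var/Mean²`.  The measurement protocol runs replicates to
steady state, discards a burn-in of five half-lives of the slower of the
mRNA and protein degradation processes, concatenates the replicate series,
and computes CV² on the pooled series (a per-replicate variant exists for
sensitivity checks).  Coupling is the normalized discrete cross-correlation

    r(tau) = (1/m) sum_pairs [ sum_{t=1}^{n-tau} (x_t - m_x)(y_{t+tau} - m_y) ]
             / ((n - tau) s_x s_y)

with full-series means and population standard deviations per pair, averaged
over the m replicate pairs; `r(x, x, 0) = 1` exactly.  Note the per-lag
`(n - tau)` normalization is unbiased but noisy as the overlap window
shrinks, and is not hard-bounded by 1 at large lags; parameter scans
therefore search the maximum over lags up to half the series length.

Interval distributions (initiation/completion events) are summarised by
mean, CV², skewness and Sarle's bimodality coefficient.  Burst statistics
count completed proteins per compartment lifetime (zeros included) and
intervals between first-production events.  Methionine incorporation curves
count labelled ATG-codon activations as a function of time since each
ribosome's own initiation, pooled over ribosomes that were observed for the
full sample window, normalized by the strand's 23 methionines — a single
completed protein reaches 23/23 = 1.

Degradation-rate compensation (used by the scans so mean levels match across
parameter cells) sets `k_dr = R_mrna/target` with
`R_mrna = 1/(1/k_eff + tau_oc)` and `k_dec = k_trans_init * target_mrna /
target_protein`, optionally refined by pilot simulations with damped
multiplicative corrections (exponent 0.7, so the loop does not chase pilot
sampling noise).  Reaching a 5% tolerance on means requires pilots long
enough that the mean estimator's own standard error is well below that; the
test suite uses shorter pilots with a correspondingly looser tolerance.

## Synthetic data

Random genes draw sense codons i.i.d. from a bundled approximate E. coli
usage table and end in TAA.  The LacZ-like fixture is a *structural*
stand-in for lacZ and its slow-insert mutants: 3072 nt, ATG at 23 fixed,
unevenly spread codon positions shared by all variants, and a fixed
mid-gene window of 24 or 48 codons replaced by GAG in the insert variants
(replacement rather than insertion keeps length and methionine coordinates
identical across variants; the real constructs' coordinates and sequences
are not reproduced).  Passing fixture-based tests therefore demonstrates the
mechanisms — codon-usage statistics, queue formation on slow stretches,
label-incorporation ordering — not sequence-level agreement with the real
lacZ constructs.

## Problem sizes in the shipped tests

The reference protocol for the noise surfaces is 100 replicates of 1e5 s per
parameter cell (available via `--paper-scale`).  The test suite asserts the
same quantities at desk scale, chosen so each check resolves its effect at
3-s.e.-style tolerances: 48-codon genes, 3–5 replicates and 5e3–3e4 s
windows for the noise and pause scans; 1e4 passages for the pause-site
fraction; 1e3 transits for the lone-RNAp oracle on the 3072-nt strand.
Trend checks (noise and correlation versus `k_eff`, `k_tr`) use shared
replicate seeds across cells, making them paired comparisons.

## Known limitations

- No mechanical ribosome–RNAp coupling: a pioneering ribosome neither pushes
  a paused RNAp nor is paused by it.
- No abortive initiation, promoter escape substates, or supercoiling.
- mRNA degradation is single-pathway (RBS-first, gradual); endonucleolytic
  cleavage variants are not modelled.
- tRNA pools, initiation/elongation/release factors are assumed abundant and
  implicit; frameshifting is subsumed into the trans-translation hazard.
- No cell growth, division, or volume effects; one gene per simulation.
- Editing is an in-place dwell (no backtracking displacement).
- The bundled codon class table is usage-derived, not measured; the four
  codons with individually measured rates are left to user configuration.
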