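"""Noise and coupling statistics for simulated RNA/protein time series.

The statistics mirror the measurement protocol used throughout the
experiments: replicate simulations are run to steady state, their sampled
time series are concatenated, noise is quantified as the squared coefficient
of variation CV² = Var/Mean², and the coupling between mRNA and protein
fluctuations is quantified by the normalized discrete cross-correlation

    r(τ) = (1/m) Σ_pairs  Σ_{t=1}^{n-τ} (x_t - m_x)(y_{t+τ} - m_y)
                           -----------------------------------------
                                     (n - τ) · s_x · s_y

over m replicate pairs of series of length n, where m_w and s_w are the
sample mean and (population) standard deviation of each full series; with
this normalization r(x, x, 0) = 1 exactly.  The maximum of r over lags is the
"normalized maximum correlation" reported by the parameter scans.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .ssa import EventLog

__all__ = [
    "cv2",
    "concatenate",
    "cross_correlation",
    "cross_correlation_function",
    "max_correlation",
    "IntervalStats",
    "interval_stats",
    "BurstStats",
    "burst_stats",
    "methionine_curve",
    "compensate_degradation",
]


def cv2(series) -> float:
    """Squared coefficient of variation, Var/Mean² (sample variance)."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("CV^2 needs at least two samples")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("CV^2 undefined for non-positive mean")
    return float(x.var(ddof=1) / mean**2)


def concatenate(series_list: Iterable) -> np.ndarray:
    """Concatenate replicate series into one, the pooling used before CV²."""
    return np.concatenate([np.asarray(s, dtype=float) for s in series_list])


def _as_pairs(pair_or_pairs) -> list[tuple[np.ndarray, np.ndarray]]:
    if isinstance(pair_or_pairs, tuple) and len(pair_or_pairs) == 2 and not isinstance(
        pair_or_pairs[0], tuple
    ):
        pair_or_pairs = [pair_or_pairs]
    pairs = []
    n = None
    for x, y in pair_or_pairs:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("each pair must be two equal-length 1-D series")
        if n is None:
            n = x.size
        elif x.size != n:
            raise ValueError("all replicate pairs must share the same length")
        pairs.append((x, y))
    if not pairs:
        raise ValueError("no series pairs given")
    if n < 2:
        raise ValueError("series too short")
    return pairs


def cross_correlation_function(pair_or_pairs, max_lag: Optional[int] = None) -> np.ndarray:
    """r(τ) for τ = 0..max_lag (default n-1), averaged over replicate pairs."""
    pairs = _as_pairs(pair_or_pairs)
    n = pairs[0][0].size
    if max_lag is None:
        max_lag = n - 1
    if not 0 <= max_lag <= n - 1:
        raise ValueError(f"max_lag must lie in [0, {n - 1}]")
    acc = np.zeros(max_lag + 1)
    for x, y in pairs:
        sx = x.std(ddof=0)
        sy = y.std(ddof=0)
        if sx == 0.0 or sy == 0.0:
            raise ValueError("cross-correlation undefined for a constant series")
        xc = x - x.mean()
        yc = y - y.mean()
        for tau in range(max_lag + 1):
            num = float(np.dot(xc[: n - tau], yc[tau:]))
            acc[tau] += num / ((n - tau) * sx * sy)
    return acc / len(pairs)


def cross_correlation(pair_or_pairs, lag: int) -> float:
    """Normalized discrete cross-correlation at one lag."""
    return float(cross_correlation_function(pair_or_pairs, max_lag=lag)[lag])


def max_correlation(pair_or_pairs, max_lag: Optional[int] = None) -> tuple[int, float]:
    """(argmax lag, max value) of r(τ); ties resolve to the smaller lag."""
    r = cross_correlation_function(pair_or_pairs, max_lag=max_lag)
    lag = int(np.argmax(r))  # argmax returns the first (smallest) maximiser
    return lag, float(r[lag])


@dataclass(frozen=True)
class IntervalStats:
    """Summary of the consecutive-interval distribution of one event type."""

    intervals: np.ndarray
    mean: float
    cv2: float
    skewness: float
    excess_kurtosis: float
    bimodality: float

    def histogram(self, bins=30):
        counts, edges = np.histogram(self.intervals, bins=bins)
        return counts, edges


def interval_stats(event_log: EventLog, event_type: str) -> IntervalStats:
    """Distribution of time intervals between consecutive events of a type."""
    times = event_log.times_of(event_type)
    if times.size < 2:
        raise ValueError(
            f"need at least 2 events of type {event_type!r}, got {times.size}"
        )
    iv = np.diff(np.sort(times))
    from scipy import stats as sps

    n = iv.size
    g1 = float(sps.skew(iv))
    g2 = float(sps.kurtosis(iv))  # excess kurtosis
    if n > 3:
        # Sarle's bimodality coefficient with the finite-sample correction;
        # uniform ~ 0.555, exponential ~ 0.75 (n large), bimodal mixtures higher.
        bc = (g1**2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3)))
    else:
        bc = float("nan")
    return IntervalStats(
        intervals=iv,
        mean=float(iv.mean()),
        cv2=float(iv.var(ddof=1) / iv.mean() ** 2) if iv.mean() > 0 else float("inf"),
        skewness=g1,
        excess_kurtosis=g2,
        bimodality=bc,
    )


@dataclass(frozen=True)
class BurstStats:
    """Proteins per mRNA compartment and intervals between bursts."""

    burst_sizes: np.ndarray          # one entry per compartment, zeros included
    inter_burst_intervals: np.ndarray  # between first completions of consecutive bursts

    @property
    def total_proteins(self) -> int:
        return int(self.burst_sizes.sum())

    @property
    def mean_burst(self) -> float:
        return float(self.burst_sizes.mean())


def burst_stats(event_log: EventLog) -> BurstStats:
    """Burst statistics from compartment-tagged production events.

    A compartment's burst size is its number of translation completions over
    its lifetime; compartments created (transcription initiation) but never
    producing a protein count as bursts of size 0.
    """
    comp_ids = []
    for t, e, c in zip(event_log.times, event_log.event_types,
                       event_log.compartment_ids):
        if e == "transcription_initiation":
            comp_ids.append(c)
    counts = {c: 0 for c in comp_ids}
    first_production: dict[int, float] = {}
    for t, e, c in zip(event_log.times, event_log.event_types,
                       event_log.compartment_ids):
        if e == "translation_completion":
            counts[c] = counts.get(c, 0) + 1
            if c not in first_production:
                first_production[c] = t
    sizes = np.array([counts[c] for c in comp_ids], dtype=int)
    firsts = np.sort(np.array(list(first_production.values())))
    return BurstStats(sizes, np.diff(firsts))


def methionine_curve(
    event_logs: Iterable[EventLog],
    sample_times: Sequence[float],
    n_methionines: int,
    *,
    run_duration: Optional[float] = None,
    pulse_time: float = 0.0,
) -> np.ndarray:
    """Normalized radioactive-methionine incorporation curve.

    ``sample_times`` are measured from each ribosome's own translation
    initiation (the pulse labels every methionine incorporated afterwards):
    for each ribosome the labelled methionine-codon activations within τ
    seconds of its start are counted, pooled over ribosomes and replicate
    logs, and normalized by ``n_methionines`` per ribosome — so a single
    ribosome that finishes its protein on a 23-methionine strand reaches
    23/23 = 1.  Logs must record ``translation_initiation`` and
    ``met_activation`` events (both tagged with the ribosome id).

    ``run_duration`` guards against truncation bias: ribosomes starting
    later than ``run_duration - sample_times[-1]`` have not been observed
    over the full window and are excluded.
    """
    if n_methionines < 1:
        raise ValueError("sequence must contain at least one methionine codon")
    sample_times = np.asarray(sample_times, dtype=float)
    rel_times: list[float] = []
    n_ribosomes = 0
    for log in event_logs:
        starts: dict[tuple[int, str], float] = {}
        horizon = (run_duration if run_duration is not None else max(log.times, default=0.0))
        cutoff = horizon - sample_times[-1]
        for t, e, c, d in zip(log.times, log.event_types, log.compartment_ids,
                              log.details):
            if e == "translation_initiation" and t > pulse_time:
                if t <= cutoff:
                    starts[(c, d)] = t
                    n_ribosomes += 1
            elif e == "met_activation":
                t0 = starts.get((c, d))
                if t0 is not None:
                    rel_times.append(t - t0)
    if n_ribosomes == 0:
        raise ValueError("no fully observed ribosomes: extend the run or "
                         "shorten the sample window")
    rel = np.sort(np.asarray(rel_times))
    counts = np.searchsorted(rel, sample_times, side="right").astype(float)
    return counts / (n_methionines * n_ribosomes)


def _rbs_clearance_time(gene, tp) -> float:
    """Mean time for a freshly bound ribosome to clear the RBS.

    The active site must advance from ribonucleotide 3 to 3*delta_rib + 2,
    i.e. activate the first ``delta_rib`` codons and translocate
    ``3*delta_rib - 1`` ribonucleotides.
    """
    rates = gene.activation_rates(tp)
    target = 3 * tp.delta_rib + 2
    n_codons = (target - 3) // 3 + 1
    t = (3 * tp.delta_rib - 1) / tp.k_tm
    for c in range(min(n_codons, len(rates))):
        if rates[c] > 0:
            t += 1.0 / rates[c]
    return t


def compensate_degradation(
    params,
    k_eff: float,
    target_mean_mrna: float,
    target_mean_protein: float,
    *,
    gene=None,
    calibrate: bool = False,
    seed: int = 0,
    pilot_duration: float = 4000.0,
    pilot_replicates: int = 2,
    tol: float = 0.05,
    max_iter: int = 4,
    n_rnap: int = 28,
):
    """Set k_dr and k_dec so mean mRNA and protein levels hit given targets.

    The analytic first pass uses the net production-rate estimates
    ``R_mrna = 1/(1/k_eff + tau_oc)`` (binding wait plus open-complex delay)
    and ``R_protein = k_trans_init * target_mean_mrna``, giving
    ``k_dr = R_mrna/target_mean_mrna`` and ``k_dec = R_protein/target_mean_protein``.
    With ``calibrate=True`` short pilot simulations refine both rates
    multiplicatively until realized means are within ``tol`` of the targets
    (RuntimeError with diagnostics if ``max_iter`` is exhausted).

    Returns a new parameter set; ``k_eff`` itself is not stored in it — pass
    the same value to the Simulation.
    """
    if target_mean_mrna <= 0:
        raise ValueError("target means must be positive")
    if target_mean_protein is not None and target_mean_protein <= 0:
        raise ValueError("target means must be positive")
    if k_eff <= 0:
        raise ValueError("k_eff must be positive")
    r_mrna = 1.0 / (1.0 / k_eff + params.tau_oc_mean)
    k_dr = r_mrna / target_mean_mrna
    if target_mean_protein is None:  # e.g. transcription-only protocols
        k_dec = params.translation.k_dec
    else:
        k_tr_eff = params.translation.k_trans_init
        if gene is not None:
            # RBS occlusion throttles initiation: the next ribosome binds only
            # after the previous one has cleared the binding site, so the
            # effective per-strand rate saturates as k_tr/(1 + k_tr*t_clear)
            t_clear = _rbs_clearance_time(gene, params.translation)
            k_tr_eff = k_tr_eff / (1.0 + k_tr_eff * t_clear)
        r_protein = k_tr_eff * target_mean_mrna
        k_dec = r_protein / target_mean_protein
    out = replace(params, k_dr=k_dr,
                  translation=params.translation.with_overrides(k_dec=k_dec))
    if not calibrate:
        return out
    if gene is None:
        raise ValueError("calibration needs the gene to simulate")
    from .coupling import Simulation  # deferred: avoids an import cycle

    for iteration in range(max_iter):
        mrna_means = []
        protein_means = []
        burn = 5.0 * np.log(2.0) / min(out.translation.k_dec, out.k_dr)
        for r in range(pilot_replicates):
            sim = Simulation(gene, out, seed=seed + 1000 * iteration + r,
                             k_eff=k_eff, n_rnap=n_rnap, log_types=frozenset())
            series, _ = sim.run(burn + pilot_duration, sample_interval=10.0)
            steady = series[series["time_s"] >= burn]
            mrna_means.append(steady["mrna"].mean())
            protein_means.append(steady["protein"].mean())
        m_hat = float(np.mean(mrna_means))
        p_hat = float(np.mean(protein_means))
        err_m = abs(m_hat - target_mean_mrna) / target_mean_mrna
        err_p = abs(p_hat - target_mean_protein) / target_mean_protein
        if err_m <= tol and err_p <= tol:
            return out
        # mean = R/k: scale each degradation rate by realized/target, damped
        # so the loop does not chase pilot sampling noise
        f_m = np.clip(m_hat / target_mean_mrna, 0.2, 5.0) ** 0.7
        f_p = np.clip(p_hat / target_mean_protein, 0.2, 5.0) ** 0.7
        out = replace(
            out,
            k_dr=out.k_dr * f_m,
            translation=out.translation.with_overrides(
                k_dec=out.translation.k_dec * f_p
            ),
        )
    raise RuntimeError(
        "degradation-rate calibration did not converge: "
        f"mRNA mean {m_hat:.3g} (target {target_mean_mrna}), "
        f"protein mean {p_hat:.3g} (target {target_mean_protein}) "
        f"after {max_iter} iterations"
    )
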