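"""Reproducible experiment protocols built on :class:`~prokexpress.coupling.Simulation`.

Four protocols are provided, mirroring the standard in-silico assays for this
model family:

* :func:`run_single` / :func:`run_replicates` — raw trajectories (and
  kymograph exports) of one gene under one parameter set.
* :func:`noise_scan` — CV² of mRNA and protein levels and the normalized
  maximum mRNA-protein correlation over a grid of effective transcription
  (k_eff) and translation (k_tr) initiation rates, with degradation rates
  compensated so mean levels are identical across cells.
* :func:`pause_experiment` — relative change of protein-level CV² caused by a
  sequence-specific long-pause site, versus a pause-free control with shared
  random seeds.
* :func:`methionine_experiment` — pulse-labelled methionine incorporation
  curves for the LacZ-like strand and its slow-codon-insert variants.

Every protocol derives replicate seeds as ``base_seed + replicate_index`` so
a batch is reproducible from its config alone, and matched arms of a
comparison reuse the same replicate seeds (common random numbers).
"""

from __future__ import annotations

import copy
from dataclasses import replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import analysis
from .coupling import Simulation
from .sequences import GeneSequence, annotate_site, make_lacz_fixture
from .transcription import KineticParameters

__all__ = [
    "run_single",
    "run_replicates",
    "noise_scan",
    "pause_experiment",
    "methionine_experiment",
    "export_kymographs",
]


def _burn_in(params: KineticParameters) -> float:
    """Default burn-in: five half-lives of the slower of mRNA and protein.

    Relaxation to steady state is limited by the slower of the two
    degradation processes, so both are considered."""
    return 5.0 * np.log(2.0) / min(params.translation.k_dec, params.k_dr)


def run_single(
    gene: GeneSequence,
    params: Optional[KineticParameters] = None,
    *,
    seed: int = 0,
    t_end: float = 400.0,
    sample_interval: float = 1.0,
    log_types=None,
    **sim_kwargs,
):
    """One trajectory; returns (time series, event log, simulation)."""
    sim = Simulation(gene, params, seed=seed, log_types=log_types, **sim_kwargs)
    series, log = sim.run(t_end, sample_interval)
    return series, log, sim


def run_replicates(
    gene: GeneSequence,
    params: Optional[KineticParameters] = None,
    *,
    n_replicates: int = 10,
    base_seed: int = 0,
    t_burn: Optional[float] = None,
    t_measure: float = 10_000.0,
    sample_interval: float = 10.0,
    log_types=frozenset(),
    **sim_kwargs,
):
    """Independent replicates; replicate r is seeded ``base_seed + r``.

    Returns a list of (steady-state time-series slice, event log) pairs; the
    slice drops the burn-in (default: five protein half-lives).
    """
    params = params if params is not None else KineticParameters()
    burn = _burn_in(params) if t_burn is None else t_burn
    out = []
    for r in range(n_replicates):
        sim = Simulation(gene, params, seed=base_seed + r, log_types=log_types,
                         **sim_kwargs)
        series, log = sim.run(burn + t_measure, sample_interval)
        out.append((series[series["time_s"] >= burn].reset_index(drop=True), log))
    return out


def noise_scan(
    gene: GeneSequence,
    k_eff_values: Sequence[float],
    k_tr_values: Sequence[float],
    *,
    base_params: Optional[KineticParameters] = None,
    replicates: int = 4,
    t_measure: float = 8000.0,
    sample_interval: float = 10.0,
    target_mean_mrna: float = 2.0,
    target_mean_protein: float = 40.0,
    max_lag_s: float = 2500.0,
    seed: int = 0,
    n_rnap: int = 28,
) -> pd.DataFrame:
    """Grid scan of expression noise versus initiation rates.

    For each (k_eff, k_tr) cell the mRNA and protein degradation rates are
    compensated analytically so the mean levels match the shared targets,
    ``replicates`` simulations are run past burn-in, the replicate series are
    concatenated, and the cell is summarised by CV²(mRNA), CV²(protein) and
    the maximum of the normalized mRNA-protein cross-correlation (computed
    per replicate pair and averaged).  Replicate seeds are shared between
    cells, so scans along either axis are paired comparisons.
    """
    if not len(k_eff_values) or not len(k_tr_values):
        raise ValueError("empty k_eff/k_tr grid")
    base = base_params if base_params is not None else KineticParameters()
    rows = []
    for k_tr in k_tr_values:
        tp = base.translation.with_overrides(k_trans_init=float(k_tr))
        params_tr = replace(base, translation=tp)
        for k_eff in k_eff_values:
            params_cell = analysis.compensate_degradation(
                params_tr, float(k_eff), target_mean_mrna, target_mean_protein,
                gene=gene,
            )
            results = run_replicates(
                gene, params_cell, n_replicates=replicates, base_seed=seed,
                t_measure=t_measure, sample_interval=sample_interval,
                k_eff=float(k_eff), n_rnap=n_rnap,
            )
            mrna = [res["mrna"].to_numpy(float) for res, _ in results]
            prot = [res["protein"].to_numpy(float) for res, _ in results]
            pairs = list(zip(mrna, prot))
            # cap the lag range at half the series: the per-lag (n - tau)
            # normalization is too noisy when the overlap window shrinks
            max_lag = min(int(max_lag_s / sample_interval), (len(mrna[0]) - 1) // 2)
            lag, corr = analysis.max_correlation(pairs, max_lag=max_lag)
            rows.append({
                "k_eff": k_eff,
                "k_tr": k_tr,
                "cv2_mrna": analysis.cv2(analysis.concatenate(mrna)),
                "cv2_protein": analysis.cv2(analysis.concatenate(prot)),
                "max_correlation": corr,
                "corr_lag_s": lag * sample_interval,
                "mean_mrna": float(analysis.concatenate(mrna).mean()),
                "mean_protein": float(analysis.concatenate(prot).mean()),
                "k_dr": params_cell.k_dr,
                "k_dec": params_cell.translation.k_dec,
            })
    return pd.DataFrame(rows)


def pause_experiment(
    gene: GeneSequence,
    *,
    durations: Sequence[float] = (100.0, 500.0),
    probability: float = 0.7,
    site_fraction: float = 0.85,
    base_params: Optional[KineticParameters] = None,
    k_eff: float = 0.02,
    replicates: int = 4,
    t_measure: float = 5000.0,
    sample_interval: float = 10.0,
    target_mean_mrna: float = 2.0,
    target_mean_protein: float = 50.0,
    seed: int = 0,
    n_bootstrap: int = 400,
    n_rnap: int = 28,
) -> pd.DataFrame:
    """Protein-noise impact of a sequence-specific long-pause site.

    Runs a pause-free baseline and one arm per pause duration on the same
    gene (site placed at ``site_fraction`` of the template, where stalled
    ribosome queues affect the most codons), with identical replicate seeds
    across arms.  Reports pooled CV²(protein) per arm, the change relative to
    baseline, and a paired bootstrap confidence interval over replicates.
    """
    base = base_params if base_params is not None else KineticParameters()
    params_cell = analysis.compensate_degradation(
        base, k_eff, target_mean_mrna, target_mean_protein, gene=gene
    )
    site_pos = max(1, min(gene.length, int(round(site_fraction * gene.length))))
    arms: list[tuple[str, Optional[float]]] = [("baseline", None)]
    arms += [(f"pause_{int(d)}s", float(d)) for d in durations]
    per_arm_series: dict[str, list[np.ndarray]] = {}
    for name, duration in arms:
        g = copy.deepcopy(gene)
        g.annotations = dict(gene.annotations)
        if duration is not None:
            annotate_site(g, site_pos, "long_pause", probability, duration)
        results = run_replicates(
            g, params_cell, n_replicates=replicates, base_seed=seed,
            t_measure=t_measure, sample_interval=sample_interval,
            k_eff=k_eff, n_rnap=n_rnap,
        )
        per_arm_series[name] = [res["protein"].to_numpy(float) for res, _ in results]

    def pooled_cv2(series_list):
        return analysis.cv2(analysis.concatenate(series_list))

    base_cv2 = pooled_cv2(per_arm_series["baseline"])
    rng = np.random.default_rng(seed)
    rows = []
    for name, duration in arms:
        c = pooled_cv2(per_arm_series[name])
        rel = c / base_cv2 - 1.0
        if name == "baseline":
            rows.append({"arm": name, "pause_duration_s": 0.0, "cv2_protein": c,
                         "rel_cv2_change": 0.0, "ci_low": 0.0, "ci_high": 0.0})
            continue
        boots = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            idx = rng.integers(0, replicates, size=replicates)
            cb = pooled_cv2([per_arm_series[name][i] for i in idx])
            c0 = pooled_cv2([per_arm_series["baseline"][i] for i in idx])
            boots[b] = cb / c0 - 1.0
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append({"arm": name, "pause_duration_s": duration, "cv2_protein": c,
                     "rel_cv2_change": rel, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def methionine_experiment(
    variants: Sequence[str] = ("wt", "insert24", "insert48"),
    *,
    base_params: Optional[KineticParameters] = None,
    replicates: int = 3,
    t_end: float = 240.0,
    sample_every: float = 10.0,
    seed: int = 0,
    fixture_seed: int = 0,
    n_rnap: int = 28,
) -> pd.DataFrame:
    """Pulse-labelled methionine incorporation for the LacZ-like variants.

    The radioactive pulse coincides with induction at t = 0, so every
    incorporated methionine is labelled; incorporation is measured every
    ``sample_every`` seconds after each ribosome's initiation of elongation,
    pooled over ribosomes and replicates, and normalized by the strand's 23
    methionines.  Slower-translating variants incorporate label more slowly,
    so their curves lie below the wild type at intermediate times.

    ``t_end`` must exceed the sample window (`sample window + slack`) so that
    ribosomes observed over the full window exist; the runner simulates for
    ``t_end + sample window``.
    """
    base = base_params if base_params is not None else KineticParameters()
    times = np.arange(0.0, t_end + 1e-9, sample_every)
    data = {"time_s": times}
    log_types = frozenset({"met_activation", "translation_initiation"})
    t_run = t_end + times[-1]
    for variant in variants:
        gene = make_lacz_fixture(variant, seed=fixture_seed)
        logs = []
        for r in range(replicates):
            sim = Simulation(gene, base, seed=seed + r, log_types=log_types,
                             n_rnap=n_rnap)
            _, log = sim.run(t_run, sample_interval=t_run)
            logs.append(log)
        data[variant] = analysis.methionine_curve(
            logs, times, len(gene.methionine_positions), run_duration=t_run
        )
    return pd.DataFrame(data)


def export_kymographs(log, out_dir) -> tuple[Path, Path]:
    """Write RNAp and ribosome position traces from a movement-logged run.

    Requires a run with ``rnap_move``/``ribosome_move`` in its log types.
    Produces ``kymograph_rnap.csv`` (time_s, rnap_id, position) and
    ``kymograph_ribosomes.csv`` (time_s, compartment_id, ribosome_id,
    position).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = log.to_dataframe()
    rnap = frame[frame["event_type"] == "rnap_move"]
    rnap_out = out_dir / "kymograph_rnap.csv"
    pd.DataFrame({
        "time_s": rnap["time_s"],
        "rnap_id": rnap["detail"],
        "position": rnap["position"],
    }).to_csv(rnap_out, index=False)
    rib = frame[frame["event_type"] == "ribosome_move"]
    rib_out = out_dir / "kymograph_ribosomes.csv"
    pd.DataFrame({
        "time_s": rib["time_s"],
        "compartment_id": rib["compartment_id"],
        "ribosome_id": rib["detail"],
        "position": rib["position"],
    }).to_csv(rib_out, index=False)
    return rnap_out, rib_out
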