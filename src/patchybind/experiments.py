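"""Run protocols end to end: build, propagate, sample complex counts.

Rates are estimated on the ensemble-averaged count series (replicates are
averaged before fitting); leave-one-out (jackknife) refits over the
replicates provide the quoted standard errors, which accounts for
run-to-run fluctuations that the fit covariance alone misses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .integrator import Simulation, SystemState
from .kinetics import (
    ComplexTimeSeries,
    RateEstimate,
    count_bound,
    estimate_koff,
    estimate_kon_short_time,
)
from .system_setup import ExperimentSpec, Protocol, build_initial_state

__all__ = ["ReplicateResult", "EnsembleResult", "run_replicate", "run_ensemble",
           "measure_koff", "measure_kon", "replicate_seeds", "jackknife_stderr"]


def replicate_seeds(seed: int, n: int) -> list[int]:
    """Deterministic, well-separated child seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(max(n, 1))]


@dataclass
class ReplicateResult:
    """One simulation run: sampled complex counts per binding channel."""

    times: np.ndarray
    counts: dict[tuple[str, str], np.ndarray]
    final_state: SystemState
    max_bond_extension: float = 0.0
    overstretch_events: int = 0


@dataclass
class EnsembleResult:
    """Replicate-resolved and averaged count series."""

    times: np.ndarray
    rep_counts: dict[tuple[str, str], np.ndarray]  # (R, T)
    spec: ExperimentSpec
    max_bond_extension: float = 0.0
    overstretch_events: int = 0

    def series(self, pair: tuple[str, str]) -> ComplexTimeSeries:
        c = self.rep_counts[pair]
        return ComplexTimeSeries(
            self.times, c.mean(axis=0), n_replicates=c.shape[0], meta=self.spec
        )

    def loo_series(self, pair: tuple[str, str], drop: int) -> ComplexTimeSeries:
        c = np.delete(self.rep_counts[pair], drop, axis=0)
        return ComplexTimeSeries(
            self.times, c.mean(axis=0), n_replicates=c.shape[0], meta=self.spec
        )

    @property
    def n_replicates(self) -> int:
        return next(iter(self.rep_counts.values())).shape[0]


def _max_bond_extension(state: SystemState) -> float:
    if not state.bonds:
        return 0.0
    box = state.box
    dmax = 0.0
    for i, j, _ in state.bonds:
        d = state.positions[j] - state.positions[i]
        d[0] -= box.lx * round(d[0] / box.lx)
        d[1] -= box.ly * round(d[1] / box.ly)
        dmax = max(dmax, float(np.linalg.norm(d)))
    return dmax


def run_replicate(spec: ExperimentSpec, seed: int | None = None) -> ReplicateResult:
    """Build and propagate one replicate, sampling every
    ``spec.sample_interval`` steps (the t = 0 configuration included)."""
    seed = spec.seed if seed is None else seed
    state = build_initial_state(replace(spec, seed=seed))
    interactions = spec.interactions()
    sim = Simulation(
        state, interactions, kT=spec.kT, dt=spec.dt, seed=seed + 1
    )
    pairs = spec.binding_pairs()
    n_samples = spec.n_steps // spec.sample_interval
    times = np.empty(n_samples + 1)
    counts = {p: np.empty(n_samples + 1) for p in pairs}
    max_ext = _max_bond_extension(state)
    for k in range(n_samples + 1):
        times[k] = state.time
        for p in pairs:
            counts[p][k] = count_bound(state, interactions, p)
        if k < n_samples:
            sim.run(spec.sample_interval, chunk=spec.sample_interval)
            if state.bonds:
                max_ext = max(max_ext, _max_bond_extension(state))
    return ReplicateResult(
        times, counts, state, max_ext, sim.overstretch_events
    )


def run_ensemble(spec: ExperimentSpec) -> EnsembleResult:
    """Run ``spec.n_replicates`` independent replicates."""
    seeds = replicate_seeds(spec.seed, spec.n_replicates)
    pairs = spec.binding_pairs()
    reps: list[ReplicateResult] = [
        run_replicate(spec, seed=s) for s in seeds[: spec.n_replicates]
    ]
    times = reps[0].times
    rep_counts = {
        p: np.vstack([r.counts[p] for r in reps]) for p in pairs
    }
    return EnsembleResult(
        times, rep_counts, spec,
        max_bond_extension=max(r.max_bond_extension for r in reps),
        overstretch_events=sum(r.overstretch_events for r in reps),
    )


def jackknife_stderr(values: np.ndarray) -> float:
    """Standard error of a statistic from its leave-one-out values."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 2:
        return 0.0
    return float(np.sqrt((n - 1) / n * np.sum((v - v.mean()) ** 2)))


def _drop_burn_in(series: ComplexTimeSeries, burn_in: float) -> ComplexTimeSeries:
    keep = series.times >= burn_in
    if keep.sum() < 3:
        return series
    return ComplexTimeSeries(
        series.times[keep], series.counts[keep],
        n_replicates=series.n_replicates, meta=series.meta,
    )


def measure_koff(
    spec: ExperimentSpec,
    ensemble: EnsembleResult | None = None,
    burn_in: float = 5.0,
) -> tuple[ComplexTimeSeries, RateEstimate]:
    """Dissociation protocol: run the ensemble and fit the exponential decay.

    The first ``burn_in`` tau are discarded before fitting: complexes are
    built at the potential minimum, and the bound population needs a few
    tau to equilibrate internally (fast initial loss of the most weakly
    held ligands) before the single-exponential escape regime sets in.
    The returned stderr is the jackknife error over replicates when more
    than one replicate is available (it dominates the fit covariance)."""
    if spec.protocol is not Protocol.DISSOCIATION:
        raise ValueError("measure_koff requires the DISSOCIATION protocol")
    ens = ensemble if ensemble is not None else run_ensemble(spec)
    pair = spec.binding_pairs()[0]
    series = _drop_burn_in(ens.series(pair), burn_in)
    est = estimate_koff(series)
    if ens.n_replicates >= 2:
        loo = [
            estimate_koff(_drop_burn_in(ens.loo_series(pair, r), burn_in)).value
            for r in range(ens.n_replicates)
        ]
        se = jackknife_stderr(np.array(loo))
        est = RateEstimate(est.value, max(est.stderr, se), est.fit_model,
                           est.fit_window, est.gof)
    return series, est


def measure_kon(
    spec: ExperimentSpec, ensemble: EnsembleResult | None = None,
    occupancy_cap: float = 0.2,
) -> tuple[ComplexTimeSeries, RateEstimate]:
    """Association protocol: run the ensemble and fit the short-time slope."""
    if spec.protocol not in (Protocol.ASSOCIATION, Protocol.CHIMERA):
        raise ValueError("measure_kon requires ASSOCIATION or CHIMERA")
    ens = ensemble if ensemble is not None else run_ensemble(spec)
    pair = spec.binding_pairs()[0]
    series = ens.series(pair)
    est = estimate_kon_short_time(
        series, spec.ligand_concentration, spec.n_receptors, occupancy_cap
    )
    if ens.n_replicates >= 2:
        loo = [
            estimate_kon_short_time(
                ens.loo_series(pair, r), spec.ligand_concentration,
                spec.n_receptors, occupancy_cap,
            ).value
            for r in range(ens.n_replicates)
        ]
        se = jackknife_stderr(np.array(loo))
        est = RateEstimate(est.value, max(est.stderr, se), est.fit_model,
                           est.fit_window, est.gof)
    return series, est
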