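"""Complex detection and kon/koff extraction.

A ligand-receptor pair counts as a *complex* when its interaction energy is
below ``-threshold_fraction * epsilon`` (default half the well depth); each
ligand is matched to at most one receptor and vice versa, lowest energy
first.  Dissociation ensembles decay exponentially,
``C(t) = C0 exp(-koff t)``, and association ensembles grow linearly at
short times, ``C(t) ~ kon [L]0 N_R t``, which gives the two fitting
protocols implemented here.  A third estimator recovers kon from the
equilibrium plateau via detailed balance; in a healthy run it agrees with
the short-time estimate within the joint uncertainty.

Rates are reported in reduced units: koff in 1/tau, kon in sigma^3/tau
(a volume per time, like a molar on-rate).
"""

from __future__ import annotations

import enum
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from . import _kernels
from .integrator import SystemState
from .potentials import InteractionKind, InteractionSpec

__all__ = [
    "ComplexTimeSeries",
    "FitModel",
    "RateEstimate",
    "detect_bound_pairs",
    "count_bound",
    "complex_timeseries",
    "estimate_koff",
    "estimate_kon_short_time",
    "estimate_kon_equilibrium",
    "equilibrium_occupancy",
    "rate_vs_diffusion",
    "transport_decomposition",
]

logger = logging.getLogger(__name__)


class FitModel(enum.Enum):
    EXP_DECAY = "exp_decay"
    SHORT_TIME_LINEAR = "short_time_linear"
    EQUILIBRIUM = "equilibrium"


@dataclass
class ComplexTimeSeries:
    """Sampled times and (possibly replicate-averaged) bound-complex counts."""

    times: np.ndarray
    counts: np.ndarray
    n_replicates: int = 1
    meta: object = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.counts.shape:
            raise ValueError("times and counts must be 1-D arrays of equal length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class RateEstimate:
    """A fitted rate constant with its uncertainty and fit diagnostics."""

    value: float
    stderr: float
    fit_model: FitModel
    fit_window: tuple[float, float]
    gof: float  # R^2 of the fit

    def __post_init__(self) -> None:
        if self.value < 0 or self.stderr < 0:
            raise ValueError("rate and stderr must be non-negative")


# ---------------------------------------------------------------------------
# bound-state detection


def _bound_matches(
    energies: np.ndarray, threshold: float
) -> list[tuple[int, int]]:
    """Greedy lowest-energy-first matching of ligands (rows) to receptors."""
    li, ri = np.nonzero(energies < threshold)
    if len(li) == 0:
        return []
    order = np.lexsort((ri, li, energies[li, ri]))
    used_l: set[int] = set()
    used_r: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for k in order:
        l, r = int(li[k]), int(ri[k])
        if l in used_l or r in used_r:
            continue
        used_l.add(l)
        used_r.add(r)
        pairs.append((l, r))
    return pairs


def detect_bound_pairs(
    state: SystemState,
    interactions: dict[tuple[str, str], InteractionSpec],
    energy_threshold_fraction: float = 0.5,
    pair: tuple[str, str] | None = None,
) -> set[tuple[int, int]]:
    """Bound (ligand_index, receptor_index) pairs in a configuration.

    A pair is bound when its angular-LJ energy is below
    ``-energy_threshold_fraction * epsilon``; each particle joins at most
    one complex (lowest energy wins, ties broken by particle id).  With
    ``pair`` given, only that (ligand species, receptor species) channel is
    examined; otherwise all angular channels in the table are.
    """
    if not 0.0 < energy_threshold_fraction < 1.0:
        raise ValueError("energy_threshold_fraction must be in (0, 1)")
    out: set[tuple[int, int]] = set()
    for (lig_name, rec_name), spec in interactions.items():
        if spec.kind is not InteractionKind.ANGULAR_LJ:
            continue
        if pair is not None and (lig_name, rec_name) != tuple(pair):
            continue
        lig_idx = state.indices_of(lig_name)
        rec_idx = state.indices_of(rec_name)
        if len(lig_idx) == 0 or len(rec_idx) == 0:
            continue
        e = np.empty((len(lig_idx), len(rec_idx)))
        _kernels.pair_energy_matrix(
            state.positions[lig_idx], state.positions[rec_idx],
            spec.epsilon, spec.sigma_pair, spec.r_cut, spec.n_geom,
            spec.theta_cut, state.box.lx, state.box.ly, e,
        )
        thr = -energy_threshold_fraction * spec.epsilon
        for l, r in _bound_matches(e, thr):
            out.add((int(lig_idx[l]), int(rec_idx[r])))
    return out


def count_bound(
    state: SystemState,
    interactions: dict[tuple[str, str], InteractionSpec],
    pair: tuple[str, str],
    energy_threshold_fraction: float = 0.5,
) -> int:
    """Number of complexes in one binding channel."""
    return len(
        detect_bound_pairs(state, interactions, energy_threshold_fraction, pair)
    )


def complex_timeseries(
    frames: Sequence[SystemState] | Sequence[Sequence[SystemState]],
    interactions: dict[tuple[str, str], InteractionSpec],
    pair: tuple[str, str] | None = None,
    energy_threshold_fraction: float = 0.5,
) -> ComplexTimeSeries:
    """Per-frame complex counts; replicate sets are averaged frame-wise."""
    if len(frames) == 0:
        raise ValueError("empty trajectory")
    replicates: Sequence[Sequence[SystemState]]
    if isinstance(frames[0], SystemState):
        replicates = [frames]  # type: ignore[list-item]
    else:
        replicates = frames  # type: ignore[assignment]
    if any(len(rep) < 2 for rep in replicates):
        raise ValueError("need at least two frames per trajectory")
    times = np.array([st.time for st in replicates[0]])
    counts = np.zeros((len(replicates), len(times)))
    for r, rep in enumerate(replicates):
        if len(rep) != len(times):
            raise ValueError("replicates must share the sampling grid")
        for k, st in enumerate(rep):
            if pair is None:
                counts[r, k] = len(
                    detect_bound_pairs(st, interactions, energy_threshold_fraction)
                )
            else:
                counts[r, k] = count_bound(
                    st, interactions, pair, energy_threshold_fraction
                )
    return ComplexTimeSeries(times, counts.mean(axis=0), n_replicates=len(replicates))


# ---------------------------------------------------------------------------
# rate estimators


def _r_squared(y: np.ndarray, yhat: np.ndarray, w: np.ndarray | None = None) -> float:
    if w is None:
        w = np.ones_like(y)
    ss_res = float(np.sum(w * (y - yhat) ** 2))
    ss_tot = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


def estimate_koff(
    series: ComplexTimeSeries, noise_floor: float = 5.0
) -> RateEstimate:
    """Dissociation rate from an exponential fit ``C(t) = C0 exp(-koff t)``.

    ``C0`` is fixed to the first sample; the fit window runs until the
    ensemble-averaged count drops below ``noise_floor`` complexes (shot
    noise dominates beyond).  A non-decaying series yields koff = 0 with a
    warning.
    """
    t = series.times
    c = series.counts
    c0 = c[0]
    if c0 <= 0:
        raise ValueError("dissociation series must start with bound complexes")
    if np.all(c == 0):
        raise ValueError("all-zero series")
    below = np.nonzero(c < noise_floor)[0]
    end = int(below[0]) if len(below) else len(c)
    end = max(end, 3)
    tw, cw = t[:end], c[:end]
    if len(tw) < 3:
        raise ValueError("too few points in the fit window")
    # initial guess from a log-linear slope over the decaying part
    pos = cw > 0
    k0 = 0.0
    if pos.sum() >= 2:
        slope = np.polyfit(tw[pos], np.log(cw[pos]), 1)[0]
        k0 = max(-slope, 0.0)
    if k0 < 1e-10:
        warnings.warn("series does not decay; koff ~ 0", stacklevel=2)
        resid = cw - c0
        return RateEstimate(0.0, 0.0, FitModel.EXP_DECAY,
                            (float(tw[0]), float(tw[-1])),
                            _r_squared(cw, np.full_like(cw, c0)))
    t0 = tw[0]

    def model(tt, k):
        # C0 anchors the window start, so a series that begins after an
        # equilibration burn-in is fitted consistently
        return c0 * np.exp(-k * (tt - t0))

    popt, pcov = optimize.curve_fit(
        model, tw, cw, p0=[k0], bounds=(0.0, np.inf), maxfev=10_000
    )
    k = float(popt[0])
    stderr = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else 0.0
    return RateEstimate(
        k, stderr, FitModel.EXP_DECAY, (float(tw[0]), float(tw[-1])),
        _r_squared(cw, model(tw, k)),
    )


def _plateau_level(t: np.ndarray, c: np.ndarray) -> float | None:
    """Mean of the final quartile if the series has genuinely saturated:
    flat in the final quartile (drift below 5% of the level) and already at
    the plateau by the middle of the run.  Returns None otherwise."""
    n = len(t)
    if n < 8:
        return None
    start = int(0.75 * n)
    tw, cw = t[start:], c[start:]
    level = float(cw.mean())
    if level <= 0:
        return None
    slope = float(np.polyfit(tw, cw, 1)[0])
    if abs(slope) * (tw[-1] - tw[0]) > 0.05 * level:
        return None
    crossed = np.nonzero(c >= 0.9 * level)[0]
    if len(crossed) == 0 or crossed[0] > n // 2:
        return None
    return level


def estimate_kon_short_time(
    series: ComplexTimeSeries,
    ligand_conc: float,
    n_receptors: float,
    occupancy_cap: float = 0.2,
) -> RateEstimate:
    """Association rate from the short-time linear regime.

    Fits ``C(t) = slope * t`` through the origin using only samples with
    occupancy at or below ``occupancy_cap`` of the receptors (before
    dissociation and depletion matter), then
    ``kon = slope / ([L]0 * N_R)``.

    When the series saturates well below the receptor cap (fast
    dissociation), the window additionally stops at half the cap fraction
    of the largest observed count, so the fit stays in the linear regime
    rather than averaging over the bend toward the plateau.
    """
    if ligand_conc <= 0 or n_receptors <= 0:
        raise ValueError("ligand_conc and n_receptors must be positive")
    t = series.times
    c = series.counts

    def _window_end(cap: float) -> int:
        mask = c <= cap
        return int(np.argmin(mask)) if not mask.all() else len(c)

    cap = occupancy_cap * float(n_receptors)
    plateau_level = _plateau_level(t, c)
    if plateau_level is not None and plateau_level < float(n_receptors):
        # the series saturates below the receptor cap (dissociation matters
        # early): stay well inside the initial linear regime
        cap = min(cap, 0.5 * occupancy_cap * plateau_level)
    end = _window_end(cap)
    if end < 3:
        # sparse counting statistics: fall back to the plain occupancy cap
        end = _window_end(occupancy_cap * float(n_receptors))
    tw, cw = t[:end], c[:end]
    if len(tw) < 3:
        raise ValueError("fewer than 3 points in the short-time window")
    stt = float(np.sum(tw * tw))
    if stt == 0.0:
        raise ValueError("degenerate time window")
    slope = float(np.sum(tw * cw)) / stt
    resid = cw - slope * tw
    dof = max(len(tw) - 1, 1)
    slope_var = float(np.sum(resid**2)) / dof / stt
    norm = ligand_conc * n_receptors
    kon = max(slope, 0.0) / norm
    return RateEstimate(
        kon, float(np.sqrt(slope_var)) / norm, FitModel.SHORT_TIME_LINEAR,
        (float(tw[0]), float(tw[-1])), _r_squared(cw, slope * tw),
    )


def equilibrium_occupancy(
    series: ComplexTimeSeries, fraction: float = 0.25, strict: bool = True
) -> tuple[float, float]:
    """Mean and standard deviation of the counts over the final ``fraction``
    of the run, after a plateau test (last-quartile slope consistent with
    zero at two standard errors).  ``strict=False`` downgrades a failed
    plateau test to a warning."""
    n = len(series.times)
    start = int((1.0 - fraction) * n)
    tw = series.times[start:]
    cw = series.counts[start:]
    if len(tw) < 4:
        raise ValueError("too few samples for a plateau estimate")
    # successive samples are strongly autocorrelated, so the slope and its
    # uncertainty come from coarse block averages rather than raw points
    n_blocks = min(8, len(tw) // 2)
    edges = np.array_split(np.arange(len(tw)), n_blocks)
    tb = np.array([tw[e].mean() for e in edges])
    cb = np.array([cw[e].mean() for e in edges])
    x = tb - tb.mean()
    sxx = float(np.sum(x * x))
    slope = float(np.sum(x * cb) / sxx)
    resid = cb - cb.mean() - slope * x
    dof = max(n_blocks - 2, 1)
    slope_se = math.sqrt(float(np.sum(resid**2)) / dof / sxx)
    drift = abs(slope) * (tw[-1] - tw[0])
    level = max(cw.mean(), 1e-12)
    plateau = abs(slope) <= 2.0 * slope_se or drift <= 0.05 * level
    if not plateau:
        msg = (
            f"no plateau: last-window slope {slope:.3g} "
            f"+/- {slope_se:.3g} drifts {drift:.3g} over the window"
        )
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    return float(cw.mean()), float(cw.std(ddof=1))


def estimate_kon_equilibrium(
    series: ComplexTimeSeries,
    koff: RateEstimate,
    ligand_conc0: float,
    n_receptors: float,
    volume: float,
) -> RateEstimate:
    """Association rate from the equilibrium condition
    ``kon [L]_eq (N_R - C_eq) = koff C_eq``.

    ``ligand_conc0`` is the initial free-ligand number density and
    ``volume`` the box volume (free ligands are depleted by binding:
    ``[L]_eq = [L]0 - C_eq / V``).
    """
    c_eq, c_sd = equilibrium_occupancy(series)
    t_lo = series.times[int(0.75 * len(series.times))]
    window = (float(t_lo), float(series.times[-1]))
    if c_eq == 0.0:
        return RateEstimate(0.0, 0.0, FitModel.EQUILIBRIUM, window, 1.0)
    free_r = n_receptors - c_eq
    conc_eq = ligand_conc0 - c_eq / volume
    if free_r <= 0 or conc_eq <= 0:
        raise ValueError("saturated system: equilibrium inversion is singular")
    kon = koff.value * c_eq / (conc_eq * free_r)
    # error propagation: koff uncertainty plus C_eq fluctuation
    n_eff = max(len(series.times) // 4, 1)
    c_se = c_sd / np.sqrt(n_eff)
    dlnk_dc = 1.0 / c_eq + 1.0 / free_r + (1.0 / volume) / conc_eq
    rel = np.sqrt(
        (koff.stderr / koff.value) ** 2 + (c_se * dlnk_dc) ** 2
        if koff.value > 0
        else (c_se * dlnk_dc) ** 2
    )
    return RateEstimate(kon, kon * float(rel), FitModel.EQUILIBRIUM, window, 1.0)


# ---------------------------------------------------------------------------
# diffusion dependence


def rate_vs_diffusion(
    results: Sequence[tuple[float, RateEstimate]],
) -> tuple[float, float, float]:
    """Weighted least-squares line through rate(D) points.

    Returns ``(slope, intercept, r_squared)``.  Points are weighted by
    ``1/stderr^2`` where available; a high ``r_squared`` certifies the
    diffusion-limited regime in which measured rates track transport.
    """
    if len(results) < 3:
        raise ValueError("need at least 3 diffusion coefficients")
    d = np.array([float(x) for x, _ in results])
    if len(np.unique(d)) < 3:
        raise ValueError("need at least 3 distinct diffusion coefficients")
    k = np.array([est.value for _, est in results])
    se = np.array([est.stderr for _, est in results])
    if np.all(se > 0):
        w = 1.0 / se**2
    else:
        w = np.ones_like(d)
    sw = w.sum()
    dbar = float(np.sum(w * d) / sw)
    kbar = float(np.sum(w * k) / sw)
    sxx = float(np.sum(w * (d - dbar) ** 2))
    slope = float(np.sum(w * (d - dbar) * (k - kbar)) / sxx)
    intercept = kbar - slope * dbar
    return slope, intercept, _r_squared(k, slope * d + intercept, w)


def transport_decomposition(k_meas: float, k_transport: float) -> float:
    """Intrinsic reaction rate from the transport-limited composition
    ``1/k_meas = 1/k_int + 1/k_T``.

    The measured rate is always below the transport rate; as
    ``k_meas -> k_T`` the intrinsic rate diverges (fully diffusion-limited),
    and as ``k_T -> inf`` the measured rate is purely intrinsic.
    """
    if k_meas <= 0:
        raise ValueError("k_meas must be positive")
    if not np.isinf(k_transport) and k_meas >= k_transport:
        raise ValueError("k_meas >= k_T is unphysical for this composition")
    inv = 1.0 / k_meas - (0.0 if np.isinf(k_transport) else 1.0 / k_transport)
    return 1.0 / inv
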