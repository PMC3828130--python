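"""Synthetic inputs with known ground truth for validating the estimators.

Everything here is generated from closed forms or exact stochastic models
(two-state Markov jump processes, the mass-action rate equation), entirely
independent of the dynamics engine, so the kinetics estimators can be
checked against known rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .integrator import BoxSpec, Domain, SpeciesSpec, SystemState
from .kinetics import ComplexTimeSeries
from .potentials import WCA_CUT_FACTOR

__all__ = [
    "exponential_series",
    "markov_dissociation_series",
    "linear_series",
    "mass_action_series",
    "sample_wlc_chain",
    "scripted_binding_frames",
    "random_state",
]


def exponential_series(
    c0: float, koff: float, times: np.ndarray,
    noise: str | None = None, rng: np.random.Generator | None = None,
) -> ComplexTimeSeries:
    """Deterministic (or Poisson-noised) exponential decay with known rate."""
    times = np.asarray(times, dtype=float)
    mean = c0 * np.exp(-koff * times)
    if noise is None:
        counts = mean
    elif noise == "poisson":
        if rng is None:
            raise ValueError("noisy series need an rng")
        counts = rng.poisson(mean).astype(float)
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    return ComplexTimeSeries(times, counts)


def markov_dissociation_series(
    c0: int, koff: float, times: np.ndarray,
    n_replicates: int, rng: np.random.Generator,
) -> ComplexTimeSeries:
    """Ensemble-averaged survivor counts of a two-state Markov process.

    Each of ``c0`` complexes dissociates independently after an
    exponentially distributed waiting time with rate ``koff`` (no
    rebinding); the exact stochastic realisation of the decay law.
    """
    times = np.asarray(times, dtype=float)
    counts = np.zeros((n_replicates, len(times)))
    for r in range(n_replicates):
        lifetimes = rng.exponential(1.0 / koff, size=c0)
        counts[r] = (lifetimes[None, :] > times[:, None]).sum(axis=1)
    return ComplexTimeSeries(times, counts.mean(axis=0), n_replicates=n_replicates)


def linear_series(
    slope: float, times: np.ndarray,
    noise_sd: float = 0.0, rng: np.random.Generator | None = None,
) -> ComplexTimeSeries:
    """Linear growth through the origin with known slope."""
    times = np.asarray(times, dtype=float)
    counts = slope * times
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noisy series need an rng")
        counts = np.clip(counts + rng.normal(0.0, noise_sd, len(times)), 0.0, None)
    return ComplexTimeSeries(times, counts)


def mass_action_series(
    kon: float, koff: float, ligand_conc0: float,
    n_receptors: float, volume: float, times: np.ndarray,
) -> ComplexTimeSeries:
    """Numerical integration of the mass-action rate equation
    ``dC/dt = kon [L] (N_R - C) - koff C`` with ligand depletion
    ``[L] = [L]0 - C/V``: a saturating association curve with known rates."""
    times = np.asarray(times, dtype=float)

    def rhs(t, c):
        conc = ligand_conc0 - c[0] / volume
        return [kon * conc * (n_receptors - c[0]) - koff * c[0]]

    sol = solve_ivp(
        rhs, (times[0], times[-1]), [0.0], t_eval=times, rtol=1e-10, atol=1e-12
    )
    return ComplexTimeSeries(times, np.clip(sol.y[0], 0.0, None))


def sample_wlc_chain(
    n_monomers: int, monomer_size: float, persistence_length: float,
    n_samples: int, rng: np.random.Generator,
) -> np.ndarray:
    """Monte-Carlo end-to-end distances of discrete worm-like chains.

    Bond directions decorrelate exponentially with correlation
    ``exp(-b / lp)`` per bond, sampled by drawing each bond direction from
    the conical distribution about the previous one whose mean cosine is
    that correlation.  Serves as the independent oracle for the
    interpolated mean-extension formula.
    """
    corr = math.exp(-monomer_size / persistence_length)
    out = np.empty(n_samples)
    for s in range(n_samples):
        d = np.array([0.0, 0.0, 1.0])
        end = np.zeros(3)
        for _ in range(n_monomers):
            end += monomer_size * d
            # sample cos(angle to d) with mean corr: use exponential-ish
            # distribution p(c) ~ exp(kappa c) with kappa solving the mean
            d = _next_direction(d, corr, rng)
        out[s] = np.linalg.norm(end)
    return out


def _kappa_from_mean_cosine(m: float) -> float:
    """Invert <cos> = coth(kappa) - 1/kappa (von Mises-Fisher mean)."""
    if m <= 0:
        return 1e-6
    k = max(3 * m / (1 - m * m), 1e-6)  # standard starting approximation
    for _ in range(50):
        f = 1.0 / math.tanh(k) - 1.0 / k - m
        df = -1.0 / math.sinh(k) ** 2 + 1.0 / k**2
        step = f / df
        k -= step
        if abs(step) < 1e-12:
            break
    return k


def _next_direction(
    d: np.ndarray, mean_cos: float, rng: np.random.Generator
) -> np.ndarray:
    kappa = _kappa_from_mean_cosine(mean_cos)
    # sample cos(theta) from the von Mises-Fisher marginal on the sphere
    u = rng.random()
    c = 1.0 + math.log(u + (1.0 - u) * math.exp(-2.0 * kappa)) / kappa
    phi = 2.0 * math.pi * rng.random()
    s = math.sqrt(max(1.0 - c * c, 0.0))
    # orthonormal frame around d
    a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return c * d + s * (math.cos(phi) * e1 + math.sin(phi) * e2)


def _two_species() -> list[SpeciesSpec]:
    return [
        SpeciesSpec("L", 0.5, 1.0, 0.1, Domain.BULK_3D),
        SpeciesSpec("R", 1.0, 2.0, 0.0, Domain.MEMBRANE_2D),
    ]


def scripted_binding_frames(
    bound_schedule: list[list[int]],
    box: BoxSpec | None = None,
    dt_sample: float = 1.0,
) -> list[SystemState]:
    """Trajectory frames with an exactly scripted set of bound pairs.

    ``bound_schedule[k]`` lists which of the receptors are bound in frame
    ``k``; bound ligands sit at the on-axis potential minimum, unbound ones
    far above the membrane.  The number of receptors is the largest index
    mentioned plus one (at least one).
    """
    n_r = max((max(frame) + 1 for frame in bound_schedule if frame), default=1)
    box = box or BoxSpec(max(4.0 * n_r, 8.0), max(4.0 * n_r, 8.0), 12.0)
    species = _two_species()
    sigma_lr = 0.75
    z_bind = WCA_CUT_FACTOR * sigma_lr
    rec_x = (np.arange(n_r) + 0.5) * (box.lx / n_r)
    frames = []
    for k, bound in enumerate(bound_schedule):
        pos = np.zeros((2 * n_r, 3))
        pos[:n_r, 0] = rec_x
        pos[:n_r, 1] = 0.5 * box.ly
        pos[n_r:, 0] = rec_x
        pos[n_r:, 1] = 0.5 * box.ly
        pos[n_r:, 2] = 0.8 * box.lz  # parked far from every receptor
        for r in bound:
            pos[n_r + r, 2] = z_bind
        spidx = np.concatenate(
            [np.full(n_r, 1, dtype=np.int64), np.zeros(n_r, dtype=np.int64)]
        )
        vel = np.zeros_like(pos)
        frames.append(
            SystemState(pos, vel, spidx, species, box, time=k * dt_sample)
        )
    return frames


def random_state(
    n_ligands: int, n_receptors: int, box: BoxSpec,
    rng: np.random.Generator, min_sep: float = 0.6,
) -> SystemState:
    """Small random mixed system for force/integrator tests."""
    species = _two_species()
    n = n_ligands + n_receptors
    pos = np.empty((n, 3))
    k = 0
    tries = 0
    while k < n:
        tries += 1
        if tries > 100_000:
            raise RuntimeError("random_state placement failed")
        is_rec = k < n_receptors
        cand = np.array([
            rng.random() * box.lx,
            rng.random() * box.ly,
            0.0 if is_rec else 0.3 + rng.random() * (box.lz - 0.6),
        ])
        if k:
            d = pos[:k] - cand
            d[:, 0] -= box.lx * np.round(d[:, 0] / box.lx)
            d[:, 1] -= box.ly * np.round(d[:, 1] / box.ly)
            if np.min(np.linalg.norm(d, axis=1)) < min_sep:
                continue
        pos[k] = cand
        k += 1
    spidx = np.concatenate([
        np.full(n_receptors, 1, dtype=np.int64),
        np.zeros(n_ligands, dtype=np.int64),
    ])
    vel = rng.standard_normal((n, 3))
    vel[:n_receptors] = 0.0
    return SystemState(pos, vel, spidx, species, box)
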