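"""Langevin dynamics of mixed-dimensionality particles in a periodic box.

Ligands are bulk (3-D) particles; receptors live in the membrane plane
z = 0 and diffuse in 2-D (or are frozen when their diffusion coefficient is
zero).  Propagation uses velocity Verlet with the BAOAB Langevin splitting,
with per-species friction ``gamma = kBT / (mass * D)`` so that each species
reproduces its configured diffusion coefficient in the free limit.

Reduced units throughout: lengths in receptor diameters ``sigma_R``,
energies in ``eps0``, masses in ligand masses, time in
``tau = sigma_R * sqrt(m_L / eps0)``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .potentials import InteractionKind, InteractionSpec, LinkerSpec

__all__ = [
    "Domain",
    "SpeciesSpec",
    "BoxSpec",
    "SystemState",
    "compute_forces",
    "langevin_step",
    "Simulation",
    "DEFAULT_DT",
]

#: Default timestep in units of tau.
DEFAULT_DT: float = 0.002


class Domain(enum.Enum):
    BULK_3D = "bulk"
    MEMBRANE_2D = "membrane"


@dataclass(frozen=True)
class SpeciesSpec:
    """One particle species.

    ``diffusion == 0`` freezes the species in place (used when receptor
    diffusion is neglected in the monovalent protocols).
    """

    name: str
    sigma: float
    mass: float
    diffusion: float
    domain: Domain

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.mass <= 0:
            raise ValueError("sigma and mass must be positive")
        if self.diffusion < 0:
            raise ValueError("diffusion must be non-negative")

    def gamma(self, kT: float) -> float:
        """Langevin friction from the Einstein relation (inf when frozen)."""
        if self.diffusion == 0.0:
            return math.inf
        return kT / (self.mass * self.diffusion)


@dataclass(frozen=True)
class BoxSpec:
    """Simulation box: periodic in x, y; reflective walls in z."""

    lx: float
    ly: float
    lz: float

    def __post_init__(self) -> None:
        if min(self.lx, self.ly, self.lz) <= 0:
            raise ValueError("box dimensions must be positive")

    @classmethod
    def from_surface_density(
        cls, n_receptors: int, surface_density: float, lz: float
    ) -> "BoxSpec":
        """Square lateral box sized so that ``n_receptors`` particles give
        the requested number per unit area."""
        if n_receptors <= 0 or surface_density <= 0:
            raise ValueError("need n_receptors > 0 and surface_density > 0")
        side = math.sqrt(n_receptors / surface_density)
        return cls(side, side, lz)

    @property
    def area(self) -> float:
        return self.lx * self.ly

    @property
    def volume(self) -> float:
        return self.lx * self.ly * self.lz


@dataclass
class SystemState:
    """Positions/velocities/species of all particles; the single source of
    truth for the integrator."""

    positions: np.ndarray  # (N, 3)
    velocities: np.ndarray  # (N, 3)
    species_index: np.ndarray  # (N,) int
    species: list[SpeciesSpec]
    box: BoxSpec
    bonds: list[tuple[int, int, LinkerSpec]] = field(default_factory=list)
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.species_index = np.ascontiguousarray(self.species_index, dtype=np.int64)
        n = self.positions.shape[0]
        if self.velocities.shape != (n, 3) or self.species_index.shape != (n,):
            raise ValueError("inconsistent array shapes")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def indices_of(self, species_name: str) -> np.ndarray:
        idx = self._species_id(species_name)
        return np.nonzero(self.species_index == idx)[0]

    def _species_id(self, name: str) -> int:
        for i, sp in enumerate(self.species):
            if sp.name == name:
                return i
        raise KeyError(f"unknown species {name!r}")

    def copy(self) -> "SystemState":
        return SystemState(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            species_index=self.species_index.copy(),
            species=list(self.species),
            box=self.box,
            bonds=list(self.bonds),
            time=self.time,
        )


# ---------------------------------------------------------------------------
# parameter tables


class _ParamTables:
    """Dense species-pair parameter matrices consumed by the kernels."""

    def __init__(
        self,
        species: list[SpeciesSpec],
        interactions: dict[tuple[str, str], InteractionSpec],
        kT: float,
        default_eps0: float = 1.0,
    ) -> None:
        s = len(species)
        names = {sp.name: i for i, sp in enumerate(species)}
        self.kind = np.full((s, s), _kernels.KIND_REPULSIVE, dtype=np.int8)
        self.eps = np.full((s, s), default_eps0, dtype=np.float64)
        self.sig = np.zeros((s, s), dtype=np.float64)
        self.rcut = np.zeros((s, s), dtype=np.float64)
        self.ngeom = np.zeros((s, s), dtype=np.float64)
        self.thcut = np.full((s, s), 0.5 * math.pi, dtype=np.float64)
        self.axis = np.zeros((s, s), dtype=np.int8)
        # defaults: WCA with the arithmetic mixing rule
        for i in range(s):
            for j in range(s):
                sij = 0.5 * (species[i].sigma + species[j].sigma)
                self.sig[i, j] = sij
                self.rcut[i, j] = 2.0 ** (1.0 / 6.0) * sij
        for (a, b), spec in interactions.items():
            i, j = names[a], names[b]
            self.sig[i, j] = self.sig[j, i] = spec.sigma_pair
            self.eps[i, j] = self.eps[j, i] = spec.epsilon
            self.rcut[i, j] = self.rcut[j, i] = spec.r_cut
            if spec.kind in (InteractionKind.WCA, InteractionKind.STERIC):
                self.kind[i, j] = self.kind[j, i] = _kernels.KIND_REPULSIVE
            elif spec.kind is InteractionKind.ANGULAR_LJ:
                self.kind[i, j] = self.kind[j, i] = _kernels.KIND_ANGULAR
                self.ngeom[i, j] = self.ngeom[j, i] = spec.n_geom
                self.thcut[i, j] = self.thcut[j, i] = spec.theta_cut
                # key order is (ligand, receptor): the receptor owns the axis
                rec = j
                if species[rec].domain is not Domain.MEMBRANE_2D and (
                    species[i].domain is Domain.MEMBRANE_2D
                ):
                    rec = i
                self.axis[i, j] = 1 if rec == i else 2
                self.axis[j, i] = 1 if rec == j else 2
            else:
                raise ValueError(
                    f"interaction table entries must be WCA/STERIC/ANGULAR_LJ, "
                    f"got {spec.kind} for pair ({a}, {b})"
                )
        # derived matrices consumed by the kernels
        self.sig2 = self.sig**2
        self.rcut2 = self.rcut**2
        src6 = (self.sig / self.rcut) ** 6
        self.rep_shift = 4.0 * self.eps * src6**2
        self.att_shift = 4.0 * self.eps * src6
        self.rmax = float(self.rcut.max())
        self.mass_s = np.array([sp.mass for sp in species])
        self.sigma_s = np.array([sp.sigma for sp in species])
        self.membrane_s = np.array(
            [1 if sp.domain is Domain.MEMBRANE_2D else 0 for sp in species],
            dtype=np.int8,
        )
        self.mobile_s = np.array(
            [0 if sp.diffusion == 0.0 else 1 for sp in species], dtype=np.int8
        )
        self.gamma_s = np.array(
            [sp.gamma(kT) if sp.diffusion > 0 else 0.0 for sp in species]
        )


def _bond_arrays(bonds: list[tuple[int, int, LinkerSpec]]):
    nb = len(bonds)
    bi = np.empty(nb, dtype=np.int64)
    bj = np.empty(nb, dtype=np.int64)
    bl0 = np.empty(nb, dtype=np.float64)
    bklp = np.empty(nb, dtype=np.float64)
    bfmax = np.empty(nb, dtype=np.float64)
    for k, (i, j, linker) in enumerate(bonds):
        bi[k] = i
        bj[k] = j
        bl0[k] = linker.contour_length
        bklp[k] = linker.temperature / linker.persistence_length
        bfmax[k] = linker.max_force
    return bi, bj, bl0, bklp, bfmax


def compute_forces(
    state: SystemState,
    interactions: dict[tuple[str, str], InteractionSpec],
    kT: float = 1.0,
    method: str = "auto",
) -> tuple[np.ndarray, float]:
    """Forces on every particle and the total potential energy.

    ``method`` selects the pair loop: ``"all_pairs"``, ``"cell_list"`` or
    ``"auto"`` (cell list when the box accommodates at least three cells per
    periodic dimension and the system is large enough to pay off).
    Raises ``ValueError`` for overlapping particles (r < 1e-6 sigma) and for
    cutoffs larger than half the smallest periodic box dimension.
    """
    tables = _ParamTables(state.species, interactions, kT)
    box = state.box
    if tables.rmax > 0.5 * min(box.lx, box.ly):
        raise ValueError("interaction cutoff exceeds half the periodic box size")
    forces = np.zeros_like(state.positions)
    bi, bj, bl0, bklp, bfmax = _bond_arrays(state.bonds)
    use_cells = _should_use_cells(method, state, tables)
    if use_cells:
        epot, err, _ = _kernels.forces_celllist(
            state.positions, state.species_index,
            tables.kind, tables.eps, tables.sig2, tables.rcut2,
            tables.rep_shift, tables.att_shift,
            tables.ngeom, tables.thcut, tables.axis,
            bi, bj, bl0, bklp, bfmax, box.lx, box.ly, box.lz, tables.rmax, forces,
        )
    else:
        epot, err, _ = _kernels.forces_allpairs(
            state.positions, state.species_index,
            tables.kind, tables.eps, tables.sig2, tables.rcut2,
            tables.rep_shift, tables.att_shift,
            tables.ngeom, tables.thcut, tables.axis,
            bi, bj, bl0, bklp, bfmax, box.lx, box.ly, forces,
        )
    if err != 0:
        raise ValueError("overlapping particles (r < 1e-6 sigma): bad configuration")
    return forces, float(epot)


def _should_use_cells(method: str, state: SystemState, tables: "_ParamTables") -> bool:
    if method == "all_pairs":
        return False
    box = state.box
    fits = (
        int(box.lx / tables.rmax) >= 3
        and int(box.ly / tables.rmax) >= 3
    )
    if method == "cell_list":
        if not fits:
            raise ValueError("box too small for a cell list at this cutoff")
        return True
    if method != "auto":
        raise ValueError(f"unknown force method {method!r}")
    n = state.n_particles
    ncell = (
        max(int(box.lx / tables.rmax), 1)
        * max(int(box.ly / tables.rmax), 1)
        * max(int(box.lz / tables.rmax), 1)
    )
    # very dilute systems: rebuilding a huge, mostly-empty grid every step
    # costs more than the O(N^2) loop saves
    return fits and n >= 64 and ncell <= max(12 * n, 4096)


# ---------------------------------------------------------------------------
# propagation


class Simulation:
    """Owns a :class:`SystemState` plus interaction table and propagates it.

    Parameters
    ----------
    state:
        Initial configuration (propagated in place).
    interactions:
        Mapping ``(species_a, species_b) -> InteractionSpec``; angular-LJ
        entries are keyed ``(ligand, receptor)``.  Unlisted pairs default to
        WCA repulsion with the mixed diameter.
    kT:
        Thermostat temperature (energy units).
    dt:
        Timestep in tau; the default 0.002 tau keeps the stiff core of the
        LJ potential stable at the well depths used here.
    seed:
        Seed of the noise stream; identical seed + state gives a
        bit-identical trajectory on the same platform.
    """

    def __init__(
        self,
        state: SystemState,
        interactions: dict[tuple[str, str], InteractionSpec],
        kT: float = 1.0,
        dt: float = DEFAULT_DT,
        seed: int = 0,
        force_method: str = "auto",
    ) -> None:
        if dt <= 0 or dt > 0.005:
            raise ValueError("dt must be in (0, 0.005] tau")
        self.state = state
        self.interactions = dict(interactions)
        self.kT = float(kT)
        self.dt = float(dt)
        self.rng = np.random.default_rng(seed)
        self.tables = _ParamTables(state.species, self.interactions, self.kT)
        if self.tables.rmax > 0.5 * min(state.box.lx, state.box.ly):
            raise ValueError("interaction cutoff exceeds half the periodic box size")
        self._bonds = _bond_arrays(state.bonds)
        self._use_cells = _should_use_cells(force_method, state, self.tables)
        self.forces, self.potential_energy = compute_forces(
            state, self.interactions, self.kT,
            "cell_list" if self._use_cells else "all_pairs",
        )
        self.overstretch_events = 0

    def run(self, n_steps: int, chunk: int = 500) -> None:
        """Advance ``n_steps`` timesteps."""
        box = self.state.box
        bi, bj, bl0, bklp, bfmax = self._bonds
        remaining = n_steps
        while remaining > 0:
            nsub = min(chunk, remaining)
            noise = self.rng.standard_normal((nsub, self.state.n_particles, 3))
            epot, err, n_over = _kernels.baoab_chunk(
                self.state.positions, self.state.velocities,
                self.state.species_index,
                self.tables.mass_s, self.tables.gamma_s,
                self.tables.mobile_s, self.tables.membrane_s, self.tables.sigma_s,
                self.tables.kind, self.tables.eps, self.tables.sig2,
                self.tables.rcut2, self.tables.rep_shift, self.tables.att_shift,
                self.tables.ngeom, self.tables.thcut, self.tables.axis,
                bi, bj, bl0, bklp, bfmax,
                box.lx, box.ly, box.lz, self.kT, self.dt,
                noise, self.forces, self._use_cells, self.tables.rmax,
            )
            if err != 0:
                raise ValueError("particle overlap during propagation")
            if not np.all(np.isfinite(self.state.positions)):
                bad = np.nonzero(~np.isfinite(self.state.positions).all(axis=1))[0]
                raise FloatingPointError(
                    f"non-finite coordinates for particles {bad[:10].tolist()} "
                    f"at t={self.state.time:.4f}"
                )
            self.potential_energy = float(epot)
            self.overstretch_events += int(n_over)
            self.state.time += nsub * self.dt
            remaining -= nsub

    def kinetic_energy(self) -> float:
        v = self.state.velocities
        m = self.tables.mass_s[self.state.species_index]
        return float(0.5 * np.sum(m[:, None] * v * v))

    def n_dof(self) -> int:
        """Translational degrees of freedom of all mobile particles."""
        dof = 0
        for i, sp in enumerate(self.state.species):
            n = int(np.sum(self.state.species_index == i))
            if sp.diffusion == 0.0:
                continue
            dof += n * (2 if sp.domain is Domain.MEMBRANE_2D else 3)
        return dof

    def instantaneous_temperature(self) -> float:
        dof = self.n_dof()
        if dof == 0:
            return 0.0
        return 2.0 * self.kinetic_energy() / dof


def langevin_step(
    state: SystemState,
    interactions: dict[tuple[str, str], InteractionSpec],
    dt: float = DEFAULT_DT,
    kT: float = 1.0,
    seed: int = 0,
) -> SystemState:
    """Single BAOAB step returning a new state (convenience wrapper).

    For production runs construct a :class:`Simulation` once and call
    :meth:`Simulation.run`; this wrapper rebuilds the parameter tables each
    call.
    """
    sim = Simulation(state.copy(), interactions, kT=kT, dt=dt, seed=seed)
    sim.run(1)
    return sim.state


def maxwell_boltzmann_velocities(
    species: list[SpeciesSpec],
    species_index: np.ndarray,
    kT: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Thermal velocities; membrane species get zero z-component and frozen
    species zero velocity."""
    n = len(species_index)
    v = rng.standard_normal((n, 3))
    for i, sp in enumerate(species):
        mask = species_index == i
        v[mask] *= math.sqrt(kT / sp.mass)
        if sp.domain is Domain.MEMBRANE_2D:
            v[mask, 2] = 0.0
        if sp.diffusion == 0.0:
            v[mask] = 0.0
    return v
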