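"""Builders for the three experiment protocols.

* **dissociation** — every receptor starts with a ligand bound at the
  on-axis potential minimum, no free ligands, a tall box and low receptor
  density so unbound ligands rarely rebind.
* **association** — all receptors start unbound; free ligands are placed
  uniformly in the bulk outside every receptor's interaction range.
* **chimera** — two diffusing membrane receptor species (AER, TER) and
  bivalent ligands (AE + TE beads joined by a worm-like-chain linker)
  placed in the bulk at the linker's equilibrium extension.

Receptor in-plane positions come from minimum-separation rejection
sampling; initial velocities are Maxwell-Boltzmann at the run temperature.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .integrator import (
    BoxSpec,
    Domain,
    SpeciesSpec,
    SystemState,
    maxwell_boltzmann_velocities,
)
from .potentials import (
    WCA_CUT_FACTOR,
    InteractionKind,
    InteractionSpec,
    LinkerSpec,
    wlc_mean_extension,
)

__all__ = ["Protocol", "ExperimentSpec", "build_dissociation", "build_association",
           "build_chimera", "build_initial_state"]

_MAX_TRIES = 10_000


class Protocol(enum.Enum):
    DISSOCIATION = "dissociation"
    ASSOCIATION = "association"
    CHIMERA = "chimera"


@dataclass(frozen=True)
class ExperimentSpec:
    """High-level description of one simulation experiment.

    All quantities are in reduced units (lengths sigma_R, energies eps0,
    times tau).  ``n_receptors`` is the activity-receptor count (N_R for the
    monovalent protocols, N_AER for the chimera protocol); ``n_ter`` is the
    targeting-receptor count and only meaningful for CHIMERA.
    ``ligand_concentration`` is a bulk number density: free monovalent
    ligands for ASSOCIATION, whole chimeras for CHIMERA.
    """

    protocol: Protocol
    n_receptors: int
    n_ter: int = 0
    ligand_concentration: float = 0.0
    surface_density: float = 0.01
    box_height: float = 20.0
    # ligand-receptor interaction (AE-AER for the chimera protocol)
    epsilon: float = 5.0
    n_geom: float = 1.0
    theta_cut: float = 0.5 * math.pi
    # targeting interaction (chimera protocol only)
    eps_te: float = 10.0
    n_geom_te: float = 2.0
    linker: LinkerSpec | None = None
    #: start every chimera with its TE bound to a TER (one chimera per TER,
    #: no bulk chimeras) -- the surface-only control for linker sweeps
    prebound_te: bool = False
    # species parameters
    sigma_ligand: float = 0.5
    sigma_receptor: float = 1.0
    mass_ligand: float = 1.0
    mass_receptor: float = 2.0
    d_ligand: float = 0.1
    d_receptor: float = 0.0
    kT: float = 1.0
    # run protocol
    dt: float = 0.002
    n_steps: int = 100_000
    sample_interval: int = 500
    n_replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_receptors < 0 or self.n_ter < 0:
            raise ValueError("receptor counts must be non-negative")
        if self.ligand_concentration < 0:
            raise ValueError("ligand_concentration must be non-negative")
        if self.protocol is Protocol.CHIMERA and self.linker is None:
            raise ValueError("chimera protocol requires a linker")

    # ---- derived geometry -------------------------------------------------
    @property
    def sigma_lr(self) -> float:
        return 0.5 * (self.sigma_ligand + self.sigma_receptor)

    def box(self) -> BoxSpec:
        # lateral size from the *activity*-receptor surface density, so a
        # sweep over targeting-receptor abundance keeps the cell area fixed
        return BoxSpec.from_surface_density(
            max(self.n_receptors, 1), self.surface_density, self.box_height
        )

    # ---- species / interaction tables ------------------------------------
    def species(self) -> list[SpeciesSpec]:
        if self.protocol is Protocol.CHIMERA:
            return [
                SpeciesSpec("AE", self.sigma_ligand, self.mass_ligand,
                            self.d_ligand, Domain.BULK_3D),
                SpeciesSpec("TE", self.sigma_ligand, self.mass_ligand,
                            self.d_ligand, Domain.BULK_3D),
                SpeciesSpec("AER", self.sigma_receptor, self.mass_receptor,
                            self.d_receptor, Domain.MEMBRANE_2D),
                SpeciesSpec("TER", self.sigma_receptor, self.mass_receptor,
                            self.d_receptor, Domain.MEMBRANE_2D),
            ]
        return [
            SpeciesSpec("L", self.sigma_ligand, self.mass_ligand,
                        self.d_ligand, Domain.BULK_3D),
            SpeciesSpec("R", self.sigma_receptor, self.mass_receptor,
                        self.d_receptor, Domain.MEMBRANE_2D),
        ]

    def interactions(self) -> dict[tuple[str, str], InteractionSpec]:
        def angular(eps: float, n: float) -> InteractionSpec:
            return InteractionSpec(
                kind=InteractionKind.ANGULAR_LJ,
                epsilon=eps,
                sigma_pair=self.sigma_lr,
                n_geom=n,
                theta_cut=self.theta_cut,
            )

        if self.protocol is Protocol.CHIMERA:
            return {
                ("AE", "AER"): angular(self.epsilon, self.n_geom),
                ("TE", "TER"): angular(self.eps_te, self.n_geom_te),
            }
        return {("L", "R"): angular(self.epsilon, self.n_geom)}

    def binding_pairs(self) -> list[tuple[str, str]]:
        """(ligand, receptor) species pairs that can form complexes."""
        if self.protocol is Protocol.CHIMERA:
            return [("AE", "AER"), ("TE", "TER")]
        return [("L", "R")]


# ---------------------------------------------------------------------------
# placement helpers


def _place_in_plane(
    n: int, box: BoxSpec, min_sep: float, rng: np.random.Generator,
    existing: np.ndarray | None = None,
) -> np.ndarray:
    """Uniform random x-y positions with a minimum pair separation."""
    placed = np.empty((n, 2))
    prior = existing[:, :2] if existing is not None and len(existing) else None
    for i in range(n):
        for attempt in range(_MAX_TRIES):
            cand = rng.random(2) * (box.lx, box.ly)
            ok = True
            pool = placed[:i]
            for ref in (pool, prior):
                if ref is None or len(ref) == 0:
                    continue
                d = ref - cand
                d[:, 0] -= box.lx * np.round(d[:, 0] / box.lx)
                d[:, 1] -= box.ly * np.round(d[:, 1] / box.ly)
                if np.min(np.hypot(d[:, 0], d[:, 1])) < min_sep:
                    ok = False
                    break
            if ok:
                placed[i] = cand
                break
        else:
            raise RuntimeError(
                f"could not place particle {i} of {n} at min separation "
                f"{min_sep}; surface density too high"
            )
    return placed


def _min_image_dist(a: np.ndarray, b: np.ndarray, box: BoxSpec) -> np.ndarray:
    """Distances from each row of *a* to point *b* (min image in x, y)."""
    d = a - b
    d[:, 0] -= box.lx * np.round(d[:, 0] / box.lx)
    d[:, 1] -= box.ly * np.round(d[:, 1] / box.ly)
    return np.linalg.norm(d, axis=1)


def _place_in_bulk(
    n: int, box: BoxSpec, sigma: float, z_min: float,
    rng: np.random.Generator,
    keep_away: list[tuple[np.ndarray, float]],
) -> np.ndarray:
    """Uniform random bulk positions keeping clearances from prior particles.

    ``keep_away`` is a list of (positions, min_distance) constraints.
    """
    placed = np.empty((n, 3))
    lo = max(0.5 * sigma, z_min)
    hi = box.lz - 0.5 * sigma
    if hi <= lo:
        raise ValueError("box too short to place bulk particles")
    for i in range(n):
        for attempt in range(_MAX_TRIES):
            cand = np.array([
                rng.random() * box.lx,
                rng.random() * box.ly,
                lo + rng.random() * (hi - lo),
            ])
            ok = True
            for ref, dmin in keep_away:
                if len(ref) and np.min(_min_image_dist(ref, cand, box)) < dmin:
                    ok = False
                    break
            if ok and i > 0:
                if np.min(_min_image_dist(placed[:i], cand, box)) < 0.9 * sigma:
                    ok = False
            if ok:
                placed[i] = cand
                break
        else:
            raise RuntimeError(f"could not place bulk particle {i} of {n}")
    return placed


# ---------------------------------------------------------------------------
# builders


def build_dissociation(spec: ExperimentSpec) -> SystemState:
    """All receptors bound (one ligand each at the on-axis minimum), no free
    ligands: the C(0) = N_R initial condition for measuring koff."""
    if spec.protocol is not Protocol.DISSOCIATION:
        raise ValueError("spec.protocol must be DISSOCIATION")
    rng = np.random.default_rng(spec.seed)
    box = spec.box()
    species = spec.species()
    n_r = spec.n_receptors
    rec_xy = _place_in_plane(n_r, box, spec.sigma_receptor, rng)
    z_bind = WCA_CUT_FACTOR * spec.sigma_lr
    pos = np.zeros((2 * n_r, 3))
    pos[:n_r, :2] = rec_xy  # receptors, z = 0
    pos[n_r:, :2] = rec_xy
    pos[n_r:, 2] = z_bind  # one ligand at the minimum above each receptor
    spidx = np.concatenate([
        np.full(n_r, 1, dtype=np.int64),  # R
        np.zeros(n_r, dtype=np.int64),    # L
    ])
    vel = maxwell_boltzmann_velocities(species, spidx, spec.kT, rng)
    return SystemState(pos, vel, spidx, species, box)


def build_association(spec: ExperimentSpec) -> SystemState:
    """All receptors unbound; free ligands at the requested concentration,
    placed outside every receptor's interaction range (C(0) = 0)."""
    if spec.protocol is not Protocol.ASSOCIATION:
        raise ValueError("spec.protocol must be ASSOCIATION")
    rng = np.random.default_rng(spec.seed)
    box = spec.box()
    species = spec.species()
    n_r = spec.n_receptors
    n_l = int(round(spec.ligand_concentration * box.volume))
    rec_xy = _place_in_plane(n_r, box, spec.sigma_receptor, rng)
    rec_pos = np.zeros((n_r, 3))
    rec_pos[:, :2] = rec_xy
    r_cut = spec.interactions()[("L", "R")].r_cut
    lig_pos = _place_in_bulk(
        n_l, box, spec.sigma_ligand, z_min=0.0, rng=rng,
        keep_away=[(rec_pos, r_cut)],
    )
    pos = np.vstack([rec_pos, lig_pos]) if n_l else rec_pos
    spidx = np.concatenate([
        np.full(n_r, 1, dtype=np.int64),
        np.zeros(n_l, dtype=np.int64),
    ])
    vel = maxwell_boltzmann_velocities(species, spidx, spec.kT, rng)
    return SystemState(pos, vel, spidx, species, box)


def build_chimera(spec: ExperimentSpec) -> SystemState:
    """Two diffusing receptor species in the plane plus bivalent AE-TE
    chimeras in the bulk, each pair bonded by the worm-like-chain linker and
    separated by its equilibrium mean extension."""
    if spec.protocol is not Protocol.CHIMERA:
        raise ValueError("spec.protocol must be CHIMERA")
    if spec.linker is None:
        raise ValueError("chimera protocol requires a linker")
    rng = np.random.default_rng(spec.seed)
    box = spec.box()
    species = spec.species()
    n_aer, n_ter = spec.n_receptors, spec.n_ter
    n_chim = int(round(spec.ligand_concentration * box.volume))
    rec_xy = _place_in_plane(n_aer + n_ter, box, spec.sigma_receptor, rng)
    rec_pos = np.zeros((n_aer + n_ter, 3))
    rec_pos[:, :2] = rec_xy
    sep = wlc_mean_extension(spec.linker)
    sigma = spec.sigma_ligand
    lo = 0.5 * sigma
    hi = box.lz - 0.5 * sigma
    if hi - lo <= sep:
        raise ValueError("box too short for the linker extension")
    if spec.prebound_te:
        return _assemble_chimera_prebound(
            spec, box, species, rec_pos, n_aer, n_ter, sep, rng
        )
    chim_pos = np.empty((2 * n_chim, 3))
    for i in range(n_chim):
        for attempt in range(_MAX_TRIES):
            ae = np.array([
                rng.random() * box.lx,
                rng.random() * box.ly,
                lo + rng.random() * (hi - lo),
            ])
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            te = ae + sep * u
            if not (lo <= te[2] <= hi):
                continue
            te[0] %= box.lx
            te[1] %= box.ly
            prior = chim_pos[: 2 * i]
            ok = True
            for cand in (ae, te):
                if np.min(_min_image_dist(rec_pos, cand, box)) < 0.9 * spec.sigma_lr:
                    ok = False
                    break
                if len(prior) and np.min(
                    _min_image_dist(prior, cand, box)
                ) < 0.9 * sigma:
                    ok = False
                    break
            if ok:
                chim_pos[2 * i] = ae
                chim_pos[2 * i + 1] = te
                break
        else:
            raise RuntimeError(f"could not place chimera {i} of {n_chim}")
    n_rec = n_aer + n_ter
    pos = np.vstack([rec_pos, chim_pos]) if n_chim else rec_pos
    spidx = np.concatenate([
        np.full(n_aer, 2, dtype=np.int64),   # AER
        np.full(n_ter, 3, dtype=np.int64),   # TER
        np.tile([0, 1], n_chim).astype(np.int64),  # AE, TE alternating
    ])
    vel = maxwell_boltzmann_velocities(species, spidx, spec.kT, rng)
    bonds = [
        (n_rec + 2 * i, n_rec + 2 * i + 1, spec.linker) for i in range(n_chim)
    ]
    return SystemState(pos, vel, spidx, species, box, bonds=bonds)


def _assemble_chimera_prebound(
    spec: ExperimentSpec,
    box: BoxSpec,
    species: list[SpeciesSpec],
    rec_pos: np.ndarray,
    n_aer: int,
    n_ter: int,
    sep: float,
    rng: np.random.Generator,
) -> SystemState:
    """Surface-only control: one chimera per TER, TE at the binding minimum."""
    z_bind = WCA_CUT_FACTOR * spec.sigma_lr
    n_chim = n_ter
    chim_pos = np.empty((2 * n_chim, 3))
    ter_pos = rec_pos[n_aer:]
    lo = 0.5 * spec.sigma_ligand
    hi = box.lz - 0.5 * spec.sigma_ligand
    for i in range(n_ter):
        te = ter_pos[i] + np.array([0.0, 0.0, z_bind])
        for attempt in range(_MAX_TRIES):
            u = rng.standard_normal(3)
            u[2] = abs(u[2])  # keep the AE above the membrane
            u /= np.linalg.norm(u)
            ae = te + sep * u
            if lo <= ae[2] <= hi:
                break
        else:
            raise RuntimeError("could not orient prebound chimera")
        ae[0] %= box.lx
        ae[1] %= box.ly
        chim_pos[2 * i] = ae
        chim_pos[2 * i + 1] = te
    n_rec = n_aer + n_ter
    pos = np.vstack([rec_pos, chim_pos]) if n_chim else rec_pos
    spidx = np.concatenate([
        np.full(n_aer, 2, dtype=np.int64),
        np.full(n_ter, 3, dtype=np.int64),
        np.tile([0, 1], n_chim).astype(np.int64),
    ])
    vel = maxwell_boltzmann_velocities(species, spidx, spec.kT, rng)
    bonds = [
        (n_rec + 2 * i, n_rec + 2 * i + 1, spec.linker) for i in range(n_chim)
    ]
    return SystemState(pos, vel, spidx, species, box, bonds=bonds)


_BUILDERS = {
    Protocol.DISSOCIATION: build_dissociation,
    Protocol.ASSOCIATION: build_association,
    Protocol.CHIMERA: build_chimera,
}


def build_initial_state(spec: ExperimentSpec) -> SystemState:
    """Dispatch to the protocol's builder."""
    return _BUILDERS[spec.protocol](spec)
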