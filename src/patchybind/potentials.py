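"""Pair potentials for the coarse-grained ligand-receptor model.

All quantities are in reduced units: energies in units of the system
characteristic energy ``eps0``, lengths in units of the receptor diameter
``sigma_R``.  Four interactions are provided:

* :func:`wca` — the purely repulsive Weeks-Chandler-Andersen potential used
  for excluded volume between particles of the same species.
* :func:`angular_lj` — an anisotropic ("patchy") Lennard-Jones potential in
  which the attractive well is modulated by the angle between the
  ligand-receptor separation vector and the receptor binding axis.  Its two
  parameters, the well depth ``epsilon`` and the geometric factor ``n_geom``,
  independently tune binding strength and angular specificity.
* :func:`steric_cross` — WCA repulsion between unlike, non-complementary
  species using the arithmetic mixing rule for the contact diameter.
* :func:`wlc_force` / :func:`wlc_mean_extension` — the interpolated
  worm-like-chain force law used as the effective linker between the two
  subunits of a chimeric ligand, and the equilibrium end-to-end distance it
  implies.

Every function here is pure and operates on scalars / small vectors; the
integrator re-implements the same algebra in compiled kernels and the test
suite checks the two against each other.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InteractionKind",
    "InteractionSpec",
    "LinkerSpec",
    "wca",
    "angular_lj",
    "steric_cross",
    "wlc_force",
    "wlc_spring_energy",
    "wlc_mean_extension",
    "kratky_porod_extension",
    "WCA_CUT_FACTOR",
]

logger = logging.getLogger(__name__)

#: Position of the Lennard-Jones minimum relative to sigma; the WCA cutoff.
WCA_CUT_FACTOR: float = 2.0 ** (1.0 / 6.0)

#: Fraction of the contour length at which the WLC force is clamped.
WLC_CAP_FRACTION: float = 0.99


class InteractionKind(enum.Enum):
    """Which functional form a pair interaction takes."""

    WCA = "wca"
    ANGULAR_LJ = "angular_lj"
    STERIC = "steric"
    WLC = "wlc"


@dataclass(frozen=True)
class InteractionSpec:
    """Parameters of one pair interaction.

    Parameters
    ----------
    kind:
        Functional form (:class:`InteractionKind`).
    epsilon:
        Interaction strength in units of ``eps0`` (well depth for the
        angular LJ, repulsion scale for WCA/steric).
    sigma_pair:
        Pair contact diameter (``sigma_LR`` for ligand-receptor pairs, the
        arithmetic mean of the two diameters for steric pairs).
    n_geom:
        Dimensionless geometric factor >= 0 controlling the angular
        specificity of the attractive patch; larger values narrow the patch.
        Only meaningful for ``ANGULAR_LJ``.
    r_cut:
        Radial cutoff.  For WCA/steric this is forced to
        ``2**(1/6) * sigma_pair``; for the angular LJ it defaults to
        ``2.5 * sigma_pair``.
    theta_cut:
        Half-width of the binding cone in radians (``ANGULAR_LJ`` only);
        outside it the interaction is purely repulsive.
    """

    kind: InteractionKind
    epsilon: float
    sigma_pair: float
    n_geom: float = 0.0
    r_cut: float | None = None
    theta_cut: float = math.pi / 2.0

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.sigma_pair <= 0:
            raise ValueError("sigma_pair must be positive")
        if self.n_geom < 0:
            raise ValueError("n_geom must be non-negative")
        if self.kind in (InteractionKind.WCA, InteractionKind.STERIC):
            object.__setattr__(self, "r_cut", WCA_CUT_FACTOR * self.sigma_pair)
        elif self.r_cut is None:
            object.__setattr__(self, "r_cut", 2.5 * self.sigma_pair)
        if self.r_cut <= 0:
            raise ValueError("r_cut must be positive")
        if self.kind is InteractionKind.ANGULAR_LJ and not (
            0.0 < self.theta_cut <= math.pi / 2.0
        ):
            raise ValueError("theta_cut must lie in (0, pi/2]")

    # The shifts are derived quantities: recomputing them on access keeps the
    # invariant V(r_cut) == 0 valid under any replace() of the primaries.
    @property
    def shift_rep(self) -> float:
        """Shift making the r^-12 branch vanish at the cutoff."""
        sr6 = (self.sigma_pair / self.r_cut) ** 6
        return -4.0 * self.epsilon * sr6 * sr6

    @property
    def shift_att(self) -> float:
        """Shift making the r^-6 branch vanish at the cutoff."""
        sr6 = (self.sigma_pair / self.r_cut) ** 6
        return 4.0 * self.epsilon * sr6


@dataclass(frozen=True)
class LinkerSpec:
    """Worm-like-chain linker between the two subunits of a chimeric ligand.

    The contour length is ``L0 = n_monomers * monomer_size`` (the length of
    the chain when completely stretched).
    """

    n_monomers: int
    monomer_size: float
    persistence_length: float
    temperature: float = 1.0
    max_force: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_monomers <= 0 or self.monomer_size <= 0:
            raise ValueError("n_monomers and monomer_size must be positive")
        if self.persistence_length <= 0:
            raise ValueError("persistence_length must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        # force at the clamp point; the divergence at r -> L0 is an artifact
        # of the continuum force law at finite timestep
        x = WLC_CAP_FRACTION
        object.__setattr__(
            self,
            "max_force",
            (self.temperature / self.persistence_length)
            * (0.25 / (1.0 - x) ** 2 - 0.25 + x),
        )

    @property
    def contour_length(self) -> float:
        return self.n_monomers * self.monomer_size


def wca(r: float, spec: InteractionSpec) -> tuple[float, float]:
    """WCA energy and radial force at separation *r*.

    Returns ``(energy, force)`` with ``force = -dV/dr`` (positive =
    repulsive).  The potential is the Lennard-Jones truncated at its minimum
    ``2**(1/6) sigma`` and shifted up by ``epsilon`` so it is zero and
    continuous at the cutoff and never attractive.
    """
    if r <= 0:
        raise ValueError("separation must be positive")
    if r >= spec.r_cut:
        return 0.0, 0.0
    sr6 = (spec.sigma_pair / r) ** 6
    energy = 4.0 * spec.epsilon * (sr6 * sr6 - sr6) + spec.epsilon
    force = 24.0 * spec.epsilon * (2.0 * sr6 * sr6 - sr6) / r
    return energy, force


def steric_cross(
    r: float, sigma_i: float, sigma_j: float, eps0: float = 1.0
) -> tuple[float, float]:
    """Purely repulsive cross interaction between unlike species.

    The WCA form evaluated at the mixed diameter
    ``sigma_ij = (sigma_i + sigma_j) / 2``.
    """
    spec = InteractionSpec(
        kind=InteractionKind.STERIC,
        epsilon=eps0,
        sigma_pair=0.5 * (sigma_i + sigma_j),
    )
    return wca(r, spec)


def _angular_weight(theta: float, n_geom: float, theta_cut: float) -> float:
    """Smooth patch modulation g(theta): 1 on-axis, 0 outside the cone.

    ``g(theta) = cos(pi*theta/(2*theta_cut)) ** (2*n_geom)`` for
    ``theta < theta_cut``, else 0 — continuous everywhere and C1 at the cone
    edge for ``n_geom >= 1``.  ``n_geom == 0`` is the isotropic convention
    (g == 1 inside the cone).
    """
    if theta >= theta_cut:
        return 0.0
    if n_geom == 0.0:
        return 1.0
    return math.cos(0.5 * math.pi * theta / theta_cut) ** (2.0 * n_geom)


def _angular_weight_deriv(theta: float, n_geom: float, theta_cut: float) -> float:
    """d g / d theta of :func:`_angular_weight`."""
    if theta >= theta_cut or n_geom == 0.0:
        return 0.0
    a = 0.5 * math.pi / theta_cut
    c = math.cos(a * theta)
    return -2.0 * n_geom * a * math.sin(a * theta) * c ** (2.0 * n_geom - 1.0)


def angular_lj(
    r_vec: np.ndarray, axis: np.ndarray, spec: InteractionSpec
) -> tuple[float, np.ndarray]:
    """Anisotropic ligand-receptor potential energy and force on the ligand.

    Parameters
    ----------
    r_vec:
        Vector from the receptor centre to the ligand centre.
    axis:
        Receptor binding-axis unit vector (the membrane normal ``+z`` in the
        simulations; receptors carry no rotational degree of freedom).
    spec:
        ``ANGULAR_LJ`` interaction parameters.

    Returns
    -------
    (energy, force):
        Energy and the 3-vector force acting on the ligand (the receptor
        feels the opposite force).

    Notes
    -----
    The potential splits the Lennard-Jones into a repulsive ``r^-12`` branch
    and an attractive ``r^-6`` branch, each shifted to vanish at the cutoff,
    and scales only the attractive branch by the angular weight ``g(theta)``::

        V(r, theta) = V_rep(r) + g(theta; n, theta_c) * V_att(r)

    so the total is zero at ``r_cut`` for every angle, and outside the
    binding cone (``theta >= theta_c``) it reduces to the repulsive branch.
    """
    r_vec = np.asarray(r_vec, dtype=float)
    axis = np.asarray(axis, dtype=float)
    r = float(np.linalg.norm(r_vec))
    a = float(np.linalg.norm(axis))
    if r <= 0.0:
        raise ValueError("zero-length separation vector")
    if a == 0.0:
        raise ValueError("zero-length binding axis")
    axis = axis / a
    if r >= spec.r_cut:
        return 0.0, np.zeros(3)

    eps = spec.epsilon
    sr6 = (spec.sigma_pair / r) ** 6
    v_rep = 4.0 * eps * sr6 * sr6 + spec.shift_rep
    v_att = -4.0 * eps * sr6 + spec.shift_att
    dvrep_dr = -48.0 * eps * sr6 * sr6 / r
    dvatt_dr = 24.0 * eps * sr6 / r

    u_hat = r_vec / r
    cos_t = float(np.clip(np.dot(u_hat, axis), -1.0, 1.0))
    theta = math.acos(cos_t)
    g = _angular_weight(theta, spec.n_geom, spec.theta_cut)
    dg = _angular_weight_deriv(theta, spec.n_geom, spec.theta_cut)

    energy = v_rep + g * v_att
    # radial part of -grad V
    force = -(dvrep_dr + g * dvatt_dr) * u_hat
    # angular part: grad(theta) = -(axis - cos t * u_hat) / (r sin t)
    sin_t = math.sqrt(max(1.0 - cos_t * cos_t, 0.0))
    if dg != 0.0 and sin_t > 1.0e-12:
        grad_theta = -(axis - cos_t * u_hat) / (r * sin_t)
        force -= v_att * dg * grad_theta
    return energy, force


def wlc_force(r: float, linker: LinkerSpec) -> float:
    """Worm-like-chain restoring tension at end-to-end distance *r*.

    Marko-Siggia interpolation::

        F(r) = (kBT / lp) * [ 1 / (4 (1 - r/L0)^2) - 1/4 + r/L0 ]

    The force is returned as a non-negative tension pulling the two chain
    ends together; it vanishes at ``r = 0`` and grows without bound as
    ``r -> L0``.  To keep the integrator stable, the tension is clamped at
    its value at ``0.99 L0``; separations at or beyond the contour length
    log a warning (over-stretch event) and return the cap.
    """
    if r < 0:
        raise ValueError("separation must be non-negative")
    l0 = linker.contour_length
    if r >= l0:
        logger.warning(
            "WLC over-stretch: r=%.4g >= contour length %.4g; force capped", r, l0
        )
        return linker.max_force
    x = r / l0
    if x >= WLC_CAP_FRACTION:
        return linker.max_force
    kT_over_lp = linker.temperature / linker.persistence_length
    return kT_over_lp * (0.25 / (1.0 - x) ** 2 - 0.25 + x)


def kratky_porod_extension(linker: LinkerSpec) -> float:
    """Root-mean-square end-to-end distance of an ideal worm-like chain.

    Uses the Kratky-Porod mean-square end-to-end distance

    ``<r^2> = 2 lp L0 [1 - (lp/L0)(1 - exp(-L0/lp))]``

    and returns ``sqrt(<r^2>)``, which interpolates between the rigid-rod
    limit (``lp >> L0`` gives ``L0``) and the flexible limit
    (``lp << L0`` gives ``sqrt(2 lp L0)``).  This describes the statistics
    of the full polymer chain; see :func:`wlc_mean_extension` for the
    extension actually realised by the two-bead effective spring used in
    the simulations.
    """
    l0 = linker.contour_length
    lp = linker.persistence_length
    ratio = l0 / lp
    if ratio < 1.0e-8:
        # series expansion avoids cancellation in the stiff limit
        r2 = l0 * l0 * (1.0 - ratio / 3.0)
    else:
        r2 = 2.0 * lp * l0 * (1.0 - (1.0 - math.exp(-ratio)) / ratio)
    return math.sqrt(r2)


def wlc_spring_energy(r: float, linker: LinkerSpec) -> float:
    """Potential energy of the capped worm-like-chain spring,
    ``U(r) = integral_0^r F``, matching :func:`wlc_force` exactly."""
    if r < 0:
        raise ValueError("separation must be non-negative")
    l0 = linker.contour_length
    kT_lp = linker.temperature / linker.persistence_length
    x = r / l0
    xc = WLC_CAP_FRACTION

    def _u(y: float) -> float:
        return kT_lp * l0 * (0.25 / (1.0 - y) - 0.25 - 0.25 * y + 0.5 * y * y)

    if x < xc:
        return _u(x)
    return _u(xc) + linker.max_force * (r - xc * l0)


def wlc_mean_extension(linker: LinkerSpec, bead_sigma: float = 0.0) -> float:
    """Equilibrium mean end-to-end distance of the simulated linker.

    The linker is realised in the dynamics as a central spring between the
    two subunit beads with the worm-like-chain tension law; its thermal
    mean separation is therefore the Boltzmann average

    ``<r> = Int r^3 exp(-U(r)/kBT) dr / Int r^2 exp(-U(r)/kBT) dr``

    over the separation ``r`` (the ``r^2`` Jacobian counts the spherical
    shell of relative positions).  This is computed by quadrature and is
    noticeably *below* the ideal-chain value of
    :func:`kratky_porod_extension` — the price of coarse-graining the
    chain into a single effective spring.  ``bead_sigma > 0`` adds the WCA
    excluded-volume of the two subunit beads (diameter ``bead_sigma``) to
    the weight, as in the simulations.
    """
    l0 = linker.contour_length
    kT = linker.temperature
    r = np.linspace(1e-9 * l0, l0 * (1.0 - 1e-9), 4001)
    x = r / l0
    kT_lp_l0 = (kT / linker.persistence_length) * l0
    u = kT_lp_l0 * (0.25 / (1.0 - np.minimum(x, WLC_CAP_FRACTION))
                    - 0.25 - 0.25 * x + 0.5 * x * x)
    over = x >= WLC_CAP_FRACTION
    if np.any(over):
        xc = WLC_CAP_FRACTION
        uc = kT_lp_l0 * (0.25 / (1.0 - xc) - 0.25 - 0.25 * xc + 0.5 * xc * xc)
        u[over] = uc + linker.max_force * (r[over] - xc * l0)
    if bead_sigma > 0.0:
        rc = WCA_CUT_FACTOR * bead_sigma
        inside = r < rc
        sr6 = (bead_sigma / np.maximum(r[inside], 1e-12)) ** 6
        u[inside] += 4.0 * (sr6 * sr6 - sr6) + 1.0
    w = np.exp(-(u - u.min()) / kT)
    num = np.trapezoid(r**3 * w, r)
    den = np.trapezoid(r**2 * w, r)
    return float(num / den)
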