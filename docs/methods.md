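# Model and methods

## The coarse-grained model

Ligands and receptors are spheres in reduced units: lengths in receptor
diameters `sigma_R`, energies in the characteristic energy `eps0`, masses
in ligand masses, and times in `tau = sigma_R * sqrt(m_L / eps0)`.
Temperature is `kBT = 1 eps0` throughout.  Receptors live in the membrane
plane `z = 0` and move only laterally (or are frozen when their diffusion
coefficient is set to zero); ligands diffuse in the 3-D half-space above
the membrane.

Three pair interactions define the model:

* **Excluded volume.**  Particles of the same species, and all
  non-complementary cross pairs, repel through the
  Weeks–Chandler–Andersen potential (Lennard-Jones truncated at its
  minimum `2^(1/6) sigma` and shifted up by `eps`), with the arithmetic
  mixing rule `sigma_ij = (sigma_i + sigma_j)/2` for unlike pairs.

* **Binding.**  A complementary ligand–receptor pair interacts through an
  anisotropic ("patchy") Lennard-Jones potential

  `V(r, theta) = V_rep(r) + g(theta; n, theta_c) * V_att(r)`

  where `V_rep = 4 eps (sigma/r)^12 + const` and
  `V_att = -4 eps (sigma/r)^6 + const` are separately shifted so the total
  vanishes at the cutoff `r_cut = 2.5 sigma_LR` for every angle, `theta`
  is the angle between the receptor's binding axis (the membrane normal;
  receptors carry no rotational degree of freedom) and the
  receptor-to-ligand vector, and

  `g(theta) = cos(pi * theta / (2 theta_c))^(2n)` for `theta < theta_c`,
  else `0`.

  `g` is continuous everywhere, `C1` at the cone edge for `n >= 1`, equals
  one on-axis, and sharpens as the geometric factor `n` grows, so `eps`
  (well depth) and `n` (angular specificity) independently tune binding
  strength and the size of the binding patch.  Outside the cone only the
  repulsive branch survives.  With `n = 0` and the default cone half-width
  `theta_c = pi/2` the potential reduces to the isotropic shifted LJ.
  The energy is `C0` but not `C1` at the radial cutoff; the residual force
  step there is of order `1e-1 eps/sigma` and irrelevant at the default
  timestep.

* **Chimera linker.**  A bivalent (chimeric) ligand is two bulk beads —
  activity element (AE) and targeting element (TE) — joined by an
  effective spring with the interpolated worm-like-chain tension

  `F(r) = (kBT/lp) [ 1/(4 (1 - r/L0)^2) - 1/4 + r/L0 ]`

  with contour length `L0 = N b` and persistence length `lp`.  The
  divergence at `r -> L0` is clamped at its value at `0.99 L0` (the
  divergence is an artifact of the continuum force law at finite
  timestep); over-stretch events are counted and logged, and none occur in
  the shipped study conditions.

### Linker extension: spring average vs ideal-chain statistics

Coarse-graining the chain into a single central spring changes its
end-to-end statistics.  The package therefore exposes two quantities:

* `wlc_mean_extension` — the Boltzmann average
  `<r> = Int r^3 e^(-U/kBT) dr / Int r^2 e^(-U/kBT) dr` of the implemented
  spring (computed by quadrature, optionally with the bead–bead excluded
  volume).  This is what a simulated chimera actually samples, and it is
  what placement and reported "linker lengths" use.
* `kratky_porod_extension` — the textbook interpolation
  `sqrt(2 lp L0 [1 - (lp/L0)(1 - e^(-L0/lp))])` for the rms end-to-end
  distance of the full ideal chain, validated against a discrete-chain
  Monte-Carlo oracle.

The spring average sits 20–25 % below the ideal-chain value at the
parameters used here; conflating the two would make the linker appear
longer than it is in the dynamics.

## Integration

Langevin dynamics with the BAOAB splitting of velocity Verlet; per-species
friction `gamma = kBT/(m D)` reproduces each species' configured diffusion
coefficient in the free limit (checked against the Einstein relations to
5 %).  Membrane species propagate only in x, y; bulk species reflect
elastically at `z = sigma/2` (membrane contact) and at the box ceiling;
x and y are periodic with minimum-image forces.  Frozen species
(`D = 0`, used when receptor diffusion is neglected in the monovalent
protocols) are pinned rather than given a high friction.

Forces come from compiled (numba) kernels — an `O(N^2)` loop and a
cell-list loop that agree to machine precision; the cell list is used
automatically when the box supports at least three cells per periodic
dimension and the grid is not grossly larger than the particle count
(very dilute boxes fall back to the `O(N^2)` loop, which is cheaper than
rebuilding a huge empty grid each step).

Defaults: `dt = 0.002 tau` for the monovalent rate measurements and
`0.004 tau` for the chimera studies (the stiffest well used there,
12 kBT, has `omega dt ~ 0.14`, well inside BAOAB's stable, accurate
range); `sigma_L = 0.5 sigma_R`, `m_R = 2 m_L` (the reported quantities
are configurational, so the mass choice is immaterial to sampling),
`D_L = 0.1 sigma^2/tau`, `D_R = 0.01 sigma^2/tau` where receptors
diffuse.  Trajectories are reproducible bit-for-bit from a seed on a
given platform.

## Measuring rates

A ligand–receptor pair is a *complex* when its pair energy is below
`-eps/2` (half the well depth); each ligand pairs with at most one
receptor and vice versa (lowest energy wins, ties broken by particle id).
The threshold is hysteresis-free; its validity is checked by the
Markov-consistency test (escape times of simulated complexes follow the
exponential law implied by the fitted rate).

* **koff** — dissociation runs start with every receptor occupied (ligand
  at the on-axis potential minimum) in a tall, dilute box so an escaped
  ligand rarely meets another receptor.  The ensemble-averaged count is
  fitted to `C(t) = C0 exp(-koff t)` with `C0` anchored at the window
  start; the window discards a burn-in (default 5 tau; the
  characterisation runs use 8) because the initial population needs a few
  tau to equilibrate between the deep bound state and near-surface
  excursions, and stops when fewer than five complexes remain (shot
  noise).  Two real artifacts of the coarse scale are worth knowing:
  escaped ligands can return to their receptor (geminate recombination),
  which for wide patches adds a slowly decaying tail that visibly bends
  the log-decay; and at moderate receptor density escaped ligands
  accumulate near the membrane and rebind elsewhere.  Narrow patches
  (`n >= 2`), low receptor density and the burn-in confine both effects
  below the fit resolution.

* **kon (short time)** — association runs start with all receptors free
  and ligands placed beyond the interaction range.  The count grows as
  `C(t) ~ kon [L]0 N_R t`; a through-origin fit over the samples below
  20 % receptor occupancy gives `kon = slope/([L]0 N_R)`.  When a series
  has genuinely saturated below the receptor cap (fast dissociation), the
  window tightens to half the cap fraction of the plateau so the fit does
  not average over the bend.  The estimator carries a small (few per
  cent) downward bias from the diffusive induction period and from
  receptor occupancy within the window; comparisons between conditions
  use matched windows so the bias cancels.

* **kon (equilibrium)** — once the count has plateaued (final-quartile
  slope consistent with zero, judged on coarse block averages because
  successive samples are strongly autocorrelated), detailed balance gives
  `kon = koff C_eq / ([L]_eq (N_R - C_eq))` with ligand depletion
  `[L]_eq = [L]0 - C_eq/V`.  The two kon estimators agree within joint
  errors when binding is not so deeply transport-limited that the surface
  layer depletes faster than the bulk can resupply it (the
  characterisation test uses a moderate patch, `n = 3`, for that reason).

* Ensembles are averaged before fitting; leave-one-out (jackknife) refits
  over replicates provide the quoted standard errors, which dominate the
  fit covariance (survival counts are autocorrelated in time, so the
  covariance alone is far too optimistic).

* **Diffusion dependence** — in the diffusion-limited regime both rates
  grow linearly with the ligand diffusion coefficient (weighted
  least-squares `R^2 >= 0.95` over a factor of 4–6 in `D`).  The koff
  sweep stays at `D <= 0.2` because escape leaves the overdamped
  (Kramers high-friction) regime at larger `D` and the rate turns over —
  a physical boundary of the linear law, not a numerical artifact.
  `transport_decomposition` inverts the standard series composition
  `1/k_meas = 1/k_int + 1/k_T` when a transport rate is available.

## The chimeric-ligand selectivity study

Study conditions (`selectivity_study_spec`): 50 activity receptors (AER)
at surface density `0.08 sigma^-2` (spacing a few diameters, so slow
receptor diffusion, `D_R = 0.01`, can still pair receptors within a run),
targeting receptors (TER) swept from 0 to twice the AER count on the
*same membrane area*, chimeras in the bulk at `0.02 sigma^-3`, linker
contour `3 sigma` with `lp = 1 sigma`, targeting interaction
`10 kBT, n = 1`, activity interaction `n = 2` with well depth 10 kBT
(HIGH) or 7.5 kBT (LOW), runs of 800 tau whose final quarter provides the
equilibrium occupancy, and the relative increment is quoted against the
zero-TER baseline.

Every numeric condition above is the package's own calibration: the
figure-level parameters of the source system are not available, so the
two affinity regimes were placed by calibrating against the package's own
`koff(eps)` and `kon(eps)` measurements such that the zero-TER baseline
sits near half occupancy (HIGH) or well below it (LOW) at the chosen
chimera concentration, and the chimera supply was sized so the targeting
channel is not starved across the sweep (anchored chimeras would
otherwise deplete the free pool and cap the gain).  The mechanism behind
the selectivity gain is a local-equilibrium effect: a TE anchored at a
TER confines its AE to a shell of roughly the linker extension, raising
the AE's local concentration at nearby AERs by an amount that is
independent of the bulk concentration — so the relative gain is largest
when the bulk-driven baseline is smallest, which is why reduced AE
affinity yields the stronger TER response.  The 800-tau window is part of
the conditions: the HIGH-affinity system approaches its plateau on a
~300-tau timescale and keeps creeping slowly beyond it (surface supply),
as the occupancy-versus-time curves this study emulates also do.

The linker-design sweep (`linker_sweep`) holds the membrane area fixed
and varies the TER count to realise each receptor spacing `d` (the mean
distance from a TER to the points of its `area/N_TER` share,
`d = (2/3) sqrt(area/(pi N_TER))` — the unique uniform-disk mean).
Shrinking the box instead would put the dense cell at its diffusive
absorption ceiling (total chimera arrival scales with membrane area) and
confound the linker physics.  The effective on-rate of the AE is measured
by the short-time estimator; for clustered receptors it peaks at a
contour length well above the bare receptor spacing (a too-short linker
strains the spring in the doubly bound state), and at fixed linker it
decays with receptor spacing — provided the linker can bridge a receptor
pair at all spacings compared; below that length anchoring only
sequesters chimeras.

## What the synthetic generators emulate

`synthetic` provides exact stochastic and closed-form references: *two-state
Markov dissociation ensembles* (independent exponential lifetimes — the
null model the dissociation protocol should reproduce), *mass-action
integration* of the rate equation with depletion (the oracle for both kon
estimators), *discrete worm-like chains* with exponentially decorrelating
bond directions (the oracle for the ideal-chain extension formula), and
*scripted trajectories* with known bound pairs (the oracle for detection
and re-analysis).  None of these contain spatial correlations, crowding,
rebinding or transport — agreement with them validates the estimators,
not the dynamics; the dynamics is validated separately through
equipartition, Einstein relations, Boltzmann sampling against direct
quadrature of the pair potential, and the Markov-consistency of simulated
escape times.

## Known limitations

* **Tethering is not free.**  Relative to a monovalent ligand plus free
  inert beads, a zero-TER chimera binds measurably less: the dangling
  partner costs configurational entropy near the wall at equilibrium
  (larger for longer linkers; ~15–40 % here) and pair drag lowers the
  diffusion-limited arrival rate (~15 %).  The idealisation that a
  chimera with no targeting receptors behaves exactly like a monovalent
  ligand does **not** hold at this model's scale and statistics — the
  corresponding acceptance check is left failing by design, as a
  documented property of the model rather than a defect of the
  implementation.
* The dissociation decay is single-exponential only after a burn-in and
  for narrow patches; wide patches at coarse scales show geminate-return
  tails.
* Receptors are 2-D disks-on-a-plane with a fixed vertical binding axis:
  no receptor rotation, no membrane fluctuations, no binding-pocket
  asymmetry.
* All acceptance magnitudes are scaled-down: tens of receptors and
  hundreds of particles per run, 4–16 replicates, runs of 60–2000 tau.
  They demonstrate the mechanisms at calibrated regimes, not quantitative
  transfer to any particular experimental system.
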