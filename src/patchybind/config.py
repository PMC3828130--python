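"""Config-file surface: YAML -> :class:`ExperimentSpec`.

One experiment per file.  A mandatory ``units`` section must declare the
reduced-unit system explicitly (energies in ``eps0``, lengths in
``sigma_R``, times in ``tau``) so that a config written in another unit
convention fails loudly instead of being silently misread.  Unknown keys
anywhere are hard errors.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .potentials import LinkerSpec
from .system_setup import ExperimentSpec, Protocol

__all__ = ["load_config", "spec_to_dict", "ConfigError"]

REQUIRED_UNITS = {"energy": "eps0", "length": "sigma_R", "time": "tau"}

_SYSTEM_KEYS = {
    "n_receptors", "n_ter", "ligand_concentration", "surface_density",
    "box_height", "prebound_te",
}
_INTERACTION_KEYS = {"epsilon", "n_geom", "theta_cut", "eps_te", "n_geom_te"}
_SPECIES_KEYS = {
    "sigma_ligand", "sigma_receptor", "mass_ligand", "mass_receptor",
    "d_ligand", "d_receptor",
}
_LINKER_KEYS = {"n_monomers", "monomer_size", "persistence_length"}
_RUN_KEYS = {"dt", "n_steps", "sample_interval", "n_replicates", "seed", "kT"}
_TOP_KEYS = {"units", "protocol", "system", "interaction", "species", "linker",
             "run", "sweep"}


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in {where}; "
            f"allowed: {sorted(allowed)}"
        )


def load_config(path: str | Path) -> tuple[ExperimentSpec, dict]:
    """Parse and validate a config file.

    Returns the :class:`ExperimentSpec` and the raw mapping (which may
    carry an optional ``sweep`` section for the sweep subcommand).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    _check_keys(raw, _TOP_KEYS, "top level")
    units = raw.get("units")
    if units != REQUIRED_UNITS:
        raise ConfigError(
            f"config must declare units exactly as {REQUIRED_UNITS}, got {units!r}"
        )
    try:
        protocol = Protocol(str(raw.get("protocol", "")).lower())
    except ValueError:
        raise ConfigError(
            f"protocol must be one of {[p.value for p in Protocol]}"
        ) from None
    system = dict(raw.get("system") or {})
    _check_keys(system, _SYSTEM_KEYS, "system")
    interaction = dict(raw.get("interaction") or {})
    _check_keys(interaction, _INTERACTION_KEYS, "interaction")
    species = dict(raw.get("species") or {})
    _check_keys(species, _SPECIES_KEYS, "species")
    run = dict(raw.get("run") or {})
    _check_keys(run, _RUN_KEYS, "run")
    linker = None
    if "linker" in raw and raw["linker"] is not None:
        lk = dict(raw["linker"])
        _check_keys(lk, _LINKER_KEYS, "linker")
        linker = LinkerSpec(
            n_monomers=int(lk["n_monomers"]),
            monomer_size=float(lk["monomer_size"]),
            persistence_length=float(lk["persistence_length"]),
            temperature=float(run.get("kT", 1.0)),
        )
    kwargs: dict = {}
    kwargs.update({k: system[k] for k in system})
    kwargs.update({k: interaction[k] for k in interaction})
    kwargs.update({k: species[k] for k in species})
    for k in run:
        if k == "kT":
            kwargs["kT"] = float(run[k])
        else:
            kwargs[k] = run[k]
    try:
        spec = ExperimentSpec(protocol=protocol, linker=linker, **kwargs)
    except TypeError as exc:
        raise ConfigError(str(exc)) from None
    return spec, raw


def spec_to_dict(spec: ExperimentSpec) -> dict:
    """Round-trippable snapshot of a spec (for run manifests)."""
    out = {
        "units": dict(REQUIRED_UNITS),
        "protocol": spec.protocol.value,
        "system": {
            "n_receptors": spec.n_receptors,
            "n_ter": spec.n_ter,
            "ligand_concentration": spec.ligand_concentration,
            "surface_density": spec.surface_density,
            "box_height": spec.box_height,
            "prebound_te": spec.prebound_te,
        },
        "interaction": {
            "epsilon": spec.epsilon,
            "n_geom": spec.n_geom,
            "theta_cut": spec.theta_cut,
            "eps_te": spec.eps_te,
            "n_geom_te": spec.n_geom_te,
        },
        "species": {
            "sigma_ligand": spec.sigma_ligand,
            "sigma_receptor": spec.sigma_receptor,
            "mass_ligand": spec.mass_ligand,
            "mass_receptor": spec.mass_receptor,
            "d_ligand": spec.d_ligand,
            "d_receptor": spec.d_receptor,
        },
        "run": {
            "dt": spec.dt,
            "n_steps": spec.n_steps,
            "sample_interval": spec.sample_interval,
            "n_replicates": spec.n_replicates,
            "seed": spec.seed,
            "kT": spec.kT,
        },
    }
    if spec.linker is not None:
        out["linker"] = {
            "n_monomers": spec.linker.n_monomers,
            "monomer_size": spec.linker.monomer_size,
            "persistence_length": spec.linker.persistence_length,
        }
    return out
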