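"""Parameter handling: the named parameter set of the signaling model.

Parameters live in a flat namespace (section structure in the YAML file is
cosmetic).  Copy numbers are molecules per cell; membrane/cytosol bimolecular
rate constants are per molecule per second; bath (ligand, hapten) binding
constants are per molar per second.  The canonical defaults ship with the
package in ``data/defaults.yaml``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any

import yaml

__all__ = ["ParameterSet", "ConfigurationError"]


class ConfigurationError(ValueError):
    """A parameter file or override is incomplete or invalid."""


_RATE_FIELDS = (
    "kp1", "km1", "kp2", "km2", "kon_hapten", "koff_hapten",
    "kpL", "kmL", "kpLs", "kmLs", "kpS", "syk_off_rate",
    "pLb", "pLbs", "pLg", "pLgs", "pLS", "pLSs", "pSS", "pSSs",
    "k_dephos", "k_dephos_cytosol", "kcat_syk_lat",
    "kpG", "kmG",
)
_PARTITION_FIELDS = ("rho_monomer", "rho_dimer", "rho_lyn", "rho_lat")
_COUNT_FIELDS = ("rec_total", "lyn_total", "syk_total", "lat_total", "grb2_total")


@dataclass(frozen=True)
class ParameterSet:
    """Complete, validated parameter set of the model.

    Construct with :meth:`defaults` (canonical values), :meth:`from_yaml`
    (a structured text config) or :meth:`replace` (overrides).
    """

    # copy numbers (molecules/cell)
    rec_total: float = 4.0e5
    lyn_total: float = 2.8e4
    syk_total: float = 4.0e5
    lat_total: float = 2.5e5
    grb2_total: float = 1.0e6
    # bivalent ligand (bath, /M/s and /s; crosslinking 2D, /molecule/s)
    kp1: float = 1.0e8
    km1: float = 0.5
    kp2: float = 2.5e-4
    km2: float = 0.5
    # monovalent hapten (bath)
    kon_hapten: float = 1.0e7
    koff_hapten: float = 1.0
    # Lyn binding
    kpL: float = 1.0e-7
    kmL: float = 0.04
    kpLs: float = 5.0e-5
    kmLs: float = 0.12
    lyn_nonraft_activity_factor: float = 0.2
    # Syk binding
    kpS: float = 2.5e-5
    syk_off_rate: float = 0.13
    # transphosphorylation within a receptor dimer (/s)
    pLb: float = 3.5
    pLbs: float = 7.0
    pLg: float = 1.0
    pLgs: float = 3.0
    pLS: float = 30.0
    pLSs: float = 100.0
    pSS: float = 100.0
    pSSs: float = 200.0
    # dephosphorylation
    k_dephos: float = 20.0
    k_dephos_cytosol: float = 20.0
    alpha: float = 0.2
    # LAT/Grb2 arm
    kcat_syk_lat: float = 0.5
    km_syk_lat: float = 1.0e5
    kpG: float = 1.7e-6
    kmG: float = 0.2
    # partition coefficients
    rho_monomer: float = 0.30
    rho_dimer: float = 0.85
    rho_lyn: float = 0.85
    rho_lat: float = 0.85
    # raft geometry/kinetics
    raft_radius: float = 1.0e-5
    coverage: float = 0.30
    cell_area: float = 8.0e-6
    raft_lifetime: float = 10.0
    diffusion_coefficient: float = 1.0e-8
    # structural flags
    syk_linker_site: bool = False
    area_concentration_scaling: bool = True
    lyn_palmitoylation_mutant: bool = False
    # units metadata (informational; not part of equality)
    units: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- construction ----------------------------------------------------
    @classmethod
    def defaults(cls) -> "ParameterSet":
        """The canonical parameter set shipped with the package."""
        path = importlib.resources.files("raftsignal.data") / "defaults.yaml"
        return cls.from_yaml(path)

    @classmethod
    def from_yaml(cls, path: str | Path | Any) -> "ParameterSet":
        """Load a parameter file (sectioned ``name: {value, units}`` entries).

        Unknown keys are rejected; missing keys fall back to the class
        defaults only when the file is a partial override of the canonical
        set (sections may be omitted, individual entries may not be partial).
        """
        text = Path(str(path)).read_text() if not hasattr(path, "read_text") else path.read_text()
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ConfigurationError(f"parameter file {path} is not a mapping")
        flat: dict[str, Any] = {}
        units: dict[str, str] = {}
        known = {f.name for f in fields(cls)} - {"units"}
        for section, entries in raw.items():
            if not isinstance(entries, dict):
                raise ConfigurationError(f"section {section!r} is not a mapping")
            for name, entry in entries.items():
                if name not in known:
                    raise ConfigurationError(f"unknown parameter {name!r} in section {section!r}")
                if name in flat:
                    raise ConfigurationError(f"duplicate parameter {name!r}")
                if isinstance(entry, dict):
                    if "value" not in entry:
                        raise ConfigurationError(f"parameter {name!r} has no value")
                    flat[name] = entry["value"]
                    if "units" in entry:
                        units[name] = str(entry["units"])
                else:
                    flat[name] = entry
        return cls(**flat, units=units)

    def replace(self, **overrides: Any) -> "ParameterSet":
        """A copy with named parameters overridden (unknown names rejected)."""
        known = {f.name for f in fields(self)}
        for key in overrides:
            if key not in known:
                raise ConfigurationError(f"unknown parameter {key!r}")
        return replace(self, **overrides)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError(f"alpha must be in [0, 1], got {self.alpha}")
        for name in _RATE_FIELDS:
            v = getattr(self, name)
            if v < 0:
                raise ConfigurationError(f"rate constant {name} must be >= 0, got {v}")
        for name in _COUNT_FIELDS:
            v = getattr(self, name)
            if v < 0:
                raise ConfigurationError(f"copy number {name} must be >= 0, got {v}")
        for name in _PARTITION_FIELDS:
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(
                    f"partition coefficient {name} must be in (0, 1), got {v}"
                )
        if not 0.0 < self.lyn_nonraft_activity_factor <= 1.0:
            raise ConfigurationError("lyn_nonraft_activity_factor must be in (0, 1]")
        if self.km_syk_lat <= 0:
            raise ConfigurationError("km_syk_lat must be positive")
        if self.raft_lifetime <= 0 or self.raft_radius <= 0 or self.cell_area <= 0:
            raise ConfigurationError("raft geometry/lifetime values must be positive")
        if not 0 < self.coverage < 1:
            raise ConfigurationError("raft coverage must be in (0, 1)")

    # -- convenience -----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = {f.name: getattr(self, f.name) for f in fields(self) if f.name != "units"}
        return d

    @property
    def rho_mutant_lyn(self) -> float:
        """Raft fraction of palmitoylation-mutant Lyn (fixed by the mutation)."""
        return 0.06


def named_variant(name: str) -> ParameterSet:
    """Named parameterizations of the hapten-inhibition analysis.

    ``faeder-default``: receptor-Syk off-rate 0.13 /s as in the base model.
    ``reduced-syk-lifetime``: off-rate 0.20 /s (35% shorter receptor-Syk
    complex lifetime), the variant under which stronger raft protection is
    inferred.
    """
    base = ParameterSet.defaults()
    variants = {
        "faeder-default": {"syk_off_rate": 0.13},
        "reduced-syk-lifetime": {"syk_off_rate": 0.2},
    }
    if name not in variants:
        raise ConfigurationError(
            f"unknown variant {name!r}; choose from {sorted(variants)}"
        )
    return base.replace(**variants[name])
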