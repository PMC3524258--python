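"""Declarative model definition: molecules, interaction rules, partitioning.

The chemistry is the membrane-proximal FcεRI cascade: a bivalent ligand
crosslinks receptors into dimers; receptor-associated Lyn transphosphorylates
the β and γ ITAMs of the partner receptor; Lyn SH2 binds phospho-β and Syk
tandem-SH2 binds phospho-γ (both bindings occlude the phosphotyrosine from
phosphatases); receptor-bound Syk is activated by trans-autophosphorylation
of its activation loop and phosphorylates LAT by Michaelis–Menten kinetics;
Grb2 SH2 binds (and protects) phospho-LAT; a monovalent hapten competes
receptors out of aggregates.  Every naked phosphosite dephosphorylates at a
base rate that is scaled by the protection factor ``alpha`` inside rafts,
and Lyn catalysis is slowed five-fold outside rafts.

The rule vocabulary is exactly what this chemistry needs (bind/unbind,
bath-species attach, in-complex transphosphorylation, naked-site
dephosphorylation, one Michaelis–Menten step); it is not a general rule
language.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .params import ConfigurationError, ParameterSet

__all__ = [
    "SiteDef",
    "MoleculeType",
    "ModelDefinition",
    "build_model",
    "assign_partition",
]

# localizations
MEMBRANE = "membrane"
CYTOSOL = "cytosolic"
BATH = "extracellular"


@dataclass(frozen=True)
class SiteDef:
    """A site on a molecule type: optional internal states, bindable or not."""

    name: str
    states: tuple[str, ...] = ()
    bindable: bool = True


@dataclass(frozen=True)
class MoleculeType:
    name: str
    sites: tuple[SiteDef, ...]
    localization: str
    copy_number: float  # molecules/cell, or molar for extracellular species

    def __post_init__(self) -> None:
        names = [s.name for s in self.sites]
        if len(names) != len(set(names)):
            raise ConfigurationError(f"duplicate site names on {self.name}")

    def site(self, name: str) -> SiteDef:
        for s in self.sites:
            if s.name == name:
                return s
        raise KeyError(f"{self.name} has no site {name!r}")


# ---------------------------------------------------------------------------
# Rule records.  These are data; the interpreter lives in network.py.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BathBindRule:
    """A constant-concentration bath species attaches to a free membrane site."""

    bath_molecule: str          # "Lig" or "Hap"
    bath_site: str              # site on the bath molecule used for this bond
    target: tuple[str, str]     # (molecule type, site) on the membrane complex
    target_state: str | None    # required internal state of the target site
    kon: str                    # parameter name, /M/s (multiplied by bath conc)
    koff: str                   # parameter name, /s


@dataclass(frozen=True)
class BindRule:
    """Two complexes join through one new bond.

    ``a_free_only`` restricts the first pattern to a lone molecule (used for
    Lyn, Syk and Grb2, which engage the receptor or LAT through exactly one
    domain at a time).  ``membrane_pair`` marks membrane–membrane
    association, which shares a location and is concentrated by compartment
    confinement.
    """

    name: str
    a: tuple[str, str]
    b: tuple[str, str]
    b_state: str | None
    kon: str
    koff: str
    a_free_only: bool = True
    membrane_pair: bool = False


@dataclass(frozen=True)
class CrosslinkRule:
    """A dangling ligand arm captures a free receptor α-chain."""

    kon: str
    koff: str


@dataclass(frozen=True)
class TransphosRule:
    """In-complex (dimer) transphosphorylation of a naked substrate site.

    ``catalyst`` identifies the enzyme by molecule type plus the site through
    which it is anchored to its receptor ("u"/"sh2" for Lyn, "tsh2" for
    Syk); for Syk catalysts ``catalyst_state`` selects the activation-loop
    state that sets the rate.  The substrate site sits on the partner
    receptor of the same dimer (or on the Syk bound to it).
    """

    catalyst: tuple[str, str]
    catalyst_state: tuple[str, str] | None
    substrate: tuple[str, str]      # ("Rec", "b"/"g") or ("Syk", "l"/"a")
    from_state: str
    to_state: str
    rate: str
    lyn_activity_scaled: bool


@dataclass(frozen=True)
class DephosRule:
    """A naked (unbound) phosphosite loses its phosphate.

    Membrane-complex sites are α-scaled in rafts; sites on free cytosolic
    molecules use the cytosolic rate and no raft scaling.
    """

    target: tuple[str, str]
    from_state: str
    to_state: str
    rate: str
    cytosolic_rate: str
    alpha_scaled: bool = True


@dataclass(frozen=True)
class MichaelisMentenRule:
    """Effective-rate-law phosphorylation of LAT by activated dimer-bound Syk."""

    substrate: tuple[str, str]
    from_state: str
    to_state: str
    kcat: str
    km: str


@dataclass(frozen=True)
class RuleSet:
    bath_binds: tuple[BathBindRule, ...]
    binds: tuple[BindRule, ...]
    crosslink: CrosslinkRule
    transphos: tuple[TransphosRule, ...]
    dephos: tuple[DephosRule, ...]
    mm: tuple[MichaelisMentenRule, ...]


@dataclass(frozen=True)
class ModelDefinition:
    """Molecule types, rules and parameters: the declarative model."""

    molecule_types: tuple[MoleculeType, ...]
    rules: RuleSet
    params: ParameterSet

    def molecule(self, name: str) -> MoleculeType:
        for m in self.molecule_types:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def phosphosites(self) -> tuple[tuple[str, str], ...]:
        """Every (molecule, site) pair carrying a U/P phosphorylation state."""
        out = []
        for m in self.molecule_types:
            for s in m.sites:
                if set(s.states) == {"U", "P"}:
                    out.append((m.name, s.name))
        return tuple(out)


def build_model(params: ParameterSet) -> ModelDefinition:
    """Assemble the model definition from a validated parameter set.

    The default Syk carries a single activation-loop phosphosite; setting
    ``syk_linker_site`` adds the linker phosphosite and the Lyn→linker
    transphosphorylation rules of the two-site structure.
    """
    params.validate()

    syk_sites = [SiteDef("tsh2"), SiteDef("a", ("U", "P"), bindable=False)]
    if params.syk_linker_site:
        syk_sites.insert(1, SiteDef("l", ("U", "P"), bindable=False))

    molecule_types = (
        MoleculeType("Lig", (SiteDef("l1"), SiteDef("l2")), BATH, 0.0),
        MoleculeType("Hap", (SiteDef("l"),), BATH, 0.0),
        MoleculeType(
            "Rec",
            (SiteDef("a"), SiteDef("b", ("U", "P")), SiteDef("g", ("U", "P"))),
            MEMBRANE,
            params.rec_total,
        ),
        MoleculeType("Lyn", (SiteDef("u"), SiteDef("sh2")), MEMBRANE, params.lyn_total),
        MoleculeType("Syk", tuple(syk_sites), CYTOSOL, params.syk_total),
        MoleculeType("LAT", (SiteDef("y", ("U", "P")),), MEMBRANE, params.lat_total),
        MoleculeType("Grb2", (SiteDef("sh2"),), CYTOSOL, params.grb2_total),
    )

    bath_binds = (
        BathBindRule("Lig", "l1", ("Rec", "a"), None, "kp1", "km1"),
        BathBindRule("Hap", "l", ("Rec", "a"), None, "kon_hapten", "koff_hapten"),
    )
    binds = (
        # constitutive Lyn unique-domain association with unphosphorylated β
        BindRule("lyn_unique", ("Lyn", "u"), ("Rec", "b"), "U", "kpL", "kmL",
                 membrane_pair=True),
        # Lyn SH2 recruitment to phospho-β
        BindRule("lyn_sh2", ("Lyn", "sh2"), ("Rec", "b"), "P", "kpLs", "kmLs",
                 membrane_pair=True),
        # Syk tandem-SH2 recruitment to phospho-γ
        BindRule("syk_tsh2", ("Syk", "tsh2"), ("Rec", "g"), "P", "kpS",
                 "syk_off_rate"),
        # Grb2 SH2 on phospho-LAT
        BindRule("grb2_sh2", ("Grb2", "sh2"), ("LAT", "y"), "P", "kpG", "kmG"),
    )
    crosslink = CrosslinkRule("kp2", "km2")

    transphos = [
        TransphosRule(("Lyn", "u"), None, ("Rec", "b"), "U", "P", "pLb", True),
        TransphosRule(("Lyn", "sh2"), None, ("Rec", "b"), "U", "P", "pLbs", True),
        TransphosRule(("Lyn", "u"), None, ("Rec", "g"), "U", "P", "pLg", True),
        TransphosRule(("Lyn", "sh2"), None, ("Rec", "g"), "U", "P", "pLgs", True),
        TransphosRule(("Syk", "tsh2"), ("a", "U"), ("Syk", "a"), "U", "P", "pSS", False),
        TransphosRule(("Syk", "tsh2"), ("a", "P"), ("Syk", "a"), "U", "P", "pSSs", False),
    ]
    if params.syk_linker_site:
        transphos += [
            TransphosRule(("Lyn", "u"), None, ("Syk", "l"), "U", "P", "pLS", True),
            TransphosRule(("Lyn", "sh2"), None, ("Syk", "l"), "U", "P", "pLSs", True),
        ]

    dephos = [
        DephosRule(("Rec", "b"), "P", "U", "k_dephos", "k_dephos_cytosol"),
        DephosRule(("Rec", "g"), "P", "U", "k_dephos", "k_dephos_cytosol"),
        DephosRule(("Syk", "a"), "P", "U", "k_dephos", "k_dephos_cytosol"),
        DephosRule(("LAT", "y"), "P", "U", "k_dephos", "k_dephos_cytosol"),
    ]
    if params.syk_linker_site:
        dephos.append(DephosRule(("Syk", "l"), "P", "U", "k_dephos", "k_dephos_cytosol"))

    mm = (MichaelisMentenRule(("LAT", "y"), "U", "P", "kcat_syk_lat", "km_syk_lat"),)

    return ModelDefinition(
        molecule_types=molecule_types,
        rules=RuleSet(
            bath_binds=bath_binds,
            binds=tuple(binds),
            crosslink=crosslink,
            transphos=tuple(transphos),
            dephos=tuple(dephos),
            mm=mm,
        ),
        params=params,
    )


def assign_partition(cpx, params: ParameterSet) -> float:
    """Raft partition coefficient of a membrane complex, by class precedence.

    Precedence: receptor dimer > (wild-type) Lyn attached to a monomeric
    receptor > free Lyn > LAT > monomeric receptor.  Cytosolic binders never
    change the class; a palmitoylation-mutant Lyn partitions weakly on its
    own (ρ = 0.06) and does not confer raft preference on a receptor it is
    bound to.

    ``cpx`` is anything exposing ``count(molecule_type) -> int``.
    """
    n_rec = cpx.count("Rec")
    n_lyn = cpx.count("Lyn")
    n_lat = cpx.count("LAT")
    if n_rec == 0 and n_lyn == 0 and n_lat == 0:
        raise ConfigurationError(
            "complex contains no membrane molecule: no partition coefficient"
        )
    mutant = params.lyn_palmitoylation_mutant
    if n_rec >= 2:
        return params.rho_dimer
    if n_rec == 1:
        if n_lyn >= 1 and not mutant:
            return params.rho_lyn
        return params.rho_monomer
    if n_lyn >= 1:  # free Lyn (possibly mutant)
        return params.rho_mutant_lyn if mutant else params.rho_lyn
    return params.rho_lat
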