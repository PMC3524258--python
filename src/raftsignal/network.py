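"""Reaction-network generation: complexes, canonical labels, rule expansion.

Species are connected molecular complexes (bond graph + per-site internal
states) carrying a location attribute: membrane complexes exist as
raft/nonraft twins that interconvert by first-order exchange, cytosolic and
extracellular complexes carry a single location.  Rules from the model
definition are applied iteratively from the seed species to closure; every
location-dependent rate (raft protection α on dephosphorylation, the
reduced nonraft Lyn activity, confinement concentration of membrane–membrane
association) is resolved into per-location reactions at generation time.

Extracellular (bath) species are held at constant concentration: they appear
in the species list and in reaction stoichiometry for bookkeeping, but their
abundances multiply rate constants instead of being integrated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .model import (
    BATH,
    CYTOSOL,
    MEMBRANE,
    ModelDefinition,
    assign_partition,
)
from .params import ParameterSet
from .rafts import (
    RaftGeometry,
    assert_below_diffusion_limit,
    entry_rate_from_partition,
)

__all__ = [
    "ComplexSpecies",
    "Reaction",
    "ReactionNetwork",
    "generate_network",
    "collapse_compartments",
    "NetworkExpansionError",
]

RAFT = "raft"
NONRAFT = "nonraft"
SINGLE = "membrane"  # collapsed, raft-free membrane

_TYPE_ORDER = {"Lig": 0, "Hap": 1, "Rec": 2, "Lyn": 3, "Syk": 4, "LAT": 5, "Grb2": 6}
_SITE_ORDER = {
    "Lig": ("l1", "l2"),
    "Hap": ("l",),
    "Rec": ("a", "b", "g"),
    "Lyn": ("u", "sh2"),
    "Syk": ("tsh2", "l", "a"),
    "LAT": ("y",),
    "Grb2": ("sh2",),
}
_SYMMETRIC_SITES = {"Lig": ("l1", "l2")}


class NetworkExpansionError(RuntimeError):
    pass


class _Mol:
    __slots__ = ("type", "states", "bonds")

    def __init__(self, type_: str, states: dict, bonds: dict):
        self.type = type_
        self.states = states  # site -> internal state
        self.bonds = bonds    # site -> (molecule index, partner site)

    def copy(self) -> "_Mol":
        return _Mol(self.type, dict(self.states), dict(self.bonds))


class Complex:
    """A connected complex: molecule instances, bonds, site states."""

    __slots__ = ("mols", "_label")

    def __init__(self, mols: list[_Mol]):
        self.mols = mols
        self._label: str | None = None

    # -- construction ---------------------------------------------------
    @classmethod
    def free(cls, model: ModelDefinition, type_name: str) -> "Complex":
        mt = model.molecule(type_name)
        states = {s.name: s.states[0] for s in mt.sites if s.states}
        return cls([_Mol(type_name, states, {})])

    def copy(self) -> "Complex":
        return Complex([m.copy() for m in self.mols])

    # -- queries ---------------------------------------------------------
    def count(self, type_name: str) -> int:
        return sum(1 for m in self.mols if m.type == type_name)

    def molecule_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.mols:
            out[m.type] = out.get(m.type, 0) + 1
        return out

    def localization(self, model: ModelDefinition) -> str:
        locs = {model.molecule(m.type).localization for m in self.mols}
        if MEMBRANE in locs:
            return MEMBRANE
        if CYTOSOL in locs:
            return CYTOSOL
        return BATH

    def free_sites(self, type_name: str, site: str, state: str | None):
        """Indices of molecules of ``type_name`` whose ``site`` is unbound
        (and in ``state``, when given)."""
        for i, m in enumerate(self.mols):
            if m.type != type_name or site in m.bonds:
                continue
            if state is not None and m.states.get(site) != state:
                continue
            yield i

    def dimer_partners(self) -> dict[int, int] | None:
        """For a ligand-bridged receptor dimer, map each Rec index to its
        partner's index; None if the complex is not a dimer."""
        recs = [i for i, m in enumerate(self.mols) if m.type == "Rec"]
        if len(recs) != 2:
            return None
        return {recs[0]: recs[1], recs[1]: recs[0]}

    def anchor_receptor(self, mi: int, site: str) -> int | None:
        """Receptor index a Lyn/Syk molecule is anchored to through ``site``."""
        bond = self.mols[mi].bonds.get(site)
        if bond is None:
            return None
        j, _ = bond
        return j if self.mols[j].type == "Rec" else None

    # -- mutation (returns new complexes) ---------------------------------
    def with_state(self, mi: int, site: str, state: str) -> "Complex":
        c = self.copy()
        c.mols[mi].states[site] = state
        return c

    def with_new_molecule_bound(
        self, model: ModelDefinition, type_name: str, new_site: str,
        mi: int, site: str
    ) -> "Complex":
        c = self.copy()
        new = Complex.free(model, type_name).mols[0]
        idx = len(c.mols)
        c.mols.append(new)
        c.mols[mi].bonds[site] = (idx, new_site)
        new.bonds[new_site] = (mi, site)
        return c

    def joined(self, other: "Complex", mi: int, site: str, mj: int, sj: str) -> "Complex":
        """Join self and other with a bond (self molecule mi.site to other
        molecule mj.sj)."""
        c = self.copy()
        off = len(c.mols)
        for m in other.mols:
            m2 = m.copy()
            m2.bonds = {s: (k + off, ps) for s, (k, ps) in m2.bonds.items()}
            c.mols.append(m2)
        c.mols[mi].bonds[site] = (mj + off, sj)
        c.mols[mj + off].bonds[sj] = (mi, site)
        return c

    def without_bond(self, mi: int, site: str) -> list["Complex"]:
        """Break the bond at (mi, site); return the resulting connected
        component(s) as new complexes (one if still connected, else two)."""
        c = self.copy()
        mj, sj = c.mols[mi].bonds.pop(site)
        del c.mols[mj].bonds[sj]
        return c.components()

    def without_molecule(self, mi: int) -> "Complex":
        """Drop molecule ``mi`` (must have no bonds left) and reindex."""
        assert not self.mols[mi].bonds
        remap = {}
        mols = []
        for i, m in enumerate(self.mols):
            if i == mi:
                continue
            remap[i] = len(mols)
            mols.append(m.copy())
        for m in mols:
            m.bonds = {s: (remap[k], ps) for s, (k, ps) in m.bonds.items()}
        return Complex(mols)

    def components(self) -> list["Complex"]:
        n = len(self.mols)
        seen = [False] * n
        out = []
        for start in range(n):
            if seen[start]:
                continue
            stack, comp = [start], []
            seen[start] = True
            while stack:
                i = stack.pop()
                comp.append(i)
                for k, _ in self.mols[i].bonds.values():
                    if not seen[k]:
                        seen[k] = True
                        stack.append(k)
            comp.sort()
            remap = {orig: new for new, orig in enumerate(comp)}
            mols = []
            for orig in comp:
                m = self.mols[orig].copy()
                m.bonds = {s: (remap[k], ps) for s, (k, ps) in m.bonds.items()}
                mols.append(m)
            out.append(Complex(mols))
        return out

    # -- canonicalization --------------------------------------------------
    def label(self) -> str:
        """Canonical label: equal iff complexes are isomorphic.

        Brute-force minimization over permutations of same-type molecules
        and over the arm symmetry of the bivalent ligand; complexes in this
        chemistry have at most two molecules of any type, so at most a few
        dozen candidate serializations exist.
        """
        if self._label is None:
            self._label = self._canonical()
        return self._label

    def _canonical(self) -> str:
        by_type: dict[str, list[int]] = {}
        for i, m in enumerate(self.mols):
            by_type.setdefault(m.type, []).append(i)
        type_groups = [by_type[t] for t in sorted(by_type, key=_TYPE_ORDER.get)]
        best: str | None = None
        for combo in itertools.product(
            *[itertools.permutations(g) for g in type_groups]
        ):
            order = [i for g in combo for i in g]
            swap_axes = [
                (False, True) if self.mols[i].type in _SYMMETRIC_SITES else (False,)
                for i in order
            ]
            for swaps in itertools.product(*swap_axes):
                s = self._serialize(order, swaps)
                if best is None or s < best:
                    best = s
        assert best is not None
        return best

    def _serialize(self, order: list[int], swaps: tuple[bool, ...]) -> str:
        pos = {orig: k for k, orig in enumerate(order)}
        bond_ids: dict[frozenset, int] = {}
        parts = []
        for k, orig in enumerate(order):
            m = self.mols[orig]
            sites = list(_SITE_ORDER[m.type])
            sites = [s for s in sites if s in m.states or s in m.bonds
                     or self._site_exists(m, s)]
            if swaps[k]:
                a, b = _SYMMETRIC_SITES[m.type]
                ia, ib = sites.index(a), sites.index(b)
                sites[ia], sites[ib] = sites[ib], sites[ia]
            # symmetric arms are printed positionally so that a swap
            # relabels them
            print_names = list(_SITE_ORDER[m.type])[: len(sites)] \
                if m.type in _SYMMETRIC_SITES else sites
            toks = []
            for print_idx, s in enumerate(sites):
                tok = print_names[print_idx]
                if s in m.states:
                    tok += f"~{m.states[s]}"
                if s in m.bonds:
                    j, sj = m.bonds[s]
                    key = frozenset({(orig, s), (j, sj)})
                    if key not in bond_ids:
                        bond_ids[key] = len(bond_ids) + 1
                    tok += f"!{bond_ids[key]}"
                toks.append(tok)
            parts.append(f"{m.type}({','.join(toks)})")
        return ".".join(parts)

    @staticmethod
    def _site_exists(m: _Mol, site: str) -> bool:
        # stateless bindable sites exist even when free and unbound
        if m.type == "Syk" and site == "l":
            return False  # present only in the two-site Syk variant
        return True


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComplexSpecies:
    """One network species: a canonical complex at a location."""

    index: int
    label: str
    location: str          # raft | nonraft | membrane | cytosol | bath
    dynamic: bool          # False for constant-concentration bath species
    rho: float | None      # partition class (membrane species only)
    counts: dict = field(compare=False, hash=False, default_factory=dict)

    @property
    def key(self) -> tuple[str, str]:
        return (self.label, self.location)


@dataclass(frozen=True)
class Reaction:
    """One unidirectional reaction.

    ``kind`` is "ma" (mass action) or "mm" (Michaelis–Menten).  ``rate`` is
    the fully resolved rate constant including match multiplicity and any
    location scaling; for bath-binding steps ``bath`` names the bath species
    whose molar concentration multiplies the rate at compile time.  For "mm"
    the reactants are (enzyme, substrate) and ``km`` the location-scaled
    Michaelis constant.
    """

    reactants: tuple[int, ...]
    products: tuple[int, ...]
    rate: float
    kind: str = "ma"
    bath: str | None = None
    km: float | None = None
    tag: str = ""


class ReactionNetwork:
    """Enumerated species + unidirectional reactions of the model."""

    def __init__(self, model: ModelDefinition, raft_resolved: bool,
                 molecules: set[str] | None = None):
        self.model = model
        self.raft_resolved = raft_resolved
        self.molecules_subset = molecules
        self.species: list[ComplexSpecies] = []
        self.reactions: list[Reaction] = []
        self._index: dict[tuple[str, str], int] = {}
        self._complexes: dict[int, Complex] = {}
        self.geometry = RaftGeometry(
            raft_radius=model.params.raft_radius,
            coverage=model.params.coverage,
            cell_area=model.params.cell_area,
        )

    # -- species bookkeeping ---------------------------------------------
    def species_index(self, label: str, location: str) -> int | None:
        return self._index.get((label, location))

    def complex_of(self, index: int) -> Complex:
        return self._complexes[index]

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def find(self, label: str, location: str) -> ComplexSpecies:
        idx = self._index.get((label, location))
        if idx is None:
            raise KeyError(f"no species {label!r} at {location!r}")
        return self.species[idx]

    def membrane_species(self) -> list[ComplexSpecies]:
        return [s for s in self.species if s.location in (RAFT, NONRAFT, SINGLE)]

    def conservation_matrix(self):
        """Per-molecule-type counting matrix over dynamic species."""
        import numpy as np

        types = [m.name for m in self.model.molecule_types
                 if m.localization != BATH]
        mat = np.zeros((len(types), self.n_species))
        for sp in self.species:
            if not sp.dynamic:
                continue
            for t, c in sp.counts.items():
                if t in types:
                    mat[types.index(t), sp.index] = c
        return types, mat


def _area_fraction(location: str, params: ParameterSet) -> float:
    if location == RAFT:
        return params.coverage
    if location == NONRAFT:
        return 1.0 - params.coverage
    return 1.0


class _Generator:
    """Worklist expansion of the rule set from the seed species."""

    def __init__(self, model: ModelDefinition, include_hapten: bool,
                 raft_resolved: bool, species_cap: int,
                 molecules: set[str] | None = None):
        self.model = model
        self.params = model.params
        self.include_hapten = include_hapten
        self.raft_resolved = raft_resolved
        self.molecules = molecules
        self.cap = species_cap
        self.net = ReactionNetwork(model, raft_resolved, molecules)
        # raw reactions keyed by (reactants, products, kind, bath, km) -> rate
        self._rxn: dict[tuple, float] = {}
        self._rxn_tag: dict[tuple, str] = {}
        self._last_rule = "<seed>"

    # -- species interning -------------------------------------------------
    def intern(self, cpx: Complex, location: str) -> int:
        label = cpx.label()
        key = (label, location)
        idx = self.net._index.get(key)
        if idx is not None:
            return idx
        if len(self.net.species) >= self.cap:
            raise NetworkExpansionError(
                f"species cap {self.cap} exceeded while applying rule "
                f"{self._last_rule!r}"
            )
        loc_kind = cpx.localization(self.model)
        dynamic = loc_kind != BATH
        rho = None
        if loc_kind == MEMBRANE and self.raft_resolved:
            rho = assign_partition(cpx, self.params)
        idx = len(self.net.species)
        sp = ComplexSpecies(
            index=idx, label=label, location=location, dynamic=dynamic,
            rho=rho, counts=cpx.molecule_counts(),
        )
        self.net.species.append(sp)
        self.net._index[key] = idx
        self.net._complexes[idx] = cpx
        self._work.append(idx)
        return idx

    def locations_for(self, cpx: Complex) -> list[str]:
        kind = cpx.localization(self.model)
        if kind == MEMBRANE:
            return [RAFT, NONRAFT] if self.raft_resolved else [SINGLE]
        if kind == CYTOSOL:
            return ["cytosol"]
        return ["bath"]

    def add_rxn(self, reactants, products, rate, kind="ma", bath=None,
                km=None, tag=""):
        if rate == 0.0:
            return
        key = (tuple(reactants), tuple(sorted(products)), kind, bath, km)
        self._rxn[key] = self._rxn.get(key, 0.0) + rate
        self._rxn_tag.setdefault(key, tag)

    # -- main loop ----------------------------------------------------------
    def run(self) -> ReactionNetwork:
        model, params = self.model, self.params
        self._work: list[int] = []
        # seed species
        seeded = set()
        for mt in model.molecule_types:
            if mt.name == "Hap" and not self.include_hapten:
                continue
            if self.molecules is not None and mt.name not in self.molecules:
                continue
            cpx = Complex.free(model, mt.name)
            for loc in self.locations_for(cpx):
                self.intern(cpx, loc)
            seeded.add(mt.name)
        # the Michaelis-Menten product state is produced by no mass-action
        # rule, so intern it up front when the enzyme machinery is present
        for rule in model.rules.mm:
            if {"Lig", "Rec", "Syk", rule.substrate[0]} <= seeded:
                sub = Complex.free(model, rule.substrate[0])
                prod = sub.with_state(0, rule.substrate[1], rule.to_state)
                for loc in self.locations_for(prod):
                    self.intern(prod, loc)
        done = 0
        while done < len(self._work):
            idx = self._work[done]
            done += 1
            self.apply_unary(idx)
            # binary rules against every species drained so far (incl. self);
            # pairs with species created later are handled at their drain
            for jdx in range(done):
                self.apply_binary(idx, jdx)
                if jdx != idx:
                    self.apply_binary(jdx, idx)
        self.apply_mm()
        if self.raft_resolved:
            self.add_exchange()
        # freeze reaction list in deterministic order
        for key in self._rxn:
            reactants, products, kind, bath, km = key
            self.net.reactions.append(
                Reaction(reactants=reactants, products=products,
                         rate=self._rxn[key], kind=kind, bath=bath, km=km,
                         tag=self._rxn_tag[key])
            )
        return self.net

    # -- rule application ----------------------------------------------------
    def apply_unary(self, idx: int) -> None:
        sp = self.net.species[idx]
        cpx = self.net.complex_of(idx)
        loc = sp.location
        params = self.params
        rules = self.model.rules
        is_membrane = loc in (RAFT, NONRAFT, SINGLE)

        # bath-species attach/detach
        for rule in rules.bath_binds:
            if rule.bath_molecule == "Hap" and not self.include_hapten:
                continue
            self._last_rule = f"bath_bind:{rule.bath_molecule}"
            if not is_membrane:
                continue
            # attach
            grouped: dict[str, tuple[Complex, int]] = {}
            for mi in cpx.free_sites(*rule.target, rule.target_state):
                prod = cpx.with_new_molecule_bound(
                    self.model, rule.bath_molecule, rule.bath_site, mi,
                    rule.target[1]
                )
                lab = prod.label()
                if lab in grouped:
                    grouped[lab] = (grouped[lab][0], grouped[lab][1] + 1)
                else:
                    grouped[lab] = (prod, 1)
            for prod, n in grouped.values():
                pidx = self.intern(prod, loc)
                self.add_rxn([idx], [pidx], n * getattr(params, rule.kon),
                             bath=rule.bath_molecule, tag="bath_bind")
            # detach: bath molecule bound through a single bond leaves
            grouped2: dict[tuple, list] = {}
            for mi, m in enumerate(cpx.mols):
                if m.type != rule.bath_molecule or len(m.bonds) != 1:
                    continue
                (site, (mj, sj)), = m.bonds.items()
                parts = cpx.without_bond(mi, site)
                # drop the freed bath molecule, keep the rest
                keep = [
                    part for part in parts
                    if not (len(part.mols) == 1
                            and part.mols[0].type == rule.bath_molecule)
                ]
                key = tuple(sorted(p.label() for p in keep))
                if key in grouped2:
                    grouped2[key][1] += 1
                else:
                    grouped2[key] = [keep, 1]
            for keep, n in grouped2.values():
                pidx = [self.intern(p, loc) for p in keep]
                self.add_rxn([idx], pidx, n * getattr(params, rule.koff),
                             tag="bath_unbind")

        # crosslink reverse: break a receptor bond of a doubly-bound ligand
        self._last_rule = "crosslink_reverse"
        grouped3: dict[tuple, list] = {}
        for mi, m in enumerate(cpx.mols):
            if m.type != "Lig" or len(m.bonds) != 2:
                continue
            for site in list(m.bonds):
                parts = cpx.without_bond(mi, site)
                key = tuple(sorted(p.label() for p in parts))
                if key in grouped3:
                    grouped3[key][1] += 1
                else:
                    grouped3[key] = [parts, 1]
        for parts, n in grouped3.values():
            pidx = [self.intern(p, loc) for p in parts]
            self.add_rxn([idx], pidx, n * getattr(params, rules.crosslink.koff),
                         tag="crosslink_off")

        # bind-rule reverse: anchored Lyn/Syk/Grb2 dissociates
        for rule in rules.binds:
            self._last_rule = f"unbind:{rule.name}"
            a_type, a_site = rule.a
            grouped4: dict[tuple, list] = {}
            for mi, m in enumerate(cpx.mols):
                if m.type != a_type or a_site not in m.bonds:
                    continue
                mj, sj = m.bonds[a_site]
                if self.cpx_site_matches(cpx, mj, sj, rule.b, rule.b_state):
                    parts = cpx.without_bond(mi, a_site)
                    key = tuple(sorted(p.label() for p in parts))
                    if key in grouped4:
                        grouped4[key][1] += 1
                    else:
                        grouped4[key] = [parts, 1]
            for parts, n in grouped4.values():
                pidx = []
                for p in parts:
                    ploc = loc if p.localization(self.model) == MEMBRANE \
                        else self.locations_for(p)[0]
                    pidx.append(self.intern(p, ploc))
                self.add_rxn([idx], pidx, n * getattr(params, rule.koff),
                             tag=f"unbind:{rule.name}")

        # transphosphorylation within a dimer
        partners = cpx.dimer_partners()
        if partners is not None:
            lyn_factor = 1.0
            if loc == NONRAFT:
                lyn_factor = params.lyn_nonraft_activity_factor
            for rule in rules.transphos:
                self._last_rule = f"transphos:{rule.rate}"
                rate = getattr(params, rule.rate)
                if rule.lyn_activity_scaled:
                    rate = rate * lyn_factor
                grouped5: dict[str, list] = {}
                for ci, cm in enumerate(cpx.mols):
                    if cm.type != rule.catalyst[0]:
                        continue
                    rec_i = cpx.anchor_receptor(ci, rule.catalyst[1])
                    if rec_i is None or rec_i not in partners:
                        continue
                    if rule.catalyst_state is not None:
                        st_site, st_val = rule.catalyst_state
                        if cm.states.get(st_site) != st_val:
                            continue
                    rec_j = partners[rec_i]
                    for si, sm in enumerate(cpx.mols):
                        if sm.type != rule.substrate[0]:
                            continue
                        if rule.substrate[0] == "Rec":
                            if si != rec_j:
                                continue
                        else:  # substrate rides on the partner receptor
                            anchor = cpx.anchor_receptor(si, "tsh2")
                            if anchor != rec_j:
                                continue
                            if si == ci:
                                continue
                        site = rule.substrate[1]
                        if sm.states.get(site) != rule.from_state:
                            continue
                        if site in sm.bonds:
                            continue
                        prod = cpx.with_state(si, site, rule.to_state)
                        lab = prod.label()
                        if lab in grouped5:
                            grouped5[lab][1] += 1
                        else:
                            grouped5[lab] = [prod, 1]
                for prod, n in grouped5.values():
                    pidx = self.intern(prod, loc)
                    self.add_rxn([idx], [pidx], n * rate,
                                 tag=f"transphos:{rule.rate}")

        # dephosphorylation of naked phosphosites
        for rule in rules.dephos:
            self._last_rule = f"dephos:{rule.target}"
            if is_membrane:
                rate = getattr(params, rule.rate)
                if loc == RAFT:
                    rate = rate * params.alpha
            else:
                rate = getattr(params, rule.cytosolic_rate)
            grouped6: dict[str, list] = {}
            for mi, m in enumerate(cpx.mols):
                if m.type != rule.target[0]:
                    continue
                site = rule.target[1]
                if m.states.get(site) != rule.from_state or site in m.bonds:
                    continue
                prod = cpx.with_state(mi, site, rule.to_state)
                lab = prod.label()
                if lab in grouped6:
                    grouped6[lab][1] += 1
                else:
                    grouped6[lab] = [prod, 1]
            for prod, n in grouped6.values():
                pidx = self.intern(prod, loc)
                self.add_rxn([idx], [pidx], n * rate, tag="dephos")

    def cpx_site_matches(self, cpx: Complex, mi: int, site: str,
                         spec: tuple[str, str], state: str | None) -> bool:
        m = cpx.mols[mi]
        if (m.type, site) != spec:
            return False
        return state is None or m.states.get(site) == state

    def apply_binary(self, ia: int, ib: int) -> None:
        spa, spb = self.net.species[ia], self.net.species[ib]
        ca, cb = self.net.complex_of(ia), self.net.complex_of(ib)
        params = self.params
        rules = self.model.rules
        mem_a = spa.location in (RAFT, NONRAFT, SINGLE)
        mem_b = spb.location in (RAFT, NONRAFT, SINGLE)

        # crosslinking: dangling ligand arm (in a) captures free Rec.a (in b)
        self._last_rule = "crosslink"
        if mem_a and mem_b and spa.location == spb.location:
            af = _area_fraction(spa.location, params) \
                if params.area_concentration_scaling else 1.0
            arms = [
                (mi, s)
                for mi, m in enumerate(ca.mols) if m.type == "Lig"
                and len(m.bonds) == 1
                for s in _SITE_ORDER["Lig"] if s not in m.bonds
            ]
            targets = list(cb.free_sites("Rec", "a", None))
            if arms and targets:
                rate = getattr(params, rules.crosslink.kon) / af
                grouped: dict[str, list] = {}
                for (mi, s) in arms:
                    for tj in targets:
                        prod = ca.joined(cb, mi, s, tj, "a")
                        lab = prod.label()
                        if lab in grouped:
                            grouped[lab][1] += 1
                        else:
                            grouped[lab] = [prod, 1]
                for prod, n in grouped.values():
                    pidx = self.intern(prod, spa.location)
                    self.add_rxn([ia, ib], [pidx], n * rate, tag="crosslink")

        # bind rules: free molecule (a) attaches to a site on b
        for rule in rules.binds:
            self._last_rule = f"bind:{rule.name}"
            a_type, a_site = rule.a
            if rule.a_free_only:
                if len(ca.mols) != 1 or ca.mols[0].type != a_type:
                    continue
            if not mem_b:
                continue
            if rule.membrane_pair:
                if not (mem_a and spa.location == spb.location):
                    continue
                af = _area_fraction(spa.location, params) \
                    if params.area_concentration_scaling else 1.0
            else:
                if mem_a:
                    continue
                af = 1.0
            rate = getattr(params, rule.kon) / af
            grouped: dict[str, list] = {}
            for tj in cb.free_sites(*rule.b, rule.b_state):
                prod = cb.joined(ca, tj, rule.b[1], 0, a_site)
                lab = prod.label()
                if lab in grouped:
                    grouped[lab][1] += 1
                else:
                    grouped[lab] = [prod, 1]
            for prod, n in grouped.values():
                pidx = self.intern(prod, spb.location)
                self.add_rxn([ia, ib], [pidx], n * rate, tag=f"bind:{rule.name}")

    def apply_mm(self) -> None:
        """Michaelis–Menten LAT phosphorylation by activated dimer-bound Syk."""
        params = self.params
        for rule in self.model.rules.mm:
            self._last_rule = "mm"
            kcat = getattr(params, rule.kcat)
            km = getattr(params, rule.km)
            # substrate species per location
            subs: dict[str, int] = {}
            prods: dict[str, int] = {}
            for sp in self.net.species:
                cpx = self.net.complex_of(sp.index)
                if len(cpx.mols) == 1 and cpx.mols[0].type == rule.substrate[0]:
                    st = cpx.mols[0].states.get(rule.substrate[1])
                    if st == rule.from_state:
                        subs[sp.location] = sp.index
                    elif st == rule.to_state and not cpx.mols[0].bonds:
                        prods[sp.location] = sp.index
            # the LAT kinase pool is receptor-bound Syk: Syk engaged on a
            # phospho-γ through its tandem SH2, on monomeric or aggregated
            # receptors alike
            for sp in list(self.net.species):
                cpx = self.net.complex_of(sp.index)
                n_active = 0
                for mi, m in enumerate(cpx.mols):
                    if m.type == "Syk" \
                            and cpx.anchor_receptor(mi, "tsh2") is not None:
                        n_active += 1
                if n_active == 0 or sp.location not in subs:
                    continue
                af = _area_fraction(sp.location, params) \
                    if params.area_concentration_scaling else 1.0
                self.add_rxn(
                    [sp.index, subs[sp.location]],
                    [sp.index, prods[sp.location]],
                    n_active * kcat, kind="mm", km=km * af, tag="mm",
                )

    def add_exchange(self) -> None:
        params = self.params
        lam = params.raft_lifetime
        geometry = self.net.geometry
        checked: set[float] = set()
        for sp in list(self.net.species):
            if sp.location != RAFT:
                continue
            twin = self.net.species_index(sp.label, NONRAFT)
            assert twin is not None
            rho = sp.rho
            if rho not in checked:
                assert_below_diffusion_limit(
                    geometry, rho, lam, params.diffusion_coefficient
                )
                checked.add(rho)
            self.add_rxn([sp.index], [twin], 1.0 / lam, tag="raft_exit")
            self.add_rxn([twin], [sp.index],
                         entry_rate_from_partition(rho, lam), tag="raft_entry")


def generate_network(
    model: ModelDefinition,
    include_hapten: bool = True,
    raft_resolved: bool = True,
    species_cap: int = 5000,
    molecules: set[str] | None = None,
) -> ReactionNetwork:
    """Expand the model rules to the full enumerated reaction network.

    ``include_hapten=False`` gives the stimulation-phase network (ligand
    only), the network whose size is conventionally reported; the
    hapten-extended network is a strict superset used to simulate the
    inhibition experiment.  ``raft_resolved=False`` generates the merged
    single-membrane network with no raft attributes, no exchange reactions,
    no α scaling and raft-level Lyn activity everywhere.
    """
    gen = _Generator(model, include_hapten=include_hapten,
                     raft_resolved=raft_resolved, species_cap=species_cap,
                     molecules=molecules)
    return gen.run()


def collapse_compartments(network: ReactionNetwork) -> ReactionNetwork:
    """The raft-free single-compartment twin of a generated network."""
    if not network.raft_resolved:
        raise ValueError("network already collapsed")
    has_hap = any(sp.counts.get("Hap") for sp in network.species) or any(
        sp.label == "Hap(l)" for sp in network.species
    )
    params = network.model.params.replace(area_concentration_scaling=False)
    from .model import build_model

    return generate_network(
        build_model(params), include_hapten=has_hap, raft_resolved=False,
        molecules=network.molecules_subset,
    )
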