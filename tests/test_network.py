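"""Network generation: canonicalization, toy-model enumeration oracle,
published network size, conservation and compartment collapse."""

import random

import numpy as np
import pytest

from raftsignal.model import build_model
from raftsignal.network import (
    Complex,
    NetworkExpansionError,
    collapse_compartments,
    generate_network,
)


def _shuffled_copy(cpx: Complex, seed: int) -> Complex:
    """Rebuild the same complex with molecule instances in another order."""
    rng = random.Random(seed)
    order = list(range(len(cpx.mols)))
    rng.shuffle(order)
    remap = {old: new for new, old in enumerate(order)}
    mols = []
    for old in order:
        m = cpx.mols[old].copy()
        m.bonds = {s: (remap[k], ps) for s, (k, ps) in m.bonds.items()}
        mols.append(m)
    return Complex(mols)


class TestCanonicalization:
    def _dimer(self, model):
        lig = Complex.free(model, "Lig")
        rec = Complex.free(model, "Rec")
        half = lig.joined(rec, 0, "l1", 0, "a")
        return half.joined(rec, 2 if False else 1, "l2", 0, "a")

    def test_permutation_invariance(self, defaults):
        model = build_model(defaults)
        lig = Complex.free(model, "Lig")
        rec = Complex.free(model, "Rec")
        lyn = Complex.free(model, "Lyn")
        dimer = lig.joined(rec, 0, "l1", 0, "a").joined(rec, 0, "l2", 0, "a")
        dimer = dimer.joined(lyn, 1, "b", 0, "u")
        label = dimer.label()
        for seed in range(10):
            assert _shuffled_copy(dimer, seed).label() == label

    def test_ligand_arm_symmetry(self, defaults):
        model = build_model(defaults)
        lig = Complex.free(model, "Lig")
        rec = Complex.free(model, "Rec")
        via_l1 = lig.joined(rec, 0, "l1", 0, "a")
        via_l2 = lig.joined(rec, 0, "l2", 0, "a")
        assert via_l1.label() == via_l2.label()

    def test_asymmetric_dimer_distinguished(self, defaults):
        model = build_model(defaults)
        lig = Complex.free(model, "Lig")
        rec = Complex.free(model, "Rec")
        dimer = lig.joined(rec, 0, "l1", 0, "a").joined(rec, 0, "l2", 0, "a")
        phos = dimer.with_state(1, "b", "P")
        assert phos.label() != dimer.label()
        # phosphorylating the other receptor gives the isomorphic complex
        assert dimer.with_state(2, "b", "P").label() == phos.label()

    def test_idempotent(self, defaults):
        model = build_model(defaults)
        c = Complex.free(model, "Rec")
        assert c.label() == c.label() == "Rec(a,b~U,g~U)"


class TestToyModel:
    """Bivalent ligand + receptor only, against exhaustive enumeration.

    Hand enumeration of ligand-occupancy complexes: the free receptor, the
    receptor with a dangling ligand, and the ligand-bridged dimer — each in
    two membrane locations — plus the bath ligand: 7 species.  Reactions:
    ligand attach/detach (2 locations x 2 directions), crosslink and its
    reverse (2 locations each), and raft exchange for the three membrane
    complexes (6): 14 unidirectional reactions.
    """

    EXPECTED_SPECIES = {
        ("Lig(l1,l2)", "bath"),
        ("Rec(a,b~U,g~U)", "raft"),
        ("Rec(a,b~U,g~U)", "nonraft"),
        ("Lig(l1!1,l2).Rec(a!1,b~U,g~U)", "raft"),
        ("Lig(l1!1,l2).Rec(a!1,b~U,g~U)", "nonraft"),
        ("Lig(l1!1,l2!2).Rec(a!1,b~U,g~U).Rec(a!2,b~U,g~U)", "raft"),
        ("Lig(l1!1,l2!2).Rec(a!1,b~U,g~U).Rec(a!2,b~U,g~U)", "nonraft"),
    }

    def test_species_match_hand_enumeration(self, toy_network):
        got = {(s.label, s.location) for s in toy_network.species}
        assert got == self.EXPECTED_SPECIES

    def test_reaction_count(self, toy_network):
        assert toy_network.n_reactions == 14

    def test_symmetric_dimer_dissociation_multiplicity(self, toy_network, defaults):
        # two equivalent crosslink bonds: dissociation carries a factor 2
        rates = [r.rate for r in toy_network.reactions
                 if r.tag == "crosslink_off"]
        assert rates and all(r == pytest.approx(2 * defaults.km2) for r in rates)


class TestPublishedSize:
    def test_stimulation_network(self, stim_network):
        assert stim_network.n_species == 348
        assert stim_network.n_reactions == 3447

    def test_hapten_extension_is_superset(self, stim_network, full_network):
        stim = {(s.label, s.location) for s in stim_network.species}
        full = {(s.label, s.location) for s in full_network.species}
        assert stim < full
        assert full_network.n_species == 381

    def test_generation_is_deterministic(self, defaults, stim_network):
        again = generate_network(build_model(defaults), include_hapten=False)
        assert [s.key for s in again.species] == \
            [s.key for s in stim_network.species]
        assert [(r.reactants, r.products, r.rate) for r in again.reactions] \
            == [(r.reactants, r.products, r.rate) for r in stim_network.reactions]


class TestConservation:
    def test_stoichiometry_conserves_every_protein(self, full_network):
        from raftsignal.simulate import _compiled

        ode = _compiled(full_network, {"Lig": 1e-9, "Hap": 1e-4})
        types, mat = full_network.conservation_matrix()
        dyn_cols = [sp.index for sp in full_network.species if sp.dynamic]
        sub = mat[:, dyn_cols]
        residual = sub @ ode.S.toarray()
        assert np.max(np.abs(residual)) == 0.0

    def test_every_species_reachable(self, stim_network):
        # every dynamic species takes part in at least one reaction
        touched = set()
        for rxn in stim_network.reactions:
            touched.update(rxn.reactants)
            touched.update(rxn.products)
        dynamic = {s.index for s in stim_network.species if s.dynamic}
        assert dynamic <= touched


class TestCollapse:
    def test_counts(self, defaults, stim_network):
        collapsed = collapse_compartments(stim_network)
        n_membrane = len(stim_network.membrane_species())
        n_other = stim_network.n_species - n_membrane
        assert collapsed.n_species == n_membrane // 2 + n_other
        assert not any(s.location in ("raft", "nonraft")
                       for s in collapsed.species)

    def test_no_exchange_or_alpha(self, stim_network):
        collapsed = collapse_compartments(stim_network)
        tags = {r.tag for r in collapsed.reactions}
        assert "raft_exit" not in tags and "raft_entry" not in tags

    def test_toy_collapse_is_raft_free_enumeration(self, toy_network):
        collapsed = collapse_compartments(toy_network)
        assert {s.label for s in collapsed.species} == {
            "Lig(l1,l2)",
            "Rec(a,b~U,g~U)",
            "Lig(l1!1,l2).Rec(a!1,b~U,g~U)",
            "Lig(l1!1,l2!2).Rec(a!1,b~U,g~U).Rec(a!2,b~U,g~U)",
        }


def test_species_cap(defaults):
    with pytest.raises(NetworkExpansionError, match="cap"):
        generate_network(build_model(defaults), species_cap=50)


def test_lifetime_below_diffusion_limit_rejected(defaults):
    with pytest.raises(ValueError, match="diffusion limit"):
        generate_network(build_model(defaults.replace(raft_lifetime=0.005)))
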