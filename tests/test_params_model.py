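"""Parameter handling, model assembly and partition-class assignment."""

import pytest

from raftsignal.model import assign_partition, build_model
from raftsignal.network import Complex, generate_network
from raftsignal.params import ConfigurationError, ParameterSet, named_variant


class TestParameters:
    def test_defaults_match_shipped_file(self, defaults):
        # the canonical YAML and the dataclass defaults agree field by field
        assert defaults.to_dict() == ParameterSet().to_dict()

    def test_units_metadata_loaded(self, defaults):
        assert defaults.units["k_dephos"] == "/s"

    def test_unknown_key_rejected(self, tmp_path):
        bad = tmp_path / "p.yaml"
        bad.write_text("misc:\n  not_a_parameter: {value: 1}\n")
        with pytest.raises(ConfigurationError, match="not_a_parameter"):
            ParameterSet.from_yaml(bad)

    def test_partial_override_file(self, tmp_path):
        part = tmp_path / "p.yaml"
        part.write_text("dephosphorylation:\n  alpha: {value: 0.5}\n")
        p = ParameterSet.from_yaml(part)
        assert p.alpha == 0.5
        assert p.k_dephos == 20.0

    @pytest.mark.parametrize("overrides", [
        {"alpha": 1.5},
        {"alpha": -0.1},
        {"k_dephos": -1.0},
        {"rho_dimer": 1.0},
        {"coverage": 0.0},
    ])
    def test_validation(self, overrides):
        with pytest.raises(ConfigurationError):
            ParameterSet().replace(**overrides)

    def test_replace_unknown(self):
        with pytest.raises(ConfigurationError):
            ParameterSet().replace(not_a_field=1)

    def test_named_variants(self):
        assert named_variant("faeder-default").syk_off_rate == 0.13
        assert named_variant("reduced-syk-lifetime").syk_off_rate == 0.2
        with pytest.raises(ConfigurationError):
            named_variant("nope")


class TestBuildModel:
    def test_molecule_inventory(self, defaults):
        model = build_model(defaults)
        assert {m.name for m in model.molecule_types} == {
            "Lig", "Hap", "Rec", "Lyn", "Syk", "LAT", "Grb2"
        }

    def test_phosphosites_have_one_dephos_rule_each(self, defaults):
        model = build_model(defaults)
        sites = set(model.phosphosites)
        ruled = [r.target for r in model.rules.dephos]
        assert set(ruled) == sites
        assert len(ruled) == len(sites)

    def test_linker_variant_adds_site_and_rules(self, defaults):
        model = build_model(defaults.replace(syk_linker_site=True))
        assert ("Syk", "l") in model.phosphosites
        assert any(r.substrate == ("Syk", "l") for r in model.rules.transphos)

    def test_no_protection_limit_equalizes_dephos_rates(self, defaults):
        # alpha = 1: every raft dephosphorylation reaction has the same rate
        # as its nonraft twin
        net = generate_network(
            build_model(defaults.replace(alpha=1.0)), include_hapten=False
        )
        rates = {}
        for rxn in net.reactions:
            if rxn.tag != "dephos":
                continue
            sp = net.species[rxn.reactants[0]]
            if sp.location in ("raft", "nonraft"):
                rates.setdefault(sp.label, {})[sp.location] = rxn.rate
        assert rates, "no membrane dephosphorylation reactions found"
        for label, by_loc in rates.items():
            if set(by_loc) == {"raft", "nonraft"}:
                assert by_loc["raft"] == pytest.approx(by_loc["nonraft"])

    def test_absolute_protection_removes_raft_dephos(self, defaults):
        net = generate_network(
            build_model(defaults.replace(alpha=0.0)), include_hapten=False
        )
        for rxn in net.reactions:
            if rxn.tag == "dephos":
                assert net.species[rxn.reactants[0]].location != "raft"


class TestAssignPartition:
    def _species(self, network, **counts):
        for sp in network.species:
            if sp.location != "raft":
                continue
            if all(sp.counts.get(k, 0) == v for k, v in counts.items()) \
                    and sum(sp.counts.values()) == sum(counts.values()):
                return sp
        raise AssertionError(f"no species with counts {counts}")

    def test_precedence_examples(self, defaults, full_network):
        net = full_network
        # unliganded receptor monomer: indifferent to rafts
        assert net.find("Rec(a,b~U,g~U)", "raft").rho == 0.30
        # free Lyn and LAT: palmitoylation-driven
        assert net.find("Lyn(u,sh2)", "raft").rho == 0.85
        assert net.find("LAT(y~U)", "raft").rho == 0.85
        # any ligand-crosslinked dimer: aggregated-receptor class
        dimer = self._species(net, Lig=1, Rec=2, Lyn=1, Syk=1)
        assert dimer.rho == 0.85
        # Lyn confers its raft preference on a bound monomeric receptor
        mono_lyn = self._species(net, Rec=1, Lyn=1)
        assert mono_lyn.rho == 0.85

    def test_cytosolic_binders_do_not_change_class(self, full_network):
        net = full_network
        mono = net.find("Rec(a,b~U,g~U)", "raft")
        mono_syk = self._species(net, Rec=1, Syk=1)
        assert mono_syk.rho == mono.rho
        lat = net.find("LAT(y~U)", "raft")
        lat_grb2 = self._species(net, LAT=1, Grb2=1)
        assert lat_grb2.rho == lat.rho

    def test_mutant_lyn(self, defaults):
        p = defaults.replace(lyn_palmitoylation_mutant=True)
        model = build_model(p)
        free_lyn = Complex.free(model, "Lyn")
        assert assign_partition(free_lyn, p) == 0.06
        # mutant Lyn on a monomeric receptor leaves it indifferent to rafts
        rec = Complex.free(model, "Rec")
        both = rec.joined(free_lyn, 0, "b", 0, "u")
        assert assign_partition(both, p) == p.rho_monomer

    def test_total_on_membrane_complexes(self, full_network):
        for sp in full_network.species:
            if sp.location in ("raft", "nonraft"):
                assert sp.rho is not None and 0 < sp.rho < 1
            else:
                assert sp.rho is None

    def test_cytosolic_complex_rejected(self, defaults):
        model = build_model(defaults)
        with pytest.raises(ConfigurationError):
            assign_partition(Complex.free(model, "Grb2"), defaults)


class TestProtection:
    """SH2-occluded phosphosites have no dephosphorylation channel."""

    @pytest.mark.parametrize("label", [
        "Grb2(sh2!1).LAT(y~P!1)",
        "LAT(y~P!1).Grb2(sh2!1)",
    ])
    def test_grb2_bound_lat_is_protected(self, full_network, label):
        net = full_network
        try:
            sp = net.find(label, "raft")
        except KeyError:
            pytest.skip(f"{label} not the canonical ordering")
        for rxn in net.reactions:
            assert not (rxn.tag == "dephos" and rxn.reactants[0] == sp.index)

    def test_syk_bound_gamma_is_protected(self, full_network):
        net = full_network
        # receptor monomers with Syk on phospho-gamma never lose that
        # phosphate while Syk is bound
        for sp in net.species:
            if sp.location != "raft" or sp.counts.get("Syk", 0) == 0:
                continue
            cpx = net.complex_of(sp.index)
            bound_pg = [
                m for m in cpx.mols
                if m.type == "Rec" and m.states["g"] == "P" and "g" in m.bonds
            ]
            if not bound_pg:
                continue
            for rxn in net.reactions:
                if rxn.tag != "dephos" or rxn.reactants[0] != sp.index:
                    continue
                # any dephosphorylation here must target a different site
                prod = net.species[rxn.products[0]]
                prod_cpx = net.complex_of(prod.index)
                still_bound = [
                    m for m in prod_cpx.mols
                    if m.type == "Rec" and m.states["g"] == "P"
                    and "g" in m.bonds
                ]
                assert len(still_bound) == len(bound_pg)
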