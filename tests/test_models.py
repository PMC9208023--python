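"""Structural tests for the CN / c-CN network builders."""

import pytest

from chemneuron import (
    GeneParams, NeuronSpec, Reaction, ReactionNetwork, Species,
    build_activation_chain, build_ccn, build_cn, default_spec,
)
from chemneuron.models import InvalidSpecError


@pytest.mark.parametrize("N", [1, 2, 3, 4, 5, 6])
@pytest.mark.parametrize("m", [1, 2, 3, 4, 5])
def test_cn_species_and_reaction_counts(N, m):
    """The CN has 3N + 1 + (m+1) species and a fixed per-channel reaction set."""
    spec = default_spec(N=N, m=m)
    net = build_cn(spec)
    assert len(net.species) == 3 * N + 1 + (m + 1)
    # per channel: input, A<->B (2), catalyzed (2), learning (2), H leak = 8
    # global: B leak + 2m chain reactions
    assert len(net.reactions) == 8 * N + 1 + 2 * m
    net.validate()


def test_cn_n2_m1_species_names():
    net = build_cn(default_spec(N=2, m=1))
    assert set(net.species_names()) == {
        "I_1", "I_2", "A_1", "A_2", "H_1", "H_2", "B", "C_0", "C_1"}


def test_learning_requires_learning_signal():
    """Weight accumulation is catalyzed by the occupied chain state C_m."""
    net = build_cn(default_spec(N=1, m=1))
    learn = [r for r in net.reactions if r.label == "learn_1"]
    assert len(learn) == 1
    assert sorted(learn[0].reactants) == ["A_1", "C_1"]
    assert sorted(learn[0].products) == ["C_1", "H_1"]


def test_zero_rate_network_is_valid_and_static():
    spec = default_spec(N=1, m=1, k_AB=0.0, k_BA=0.0, k_cat=0.0,
                        k_cat_rev=0.0, k_learn=0.0, k_learn_rev=0.0,
                        d_H=0.0, d_B=0.0)
    net = build_cn(spec)
    net.validate()
    # all non-chain, non-input reactions have zero rate
    assert all(r.rate_constant == 0 for r in net.reactions
               if not r.label.startswith(("chain", "input")))


@pytest.mark.parametrize("bad", [dict(N=0), dict(m=0), dict(beta=0),
                                 dict(coop_factor=0.0), dict(coop_factor=1.5),
                                 dict(k_AB=-1.0), dict(E_total=0)])
def test_invalid_specs_rejected(bad):
    with pytest.raises(InvalidSpecError):
        default_spec(**bad)


def test_h_init_validation():
    spec = default_spec(N=3, H_init=(1, 2, 3))
    assert spec.H_init == (1, 2, 3)
    with pytest.raises(InvalidSpecError):
        default_spec(N=3, H_init=(1, 2))


def test_threshold_is_dissociation_ratio():
    spec = default_spec(k_plus=10.0, k_minus=1000.0)
    assert spec.threshold == pytest.approx(100.0)


@pytest.mark.parametrize("m", [1, 3])
def test_activation_chain_shape(m):
    """2m reactions; exactly one unbinding step is slowed by rho."""
    rxns = build_activation_chain(m, 10.0, 1000.0, 0.01)
    assert len(rxns) == 2 * m
    binds = [r for r in rxns if len(r.reactants) == 2]
    unbinds = [r for r in rxns if len(r.reactants) == 1]
    assert len(binds) == m and len(unbinds) == m
    slow = [r for r in unbinds if r.rate_constant == pytest.approx(10.0)]
    assert len(slow) == 1
    assert slow[0].reactants == (f"C_{m}",)


def test_activation_chain_guards():
    with pytest.raises(InvalidSpecError):
        build_activation_chain(0, 1.0, 1.0, 0.5)
    with pytest.raises(InvalidSpecError):
        build_activation_chain(2, 1.0, 1.0, 0.0)


def test_ccn_structure():
    """Two compartments share the bulk B but carry their own chains."""
    spec = default_spec(N=2, m=2)
    net = build_ccn(spec)
    names = set(net.species_names())
    assert "B" in names
    for i in (1, 2):
        for base in ("A", "Astar", "h0", "h", "H", "C_0", "C_2"):
            assert f"{base}_{i}" in names
    b_species = [s for s in net.species if s.name == "B"]
    assert b_species[0].compartment == "bulk"
    comp1 = {s.name for s in net.species if s.compartment == "1"}
    assert "A_1" in comp1 and "A_2" not in comp1
    net.validate()


def test_ccn_leak_only_when_gene_silent():
    """With zero leak expression and no activation, H only decays."""
    gp = GeneParams(leak_expression_rate=0.0, activation_rate=0.0)
    net = build_ccn(default_spec(N=1, m=1, H_init=(7,)), gp)
    produce_h = [r for r in net.reactions
                 if "H_1" in r.products and "H_1" not in r.reactants]
    assert all(r.rate_constant == 0.0 or r.reactants[0] == "h_1"
               for r in produce_h)
    # the activated path is off, so h_1 can never be produced
    assert all(r.rate_constant == 0.0 for r in net.reactions
               if r.label == "activate_1")


def test_ccn_single_compartment_maps_to_cn_channel():
    """Restricted to one compartment with direct A->H conversion, the c-CN
    channel touches the same signal species as the CN channel."""
    spec = default_spec(N=1, m=1)
    ccn = build_ccn(spec)
    cn = build_cn(spec)
    # both networks convert A to B (export) and leak B and H
    for net in (cn, ccn):
        labels = {r.label for r in net.reactions}
        assert "input_1" in labels and "leak_B" in labels
        assert any("leak_H" in lb for lb in labels)
        assert any(r.reactants and "A_1" in r.reactants and "B" in r.products
                   for r in net.reactions)


def test_text_round_trip():
    net = build_cn(default_spec(N=2, m=2))
    text = net.to_text()
    net2 = ReactionNetwork.from_text(text)
    assert net2.species_names() == net.species_names()
    assert [r.label for r in net2.reactions] == [r.label for r in net.reactions]
    assert net2.to_text() == text


def test_json_round_trip():
    net = build_cn(default_spec(N=3, m=1), activation="hill")
    doc = net.to_json()
    net2 = ReactionNetwork.from_json(doc)
    assert net2.to_json() == doc
    assert any(r.modifier == "E_active" for r in net2.reactions)


def test_yaml_spec_round_trip():
    spec = default_spec(N=4, m=3, H_init=(1, 0, 2, 5))
    spec2 = NeuronSpec.from_yaml(spec.to_yaml())
    assert spec2 == spec


def test_network_validation_rejects_unknown_species():
    net = ReactionNetwork(species=[Species("X")],
                          reactions=[Reaction(("X",), ("Y",), 1.0, "bad")])
    with pytest.raises(InvalidSpecError):
        net.validate()
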