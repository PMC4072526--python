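"""Data model, .rxn parsing/writing, classification, stoichiometry."""

import numpy as np
import pytest

from ergokit import (
    bimolecular_stoichiometry,
    build_fixture,
    evaluate_propensities,
    fixture_names,
    parse_network,
    stoichiometry_matrix,
    write_network,
)
from ergokit.network import ParseError, ReactionNetwork


def test_parse_birth_death_minimal():
    net = parse_network(
        "species: X\nreaction b: -> X @ ma(2.0)\nreaction d: X -> @ ma(1.0)"
    )
    assert net.d == 1 and net.K == 2
    assert list(net.reactions[0].zeta) == [1]
    assert list(net.reactions[1].zeta) == [-1]
    assert net.class_tag == "unimolecular"


def test_parse_full_grammar():
    text = """
    # a comment
    species: A, B, C
    param k1 = 10.0
    reaction R1: 2 A + B -> C @ ma(k1)
    reaction R2: -> A @ bounded(sup=5.0, hint="k1/(1+C^2)")
    reaction R3: A -> @ bounded(sup=1.5, per=B, hint="1.5*B*A/(A+1)")
    interval k1 = [0.5, 2.0]
    """
    net = parse_network(text)
    assert net.species == ["A", "B", "C"]
    r1 = net.reactions[0]
    assert r1.propensity.rate_constant == 10.0
    assert list(r1.zeta) == [-2, -1, 1]
    assert net.reactions[1].propensity.kind == "bounded_function"
    assert net.reactions[2].propensity.kind == "scaled_bounded"
    assert net.rate_intervals["R1"] == (0.5, 2.0)


@pytest.mark.parametrize("bad, fragment", [
    ("reaction r: Y -> @ ma(1)", "species"),           # undeclared species
    ("species: X\nreaction r: X -> @ ma(-1)", "rate"),  # negative rate
    ("species: X\nreaction r: -> X @ bounded(hint=\"1\")", "sup"),  # no sup
])
def test_parse_errors(bad, fragment):
    with pytest.raises(ParseError) as exc:
        parse_network(bad)
    assert "line" in str(exc.value)


def test_roundtrip_on_registry():
    for name in fixture_names():
        net = build_fixture(name)
        assert parse_network(write_network(net)) == net, name


def test_stoichiometry_matrices(dimerization, sir):
    assert stoichiometry_matrix(build_fixture("birth_death")).tolist() == [[1, -1]]
    S = stoichiometry_matrix(dimerization)
    assert S.T.tolist() == [[1, 0], [-1, 0], [-2, 1], [0, -1]]
    assert bimolecular_stoichiometry(dimerization).T.tolist() == [[-2, 1]]
    # contamination column of the SIR model
    contact = sir.reactions[[r.label for r in sir.reactions].index("contact")]
    assert list(contact.zeta) == [-1, 1, 0]
    assert bimolecular_stoichiometry(sir).T.tolist() == [[-1, 1, 0]]
    # unimolecular network: no order-2 columns
    assert bimolecular_stoichiometry(build_fixture("birth_death")).shape == (1, 0)


def test_classification_and_counts():
    assert build_fixture("dimerization_29").class_tag == "bimolecular"
    assert build_fixture("schlogl_40").class_tag == "general_mass_action"
    assert build_fixture("toggle_switch_35").class_tag == "unimolecular"
    circ = build_fixture("circadian_vilar")
    assert (circ.d, circ.K) == (9, 18)
    rep = build_fixture("repressilator_36")
    assert rep.d == 6  # mRNA + protein per gene, 3 genes
    assert all(
        r.propensity.kind == "bounded_function"
        for r in rep.reactions if r.label.startswith("tx")
    )


def test_fixture_registry_errors():
    with pytest.raises(KeyError):
        build_fixture("nonexistent")
    with pytest.raises(KeyError):
        build_fixture("birth_death", {"not_a_param": 1.0})


def test_invalid_reactions_rejected():
    net = ReactionNetwork(["A"])
    with pytest.raises(ValueError):
        net.add_reaction("noop", {"A": 1}, {"A": 1}, 1.0)  # zeta = 0
    with pytest.raises(ValueError):
        net.add_reaction("deep", {"A": 4}, {}, 1.0)  # order > 3
    with pytest.raises(ValueError):
        net.add_reaction("neg", {}, {"A": 1}, -2.0)  # negative rate


def test_positivity_at_depleted_states():
    """Any channel consuming species i has zero propensity when x_i is
    below its reactant multiplicity, on every fixture."""
    for name in fixture_names():
        net = build_fixture(name)
        if any(r.propensity.kind != "mass_action" for r in net.reactions):
            continue
        x = np.zeros(net.d)
        lam = evaluate_propensities(net, x)
        for k, r in enumerate(net.reactions):
            if any(m > 0 for m in r.propensity.reactant_multiset.values()):
                assert lam[k] == 0.0, (name, r.label)


def test_conservation_in_conversion_network(conversion):
    S = stoichiometry_matrix(conversion)
    assert np.all(np.array([1, 1]) @ S == 0)


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @st.composite
    def small_networks(draw):
        d = draw(st.integers(1, 4))
        species = [f"S{i}" for i in range(d)]
        net = ReactionNetwork(species)
        n_rxn = draw(st.integers(1, 5))
        for k in range(n_rxn):
            order = draw(st.integers(0, 2))
            reactants = {}
            for _ in range(order):
                s = draw(st.sampled_from(species))
                reactants[s] = reactants.get(s, 0) + 1
            products = {}
            for _ in range(draw(st.integers(0, 2))):
                s = draw(st.sampled_from(species))
                products[s] = products.get(s, 0) + 1
            rate = draw(st.floats(0.0, 100.0, allow_nan=False))
            try:
                net.add_reaction(f"r{k}", reactants, products, rate)
            except ValueError:
                pass  # no-op reaction drawn; skip it
        return net

    @given(small_networks())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_roundtrip_property(net):
        """parse ∘ write is the identity on arbitrary small networks."""
        assert parse_network(write_network(net)) == net
except ImportError:  # pragma: no cover - hypothesis is a test extra
    pass


def test_empty_network_document():
    net = ReactionNetwork(["A"])
    text = write_network(net)
    assert "species: A" in text
    assert parse_network(text) == net
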