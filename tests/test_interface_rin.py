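import networkx as nx
import numpy as np
import pytest

from dnahotspot.interface_rin import (
    Contact,
    InteractionCriteria,
    build_rin,
    centrality_features,
    detect_interactions,
    distance_interface,
    export_edge_list,
    interface_calls,
    sasa_interface,
)
from dnahotspot.structure_io import Atom, Chain, Complex, Residue
from dnahotspot.synthetic_fixtures import (
    make_disulfide_fixture,
    make_pi_stack_fixture,
    make_salt_bridge_fixture,
)


# --------------------------------------------------------------------------
# interface rules

def test_sasa_rule_flags_contacting_face(toy_complex, toy_truth):
    calls = sasa_interface(toy_complex, "A")
    flagged = {k for k, v in calls.items() if v["by_sasa_rule"]}
    assert toy_truth <= flagged  # every true contact loses > 1 A^2


def test_distant_residues_lose_no_area(far_bundle):
    _, _, cx = far_bundle
    calls = sasa_interface(cx, "A")
    for v in calls.values():
        assert abs(v["delta_asa"]) < 1e-9
        assert not v["by_sasa_rule"]


def test_buried_residue_excluded_by_rasa_conjunction(toy_complex):
    # force the RASA gate shut: with an absurd threshold nothing passes
    calls = sasa_interface(toy_complex, "A", rasa_min_pct=1000.0)
    assert not any(v["by_sasa_rule"] for v in calls.values())


def _one_atom_complex(dist):
    res = Residue(key=("A", 1, ""), name="GLY", polymer_class="protein",
                  atoms=[Atom("CA", "C", np.zeros(3))])
    nuc = Residue(key=("D", 1, ""), name="DA", polymer_class="dna",
                  atoms=[Atom("P", "P", np.array([dist, 0.0, 0.0]))])
    return Complex(id="x", chains=[
        Chain(id="A", residues=[res], polymer_class="protein"),
        Chain(id="D", residues=[nuc], polymer_class="dna")])


def test_distance_rule_strict_boundary():
    assert distance_interface(_one_atom_complex(4.99), "A")[("A", 1, "")]["by_distance_rule"]
    assert not distance_interface(_one_atom_complex(5.00), "A")[("A", 1, "")]["by_distance_rule"]


def test_min_distances_match_all_pairs_oracle(toy_complex):
    out = distance_interface(toy_complex, "A")
    dna_atoms = np.array([
        a.position
        for c in toy_complex.dna_chains
        for r in c.residues for a in r.heavy_atoms()])
    for res in toy_complex.chain("A").residues:
        coords = np.array([a.position for a in res.heavy_atoms()])
        d = np.linalg.norm(coords[:, None] - dna_atoms[None], axis=2).min()
        assert out[res.key]["min_dist_to_dna"] == pytest.approx(d, abs=1e-9)


def test_missing_chain_lists_available(toy_complex):
    with pytest.raises(KeyError, match="available"):
        distance_interface(toy_complex, "Z")


def test_no_dna_chain_errors():
    res = Residue(key=("A", 1, ""), name="GLY", polymer_class="protein",
                  atoms=[Atom("CA", "C", np.zeros(3))])
    cx = Complex(id="x", chains=[Chain(id="A", residues=[res],
                                       polymer_class="protein")])
    with pytest.raises(ValueError):
        distance_interface(cx, "A")


def test_interface_union_vs_intersection(toy_complex):
    union = interface_calls(toy_complex, "A", policy="union")
    inter = interface_calls(toy_complex, "A", policy="intersection")
    u = {c.key for c in union if c.is_interface}
    i = {c.key for c in inter if c.is_interface}
    assert i <= u
    for c in union:
        assert c.is_interface == (c.by_sasa_rule or c.by_distance_rule)


def test_calls_invariant_under_rigid_motion(toy_complex):
    before = interface_calls(toy_complex, "A")
    # rotate + translate every atom
    theta = 0.8
    rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
    shift = np.array([11.0, -4.0, 7.0])
    import copy
    moved = copy.deepcopy(toy_complex)
    for r in moved.iter_residues():
        for a in r.atoms:
            a.position = rot @ a.position + shift
    after = interface_calls(moved, "A")
    for b, a in zip(before, after):
        assert b.is_interface == a.is_interface
        assert b.min_dist_to_dna == pytest.approx(a.min_dist_to_dna, abs=1e-6)


def test_distance_flag_monotone_in_cutoff(toy_complex):
    flags_lo = {k: v["by_distance_rule"]
                for k, v in distance_interface(toy_complex, "A", cutoff=4.0).items()}
    flags_hi = {k: v["by_distance_rule"]
                for k, v in distance_interface(toy_complex, "A", cutoff=6.5).items()}
    for k in flags_lo:
        assert not flags_lo[k] or flags_hi[k]


# --------------------------------------------------------------------------
# typed contacts

def test_disulfide_detection():
    contacts = detect_interactions(make_disulfide_fixture())
    assert {"disulfide"} <= {c.type for c in contacts}
    ss = [c for c in contacts if c.type == "disulfide"][0]
    assert ss.distance == pytest.approx(2.05, abs=0.01)


def test_salt_bridge_detection():
    contacts = detect_interactions(make_salt_bridge_fixture())
    sb = [c for c in contacts if c.type == "salt_bridge"]
    assert sb and sb[0].distance == pytest.approx(3.0, abs=0.01)


def test_pi_pi_and_pi_cation_detection():
    contacts = detect_interactions(make_pi_stack_fixture())
    types = {c.type for c in contacts}
    assert "pi_pi" in types and "pi_cation" in types


def test_far_apart_residues_yield_no_edge():
    r1 = Residue(key=("A", 1, ""), name="GLY", polymer_class="protein",
                 atoms=[Atom("CA", "C", np.zeros(3))])
    r2 = Residue(key=("A", 2, ""), name="GLY", polymer_class="protein",
                 atoms=[Atom("CA", "C", np.array([10.0, 0, 0]))])
    cx = Complex(id="x", chains=[Chain(id="A", residues=[r1, r2],
                                       polymer_class="protein")])
    assert detect_interactions(cx) == []


# --------------------------------------------------------------------------
# network construction

def test_rin_isolated_nodes_allowed():
    keys = [("A", i, "") for i in (1, 2, 3)]
    g = build_rin([], keys)
    assert g.number_of_nodes() == 3 and g.number_of_edges() == 0


def test_rin_parallel_contacts_collapse():
    a, b = ("A", 1, ""), ("A", 2, "")
    g = build_rin([
        Contact(a, b, "hbond", 2.9),
        Contact(a, b, "salt_bridge", 3.1),
    ], [a, b])
    assert g.number_of_edges() == 1
    assert g.edges[a, b]["weight"] == pytest.approx(2.9)
    assert g.edges[a, b]["types"] == {"hbond", "salt_bridge"}


def test_rin_one_edge_per_contacting_pair(toy_complex):
    contacts = detect_interactions(toy_complex)
    pairs = {frozenset((c.a, c.b)) for c in contacts}
    g = build_rin(contacts)
    assert g.number_of_edges() == len(pairs)


def test_edge_list_export_round_numbers():
    a, b = ("A", 1, ""), ("D", 2, "")
    g = build_rin([Contact(a, b, "hbond", 2.875)], [a])
    text = export_edge_list(g)
    assert "hbond" in text and "2.875" in text.replace("2.875", "2.875")
    assert text.startswith("node_a\tnode_b\ttypes\tweight")


# --------------------------------------------------------------------------
# centralities: small closed-form cases (the random-graph oracle suite is
# exercised in the acceptance tests)

def _path3():
    g = nx.Graph()
    g.add_edge("a", "b", weight=1.0, types={"hbond"})
    g.add_edge("b", "c", weight=1.0, types={"hbond"})
    return g


def test_path_graph_degree_and_betweenness():
    cf = centrality_features(_path3())
    assert cf["b"]["degree"] == 2
    assert cf["b"]["betweenness"] == pytest.approx(1.0)
    assert cf["a"]["betweenness"] == pytest.approx(0.0)


def test_four_cycle_eigenvector_symmetric():
    g = nx.Graph()
    for u, v in [(0, 1), (1, 2), (2, 3), (3, 0)]:
        g.add_edge(u, v, weight=1.0, types={"vdw"})
    cf = centrality_features(g)
    vals = [cf[v]["eigenvector"] for v in g.nodes]
    np.testing.assert_allclose(vals, vals[0], atol=1e-9)


def test_katz_matches_power_series():
    cf = centrality_features(_path3(), katz_alpha=0.1, katz_beta=1.0)
    A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
    x = np.zeros(3)
    term = np.ones(3)
    for k in range(200):
        x += term
        term = 0.1 * A @ term
    for i, v in enumerate(["a", "b", "c"]):
        assert cf[v]["katz"] == pytest.approx(x[i], abs=1e-8)


def test_singleton_conventions():
    g = nx.Graph()
    g.add_node("solo")
    cf = centrality_features(g)
    s = cf["solo"]
    assert s["closeness"] == 0 and s["eccentricity"] == 0
    assert s["eigenvector"] == 1.0 and s["katz"] == 1.0
    assert s["flow_closeness"] == 0


def test_empty_network_rejected():
    with pytest.raises(ValueError):
        centrality_features(nx.Graph())
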