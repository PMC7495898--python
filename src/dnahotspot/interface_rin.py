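"""Protein-DNA interface calling, typed contact detection, the
distance-weighted residue interaction network (RIN), and its ten
centrality features.

Interface residues are determined by two rules and combined by union
(configurable to intersection):

* solvent-accessibility rule — losing more than 1 A^2 of accessible area on
  binding (dASA > 1) while being at least 5% exposed in the unbound chain
  (RASA > 5%);
* distance rule — any heavy atom strictly closer than 5 A to a DNA heavy
  atom.

Contacts between residues and nucleotides are typed geometrically (hydrogen
bond, van der Waals, disulfide, salt bridge, pi-pi, pi-cation); every
threshold is a parameter.  Edges of the RIN carry the minimum contact
distance as weight; path-based centralities (closeness, betweenness,
eccentricity, flow closeness) use these weights as lengths/resistances,
while spectral and neighbourhood measures (degree, clustering, eigenvector,
Katz, average neighbour degree, square clustering) use the unweighted
adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Complex, Residue
from .surface_exposure import SasaParams, load_reference_asa, relative_asa, shrake_rupley_sasa

__all__ = [
    "InterfaceCall",
    "InteractionCriteria",
    "Contact",
    "sasa_interface",
    "distance_interface",
    "interface_calls",
    "detect_interactions",
    "build_rin",
    "centrality_features",
    "CENTRALITY_NAMES",
    "export_edge_list",
]

CENTRALITY_NAMES = (
    "degree",
    "clustering",
    "closeness",
    "betweenness",
    "eigenvector",
    "eccentricity",
    "average_neighbor_degree",
    "flow_closeness",
    "square_clustering",
    "katz",
)


@dataclass
class InterfaceCall:
    key: tuple
    delta_asa: float
    rasa_unbound: float
    min_dist_to_dna: float
    by_sasa_rule: bool
    by_distance_rule: bool
    is_interface: bool


@dataclass
class InteractionCriteria:
    """Geometric contact thresholds (A); standard literature values."""
    hbond_max: float = 3.5
    vdw_slack: float = 0.5
    disulfide_max: float = 2.5
    salt_bridge_max: float = 4.0
    pi_pi_max: float = 5.5
    pi_cation_max: float = 6.0


@dataclass
class Contact:
    a: tuple
    b: tuple
    type: str
    distance: float


def _heavy_coords(res: Residue) -> np.ndarray:
    return np.array([a.position for a in res.heavy_atoms()])


def sasa_interface(
    complex_: Complex,
    protein_chain: str,
    dna_chains: Optional[Sequence[str]] = None,
    params: Optional[SasaParams] = None,
    *,
    delta_asa_min: float = 1.0,
    rasa_min_pct: float = 5.0,
) -> Dict[tuple, dict]:
    """Solvent-accessibility interface rule.

    dASA = ASA(protein chain alone) - ASA(protein chain in complex with the
    DNA chains); the rule flags residues with dASA > ``delta_asa_min`` AND
    unbound RASA > ``rasa_min_pct``.
    """
    params = params or SasaParams()
    chain = complex_.chain(protein_chain)
    if dna_chains is None:
        dna_chains = [c.id for c in complex_.dna_chains]
    dna = [complex_.chain(c) for c in dna_chains]
    unbound = shrake_rupley_sasa(chain, params)
    bound = shrake_rupley_sasa([chain] + dna, params)
    reference = load_reference_asa()
    out: Dict[tuple, dict] = {}
    for res in chain.residues:
        asa_u = unbound.residue_asa.get(res.key, 0.0)
        asa_b = bound.residue_asa.get(res.key, 0.0)
        delta = asa_u - asa_b
        try:
            rasa_u = relative_asa(asa_u, res.name, reference)
        except KeyError:
            rasa_u = relative_asa(asa_u, res.name, reference, allow_fallback=True)
        out[res.key] = dict(
            delta_asa=delta,
            rasa_unbound=rasa_u,
            by_sasa_rule=(delta > delta_asa_min) and (rasa_u > rasa_min_pct),
        )
    return out


def distance_interface(
    complex_: Complex,
    protein_chain: str,
    dna_chains: Optional[Sequence[str]] = None,
    cutoff: float = 5.0,
) -> Dict[tuple, dict]:
    """Distance interface rule: minimum heavy-atom distance from each
    protein residue to any DNA heavy atom; flagged when strictly < cutoff."""
    chain = complex_.chain(protein_chain)
    if dna_chains is None:
        dna_chains = [c.id for c in complex_.dna_chains]
    if not dna_chains:
        raise ValueError("no DNA chains present or specified")
    dna_atoms = []
    for cid in dna_chains:
        for res in complex_.chain(cid).residues:
            dna_atoms.extend(a.position for a in res.heavy_atoms())
    if not dna_atoms:
        raise ValueError("DNA chains contain no heavy atoms")
    tree = cKDTree(np.array(dna_atoms))
    out: Dict[tuple, dict] = {}
    for res in chain.residues:
        coords = _heavy_coords(res)
        d, _ = tree.query(coords)
        dmin = float(d.min())
        out[res.key] = dict(min_dist_to_dna=dmin, by_distance_rule=dmin < cutoff)
    return out


def interface_calls(
    complex_: Complex,
    protein_chain: str,
    dna_chains: Optional[Sequence[str]] = None,
    params: Optional[SasaParams] = None,
    *,
    policy: str = "union",
    delta_asa_min: float = 1.0,
    rasa_min_pct: float = 5.0,
    distance_cutoff: float = 5.0,
) -> List[InterfaceCall]:
    """Combine the two interface rules; ``policy`` is 'union' or
    'intersection'."""
    if policy not in ("union", "intersection"):
        raise ValueError("policy must be 'union' or 'intersection'")
    s = sasa_interface(complex_, protein_chain, dna_chains, params,
                       delta_asa_min=delta_asa_min, rasa_min_pct=rasa_min_pct)
    d = distance_interface(complex_, protein_chain, dna_chains, distance_cutoff)
    calls = []
    for key in s:
        sr, dr = s[key]["by_sasa_rule"], d[key]["by_distance_rule"]
        is_if = (sr or dr) if policy == "union" else (sr and dr)
        calls.append(InterfaceCall(
            key=key,
            delta_asa=s[key]["delta_asa"],
            rasa_unbound=s[key]["rasa_unbound"],
            min_dist_to_dna=d[key]["min_dist_to_dna"],
            by_sasa_rule=sr,
            by_distance_rule=dr,
            is_interface=is_if,
        ))
    return calls


# ---------------------------------------------------------------------------
# typed contact detection

_HB_DONOR_EL = {"N", "O", "S"}
_HB_ACCEPTOR_EL = {"N", "O"}
_BASIC_N = {
    "LYS": {"NZ"},
    "ARG": {"NH1", "NH2", "NE"},
    "HIS": {"ND1", "NE2"},
}
_ACIDIC_O = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}
_PHOSPHATE_O = {"OP1", "OP2", "O1P", "O2P"}
_RING_ATOMS = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
}
_DNA_RING = {"N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"}
_CATION_N = {"LYS": {"NZ"}, "ARG": {"NH1", "NH2", "NE"}}


def _ring_centroid(res: Residue) -> Optional[np.ndarray]:
    if res.polymer_class == "dna":
        names = _DNA_RING
    else:
        names = _RING_ATOMS.get(res.name)
        if names is None:
            return None
    pts = [a.position for a in res.atoms if a.name in names]
    if len(pts) < 4:
        return None
    return np.mean(pts, axis=0)


def detect_interactions(
    complex_: Complex,
    criteria: Optional[InteractionCriteria] = None,
    radii_table: Optional[Dict[str, float]] = None,
) -> List[Contact]:
    """Typed geometric contacts between all residue/nucleotide pairs.

    For each pair every applicable type is emitted; van der Waals is only
    reported when no more specific type applies to the pair.  Residues
    lacking the atoms a type requires simply yield no contact of that type.
    """
    criteria = criteria or InteractionCriteria()
    radii = radii_table or SasaParams().radii_table
    residues = [r for r in complex_.iter_residues()
                if r.polymer_class in ("protein", "dna")]
    coords = [_heavy_coords(r) for r in residues]
    names = [[a.name for a in r.heavy_atoms()] for r in residues]
    elements = [[a.element for a in r.heavy_atoms()] for r in residues]
    centroids = [_ring_centroid(r) for r in residues]

    # coarse pair pruning via residue bounding spheres
    centers = np.array([c.mean(axis=0) for c in coords])
    spans = np.array([np.linalg.norm(c - m, axis=1).max()
                      for c, m in zip(coords, centers)])
    reach = max(criteria.pi_cation_max, criteria.pi_pi_max, 6.0) + 2 * 2.0
    tree = cKDTree(centers)
    contacts: List[Contact] = []
    for i, j in sorted(tree.query_pairs(r=float(2 * spans.max() + reach))):
        ri, rj = residues[i], residues[j]
        dmat = np.linalg.norm(coords[i][:, None, :] - coords[j][None, :, :], axis=2)
        pair_types: List[Tuple[str, float]] = []

        # disulfide
        if ri.name == "CYS" and rj.name == "CYS":
            for ai, ni in enumerate(names[i]):
                for aj, nj in enumerate(names[j]):
                    if ni == "SG" and nj == "SG" and dmat[ai, aj] <= criteria.disulfide_max:
                        pair_types.append(("disulfide", float(dmat[ai, aj])))

        # salt bridge (basic N vs acidic/phosphate O, either direction)
        def _salt(a_res, a_names, b_res, b_names, d, transpose):
            basic = _BASIC_N.get(a_res.name, set())
            acidic = _ACIDIC_O.get(b_res.name, set()) | (
                _PHOSPHATE_O if b_res.polymer_class == "dna" else set())
            best = None
            for ai, ni in enumerate(a_names):
                if ni not in basic:
                    continue
                for bj, nj in enumerate(b_names):
                    if nj not in acidic:
                        continue
                    dist = d[bj, ai] if transpose else d[ai, bj]
                    if dist <= criteria.salt_bridge_max:
                        best = dist if best is None else min(best, dist)
            return best

        sb = _salt(ri, names[i], rj, names[j], dmat, False)
        sb2 = _salt(rj, names[j], ri, names[i], dmat, True)
        for val in (sb, sb2):
            if val is not None:
                pair_types.append(("salt_bridge", float(val)))

        # hydrogen bond: donor-element heavy atom to acceptor-element heavy atom
        hb_best = None
        for ai, ei in enumerate(elements[i]):
            for aj, ej in enumerate(elements[j]):
                ok = (ei in _HB_DONOR_EL and ej in _HB_ACCEPTOR_EL) or (
                    ej in _HB_DONOR_EL and ei in _HB_ACCEPTOR_EL)
                if ok and dmat[ai, aj] <= criteria.hbond_max:
                    hb_best = dmat[ai, aj] if hb_best is None else min(hb_best, dmat[ai, aj])
        if hb_best is not None:
            pair_types.append(("hbond", float(hb_best)))

        # pi-pi and pi-cation
        ci, cj = centroids[i], centroids[j]
        if ci is not None and cj is not None:
            d = float(np.linalg.norm(ci - cj))
            if d <= criteria.pi_pi_max:
                pair_types.append(("pi_pi", d))
        for (res_a, cent_b) in ((ri, cj), (rj, ci)):
            if cent_b is None:
                continue
            cation = _CATION_N.get(res_a.name, set())
            atoms_a = ri if res_a is ri else rj
            for atom in atoms_a.heavy_atoms():
                if atom.name in cation:
                    d = float(np.linalg.norm(atom.position - cent_b))
                    if d <= criteria.pi_cation_max:
                        pair_types.append(("pi_cation", d))

        # van der Waals: only when no tighter type applies
        if not pair_types:
            vdw_best = None
            for ai, ei in enumerate(elements[i]):
                for aj, ej in enumerate(elements[j]):
                    cut = radii.get(ei.upper(), 1.8) + radii.get(ej.upper(), 1.8) + criteria.vdw_slack
                    if dmat[ai, aj] <= cut:
                        vdw_best = dmat[ai, aj] if vdw_best is None else min(vdw_best, dmat[ai, aj])
            if vdw_best is not None:
                pair_types.append(("vdw", float(vdw_best)))

        for t, d in pair_types:
            contacts.append(Contact(a=ri.key, b=rj.key, type=t, distance=d))
    return contacts


def build_rin(
    contacts: Iterable[Contact],
    protein_residue_keys: Iterable[tuple] = (),
) -> nx.Graph:
    """Distance-weighted residue interaction network.

    One node per residue/nucleotide participating in at least one contact,
    plus every protein-chain residue key given (isolated nodes allowed).
    Parallel typed contacts between a pair collapse to one edge whose weight
    is the minimum contact distance; type labels are merged into the edge's
    ``types`` set.
    """
    g = nx.Graph()
    for key in protein_residue_keys:
        g.add_node(key)
    for c in contacts:
        if c.a == c.b:
            continue
        if g.has_edge(c.a, c.b):
            data = g.edges[c.a, c.b]
            data["weight"] = min(data["weight"], c.distance)
            data["types"].add(c.type)
        else:
            g.add_edge(c.a, c.b, weight=c.distance, types={c.type})
    return g


# ---------------------------------------------------------------------------
# centralities

def _eigenvector_component(adj: np.ndarray) -> np.ndarray:
    """Principal eigenvector of the component adjacency, non-negative,
    unit L2 norm."""
    vals, vecs = np.linalg.eigh(adj)
    v = vecs[:, -1]
    if v.sum() < 0:
        v = -v
    v = np.abs(v)  # Perron vector is non-negative up to sign
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _katz_component(adj: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Katz centrality x = beta * sum_k alpha^k A^k 1 = (I - alpha A)^-1 beta 1,
    with alpha shrunk below the inverse spectral radius when necessary."""
    n = adj.shape[0]
    if n == 1:
        return np.array([beta])
    lam = float(np.linalg.eigvalsh(adj)[-1])
    if lam > 0 and alpha >= 1.0 / lam:
        alpha = 0.9 / lam
    return np.linalg.solve(np.eye(n) - alpha * adj, beta * np.ones(n))


def _flow_closeness_component(
    nodes: list, g: nx.Graph, n_total: int
) -> Dict:
    """Current-flow (information) closeness with edge distance as
    resistance: C(v) = (k-1) / sum_w R_eff(v, w), scaled by (k-1)/(n-1) for
    disconnected graphs, where k is the component size."""
    k = len(nodes)
    if k == 1:
        return {nodes[0]: 0.0}
    idx = {v: i for i, v in enumerate(nodes)}
    lap = np.zeros((k, k))
    for u, v, data in g.edges(nodes, data=True):
        if u in idx and v in idx:
            c = 1.0 / data["weight"]
            i, j = idx[u], idx[v]
            lap[i, i] += c
            lap[j, j] += c
            lap[i, j] -= c
            lap[j, i] -= c
    pinv = np.linalg.pinv(lap)
    diag = np.diag(pinv)
    r_eff = diag[:, None] + diag[None, :] - 2 * pinv
    totals = r_eff.sum(axis=1)
    scale = (k - 1) / (n_total - 1) if n_total > 1 else 1.0
    return {v: float((k - 1) / totals[idx[v]] * scale) for v in nodes}


def centrality_features(
    g: nx.Graph,
    *,
    katz_alpha: float = 0.1,
    katz_beta: float = 1.0,
) -> Dict[tuple, Dict[str, float]]:
    """The ten per-node centrality features of the RIN.

    Weighted measures treat edge weight as a path length (resistance for
    flow closeness); spectral/neighbourhood measures use the unweighted
    adjacency.  Disconnected graphs are handled per component; singleton
    conventions: closeness 0, eccentricity 0, eigenvector 1, katz = beta,
    flow closeness 0.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    n = g.number_of_nodes()
    out: Dict[tuple, Dict[str, float]] = {v: {} for v in g.nodes}

    degree = dict(g.degree())
    clustering = nx.clustering(g)
    avg_nbr = nx.average_neighbor_degree(g)
    square = nx.square_clustering(g)
    betweenness = nx.betweenness_centrality(g, weight="weight", normalized=True)
    closeness = nx.closeness_centrality(g, distance="weight")

    eccentricity: Dict = {}
    eig: Dict = {}
    katz: Dict = {}
    flow: Dict = {}
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        sub = g.subgraph(nodes)
        if len(nodes) == 1:
            v = nodes[0]
            eccentricity[v] = 0.0
            eig[v] = 1.0
            katz[v] = katz_beta
            flow[v] = 0.0
            continue
        ecc = nx.eccentricity(sub, weight="weight")
        eccentricity.update(ecc)
        adj = nx.to_numpy_array(sub, nodelist=nodes, weight=None)
        ev = _eigenvector_component(adj)
        kz = _katz_component(adj, katz_alpha, katz_beta)
        for i, v in enumerate(nodes):
            eig[v] = float(ev[i])
            katz[v] = float(kz[i])
        flow.update(_flow_closeness_component(nodes, g, n))

    for v in g.nodes:
        out[v] = dict(
            degree=float(degree[v]),
            clustering=float(clustering[v]),
            closeness=float(closeness[v]),
            betweenness=float(betweenness[v]),
            eigenvector=float(eig[v]),
            eccentricity=float(eccentricity[v]),
            average_neighbor_degree=float(avg_nbr[v]),
            flow_closeness=float(flow[v]),
            square_clustering=float(square[v]),
            katz=float(katz[v]),
        )
    return out


def export_edge_list(g: nx.Graph) -> str:
    """Simple text edge list: node_a TAB node_b TAB type_labels TAB weight."""
    lines = ["node_a\tnode_b\ttypes\tweight"]
    for u, v, data in sorted(g.edges(data=True)):
        ku = ":".join(str(x) for x in u)
        kv = ":".join(str(x) for x in v)
        types = ",".join(sorted(data.get("types", set())))
        lines.append(f"{ku}\t{kv}\t{types}\t{data['weight']:.3f}")
    return "\n".join(lines) + "\n"
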