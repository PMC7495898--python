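"""Synthetic test inputs: toy protein-DNA complexes with a
known-by-construction interface, planted-signal feature tables, and
synthetic mutation tables.

The toy complex is an idealized alpha-helix (N/CA/C/O/CB backbone on a
2.3 A-radius, 1.5 A-rise, 100 deg-twist helix) placed beside an idealized
straight B-form-like DNA duplex (phosphate, sugar and base-ring atoms,
3.4 A rise, no helical twist).  Geometry is a scaffold for distance-based
detectors, not an energy-minimized model: contact distances are exact by
construction, conformational realism is not attempted.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
import pandas as pd

from .structure_io import AA3_TO_1, Atom, Chain, Complex, Residue, write_pdb

__all__ = [
    "ToyComplexSpec",
    "PlantedTableSpec",
    "make_toy_complex",
    "make_planted_table",
    "make_mutation_table",
    "make_disulfide_fixture",
    "make_salt_bridge_fixture",
    "make_pi_stack_fixture",
]

_AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
# palette avoids GLY (keeps CB geometry uniform) and PRO
_PALETTE = "AKLSERFDQTNVYWHIM"


@dataclass
class ToyComplexSpec:
    helix_length: int = 12
    dna_base_pairs: int = 8
    approach_distance: float = 3.5  # closest heavy-atom gap, A
    seed: int = 0
    contact_cutoff: float = 5.0  # ground-truth interface rule, A

    def __post_init__(self) -> None:
        if self.helix_length < 4:
            raise ValueError("helix_length must be >= 4")
        if self.approach_distance <= 0:
            raise ValueError("approach_distance must be positive")


@dataclass
class PlantedTableSpec:
    n_samples: int = 200
    n_informative: int = 3
    n_noise: int = 17
    class_shift: float = 1.5  # standardized mean difference
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative < 0 or self.n_noise < 0:
            raise ValueError("column counts must be non-negative")


def _helix_residues(length: int, sequence: str) -> List[Residue]:
    """Ideal helix backbone: CA on a 2.3 A-radius helix, CB radially
    outward, N/C along the chain direction, O off the carbonyl."""
    radius, rise, twist = 2.3, 1.5, np.deg2rad(100.0)
    ca = np.array(
        [
            (radius * np.cos(i * twist), radius * np.sin(i * twist), i * rise)
            for i in range(length)
        ]
    )
    residues = []
    for i in range(length):
        prev_dir = ca[i] - ca[i - 1] if i > 0 else ca[0] - ca[1]
        next_dir = ca[i + 1] - ca[i] if i < length - 1 else ca[-1] - ca[-2]
        prev_dir = prev_dir / np.linalg.norm(prev_dir)
        next_dir = next_dir / np.linalg.norm(next_dir)
        radial = np.array([np.cos(i * twist), np.sin(i * twist), 0.0])
        aa3 = _AA1_TO_3[sequence[i]]
        atoms = [
            Atom("N", "N", ca[i] - 1.46 * prev_dir),
            Atom("CA", "C", ca[i].copy()),
            Atom("C", "C", ca[i] + 1.52 * next_dir),
            Atom("O", "O", ca[i] + 1.52 * next_dir + 1.23 * radial),
            Atom("CB", "C", ca[i] + 1.53 * radial),
        ]
        residues.append(
            Residue(key=("A", i + 1, ""), name=aa3, atoms=atoms,
                    polymer_class="protein")
        )
    return residues


# minimal purine-like coordinate template (local frame: backbone at +y,
# base extending toward y = 0); names cover sugar + ring so centroids and
# phosphate contacts exist.
_NUC_TEMPLATE = [
    ("P", "P", (0.0, 8.0, 0.0)),
    ("OP1", "O", (0.8, 9.0, 0.0)),
    ("OP2", "O", (-0.8, 9.0, 0.0)),
    ("O5'", "O", (0.0, 7.0, 0.5)),
    ("C5'", "C", (0.0, 6.5, 0.0)),
    ("C4'", "C", (0.0, 6.0, 0.0)),
    ("O4'", "O", (0.7, 5.6, 0.0)),
    ("C3'", "C", (-0.7, 5.6, 0.0)),
    ("C2'", "C", (0.0, 5.2, 0.0)),
    ("C1'", "C", (0.0, 4.8, 0.0)),
    ("N9", "N", (0.0, 4.0, 0.0)),
    ("C8", "C", (0.9, 3.6, 0.0)),
    ("N7", "N", (0.9, 2.7, 0.0)),
    ("C5", "C", (0.0, 2.4, 0.0)),
    ("C4", "C", (-0.8, 3.2, 0.0)),
    ("N3", "N", (-1.2, 2.2, 0.0)),
    ("C2", "C", (-0.6, 1.6, 0.0)),
    ("N1", "N", (0.4, 1.6, 0.0)),
    ("C6", "C", (0.8, 2.2, 0.0)),
]


def _dna_chains(n_bp: int) -> Tuple[Chain, Chain]:
    rise = 3.4
    names = ["DA", "DG", "DC", "DT"]
    chain_d = Chain(id="D", polymer_class="dna")
    chain_e = Chain(id="E", polymer_class="dna")
    for j in range(n_bp):
        z = j * rise
        for chain, sign, zoff, offset in ((chain_d, 1.0, 0.0, 0), (chain_e, -1.0, 1.7, 2)):
            name = names[(j + offset) % 4]
            atoms = [
                Atom(an, el, np.array([x, sign * y, z + zoff + dz]))
                for an, el, (x, y, dz) in _NUC_TEMPLATE
            ]
            chain.residues.append(
                Residue(key=(chain.id, j + 1, ""), name=name, atoms=atoms,
                        polymer_class="dna")
            )
    return chain_d, chain_e


def _min_heavy_distance(res_a: List[Residue], res_b: List[Residue]) -> float:
    xa = np.vstack([[a.position for a in r.heavy_atoms()] for r in res_a])
    xb = np.vstack([[a.position for a in r.heavy_atoms()] for r in res_b])
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2)
    return float(d.min())


def make_toy_complex(
    spec: Optional[ToyComplexSpec] = None,
) -> Tuple[str, Set[tuple], Complex]:
    """Build the toy complex; returns (PDB text, ground-truth interface
    residue keys, the Complex object itself).

    Ground truth is recorded from the generator's own all-pairs distance
    scan: protein residues with any heavy atom closer than
    ``spec.contact_cutoff`` to any DNA heavy atom.
    """
    spec = spec or ToyComplexSpec()
    rng = np.random.default_rng(spec.seed)
    sequence = "".join(rng.choice(list(_PALETTE), size=spec.helix_length))
    protein = Chain(id="A", polymer_class="protein",
                    residues=_helix_residues(spec.helix_length, sequence))
    chain_d, chain_e = _dna_chains(spec.dna_base_pairs)
    dna_res = chain_d.residues + chain_e.residues

    # centre the DNA block alongside the helix in z, then bisection on an
    # x-translation so the closest heavy-atom gap equals approach_distance
    helix_zmid = (spec.helix_length - 1) * 1.5 / 2.0
    dna_zmid = ((spec.dna_base_pairs - 1) * 3.4 + 1.7) / 2.0
    base_shift = np.array([0.0, 0.0, helix_zmid - dna_zmid])
    for res in dna_res:
        for atom in res.atoms:
            atom.position = atom.position + base_shift

    def gap_at(x: float) -> float:
        shifted = [
            Residue(key=r.key, name=r.name, polymer_class="dna",
                    atoms=[Atom(a.name, a.element, a.position + np.array([x, 0.0, 0.0]))
                           for a in r.atoms])
            for r in dna_res
        ]
        return _min_heavy_distance(protein.residues, shifted)

    lo, hi = 0.0, 200.0
    if gap_at(lo) > spec.approach_distance:
        raise ValueError("approach_distance smaller than achievable gap")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if gap_at(mid) < spec.approach_distance:
            lo = mid
        else:
            hi = mid
    x_shift = 0.5 * (lo + hi)
    for res in dna_res:
        for atom in res.atoms:
            atom.position = atom.position + np.array([x_shift, 0.0, 0.0])

    complex_ = Complex(id=f"toy{spec.seed}", chains=[protein, chain_d, chain_e])

    truth: Set[tuple] = set()
    for res in protein.residues:
        d = _min_heavy_distance([res], dna_res)
        if d < spec.contact_cutoff:
            truth.add(res.key)
    return write_pdb(complex_), truth, complex_


def make_planted_table(spec: Optional[PlantedTableSpec] = None) -> pd.DataFrame:
    """Labeled feature table with planted informative columns.

    Informative columns are class-conditional normals whose means differ by
    ``class_shift`` standard deviations; noise columns are standard normal
    independent of the label.  Labels are balanced within one sample.
    """
    spec = spec or PlantedTableSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    labels = np.zeros(n, dtype=int)
    labels[: n // 2] = 1
    rng.shuffle(labels)
    cols = {}
    for i in range(spec.n_informative):
        x = rng.normal(size=n)
        x[labels == 1] += spec.class_shift
        cols[f"inf_{i}"] = x
    for i in range(spec.n_noise):
        cols[f"noise_{i}"] = rng.normal(size=n)
    df = pd.DataFrame(cols)
    df["label"] = labels
    df.index = [f"s{i}" for i in range(n)]
    return df


def make_mutation_table(
    ground_truth: Set[tuple],
    complex_: Complex,
    hot_fraction: float = 0.5,
    ddg_ranges: Tuple[Tuple[float, float], Tuple[float, float]] = ((1.0, 3.0), (0.0, 0.99)),
    seed: int = 0,
    n_rows: Optional[int] = None,
) -> pd.DataFrame:
    """Synthetic mutation table referencing real residues of the toy complex.

    Hot rows draw ddG from ``ddg_ranges[0]`` (>= 1.0 by default), non-hot
    rows from ``ddg_ranges[1]``.  Rows cite interface residues from the
    ground-truth set so they survive interface filtering.
    """
    if not 0.0 <= hot_fraction <= 1.0:
        raise ValueError("hot_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    keys = sorted(ground_truth)
    if not keys:
        raise ValueError("ground-truth interface set is empty")
    n_rows = n_rows if n_rows is not None else len(keys)
    n_hot = int(round(hot_fraction * n_rows))
    rows = []
    res_by_key = {r.key: r for r in complex_.iter_residues()}
    for i in range(n_rows):
        key = keys[i % len(keys)]
        res = res_by_key[key]
        wt = AA3_TO_1.get(res.name, "X")
        mut = rng.choice([a for a in "ACDEFGHIKLMNPQRSTVWY" if a != wt])
        hot = i < n_hot
        lo, hi = ddg_ranges[0] if hot else ddg_ranges[1]
        ddg = float(rng.uniform(lo, hi))
        rows.append(
            dict(pdb_id=complex_.id, chain=key[0], wt_aa=wt, position=key[1],
                 icode=key[2], mut_aa=mut, ddg_kcal_mol=round(ddg, 3),
                 source="synthetic")
        )
    return pd.DataFrame(rows)


def _mini_residue(key, name, atoms) -> Residue:
    return Residue(key=key, name=name, polymer_class="protein",
                   atoms=[Atom(n, e, np.array(p, dtype=float)) for n, e, p in atoms])


def make_disulfide_fixture() -> Complex:
    """Two cysteines with SG-SG at 2.05 A (a disulfide bond)."""
    r1 = _mini_residue(("A", 1, ""), "CYS", [
        ("N", "N", (-2.0, 1.0, 0.0)), ("CA", "C", (-1.5, 0.0, 0.0)),
        ("C", "C", (-2.0, -1.0, 0.0)), ("O", "O", (-3.0, -1.2, 0.0)),
        ("CB", "C", (-1.0, 0.5, 1.0)), ("SG", "S", (-1.025, 0.0, 2.0)),
    ])
    r2 = _mini_residue(("A", 2, ""), "CYS", [
        ("N", "N", (2.0, 1.0, 0.0)), ("CA", "C", (1.5, 0.0, 0.0)),
        ("C", "C", (2.0, -1.0, 0.0)), ("O", "O", (3.0, -1.2, 0.0)),
        ("CB", "C", (1.0, 0.5, 1.0)), ("SG", "S", (1.025, 0.0, 2.0)),
    ])
    chain = Chain(id="A", residues=[r1, r2], polymer_class="protein")
    return Complex(id="ssfix", chains=[chain])


def make_salt_bridge_fixture() -> Complex:
    """A lysine NZ placed 3.0 A from a DNA phosphate oxygen."""
    lys = _mini_residue(("A", 1, ""), "LYS", [
        ("N", "N", (-6.0, 1.0, 0.0)), ("CA", "C", (-5.5, 0.0, 0.0)),
        ("C", "C", (-6.0, -1.0, 0.0)), ("O", "O", (-7.0, -1.2, 0.0)),
        ("CB", "C", (-4.5, 0.0, 0.5)), ("NZ", "N", (-3.0, 0.0, 0.0)),
    ])
    nuc = Residue(key=("D", 1, ""), name="DG", polymer_class="dna", atoms=[
        Atom(n, e, np.array(p, dtype=float)) for n, e, p in [
            ("P", "P", (1.0, 0.0, 0.0)), ("OP1", "O", (0.0, 0.0, 0.0)),
            ("OP2", "O", (1.5, 1.2, 0.0)), ("C1'", "C", (2.5, -1.0, 0.0)),
            ("N9", "N", (3.5, -1.5, 0.0)), ("C8", "C", (4.4, -0.9, 0.0)),
            ("N7", "N", (5.2, -1.7, 0.0)), ("C5", "C", (4.8, -2.9, 0.0)),
            ("C4", "C", (3.6, -2.8, 0.0)),
        ]
    ])
    protein = Chain(id="A", residues=[lys], polymer_class="protein")
    dna = Chain(id="D", residues=[nuc], polymer_class="dna")
    return Complex(id="sbfix", chains=[protein, dna])


def make_pi_stack_fixture() -> Complex:
    """A phenylalanine ring stacked 4.0 A over a DNA purine ring, with a
    lysine NZ 4.5 A from the base centroid (pi-pi and pi-cation)."""
    ring = [("CG", (0.0, 1.4)), ("CD1", (1.2, 0.7)), ("CD2", (-1.2, 0.7)),
            ("CE1", (1.2, -0.7)), ("CE2", (-1.2, -0.7)), ("CZ", (0.0, -1.4))]
    phe = _mini_residue(("A", 1, ""), "PHE", [
        ("N", "N", (0.0, 3.5, 4.0)), ("CA", "C", (0.5, 2.8, 4.0)),
        ("C", "C", (1.5, 3.2, 4.0)), ("O", "O", (2.5, 2.8, 4.0)),
        ("CB", "C", (0.0, 2.4, 4.0)),
    ] + [(n, "C", (x, y, 4.0)) for n, (x, y) in ring])
    lys = _mini_residue(("A", 2, ""), "LYS", [
        ("N", "N", (5.0, 3.5, 0.0)), ("CA", "C", (5.5, 2.8, 0.0)),
        ("C", "C", (6.5, 3.2, 0.0)), ("O", "O", (7.5, 2.8, 0.0)),
        ("CB", "C", (5.0, 2.0, 0.0)), ("NZ", "N", (4.5, 0.0, 0.0)),
    ])
    base = [("N9", (0.0, 1.4)), ("C8", (1.2, 0.7)), ("N7", (1.2, -0.7)),
            ("C5", (0.0, -1.4)), ("C4", (-1.2, -0.7)), ("N3", (-1.2, 0.7))]
    nuc = Residue(key=("D", 1, ""), name="DA", polymer_class="dna", atoms=[
        Atom("C1'", "C", np.array([-2.5, 2.0, 0.0])),
    ] + [Atom(n, n[0], np.array([x, y, 0.0])) for n, (x, y) in base])
    protein = Chain(id="A", residues=[phe, lys], polymer_class="protein")
    dna = Chain(id="D", residues=[nuc], polymer_class="dna")
    return Complex(id="pifix", chains=[protein, dna])
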