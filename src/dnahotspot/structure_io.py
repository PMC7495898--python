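"""PDB structure parsing into a typed residue hierarchy.

Parses fixed-column ATOM/HETATM records into Complex -> Chain -> Residue ->
Atom, classifies chains as protein / DNA / other, and writes the hierarchy
back out as PDB text.  Author numbering (resSeq + insertion code) is the
canonical residue coordinate throughout the package; no renumbering ever
happens.  Only the first model (or an explicitly selected one) is retained,
alternate locations are collapsed to the highest-occupancy conformer, and
waters / non-polymer heterogens are kept in a separate bucket so interface
geometry never sees them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Union

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Complex",
    "PdbParseError",
    "EmptyStructureError",
    "parse_pdb",
    "write_pdb",
    "classify_chain",
    "extract_sequence",
    "STANDARD_AA3",
    "AA3_TO_1",
    "DNA_RESNAMES",
]

# Canonical 3-letter -> 1-letter amino-acid codes; MSE (selenomethionine) is
# remappable to M at sequence extraction.
AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
STANDARD_AA3 = frozenset(AA3_TO_1)
MODIFIED_AA3_TO_1 = {"MSE": "M"}

DNA_RESNAMES = frozenset({"DA", "DT", "DG", "DC", "DI", "DU"})
_BARE_NUC = frozenset({"A", "T", "G", "C", "U", "I"})
_SUGAR_ATOMS = frozenset({"C1'", "C2'", "C3'", "C4'", "O4'", "C5'"})
WATER_RESNAMES = frozenset({"HOH", "WAT", "DOD"})


class PdbParseError(ValueError):
    """Malformed PDB record; message names the offending line number."""


class EmptyStructureError(ValueError):
    """Parsed text contained no polymer residues."""


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H" or self.element == "D"


@dataclass
class Residue:
    key: tuple  # (chain_id, author resSeq, insertion code)
    name: str
    atoms: list = field(default_factory=list)
    polymer_class: str = "other"  # protein | dna | other
    hetero: bool = False

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list:
        return [a for a in self.atoms if not a.is_hydrogen]

    @property
    def modelable(self) -> bool:
        """Protein residue usable for CA-based geometry."""
        return self.polymer_class == "protein" and self.atom("CA") is not None


@dataclass
class Chain:
    id: str
    residues: list = field(default_factory=list)
    polymer_class: str = "other"

    def residue(self, resseq: int, icode: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.key[1] == resseq and r.key[2] == icode:
                return r
        return None


@dataclass
class Complex:
    id: str
    chains: list = field(default_factory=list)
    model_index: int = 1
    other_residues: list = field(default_factory=list)  # waters, ligands

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(
            f"chain {chain_id!r} not found; available: "
            f"{[c.id for c in self.chains]}"
        )

    @property
    def protein_chains(self) -> list:
        return [c for c in self.chains if c.polymer_class == "protein"]

    @property
    def dna_chains(self) -> list:
        return [c for c in self.chains if c.polymer_class == "dna"]

    def iter_residues(self) -> Iterable[Residue]:
        for c in self.chains:
            yield from c.residues


def _parse_float(text: str, what: str, lineno: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise PdbParseError(
            f"line {lineno}: malformed {what} field {text.strip()!r}"
        ) from None


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return ""
    if name[0].isdigit():  # e.g. 1HB2
        name = name.lstrip("0123456789")
    if len(name) >= 2 and name[:2].capitalize() in ("Fe", "Zn", "Mg", "Mn", "Se", "Cl", "Br", "Na"):
        return name[:2].capitalize()
    return name[0].upper()


def parse_pdb(
    source: Union[str, IO[str]],
    *,
    structure_id: str = "struct",
    model: Optional[int] = None,
) -> Complex:
    """Parse PDB-format text into a :class:`Complex`.

    Parameters
    ----------
    source
        PDB text or a readable text stream.
    structure_id
        Identifier stored on the returned complex.
    model
        MODEL serial to keep; by default the first model encountered.

    Only one model is retained.  Alternate locations collapse to the
    highest-occupancy conformer per (residue, atom name).  Waters and
    non-polymer HETATM residues land in ``Complex.other_residues``.
    """
    text = source if isinstance(source, str) else source.read()
    lines = text.splitlines()

    current_model = 1
    keep_model: Optional[int] = model
    seen_model_record = False
    model_done = False

    # (chain_id, resseq, icode) -> Residue ; atom name -> Atom for altloc
    order: list = []  # residue keys in file order
    residues: dict = {}
    res_hetero: dict = {}
    kept_model_index = 1

    for lineno, line in enumerate(lines, start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            seen_model_record = True
            try:
                current_model = int(line[10:14].strip() or line[6:].strip())
            except ValueError:
                raise PdbParseError(f"line {lineno}: malformed MODEL serial")
            if keep_model is None:
                keep_model = current_model
            continue
        if rec.startswith("ENDMDL"):
            if seen_model_record and keep_model == current_model:
                model_done = True
            continue
        if rec not in ("ATOM  ", "HETATM"):
            continue
        if model_done:
            continue
        if seen_model_record and keep_model is not None and current_model != keep_model:
            continue
        if len(line) < 54:
            raise PdbParseError(f"line {lineno}: truncated coordinate record")

        atom_name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain_id = line[21].strip() or " "
        try:
            resseq = int(line[22:26])
        except ValueError:
            raise PdbParseError(
                f"line {lineno}: malformed residue number {line[22:26]!r}"
            ) from None
        icode = line[26].strip()
        x = _parse_float(line[30:38], "x-coordinate", lineno)
        y = _parse_float(line[38:46], "y-coordinate", lineno)
        z = _parse_float(line[46:54], "z-coordinate", lineno)
        occ = _parse_float(line[54:60], "occupancy", lineno) if line[54:60].strip() else 1.0
        bfac = _parse_float(line[60:66], "B-factor", lineno) if line[60:66].strip() else 0.0
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = _guess_element(atom_name)

        if not np.isfinite([x, y, z]).all():
            raise PdbParseError(f"line {lineno}: non-finite coordinate")
        if occ < 0.0 or occ > 1.0:
            warnings.warn(
                f"line {lineno}: occupancy {occ} outside [0, 1]; clamped"
            )
            occ = min(max(occ, 0.0), 1.0)

        key = (chain_id, resseq, icode)
        if key not in residues:
            residues[key] = Residue(key=key, name=resname)
            res_hetero[key] = rec == "HETATM"
            order.append(key)
        res = residues[key]
        atom = Atom(
            name=atom_name,
            element=element.capitalize(),
            position=np.array([x, y, z], dtype=float),
            occupancy=occ,
            b_factor=bfac,
            altloc=altloc,
        )
        existing = res.atom(atom_name)
        if existing is not None and (existing.altloc or altloc):
            if atom.occupancy > existing.occupancy:
                res.atoms[res.atoms.index(existing)] = atom
        else:
            res.atoms.append(atom)
        kept_model_index = current_model

    # Bucket residues: polymer vs other
    chains: dict = {}
    chain_order: list = []
    other: list = []
    for key in order:
        res = residues[key]
        if res.name in WATER_RESNAMES or (
            res_hetero[key]
            and res.name not in STANDARD_AA3
            and res.name not in MODIFIED_AA3_TO_1
            and res.name not in DNA_RESNAMES
        ):
            other.append(res)
            continue
        cid = key[0]
        if cid not in chains:
            chains[cid] = Chain(id=cid)
            chain_order.append(cid)
        res.hetero = res_hetero[key]
        chains[cid].residues.append(res)

    complex_ = Complex(
        id=structure_id,
        chains=[chains[c] for c in chain_order],
        model_index=kept_model_index,
        other_residues=other,
    )
    if not any(c.residues for c in complex_.chains):
        raise EmptyStructureError("no polymer residues found in input")
    for chain in complex_.chains:
        chain.polymer_class = classify_chain(chain)
        for res in chain.residues:
            res.polymer_class = _residue_class(res)
    return complex_


def _residue_class(res: Residue) -> str:
    if res.name in STANDARD_AA3 or res.name in MODIFIED_AA3_TO_1:
        return "protein"
    if res.name in DNA_RESNAMES:
        return "dna"
    if res.name in _BARE_NUC and any(a.name in _SUGAR_ATOMS for a in res.atoms):
        return "dna"
    return "other"


def classify_chain(chain: Chain) -> str:
    """Majority-vote polymer class: >50% amino acids -> protein, >50%
    deoxynucleotides -> dna, anything else -> other."""
    if not chain.residues:
        return "other"
    n = len(chain.residues)
    n_aa = sum(
        1
        for r in chain.residues
        if r.name in STANDARD_AA3 or r.name in MODIFIED_AA3_TO_1
    )
    n_nuc = sum(1 for r in chain.residues if _residue_class(r) == "dna")
    if n_aa * 2 > n:
        return "protein"
    if n_nuc * 2 > n:
        return "dna"
    return "other"


def extract_sequence(chain: Chain, *, remap_selenomet: bool = True) -> str:
    """One-letter sequence of a protein chain, in residue order.

    Nonstandard residues map to ``X``; selenomethionine maps to ``M`` unless
    ``remap_selenomet`` is disabled.
    """
    if classify_chain(chain) != "protein":
        raise ValueError(f"chain {chain.id!r} is not a protein chain")
    out = []
    for res in chain.residues:
        if res.name in AA3_TO_1:
            out.append(AA3_TO_1[res.name])
        elif remap_selenomet and res.name in MODIFIED_AA3_TO_1:
            out.append(MODIFIED_AA3_TO_1[res.name])
        else:
            out.append("X")
    return "".join(out)


def write_pdb(complex_: Complex) -> str:
    """Serialize a Complex back to fixed-column PDB text (polymer chains
    first, then the other-residue bucket as HETATM)."""
    lines = []
    serial = 1

    def fmt(rec: str, res: Residue, atom: Atom) -> str:
        nonlocal serial
        cid, resseq, icode = res.key
        name = atom.name
        # atom-name column convention: 1/2-char element names start col 14
        if len(name) < 4 and (len(atom.element) == 1 or not atom.element):
            name = " " + name
        line = (
            f"{rec:<6}{serial:>5} {name:<4}{atom.altloc or ' ':1}"
            f"{res.name:>3} {cid:1}{resseq:>4}{icode or ' ':1}   "
            f"{atom.position[0]:8.3f}{atom.position[1]:8.3f}{atom.position[2]:8.3f}"
            f"{atom.occupancy:6.2f}{atom.b_factor:6.2f}          "
            f"{atom.element:>2}"
        )
        serial += 1
        return line

    for chain in complex_.chains:
        for res in chain.residues:
            rec = "HETATM" if res.hetero else "ATOM"
            for atom in res.atoms:
                lines.append(fmt(rec, res, atom))
        lines.append(f"TER   {serial:>5}      {chain.residues[-1].name:>3} "
                     f"{chain.id:1}{chain.residues[-1].key[1]:>4}")
        serial += 1
    for res in complex_.other_residues:
        for atom in res.atoms:
            lines.append(fmt("HETATM", res, atom))
    lines.append("END")
    return "\n".join(lines) + "\n"
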