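"""Per-residue feature computation, external feature-file readers, and
assembly of the residue-keyed feature table.

Internally derivable features — the ten interaction-network centralities,
solvent exposure (ASA, RASA, half-sphere exposure, contact number, residue
depth), B-factor, hydrogen-bond counts, BLOSUM62 substitution scores, eight
physicochemical scales, Jensen-Shannon conservation and local structural
entropy — are computed from the structure and sequence alone
(``structure_only`` profile).  Features that in practice come from external
predictors (PSI-BLAST profiles, DSSP, secondary-structure/RSA predictor
tables) are joined from their native file dialects by the readers here
(``full`` profile).  Every column carries a provenance tag
(``internal`` | ``reader:<dialect>`` | ``user``) and missing values stay
explicitly missing (NaN) — never silently zero-filled.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, IO, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .interface_rin import build_rin, centrality_features, detect_interactions
from .structure_io import AA3_TO_1, Complex
from .surface_exposure import SasaParams, exposure_profile

__all__ = [
    "FeatureTable",
    "PssmProfile",
    "AMINO_ACIDS",
    "BLOSUM_BACKGROUND",
    "PHYSCHEM_PROPERTIES",
    "blosum_features",
    "physchem_features",
    "jsd_conservation",
    "local_structural_entropy",
    "LseTable",
    "read_pssm",
    "write_pssm",
    "read_predictor_table",
    "assemble_features",
]

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

# Background amino-acid frequencies underlying BLOSUM62 (Robinson-Robinson
# style composition), normalized; used as the conservation background.
BLOSUM_BACKGROUND = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}
_BG_TOTAL = sum(BLOSUM_BACKGROUND.values())
BLOSUM_BACKGROUND = {k: v / _BG_TOTAL for k, v in BLOSUM_BACKGROUND.items()}

PHYSCHEM_PROPERTIES = (
    "helix_propensity",
    "polarity",
    "hydrophilicity",
    "avg_accessible_area",
    "hydrophobic_moment",
    "flexibility",
    "hydrophobicity",
    "polarizability",
)

_blosum62 = None


def _get_blosum62():
    global _blosum62
    if _blosum62 is None:
        _blosum62 = substitution_matrices.load("BLOSUM62")
    return _blosum62


def blosum_features(wild_type_aa: str, mutant_aa: str) -> Dict[str, float]:
    """BLOSUM62 row of the wild type (20 values, ``blosum_<X>``) plus the
    wild-type -> mutant substitution score (``blosum_wt_mut``)."""
    m = _get_blosum62()
    for aa in (wild_type_aa, mutant_aa):
        if aa not in AMINO_ACIDS:
            raise KeyError(f"unknown amino acid code {aa!r}")
    out = {f"blosum_{aa}": float(m[wild_type_aa][aa]) for aa in AMINO_ACIDS}
    out["blosum_wt_mut"] = float(m[wild_type_aa][mutant_aa])
    return out


_physchem_tables: Optional[Dict[str, Dict[str, float]]] = None


def _load_physchem() -> Dict[str, Dict[str, float]]:
    global _physchem_tables
    if _physchem_tables is None:
        tables: Dict[str, Dict[str, float]] = {}
        for prop in PHYSCHEM_PROPERTIES:
            text = resources.files("dnahotspot").joinpath(
                "data", "physchem", f"{prop}.txt").read_text()
            table: Dict[str, float] = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                aa, val = line.split()
                table[aa] = float(val)
            if set(table) != set(AMINO_ACIDS):
                raise RuntimeError(f"physchem table {prop} incomplete")
            tables[prop] = table
        _physchem_tables = tables
    return _physchem_tables


def physchem_features(residue_aa: str) -> Dict[str, float]:
    """The eight physicochemical scale values for one amino acid, in the
    fixed registry order of :data:`PHYSCHEM_PROPERTIES`."""
    if residue_aa not in AMINO_ACIDS:
        raise KeyError(f"unknown amino acid code {residue_aa!r}")
    tables = _load_physchem()
    return {prop: tables[prop][residue_aa] for prop in PHYSCHEM_PROPERTIES}


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


def jsd_conservation(
    alignment_column: Sequence[str],
    background: Optional[Mapping[str, float]] = None,
    lambda_weight: float = 0.5,
) -> Tuple[float, float]:
    """Jensen-Shannon divergence conservation of one alignment column.

    Returns (score in [0, 1], gap fraction).  The score is
    lambda*KL(p||m) + (1-lambda)*KL(q||m) with m = lambda*p + (1-lambda)*q,
    in bits, normalized by its maximum (log2 with lambda = 0.5); p is the
    column's empirical amino-acid distribution (gaps excluded), q the
    background.
    """
    if not alignment_column:
        raise ValueError("empty alignment column")
    background = background or BLOSUM_BACKGROUND
    col = [c.upper() for c in alignment_column]
    gaps = sum(1 for c in col if c in "-.")
    residues = [c for c in col if c in AMINO_ACIDS]
    gap_fraction = gaps / len(col)
    if not residues:
        return 0.0, gap_fraction
    p = np.array([residues.count(a) for a in AMINO_ACIDS], dtype=float)
    p /= p.sum()
    q = np.array([background[a] for a in AMINO_ACIDS], dtype=float)
    q /= q.sum()
    lam = lambda_weight
    m = lam * p + (1 - lam) * q
    jsd = lam * _kl(p, m) + (1 - lam) * _kl(q, m)
    # maximum of the weighted JSD in bits: -lam*log2(lam)-(1-lam)*log2(1-lam)
    zmax = -(lam * math.log2(lam) + (1 - lam) * math.log2(1 - lam)) if 0 < lam < 1 else 1.0
    return min(jsd / zmax, 1.0), gap_fraction


class LseTable:
    """4-mer word -> local-structural-entropy value, with a table mean
    fallback for missing words (counted in ``misses``).

    The default table is a synthetic compositional toy: the word value is
    the mean of a per-letter conformational-variability propensity (derived
    from the shipped flexibility scale).  Real LSE tables can be loaded
    from a two-column text file (word value)."""

    def __init__(self, table: Optional[Mapping[str, float]] = None):
        self._table = dict(table) if table is not None else None
        self._letter = None
        if self._table is None:
            self._letter = _load_physchem()["flexibility"]
        self.misses = 0
        self._mean = (
            float(np.mean(list(self._table.values())))
            if self._table else float(np.mean(list(self._letter.values())))
        )

    @classmethod
    def from_file(cls, source: Union[str, IO[str]]) -> "LseTable":
        text = source.read() if hasattr(source, "read") else source
        table: Dict[str, float] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            word, val = line.split()
            table[word.upper()] = float(val)
        return cls(table)

    def value(self, word: str) -> float:
        if self._table is not None:
            if word in self._table:
                return self._table[word]
            self.misses += 1
            return self._mean
        vals = [self._letter.get(c) for c in word]
        if any(v is None for v in vals):
            self.misses += 1
            return self._mean
        return float(np.mean(vals))


def local_structural_entropy(
    sequence: str,
    lse_table: Optional[LseTable] = None,
) -> List[float]:
    """Per-residue LSE: mean of the (up to four) 4-mer window values that
    cover each position; terminal residues average over fewer windows."""
    if len(sequence) < 4:
        raise ValueError("sequence must have length >= 4")
    table = lse_table or LseTable()
    n = len(sequence)
    window_vals = [table.value(sequence[i:i + 4]) for i in range(n - 3)]
    out = []
    for i in range(n):
        covering = [window_vals[w] for w in range(max(0, i - 3), min(n - 3, i + 1))]
        out.append(float(np.mean(covering)))
    return out


@dataclass
class PssmProfile:
    """Parsed PSI-BLAST ASCII profile: per-position 20 log-odds integers and
    20 percentage frequencies in the standard column order, plus the query
    sequence."""
    query: str
    log_odds: np.ndarray     # (L, 20) int
    frequencies: np.ndarray  # (L, 20) float, percent
    aa_order: str = AMINO_ACIDS

    def score(self, position: int, aa: str) -> float:
        """Log-odds at 1-based ``position`` for amino acid ``aa``."""
        return float(self.log_odds[position - 1, self.aa_order.index(aa)])


def read_pssm(source: Union[str, IO[str]]) -> PssmProfile:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file."""
    text = source.read() if hasattr(source, "read") else source
    lines = text.splitlines()
    header_order: Optional[str] = None
    rows: List[Tuple[int, str, List[int], List[float]]] = []
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        parts = stripped.split()
        if header_order is None:
            # header row: 40 single-letter amino-acid column labels
            if len(parts) >= 40 and all(p in AMINO_ACIDS for p in parts[:40]):
                header_order = "".join(parts[:20])
                if header_order != "".join(parts[20:40]):
                    raise ValueError(
                        f"line {lineno}: log-odds and frequency column "
                        "orders disagree")
            continue
        if not parts[0].isdigit():
            continue  # trailing statistics block
        if len(parts) < 42:
            raise ValueError(
                f"line {lineno}: expected 42+ fields (pos, aa, 20 log-odds, "
                f"20 frequencies), got {len(parts)}")
        pos = int(parts[0])
        aa = parts[1]
        try:
            lo = [int(x) for x in parts[2:22]]
            fr = [float(x) for x in parts[22:42]]
        except ValueError:
            raise ValueError(f"line {lineno}: malformed numeric field") from None
        rows.append((pos, aa, lo, fr))
    if header_order is None or not rows:
        raise ValueError("not a PSI-BLAST ASCII PSSM (missing header or rows)")
    query = "".join(r[1] for r in rows)
    lo = np.array([r[2] for r in rows], dtype=int)
    fr = np.array([r[3] for r in rows], dtype=float)
    # reorder columns into the canonical order if the file differs
    if header_order != AMINO_ACIDS:
        perm = [header_order.index(a) for a in AMINO_ACIDS]
        lo = lo[:, perm]
        fr = fr[:, perm]
    return PssmProfile(query=query, log_odds=lo, frequencies=fr)


def write_pssm(profile: PssmProfile) -> str:
    """Serialize a profile back to the PSI-BLAST ASCII dialect."""
    hdr = "Last position-specific scoring matrix computed"
    cols = "            " + "  ".join(AMINO_ACIDS) + "   " + "  ".join(AMINO_ACIDS)
    lines = ["", hdr, cols]
    for i in range(len(profile.query)):
        lo = " ".join(f"{v:3d}" for v in profile.log_odds[i])
        fr = " ".join(f"{v:4.0f}" for v in profile.frequencies[i])
        lines.append(f"{i + 1:5d} {profile.query[i]}  {lo}  {fr}")
    return "\n".join(lines) + "\n"


_DIALECTS = ("dssp", "spot1d", "netsurfp2", "generic_csv")


def _read_dssp(text: str) -> pd.DataFrame:
    lines = text.splitlines()
    start = None
    for i, line in enumerate(lines):
        if line.lstrip().startswith("#  RESIDUE"):
            start = i + 1
            break
    if start is None:
        raise ValueError("not a DSSP file: data header '#  RESIDUE' not found")
    rows = []
    for line in lines[start:]:
        if len(line) < 115 or line[13] == "!":
            continue
        rows.append(dict(
            position=int(line[5:10]),
            chain=line[11].strip(),
            aa=line[13],
            dssp_ss=line[16].strip() or "-",
            dssp_acc=int(line[34:38]),
            dssp_alpha=float(line[97:103]),
            dssp_phi=float(line[103:109]),
            dssp_psi=float(line[109:115]),
        ))
    if not rows:
        raise ValueError("DSSP file contains no residue rows")
    return pd.DataFrame(rows)


def _read_tabular(text: str, dialect: str) -> pd.DataFrame:
    if dialect == "generic_csv":
        df = pd.read_csv(io.StringIO(text))
    elif dialect == "spot1d":
        df = pd.read_csv(io.StringIO(text), sep=r"\s+")
        df = df.rename(columns={"#": "position"})
    elif dialect == "netsurfp2":
        df = pd.read_csv(io.StringIO(text))
        df = df.rename(columns={"n": "position"})
    position_aliases = ("position", "resnum", "res_no", "residue_number")
    for alias in position_aliases:
        if alias in df.columns:
            if alias != "position":
                df = df.rename(columns={alias: "position"})
            break
    else:
        raise ValueError(
            f"{dialect} table must name a residue-number column "
            f"(one of {position_aliases})")
    return df


def read_predictor_table(
    source: Union[str, IO[str]],
    dialect: str,
    prefix: Optional[str] = None,
) -> pd.DataFrame:
    """Read an external per-residue feature file into a DataFrame with a
    ``position`` column; feature columns gain ``<dialect>_`` prefixes unless
    ``prefix`` overrides."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    text = source.read() if hasattr(source, "read") else source
    if dialect == "dssp":
        df = _read_dssp(text)
    else:
        df = _read_tabular(text, dialect)
    tag = prefix if prefix is not None else (
        "" if dialect == "generic_csv" else f"{dialect}_")
    keep_plain = {"position", "chain", "aa"}
    df = df.rename(columns={
        c: (c if c in keep_plain or str(c).startswith(tag) else f"{tag}{c}")
        for c in df.columns})
    return df


@dataclass
class FeatureTable:
    """Residue-keyed feature matrix with per-column provenance.

    ``df`` is indexed by (structure id, chain, position, icode, wt, mut)
    tuples serialized as strings; ``provenance`` maps column name ->
    ``internal`` | ``reader:<dialect>`` | ``user``.
    """
    df: pd.DataFrame
    provenance: Dict[str, str] = field(default_factory=dict)

    def to_text(self, sep: str = "\t") -> Tuple[str, str]:
        """(table text, side-car provenance text)."""
        prov = "\n".join(f"{c}\t{t}" for c, t in self.provenance.items())
        return self.df.to_csv(sep=sep, index=True), prov + "\n"


def _row_key(structure_id: str, key: tuple, wt: str, mut: str) -> str:
    return f"{structure_id}:{key[0]}:{key[1]}:{key[2]}:{wt}:{mut}"


def assemble_features(
    complex_: Complex,
    protein_chain: str,
    target_residues: Sequence[tuple],
    *,
    mutations: Optional[Mapping[tuple, str]] = None,
    profile: str = "structure_only",
    reader_tables: Sequence[Tuple[str, pd.DataFrame]] = (),
    sasa_params: Optional[SasaParams] = None,
    hse_radius: float = 13.0,
    delta_asa: Optional[Mapping[tuple, float]] = None,
) -> FeatureTable:
    """Assemble the per-residue feature table.

    One row per target residue (key = (chain, position, icode)), with the
    wild-type/mutant amino acids in the row key (mutant ``-`` when no
    mutation is given).  ``reader_tables`` are (dialect, DataFrame) pairs
    from :func:`read_predictor_table`, joined by residue number; unmatched
    residues stay missing, and a table matching fewer than half the targets
    raises (a numbering mismatch is more likely than genuine absence).
    """
    if profile not in ("structure_only", "full"):
        raise ValueError("profile must be 'structure_only' or 'full'")
    chain = complex_.chain(protein_chain)
    res_by_key = {r.key: r for r in chain.residues}
    for key in target_residues:
        if key not in res_by_key:
            raise KeyError(
                f"target residue {key} not found in chain {protein_chain!r}")

    params = sasa_params or SasaParams()
    prof = exposure_profile(complex_, params, hse_radius)
    contacts = detect_interactions(complex_)
    rin = build_rin(contacts, [r.key for r in chain.residues])
    cents = centrality_features(rin)
    hbond_count = {r.key: 0 for r in chain.residues}
    for u, v, data in rin.edges(data=True):
        if "hbond" in data["types"]:
            for node in (u, v):
                if node in hbond_count:
                    hbond_count[node] += 1

    seq = "".join(AA3_TO_1.get(r.name, "X") for r in chain.residues)
    lse_vals = (
        local_structural_entropy(seq) if len(seq) >= 4 else [np.nan] * len(seq))
    seq_pos = {r.key: i for i, r in enumerate(chain.residues)}

    rows = []
    index = []
    provenance: Dict[str, str] = {}
    for key in target_residues:
        res = res_by_key[key]
        wt = AA3_TO_1.get(res.name, "X")
        mut = (mutations or {}).get(key, "-")
        row: Dict[str, float] = {}

        for name in cents.get(key, {}):
            row[f"rin_{name}"] = cents[key][name]
        row["asa"] = prof.asa.get(key, np.nan)
        row["rasa"] = prof.rasa.get(key, np.nan)
        row["hse_up"] = np.nan if prof.hse_up.get(key) is None else prof.hse_up[key]
        row["hse_down"] = np.nan if prof.hse_down.get(key) is None else prof.hse_down[key]
        row["contact_number"] = (
            np.nan if prof.contact_number.get(key) is None else prof.contact_number[key])
        row["residue_depth"] = prof.residue_depth.get(key, np.nan)
        bfs = [a.b_factor for a in res.heavy_atoms()]
        row["b_factor"] = float(np.mean(bfs)) if bfs else np.nan
        row["hbond_count"] = hbond_count.get(key, 0)
        if delta_asa is not None:
            row["delta_asa"] = delta_asa.get(key, np.nan)
        row["lse"] = lse_vals[seq_pos[key]]

        if wt in AMINO_ACIDS:
            for prop, val in physchem_features(wt).items():
                row[f"pc_{prop}"] = val
            bl = blosum_features(wt, mut if mut in AMINO_ACIDS else wt)
            for name, val in bl.items():
                row[name] = val
            if mut in AMINO_ACIDS:
                mut_pc = physchem_features(mut)
                for prop in PHYSCHEM_PROPERTIES:
                    row[f"pc_delta_{prop}"] = mut_pc[prop] - row[f"pc_{prop}"]
        rows.append(row)
        index.append(_row_key(complex_.id, key, wt, mut))

    df = pd.DataFrame(rows, index=index)
    for c in df.columns:
        provenance[c] = "internal"

    if profile == "full" and reader_tables:
        pos_of = {i: key[1] for i, key in zip(index, target_residues)}
        for dialect, table in reader_tables:
            if "position" not in table.columns:
                raise ValueError(f"reader table ({dialect}) lacks a position column")
            feat_cols = [c for c in table.columns
                         if c not in ("position", "chain", "aa")]
            lookup = table.set_index("position")
            matched = 0
            for col in feat_cols:
                values = []
                for i in index:
                    pos = pos_of[i]
                    if pos in lookup.index:
                        values.append(lookup.at[pos, col])
                    else:
                        values.append(np.nan)
                df[col] = pd.to_numeric(pd.Series(values, index=df.index),
                                        errors="coerce")
                provenance[col] = f"reader:{dialect}"
            matched = sum(1 for i in index if pos_of[i] in lookup.index)
            if matched * 2 < len(index):
                raise ValueError(
                    f"reader table ({dialect}) matched only {matched}/"
                    f"{len(index)} target residues; residue-numbering "
                    "mismatch suspected")

    return FeatureTable(df=df, provenance=provenance)
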