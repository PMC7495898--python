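"""Mutation tables -> labeled, redundancy-filtered, complex-level-split
datasets.

A mutation record carries the experimentally measured binding free-energy
change (ddG, kcal/mol, positive = destabilizing) for one point mutation at
an author-numbered residue.  Interface residues with ddG >= 1.0 kcal/mol
are hot spots; non-interface records are excluded with a logged reason.
Redundancy removal follows the CD-HIT ethos — greedy longest-first
clustering at >40% global-alignment identity — and train/validation splits
are assigned at the whole-complex level so no structure leaks across the
split.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Dict, IO, Iterable, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from Bio import Align

from .structure_io import AA3_TO_1, Complex

__all__ = [
    "MutationRecord",
    "LabeledSample",
    "read_mutation_table",
    "write_mutation_table",
    "validate_records",
    "label_hotspots",
    "sequence_identity",
    "redundancy_filter",
    "split_dataset",
    "MUTATION_COLUMNS",
]

MUTATION_COLUMNS = [
    "pdb_id", "chain", "wt_aa", "position", "icode", "mut_aa",
    "ddg_kcal_mol", "source",
]


@dataclass
class MutationRecord:
    pdb_id: str
    chain: str
    wt_aa: str
    position: int
    icode: str
    mut_aa: str
    ddg: float
    source: str = "literature"

    def __post_init__(self) -> None:
        if not np.isfinite(self.ddg):
            raise ValueError(f"non-finite ddG for {self.pdb_id} {self.wt_aa}{self.position}")

    @property
    def residue_key(self) -> tuple:
        return (self.chain, self.position, self.icode)


@dataclass
class LabeledSample:
    record: MutationRecord
    is_interface: bool
    label: int  # hot = 1, non-hot = 0
    split: str = ""  # benchmark | independent | ""


def read_mutation_table(source: Union[str, IO[str]], sep: str = "\t") -> List[MutationRecord]:
    """Read the delimited mutation-table dialect (header row with the
    columns pdb_id, chain, wt_aa, position, icode, mut_aa, ddg_kcal_mol,
    source)."""
    df = pd.read_csv(source if not isinstance(source, str) or "\n" not in source
                     else io.StringIO(source), sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in MUTATION_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(MutationRecord(
            pdb_id=row["pdb_id"], chain=row["chain"], wt_aa=row["wt_aa"],
            position=int(row["position"]), icode=row.get("icode", ""),
            mut_aa=row["mut_aa"], ddg=float(row["ddg_kcal_mol"]),
            source=row.get("source", "literature"),
        ))
    return records


def write_mutation_table(records: Iterable[MutationRecord], sep: str = "\t") -> str:
    rows = [
        dict(pdb_id=r.pdb_id, chain=r.chain, wt_aa=r.wt_aa, position=r.position,
             icode=r.icode, mut_aa=r.mut_aa, ddg_kcal_mol=r.ddg, source=r.source)
        for r in records
    ]
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS).to_csv(sep=sep, index=False)


def validate_records(
    records: Iterable[MutationRecord],
    complexes: Dict[str, Complex],
) -> Tuple[List[MutationRecord], List[str]]:
    """Check each record's wild-type residue against the structure.

    Returns (valid records, error log).  A record whose structure is
    missing, whose residue is absent, or whose wild-type amino acid
    disagrees with the structure is excluded with a logged reason.
    """
    ok: List[MutationRecord] = []
    errors: List[str] = []
    for rec in records:
        cx = complexes.get(rec.pdb_id)
        if cx is None:
            errors.append(f"{rec.pdb_id}: structure not provided")
            continue
        try:
            chain = cx.chain(rec.chain)
        except KeyError as exc:
            errors.append(f"{rec.pdb_id}: {exc}")
            continue
        res = chain.residue(rec.position, rec.icode)
        if res is None:
            errors.append(
                f"{rec.pdb_id} {rec.chain}{rec.position}{rec.icode}: residue not in structure")
            continue
        wt = AA3_TO_1.get(res.name, "X")
        if wt != rec.wt_aa:
            errors.append(
                f"{rec.pdb_id} {rec.chain}{rec.position}: wild-type mismatch "
                f"(table {rec.wt_aa}, structure {wt})")
            continue
        ok.append(rec)
    return ok, errors


def label_hotspots(
    records: Iterable[MutationRecord],
    interface_keys: Dict[str, Set[tuple]],
    threshold: float = 1.0,
) -> Tuple[List[LabeledSample], List[str]]:
    """Label interface records as hot (ddG >= threshold, inclusive) or
    non-hot; non-interface records are excluded with a reason log.

    ``interface_keys`` maps structure id -> set of interface residue keys.
    """
    samples: List[LabeledSample] = []
    log: List[str] = []
    for rec in records:
        keys = interface_keys.get(rec.pdb_id, set())
        if rec.residue_key not in keys:
            log.append(
                f"{rec.pdb_id} {rec.chain}{rec.position}{rec.icode}: not interface")
            continue
        samples.append(LabeledSample(
            record=rec, is_interface=True,
            label=1 if rec.ddg >= threshold else 0,
        ))
    return samples, log


def _aligner(match: float = 1.0, mismatch: float = 0.0, gap: float = -1.0) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = gap
    a.extend_gap_score = gap
    return a


def sequence_identity(
    seq_a: str,
    seq_b: str,
    *,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = -1.0,
) -> float:
    """Percent identity from a global alignment (match +1, mismatch 0,
    linear gap -1 by default): matches / alignment length * 100."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be nonempty")
    aln = _aligner(match, mismatch, gap).align(seq_a, seq_b)[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length


def redundancy_filter(
    sequences: Dict[str, str],
    threshold_pct: float = 40.0,
) -> Tuple[List[str], Dict[str, str]]:
    """Greedy longest-first clustering (CD-HIT-style).

    A sequence joins the first existing cluster whose representative shares
    identity strictly greater than ``threshold_pct``; otherwise it founds a
    new cluster.  Returns (retained representative ids, member id ->
    representative id map).
    """
    order = sorted(sequences, key=lambda k: (-len(sequences[k]), k))
    reps: List[str] = []
    assignment: Dict[str, str] = {}
    for sid in order:
        placed = False
        for rep in reps:
            if sequence_identity(sequences[rep], sequences[sid]) > threshold_pct:
                assignment[sid] = rep
                placed = True
                break
        if not placed:
            reps.append(sid)
            assignment[sid] = sid
    return reps, assignment


def split_dataset(
    samples: Sequence[LabeledSample],
    benchmark_complex_count: int,
    seed: int = 0,
    *,
    balance: bool = False,
    restarts: int = 200,
) -> Dict[str, str]:
    """Assign whole complexes to the benchmark / independent splits.

    Complexes — never individual samples — are assigned, so no structure
    spans both splits.  Selection is seeded-random; with ``balance`` the
    assignment among ``restarts`` seeded shuffles with the most even
    hot/non-hot benchmark counts is kept.  Returns complex id -> split.
    """
    complex_ids = sorted({s.record.pdb_id for s in samples})
    if benchmark_complex_count >= len(complex_ids):
        raise ValueError(
            f"benchmark_complex_count={benchmark_complex_count} must be "
            f"smaller than the number of complexes ({len(complex_ids)})")
    counts: Dict[str, np.ndarray] = {
        cid: np.zeros(2, dtype=int) for cid in complex_ids}
    for s in samples:
        counts[s.record.pdb_id][s.label] += 1

    rng = np.random.default_rng(seed)

    def one_assignment(r: np.random.Generator) -> Tuple[List[str], int]:
        ids = complex_ids.copy()
        r.shuffle(ids)
        chosen = ids[:benchmark_complex_count]
        tally = sum((counts[c] for c in chosen), np.zeros(2, dtype=int))
        return chosen, abs(int(tally[1]) - int(tally[0]))

    if balance:
        best, best_imb = None, None
        for _ in range(restarts):
            chosen, imb = one_assignment(rng)
            if best_imb is None or imb < best_imb:
                best, best_imb = chosen, imb
            if best_imb == 0:
                break
        chosen = best
    else:
        chosen, _ = one_assignment(rng)

    chosen_set = set(chosen)
    assignment = {
        cid: ("benchmark" if cid in chosen_set else "independent")
        for cid in complex_ids
    }
    for s in samples:
        s.split = assignment[s.record.pdb_id]
    return assignment
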