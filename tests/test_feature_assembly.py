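import io
import math

import numpy as np
import pandas as pd
import pytest

from dnahotspot.feature_assembly import (
    AMINO_ACIDS,
    BLOSUM_BACKGROUND,
    PHYSCHEM_PROPERTIES,
    LseTable,
    assemble_features,
    blosum_features,
    jsd_conservation,
    local_structural_entropy,
    physchem_features,
    read_predictor_table,
    read_pssm,
    write_pssm,
)


# --------------------------------------------------------------------------
# substitution / physicochemical lookups

def test_blosum_diagonal_values_match_published_matrix():
    assert blosum_features("E", "E")["blosum_wt_mut"] == 5.0
    assert blosum_features("A", "A")["blosum_wt_mut"] == 4.0


def test_blosum_row_contract_and_symmetry():
    out = blosum_features("E", "D")
    assert len(out) == 21  # 20-value row + wt->mut score
    assert out["blosum_D"] == out["blosum_wt_mut"]
    for x in AMINO_ACIDS:
        for y in AMINO_ACIDS:
            assert (blosum_features(x, y)["blosum_wt_mut"]
                    == blosum_features(y, x)["blosum_wt_mut"])


def test_blosum_unknown_code():
    with pytest.raises(KeyError):
        blosum_features("B", "A")


def test_physchem_contract_and_determinism():
    v1 = physchem_features("W")
    v2 = physchem_features("W")
    assert v1 == v2
    assert list(v1) == list(PHYSCHEM_PROPERTIES)
    assert all(np.isfinite(list(v1.values())))
    with pytest.raises(KeyError):
        physchem_features("Z")


def test_hydrophobicity_ordering():
    assert (physchem_features("I")["hydrophobicity"]
            > physchem_features("D")["hydrophobicity"])


# --------------------------------------------------------------------------
# conservation

def test_jsd_background_column_scores_zero():
    # column drawn exactly as the background distribution
    col = []
    for aa, freq in BLOSUM_BACKGROUND.items():
        col.extend([aa] * int(round(freq * 1000)))
    score, gaps = jsd_conservation(col)
    assert score == pytest.approx(0.0, abs=1e-3)
    assert gaps == 0.0


def test_jsd_conserved_column_is_maximal():
    conserved, _ = jsd_conservation(["W"] * 50)
    for aa in "ACDEF":
        mixed, _ = jsd_conservation([aa] * 25 + ["W"] * 25)
        assert conserved > mixed
    assert 0 < conserved <= 1.0


def test_jsd_matches_hand_computation():
    # 3-symbol column: direct two-KL-term evaluation
    col = ["A"] * 6 + ["C"] * 3 + ["V"] * 1
    lam = 0.5
    p = {a: 0.0 for a in AMINO_ACIDS}
    p.update({"A": 0.6, "C": 0.3, "V": 0.1})
    q = BLOSUM_BACKGROUND
    m = {a: lam * p[a] + (1 - lam) * q[a] for a in AMINO_ACIDS}
    kl_pm = sum(p[a] * math.log2(p[a] / m[a]) for a in AMINO_ACIDS if p[a] > 0)
    kl_qm = sum(q[a] * math.log2(q[a] / m[a]) for a in AMINO_ACIDS if q[a] > 0)
    expected = (lam * kl_pm + (1 - lam) * kl_qm) / 1.0  # log2 normalizer
    score, _ = jsd_conservation(col, lambda_weight=lam)
    assert score == pytest.approx(expected, abs=1e-10)


def test_jsd_gap_fraction_reported():
    _, gaps = jsd_conservation(["A", "A", "-", "-"])
    assert gaps == pytest.approx(0.5)
    with pytest.raises(ValueError):
        jsd_conservation([])


# --------------------------------------------------------------------------
# local structural entropy

def test_lse_single_window():
    vals = local_structural_entropy("ACDE")
    assert len(vals) == 4
    np.testing.assert_allclose(vals, vals[0])


def test_lse_constant_table():
    table = LseTable({w: 2.5 for w in ["ACDEFG"[i:i + 4] for i in range(3)]})
    vals = local_structural_entropy("ACDEFG", table)
    np.testing.assert_allclose(vals, 2.5)


def test_lse_window_means_hand_computed():
    table = LseTable({"ACDE": 1.0, "CDEF": 2.0, "DEFG": 4.0})
    vals = local_structural_entropy("ACDEFG", table)
    expected = [1.0, 1.5, 7 / 3, 7 / 3, 3.0, 4.0]
    np.testing.assert_allclose(vals, expected)
    assert table.misses == 0


def test_lse_missing_word_falls_back_to_mean():
    table = LseTable({"ACDE": 1.0})
    vals = local_structural_entropy("ACDEF", table)
    assert table.misses == 1
    assert vals[-1] == pytest.approx((1.0 + 1.0) / 2)  # window mean fallback

    with pytest.raises(ValueError):
        local_structural_entropy("ACD")


# --------------------------------------------------------------------------
# PSSM reader

def _pssm_text(rows):
    cols = "            " + "  ".join(AMINO_ACIDS) + "   " + "  ".join(AMINO_ACIDS)
    lines = ["", "Last position-specific scoring matrix computed", cols]
    for i, (aa, lo, fr) in enumerate(rows):
        lines.append(f"{i+1:5d} {aa}  " + " ".join(f"{v:3d}" for v in lo)
                     + "  " + " ".join(f"{v:4.0f}" for v in fr))
    return "\n".join(lines) + "\n"


def test_pssm_two_position_fixture():
    rows = [("M", list(range(-10, 10)), [5.0] * 20),
            ("K", list(range(10, -10, -1)), [0.0] * 20)]
    prof = read_pssm(_pssm_text(rows))
    assert prof.query == "MK"
    assert prof.log_odds.shape == (2, 20)
    assert prof.score(1, "A") == -10
    assert prof.score(2, "A") == 10


def test_pssm_missing_column_is_parse_error():
    rows = [("M", list(range(-10, 10)), [5.0] * 20)]
    text = _pssm_text(rows)
    broken = "\n".join(
        line if not line.strip().startswith("1") else " ".join(line.split()[:-1])
        for line in text.splitlines())
    with pytest.raises(ValueError, match="line"):
        read_pssm(broken)


def test_pssm_round_trip():
    rows = [("M", list(range(-10, 10)), [float(i) for i in range(20)]),
            ("K", [1] * 20, [5.0] * 20)]
    prof = read_pssm(_pssm_text(rows))
    again = read_pssm(write_pssm(prof))
    assert again.query == prof.query
    np.testing.assert_array_equal(again.log_odds, prof.log_odds)
    np.testing.assert_array_equal(again.frequencies, prof.frequencies)


# --------------------------------------------------------------------------
# predictor-table readers

def test_generic_csv_reader_and_join(toy_complex):
    csv = "position,predA,predB\n1,0.5,1.0\n4,0.25,2.0\n5,0.75,3.0\n"
    table = read_predictor_table(csv, "generic_csv")
    assert list(table.columns) == ["position", "predA", "predB"]

    targets = [("A", 1, ""), ("A", 4, ""), ("A", 5, "")]
    ft = assemble_features(toy_complex, "A", targets, profile="full",
                           reader_tables=[("generic_csv", table)])
    assert ft.df["predA"].tolist() == [0.5, 0.25, 0.75]
    assert ft.provenance["predA"] == "reader:generic_csv"


def test_unknown_dialect_rejected():
    with pytest.raises(ValueError, match="dialect"):
        read_predictor_table("x", "psipred")


def _dssp_line(serial, resnum, chain, aa, ss, acc, alpha, phi, psi):
    """Assemble one data row at the classic DSSP fixed-column positions."""
    line = [" "] * 140
    def put(start, text):
        for i, ch in enumerate(text):
            line[start + i] = ch
    put(0, f"{serial:5d}")
    put(5, f"{resnum:5d}")
    put(11, chain)
    put(13, aa)
    put(16, ss)
    put(34, f"{acc:4d}")
    put(97, f"{alpha:6.1f}")
    put(103, f"{phi:6.1f}")
    put(109, f"{psi:6.1f}")
    return "".join(line)


_DSSP_FIXTURE = "\n".join([
    "==== Secondary Structure Definition by the program DSSP ====",
    "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N"
    "    N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA",
    _dssp_line(1, 1, "A", "M", "H", 155, 48.4, -57.1, -47.1),
    _dssp_line(2, 2, "A", "K", "H", 88, 50.1, -58.0, -45.2),
]) + "\n"


def test_dssp_reader_extracts_ss_and_acc():
    df = read_predictor_table(_DSSP_FIXTURE, "dssp")
    assert df.loc[0, "dssp_ss"] == "H"
    assert df.loc[0, "dssp_acc"] == 155
    assert df.loc[1, "position"] == 2
    assert df.loc[0, "dssp_alpha"] == pytest.approx(48.4)


def test_join_marks_unmatched_residues_missing(toy_complex):
    csv = "position,pred\n1,0.5\n4,0.25\n"
    targets = [("A", 1, ""), ("A", 4, ""), ("A", 5, "")]
    ft = assemble_features(
        toy_complex, "A", targets, profile="full",
        reader_tables=[("generic_csv", read_predictor_table(csv, "generic_csv"))])
    assert np.isnan(ft.df.loc[ft.df.index[2], "pred"])


def test_join_mostly_unmatched_is_hard_error(toy_complex):
    csv = "position,pred\n901,0.5\n"
    targets = [("A", 1, ""), ("A", 4, ""), ("A", 5, "")]
    with pytest.raises(ValueError, match="numbering"):
        assemble_features(
            toy_complex, "A", targets, profile="full",
            reader_tables=[("generic_csv", read_predictor_table(csv, "generic_csv"))])


# --------------------------------------------------------------------------
# assembly

def test_structure_only_profile_column_contract(toy_complex, toy_truth):
    ft = assemble_features(toy_complex, "A", sorted(toy_truth))
    cols = set(ft.df.columns)
    expected = {"asa", "rasa", "hse_up", "hse_down", "contact_number",
                "residue_depth", "b_factor", "hbond_count", "lse"}
    expected |= {f"rin_{n}" for n in (
        "degree", "clustering", "closeness", "betweenness", "eigenvector",
        "eccentricity", "average_neighbor_degree", "flow_closeness",
        "square_clustering", "katz")}
    assert expected <= cols
    assert len(cols) >= 20  # fully internal, no external files
    assert all(tag == "internal" for tag in ft.provenance.values())


def test_assembly_deterministic_and_stable_order(toy_complex, toy_truth):
    a = assemble_features(toy_complex, "A", sorted(toy_truth))
    b = assemble_features(toy_complex, "A", sorted(toy_truth))
    assert a.to_text() == b.to_text()
    assert list(a.df.columns) == list(b.df.columns)


def test_absent_target_residue_named_in_error(toy_complex):
    with pytest.raises(KeyError, match="999"):
        assemble_features(toy_complex, "A", [("A", 999, "")])


def test_mutation_aware_columns(toy_complex, toy_truth):
    key = sorted(toy_truth)[0]
    ft = assemble_features(toy_complex, "A", [key], mutations={key: "A"})
    assert "blosum_wt_mut" in ft.df.columns
    assert any(c.startswith("pc_delta_") for c in ft.df.columns)
    assert ft.df.index[0].endswith(":A")
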