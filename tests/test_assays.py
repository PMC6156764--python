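import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eduscan.assays import (
    ProteinSequence,
    ResidueInterval,
    alanine_cassette_mutants,
    coip_normalize,
    ddct_fold_change,
    fragment_registry,
    interval_length,
    lookup_fragment,
    luciferase_normalize,
    read_fasta,
    spreading_classify,
    write_fasta,
)


def ct_table(rows):
    return pd.DataFrame(rows, columns=["sample", "gene", "ct"])


# ----------------------------------------------------------------- ddCt


def test_equal_dct_gives_fold_change_one():
    t = ct_table([
        ("control", "FOXM1", 25.0), ("control", "RPL37A", 20.0),
        ("treated", "FOXM1", 26.0), ("treated", "RPL37A", 21.0),
    ])
    fc = ddct_fold_change(t, "FOXM1", "treated", control_condition="control")
    assert fc == pytest.approx(1.0)


@pytest.mark.parametrize("ddct,expected", [(1.0, 0.5), (-2.0, 4.0), (0.0, 1.0)])
def test_fold_change_is_two_to_minus_ddct(ddct, expected):
    # ddCt = dCt(control) - dCt(condition); build dCt(control)=5, dCt(cond)=5-ddct
    t = ct_table([
        ("control", "g", 25.0), ("control", "RPL37A", 20.0),
        ("cond", "g", 25.0 - ddct), ("cond", "RPL37A", 20.0),
    ])
    assert ddct_fold_change(t, "g", "cond", control_condition="control") == \
        pytest.approx(expected)


def test_ct_replicates_aggregated_by_mean():
    t = ct_table([
        ("control", "g", 24.0), ("control", "g", 26.0),
        ("control", "RPL37A", 20.0),
        ("cond", "g", 24.0), ("cond", "RPL37A", 20.0),
    ])
    # mean control target Ct = 25 -> dCt 5; cond dCt 4 -> ddCt = 1 -> 0.5
    assert ddct_fold_change(t, "g", "cond", control_condition="control") == \
        pytest.approx(0.5)


def test_missing_reference_gene_raises():
    t = ct_table([("control", "g", 25.0), ("cond", "g", 24.0),
                  ("cond", "RPL37A", 20.0)])
    with pytest.raises(ValueError, match="RPL37A"):
        ddct_fold_change(t, "g", "cond", control_condition="control")


def test_fold_change_strictly_decreasing_in_ddct():
    folds = []
    for ddct in (-2.0, -1.0, 0.0, 1.0, 2.0):
        t = ct_table([
            ("control", "g", 25.0), ("control", "RPL37A", 20.0),
            ("cond", "g", 25.0 - ddct), ("cond", "RPL37A", 20.0),
        ])
        folds.append(ddct_fold_change(t, "g", "cond", control_condition="control"))
    assert all(a > b for a, b in zip(folds, folds[1:]))


# ------------------------------------------------------------------- co-IP


def test_positive_control_self_normalizes_to_one():
    recs = [
        {"condition": "pos", "tead_signal": 10.0, "flag_signal": 5.0, "igg_signal": 2.0},
        {"condition": "mut", "tead_signal": 10.0, "flag_signal": 5.0, "igg_signal": 2.0},
    ]
    rel = coip_normalize(recs, "pos")
    assert rel["pos"] == pytest.approx(1.0)
    assert rel["mut"] == pytest.approx(1.0)


def test_halved_tead_gives_half_binding():
    recs = [
        {"condition": "pos", "tead_signal": 10.0, "flag_signal": 5.0, "igg_signal": 2.0},
        {"condition": "mut", "tead_signal": 5.0, "flag_signal": 5.0, "igg_signal": 2.0},
    ]
    assert coip_normalize(recs, "pos")["mut"] == pytest.approx(0.5)


def test_coip_matches_step_by_step_arithmetic(rng):
    conds = [f"c{i}" for i in range(5)]
    recs = [
        {"condition": c,
         "tead_signal": rng.uniform(1, 10),
         "flag_signal": rng.uniform(1, 10),
         "igg_signal": rng.uniform(1, 10)}
        for c in conds
    ]
    rel = coip_normalize(recs, "c0")
    raw = {r["condition"]: r["tead_signal"] / (r["flag_signal"] / r["igg_signal"])
           for r in recs}
    for c in conds:
        assert rel[c] == pytest.approx(raw[c] / raw["c0"])


def test_zero_signal_rejected():
    recs = [{"condition": "pos", "tead_signal": 1.0, "flag_signal": 0.0,
             "igg_signal": 1.0}]
    with pytest.raises(ValueError):
        coip_normalize(recs, "pos")


# -------------------------------------------------------------- luciferase


@pytest.mark.parametrize("ff,ren,expected", [(10, 10, 1.0), (0, 5, 0.0), (6, 3, 2.0)])
def test_luciferase_ratio(ff, ren, expected):
    assert luciferase_normalize(ff, ren) == pytest.approx(expected)


def test_nonpositive_renilla_rejected():
    with pytest.raises(ValueError):
        luciferase_normalize(1.0, 0.0)


# --------------------------------------------------------------- spreading


def test_split_sample_half_half():
    assert spreading_classify([100.0, 130.0]) == (0.5, 0.5)


def test_all_below():
    assert spreading_classify([10.0, 20.0], cutoff=120.0) == (1.0, 0.0)


def test_tie_at_cutoff_counts_below():
    below, above = spreading_classify([120.0], cutoff=120.0)
    assert below == 1.0


@settings(deadline=None, max_examples=50)
@given(st.lists(st.floats(1.0, 1e4), min_size=1, max_size=50))
def test_fractions_sum_to_one(areas):
    below, above = spreading_classify(areas)
    assert below + above == pytest.approx(1.0)


def test_empty_area_list_rejected():
    with pytest.raises(ValueError):
        spreading_classify([])


# ------------------------------------------------ alanine cassette mutants


@pytest.fixture(scope="module")
def long_protein():
    rng = np.random.default_rng(2024)
    letters = np.array(list("CDEFGHIKLMNPQRSTVWY"))  # no A: substitutions visible
    return ProteinSequence("synthetic_gbp1_like",
                           "".join(rng.choice(letters, 600)))


def test_seven_cassettes_over_49_residues(long_protein):
    region = ResidueInterval(376, 424)
    muts = alanine_cassette_mutants(long_protein, region, 7)
    assert len(muts) == 7
    # first mutant substitutes residues 376-382 (1-based)
    m1 = muts[0].sequence
    assert m1[375:382] == "A" * 7
    assert m1[:375] == long_protein.sequence[:375]
    assert m1[382:] == long_protein.sequence[382:]


def test_single_cassette_covers_whole_region(long_protein):
    region = ResidueInterval(10, 19)
    muts = alanine_cassette_mutants(long_protein, region, 10)
    assert len(muts) == 1
    assert muts[0].sequence[9:19] == "A" * 10


def test_each_mutant_differs_at_exactly_cassette_positions(long_protein):
    region = ResidueInterval(376, 424)
    for i, m in enumerate(alanine_cassette_mutants(long_protein, region, 7)):
        diffs = [
            j for j, (a, b) in enumerate(zip(long_protein.sequence, m.sequence))
            if a != b
        ]
        assert len(diffs) == 7
        assert all(m.sequence[j] == "A" for j in diffs)
        # cassettes tile the region contiguously, no gaps or overlaps
        assert diffs == list(range(375 + 7 * i, 375 + 7 * (i + 1)))


def test_indivisible_region_rejected(long_protein):
    with pytest.raises(ValueError, match="divisible"):
        alanine_cassette_mutants(long_protein, ResidueInterval(1, 50), 7)


def test_region_beyond_sequence_rejected():
    with pytest.raises(ValueError):
        alanine_cassette_mutants(ProteinSequence("s", "MKV"),
                                 ResidueInterval(1, 7), 7)


def test_fasta_round_trip(tmp_path, long_protein):
    muts = alanine_cassette_mutants(long_protein, ResidueInterval(376, 424), 7)
    p = tmp_path / "muts.fasta"
    write_fasta(p, muts)
    back = read_fasta(p)
    assert [m.sequence for m in back] == [m.sequence for m in muts]


# -------------------------------------------------------- interval registry


@pytest.mark.parametrize("interval,expected", [
    ((376, 424), 49),
    ((1, 1), 1),
    ((291, 592), 302),
])
def test_inclusive_interval_length(interval, expected):
    assert interval_length(ResidueInterval(*interval)) == expected


def test_registry_has_the_eight_constructs():
    reg = fragment_registry()
    assert len(reg) == 8
    assert (reg["α9"].start, reg["α9"].end) == (376, 424)
    assert (reg["Glo"].start, reg["Glo"].end) == (1, 290)
    assert (reg["Hel"].start, reg["Hel"].end) == (291, 592)
    assert (reg["α7–11"].start, reg["α7–11"].end) == (311, 478)
    assert (reg["α7–9"].start, reg["α7–9"].end) == (311, 424)
    assert (reg["α9–11"].start, reg["α9–11"].end) == (376, 478)
    assert (reg["α12–13"].start, reg["α12–13"].end) == (484, 582)
    assert (reg["α7–13"].start, reg["α7–13"].end) == (311, 582)


def test_ascii_alias_lookup():
    assert lookup_fragment("a9") == lookup_fragment("α9")


def test_unknown_fragment_raises():
    with pytest.raises(KeyError):
        lookup_fragment("α99")


def test_invalid_interval_rejected():
    with pytest.raises(ValueError):
        ResidueInterval(5, 4)


def test_nonstandard_residues_rejected():
    with pytest.raises(ValueError):
        ProteinSequence("bad", "MKVX")
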