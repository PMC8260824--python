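"""Pileup construction, region summaries, error statistics and uniformity."""

import re

import numpy as np
import pysam
import pytest

from sluptools.library_design import LibrarySpec, MutationSite
from sluptools.library_qc import (
    compare_observed_expected,
    error_rate,
    pileup_from_sam,
    pileup_table,
    summarize_regions,
)
from sluptools.synthetic import SimulationConfig, cre_like_spec, simulate_library_reads

REF = "ACGTACGTACGTACGTACGT"  # 20 nt toy reference


def write_sam(path, records, ref_name="ref", ref_len=len(REF)):
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": ref_name, "LN": ref_len}]}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, (start, cigar, seq, flag) in enumerate(records):
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = f"r{i}"
            rec.flag = flag
            rec.reference_id = 0
            rec.reference_start = start
            rec.mapping_quality = 60
            rec.cigarstring = cigar
            rec.query_sequence = seq
            rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            out.write(rec)
    return str(path)


def naive_pileup_oracle(sam_path, ref_len):
    """Independent pileup: parse SAM text directly and place bases by CIGAR."""
    counts = {b: [0] * ref_len for b in "ACGT"}
    for line in open(sam_path):
        if line.startswith("@"):
            continue
        f = line.rstrip("\n").split("\t")
        flag, pos, cigar, seq = int(f[1]), int(f[3]) - 1, f[5], f[9]
        if flag & (0x4 | 0x100 | 0x800):  # unmapped / secondary / supplementary
            continue
        rpos, qpos = pos, 0
        for length, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
            n = int(length)
            if op in "M=X":
                for k in range(n):
                    base = seq[qpos + k]
                    if base in "ACGT" and 0 <= rpos + k < ref_len:
                        counts[base][rpos + k] += 1
                rpos += n
                qpos += n
            elif op in "IS":
                qpos += n
            elif op in "DN":
                rpos += n
    return counts


def test_simple_column_counts(tmp_path):
    """6 reads carrying A and 4 carrying C over one position."""
    # reads span positions 4..8; vary only the last base (position 8)
    records = [(4, "5M", REF[4:8] + b, 0) for b in "AAAAAACCCC"]
    sam = write_sam(tmp_path / "t.sam", records)
    cols = pileup_from_sam(sam, reference=REF)
    col = cols[8]
    assert col.counts == {"A": 6, "C": 4, "G": 0, "T": 0}
    assert col.depth == 10
    assert col.fractions["A"] == pytest.approx(0.6)
    assert col.fractions["C"] == pytest.approx(0.4)
    for c in cols:
        if c.depth:
            assert sum(c.fractions.values()) == pytest.approx(1.0)
        else:
            assert all(v == 0.0 for v in c.fractions.values())


def test_deletion_contributes_nothing_to_deleted_columns(tmp_path):
    # 5M2D5M starting at 0: query bases map to ref 0-4 and 7-11; 5,6 deleted
    seq = REF[0:5] + REF[7:12]
    sam = write_sam(tmp_path / "t.sam", [(0, "5M2D5M", seq, 0)])
    cols = pileup_from_sam(sam, reference=REF)
    assert cols[5].depth == 0 and cols[6].depth == 0
    assert cols[5].deletions == 1
    assert cols[4].depth == 1 and cols[7].depth == 1
    assert cols[7].counts[REF[7]] == 1


def test_softclips_insertions_and_skips_are_not_counted(tmp_path):
    # 3S4M2I3M: clipped and inserted bases must not hit the reference
    seq = "GGG" + REF[5:9] + "TT" + REF[9:12]
    sam = write_sam(tmp_path / "t.sam", [(5, "3S4M2I3M", seq, 0)])
    cols = pileup_from_sam(sam, reference=REF)
    for p in range(len(REF)):
        assert cols[p].depth == (1 if 5 <= p < 12 else 0)


def test_secondary_and_unmapped_reads_are_skipped(tmp_path):
    records = [
        (0, "5M", REF[:5], 0),
        (0, "5M", REF[:5], 0x100),  # secondary
        (0, "5M", REF[:5], 0x800),  # supplementary
        (0, "5M", REF[:5], 0x4),  # unmapped
    ]
    sam = write_sam(tmp_path / "t.sam", records)
    cols = pileup_from_sam(sam, reference=REF)
    assert cols[0].depth == 1


def test_reference_name_mismatch_raises(tmp_path):
    sam = write_sam(tmp_path / "t.sam", [(0, "5M", REF[:5], 0)])
    with pytest.raises(ValueError, match="reference"):
        pileup_from_sam(sam, reference=REF, reference_name="other")


def test_cigar_walker_matches_naive_oracle_on_random_alignments(tmp_path):
    """Production walker vs independent text-level oracle, with S/I/D ops."""
    spec = cre_like_spec(template_length=400, seed=3, first_codon=60, spacing=30)
    config = SimulationConfig(
        spec=spec,
        n_reads=50,
        read_length=80,
        error_rate=0.01,
        seed=13,
        complex_cigar_fraction=0.6,
    )
    sam = tmp_path / "mixed.sam"
    simulate_library_reads(config, sam)
    cols = pileup_from_sam(str(sam), reference=spec.template)
    oracle = naive_pileup_oracle(str(sam), len(spec.template))
    for p in range(len(spec.template)):
        assert cols[p].counts == {b: oracle[b][p] for b in "ACGT"}


def test_error_free_reads_give_modal_fraction_one(tmp_path):
    spec = cre_like_spec(template_length=300, seed=1, first_codon=30, spacing=30)
    sam = tmp_path / "clean.sam"
    simulate_library_reads(
        SimulationConfig(spec=spec, n_reads=400, read_length=100, error_rate=0.0, seed=2),
        sam,
    )
    cols = pileup_from_sam(str(sam), reference=spec.template)
    mutated = set(spec.mutated_positions())
    for col in cols:
        if col.depth and col.position not in mutated:
            assert col.fractions[spec.template[col.position]] == 1.0


def test_pileup_table_format():
    from sluptools.library_qc import PileupColumn

    table = pileup_table([PileupColumn(0, {"A": 3, "C": 1, "G": 0, "T": 0})])
    line = table.splitlines()[1].split("\t")
    assert line[0] == "1" and line[5] == "4"
    assert float(line[1]) == pytest.approx(0.75)


# -- region summaries ----------------------------------------------------------


def _columns_from_counts(counts_by_pos, length):
    from sluptools.library_qc import PileupColumn

    cols = []
    for p in range(length):
        counts = counts_by_pos.get(p, {"A": 0, "C": 0, "G": 0, "T": 0})
        cols.append(PileupColumn(position=p, counts=counts))
    return cols


def test_summarize_regions_flags_unexpected_bases():
    template = "TTTTCTTTT"
    spec = LibrarySpec(
        template=template,
        sites=(MutationSite(start=4, reference="C", replacement="M"),),
    )
    cols = _columns_from_counts({4: {"A": 580, "C": 420, "G": 1, "T": 0}}, len(template))
    rows = summarize_regions(cols, spec)
    assert len(rows) == 1
    r = rows[0]
    assert r.label == "5 C > M"
    assert r.expected_bases == frozenset("AC")
    assert r.encoded_by_primer("A") and r.encoded_by_primer("C")
    assert not r.encoded_by_primer("G") and not r.encoded_by_primer("T")
    assert r.encoded_by_template("C") and not r.encoded_by_template("A")
    assert not r.no_coverage
    rendered = r.render()
    assert rendered.startswith("A 57.9%, [C] 42.0%, g 0.1%")


def test_summarize_regions_zero_depth_flag_and_empty_spec():
    template = "AAAA"
    spec = LibrarySpec(
        template=template, sites=(MutationSite(start=1, reference="A", replacement="R"),)
    )
    rows = summarize_regions(_columns_from_counts({}, 4), spec)
    assert rows[0].no_coverage
    empty = LibrarySpec(template=template)
    assert summarize_regions(_columns_from_counts({}, 4), empty) == []


# -- error statistics ----------------------------------------------------------


def test_error_rate_zero_on_error_free_reads(tmp_path):
    spec = cre_like_spec(template_length=300, seed=5, first_codon=60, spacing=30)
    sam = tmp_path / "clean.sam"
    simulate_library_reads(
        SimulationConfig(spec=spec, n_reads=500, read_length=120, error_rate=0.0, seed=6),
        sam,
    )
    cols = pileup_from_sam(str(sam), reference=spec.template)
    st = error_rate(cols, spec)
    assert st.mean_unexpected_fraction == 0.0
    assert st.sd_unexpected_fraction == 0.0
    assert st.trim_5p == 25
    assert st.n_positions <= len(spec.template) - 25 - len(spec.mutated_positions())


def test_error_rate_recovers_injected_substitution_rate(tmp_path):
    eps = 0.002
    spec = cre_like_spec(template_length=1000, seed=8, first_codon=99, spacing=48)
    sam = tmp_path / "noisy.sam"
    simulate_library_reads(
        SimulationConfig(spec=spec, n_reads=2000, read_length=150, error_rate=eps, seed=9),
        sam,
    )
    cols = pileup_from_sam(str(sam), reference=spec.template)
    st = error_rate(cols, spec)
    # 3 standard errors of the mean over ~300k counted bases
    total = st.mean_depth * st.n_positions
    se = np.sqrt(eps * (1 - eps) / total)
    assert abs(st.mean_unexpected_fraction - eps) < 3 * se


def test_error_rate_trim_and_exclusion_behaviour():
    template = "A" * 30
    spec = LibrarySpec(
        template=template, sites=(MutationSite(start=27, reference="A", replacement="R"),)
    )
    cols = _columns_from_counts(
        {p: {"A": 9, "C": 1, "G": 0, "T": 0} for p in range(30)}, 30
    )
    st = error_rate(cols, spec, trim_5p=25, trim_3p=0)
    assert st.n_positions == 4  # 25..29 minus the mutated position
    assert st.mean_unexpected_fraction == pytest.approx(0.1)
    near = error_rate(cols, spec, trim_5p=0, near_exclusion=3)
    assert near.n_positions == 30 - 6  # site +/- 3 nt excluded (clipped at the end)
    with pytest.raises(ValueError, match="no positions"):
        error_rate(cols, spec, trim_5p=len(template))


# -- observed vs expected -------------------------------------------------------


def test_compare_observed_expected_chi_square():
    template = "T" * 9
    spec = LibrarySpec(
        template=template,
        sites=(
            MutationSite(start=2, reference="T", replacement="V"),
            MutationSite(start=6, reference="T", replacement="R"),
        ),
    )
    cols = _columns_from_counts(
        {
            2: {"A": 400, "C": 300, "G": 300, "T": 0},
            6: {"A": 500, "C": 0, "G": 500, "T": 0},
        },
        9,
    )
    rows = compare_observed_expected(summarize_regions(cols, spec), spec)
    v = next(r for r in rows if r.symbol == "V")
    assert v.chi_square == pytest.approx(20.0)
    assert v.dof == 2
    assert v.max_abs_deviation == pytest.approx(400 / 1000 - 1 / 3)
    r = next(r for r in rows if r.symbol == "R")
    assert r.chi_square == pytest.approx(0.0)
    assert r.max_abs_deviation == pytest.approx(0.0)
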