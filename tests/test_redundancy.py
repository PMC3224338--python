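"""Pileup column tallies and the variant/error position classifier."""

import itertools
from collections import Counter

import pysam
import pytest

from estsurvey import redundancy as red
from estsurvey import simulate
from estsurvey.exceptions import ConfigError

REF = "ACGTACGTACGTACGTACGT"  # 20 bp


def header(ref=REF, name="ref"):
    return pysam.AlignmentHeader.from_dict(
        {"SQ": [{"SN": name, "LN": len(ref)}]})


def seg(name, start, seq, cigar, hdr=None):
    s = pysam.AlignedSegment(hdr or header())
    s.query_name = name
    s.query_sequence = seq
    s.flag = 0
    s.reference_id = 0
    s.reference_start = start
    s.mapping_quality = 60
    s.cigarstring = cigar
    return s


def sub_seq(ref, start, length, changes=()):
    """Reference substring with substitutions {0-based ref pos: base}."""
    changes = dict(changes)
    return "".join(changes.get(p, ref[p]) for p in range(start, start + length))


# ---------------------------------------------------------------------------
# pileup walker

class TestPileupColumns:
    def test_identical_query_gives_depth_one_no_events(self):
        pileup = red.pileup_columns([seg("q", 0, REF, "20M")], REF)
        assert len(pileup.tallies) == 20
        for t in pileup.tallies.values():
            assert t.depth == 1 and not t.has_events

    def test_insertion_anchored_to_preceding_reference_position(self):
        # 10M2I10M: insertion of 2 bases between ref positions 10 and 11
        query = REF[:10] + "GG" + REF[10:]
        pileup = red.pileup_columns([seg("q", 0, query, "10M2I10M")], REF)
        assert pileup.tallies[10].insertions == {"GG": 1}
        assert all(not t.insertions for p, t in pileup.tallies.items()
                   if p != 10)

    def test_deletion_spans_each_deleted_position(self):
        query = REF[:5] + REF[8:]
        pileup = red.pileup_columns([seg("q", 0, query, "5M3D12M")], REF)
        for pos in (6, 7, 8):  # 1-based deleted positions
            assert pileup.tallies[pos].deletions == {3: 1}
            assert pileup.tallies[pos].depth == 1

    def test_shared_substitution_groups_by_allele(self):
        changes = {6: "A"}  # ref[6] = 'G' (1-based position 7)
        queries = [seg("q1", 0, sub_seq(REF, 0, 20, changes), "20M"),
                   seg("q2", 2, sub_seq(REF, 2, 10, changes), "10M")]
        pileup = red.pileup_columns(queries, REF)
        assert pileup.tallies[7].substitutions == {"A": 2}

    def test_soft_clips_are_skipped(self):
        query = "TT" + REF[5:12]
        pileup = red.pileup_columns([seg("q", 5, query, "2S7M")], REF)
        assert all(not t.has_events for t in pileup.tallies.values())
        assert min(pileup.tallies) == 6 and max(pileup.tallies) == 12

    def test_cigar_sequence_mismatch_skipped_with_warning(self):
        bad = seg("bad", 0, REF[:10], "12M")
        good = seg("good", 0, REF, "20M")
        with pytest.warns(UserWarning, match="skipped"):
            pileup = red.pileup_columns([bad, good], REF)
        assert pileup.n_reads_mapped == 1 and pileup.n_skipped == 1


# ---------------------------------------------------------------------------
# brute-force oracle: materialize full alignment matrices

def brute_force_counts(records, ref, thr):
    """Classify columns from explicit per-query alignment rows.

    Each query is rendered as a row over reference coordinates (None =
    not covered, '-' = deleted) plus insertion annotations; the rules are
    applied directly to the materialized columns.
    """
    rows = []
    insertions = Counter()
    for name, start, query, cigar in records:
        row = {}
        rpos, qpos = start, 0
        for op, ln in cigar:
            if op in (0, 7, 8):
                for _ in range(ln):
                    row[rpos] = query[qpos]
                    rpos += 1
                    qpos += 1
            elif op == 1:
                insertions[(rpos - 1, query[qpos:qpos + ln])] += 1
                qpos += ln
            elif op == 2:
                for _ in range(ln):
                    row[rpos] = "-"
                    rpos += 1
            elif op == 4:
                qpos += ln
        rows.append(row)

    n_id = n_var = n_err = 0
    covered = sorted({p for row in rows for p in row})
    for p in covered:
        col = [row[p] for row in rows if p in row]
        sub_alleles = Counter(b for b in col if b not in ("-", ref[p]))
        del_events = Counter()
        for row in rows:
            if row.get(p) == "-":
                # length of this query's deletion run containing p
                q = p
                while row.get(q - 1) == "-":
                    q -= 1
                length = 0
                while row.get(q + length) == "-":
                    length += 1
                del_events[length] += 1
        ins_events = Counter({ins: n for (pos, ins), n in insertions.items()
                              if pos == p})
        if not sub_alleles and not del_events and not ins_events:
            n_id += 1
            continue
        variant = error = False
        for support in sub_alleles.values():
            if support >= thr.snp_min_support:
                variant = True
            else:
                error = True
        events = [(len(s), n) for s, n in ins_events.items()]
        events += [(length, n) for length, n in del_events.items()]
        for length, support in events:
            if length % 3 == 0:
                if support >= thr.indel_min_support:
                    variant = True
                elif thr.inframe_below_threshold_as_error:
                    error = True
            else:
                error = True
        n_var += variant
        n_err += error
    return n_id, n_var, n_err


CATALOGUE = [
    ("full", 0, REF, [(0, 20)]),
    ("sub7", 2, sub_seq(REF, 2, 10, {6: "A"}), [(0, 10)]),
    ("sub7b", 5, sub_seq(REF, 5, 6, {6: "A"}), [(0, 6)]),
    ("ins2", 4, REF[4:9] + "GG" + REF[9:14], [(0, 5), (1, 2), (0, 5)]),
    ("ins3", 0, REF[0:4] + "TTT" + REF[4:8], [(0, 4), (1, 3), (0, 4)]),
    ("del1", 6, REF[6:11] + REF[12:17], [(0, 5), (2, 1), (0, 5)]),
    ("del3", 1, REF[1:4] + REF[7:10], [(0, 3), (2, 3), (0, 3)]),
    ("clip", 12, "TT" + REF[14:20], [(4, 2), (0, 6)]),
]


@pytest.mark.parametrize("inframe_as_error", [False, True])
def test_classifier_matches_brute_force_on_enumerated_alignments(
        inframe_as_error):
    """Every subset of <= 3 toy alignments classifies identically under
    the pileup walker and the matrix-materializing oracle."""
    thr = red.ClassifierThresholds(
        snp_min_support=2, indel_min_support=2,
        inframe_below_threshold_as_error=inframe_as_error)
    n_checked = 0
    for size in (1, 2, 3):
        for subset in itertools.combinations(CATALOGUE, size):
            segments = [seg(n, s, q, "".join(
                f"{ln}{'MIDNSHP=X'[op]}" for op, ln in cig))
                for n, s, q, cig in subset]
            pileup = red.pileup_columns(segments, REF)
            counts = red.classify_positions(pileup, thr)
            expected = brute_force_counts(subset, REF, thr)
            got = (counts.n_identical, counts.n_variant, counts.n_error)
            assert got == expected, f"subset {[r[0] for r in subset]}"
            n_checked += 1
    assert n_checked == 8 + 28 + 56


# ---------------------------------------------------------------------------
# threshold rules

class TestClassifyPositions:
    def _pileup_with_shared_sub(self, n_carriers, n_total=40):
        changes = {9: "G"}  # REF[9] = 'C', so this is a real substitution
        queries = []
        for i in range(n_total):
            ch = changes if i < n_carriers else {}
            queries.append(seg(f"q{i}", 0, sub_seq(REF, 0, 20, ch), "20M"))
        return red.pileup_columns(queries, REF)

    def test_support_at_threshold_is_variant_not_error(self):
        counts = red.classify_positions(self._pileup_with_shared_sub(30))
        assert counts.n_variant == 1 and counts.n_error == 0
        assert counts.n_identical == 19

    def test_support_below_threshold_is_error_only(self):
        counts = red.classify_positions(self._pileup_with_shared_sub(24))
        assert counts.n_variant == 0 and counts.n_error == 1

    def _pileup_with_insertions(self, ins, n_events):
        queries = [seg(f"q{i}", 0, REF[:10] + ins + REF[10:],
                       f"10M{len(ins)}I10M") for i in range(n_events)]
        queries.append(seg("ref", 0, REF, "20M"))
        return red.pileup_columns(queries, REF)

    def test_inframe_indel_at_threshold_is_variant(self):
        counts = red.classify_positions(self._pileup_with_insertions("GGG", 4))
        assert counts.n_variant == 1 and counts.n_error == 0

    def test_out_of_frame_indel_is_error(self):
        counts = red.classify_positions(self._pileup_with_insertions("GG", 4))
        assert counts.n_variant == 0 and counts.n_error == 1

    def test_inframe_below_threshold_is_unclassified_by_default(self):
        pileup = self._pileup_with_insertions("GGG", 2)
        default = red.classify_positions(pileup)
        assert default.n_variant == 0 and default.n_error == 0
        as_error = red.classify_positions(
            pileup, red.ClassifierThresholds(
                inframe_below_threshold_as_error=True))
        assert as_error.n_error == 1

    def test_all_identical_queries(self):
        queries = [seg(f"q{i}", 0, REF, "20M") for i in range(5)]
        counts = red.classify_positions(red.pileup_columns(queries, REF))
        assert counts.n_identical == 20
        assert counts.n_variant == 0 and counts.n_error == 0

    def test_planted_variants_recovered_from_haplotype_mixture(self):
        aln = simulate.simulate_alignment_set(seed=5)
        segments = red.segments_from_ungapped(aln.queries, aln.ref_name,
                                              len(aln.ref_seq))
        pileup = red.pileup_columns(segments, aln.ref_seq)
        counts, flags = red.classify_positions(pileup, return_flags=True)
        variant_flagged = set(flags[flags["variant"]]["position"])
        assert set(aln.variant_positions) <= variant_flagged


# ---------------------------------------------------------------------------
# report table and correlation

class TestSummarizeTable:
    def test_percentages_to_one_decimal(self):
        r = red.PositionClassCounts(reference="x", length=200,
                                    n_reads_mapped=10, n_identical=50,
                                    n_variant=10, n_error=41)
        table = red.summarize_table([r])
        row = table.iloc[0]
        assert row["identical_pct"] == 25.0
        assert row["putative_variant_pct"] == 5.0
        assert row["putative_error_pct"] == 20.5

    def test_zero_mapped_reads_formats_as_nd_and_dashes(self):
        r = red.PositionClassCounts(reference="x", length=100,
                                    n_reads_mapped=0, n_identical=0,
                                    n_variant=0, n_error=0)
        formatted = red.format_summary_table(red.summarize_table([r]))
        row = formatted.iloc[0]
        assert row["identical_pct"] == "--"
        assert row["putative_variant"] == "nd"
        assert row["putative_error_pct"] == "nd"


class TestReadsVsUnigenesCorrelation:
    def test_identical_profiles_are_perfectly_correlated(self):
        p = {"a": 4, "b": 2, "c": 3}
        assert red.reads_vs_unigenes_correlation(p, p) == pytest.approx(1.0)

    def test_reversed_ranks_are_anticorrelated(self):
        assert red.reads_vs_unigenes_correlation(
            {"a": 1, "b": 2, "c": 3}, {"a": 3, "b": 2, "c": 1}) == \
            pytest.approx(-1.0)

    def test_rank_invariance_under_monotone_scaling(self):
        assert red.reads_vs_unigenes_correlation(
            {"a": 4, "b": 2, "c": 3}, {"a": 8, "b": 4, "c": 6}) == \
            pytest.approx(1.0)

    def test_too_few_genes_is_an_error(self):
        with pytest.raises(ConfigError):
            red.reads_vs_unigenes_correlation({"a": 1}, {"a": 2})


def test_pileup_from_sam_roundtrip(tmp_path):
    ref_path = tmp_path / "ref.fasta"
    ref_path.write_text(f">ref\n{REF}\n")
    sam_path = tmp_path / "unigenes.sam"
    sam_path.write_text(
        "@HD\tVN:1.6\tSO:coordinate\n"
        f"@SQ\tSN:ref\tLN:{len(REF)}\n"
        f"u1\t0\tref\t1\t60\t20M\t*\t0\t0\t{REF}\t*\n"
        f"u2\t0\tref\t3\t60\t10M\t*\t0\t0\t{sub_seq(REF, 2, 10, {6: 'A'})}\t*\n")
    pileups = red.pileup_from_sam(sam_path, ref_path)
    assert set(pileups) == {"ref"}
    assert pileups["ref"].n_reads_mapped == 2
    assert pileups["ref"].tallies[7].substitutions == {"A": 1}
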