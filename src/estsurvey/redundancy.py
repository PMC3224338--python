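"""Per-position classification of unigene-vs-reference alignment columns.

When many unigenes map to one reference cDNA, each alignment column is
read out and classified:

* **identical** — the position is covered and every covering unigene
  carries the reference base (no substitution, insertion or deletion
  event);
* **putative biological variant** — some substitution allele is supported
  by at least ``snp_min_support`` (default 25) identical point mutations,
  or some in-frame indel event (length divisible by 3) is supported by at
  least ``indel_min_support`` (default 4) identical events;
* **putative sequencing error** — some substitution allele is supported
  by fewer than ``snp_min_support`` unigenes, or some out-of-frame indel
  (length not divisible by 3) occurs.

Variant and error flags may co-occur at one position (different alleles),
so the per-reference percentages can sum to more than 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from estsurvey.exceptions import ConfigError, FormatError


@dataclass
class ClassifierThresholds:
    snp_min_support: int = 25
    indel_min_support: int = 4
    inframe_modulus: int = 3
    #: count in-frame indels below indel_min_support as errors instead of
    #: leaving them unclassified
    inframe_below_threshold_as_error: bool = False

    def __post_init__(self):
        if min(self.snp_min_support, self.indel_min_support,
               self.inframe_modulus) < 1:
            raise ConfigError("thresholds must be >= 1")


@dataclass
class ColumnTally:
    """Events observed at one reference position (1-based).

    Insertions are anchored to the reference position immediately 5' of
    the inserted bases and keyed by the inserted sequence; deletions span
    their deleted positions and are keyed by deletion length, so
    identical events group together.
    """

    position: int
    ref_base: str
    depth: int = 0
    substitutions: dict[str, int] = field(default_factory=dict)
    insertions: dict[str, int] = field(default_factory=dict)
    deletions: dict[int, int] = field(default_factory=dict)

    @property
    def has_events(self) -> bool:
        return bool(self.substitutions or self.insertions or self.deletions)


@dataclass
class Pileup:
    reference: str
    ref_length: int
    tallies: dict[int, ColumnTally]
    n_reads_mapped: int
    n_skipped: int


_CONSUMES_QUERY = {0, 1, 4, 7, 8}  # M, I, S, =, X
_CONSUMES_REF = {0, 2, 3, 7, 8}  # M, D, N, =, X


def pileup_columns(alignments, ref_seq: str, reference: str = "ref") -> Pileup:
    """Tally alignment columns of mapped segments against one reference.

    ``alignments`` is an iterable of :class:`pysam.AlignedSegment`.
    Records whose CIGAR does not consume exactly the stored query sequence
    are skipped with a warning and counted in ``n_skipped``. Deleted
    reference positions count toward depth (the query spans them).
    """
    tallies: dict[int, ColumnTally] = {}
    ref_len = len(ref_seq)

    def tally(pos0: int) -> ColumnTally:
        pos1 = pos0 + 1
        t = tallies.get(pos1)
        if t is None:
            t = ColumnTally(position=pos1, ref_base=ref_seq[pos0])
            tallies[pos1] = t
        return t

    n_used = 0
    n_skipped = 0
    for seg in alignments:
        if seg.is_unmapped or seg.cigartuples is None:
            n_skipped += 1
            continue
        query = seg.query_sequence or ""
        consumed = sum(length for op, length in seg.cigartuples
                       if op in _CONSUMES_QUERY)
        if consumed != len(query):
            warnings.warn(
                f"{seg.query_name}: CIGAR consumes {consumed} query bases but "
                f"sequence has {len(query)}; record skipped")
            n_skipped += 1
            continue
        pos = seg.reference_start  # 0-based
        qpos = 0
        for op, length in seg.cigartuples:
            if op in (0, 7, 8):  # aligned block
                for i in range(length):
                    if not 0 <= pos + i < ref_len:
                        raise FormatError(
                            f"{seg.query_name}: alignment exceeds reference "
                            f"length {ref_len}")
                    t = tally(pos + i)
                    t.depth += 1
                    qbase = query[qpos + i].upper()
                    if qbase != t.ref_base.upper():
                        t.substitutions[qbase] = t.substitutions.get(qbase, 0) + 1
                pos += length
                qpos += length
            elif op == 1:  # insertion: anchor to preceding reference position
                ins = query[qpos:qpos + length].upper()
                if pos > 0:
                    t = tally(pos - 1)
                    t.insertions[ins] = t.insertions.get(ins, 0) + 1
                qpos += length
            elif op == 2:  # deletion spans its deleted positions
                for j in range(length):
                    t = tally(pos + j)
                    t.depth += 1
                    t.deletions[length] = t.deletions.get(length, 0) + 1
                pos += length
            elif op == 3:  # skipped region
                pos += length
            elif op in (4,):  # soft clip
                qpos += length
            # hard clip (5) and padding (6) consume nothing tracked here
        n_used += 1
    return Pileup(reference=reference, ref_length=ref_len, tallies=tallies,
                  n_reads_mapped=n_used, n_skipped=n_skipped)


@dataclass
class PositionClassCounts:
    """Per-reference classification counts and percentages (1 dp).

    Percentages are relative to the reference length; they are ``NaN``
    when no reads mapped. Variant and error flags co-occur, so the three
    percentages may sum to more than 100.
    """

    reference: str
    length: int
    n_reads_mapped: int
    n_identical: int
    n_variant: int
    n_error: int

    def _pct(self, count: int) -> float:
        if self.n_reads_mapped == 0:
            return float("nan")
        return round(100.0 * count / self.length, 1)

    @property
    def pct_identical(self) -> float:
        return self._pct(self.n_identical)

    @property
    def pct_variant(self) -> float:
        return self._pct(self.n_variant)

    @property
    def pct_error(self) -> float:
        return self._pct(self.n_error)


def classify_column(tally: ColumnTally,
                    thr: ClassifierThresholds) -> tuple[bool, bool, bool]:
    """(identical, variant, error) flags for one column."""
    if tally.depth < 1 and not tally.has_events:
        return False, False, False
    if not tally.has_events:
        return True, False, False
    variant = False
    error = False
    for support in tally.substitutions.values():
        if support >= thr.snp_min_support:
            variant = True
        elif support >= 1:
            error = True
    indel_events = [(len(seq), n) for seq, n in tally.insertions.items()]
    indel_events += list(tally.deletions.items())
    for length, support in indel_events:
        if length % thr.inframe_modulus == 0:
            if support >= thr.indel_min_support:
                variant = True
            elif thr.inframe_below_threshold_as_error:
                error = True
        else:
            error = True
    return False, variant, error


def classify_positions(
    pileup: Pileup,
    thr: ClassifierThresholds | None = None,
    return_flags: bool = False,
):
    """Classify every covered column of one reference.

    Returns a :class:`PositionClassCounts`; with ``return_flags`` also a
    per-position DataFrame of the three flags (for BED-like export).
    """
    thr = thr or ClassifierThresholds()
    n_id = n_var = n_err = 0
    rows = []
    for pos in sorted(pileup.tallies):
        ident, variant, error = classify_column(pileup.tallies[pos], thr)
        n_id += ident
        n_var += variant
        n_err += error
        if return_flags:
            rows.append((pos, ident, variant, error))
    counts = PositionClassCounts(
        reference=pileup.reference, length=pileup.ref_length,
        n_reads_mapped=pileup.n_reads_mapped,
        n_identical=n_id, n_variant=n_var, n_error=n_err)
    if return_flags:
        flags = pd.DataFrame(rows, columns=["position", "identical",
                                            "variant", "error"])
        return counts, flags
    return counts


def summarize_table(results) -> pd.DataFrame:
    """One row per reference: length, reads mapped, counts and percentages
    of identical / putative-variant / putative-error positions."""
    rows = []
    for r in results:
        rows.append((r.reference, r.length, r.n_reads_mapped,
                     r.n_identical, r.pct_identical,
                     r.n_variant, r.pct_variant,
                     r.n_error, r.pct_error))
    return pd.DataFrame(rows, columns=[
        "reference", "length", "n_reads_mapped",
        "identical", "identical_pct",
        "putative_variant", "putative_variant_pct",
        "putative_error", "putative_error_pct"])


def format_summary_table(table: pd.DataFrame) -> pd.DataFrame:
    """Report formatting: '--' for percentages of zero counts; variant and
    error columns of references with no mapped reads become 'nd'."""
    out = table.copy().astype(object)
    for pct_col, cnt_col in [("identical_pct", "identical"),
                             ("putative_variant_pct", "putative_variant"),
                             ("putative_error_pct", "putative_error")]:
        pcts, cnts = [], []
        for pct, count, mapped in zip(table[pct_col], table[cnt_col],
                                      table["n_reads_mapped"]):
            if mapped == 0 and cnt_col != "identical":
                pcts.append("nd")
                cnts.append("nd")
            elif count == 0:
                pcts.append("--")
                cnts.append(count)
            else:
                pcts.append(f"{pct:.1f}")
                cnts.append(count)
        out[pct_col] = pcts
        out[cnt_col] = cnts
    return out


def reads_vs_unigenes_correlation(profile_reads, profile_unigenes) -> float:
    """Spearman rho between per-gene read counts and per-gene unigene
    counts over the union of genes (absent = 0, average ranks on ties)."""
    a = pd.Series(dict(profile_reads) if not isinstance(profile_reads, pd.Series)
                  else profile_reads)
    b = pd.Series(dict(profile_unigenes)
                  if not isinstance(profile_unigenes, pd.Series)
                  else profile_unigenes)
    universe = sorted(set(a.index) | set(b.index))
    if len(universe) < 3:
        raise ConfigError("need at least 3 genes for a rank correlation")
    av = a.reindex(universe).fillna(0).to_numpy()
    bv = b.reindex(universe).fillna(0).to_numpy()
    return float(stats.spearmanr(av, bv).statistic)


# ---------------------------------------------------------------------------
# SAM interop

def segments_from_ungapped(queries, reference: str,
                           ref_length: int) -> list[pysam.AlignedSegment]:
    """Build full-match AlignedSegments from (name, 0-based start, seq)
    triples (e.g. from :func:`estsurvey.simulate.simulate_alignment_set`)."""
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"},
         "SQ": [{"SN": reference, "LN": ref_length}]})
    segments = []
    for name, start, seq in queries:
        seg = pysam.AlignedSegment(header)
        seg.query_name = name
        seg.query_sequence = seq
        seg.flag = 0
        seg.reference_id = 0
        seg.reference_start = start
        seg.mapping_quality = 60
        seg.cigarstring = f"{len(seq)}M"
        segments.append(seg)
    return segments


def pileup_from_sam(sam_path, ref_fasta_path) -> dict[str, Pileup]:
    """Pile up a SAM/BAM of unigenes against its reference FASTA,
    per reference sequence."""
    from Bio import SeqIO

    refs = {rec.id: str(rec.seq)
            for rec in SeqIO.parse(str(ref_fasta_path), "fasta")}
    pileups: dict[str, Pileup] = {}
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as af:
        by_ref: dict[str, list[pysam.AlignedSegment]] = {}
        for seg in af.fetch(until_eof=True):
            if seg.is_unmapped:
                continue
            by_ref.setdefault(seg.reference_name, []).append(seg)
    for name, segs in by_ref.items():
        if name not in refs:
            warnings.warn(f"reference {name!r} absent from FASTA; skipped")
            continue
        pileups[name] = pileup_columns(segs, refs[name], reference=name)
    return pileups
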