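"""Best-hit gene tagging from tabular homology-search output.

Consumes 12-column tab-separated hit files (the common tabular output of
protein/translated searches: query, subject, pident, length, mismatch,
gapopen, qstart, qend, sstart, send, evalue, bitscore), assigns each query
to the reference gene of its best passing hit (e-value <= 1e-4 by
default), and builds per-library expression profiles (gene -> read
count). Also computes reference-proteome coverage from subject-interval
unions and 5'/3' terminal-window bias counts.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import pandas as pd

from estsurvey.exceptions import ParseError

HIT_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

_ISOFORM_RE = re.compile(r"\.\d+$")

DEFAULT_EVALUE_CUTOFF = 1e-4


def parse_hits(source) -> pd.DataFrame:
    """Parse a 12-column tabular hit file (path or iterable of lines).

    Subject coordinates are orientation-normalized so sstart <= send.
    Malformed rows raise :class:`ParseError` with the line number.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source) as fh:
            return parse_hits(fh)
    rows = []
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 12:
            raise ParseError(f"expected 12 tab-separated columns, got {len(parts)}",
                             lineno)
        try:
            row = (parts[0], parts[1], float(parts[2]), int(parts[3]),
                   int(parts[4]), int(parts[5]), int(parts[6]), int(parts[7]),
                   int(parts[8]), int(parts[9]), float(parts[10]),
                   float(parts[11]))
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from exc
        if row[10] < 0:
            raise ParseError(f"negative e-value {row[10]}", lineno)
        rows.append(row)
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    if len(df):
        lo = df[["sstart", "send"]].min(axis=1)
        hi = df[["sstart", "send"]].max(axis=1)
        df["sstart"], df["send"] = lo, hi
    return df


def collapse_isoform(subject: str) -> str:
    """Collapse 'GENE.n' splice-variant ids to their locus id 'GENE'."""
    return _ISOFORM_RE.sub("", subject)


@dataclass
class GeneAssignment:
    """query -> (gene, evalue, bitscore); at most one gene per query."""

    table: pd.DataFrame  # columns: query, gene, evalue, bitscore

    def genes(self) -> set[str]:
        return set(self.table["gene"])

    def __len__(self) -> int:
        return len(self.table)


def assign_best_hit(
    hits: pd.DataFrame,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    collapse_isoforms: bool = True,
) -> GeneAssignment:
    """Assign each query its best hit among those with e-value <= cutoff.

    Best = maximal bit score; ties broken by lower e-value, then by
    lexicographically smallest subject id, so output is deterministic.
    Queries with no passing hit are absent from the result.
    """
    passing = hits[hits["evalue"] <= evalue_cutoff]
    if not len(passing):
        return GeneAssignment(pd.DataFrame(
            columns=["query", "gene", "evalue", "bitscore"]))
    ranked = passing.sort_values(
        ["query", "bitscore", "evalue", "subject"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    best = ranked.drop_duplicates("query", keep="first")
    gene = best["subject"].map(collapse_isoform) if collapse_isoforms \
        else best["subject"]
    table = pd.DataFrame({
        "query": best["query"].to_numpy(),
        "gene": gene.to_numpy(),
        "evalue": best["evalue"].to_numpy(),
        "bitscore": best["bitscore"].to_numpy(),
    }).reset_index(drop=True)
    return GeneAssignment(table)


@dataclass
class ExpressionProfile:
    """Per-library gene -> read count (genes with zero reads are absent)."""

    library: str
    counts: pd.Series  # index: gene id, values: int counts >= 1

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def genes(self) -> set[str]:
        return set(self.counts.index)


def build_profile(assignments: GeneAssignment, library: str) -> ExpressionProfile:
    """Count assigned reads per gene; total equals the number of assigned
    reads."""
    counts = assignments.table.groupby("gene").size().sort_index()
    counts.name = "count"
    return ExpressionProfile(library=library, counts=counts)


def profile_from_labels(labels, library: str) -> ExpressionProfile:
    """Profile directly from an iterable of per-read gene labels (e.g.
    simulator ground truth)."""
    counts = pd.Series(list(labels)).value_counts().sort_index()
    counts.name = "count"
    return ExpressionProfile(library=library, counts=counts)


def _merge_intervals(intervals):
    """Union length of 1-based inclusive intervals."""
    merged = 0
    last_end = 0
    for start, end in sorted(intervals):
        start = max(start, last_end + 1)
        if end > last_end:
            merged += end - start + 1
            last_end = end
    return merged


def proteome_coverage(
    hits: pd.DataFrame,
    subject_lengths: dict[str, int],
) -> tuple[pd.Series, float]:
    """Fraction of subject residues covered by >= 1 hit interval.

    Returns per-subject coverage fractions and the aggregate fraction
    (covered residues / total residues) over all tagged subjects. Hit
    intervals extending past the subject length are clipped with a
    warning.
    """
    per_subject = {}
    covered_total = 0
    length_total = 0
    for subject, group in hits.groupby("subject"):
        if subject not in subject_lengths:
            warnings.warn(f"no length for subject {subject!r}; skipped")
            continue
        length = subject_lengths[subject]
        intervals = []
        for start, end in zip(group["sstart"], group["send"]):
            if end > length:
                warnings.warn(
                    f"hit interval {start}..{end} exceeds {subject!r} length "
                    f"{length}; clipped")
                end = length
            if start > length:
                continue
            intervals.append((int(start), int(end)))
        covered = _merge_intervals(intervals)
        per_subject[subject] = covered / length
        covered_total += covered
        length_total += length
    series = pd.Series(per_subject, name="coverage").sort_index()
    aggregate = covered_total / length_total if length_total else 0.0
    return series, aggregate


def terminal_window_bias(
    hits: pd.DataFrame,
    subject_lengths: dict[str, int],
    window: int = 100,
) -> dict[str, int]:
    """Count queries hitting the full protein vs its 5'/3' terminal windows.

    A query counts for a window iff any of its subject intervals overlaps
    the first (5') or last (3') ``window`` residues; when the subject is
    shorter than the window the whole subject is the window. With
    3'-biased read generation the 3' count exceeds the 5' count.
    """
    full: set[str] = set()
    five: set[str] = set()
    three: set[str] = set()
    for row in hits.itertuples(index=False):
        if row.subject not in subject_lengths:
            continue
        length = subject_lengths[row.subject]
        w = min(window, length)
        full.add(row.query)
        if row.sstart <= w:
            five.add(row.query)
        if row.send >= length - w + 1:
            three.add(row.query)
    return {"full": len(full), "five_prime": len(five), "three_prime": len(three)}


# ---------------------------------------------------------------------------
# I/O helpers

def read_subject_lengths(path) -> dict[str, int]:
    """Subject lengths from a 2-column TSV (id, length) or a FASTA file."""
    path = str(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        from Bio import SeqIO
        return {rec.id: len(rec.seq) for rec in SeqIO.parse(path, "fasta")}
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "length"],
                     comment="#")
    return dict(zip(df["id"], df["length"].astype(int)))


def write_assignments(assignment: GeneAssignment, path) -> None:
    assignment.table.to_csv(path, sep="\t", index=False)


def write_profile(profile: ExpressionProfile, path) -> None:
    df = profile.counts.rename_axis("gene_id").reset_index()
    df.insert(0, "library", profile.library)
    df.to_csv(path, sep="\t", index=False)


def read_profile(path) -> ExpressionProfile:
    df = pd.read_csv(path, sep="\t", comment="#")
    library = str(df["library"].iloc[0]) if len(df) else ""
    counts = pd.Series(df["count"].to_numpy(), index=df["gene_id"], name="count")
    return ExpressionProfile(library=library, counts=counts)
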