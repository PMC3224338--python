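"""Read clean-up after primer/vector masking.

Screening tools mark contaminated stretches by X-masking or
lower-casing; this module clips those stretches by keeping the longest
contiguous unmasked segment of each read, slices any parallel quality
scores identically, and discards reads whose remaining segment is shorter
than a minimum length (default 50 nt).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO

from estsurvey.exceptions import FormatError


@dataclass
class ReadRecord:
    """One sequencing read; uppercase bases are kept, masked characters
    (lowercase, 'X', and by default 'N') mark contamination."""

    id: str
    sequence: str
    quality: list[int] | None = None
    library: str = ""

    def __post_init__(self):
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise FormatError(
                f"read {self.id}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TrimConfig:
    min_length: int = 50
    #: treat 'N'/'n' as masked in addition to lowercase and 'X'/'x'
    mask_n: bool = True

    def __post_init__(self):
        if self.min_length < 1:
            raise FormatError("min_length must be >= 1")

    def is_masked(self, ch: str) -> bool:
        if ch.islower() or ch in "Xx":
            return True
        return self.mask_n and ch in "Nn"


def _longest_clear_segment(seq: str, cfg: TrimConfig) -> tuple[int, int]:
    """Half-open (start, end) of the longest unmasked run; leftmost on ties."""
    best = (0, 0)
    start = None
    for i, ch in enumerate(seq):
        if cfg.is_masked(ch):
            if start is not None and i - start > best[1] - best[0]:
                best = (start, i)
            start = None
        elif start is None:
            start = i
    if start is not None and len(seq) - start > best[1] - best[0]:
        best = (start, len(seq))
    return best


def clip_masked(read: ReadRecord, cfg: TrimConfig | None = None) -> ReadRecord | None:
    """Clip masked contamination from a read.

    Returns the longest contiguous unmasked segment (quality sliced to
    match), or ``None`` if that segment is shorter than
    ``cfg.min_length``. Reads with no sequence raise ``FormatError``.
    """
    cfg = cfg or TrimConfig()
    if not read.sequence:
        raise FormatError(f"read {read.id}: empty sequence")
    start, end = _longest_clear_segment(read.sequence, cfg)
    if end - start < cfg.min_length:
        return None
    qual = read.quality[start:end] if read.quality is not None else None
    return ReadRecord(id=read.id, sequence=read.sequence[start:end],
                      quality=qual, library=read.library)


@dataclass
class FilterSummary:
    n_in: int = 0
    n_kept: int = 0
    mean_length_in: float | None = None
    mean_length_kept: float | None = None
    masked_bases_in: int = 0

    def as_row(self) -> dict:
        return {
            "n_in": self.n_in, "n_kept": self.n_kept,
            "mean_length_in": self.mean_length_in,
            "mean_length_kept": self.mean_length_kept,
            "masked_bases_in": self.masked_bases_in,
        }


def filter_library(reads, cfg: TrimConfig | None = None):
    """Clip every read and drop short ones.

    Returns ``(kept_reads, FilterSummary)``; means are ``None`` (not 0)
    when the corresponding set is empty.
    """
    cfg = cfg or TrimConfig()
    kept: list[ReadRecord] = []
    total_in = 0
    total_kept = 0
    n_in = 0
    masked = 0
    for read in reads:
        n_in += 1
        total_in += len(read)
        masked += sum(1 for ch in read.sequence if cfg.is_masked(ch))
        out = clip_masked(read, cfg)
        if out is not None:
            kept.append(out)
            total_kept += len(out)
    summary = FilterSummary(
        n_in=n_in,
        n_kept=len(kept),
        mean_length_in=(total_in / n_in) if n_in else None,
        mean_length_kept=(total_kept / len(kept)) if kept else None,
        masked_bases_in=masked,
    )
    return kept, summary


# ---------------------------------------------------------------------------
# FASTA (+ optional parallel .qual) I/O

def read_fasta(path, qual_path=None, library: str = "") -> list[ReadRecord]:
    quals = {}
    if qual_path is not None:
        for rec in SeqIO.parse(str(qual_path), "qual"):
            quals[rec.id] = rec.letter_annotations["phred_quality"]
    reads = []
    for rec in SeqIO.parse(str(path), "fasta"):
        q = quals.get(rec.id) if quals else None
        reads.append(ReadRecord(id=rec.id, sequence=str(rec.seq), quality=q,
                                library=library))
    return reads


def write_fasta(reads: list[ReadRecord], path, qual_path=None) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id}\n{r.sequence}\n")
    if qual_path is not None:
        with open(qual_path, "w") as fh:
            for r in reads:
                if r.quality is None:
                    continue
                fh.write(f">{r.id}\n{' '.join(map(str, r.quality))}\n")
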