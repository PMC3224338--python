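"""Ground-truth simulator for 454-style EST libraries.

Emulates the statistical structure a de novo EST survey sees: a
transcriptome carrying allelic and paralogous sequence variants, strongly
skewed expression, optional duplex-specific-nuclease-style library
normalization (partial flattening of the abundance distribution), platform
read lengths (GS20 ~100 nt, GS FLX ~230 nt), ~1% sequencing error
concentrated in homopolymer runs, and a mild 3' positional bias from
poly-dT-primed library construction.

Every stochastic choice is recorded in a :class:`SimTruth` table so that
downstream stages (tagging, rarefaction, redundancy classification) can be
tested against known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from estsurvey.exceptions import ConfigError
from estsurvey.read_prep import ReadRecord

_BASES = np.array(list("ACGT"))

# substream tags so each stage gets an independent, reproducible generator
_STREAM_TRANSCRIPTOME = 1
_STREAM_WEIGHTS = 2
_STREAM_READS = 3
_STREAM_PROFILES = 4
_STREAM_ALIGNMENTS = 5

#: platform read-length defaults (mean, sd) in nucleotides
PLATFORM_READ_LENGTHS = {"GS20": (100.0, 8.0), "GSFLX": (230.0, 12.0)}


def _rng(seed: int, stream: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream), int(extra)])


@dataclass
class SimConfig:
    """Parameters of one simulated library.

    Defaults describe a scaled-down but structurally faithful survey
    library: Zipf-skewed expression (exponent ``expression_shape``),
    normalization as weight exponentiation with ``gamma`` (1 = none,
    0 = complete flattening), a total error rate of roughly 1% per base
    split between uniform substitutions and homopolymer-run length
    changes, and a mild 3' start-position bias.
    """

    n_genes: int = 500
    length_range: tuple[int, int] = (400, 2000)
    expression_model: str = "zipf"  # or "lognormal"
    expression_shape: float = 1.4
    gamma: float = 0.35
    platform: str = "GS20"
    read_length_mean: float | None = None
    read_length_sd: float | None = None
    sub_rate: float = 0.008
    hp_indel_rate: float = 0.01
    three_prime_lambda: float = 0.001
    p_allelic: float = 0.3
    allelic_div: float = 0.01
    p_paralog: float = 0.1
    paralog_div: float = 0.05
    n_reads: int = 20000
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.n_reads < 1:
            raise ConfigError("n_reads must be >= 1")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ConfigError(f"invalid length_range {self.length_range}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ConfigError("gamma must lie in [0, 1]")
        if self.expression_shape <= 0:
            raise ConfigError("expression_shape must be > 0")
        if self.expression_model not in ("zipf", "lognormal"):
            raise ConfigError(f"unknown expression_model {self.expression_model!r}")
        if self.platform not in PLATFORM_READ_LENGTHS:
            raise ConfigError(f"unknown platform {self.platform!r}")
        for name in ("sub_rate", "hp_indel_rate", "p_allelic", "allelic_div",
                     "p_paralog", "paralog_div"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.three_prime_lambda < 0:
            raise ConfigError("three_prime_lambda must be >= 0")

    def resolved_read_length(self) -> tuple[float, float]:
        mean, sd = PLATFORM_READ_LENGTHS[self.platform]
        if self.read_length_mean is not None:
            mean = self.read_length_mean
        if self.read_length_sd is not None:
            sd = self.read_length_sd
        return mean, sd

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class SimTranscriptome:
    """Gene id -> haplotype sequences, plus paralog-group membership.

    Paralog copies are separate gene entries (they are discovered as
    separate loci by tagging) sharing a ``paralog_group`` id with their
    parent.
    """

    sequences: dict[str, list[str]]
    paralog_group: dict[str, str]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.sequences)

    @property
    def n_genes(self) -> int:
        return len(self.sequences)


@dataclass
class WeightPair:
    """Raw and normalized per-gene sampling weights (each sums to 1)."""

    raw: pd.Series
    norm: pd.Series


@dataclass
class SimTruth:
    """Ground truth of one simulated library.

    ``reads``: one row per read (read_id, gene_id, haplotype, start, end,
    n_sub, n_indel, sub_positions, indel_positions, truncated); positions
    are 0-based read coordinates. ``genes``: one row per gene (gene_id,
    raw_weight, norm_weight, sampling_weight, count).
    """

    reads: pd.DataFrame
    genes: pd.DataFrame


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, div: float) -> str:
    """Substitute each base independently with probability ``div``."""
    if div <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1").copy()
    hits = np.flatnonzero(rng.random(arr.size) < div)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def build_transcriptome(config: SimConfig) -> SimTranscriptome:
    """Generate a transcript set with allelic and paralogous variants.

    Deterministic given ``config.seed``. With probability ``p_allelic`` a
    gene carries a second haplotype diverged at ``allelic_div`` per base;
    with probability ``p_paralog`` a diverged duplicate is added as a
    separate gene sharing the parent's paralog group.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_TRANSCRIPTOME)
    lo, hi = config.length_range
    sequences: dict[str, list[str]] = {}
    groups: dict[str, str] = {}
    for i in range(config.n_genes):
        gid = f"g{i:05d}"
        group = f"pg{i:05d}"
        length = int(rng.integers(lo, hi + 1))
        seq = _random_seq(rng, length)
        haps = [seq]
        if rng.random() < config.p_allelic:
            haps.append(_mutate(rng, seq, config.allelic_div))
        sequences[gid] = haps
        groups[gid] = group
        if rng.random() < config.p_paralog:
            pid = f"g{i:05d}d"
            sequences[pid] = [_mutate(rng, seq, config.paralog_div)]
            groups[pid] = group
    return SimTranscriptome(sequences=sequences, paralog_group=groups)


def _raw_weights(rng: np.random.Generator, n: int, model: str, shape: float) -> np.ndarray:
    if model == "zipf":
        ranks = rng.permutation(n) + 1
        w = ranks.astype(float) ** (-shape)
    else:  # lognormal, shape = sigma of log
        w = np.exp(rng.normal(0.0, shape, size=n))
    return w / w.sum()


def draw_weights(transcriptome: SimTranscriptome, config: SimConfig) -> WeightPair:
    """Draw raw expression weights and their normalized counterpart.

    Normalization is modelled as exponentiation: ``norm_i ∝ raw_i**gamma``
    renormalized to sum 1, so ``gamma=1`` is the identity and ``gamma=0``
    flattens expression completely while preserving ranks.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_WEIGHTS)
    ids = transcriptome.gene_ids
    raw = _raw_weights(rng, len(ids), config.expression_model, config.expression_shape)
    norm = raw ** config.gamma
    norm = norm / norm.sum()
    return WeightPair(raw=pd.Series(raw, index=ids, name="raw_weight"),
                      norm=pd.Series(norm, index=ids, name="norm_weight"))


def homopolymer_runs(seq: str, min_len: int = 2) -> list[tuple[int, int]]:
    """(start, run length) of every homopolymer run of length >= min_len."""
    runs = []
    i, n = 0, len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j - i))
        i = j
    return runs


def apply_454_errors(
    seq: str,
    rng: np.random.Generator,
    sub_rate: float,
    hp_indel_rate: float,
) -> tuple[str, list[int], list[int]]:
    """Plant 454-style errors into ``seq``.

    At each homopolymer run of length r >= 2, with probability
    ``hp_indel_rate * (r - 1)`` the run length changes by exactly one
    repeat unit (insertion or deletion, equiprobable). Afterwards each
    base is substituted independently with probability ``sub_rate``.

    Returns the mutated sequence, the 0-based substitution positions and
    the 0-based run-start positions of indel events (all in coordinates of
    the returned sequence).
    """
    indel_positions: list[int] = []
    if hp_indel_rate > 0:
        pieces: list[str] = []
        prev = 0
        offset = 0
        for start, runlen in homopolymer_runs(seq):
            p = min(1.0, hp_indel_rate * (runlen - 1))
            if rng.random() < p:
                base = seq[start]
                pieces.append(seq[prev:start])
                if rng.random() < 0.5:
                    pieces.append(base * (runlen + 1))
                else:
                    pieces.append(base * (runlen - 1))
                indel_positions.append(start + offset)
                offset += len(pieces[-1]) - runlen
                prev = start + runlen
        pieces.append(seq[prev:])
        seq = "".join(pieces)

    sub_positions: list[int] = []
    if sub_rate > 0 and seq:
        arr = list(seq)
        hits = np.flatnonzero(rng.random(len(arr)) < sub_rate)
        for i in hits:
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[rng.integers(0, 3)]
            sub_positions.append(int(i))
        seq = "".join(arr)
    return seq, sub_positions, indel_positions


def _sample_start(rng: np.random.Generator, max_start: int, lam: float) -> int:
    """Start position in [0, max_start]; geometric bias toward the 3' end.

    With decay ``lam`` the probability of starting j bases short of the
    3'-most possible start is proportional to exp(-lam * j); lam = 0 is
    uniform.
    """
    if max_start <= 0:
        return 0
    if lam <= 0:
        return int(rng.integers(0, max_start + 1))
    q = math.exp(-lam)
    # truncated geometric over offsets 0..max_start via inverse CDF
    u = rng.random()
    j = int(math.floor(math.log1p(-u * (1.0 - q ** (max_start + 1))) / math.log(q)))
    j = min(j, max_start)
    return max_start - j


def generate_reads(
    transcriptome: SimTranscriptome,
    weights: WeightPair,
    config: SimConfig,
    normalized: bool = False,
    library: str = "sim",
) -> tuple[list[ReadRecord], SimTruth]:
    """Draw a library of error-bearing reads with full ground truth.

    Reads are drawn i.i.d. by gene weight (the normalized weights when
    ``normalized`` is true), from a uniformly chosen haplotype, with
    normal read lengths (platform defaults unless overridden), start
    positions biased toward the 3' end by ``three_prime_lambda``, and
    planted homopolymer indels and substitutions. Reads longer than their
    source transcript are truncated to it (flagged in the truth table).
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_READS, int(normalized))
    ids = transcriptome.gene_ids
    w = (weights.norm if normalized else weights.raw).to_numpy()
    mean, sd = config.resolved_read_length()

    gene_idx = rng.choice(len(ids), size=config.n_reads, p=w)
    reads: list[ReadRecord] = []
    rows = []
    for r, gi in enumerate(gene_idx):
        gid = ids[gi]
        haps = transcriptome.sequences[gid]
        hap = int(rng.integers(0, len(haps)))
        src = haps[hap]
        length = int(round(rng.normal(mean, sd)))
        length = max(30, length)
        truncated = length >= len(src)
        if truncated:
            start, end = 0, len(src)
        else:
            start = _sample_start(rng, len(src) - length, config.three_prime_lambda)
            end = start + length
        raw = src[start:end]
        seq, subs, indels = apply_454_errors(raw, rng, config.sub_rate,
                                             config.hp_indel_rate)
        rid = f"{library}_r{r:06d}"
        reads.append(ReadRecord(id=rid, sequence=seq, quality=None, library=library))
        rows.append((rid, gid, hap, start, end, len(subs), len(indels),
                     ",".join(map(str, subs)), ",".join(map(str, indels)),
                     truncated))

    reads_df = pd.DataFrame(rows, columns=[
        "read_id", "gene_id", "haplotype", "start", "end", "n_sub", "n_indel",
        "sub_positions", "indel_positions", "truncated"])
    counts = np.bincount(gene_idx, minlength=len(ids))
    genes_df = pd.DataFrame({
        "gene_id": ids,
        "raw_weight": weights.raw.to_numpy(),
        "norm_weight": weights.norm.to_numpy(),
        "sampling_weight": w,
        "count": counts,
    })
    return reads, SimTruth(reads=reads_df, genes=genes_df)


def simulate_count_profiles(config: SimConfig, normalized_reads: int | None = None,
                            raw_reads: int | None = None) -> pd.DataFrame:
    """Fast path: per-gene read counts of a raw and a normalized library.

    Skips sequence generation entirely (counts are multinomial in the
    sampling weights, exactly as realized counts from
    :func:`generate_reads` are); useful for rarefaction / normalization
    properties at larger gene counts. Paralogs and haplotypes are ignored:
    the profile is over ``n_genes`` loci.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_PROFILES)
    g = config.n_genes
    raw_w = _raw_weights(rng, g, config.expression_model, config.expression_shape)
    norm_w = raw_w ** config.gamma
    norm_w = norm_w / norm_w.sum()
    n_raw = raw_reads if raw_reads is not None else config.n_reads
    n_norm = normalized_reads if normalized_reads is not None else config.n_reads
    return pd.DataFrame({
        "gene_id": [f"g{i:05d}" for i in range(g)],
        "raw_weight": raw_w,
        "norm_weight": norm_w,
        "raw_count": rng.multinomial(n_raw, raw_w),
        "norm_count": rng.multinomial(n_norm, norm_w),
    })


@dataclass
class AlignmentSimulation:
    """Simulated ungapped unigene-vs-reference alignment set.

    ``queries`` holds (name, 0-based reference start, sequence) triples;
    every query aligns to the reference as a full-length match block.
    ``variant_positions`` are the 1-based reference positions at which the
    two haplotypes differ; ``error_positions`` the 1-based reference
    positions at which at least one planted sequencing error landed.
    """

    ref_name: str
    ref_seq: str
    variant_positions: list[int]
    error_positions: set[int]
    queries: list[tuple[str, int, str]] = field(default_factory=list)


def simulate_alignment_set(
    ref_length: int = 600,
    n_queries: int = 60,
    n_variant_positions: int = 3,
    error_rate: float = 0.005,
    query_length_range: tuple[int, int] = (500, 600),
    margin: int = 100,
    seed: int = 0,
    ref_name: str = "ref",
) -> AlignmentSimulation:
    """Simulate unigenes from a two-haplotype gene aligned to haplotype 1.

    Half the queries descend from each haplotype; the haplotypes differ at
    ``n_variant_positions`` planted positions drawn at least ``margin``
    bases from the reference ends so every variant-carrying unigene
    covers them (defaults give each variant allele support from all
    second-haplotype unigenes). Each query base is further substituted
    with probability ``error_rate`` (planted sequencing error). All
    alignments are ungapped full-match blocks, mirroring same-species
    cDNA references where the aligner reports no indels.
    """
    rng = _rng(seed, _STREAM_ALIGNMENTS)
    ref = _random_seq(rng, ref_length)
    interior = np.arange(margin, ref_length - margin)
    if len(interior) < n_variant_positions:
        raise ConfigError("reference too short for the requested margin")
    var_pos = sorted(rng.choice(interior, size=n_variant_positions,
                                replace=False).tolist())
    hap2 = list(ref)
    for p in var_pos:
        choices = [b for b in "ACGT" if b != hap2[p]]
        hap2[p] = choices[rng.integers(0, 3)]
    hap2 = "".join(hap2)

    queries: list[tuple[str, int, str]] = []
    err_pos: set[int] = set()
    lo, hi = query_length_range
    for q in range(n_queries):
        src = ref if q % 2 == 0 else hap2
        qlen = int(rng.integers(lo, min(hi, ref_length) + 1))
        start = int(rng.integers(0, ref_length - qlen + 1))
        seq = list(src[start:start + qlen])
        hits = np.flatnonzero(rng.random(qlen) < error_rate)
        for i in hits:
            choices = [b for b in "ACGT" if b != seq[i]]
            seq[i] = choices[rng.integers(0, 3)]
            err_pos.add(start + int(i) + 1)
        queries.append((f"u{q:04d}", start, "".join(seq)))

    return AlignmentSimulation(
        ref_name=ref_name,
        ref_seq=ref,
        variant_positions=[p + 1 for p in var_pos],
        error_positions=err_pos,
        queries=queries,
    )


# ---------------------------------------------------------------------------
# I/O

def write_reads_fasta(reads: list[ReadRecord], path) -> None:
    records = [SeqRecord(Seq(r.sequence), id=r.id, description=r.library)
               for r in reads]
    SeqIO.write(records, str(path), "fasta")


def write_transcriptome_fasta(transcriptome: SimTranscriptome, path) -> None:
    records = []
    for gid, haps in transcriptome.sequences.items():
        for h, seq in enumerate(haps):
            records.append(SeqRecord(Seq(seq), id=f"{gid}|hap{h}",
                                     description=transcriptome.paralog_group[gid]))
    SeqIO.write(records, str(path), "fasta")


def write_truth(truth: SimTruth, reads_path, genes_path) -> None:
    truth.reads.to_csv(reads_path, sep="\t", index=False)
    truth.genes.to_csv(genes_path, sep="\t", index=False)
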