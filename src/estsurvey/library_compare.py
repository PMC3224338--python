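"""Pairwise library comparison and the annotation-retention chimera proxy.

Normalization assessment: the Spearman rank correlation between per-gene
read counts of two libraries measures how much quantitative expression
information a normalized library retains relative to a non-normalized
one. Chimera proxy: the fraction of reference genes tagged by the raw
reads that is still tagged after each assembly pass — a sharp drop
between passes indicates chimeric contigs joined distinct transcripts and
their annotations were lost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import pandas as pd
from scipy import stats

from estsurvey.exceptions import ConfigError
from estsurvey.gene_tagging import ExpressionProfile

#: gene universes: "both" = genes detected in both libraries (default),
#: "union" = genes detected in either, absent treated as count 0
UNIVERSE_POLICIES = ("both", "union")


@dataclass
class ComparisonResult:
    library_a: str
    library_b: str
    rho: float
    n_genes: int
    universe: str

    @property
    def degenerate(self) -> bool:
        return math.isnan(self.rho)


def spearman_profiles(
    p1: ExpressionProfile,
    p2: ExpressionProfile,
    universe: str = "both",
) -> ComparisonResult:
    """Spearman rank correlation of two expression profiles.

    Average ranks on ties. A degenerate (constant) count vector yields
    ``rho = NaN`` with the result flagged rather than raising.
    """
    if universe not in UNIVERSE_POLICIES:
        raise ConfigError(f"unknown universe policy {universe!r}")
    if universe == "both":
        genes = sorted(p1.genes() & p2.genes())
    else:
        genes = sorted(p1.genes() | p2.genes())
    if len(genes) < 3:
        raise ConfigError(
            f"only {len(genes)} genes in the chosen universe; need >= 3")
    a = p1.counts.reindex(genes).fillna(0).to_numpy()
    b = p2.counts.reindex(genes).fillna(0).to_numpy()
    if len(set(a)) < 2 or len(set(b)) < 2:
        rho = float("nan")
    else:
        rho = float(stats.spearmanr(a, b).statistic)
    return ComparisonResult(library_a=p1.library, library_b=p2.library,
                            rho=rho, n_genes=len(genes), universe=universe)


def correlation_matrix(
    profiles: list[ExpressionProfile],
    universe: str = "both",
) -> pd.DataFrame:
    """All pairwise Spearman correlations as a symmetric matrix
    (diagonal 1)."""
    labels = [p.library for p in profiles]
    mat = pd.DataFrame(1.0, index=labels, columns=labels)
    for pa, pb in combinations(profiles, 2):
        r = spearman_profiles(pa, pb, universe=universe)
        mat.loc[pa.library, pb.library] = r.rho
        mat.loc[pb.library, pa.library] = r.rho
    return mat


@dataclass
class RetentionResult:
    """Annotation retention of assembly passes against the read-level
    gene set."""

    n_reads_level: int
    n_pass1: int
    n_pass2: int
    retained_pass1: float
    retained_pass2: float


def annotation_retention(genes_reads: set, genes_pass1: set,
                         genes_pass2: set) -> RetentionResult:
    """Fraction of read-level genes still tagged by each assembly pass.

    Genes novel to a pass (absent from the read-level set) do not count
    toward retention.
    """
    genes_reads = set(genes_reads)
    if not genes_reads:
        raise ConfigError("read-level gene set is empty")
    genes_pass1 = set(genes_pass1)
    genes_pass2 = set(genes_pass2)
    n = len(genes_reads)
    return RetentionResult(
        n_reads_level=n,
        n_pass1=len(genes_pass1),
        n_pass2=len(genes_pass2),
        retained_pass1=len(genes_pass1 & genes_reads) / n,
        retained_pass2=len(genes_pass2 & genes_reads) / n,
    )
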