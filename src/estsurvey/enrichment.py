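"""Category-enrichment testing of library gene sets.

For each (hierarchical) functional category, membership counts of a test
gene set are compared against a background (the union of all relevant
libraries) with Fisher's exact test; p-values are corrected across the
categories of one comparison by Benjamini-Hochberg FDR and transformed
into signed z-scores (positive for over-representation, so p = 0.05 maps
to |z| = 1.96) for heatmap-style matrices.

Category codes are dotted paths (e.g. ``29.5`` is a child of ``29``);
propagation adds every gene to all ancestors of its categories.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from estsurvey.exceptions import ConfigError

_CODE_RE = re.compile(r"^[^.\s]+(\.[^.\s]+)*$")

DEFAULT_Z_MAX = 10.0

#: gene id -> set of category codes
CategoryMap = dict[str, set]


def _validate_code(code: str) -> None:
    if not _CODE_RE.match(code):
        raise ConfigError(f"invalid category code {code!r}")


def ancestors(code: str) -> list[str]:
    """All proper ancestors of a dotted code, nearest first."""
    parts = code.split(".")
    return [".".join(parts[:i]) for i in range(len(parts) - 1, 0, -1)]


def propagate_hierarchy(cat_map: CategoryMap) -> CategoryMap:
    """Close the map under the hierarchy: membership in ``x.y`` implies
    membership in ``x``."""
    out: CategoryMap = {}
    for gene, codes in cat_map.items():
        full = set()
        for code in codes:
            _validate_code(str(code))
            full.add(str(code))
            full.update(ancestors(str(code)))
        out[gene] = full
    return out


def all_categories(cat_map: CategoryMap) -> list[str]:
    cats: set = set()
    for codes in cat_map.values():
        cats.update(codes)
    return sorted(cats)


@dataclass
class EnrichmentResult:
    category: str
    k: int  # test genes in category
    n: int  # test genes
    K: int  # background genes in category
    N: int  # background genes
    p: float
    direction: str  # 'over' | 'under' | 'none'
    p_adj: float | None = None
    z: float | None = None


def fisher_category(
    test_set: set,
    background_set: set,
    category: str,
    cat_map: CategoryMap,
) -> EnrichmentResult | None:
    """Two-sided Fisher's exact test of one category.

    The 2x2 table is [[k, n-k], [K-k, (N-n)-(K-k)]] with k = test genes in
    the category, n = test genes, K = background genes in the category,
    N = background genes; two-sided by the point-probability method (sum
    of all tables at fixed margins with probability <= the observed one).
    Returns ``None`` when the category is absent from the background.
    """
    test_set = set(test_set)
    background_set = set(background_set)
    if not background_set:
        raise ConfigError("background set is empty")
    if not test_set <= background_set:
        raise ConfigError("test set must be a subset of the background set")
    n = len(test_set)
    N = len(background_set)
    members = {g for g, codes in cat_map.items() if category in codes}
    K = len(members & background_set)
    if K == 0:
        return None
    k = len(members & test_set)
    table = [[k, n - k], [K - k, (N - n) - (K - k)]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if n == 0:
        direction = "none"
    elif k / n > K / N:
        direction = "over"
    elif k / n < K / N:
        direction = "under"
    else:
        direction = "none"
    return EnrichmentResult(category=category, k=k, n=n, K=K, N=N,
                            p=float(p), direction=direction)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ConfigError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def signed_z(p: float, direction: str = "over",
             z_max: float = DEFAULT_Z_MAX) -> float:
    """z = +-Phi^-1(1 - p/2), positive for over-representation.

    p = 0 is capped at ``z_max``; p = 1 maps to 0.
    """
    if not 0.0 <= p <= 1.0:
        raise ConfigError(f"p-value {p} outside [0, 1]")
    sign = -1.0 if direction == "under" else 1.0
    if p == 0.0:
        return sign * z_max
    z = float(stats.norm.isf(p / 2.0))
    return sign * min(z, z_max)


def enrich(
    test_set: set,
    background_set: set,
    cat_map: CategoryMap,
    categories=None,
    fdr: bool = True,
    z_max: float = DEFAULT_Z_MAX,
) -> pd.DataFrame:
    """Test every category; adjust across the tested family; attach z.

    With ``fdr=False`` (uncorrected variant) z-scores are computed from
    the raw p-values. Categories absent from the background are skipped
    and listed in the DataFrame's ``attrs['skipped']``.
    """
    if categories is None:
        categories = all_categories(cat_map)
    results: list[EnrichmentResult] = []
    skipped: list[str] = []
    for cat in categories:
        r = fisher_category(test_set, background_set, cat, cat_map)
        if r is None:
            skipped.append(cat)
        else:
            results.append(r)
    if results:
        padj = bh_adjust([r.p for r in results])
        for r, pa in zip(results, padj):
            r.p_adj = float(pa)
            r.z = signed_z(r.p_adj if fdr else r.p, r.direction, z_max)
    df = pd.DataFrame([vars(r) for r in results])
    df.attrs["skipped"] = skipped
    return df


def z_matrix(
    library_sets: dict[str, set],
    background_set: set,
    cat_map: CategoryMap,
    categories=None,
    fdr: bool = True,
    z_max: float = DEFAULT_Z_MAX,
) -> pd.DataFrame:
    """Signed z-score matrix (categories x libraries) for heatmap
    rendering; BH correction is applied per library column."""
    if categories is None:
        categories = all_categories(cat_map)
    cols = {}
    for label, genes in library_sets.items():
        df = enrich(genes, background_set, cat_map, categories=categories,
                    fdr=fdr, z_max=z_max)
        cols[label] = df.set_index("category")["z"] if len(df) else pd.Series(dtype=float)
    return pd.DataFrame(cols).reindex(categories)


# ---------------------------------------------------------------------------
# I/O

def load_category_map(path) -> CategoryMap:
    """Category map from TSV columns (gene_id, code[, name])."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ConfigError("category map needs at least 2 columns")
    out: CategoryMap = {}
    for gene, code in zip(df[0], df[1]):
        _validate_code(code)
        out.setdefault(gene, set()).add(code)
    return out


def load_gene_set(path) -> set:
    """Gene set from a one-id-per-line text file."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()
                and not line.startswith("#")}
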