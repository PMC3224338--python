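"""Gene-discovery rarefaction by subsampling a read pool.

A read pool is the multiset of gene labels of all assigned reads of one
library (or of all libraries combined). Random subsets of increasing size
are drawn without replacement and, per size, the number of genes tagged
at least k times (k in {1, 5, 10, 100} by default) is recorded. The exact
expectation E[detections] = sum_g P(X_g >= k) with X_g hypergeometric
serves as closed-form oracle for the Monte-Carlo sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from estsurvey.exceptions import ConfigError

DEFAULT_THRESHOLDS = (1, 5, 10, 100)
DEFAULT_GRID_POINTS = 20
DEFAULT_REPS = 10


@dataclass
class ReadPool:
    """Multiset of per-read gene labels, stored as per-gene counts."""

    counts: pd.Series  # index: gene id, values: reads per gene

    def __post_init__(self):
        self.counts = self.counts[self.counts > 0].astype(int)

    @classmethod
    def from_labels(cls, labels) -> "ReadPool":
        return cls(pd.Series(list(labels)).value_counts().sort_index())

    @classmethod
    def from_profile(cls, profile) -> "ReadPool":
        return cls(profile.counts.copy())

    @property
    def n_reads(self) -> int:
        return int(self.counts.sum())

    @property
    def n_genes(self) -> int:
        return len(self.counts)

    def combine(self, other: "ReadPool") -> "ReadPool":
        return ReadPool(self.counts.add(other.counts, fill_value=0).astype(int))


@dataclass
class DetectionCurve:
    """Rarefaction curve at one tag-threshold k.

    ``data`` is long format (n, rep, detections); ``final_x`` is the full
    pool size so the fitted slope can be evaluated at the library's actual
    read count.
    """

    k: int
    data: pd.DataFrame
    final_x: int
    n_genes: int

    def mean_curve(self) -> pd.DataFrame:
        g = self.data.groupby("n")["detections"]
        out = g.mean().rename("detections").reset_index()
        out["sd"] = g.std(ddof=1).to_numpy()
        return out


def subsample_detections(
    pool: ReadPool,
    n: int,
    k: int = 1,
    reps: int = DEFAULT_REPS,
    seed: int | np.random.Generator = 0,
) -> tuple[float, np.ndarray]:
    """Monte-Carlo detections at sample size n and threshold k.

    Each replicate draws ``n`` reads without replacement (multivariate
    hypergeometric over the per-gene counts) and counts genes drawn at
    least ``k`` times. Returns (mean, per-replicate values).
    """
    if not 0 <= n <= pool.n_reads:
        raise ConfigError(f"sample size {n} outside [0, {pool.n_reads}]")
    if k < 1:
        raise ConfigError("threshold k must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    colors = pool.counts.to_numpy()
    vals = np.empty(reps)
    for r in range(reps):
        draw = rng.multivariate_hypergeometric(colors, n)
        vals[r] = int((draw >= k).sum())
    return float(vals.mean()), vals


def expected_detections(pool: ReadPool, n: int, k: int = 1) -> float:
    """Exact E[detections] for a without-replacement sample of size n.

    E = sum over genes of P(X_g >= k) with X_g ~ Hypergeom(N, c_g, n).
    """
    if not 0 <= n <= pool.n_reads:
        raise ConfigError(f"sample size {n} outside [0, {pool.n_reads}]")
    if k < 1:
        raise ConfigError("threshold k must be >= 1")
    c = pool.counts.to_numpy()
    return float(stats.hypergeom.sf(k - 1, pool.n_reads, c, n).sum())


def sample_size_grid(n_total: int, points: int = DEFAULT_GRID_POINTS) -> np.ndarray:
    """Geometrically spaced sample sizes ending at the full pool size."""
    if n_total < 1:
        raise ConfigError("pool is empty")
    points = min(points, n_total)
    grid = np.unique(np.round(np.geomspace(1, n_total, points)).astype(int))
    return grid


def build_curves(
    pool: ReadPool,
    grid: np.ndarray | None = None,
    thresholds=DEFAULT_THRESHOLDS,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
) -> dict[int, DetectionCurve]:
    """One detection curve per threshold over a common sample-size grid.

    The grid defaults to 20 geometrically spaced sizes ending at the full
    pool; each (threshold) curve uses its own seeded substream.
    """
    if grid is None:
        grid = sample_size_grid(pool.n_reads)
    grid = np.asarray(grid, dtype=int)
    if len(grid) and grid.max() > pool.n_reads:
        raise ConfigError("grid exceeds pool size")
    curves: dict[int, DetectionCurve] = {}
    for k in thresholds:
        rng = np.random.default_rng([int(seed), int(k)])
        rows = []
        for n in grid:
            _, vals = subsample_detections(pool, int(n), k, reps, rng)
            rows.extend((int(n), r, int(v)) for r, v in enumerate(vals))
        data = pd.DataFrame(rows, columns=["n", "rep", "detections"])
        curves[k] = DetectionCurve(k=k, data=data, final_x=pool.n_reads,
                                   n_genes=pool.n_genes)
    return curves


def expected_curve(pool: ReadPool, grid: np.ndarray | None = None,
                   k: int = 1) -> DetectionCurve:
    """Closed-form (noise-free) detection curve, usable directly by the
    saturation fit."""
    if grid is None:
        grid = sample_size_grid(pool.n_reads)
    grid = np.asarray(grid, dtype=int)
    rows = [(int(n), 0, expected_detections(pool, int(n), k)) for n in grid]
    data = pd.DataFrame(rows, columns=["n", "rep", "detections"])
    return DetectionCurve(k=k, data=data, final_x=pool.n_reads,
                          n_genes=pool.n_genes)


def curves_to_tsv(curves: dict[int, DetectionCurve], path) -> None:
    frames = []
    for k, curve in curves.items():
        df = curve.data.copy()
        df.insert(0, "k", k)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def curves_from_tsv(path) -> dict[int, DetectionCurve]:
    df = pd.read_csv(path, sep="\t", comment="#")
    curves = {}
    for k, sub in df.groupby("k"):
        data = sub[["n", "rep", "detections"]].reset_index(drop=True)
        curves[int(k)] = DetectionCurve(k=int(k), data=data,
                                        final_x=int(sub["n"].max()),
                                        n_genes=0)
    return curves
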