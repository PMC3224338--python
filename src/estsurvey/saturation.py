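"""Hyperbolic saturation model for gene-discovery curves.

The number of genes detected after sampling x reads is modelled as

    y = a * x / (b + x)

where ``a`` is the asymptotic number of detectable genes in the pool and
``b`` the half-saturation read count (the depth at which half of ``a`` is
reached). The derivative a*b/(b+x)^2 evaluated at the library's final
read count measures how many additional genes one more read would be
expected to discover — a small final slope indicates the library was
sequenced to exhaustion.

The fit follows the Model/Results convention: build a
:class:`SaturationModel` from data (or a detection curve), call ``fit()``,
inspect the returned :class:`SaturationFitResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from estsurvey.exceptions import ConfigError
from estsurvey.rarefaction import DetectionCurve

MAX_ITER = 500
XTOL = 1e-8


def predict_detections(a: float, b: float, x) -> np.ndarray | float:
    """Model value a*x/(b+x)."""
    x = np.asarray(x, dtype=float)
    out = a * x / (b + x)
    return float(out) if out.ndim == 0 else out


def slope_at(a: float, b: float, x) -> np.ndarray | float:
    """Analytic derivative d/dx [a*x/(b+x)] = a*b/(b+x)^2."""
    x = np.asarray(x, dtype=float)
    out = a * b / (b + x) ** 2
    return float(out) if out.ndim == 0 else out


def _initial_guess(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """a0 = 1.2 * max(y); b0 = x at which y first exceeds a0/2
    (linearly interpolated)."""
    a0 = 1.2 * float(y.max())
    half = a0 / 2.0
    above = np.flatnonzero(y >= half)
    if len(above) == 0:
        b0 = float(x.max())
    else:
        i = above[0]
        if i == 0:
            b0 = float(x[0])
        else:
            x0, x1 = x[i - 1], x[i]
            y0, y1 = y[i - 1], y[i]
            b0 = float(x0 + (half - y0) * (x1 - x0) / (y1 - y0)) if y1 > y0 \
                else float(x1)
    return a0, max(b0, 1.0)


class SaturationModel:
    """Nonlinear least squares for y = a*x/(b+x).

    Parameters
    ----------
    x : array-like
        Sample sizes (reads drawn).
    y : array-like
        Detections (genes tagged at least k times).
    """

    def __init__(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ConfigError("x and y must have equal length")
        order = np.argsort(x)
        self.x, self.y = x[order], y[order]
        if len(np.unique(self.x[self.y > 0])) < 3:
            raise ConfigError(
                "need at least 3 distinct sample sizes with positive detections")

    @classmethod
    def from_curve(cls, curve: DetectionCurve, use: str = "mean") -> "SaturationModel":
        """Build from a detection curve, using replicate means (default)
        or every replicate point (``use='replicates'``)."""
        if use == "mean":
            mc = curve.mean_curve()
            model = cls(mc["n"], mc["detections"])
        elif use == "replicates":
            model = cls(curve.data["n"], curve.data["detections"])
        else:
            raise ConfigError(f"unknown use={use!r}")
        model.final_x = curve.final_x
        model.k = curve.k
        return model

    final_x: float | None = None
    k: int | None = None

    def fit(self, final_x: float | None = None) -> "SaturationFitResults":
        """Levenberg-Marquardt least squares with data-driven start values.

        ``final_x`` (default: the largest sample size, or the curve's full
        pool size) is where the final slope is evaluated.
        """
        if final_x is None:
            final_x = self.final_x if self.final_x is not None else float(self.x.max())
        p0 = _initial_guess(self.x, self.y)
        converged = True
        try:
            popt, pcov, infodict, mesg, ier = optimize.curve_fit(
                lambda x, a, b: a * x / (b + x),
                self.x, self.y, p0=p0, method="lm",
                xtol=XTOL, maxfev=MAX_ITER * 3, full_output=True)
            converged = ier in (1, 2, 3, 4)
        except RuntimeError:
            converged = False
            popt = np.array([np.nan, np.nan])
            pcov = np.full((2, 2), np.nan)
        return SaturationFitResults(model=self, a=float(popt[0]), b=float(popt[1]),
                                    cov=np.asarray(pcov, dtype=float),
                                    final_x=float(final_x), converged=converged)


@dataclass
class SaturationFitResults:
    """Estimates and diagnostics of a hyperbolic saturation fit."""

    model: SaturationModel
    a: float
    b: float
    cov: np.ndarray
    final_x: float
    converged: bool

    @property
    def params(self) -> pd.Series:
        return pd.Series({"a": self.a, "b": self.b})

    @property
    def bse(self) -> pd.Series:
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(self.cov))
        return pd.Series(se, index=["a", "b"])

    @property
    def fittedvalues(self) -> np.ndarray:
        return predict_detections(self.a, self.b, self.model.x)

    @property
    def r_squared(self) -> float:
        """1 - SSE/SST with SST about the mean of y."""
        if not self.converged:
            return float("nan")
        resid = self.model.y - self.fittedvalues
        sst = float(np.sum((self.model.y - self.model.y.mean()) ** 2))
        if sst == 0:
            return float("nan")
        return 1.0 - float(np.sum(resid ** 2)) / sst

    @property
    def slope_final(self) -> float:
        """Derivative of the fitted curve at the final read count."""
        return slope_at(self.a, self.b, self.final_x)

    def predict(self, x) -> np.ndarray | float:
        return predict_detections(self.a, self.b, x)

    def slope(self, x) -> np.ndarray | float:
        return slope_at(self.a, self.b, x)

    def summary(self) -> str:
        lines = [
            "Hyperbolic saturation fit  y = a*x/(b+x)",
            "-" * 46,
            f"observations          {len(self.model.x):>12d}",
            f"converged             {str(self.converged):>12s}",
            f"a (asymptote, genes)  {self.a:>12.1f}  (se {self.bse['a']:.1f})",
            f"b (half-sat., reads)  {self.b:>12.1f}  (se {self.bse['b']:.1f})",
            f"R^2                   {self.r_squared:>12.4f}",
            f"final read count      {self.final_x:>12.0f}",
            f"slope at final count  {self.slope_final:>12.4f}  genes/read",
        ]
        return "\n".join(lines)


def fit_hyperbola(curve: DetectionCurve, use: str = "mean") -> SaturationFitResults:
    """Convenience wrapper: fit the saturation model to a detection curve."""
    return SaturationModel.from_curve(curve, use=use).fit()


def fit_table(curve_sets: dict[str, dict[int, DetectionCurve]]) -> pd.DataFrame:
    """Fit every (library, threshold) curve; one row per fit.

    Mirrors the per-library summary layout: a, b, R^2, total detections in
    the full pool, and the slope at the final read count.
    """
    rows = []
    for library, curves in curve_sets.items():
        for k, curve in sorted(curves.items()):
            full = curve.data[curve.data["n"] == curve.final_x]["detections"]
            total = float(full.mean()) if len(full) else float("nan")
            try:
                res = fit_hyperbola(curve)
            except ConfigError:
                rows.append((library, k, np.nan, np.nan, np.nan, total, np.nan,
                             False))
                continue
            rows.append((library, k, res.a, res.b, res.r_squared, total,
                         res.slope_final, res.converged))
    return pd.DataFrame(rows, columns=[
        "library", "k", "a", "b", "r_squared", "total_detected",
        "slope_final", "converged"])


def plot_curves(curves: dict[int, DetectionCurve],
                fits: dict[int, SaturationFitResults] | None = None,
                ax=None):
    """Plot detection curves (points) and fitted hyperbolas (lines)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for k, curve in sorted(curves.items()):
        mc = curve.mean_curve()
        pts = ax.plot(mc["n"], mc["detections"], "o", ms=4, label=f"k={k}")
        if fits and k in fits and fits[k].converged:
            grid = np.linspace(0, curve.final_x, 200)
            ax.plot(grid, fits[k].predict(grid), "-",
                    color=pts[0].get_color())
    ax.set_xlabel("reads sampled")
    ax.set_ylabel("genes detected")
    ax.legend()
    return ax
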