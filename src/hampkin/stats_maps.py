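"""Joint distributions of descriptor pairs and their local maxima.

The correlation analyses reduce a pair of per-frame descriptors to a
normalized 2-D density (histogram with Scott-rule bins by default, or a
Gaussian KDE) and mark its local maxima — the "bullets" used to read main
tendencies off the contour maps — then summarize how the maxima of one
parameter move against the architecture asymmetry ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .series import DescriptorSeries

__all__ = [
    "JointDistribution",
    "joint_distribution",
    "local_maxima",
    "correlation_report",
]


@dataclass
class JointDistribution:
    """Normalized density of two descriptors on a regular grid."""

    x_name: str
    y_name: str
    x_units: str
    y_units: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    density: np.ndarray            # (nx, ny), integrates to 1
    method: str = "histogram"
    bandwidth: tuple[float, float] = (0.0, 0.0)
    maxima: list[tuple[float, float, float]] = field(default_factory=list)

    @property
    def cell_area(self) -> float:
        return float((self.x_edges[1] - self.x_edges[0])
                     * (self.y_edges[1] - self.y_edges[0]))

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def integral(self) -> float:
        return float(self.density.sum() * self.cell_area)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.density,
                          index=pd.Index(self.x_centers, name=self.x_name),
                          columns=pd.Index(self.y_centers, name=self.y_name))
        df.to_csv(path)


def _series_values(s) -> tuple[np.ndarray, str, str]:
    if isinstance(s, DescriptorSeries):
        return s.values, s.name, s.units
    return np.asarray(s, dtype=float), "", ""


def _scott_bins(v: np.ndarray) -> int:
    # Scott rule for a two-dimensional histogram: h = 3.5 sigma n^(-1/4)
    width = 3.5 * v.std(ddof=1) * len(v) ** (-0.25)
    span = v.max() - v.min()
    return int(np.clip(np.ceil(span / width), 5, 200))


def joint_distribution(series_x, series_y, method: str = "histogram",
                       resolution: int | None = None,
                       margin: float = 0.025) -> JointDistribution:
    """Normalized 2-D density covering the data plus a 5% margin
    (2.5% of the span added on each side).

    ``resolution`` overrides the Scott-rule bin count (same on both axes).
    A constant series has no usable axis and raises.
    """
    x, x_name, x_units = _series_values(series_x)
    y, y_name, y_units = _series_values(series_y)
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if len(x) < 100:
        raise ValueError("need at least 100 samples for a joint distribution")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance axis: constant descriptor series")
    if method not in ("histogram", "kde"):
        raise ValueError("method must be 'histogram' or 'kde'")

    def padded(v):
        lo, hi = v.min(), v.max()
        pad = margin * (hi - lo)
        return lo - pad, hi + pad

    nx = resolution or _scott_bins(x)
    ny = resolution or _scott_bins(y)
    x_edges = np.linspace(*padded(x), nx + 1)
    y_edges = np.linspace(*padded(y), ny + 1)
    if method == "histogram":
        h, _, _ = np.histogram2d(x, y, bins=(x_edges, y_edges), density=True)
        density = h
        bw = (x_edges[1] - x_edges[0], y_edges[1] - y_edges[0])
    else:
        kde = sps.gaussian_kde(np.vstack([x, y]), bw_method="scott")
        xc = 0.5 * (x_edges[:-1] + x_edges[1:])
        yc = 0.5 * (y_edges[:-1] + y_edges[1:])
        gx, gy = np.meshgrid(xc, yc, indexing="ij")
        density = kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(nx, ny)
        area = (x_edges[1] - x_edges[0]) * (y_edges[1] - y_edges[0])
        density = density / (density.sum() * area)
        bw = (float(kde.factor * x.std(ddof=1)), float(kde.factor * y.std(ddof=1)))
    dist = JointDistribution(
        x_name=x_name, y_name=y_name, x_units=x_units, y_units=y_units,
        x_edges=x_edges, y_edges=y_edges, density=density,
        method=method, bandwidth=bw,
    )
    dist.maxima = local_maxima(dist)
    return dist


def local_maxima(dist: JointDistribution,
                 min_prominence: float = 0.2) -> list[tuple[float, float, float]]:
    """Grid cells beating all 8 neighbors and the prominence floor.

    Maxima closer than one bandwidth are merged (highest kept); the result
    is sorted by density, descending. For histogram densities the peak
    search runs on a one-cell Gaussian smoothing of the grid so that
    counting noise does not fragment a single mode (the stored density is
    left untouched).
    """
    d = dist.density
    if d.shape[0] < 5 or d.shape[1] < 5:
        raise ValueError("density grid must be at least 5x5")
    if dist.method == "histogram":
        from scipy.ndimage import gaussian_filter
        d = gaussian_filter(d, sigma=1.0, mode="nearest")
    floor = min_prominence * d.max()
    peaks = []
    nx, ny = d.shape
    for i in range(nx):
        for j in range(ny):
            v = d[i, j]
            if v < floor or v <= 0:
                continue
            neigh = d[max(i - 1, 0):i + 2, max(j - 1, 0):j + 2]
            if v >= neigh.max() and (neigh < v).sum() == neigh.size - 1:
                peaks.append((i, j, v))
    # merge within one bandwidth
    xc, yc = dist.x_centers, dist.y_centers
    bx = dist.bandwidth[0] or (dist.x_edges[1] - dist.x_edges[0])
    by = dist.bandwidth[1] or (dist.y_edges[1] - dist.y_edges[0])
    peaks.sort(key=lambda p: -p[2])
    kept: list[tuple[int, int, float]] = []
    for i, j, v in peaks:
        close = any(abs(xc[i] - xc[i2]) <= bx and abs(yc[j] - yc[j2]) <= by
                    for i2, j2, _ in kept)
        if not close:
            kept.append((i, j, v))
    return [(float(xc[i]), float(yc[j]), float(v)) for i, j, v in kept]


def correlation_report(table: pd.DataFrame, ratio_column: str = "ratio",
                       parameters: list[str] | None = None,
                       method: str = "histogram",
                       min_prominence: float = 0.2,
                       resolution: int | None = None) -> dict:
    """Joint distribution, maxima and maxima-trend per (parameter, ratio) pair.

    The trend summary ranks the local maxima by their parameter coordinate
    and reports the Spearman correlation (and its sign) between parameter
    and ratio coordinates of the maxima; with fewer than three maxima no
    trend is claimed (rho = 0).
    """
    if ratio_column not in table.columns:
        raise ValueError(f"table has no ratio column {ratio_column!r}")
    if parameters is None:
        parameters = [c for c in table.columns
                      if c not in (ratio_column, "time_ps", "frame")]
    if not parameters:
        raise ValueError("no parameter columns to correlate with the ratio")
    ratio = table[ratio_column].to_numpy(float)
    report: dict = {"ratio_column": ratio_column, "pairs": {}}
    for name in parameters:
        dist = joint_distribution(
            DescriptorSeries(name, "", table[name].to_numpy(float)),
            DescriptorSeries(ratio_column, "", ratio),
            method=method, resolution=resolution)
        maxima = local_maxima(dist, min_prominence=min_prominence)
        if len(maxima) >= 3:
            px = [m[0] for m in maxima]
            py = [m[1] for m in maxima]
            rho = float(sps.spearmanr(px, py).statistic)
        else:
            rho = 0.0
        report["pairs"][name] = {
            "n_maxima": len(maxima),
            "maxima": [list(m) for m in maxima],
            "spearman_rho": rho,
            "trend_sign": int(np.sign(rho)),
        }
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1))
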