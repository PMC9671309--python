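"""Diagnostic spectrum: probability vectors on the equilateral triangle.

Each participant's 3-class probability vector (BD, HC, BPD) lies on the
2-simplex, drawn as an equilateral triangle with vertices BD at the lower
left, HC at the lower right and BPD at the apex.  Group-wise kernel density
estimates with highest-density-region contours (25/50/75% mass) visualise how
tightly each diagnostic group clusters at its own vertex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .encoding import CLASSES

logger = logging.getLogger(__name__)

#: Triangle vertices in class order (BD, HC, BPD).
VERTICES = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3.0) / 2.0]])


@dataclass
class SimplexPoint:
    """A 2-D point inside the probability triangle."""

    xy: np.ndarray

    def barycentric(self) -> np.ndarray:
        """Recover the (BD, HC, BPD) probability weights from the 2-D point."""
        T = np.column_stack([VERTICES[0] - VERTICES[2], VERTICES[1] - VERTICES[2]])
        ab = np.linalg.solve(T, self.xy - VERTICES[2])
        return np.array([ab[0], ab[1], 1.0 - ab.sum()])


def simplex_project(prob: Sequence[float]) -> SimplexPoint:
    """Barycentric interpolation of a probability 3-vector onto the triangle."""
    p = np.asarray(prob, dtype=float)
    if p.shape != (3,):
        raise ValueError("probability vector must have exactly 3 components")
    if np.any(p < -1e-6):
        raise ValueError(f"negative probability component in {p}")
    p = np.clip(p, 0.0, None)
    s = p.sum()
    if not np.isclose(s, 1.0, atol=1e-6):
        logger.debug("renormalising probability vector summing to %.6f", s)
    p = p / s
    return SimplexPoint(xy=p @ VERTICES)


def _hdr_thresholds(density: np.ndarray, masses: Sequence[float]) -> list[float]:
    """Density thresholds whose superlevel sets enclose the given mass fractions."""
    flat = np.sort(density.ravel())[::-1]
    cum = np.cumsum(flat)
    cum /= cum[-1]
    return [float(flat[np.searchsorted(cum, m)]) for m in masses]


def density_contours(
    points: np.ndarray,
    levels: Sequence[float] = (0.25, 0.50, 0.75),
    grid_n: int = 200,
) -> dict[float, list[np.ndarray]]:
    """Highest-density-region contours of a 2-D Gaussian KDE on the triangle.

    ``points`` is (n, 2) with n >= 5.  Bandwidth follows Scott's rule; each
    returned contour level encloses approximately the stated probability mass
    (25/50/75% by default).  Returns ``{mass_level: [polyline, ...]}``; for
    degenerate (all-identical) point sets a warning is logged and the single
    point is returned as a zero-length polyline at every level.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if pts.shape[0] < 5:
        raise ValueError("need at least 5 points for a density estimate")
    if np.allclose(pts, pts[0], atol=1e-12):
        logger.warning("all points identical; emitting a point marker")
        return {lv: [pts[0:1].copy()] for lv in levels}
    try:
        kde = gaussian_kde(pts.T, bw_method="scott")
    except np.linalg.LinAlgError:
        logger.warning("degenerate point configuration; jittering for KDE")
        jitter = np.random.default_rng(0).normal(scale=1e-6, size=pts.shape)
        kde = gaussian_kde((pts + jitter).T, bw_method="scott")
    pad = 0.15
    xs = np.linspace(-pad, 1.0 + pad, grid_n)
    ys = np.linspace(-pad, VERTICES[2, 1] + pad, grid_n)
    XX, YY = np.meshgrid(xs, ys)
    density = kde(np.vstack([XX.ravel(), YY.ravel()])).reshape(XX.shape)
    thresholds = _hdr_thresholds(density, levels)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    out: dict[float, list[np.ndarray]] = {}
    for mass, thr in zip(levels, thresholds):
        cs = ax.contour(XX, YY, density, levels=[thr])
        polylines = [np.asarray(p) for p in cs.allsegs[0]]
        out[mass] = polylines
    plt.close(fig)
    return out


def enclosed_mass(
    points: np.ndarray, polylines: list[np.ndarray], n_samples: int = 20000, seed: int = 0
) -> float:
    """Monte-Carlo estimate of KDE mass inside a set of contour polylines.

    Used to verify that the returned highest-density regions enclose the
    advertised probability; counts samples from the KDE that fall inside any
    polyline (treated as a closed polygon via matplotlib paths).
    """
    from matplotlib.path import Path

    kde = gaussian_kde(np.asarray(points, dtype=float).T, bw_method="scott")
    samples = kde.resample(n_samples, seed=seed).T
    inside = np.zeros(n_samples, dtype=bool)
    for poly in polylines:
        if len(poly) >= 3:
            inside |= Path(poly).contains_points(samples)
    return float(inside.mean())


def plot_spectrum(
    group_points: dict[str, np.ndarray],
    out_path: str,
    levels: Sequence[float] = (0.25, 0.50, 0.75),
) -> None:
    """Per-group triangle density plots with 25/50/75% HDR contours.

    Vertex assignment (BD lower-left, HC lower-right, BPD apex) is stated in
    each legend.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = [g for g in CLASSES if g in group_points]
    fig, axes = plt.subplots(len(groups), 1, figsize=(5, 4.2 * len(groups)))
    axes = np.atleast_1d(axes)
    tri = np.vstack([VERTICES, VERTICES[0]])
    shades = ["#ffb3b3", "#ff6666", "#cc0000"]  # light -> dark = 75 -> 25%
    for ax, group in zip(axes, groups):
        pts = np.asarray(group_points[group])
        ax.plot(tri[:, 0], tri[:, 1], "k-", lw=1)
        ax.scatter(pts[:, 0], pts[:, 1], s=12, c="steelblue", alpha=0.6,
                   label=f"{group} participants")
        if pts.shape[0] >= 5 and not np.allclose(pts, pts[0]):
            contours = density_contours(pts, levels=levels)
            for mass, color in zip(sorted(levels, reverse=True), shades):
                for poly in contours[mass]:
                    if len(poly) >= 2:
                        ax.plot(poly[:, 0], poly[:, 1], color=color, lw=1.2)
        for name, (x, y) in zip(CLASSES, VERTICES):
            ax.annotate(name, (x, y), textcoords="offset points", xytext=(0, 5),
                        ha="center")
        ax.set_title(f"Predicted-probability spectrum: {group}")
        ax.legend(loc="upper right", fontsize=8,
                  title="BD lower-left, HC lower-right, BPD apex",
                  title_fontsize=7)
        ax.set_aspect("equal")
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
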