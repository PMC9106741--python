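"""Gene dynamics along a supplied pseudotime.

Pseudotime is an input here (computed upstream by any trajectory method);
this module fits each gene's counts with an NB GLM on a 3-df natural spline
of pseudotime (size-factor offset), evaluates the smooth on a uniform grid,
z-scales the fitted curve, and derives:

* onset — the first upward zero-crossing of the centered, z-scaled curve
  (with one-grid-step persistence against spline wiggle), linearly
  interpolated between bracketing grid points; the median over a gene set
  gives a global onset estimate (e.g. of a metabolic-stress program);
* kinetic clusters — Ward (ward.D2-equivalent) hierarchical clustering of
  the z-scaled curves, cut at k groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from ._glm import NaturalSpline, fit_nb_glm

__all__ = [
    "PseudotimeCurve",
    "smooth_over_pseudotime",
    "onset_pseudotime",
    "global_onset",
    "cluster_gene_dynamics",
]


@dataclass
class PseudotimeCurve:
    """Spline-smoothed expression of one gene over a pseudotime grid."""

    gene: str
    grid: np.ndarray
    fitted: np.ndarray
    z_scaled: np.ndarray
    constant: bool = False  # fitted curve had ~zero variance


def _z_scale(fitted: np.ndarray) -> tuple[np.ndarray, bool]:
    sd = float(np.std(fitted, ddof=0))
    if sd < 1e-12 * max(1.0, abs(float(np.mean(fitted)))) or sd == 0.0:
        return np.zeros_like(fitted), True
    return (fitted - np.mean(fitted)) / sd, False


def smooth_over_pseudotime(
    y,
    pseudotime,
    size_factors=None,
    df: int = 3,
    grid_size: int = 100,
    gene: str = "",
) -> PseudotimeCurve:
    """NB-GLM natural-spline fit of one gene's counts over pseudotime.

    ``y`` are raw UMI counts; ``size_factors`` enter as a log offset so the
    fitted curve is expression per unit size factor. The smooth is evaluated
    on ``grid_size`` evenly spaced points spanning the observed pseudotime,
    then centered and scaled to unit variance.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(pseudotime, dtype=float)
    finite = np.isfinite(t)
    if finite.sum() < 10:
        raise ValueError("need >= 10 cells with finite pseudotime")
    y, t = y[finite], t[finite]
    if np.ptp(t) == 0:
        raise ValueError("pseudotime is constant")
    offset = None
    if size_factors is not None:
        f = np.asarray(size_factors, dtype=float)[finite]
        offset = np.log(f)
    spline = NaturalSpline(t, df=df)
    X = np.column_stack([np.ones(t.size), spline.design(t)])
    fit = fit_nb_glm(y, X, offset=offset)
    grid = np.linspace(t.min(), t.max(), grid_size)
    Xg = np.column_stack([np.ones(grid_size), spline.design(grid)])
    fitted = np.exp(np.clip(Xg @ fit.beta, -500, 500))
    z, const = _z_scale(fitted)
    return PseudotimeCurve(gene=gene, grid=grid, fitted=fitted, z_scaled=z, constant=const)


def onset_pseudotime(curve: PseudotimeCurve) -> float | None:
    """First persistent upward zero-crossing of the z-scaled curve.

    The onset is the smallest grid point t where z(t) >= 0 and z stays >= 0
    for the following grid step (so a single wiggle above zero does not
    count), linearly interpolated between the bracketing grid points.
    Returns None when the curve never crosses upward (e.g. a downregulated
    or constant gene).
    """
    if curve.constant:
        return None
    z = curve.z_scaled
    g = curve.grid
    for i in range(1, z.size):
        if z[i - 1] < 0 <= z[i]:
            if i + 1 < z.size and z[i + 1] < 0:
                continue  # not persistent
            frac = -z[i - 1] / (z[i] - z[i - 1])
            return float(g[i - 1] + frac * (g[i] - g[i - 1]))
    if z[0] >= 0 and np.all(z >= 0):
        return None  # never below zero: no crossing to speak of
    return None


def global_onset(curves) -> float:
    """Median per-gene onset over a gene set (genes without onset skipped)."""
    onsets = [o for o in (onset_pseudotime(c) for c in curves) if o is not None]
    if not onsets:
        raise ValueError("no gene in the set has a defined onset")
    return float(np.median(onsets))


def cluster_gene_dynamics(z_matrix, k: int = 4):
    """Ward clustering of z-scaled pseudotime curves.

    ``z_matrix`` is genes x grid (rows are z-scaled curves). Returns
    (labels, leaf_order): 1..k cluster labels per gene and the dendrogram
    leaf order for heatmap display. Ward linkage on Euclidean distances
    (the ward.D2 criterion).
    """
    Z = np.asarray(z_matrix, dtype=float)
    n = Z.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of genes ({n})")
    link = hierarchy.linkage(pdist(Z), method="ward")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    order = hierarchy.leaves_list(link)
    return labels, order
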