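"""Two-pass loess normalization of spot log2 ratios.

Per array, each spot contributes M = log2(ch1/ch2) and A = mean of the two
log2 channel intensities (no background subtraction by default; background
enters QC only).  Two successive smoothings remove systematic bias:

1. intensity pass - loess of M on A (span 0.3); the fitted curve captures
   intensity-dependent dye bias and is subtracted;
2. spatial pass - a local-regression surface over the slide coordinates
   (span 0.002 of the spots, i.e. a k-nearest-neighbor neighborhood with
   k = round(span * n)), subtracted from the intensity-normalized ratios.

Both passes use degree-1 local regression with tricube weights.  By default
no robustness iterations are applied: in a direct parent-of-origin
comparison a double-digit percentage of spots is genuinely differential
with a common sign, and bisquare reweighting then systematically pulls the
fitted bias curve toward the background class, biasing fold-change
estimates; the plain local mean is the balanced choice.  Robustness
iterations remain available via ``iterations`` for data with heavy-tailed
artifacts.  The spatial fit at each spot excludes the spot itself: with
neighborhoods of a few dozen spots, self-influence would otherwise shrink
each spot's own signal toward zero.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from statsmodels.nonparametric.smoothers_lowess import lowess

from .types import Hybridization

logger = logging.getLogger(__name__)

DEFAULT_INTENSITY_SPAN = 0.3
DEFAULT_SPATIAL_SPAN = 0.002
MIN_SPATIAL_NEIGHBORS = 10

MA_COLUMNS = ["probe_id", "M", "A", "x", "y"]


def compute_ma(hyb: Hybridization, background_subtract: bool = False) -> pd.DataFrame:
    """MA values of a (QC-filtered) hybridization.

    M = log2(fg_ch1 / fg_ch2), A = (log2 fg_ch1 + log2 fg_ch2) / 2.  Spots
    with a nonpositive intensity in either channel are dropped; the count
    is logged and stored in ``result.attrs["n_dropped_nonpositive"]``.
    With ``background_subtract`` the per-channel background median is
    subtracted first (documented switch; off by default).
    """
    s = hyb.spots
    ch1 = s["fg_median_ch1"].to_numpy(dtype=float)
    ch2 = s["fg_median_ch2"].to_numpy(dtype=float)
    if background_subtract:
        ch1 = ch1 - s["bg_median_ch1"].to_numpy(dtype=float)
        ch2 = ch2 - s["bg_median_ch2"].to_numpy(dtype=float)
    ok = (ch1 > 0) & (ch2 > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("%s: dropped %d spots with nonpositive intensity",
                    hyb.array_id, n_dropped)
    l1 = np.log2(ch1[ok])
    l2 = np.log2(ch2[ok])
    out = pd.DataFrame({
        "probe_id": s.loc[ok, "probe_id"].to_numpy(),
        "M": l1 - l2,
        "A": (l1 + l2) / 2.0,
        "x": s.loc[ok, "x"].to_numpy(dtype=float),
        "y": s.loc[ok, "y"].to_numpy(dtype=float),
    })
    out.attrs["n_dropped_nonpositive"] = n_dropped
    return out


def intensity_normalize(points: pd.DataFrame,
                        span: float = DEFAULT_INTENSITY_SPAN,
                        iterations: int = 0) -> pd.DataFrame:
    """Replace M by the residual from a loess fit of M on A."""
    if not 0.0 < span <= 1.0:
        raise ValueError(f"span must be in (0, 1], got {span}")
    if len(points) < 10:
        raise ValueError("need at least 10 points for intensity loess")
    fit = lowess(points["M"].to_numpy(), points["A"].to_numpy(),
                 frac=span, it=iterations, delta=0.0, return_sorted=False)
    out = points.copy()
    out["M"] = points["M"].to_numpy() - fit
    return out


def _local_surface(x: np.ndarray, y: np.ndarray, z: np.ndarray,
                   k: int, iterations: int) -> np.ndarray:
    """Leave-one-out degree-1 local regression surface over (x, y).

    For each point, fit a tricube-weighted plane through its k nearest
    neighbors (the point itself excluded) and evaluate it at the point.
    """
    n = len(x)
    pts = np.column_stack([x, y])
    tree = cKDTree(pts)
    dist, idx = tree.query(pts, k=min(k + 1, n))
    # drop the self column (distance 0; with duplicate coordinates the self
    # index may not come first, so remove by index match)
    self_col = idx == np.arange(n)[:, None]
    first_self = self_col.argmax(axis=1)
    keep = np.ones_like(idx, dtype=bool)
    keep[np.arange(n), first_self] = False
    kk = idx.shape[1] - 1
    idx = idx[keep].reshape(n, kk)
    dist = dist[keep].reshape(n, kk)

    dmax = dist[:, -1]
    dmax = np.where(dmax <= 0, 1.0, dmax) * (1.0 + 1e-9)
    w = (1.0 - (dist / dmax[:, None]) ** 3) ** 3
    w = np.clip(w, 0.0, None)

    dx = x[idx] - x[:, None]
    dy = y[idx] - y[:, None]
    B = np.stack([np.ones_like(dx), dx, dy], axis=2)  # (n, k, 3)
    znb = z[idx]

    rw = np.ones(n)  # robustness weights, per point
    fitted = np.zeros(n)
    for it in range(iterations + 1):
        wt = w * rw[idx]
        G = np.einsum("nki,nk,nkj->nij", B, wt, B)
        # tiny ridge keeps degenerate neighborhoods solvable without
        # perturbing well-posed fits
        G += 1e-10 * np.eye(3)
        rhs = np.einsum("nki,nk->ni", B, wt * znb)
        beta = np.linalg.solve(G, rhs[..., None])[..., 0]
        fitted = beta[:, 0]
        if it == iterations:
            break
        resid = z - fitted
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        u = np.clip(resid / (6.0 * s), -1.0, 1.0)
        rw = (1.0 - u ** 2) ** 2
    return fitted


def spatial_normalize(points: pd.DataFrame,
                      span: float = DEFAULT_SPATIAL_SPAN,
                      iterations: int = 0) -> pd.DataFrame:
    """Replace M by the residual from a local-regression surface over the
    slide coordinates.

    The neighborhood size is ``k = round(span * n)`` spots, widened to
    :data:`MIN_SPATIAL_NEIGHBORS` with a warning when the span would give
    fewer effective neighbors.
    """
    if not 0.0 < span <= 1.0:
        raise ValueError(f"span must be in (0, 1], got {span}")
    n = len(points)
    x = points["x"].to_numpy(dtype=float)
    y = points["y"].to_numpy(dtype=float)
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("degenerate coordinates: all spots at one location")
    k = int(round(span * n))
    if k < MIN_SPATIAL_NEIGHBORS:
        warnings.warn(
            f"span {span} gives only {k} neighbors at n={n}; "
            f"widening to {MIN_SPATIAL_NEIGHBORS}", stacklevel=2)
        k = MIN_SPATIAL_NEIGHBORS
    k = min(k, n - 1)
    fit = _local_surface(x, y, points["M"].to_numpy(dtype=float), k, iterations)
    out = points.copy()
    out["M"] = points["M"].to_numpy() - fit
    return out


def normalize_hybridization(hyb: Hybridization,
                            intensity_span: float = DEFAULT_INTENSITY_SPAN,
                            spatial_span: float = DEFAULT_SPATIAL_SPAN,
                            iterations: int = 0,
                            background_subtract: bool = False) -> pd.DataFrame:
    """MA computation followed by the fixed two-pass normalization
    (intensity loess, then spatial surface)."""
    ma = compute_ma(hyb, background_subtract=background_subtract)
    ma = intensity_normalize(ma, span=intensity_span, iterations=iterations)
    ma = spatial_normalize(ma, span=spatial_span, iterations=iterations)
    return ma
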