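"""Per-gene differential expression from dye-swapped direct comparisons.

Each array contributes one orientation-corrected log2 ratio per gene; the
per-gene model is a one-sample mean across arrays (the direct-design linear
model), with empirical-Bayes variance moderation: per-gene sample variances
are shrunk toward a common prior s0² with prior degrees of freedom d0,
estimated by moment-matching the marginal distribution of log s² against a
scaled-F model.  Significance is assessed by the moderated t-statistic with
d0 + d_g degrees of freedom, Benjamini-Hochberg q-values, and an empirical
permutation FDR whose null is generated by randomly flipping each array's
dye orientation — the natural exchangeable null for a direct two-color
design.  A median-based fold-change estimator is computed alongside as a
second, independent estimator, and their concordance is always reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MIN_ARRAYS_PER_GENE = 2


@dataclass
class ExpressionMatrix:
    """Genes x arrays matrix of normalized M with array metadata.

    ``values`` may contain NaN for QC-dropped spots; genes need at least
    :data:`MIN_ARRAYS_PER_GENE` non-missing arrays to be testable.
    """

    values: pd.DataFrame
    orientations: np.ndarray
    batches: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.orientations = np.asarray(self.orientations, dtype=int)
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 arrays")
        if len(self.orientations) != self.values.shape[1]:
            raise ValueError("orientations length != number of arrays")
        if not np.all(np.isin(self.orientations, (-1, 1))):
            raise ValueError("orientations must be +1/-1")
        if not self.batches:
            self.batches = ["batch1"] * self.values.shape[1]

    @property
    def oriented(self) -> np.ndarray:
        """Orientation-corrected values: positive = higher in genotype A."""
        return self.values.to_numpy(dtype=float) * self.orientations


def assemble_matrix(ma_tables, hybs) -> ExpressionMatrix:
    """Pivot per-array normalized MA tables into a genes x arrays matrix."""
    cols = {}
    for ma, hyb in zip(ma_tables, hybs):
        cols[hyb.array_id] = ma.set_index("probe_id")["M"]
    values = pd.DataFrame(cols)
    return ExpressionMatrix(
        values=values,
        orientations=np.array([h.orientation for h in hybs], dtype=int),
        batches=[h.batch for h in hybs],
    )


def fit_contrast(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Ordinary per-gene fit: orientation-corrected mean, variance, df.

    Genes with fewer than two non-missing arrays are flagged untestable
    (NaN statistics).  Raises if no gene is testable.
    """
    Y = matrix.oriented
    n_g = np.sum(~np.isnan(Y), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fc = np.nanmean(Y, axis=1)
        s2 = np.nanvar(Y, axis=1, ddof=1)
        med = np.nanmedian(Y, axis=1)
    testable = n_g >= MIN_ARRAYS_PER_GENE
    if not testable.any():
        raise ValueError("no testable genes (all have < 2 non-missing arrays)")
    fc[~testable] = np.nan
    s2[~testable] = np.nan
    med[~testable] = np.nan
    return pd.DataFrame({
        "log2fc": fc,
        "median_fc": med,
        "s2": s2,
        "df": np.where(testable, n_g - 1, 0),
        "n_arrays": n_g,
        "testable": testable,
    }, index=matrix.values.index)


def _trigamma_inverse(t: float) -> float:
    """Solve trigamma(x) = t for x > 0 by Newton iteration."""
    if t <= 0:
        return np.inf
    if t > 1e7:
        return 1.0 / np.sqrt(t)
    if t < 1e-6:
        return 1.0 / t
    x = 0.5 + 1.0 / t
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / t) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def moderate_variances(s2, df):
    """Empirical-Bayes moderation of per-gene variances.

    Moment-matches log s² against a scaled-F model: with e_g = log s²_g -
    digamma(d_g/2) + log(d_g/2), the marginal mean and variance of e give
    digamma/trigamma equations for (d0, s0²).  Returns (d0, s0²,
    posterior variances).  When the trigamma equation has no positive
    solution the prior df is infinite and all variances shrink to the
    common value exp(mean e).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (df >= 1) & (s2 > 0)
    if ok.sum() < 10:
        warnings.warn("fewer than 10 usable variances; using pooled variance")
        s02 = float(np.nanmean(s2[ok])) if ok.any() else np.nan
        return np.inf, s02, np.full_like(s2, s02)
    z = np.log(s2[ok])
    e = z - special.digamma(df[ok] / 2.0) + np.log(df[ok] / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1)
    t2 = evar - np.mean(special.polygamma(1, df[ok] / 2.0))
    if t2 > 0:
        d0 = 2.0 * _trigamma_inverse(t2)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no detectable gene-to-gene variance heterogeneity: infinite prior
        # df, all variances shrink to the pooled sample variance
        d0 = np.inf
        s02 = float(np.mean(s2[ok]))
    s2_post = posterior_variances(s2, df, d0, s02)
    return d0, s02, s2_post


def posterior_variances(s2, df, d0, s02):
    """Shrunken variances (d0*s0² + d*s²)/(d0 + d); s² itself at d0 = 0."""
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    if np.isinf(d0):
        return np.where(np.isfinite(s2), s02, np.nan)
    if d0 == 0:
        return s2.copy()
    return (d0 * s02 + df * s2) / (d0 + df)


def moderated_t(fc, s2_post, n, df_total):
    """Moderated t and two-sided p from the t distribution."""
    fc = np.asarray(fc, dtype=float)
    n = np.asarray(n, dtype=float)
    s2_post = np.asarray(s2_post, dtype=float)
    df_total = np.asarray(df_total, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fc / np.sqrt(s2_post / n)
    p = np.full_like(t, np.nan)
    fin = np.isfinite(t)
    dfin = np.where(np.isfinite(df_total), df_total, 1e12)
    p[fin] = 2.0 * stats.t.sf(np.abs(t[fin]), dfin[fin])
    return t, p


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (NaN-tolerant)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _moderated_t_for(Xz, mask, n_g, Sx2, signs, d0=None, s02=None):
    """Moderated |t| for one sign-flip pattern, from precomputed sums."""
    fc = (Xz @ signs) / n_g
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = np.clip(Sx2 - n_g * fc ** 2, 0.0, None) / (n_g - 1)
    df = n_g - 1.0
    if d0 is None:
        d0, s02, s2_post = moderate_variances(s2, df)
    else:
        s2_post = posterior_variances(s2, df, d0, s02)
    t, _ = moderated_t(fc, s2_post, n_g, df + (0 if np.isinf(d0) else d0))
    return t


def permutation_fdr(matrix: ExpressionMatrix, n_perm: int = 200,
                    seed: int = 0, t_obs=None):
    """Empirical FDR from a dye-orientation sign-flip null.

    The null distribution pools moderated |t| over ``n_perm`` random sign
    patterns of the arrays (identity excluded).  For threshold τ, FDR(τ) =
    mean null count of |t| >= τ over the observed count, capped at 1; the
    per-gene value is the monotonized estimate at that gene's own |t|
    (minimum over all thresholds at or below it, q-value style).
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    J = matrix.values.shape[1]
    if J < 4:
        warnings.warn(f"only {J} arrays: sign-flip null space is small")
    rng = np.random.default_rng(seed)

    Y = matrix.oriented
    mask = ~np.isnan(Y)
    n_g = mask.sum(axis=1)
    testable = n_g >= MIN_ARRAYS_PER_GENE
    Xz = np.where(mask, Y, 0.0)
    Sx2 = (Xz ** 2).sum(axis=1)

    safe_n = np.where(testable, n_g, np.nan)
    if t_obs is None:
        t_obs = _moderated_t_for(Xz, mask, safe_n, Sx2, np.ones(J))
    t_obs = np.asarray(t_obs, dtype=float)

    abs_obs = np.abs(t_obs[np.isfinite(t_obs)])
    abs_obs_sorted = np.sort(abs_obs)
    null_all = []
    identity = np.ones(J, dtype=int)
    for _ in range(n_perm):
        while True:
            signs = rng.choice((-1, 1), size=J)
            if not np.array_equal(signs, identity):
                break
        t_null = _moderated_t_for(Xz, mask, safe_n, Sx2, signs)
        null_all.append(np.abs(t_null[np.isfinite(t_null)]))
    null_sorted = np.sort(np.concatenate(null_all))

    fdr = np.full_like(t_obs, np.nan)
    fin = np.isfinite(t_obs)
    at = np.abs(t_obs[fin])
    n_null_ge = len(null_sorted) - np.searchsorted(null_sorted, at, side="left")
    n_obs_ge = len(abs_obs_sorted) - np.searchsorted(abs_obs_sorted, at, side="left")
    raw = np.minimum((n_null_ge / n_perm) / np.maximum(n_obs_ge, 1), 1.0)
    # monotonize: running minimum from the smallest |t| upward
    order = np.argsort(at)
    run = np.minimum.accumulate(raw[order])
    mono = np.empty_like(raw)
    mono[order] = run
    fdr[fin] = mono
    return fdr


def batch_concordance(matrix: ExpressionMatrix):
    """Spearman correlation of per-batch fold-change estimates.

    Returns a dict mapping (batch_i, batch_j) -> rho for every batch pair,
    or an empty dict with a single batch.
    """
    batches = np.asarray(matrix.batches)
    uniq = list(dict.fromkeys(batches))
    if len(uniq) < 2:
        return {}
    Y = matrix.oriented
    fcs = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for b in uniq:
            fcs[b] = np.nanmean(Y[:, batches == b], axis=1)
    out = {}
    for i, bi in enumerate(uniq):
        for bj in uniq[i + 1:]:
            ok = np.isfinite(fcs[bi]) & np.isfinite(fcs[bj])
            rho = stats.spearmanr(fcs[bi][ok], fcs[bj][ok])[0]
            out[(bi, bj)] = float(rho)
    return out


def contrast_result(matrix: ExpressionMatrix, n_perm: int = 200,
                    seed: int = 0) -> pd.DataFrame:
    """Full per-gene contrast table.

    Columns: log2fc (orientation-corrected mean), median_fc (the
    median-based alternative estimator), s2, df, t (moderated), p, q (BH),
    perm_fdr.  The shared prior (d0, s0²) is stored in ``result.attrs``.
    """
    fit = fit_contrast(matrix)
    d0, s02, s2_post = moderate_variances(fit["s2"], fit["df"])
    df_total = fit["df"].to_numpy(dtype=float) + (0.0 if np.isinf(d0) else d0)
    df_total[~fit["testable"].to_numpy()] = np.nan
    t, p = moderated_t(fit["log2fc"], s2_post, fit["n_arrays"], df_total)
    q = bh_fdr(p)
    perm = permutation_fdr(matrix, n_perm=n_perm, seed=seed, t_obs=t)
    out = fit.copy()
    out["s2_post"] = s2_post
    out["t"] = t
    out["p"] = p
    out["q"] = q
    out["perm_fdr"] = perm
    out.attrs["d0"] = float(d0) if np.isfinite(d0) else np.inf
    out.attrs["s02"] = float(s02)
    logger.info("contrast: %d/%d testable genes, d0=%.3g s02=%.3g",
                int(fit["testable"].sum()), len(fit), d0, s02)
    return out
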