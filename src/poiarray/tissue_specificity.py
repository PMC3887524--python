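"""Tissue-specificity classification from an expression atlas.

Genes are called tissue-specific with the τ index computed over a
20-tissue atlas: τ = Σ(1 - x̂ᵢ)/(N - 1) with x̂ᵢ = xᵢ/max(x), 0 for a
uniformly expressed gene and 1 for single-tissue expression.  Following the
standard preprocessing for presence/absence-called atlases, "absent"
entries are set to an expression level of 1 and, when several probe sets
map to one gene, only the probe set with the strongest total signal across
tissues is kept.  τ is computed on log2-transformed values, so the absent
floor maps to 0 and fold-differences among well-expressed tissues are
downweighted; a raw-scale switch is provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 20-tissue nonredundant atlas panel.
TISSUES = (
    "adult brain",
    "adult accessory gland",
    "adult crop",
    "adult eye",
    "adult fat body",
    "adult hindgut",
    "adult heart",
    "adult midgut",
    "adult salivary gland",
    "adult thoracicoabdominal ganglion",
    "ejaculatory duct",
    "female spermathecaea",
    "larval central nervous system",
    "larval hindgut",
    "larval midgut",
    "larval salivary gland",
    "larval trachea",
    "larval malpighian tubules",
    "ovary",
    "testes",
)


@dataclass
class TissueAtlas:
    """Probe-set x tissue expression values with presence calls.

    ``values`` and ``present`` are aligned DataFrames indexed by probe set;
    ``genes`` maps probe set -> gene id.  After :func:`preprocess_atlas`
    there is exactly one row per gene and all values are >= 1.
    """

    values: pd.DataFrame
    present: pd.DataFrame
    genes: pd.Series

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.present.columns):
            raise ValueError("values/present tissue columns differ")
        if not self.values.index.equals(self.present.index):
            raise ValueError("values/present probe-set indices differ")
        if not self.values.index.equals(self.genes.index):
            raise ValueError("genes index does not match probe sets")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate probe-set ids")

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)


def preprocess_atlas(raw: TissueAtlas) -> TissueAtlas:
    """Apply absent-call flooring and probe-set collapsing.

    Entries with an "absent" call are set to 1, all values are floored at 1,
    and for genes with multiple probe sets only the one with the largest
    total signal across tissues is retained (ties: first listed).  The
    result has one row per gene, indexed by gene id.
    """
    values = raw.values.where(raw.present, other=1.0).clip(lower=1.0)
    totals = values.sum(axis=1)
    order = pd.DataFrame({"gene": raw.genes, "total": totals})
    keep = order.groupby("gene", sort=False)["total"].idxmax()
    dropped = len(values) - len(keep)
    if dropped:
        logger.info("probe-set collapse: dropped %d redundant probe sets", dropped)
    values = values.loc[keep]
    present = raw.present.loc[keep]
    genes = raw.genes.loc[keep]
    values.index = genes.to_numpy()
    present.index = genes.to_numpy()
    out_genes = pd.Series(genes.to_numpy(), index=genes.to_numpy(), name="gene_id")
    return TissueAtlas(values=values, present=present, genes=out_genes)


def tau(profile, log_transform: bool = True) -> float:
    """τ specificity index of one expression profile (values >= 1).

    With ``log_transform`` (the default) the index is computed on log2
    values, so tissues at the absent floor of 1 contribute their full
    weight.  A profile that is entirely at the floor has no expression
    signal and returns 0 by convention.
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("profile must be 1-D with at least two tissues")
    if (x < 1.0 - 1e-12).any():
        raise ValueError("profile values must be >= 1 (preprocess first)")
    if log_transform:
        x = np.log2(x)
    xmax = x.max()
    if xmax <= 0.0:
        return 0.0
    xhat = x / xmax
    return float(np.sum(1.0 - xhat) / (x.size - 1))


def enrichment_score(profile, tissue: str, tissues=TISSUES) -> float:
    """log2 expression in ``tissue`` minus the mean log2 over other tissues."""
    tissues = list(tissues)
    if tissue not in tissues:
        raise KeyError(f"tissue {tissue!r} not in atlas")
    x = np.log2(np.asarray(profile, dtype=float))
    i = tissues.index(tissue)
    others = np.delete(x, i)
    return float(x[i] - others.mean())


def classify_specific(atlas: TissueAtlas, cutoff: float = 0.9,
                      log_transform: bool = True) -> pd.DataFrame:
    """Per-gene specificity calls from a preprocessed atlas.

    A gene is specific iff τ strictly exceeds ``cutoff`` and the maximal
    tissue is unique; the called tissue is the argmax.  The result also
    carries a per-tissue quantitative enrichment score (log2 ratio of the
    tissue to the mean of the others).
    """
    V = atlas.values.to_numpy(dtype=float)
    tissues = atlas.tissues
    taus = np.array([tau(row, log_transform=log_transform) for row in V])
    arg = V.argmax(axis=1)
    n_at_max = (V == V.max(axis=1, keepdims=True)).sum(axis=1)
    unique_max = n_at_max == 1
    specific = (taus > cutoff) & unique_max

    logV = np.log2(V)
    total = logV.sum(axis=1)
    nt = len(tissues)
    # score for tissue i: log2 v_i - (total - log2 v_i)/(nt - 1)
    enrich = logV - (total[:, None] - logV) / (nt - 1)

    out = pd.DataFrame({
        "gene_id": atlas.values.index,
        "tau": taus,
        "argmax_tissue": [tissues[i] for i in arg],
        "specific": specific,
    })
    for i, t in enumerate(tissues):
        out[f"enrichment:{t}"] = enrich[:, i]
    return out
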