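"""Statistical battery applied to differential-expression results.

Chromosomal-distribution goodness-of-fit tests with mapped-only
denominators, 2x2 odds-ratio/Fisher tests for class-by-direction
enrichment, Mann-Whitney group-shift tests, Spearman concordance, standard
major axis (SMA) regression, and direction-bias binomial tests.  Fisher
exact p-values are two-sided by summation of table probabilities at or
below the observed table; χ² goodness-of-fit is uncorrected by default
with a Yates-corrected 2-category variant available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import ARMS

MAPPED_ARMS = tuple(a for a in ARMS if a != "Other")


@dataclass
class TestReport:
    """One statistical test: name, inputs, statistic(s), p-value, notes."""

    name: str
    statistic: dict
    p: float | None
    inputs: dict = field(default_factory=dict)
    notes: str = ""

    def to_row(self) -> dict:
        row = {"test": self.name, "p": self.p, "notes": self.notes}
        for k, v in self.statistic.items():
            row[k] = v
        row["inputs"] = ";".join(f"{k}={v}" for k, v in self.inputs.items())
        return row


def contingency_test(a: int, b: int, c: int, d: int,
                     name: str = "fisher_2x2") -> TestReport:
    """Odds ratio and two-sided Fisher exact test of a 2x2 table.

    The table is [[a, b], [c, d]] with rows = direction (or class 1 vs 2)
    and columns = class A vs B.  OR = ad/(bc), undefined (None) when b or c
    is zero.
    """
    counts = (a, b, c, d)
    if any(v < 0 for v in counts):
        raise ValueError("negative counts")
    if sum(counts) == 0:
        raise ValueError("empty table")
    orr = (a * d) / (b * c) if (b > 0 and c > 0) else None
    p = float(stats.fisher_exact([[a, b], [c, d]])[1])
    return TestReport(
        name=name,
        statistic={"odds_ratio": orr},
        p=p,
        inputs={"a": a, "b": b, "c": c, "d": d},
        notes="OR undefined (zero margin cell)" if orr is None else "",
    )


def chisq_gof(observed, expected_proportions, yates: bool = False,
              name: str = "chisq_gof") -> TestReport:
    """χ² goodness-of-fit of observed counts against expected proportions.

    ``yates``: continuity-corrected variant for 2-category tests (the
    one-arm-vs-rest convenience form).
    """
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if obs.shape != props.shape:
        raise ValueError("observed and proportions differ in length")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {props.sum()}, not 1")
    total = obs.sum()
    if total <= 0:
        raise ValueError("observed total must be > 0")
    exp = total * props
    if (exp == 0).any():
        raise ValueError("expected count of 0")
    diff = np.abs(obs - exp)
    if yates:
        if obs.size != 2:
            raise ValueError("Yates correction applies to 2 categories")
        diff = np.clip(diff - 0.5, 0.0, None)
    chi2 = float(np.sum(diff ** 2 / exp))
    p = float(stats.chi2.sf(chi2, df=obs.size - 1))
    return TestReport(
        name=name,
        statistic={"chi2": chi2, "df": obs.size - 1},
        p=p,
        inputs={"observed": list(map(int, obs)), "total": int(total)},
        notes="Yates-corrected" if yates else "",
    )


def mannwhitney_shift(group, rest, name: str = "mannwhitney") -> TestReport:
    """Two-sided Mann-Whitney test of a group against the rest.

    Exact for small untied samples, otherwise the normal approximation
    with tie correction.  Reports both medians and their difference.
    """
    g = np.asarray(group, dtype=float)
    r = np.asarray(rest, dtype=float)
    g = g[np.isfinite(g)]
    r = r[np.isfinite(r)]
    if g.size == 0 or r.size == 0:
        raise ValueError("both groups must be nonempty")
    u, p = stats.mannwhitneyu(g, r, alternative="two-sided")
    return TestReport(
        name=name,
        statistic={
            "U": float(u),
            "median_group": float(np.median(g)),
            "median_rest": float(np.median(r)),
            "median_difference": float(np.median(g) - np.median(r)),
        },
        p=float(p),
        inputs={"n_group": g.size, "n_rest": r.size},
    )


def spearman_corr(x, y, name: str = "spearman") -> TestReport:
    """Spearman rank correlation (average ranks for ties, t-approx p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y differ in length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return TestReport(
        name=name,
        statistic={"rho": float(rho)},
        p=float(p),
        inputs={"n": int(x.size)},
    )


def sma_fit(x, y, name: str = "sma_regression") -> TestReport:
    """Standard major axis regression: slope = sign(r) * sd(y)/sd(x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired values")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance")
    r = np.corrcoef(x, y)[0, 1]
    slope = float(np.sign(r) * sy / sx) if r != 0 else float(sy / sx)
    intercept = float(y.mean() - slope * x.mean())
    return TestReport(
        name=name,
        statistic={"slope": slope, "intercept": intercept, "r": float(r)},
        p=None,
        inputs={"n": int(x.size)},
    )


def chromosome_table(de_genes, all_genes, annotation: pd.DataFrame,
                     alpha: float = 0.05):
    """Chromosomal distribution of differentially expressed genes.

    Counts per arm (including unmapped "Other"), percentages over mapped
    genes only, and a per-arm 2-category χ² goodness-of-fit of the DE set
    against the all-genes proportions, flagged at a BH-adjusted ``alpha``.
    Returns (table DataFrame, list of per-arm TestReports).
    """
    ann = annotation.set_index("gene_id")["arm"] \
        if "gene_id" in annotation.columns else annotation["arm"]
    de_genes = list(de_genes)
    all_genes = list(all_genes)
    missing = [g for g in all_genes if g not in ann.index]
    if missing:
        raise KeyError(f"genes without annotation, e.g. {missing[:3]}")
    arm_all = ann.loc[all_genes]
    arm_de = ann.loc[de_genes]

    counts_all = arm_all.value_counts().reindex(ARMS, fill_value=0)
    counts_de = arm_de.value_counts().reindex(ARMS, fill_value=0)
    mapped_all = int(counts_all[list(MAPPED_ARMS)].sum())
    mapped_de = int(counts_de[list(MAPPED_ARMS)].sum())

    pct_all = {a: 100.0 * counts_all[a] / mapped_all if mapped_all else np.nan
               for a in MAPPED_ARMS}
    pct_de = {a: 100.0 * counts_de[a] / mapped_de if mapped_de else np.nan
              for a in MAPPED_ARMS}

    reports: list[TestReport] = []
    pvals = []
    if len(de_genes) > 0:
        for a in ARMS:
            if a == "Other":
                prop = counts_all[a] / len(all_genes)
                obs = [counts_de[a], len(de_genes) - counts_de[a]]
            else:
                if mapped_all == 0 or mapped_de == 0:
                    continue
                prop = counts_all[a] / mapped_all
                obs = [counts_de[a], mapped_de - counts_de[a]]
            if prop in (0.0, 1.0):
                continue
            rep = chisq_gof(obs, [prop, 1.0 - prop],
                            name=f"chisq_arm_{a}")
            reports.append(rep)
            pvals.append(rep.p)
        from .differential_expression import bh_fdr
        qs = bh_fdr(np.array(pvals))
        for rep, q in zip(reports, qs):
            rep.statistic["q_bh"] = float(q)
            rep.statistic["flagged"] = bool(q < alpha)

    flagged = {rep.name.replace("chisq_arm_", ""): rep.statistic.get("flagged", False)
               for rep in reports}
    table = pd.DataFrame({
        "arm": list(ARMS),
        "n_all": [int(counts_all[a]) for a in ARMS],
        "pct_all_mapped": [pct_all.get(a, np.nan) for a in ARMS],
        "n_de": [int(counts_de[a]) for a in ARMS],
        "pct_de_mapped": [pct_de.get(a, np.nan) for a in ARMS],
        "flagged": [bool(flagged.get(a, False)) for a in ARMS],
    })
    return table, reports


def direction_bias(de_results: pd.DataFrame, gene_class,
                   alpha: float = 0.05, fdr_column: str = "q",
                   name: str = "direction_bias") -> TestReport:
    """Down/up bias among significant genes of a class.

    ``gene_class`` is a boolean mask aligned with ``de_results`` marking
    class membership.  Positive log2fc counts as "down" in the genotype
    inheriting the paternal X / maternal Y (the ratio numerator genotype is
    higher).  Reports k down of n significant class members, the
    class-vs-rest x down-vs-up Fisher p, and the within-class exact
    binomial p against 0.5.
    """
    cls = np.asarray(gene_class, dtype=bool)
    if len(cls) != len(de_results):
        raise ValueError("gene_class length mismatch")
    sig = (de_results[fdr_column].to_numpy() < alpha) & \
        de_results["testable"].to_numpy()
    down = de_results["log2fc"].to_numpy() > 0
    n_cls_sig = int((sig & cls).sum())
    if n_cls_sig == 0:
        return TestReport(name=name, statistic={"k_down": None, "n": 0},
                          p=None, notes="NA: class absent from significant set")
    k_down = int((sig & cls & down).sum())
    a = k_down
    b = int((sig & ~cls & down).sum())
    c = n_cls_sig - k_down
    d = int((sig & ~cls & ~down).sum())
    fisher = contingency_test(a, b, c, d)
    binom_p = float(stats.binomtest(k_down, n_cls_sig, 0.5).pvalue)
    return TestReport(
        name=name,
        statistic={
            "k_down": k_down,
            "n": n_cls_sig,
            "frac_down": k_down / n_cls_sig,
            "odds_ratio": fisher.statistic["odds_ratio"],
            "fisher_p": fisher.p,
        },
        p=binom_p,
        inputs={"a": a, "b": b, "c": c, "d": d, "alpha": alpha},
    )


def build_report(reports) -> pd.DataFrame:
    """Flatten a list of TestReports into one tidy table."""
    return pd.DataFrame([r.to_row() for r in reports])
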