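"""End-to-end orchestration: simulate -> QC -> normalize -> DE ->
specificity -> statistics.

Every stage reads and writes plain tab-delimited files in a run directory,
so stages are independently runnable (see :mod:`poiarray.cli`).  A manifest
records the configuration hash and seed; identical configuration and seed
give byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import array_io
from .differential_expression import assemble_matrix, batch_concordance, contrast_result
from .enrichment_stats import (
    TestReport, build_report, chromosome_table, contingency_test,
    direction_bias, mannwhitney_shift, spearman_corr,
)
from .normalization import (
    DEFAULT_INTENSITY_SPAN, DEFAULT_SPATIAL_SPAN, normalize_hybridization,
)
from .spot_qc import filter_hybridization
from .synthetic_data import SimulationConfig, simulate_experiment
from .tissue_specificity import classify_specific, preprocess_atlas

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    Either ``simulate`` holds a :class:`SimulationConfig` or the three
    input paths point at existing spot tables, annotation and atlas.
    """

    simulate: SimulationConfig | None = None
    spot_table_paths: list = field(default_factory=list)
    annotation_path: str | None = None
    atlas_path: str | None = None
    qc: bool = True
    intensity_span: float = DEFAULT_INTENSITY_SPAN
    spatial_span: float = DEFAULT_SPATIAL_SPAN
    fdr_method: str = "bh"
    n_perm: int = 200
    alpha: float = 0.05
    tau_cutoff: float = 0.9
    seed: int = 0
    outdir: str = "poiarray_run"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("intensity_span", "spatial_span"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.fdr_method not in ("bh", "permutation"):
            raise ValueError("fdr_method must be 'bh' or 'permutation'")
        if self.simulate is None and not self.spot_table_paths:
            raise ValueError("either a simulate block or input paths required")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_dict()
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            if "grid_shape" in sim:
                sim["grid_shape"] = tuple(sim["grid_shape"])
            if sim.get("dye_swap_pattern") is not None:
                sim["dye_swap_pattern"] = tuple(sim["dye_swap_pattern"])
            sim = SimulationConfig(**sim)
        return cls(simulate=sim, **raw)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write tables, report and manifest to
    ``config.outdir``.  Returns a dict of in-memory results."""
    os.makedirs(config.outdir, exist_ok=True)
    out = lambda name: os.path.join(config.outdir, name)  # noqa: E731

    # --- inputs -----------------------------------------------------------
    try:
        if config.simulate is not None:
            catalog, truth, atlas, hybs = simulate_experiment(config.simulate)
            array_io.write_annotation_table(catalog, out("annotation.tsv"))
            array_io.write_truth_table(truth, out("truth.tsv"))
        else:
            truth = None
            hybs = [array_io.read_spot_table(p) for p in config.spot_table_paths]
            catalog = (array_io.read_annotation_table(config.annotation_path)
                       if config.annotation_path else None)
            atlas = (array_io.read_atlas_table(config.atlas_path)
                     if config.atlas_path else None)
    except (OSError, ValueError) as exc:
        raise StageError(f"input stage failed: {exc}") from exc

    # --- QC ---------------------------------------------------------------
    qc_reports = []
    if config.qc:
        filtered = []
        for hyb in hybs:
            fh, rep = filter_hybridization(hyb)
            filtered.append(fh)
            qc_reports.append(rep)
            logger.info("qc %s: %d/%d spots retained", hyb.array_id,
                        rep["n_passed"], rep["n_spots"])
        hybs = filtered
        array_io.write_qc_report(qc_reports, out("qc_report.tsv"))

    # --- normalization ----------------------------------------------------
    try:
        ma_tables = []
        for hyb in hybs:
            ma = normalize_hybridization(
                hyb, intensity_span=config.intensity_span,
                spatial_span=config.spatial_span)
            ma_tables.append(ma)
            array_io.write_ma_table(ma, out(f"ma_{hyb.array_id}.tsv"))
            logger.info("normalize %s: %d spots", hyb.array_id, len(ma))
    except ValueError as exc:
        raise StageError(f"normalization stage failed: {exc}") from exc

    # --- differential expression -----------------------------------------
    try:
        matrix = assemble_matrix(ma_tables, hybs)
        contrast = contrast_result(matrix, n_perm=config.n_perm,
                                   seed=config.seed)
    except ValueError as exc:
        raise StageError(f"differential-expression stage failed: {exc}") from exc
    concordance = batch_concordance(matrix)

    # --- tissue specificity ----------------------------------------------
    calls = None
    if atlas is not None:
        pre = preprocess_atlas(atlas)
        calls = classify_specific(pre, cutoff=config.tau_cutoff)
        calls.to_csv(out("specificity.tsv"), sep="\t", index=False,
                     float_format="%.12g")

    # --- statistics -------------------------------------------------------
    fdr_col = "perm_fdr" if config.fdr_method == "permutation" else "q"
    reports = statistics_battery(contrast, catalog, calls, alpha=config.alpha,
                                 fdr_column=fdr_col)
    for (bi, bj), rho in concordance.items():
        reports.append(TestReport(name=f"batch_concordance:{bi}:{bj}",
                                  statistic={"rho": rho}, p=None))
    report_df = build_report(reports)
    array_io.write_results(contrast, report_df, out("genes.tsv"),
                           out("stats_report.tsv"), annotation=catalog)

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_arrays": len(hybs),
        "n_genes_tested": int(contrast["testable"].sum()),
        "n_significant": int(((contrast[fdr_col] < config.alpha)
                              & contrast["testable"]).sum()),
    }
    with open(out("manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "catalog": catalog,
        "truth": truth,
        "qc_reports": qc_reports,
        "ma_tables": ma_tables,
        "matrix": matrix,
        "contrast": contrast,
        "specificity": calls,
        "stats_report": report_df,
        "batch_concordance": concordance,
        "manifest": manifest,
    }


def statistics_battery(contrast: pd.DataFrame, catalog: pd.DataFrame | None,
                       calls: pd.DataFrame | None, alpha: float = 0.05,
                       fdr_column: str = "q"):
    """The standard post-DE test battery.

    Chromosomal distribution (per-arm χ² with BH flags), tissue-class
    enrichment among significant genes (Fisher), direction bias within the
    testis and midgut classes, group median-shift Mann-Whitney tests, and
    the concordance of the two fold-change estimators.
    """
    reports = []
    genes = contrast.index

    cls = None
    if calls is not None:
        spec = calls.set_index("gene_id")
        spec_class = pd.Series("", index=spec.index, dtype=object)
        mask = spec["specific"].to_numpy()
        spec_class[mask] = spec.loc[mask, "argmax_tissue"]
        cls = spec_class.reindex(genes).fillna("")
    elif catalog is not None and "tissue_class" in catalog.columns:
        mapping = {"testis": "testes", "midgut": "adult midgut", "none": ""}
        cls = catalog.set_index("gene_id")["tissue_class"].map(mapping)
        cls = cls.reindex(genes).fillna("")

    if catalog is not None and "arm" in catalog.columns:
        sig = (contrast[fdr_column] < alpha) & contrast["testable"]
        de_genes = genes[sig.to_numpy()]
        all_genes = genes[contrast["testable"].to_numpy()]
        table, arm_reports = chromosome_table(de_genes, all_genes, catalog,
                                              alpha=alpha)
        reports.extend(arm_reports)
        reports.append(TestReportTable(table))

    if cls is not None:
        sig = ((contrast[fdr_column] < alpha) & contrast["testable"]).to_numpy()
        fc = contrast["log2fc"].to_numpy()
        for tissue, label in (("testes", "testis"), ("adult midgut", "midgut")):
            member = (cls == tissue).to_numpy()
            # class enrichment among significant genes
            a = int((sig & member).sum())
            b = int((sig & ~member).sum())
            c = int((~sig & member).sum())
            d = int((~sig & ~member).sum())
            if a + c > 0:
                reports.append(contingency_test(
                    a, b, c, d, name=f"{label}_enrichment_in_significant"))
            rep = direction_bias(contrast, member, alpha=alpha,
                                 fdr_column=fdr_column,
                                 name=f"{label}_direction_bias")
            reports.append(rep)
            ok = np.isfinite(fc)
            if (member & ok).any() and (~member & ok).any():
                reports.append(mannwhitney_shift(
                    fc[member & ok], fc[~member & ok],
                    name=f"{label}_median_shift"))

    ok = contrast["testable"].to_numpy()
    reports.append(spearman_corr(
        contrast.loc[ok, "log2fc"], contrast.loc[ok, "median_fc"],
        name="estimator_concordance"))
    return reports


class TestReportTable:
    """Adapter so a chromosome table can ride along in the report list."""

    def __init__(self, table: pd.DataFrame):
        self.name = "chromosome_table"
        self.table = table
        self.statistic = {}
        self.p = None
        self.inputs = {}
        self.notes = "see columns"

    def to_row(self) -> dict:
        flat = {f"{r.arm}:{c}": getattr(r, c) for r in self.table.itertuples()
                for c in ("n_all", "n_de")}
        return {"test": self.name, "p": None, "notes": json.dumps(flat),
                "inputs": ""}
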