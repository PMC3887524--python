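"""Reading and writing the pipeline's tab-delimited tables.

Spot tables use a GenePix-results-like dialect: a tab-delimited UTF-8 file
with a fixed header vocabulary (see :data:`poiarray.types.SPOT_COLUMNS`)
preceded by ``# key=value`` metadata lines carrying the array id, batch and
dye orientation.  A column-mapping dict allows ingesting real exports whose
quantification software names columns differently (e.g. "% > B635+2SD").
Annotation, atlas, truth and result tables are plain tab-delimited files
with headers.  All numeric round trips are lossless at 12+ significant
digits (full ``repr`` precision is written).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .types import ARMS, SPOT_COLUMNS, Hybridization
from .tissue_specificity import TissueAtlas


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


def _read_header_meta(path):
    meta = {}
    n_meta = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_meta += 1
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta, n_meta


def read_spot_table(path, column_map: dict | None = None) -> Hybridization:
    """Read one spot-level array table.

    ``column_map`` maps dialect column names in the file to the canonical
    names (e.g. ``{"% > B635+2SD": "frac_fg_gt_bg2sd_ch1"}``).  Missing
    required columns raise :class:`FormatError` naming the column;
    non-numeric cells raise a parse error with the row number.
    """
    meta, n_meta = _read_header_meta(path)
    df = pd.read_csv(path, sep="\t", skiprows=n_meta, dtype=str)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    df = df[SPOT_COLUMNS].copy()
    for col in SPOT_COLUMNS[1:]:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            rownum = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise FormatError(
                f"non-numeric value in column {col!r} at data row {rownum}")
    for col in ("block", "row", "col", "fg_pixels_ch1", "fg_pixels_ch2"):
        df[col] = df[col].astype(int)
    return Hybridization(
        array_id=meta.get("array_id", os.path.basename(path)),
        batch=meta.get("batch", "batch1"),
        orientation=int(meta.get("orientation", "1")),
        spots=df,
    )


def write_spot_table(hyb: Hybridization, path) -> None:
    """Write one hybridization in the spot-table dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# array_id={hyb.array_id}\n")
        fh.write(f"# batch={hyb.batch}\n")
        fh.write(f"# orientation={hyb.orientation}\n")
        hyb.spots.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_annotation_table(path) -> pd.DataFrame:
    """Gene annotation table: gene_id, arm, optional chromatin_color.

    Duplicate gene ids and arm labels outside the closed vocabulary are
    errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "arm"):
        if col not in df.columns:
            raise FormatError(f"missing required column(s): {col}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"duplicate gene_id {dup!r} in annotation")
    bad = ~df["arm"].isin(ARMS)
    if bad.any():
        raise FormatError(
            f"unknown arm label {df.loc[bad, 'arm'].iloc[0]!r}")
    return df


def write_annotation_table(catalog: pd.DataFrame, path) -> None:
    catalog.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_atlas_table(path) -> TissueAtlas:
    """Tissue atlas in wide form: probe_set_id, gene_id, then one value
    column per tissue and one ``<tissue>.call`` column (P/A)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("probe_set_id", "gene_id"):
        if col not in df.columns:
            raise FormatError(f"missing required column(s): {col}")
    tissues = [c for c in df.columns
               if c not in ("probe_set_id", "gene_id")
               and not c.endswith(".call")]
    for t in tissues:
        if f"{t}.call" not in df.columns:
            raise FormatError(f"missing call column for tissue {t!r}")
    df = df.set_index("probe_set_id")
    values = df[tissues].astype(float)
    present = df[[f"{t}.call" for t in tissues]].eq("P")
    present.columns = tissues
    return TissueAtlas(values=values, present=present,
                       genes=df["gene_id"].rename("gene_id"))


def write_atlas_table(atlas: TissueAtlas, path) -> None:
    out = pd.DataFrame({"probe_set_id": atlas.values.index,
                        "gene_id": atlas.genes.to_numpy()})
    for t in atlas.tissues:
        out[t] = atlas.values[t].to_numpy()
        out[f"{t}.call"] = np.where(atlas.present[t].to_numpy(), "P", "A")
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_annotation_tables(annotation_path, atlas_path):
    """Read the gene annotation and tissue atlas together."""
    return read_annotation_table(annotation_path), read_atlas_table(atlas_path)


def write_ma_table(ma: pd.DataFrame, path) -> None:
    ma.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_ma_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_qc_report(reports, path) -> None:
    pd.DataFrame(reports).to_csv(path, sep="\t", index=False)


def write_results(contrast: pd.DataFrame, report: pd.DataFrame,
                  gene_path, report_path,
                  annotation: pd.DataFrame | None = None) -> None:
    """Write the per-gene result table and the statistical-test report.

    The gene table carries gene, arm, tissue class (when annotation is
    given), log2FC, moderated t, p, BH q and permutation FDR at full
    precision plus a rounded display column for the fold-change.
    """
    out = contrast.copy()
    out.insert(0, "gene_id", out.index)
    if annotation is not None:
        ann = annotation.set_index("gene_id")
        for col in ("arm", "tissue_class", "chromatin_color"):
            if col in ann.columns:
                out.insert(1, col, ann[col].reindex(out.index).to_numpy())
    out["log2fc_display"] = out["log2fc"].astype(float).round(3)
    out.to_csv(gene_path, sep="\t", index=False, float_format="%.12g")
    report.to_csv(report_path, sep="\t", index=False, float_format="%.12g")


def read_results(gene_path) -> pd.DataFrame:
    df = pd.read_csv(gene_path, sep="\t")
    return df.set_index("gene_id")


def write_truth_table(truth, path) -> None:
    """Planted truth as a tab-delimited table (one row per gene, QC-fail
    flags as one column per array)."""
    out = pd.DataFrame({
        "gene_id": truth.effects.index,
        "effect": truth.effects.to_numpy(),
        "tissue_class": truth.tissue_class.to_numpy(),
    })
    for col in truth.qc_fail.columns:
        out[f"qc_fail:{col}"] = truth.qc_fail[col].to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")
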