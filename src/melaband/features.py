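"""Per-patient prognostic factors from gated, band-annotated cells.

Cell categories follow the marker biology: *tumor* cells are S100+,
*colocalized* cells are S100+ and Ki67+ (proliferating tumor cells), and
*total* counts every detected cell inside the tumor. For each band
(superficial/middle/invasive, plus the whole tumor as "overall") the
factor set comprises cell and colocalized-cell densities (cells/mm²),
colocalized-to-total and colocalized-to-tumor ratios, and the mean
nucleus area (µm²) of each category — joined with the clinical factors
(age, mitoses per HPF, Breslow thickness) and the geometry-derived
estimated thickness in mm.

A band with no cells of a category yields a *missing* mean size (never
zero); a ratio with a zero denominator is missing while a zero numerator
over a positive denominator is 0.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from melaband.geometry import BANDS, BandGeometry

logger = logging.getLogger(__name__)

CATEGORIES = ("total", "tumor", "coloc")
FEATURE_BANDS = BANDS + ("overall",)


class PipelineOrderError(RuntimeError):
    """A stage ran before its inputs were attached to the cell table."""


def classify_categories(cells: pd.DataFrame) -> pd.DataFrame:
    """Attach total / tumor / colocalized flags to band-annotated cells."""
    for col in ("ki67_pos", "s100_pos"):
        if col not in cells.columns:
            raise PipelineOrderError(f"cells lack {col!r}; run marker gating first")
    if "band" not in cells.columns:
        raise PipelineOrderError("cells lack 'band'; run band annotation first")
    out = cells.copy()
    out["cat_total"] = out["band"].isin(BANDS).to_numpy()
    out["cat_tumor"] = out["cat_total"] & out["s100_pos"].to_numpy()
    out["cat_coloc"] = out["cat_tumor"] & out["ki67_pos"].to_numpy()
    return out


def band_aggregates(cells: pd.DataFrame, geom: BandGeometry) -> pd.DataFrame:
    """Counts, densities and mean nucleus sizes per band and category.

    One row per (band, category), bands including "overall" (the whole
    tumor; its area is the sum of the band areas). Densities are
    count / band area in mm²; empty category-band intersections get a
    missing mean size.
    """
    if "cat_total" not in cells.columns:
        cells = classify_categories(cells)
    areas = dict(geom.band_areas_mm2)
    areas["overall"] = sum(areas.values())
    rows = []
    for band in FEATURE_BANDS:
        if areas.get(band, 0.0) <= 0.0:
            raise ValueError(f"band {band!r} has zero area")
        in_band = (
            cells["cat_total"]
            if band == "overall"
            else (cells["band"] == band).to_numpy()
        )
        for cat in CATEGORIES:
            sel = in_band & cells[f"cat_{cat}"].to_numpy()
            count = int(sel.sum())
            mean_size = float(cells.loc[sel, "nucleus_area_um2"].mean()) if count else np.nan
            if count == 0:
                logger.warning("no %s cells in band %r", cat, band)
            rows.append(
                {
                    "band": band,
                    "category": cat,
                    "count": count,
                    "area_mm2": areas[band],
                    "density_per_mm2": count / areas[band],
                    "mean_nucleus_area_um2": mean_size,
                }
            )
    return pd.DataFrame(rows)


_SIZE_NAME = {"total": "mean_nuclei_size", "tumor": "mean_tumor_nuclei_size",
              "coloc": "mean_coloc_nuclei_size"}


def assemble_features(
    clinical_row: pd.Series, aggregates: pd.DataFrame, geom: BandGeometry
) -> pd.Series:
    """Assemble one patient's full factor vector.

    Columns follow ``<band>_<factor>`` naming, e.g.
    ``invasive_mean_nuclei_size`` or ``overall_coloc_to_total_ratio``.
    """
    out: dict[str, float] = {
        "patient_id": clinical_row["patient_id"],
        "age": clinical_row["age"],
        "mitosis": clinical_row["mitosis"],
        "thickness_mm": clinical_row["thickness_mm"],
        "estimated_thickness_mm": geom.thickness_mm,
    }
    pivot = aggregates.set_index(["band", "category"])
    for band in FEATURE_BANDS:
        total = pivot.loc[(band, "total")]
        tumor = pivot.loc[(band, "tumor")]
        coloc = pivot.loc[(band, "coloc")]
        out[f"{band}_cell_density"] = total["density_per_mm2"]
        out[f"{band}_coloc_cell_density"] = coloc["density_per_mm2"]
        out[f"{band}_coloc_to_total_ratio"] = (
            coloc["count"] / total["count"] if total["count"] else np.nan
        )
        out[f"{band}_coloc_to_tumor_ratio"] = (
            coloc["count"] / tumor["count"] if tumor["count"] else np.nan
        )
        for cat in CATEGORIES:
            out[f"{band}_{_SIZE_NAME[cat]}"] = pivot.loc[(band, cat)][
                "mean_nucleus_area_um2"
            ]
        for cat in CATEGORIES:  # audit counts
            out[f"{band}_{cat}_count"] = pivot.loc[(band, cat)]["count"]
    return pd.Series(out)


#: the factor columns entered into the survival screen, in report order
FACTOR_COLUMNS = (
    ["mitosis", "thickness_mm", "estimated_thickness_mm", "age"]
    + [f"{b}_coloc_cell_density" for b in ("invasive", "middle", "superficial", "overall")]
    + [f"{b}_cell_density" for b in ("invasive", "middle", "superficial", "overall")]
    + [f"{b}_mean_nuclei_size" for b in ("invasive", "middle", "superficial", "overall")]
    + [f"{b}_mean_tumor_nuclei_size" for b in ("invasive", "middle", "superficial", "overall")]
    + [f"{b}_mean_coloc_nuclei_size" for b in ("invasive", "middle", "superficial", "overall")]
)


def build_feature_table(
    clinical: pd.DataFrame,
    aggregates_by_patient: dict[str, pd.DataFrame],
    geoms_by_patient: dict[str, BandGeometry],
) -> pd.DataFrame:
    """One feature row per patient; clinical patients without a slide are
    logged and excluded (quality-control drop-out)."""
    rows = []
    for _, rec in clinical.iterrows():
        pid = rec["patient_id"]
        if pid not in aggregates_by_patient or pid not in geoms_by_patient:
            logger.warning("patient %s has no slide; excluded from features", pid)
            continue
        rows.append(assemble_features(rec, aggregates_by_patient[pid], geoms_by_patient[pid]))
    return pd.DataFrame(rows).reset_index(drop=True)
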