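"""Factor correlation analysis, publication-style figures, and the
end-to-end pipeline driver.

``run_pipeline`` composes the full analysis on a directory of slides (or
a bundled simulation): marker gating, band segmentation, feature
assembly, univariable and multivariable Cox models, and factor
correlation — writing every table as CSV, model objects as JSON, the
figures as SVG, and a manifest with config hash and seed, so reruns
under a fixed seed are reproducible.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from melaband import features as ft
from melaband import gating, geometry, io, survival, synthetic

logger = logging.getLogger(__name__)

#: significance-star thresholds (p strictly below the threshold)
STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Map a p-value to its star annotation: *, **, *** below
    0.05 / 0.01 / 0.001 respectively, empty otherwise."""
    if np.isnan(p):
        return ""
    for threshold, stars_ in STAR_LEVELS:
        if p < threshold:
            return stars_
    return ""


@dataclass
class CorrelationMatrix:
    factors: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    method: str


def correlation_matrix(
    features: pd.DataFrame,
    factors: list[str] | None = None,
    method: str = "pearson",
) -> CorrelationMatrix:
    """Pairwise complete-case correlation among factors with p-values.

    p-values come from the t-distribution transform of r (exact under
    bivariate normality); each pair needs at least 3 complete
    observations. A constant factor gets a missing row/column.
    """
    if factors is None:
        factors = [c for c in ft.FACTOR_COLUMNS if c in features.columns]
    corr_fn = {"pearson": stats.pearsonr, "spearman": stats.spearmanr}[method]
    k = len(factors)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                if features[factors[i]].dropna().nunique() <= 1:
                    warnings.warn(f"factor {factors[i]!r} is constant", stacklevel=2)
                else:
                    r[i, i], p[i, i] = 1.0, 0.0
                continue
            pair = features[[factors[i], factors[j]]].dropna()
            if len(pair) < 3:
                continue
            x, y = pair[factors[i]], pair[factors[j]]
            if x.nunique() <= 1 or y.nunique() <= 1:
                continue
            res = corr_fn(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    rdf = pd.DataFrame(r, index=factors, columns=factors)
    pdf = pd.DataFrame(p, index=factors, columns=factors)
    sdf = pdf.map(significance_stars)
    return CorrelationMatrix(factors=list(factors), r=rdf, p=pdf, stars=sdf, method=method)


# ---------------------------------------------------------------------------
# figures (side artifacts; every number in them is also written as CSV)


def plot_gate_histogram(gate, values, path: str | Path, bins: int = 100) -> None:
    """Expression histogram with the foreground split, the fitted mixture
    and the final threshold overlaid."""
    values = np.asarray(values, dtype=float)
    values = values[values > 0]
    logv = np.log(values)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(logv, bins=bins, density=True, color="0.8", label="all cells")
    if gate.otsu is not None:
        t1 = logv[logv > gate.otsu.threshold]  # gate Otsu is in log units
        ax.hist(t1, bins=bins, density=True, color="gold", alpha=0.7, label="foreground (T1)")
    if gate.mixture is not None:
        grid = np.linspace(logv.min(), logv.max(), 400)
        total = np.zeros_like(grid)
        frac_t1 = t1.size / logv.size
        for w, m, s in zip(gate.mixture.weights, gate.mixture.means, gate.mixture.sds):
            comp = frac_t1 * w * stats.norm.pdf(grid, m, s)
            ax.plot(grid, comp, color="tab:blue", lw=1)
            total += comp
        ax.plot(grid, total, color="tab:red", lw=1.5, label="mixture fit")
    if gate.final_threshold is not None:
        ax.axvline(np.log(gate.final_threshold), color="green", ls="--", label="threshold")
    ax.set_xlabel(f"log {gate.marker} {gate.compartment} mean intensity")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_band_overlay(annotation, geom, cells: pd.DataFrame | None, path: str | Path) -> None:
    """Tumor band overlay: band regions, invasive margin and, if given,
    the gated cells."""
    fig, ax = plt.subplots(figsize=(6, 5))
    colors = {"superficial": "0.95", "middle": "lightsteelblue", "invasive": "steelblue"}
    for band, mp in geom.band_polygons.items():
        for poly in getattr(mp, "geoms", []):
            xs, ys = poly.exterior.xy
            ax.fill(xs, ys, color=colors[band], label=band)
    xs, ys = annotation.epidermis.exterior.xy
    ax.fill(xs, ys, color="peachpuff", label="epidermis")
    for line in getattr(geom.invasive_margin, "geoms", []):
        lx, ly = line.xy
        ax.plot(lx, ly, color="crimson", lw=2)
    if cells is not None and "s100_pos" in cells.columns:
        tum = cells[cells["s100_pos"]]
        ax.scatter(tum["centroid_x_um"], tum["centroid_y_um"], s=1, c="navy", alpha=0.3)
    handles, labels = ax.get_legend_handles_labels()
    seen = dict(zip(labels, handles))
    ax.legend(seen.values(), seen.keys(), fontsize=8, loc="upper right")
    ax.set_aspect("equal")
    ax.invert_yaxis()  # image convention: depth increases downward
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_nuclei_boxplots(features: pd.DataFrame, path: str | Path) -> None:
    """Per-band boxplots of the three mean nuclei-size factors."""
    fig, axes = plt.subplots(1, 3, figsize=(10, 4), sharey=True)
    kinds = [
        ("mean_nuclei_size", "all cells"),
        ("mean_tumor_nuclei_size", "tumor cells"),
        ("mean_coloc_nuclei_size", "colocalized cells"),
    ]
    bands = ["invasive", "middle", "superficial"]
    for ax, (suffix, title) in zip(axes, kinds):
        data = [features[f"{b}_{suffix}"].dropna() for b in bands]
        ax.boxplot(data, tick_labels=bands)
        ax.set_title(title, fontsize=9)
        ax.tick_params(axis="x", rotation=30)
    axes[0].set_ylabel("mean nucleus area (µm²)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_concordance_forest(table: pd.DataFrame, path: str | Path) -> None:
    """Forest plot of per-factor concordance indices with 95% CIs."""
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(table) + 1.5))
    y = np.arange(len(table))[::-1]
    ax.errorbar(
        table["c_index"],
        y,
        xerr=[
            table["c_index"] - table["c_ci_lower"],
            table["c_ci_upper"] - table["c_index"],
        ],
        fmt="o",
        color="k",
        ms=3,
        capsize=2,
    )
    ax.axvline(0.5, color="0.6", ls=":")
    ax.set_yticks(y)
    ax.set_yticklabels(table["factor"], fontsize=7)
    ax.set_xlabel("Harrell's C (95% CI)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_correlation_heatmap(cm: CorrelationMatrix, path: str | Path) -> None:
    """Correlation heatmap with significance stars."""
    k = len(cm.factors)
    fig, ax = plt.subplots(figsize=(0.6 * k + 2, 0.6 * k + 1.5))
    im = ax.imshow(cm.r.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    for i in range(k):
        for j in range(k):
            star = cm.stars.iat[i, j]
            if star and i != j:
                ax.text(j, i, star, ha="center", va="center", fontsize=7)
    ax.set_xticks(range(k))
    ax.set_yticks(range(k))
    ax.set_xticklabels(cm.factors, rotation=90, fontsize=7)
    ax.set_yticklabels(cm.factors, fontsize=7)
    fig.colorbar(im, ax=ax, label="r")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


# ---------------------------------------------------------------------------
# pipeline driver


def process_slide(
    annotation: io.SlideAnnotation,
    cells: pd.DataFrame,
    resolution_um: float = 10.0,
    markers: tuple[str, ...] = ("ki67", "s100"),
):
    """Gate, band and aggregate one slide.

    Returns ``(gates, geom, annotated_cells, aggregates)``.
    """
    gates = {}
    cells = cells.copy()
    for marker in markers:
        gate, flags = gating.gate_marker(cells, marker, slide_id=annotation.slide_id)
        gates[marker] = gate
        cells[f"{marker}_pos"] = flags
    thickness = geometry.estimate_thickness(annotation)
    geom = geometry.partition_bands(annotation, thickness, resolution_um=resolution_um)
    cells = geometry.annotate_cells(cells, geom, tumor=annotation.tumor)
    cells = ft.classify_categories(cells)
    aggregates = ft.band_aggregates(cells, geom)
    return gates, geom, cells, aggregates


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Run the full analysis and write the report bundle.

    ``config`` is a dict (or YAML path) with either a ``simulation``
    block (:class:`melaband.synthetic.StudySimConfig` fields) or an
    ``inputs`` block (``slides_dir`` with ``<patient>.cells.csv`` and
    ``<patient>.annotation.geojson``, plus ``clinical``); optional keys:
    ``seed``, ``resolution_um``, ``bootstrap_B``, ``endpoint``.

    Writes features/results CSVs, gate and model JSONs, figures (SVG)
    and a manifest; returns the manifest. Reruns with the same config
    and seed produce identical tables.
    """
    if not isinstance(config, dict):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "figures").mkdir(exist_ok=True)
    seed = int(config.get("seed", 0))
    resolution = float(config.get("resolution_um", 10.0))
    B = int(config.get("bootstrap_B", 1000))

    if "simulation" in config:
        sim = dict(config["simulation"])
        if "slide" in sim:
            sim["slide"] = synthetic.SlideSimConfig(**sim["slide"])
        sim.setdefault("seed", seed)
        study = synthetic.generate_study(synthetic.StudySimConfig(**sim))
        annotations, cell_tables, clinical = (
            study.annotations,
            study.cell_tables,
            study.clinical,
        )
    elif "inputs" in config:
        slides_dir = Path(config["inputs"]["slides_dir"])
        clinical = io.read_clinical(config["inputs"]["clinical"])
        annotations, cell_tables = {}, {}
        for ann_path in sorted(slides_dir.glob("*.annotation.geojson")):
            pid = ann_path.name.removesuffix(".annotation.geojson")
            annotations[pid] = io.read_annotation(ann_path, slide_id=pid)
            cell_tables[pid] = io.read_cell_table(
                slides_dir / f"{pid}.cells.csv", slide_id=pid
            ).cells
    else:
        raise ValueError("config needs a 'simulation' or 'inputs' block")

    aggregates_by_patient, geoms_by_patient, gate_records = {}, {}, []
    excluded = []
    first_pid = None
    for pid in annotations:
        try:
            gates, geom, cells, aggregates = process_slide(
                annotations[pid], cell_tables[pid], resolution_um=resolution
            )
        except (geometry.DegenerateGeometryError, geometry.ResolutionError) as exc:
            logger.warning("slide %s excluded: %s", pid, exc)
            excluded.append({"patient_id": pid, "reason": str(exc)})
            continue
        aggregates_by_patient[pid] = aggregates
        geoms_by_patient[pid] = geom
        for marker, gate in gates.items():
            io.write_result_json(gate, outdir / f"gate_{pid}_{marker}.json", seed=seed)
            gate_records.append(
                {
                    "patient_id": pid,
                    "marker": marker,
                    "final_threshold": gate.final_threshold,
                    "failed": gate.failed,
                    "fallback_used": gate.fallback_used,
                }
            )
        if first_pid is None:
            first_pid = pid
            plot_band_overlay(
                annotations[pid], geom, cells, outdir / "figures" / "band_overlay.svg"
            )
            for marker, gate in gates.items():
                if not gate.failed:
                    plot_gate_histogram(
                        gate,
                        cell_tables[pid][f"{marker}_{gate.compartment}_mean"],
                        outdir / "figures" / f"gate_{marker}.svg",
                    )

    pd.DataFrame(gate_records).to_csv(outdir / "gates.csv", index=False)
    feature_table = ft.build_feature_table(clinical, aggregates_by_patient, geoms_by_patient)
    merged = feature_table.merge(
        clinical[["patient_id", "time_months", "event"]], on="patient_id"
    )
    merged.to_csv(outdir / "features.csv", index=False)

    summary = survival.summarize_cohort(clinical)
    uni = survival.univariate_screen(merged, B=B, seed=seed)
    uni.to_csv(outdir / "univariate.csv", index=False)
    multi = survival.multivariable_models(merged, B=B, seed=seed + 1)
    multi_table = survival.multivariable_table(multi)
    multi_table.to_csv(outdir / "multivariable.csv", index=False)
    for res in multi:
        io.write_result_json(res, outdir / f"cox_{res.model_id}.json", seed=seed)

    size_factors = [c for c in ft.FACTOR_COLUMNS if c.endswith("size")] + [
        "mitosis",
        "thickness_mm",
    ]
    cm = correlation_matrix(merged, [c for c in size_factors if c in merged.columns])
    cm.r.to_csv(outdir / "correlation_r.csv")
    cm.p.to_csv(outdir / "correlation_p.csv")

    plot_nuclei_boxplots(merged, outdir / "figures" / "nuclei_boxplots.svg")
    if len(uni):
        plot_concordance_forest(uni, outdir / "figures" / "concordance_forest.svg")
    plot_correlation_heatmap(cm, outdir / "figures" / "correlation_heatmap.svg")

    from melaband import __version__

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": io.config_hash(config),
        "n_patients": int(len(feature_table)),
        "n_excluded": len(excluded),
        "excluded": excluded,
        "cohort_summary": summary,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
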