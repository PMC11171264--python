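"""Synthetic slides and cohorts with the structure the pipeline assumes.

No per-cell melanoma dataset with annotations is publicly deposited, so
every downstream stage is exercised on simulated data that carries its
own ground truth:

* :func:`generate_slide` scatters cells uniformly inside a tumor polygon
  (rectangle or smoothed blob) with an epidermis strip along its
  superficial edge. Marker intensities are drawn from a two-component
  log-normal mixture (background vs expressing cells), giving the
  bimodal log-scale expression histograms the gating stage expects, and
  nucleus areas are normal with a per-band mean shift. The latent
  positivity labels, true depths and bands go to a *truth sidecar*,
  never into the cell table, so pipeline code cannot consume them.
* :func:`generate_cohort` draws per-patient feature vectors and survival
  times from a Weibull proportional-hazards model with a configurable
  log-hazard vector, under independent exponential censoring calibrated
  to a requested expected censoring fraction.
* :func:`generate_study` composes the two: one slide per patient whose
  invasive-band nucleus-size shift is driven by a latent per-patient
  score that also drives the hazard — a cohort in which invasive-band
  nuclear morphometry is genuinely prognostic.

All draws flow from a single :class:`numpy.random.Generator` seeded per
call, so identical seeds yield identical outputs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import shapely.affinity
from scipy.optimize import brentq
from shapely.geometry import Polygon

from melaband import io
from melaband.gating import DEFAULT_COMPARTMENTS
from melaband.io import SlideAnnotation


class ConfigurationError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass(frozen=True)
class MarkerMix:
    """Two-component log-normal intensity model for one marker."""

    bg_log_mean: float
    bg_log_sd: float
    fg_log_mean: float
    fg_log_sd: float
    fg_fraction: float

    def __post_init__(self) -> None:
        if not self.fg_log_mean > self.bg_log_mean:
            raise ConfigurationError("fg_log_mean must exceed bg_log_mean")
        if not 0.0 < self.fg_fraction < 1.0:
            raise ConfigurationError("fg_fraction must lie strictly in (0, 1)")
        if self.bg_log_sd <= 0 or self.fg_log_sd <= 0:
            raise ConfigurationError("log-sds must be positive")


def _default_marker_mix() -> dict[str, MarkerMix]:
    # 4-sd log separation between expressing and background populations
    return {
        "dapi": MarkerMix(2.0, 0.4, 4.0, 0.4, 0.95),
        "ki67": MarkerMix(1.0, 0.5, 3.0, 0.5, 0.30),
        "s100": MarkerMix(1.0, 0.5, 3.0, 0.5, 0.60),
    }


@dataclass
class SlideSimConfig:
    """One simulated slide: geometry, cellularity, marker and size models."""

    tumor_shape: str = "rectangle"  # rectangle | blob
    tumor_depth_mm: float = 3.0
    tumor_width_mm: float = 6.0
    epidermis_band_mm: float = 0.3
    cell_density_per_mm2: float = 200.0
    marker_mix: dict[str, MarkerMix] = field(default_factory=_default_marker_mix)
    nucleus_area_base_um2: float = 40.0
    nucleus_area_sd_um2: float = 8.0
    nucleus_area_band_shift_um2: dict[str, float] = field(
        default_factory=lambda: {"superficial": 0.0, "middle": 0.0, "invasive": 0.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tumor_shape not in ("rectangle", "blob"):
            raise ConfigurationError(f"unknown tumor_shape {self.tumor_shape!r}")
        for name in (
            "tumor_depth_mm",
            "tumor_width_mm",
            "epidermis_band_mm",
            "cell_density_per_mm2",
            "nucleus_area_base_um2",
            "nucleus_area_sd_um2",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        fixed = {}
        for marker, mix in self.marker_mix.items():
            fixed[marker] = mix if isinstance(mix, MarkerMix) else MarkerMix(**mix)
        self.marker_mix = fixed


def _tumor_polygon(config: SlideSimConfig, rng: np.random.Generator) -> Polygon:
    w = config.tumor_width_mm * 1000.0
    d = config.tumor_depth_mm * 1000.0
    if config.tumor_shape == "rectangle":
        return Polygon([(0, 0), (w, 0), (w, d), (0, d)])
    # blob: smoothed random radial polygon squeezed to the requested extents
    theta = np.linspace(0, 2 * np.pi, 181)[:-1]
    radius = np.ones_like(theta)
    for harmonic in (2, 3, 5):
        radius += 0.12 * rng.normal() * np.cos(harmonic * theta + rng.uniform(0, 2 * np.pi))
    radius = np.clip(radius, 0.4, None)
    x = w / 2 + (w / 2) * radius * np.cos(theta) / radius.max()
    y = d / 2 + (d / 2) * radius * np.sin(theta) / radius.max()
    poly = Polygon(np.stack([x, y], axis=1)).buffer(0)
    minx, miny, maxx, maxy = poly.bounds
    # rescale so the blob spans exactly the configured width and depth
    sx, sy = w / (maxx - minx), d / (maxy - miny)
    return shapely.affinity.scale(
        shapely.affinity.translate(poly, -minx, -miny), sx, sy, origin=(0, 0)
    )


def _true_band(depth_um: np.ndarray, depth_extent_um: float) -> np.ndarray:
    d1, d2 = depth_extent_um / 3.0, 2.0 * depth_extent_um / 3.0
    band = np.where(depth_um < d1, "superficial", np.where(depth_um < d2, "middle", "invasive"))
    return band


def generate_slide(
    config: SlideSimConfig, slide_id: str = "sim"
) -> tuple[SlideAnnotation, pd.DataFrame, pd.DataFrame]:
    """Simulate one slide: annotation, cell table, and truth sidecar.

    Cells are a Poisson scatter at the configured density inside the
    tumor polygon; the epidermis strip sits on the superficial (low-y)
    edge. Returns ``(annotation, cells, truth)`` — ``truth`` holds the
    latent positivity labels, true depth and true band per cell and must
    only be used for accuracy checks, never by the pipeline itself.
    """
    rng = np.random.default_rng(config.seed)
    tumor = _tumor_polygon(config, rng)
    minx, miny, maxx, maxy = tumor.bounds
    epi_um = config.epidermis_band_mm * 1000.0
    epidermis = Polygon(
        [(minx, miny - epi_um), (maxx, miny - epi_um), (maxx, miny), (minx, miny)]
    )
    annotation = SlideAnnotation(slide_id=slide_id, tumor=tumor, epidermis=epidermis)

    area_mm2 = tumor.area / 1e6
    n = int(rng.poisson(config.cell_density_per_mm2 * area_mm2))
    xs = np.empty(0)
    ys = np.empty(0)
    while xs.size < n:  # rejection sampling in the bounding box
        m = max(2 * (n - xs.size), 16)
        cx = rng.uniform(minx, maxx, m)
        cy = rng.uniform(miny, maxy, m)
        keep = shapely.contains_xy(tumor, cx, cy)
        xs = np.concatenate([xs, cx[keep]])
        ys = np.concatenate([ys, cy[keep]])
    xs, ys = xs[:n], ys[:n]

    depth = ys - miny
    band = _true_band(depth, maxy - miny)
    shift = np.array([config.nucleus_area_band_shift_um2.get(b, 0.0) for b in band])
    area = np.maximum(
        rng.normal(config.nucleus_area_base_um2 + shift, config.nucleus_area_sd_um2), 1.0
    )

    cells = pd.DataFrame(
        {
            "cell_id": [f"{slide_id}-{i}" for i in range(n)],
            "centroid_x_um": xs,
            "centroid_y_um": ys,
            "nucleus_area_um2": area,
        }
    )
    truth = pd.DataFrame(
        {"cell_id": cells["cell_id"], "depth_um": depth, "band": band}
    )
    for channel in io.CHANNELS:
        mix = config.marker_mix.get(channel)
        primary = DEFAULT_COMPARTMENTS.get(channel, "nucleus")
        for compartment in io.COMPARTMENTS:
            col = f"{channel}_{compartment}_mean"
            if mix is None:
                cells[col] = np.exp(rng.normal(1.0, 0.5, n))
                continue
            if compartment == primary:
                latent = rng.random(n) < mix.fg_fraction
                logv = np.where(
                    latent,
                    rng.normal(mix.fg_log_mean, mix.fg_log_sd, n),
                    rng.normal(mix.bg_log_mean, mix.bg_log_sd, n),
                )
                cells[col] = np.exp(logv)
                truth[f"{channel}_pos"] = latent
            else:
                cells[col] = np.exp(rng.normal(mix.bg_log_mean, mix.bg_log_sd, n))
    cells["slide_id"] = slide_id
    return annotation, cells, truth


def write_slide(
    outdir: str | Path,
    annotation: SlideAnnotation,
    cells: pd.DataFrame,
    truth: pd.DataFrame | None = None,
) -> None:
    """Write a simulated slide in the on-disk layout the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sid = annotation.slide_id
    io.write_cell_table(cells, outdir / f"{sid}.cells.csv")
    io.write_annotation(annotation, outdir / f"{sid}.annotation.geojson")
    if truth is not None:
        truth.to_csv(outdir / f"{sid}.truth.csv", index=False)


# ---------------------------------------------------------------------------
# cohort-level simulation


@dataclass
class CohortSimConfig:
    """Feature vectors plus Weibull proportional-hazards outcomes."""

    n_patients: int = 26
    beta: dict[str, float] = field(default_factory=dict)
    baseline_hazard_scale: float = 60.0  # Weibull scale, months
    baseline_hazard_shape: float = 1.2
    censoring_rate: float = 0.3
    feature_means: dict[str, float] = field(default_factory=dict)
    feature_sds: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ConfigurationError("n_patients must be >= 2")
        if self.baseline_hazard_scale <= 0 or self.baseline_hazard_shape <= 0:
            raise ConfigurationError("Weibull hazard parameters must be positive")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ConfigurationError("censoring_rate must lie in [0, 1)")

    @property
    def factors(self) -> list[str]:
        names = dict.fromkeys(self.beta) | dict.fromkeys(self.feature_means)
        return list(names) or ["factor_1"]


def _calibrated_censoring_times(
    event_times: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Exponential censoring times whose expected censored fraction is `rate`.

    The exponential rate lambda solves E[1 - exp(-lambda*T)] = rate over
    the realized event times T (monotone in lambda, solved by brentq).
    """
    if rate == 0.0:
        return np.full(event_times.size, np.inf)

    def frac(lam: float) -> float:
        return float(np.mean(1.0 - np.exp(-lam * event_times))) - rate

    lo, hi = 1e-12, 1e12
    lam = brentq(frac, lo, hi)
    return rng.exponential(1.0 / lam, event_times.size)


@dataclass
class CohortSample:
    features: pd.DataFrame  # patient_id + one column per factor
    survival: pd.DataFrame  # patient_id, time_months, event
    truth: pd.DataFrame  # patient_id, linear_predictor, latent event/censor times


def generate_cohort(config: CohortSimConfig) -> CohortSample:
    """Draw features and Weibull proportional-hazards survival outcomes.

    Survival times satisfy S(t|x) = exp(-(t/scale)^shape * exp(eta)) with
    eta the configured linear predictor; censoring is independent
    exponential at the calibrated expected rate. The truth table carries
    the per-patient linear predictor for oracle checks.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    pid = [f"P{i:04d}" for i in range(n)]
    features = pd.DataFrame({"patient_id": pid})
    eta = np.zeros(n)
    for factor in config.factors:
        mean = config.feature_means.get(factor, 0.0)
        sd = config.feature_sds.get(factor, 1.0)
        x = rng.normal(mean, sd, n)
        features[factor] = x
        eta += config.beta.get(factor, 0.0) * x

    shape, scale = config.baseline_hazard_shape, config.baseline_hazard_scale
    u = rng.exponential(1.0, n)
    t_event = scale * (u / np.exp(eta)) ** (1.0 / shape)
    t_cens = _calibrated_censoring_times(t_event, config.censoring_rate, rng)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens

    survival = pd.DataFrame({"patient_id": pid, "time_months": time, "event": event})
    truth = pd.DataFrame(
        {
            "patient_id": pid,
            "linear_predictor": eta,
            "event_time": t_event,
            "censor_time": t_cens,
        }
    )
    return CohortSample(features=features, survival=survival, truth=truth)


# ---------------------------------------------------------------------------
# end-to-end study: slides whose morphology drives the hazard


@dataclass
class StudySimConfig:
    """A cohort of slides with a prognostic invasive-band nucleus-size shift.

    Each patient carries a latent standard-normal morphology score ``z``;
    their slide's invasive-band nucleus areas are shifted by
    ``size_shift_scale_um2 * z`` and their hazard is multiplied by
    ``exp(beta_invasive_size * z)``, so the invasive-band mean nuclei
    size measured by the pipeline is a genuine prognostic factor.
    """

    n_patients: int = 40
    beta_invasive_size: float = 0.8  # log-hazard per sd of the latent score
    size_shift_scale_um2: float = 6.0
    slide: SlideSimConfig = field(
        default_factory=lambda: SlideSimConfig(
            tumor_depth_mm=2.0, tumor_width_mm=4.0, cell_density_per_mm2=150.0
        )
    )
    baseline_hazard_scale: float = 60.0
    baseline_hazard_shape: float = 1.2
    censoring_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ConfigurationError("n_patients must be >= 2")


@dataclass
class StudySample:
    annotations: dict[str, SlideAnnotation]
    cell_tables: dict[str, pd.DataFrame]
    truth_tables: dict[str, pd.DataFrame]
    clinical: pd.DataFrame
    patient_truth: pd.DataFrame  # latent score and linear predictor


def generate_study(config: StudySimConfig) -> StudySample:
    """Simulate a full cohort of slides plus matched clinical outcomes."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    z = rng.normal(0.0, 1.0, n)
    eta = config.beta_invasive_size * z

    shape, scale = config.baseline_hazard_shape, config.baseline_hazard_scale
    u = rng.exponential(1.0, n)
    t_event = scale * (u / np.exp(eta)) ** (1.0 / shape)
    t_cens = _calibrated_censoring_times(t_event, config.censoring_rate, rng)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens

    annotations, cell_tables, truth_tables = {}, {}, {}
    rows = []
    base_slide = dataclasses.asdict(config.slide)
    for i in range(n):
        pid = f"P{i:04d}"
        slide_cfg = dict(base_slide)
        slide_cfg["nucleus_area_band_shift_um2"] = {
            "superficial": 0.0,
            "middle": 0.0,
            "invasive": config.size_shift_scale_um2 * z[i],
        }
        # patient-to-patient anatomical variation (non-prognostic here)
        slide_cfg["tumor_depth_mm"] = config.slide.tumor_depth_mm * math.exp(
            rng.normal(0.0, 0.15)
        )
        slide_cfg["tumor_width_mm"] = config.slide.tumor_width_mm * math.exp(
            rng.normal(0.0, 0.15)
        )
        slide_cfg["seed"] = int(rng.integers(0, 2**31 - 1))
        annotation, cells, truth = generate_slide(SlideSimConfig(**slide_cfg), slide_id=pid)
        annotations[pid] = annotation
        cell_tables[pid] = cells
        truth_tables[pid] = truth
        rows.append(
            {
                "patient_id": pid,
                "age": float(np.clip(rng.normal(62.0, 12.0), 20.0, 90.0)),
                "mitosis": int(rng.poisson(3.0)),
                "thickness_mm": float(
                    slide_cfg["tumor_depth_mm"] * math.exp(rng.normal(0.0, 0.05))
                ),
                "time_months": float(time[i]),
                "event": bool(event[i]),
                "endpoint": "PFS",
                "sex": "M" if rng.random() < 0.77 else "F",
            }
        )
    clinical = pd.DataFrame(rows)
    patient_truth = pd.DataFrame(
        {
            "patient_id": clinical["patient_id"],
            "latent_score": z,
            "linear_predictor": eta,
        }
    )
    return StudySample(
        annotations=annotations,
        cell_tables=cell_tables,
        truth_tables=truth_tables,
        clinical=clinical,
        patient_truth=patient_truth,
    )


def write_study(sample: StudySample, outdir: str | Path) -> None:
    """Write a simulated study in the directory layout the pipeline reads."""
    outdir = Path(outdir)
    (outdir / "slides").mkdir(parents=True, exist_ok=True)
    for pid, annotation in sample.annotations.items():
        write_slide(
            outdir / "slides", annotation, sample.cell_tables[pid], sample.truth_tables[pid]
        )
    io.write_clinical(sample.clinical, outdir / "clinical.csv")
    sample.patient_truth.to_csv(outdir / "patient_truth.csv", index=False)
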