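"""Per-slide adaptive marker gating.

Marker positivity is decided slide by slide with a two-phase threshold
on the per-cell mean intensity of one compartment:

1. **Otsu split.** An exhaustive scan over histogram bin boundaries
   finds the threshold ``t*`` maximizing the between-class variance
   ``sigma_B^2(t) = w0(t) * w1(t) * (mu0(t) - mu1(t))**2``. This splits
   the expression distribution into a background component T0 (noise and
   truly negative cells) and a foreground component T1; only T1
   progresses. Within :func:`gate_marker` the split is taken on the log
   intensities — the scale on which fluorescence expression histograms
   are bimodal (a heavy-tailed linear-scale histogram would otherwise
   pull the cut into the expressing population).
2. **Log-space mixture intersection.** A 2-component Gaussian mixture is
   fitted to ``ln(T1)`` by EM with weak conjugate (Dirichlet +
   normal-inverse-gamma) priors, and the final threshold is placed where
   the two weighted component densities intersect,
   ``pi1 N(x|mu1,s1) = pi2 N(x|mu2,s2)``, between the two means. The
   component with the higher mean is the positive population.

A cell is called positive iff its intensity lies in T1 *and* its log
intensity is at or above the intersection threshold. All thresholds are
deterministic: the EM is initialized from a median split of the log
foreground, so a slide gates identically on every run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

#: which compartment's mean intensity each marker is gated on
DEFAULT_COMPARTMENTS = {"ki67": "nucleus", "s100": "cytoplasm", "dapi": "nucleus"}


class DegenerateInputError(ValueError):
    """Input has no exploitable structure (e.g. all values identical)."""


class GateError(RuntimeError):
    """The two-phase gate could not be fitted for this slide/marker."""


@dataclass(frozen=True)
class OtsuSplit:
    """Otsu threshold with the class statistics at the optimum."""

    threshold: float
    omega0: float
    omega1: float
    mu0: float
    mu1: float
    between_class_variance: float


@dataclass
class LogMixture:
    """2-component Gaussian mixture in log-intensity space, mu1 <= mu2."""

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    n_iter_used: int
    converged: bool
    objective_trace: list[float] = field(default_factory=list, repr=False)


@dataclass
class MarkerGate:
    """Fitted two-phase gate for one marker on one slide.

    ``final_threshold`` is on the linear intensity scale (exp of the
    log-space intersection); ``positive_component`` indexes the
    higher-mean mixture component.
    """

    slide_id: str
    marker: str
    compartment: str
    otsu: OtsuSplit | None
    mixture: LogMixture | None
    final_threshold: float | None
    positive_component: int = 1
    fallback_used: bool = False
    refined: bool = True  # mixture intersection accepted over the Otsu cut
    failed: bool = False
    failure_reason: str = ""
    n_dropped_nonpositive: int = 0


def otsu_threshold(values, n_bins: int = 256) -> OtsuSplit:
    """Otsu's method by exhaustive scan over histogram bin boundaries.

    The histogram spans the 1st–99th percentile of the values (outliers
    clamp into the end bins) so a single extreme value cannot stretch
    the binning. Class means are computed from the actual values in each
    class, not from bin centers, so the returned split is exactly the
    maximizer of the between-class variance over all bin boundaries.
    Ties are resolved by reporting the midpoint of the first and last
    maximizing boundaries (class statistics from the first).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2 or np.ptp(values) == 0:
        raise DegenerateInputError("need >= 2 distinct values for an Otsu split")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")

    lo, hi = np.percentile(values, [1.0, 99.0])
    if hi <= lo:  # heavy ties; fall back to the full observed range
        lo, hi = float(values.min()), float(values.max())
    clamped = np.clip(values, lo, hi)
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(clamped, bins=edges)
    sums, _ = np.histogram(clamped, bins=edges, weights=clamped)

    n = values.size
    c0 = np.cumsum(counts)[:-1]  # class 0 size at each interior boundary
    s0 = np.cumsum(sums)[:-1]
    c1 = n - c0
    s1 = sums.sum() - s0
    valid = (c0 > 0) & (c1 > 0)
    if not valid.any():
        raise DegenerateInputError("all values fall in a single histogram bin")
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = s0 / c0
        mu1 = s1 / c1
        sigma_b2 = (c0 / n) * (c1 / n) * (mu0 - mu1) ** 2
    sigma_b2[~valid] = -np.inf

    best = float(sigma_b2.max())
    tied = np.flatnonzero(sigma_b2 >= best - 0.0)  # exact ties only
    first, last = tied[0], tied[-1]
    boundary = edges[1:-1]
    threshold = float((boundary[first] + boundary[last]) / 2.0)
    return OtsuSplit(
        threshold=threshold,
        omega0=float(c0[first] / n),
        omega1=float(c1[first] / n),
        mu0=float(mu0[first]),
        mu1=float(mu1[first]),
        between_class_variance=best,
    )


def split_t0_t1(values, otsu: OtsuSplit) -> tuple[np.ndarray, np.ndarray]:
    """Partition values at the Otsu threshold: T0 <= t* < T1."""
    values = np.asarray(values, dtype=float).ravel()
    above = values > otsu.threshold
    t0, t1 = values[~above], values[above]
    if t1.size == 0:
        raise GateError("empty foreground (T1) after the Otsu split")
    return t0, t1


# ---------------------------------------------------------------------------
# MAP-EM for the 2-component log-normal mixture

_KAPPA0 = 1e-3  # prior pseudo-count on each component mean
_A0 = 1e-3  # inverse-gamma shape on component variances
_ALPHA0 = 1.0  # symmetric Dirichlet concentration on weights


def fit_log_mixture(
    t1_values,
    max_iter: int = 3000,
    tol: float = 1e-6,
    seed: int | None = None,
) -> LogMixture:
    """Fit a 2-component Gaussian mixture to ``ln(T1)`` by MAP-EM.

    Weak conjugate priors (symmetric Dirichlet concentration 1 on the
    weights; normal-inverse-gamma, centered on the data, on the
    component parameters) regularize the fit without moving it on
    well-separated data. Initialization is a deterministic median split
    of the log values, so ``seed`` is accepted only for interface
    symmetry. The penalized log-likelihood trace is non-decreasing; the
    fit is flagged unconverged (but still usable) if the change has not
    fallen below ``tol`` within ``max_iter`` sweeps.
    """
    del seed  # deterministic initialization; no randomness used
    t1 = np.asarray(t1_values, dtype=float).ravel()
    n_nonpos = int((t1 <= 0).sum())
    if n_nonpos:
        logger.warning("dropping %d non-positive values before log transform", n_nonpos)
        t1 = t1[t1 > 0]
    if t1.size < 10:
        raise GateError(f"foreground too small to fit a mixture (n={t1.size})")
    x = np.log(t1)
    if np.ptp(x) == 0:
        raise DegenerateInputError("foreground values are all identical")

    m0, v0 = float(x.mean()), float(x.var())
    b0 = _A0 * v0
    # deterministic init: split at the median
    med = np.median(x)
    lowhigh = [x[x <= med], x[x > med]]
    if any(part.size == 0 for part in lowhigh):
        lowhigh = [x[: x.size // 2], x[x.size // 2 :]]
    mu = np.array([part.mean() for part in lowhigh])
    var = np.array([max(part.var(), 1e-6 * v0, 1e-12) for part in lowhigh])
    pi = np.array([part.size / x.size for part in lowhigh])

    trace: list[float] = []
    converged = False
    n = x.size
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        log_comp = (
            np.log(pi)[None, :]
            - 0.5 * np.log(2 * np.pi * var)[None, :]
            - (x[:, None] - mu[None, :]) ** 2 / (2 * var[None, :])
        )
        log_norm = np.logaddexp(log_comp[:, 0], log_comp[:, 1])
        resp = np.exp(log_comp - log_norm[:, None])

        # penalized objective: log-likelihood + log prior
        log_prior = 0.0
        for k in range(2):
            log_prior += (
                -0.5 * math.log(2 * math.pi * var[k] / _KAPPA0)
                - _KAPPA0 * (mu[k] - m0) ** 2 / (2 * var[k])
                - (_A0 + 1) * math.log(var[k])
                - b0 / var[k]
            )
        trace.append(float(log_norm.sum() + log_prior))
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break

        # M-step (MAP with conjugate priors)
        nk = resp.sum(axis=0)
        pi = (nk + _ALPHA0 - 1.0) / (n + 2.0 * (_ALPHA0 - 1.0))
        mu = (_KAPPA0 * m0 + resp.T @ x) / (_KAPPA0 + nk)
        sq = ((x[:, None] - mu[None, :]) ** 2 * resp).sum(axis=0)
        var = (2 * b0 + _KAPPA0 * (mu - m0) ** 2 + sq) / (nk + 3 + 2 * _A0)

    order = np.argsort(mu)
    return LogMixture(
        weights=tuple(float(p) for p in pi[order]),
        means=tuple(float(m) for m in mu[order]),
        sds=tuple(float(np.sqrt(v)) for v in var[order]),
        n_iter_used=it,
        converged=converged,
        objective_trace=trace,
    )


#: minimum Ashman's D for the fitted components to count as two real modes
BIMODALITY_MIN_D = 2.0
#: minimum weight of the lighter component (below this the lower component
#: is a truncation-edge remnant, not a population)
BIMODALITY_MIN_WEIGHT = 0.10


def _mixture_is_bimodal(mix: LogMixture) -> bool:
    """Whether the fitted pair describes genuine bimodality of T1.

    Ashman's D = sqrt(2)|mu2-mu1|/sqrt(s1^2+s2^2) >= 2 is the standard
    clean-separation criterion for a two-Gaussian fit; the weight floor
    rejects fits whose lower component merely wraps the few background
    stragglers at the foreground's truncation edge. When the check fails
    the intersection threshold would bisect a single population, so the
    gate falls back to the Otsu boundary.
    """
    (w1, w2), (mu1, mu2), (s1, s2) = mix.weights, mix.means, mix.sds
    d = math.sqrt(2.0) * (mu2 - mu1) / math.sqrt(s1**2 + s2**2)
    return d >= BIMODALITY_MIN_D and min(w1, w2) >= BIMODALITY_MIN_WEIGHT


def _log_weighted_density(x, pi, mu, sd):
    return (
        math.log(pi)
        - 0.5 * math.log(2 * math.pi)
        - math.log(sd)
        - (x - mu) ** 2 / (2 * sd**2)
    )


def mixture_intersection(mix: LogMixture) -> tuple[float, bool]:
    """Log-space threshold where the two weighted densities intersect.

    Solves ``pi1 N(x|mu1,s1) = pi2 N(x|mu2,s2)`` for the root in the
    open interval ``(mu1, mu2)``. Equal component variances make the
    equation linear with a single root; otherwise the quadratic may have
    no root between the means under extreme weight imbalance, in which
    case the point in ``[mu1, mu2]`` where the weighted log-densities
    are closest is returned and flagged (``fallback_used=True``).
    """
    (pi1, pi2), (mu1, mu2), (s1, s2) = mix.weights, mix.means, mix.sds
    if not mu1 < mu2:
        raise DegenerateInputError("mixture means are not distinct")
    c = math.log(pi1 / pi2) + math.log(s2 / s1)
    if abs(s1 - s2) < 1e-12 * (s1 + s2):
        # linear: (x-mu2)^2 - (x-mu1)^2 = 2 s^2 c
        root = (mu1 + mu2) / 2.0 + s1**2 * c / (mu2 - mu1)
        if mu1 < root < mu2:
            return float(root), False
        roots = []
    else:
        # quadratic a x^2 + b x + g = 0 from equating log densities
        a = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
        b = mu1 / s1**2 - mu2 / s2**2
        g = mu2**2 / (2 * s2**2) - mu1**2 / (2 * s1**2) + c
        disc = b * b - 4 * a * g
        roots = []
        if disc >= 0:
            sq = math.sqrt(disc)
            roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
        roots = [r for r in roots if mu1 < r < mu2]
    if roots:
        return float(min(roots)), False

    # degenerate branch: closest approach of the two weighted densities
    grid = np.linspace(mu1, mu2, 2001)
    gap = np.abs(
        _log_weighted_density(grid, pi1, mu1, s1)
        - _log_weighted_density(grid, pi2, mu2, s2)
    )
    x0 = grid[int(np.argmin(gap))]
    span = (mu2 - mu1) / 2000.0
    res = minimize_scalar(
        lambda x: abs(
            _log_weighted_density(x, pi1, mu1, s1)
            - _log_weighted_density(x, pi2, mu2, s2)
        ),
        bounds=(max(mu1, x0 - span), min(mu2, x0 + span)),
        method="bounded",
    )
    return float(res.x), True


def gate_marker(
    cells: pd.DataFrame,
    marker: str,
    compartment: str | None = None,
    slide_id: str = "",
    n_bins: int = 256,
    max_iter: int = 3000,
    tol: float = 1e-6,
) -> tuple[MarkerGate, pd.Series]:
    """Run the full two-phase gate for one marker and flag every cell.

    Returns the fitted :class:`MarkerGate` and a boolean Series aligned
    with ``cells``. On any fitting failure (empty input, degenerate
    distribution, unimodal foreground) the gate is returned with
    ``failed=True``, the reason logged, and every cell flagged negative.
    """
    compartment = compartment or DEFAULT_COMPARTMENTS.get(marker, "nucleus")
    col = f"{marker}_{compartment}_mean"
    if col not in cells.columns:
        raise KeyError(f"cells lack intensity column {col!r}")
    values = cells[col].to_numpy(dtype=float)
    flags = pd.Series(False, index=cells.index, name=f"{marker}_pos")

    gate = MarkerGate(
        slide_id=slide_id,
        marker=marker,
        compartment=compartment,
        otsu=None,
        mixture=None,
        final_threshold=None,
    )
    try:
        if values.size == 0:
            raise GateError("no cells to gate")
        # the expression histogram is bimodal on the log scale, so both
        # phases operate there; cells at non-positive intensity are
        # unambiguously background
        gate.n_dropped_nonpositive = int((values <= 0).sum())
        logv = np.log(values, out=np.full_like(values, -np.inf), where=values > 0)
        gate.otsu = otsu_threshold(logv[np.isfinite(logv)], n_bins=n_bins)
        _, t1_log = split_t0_t1(logv, gate.otsu)
        gate.mixture = fit_log_mixture(np.exp(t1_log), max_iter=max_iter, tol=tol)
        if gate.mixture.means[1] - gate.mixture.means[0] < 1e-6:
            raise GateError("foreground is unimodal (mixture means coincide)")
        if _mixture_is_bimodal(gate.mixture):
            log_thr, gate.fallback_used = mixture_intersection(gate.mixture)
        else:
            # T1 carries no second mode to refine on (the Otsu cut already
            # sits in the expression valley): keep the phase-1 boundary
            log_thr, gate.refined = gate.otsu.threshold, False
        gate.final_threshold = float(np.exp(log_thr))
    except (GateError, DegenerateInputError) as exc:
        gate.failed = True
        gate.failure_reason = str(exc)
        logger.warning(
            "gate failed for %s/%s on slide %s: %s", marker, compartment, slide_id, exc
        )
        return gate, flags

    flags[:] = (logv > gate.otsu.threshold) & (logv >= np.log(gate.final_threshold))
    return gate, flags
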