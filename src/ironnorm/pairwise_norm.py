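"""Pair-wise iterative rank-order normalization — the core algorithm.

One sample chip is normalized against one reference chip in five stages:

1. **Training-set candidates** — drop unassigned and masked probes, probes
   tied at either chip's minimum or maximum intensity, and saturated probes
   (above the 16-bit detector ceiling on either chip).
2. **Iterative rank-order pruning** — rank the candidates on each chip and
   repeatedly discard the most rank-divergent probes (cutoff = current
   worst percentile difference minus a decrement) until every survivor's
   rank differs by at most 1% of the set size.  The survivors approximate a
   set of non-differentially-expressed probes, even when differential
   expression is strongly one-sided — the situation where distribution- or
   symmetry-based methods break.
3. **Density-weighted sliding-window fit** — in MA coordinates
   (A = log(X·Y), M = log(X/Y), X reference, Y sample), fit weighted
   least-squares lines of M on A in a sliding window 10% of the training
   set; each point's fitted value averages the slopes and offsets of every
   window containing it.  Weights σ_avg⁴ (σ from 1%-windows over A)
   up-weight sparse regions so dense mid-intensity probes do not dominate.
4. **Fit curve** — project each training point onto the fitted curve
   (half the residual to each axis) and keep the projected Y coordinate
   with its correction factor; co-located projections are averaged.
5. **Application** — every probe's log intensity is shifted by the
   correction interpolated at its Y value; beyond the trained range the
   mean correction of the terminal fit points is used.

Everything here is deterministic and a pure function of the two vectors and
the config — normalizing one pair is unaffected by any other chips, which
is what makes incremental renormalization exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import rankdata

from .data_model import ChipLayout, PipelineConfig, safe_log

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingSet",
    "FitCurve",
    "NormalizationError",
    "build_training_set",
    "iterative_rank_prune",
    "density_weights",
    "fit_correction",
    "build_fit_curve",
    "apply_fit_curve",
    "normalize_pair",
    "median_scale_pair",
]


class NormalizationError(ValueError):
    """Raised when a normalization stage cannot proceed."""

    def __init__(self, message: str, trajectory: list[int] | None = None):
        super().__init__(message)
        self.trajectory = trajectory or []


@dataclass
class TrainingSet:
    """Rank-invariant probe set surviving pruning.

    ``indices`` are positions into the vectors given to
    :func:`iterative_rank_prune`; ``iteration_sizes`` starts with the
    initial candidate count and appends the size after each pruning pass
    (strictly decreasing until convergence).
    """

    indices: np.ndarray
    x: np.ndarray
    y: np.ndarray
    iteration_sizes: list[int] = field(default_factory=list)
    converged: bool = False

    @property
    def size(self) -> int:
        return int(self.indices.size)

    @property
    def n_iterations(self) -> int:
        return len(self.iteration_sizes) - 1


@dataclass
class FitCurve:
    """Projected fit points sorted by projected sample (Y) log intensity.

    For every point ``x_proj − y_proj == correction`` and
    ``x_proj + y_proj`` equals the generating training point's A value.
    ``head_correction`` / ``tail_correction`` are the mean corrections of
    the first / last ``extrapolation_points`` points, applied outside the
    trained intensity range.
    """

    y_proj: np.ndarray
    x_proj: np.ndarray
    correction: np.ndarray
    head_correction: float
    tail_correction: float

    @property
    def n_points(self) -> int:
        return int(self.y_proj.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"y_proj": self.y_proj, "x_proj": self.x_proj, "correction": self.correction}
        )


# ---------------------------------------------------------------------------
# Stage 1: candidate selection
# ---------------------------------------------------------------------------

def build_training_set(
    sample: np.ndarray,
    reference: np.ndarray,
    layout: ChipLayout | None = None,
    config: PipelineConfig | None = None,
    feature_ids: list[str] | None = None,
) -> np.ndarray:
    """Indices of probes eligible for curve training.

    Excluded: probes outside any probeset and masked probes (when a layout
    and feature IDs are given); every probe tied at the chip minimum or the
    chip maximum on either chip; probes above the saturation threshold on
    either chip.  Without a layout only the intensity rules apply.
    """
    config = config or PipelineConfig()
    y = np.asarray(sample, dtype=float)
    x = np.asarray(reference, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise NormalizationError("sample and reference must be aligned 1-D vectors")
    keep = np.ones(x.size, dtype=bool)
    if layout is not None:
        if feature_ids is None:
            raise NormalizationError("layout rules require feature_ids")
        assigned = layout.probe_to_probeset
        masked = layout.masked
        keep &= np.array(
            [fid in assigned and fid not in masked for fid in feature_ids], dtype=bool
        )
    for v in (x, y):
        keep &= v != v.min()
        keep &= v != v.max()
        keep &= v <= config.saturation_threshold
    idx = np.flatnonzero(keep)
    if idx.size < config.min_training_size:
        raise NormalizationError(
            f"only {idx.size} candidate training probes survive exclusions "
            f"(need ≥ {config.min_training_size})"
        )
    return idx


# ---------------------------------------------------------------------------
# Stage 2: iterative rank-order pruning
# ---------------------------------------------------------------------------

def iterative_rank_prune(
    x: np.ndarray, y: np.ndarray, config: PipelineConfig | None = None
) -> TrainingSet:
    """Prune rank-divergent points until ≤ convergence_pct rank agreement.

    Each pass ranks the surviving points on both chips (average ranks for
    ties), computes each point's absolute rank difference as a percentage of
    the current set size, and — unless the worst difference is already within
    ``convergence_pct`` — removes every point above
    ``max %Δ − prune_decrement_pct``, then re-ranks.  The cutoff always sits
    below the current maximum, so at least one point leaves per pass and the
    loop terminates.
    """
    config = config or PipelineConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise NormalizationError("x and y must be aligned 1-D vectors")
    if x.size < config.min_training_size:
        raise NormalizationError(
            f"training set of {x.size} below minimum {config.min_training_size}"
        )
    alive = np.arange(x.size)
    sizes = [int(alive.size)]
    while True:
        rx = rankdata(x[alive], method="average")
        ry = rankdata(y[alive], method="average")
        pct = np.abs(rx - ry) / alive.size * 100.0
        worst = pct.max()
        if worst <= config.convergence_pct:
            return TrainingSet(
                indices=alive, x=x[alive], y=y[alive],
                iteration_sizes=sizes, converged=True,
            )
        cutoff = worst - config.prune_decrement_pct
        alive = alive[pct <= cutoff]
        sizes.append(int(alive.size))
        if alive.size < config.min_training_size:
            raise NormalizationError(
                f"rank pruning shrank the training set to {alive.size} "
                f"(< {config.min_training_size}) before convergence",
                trajectory=sizes,
            )


# ---------------------------------------------------------------------------
# Stage 3: density weighting + sliding-window weighted least squares
# ---------------------------------------------------------------------------

def _window_membership(n: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    """For stride-1 length-w windows over n sorted points, the first and last
    window index containing each point (windows are truncated at the ends —
    terminal points simply belong to fewer windows)."""
    pos = np.arange(n)
    lo = np.maximum(0, pos - w + 1)
    hi = np.minimum(pos, n - w)
    return lo, hi


def _window_mean(per_window: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    csum = np.concatenate(([0.0], np.cumsum(per_window)))
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def density_weights(a: np.ndarray, config: PipelineConfig | None = None) -> np.ndarray:
    """σ_avg^exponent weights from sliding windows over sorted A values.

    ``a`` must be ascending.  Window size is ``window_frac_sigma`` of the set
    (at least 2 points); each window contributes its sample standard
    deviation, each point's σ_avg averages the deviations of every window
    containing it, and the weight is σ_avg raised to ``weight_exponent``.
    Sparse regions (locally large A spacing) therefore receive large
    weights.  A constant input yields uniform weights with a warning.
    """
    config = config or PipelineConfig()
    a = np.asarray(a, dtype=float)
    n = a.size
    if n < 2:
        raise NormalizationError("need ≥ 2 points for density weights")
    if np.any(np.diff(a) < 0):
        raise NormalizationError("density_weights expects ascending input")
    if np.ptp(a) == 0:
        logger.warning("constant A vector; density weights are uniform")
        return np.ones(n)
    w = min(n, max(2, round(config.window_frac_sigma * n)))
    stds = sliding_window_view(a, w).std(axis=1, ddof=1)
    lo, hi = _window_membership(n, w)
    sigma_avg = _window_mean(stds, lo, hi)
    weights = sigma_avg ** config.weight_exponent
    if np.any(weights <= 0):
        # locally constant stretch: keep weights strictly positive
        floor = weights[weights > 0].min()
        weights = np.maximum(weights, floor)
    return weights


def fit_correction(
    x: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    config: PipelineConfig | None = None,
) -> np.ndarray:
    """Per-point fitted log-ratio from sliding-window weighted least squares.

    Inputs must be sorted ascending by A = x + y.  Every stride-1 window of
    size ``window_frac_fit·n`` (≥ 3) yields a weighted least-squares line of
    M = x − y on A; for each point the slopes and offsets of all windows
    containing it are averaged and evaluated at the point's A.  A window
    with zero weight or zero A variance contributes a horizontal line at
    its (weighted) mean M.
    """
    config = config or PipelineConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    weights = np.asarray(weights, dtype=float)
    n = x.size
    if y.size != n or weights.size != n:
        raise NormalizationError("x, y, weights must be aligned")
    a = x + y
    m = x - y
    if np.any(np.diff(a) < 0):
        raise NormalizationError("fit_correction expects input sorted by A = x + y")
    w2 = min(n, max(3, round(config.window_frac_fit * n)))
    if n < 3:
        raise NormalizationError("need ≥ 3 points for the sliding-window fit")

    # Scale-invariant conditioning: WLS lines are unchanged by rescaling the
    # weights; centring A changes offsets but not the fitted values, and the
    # per-point averaging commutes with the shift.
    wn = weights / weights.max()
    ac = a - a.mean()

    def prefix(v: np.ndarray) -> np.ndarray:
        return np.concatenate(([0.0], np.cumsum(v)))

    pw, pwa, pwm = prefix(wn), prefix(wn * ac), prefix(wn * m)
    pwaa, pwam = prefix(wn * ac * ac), prefix(wn * ac * m)
    nwin = n - w2 + 1
    i0 = np.arange(nwin)
    i1 = i0 + w2
    sw = pw[i1] - pw[i0]
    swa = pwa[i1] - pwa[i0]
    swm = pwm[i1] - pwm[i0]
    swaa = pwaa[i1] - pwaa[i0]
    swam = pwam[i1] - pwam[i0]

    denom = sw * swaa - swa * swa
    a_span = ac[i1 - 1] - ac[i0]  # input sorted by A, so this is the window range
    degenerate = (sw <= 0) | (denom <= 0) | (a_span == 0)
    safe_denom = np.where(degenerate, 1.0, denom)
    slope = np.where(degenerate, 0.0, (sw * swam - swa * swm) / safe_denom)
    # zero-total-weight window falls back to the plain mean M
    pm = prefix(m)
    plain_mean = (pm[i1] - pm[i0]) / w2
    safe_sw = np.where(sw > 0, sw, 1.0)
    offset = np.where(degenerate, np.where(sw > 0, swm / safe_sw, plain_mean),
                      (swm - slope * swa) / safe_sw)
    if degenerate.any():
        logger.debug("%d degenerate fit windows fell back to horizontal lines",
                     int(degenerate.sum()))

    lo, hi = _window_membership(n, w2)
    slope_bar = _window_mean(slope, lo, hi)
    offset_bar = _window_mean(offset, lo, hi)
    return slope_bar * ac + offset_bar


# ---------------------------------------------------------------------------
# Stage 4: fit curve construction
# ---------------------------------------------------------------------------

def build_fit_curve(
    x: np.ndarray,
    y: np.ndarray,
    fitted: np.ndarray,
    config: PipelineConfig | None = None,
) -> FitCurve:
    """Project training points onto the fitted curve and index it by Y.

    The residual d = fitted − observed M is split evenly between the two
    axes (x_proj = x + d/2, y_proj = y − d/2), which preserves each point's
    A coordinate.  Points landing on the same projected Y are merged by
    averaging their corrections; the curve is sorted by y_proj.
    """
    config = config or PipelineConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if not (x.size == y.size == fitted.size) or x.size == 0:
        raise NormalizationError("x, y, fitted must be aligned and non-empty")
    d = fitted - (x - y)
    y_proj = y - d / 2.0
    uniq, inverse = np.unique(y_proj, return_inverse=True)
    corr = np.bincount(inverse, weights=fitted) / np.bincount(inverse)
    x_proj = uniq + corr
    k = min(config.extrapolation_points, uniq.size)
    return FitCurve(
        y_proj=uniq,
        x_proj=x_proj,
        correction=corr,
        head_correction=float(corr[:k].mean()),
        tail_correction=float(corr[-k:].mean()),
    )


# ---------------------------------------------------------------------------
# Stage 5: application
# ---------------------------------------------------------------------------

def apply_fit_curve(
    sample: np.ndarray, curve: FitCurve, config: PipelineConfig | None = None
) -> np.ndarray:
    """Normalize every probe on the chip through the fit curve.

    The correction at a probe's log intensity is linearly interpolated over
    the curve's y_proj grid; below/above the trained range the head/tail
    mean correction applies.  The corrected intensity is
    base^(log(y) + correction); probes excluded from training are corrected
    like any other.
    """
    config = config or PipelineConfig()
    if curve.n_points < 2:
        raise NormalizationError("fit curve needs ≥ 2 points to interpolate")
    logy = safe_log(np.asarray(sample, dtype=float), config.log_base)
    corr = np.interp(logy, curve.y_proj, curve.correction)
    corr = np.where(logy < curve.y_proj[0], curve.head_correction, corr)
    corr = np.where(logy > curve.y_proj[-1], curve.tail_correction, corr)
    return config.exp(logy + corr)


# ---------------------------------------------------------------------------
# Full pair
# ---------------------------------------------------------------------------

def normalize_pair(
    sample: np.ndarray,
    reference: np.ndarray,
    layout: ChipLayout | None = None,
    config: PipelineConfig | None = None,
    feature_ids: list[str] | None = None,
    training_sample: np.ndarray | None = None,
    training_reference: np.ndarray | None = None,
) -> tuple[np.ndarray, FitCurve, TrainingSet, dict]:
    """Normalize one sample vector against one reference vector.

    ``training_sample`` / ``training_reference`` optionally supply the raw
    (pre-background-subtraction) intensities used only for the candidate
    exclusion rules (saturation is a property of the scanner reading, not of
    the corrected value); curve training and application always use
    ``sample`` and ``reference``.  The reference is never modified, and
    normalizing a vector against itself returns it unchanged.

    Returns (normalized vector, fit curve, training set, report record).
    """
    config = config or PipelineConfig()
    sample = np.asarray(sample, dtype=float)
    reference = np.asarray(reference, dtype=float)
    ts_sample = sample if training_sample is None else np.asarray(training_sample, float)
    ts_reference = (
        reference if training_reference is None else np.asarray(training_reference, float)
    )
    try:
        candidates = build_training_set(
            ts_sample, ts_reference, layout=layout, config=config, feature_ids=feature_ids
        )
        logx = safe_log(reference, config.log_base)[candidates]
        logy = safe_log(sample, config.log_base)[candidates]
        training = iterative_rank_prune(logx, logy, config)
    except NormalizationError as exc:
        raise NormalizationError(f"training-set stage: {exc}", exc.trajectory) from exc
    # map surviving indices back to full-vector positions
    training.indices = candidates[training.indices]

    order = np.argsort(training.x + training.y, kind="stable")
    xs, ys = training.x[order], training.y[order]
    weights = density_weights(xs + ys, config)
    fitted = fit_correction(xs, ys, weights, config)
    curve = build_fit_curve(xs, ys, fitted, config)
    normalized = apply_fit_curve(sample, curve, config)

    record = {
        "iterations": training.n_iterations,
        "initial_training_size": training.iteration_sizes[0],
        "final_training_size": training.size,
        "iteration_sizes": list(training.iteration_sizes),
        "converged": training.converged,
        "correction_min": float(curve.correction.min()),
        "correction_median": float(np.median(curve.correction)),
        "correction_max": float(curve.correction.max()),
    }
    return normalized, curve, training, record


def median_scale_pair(sample: np.ndarray, reference: np.ndarray,
                      log_base: float = 2.0) -> np.ndarray:
    """Naive global-median scaling baseline (single multiplicative factor).

    Included only for comparison: it matches the median log ratio but cannot
    remove intensity-dependent distortion and is biased by one-sided
    differential expression.
    """
    ls = safe_log(np.asarray(sample, float), log_base)
    lr = safe_log(np.asarray(reference, float), log_base)
    shift = float(np.median(lr - ls))
    return np.asarray(sample, float) * log_base ** shift
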