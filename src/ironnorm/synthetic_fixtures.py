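"""Synthetic chip sets with known ground truth.

The generator emulates the intensity structure the normalization pipeline
is built for: a shared true signal per probe — log-normal latent probeset
expression times a log-normal probe affinity, plus an exponentially
distributed signal component — observed on each chip through a chip-
specific strictly monotone distortion (nonlinear scanner/labelling
response), with additive normal background noise, a small multiplicative
log-normal measurement term, saturation clipping, and an optional
uni-directional "arm" of differentially expressed probesets shifted up on
designated chips (the asymmetric situation that defeats symmetry-assuming
normalization).

Truth tables record latent expression, arm membership and per-chip
distortions, so every recovery metric can be computed exactly.  The same
seed always reproduces the same data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .data_model import ChipLayout, ExpressionMatrix

__all__ = ["SimSpec", "simulate_chip_set", "distortion_library"]


def distortion_library(name: str, params: dict | None = None) -> Callable[[np.ndarray], np.ndarray]:
    """Named strictly increasing maps on positive intensities.

    - ``identity``: f(x) = x
    - ``gain``: f(x) = c·x  (params: c > 0)
    - ``gamma_curve``: f(x) = pivot·(x/pivot)^g — a power-law response
      pivoted so the intensity ``pivot`` (typically the chip median) is
      preserved (params: g > 0, pivot > 0)
    - ``smooth_spline_warp``: monotone PCHIP interpolant through anchor
      points in log2 space, linear beyond the anchors
      (params: anchors = [(x, y), ...], both coordinates strictly increasing)
    """
    params = dict(params or {})
    if name == "identity":
        return lambda x: np.asarray(x, dtype=float)
    if name == "gain":
        c = float(params.get("c", 1.0))
        if c <= 0:
            raise ValueError("gain requires c > 0")
        return lambda x: c * np.asarray(x, dtype=float)
    if name == "gamma_curve":
        g = float(params.get("g", 1.0))
        pivot = float(params.get("pivot", 1.0))
        if g <= 0 or pivot <= 0:
            raise ValueError("gamma_curve requires g > 0 and pivot > 0")
        return lambda x: pivot * (np.asarray(x, dtype=float) / pivot) ** g
    if name == "smooth_spline_warp":
        anchors = np.asarray(params["anchors"], dtype=float)
        if anchors.ndim != 2 or anchors.shape[0] < 2:
            raise ValueError("smooth_spline_warp needs ≥ 2 (x, y) anchors")
        ax, ay = np.log2(anchors[:, 0]), np.log2(anchors[:, 1])
        if np.any(np.diff(ax) <= 0) or np.any(np.diff(ay) <= 0):
            raise ValueError("anchor set must be strictly increasing in x and y")
        interp = PchipInterpolator(ax, ay, extrapolate=False)
        slope_lo = (ay[1] - ay[0]) / (ax[1] - ax[0])
        slope_hi = (ay[-1] - ay[-2]) / (ax[-1] - ax[-2])

        def warp(x: np.ndarray) -> np.ndarray:
            lx = np.log2(np.asarray(x, dtype=float))
            ly = interp(lx)
            ly = np.where(lx < ax[0], ay[0] + slope_lo * (lx - ax[0]), ly)
            ly = np.where(lx > ax[-1], ay[-1] + slope_hi * (lx - ax[-1]), ly)
            return np.power(2.0, ly)

        return warp
    raise ValueError(f"unknown distortion {name!r}")


@dataclass
class SimSpec:
    """Simulation parameters.

    Defaults describe a well-hybridized single-channel oligo array: latent
    probeset expression log-normal around 2^11 with 2.5 log2 units of
    spread, ×5 probes per probeset with 1 log2 unit of affinity spread, an
    exponential signal component of mean 200 (rate 0.005), additive normal
    background N(100, 15²), ~1% CV of multiplicative measurement noise at
    moderate-to-high intensity (the additive background supplies the
    low-intensity noise), and 16-bit saturation at 65 535.
    """

    n_probes: int = 10_000
    n_probesets: int = 2_000
    probes_per_set: int = 5
    n_chips: int = 2
    bg_mu: float = 100.0
    bg_sigma: float = 15.0
    signal_rate: float = 0.005
    latent_log2_mean: float = 11.0
    latent_log2_sd: float = 2.5
    affinity_log2_sd: float = 1.0
    noise_log2_sd: float = 0.015
    distortion: list[tuple[str, dict]] | None = None
    arm_fraction: float = 0.0
    arm_log2_shift: tuple[float, float] = (1.0, 3.0)
    arm_chips: list[int] | None = None
    masked_fraction: float = 0.0
    qc_fraction: float = 0.0
    saturation_cap: float = 65_535.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.arm_fraction < 1.0):
            raise ValueError("arm_fraction must be in [0, 1)")
        for name in ("signal_rate", "latent_log2_sd", "affinity_log2_sd", "saturation_cap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("bg_sigma", "noise_log2_sd", "masked_fraction", "qc_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")
        if self.n_probesets * self.probes_per_set != self.n_probes:
            raise ValueError(
                f"infeasible spec: {self.n_probesets} probesets × "
                f"{self.probes_per_set} probes ≠ {self.n_probes} probes"
            )
        if self.n_chips < 1:
            raise ValueError("need ≥ 1 chip")


def simulate_chip_set(spec: SimSpec) -> tuple[ExpressionMatrix, ChipLayout, dict[str, pd.DataFrame]]:
    """Generate (matrix, layout, truth tables) for a chip set.

    The per-probe true signal (latent × affinity + exponential component)
    is drawn once and shared across chips; per-chip variation comes from
    the distortion, the arm shifts, the multiplicative measurement noise
    and the additive background.  Arm probesets are an exact
    ``round(arm_fraction · n_probesets)``-size random subset, shifted by a
    per-probeset Uniform(arm_log2_shift) factor on the designated chips
    (default: every chip except the first, so chip 0 can serve as an
    undistorted reference).
    """
    rng = np.random.default_rng(spec.seed)
    n_ps, k, n_p, n_c = spec.n_probesets, spec.probes_per_set, spec.n_probes, spec.n_chips

    probeset_ids = [f"ps{is_:05d}" for is_ in range(n_ps)]
    probe_ids = [f"p{ip:06d}" for ip in range(n_p)]
    set_of_probe = np.repeat(np.arange(n_ps), k)

    latent_log2 = rng.normal(spec.latent_log2_mean, spec.latent_log2_sd, n_ps)
    affinity_log2 = rng.normal(0.0, spec.affinity_log2_sd, n_p)
    base_signal = np.power(2.0, latent_log2[set_of_probe] + affinity_log2)
    expo = rng.exponential(1.0 / spec.signal_rate, n_p)
    true_signal = base_signal + expo

    n_arm = round(spec.arm_fraction * n_ps)
    arm_sets = np.zeros(n_ps, dtype=bool)
    arm_sets[rng.permutation(n_ps)[:n_arm]] = True
    arm_shift_log2 = np.where(
        arm_sets, rng.uniform(*spec.arm_log2_shift, n_ps), 0.0
    )
    arm_probes = arm_sets[set_of_probe]
    arm_chips = set(spec.arm_chips if spec.arm_chips is not None else range(1, n_c))

    distortions = spec.distortion or [("identity", {})] * n_c
    if len(distortions) != n_c:
        raise ValueError(f"need one distortion per chip ({n_c}), got {len(distortions)}")

    values = np.empty((n_p, n_c))
    chip_rows = []
    for c in range(n_c):
        name, params = distortions[c]
        signal = true_signal.copy()
        if c in arm_chips:
            signal = signal * np.power(2.0, arm_shift_log2[set_of_probe])
        if name == "gamma_curve" and "pivot" not in params:
            params = {**params, "pivot": float(np.median(signal))}
        f = distortion_library(name, params)
        distorted = f(signal)
        if spec.noise_log2_sd > 0:
            distorted = distorted * np.power(
                2.0, rng.normal(0.0, spec.noise_log2_sd, n_p)
            )
        observed = distorted + rng.normal(spec.bg_mu, spec.bg_sigma, n_p)
        values[:, c] = np.clip(observed, 0.0, spec.saturation_cap)
        chip_rows.append(
            {"sample_id": f"chip{c:02d}", "distortion": name,
             "params": json.dumps(params, sort_keys=True),
             "arm_applied": c in arm_chips}
        )

    layout = ChipLayout(
        probe_to_probeset={p: probeset_ids[s] for p, s in zip(probe_ids, set_of_probe)}
    )
    n_masked = round(spec.masked_fraction * n_p)
    n_qc = round(spec.qc_fraction * n_p)
    flagged = rng.permutation(n_p)
    layout.masked = {probe_ids[i] for i in flagged[:n_masked]}
    layout.qc_probes = {probe_ids[i] for i in flagged[n_masked:n_masked + n_qc]}

    matrix = ExpressionMatrix(
        probe_ids, [r["sample_id"] for r in chip_rows], values, "linear"
    )
    truth = {
        "latent": pd.DataFrame(
            {"probeset_id": probeset_ids, "latent_log2": latent_log2,
             "arm": arm_sets, "arm_shift_log2": arm_shift_log2}
        ),
        "probes": pd.DataFrame(
            {"probe_id": probe_ids,
             "probeset_id": [probeset_ids[s] for s in set_of_probe],
             "affinity_log2": affinity_log2,
             "true_signal": true_signal,
             "arm": arm_probes}
        ),
        "chips": pd.DataFrame(chip_rows),
    }
    return matrix, layout, truth
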