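"""Ex vivo intact-muscle mechanics: PCSA normalization, force–frequency
sigmoid fitting, curve comparison, and fatigue.

Specific force is raw force (mN) divided by the physiological
cross-sectional area,

    PCSA (cm²) = muscle mass (g) · cos(θ) / (ρ (g·cm⁻³) · fiber length (cm)),

with pennation angle θ and fiber length = (fiber length / muscle length
ratio) · optimal muscle length L0. The force–frequency relation is fit with
the four-parameter sigmoid

    P0(F) = P0min + (P0max − P0min) / (1 + exp[(Fhalf − F) / k]),

where Fhalf is the frequency at half-maximal activation and 1/k the
steepness. Genotype curves are compared with an extra-sum-of-squares F-test
(pooled single-curve fit vs per-group fits). Fatiguability over repeated
tetani is summarized by the index mean(last 5 forces)/mean(first 5 forces).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from lmfit import Model
from scipy.stats import f as f_dist

__all__ = [
    "MUSCLE_DENSITY",
    "SOL_FREQUENCIES",
    "EDL_FREQUENCIES",
    "MuscleGeometry",
    "SigmoidParams",
    "SigmoidFit",
    "FTestResult",
    "sigmoid",
    "compute_pcsa",
    "fit_force_frequency",
    "compare_curves_f_test",
    "fatigue_index",
    "simulate_force_frequency",
]

MUSCLE_DENSITY = 1.056  # g·cm⁻³, standard mammalian skeletal muscle

# Stimulation grids used in the force–frequency protocol; the EDL adds two
# high-frequency points to capture its faster activation.
SOL_FREQUENCIES = (1.0, 5.0, 10.0, 20.0, 40.0, 60.0, 80.0, 100.0, 150.0)
EDL_FREQUENCIES = SOL_FREQUENCIES + (200.0, 250.0)

_N_SIGMOID_PARAMS = 4


@dataclass(frozen=True)
class MuscleGeometry:
    """Geometry needed for PCSA: mass, optimal length, pennation, fiber ratio."""

    mass_g: float
    length_cm: float  # optimal muscle length L0
    pennation_deg: float
    fiber_length_ratio: float  # fiber length / muscle length
    density: float = MUSCLE_DENSITY

    def __post_init__(self) -> None:
        if min(self.mass_g, self.length_cm, self.fiber_length_ratio, self.density) <= 0:
            raise ValueError("geometry fields must be positive")
        if not (0.0 <= self.pennation_deg < 90.0):
            raise ValueError("pennation angle must lie in [0, 90) degrees")

    @property
    def fiber_length_cm(self) -> float:
        return self.fiber_length_ratio * self.length_cm


@dataclass(frozen=True)
class SigmoidParams:
    """Force–frequency sigmoid parameters (specific-force units, Hz)."""

    p0min: float
    p0max: float
    fhalf: float
    k: float

    def __post_init__(self) -> None:
        if self.p0max < self.p0min:
            raise ValueError("p0max must be >= p0min")
        if self.k <= 0 or self.fhalf <= 0:
            raise ValueError("k and fhalf must be positive")


@dataclass(frozen=True)
class SigmoidFit:
    params: SigmoidParams
    rss: float
    n_points: int
    converged: bool
    degenerate: bool  # flat data: fitted amplitude ≈ 0


@dataclass(frozen=True)
class FTestResult:
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    rss_pooled: float
    rss_separate: float


def sigmoid(freq, p0min: float, p0max: float, fhalf: float, k: float):
    """Evaluate the force–frequency sigmoid at ``freq`` (Hz)."""
    freq = np.asarray(freq, dtype=float)
    out = p0min + (p0max - p0min) / (1.0 + np.exp((fhalf - freq) / k))
    return out if out.ndim else float(out)


def compute_pcsa(geom: MuscleGeometry) -> float:
    """Physiological cross-sectional area in cm²."""
    return (
        geom.mass_g
        * math.cos(math.radians(geom.pennation_deg))
        / (geom.density * geom.fiber_length_cm)
    )


def _fit_sigmoid(freqs: np.ndarray, forces: np.ndarray) -> SigmoidFit:
    span = float(freqs[-1] - freqs[0])
    mid = (forces.min() + forces.max()) / 2.0
    fhalf0 = float(freqs[np.argmin(np.abs(forces - mid))])
    model = Model(sigmoid, independent_vars=["freq"])
    params = model.make_params(
        p0min=float(forces.min()),
        p0max=float(forces.max()),
        fhalf=max(fhalf0, 1e-3),
        k=span / 4.0,
    )
    params["k"].set(min=1e-6, max=10 * span)
    params["fhalf"].set(min=1e-6, max=10 * freqs[-1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(forces, params, freq=freqs)
    v = result.params.valuesdict()
    scale = max(1.0, float(np.max(np.abs(forces))))
    amplitude = v["p0max"] - v["p0min"]
    fitted = SigmoidParams(
        p0min=min(v["p0min"], v["p0max"]),
        p0max=max(v["p0min"], v["p0max"]),
        fhalf=v["fhalf"],
        k=v["k"],
    )
    return SigmoidFit(
        params=fitted,
        rss=float(np.sum(result.residual**2)),
        n_points=int(freqs.size),
        converged=bool(result.success),
        degenerate=bool(abs(amplitude) <= 1e-8 + 1e-4 * scale),
    )


def fit_force_frequency(freqs, forces) -> SigmoidFit:
    """Least-squares fit of the four-parameter force–frequency sigmoid.

    Initialization comes from the data: P0min/P0max from the force extremes,
    Fhalf from the frequency nearest mid-range force, k from a quarter of the
    frequency span. The data need not be monotone (noise is allowed); flat
    data are flagged ``degenerate``.
    """
    freqs = np.asarray(freqs, dtype=float)
    forces = np.asarray(forces, dtype=float)
    if freqs.size != forces.size:
        raise ValueError("frequencies and forces differ in length")
    if np.unique(freqs).size < 5:
        raise ValueError("need at least 5 distinct stimulation frequencies")
    if np.any(freqs <= 0) or np.any(np.diff(freqs) <= 0):
        raise ValueError("frequencies must be positive and strictly increasing")
    return _fit_sigmoid(freqs, forces)


def _pooled_rss(curves: list[tuple[np.ndarray, np.ndarray]]) -> float:
    freqs = np.concatenate([np.asarray(f, dtype=float) for f, _ in curves])
    forces = np.concatenate([np.asarray(y, dtype=float) for _, y in curves])
    order = np.argsort(freqs, kind="stable")
    f_sorted, y_sorted = freqs[order], forces[order]
    # allow ties across curves: collapse to strictly increasing grid for the
    # monotonicity check by fitting on the raw points directly
    span = float(f_sorted[-1] - f_sorted[0])
    mid = (y_sorted.min() + y_sorted.max()) / 2.0
    model = Model(sigmoid, independent_vars=["freq"])
    params = model.make_params(
        p0min=float(y_sorted.min()),
        p0max=float(y_sorted.max()),
        fhalf=max(float(f_sorted[np.argmin(np.abs(y_sorted - mid))]), 1e-3),
        k=max(span / 4.0, 1e-3),
    )
    params["k"].set(min=1e-6, max=10 * max(span, 1.0))
    params["fhalf"].set(min=1e-6, max=10 * f_sorted[-1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(y_sorted, params, freq=f_sorted)
    return float(np.sum(result.residual**2))


def compare_curves_f_test(group_a, group_b) -> FTestResult:
    """Extra-sum-of-squares F-test for a genotype effect on the sigmoid.

    Groups are lists of ``(frequencies, forces)`` curves. The null model fits
    one sigmoid to all points of both groups; the alternative fits one per
    group. F = [(RSS_pooled − RSS_sep)/(df_pooled − df_sep)] / (RSS_sep/df_sep)
    with df = n_points − n_parameters.
    """
    group_a = [(np.asarray(f, float), np.asarray(y, float)) for f, y in group_a]
    group_b = [(np.asarray(f, float), np.asarray(y, float)) for f, y in group_b]
    if not group_a or not group_b:
        raise ValueError("each group needs at least one curve")
    n_total = sum(y.size for _, y in group_a + group_b)
    df_sep = n_total - 2 * _N_SIGMOID_PARAMS
    df_pooled = n_total - _N_SIGMOID_PARAMS
    if df_sep <= 0:
        raise ValueError("too few points for the separate-curves model")

    rss_pooled = _pooled_rss(group_a + group_b)
    rss_sep = _pooled_rss(group_a) + _pooled_rss(group_b)

    df_num = df_pooled - df_sep
    extra = max(rss_pooled - rss_sep, 0.0)
    if rss_sep <= 1e-12 * max(1.0, rss_pooled):
        # both models interpolate: no evidence of a group effect
        f_stat = 0.0 if extra <= 1e-12 else float("inf")
    else:
        f_stat = (extra / df_num) / (rss_sep / df_sep)
    p_value = float(f_dist.sf(f_stat, df_num, df_sep))
    return FTestResult(
        f_statistic=float(f_stat),
        df_num=df_num,
        df_den=df_sep,
        p_value=p_value,
        rss_pooled=rss_pooled,
        rss_separate=rss_sep,
    )


def fatigue_index(forces) -> float:
    """mean(last 5 forces) / mean(first 5 forces) over a fatigue series."""
    forces = np.asarray(forces, dtype=float)
    if forces.size < 10:
        raise ValueError("fatigue series needs at least 10 repetitions")
    first = float(np.mean(forces[:5]))
    if first == 0.0:
        raise ValueError("mean of the first 5 forces is zero")
    return float(np.mean(forces[-5:])) / first


def simulate_force_frequency(
    params: SigmoidParams,
    frequencies=EDL_FREQUENCIES,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sigmoid evaluated on a stimulation grid plus Gaussian noise; seeded."""
    freqs = np.asarray(frequencies, dtype=float)
    forces = sigmoid(freqs, params.p0min, params.p0max, params.fhalf, params.k)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        forces = forces + rng.normal(0.0, noise_sd, size=freqs.size)
    return freqs, np.asarray(forces, dtype=float)
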