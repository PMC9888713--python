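"""The Modulated Ricker Wavelet (MRW) tuning-curve model and its response operator.

The MRW is a four-parameter family of spectral tuning curves interpolating
between a Gaussian (no inhibitory sidebands) and a Ricker ("Mexican hat")
wavelet with symmetric sidebands, with a skewness term that can suppress one
sideband entirely:

    MRW(f) = A * (w^2 - IE * (f - mu)^2) * exp(-(f - mu)^2 / (2 w^2)) * phi*(f)

    phi*(f) = (0.5 + 0.5 s) * Phi(f; mu, w/2) + (0.5 - 0.5 s) * (1 - Phi(f; mu, w/2))

where f is frequency in octaves, Phi is the Gaussian CDF, and A normalizes
the maximum to 1.  IE = 1, s = 0 recovers the classic Ricker wavelet;
IE = 0 a pure Gaussian; s = +1 leaves inhibition only above the peak.

A model neuron's response to a stimulus is the positively rectified inner
product of its tuning curve with the stimulus spectrum vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .stimgrid import FrequencyAxis, SpectrumVector, StimulusGrid, stimulus_matrix

__all__ = [
    "MRWParams",
    "TuningCurve",
    "ModelFBRA",
    "phi_star",
    "mrw_eval",
    "mrw_weights",
    "respond",
    "model_fbra",
    "model_nfbra",
]

#: The phi* sigmoid's standard deviation as a fraction of w.
PHI_SIGMA_FRACTION = 0.5

#: Parameter bounds.
W_MIN_OCT = 0.05


@dataclass(frozen=True)
class MRWParams:
    """MRW parameters: position mu (oct re 1 kHz), width w (oct), IE, skew s."""

    mu: float
    w: float
    IE: float
    s: float

    def __post_init__(self):
        if self.w < W_MIN_OCT:
            raise ValueError(f"w must be >= {W_MIN_OCT} octaves")
        if not 0 <= self.IE <= 1:
            raise ValueError("IE must lie in [0, 1]")
        if not -1 <= self.s <= 1:
            raise ValueError("s must lie in [-1, 1]")

    @property
    def mu_khz(self) -> float:
        return float(2.0**self.mu)

    @classmethod
    def from_khz(cls, mu_khz: float, w: float, IE: float, s: float) -> "MRWParams":
        return cls(mu=float(np.log2(mu_khz)), w=w, IE=IE, s=s)


@dataclass(frozen=True)
class TuningCurve:
    """Signed spectral weights, normalized so the maximum is 1."""

    axis: FrequencyAxis
    weights: np.ndarray
    norm_A: float
    params: MRWParams | None = field(default=None, compare=False)


@dataclass(frozen=True)
class ModelFBRA:
    """Predicted (rectified, >= 0) responses over a stimulus grid."""

    grid: StimulusGrid
    values: np.ndarray  # (n_bandwidths, n_center_freqs)

    @property
    def flat(self) -> np.ndarray:
        """Condition-ordered vector (bandwidth-major, matching grid.specs)."""
        return self.values.ravel()


def phi_star(f, mu: float, w: float, s: float):
    """Sigmoid-mixture modulation weight in [0, 1].

    A weighted sum of a rising and a falling Gaussian CDF (sigma = w/2);
    s = 0 gives a constant 1/2, s = +/-1 a single sigmoid.
    """
    if w <= 0:
        raise ValueError("w must be positive")
    z = (np.asarray(f, dtype=float) - mu) / (PHI_SIGMA_FRACTION * w)
    cdf = ndtr(z)
    return (0.5 + 0.5 * s) * cdf + (0.5 - 0.5 * s) * (1.0 - cdf)


def mrw_weights(params: MRWParams, f_oct: np.ndarray) -> np.ndarray:
    """Unnormalized MRW evaluated at frequencies f_oct (octaves)."""
    d = np.asarray(f_oct, dtype=float) - params.mu
    poly = params.w**2 - params.IE * d**2
    env = np.exp(-(d**2) / (2.0 * params.w**2))
    return poly * env * phi_star(f_oct, params.mu, params.w, params.s)


def mrw_eval(params: MRWParams, axis: FrequencyAxis) -> TuningCurve:
    """Evaluate the MRW on an axis and normalize its maximum to 1."""
    x = axis.oct
    if not x[0] <= params.mu <= x[-1]:
        raise ValueError("axis does not cover the excitatory peak at mu")
    raw = mrw_weights(params, x)
    peak = raw.max()
    if peak <= 0:
        raise ValueError("MRW has no positive peak on this axis")
    A = 1.0 / peak
    return TuningCurve(axis=axis, weights=raw * A, norm_A=A, params=params)


def respond(curve: TuningCurve, stim: SpectrumVector) -> float:
    """Rectified inner product of tuning curve and stimulus spectrum.

    step_oct is the integration measure, so responses are resolution-independent.
    """
    if curve.axis != stim.axis:
        raise ValueError("tuning curve and stimulus are on different axes")
    v = float(np.dot(curve.weights, stim.weights)) * curve.axis.step_oct
    return max(0.0, v)


def _respond_matrix(curve_weights: np.ndarray, S: np.ndarray, step_oct: float) -> np.ndarray:
    """Vectorized rectified responses for a stimulus matrix S (n_cond, n_bins)."""
    return np.maximum(0.0, S @ curve_weights * step_oct)


def model_fbra(
    params: MRWParams,
    grid: StimulusGrid,
    axis: FrequencyAxis,
    S: np.ndarray | None = None,
) -> ModelFBRA:
    """Predicted FBRA: one rectified response per grid cell.

    A precomputed stimulus matrix `S` (from stimgrid.stimulus_matrix) may be
    passed to avoid rebuilding the spectral vectors.
    """
    if S is None:
        S = stimulus_matrix(grid, axis)
    curve = mrw_eval(params, axis)
    vals = _respond_matrix(curve.weights, S, axis.step_oct)
    return ModelFBRA(grid=grid, values=vals.reshape(grid.shape))


def model_nfbra(
    params: MRWParams,
    notch_grid: StimulusGrid,
    axis: FrequencyAxis,
    S: np.ndarray | None = None,
) -> ModelFBRA:
    """Predicted nFBRA: identical response machinery on the notch grid."""
    return model_fbra(params, notch_grid, axis, S=S)
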