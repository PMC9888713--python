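"""Quadrant classification and top- vs bottom-edge frequency tuning.

Units with strong inhibition above the excitatory band (high IE, positive s;
"Q1") are candidate spectral-edge detectors: their responses should be a
function of the top edge frequency f_t = f_c * 2^(b/2) of a broadband
stimulus rather than of its bottom edge f_b = f_c * 2^(-b/2).  This module
classifies fitted units into the s x IE quadrants, fits Gaussians to the
response-vs-edge-frequency scatters, and compares the goodness-of-fit gap
delta_R2 = R2_top - R2_bottom between Q1 and the remaining units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .fbra_builder import FBRA
from .mrw_model import MRWParams

__all__ = [
    "QuadrantLabel",
    "TuningFit",
    "EdgeTestResult",
    "edge_frequencies",
    "edge_tuning_fit",
    "classify_quadrant",
    "population_edge_test",
]

DEFAULT_S_CUT = 0.0
DEFAULT_IE_CUT = 0.5


@dataclass(frozen=True)
class QuadrantLabel:
    label: str  # Q1..Q4
    s_cut: float
    ie_cut: float


@dataclass(frozen=True)
class TuningFit:
    """Gaussian fit of responses against one edge frequency (log2 domain)."""

    edge: str  # "top" or "bottom"
    amplitude: float
    mean_oct: float  # octaves re 1 kHz
    sd_oct: float
    offset: float
    r2: float
    degenerate: bool = False

    @property
    def mean_khz(self) -> float:
        return float(2.0**self.mean_oct)


@dataclass(frozen=True)
class EdgeTestResult:
    delta_r2: np.ndarray  # per unit
    q1_mask: np.ndarray
    t_stat: float | None
    p_value: float | None
    mean_q1: float | None
    mean_rest: float | None
    skipped: bool
    notice: str | None = None


def edge_frequencies(f_c: float, b: float) -> tuple[float, float]:
    """Bottom and top edges (f_b, f_t) = f_c * 2^(-b/2), f_c * 2^(b/2)."""
    return f_c * 2.0 ** (-b / 2.0), f_c * 2.0 ** (b / 2.0)


def _gauss(x, amp, mean, sd, offset):
    return amp * np.exp(-((x - mean) ** 2) / (2.0 * sd**2)) + offset


def edge_tuning_fit(
    fbra: FBRA,
    grid=None,
    edge: str = "top",
    fit_offset: bool = False,
) -> TuningFit:
    """Least-squares Gaussian fit of all cell responses against log2(edge freq).

    Pure tones are included (f_t = f_b = f_c).  The fit runs on log2
    frequency (octaves); the additive offset defaults to 0 and can be freed
    with `fit_offset`.
    """
    grid = grid if grid is not None else fbra.grid
    if edge not in ("top", "bottom"):
        raise ValueError("edge must be 'top' or 'bottom'")
    fb, ft = grid.edge_frequencies()
    x = np.log2(ft if edge == "top" else fb)
    if len(np.unique(np.round(x, 9))) < 6:
        raise ValueError("need at least 6 distinct edge-frequency values")
    y = fbra.flat
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0:
        return TuningFit(edge, np.nan, np.nan, np.nan, np.nan, np.nan, degenerate=True)

    amp0 = float(y.max() - y.min())
    mean0 = float(x[np.argmax(y)])
    sd0 = 0.5
    span = x.max() - x.min()
    if fit_offset:
        p0 = [amp0, mean0, sd0, float(y.min())]
        bounds = ([0, x.min() - span, 0.01, -np.inf], [np.inf, x.max() + span, 8.0, np.inf])
        model = _gauss
    else:
        p0 = [amp0, mean0, sd0]
        bounds = ([0, x.min() - span, 0.01], [np.inf, x.max() + span, 8.0])

        def model(xx, amp, mean, sd):
            return _gauss(xx, amp, mean, sd, 0.0)

    try:
        popt, _ = optimize.curve_fit(model, x, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError:
        popt = p0
    yhat = model(x, *popt)
    r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / sstot
    offset = popt[3] if fit_offset else 0.0
    return TuningFit(
        edge=edge,
        amplitude=float(popt[0]),
        mean_oct=float(popt[1]),
        sd_oct=float(popt[2]),
        offset=float(offset),
        r2=max(r2, 0.0) if r2 > -np.inf else np.nan,
    )


def classify_quadrant(
    params: MRWParams,
    s_cut: float = DEFAULT_S_CUT,
    ie_cut: float = DEFAULT_IE_CUT,
) -> QuadrantLabel:
    """s x IE quadrants; Q1 (s >= s_cut and IE >= ie_cut) is the candidate
    top-edge-detector group, Q2-Q3 the low-IE energy summers."""
    if params.s >= s_cut:
        label = "Q1" if params.IE >= ie_cut else "Q2"
    else:
        label = "Q4" if params.IE >= ie_cut else "Q3"
    return QuadrantLabel(label=label, s_cut=s_cut, ie_cut=ie_cut)


def population_edge_test(
    tuning_fits: list[tuple[TuningFit, TuningFit]],
    quadrant_labels: list[QuadrantLabel],
) -> EdgeTestResult:
    """Two-sample t-test of delta_R2 = R2_top - R2_bottom, Q1 vs Q2-Q4.

    `tuning_fits` pairs (top fit, bottom fit) per unit, aligned with
    `quadrant_labels`.
    """
    if len(tuning_fits) != len(quadrant_labels):
        raise ValueError("tuning_fits and quadrant_labels must align")
    delta = np.array([tf.r2 - bf.r2 for tf, bf in tuning_fits])
    q1 = np.array([q.label == "Q1" for q in quadrant_labels])
    valid = np.isfinite(delta)
    a, b = delta[q1 & valid], delta[~q1 & valid]
    if len(a) < 2 or len(b) < 2:
        return EdgeTestResult(
            delta_r2=delta,
            q1_mask=q1,
            t_stat=None,
            p_value=None,
            mean_q1=float(a.mean()) if len(a) else None,
            mean_rest=float(b.mean()) if len(b) else None,
            skipped=True,
            notice="a group has < 2 units; comparison skipped",
        )
    t, p = stats.ttest_ind(a, b)
    return EdgeTestResult(
        delta_r2=delta,
        q1_mask=q1,
        t_stat=float(t),
        p_value=float(p),
        mean_q1=float(a.mean()),
        mean_rest=float(b.mean()),
        skipped=False,
    )
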