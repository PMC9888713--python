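"""From trial-resolved spikes to PSTHs, evoked-rate FBRAs, and a responsiveness screen.

Evoked rate for a condition is the mean over trials of
(stimulus-window count - preceding-baseline count) / window duration;
the stimulus and baseline windows are both 100 ms.  Responsiveness is a
Bonferroni-corrected one-tailed paired t-test of stimulus vs baseline counts,
requiring a significant excitatory ON response to at least one broadband
stimulus (b > 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .stimgrid import StimulusGrid

__all__ = [
    "UnitSpikes",
    "FBRA",
    "PSTH",
    "ScreenResult",
    "evoked_rate",
    "build_fbra",
    "build_psth",
    "responsiveness_screen",
    "read_spike_table",
    "write_spike_table",
    "write_fbra",
    "read_fbra",
]

log = logging.getLogger(__name__)

DEFAULT_WINDOW_MS = 100.0
PSTH_BIN_MS = 10.0
#: "highly responsive" cut: minimum peak evoked rate (spikes/s).
DEFAULT_MIN_PEAK_RATE = 5.0


@dataclass
class UnitSpikes:
    """Per-presentation spike counts for one unit.

    Arrays are parallel over presentations: condition index (into the grid's
    spec ordering), trial index, spike count in the 100 ms stimulus window,
    and spike count in the 100 ms immediately before.
    """

    unit_id: str
    condition: np.ndarray
    trial: np.ndarray
    stim_count: np.ndarray
    pre_count: np.ndarray
    window_ms: float = DEFAULT_WINDOW_MS
    spike_times: list | None = None  # optional, per presentation, s re onset

    def __post_init__(self):
        self.condition = np.asarray(self.condition, dtype=int)
        self.trial = np.asarray(self.trial, dtype=int)
        self.stim_count = np.asarray(self.stim_count)
        self.pre_count = np.asarray(self.pre_count)
        n = len(self.condition)
        if not (len(self.trial) == len(self.stim_count) == len(self.pre_count) == n):
            raise ValueError("presentation arrays must have equal length")
        if (self.stim_count < 0).any() or (self.pre_count < 0).any():
            raise ValueError("spike counts must be non-negative")
        pairs = set(zip(self.condition.tolist(), self.trial.tolist()))
        if len(pairs) != n:
            raise ValueError("duplicate (condition, trial) presentation")

    def counts_for(self, cond: int) -> tuple[np.ndarray, np.ndarray]:
        m = self.condition == cond
        order = np.argsort(self.trial[m])
        return self.stim_count[m][order], self.pre_count[m][order]


@dataclass(frozen=True)
class FBRA:
    """Mean evoked rates (spikes/s) over the (bandwidth x center-frequency) grid."""

    grid: StimulusGrid
    values: np.ndarray
    n_trials: np.ndarray = field(default=None)
    unit_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.shape:
            raise ValueError(f"values shape {v.shape} != grid shape {self.grid.shape}")
        if not np.isfinite(v).all():
            raise ValueError("FBRA values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def flat(self) -> np.ndarray:
        return self.values.ravel()


@dataclass(frozen=True)
class PSTH:
    """Per-condition peri-stimulus time histograms at 10 ms bins."""

    bin_edges_ms: np.ndarray
    rates: np.ndarray  # (n_conditions, n_bins), spikes/s


@dataclass(frozen=True)
class ScreenResult:
    responsive: bool
    p_values: np.ndarray  # per condition
    alpha_corrected: float
    peak_evoked_rate: float
    highly_responsive: bool


def evoked_rate(stim_counts, pre_counts, window_ms: float = DEFAULT_WINDOW_MS) -> float:
    """Mean over trials of (stim - baseline) count difference, as spikes/s."""
    stim = np.asarray(stim_counts, dtype=float)
    pre = np.asarray(pre_counts, dtype=float)
    if stim.size == 0 or stim.shape != pre.shape:
        raise ValueError("need equal-length, non-empty trial vectors")
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    return float(np.mean(stim - pre) / (window_ms / 1000.0))


def build_fbra(unit: UnitSpikes, grid: StimulusGrid) -> FBRA:
    """Evoked-rate FBRA for one unit; the same machinery builds nFBRAs.

    Every grid cell must have at least one presentation; missing conditions
    are reported explicitly.
    """
    present = set(np.unique(unit.condition).tolist())
    missing = [c for c in range(grid.n_conditions) if c not in present]
    if missing:
        named = [
            f"(f_c={grid.specs[c].f_c:.3g} kHz, b={grid.specs[c].b:.3g} oct)"
            for c in missing[:5]
        ]
        raise ValueError(
            f"unit {unit.unit_id}: {len(missing)} grid conditions have no trials: "
            + ", ".join(named)
            + ("..." if len(missing) > 5 else "")
        )
    vals = np.empty(grid.n_conditions)
    ntr = np.empty(grid.n_conditions, dtype=int)
    for c in range(grid.n_conditions):
        s, p = unit.counts_for(c)
        vals[c] = evoked_rate(s, p, unit.window_ms)
        ntr[c] = len(s)
    return FBRA(
        grid=grid,
        values=vals.reshape(grid.shape),
        n_trials=ntr.reshape(grid.shape),
        unit_id=unit.unit_id,
    )


def build_psth(unit: UnitSpikes, grid: StimulusGrid, t_max_ms: float | None = None) -> PSTH:
    """10 ms-bin PSTH per condition from per-presentation spike times (s)."""
    if unit.spike_times is None:
        raise ValueError("unit has no spike times")
    t_max = t_max_ms if t_max_ms is not None else unit.window_ms
    edges = np.arange(0.0, t_max + PSTH_BIN_MS / 2, PSTH_BIN_MS)
    rates = np.zeros((grid.n_conditions, len(edges) - 1))
    counts = np.zeros(grid.n_conditions)
    for i in range(len(unit.condition)):
        c = unit.condition[i]
        times_ms = np.asarray(unit.spike_times[i]) * 1000.0
        h, _ = np.histogram(times_ms, bins=edges)
        rates[c] += h
        counts[c] += 1
    with np.errstate(invalid="ignore"):
        rates = rates / counts[:, None] / (PSTH_BIN_MS / 1000.0)
    return PSTH(bin_edges_ms=edges, rates=np.nan_to_num(rates))


def _paired_onetail_p(stim: np.ndarray, pre: np.ndarray) -> float:
    """One-tailed paired t-test p-value for stim > pre, with zero-variance rules."""
    d = stim.astype(float) - pre.astype(float)
    if np.ptp(d) == 0:
        if d.mean() > 0:
            # all-positive constant differences: exact by convention
            log.info("zero-variance positive differences; p set to 0 by convention")
            return 0.0
        return 1.0
    t, p = stats.ttest_rel(stim.astype(float), pre.astype(float), alternative="greater")
    return float(p)


def responsiveness_screen(
    unit: UnitSpikes,
    grid: StimulusGrid,
    alpha: float = 0.05,
    min_peak_rate: float = DEFAULT_MIN_PEAK_RATE,
) -> ScreenResult:
    """Bonferroni-corrected excitatory ON-response screen.

    A unit passes iff some b > 0 (broadband) condition shows stim > baseline
    at p < alpha / n_conditions.  Inhibited-only or notch-only units fail.
    The `highly_responsive` flag additionally requires a peak evoked rate of
    at least `min_peak_rate` spikes/s.
    """
    p = np.ones(grid.n_conditions)
    peak = -np.inf
    for c in range(grid.n_conditions):
        s, pre = unit.counts_for(c)
        if len(s) < 2:
            raise ValueError(f"condition {c} has < 2 trials")
        p[c] = _paired_onetail_p(s, pre)
        peak = max(peak, evoked_rate(s, pre, unit.window_ms))
    alpha_c = alpha / grid.n_conditions
    bbs_mask = ~grid.is_pure_tone
    responsive = bool((p[bbs_mask] < alpha_c).any())
    return ScreenResult(
        responsive=responsive,
        p_values=p,
        alpha_corrected=alpha_c,
        peak_evoked_rate=float(peak),
        highly_responsive=responsive and peak >= min_peak_rate,
    )


# ---------------------------------------------------------------------------
# External interfaces: delimited-text spike tables and FBRA matrices
# ---------------------------------------------------------------------------

SPIKE_COLUMNS = ["unit_id", "condition", "trial", "stim_count", "pre_count"]


def write_spike_table(units: list[UnitSpikes], path: str | Path) -> None:
    frames = []
    for u in units:
        frames.append(
            pd.DataFrame(
                dict(
                    unit_id=u.unit_id,
                    condition=u.condition,
                    trial=u.trial,
                    stim_count=u.stim_count,
                    pre_count=u.pre_count,
                )
            )
        )
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def read_spike_table(path: str | Path, window_ms: float = DEFAULT_WINDOW_MS) -> list[UnitSpikes]:
    df = pd.read_csv(path, sep="\t")
    missing = set(SPIKE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"spike table missing columns: {sorted(missing)}")
    units = []
    for uid, g in df.groupby("unit_id", sort=True):
        units.append(
            UnitSpikes(
                unit_id=str(uid),
                condition=g["condition"].to_numpy(),
                trial=g["trial"].to_numpy(),
                stim_count=g["stim_count"].to_numpy(),
                pre_count=g["pre_count"].to_numpy(),
                window_ms=window_ms,
            )
        )
    return units


def write_fbra(fbra: FBRA, path: str | Path) -> None:
    """FBRA as a delimited matrix: rows bandwidths, columns center freqs (kHz)."""
    df = pd.DataFrame(
        fbra.values,
        index=pd.Index(fbra.grid.bandwidths, name="b_oct"),
        columns=[f"{f:.6g}" for f in fbra.grid.center_freqs],
    )
    df.to_csv(path, sep="\t")


def read_fbra(path: str | Path, grid: StimulusGrid, unit_id: str = "") -> FBRA:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FBRA(grid=grid, values=df.to_numpy(), unit_id=unit_id)
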