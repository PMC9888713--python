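"""Stimulus definitions: frequency grids, tone-complex synthesis, spectral vectors.

The stimulus set is a two-dimensional array of band-limited tone complexes
(BBS, "broadband stimuli") varying in center frequency f_c and full bandwidth
b (octaves), plus the pure tones (b = 0) and the complementary notch stimuli.
Spectrum level is held fixed across bandwidths, so total sound level grows
with bandwidth.

Frequencies live on a log2 axis in octaves re 1 kHz throughout.
"""

from __future__ import annotations

import enum
import wave as _wave
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StimKind",
    "FrequencyAxis",
    "StimulusSpec",
    "StimulusGrid",
    "SpectrumVector",
    "Waveform",
    "default_model_axis",
    "make_center_frequencies",
    "make_bandwidths",
    "make_grid",
    "synthesize_waveform",
    "waveform_level_dbspl",
    "spectral_vector",
    "stimulus_matrix",
    "write_manifest",
    "read_manifest",
    "write_wav",
]

# ---------------------------------------------------------------------------
# Configuration constants (study-wide defaults)
# ---------------------------------------------------------------------------

#: Model frequency axis: octaves re 1 kHz, 0.005-oct step, 1-256 kHz.
MODEL_AXIS_LO_KHZ = 1.0
MODEL_AXIS_HI_KHZ = 256.0
MODEL_AXIS_STEP_OCT = 0.005

#: Cochlear-widening ramp width appended to each rectangular stimulus edge.
RAMP_HALF_OCT = 0.5

#: Synthesis defaults.
COMPONENT_SPACING_OCT = 0.001  # 0.1% octave tone spacing
DEFAULT_DURATION_MS = 100.0
DEFAULT_RAMP_MS = 5.0
DEFAULT_SAMPLE_RATE_HZ = 500_000

#: Calibration: a single pure tone at unit component amplitude maps to this SPL.
PURE_TONE_DBSPL = 55.0

#: Notch global band: low edge fixed, high edge one octave above the top pure tone.
NOTCH_BAND_LO_KHZ = 2.0


class StimKind(str, enum.Enum):
    pure_tone = "pure_tone"
    bbs = "bbs"
    notch = "notch"


def _oct(f_khz):
    """kHz -> octaves re 1 kHz."""
    return np.log2(np.asarray(f_khz, dtype=float))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrequencyAxis:
    """Log2-spaced frequency axis (kHz bin centers)."""

    lo_khz: float
    hi_khz: float
    step_oct: float
    values: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if self.lo_khz <= 0 or self.step_oct <= 0:
            raise ValueError("lo_khz and step_oct must be positive")
        if self.lo_khz >= self.hi_khz:
            raise ValueError("lo_khz must be < hi_khz")
        if self.values is None:
            n = int(round(np.log2(self.hi_khz / self.lo_khz) / self.step_oct)) + 1
            vals = self.lo_khz * 2.0 ** (self.step_oct * np.arange(n))
            object.__setattr__(self, "values", vals)
        steps = np.diff(np.log2(self.values))
        if not np.allclose(steps, self.step_oct, atol=1e-9):
            raise ValueError("axis values are not uniformly log2-spaced")

    @property
    def oct(self) -> np.ndarray:
        """Bin centers in octaves re 1 kHz."""
        return np.log2(self.values)

    def __len__(self):
        return len(self.values)

    def __eq__(self, other):
        return (
            isinstance(other, FrequencyAxis)
            and self.lo_khz == other.lo_khz
            and self.hi_khz == other.hi_khz
            and self.step_oct == other.step_oct
        )

    def __hash__(self):
        return hash((self.lo_khz, self.hi_khz, self.step_oct))


def default_model_axis() -> FrequencyAxis:
    return FrequencyAxis(MODEL_AXIS_LO_KHZ, MODEL_AXIS_HI_KHZ, MODEL_AXIS_STEP_OCT)


@dataclass(frozen=True)
class StimulusSpec:
    """One stimulus condition: kind, center frequency (kHz), full bandwidth (oct)."""

    kind: StimKind
    f_c: float
    b: float
    component_spacing_oct: float = COMPONENT_SPACING_OCT
    duration_ms: float = DEFAULT_DURATION_MS
    ramp_ms: float = DEFAULT_RAMP_MS
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    # notch stimuli need the global band edges (kHz)
    band_lo_khz: float = NOTCH_BAND_LO_KHZ
    band_hi_khz: float | None = None

    def __post_init__(self):
        if self.f_c <= 0:
            raise ValueError("f_c must be positive")
        if self.kind == StimKind.pure_tone and self.b != 0:
            raise ValueError("pure_tone requires b == 0")
        if self.kind != StimKind.pure_tone and self.b <= 0:
            raise ValueError(f"{self.kind.value} requires b > 0")
        if self.ramp_ms >= self.duration_ms / 2:
            raise ValueError("ramp_ms must be < duration_ms / 2")

    @property
    def edges_khz(self) -> tuple[float, float]:
        """Bottom and top edge frequencies f_c * 2^(±b/2)."""
        return self.f_c * 2.0 ** (-self.b / 2), self.f_c * 2.0 ** (self.b / 2)


@dataclass(frozen=True)
class StimulusGrid:
    """All (f_c, b) conditions of one protocol, ordered bandwidth-major."""

    center_freqs: tuple[float, ...]
    bandwidths: tuple[float, ...]
    kind: StimKind
    n_trials: int = 10
    band_hi_khz: float | None = None
    specs: tuple[StimulusSpec, ...] = field(default=None, repr=False)

    def __post_init__(self):
        if not self.center_freqs or not self.bandwidths:
            raise ValueError("center_freqs and bandwidths must be non-empty")
        if list(self.bandwidths) != sorted(self.bandwidths):
            raise ValueError("bandwidths must be sorted ascending")
        if self.kind == StimKind.notch and any(b == 0 for b in self.bandwidths):
            raise ValueError("notch grids cannot contain b == 0")
        band_hi = self.band_hi_khz
        if band_hi is None:
            band_hi = 2.0 * max(self.center_freqs)  # one octave above top pure tone
            object.__setattr__(self, "band_hi_khz", band_hi)
        if self.specs is None:
            specs = []
            for b in self.bandwidths:
                for f_c in self.center_freqs:
                    kind = StimKind.pure_tone if b == 0 else self.kind
                    specs.append(
                        StimulusSpec(kind=kind, f_c=f_c, b=b, band_hi_khz=band_hi)
                    )
            object.__setattr__(self, "specs", tuple(specs))

    @property
    def n_conditions(self) -> int:
        return len(self.specs)

    @property
    def shape(self) -> tuple[int, int]:
        """(n_bandwidths, n_center_freqs), the FBRA matrix shape."""
        return len(self.bandwidths), len(self.center_freqs)

    def condition_index(self, i_bw: int, j_freq: int) -> int:
        return i_bw * len(self.center_freqs) + j_freq

    @property
    def is_pure_tone(self) -> np.ndarray:
        """Boolean mask over conditions: True where b == 0."""
        return np.array([s.kind == StimKind.pure_tone for s in self.specs])

    def edge_frequencies(self) -> tuple[np.ndarray, np.ndarray]:
        """(f_b, f_t) arrays over conditions, kHz."""
        fb = np.array([s.edges_khz[0] for s in self.specs])
        ft = np.array([s.edges_khz[1] for s in self.specs])
        return fb, ft

    def presentation_order(self, seed: int) -> np.ndarray:
        """Pseudo-random order of (condition, trial) presentations."""
        rng = np.random.default_rng(seed)
        pairs = [(c, t) for c in range(self.n_conditions) for t in range(self.n_trials)]
        return rng.permutation(len(pairs)), pairs


@dataclass(frozen=True)
class SpectrumVector:
    """A stimulus as spectrum-level weights (plateau height 1) on a log-f axis."""

    axis: FrequencyAxis
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if len(w) != len(self.axis):
            raise ValueError("weights length must match axis")
        if w.min() < -1e-12 or w.max() > 1 + 1e-9:
            raise ValueError("weights must lie in [0, 1]")
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class Waveform:
    """Synthesized pressure waveform with its calibrated sound level."""

    samples: np.ndarray
    sample_rate_hz: float
    level_dbspl: float


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def make_center_frequencies(lo_khz: float, hi_khz: float, step_oct: float) -> np.ndarray:
    """Log-uniform center frequencies lo * 2^(k * step_oct), k = 0..K.

    K = floor(log2(hi/lo) / step_oct); the top endpoint is included when hi
    is an exact multiple (e.g. 4 -> 64 kHz in quarter octaves: 17 values).
    """
    if lo_khz <= 0 or step_oct <= 0:
        raise ValueError("frequencies and step must be positive")
    if hi_khz < lo_khz:
        raise ValueError("hi_khz must be >= lo_khz")
    span = np.log2(hi_khz / lo_khz) / step_oct
    k_max = int(np.floor(span + 1e-9))
    return lo_khz * 2.0 ** (step_oct * np.arange(k_max + 1))


def make_bandwidths(
    n_nonzero: int = 10, lo_oct: float = 0.05, hi_oct: float = 1.0, include_zero: bool = True
) -> np.ndarray:
    """Bandwidths linearly spaced between 5% and 100% octave, optionally with b=0."""
    if n_nonzero < 1:
        raise ValueError("need at least one nonzero bandwidth")
    bws = np.linspace(lo_oct, hi_oct, n_nonzero)
    if include_zero:
        bws = np.concatenate([[0.0], bws])
    return bws


def make_grid(
    center_freqs,
    bandwidths,
    kind: StimKind | str = StimKind.bbs,
    n_trials: int = 10,
    band_hi_khz: float | None = None,
) -> StimulusGrid:
    """Build the full (f_c, b) condition grid; b == 0 cells render as pure tones."""
    kind = StimKind(kind)
    return StimulusGrid(
        center_freqs=tuple(float(f) for f in center_freqs),
        bandwidths=tuple(float(b) for b in bandwidths),
        kind=kind,
        n_trials=n_trials,
        band_hi_khz=band_hi_khz,
    )


def _component_freqs_khz(spec: StimulusSpec) -> np.ndarray:
    """Tone-complex component frequencies, spaced component_spacing_oct apart."""
    if spec.kind == StimKind.pure_tone:
        return np.array([spec.f_c])
    lo, hi = spec.edges_khz
    if spec.kind == StimKind.bbs:
        n = int(round(spec.b / spec.component_spacing_oct))
        return lo * 2.0 ** (spec.component_spacing_oct * np.arange(n + 1))
    # notch: complement of [lo, hi] within the global band
    if spec.band_hi_khz is None:
        raise ValueError("notch synthesis requires the global band edges")
    segs = []
    for seg_lo, seg_hi in [(spec.band_lo_khz, lo), (hi, spec.band_hi_khz)]:
        if seg_hi <= seg_lo:
            continue
        span = np.log2(seg_hi / seg_lo)
        n = int(round(span / spec.component_spacing_oct))
        segs.append(seg_lo * 2.0 ** (spec.component_spacing_oct * np.arange(n + 1)))
    return np.concatenate(segs)


def synthesize_waveform(spec: StimulusSpec, phase_seed: int, amplitude: float = 1.0) -> Waveform:
    """Sum equal-amplitude cosines with random phases; 5 ms linear on/off ramps.

    The per-component amplitude is fixed across all specs (fixed spectrum
    level), so total level grows with bandwidth. Level is calibrated so a
    single pure tone at `amplitude` measures PURE_TONE_DBSPL.
    """
    freqs_khz = _component_freqs_khz(spec)
    freqs_hz = freqs_khz * 1000.0
    if spec.sample_rate_hz < 2 * freqs_hz.max():
        raise ValueError(
            f"sample rate {spec.sample_rate_hz} Hz below Nyquist for "
            f"{freqs_hz.max():.0f} Hz component"
        )
    n_samples = int(round(spec.duration_ms * spec.sample_rate_hz / 1000.0))
    t = np.arange(n_samples) / spec.sample_rate_hz
    rng = np.random.default_rng(phase_seed)
    phases = rng.uniform(0.0, 2 * np.pi, size=len(freqs_hz))
    x = np.zeros(n_samples)
    for i in range(0, len(freqs_hz), 64):  # chunked: full outer product is ~GB-scale
        fi = freqs_hz[i : i + 64, None]
        pi = phases[i : i + 64, None]
        x += np.cos(2 * np.pi * fi * t[None, :] + pi).sum(axis=0)
    x *= amplitude
    n_ramp = int(round(spec.ramp_ms * spec.sample_rate_hz / 1000.0))
    if n_ramp > 0:
        ramp = np.linspace(0.0, 1.0, n_ramp, endpoint=False)
        x[:n_ramp] *= ramp
        x[-n_ramp:] *= ramp[::-1]
    level = waveform_level_dbspl(
        x, amplitude, duration_ms=spec.duration_ms, ramp_ms=spec.ramp_ms
    )
    return Waveform(samples=x, sample_rate_hz=spec.sample_rate_hz, level_dbspl=level)


def waveform_level_dbspl(
    samples: np.ndarray,
    pure_tone_amplitude: float = 1.0,
    duration_ms: float = DEFAULT_DURATION_MS,
    ramp_ms: float = DEFAULT_RAMP_MS,
) -> float:
    """SPL from waveform RMS, re a pure tone at `pure_tone_amplitude` = PURE_TONE_DBSPL.

    The calibration reference is a pure tone with the same on/off ramps, so a
    calibrated pure tone measures exactly PURE_TONE_DBSPL (each linear ramp
    carries 1/3 of the plateau power).
    """
    rms = np.sqrt(np.mean(np.square(samples)))
    ramp_power = 1.0 - 4.0 * ramp_ms / (3.0 * duration_ms)
    ref_rms = pure_tone_amplitude / np.sqrt(2.0) * np.sqrt(ramp_power)
    return PURE_TONE_DBSPL + 20.0 * np.log10(rms / ref_rms)


def _ramped_band(x: np.ndarray, lo_oct: float, hi_oct: float) -> np.ndarray:
    """Height-1 rectangle on [lo, hi] (octaves) with linear half-octave skirts.

    lo == hi gives the pure-tone triangle.
    """
    up = (x - (lo_oct - RAMP_HALF_OCT)) / RAMP_HALF_OCT
    down = ((hi_oct + RAMP_HALF_OCT) - x) / RAMP_HALF_OCT
    return np.clip(np.minimum(np.minimum(up, down), 1.0), 0.0, 1.0)


def spectral_vector(spec: StimulusSpec, axis: FrequencyAxis) -> SpectrumVector:
    """Stimulus as spectrum-level weights with cochlear widening.

    BBS: height-1 rectangle on [f_c 2^(-b/2), f_c 2^(b/2)] in log frequency
    with linear (in octaves) ramps to 0 at 0.5 oct outside each edge.
    Pure tone: the b -> 0 triangle. Notch: all-ones over the global band with
    the mirrored ramped dip (weights descend into the notch starting 0.5 oct
    outside each notch edge), so a BBS and its complementary notch sum to the
    band profile.
    """
    x = axis.oct
    lo_khz, hi_khz = spec.edges_khz
    lo, hi = _oct(lo_khz), _oct(hi_khz)
    if spec.kind in (StimKind.bbs, StimKind.pure_tone):
        if lo - RAMP_HALF_OCT < x[0] or hi + RAMP_HALF_OCT > x[-1]:
            raise ValueError("axis too narrow to contain the stimulus ramps")
        w = _ramped_band(x, lo, hi)
    else:
        if spec.band_hi_khz is None:
            raise ValueError("notch vector requires the global band edges")
        band_lo, band_hi = _oct(spec.band_lo_khz), _oct(spec.band_hi_khz)
        if band_lo < x[0] or band_hi > x[-1]:
            raise ValueError("axis too narrow for the notch global band")
        band = (x >= band_lo) & (x <= band_hi)
        w = np.where(band, 1.0 - _ramped_band(x, lo, hi), 0.0)
    return SpectrumVector(axis=axis, weights=w)


def stimulus_matrix(grid: StimulusGrid, axis: FrequencyAxis) -> np.ndarray:
    """(n_conditions, n_bins) matrix of spectral vectors, in grid order."""
    return np.vstack([spectral_vector(s, axis).weights for s in grid.specs])


# ---------------------------------------------------------------------------
# External interfaces
# ---------------------------------------------------------------------------


def write_manifest(grid: StimulusGrid, seed: int, path: str | Path, isi_s: float = 1.0) -> pd.DataFrame:
    """Write the presentation manifest (pseudo-random order, 1 s ISI) as TSV."""
    order, pairs = grid.presentation_order(seed)
    rows = []
    for onset_rank, idx in enumerate(order):
        cond, trial = pairs[idx]
        spec = grid.specs[cond]
        rows.append(
            dict(
                presentation=onset_rank,
                onset_s=onset_rank * (spec.duration_ms / 1000.0 + isi_s),
                condition=cond,
                trial=trial,
                kind=spec.kind.value,
                f_c_khz=spec.f_c,
                b_oct=spec.b,
            )
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def grid_from_manifest(df: pd.DataFrame) -> StimulusGrid:
    """Reconstruct the condition grid from a manifest table."""
    conds = df.drop_duplicates("condition").sort_values("condition")
    freqs = sorted(conds["f_c_khz"].unique())
    bws = sorted(conds["b_oct"].unique())
    kinds = set(conds["kind"]) - {"pure_tone"}
    kind = StimKind(kinds.pop()) if kinds else StimKind.bbs
    n_trials = int(df.groupby("condition")["trial"].nunique().max())
    return make_grid(freqs, bws, kind=kind, n_trials=n_trials)


def write_wav(wf: Waveform, path: str | Path, peak_fraction: float = 0.5) -> None:
    """Write a waveform as 16-bit mono RIFF WAV (header accepts 500 kHz)."""
    x = wf.samples
    scale = peak_fraction * 32767.0 / max(np.abs(x).max(), 1e-12)
    data = (x * scale).astype("<i2").tobytes()
    with _wave.open(str(path), "wb") as f:
        f.setnchannels(1)
        f.setsampwidth(2)
        f.setframerate(int(wf.sample_rate_hz))
        f.writeframes(data)
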