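"""Fit MRW parameters to a neuronal FBRA by penalized correlation maximization.

The objective is the negative Pearson correlation between neuronal and model
FBRAs (pure-tone cells excluded) plus a width penalty 0.05 * w that guards
against unrealistically wide tuning curves.  Minimization is a bounded
derivative-free simplex search: parameters are mapped through a sinusoidal
transform onto an unconstrained space (the standard fminsearch-with-bounds
construction) and polished with Nelder-Mead from multiple restarts.

The shuffle control refits after randomly permuting the cell values across
the (f_c, b) grid and reports the mean fitted correlation over shuffles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .fbra_builder import FBRA
from .mrw_model import W_MIN_OCT, MRWParams, model_nfbra, phi_star
from .stimgrid import FrequencyAxis, StimulusGrid, stimulus_matrix

__all__ = [
    "FitConfig",
    "FitResult",
    "objective",
    "fit",
    "shuffle_control",
    "validate_notch",
    "pearson",
]

WIDTH_PENALTY = 0.05  # per octave of w
W_MAX_OCT = 2.0  # upper bound for the sinusoidal transform; the penalty
#                  makes larger widths never optimal


@dataclass(frozen=True)
class FitConfig:
    """Bounds, penalty, restart and shuffle settings for one fit."""

    mu_bounds: tuple[float, float] | None = None  # octaves; None -> presented range
    w_bounds: tuple[float, float] = (W_MIN_OCT, W_MAX_OCT)
    ie_bounds: tuple[float, float] = (0.0, 1.0)
    s_bounds: tuple[float, float] = (-1.0, 1.0)
    width_penalty: float = WIDTH_PENALTY
    exclude_pure_tones: bool = True
    n_restarts: int = 12
    n_shuffles: int = 100
    seed: int = 0
    xatol: float = 1e-4
    fatol: float = 1e-4
    maxfev: int = 2000

    def __post_init__(self):
        if self.width_penalty < 0:
            raise ValueError("width_penalty must be >= 0")
        for name in ("w_bounds", "ie_bounds", "s_bounds"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} out of order")

    def resolved_mu_bounds(self, grid: StimulusGrid) -> tuple[float, float]:
        if self.mu_bounds is not None:
            return self.mu_bounds
        freqs = np.log2(np.asarray(grid.center_freqs))
        return float(freqs.min()), float(freqs.max())


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters with correlation diagnostics."""

    params: MRWParams
    fbra_corr: float
    objective: float
    n_evals: int
    n_restarts_run: int
    converged: bool
    shuffle_corr_mean: float | None = None
    nfbra_corr: float | None = None
    warning: str | None = None
    unit_id: str = ""


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r with the constant-vector convention used by the objective:
    if either vector has zero variance the correlation term is 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.dot(a - a.mean(), b - b.mean()) / (len(a) * sa * sb))


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------


class _FastObjective:
    """Precomputes everything fixed across evaluations of one fit."""

    def __init__(self, fbra: FBRA, grid: StimulusGrid, axis: FrequencyAxis, config: FitConfig):
        self.axis = axis
        self.config = config
        mask = ~grid.is_pure_tone if config.exclude_pure_tones else np.ones(grid.n_conditions, bool)
        y = fbra.flat[mask]
        if len(y) < 3:
            raise ValueError("need at least 3 non-pure-tone cells")
        if y.std() == 0:
            raise ValueError("neuronal FBRA has zero variance; fit refused")
        self.S = stimulus_matrix(grid, axis)[mask]
        self.x_oct = axis.oct
        self.step = axis.step_oct
        # center/normalize the neuronal vector once
        yc = y - y.mean()
        self.y_hat = yc / np.linalg.norm(yc)
        self.n_evals = 0

    def corr_and_obj(self, mu, w, IE, s):
        self.n_evals += 1
        d = self.x_oct - mu
        raw = (w**2 - IE * d**2) * np.exp(-(d**2) / (2 * w**2)) * phi_star(self.x_oct, mu, w, s)
        peak = raw.max()
        if peak <= 0:
            return 0.0, self.config.width_penalty * w
        m = np.maximum(0.0, self.S @ raw)  # normalization/step cancel in r
        mc = m - m.mean()
        nrm = np.linalg.norm(mc)
        r = 0.0 if nrm == 0 else float(np.dot(self.y_hat, mc) / nrm)
        return r, -r + self.config.width_penalty * w

    def __call__(self, theta):
        return self.corr_and_obj(*theta)[1]


def objective(
    params: MRWParams,
    fbra: FBRA,
    grid: StimulusGrid,
    axis: FrequencyAxis,
    config: FitConfig = FitConfig(),
) -> float:
    """-pearson(neuronal, model over b > 0 cells) + width_penalty * w.

    A model rectified to a constant contributes a correlation term of 0.
    """
    fo = _FastObjective(fbra, grid, axis, config)
    return fo((params.mu, params.w, params.IE, params.s))


# ---------------------------------------------------------------------------
# Bounded simplex search
# ---------------------------------------------------------------------------


class _BoundTransform:
    """p = lo + (hi - lo) * (sin(z) + 1) / 2 per coordinate; fixed where lo == hi."""

    def __init__(self, bounds: list[tuple[float, float]]):
        self.lo = np.array([b[0] for b in bounds])
        self.hi = np.array([b[1] for b in bounds])
        self.span = self.hi - self.lo
        self.free = self.span > 1e-12

    def to_params(self, z: np.ndarray) -> np.ndarray:
        p = self.lo.copy()
        p[self.free] = (
            self.lo[self.free]
            + self.span[self.free] * (np.sin(z[self.free]) + 1.0) / 2.0
        )
        return p

    def to_z(self, p: np.ndarray) -> np.ndarray:
        z = np.zeros_like(self.lo)
        frac = np.clip((p[self.free] - self.lo[self.free]) / self.span[self.free], 0, 1)
        z[self.free] = np.arcsin(2.0 * frac - 1.0)
        return z


def _restart_grid(grid: StimulusGrid, config: FitConfig) -> tuple[np.ndarray, np.ndarray]:
    """Candidate start points: mu at each presented f_c x w {0.1, 0.4} x
    IE {0, 1} x s {-1, 0, 1}, clipped into bounds.

    Returns (starts, corner_id) where corner_id indexes the (IE, s) corner,
    used to stratify restart selection across basins.
    """
    mu_lo, mu_hi = config.resolved_mu_bounds(grid)
    mus = np.clip(np.log2(np.asarray(grid.center_freqs)), mu_lo, mu_hi)
    starts, corners = [], []
    for mu in mus:
        for w in (0.1, 0.4):
            for ci, ie in enumerate((0.0, 1.0)):
                for cj, s in enumerate((-1.0, 0.0, 1.0)):
                    starts.append((mu, np.clip(w, *config.w_bounds), ie, s))
                    corners.append(ci * 3 + cj)
    return np.array(starts), np.array(corners)


def _select_restarts(start_objs: np.ndarray, corners: np.ndarray, n: int) -> np.ndarray:
    """Indices of the starts to polish: best per (IE, s) corner first, so every
    basin family gets at least one restart, then best remaining overall."""
    n = max(1, min(n, len(start_objs)))
    order = np.argsort(start_objs, kind="stable")
    chosen: list[int] = []
    seen_corners: set[int] = set()
    for idx in order:
        if corners[idx] not in seen_corners:
            chosen.append(int(idx))
            seen_corners.add(int(corners[idx]))
    for idx in order:
        if len(chosen) >= n:
            break
        if int(idx) not in chosen:
            chosen.append(int(idx))
    # every corner is always polished, even when n < the number of corners
    return np.array(chosen[: max(n, len(seen_corners))])


def fit(
    fbra: FBRA,
    grid: StimulusGrid,
    axis: FrequencyAxis,
    config: FitConfig = FitConfig(),
) -> FitResult:
    """Bound-constrained Nelder-Mead fit of MRW parameters to an FBRA.

    The objective is evaluated at every start-grid point; the best
    `config.n_restarts` points seed full simplex runs, and the best restart
    wins.  Deterministic given (fbra, config).
    """
    fo = _FastObjective(fbra, grid, axis, config)
    mu_bounds = config.resolved_mu_bounds(grid)
    bounds = [mu_bounds, config.w_bounds, config.ie_bounds, config.s_bounds]
    tr = _BoundTransform(bounds)

    starts, corners = _restart_grid(grid, config)
    start_objs = np.array([fo(th) for th in starts])
    order = _select_restarts(start_objs, corners, config.n_restarts)

    def zobj(z):
        return fo(tr.to_params(z))

    best_theta, best_obj = starts[order[0]], start_objs[order[0]]
    converged = False
    for idx in order:
        z0 = tr.to_z(starts[idx])
        res = optimize.minimize(
            zobj,
            z0,
            method="Nelder-Mead",
            options=dict(
                xatol=config.xatol,
                fatol=config.fatol,
                maxfev=config.maxfev,
                initial_simplex=_initial_simplex(z0),
            ),
        )
        if res.fun < best_obj:
            best_obj = float(res.fun)
            best_theta = tr.to_params(res.x)
            converged = converged or bool(res.success)
    warning = None
    if not converged and best_obj >= start_objs[order[0]]:
        warning = "no restart improved on its initial simplex"
    params = MRWParams(
        mu=float(best_theta[0]),
        w=float(max(best_theta[1], W_MIN_OCT)),
        IE=float(np.clip(best_theta[2], 0, 1)),
        s=float(np.clip(best_theta[3], -1, 1)),
    )
    r, _ = fo.corr_and_obj(params.mu, params.w, params.IE, params.s)
    return FitResult(
        params=params,
        fbra_corr=r,
        objective=best_obj,
        n_evals=fo.n_evals,
        n_restarts_run=len(order),
        converged=converged,
        unit_id=fbra.unit_id,
    )


def _initial_simplex(z0: np.ndarray, step: float = 0.25) -> np.ndarray:
    """Non-degenerate simplex around z0 (fixed step; z-space is O(pi)-scaled)."""
    n = len(z0)
    simplex = np.tile(z0, (n + 1, 1))
    for i in range(n):
        simplex[i + 1, i] += step
    return simplex


# ---------------------------------------------------------------------------
# Shuffle control and notch validation
# ---------------------------------------------------------------------------


def shuffle_control(
    fbra: FBRA,
    grid: StimulusGrid,
    axis: FrequencyAxis,
    config: FitConfig = FitConfig(),
) -> float:
    """Mean fitted correlation after permuting cell values across the grid.

    Each shuffle randomizes the location of every mean response along the
    (f_c, b) grid, refits the model, and records the fitted correlation;
    the mean over `config.n_shuffles` shuffles is returned.
    """
    rng = np.random.default_rng(config.seed)
    flat = fbra.flat
    rs = []
    for _ in range(config.n_shuffles):
        perm = rng.permutation(len(flat))
        shuffled = FBRA(
            grid=grid,
            values=flat[perm].reshape(grid.shape),
            unit_id=fbra.unit_id,
        )
        rs.append(fit(shuffled, grid, axis, config).fbra_corr)
    return float(np.mean(rs))


def validate_notch(
    fitres: FitResult,
    unit_nfbra: FBRA,
    notch_grid: StimulusGrid,
    axis: FrequencyAxis,
) -> float:
    """Pearson r between the BBS-fitted model's predicted nFBRA and the
    measured nFBRA, over all notch cells."""
    if unit_nfbra.grid.shape != notch_grid.shape:
        raise ValueError("nFBRA grid does not match the notch grid")
    pred = model_nfbra(fitres.params, notch_grid, axis)
    return pearson(pred.flat, unit_nfbra.flat)
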