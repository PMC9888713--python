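"""Shared fixtures: the 11-frequency protocol grids and a fitted synthetic population.

The heavy session fixture (`fitted_population`) simulates the default
50-unit mixture population at 10 Poisson trials, fits every unit, runs a
small shuffle control, and predicts/measures notch responses; several test
modules score different aspects of the same run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pytest

import mrwfbra as m
from mrwfbra.fbra_builder import build_fbra
from mrwfbra.model_fitting import FitConfig, fit, shuffle_control, validate_notch
from mrwfbra.synthetic_data import PopulationConfig, draw_population_params, simulate_unit

ELEVEN_FREQ_TOP_KHZ = 4.0 * 2**2.5  # prints as 22.6


@pytest.fixture(scope="session")
def axis():
    return m.default_model_axis()


@pytest.fixture(scope="session")
def grid11():
    """11 center freqs x (pure tone + 10 bandwidths) = 121 cells."""
    cfs = m.make_center_frequencies(4.0, ELEVEN_FREQ_TOP_KHZ, 0.25)
    return m.make_grid(cfs, m.make_bandwidths(10))


@pytest.fixture(scope="session")
def notch_grid11(grid11):
    bws = np.asarray(grid11.bandwidths)
    return m.make_grid(grid11.center_freqs, bws[bws > 0], kind=m.StimKind.notch)


@dataclass
class FittedUnit:
    true_params: m.MRWParams
    gain: float
    fit_result: object
    fbra_corr: float
    shuffle_corr_mean: float
    nfbra_corr: float


@pytest.fixture(scope="session")
def fitted_population(grid11, notch_grid11, axis) -> list[FittedUnit]:
    """Default 50-unit population, fitted, with 2-shuffle controls and notch
    validation.  Seeded; identical across runs."""
    S = m.stimulus_matrix(grid11, axis)
    Sn = m.stimulus_matrix(notch_grid11, axis)
    pop = PopulationConfig(n_units=50, master_seed=123)
    cfgs = draw_population_params(pop, grid11)
    fitcfg = FitConfig(seed=1)
    out = []
    for ucfg in cfgs:
        unit = simulate_unit(ucfg, grid11, axis, S=S)
        fbra = build_fbra(unit, grid11)
        res = fit(fbra, grid11, axis, fitcfg)
        sh = shuffle_control(
            fbra, grid11, axis, dataclasses.replace(fitcfg, n_shuffles=2)
        )
        notch_unit = simulate_unit(
            dataclasses.replace(ucfg, seed=ucfg.seed + 1_000_003),
            notch_grid11,
            axis,
            S=Sn,
        )
        nfbra = build_fbra(notch_unit, notch_grid11)
        out.append(
            FittedUnit(
                true_params=ucfg.true_params,
                gain=ucfg.gain,
                fit_result=res,
                fbra_corr=res.fbra_corr,
                shuffle_corr_mean=sh,
                nfbra_corr=validate_notch(res, nfbra, notch_grid11, axis),
            )
        )
    return out
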