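"""Shared fixtures: reference matrices and small simulation configs.

The PWM fixtures are built so that their achievable score levels sit far
from the 1-per-10 kb calibration target on both sides, keeping the
empirical threshold identifiable:

* ``strong8``   — 8 identical highly conserved columns; only the consensus
                  is rare enough, so the calibrated threshold is 1.0.
* ``kink8``     — 7 conserved columns plus one near-ambiguous column; the
                  consensus and its one strong competitor are both rare,
                  so the threshold drops just below 1.0.
* ``weak6``     — short and weakly informative; even a perfect match is
                  too frequent and the threshold caps at 1.0.
"""

import numpy as np
import pytest

from adipodiff.pwm import PwmModel
from adipodiff.simulate import SimulationConfig


def column(counts4):
    return np.asarray(counts4, dtype=float)


def matrix_from_columns(matrix_id, cols):
    return PwmModel(matrix_id, np.array(cols, dtype=float).T)


@pytest.fixture
def strong8():
    cols = [[97, 1, 1, 1], [1, 97, 1, 1], [1, 1, 97, 1], [1, 1, 1, 97]] * 2
    return matrix_from_columns("STRONG8", cols)


@pytest.fixture
def kink8():
    cols = [[97, 1, 1, 1], [1, 97, 1, 1], [1, 1, 97, 1], [97, 1, 1, 1],
            [1, 1, 1, 97], [1, 97, 1, 1], [97, 1, 1, 1], [49, 47, 2, 2]]
    return matrix_from_columns("KINK8", cols)


@pytest.fixture
def weak6():
    cols = [[90, 4, 3, 3]] * 6
    return matrix_from_columns("WEAK6", cols)


def planted_matrix(matrix_id, consensus, conservation=0.9):
    """L-column matrix with ``conservation`` weight on the consensus base."""
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    cols = []
    for b in consensus:
        col = [round((1 - conservation) / 3 * 100, 6)] * 4
        col[base_index[b]] = conservation * 100
        cols.append(col)
    return matrix_from_columns(matrix_id, cols)


@pytest.fixture
def small_config():
    return SimulationConfig(n_genes=120, n_null_genes=48, noise_sd=0.3,
                            n_experiments=3, seed=11)


@pytest.fixture
def zero_noise_config():
    return SimulationConfig(n_genes=60, n_null_genes=36, noise_sd=0.0,
                            n_experiments=3, seed=5)


def uniform_background(rng, n_bases, n_chunks=4):
    """i.i.d. uniform A/C/G/T background split into a few sequences."""
    per = n_bases // n_chunks
    return ["".join(rng.choice(list("ACGT"), size=per)) for _ in range(n_chunks)]
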