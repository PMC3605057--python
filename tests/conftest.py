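"""Shared fixtures: small simulated experiments with known ground truth."""

import numpy as np
import pytest

from ploidypheno.growth import ExtractionParams, extract_table
from ploidypheno.normalize import build_trait_matrix
from ploidypheno.synthetic import (
    TruthConfig,
    make_design,
    make_panel,
    simulate_experiment,
    meta_to_frame,
)

BLANK = 0.05


@pytest.fixture(scope="session")
def times():
    """20-min sampling grid over 72 h."""
    return np.arange(0, 72.001, 1.0 / 3.0)


@pytest.fixture(scope="session")
def small_experiment():
    """A 3+3-strain, 2-environment simulated experiment."""
    panel = make_panel(3, 3, seed=11)
    design = make_design(
        panel=panel,
        environments=["SD_basal", "NaCl_0.85M"],
        replicates_per_mating_type=1,
        replicates_diploid=2,
        standards_per_run=3,
    )
    curves, truth = simulate_experiment(design, TruthConfig(), seed=11)
    return design, curves, truth


@pytest.fixture(scope="session")
def small_components(small_experiment):
    design, curves, truth = small_experiment
    return extract_table(curves, ExtractionParams(blank=BLANK))


@pytest.fixture(scope="session")
def small_matrix(small_components):
    matrix, counts = build_trait_matrix(small_components)
    return matrix


@pytest.fixture(scope="session")
def small_meta(small_experiment):
    design, curves, truth = small_experiment
    return meta_to_frame(curves, design.panel)
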