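"""Shared fixtures: one study-scale synthetic cohort and one forward model,
built once per session (they are deterministic functions of fixed seeds)."""

import numpy as np
import pytest

from erpstates.forward import HeadModel, build_grid, fit_sphere, leadfield
from erpstates.simulate import (
    SimulationSpec,
    default_design,
    generate_montage,
    generate_templates,
    grand_means,
    simulate_study_evoked,
)


@pytest.fixture(scope="session")
def montage():
    m = generate_montage(204, seed=1)
    fit_sphere(m)
    return m


@pytest.fixture(scope="session")
def head(montage):
    return HeadModel.from_montage(montage)


@pytest.fixture(scope="session")
def grid(head):
    return build_grid(head)


@pytest.fixture(scope="session")
def lead(montage, grid, head):
    return leadfield(montage, grid, head)


@pytest.fixture(scope="session")
def templates(montage, grid, head):
    maps, sources = generate_templates(7, montage, grid, head, seed=2)
    return maps


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def study(templates, montage):
    """Study-scale cohort at the default conditions (59 subjects × 3 conditions)."""
    spec = SimulationSpec()
    evokeds, truth = simulate_study_evoked(spec, templates, montage, seed=3)
    return spec, evokeds, truth


@pytest.fixture(scope="session")
def cells(study):
    _, evokeds, _ = study
    return grand_means(evokeds)
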