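import numpy as np
import pytest

from enmrisk.grids import GridSpec, RasterGrid
from enmrisk.occurrences import assemble_response, generate_pseudo_absences, thin_to_cells
from enmrisk.predictors import extract_values
from enmrisk.synthetic import (
    VirtualSpeciesConfig,
    generate_environment,
    generate_virtual_species,
)


@pytest.fixture(scope="session")
def species_config():
    return VirtualSpeciesConfig(seed=11)


@pytest.fixture(scope="session")
def ref_stack(species_config):
    return generate_environment(species_config)


@pytest.fixture(scope="session")
def ref_species(ref_stack, species_config):
    truth, occ = generate_virtual_species(ref_stack, species_config)
    return truth, occ


@pytest.fixture(scope="session")
def ref_presences(ref_species, species_config):
    _, occ = ref_species
    return thin_to_cells(occ, species_config.grid)


@pytest.fixture(scope="session")
def ref_absences(ref_presences):
    return generate_pseudo_absences(ref_presences, n_per_dataset=400, n_datasets=2, seed=7)


@pytest.fixture(scope="session")
def ref_table(ref_stack, ref_presences, ref_absences):
    """Feature table for the first absence dataset (10 predictors + label/weight)."""
    return extract_values(ref_stack, assemble_response(ref_presences, ref_absences[0]))


@pytest.fixture
def small_grid():
    """3x3 one-degree grid with NW corner at (0, 0)."""
    return GridSpec(n_rows=3, n_cols=3, lon_origin=0.0, lat_origin=0.0, cell_size=1.0)


@pytest.fixture
def numbered_raster(small_grid):
    return RasterGrid(small_grid, np.arange(1.0, 10.0).reshape(3, 3))
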