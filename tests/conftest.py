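import numpy as np
import pytest

from etcomplex.grid_potentials import assign_lj_categories, build_gridset
from etcomplex.structure_props import build_mobile_body
from etcomplex.synthetic_smfs import AcquisitionParams, generate_dataset, get_preset
from etcomplex.toys import bead_body, two_site_receptor


@pytest.fixture(scope="session")
def acquisition():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def wt_bundle(acquisition):
    """2000 synthetic curves for the wild-type 10 mM ox/red condition."""
    return generate_dataset(get_preset("WT_10mM_oxred"), acquisition, 2000, seed=42)


@pytest.fixture(scope="session")
def toy_body():
    atoms = bead_body()
    assign_lj_categories(atoms)
    return build_mobile_body(atoms)


@pytest.fixture(scope="session")
def two_well_system(toy_body):
    """Two-well toy receptor with grids at 10 mM (deep proximal, weak distal)."""
    receptor, annotations = two_site_receptor()
    grids = build_gridset(receptor, ionic_strength_mM=10.0, spacing=1.0, margin_A=12.0)
    return receptor, annotations, grids, toy_body
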