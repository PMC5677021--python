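import numpy as np
import pytest

from depforce import dep_force as dfm
from depforce import field_model as fem
from depforce import rupture_model as rm


@pytest.fixture(scope="session")
def paper_field():
    """Reference chip at the nominal grid: 40/10 um electrodes, 0.8 um oxide,
    0.2 um spacing, 1 V_pp at 1 MHz."""
    geom = fem.ElectrodeGeometry()
    return fem.solve_potential(geom, fem.DriveSignal(frequency=1e6, v_pp=1.0))


@pytest.fixture(scope="session")
def coarse_field():
    """Same chip on a 0.4 um grid: fast enough for per-test use."""
    geom = fem.ElectrodeGeometry(grid_spacing=0.4)
    return fem.solve_potential(geom, fem.DriveSignal(frequency=1e6, v_pp=1.0))


@pytest.fixture(scope="session")
def water():
    return dfm.MediumProperties()


@pytest.fixture(scope="session")
def bead():
    return dfm.ParticleProperties()


@pytest.fixture(scope="session")
def bond():
    return rm.reference_bond()


def synthetic_field(phi_fn, spacing=0.5, width=20.0, height=20.0, v_pp=1.0):
    """FieldSolution wrapping an analytic Phi(x, z) sampled on a grid.

    Used to feed closed-form potentials (uniform field, polynomials) through
    the derivative/energy machinery.
    """
    gap = 4 * spacing
    geom = fem.ElectrodeGeometry(
        electrode_width=width / 2 - gap, gap=gap,
        oxide_thickness=0.0, domain_height=max(height, width),
        grid_spacing=spacing,
    )
    nx = int(round(geom.period / spacing))
    nz = int(round(height / spacing)) + 1
    x = np.arange(nx) * spacing
    z = np.arange(nz) * spacing
    xx, zz = np.meshgrid(x, z, indexing="ij")
    return fem.FieldSolution(
        phi=phi_fn(xx, zz), x_axis=x, z_axis=z,
        applied=fem.DriveSignal(v_pp=v_pp), geometry=geom,
        boundary_note="synthetic analytic field (test fixture)",
    )
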