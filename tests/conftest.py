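import numpy as np
import pytest

import nanoheat as nh


@pytest.fixture(scope="session")
def brownian_traj():
    """500 particles x 2000 frames of free Brownian motion, D = 0.25 nm^2/ps."""
    spec = nh.BrownianSpec(
        diffusion_coefficient=0.25, n_particles=500, n_frames=2000, dt=1.0, seed=42
    )
    return spec, nh.generate_brownian_trajectory(spec)


@pytest.fixture(scope="session")
def layered_spec():
    """Two near-wall peaks above bulk within ~1 nm of the wall, 1.82 nm gap.

    The gallery's plateau sits above the 0.997 g/cm^3 reference bulk so the
    super-bulk span is the full gap, as in a strongly intercalated layer.
    """
    return nh.LayeredDensitySpec(
        bulk_density=1.05,
        peaks=[(0.35, 1.3, 0.08), (0.70, 0.55, 0.09)],
        gap_extent=1.82,
        n_molecules=100_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def layered_profile(layered_spec):
    traj = nh.generate_layered_positions(layered_spec)
    return nh.density_profile(
        traj, bin_width=0.1, z_max=layered_spec.gap_extent, bulk_density=0.997
    )


@pytest.fixture()
def paper_sheet():
    """Graphene sheet with the standard constants (areal C = rho*c*d)."""
    return nh.GrapheneSheet(rho_g=2.265, c_g=2.1, d=0.34, A=27.55)


def make_step_profile(bulk=0.997, lo=0.3, hi=1.5, level=1.2, z_max=2.0, bw=0.1):
    """Rectangular density step: level*bulk on [lo, hi), bulk*0.5 elsewhere."""
    edges = np.arange(0.0, z_max + bw / 2, bw)
    centers = 0.5 * (edges[:-1] + edges[1:])
    dens = np.where((centers >= lo) & (centers < hi), level * bulk, 0.5 * bulk)
    return nh.DensityProfile(bin_edges=edges, density=dens, area=25.0, bulk_density=bulk)
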