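import pytest

from memscatter import default_table
from memscatter.fixtures import (
    BilayerFixtureSpec,
    make_bilayer_frames,
    make_slab_profile,
    make_water_frames,
)

# solvent / substrate SLDs used across tests (Å⁻²)
D2O = 6.35e-6
H2O = -0.56e-6
SI = 2.07e-6


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def water_frames():
    # 0.0333 molecules/Å³ — liquid-water density in a 40 Å cube
    return make_water_frames(n_waters=2133, box=(40.0, 40.0, 40.0), n_frames=6, seed=11)


@pytest.fixture(scope="session")
def bilayer_frames():
    return make_bilayer_frames(BilayerFixtureSpec(n_frames=20, seed=7))


def lamellar_unit(bin_width=0.5, half_gap=21.0, solvent=D2O):
    """Symmetric 66 Å lamellar unit cell: half gap | head | tail | head | half gap."""
    return make_slab_profile(
        [
            (half_gap, solvent),
            (6.5, 1.8e-6),
            (11.0, -0.4e-6),
            (6.5, 1.8e-6),
            (half_gap, solvent),
        ],
        bin_width=bin_width,
        backing=solvent,
    )


@pytest.fixture()
def unit_cell():
    return lamellar_unit()
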