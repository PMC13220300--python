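import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from secwall import harddisk as hd

# geometry of the wheat-straw microfibril cross-section model
RADIUS = 13.5  # Å
SHEATH = 4.7  # Å minimum surface separation
PHI_PHYS = 0.29


@pytest.fixture(scope="session")
def paper_geometry():
    r_eff = hd.effective_radius(RADIUS, SHEATH)
    phi_eff = hd.effective_area_fraction(PHI_PHYS, RADIUS, r_eff)
    return {"radius": RADIUS, "sheath": SHEATH, "phi_phys": PHI_PHYS,
            "radius_eff": r_eff, "phi_eff": phi_eff}


@pytest.fixture(scope="session")
def packed_config(paper_geometry):
    """Equilibrated 2000-disk packing at the wheat-straw geometry."""
    return hd.generate_configuration(
        2000,
        paper_geometry["phi_eff"],
        paper_geometry["radius_eff"],
        paper_geometry["radius"],
        seed=1,
    )


@pytest.fixture(scope="session")
def sf_table(paper_geometry):
    """Single-phi structure-factor table covering the SAXS fit window."""
    x_hi = 0.7 * hd.effective_radius(15.5, SHEATH) * 1.05
    return hd.build_structure_factor_table(
        phi_grid=[paper_geometry["phi_eff"]],
        x_grid=np.linspace(0.2, x_hi, 90),
        n_disks=1000,
        n_samples=30,
        seed=11,
    )
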