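import numpy as np
import pytest

from gliomark import ShellSpec, load_reference_cohort, make_shell_phantom


@pytest.fixture(scope="session")
def uniform_shell():
    """Even spherical shell: inner radius 10 mm, outer 20 mm, 1 mm voxels."""
    return make_shell_phantom(ShellSpec(inner_radius=10.0, outer_radius_base=20.0))


@pytest.fixture(scope="session")
def twomass_shell():
    """Thin-shell two-mass rim: widths 5 and 10 mm, bump on 20% of solid angle."""
    return make_shell_phantom(
        ShellSpec(
            inner_radius=30.0,
            outer_radius_base=35.0,
            bump_fraction=0.2,
            bump_outer_radius=40.0,
        )
    )


@pytest.fixture(scope="session")
def cohort():
    """The bundled 40-patient glioblastoma cohort table."""
    return load_reference_cohort()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
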