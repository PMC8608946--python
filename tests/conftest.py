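import pytest

from gelmech.aspiration import PipetteSpec
from gelmech.indentation import GelCylinder, IndenterSpec
from gelmech.synthetic import default_indenter_catalog


@pytest.fixture
def gel():
    """Lab-scale gel: 4 mm tall, 8 mm across (Rh/D^2 ~ 0.05-0.1)."""
    return GelCylinder(height_mm=4.0, diameter_mm=8.0)


@pytest.fixture
def steel_sphere():
    return IndenterSpec(label="SS2.0", mass_mg=261.4, radius_mm=2.0, material="steel")


@pytest.fixture
def catalog():
    return default_indenter_catalog()


@pytest.fixture
def pipette():
    """The standard capillary: a = 0.375 mm, A = 0.5 mm."""
    return PipetteSpec()
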