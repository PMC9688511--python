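import numpy as np
import pytest

from flimcell import AcquisitionConfig, DecaySpec, make_irf, render_phantom_scene


@pytest.fixture(scope="session")
def cfg():
    """Default acquisition: 80 MHz sync (12.5 ns window), 256 bins, 0.2 ns IRF."""
    return AcquisitionConfig(seed=42)


@pytest.fixture(scope="session")
def cfg_nodark():
    return AcquisitionConfig(seed=42, dark_count_fraction=0.0)


@pytest.fixture(scope="session")
def irf(cfg):
    return make_irf(cfg)


@pytest.fixture(scope="session")
def nadh_spec():
    """Baseline free/bound NAD(P)H mixture: 0.38 / 2.7 ns, a1 = 77%."""
    return DecaySpec((0.38, 2.7), (0.77, 0.23), label="nadh")


@pytest.fixture(scope="session")
def dox_spec():
    """DOX in growth medium: monoexponential, ~1.0 ns."""
    return DecaySpec((1.0,), (1.0,), label="dox")


@pytest.fixture(scope="session")
def phantom(nadh_spec):
    """Five-cell phantom scene with nuclei at a higher free fraction."""
    cfg = AcquisitionConfig(seed=1234)
    nuc = DecaySpec((0.38, 2.7), (0.80, 0.20), label="nadh-nuc")
    return render_phantom_scene(
        5, cfg, {"cytoplasm": nadh_spec, "nucleus": nuc}
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
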