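import numpy as np
import pytest

from pouchsim import CryptVillusUnit, GeometryIndex, lattice_pouch
from pouchsim.scenarios_io import ScenarioConfig, default_config


@pytest.fixture
def toy_unit() -> CryptVillusUnit:
    """A minimal 2-row x 2-col unit for hand-enumerable folds."""
    return CryptVillusUnit(
        villus_height=2, crypt_depth=2, face_width=2, n_faces=4, cap_rows=1
    )


@pytest.fixture
def toy_index(toy_unit) -> GeometryIndex:
    return GeometryIndex(lattice_pouch(2, 2, toy_unit))


@pytest.fixture
def small_unit() -> CryptVillusUnit:
    return CryptVillusUnit(
        villus_height=10, crypt_depth=6, face_width=3, n_faces=4, cap_rows=1
    )


@pytest.fixture
def small_index(small_unit) -> GeometryIndex:
    return GeometryIndex(lattice_pouch(3, 3, small_unit))


def small_config(scenario: str = "homeostasis", seed: int = 1, **kw) -> ScenarioConfig:
    """Desk-top-test configuration: a 3x3 lattice of small units."""
    cfg = default_config(scenario, seed=seed)
    cfg.geometry.sim_n_axial = 3
    cfg.geometry.sim_n_circ = 3
    cfg.geometry.villus_height = 10
    cfg.geometry.crypt_depth = 6
    cfg.geometry.face_width = 3
    for k, v in kw.items():
        setattr(cfg, k, v)
    return cfg


@pytest.fixture(scope="session")
def homeostasis_run():
    """One medium homeostasis run shared by steady-state tests.

    4x4 units with the default template, 2000 steps: large enough for a
    meaningful villus:crypt ratio and flux balance, small enough for the
    suite.
    """
    from pouchsim.scenarios_io import build_simulation

    cfg = default_config("homeostasis", seed=1)
    cfg.geometry.sim_n_axial = 4
    cfg.geometry.sim_n_circ = 4
    sim = build_simulation(cfg)
    sim.run(2000)
    return sim
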