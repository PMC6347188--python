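import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gutdock.structio import Atom, StructureModel

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def cloud(model_id, coords, element="C", chain="L", residue="LIG"):
    """Build a StructureModel from an (n, 3) coordinate array."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    atoms = tuple(
        Atom(
            serial=i,
            name=f"{element}{i}",
            element=element,
            residue_name=residue,
            residue_number=1,
            chain=chain,
            coordinates=tuple(xyz),
        )
        for i, xyz in enumerate(coords, 1)
    )
    return StructureModel(id=model_id, atoms=atoms)


@pytest.fixture
def rng():
    return np.random.default_rng(20190125)


@pytest.fixture
def stub_engine(tmp_path):
    from gutdock.synthfix import write_stub_engine

    return write_stub_engine(tmp_path / "vina_stub.py")
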