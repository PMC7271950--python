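import numpy as np
import pytest

from embuild.map_io import DensityMap
from embuild.pipeline import TargetSet
from embuild.reference_targets import build_ca_target, build_cb_targets, simulate_reference
from embuild.synthetic import SyntheticSpec, default_reference_model, make_map, make_model


@pytest.fixture(scope="session")
def reference():
    model, _ = default_reference_model()
    return simulate_reference(model, 3.0)


@pytest.fixture(scope="session")
def ca_target(reference):
    return build_ca_target(reference)


@pytest.fixture(scope="session")
def cb_targets(reference):
    return build_cb_targets(reference, variance_floor_frac=0.08)


@pytest.fixture(scope="session")
def target_set(reference):
    return TargetSet.from_reference(reference)


@pytest.fixture(scope="session")
def helix30():
    """Noise-free 30-residue poly-alanine-like helix fixture."""
    spec = SyntheticSpec(n_res=30, fold="helix", rng_seed=3)
    model, seq = make_model(spec)
    dmap = make_map(model, 3.0, 1.0)
    cas = np.array(
        [[a.pos.x, a.pos.y, a.pos.z] for ch in model[0] for r in ch for a in r if a.name == "CA"]
    )
    return model, seq, dmap, cas


@pytest.fixture(scope="session")
def hts60():
    """Noise-free 60-residue helix-turn-strand fixture (the workhorse)."""
    spec = SyntheticSpec(n_res=60, fold="helix-turn-strand", rng_seed=5)
    model, seq = make_model(spec)
    dmap = make_map(model, 3.0, 1.0)
    cas = np.array(
        [[a.pos.x, a.pos.y, a.pos.z] for ch in model[0] for r in ch for a in r if a.name == "CA"]
    )
    return model, seq, dmap, cas


@pytest.fixture()
def small_map():
    """A tiny deterministic non-trivial grid."""
    rng = np.random.default_rng(7)
    return DensityMap(rng.standard_normal((12, 10, 14)), np.array([1.0, 1.2, 0.9]))
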