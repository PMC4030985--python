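import numpy as np
import pytest

from knotfold.forcefield import PotentialEnergyModel, QuasiChemicalParams
from knotfold.structure import CaTrace, build_contact_map


def compact_random_native(n=15, seed=0):
    """Compact self-avoiding chain usable as a toy native structure."""
    rng = np.random.default_rng(seed)
    pts = [np.zeros(3)]
    while len(pts) < n:
        step = rng.standard_normal(3)
        step /= np.linalg.norm(step)
        step = 0.6 * step - 0.4 * (pts[-1] / (np.linalg.norm(pts[-1]) + 1.0))
        step /= np.linalg.norm(step)
        cand = pts[-1] + 3.8 * step
        prior = np.asarray(pts[:-1])
        if len(prior) == 0 or np.min(np.linalg.norm(prior - cand, axis=1)) > 3.5:
            pts.append(cand)
    return np.asarray(pts)


@pytest.fixture(scope="session")
def small_native():
    pts = compact_random_native(15, seed=0)
    trace = CaTrace(positions=pts, residue_type=list("ACDEFGHIKLMNPQR"),
                    ss_label=["coil"] * 15)
    cmap = build_contact_map(trace)
    return trace, cmap


@pytest.fixture(scope="session")
def small_model(small_native):
    trace, cmap = small_native
    return PotentialEnergyModel(trace, cmap,
                                qc_params=QuasiChemicalParams(lambda_nn=0.8))


@pytest.fixture(scope="session")
def small_go_model(small_native):
    trace, cmap = small_native
    return PotentialEnergyModel(trace, cmap)
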