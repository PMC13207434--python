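import numpy as np
import pytest

from ssetopo.sse_io import DensityStick, ModelSSE
from ssetopo.synthetic import SimulationConfig, simulate_protein


def straight_sse(sse_id="H1", sse_type="helix", start=(0.0, 0.0, 0.0),
                 step=(3.0, 0.0, 0.0), n=5, chain="A", first_res=1):
    """A straight-line model SSE, handy for exact-arithmetic checks."""
    coords = np.asarray(start, float) + np.outer(np.arange(n), np.asarray(step, float))
    return ModelSSE(
        sse_id=sse_id,
        sse_type=sse_type,
        chain_id=chain,
        residue_range=(first_res, first_res + n - 1),
        calpha_coords=coords,
    )


def stick_from(sse, stick_id="V1", reverse=False):
    pts = np.array(sse.calpha_coords)
    if reverse:
        pts = pts[::-1]
    return DensityStick(stick_id=stick_id, sse_type=sse.sse_type, axis_points=pts)


@pytest.fixture
def clean_protein():
    """Small noise-free simulated protein: sticks exactly depict their SSEs."""
    return simulate_protein(SimulationConfig(n_helices=4, n_strands=3, seed=11))


@pytest.fixture
def noisy_protein():
    return simulate_protein(
        SimulationConfig(
            n_helices=5, n_strands=4, noise_sigma=0.5, erosion_frac=0.1, seed=7
        )
    )
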