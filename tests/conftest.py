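import numpy as np
import pytest

import glimetry as g


@pytest.fixture(scope="session")
def acq() -> g.AcquisitionConfig:
    """Default acquisition on a small grid (dx=dy=0.25 µm, dz=1 µm)."""
    return g.AcquisitionConfig(seed=7)


@pytest.fixture(scope="session")
def phantom_scene(acq):
    """One phantom with its true phase, noiseless stack and reconstruction.

    Session-scoped: several modules reuse the same scene read-only.
    """
    rng = acq.rng()
    phantom = g.make_phantom((24, 160, 160), 3, config=acq, rng=rng)
    phase_true = g.project_phase(phantom, acq)
    stack = g.simulate_interferograms(phase_true, config=acq, noise_sd=0.01, rng=rng)
    recon = g.integrate_gradient_hilbert(g.retrieve_phase_gradient(stack))
    return {"phantom": phantom, "phase_true": phase_true, "stack": stack,
            "recon": recon, "config": acq}


@pytest.fixture
def square_trace():
    """Square outlines on two z-slices: an axis-aligned box."""
    sq = [(0, 0), (10, 0), (10, 10), (0, 10)]
    return g.CellTrace("cube", [(0, sq), (9, sq)])
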