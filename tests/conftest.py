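import numpy as np
import pytest

import mobflim as mf
from mobflim.phasor import DecayStack
from mobflim.synthetic import decay_pmf


@pytest.fixture
def acq():
    return mf.AcquisitionConfig()  # 12.5 ns period, 256 bins, harmonic 1


@pytest.fixture
def omega(acq):
    return acq.omega


def make_stack(pmf: np.ndarray, acq: mf.AcquisitionConfig, n_photons: float = 1e7,
               shape=(1, 1)) -> DecayStack:
    """Deterministic (rounded-expectation) decay stack from a per-bin pmf."""
    counts = np.rint(pmf * n_photons).astype(np.int64)
    stack = np.broadcast_to(counts[:, None, None], (counts.size, *shape)).copy()
    return DecayStack(counts=stack, bin_centers=acq.bin_centers,
                      laser_period=acq.laser_period)


def single_exp_stack(tau: float, acq: mf.AcquisitionConfig,
                     n_photons: float = 1e7) -> DecayStack:
    # alpha=1 mixture: the free component gets zero weight
    pmf = decay_pmf(1.0, tau / 2, tau, acq)
    return make_stack(pmf, acq, n_photons)


@pytest.fixture
def disk():
    """A discretized disk mask of radius 20 plus its coordinate grids."""
    r = 20
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (yy ** 2 + xx ** 2 <= r ** 2), yy, xx, r


@pytest.fixture
def demo_truth_cell():
    return mf.CellTruth(
        cell_id=1, population="HSC", center=(20.0, 20.0), radius=8.0,
        alpha_bound_true=0.7, tau_bound_true=3.5, tau_free_true=0.45,
        total_photons=2e5, orr_true=0.3,
    )
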