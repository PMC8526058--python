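import logging

import numpy as np
import pytest

from optomap.core import SweepRecord
from optomap.synthgen import SynthConfig, make_epsc_kernel

logging.getLogger("optomap").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_scracm_config():
    """Tiny noiseless sCRACM config for exact-identity checks."""
    return SynthConfig.for_mode("sCRACM", seed=7, n_pairs=2, grid_rows=4,
                                grid_cols=4, noise_sd=0.0, pair_amp_cv=0.0)


def kernel_sweep(amp=100.0, tau_rise=0.5, tau_decay=5.0, onset_after_stim=1.0,
                 stim_onset=10.0, dt=0.1, sweep_len=150.0, noise_sd=0.0,
                 rng=None, **kw):
    """A SweepRecord containing one EPSC kernel (plus optional noise)."""
    tr = make_epsc_kernel(amp, tau_rise, tau_decay, stim_onset + onset_after_stim,
                          dt, sweep_len)
    if noise_sd > 0:
        tr = tr + rng.normal(0, noise_sd, tr.size)
    kw.setdefault("stim_kind", "laser")
    kw.setdefault("power", 10.0)
    return SweepRecord(tr, dt, stim_onset, **kw)
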