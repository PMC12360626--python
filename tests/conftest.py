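import numpy as np
import pytest

from oepsc.sweeps import SweepSet
from oepsc.synth import epsc_kernel

FS = 20000.0
DT_MS = 1000.0 / FS
STIM = 0.055
DUR = 0.12


def grid_snap(latency_ms: float) -> float:
    return round(latency_ms / DT_MS) * DT_MS


def kernel_sweepset(
    event_lists,
    tau_rise=0.5,
    tau_decay=5.0,
    noise_sd=0.0,
    seed=0,
    condition="baseline",
    snap=True,
):
    """Build a SweepSet of noise(+kernel) sweeps; event_lists is a list
    (per sweep) of (onset_ms_re_flash, amplitude_pa) pairs."""
    n = int(DUR * FS)
    t_ms = (np.arange(n) / FS - STIM) * 1000.0
    rng = np.random.default_rng(seed)
    rows = []
    for events in event_lists:
        tr = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
        for onset, amp in events:
            if snap:
                onset = grid_snap(onset)
            tr = tr + epsc_kernel(t_ms - onset, tau_rise, tau_decay, amp)
        rows.append(tr)
    return SweepSet("cellX", condition, FS, STIM, np.array(rows))


@pytest.fixture
def single_kernel_set():
    return kernel_sweepset([[(2.5, 200.0)]] * 3)
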