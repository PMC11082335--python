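"""Shared fixtures: protocols, tissue, and an independent Bloch oracle."""

import math

import numpy as np
import pytest

from csfpulse import AcquisitionProtocol, TissueParams
from csfpulse.acquisition import build_slice_order


@pytest.fixture(scope="session")
def protocol():
    """The study protocol: TR 2000 ms, 31 slices of 4 mm, 160 measurements."""
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def tissue():
    """CSF at 3 T: T1 = 4300 ms, unit equilibrium magnetization."""
    return TissueParams()


@pytest.fixture(scope="session")
def small_protocol():
    """A fast 6-slice protocol for brute-force physics comparisons."""
    return AcquisitionProtocol(
        tr_ms=1200.0, n_slices=6, slice_thickness_mm=4.0, n_measurements=20
    )


def brute_force_schedule(
    protocol: AcquisitionProtocol,
    t1_ms: float,
    m0: float,
    velocity_mm_s: float,
    n_cycles: int,
    dt_ms: float = 0.25,
    dx_mm: float = 0.1,
    margin_slices: float = 2.0,
) -> np.ndarray:
    """Fine-time-step integrator of the same physics, no event shortcuts.

    Relaxation and advection are applied in small ``dt_ms`` steps; each
    slice's saturation pulse fires when the clock reaches its slot.
    Returns the per-slice readout signals of the final cycle, indexed by
    anatomical slice.
    """
    n = protocol.n_slices
    th = protocol.slice_thickness_mm
    slot_ms = protocol.tr_ms / n
    order = build_slice_order(protocol)
    lo_b = -margin_slices * th
    hi_b = (n + margin_slices) * th
    pos = np.arange(lo_b + dx_mm / 2.0, hi_b, dx_mm)
    mz = np.full(pos.size, m0)
    steps_per_slot = max(1, int(round(slot_ms / dt_ms)))
    dt = slot_ms / steps_per_slot
    decay = math.exp(-dt / t1_ms)
    v = velocity_mm_s / 1000.0  # mm per ms
    signals = np.empty(n)
    for _cycle in range(n_cycles):
        for slice_idx in order:
            slab = (pos >= (slice_idx - 1) * th) & (pos < slice_idx * th)
            signals[slice_idx - 1] = float(mz[slab].mean())
            mz[slab] = 0.0  # 90-degree saturation
            for _ in range(steps_per_slot):
                mz = m0 + (mz - m0) * decay
                pos = pos + v * dt
                if v > 0:
                    keep = pos <= hi_b
                    pos, mz = pos[keep], mz[keep]
                    while pos[0] - dx_mm >= lo_b:
                        pos = np.concatenate([[pos[0] - dx_mm], pos])
                        mz = np.concatenate([[m0], mz])
                elif v < 0:
                    keep = pos >= lo_b
                    pos, mz = pos[keep], mz[keep]
                    while pos[-1] + dx_mm <= hi_b:
                        pos = np.concatenate([pos, [pos[-1] + dx_mm]])
                        mz = np.concatenate([mz, [m0]])
    return signals
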