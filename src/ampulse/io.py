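"""Waveform file I/O: two-column ASCII (signed amplitude in microtesla,
phase in radians) with a JSON sidecar carrying dwell, flip angle and design
provenance.  AM-only files (absent or constant-zero phase column) are
auto-detected on read."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .metrics import am_fm_decompose
from .slr import GAMMA_1H, RFPulse

__all__ = ["write_waveform", "read_waveform"]


def write_waveform(path, pulse: RFPulse, flip_angle: float | None = None,
                   provenance: dict | None = None) -> Path:
    """Write the pulse as signed-amplitude/phase columns plus a ``.json``
    sidecar.  Real (AM) pulses are written with a single signed column."""
    path = Path(path)
    amp_scale = 1e6 / (GAMMA_1H * pulse.dwell)      # rad/sample -> uT
    if pulse.is_am:
        signed, _, phi0 = am_fm_decompose(pulse)
        cols = (signed * np.cos(phi0) * amp_scale)[:, None]
        header = "signed_amplitude_uT"
    else:
        cols = np.column_stack([np.abs(pulse.samples) * amp_scale,
                                np.angle(pulse.samples)])
        header = "amplitude_uT phase_rad"
    np.savetxt(path, cols, header=header)
    meta = {
        "dwell_s": pulse.dwell,
        "n_samples": pulse.n_samples,
        "flip_angle_rad": flip_angle,
        "am_only": bool(pulse.is_am),
        "provenance": provenance or pulse.carrier_offsets_meta,
    }
    side = path.with_suffix(path.suffix + ".json")
    side.write_text(json.dumps(meta, indent=1, default=str))
    return path


def read_waveform(path) -> RFPulse:
    path = Path(path)
    side = path.with_suffix(path.suffix + ".json")
    meta = json.loads(side.read_text()) if side.exists() else {}
    dwell = float(meta.get("dwell_s", 6.4e-6))
    data = np.atleast_2d(np.loadtxt(path))
    if data.shape[0] == 1 and data.shape[1] > 2:
        data = data.T
    amp_scale = GAMMA_1H * dwell / 1e6              # uT -> rad/sample
    if data.shape[1] == 1 or np.ptp(data[:, 1]) < 1e-12:
        samples = data[:, 0] * amp_scale + 0j       # signed AM
    else:
        samples = data[:, 0] * amp_scale * np.exp(1j * data[:, 1])
    return RFPulse(samples, dwell, dict(meta.get("provenance") or {}))
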