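"""CSV persistence of bladder-pressure traces."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ..synthetic_data.pressure import BladderTrace

__all__ = ["save_bp_csv", "load_bp_csv"]


def save_bp_csv(trace: BladderTrace, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "time_s": trace.time_s,
            "pressure_cmH2O": trace.pressure_cmh2o,
            "phase": trace.phase,
        }
    )
    df.to_csv(path, index=False)
    return path


def load_bp_csv(path: str | Path, target_rate_hz: float | None = None) -> BladderTrace:
    """Load a trace, validating the time grid.

    Non-monotone or duplicate timestamps raise.  If ``target_rate_hz``
    differs from the native rate the pressure is linearly interpolated
    onto the target grid (phase labels taken from the nearest sample).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time_s", "pressure_cmH2O"):
        if col not in df.columns:
            raise ValueError(f"CSV {path} is missing required column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    p = df["pressure_cmH2O"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("trace needs at least 2 samples")
    dt = np.diff(t)
    if np.any(dt == 0):
        raise ValueError("duplicate timestamps in trace")
    if np.any(dt < 0):
        raise ValueError("non-monotone time in trace")
    phase = (
        df["phase"].to_numpy(dtype=object).astype(str)
        if "phase" in df.columns
        else np.full(t.size, "", dtype=object).astype(str)
    )

    native_rate = 1.0 / dt[0]
    uniform = np.allclose(dt, dt[0], rtol=0, atol=1e-9)
    if target_rate_hz is None or (uniform and np.isclose(native_rate, target_rate_hz)):
        if not uniform:
            raise ValueError("non-uniform time grid; pass target_rate_hz to resample")
        return BladderTrace(
            time_s=t, pressure_cmh2o=p, phase=phase, sampling_rate_hz=native_rate
        )

    new_t = np.arange(t[0], t[-1] + 0.5 / target_rate_hz, 1.0 / target_rate_hz)
    new_t = new_t[new_t <= t[-1] + 1e-9]
    new_p = np.interp(new_t, t, p)
    nearest = np.searchsorted(t, new_t)
    nearest = np.clip(nearest, 0, t.size - 1)
    left = np.clip(nearest - 1, 0, t.size - 1)
    use_left = np.abs(t[left] - new_t) <= np.abs(t[nearest] - new_t)
    idx = np.where(use_left, left, nearest)
    return BladderTrace(
        time_s=new_t,
        pressure_cmh2o=new_p,
        phase=phase[idx],
        sampling_rate_hz=target_rate_hz,
    )
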