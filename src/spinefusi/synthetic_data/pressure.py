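"""Intravesical bladder-pressure simulation and %BP conversion.

Pressure model: ``P(t) = P0 + k * V(t) + c * R(t) + noise`` where ``V``
integrates the signed pump rate (floored at zero) and ``R`` is a
viscoelastic component driven by active infusion that relaxes
exponentially with time constant ``tau`` once the pump stops.  The model
reproduces the characteristic pressure drop ("accommodation") during the
hold periods and the return toward resting pressure during washout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocol import ProtocolSpec

__all__ = [
    "PressureParams",
    "BladderTrace",
    "simulate_bladder_pressure",
    "percent_bp",
    "DegenerateReferenceError",
]


class DegenerateReferenceError(ValueError):
    """Raised when the %BP reference window has non-positive mean pressure."""


@dataclass(frozen=True)
class PressureParams:
    """Compliance / viscoelastic parameters of the pressure model.

    ``p0`` resting pressure (cmH2O), ``k`` linear compliance slope
    (cmH2O/ml), ``c`` viscoelastic gain (cmH2O per ml of transient
    volume), ``tau`` relaxation time constant (s), ``noise_sd`` additive
    white-noise SD (cmH2O).  The defaults give a hold-onset pressure drop
    of roughly 15% of the running pressure.
    """

    p0: float = 10.0
    k: float = 0.25
    c: float = 0.55
    tau: float = 40.0
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("compliance k must be > 0")
        if self.tau <= 0:
            raise ValueError("relaxation time constant tau must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class BladderTrace:
    """Uniformly sampled pressure trace with phase annotations.

    ``reference_window_s`` marks the initial window whose mean pressure
    anchors the %BP change computation (30 s).
    """

    time_s: np.ndarray
    pressure_cmh2o: np.ndarray
    phase: np.ndarray
    sampling_rate_hz: float = 1.0
    reference_window_s: float = 30.0
    volume_ml: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.pressure_cmh2o = np.asarray(self.pressure_cmh2o, dtype=float)
        if self.time_s.shape != self.pressure_cmh2o.shape:
            raise ValueError("time and pressure must have the same length")
        if self.time_s.size >= 2:
            dt = np.diff(self.time_s)
            if not np.allclose(dt, dt[0], rtol=0, atol=1e-9):
                raise ValueError("time grid must be strictly uniform")
            if dt[0] <= 0:
                raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return self.time_s.size


def simulate_bladder_pressure(
    protocol: ProtocolSpec,
    params: PressureParams = PressureParams(),
    seed: int = 0,
) -> BladderTrace:
    """Simulate a bladder-pressure trace over the full protocol.

    Deterministic for a fixed seed.  The viscoelastic state is advanced
    with the exact single-step solution of ``dR/dt = q_in - R/tau`` over
    each sample interval, with ``q_in = max(pump_rate, 0)`` so that only
    active infusion builds transient pressure; during holds and washout
    the component decays as ``exp(-dt/tau)``, producing a strictly
    decreasing noiseless pressure over each hold.
    """
    fs = protocol.sampling_rate_hz
    dt = 1.0 / fs
    rates = protocol.pump_rate_series()  # ml/s, signed
    n = rates.size

    decay = np.exp(-dt / params.tau)
    volume = np.empty(n)
    relax = np.empty(n)
    v = 0.0
    r = 0.0
    for i in range(n):
        q = rates[i]
        v = max(v + q * dt, 0.0)
        q_in = max(q, 0.0)
        # exact step of dR/dt = q_in - R/tau with q_in held over the interval
        r = r * decay + q_in * params.tau * (1.0 - decay)
        volume[i] = v
        relax[i] = r

    pressure = params.p0 + params.k * volume + params.c * relax
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        pressure = pressure + rng.normal(0.0, params.noise_sd, n)
    pressure = np.maximum(pressure, 1e-3)  # physical: gauge pressure stays positive

    time = np.arange(n) / fs
    return BladderTrace(
        time_s=time,
        pressure_cmh2o=pressure,
        phase=protocol.phase_label_series(),
        sampling_rate_hz=fs,
        volume_ml=volume,
    )


def percent_bp(trace: BladderTrace) -> np.ndarray:
    """Percent pressure change relative to the mean of the first 30 s.

    ``%BP(t) = 100 * (P(t) - Pref) / Pref`` with ``Pref`` the mean
    pressure over ``trace.reference_window_s``.
    """
    n_ref = int(round(trace.reference_window_s * trace.sampling_rate_hz))
    if len(trace) < n_ref or n_ref < 1:
        raise ValueError(
            f"trace must cover at least {trace.reference_window_s} s "
            f"({n_ref} samples), got {len(trace)}"
        )
    ref = float(np.mean(trace.pressure_cmh2o[:n_ref]))
    if ref <= 0:
        raise DegenerateReferenceError(f"reference-window mean pressure {ref} <= 0")
    return 100.0 * (trace.pressure_cmh2o - ref) / ref
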