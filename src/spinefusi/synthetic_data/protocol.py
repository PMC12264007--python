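"""Urodynamic experiment protocol: phase timeline and pump schedule."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PHASE_LABELS = ("baseline", "fill1", "hold1", "fill2", "hold2", "empty", "washout")

#: Phases during which the pump must be off.
_PUMP_OFF = frozenset({"baseline", "hold1", "hold2", "washout"})
#: Phases during which the pump infuses (rate must be positive).
_PUMP_IN = frozenset({"fill1", "fill2"})


@dataclass(frozen=True)
class Phase:
    """One protocol phase.

    Attributes
    ----------
    label : str
        One of :data:`PHASE_LABELS`.
    duration_s : float
        Phase duration in seconds (> 0).
    pump_rate_ml_min : float
        Signed pump rate; positive = infusion, negative = withdrawal,
        zero = pump off.
    """

    label: str
    duration_s: float
    pump_rate_ml_min: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in PHASE_LABELS:
            raise ValueError(f"unknown phase label {self.label!r}")
        if not np.isfinite(self.duration_s) or self.duration_s <= 0:
            raise ValueError(f"phase {self.label!r}: duration must be > 0")
        if self.label in _PUMP_OFF and self.pump_rate_ml_min != 0.0:
            raise ValueError(f"phase {self.label!r}: pump must be off")
        if self.label in _PUMP_IN and self.pump_rate_ml_min <= 0.0:
            raise ValueError(f"phase {self.label!r}: infusion rate must be positive")
        if self.label == "empty" and self.pump_rate_ml_min >= 0.0:
            raise ValueError("phase 'empty': withdrawal rate must be negative")


@dataclass(frozen=True)
class ProtocolSpec:
    """Ordered phase list plus sampling rate.

    The default protocol is: 5 min baseline; 6 min 40 s infusion at
    90 ml/min (600 ml); hold; 1 min infusion; hold; 7 min 40 s withdrawal
    at 90 ml/min; 2 min 20 s washout.  The nominal hold durations are
    90 s each; a configurable pad (default 14 s total) is split between
    the two holds so the post-baseline experiment period defaults to
    exactly 1254 frames at 1 Hz.
    """

    phases: tuple[Phase, ...] = field(default_factory=tuple)
    sampling_rate_hz: float = 1.0

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("protocol needs at least one phase")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        labels = [p.label for p in self.phases]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate phase labels")

    @classmethod
    def default(cls, experiment_frames: int = 1254, sampling_rate_hz: float = 1.0) -> "ProtocolSpec":
        """Default timeline with holds padded to hit ``experiment_frames``.

        The unpadded post-baseline duration is 1240 s (fill1 400 + hold1 90
        + fill2 60 + hold2 90 + empty 460 + washout 140); the difference to
        ``experiment_frames`` (at 1 Hz) is distributed across the two holds.
        """
        pad = experiment_frames / sampling_rate_hz - 1240.0
        if pad < -60.0:
            raise ValueError("experiment_frames too small for the default timeline")
        h1 = 90.0 + pad / 2.0
        h2 = 90.0 + pad - pad / 2.0
        return cls(
            phases=(
                Phase("baseline", 300.0, 0.0),
                Phase("fill1", 400.0, 90.0),
                Phase("hold1", h1, 0.0),
                Phase("fill2", 60.0, 90.0),
                Phase("hold2", h2, 0.0),
                Phase("empty", 460.0, -90.0),
                Phase("washout", 140.0, 0.0),
            ),
            sampling_rate_hz=sampling_rate_hz,
        )

    @classmethod
    def scaled(cls, time_scale: float, sampling_rate_hz: float = 1.0) -> "ProtocolSpec":
        """Default timeline with every phase duration scaled down.

        Useful for fast synthetic runs; durations are rounded to whole
        samples and the baseline keeps at least 30 s (the %BP reference
        window) plus 2 frames.
        """
        if not 0 < time_scale <= 1:
            raise ValueError("time_scale must be in (0, 1]")
        base = cls.default(sampling_rate_hz=sampling_rate_hz)
        if time_scale == 1.0:
            return base
        min_baseline = max(30.0, 2.0 / sampling_rate_hz)
        phases = []
        for p in base.phases:
            dur = max(round(p.duration_s * time_scale * sampling_rate_hz), 1) / sampling_rate_hz
            if p.label == "baseline":
                dur = max(dur, min_baseline)
            phases.append(Phase(p.label, dur, p.pump_rate_ml_min))
        return cls(phases=tuple(phases), sampling_rate_hz=sampling_rate_hz)

    @property
    def total_duration_s(self) -> float:
        return float(sum(p.duration_s for p in self.phases))

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration_s * self.sampling_rate_hz))

    @property
    def baseline_duration_s(self) -> float:
        return self.phases[0].duration_s if self.phases[0].label == "baseline" else 0.0

    @property
    def baseline_frames(self) -> int:
        return int(round(self.baseline_duration_s * self.sampling_rate_hz))

    @property
    def experiment_frames(self) -> int:
        """Post-baseline sample count."""
        return self.n_samples - self.baseline_frames

    def phase_boundaries_s(self) -> dict[str, tuple[float, float]]:
        """Map label -> (start_s, end_s)."""
        out: dict[str, tuple[float, float]] = {}
        t = 0.0
        for p in self.phases:
            out[p.label] = (t, t + p.duration_s)
            t += p.duration_s
        return out

    def pump_rate_series(self) -> np.ndarray:
        """Signed pump rate in ml/s on the uniform sample grid."""
        fs = self.sampling_rate_hz
        rates = np.empty(self.n_samples)
        i = 0
        for p in self.phases:
            n = int(round(p.duration_s * fs))
            rates[i : i + n] = p.pump_rate_ml_min / 60.0
            i += n
        rates[i:] = 0.0
        return rates

    def phase_label_series(self) -> np.ndarray:
        fs = self.sampling_rate_hz
        labels = np.empty(self.n_samples, dtype=object)
        i = 0
        for p in self.phases:
            n = int(round(p.duration_s * fs))
            labels[i : i + n] = p.label
            i += n
        labels[i:] = self.phases[-1].label
        return labels.astype(str)

    def infused_volume_at_end_of(self, label: str) -> float:
        """Cumulative signed pumped volume (ml) at the end of a phase."""
        v = 0.0
        for p in self.phases:
            v += p.pump_rate_ml_min / 60.0 * p.duration_s
            if p.label == label:
                return v
        raise KeyError(f"no phase labelled {label!r}")
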