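"""Core domain types for dual-site spike/LFP sessions.

All times are seconds from session start (double precision, 0-based);
intervals are half-open ``[t, t + dt)``.  The two recorded regions are the
locus coeruleus (``LC``) and the trigeminocervical complex (``TCC``; the
caudal spinal trigeminal nucleus Sp5C — ``Sp5C`` is accepted as an alias on
read).  Phases are wrapped to ``(-pi, pi]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

REGIONS = ("LC", "TCC")
REGION_ALIASES = {"SP5C": "TCC", "Sp5C": "TCC"}
UNIT_KINDS = ("SU", "MUA")
SIGNAL_KINDS = ("lfp_raw", "lfp_decimated", "rate", "phase", "band_power")
CONDITIONS = ("naive", "sensitized", "propranolol", "acsf_control")
EVENT_LABELS = ("cutaneous", "meningeal", "IS_infusion", "microinjection")

# the two electrical stimulation modalities: (pulse_width s, inter-stimulus s)
PROTOCOL_CUTANEOUS = (0.0008, 1.5)
PROTOCOL_MENINGEAL = (0.005, 2.0)


class ValidationError(ValueError):
    """An object violates a domain invariant."""


class FormatError(ValueError):
    """A container is missing required structure."""


def canonical_region(region: str) -> str:
    region = REGION_ALIASES.get(region, region)
    if region not in REGIONS:
        raise ValidationError(f"unknown region {region!r}; expected one of {REGIONS}")
    return region


def wrap_phase(phi):
    """Wrap angle(s) to (-pi, pi]."""
    out = -np.mod(-np.asarray(phi, dtype=float) + np.pi, 2 * np.pi) + np.pi
    return out if np.ndim(phi) else float(out)


@dataclass
class SpikeTrain:
    """Ordered event times of one single unit or multi-unit cluster."""

    times: np.ndarray
    region: str
    unit_kind: str = "SU"
    id: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.region = canonical_region(self.region)
        if self.unit_kind not in UNIT_KINDS:
            raise ValidationError(
                f"train {self.id!r}: unit_kind {self.unit_kind!r} not in {UNIT_KINDS}"
            )
        if self.times.ndim != 1:
            raise ValidationError(f"train {self.id!r}: times must be 1-D")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            k = int(np.argmax(np.diff(self.times) <= 0))
            raise ValidationError(
                f"train {self.id!r}: times not strictly increasing at index {k} "
                f"({self.times[k]} -> {self.times[k + 1]})"
            )
        if self.times.size and self.times[0] < 0:
            raise ValidationError(f"train {self.id!r}: negative spike time {self.times[0]}")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class EventSeries:
    """Stimulus onsets with their protocol parameters."""

    onsets: np.ndarray
    pulse_width: float
    isi: float
    label: str = "cutaneous"

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.label not in EVENT_LABELS:
            raise ValidationError(f"unknown event label {self.label!r}")
        if self.onsets.size and np.any(np.diff(self.onsets) <= 0):
            raise ValidationError(f"events {self.label!r}: onsets not strictly increasing")
        if self.label in ("cutaneous", "meningeal") and self.onsets.size > 1:
            if np.any(np.abs(np.diff(self.onsets) - self.isi) > 1e-9):
                raise ValidationError(
                    f"events {self.label!r}: electrical-train onset spacing deviates "
                    f"from isi={self.isi}"
                )

    def __len__(self) -> int:
        return int(self.onsets.size)


@dataclass
class UniformSignal:
    """Regularly sampled signal; sample k is at t0 + k / fs."""

    values: np.ndarray
    fs: float
    t0: float = 0.0
    kind: str = "rate"
    edge_margin: float = 0.0  # seconds at each end contaminated by filter edges

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in SIGNAL_KINDS:
            raise ValidationError(f"unknown signal kind {self.kind!r}")
        if not self.fs > 0:
            raise ValidationError("fs must be positive")
        if self.values.size < 2:
            raise ValidationError("signal must hold at least 2 samples")
        if self.kind == "phase":
            v = self.values
            if np.any(v > np.pi) or np.any(v <= -np.pi):
                raise ValidationError("phase values must lie in (-pi, pi]")

    @property
    def duration(self) -> float:
        return self.values.size / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs

    def slice(self, start: float, stop: float) -> "UniformSignal":
        """Samples with timestamps in [start, stop)."""
        i0 = int(np.ceil((start - self.t0) * self.fs - 1e-9))
        i1 = int(np.ceil((stop - self.t0) * self.fs - 1e-9))
        i0, i1 = max(i0, 0), min(i1, self.values.size)
        if i1 - i0 < 2:
            raise ValidationError(f"slice [{start}, {stop}) holds fewer than 2 samples")
        return UniformSignal(self.values[i0:i1], self.fs, self.t0 + i0 / self.fs, self.kind)


@dataclass
class Session:
    """One simultaneous two-region recording."""

    duration: float
    spike_trains: list = field(default_factory=list)
    events: list = field(default_factory=list)
    lfp: dict = field(default_factory=dict)  # region -> UniformSignal
    condition: str = "naive"
    ground_truth: Optional[dict] = None  # generator parameters, synthetic only

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if not self.duration > 0:
            raise ValidationError("duration must be positive")
        for tr in self.spike_trains:
            if tr.times.size and tr.times[-1] > self.duration + 1e-9:
                raise ValidationError(
                    f"train {tr.id!r}: spike at {tr.times[-1]} beyond duration {self.duration}"
                )
        self.lfp = {canonical_region(r): s for r, s in self.lfp.items()}

    def trains(self, region: str, unit_kind: Optional[str] = None) -> list:
        region = canonical_region(region)
        out = [t for t in self.spike_trains if t.region == region]
        if unit_kind is not None:
            out = [t for t in out if t.unit_kind == unit_kind]
        return out

    def events_by_label(self, label: str) -> list:
        return [e for e in self.events if e.label == label]


# fields of the per-session summary that are plain floats
_REPORT_SCALARS = (
    "precession",
    "r2max",
    "lfp_lag",
    "lc_tcc_ratio",
)


@dataclass
class CouplingReport:
    """Per-session coupling summary.

    ``evoked`` maps region -> list of component dicts; ``periods`` maps
    region -> {"slow": s, "intermediate": s}; ``preferred_phase`` maps
    region -> {rhythm: radians}; ``delta_ratio`` maps region -> [0, 1].
    ``lfp_lag`` is in seconds, positive when the LC leads the TCC.
    Any analysis that could not run is None, with the reason recorded in
    ``reasons``.
    """

    condition: str = "naive"
    evoked: Optional[dict] = None
    periods: Optional[dict] = None
    preferred_phase: Optional[dict] = None
    precession: Optional[float] = None
    delta_ratio: Optional[dict] = None
    r2max: Optional[float] = None
    lfp_lag: Optional[float] = None
    lc_tcc_ratio: Optional[float] = None
    reasons: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.r2max is not None and not (0.0 <= self.r2max <= 1.0 + 1e-12):
            raise ValidationError(f"r2max {self.r2max} outside [0, 1]")
        if self.delta_ratio is not None:
            for region, v in self.delta_ratio.items():
                if v is not None and not (0.0 <= v <= 1.0 + 1e-12):
                    raise ValidationError(f"delta_ratio[{region}] {v} outside [0, 1]")
        if self.precession is not None:
            self.precession = wrap_phase(self.precession)
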