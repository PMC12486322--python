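"""Cutaneous afferent recording analysis.

Implements the classification chain used in ex vivo skin–nerve recordings:
conduction velocity from receptive-field distance and spike latency
(``mm/ms == m/s``); Aβ/Aδ assignment (Aβ strictly above 10 m/s, Aδ within
[1.5, 10]); per-epoch spike counts and rates against a ramp-and-hold /
vibration stimulus protocol; mechanical threshold as the stimulus force at
the first spike of a force-ramp epoch; and the afferent-class decision
tree (RAM, SAM, D-hair, AM, tap-unit, mechano-insensitive).

Epoch membership is half-open ``[start, end)`` so a spike on a boundary is
counted exactly once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np

from .stats import ContingencyTable

__all__ = [
    "ABETA",
    "ADELTA",
    "UNCLASSIFIED",
    "AFFERENT_CLASSES",
    "Epoch",
    "StimulusProtocol",
    "SpikeTrain",
    "ClassifierConfig",
    "FiberRecord",
    "EpochCount",
    "conduction_velocity",
    "classify_by_cv",
    "detect_spikes",
    "phase_spike_rates",
    "mechanical_threshold",
    "classify_afferent",
    "classify_fiber",
    "insensitive_proportion",
    "ramp_hold_pair",
    "standard_protocol",
]

ABETA = "Abeta"
ADELTA = "Adelta"
UNCLASSIFIED = "unclassified"

AFFERENT_CLASSES = (
    "RAM",
    "SAM",
    "D-hair",
    "AM",
    "tap-unit",
    "mechano-insensitive",
)

EPOCH_KINDS = ("ramp", "hold", "vibration-ramp", "manual-tap", "none")
#: epochs delivered by the electromechanical stimulator (vs manual taps)
CONTROLLED_KINDS = ("ramp", "hold", "vibration-ramp")


@dataclass(frozen=True)
class Epoch:
    """One stimulus epoch with its force/velocity parameters.

    ``force_mN`` is the peak (ramp), plateau (hold) or tap force;
    ``amplitude_mN`` the final amplitude of a vibration envelope that
    grows linearly from zero.
    """

    kind: str
    start_s: float
    end_s: float
    velocity_mm_s: float | None = None
    force_mN: float | None = None
    frequency_hz: float | None = None
    amplitude_mN: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in EPOCH_KINDS:
            raise ValueError(f"unknown epoch kind {self.kind!r}")
        if not self.end_s > self.start_s:
            raise ValueError("epoch must have positive duration")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def force_at(self, t: float) -> float:
        """Instantaneous stimulus force (mN) at time ``t`` inside the epoch."""
        frac = (t - self.start_s) / self.duration_s
        frac = min(max(frac, 0.0), 1.0)
        if self.kind == "ramp":
            return (self.force_mN or 0.0) * frac
        if self.kind == "hold":
            return self.force_mN or 0.0
        if self.kind == "vibration-ramp":
            return (self.amplitude_mN or 0.0) * frac
        if self.kind == "manual-tap":
            return self.force_mN or 0.0
        return 0.0


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered, non-overlapping stimulus epochs."""

    epochs: tuple[Epoch, ...]

    def __post_init__(self) -> None:
        eps = tuple(self.epochs)
        object.__setattr__(self, "epochs", eps)
        for prev, nxt in zip(eps, eps[1:]):
            if nxt.start_s < prev.end_s:
                raise ValueError("epochs must be ordered and non-overlapping")

    @property
    def duration_s(self) -> float:
        return self.epochs[-1].end_s if self.epochs else 0.0

    def of_kind(self, *kinds: str) -> tuple[Epoch, ...]:
        return tuple(e for e in self.epochs if e.kind in kinds)


@dataclass
class SpikeTrain:
    """Spike times (s) of one fibre; optionally a raw voltage trace."""

    fiber_id: str
    times: np.ndarray
    trace: tuple[np.ndarray, np.ndarray] | None = None  # (time_s, voltage)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size:
            if self.times.min() < 0:
                raise ValueError("spike times must be non-negative")
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class ClassifierConfig:
    """Cutoffs of the CV and afferent-class decision rules."""

    abeta_cutoff_m_s: float = 10.0  # strict >
    adelta_band_m_s: tuple[float, float] = (1.5, 10.0)  # inclusive
    sam_min_hold_spikes: int = 1
    tap_ceiling_mm_s: float = 1.5
    dhair_threshold_mN: float = 1.0
    detector_sd_multiplier: float = 5.0
    detector_refractory_ms: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.adelta_band_m_s
        if not (0 < lo < hi):
            raise ValueError("Adelta band must satisfy 0 < lower < upper")
        if self.abeta_cutoff_m_s <= 0:
            raise ValueError("Abeta cutoff must be positive")


@dataclass
class FiberRecord:
    """One characterized fibre (one CSV row)."""

    fiber_id: str
    distance_mm: float | None = None
    delay_ms: float | None = None
    cv_m_s: float | None = None
    cv_class: str = UNCLASSIFIED
    afferent_class: str | None = None
    threshold_mN: float | None = None
    epoch_rates_hz: dict[str, float] = field(default_factory=dict)

    def to_row(self) -> dict[str, Any]:
        row = {
            "fiber_id": self.fiber_id,
            "distance_mm": self.distance_mm,
            "delay_ms": self.delay_ms,
            "cv_m_s": self.cv_m_s,
            "cv_class": self.cv_class,
            "afferent_class": self.afferent_class,
            "threshold_mN": self.threshold_mN,
        }
        row.update(self.epoch_rates_hz)
        return row


@dataclass(frozen=True)
class EpochCount:
    """Spike count and mean rate within one epoch."""

    epoch: Epoch
    count: int
    rate_hz: float


def conduction_velocity(distance_mm: float, delay_ms: float) -> float:
    """CV in m/s from receptive-field distance (mm) and latency (ms)."""
    if distance_mm <= 0 or delay_ms <= 0:
        raise ValueError("distance and delay must be positive")
    return distance_mm / delay_ms  # mm/ms == m/s


def classify_by_cv(cv_m_s: float, config: ClassifierConfig | None = None) -> str:
    """Aβ above the cutoff (strict), Aδ within the band (inclusive)."""
    config = config or ClassifierConfig()
    if cv_m_s <= 0:
        raise ValueError("conduction velocity must be positive")
    if cv_m_s > config.abeta_cutoff_m_s:
        return ABETA
    lo, hi = config.adelta_band_m_s
    if lo <= cv_m_s <= hi:
        return ADELTA
    return UNCLASSIFIED


def detect_spikes(
    voltage: np.ndarray,
    sample_interval_s: float,
    config: ClassifierConfig | None = None,
    fiber_id: str = "",
) -> SpikeTrain:
    """Threshold-crossing spike detection on a uniformly sampled trace.

    The threshold is the trace mean plus ``detector_sd_multiplier`` SDs;
    a spike is an upward crossing, and crossings within the refractory
    period of the previous one are discarded. Intended for synthetic
    traces — real spike sorting is out of scope.
    """
    config = config or ClassifierConfig()
    if sample_interval_s <= 0:
        raise ValueError("sampling interval must be positive")
    v = np.asarray(voltage, dtype=float)
    if v.size < 2:
        return SpikeTrain(fiber_id=fiber_id, times=np.empty(0))
    threshold = v.mean() + config.detector_sd_multiplier * v.std()
    above = v > threshold
    crossings = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    refractory_s = config.detector_refractory_ms / 1000.0
    times: list[float] = []
    for idx in crossings:
        t = idx * sample_interval_s
        if not times or t - times[-1] >= refractory_s:
            times.append(t)
    return SpikeTrain(fiber_id=fiber_id, times=np.asarray(times))


def phase_spike_rates(
    spikes: SpikeTrain, protocol: StimulusProtocol
) -> list[EpochCount]:
    """Spike count and mean rate per epoch (half-open membership)."""
    times = spikes.times
    out = []
    for epoch in protocol.epochs:
        count = int(np.count_nonzero((times >= epoch.start_s) & (times < epoch.end_s)))
        out.append(EpochCount(epoch=epoch, count=count, rate_hz=count / epoch.duration_s))
    return out


def mechanical_threshold(
    spikes: SpikeTrain, protocol: StimulusProtocol
) -> float | None:
    """Force (mN) at the first spike of a force-bearing ramp epoch.

    Vibration-ramp epochs are used when present, otherwise force ramps.
    Returns the minimum over qualifying epochs, or ``None`` (undefined)
    when no qualifying epoch contains a spike.
    """
    candidates = protocol.of_kind("vibration-ramp") or tuple(
        e for e in protocol.of_kind("ramp") if e.force_mN is not None
    )
    if not candidates:
        raise ValueError("protocol has no force-bearing ramp epoch")
    forces = []
    for epoch in candidates:
        inside = spikes.times[
            (spikes.times >= epoch.start_s) & (spikes.times < epoch.end_s)
        ]
        if inside.size:
            forces.append(epoch.force_at(float(inside[0])))
    if not forces:
        if len(spikes):
            warnings.warn(
                "spikes present but none inside a force-bearing epoch; "
                "mechanical threshold undefined",
                stacklevel=2,
            )
        return None
    return min(forces)


def classify_afferent(
    epoch_counts: Sequence[EpochCount],
    cv_class: str,
    config: ClassifierConfig | None = None,
    threshold_mN: float | None = None,
) -> str:
    """Afferent-class decision tree.

    In order: (1) silent to every stimulus → mechano-insensitive;
    (2) at most one spike, only to a manual tap → tap-unit; (3) Aβ with at
    least ``sam_min_hold_spikes`` during holds → SAM, else RAM; (4) Aδ
    with mechanical threshold ≤ ``dhair_threshold_mN`` and a dynamic
    response at the slowest ramp → D-hair, else AM.
    """
    config = config or ClassifierConfig()
    if cv_class is None:
        raise ValueError("CV class required to classify an afferent")
    controlled = sum(ec.count for ec in epoch_counts if ec.epoch.kind in CONTROLLED_KINDS)
    tap = sum(ec.count for ec in epoch_counts if ec.epoch.kind == "manual-tap")
    if controlled == 0 and tap == 0:
        return "mechano-insensitive"
    if controlled == 0 and tap <= 1:
        return "tap-unit"
    if cv_class == ABETA:
        hold = sum(ec.count for ec in epoch_counts if ec.epoch.kind == "hold")
        return "SAM" if hold >= config.sam_min_hold_spikes else "RAM"
    if cv_class == ADELTA:
        ramps = [ec for ec in epoch_counts if ec.epoch.kind == "ramp"]
        slow_response = False
        if ramps:
            slowest = min(
                (ec for ec in ramps if ec.epoch.velocity_mm_s is not None),
                key=lambda ec: ec.epoch.velocity_mm_s,
                default=None,
            )
            slow_response = slowest is not None and slowest.count >= 1
        if (
            threshold_mN is not None
            and threshold_mN <= config.dhair_threshold_mN
            and slow_response
        ):
            return "D-hair"
        return "AM"
    return UNCLASSIFIED


def classify_fiber(
    spikes: SpikeTrain,
    protocol: StimulusProtocol,
    distance_mm: float | None = None,
    delay_ms: float | None = None,
    cv_m_s: float | None = None,
    config: ClassifierConfig | None = None,
) -> FiberRecord:
    """End-to-end characterization of one fibre.

    CV may be given directly or via distance and latency; epoch rates,
    mechanical threshold and the afferent class are derived from the
    spike train against the protocol.
    """
    config = config or ClassifierConfig()
    if cv_m_s is None:
        if distance_mm is None or delay_ms is None:
            raise ValueError("need either cv_m_s or distance_mm and delay_ms")
        cv_m_s = conduction_velocity(distance_mm, delay_ms)
    cv_class = classify_by_cv(cv_m_s, config)
    counts = phase_spike_rates(spikes, protocol)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        threshold = mechanical_threshold(spikes, protocol)
    afferent = classify_afferent(counts, cv_class, config, threshold_mN=threshold)
    rates = {
        f"rate_hz_epoch{i:02d}_{ec.epoch.kind}": ec.rate_hz
        for i, ec in enumerate(counts)
    }
    return FiberRecord(
        fiber_id=spikes.fiber_id,
        distance_mm=distance_mm,
        delay_ms=delay_ms,
        cv_m_s=cv_m_s,
        cv_class=cv_class,
        afferent_class=afferent,
        threshold_mN=threshold,
        epoch_rates_hz=rates,
    )


def insensitive_proportion(
    groups: Mapping[str, Iterable[bool]],
) -> tuple[ContingencyTable, dict[str, float]]:
    """2×2 counts (group × insensitive/sensitive) and percentages.

    ``groups`` maps a group label to per-fibre mechano-insensitive flags.
    """
    if len(groups) != 2:
        raise ValueError("exactly two groups required for a 2x2 table")
    labels, rows, pct = [], [], {}
    for name, flags in groups.items():
        flags = [bool(f) for f in flags]
        if not flags:
            raise ValueError(f"group {name!r} is empty")
        n_ins = sum(flags)
        rows.append([n_ins, len(flags) - n_ins])
        pct[name] = 100.0 * n_ins / len(flags)
        labels.append(name)
    table = ContingencyTable(
        counts=np.asarray(rows, dtype=int),
        row_labels=tuple(labels),
        col_labels=("insensitive", "sensitive"),
    )
    return table, pct


# ---------------------------------------------------------------------------
# protocol builders

RAMP_VELOCITIES_MM_S = (0.075, 0.15, 0.45, 1.5)


def ramp_hold_pair(
    start_s: float,
    velocity_mm_s: float,
    displacement_um: float = 96.0,
    hold_force_mN: float = 40.0,
    hold_s: float = 2.0,
) -> tuple[Epoch, Epoch]:
    """A ramp at constant velocity reaching ``hold_force_mN``, then a hold.

    The ramp duration follows from the probe displacement and velocity.
    """
    ramp_s = (displacement_um / 1000.0) / velocity_mm_s
    ramp = Epoch(
        "ramp", start_s, start_s + ramp_s, velocity_mm_s=velocity_mm_s,
        force_mN=hold_force_mN,
    )
    hold = Epoch("hold", ramp.end_s, ramp.end_s + hold_s, force_mN=hold_force_mN)
    return ramp, hold


def standard_protocol(
    velocities_mm_s: Sequence[float] = RAMP_VELOCITIES_MM_S,
    displacement_um: float = 96.0,
    hold_force_mN: float = 40.0,
    hold_s: float = 2.0,
    gap_s: float = 0.5,
    vibration_hz: float = 50.0,
    vibration_peak_mN: float = 50.0,
    vibration_s: float = 5.0,
    tap_s: float = 0.05,
    tap_force_mN: float = 150.0,
) -> StimulusProtocol:
    """The characterization sequence used throughout the package.

    Ramp-and-hold pairs at each probe velocity (constant displacement, so
    slower ramps last longer), a vibration stimulus of linearly increasing
    amplitude for threshold determination, and one manual tap.
    """
    epochs: list[Epoch] = []
    t = 0.0
    for v in velocities_mm_s:
        ramp, hold = ramp_hold_pair(
            t, v, displacement_um=displacement_um,
            hold_force_mN=hold_force_mN, hold_s=hold_s,
        )
        epochs.extend([ramp, hold])
        t = hold.end_s + gap_s
    epochs.append(
        Epoch(
            "vibration-ramp", t, t + vibration_s,
            frequency_hz=vibration_hz, amplitude_mN=vibration_peak_mN,
        )
    )
    t += vibration_s + gap_s
    epochs.append(Epoch("manual-tap", t, t + tap_s, force_mN=tap_force_mN))
    return StimulusProtocol(epochs=tuple(epochs))
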