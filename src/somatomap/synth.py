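"""Synthetic phantoms and spike trains with known ground truth.

Two families of generators make every downstream stage testable without
any imaging or recording data:

**Stack phantoms.** Anisotropic Gaussian intensity blobs over an
autofluorescent background with additive Gaussian noise (clipped at zero,
identical statistics in both channels so channel subtraction is
meaningful) and sparse hot pixels. Ground truth is computed from the
noise-free support at half maximum. Cohort phantoms emulate a labelled
terminal field as a curved sheet: an elliptical territory in the
rostrocaudal × mediolateral plane carrying a plateau-like thickness
profile around a gently waving midline surface. Group effects act on the
territory semi-axes (span multipliers), on the sheet thickness (density
multiplier — the dorsoventral areal density *is* the mean thickness) and
on the territory centre (planar focus displacement), so span, density
and focus effects are configured independently — mirroring the
observation that a terminal field can spread out without gaining
labelled voxels.

**Fibre responses.** Seeded inhomogeneous Poisson spike trains thinned by
an absolute refractory period, with class-specific rate rules: rapidly
adapting mechanoreceptors (RAMs) fire only during ramps, slowly adapting
ones (SAMs) also during holds in proportion to suprathreshold force,
tap-units fire a single spike only to a manual tap, and
mechano-insensitive fibres never fire to mechanical stimulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .ephys import (
    Epoch,
    SpikeTrain,
    StimulusProtocol,
)
from .morpho import BorderAnnotation
from .stacks import VoxelGrid

__all__ = [
    "Blob",
    "StackPhantomParams",
    "StackGroundTruth",
    "FieldPhantomParams",
    "GroupEffect",
    "CohortParams",
    "CohortSpecimen",
    "generate_terminal_stack",
    "generate_cohort",
    "FiberModel",
    "make_fiber",
    "generate_fiber_response",
    "synthesize_trace",
]

#: half-maximum radius of a Gaussian, in units of its SD
HALF_MAX_SIGMA = float(np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class Blob:
    """One anisotropic Gaussian blob; centre and SD spreads in µm (z,y,x)."""

    centre_um: tuple[float, float, float]
    spread_um: tuple[float, float, float]
    peak: float = 60.0

    def __post_init__(self) -> None:
        if min(self.spread_um) <= 0:
            raise ValueError("blob spreads must be positive")
        if self.peak <= 0:
            raise ValueError("blob peak must be positive")


@dataclass(frozen=True)
class StackPhantomParams:
    """Parameters of a two-channel blob phantom.

    The default voxel size matches the imaging configuration the pipeline
    targets (1 µm × 1 µm pixels, 2 µm z step). The default phantom is a
    tight crop around one labelled cloud: with the blob occupying a few
    percent of the stack the whole-stack mean + 3 SD threshold falls at
    the blob's half-maximum — the regime the stack-histogram rule
    presumes (see the methods note).
    """

    shape: tuple[int, int, int] = (25, 49, 49)
    voxel_size_um: tuple[float, float, float] = (2.0, 1.0, 1.0)
    blobs: tuple[Blob, ...] = (
        Blob(centre_um=(24.0, 24.0, 24.0), spread_um=(5.0, 10.0, 10.0)),
    )
    background_mean: float = 20.0
    background_sd: float = 2.0
    hot_pixel_rate: float = 5e-5
    hot_pixel_intensity: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) <= 0:
            raise ValueError("grid shape must be positive")
        if min(self.voxel_size_um) <= 0:
            raise ValueError("voxel sizes must be positive")
        if not 0.0 <= self.hot_pixel_rate <= 1.0:
            raise ValueError("hot-pixel rate must lie in [0, 1]")
        if self.background_sd < 0:
            raise ValueError("background SD must be non-negative")


@dataclass
class StackGroundTruth:
    """Truth computed from the noise-free blob support at half maximum."""

    centre_voxel: tuple[float, float, float]
    centre_um: tuple[float, float, float]
    count: int
    extent_um: tuple[float, float, float]  # (DV, RC, ML)
    projection_area_um2: dict[str, float]  # collapsed axis -> occupied area


def _render_blobs(
    shape: tuple[int, int, int],
    voxel: tuple[float, float, float],
    blobs: Sequence[Blob],
    cut_sigmas: float = 4.5,
) -> np.ndarray:
    """Noise-free summed blob intensity, rendered in local windows."""
    signal = np.zeros(shape, dtype=np.float64)
    axes_um = [np.arange(n) * v for n, v in zip(shape, voxel)]
    for blob in blobs:
        slices, profiles = [], []
        empty = False
        for ax in range(3):
            c, s, v = blob.centre_um[ax], blob.spread_um[ax], voxel[ax]
            lo = max(int(np.floor((c - cut_sigmas * s) / v)), 0)
            hi = min(int(np.ceil((c + cut_sigmas * s) / v)) + 1, shape[ax])
            if hi <= lo:
                empty = True
                break
            u = axes_um[ax][lo:hi]
            profiles.append(np.exp(-0.5 * ((u - c) / s) ** 2))
            slices.append(slice(lo, hi))
        if empty:
            continue
        signal[tuple(slices)] += blob.peak * (
            profiles[0][:, None, None] * profiles[1][None, :, None] * profiles[2][None, None, :]
        )
    return signal


def _truth_from_signal(
    signal: np.ndarray,
    voxel: tuple[float, float, float],
    half_max: float,
) -> StackGroundTruth:
    """Ground truth from the support ``signal > half_max``."""
    support = signal > half_max
    count = int(support.sum())
    if count == 0:
        raise ValueError("phantom support is empty; blobs fall outside the grid")
    coords = np.argwhere(support)
    centre_voxel = coords.mean(axis=0)
    centre_um = centre_voxel * np.asarray(voxel)
    extent = tuple(
        float((coords[:, ax].max() - coords[:, ax].min() + 1) * voxel[ax])
        for ax in range(3)
    )
    areas = {}
    for label, ax in (("DV", 0), ("RC", 1), ("ML", 2)):
        remaining = [i for i in range(3) if i != ax]
        pixel_area = voxel[remaining[0]] * voxel[remaining[1]]
        areas[label] = float(support.any(axis=ax).sum() * pixel_area)
    return StackGroundTruth(
        centre_voxel=tuple(float(c) for c in centre_voxel),
        centre_um=tuple(float(c) for c in centre_um),
        count=count,
        extent_um=extent,  # type: ignore[arg-type]
        projection_area_um2=areas,
    )


def _add_channels(
    signal: np.ndarray,
    params_mean: float,
    params_sd: float,
    hot_rate: float,
    hot_intensity: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Tracer (signal + background + hot pixels) and autofluorescence."""
    shape = signal.shape
    tracer = signal + rng.normal(params_mean, params_sd, shape)
    auto = rng.normal(params_mean, params_sd, shape)
    if hot_rate > 0:
        hot = rng.random(shape) < hot_rate
        tracer = tracer + hot * hot_intensity
    np.clip(tracer, 0.0, None, out=tracer)
    np.clip(auto, 0.0, None, out=auto)
    return tracer.astype(np.float32), auto.astype(np.float32)


def generate_terminal_stack(
    params: StackPhantomParams,
) -> tuple[VoxelGrid, StackGroundTruth]:
    """Generate a two-channel blob phantom and its ground truth.

    Channel 1 carries the blob intensities plus background noise and hot
    pixels; channel 2 carries background noise of identical statistics
    without blobs. Truth is derived from the noise-free support at half
    of the maximum blob peak. Identical parameters and seed reproduce the
    stack bit for bit.
    """
    if min(params.shape) < 3:
        raise ValueError("degenerate grid: every dimension must be >= 3 voxels")
    if not params.blobs:
        raise ValueError("phantom needs at least one blob")
    rng = np.random.default_rng(params.seed)
    signal = _render_blobs(params.shape, params.voxel_size_um, params.blobs)
    half_max = 0.5 * max(b.peak for b in params.blobs)
    truth = _truth_from_signal(signal, params.voxel_size_um, half_max)
    tracer, auto = _add_channels(
        signal, params.background_mean, params.background_sd,
        params.hot_pixel_rate, params.hot_pixel_intensity, rng,
    )
    grid = VoxelGrid(
        tracer=tracer, autofluorescence=auto, voxel_size_um=params.voxel_size_um
    )
    return grid, truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class FieldPhantomParams:
    """Curved-sheet phantom of one terminal field.

    The labelled territory is an ellipse in the RC×ML plane (semi-axes
    ``field_semi_um``) carrying a domed thickness profile (maximum
    ``thickness_max_um``; the dorsoventral areal density *is* the mean
    thickness). The sheet's midline waves along RC with an amplitude
    solved per specimen so that the occupied dorsoventral extent equals
    ``dv_extent_um`` — span, density and focus effects therefore act
    independently. Intensity inside the sheet is ``peak`` modulated by
    the dome, far above the noise, so the processing chain recovers the
    support essentially exactly.
    """

    shape: tuple[int, int, int] = (48, 384, 160)
    voxel_size_um: tuple[float, float, float] = (2.0, 1.0, 1.0)
    field_semi_um: tuple[float, float] = (60.0, 24.0)  # (RC, ML)
    thickness_max_um: float = 30.0
    dv_extent_um: float = 40.0
    peak: float = 60.0
    background_mean: float = 20.0
    background_sd: float = 2.0
    hot_pixel_rate: float = 5e-5
    hot_pixel_intensity: float = 300.0
    centre_jitter_um: tuple[float, float, float] = (2.0, 4.0, 3.0)
    size_jitter_sd: float = 0.03
    thickness_jitter_sd: float = 0.03
    border_dorsal_um: float = 4.0
    border_medial_um: float = 8.0

    def __post_init__(self) -> None:
        if min(self.shape) <= 0 or min(self.voxel_size_um) <= 0:
            raise ValueError("grid shape and voxel sizes must be positive")
        if min(self.field_semi_um) <= 0 or self.thickness_max_um <= 0:
            raise ValueError("field semi-axes and thickness must be positive")
        if self.dv_extent_um <= 0:
            raise ValueError("dorsoventral extent must be positive")


@dataclass(frozen=True)
class GroupEffect:
    """Multiplicative group effects on the base field phantom."""

    span_ml: float = 1.0
    span_rc: float = 1.0
    span_dv: float = 1.0
    density: float = 1.0
    shift_ml_um: float = 0.0
    shift_dv_um: float = 0.0

    def __post_init__(self) -> None:
        if min(self.span_ml, self.span_rc, self.span_dv, self.density) <= 0:
            raise ValueError("multipliers must be positive")


#: defaults mirroring the measured genotype effects: mediolateral span
#: +14%, rostrocaudal span +30%, dorsoventral span unchanged, dorsoventral
#: areal density −22%, focus shifted 18.75 µm laterally / 1.42 µm ventrally
MUTANT_DEFAULT = GroupEffect(
    span_ml=1.14, span_rc=1.30, span_dv=1.00, density=0.78,
    shift_ml_um=18.75, shift_dv_um=1.42,
)


@dataclass(frozen=True)
class CohortParams:
    """A two-group cohort of field phantoms with known effects."""

    base: FieldPhantomParams = FieldPhantomParams()
    control: GroupEffect = GroupEffect()
    mutant: GroupEffect = MUTANT_DEFAULT
    n_per_group: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least two specimens per group")


@dataclass
class CohortSpecimen:
    """One generated specimen: stack (optional), truth, group, borders."""

    specimen_id: str
    group: str
    index: int
    truth: StackGroundTruth
    borders: BorderAnnotation
    grid: VoxelGrid | None = None


#: rim steepness of the thickness profile: (1 − ρ^P)^½ is a plateau with a
#: rounded rim, so threshold level barely moves the measured footprint
_RIM_EXPONENT = 16
#: crest flattening of the midline wave (tanh-saturated sine)
_WAVE_SAT = 2.5


def _field_signal(
    base: FieldPhantomParams, effect: GroupEffect, rng: np.random.Generator
) -> np.ndarray:
    """Noise-free intensity of one curved-sheet terminal field."""
    vz, vy, vx = base.voxel_size_um
    nz, ny, nx = base.shape
    # per-specimen biological variability, then group effects
    jit = 1.0 + rng.normal(0.0, base.size_jitter_sd, 3)  # (RC, ML, DV extent)
    t_jit = 1.0 + rng.normal(0.0, base.thickness_jitter_sd)
    r_rc = base.field_semi_um[0] * effect.span_rc * jit[0]
    r_ml = base.field_semi_um[1] * effect.span_ml * jit[1]
    dv_extent = base.dv_extent_um * effect.span_dv * jit[2]
    thickness = base.thickness_max_um * effect.density * t_jit

    grid_um = (np.asarray(base.shape) - 1) * np.asarray(base.voxel_size_um)
    centre = grid_um / 2.0 + np.array([effect.shift_dv_um, 0.0, effect.shift_ml_um])
    centre = centre + rng.normal(0.0, np.asarray(base.centre_jitter_um))

    dy = (np.arange(ny) * vy - centre[1])[:, None] / r_rc
    dx = (np.arange(nx) * vx - centre[2])[None, :] / r_ml
    rho2 = dy**2 + dx**2
    inside = rho2 < 1.0
    rho = np.sqrt(rho2)
    dome = np.sqrt(np.clip(1.0 - rho**_RIM_EXPONENT, 0.0, None))
    t_map = thickness * dome  # local sheet thickness (µm)
    # midline wave amplitude solved so the occupied DV extent matches the
    # configured span: extent = 2·A + thickness (crests sit on the plateau)
    amp = max((dv_extent - thickness) / 2.0, 0.0)
    wave = np.tanh(_WAVE_SAT * np.sin(1.5 * np.pi * dy)) / np.tanh(_WAVE_SAT)
    u_map = centre[0] + amp * wave * np.ones_like(dx)

    z_lo = u_map - t_map / 2.0
    z_hi = u_map + t_map / 2.0
    klo = np.ceil(z_lo / vz).astype(int)
    khi = np.ceil(z_hi / vz).astype(int)  # occupy klo..khi-1
    klo = np.clip(klo, 0, nz)
    khi = np.clip(khi, 0, nz)
    value = base.peak * (0.7 + 0.3 * dome)
    signal = np.zeros(base.shape, dtype=np.float64)
    yy, xx = np.nonzero(inside & (khi > klo))
    klo_f, khi_f, val_f = klo[yy, xx], khi[yy, xx], value[yy, xx]
    max_t = int((khi_f - klo_f).max()) if len(yy) else 0
    for t in range(max_t):
        sel = klo_f + t < khi_f
        signal[klo_f[sel] + t, yy[sel], xx[sel]] = val_f[sel]
    return signal


def _specimen(
    params: CohortParams, group: str, effect: GroupEffect, index: int, render: bool
) -> CohortSpecimen:
    # seed depends on the cohort seed and specimen index only — not on the
    # group — so identity effects yield seed-matched identical pairs
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, index]))
    base = params.base
    signal = _field_signal(base, effect, rng)
    # intensity floor is 0.7·peak, so half of the maximum recovers the
    # full sheet support
    truth = _truth_from_signal(signal, base.voxel_size_um, 0.5 * base.peak)
    grid = None
    if render:
        tracer, auto = _add_channels(
            signal, base.background_mean, base.background_sd,
            base.hot_pixel_rate, base.hot_pixel_intensity, rng,
        )
        grid = VoxelGrid(
            tracer=tracer, autofluorescence=auto, voxel_size_um=base.voxel_size_um
        )
    borders = BorderAnnotation(
        dorsal_um=base.border_dorsal_um, medial_um=base.border_medial_um
    )
    return CohortSpecimen(
        specimen_id=f"{group}-{index:02d}", group=group, index=index,
        truth=truth, borders=borders, grid=grid,
    )


def generate_cohort(
    params: CohortParams, render: bool = True
) -> Iterator[CohortSpecimen]:
    """Yield control then mutant specimens, lazily.

    Stacks are generated one at a time (a rendered two-channel stack is
    tens of MB); with ``render=False`` only the noise-free ground truth is
    computed, which is enough for truth-level statistics. Identical seeds
    reproduce every specimen exactly, independent of consumption order.
    """
    for group, effect in (("control", params.control), ("mutant", params.mutant)):
        for index in range(params.n_per_group):
            yield _specimen(params, group, effect, index, render)


# ---------------------------------------------------------------------------
# fibre models and spike generation


@dataclass(frozen=True)
class FiberModel:
    """Generative model of one afferent fibre.

    ``dynamic_gain`` sets the firing rate during ramps (Hz per mm/s of
    probe velocity), ``static_gain`` the hold rate (Hz per mN above
    threshold, SAMs only). ``threshold_mN`` is infinite for fibres with no
    mechanosensitive receptive field.
    """

    label: str
    cv_m_s: float
    threshold_mN: float = 10.0
    dynamic_gain: float = 150.0
    static_gain: float = 0.0
    refractory_ms: float = 1.0
    vibration_rate_hz: float = 100.0
    tap_rate_hz: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_m_s <= 0:
            raise ValueError("conduction velocity must be positive")
        if self.threshold_mN < 0:
            raise ValueError("threshold must be non-negative")
        if min(self.dynamic_gain, self.static_gain) < 0:
            raise ValueError("gains must be non-negative")


#: class-typical parameters: (CV mean, CV sd, CV clip range), threshold
#: mean ± sd (mN), dynamic gain, static gain
_CLASS_DEFAULTS = {
    "RAM": ((14.0, 1.5, (10.5, 22.0)), (10.0, 2.0), 150.0, 0.0),
    "SAM": ((15.0, 1.5, (10.5, 22.0)), (7.5, 1.5), 150.0, 0.75),
    "D-hair": ((5.0, 1.0, (1.5, 10.0)), (0.5, 0.15), 400.0, 0.0),
    "AM": ((4.0, 1.0, (1.5, 10.0)), (30.0, 5.0), 40.0, 0.0),
    "tap-unit": ((13.0, 1.5, (10.5, 22.0)), (np.inf, 0.0), 0.0, 0.0),
    "mechano-insensitive": ((12.0, 2.0, (10.5, 22.0)), (np.inf, 0.0), 0.0, 0.0),
}


def make_fiber(label: str, seed: int = 0) -> FiberModel:
    """A fibre with class-typical parameters, jittered reproducibly."""
    if label not in _CLASS_DEFAULTS:
        raise ValueError(f"unknown fibre class {label!r}")
    (cv_mu, cv_sd, cv_clip), (thr_mu, thr_sd), dyn, stat = _CLASS_DEFAULTS[label]
    label_key = sum(label.encode()) % 2**31  # stable across processes
    rng = np.random.default_rng(np.random.SeedSequence([label_key, seed]))
    cv = float(np.clip(rng.normal(cv_mu, cv_sd), *cv_clip))
    thr = np.inf if np.isinf(thr_mu) else float(max(rng.normal(thr_mu, thr_sd), 0.1))
    return FiberModel(
        label=label, cv_m_s=cv, threshold_mN=thr,
        dynamic_gain=dyn, static_gain=stat, seed=seed,
    )


def _rate_segments(
    model: FiberModel, epoch: Epoch
) -> list[tuple[float, float, float]]:
    """Piecewise-constant firing rate (t0, t1, Hz) within one epoch."""
    label = model.label
    if label == "mechano-insensitive":
        return []
    if label == "tap-unit":
        return []  # handled deterministically
    if epoch.kind == "ramp":
        force = epoch.force_mN or 0.0
        if force > model.threshold_mN and epoch.velocity_mm_s:
            rate = model.dynamic_gain * epoch.velocity_mm_s
            return [(epoch.start_s, epoch.end_s, rate)]
        return []
    if epoch.kind == "hold":
        force = epoch.force_mN or 0.0
        rate = model.static_gain * max(force - model.threshold_mN, 0.0)
        return [(epoch.start_s, epoch.end_s, rate)] if rate > 0 else []
    if epoch.kind == "vibration-ramp":
        amp = epoch.amplitude_mN or 0.0
        if amp <= model.threshold_mN:
            return []
        # envelope grows linearly from zero; firing begins at the
        # threshold crossing
        t_cross = epoch.start_s + epoch.duration_s * model.threshold_mN / amp
        return [(t_cross, epoch.end_s, model.vibration_rate_hz)]
    if epoch.kind == "manual-tap":
        if np.isfinite(model.threshold_mN):
            return [(epoch.start_s, epoch.end_s, model.tap_rate_hz)]
        return []
    return []


def generate_fiber_response(
    model: FiberModel, protocol: StimulusProtocol
) -> SpikeTrain:
    """Seeded spike train of one fibre for one protocol.

    Inhomogeneous Poisson sampling of the class-specific rate profile,
    thinned by the absolute refractory period. Tap-units emit exactly one
    deterministic spike shortly after tap onset; mechano-insensitive
    fibres stay silent.
    """
    rng = np.random.default_rng(model.seed)
    candidates: list[float] = []
    for epoch in protocol.epochs:
        if model.label == "tap-unit" and epoch.kind == "manual-tap":
            candidates.append(epoch.start_s + 0.002)
            continue
        for t0, t1, rate in _rate_segments(model, epoch):
            if rate <= 0:
                continue
            t = t0
            while True:
                t = t + rng.exponential(1.0 / rate)
                if t >= t1:
                    break
                candidates.append(t)
    candidates.sort()
    refractory = model.refractory_ms / 1000.0
    times: list[float] = []
    for t in candidates:
        if not times or t - times[-1] >= refractory:
            times.append(t)
    return SpikeTrain(fiber_id=f"{model.label}-{model.seed}", times=np.asarray(times))


def synthesize_trace(
    spike_times: Sequence[float],
    duration_s: float,
    fs_hz: float = 20000.0,
    amplitude: float = 1.0,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Toy extracellular voltage trace with injected spikes.

    Each spike is a short biphasic pulse on Gaussian baseline noise —
    just enough structure to exercise threshold-crossing detection.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    v = rng.normal(0.0, noise_sd, n)
    pulse = amplitude * np.array([1.0, 0.6, -0.4, -0.2])
    for st in spike_times:
        idx = int(round(st * fs_hz))
        if 0 <= idx < n - len(pulse):
            v[idx : idx + len(pulse)] += pulse
    return t, v
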