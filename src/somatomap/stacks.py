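"""Turn a raw two-channel image stack into a denoised binary mask.

The processing chain mirrors how transganglionically traced terminal fields
are extracted from cleared-tissue two-photon stacks:

1. :func:`subtract_autofluorescence` — remove shared background by
   subtracting the autofluorescence channel from the tracer channel,
   clamping at zero.
2. :func:`binarize_stack` — stack-histogram thresholding: a voxel is
   terminal-positive when its intensity exceeds the whole-stack mean grey
   value plus ``k_bin`` standard deviations (default 3, population SD).
3. :func:`remove_isolated_voxels` — drop voxels with no positive neighbour
   under a configurable 3D connectivity, eliminating hot pixels.

Axis convention throughout the package: ``(z, y, x)`` = (dorsoventral,
rostrocaudal, mediolateral), with per-axis voxel sizes in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy import ndimage

__all__ = [
    "PipelineConfig",
    "VoxelGrid",
    "BinaryMask",
    "subtract_autofluorescence",
    "binarize_stack",
    "remove_isolated_voxels",
    "process_stack",
]

#: scipy.ndimage connectivity rank for each neighbour count in 3D
_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable knobs of the mask-extraction and span-measurement steps.

    Parameters
    ----------
    k_bin:
        SD multiplier of the stack-histogram binarization threshold.
    k_span:
        SD multiplier of the projection threshold used for span
        measurement.
    connectivity:
        3D neighbourhood (6, 18 or 26 neighbours) defining "isolated".
    strict:
        Use strict ``>`` at thresholds (a constant stack yields an empty
        mask); ``False`` switches to ``>=``.
    density_on_thresholded:
        If True, the areal-density denominator uses the span-thresholded
        projection instead of all pixels > 0.
    """

    k_bin: float = 3.0
    k_span: float = 1.0
    connectivity: int = 26
    strict: bool = True
    density_on_thresholded: bool = False

    def __post_init__(self) -> None:
        if self.k_bin <= 0 or self.k_span <= 0:
            raise ValueError("threshold multipliers must be positive")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError("connectivity must be one of 6, 18, 26")

    def to_dict(self) -> dict[str, Any]:
        return {
            "k_bin": self.k_bin,
            "k_span": self.k_span,
            "connectivity": self.connectivity,
            "strict": self.strict,
            "density_on_thresholded": self.density_on_thresholded,
        }


@dataclass
class VoxelGrid:
    """A (possibly two-channel) 3D intensity stack with physical voxel sizes.

    ``tracer`` holds the tracer-fluorescence channel; ``autofluorescence``
    is the second channel or ``None`` after background subtraction.
    """

    tracer: np.ndarray
    voxel_size_um: tuple[float, float, float]
    autofluorescence: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tracer = np.asarray(self.tracer)
        if self.tracer.ndim != 3:
            raise ValueError("tracer channel must be a 3D array")
        vz, vy, vx = self.voxel_size_um
        if min(vz, vy, vx) <= 0:
            raise ValueError("voxel sizes must be positive")
        self.voxel_size_um = (float(vz), float(vy), float(vx))
        if self.tracer.size and self.tracer.min() < 0:
            raise ValueError("intensities must be non-negative")
        if self.autofluorescence is not None:
            self.autofluorescence = np.asarray(self.autofluorescence)
            if self.autofluorescence.shape != self.tracer.shape:
                raise ValueError(
                    "channel shape mismatch: tracer "
                    f"{self.tracer.shape} vs autofluorescence "
                    f"{self.autofluorescence.shape}"
                )
            if self.autofluorescence.size and self.autofluorescence.min() < 0:
                raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tracer.shape  # type: ignore[return-value]

    @property
    def has_autofluorescence(self) -> bool:
        return self.autofluorescence is not None


@dataclass
class BinaryMask:
    """A boolean grid of terminal-positive voxels plus provenance.

    ``provenance`` records at least the binarization threshold used and
    the number of voxels removed by denoising.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be a 3D array")
        vz, vy, vx = self.voxel_size_um
        if min(vz, vy, vx) <= 0:
            raise ValueError("voxel sizes must be positive")
        self.voxel_size_um = (float(vz), float(vy), float(vx))

    @property
    def count(self) -> int:
        """Number of positive voxels."""
        return int(np.count_nonzero(self.data))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


def subtract_autofluorescence(grid: VoxelGrid) -> VoxelGrid:
    """Subtract the autofluorescence channel from the tracer channel.

    Negative differences are clamped to zero (intensities are physical
    counts). Returns a single-channel grid with voxel sizes preserved.
    """
    if not grid.has_autofluorescence:
        raise ValueError("grid has no autofluorescence channel to subtract")
    diff = grid.tracer.astype(np.float64) - grid.autofluorescence.astype(np.float64)
    np.clip(diff, 0.0, None, out=diff)
    return VoxelGrid(tracer=diff, voxel_size_um=grid.voxel_size_um)


def _stack_threshold(values: np.ndarray, k: float) -> float:
    """Whole-stack mean grey value + k * population SD."""
    return float(values.mean() + k * values.std())


def binarize_stack(grid: VoxelGrid, config: PipelineConfig | None = None) -> BinaryMask:
    """Binarize via stack-histogram thresholding (mean + ``k_bin`` SD).

    The statistics run over *all* voxels of the (already background
    subtracted) stack, including the zero background — which is what makes
    mean + 3 SD a high-percentile cut. Population SD; strict ``>`` by
    default, so a constant stack yields an empty mask.
    """
    config = config or PipelineConfig()
    arr = grid.tracer
    if arr.size == 0:
        raise ValueError("cannot binarize an empty stack")
    threshold = _stack_threshold(arr.astype(np.float64, copy=False), config.k_bin)
    data = arr > threshold if config.strict else arr >= threshold
    return BinaryMask(
        data=data,
        voxel_size_um=grid.voxel_size_um,
        provenance={"threshold": threshold, "config": config.to_dict()},
    )


def remove_isolated_voxels(
    mask: BinaryMask, config: PipelineConfig | None = None
) -> BinaryMask:
    """Remove positive voxels with zero positive neighbours.

    "Neighbour" is defined by ``config.connectivity`` in 3D. Isolated
    voxels are exactly the size-1 connected components, so removal is
    idempotent: an isolated voxel is nobody's neighbour, hence removing it
    cannot isolate another voxel.
    """
    config = config or PipelineConfig()
    structure = ndimage.generate_binary_structure(
        3, _CONNECTIVITY_RANK[config.connectivity]
    )
    labels, n_components = ndimage.label(mask.data, structure=structure)
    if n_components == 0:
        kept = mask.data.copy()
        removed = 0
    else:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0  # background
        keep = sizes > 1
        kept = keep[labels]
        removed = int(mask.data.sum() - kept.sum())
    provenance = dict(mask.provenance)
    provenance["removed_isolated"] = provenance.get("removed_isolated", 0) + removed
    provenance["connectivity"] = config.connectivity
    return BinaryMask(data=kept, voxel_size_um=mask.voxel_size_um, provenance=provenance)


def process_stack(grid: VoxelGrid, config: PipelineConfig | None = None) -> BinaryMask:
    """Full chain: subtract channels, binarize, drop isolated voxels."""
    config = config or PipelineConfig()
    single = subtract_autofluorescence(grid) if grid.has_autofluorescence else grid
    return remove_isolated_voxels(binarize_stack(single, config), config)
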