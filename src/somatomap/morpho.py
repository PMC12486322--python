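"""Terminal-field morphometry on binary voxel masks.

Measurements made on a denoised binary mask of tracer-positive voxels:

* centre of mass — unweighted centroid of positive voxels (the field's
  somatotopic *focus*);
* centre-of-mass-aligned crops for comparative averaging;
* summed projections along the dorsoventral (DV), rostrocaudal (RC) and
  mediolateral (ML) axes (pixel value = voxels collapsed onto it);
* spans — extents of the axis-aligned bounding rectangle of the
  projection pixels surviving a mean + ``k_span`` SD threshold: ML and RC
  spans from the DV projection, DV span from the RC projection;
* areal densities — positive-voxel count divided by the occupied area
  (µm²) of each summed projection;
* focus offsets to the dorsal and medial grey–white-matter borders;
* derived comparisons: percent change and planar (2D Euclidean) shift.

Axis order is ``(z, y, x) = (DV, RC, ML)``; micrometre coordinates are
``index * voxel_size`` per axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

from .stacks import BinaryMask, PipelineConfig

__all__ = [
    "AXIS_LABELS",
    "Projection2D",
    "BorderAnnotation",
    "TerminalFieldMetrics",
    "centre_of_mass",
    "align_to_centre",
    "summed_projection",
    "measure_spans",
    "areal_density",
    "focus_offsets",
    "planar_shift",
    "percent_change",
    "measure_terminal_field",
]

#: collapse-axis index for each anatomical axis label
AXIS_LABELS: Mapping[str, int] = {"DV": 0, "RC": 1, "ML": 2}


@dataclass
class Projection2D:
    """A summed projection: per-pixel counts of collapsed voxels."""

    data: np.ndarray
    collapsed: str  # "DV" | "RC" | "ML"
    pixel_size_um: tuple[float, float]  # sizes of the two remaining axes

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("projection must be 2D")

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um[0] * self.pixel_size_um[1]


@dataclass(frozen=True)
class BorderAnnotation:
    """Grey–white-matter border coordinates (µm).

    ``dorsal_um`` is the DV coordinate of the dorsal border as seen in the
    rostrocaudal projection; ``medial_um`` the ML coordinate of the medial
    border as seen in the dorsoventral projection.
    """

    dorsal_um: float
    medial_um: float


@dataclass
class TerminalFieldMetrics:
    """Per-specimen morphometry bundle (one CSV row)."""

    specimen_id: str
    count: int
    com_voxel: tuple[float, float, float]
    com_um: tuple[float, float, float]
    span_ml_um: float
    span_rc_um: float
    span_dv_um: float
    density_dv: float
    density_rc: float
    density_ml: float
    offset_ml_um: float | None = None
    offset_dv_um: float | None = None
    extra: dict[str, Any] = field(default_factory=dict)

    def to_row(self) -> dict[str, Any]:
        row = {
            "specimen_id": self.specimen_id,
            "count": self.count,
            "com_dv_um": self.com_um[0],
            "com_rc_um": self.com_um[1],
            "com_ml_um": self.com_um[2],
            "span_ml_um": self.span_ml_um,
            "span_rc_um": self.span_rc_um,
            "span_dv_um": self.span_dv_um,
            "density_dv": self.density_dv,
            "density_rc": self.density_rc,
            "density_ml": self.density_ml,
            "offset_ml_um": self.offset_ml_um,
            "offset_dv_um": self.offset_dv_um,
        }
        row.update(self.extra)
        return row


def _require_positive(mask: BinaryMask) -> None:
    if mask.count == 0:
        raise ValueError("mask has no positive voxels")


def centre_of_mass(mask: BinaryMask) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted centroid of positive voxels.

    Returns ``(centre_voxel, centre_um)``; the µm form scales each axis by
    its voxel size. Raises on an empty mask.
    """
    _require_positive(mask)
    coords = np.argwhere(mask.data)
    centre_voxel = coords.mean(axis=0)
    centre_um = centre_voxel * np.asarray(mask.voxel_size_um)
    return centre_voxel, centre_um


def align_to_centre(mask: BinaryMask, window_shape: tuple[int, int, int]) -> BinaryMask:
    """Crop/pad to ``window_shape`` centred on the centre of mass.

    The centre is rounded to the nearest voxel with ties toward negative
    infinity; out-of-window regions are zero-filled, so the positive-voxel
    count is preserved whenever the window covers the cloud.
    """
    _require_positive(mask)
    window = tuple(int(w) for w in window_shape)
    if any(w <= 0 for w in window):
        raise ValueError("window shape must be positive")
    centre_voxel, _ = centre_of_mass(mask)
    # nearest voxel, ties toward -inf: ceil(c - 0.5)
    centre = np.ceil(centre_voxel - 0.5).astype(int)
    out = np.zeros(window, dtype=bool)
    starts = centre - np.asarray(window) // 2
    src_lo = np.maximum(starts, 0)
    src_hi = np.minimum(starts + window, mask.data.shape)
    dst_lo = src_lo - starts
    dst_hi = dst_lo + (src_hi - src_lo)
    if np.all(src_hi > src_lo):
        out[
            dst_lo[0] : dst_hi[0], dst_lo[1] : dst_hi[1], dst_lo[2] : dst_hi[2]
        ] = mask.data[
            src_lo[0] : src_hi[0], src_lo[1] : src_hi[1], src_lo[2] : src_hi[2]
        ]
    provenance = dict(mask.provenance)
    provenance["aligned_window"] = window
    return BinaryMask(data=out, voxel_size_um=mask.voxel_size_um, provenance=provenance)


def summed_projection(mask: BinaryMask, collapse: str) -> Projection2D:
    """Sum positive voxels along one anatomical axis.

    Conservation: the projection pixels sum to the mask's positive-voxel
    count.
    """
    if collapse not in AXIS_LABELS:
        raise ValueError(f"unknown axis label {collapse!r}; use DV, RC or ML")
    axis = AXIS_LABELS[collapse]
    data = mask.data.sum(axis=axis, dtype=np.int64)
    remaining = [i for i in range(3) if i != axis]
    pixel_size = (mask.voxel_size_um[remaining[0]], mask.voxel_size_um[remaining[1]])
    return Projection2D(data=data, collapsed=collapse, pixel_size_um=pixel_size)


def _threshold_projection(proj: Projection2D, config: PipelineConfig) -> np.ndarray:
    values = proj.data.astype(np.float64)
    threshold = values.mean() + config.k_span * values.std()
    return values > threshold if config.strict else values >= threshold


def _extent_um(indices: np.ndarray, step_um: float) -> float:
    """Bounding extent of occupied indices, in µm (voxel-count × size)."""
    if indices.size == 0:
        return 0.0
    return float((indices.max() - indices.min() + 1) * step_um)


def measure_spans(
    mask: BinaryMask, config: PipelineConfig | None = None
) -> dict[str, float]:
    """ML/RC/DV spans (µm) of the thresholded summed projections.

    Each projection is thresholded at its mean + ``k_span`` SD (over all
    pixels, population SD, strict ``>`` by default); the span is the
    extent of the axis-aligned bounding rectangle of surviving pixels. ML
    and RC come from the dorsoventral projection, DV from the rostrocaudal
    projection. A projection with no surviving pixel yields span 0.
    """
    config = config or PipelineConfig()
    _require_positive(mask)
    vz, vy, vx = mask.voxel_size_um

    dv_proj = summed_projection(mask, "DV")  # rows=RC, cols=ML
    dv_keep = _threshold_projection(dv_proj, config)
    rows, cols = np.nonzero(dv_keep)
    span_rc = _extent_um(rows, vy)
    span_ml = _extent_um(cols, vx)

    rc_proj = summed_projection(mask, "RC")  # rows=DV, cols=ML
    rc_keep = _threshold_projection(rc_proj, config)
    zrows, _ = np.nonzero(rc_keep)
    span_dv = _extent_um(zrows, vz)

    return {"ML": span_ml, "RC": span_rc, "DV": span_dv}


def areal_density(
    mask: BinaryMask, collapse: str, config: PipelineConfig | None = None
) -> float:
    """Positive voxels per µm² of occupied projection area.

    The denominator counts pixels with value > 0 in the summed projection
    (times the pixel area); with ``config.density_on_thresholded`` the
    span threshold is applied to the projection first.
    """
    config = config or PipelineConfig()
    _require_positive(mask)
    proj = summed_projection(mask, collapse)
    if config.density_on_thresholded:
        occupied = int(np.count_nonzero(_threshold_projection(proj, config)))
    else:
        occupied = int(np.count_nonzero(proj.data))
    if occupied == 0:
        raise ValueError("projection has no occupied pixels")
    return mask.count / (occupied * proj.pixel_area_um2)


def focus_offsets(
    mask: BinaryMask, borders: BorderAnnotation
) -> tuple[float, float]:
    """Distances (µm) of the focus to the medial and dorsal borders.

    Returns ``(ML offset, DV offset)``: |COM_ML − medial border| as seen
    in the dorsoventral projection and |COM_DV − dorsal border| as seen in
    the rostrocaudal projection.
    """
    if borders is None:
        raise ValueError("border annotation required")
    _, com_um = centre_of_mass(mask)
    return (
        abs(float(com_um[2]) - borders.medial_um),
        abs(float(com_um[0]) - borders.dorsal_um),
    )


def planar_shift(delta_ml_um: float, delta_dv_um: float) -> float:
    """Euclidean norm of a 2D focus displacement (µm)."""
    if not (np.isfinite(delta_ml_um) and np.isfinite(delta_dv_um)):
        raise ValueError("displacement components must be finite")
    return float(np.hypot(delta_ml_um, delta_dv_um))


def percent_change(reference: float, comparison: float) -> float:
    """100 × (comparison − reference) / reference."""
    if reference == 0:
        raise ValueError("reference must be non-zero")
    return 100.0 * (comparison - reference) / reference


def measure_terminal_field(
    mask: BinaryMask,
    borders: BorderAnnotation | None = None,
    config: PipelineConfig | None = None,
    specimen_id: str = "",
) -> TerminalFieldMetrics:
    """All per-specimen measurements in one bundle."""
    config = config or PipelineConfig()
    com_voxel, com_um = centre_of_mass(mask)
    spans = measure_spans(mask, config)
    densities = {ax: areal_density(mask, ax, config) for ax in ("DV", "RC", "ML")}
    if borders is not None:
        offset_ml, offset_dv = focus_offsets(mask, borders)
    else:
        offset_ml = offset_dv = None
    return TerminalFieldMetrics(
        specimen_id=specimen_id,
        count=mask.count,
        com_voxel=tuple(float(c) for c in com_voxel),
        com_um=tuple(float(c) for c in com_um),
        span_ml_um=spans["ML"],
        span_rc_um=spans["RC"],
        span_dv_um=spans["DV"],
        density_dv=densities["DV"],
        density_rc=densities["RC"],
        density_ml=densities["ML"],
        offset_ml_um=offset_ml,
        offset_dv_um=offset_dv,
    )
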