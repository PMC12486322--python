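"""Readers and writers for the package's on-disk formats.

Stacks travel as multi-page TIFF (axes ``ZCYX`` for two-channel stacks,
``ZYX`` for masks) with a JSON sidecar (``<file>.json``) as the
authoritative carrier of voxel sizes and channel order — TIFF z-spacing
conventions vary too much to rely on tags alone, though ImageJ-style
metadata is written and read as a fallback. Masks are 8-bit 0/255.
Protocols, spike trains, border annotations and fibre records are plain
CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile

from .ephys import Epoch, FiberRecord, SpikeTrain, StimulusProtocol
from .morpho import BorderAnnotation, TerminalFieldMetrics
from .stacks import BinaryMask, VoxelGrid

__all__ = [
    "write_stack",
    "read_stack",
    "write_mask",
    "read_mask",
    "write_protocol_csv",
    "read_protocol_csv",
    "write_spikes_csv",
    "read_spikes_csv",
    "read_borders_csv",
    "metrics_to_csv",
    "fiber_records_to_csv",
]


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_stack(path: str | Path, grid: VoxelGrid) -> None:
    """Write a two-channel stack as ZCYX TIFF plus a JSON sidecar."""
    path = Path(path)
    if not grid.has_autofluorescence:
        raise ValueError("write_stack expects a two-channel grid")
    data = np.stack(
        [np.asarray(grid.tracer), np.asarray(grid.autofluorescence)], axis=1
    ).astype(np.float32)
    vz, vy, vx = grid.voxel_size_um
    tifffile.imwrite(
        path, data, imagej=True,
        resolution=(1.0 / vx, 1.0 / vy),
        metadata={"spacing": vz, "unit": "um", "axes": "ZCYX"},
    )
    _sidecar(path).write_text(json.dumps({
        "axes": "ZCYX",
        "voxel_size_um": [vz, vy, vx],
        "channels": ["tracer", "autofluorescence"],
    }))


def read_stack(
    path: str | Path,
    voxel_size_um: tuple[float, float, float] | None = None,
) -> VoxelGrid:
    """Read a two-channel stack; the sidecar wins over TIFF metadata.

    ``voxel_size_um`` overrides both. Raises when the file does not carry
    exactly two channels, or when no voxel size can be determined.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        meta = tif.imagej_metadata or {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        axes = info.get("axes", axes)
        if voxel_size_um is None and "voxel_size_um" in info:
            voxel_size_um = tuple(info["voxel_size_um"])  # type: ignore[assignment]
    if voxel_size_um is None and "spacing" in meta:
        # xy resolution tags are in pixels per unit
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            xres = page.tags.get("XResolution")
            yres = page.tags.get("YResolution")
        if xres and yres:
            vx = xres.value[1] / xres.value[0]
            vy = yres.value[1] / yres.value[0]
            voxel_size_um = (float(meta["spacing"]), float(vy), float(vx))
    if voxel_size_um is None:
        raise ValueError(
            f"{path}: no voxel size in sidecar or metadata; pass voxel_size_um"
        )
    axes = axes.upper()
    if "C" not in axes:
        raise ValueError(f"{path}: expected a two-channel stack, found one channel")
    # normalize any permutation of Z, C, Y, X to ZCYX
    order = [axes.index(a) for a in "ZCYX" if a in axes]
    if sorted(axes) != sorted("ZCYX"):
        raise ValueError(f"{path}: unsupported axes {axes!r}; expected Z, C, Y, X")
    data = np.transpose(data, order)
    if data.shape[1] != 2:
        raise ValueError(
            f"{path}: expected exactly 2 channels (tracer, autofluorescence), "
            f"found {data.shape[1]}"
        )
    return VoxelGrid(
        tracer=data[:, 0], autofluorescence=data[:, 1],
        voxel_size_um=tuple(float(v) for v in voxel_size_um),  # type: ignore[arg-type]
    )


def write_mask(path: str | Path, mask: BinaryMask) -> None:
    """Write a mask as 0/255 8-bit ZYX TIFF plus a provenance sidecar."""
    path = Path(path)
    vz, vy, vx = mask.voxel_size_um
    tifffile.imwrite(
        path, (mask.data.astype(np.uint8) * 255), imagej=True,
        resolution=(1.0 / vx, 1.0 / vy),
        metadata={"spacing": vz, "unit": "um", "axes": "ZYX"},
    )
    provenance = {
        k: v for k, v in mask.provenance.items()
        if isinstance(v, (int, float, str, bool, list, dict))
    }
    _sidecar(path).write_text(json.dumps({
        "axes": "ZYX",
        "voxel_size_um": [vz, vy, vx],
        "provenance": provenance,
    }))


def read_mask(path: str | Path) -> BinaryMask:
    path = Path(path)
    data = tifffile.imread(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise ValueError(f"{path}: mask sidecar {sidecar.name} missing")
    info = json.loads(sidecar.read_text())
    return BinaryMask(
        data=data > 0,
        voxel_size_um=tuple(info["voxel_size_um"]),
        provenance=info.get("provenance", {}),
    )


_PROTOCOL_COLUMNS = [
    "epoch_id", "kind", "start_s", "end_s",
    "velocity_mm_s", "force_mN", "frequency_hz", "amplitude_mN",
]


def _num(value: float | None) -> str | None:
    # repr round-trips every float exactly through read_csv
    return None if value is None else repr(float(value))


def write_protocol_csv(path: str | Path, protocol: StimulusProtocol) -> None:
    rows = [
        {
            "epoch_id": i, "kind": e.kind,
            "start_s": _num(e.start_s), "end_s": _num(e.end_s),
            "velocity_mm_s": _num(e.velocity_mm_s), "force_mN": _num(e.force_mN),
            "frequency_hz": _num(e.frequency_hz),
            "amplitude_mN": _num(e.amplitude_mN),
        }
        for i, e in enumerate(protocol.epochs)
    ]
    pd.DataFrame(rows, columns=_PROTOCOL_COLUMNS).to_csv(path, index=False)


def read_protocol_csv(path: str | Path) -> StimulusProtocol:
    df = pd.read_csv(path, float_precision="round_trip")
    epochs = []
    for _, row in df.sort_values("epoch_id").iterrows():
        kwargs = {
            col: (None if pd.isna(row[col]) else float(row[col]))
            for col in ("velocity_mm_s", "force_mN", "frequency_hz", "amplitude_mN")
        }
        epochs.append(
            Epoch(kind=row["kind"], start_s=float(row["start_s"]),
                  end_s=float(row["end_s"]), **kwargs)
        )
    return StimulusProtocol(epochs=tuple(epochs))


def write_spikes_csv(path: str | Path, trains: Iterable[SpikeTrain]) -> None:
    rows = [
        {"fiber_id": tr.fiber_id, "time_s": _num(float(t))}
        for tr in trains for t in tr.times
    ]
    pd.DataFrame(rows, columns=["fiber_id", "time_s"]).to_csv(path, index=False)


def read_spikes_csv(path: str | Path) -> list[SpikeTrain]:
    df = pd.read_csv(path, float_precision="round_trip")
    trains = []
    for fid, sub in df.groupby("fiber_id", sort=False):
        trains.append(
            SpikeTrain(fiber_id=str(fid), times=np.sort(sub["time_s"].to_numpy()))
        )
    return trains


def read_borders_csv(path: str | Path) -> Mapping[str, BorderAnnotation]:
    """CSV columns: specimen_id, dorsal_border_um, medial_border_um."""
    df = pd.read_csv(path)
    return {
        str(row["specimen_id"]): BorderAnnotation(
            dorsal_um=float(row["dorsal_border_um"]),
            medial_um=float(row["medial_border_um"]),
        )
        for _, row in df.iterrows()
    }


def metrics_to_csv(path: str | Path, metrics: Iterable[TerminalFieldMetrics]) -> None:
    df = pd.DataFrame([m.to_row() for m in metrics])
    df.to_csv(path, index=False, float_format="%.6g")


def fiber_records_to_csv(path: str | Path, records: Iterable[FiberRecord]) -> None:
    df = pd.DataFrame([r.to_row() for r in records])
    df.to_csv(path, index=False, float_format="%.6g")
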