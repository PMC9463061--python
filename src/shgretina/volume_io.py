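"""Image-volume and trace I/O.

Conventions used throughout the package:

* volumes are 4D arrays indexed ``(channel, z, y, x)``;
* z index 0 is the innermost (ganglion-cell-side) plane, i.e. the plane
  facing the vitreous in a wholemount imaged from the vitreal side;
* all coordinates in trace files are physical micrometres, never voxel
  indices.

Volumes are stored as OME-TIFF with voxel sizes and channel names embedded
in the OME-XML; plain TIFFs can be read only when a sidecar metadata file
supplies the voxel size (silently assuming 1 µm is never acceptable).
Traces are stored either as SWC (one unbranched tree per trace, type code 2)
or as a flat CSV table.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "Volume",
    "MetadataError",
    "read_volume",
    "write_volume",
    "write_traces",
    "read_traces",
    "traces_to_table",
    "TRACE_COLUMNS",
]

TRACE_COLUMNS = [
    "trace_id",
    "point_index",
    "z_um",
    "y_um",
    "x_um",
    "radius_um",
    "intensity",
]


class MetadataError(ValueError):
    """Raised when physical metadata (voxel size) cannot be determined."""


@dataclass
class Volume:
    """A multi-channel 3D intensity grid with physical voxel sizes.

    Attributes
    ----------
    data : ndarray, shape (channel, z, y, x)
        Non-negative intensities.
    voxel_um : tuple of float
        ``(dz, dy, dx)`` in micrometres.
    channel_names : list of str
        One name per channel.
    origin_um : tuple of float
        Physical position of voxel (0, 0, 0), ``(z0, y0, x0)``.
    """

    data: np.ndarray
    voxel_um: tuple[float, float, float]
    channel_names: list[str]
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:  # single channel given as (z, y, x)
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValueError(f"expected (channel, z, y, x) data, got shape {self.data.shape}")
        self.voxel_um = tuple(float(v) for v in self.voxel_um)
        if any(v <= 0 for v in self.voxel_um):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_um}")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} channels"
            )
        if np.issubdtype(self.data.dtype, np.floating) and np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    # -- convenience ------------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            try:
                return self.channel_names.index(channel)
            except ValueError:
                raise KeyError(
                    f"channel {channel!r} not in {self.channel_names}"
                ) from None
        return int(channel)

    def channel_data(self, channel: int | str) -> np.ndarray:
        return self.data[self.channel_index(channel)]

    def z_um(self) -> np.ndarray:
        """Physical z coordinate of every plane."""
        nz = self.data.shape[1]
        return self.origin_um[0] + self.voxel_um[0] * np.arange(nz)


# ---------------------------------------------------------------------------
# OME-TIFF volumes
# ---------------------------------------------------------------------------

def write_volume(volume: Volume, path: str | Path) -> Path:
    """Write a :class:`Volume` as OME-TIFF with embedded physical metadata."""
    path = Path(path)
    dz, dy, dx = volume.voxel_um
    metadata = {
        "axes": "CZYX",
        "PhysicalSizeZ": dz,
        "PhysicalSizeZUnit": "µm",
        "PhysicalSizeY": dy,
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeX": dx,
        "PhysicalSizeXUnit": "µm",
        "Channel": {"Name": list(volume.channel_names)},
    }
    tifffile.imwrite(path, volume.data, ome=True, metadata=metadata)
    return path


def _parse_ome_metadata(xml: str) -> tuple[tuple[float, float, float] | None, list[str]]:
    root = ET.fromstring(xml)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    pixels = root.find(".//ome:Pixels", ns)
    if pixels is None:
        return None, []
    sizes = tuple(
        pixels.get(f"PhysicalSize{ax}") for ax in ("Z", "Y", "X")
    )
    voxel = None
    if all(s is not None for s in sizes):
        voxel = tuple(float(s) for s in sizes)  # type: ignore[arg-type]
    names = [
        ch.get("Name") or f"ch{i}"
        for i, ch in enumerate(pixels.findall("ome:Channel", ns))
    ]
    return voxel, names


def read_volume(path: str | Path, sidecar: str | Path | None = None) -> Volume:
    """Read a TIFF/OME-TIFF stack into a :class:`Volume`.

    Voxel sizes come from the OME metadata when present, otherwise from a
    YAML sidecar (``sidecar`` argument, or ``<path>.meta.yaml`` next to the
    file). A stack without any physical metadata raises
    :class:`MetadataError`.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            data = series.asarray()
            axes = series.axes
            ome_xml = tf.ome_metadata
    except (tifffile.TiffFileError, ValueError) as exc:
        raise ValueError(f"{path} is not a readable TIFF file: {exc}") from exc

    voxel, names = (None, [])
    if ome_xml:
        voxel, names = _parse_ome_metadata(ome_xml)

    # normalize axis order to (C, Z, Y, X): Y/X are the lateral image axes,
    # C (or S) the channel axis, and every other axis (Z, T, Q, I ...)
    # collapses into the axial dimension
    axes = axes.replace("S", "C")
    if "Y" not in axes or "X" not in axes:
        raise ValueError(f"{path}: cannot identify image axes in {axes!r}")
    other = [i for i, a in enumerate(axes) if a not in "CYX"]
    c_idx = [i for i, a in enumerate(axes) if a == "C"]
    order = c_idx + other + [axes.index("Y"), axes.index("X")]
    data = np.transpose(data, order)
    nc = data.shape[0] if c_idx else 1
    ny, nx = data.shape[-2:]
    data = data.reshape(nc, -1, ny, nx)

    if voxel is None:
        sidecar_path = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".meta.yaml")
        if sidecar_path.exists():
            meta = yaml.safe_load(sidecar_path.read_text())
            voxel = tuple(float(v) for v in meta["voxel_um"])
            names = list(meta.get("channel_names", names))
        else:
            raise MetadataError(
                f"{path}: no OME voxel size and no sidecar {sidecar_path}; "
                "refusing to assume a voxel size"
            )
    if not names or len(names) != data.shape[0]:
        names = [f"ch{i}" for i in range(data.shape[0])]
    return Volume(data=data, voxel_um=voxel, channel_names=names)


# ---------------------------------------------------------------------------
# Traces (SWC / CSV)
# ---------------------------------------------------------------------------

#: SWC type code for axons, per the standard field convention.
SWC_AXON_TYPE = 2


def traces_to_table(traces: Sequence) -> pd.DataFrame:
    """Flatten traces into the canonical table schema.

    Accepts any objects exposing ``id`` and ``points`` where each point has
    ``z_um``, ``y_um``, ``x_um``, ``radius_um`` and ``peak_intensity``
    (duck-typed so this module does not depend on the tracing module).
    """
    rows = []
    for trace in traces:
        for i, p in enumerate(trace.points):
            rows.append(
                (trace.id, i, p.z_um, p.y_um, p.x_um,
                 getattr(p, "radius_um", 0.0) or 0.0,
                 getattr(p, "peak_intensity", np.nan))
            )
    table = pd.DataFrame(rows, columns=TRACE_COLUMNS)
    return table.astype({"trace_id": int, "point_index": int})


def write_traces(traces: Sequence, path: str | Path, format: str = "csv") -> Path:
    """Serialize traces as SWC or CSV (coordinates in µm)."""
    path = Path(path)
    table = traces if isinstance(traces, pd.DataFrame) else traces_to_table(traces)
    if format == "csv":
        table.to_csv(path, index=False)
    elif format == "swc":
        lines = [
            "# SWC export: unbranched axon traces, coordinates in um",
            "# z axis: 0 = innermost (GCL-side) plane",
            "# n type x y z radius parent",
        ]
        node = 0
        for _, group in table.groupby("trace_id", sort=True):
            parent = -1
            for _, row in group.sort_values("point_index").iterrows():
                node += 1
                lines.append(
                    f"{node} {SWC_AXON_TYPE} {row.x_um:.4f} {row.y_um:.4f} "
                    f"{row.z_um:.4f} {row.radius_um:.4f} {parent}"
                )
                parent = node
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown trace format {format!r}; use 'swc' or 'csv'")
    return path


def read_traces(path: str | Path, format: str = "csv") -> pd.DataFrame:
    """Read traces back into the canonical table (inverse of write_traces)."""
    path = Path(path)
    if format == "csv":
        table = pd.read_csv(path, comment="#")
        missing = set(TRACE_COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"{path}: missing trace columns {sorted(missing)}")
        return table[TRACE_COLUMNS]
    if format == "swc":
        rows = []
        trace_id = -1
        point_index = 0
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            n, _type, x, y, z, radius, parent = line.split()
            if int(parent) == -1:
                trace_id += 1
                point_index = 0
            rows.append((trace_id, point_index, float(z), float(y), float(x),
                         float(radius), np.nan))
            point_index += 1
        return pd.DataFrame(rows, columns=TRACE_COLUMNS)
    raise ValueError(f"unknown trace format {format!r}; use 'swc' or 'csv'")
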