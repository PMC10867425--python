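"""TIFF/OME-TIFF stack I/O and run manifests."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import tifffile

from .quantify import ImageStack

__all__ = ["read_stack", "write_stack", "RunManifest"]

_AXES_ORDER = "TZCYX"


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as OME-TIFF with TZCYX axes and physical metadata."""
    data = stack.data
    if data.dtype == np.float64:
        data = data.astype(np.float32)
    # content-derived UUID keeps re-runs bit-identical
    digest = hashlib.sha256(data.tobytes()).hexdigest()
    uuid = f"urn:uuid:{digest[:8]}-{digest[8:12]}-{digest[12:16]}-{digest[16:20]}-{digest[20:32]}"
    tifffile.imwrite(
        str(path),
        data,
        ome=True,
        metadata={
            "UUID": uuid,
            "axes": _AXES_ORDER,
            "PhysicalSizeX": stack.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.z_step_um,
            "PhysicalSizeZUnit": "µm",
            "TimeIncrement": stack.frame_interval_min,
            "TimeIncrementUnit": "min",
            "Channel": {"Name": stack.channel_names},
        },
    )


def read_stack(
    path: str | Path,
    axes_hint: str | None = None,
    channel_names: list[str] | None = None,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
    frame_interval_min: float | None = None,
    reference_channel: str | None = None,
    measurement_channel: str | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF into a T×Z×C×Y×X stack.

    Axes are taken from the file's metadata or from ``axes_hint``; missing
    axes are inserted with size 1. Physical calibration is read from OME
    metadata, with explicit arguments taking precedence.
    """
    with tifffile.TiffFile(str(path)) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = axes_hint or series.axes
        axes = axes.upper().replace("S", "C").replace("Q", "")
        if len(axes) != data.ndim:
            raise ValueError(
                f"cannot resolve axes for {path}: data is {data.ndim}D but axes "
                f"{axes!r}; pass axes_hint (candidates: permutations of {_AXES_ORDER})"
            )
        unknown = set(axes) - set(_AXES_ORDER)
        if unknown:
            raise ValueError(f"unsupported axes {sorted(unknown)}; pass axes_hint")
        # reorder / insert missing axes
        for ax in _AXES_ORDER:
            if ax not in axes:
                data = np.expand_dims(data, axis=0)
                axes = ax + axes
        data = np.transpose(data, [axes.index(ax) for ax in _AXES_ORDER])

        meta = {}
        if tif.ome_metadata:
            try:
                import xml.etree.ElementTree as ET

                root = ET.fromstring(tif.ome_metadata)
                ns = {"ome": root.tag.split("}")[0].strip("{")}
                px = root.find(".//ome:Pixels", ns)
                if px is not None:
                    meta = px.attrib
            except Exception:  # malformed OME block: fall back to arguments
                meta = {}

    n_c = data.shape[2]
    names = channel_names or [f"C{i}" for i in range(n_c)]
    if channel_names is None and n_c == 2:
        names = ["reference", "measurement"]
    return ImageStack(
        data=data,
        channel_names=names,
        pixel_size_um=pixel_size_um or float(meta.get("PhysicalSizeX", 0) or 0) or 1.0,
        z_step_um=z_step_um or float(meta.get("PhysicalSizeZ", 0) or 0) or 0.6,
        frame_interval_min=frame_interval_min or float(meta.get("TimeIncrement", 0) or 0) or 6.0,
        reference_channel=reference_channel or names[0],
        measurement_channel=measurement_channel or names[-1],
    )


@dataclass
class RunManifest:
    """Reproducibility record written next to every pipeline output."""

    tool_version: str
    config: dict
    input_hashes: dict[str, str] = field(default_factory=dict)
    seed: int | None = None
    created: str = ""

    @staticmethod
    def hash_file(path: str | Path) -> str:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
        return h.hexdigest()

    @classmethod
    def create(cls, config: dict, inputs: dict[str, str | Path] | None = None,
               seed: int | None = None) -> "RunManifest":
        from . import __version__

        return cls(
            tool_version=__version__,
            config=config,
            input_hashes={k: cls.hash_file(v) for k, v in (inputs or {}).items()},
            seed=seed,
            created=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, path: str | Path) -> None:
        doc = {
            "tool_version": self.tool_version,
            "platform": platform.platform(),
            "config": self.config,
            "input_hashes": self.input_hashes,
            "seed": self.seed,
            "created": self.created,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
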