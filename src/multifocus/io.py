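"""Reading and writing multifocus stacks: multi-page TIFF + YAML sidecar.

Pixel data travel as ordinary multi-page TIFF (8/16-bit integer or 32-bit
float, grayscale or RGB).  The acquisition metadata a reconstruction needs
— one EFTL current per page, the pixel pitch, the effective blur
coefficient R0 and optionally the optics constants — live in a small
human-readable YAML sidecar next to the TIFF, so stacks stay inspectable
and diffable with standard tools.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .optics import OpticsConfig
from .stack import MultifocusStack

__all__ = ["StackMetadata", "read_stack", "write_stack", "read_metadata", "write_metadata"]

_SUPPORTED_DTYPES = ("uint8", "uint16", "float32", "float64")


@dataclass
class StackMetadata:
    """Sidecar metadata of a multifocus stack."""

    currents_mA: list[float]
    pixel_pitch_um: float = 5.5
    bit_depth: int = 8
    R0_px_per_mA: float | None = None
    registered: bool = False
    optics: dict | None = None
    notes: str = ""

    def optics_config(self) -> OpticsConfig:
        """OpticsConfig from the sidecar's optics block (defaults elsewhere)."""
        if not self.optics:
            return OpticsConfig()
        kwargs = dict(self.optics)
        if "power_calibration" in kwargs:
            kwargs["power_calibration"] = tuple(
                tuple(pair) for pair in kwargs["power_calibration"]
            )
        return OpticsConfig(**kwargs)


def write_metadata(meta: StackMetadata, path: str | Path) -> None:
    data = dataclasses.asdict(meta)
    data["currents_mA"] = [float(j) for j in meta.currents_mA]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_metadata(path: str | Path) -> StackMetadata:
    data = yaml.safe_load(Path(path).read_text())
    return StackMetadata(**data)


def write_stack(
    stack: MultifocusStack,
    tiff_path: str | Path,
    metadata_path: str | Path | None = None,
    R0_px_per_mA: float | None = None,
    notes: str = "",
) -> StackMetadata:
    """Write a stack as multi-page TIFF plus YAML sidecar.

    Integer slices are written verbatim; float slices as 32-bit float
    pages.  Returns the metadata object written to the sidecar (default
    sidecar path: TIFF path with a ``.yaml`` suffix).
    """
    data = np.asarray(stack.slices)
    if data.shape[0] < 1:
        raise ValueError("refusing to write an empty stack")
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    elif data.dtype.name not in _SUPPORTED_DTYPES:
        raise ValueError(f"unsupported dtype {data.dtype}; use uint8/uint16/float")
    tiff_path = Path(tiff_path)
    tifffile.imwrite(
        tiff_path,
        data,
        photometric="rgb" if stack.is_rgb else "minisblack",
        metadata=None,
    )
    meta = StackMetadata(
        currents_mA=[float(j) for j in stack.currents_mA],
        pixel_pitch_um=float(stack.pixel_pitch_um),
        bit_depth=int(stack.bit_depth),
        R0_px_per_mA=R0_px_per_mA,
        registered=bool(stack.registered),
        notes=notes,
    )
    if metadata_path is None:
        metadata_path = tiff_path.with_suffix(".yaml")
    write_metadata(meta, metadata_path)
    return meta


def read_stack(
    tiff_path: str | Path, metadata_path: str | Path | None = None
) -> tuple[MultifocusStack, StackMetadata]:
    """Read a multi-page TIFF and its sidecar into a MultifocusStack.

    The page count must match the sidecar's current count; unsupported
    dtypes are rejected.
    """
    tiff_path = Path(tiff_path)
    if metadata_path is None:
        metadata_path = tiff_path.with_suffix(".yaml")
    meta = read_metadata(metadata_path)
    data = tifffile.imread(tiff_path)
    if data.ndim == 2:
        data = data[None]
    if data.dtype.name not in _SUPPORTED_DTYPES:
        raise ValueError(f"unsupported TIFF dtype {data.dtype}")
    if data.shape[0] != len(meta.currents_mA):
        raise ValueError(
            f"{data.shape[0]} TIFF pages but {len(meta.currents_mA)} currents in sidecar"
        )
    stack = MultifocusStack(
        slices=data,
        currents_mA=np.asarray(meta.currents_mA, dtype=float),
        pixel_pitch_um=meta.pixel_pitch_um,
        bit_depth=meta.bit_depth,
        registered=meta.registered,
    )
    return stack, meta
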