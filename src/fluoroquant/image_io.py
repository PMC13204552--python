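"""Multi-channel image and manifest I/O.

Images are 2-D multi-channel rasters (TIFF, 8/12/16-bit unsigned or float).
Pixel values are kept losslessly as loaded — no rescaling, no histogram
stretching; normalization is the job of downstream pipelines.  All
coordinates are (row, col), origin top-left, 0-based; physical lengths are
converted to micrometres only at measurement time via ``pixel_size_um``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigurationError, FormatError

__all__ = [
    "MultiChannelImage",
    "ManifestEntry",
    "BatchManifest",
    "load_image",
    "write_records",
    "read_manifest",
    "write_manifest",
]

# a channel axis is recognised as the smallest axis of length <= this
_MAX_CHANNELS = 5


@dataclass(frozen=True)
class MultiChannelImage:
    """A calibrated 2-D image with named channels.

    Parameters
    ----------
    pixels:
        Array of shape ``(n_channels, height, width)``.  Integer dtypes are
        preserved from file; computations cast to float on demand.
    channel_names:
        Unique, ordered channel labels (e.g. ``("red", "green")``).
    pixel_size_um:
        Physical size of one pixel in micrometres (> 0).
    """

    pixels: np.ndarray
    channel_names: tuple[str, ...]
    pixel_size_um: float
    source_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 2:
            px = px[np.newaxis]
        if px.ndim != 3:
            raise ConfigurationError(
                f"pixels must be (channels, height, width); got shape {px.shape}"
            )
        object.__setattr__(self, "pixels", px)
        names = tuple(self.channel_names)
        if len(names) != px.shape[0]:
            raise ConfigurationError(
                f"{len(names)} channel names for {px.shape[0]} channels"
            )
        if len(set(names)) != len(names):
            raise ConfigurationError(f"channel names not unique: {names}")
        object.__setattr__(self, "channel_names", names)
        if not self.pixel_size_um > 0:
            raise ConfigurationError(
                f"pixel_size_um must be positive, got {self.pixel_size_um}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of every channel."""
        return self.pixels.shape[1:]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a float64 2-D view-copy."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise ConfigurationError(
                f"no channel {name!r}; available: {self.channel_names}"
            ) from None
        return np.asarray(self.pixels[idx], dtype=np.float64)

    def has_channel(self, name: str) -> bool:
        return name in self.channel_names


@dataclass(frozen=True)
class ManifestEntry:
    path: str
    condition: str
    channel_roles: Mapping[int, str]
    pixel_size_um: float


@dataclass
class BatchManifest:
    """Assignment of image files to conditions and channel roles."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ConfigurationError("manifest must contain at least one entry")

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e.condition not in seen:
                seen.append(e.condition)
        return seen

    def load_all(self) -> list[MultiChannelImage]:
        return [
            load_image(
                e.path,
                e.channel_roles,
                e.pixel_size_um,
                condition=e.condition,
            )
            for e in self.entries
        ]


def _find_channel_axis(shape: tuple[int, ...], declared: int | None) -> int:
    if declared is not None:
        if not -len(shape) <= declared < len(shape):
            raise ConfigurationError(
                f"channel_axis {declared} out of range for shape {shape}"
            )
        return declared % len(shape)
    candidates = [ax for ax, n in enumerate(shape) if n <= _MAX_CHANNELS]
    if not candidates:
        raise ConfigurationError(
            f"cannot locate channel axis in shape {shape}; "
            f"no axis of length <= {_MAX_CHANNELS} (declare channel_axis explicitly)"
        )
    return min(candidates, key=lambda ax: shape[ax])


def load_image(
    path: str | Path,
    channel_roles: Mapping[int, str],
    pixel_size_um: float,
    *,
    condition: str = "",
    channel_axis: int | None = None,
) -> MultiChannelImage:
    """Read a TIFF and relabel channels by role.

    ``channel_roles`` maps channel indices (along the channel axis) to role
    names, e.g. ``{0: "red", 1: "green"}``.  The channel axis is either
    declared or auto-detected as the smallest axis of length <= 5.  Integer
    pixel values are preserved exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - surfaced as a format error
        raise FormatError(f"cannot read {path} as TIFF: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    elif arr.ndim == 3:
        axis = _find_channel_axis(arr.shape, channel_axis)
        arr = np.moveaxis(arr, axis, 0)
    else:
        raise FormatError(
            f"{path}: expected a 2-D image or channel stack, got ndim={arr.ndim}"
        )
    n_chan = arr.shape[0]
    if len(channel_roles) != n_chan:
        raise ConfigurationError(
            f"{path}: {n_chan} channels in file but {len(channel_roles)} roles given"
        )
    indices = sorted(channel_roles)
    if indices != list(range(n_chan)):
        raise ConfigurationError(
            f"{path}: channel role indices {indices} must be 0..{n_chan - 1}"
        )
    names = tuple(channel_roles[i] for i in indices)
    return MultiChannelImage(
        pixels=arr,
        channel_names=names,
        pixel_size_um=pixel_size_um,
        source_id=path.name,
        condition=condition,
    )


def _record_to_dict(record) -> dict:
    if dataclasses.is_dataclass(record) and not isinstance(record, type):
        d = {}
        for f in dataclasses.fields(record):
            v = getattr(record, f.name)
            # nested dataclasses and arrays are not tabular; keep scalars/strings
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                continue
            if isinstance(v, np.ndarray):
                continue
            d[f.name] = v
        return d
    return dict(record)


def write_records(records: Sequence, path: str | Path, *, columns=None) -> None:
    """Write result rows to CSV with a header, full float precision.

    Accepts dataclass instances or mappings.  An empty list yields a
    header-only file when ``columns`` is given, otherwise an empty table.
    """
    rows = [_record_to_dict(r) for r in records]
    df = pd.DataFrame(rows, columns=columns)
    try:
        # repr() keeps the shortest round-trip representation of each float
        df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def read_manifest(path: str | Path, *, default_pixel_size_um: float | None = None) -> BatchManifest:
    """Parse a manifest CSV with columns path, condition, channels[, pixel_size_um].

    ``channels`` encodes the role mapping as ``"0:red;1:green"``.  Relative
    image paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"path", "condition", "channels"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"manifest {path} missing columns: {sorted(missing)}")
    entries = []
    for _, row in df.iterrows():
        roles: dict[int, str] = {}
        for part in str(row["channels"]).split(";"):
            idx, _, name = part.strip().partition(":")
            if not name:
                raise ConfigurationError(
                    f"manifest {path}: bad channel spec {part!r} (want index:name)"
                )
            roles[int(idx)] = name
        if "pixel_size_um" in df.columns and not pd.isna(row["pixel_size_um"]):
            px = float(row["pixel_size_um"])
        elif default_pixel_size_um is not None:
            px = float(default_pixel_size_um)
        else:
            raise ConfigurationError(
                f"manifest {path}: no pixel_size_um column and no default given"
            )
        img_path = Path(str(row["path"]))
        if not img_path.is_absolute():
            img_path = path.parent / img_path
        entries.append(
            ManifestEntry(
                path=str(img_path),
                condition=str(row["condition"]),
                channel_roles=roles,
                pixel_size_um=px,
            )
        )
    return BatchManifest(entries=entries)


def write_manifest(manifest: BatchManifest, path: str | Path) -> None:
    rows = []
    for e in manifest.entries:
        chan = ";".join(f"{i}:{e.channel_roles[i]}" for i in sorted(e.channel_roles))
        rows.append(
            {
                "path": e.path,
                "condition": e.condition,
                "channels": chan,
                "pixel_size_um": e.pixel_size_um,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
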