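"""Binary segmentation and object labeling.

Three thresholding entry points cover the pipelines' needs:

* per-channel Otsu followed by morphological closing (colocalization masks),
* a combined red/green mask for dual-channel JC-1 images, and
* a single *batch-global* Otsu threshold pooled across every image of every
  experimental condition, so that inter-condition intensity differences are
  preserved rather than equalized away by per-image thresholding.

Otsu's threshold maximizes the between-class variance of a 256-bin histogram
spanning the observed min-max of the pooled values, for every bit depth.
Foreground is strictly ``value > threshold``; ties go to background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as _sk_label
from skimage.morphology import closing as _closing, disk

from .errors import DegenerateInputError

__all__ = [
    "BinaryMask",
    "LabeledObjects",
    "otsu_threshold",
    "channel_mask",
    "combined_channel_mask",
    "global_otsu",
    "label_components",
]

OTSU_BINS = 256


@dataclass(frozen=True)
class BinaryMask:
    """A boolean foreground mask with threshold provenance."""

    grid: np.ndarray
    threshold: float
    closing_radius_px: int = 0
    # for combined dual-channel masks: per-channel thresholds
    thresholds: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=bool)
        object.__setattr__(self, "grid", g)
        if not self.thresholds:
            object.__setattr__(self, "thresholds", (float(self.threshold),))

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def __and__(self, other: "BinaryMask") -> np.ndarray:
        return self.grid & other.grid

    def __or__(self, other: "BinaryMask") -> np.ndarray:
        return self.grid | other.grid


@dataclass(frozen=True)
class LabeledObjects:
    """Connected-component labeling: 0 = background, labels 1..count."""

    labels: np.ndarray
    count: int
    connectivity: int

    def __iter__(self):
        for lab in range(1, self.count + 1):
            yield lab, self.labels == lab


def _as_values(values) -> np.ndarray:
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size < 2:
        raise DegenerateInputError("Otsu needs at least 2 values")
    return v


def otsu_threshold(values) -> float:
    """Histogram threshold maximizing between-class variance.

    Uses a 256-bin histogram over the observed min-max range regardless of
    input bit depth, so 8- and 16-bit images are treated identically.
    Pixels strictly above the returned threshold are foreground.
    """
    v = _as_values(values)
    vmin, vmax = v.min(), v.max()
    if vmin == vmax:
        raise DegenerateInputError("constant input: Otsu threshold undefined")
    return float(threshold_otsu(v, nbins=OTSU_BINS))


def channel_mask(channel: np.ndarray, closing_radius: int = 1) -> BinaryMask:
    """Otsu threshold one channel, then binary-close with a disk.

    ``closing_radius = 0`` returns the pure threshold mask.
    """
    chan = np.asarray(channel, dtype=np.float64)
    thr = otsu_threshold(chan)
    mask = chan > thr
    if closing_radius > 0:
        mask = _closing(mask, disk(closing_radius)).astype(bool)
    return BinaryMask(grid=mask, threshold=thr, closing_radius_px=int(closing_radius))


def combined_channel_mask(
    red: np.ndarray,
    green: np.ndarray,
    closing_radius: int = 1,
    mode: Literal["union", "sum"] = "union",
) -> BinaryMask:
    """Dual-channel mask for JC-1 images.

    ``union`` (default): union of the per-channel Otsu masks, so mitochondria
    visible in only one JC-1 form (monomer-only at low membrane potential,
    aggregate-only at high) are retained.  ``sum``: Otsu on the summed
    channels.  A channel that is constant contributes an empty mask; if both
    are constant the input is degenerate.
    """
    red = np.asarray(red, dtype=np.float64)
    green = np.asarray(green, dtype=np.float64)
    if red.shape != green.shape:
        raise DegenerateInputError(
            f"channel shapes differ: {red.shape} vs {green.shape}"
        )
    if mode == "sum":
        m = channel_mask(red + green, closing_radius)
        return BinaryMask(
            grid=m.grid,
            threshold=m.threshold,
            closing_radius_px=int(closing_radius),
        )
    masks: list[np.ndarray] = []
    thresholds: list[float] = []
    for chan in (red, green):
        try:
            m = channel_mask(chan, closing_radius)
        except DegenerateInputError:
            continue
        masks.append(m.grid)
        thresholds.append(m.threshold)
    if not masks:
        raise DegenerateInputError("both channels constant: no combined mask")
    union = np.logical_or.reduce(masks)
    return BinaryMask(
        grid=union,
        threshold=thresholds[0],
        closing_radius_px=int(closing_radius),
        thresholds=tuple(thresholds),
    )


def global_otsu(batch: Iterable[np.ndarray]) -> float:
    """One Otsu threshold over the pooled histogram of a whole batch.

    Every image in the batch is then binarized with this identical
    threshold, which preserves genuine intensity differences between
    experimental conditions.  Invariant to batch order and to how the same
    pixels are split across images.
    """
    grids = [np.asarray(g, dtype=np.float64).ravel() for g in batch]
    if not grids:
        raise DegenerateInputError("empty batch")
    pooled = np.concatenate(grids)
    return otsu_threshold(pooled)


def label_components(mask: BinaryMask | np.ndarray, connectivity: int = 8) -> LabeledObjects:
    """Label maximal connected foreground regions 1..n.

    ``connectivity`` is 4 (edge-adjacent) or 8 (edge- or corner-adjacent,
    the default for foreground).
    """
    grid = mask.grid if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if connectivity not in (4, 8):
        raise DegenerateInputError(f"connectivity must be 4 or 8, got {connectivity}")
    sk_conn = 1 if connectivity == 4 else 2
    labels, count = _sk_label(grid, connectivity=sk_conn, return_num=True)
    return LabeledObjects(labels=labels, count=int(count), connectivity=connectivity)
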