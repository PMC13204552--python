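"""Two-channel colocalization statistics.

Quantifies the spatial co-occurrence of two fluorescence channels (e.g. a
drug's intrinsic fluorescence against an organelle marker) with four
complementary statistics:

* Pearson correlation (PCC), computed two ways: pixel-wise over the union
  of the per-channel Otsu masks, and along an algorithmically optimized
  scan line through the signal;
* Manders' coefficients M1/M2 — the fraction of each channel's integrated
  intensity lying within the other channel's mask (thresholded variant);
* the Intensity Correlation Quotient (ICQ) — a sign-based covariation
  statistic in [-0.5, +0.5].

The scan line is the full-image chord through the union-mask centroid whose
orientation, among ``n_orientations`` evenly spaced in [0, pi), maximizes
the summed product of the two channels' bilinearly interpolated intensities;
ties break to the smallest orientation index.  A statistic that is undefined
on the input (constant channel, empty mask) is reported as missing with a
reason — never coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._sampling import bilinear_sample, clip_chord_to_image, line_points
from .errors import NoSignalError, UndefinedStatisticError
from .image_io import MultiChannelImage
from .segmentation import BinaryMask, channel_mask

__all__ = [
    "ScanLine",
    "ColocalizationResult",
    "ColocParams",
    "pearson",
    "manders",
    "icq",
    "optimize_scan_line",
    "line_profile",
    "colocalize",
]


@dataclass(frozen=True)
class ScanLine:
    """A sub-pixel sampling segment with the objective that selected it."""

    start: tuple[float, float]
    end: tuple[float, float]
    sample_step_px: float
    objective_value: float
    orientation_rad: float = 0.0
    orientation_index: int = 0

    def __post_init__(self) -> None:
        if self.start == self.end:
            raise ValueError("scan line endpoints must be distinct")
        if not self.sample_step_px > 0:
            raise ValueError("sample_step_px must be positive")


@dataclass(frozen=True)
class ColocParams:
    closing_radius_px: int = 1
    n_orientations: int = 36
    sample_step_px: float = 0.5


@dataclass(frozen=True)
class ColocalizationResult:
    """All colocalization statistics for one channel pair of one image.

    Undefined statistics are ``None`` with the reason in ``missing``.
    """

    channel_a: str
    channel_b: str
    pcc_pixel: float | None
    pcc_line: float | None
    m1: float | None
    m2: float | None
    icq: float | None
    n_pixels_union: int
    threshold_a: float
    threshold_b: float
    closing_radius_px: int
    scan_line: ScanLine | None = None
    source_id: str = ""
    condition: str = ""
    missing: str = ""


def pearson(a, b) -> float:
    """Sample Pearson correlation of paired intensities.

    Raises :class:`UndefinedStatisticError` when either coordinate is
    constant (zero variance) or fewer than 2 pairs are given.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 2:
        raise UndefinedStatisticError("Pearson needs >= 2 pairs")
    da = a - a.mean()
    db = b - b.mean()
    ssa = float(da @ da)
    ssb = float(db @ db)
    if ssa == 0.0 or ssb == 0.0:
        raise UndefinedStatisticError("Pearson undefined for constant input")
    r = float(da @ db) / np.sqrt(ssa * ssb)
    return float(np.clip(r, -1.0, 1.0))


def manders(
    a: np.ndarray,
    b: np.ndarray,
    mask_a: BinaryMask | np.ndarray,
    mask_b: BinaryMask | np.ndarray,
) -> tuple[float, float]:
    """Thresholded Manders coefficients (M1, M2).

    M1 = sum of channel-A intensity over mask_a & mask_b, divided by the sum
    over mask_a; M2 swaps the roles.  Both lie in [0, 1].
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    ma = mask_a.grid if isinstance(mask_a, BinaryMask) else np.asarray(mask_a, bool)
    mb = mask_b.grid if isinstance(mask_b, BinaryMask) else np.asarray(mask_b, bool)
    if not (a.shape == b.shape == ma.shape == mb.shape):
        raise ValueError("channel/mask shapes differ")
    denom_a = float(a[ma].sum())
    denom_b = float(b[mb].sum())
    if denom_a <= 0.0 or denom_b <= 0.0:
        raise UndefinedStatisticError("Manders undefined: zero mask-integrated signal")
    both = ma & mb
    m1 = float(a[both].sum()) / denom_a
    m2 = float(b[both].sum()) / denom_b
    return float(np.clip(m1, 0.0, 1.0)), float(np.clip(m2, 0.0, 1.0))


def icq(a: np.ndarray, b: np.ndarray, mask: BinaryMask | np.ndarray) -> float:
    """Intensity Correlation Quotient within a mask.

    With means taken over the mask, counts pixels whose mean-deviation
    product (a - a_mean)(b - b_mean) is positive, divides by the number of
    pixels with a nonzero product, and subtracts 0.5.  Zero products are
    excluded from both counts to avoid bias from masked-out zeros.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    m = mask.grid if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    av, bv = a[m], b[m]
    if av.size < 2:
        raise UndefinedStatisticError("ICQ needs >= 2 mask pixels")
    prod = (av - av.mean()) * (bv - bv.mean())
    nonzero = prod != 0.0
    n_nonzero = int(nonzero.sum())
    if n_nonzero == 0:
        raise UndefinedStatisticError("ICQ undefined: all mean-deviation products zero")
    n_pos = int((prod > 0.0).sum())
    val = n_pos / n_nonzero - 0.5
    return float(np.clip(val, -0.5, 0.5))


def optimize_scan_line(
    a: np.ndarray,
    b: np.ndarray,
    mask_a: BinaryMask | np.ndarray,
    mask_b: BinaryMask | np.ndarray,
    n_orientations: int = 36,
    sample_step_px: float = 0.5,
) -> ScanLine:
    """Pick the scan line maximizing summed joint intensity.

    Candidates are full-image chords through the centroid of the union mask
    at ``n_orientations`` orientations evenly spaced in [0, pi).  The
    objective is sum(a_i * b_i) over bilinear samples along the chord.
    Deterministic tie-break: the smallest orientation index wins.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    ma = mask_a.grid if isinstance(mask_a, BinaryMask) else np.asarray(mask_a, bool)
    mb = mask_b.grid if isinstance(mask_b, BinaryMask) else np.asarray(mask_b, bool)
    union = ma | mb
    if not union.any():
        raise NoSignalError("empty union mask: no scan line")
    if n_orientations < 1:
        raise ValueError("n_orientations must be >= 1")
    rows, cols = np.nonzero(union)
    center = (float(rows.mean()), float(cols.mean()))
    best: ScanLine | None = None
    for k in range(n_orientations):
        theta = np.pi * k / n_orientations
        # orientation 0 = horizontal chord: direction along columns
        direction = (float(np.sin(theta)), float(np.cos(theta)))
        p0, p1 = clip_chord_to_image(center, direction, a.shape)
        rr, cc = line_points(p0, p1, sample_step_px)
        obj = float(np.sum(bilinear_sample(a, rr, cc) * bilinear_sample(b, rr, cc)))
        if best is None or obj > best.objective_value + 1e-12:
            best = ScanLine(
                start=p0,
                end=p1,
                sample_step_px=sample_step_px,
                objective_value=obj,
                orientation_rad=theta,
                orientation_index=k,
            )
    assert best is not None
    return best


def line_profile(channel: np.ndarray, line: ScanLine) -> np.ndarray:
    """Bilinear intensity profile along a scan line, endpoint-inclusive."""
    rr, cc = line_points(line.start, line.end, line.sample_step_px)
    return bilinear_sample(channel, rr, cc)


def colocalize(
    image: MultiChannelImage,
    role_a: str,
    role_b: str,
    params: ColocParams = ColocParams(),
) -> ColocalizationResult:
    """Full colocalization analysis of one channel pair.

    Builds per-channel Otsu + closing masks, the union mask, and the
    optimized scan line, then computes pixel-wise PCC (union mask),
    line-profile PCC, Manders M1/M2 and ICQ.  Statistics that are undefined
    on this image are reported as ``None`` with the reason in ``missing``.
    """
    a = image.channel(role_a)
    b = image.channel(role_b)
    mask_a = channel_mask(a, params.closing_radius_px)
    mask_b = channel_mask(b, params.closing_radius_px)
    union = mask_a.grid | mask_b.grid
    n_union = int(union.sum())

    missing: list[str] = []

    pcc_pixel = None
    if n_union >= 2:
        try:
            pcc_pixel = pearson(a[union], b[union])
        except UndefinedStatisticError as exc:
            missing.append(f"pcc_pixel: {exc}")
    else:
        missing.append("pcc_pixel: union mask has < 2 pixels")

    m1 = m2 = None
    try:
        m1, m2 = manders(a, b, mask_a, mask_b)
    except UndefinedStatisticError as exc:
        missing.append(f"manders: {exc}")

    icq_val = None
    try:
        icq_val = icq(a, b, union)
    except UndefinedStatisticError as exc:
        missing.append(f"icq: {exc}")

    scan = None
    pcc_line = None
    try:
        scan = optimize_scan_line(
            a, b, mask_a, mask_b, params.n_orientations, params.sample_step_px
        )
        prof_a = line_profile(a, scan)
        prof_b = line_profile(b, scan)
        pcc_line = pearson(prof_a, prof_b)
    except (NoSignalError, UndefinedStatisticError) as exc:
        missing.append(f"pcc_line: {exc}")

    return ColocalizationResult(
        channel_a=role_a,
        channel_b=role_b,
        pcc_pixel=pcc_pixel,
        pcc_line=pcc_line,
        m1=m1,
        m2=m2,
        icq=icq_val,
        n_pixels_union=n_union,
        threshold_a=mask_a.threshold,
        threshold_b=mask_b.threshold,
        closing_radius_px=params.closing_radius_px,
        scan_line=scan,
        source_id=image.source_id,
        condition=image.condition,
        missing="; ".join(missing),
    )
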