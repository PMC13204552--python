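"""JC-1 mitochondrial membrane-potential profiling.

JC-1 is a ratiometric dye: at low membrane potential it stays a green
monomer, at high potential it forms red aggregates, so the red/green ratio
along a mitochondrion maps the spatial distribution of potential.  The
pipeline segments mitochondria from the combined red/green mask, finds each
object's principal axis by PCA of its (intensity-weighted) pixel
coordinates, samples both channels along that axis with bilinear
interpolation, normalizes each profile to its own maximum, and reports the
red/green ratio profile plus the pixel-wise red-green Pearson correlation
within the object ("pix PCC").  A spatially uniform potential gives
pix PCC near +1; a mosaic object — red-dominant at one end, green-dominant
at the other — gives a negative pix PCC and a monotone ratio profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._sampling import bilinear_sample
from .errors import DegenerateInputError, UndefinedStatisticError
from .colocalization import pearson
from .image_io import MultiChannelImage
from .segmentation import combined_channel_mask, label_components

__all__ = [
    "PrincipalAxis",
    "AxialProfile",
    "JC1Params",
    "JC1Summary",
    "principal_axis",
    "sample_axis",
    "normalize_profile",
    "jc1_pipeline",
]

# eigenvalue ratio below which an object is flagged near-isotropic
_ISOTROPY_RATIO = 1.2


@dataclass(frozen=True)
class PrincipalAxis:
    """Leading PCA axis of one object's pixel distribution."""

    centroid: tuple[float, float]
    direction: tuple[float, float]  # unit (row, col), row-component >= 0
    t_min: float  # projection range of object pixels, px
    t_max: float
    eigenvalue_ratio: float
    near_isotropic: bool

    @property
    def half_length_px(self) -> float:
        return 0.5 * (self.t_max - self.t_min)


@dataclass(frozen=True)
class AxialProfile:
    """Dual-channel normalized intensity profile along one object's axis."""

    object_label: int
    axis: PrincipalAxis
    positions_um: np.ndarray  # strictly increasing, centered on the centroid
    green_norm: np.ndarray
    red_norm: np.ndarray
    ratio: np.ndarray  # red_norm/green_norm where green_norm > ratio_floor, else nan
    pix_pcc: float | None
    ratio_axial_variance: float  # mosaic readout: variance of ratio along axis
    red_flagged: bool = False  # all-zero red profile: normalization undefined
    green_flagged: bool = False
    source_id: str = ""
    condition: str = ""


@dataclass(frozen=True)
class JC1Params:
    red_channel: str = "red"
    green_channel: str = "green"
    closing_radius_px: int = 1
    connectivity: int = 8
    step_px: float = 0.25
    weighted_pca: bool = True
    ratio_floor: float = 0.05
    min_object_px: int = 2


@dataclass
class JC1Summary:
    """Per-image aggregate of the JC-1 analysis."""

    n_objects: int
    n_skipped_degenerate: int
    mean_pix_pcc: float | None
    frac_anticorrelated: float | None  # fraction of objects with pix_pcc < 0
    source_id: str = ""
    condition: str = ""


def principal_axis(
    object_pixels: np.ndarray,
    weights: np.ndarray | None = None,
) -> PrincipalAxis:
    """Leading eigenvector of the (weighted) covariance of pixel coordinates.

    ``object_pixels`` is an (n, 2) array of (row, col) coordinates; weights
    default to uniform.  The direction sign is fixed so the row component is
    >= 0 (ties: col >= 0).  Objects whose eigenvalue ratio is below 1.2 are
    flagged near-isotropic (any direction is equally valid).
    """
    pts = np.asarray(object_pixels, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise DegenerateInputError("principal axis needs >= 2 pixels")
    if weights is None:
        w = np.ones(pts.shape[0])
    else:
        w = np.asarray(weights, dtype=np.float64).ravel()
        if w.shape[0] != pts.shape[0]:
            raise ValueError("weights length must match pixel count")
        if w.sum() <= 0:
            w = np.ones(pts.shape[0])
    w = w / w.sum()
    centroid = w @ pts
    centered = pts - centroid
    cov = (centered * w[:, None]).T @ centered
    evals, evecs = np.linalg.eigh(cov)  # ascending
    direction = evecs[:, -1]
    if direction[0] < 0 or (direction[0] == 0 and direction[1] < 0):
        direction = -direction
    lam_major, lam_minor = float(evals[-1]), float(evals[0])
    ratio = lam_major / lam_minor if lam_minor > 1e-12 else np.inf
    t = centered @ direction
    return PrincipalAxis(
        centroid=(float(centroid[0]), float(centroid[1])),
        direction=(float(direction[0]), float(direction[1])),
        t_min=float(t.min()),
        t_max=float(t.max()),
        eigenvalue_ratio=float(ratio),
        near_isotropic=bool(ratio < _ISOTROPY_RATIO),
    )


def sample_axis(channel: np.ndarray, axis: PrincipalAxis, step_px: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear samples of ``channel`` along the axis.

    Returns (positions_px, values): positions are the signed projection
    parameter t spanning [t_min, t_max] at the requested step,
    endpoint-inclusive; sample points are centroid + t * direction.
    """
    extent = axis.t_max - axis.t_min
    if extent <= 0:
        raise DegenerateInputError("axis extent must be positive")
    n = max(int(np.ceil(extent / step_px)), 1)
    t = np.linspace(axis.t_min, axis.t_max, n + 1)
    rows = axis.centroid[0] + t * axis.direction[0]
    cols = axis.centroid[1] + t * axis.direction[1]
    return t, bilinear_sample(channel, rows, cols)


def normalize_profile(values: Sequence[float]) -> np.ndarray:
    """Divide a non-negative profile by its maximum (result in [0, 1]).

    Raises :class:`UndefinedStatisticError` on an all-zero profile; the
    pipeline then reports the raw profile with a flag instead of dividing.
    """
    v = np.asarray(values, dtype=np.float64)
    vmax = float(v.max(initial=0.0))
    if vmax <= 0.0:
        raise UndefinedStatisticError("all-zero profile: normalization undefined")
    return v / vmax


def _object_profile(
    red: np.ndarray,
    green: np.ndarray,
    mask: np.ndarray,
    label: int,
    pixel_size_um: float,
    params: JC1Params,
    source_id: str,
    condition: str,
) -> AxialProfile:
    rows, cols = np.nonzero(mask)
    pts = np.column_stack([rows, cols])
    weights = (red[mask] + green[mask]) if params.weighted_pca else None
    axis = principal_axis(pts, weights)
    t, red_raw = sample_axis(red, axis, params.step_px)
    _, green_raw = sample_axis(green, axis, params.step_px)

    red_flag = green_flag = False
    try:
        red_norm = normalize_profile(red_raw)
    except UndefinedStatisticError:
        red_norm, red_flag = red_raw.copy(), True
    try:
        green_norm = normalize_profile(green_raw)
    except UndefinedStatisticError:
        green_norm, green_flag = green_raw.copy(), True

    ratio = np.full_like(red_norm, np.nan)
    defined = green_norm > params.ratio_floor
    ratio[defined] = red_norm[defined] / green_norm[defined]
    finite = ratio[np.isfinite(ratio)]
    ratio_var = float(np.var(finite)) if finite.size >= 2 else 0.0

    try:
        pcc = pearson(red[mask], green[mask])
    except UndefinedStatisticError:
        pcc = None

    return AxialProfile(
        object_label=label,
        axis=axis,
        positions_um=t * pixel_size_um,
        green_norm=green_norm,
        red_norm=red_norm,
        ratio=ratio,
        pix_pcc=pcc,
        ratio_axial_variance=ratio_var,
        red_flagged=red_flag,
        green_flagged=green_flag,
        source_id=source_id,
        condition=condition,
    )


def jc1_pipeline(
    image: MultiChannelImage,
    params: JC1Params = JC1Params(),
) -> tuple[list[AxialProfile], JC1Summary]:
    """Segment mitochondria and profile membrane potential along each axis.

    Objects smaller than ``min_object_px`` or with a degenerate axis are
    skipped and counted.  The summary reports the mean pix PCC and the
    fraction of objects with within-object red/green anticorrelation
    (pix PCC < 0), the signature of mosaic potential distributions.
    """
    red = image.channel(params.red_channel)
    green = image.channel(params.green_channel)
    mask = combined_channel_mask(red, green, params.closing_radius_px)
    labeled = label_components(mask, params.connectivity)

    profiles: list[AxialProfile] = []
    n_skipped = 0
    for lab, obj_mask in labeled:
        if int(obj_mask.sum()) < params.min_object_px:
            n_skipped += 1
            continue
        try:
            profiles.append(
                _object_profile(
                    red,
                    green,
                    obj_mask,
                    lab,
                    image.pixel_size_um,
                    params,
                    image.source_id,
                    image.condition,
                )
            )
        except DegenerateInputError:
            n_skipped += 1

    pccs = [p.pix_pcc for p in profiles if p.pix_pcc is not None]
    summary = JC1Summary(
        n_objects=len(profiles),
        n_skipped_degenerate=n_skipped,
        mean_pix_pcc=float(np.mean(pccs)) if pccs else None,
        frac_anticorrelated=(float(np.mean([p < 0 for p in pccs])) if pccs else None),
        source_id=image.source_id,
        condition=image.condition,
    )
    return profiles, summary
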