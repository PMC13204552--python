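"""Synthetic fluorescence fields with exact ground truth.

Generates the three kinds of imagery the analysis pipelines assume, with
every generative parameter recorded so each stage can be validated without
any external data:

* tube fields — curvilinear organelles with Gaussian cross-sections along
  smooth random polylines of known (analytic) centerline length;
* colocalization fields — two-channel punctate vesicle fields where a
  designed fraction ``f`` of spots is placed at identical positions in both
  channels and the rest are kept apart;
* JC-1 fields — dual-channel tubes whose red/green amplitude varies along
  the centerline (uniform, half-and-half, or a linear gradient), emulating
  mosaic membrane-potential distributions.

The noise model is standard shot + read noise: the clean render is passed
through a Poisson draw (mean = clean * poisson_scale, divided back), plus
additive Gaussian read noise, clipped at zero and quantized to 16 bits.
Fields are bit-identical for a fixed seed and parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree

from .errors import DensityError
from .image_io import MultiChannelImage

__all__ = [
    "NoiseParams",
    "TubeSpec",
    "SpotSpec",
    "SyntheticTruth",
    "make_tube_field",
    "make_coloc_field",
    "make_jc1_field",
]

MosaicMode = Literal["uniform", "half-half", "gradient"]


@dataclass(frozen=True)
class NoiseParams:
    """Shot + read noise and a smooth additive background.

    ``poisson_scale`` is the photon count per intensity unit (higher =
    cleaner); ``gaussian_sd`` the read-noise standard deviation in intensity
    units; the background is a constant level modulated by a smooth
    low-frequency gradient of the given relative amplitude.
    """

    poisson_scale: float = 1.0
    gaussian_sd: float = 50.0
    background_level: float = 300.0
    background_gradient: float = 0.2


@dataclass(frozen=True)
class TubeSpec:
    """One rendered tube: exact centerline polyline and rendering params."""

    polyline: np.ndarray  # (n, 2) float (row, col); segments of equal length
    width_sigma_px: float  # Gaussian cross-section sigma
    amplitude: float
    length_px: float  # analytic polyline length
    mosaic_mode: MosaicMode = "uniform"


@dataclass(frozen=True)
class SpotSpec:
    center: tuple[float, float]
    sigma_px: float
    amplitude_a: float
    amplitude_b: float
    colocalized: bool


@dataclass
class SyntheticTruth:
    """Everything the generator decided, for pipeline-versus-truth tests."""

    seed: int
    pixel_size_um: float
    noise: NoiseParams
    tubes: list[TubeSpec] = field(default_factory=list)
    spots: list[SpotSpec] = field(default_factory=list)
    true_lengths_um: list[float] = field(default_factory=list)
    designed_overlap_fraction: float | None = None
    analytic_overlap: float | None = None  # intensity-weighted overlap of channel A
    mosaic_spec: list[str] = field(default_factory=list)
    centerline_mask: np.ndarray | None = None


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

_STEP_PX = 2.0  # polyline segment length; true length = n_segments * _STEP_PX


def _inside(p: np.ndarray, shape: tuple[int, int], margin: float) -> bool:
    return (
        margin <= p[0] <= shape[0] - 1 - margin
        and margin <= p[1] <= shape[1] - 1 - margin
    )


def _random_polyline(
    rng: np.random.Generator,
    shape: tuple[int, int],
    length_px: float,
    margin: float,
    max_turn: float,
) -> np.ndarray | None:
    """Smooth random polyline of (quantized) target length, or None.

    Heading performs a bounded random walk (curvature cap ``max_turn`` per
    ``_STEP_PX`` step); near the border the walk steers toward the field
    center.  Every segment has exactly ``_STEP_PX`` length, so the analytic
    length is n_segments * _STEP_PX.
    """
    n_steps = max(int(round(length_px / _STEP_PX)), 1)
    center = np.array([(shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0])
    pos = np.array(
        [
            rng.uniform(margin, shape[0] - 1 - margin),
            rng.uniform(margin, shape[1] - 1 - margin),
        ]
    )
    heading = rng.uniform(0.0, 2.0 * np.pi)
    pts = [pos.copy()]
    for _ in range(n_steps):
        heading += rng.uniform(-max_turn, max_turn)
        for _try in range(64):
            nxt = pos + _STEP_PX * np.array([np.sin(heading), np.cos(heading)])
            if _inside(nxt, shape, margin):
                break
            to_center = np.arctan2(*(center - pos))
            delta = (to_center - heading + np.pi) % (2.0 * np.pi) - np.pi
            heading += float(np.clip(delta, -max_turn, max_turn))
        else:
            return None
        pos = nxt
        pts.append(pos.copy())
    return np.asarray(pts)


def _densify(polyline: np.ndarray, step: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at fine steps; returns (points, arclength in [0,1])."""
    segs = np.diff(polyline, axis=0)
    seg_len = np.hypot(segs[:, 0], segs[:, 1])
    total = float(seg_len.sum())
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = np.arange(0.0, total + step, step)
    s = np.clip(s, 0.0, total)
    rows = np.interp(s, cum, polyline[:, 0])
    cols = np.interp(s, cum, polyline[:, 1])
    frac = s / total if total > 0 else np.zeros_like(s)
    return np.column_stack([rows, cols]), frac


def _render_tube(
    canvas_shape: tuple[int, int],
    polyline: np.ndarray,
    sigma: float,
    amp_profile,
) -> np.ndarray:
    """Gaussian-cross-section render of one tube.

    ``amp_profile(s)`` maps normalized arclength in [0, 1] to amplitude.
    Pixel intensity = amp_profile(s of nearest centerline point) *
    exp(-d^2 / 2 sigma^2), with d the distance to the centerline.
    """
    pts, frac = _densify(polyline)
    line = np.zeros(canvas_shape, dtype=bool)
    rr = np.clip(np.round(pts[:, 0]).astype(int), 0, canvas_shape[0] - 1)
    cc = np.clip(np.round(pts[:, 1]).astype(int), 0, canvas_shape[1] - 1)
    # keep the *first* sample landing on a pixel so arclength lookups are stable
    s_grid = np.full(canvas_shape, np.nan)
    for (r, c), s in zip(zip(rr, cc), frac):
        if not line[r, c]:
            line[r, c] = True
            s_grid[r, c] = s
    dist, (ir, ic) = distance_transform_edt(~line, return_indices=True)
    s_near = s_grid[ir, ic]
    amp = amp_profile(s_near)
    out = amp * np.exp(-(dist**2) / (2.0 * sigma**2))
    out[dist > 4.0 * sigma] = 0.0
    return out


def apply_noise(
    clean: np.ndarray,
    noise: NoiseParams,
    rng: np.random.Generator,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Background + shot noise + read noise + 16-bit quantization."""
    shape = clean.shape if shape is None else shape
    rows = np.linspace(0.0, 1.0, shape[0])[:, None]
    cols = np.linspace(0.0, 1.0, shape[1])[None, :]
    bg = noise.background_level * (
        1.0 + noise.background_gradient * 0.5 * (np.sin(2.1 * rows) + np.cos(1.7 * cols))
    )
    total = np.maximum(clean + bg, 0.0)
    lam = total * noise.poisson_scale
    shot = rng.poisson(lam).astype(np.float64) / noise.poisson_scale
    noisy = shot + rng.normal(0.0, noise.gaussian_sd, size=shape)
    return np.clip(np.round(noisy), 0, 65535).astype(np.uint16)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def make_tube_field(
    n_tubes: int = 12,
    length_um_range: tuple[float, float] = (1.0, 15.0),
    width_px_range: tuple[float, float] = (2.0, 5.0),
    pixel_size_um: float = 0.1,
    noise: NoiseParams = NoiseParams(),
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    amplitude_range: tuple[float, float] = (6000.0, 9000.0),
    max_turn: float = 0.2,
    min_separation_px: float = 12.0,
    channel_name: str = "mito",
    max_retries: int = 200,
) -> tuple[MultiChannelImage, SyntheticTruth]:
    """Single-channel field of non-overlapping curvilinear tubes.

    ``width_px_range`` is the visible tube width (full width at half
    maximum); the Gaussian cross-section sigma is width / 2.355.  Truth
    records each tube's exact centerline length (quantized to the polyline
    step of 2 px) in micrometres.
    """
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed, pixel_size_um=pixel_size_um, noise=noise)
    clean = np.zeros(shape, dtype=np.float64)
    line_mask = np.zeros(shape, dtype=bool)
    placed_pts: list[np.ndarray] = []
    tree: cKDTree | None = None

    for _tube in range(n_tubes):
        placed = False
        for _attempt in range(max_retries):
            length_um = rng.uniform(*length_um_range)
            width = rng.uniform(*width_px_range)
            sigma = width / 2.355
            amp = rng.uniform(*amplitude_range)
            margin = 6.0 + 4.0 * sigma
            poly = _random_polyline(rng, shape, length_um / pixel_size_um, margin, max_turn)
            if poly is None:
                continue
            pts, _ = _densify(poly, step=1.0)
            if tree is not None:
                d, _i = tree.query(pts, k=1)
                if np.min(d) < min_separation_px:
                    continue
            n_segments = poly.shape[0] - 1
            true_len_um = n_segments * _STEP_PX * pixel_size_um
            clean = np.maximum(clean, _render_tube(shape, poly, sigma, lambda s: amp))
            fine, _ = _densify(poly, step=0.5)
            fr = np.clip(np.round(fine[:, 0]).astype(int), 0, shape[0] - 1)
            fc = np.clip(np.round(fine[:, 1]).astype(int), 0, shape[1] - 1)
            line_mask[fr, fc] = True
            truth.tubes.append(
                TubeSpec(
                    polyline=poly,
                    width_sigma_px=sigma,
                    amplitude=amp,
                    length_px=n_segments * _STEP_PX,
                )
            )
            truth.true_lengths_um.append(true_len_um)
            placed_pts.append(pts)
            tree = cKDTree(np.vstack(placed_pts))
            placed = True
            break
        if not placed:
            raise DensityError(
                f"could not place tube {_tube + 1}/{n_tubes} after {max_retries} retries"
            )

    truth.centerline_mask = line_mask
    pixels = apply_noise(clean, noise, rng)
    image = MultiChannelImage(
        pixels=pixels[np.newaxis],
        channel_names=(channel_name,),
        pixel_size_um=pixel_size_um,
        source_id=f"tubes_seed{seed}",
    )
    return image, truth


def _place_spots(
    rng: np.random.Generator,
    n_points: int,
    shape: tuple[int, int],
    min_sep: float,
    margin: float,
    max_retries: int,
) -> np.ndarray:
    """Uniform random points with pairwise minimum separation."""
    pts: list[np.ndarray] = []
    tree = None
    for _ in range(n_points):
        for _attempt in range(max_retries):
            p = np.array(
                [
                    rng.uniform(margin, shape[0] - 1 - margin),
                    rng.uniform(margin, shape[1] - 1 - margin),
                ]
            )
            if tree is None or tree.query(p, k=1)[0] >= min_sep:
                pts.append(p)
                tree = cKDTree(np.vstack(pts))
                break
        else:
            raise DensityError(
                f"could not place {n_points} spots with separation {min_sep:.1f}px"
            )
    return np.vstack(pts)


def _stamp_spot(canvas: np.ndarray, center: np.ndarray, sigma: float, amp: float) -> None:
    r0 = int(np.floor(center[0] - 4 * sigma))
    r1 = int(np.ceil(center[0] + 4 * sigma)) + 1
    c0 = int(np.floor(center[1] - 4 * sigma))
    c1 = int(np.ceil(center[1] + 4 * sigma)) + 1
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, canvas.shape[0]), min(c1, canvas.shape[1])
    rr = np.arange(r0, r1)[:, None]
    cc = np.arange(c0, c1)[None, :]
    canvas[r0:r1, c0:c1] += amp * np.exp(
        -((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2.0 * sigma**2)
    )


def make_coloc_field(
    n_spots: int = 200,
    overlap_fraction: float = 0.5,
    spot_sigma: float = 2.0,
    amplitudes: tuple[float, float] = (3000.0, 9000.0),
    noise: NoiseParams = NoiseParams(),
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    channel_names: tuple[str, str] = ("red", "green"),
    max_retries: int = 2000,
) -> tuple[MultiChannelImage, SyntheticTruth]:
    """Two-channel punctate field with a designed colocalized fraction.

    ``round(f * n_spots)`` channel-A spots are duplicated at identical
    positions in channel B; the remaining spots of each channel are placed
    at disjoint positions.  All spot centers keep a minimum separation of
    4 * spot_sigma.  Truth records the designed ``f`` and the realized
    intensity-weighted overlap of channel A.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError(f"overlap_fraction must be in [0,1], got {overlap_fraction}")
    rng = np.random.default_rng(seed)
    n_coloc = int(round(overlap_fraction * n_spots))
    n_total = 2 * n_spots - n_coloc  # coloc + A-only + B-only positions
    min_sep = 4.0 * spot_sigma
    positions = _place_spots(rng, n_total, shape, min_sep, margin=4.0 * spot_sigma, max_retries=max_retries)

    chan_a = np.zeros(shape, dtype=np.float64)
    chan_b = np.zeros(shape, dtype=np.float64)
    truth = SyntheticTruth(
        seed=seed,
        pixel_size_um=0.1,
        noise=noise,
        designed_overlap_fraction=overlap_fraction,
    )
    amp_coloc_a = 0.0
    amp_total_a = 0.0
    for i in range(n_total):
        is_coloc = i < n_coloc
        is_a = i < n_spots  # coloc spots first, then A-only, then B-only
        amp_a = rng.uniform(*amplitudes) if is_a else 0.0
        # colocalized spots are exact duplicates: same position, same amplitude
        amp_b = amp_a if is_coloc else (rng.uniform(*amplitudes) if not is_a else 0.0)
        if amp_a > 0:
            _stamp_spot(chan_a, positions[i], spot_sigma, amp_a)
            amp_total_a += amp_a
            if is_coloc:
                amp_coloc_a += amp_a
        if amp_b > 0:
            _stamp_spot(chan_b, positions[i], spot_sigma, amp_b)
        truth.spots.append(
            SpotSpec(
                center=(float(positions[i][0]), float(positions[i][1])),
                sigma_px=spot_sigma,
                amplitude_a=amp_a,
                amplitude_b=amp_b,
                colocalized=is_coloc,
            )
        )
    truth.analytic_overlap = amp_coloc_a / amp_total_a if amp_total_a > 0 else 0.0

    pix_a = apply_noise(chan_a, noise, rng)
    pix_b = apply_noise(chan_b, noise, rng)
    image = MultiChannelImage(
        pixels=np.stack([pix_a, pix_b]),
        channel_names=channel_names,
        pixel_size_um=0.1,
        source_id=f"coloc_f{overlap_fraction:.2f}_seed{seed}",
    )
    return image, truth


def make_jc1_field(
    n_objects: int = 8,
    mosaic_mode: MosaicMode = "uniform",
    noise: NoiseParams = NoiseParams(),
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    length_um_range: tuple[float, float] = (2.0, 8.0),
    width_px_range: tuple[float, float] = (3.0, 5.0),
    pixel_size_um: float = 0.1,
    amplitude_range: tuple[float, float] = (4000.0, 12000.0),
    max_turn: float = 0.1,
    min_separation_px: float = 16.0,
    max_retries: int = 200,
) -> tuple[MultiChannelImage, SyntheticTruth]:
    """Dual-channel (red aggregate / green monomer) tube field.

    The red/green amplitude varies along each tube's normalized arclength s
    according to ``mosaic_mode``: ``uniform`` — both channels constant
    (spatially uniform membrane potential); ``half-half`` — red dominates
    for s < 0.5, green for s >= 0.5; ``gradient`` — red falls and green
    rises linearly in s.  Truth records the mode per object.
    """
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed, pixel_size_um=pixel_size_um, noise=noise)
    red = np.zeros(shape, dtype=np.float64)
    green = np.zeros(shape, dtype=np.float64)
    placed_pts: list[np.ndarray] = []
    tree: cKDTree | None = None
    # dominated channel keeps a faint floor so masks stay contiguous
    floor = 0.12

    for k in range(n_objects):
        placed = False
        for _attempt in range(max_retries):
            length_um = rng.uniform(*length_um_range)
            width = rng.uniform(*width_px_range)
            sigma = width / 2.355
            amp = rng.uniform(*amplitude_range)
            margin = 6.0 + 4.0 * sigma
            poly = _random_polyline(rng, shape, length_um / pixel_size_um, margin, max_turn)
            if poly is None:
                continue
            pts, _ = _densify(poly, step=1.0)
            if tree is not None and np.min(tree.query(pts, k=1)[0]) < min_separation_px:
                continue
            if mosaic_mode == "uniform":
                red_prof = lambda s, a=amp: np.full_like(np.asarray(s, float), a)
                green_prof = lambda s, a=amp: np.full_like(np.asarray(s, float), a)
            elif mosaic_mode == "half-half":
                red_prof = lambda s, a=amp: a * np.where(np.asarray(s) < 0.5, 1.0, floor)
                green_prof = lambda s, a=amp: a * np.where(np.asarray(s) < 0.5, floor, 1.0)
            elif mosaic_mode == "gradient":
                red_prof = lambda s, a=amp: a * (floor + (1.0 - floor) * (1.0 - np.asarray(s, float)))
                green_prof = lambda s, a=amp: a * (floor + (1.0 - floor) * np.asarray(s, float))
            else:
                raise ValueError(f"unknown mosaic_mode {mosaic_mode!r}")
            red = np.maximum(red, _render_tube(shape, poly, sigma, red_prof))
            green = np.maximum(green, _render_tube(shape, poly, sigma, green_prof))
            n_segments = poly.shape[0] - 1
            truth.tubes.append(
                TubeSpec(
                    polyline=poly,
                    width_sigma_px=sigma,
                    amplitude=amp,
                    length_px=n_segments * _STEP_PX,
                    mosaic_mode=mosaic_mode,
                )
            )
            truth.true_lengths_um.append(n_segments * _STEP_PX * pixel_size_um)
            truth.mosaic_spec.append(mosaic_mode)
            placed_pts.append(pts)
            tree = cKDTree(np.vstack(placed_pts))
            placed = True
            break
        if not placed:
            raise DensityError(
                f"could not place JC-1 object {k + 1}/{n_objects} after {max_retries} retries"
            )

    pix_red = apply_noise(red, noise, rng)
    pix_green = apply_noise(green, noise, rng)
    image = MultiChannelImage(
        pixels=np.stack([pix_red, pix_green]),
        channel_names=("red", "green"),
        pixel_size_um=pixel_size_um,
        source_id=f"jc1_{mosaic_mode}_seed{seed}",
    )
    return image, truth
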