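"""Synthetic 2-DE gel image simulation.

Generates greyscale gel-like images — dark, roughly Gaussian protein spots on
a light noisy background with optional shading, crack-like line artifacts and
patches of elevated noise — together with labelled regions of interest (ROIs)
for the downstream spot-versus-noise classification task.

Conventions: pixels are 8-bit grey levels (0 = black), coordinates are 0-based
row-major, bounding boxes are half-open ``(row0, col0, row1, col1)``. A single
integer seed drives a hierarchical per-image random substream, so any image of
a dataset can be regenerated independently of the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.draw import line as _draw_line

__all__ = [
    "GelImage",
    "SpotModel",
    "ROISample",
    "GelSimConfig",
    "render_spot",
    "render_crack",
    "sample_noise_rois",
    "generate_image",
    "generate_dataset",
    "allocate_counts",
]


@dataclass
class SpotModel:
    """An anisotropic Gaussian darkening profile.

    ``amplitude`` is the grey-level depth at the spot centre (how much darker
    the minimum is than the local background); ``vertical_tail`` skews the
    profile downwards to emulate streaking.
    """

    center: tuple[int, int]
    amplitude: float
    sigma_row: float
    sigma_col: float
    vertical_tail: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("spot amplitude must be >= 0")
        if self.sigma_row <= 0 or self.sigma_col <= 0:
            raise ValueError("spot sigmas must be > 0")
        if self.vertical_tail < 0:
            raise ValueError("vertical_tail must be >= 0")


@dataclass
class GelImage:
    """An 8-bit greyscale gel image plus the artifact metadata of its render."""

    pixels: np.ndarray
    seed: int = 0
    spot_support: np.ndarray | None = None
    crack_mask: np.ndarray | None = None
    noise_patches: list[tuple[int, int, int, int]] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def copy(self) -> "GelImage":
        return replace(
            self,
            pixels=self.pixels.copy(),
            spot_support=None if self.spot_support is None else self.spot_support.copy(),
            crack_mask=None if self.crack_mask is None else self.crack_mask.copy(),
            noise_patches=list(self.noise_patches),
        )


@dataclass
class ROISample:
    """A labelled masked patch of a gel image.

    ``pixels`` and ``mask`` are crops over the bounding box; ``label`` is
    ``"spot"`` or ``"noise"``; ``provenance`` records the noise subtype
    (background / noisy / crack) or ``"spot"``.
    """

    image_id: int
    roi_id: int
    bbox: tuple[int, int, int, int]
    pixels: np.ndarray
    mask: np.ndarray
    label: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.mask.sum() == 0:
            raise ValueError("ROI mask must be non-empty")
        if self.label not in ("spot", "noise"):
            raise ValueError(f"unknown ROI label {self.label!r}")


@dataclass
class GelSimConfig:
    """Study-design parameters of the simulation.

    Defaults reproduce the reference design: ten 1024 x 1024 8-bit images,
    50 spot + 50 noise ROIs each (1000 ROIs, balanced classes).
    """

    n_images: int = 10
    height: int = 1024
    width: int = 1024
    spots_per_image: int = 50
    noise_per_image: int = 50
    background: float = 220.0
    noise_sd: float = 8.0
    shading_amplitude: float = 6.0
    amplitude_range: tuple[float, float] = (15.0, 180.0)
    sigma_range: tuple[float, float] = (3.0, 8.0)
    tail_range: tuple[float, float] = (0.0, 0.8)
    n_cracks: int = 3
    crack_depth_range: tuple[float, float] = (60.0, 120.0)
    crack_width_range: tuple[int, int] = (1, 3)
    n_noise_patches: int = 6
    noise_patch_sd: float = 20.0
    noise_patch_size: tuple[int, int] = (48, 96)
    noise_roi_size: tuple[int, int] = (16, 40)
    noise_mix: dict[str, float] = field(
        default_factory=lambda: {"background": 0.4, "noisy": 0.3, "crack": 0.3}
    )
    spot_mask_margin: float = 0.2
    min_roi_side: int = 16
    max_placement_tries: int = 500


# ----------------------------------------------------------------- rendering


def _spot_profile(spot: SpotModel, shape: tuple[int, int]) -> tuple[np.ndarray, tuple]:
    """Truncated anisotropic Gaussian darkening, returned as a window crop."""
    r0, c0 = spot.center
    reach_up = 4.0 * spot.sigma_row
    reach_down = 4.0 * spot.sigma_row * (1.0 + spot.vertical_tail)
    reach_c = 4.0 * spot.sigma_col
    lo_r = max(0, int(np.floor(r0 - reach_up)))
    hi_r = min(shape[0], int(np.ceil(r0 + reach_down)) + 1)
    lo_c = max(0, int(np.floor(c0 - reach_c)))
    hi_c = min(shape[1], int(np.ceil(c0 + reach_c)) + 1)
    rr = np.arange(lo_r, hi_r)[:, None] - r0
    cc = np.arange(lo_c, hi_c)[None, :] - c0
    sig_r = np.where(rr > 0, spot.sigma_row * (1.0 + spot.vertical_tail), spot.sigma_row)
    prof = spot.amplitude * np.exp(
        -0.5 * (rr / sig_r) ** 2 - 0.5 * (cc / spot.sigma_col) ** 2
    )
    return prof, (lo_r, hi_r, lo_c, hi_c)


def render_spot(image: GelImage, spot: SpotModel) -> GelImage:
    """Darken ``image`` by the spot profile; returns a new :class:`GelImage`.

    The centre pixel drops by exactly ``amplitude`` (then clips to [0, 255]).
    """
    h, w = image.shape
    r0, c0 = spot.center
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValueError(f"spot center {spot.center} outside image of shape {image.shape}")
    out = image.copy()
    if spot.amplitude == 0:
        return out
    prof, (lo_r, hi_r, lo_c, hi_c) = _spot_profile(spot, image.shape)
    window = out.pixels[lo_r:hi_r, lo_c:hi_c].astype(np.float64)
    window -= prof
    out.pixels[lo_r:hi_r, lo_c:hi_c] = np.clip(np.rint(window), 0, 255).astype(np.uint8)
    if out.spot_support is None:
        out.spot_support = np.zeros(image.shape, dtype=bool)
    # support = pixels darkened by at least one grey level
    out.spot_support[lo_r:hi_r, lo_c:hi_c] |= prof >= 1.0
    return out


def render_crack(image: GelImage, rng: np.random.Generator, config: GelSimConfig) -> GelImage:
    """Add one dark line segment (1-3 px wide, random orientation) in place."""
    h, w = image.shape
    r0, c0 = rng.integers(0, h), rng.integers(0, w)
    length = rng.integers(min(h, w) // 4, min(h, w) // 2)
    angle = rng.uniform(0, np.pi)
    r1 = int(np.clip(r0 + length * np.sin(angle), 0, h - 1))
    c1 = int(np.clip(c0 + length * np.cos(angle), 0, w - 1))
    rr, cc = _draw_line(int(r0), int(c0), r1, c1)
    mask = np.zeros(image.shape, dtype=bool)
    mask[rr, cc] = True
    width = int(rng.integers(config.crack_width_range[0], config.crack_width_range[1] + 1))
    if width > 1:
        mask = ndimage.binary_dilation(mask, iterations=width - 1)
    depth = rng.uniform(*config.crack_depth_range)
    px = image.pixels.astype(np.float64)
    px[mask] -= depth
    image.pixels = np.clip(np.rint(px), 0, 255).astype(np.uint8)
    if image.crack_mask is None:
        image.crack_mask = np.zeros(image.shape, dtype=bool)
    image.crack_mask |= mask
    return image


def _render_background(shape: tuple[int, int], rng: np.random.Generator,
                       config: GelSimConfig) -> np.ndarray:
    h, w = shape
    canvas = np.full(shape, config.background, dtype=np.float64)
    if config.shading_amplitude > 0:
        fr, fc = rng.uniform(0.5, 1.5, size=2)
        phase_r, phase_c = rng.uniform(0, 2 * np.pi, size=2)
        rows = np.cos(2 * np.pi * fr * np.arange(h) / h + phase_r)
        cols = np.cos(2 * np.pi * fc * np.arange(w) / w + phase_c)
        canvas += config.shading_amplitude * rows[:, None] * cols[None, :]
    canvas += rng.normal(0.0, config.noise_sd, size=shape)
    return canvas


# --------------------------------------------------------------- ROI sampling


def allocate_counts(proportions: dict[str, float], n: int) -> dict[str, int]:
    """Deterministic largest-remainder allocation of ``n`` among categories."""
    keys = list(proportions)
    total = sum(proportions[k] for k in keys)
    quotas = np.array([proportions[k] / total * n for k in keys])
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    for idx in order[:remainder]:
        counts[idx] += 1
    return dict(zip(keys, counts.astype(int)))


def _free_rect(occupied: np.ndarray, r0: int, c0: int, r1: int, c1: int) -> bool:
    return not occupied[r0:r1, c0:c1].any()


def sample_noise_rois(
    image: GelImage,
    n: int,
    config: GelSimConfig,
    rng: np.random.Generator,
    image_id: int = 0,
    roi_id_start: int = 0,
) -> list[ROISample]:
    """Sample ``n`` rectangular noise ROIs avoiding every spot support pixel.

    The mixture over noise subtypes (plain background / elevated-noise patch /
    crack artifact) follows ``config.noise_mix`` via largest-remainder
    allocation. Raises ``RuntimeError`` if the image is too crowded to place a
    ROI within the configured retry budget.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    h, w = image.shape
    occupied = np.zeros(image.shape, dtype=bool)
    if image.spot_support is not None:
        occupied |= image.spot_support
    taken = np.zeros(image.shape, dtype=bool)

    mix = dict(config.noise_mix)
    if image.crack_mask is None or not image.crack_mask.any():
        mix.pop("crack", None)
    if not image.noise_patches:
        mix.pop("noisy", None)
    if not mix:
        mix = {"background": 1.0}
    counts = allocate_counts(mix, n)

    crack_pts = None
    if "crack" in counts and counts["crack"] > 0:
        crack_pts = np.argwhere(image.crack_mask)

    rois: list[ROISample] = []
    rid = roi_id_start
    # most constrained subtypes first so earlier placements cannot exhaust them
    order = [k for k in ("noisy", "crack", "background") if k in counts]
    for kind in order:
        for _ in range(counts[kind]):
            placed = False
            for _try in range(config.max_placement_tries):
                if _try >= config.max_placement_tries // 2:
                    # fall back to the minimum size once space gets tight
                    side_r = side_c = config.noise_roi_size[0]
                else:
                    side_r = int(rng.integers(config.noise_roi_size[0], config.noise_roi_size[1] + 1))
                    side_c = int(rng.integers(config.noise_roi_size[0], config.noise_roi_size[1] + 1))
                if kind == "crack":
                    pr, pc = crack_pts[rng.integers(len(crack_pts))]
                    r0 = int(np.clip(pr - side_r // 2, 0, h - side_r))
                    c0 = int(np.clip(pc - side_c // 2, 0, w - side_c))
                elif kind == "noisy":
                    pr0, pc0, pr1, pc1 = image.noise_patches[
                        int(rng.integers(len(image.noise_patches)))
                    ]
                    r0 = int(rng.integers(pr0, max(pr0 + 1, pr1 - side_r)))
                    c0 = int(rng.integers(pc0, max(pc0 + 1, pc1 - side_c)))
                    r0 = min(r0, h - side_r)
                    c0 = min(c0, w - side_c)
                else:
                    r0 = int(rng.integers(0, h - side_r + 1))
                    c0 = int(rng.integers(0, w - side_c + 1))
                r1, c1 = r0 + side_r, c0 + side_c
                # never overlap spot supports; stay disjoint from other ROIs
                # while space allows, tolerating partial overlap (<= half the
                # area) late in the retry budget when cracks/patches are short
                late = _try >= 3 * config.max_placement_tries // 4
                overlap = taken[r0:r1, c0:c1].mean()
                disjoint_ok = overlap == 0 or (
                    late and kind in ("crack", "noisy") and overlap <= 0.5
                )
                ok = _free_rect(occupied, r0, c0, r1, c1) and disjoint_ok
                if ok and kind == "background" and image.crack_mask is not None:
                    ok = not image.crack_mask[r0:r1, c0:c1].any()
                if ok:
                    taken[r0:r1, c0:c1] = True
                    mask = np.ones((side_r, side_c), dtype=bool)
                    rois.append(
                        ROISample(
                            image_id=image_id,
                            roi_id=rid,
                            bbox=(r0, c0, r1, c1),
                            pixels=image.pixels[r0:r1, c0:c1].copy(),
                            mask=mask,
                            label="noise",
                            provenance=kind,
                        )
                    )
                    rid += 1
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    f"could not place noise ROI ({kind}) after "
                    f"{config.max_placement_tries} tries; image too crowded"
                )
    return rois


def _spot_roi(image: GelImage, spot: SpotModel, config: GelSimConfig,
              image_id: int, roi_id: int) -> ROISample:
    """ROI around one spot: its support dilated by a relative margin."""
    prof, (lo_r, hi_r, lo_c, hi_c) = _spot_profile(spot, image.shape)
    support = prof >= 1.0
    radius = 0.5 * (support.shape[0] + support.shape[1]) / 2.0
    margin = max(1, int(np.ceil(config.spot_mask_margin * radius / 2.0)))
    mask_full = np.zeros(image.shape, dtype=bool)
    mask_full[lo_r:hi_r, lo_c:hi_c] = support
    if support.any():
        mask_full = ndimage.binary_dilation(mask_full, iterations=margin)
    else:
        # invisible spot (zero or sub-threshold amplitude): fall back to a
        # minimum-size box around the nominal centre
        half = config.min_roi_side // 2
        rr, cc = spot.center
        mask_full[max(0, rr - half):rr + half, max(0, cc - half):cc + half] = True
    rows = np.any(mask_full, axis=1).nonzero()[0]
    cols = np.any(mask_full, axis=0).nonzero()[0]
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    # pad to the minimum side so every feature family is computable
    h, w = image.shape
    while r1 - r0 < config.min_roi_side:
        r0 = max(0, r0 - 1)
        r1 = min(h, r1 + 1)
    while c1 - c0 < config.min_roi_side:
        c0 = max(0, c0 - 1)
        c1 = min(w, c1 + 1)
    mask = mask_full[r0:r1, c0:c1] | False
    # the rectangle padding pixels belong to the ROI's area of influence
    mask = ndimage.binary_dilation(mask, iterations=1)
    return ROISample(
        image_id=image_id,
        roi_id=roi_id,
        bbox=(r0, c0, r1, c1),
        pixels=image.pixels[r0:r1, c0:c1].copy(),
        mask=mask,
        label="spot",
        provenance="spot",
    )


def generate_image(
    config: GelSimConfig, rng: np.random.Generator, image_id: int = 0, seed: int = 0
) -> tuple[GelImage, list[ROISample]]:
    """Render one gel image and its labelled ROIs."""
    h, w = config.height, config.width
    canvas = _render_background((h, w), rng, config)
    image = GelImage(
        pixels=np.clip(np.rint(canvas), 0, 255).astype(np.uint8),
        seed=seed,
        spot_support=np.zeros((h, w), dtype=bool),
        crack_mask=np.zeros((h, w), dtype=bool),
    )

    # elevated-noise patches (non-protein smudges)
    for _ in range(config.n_noise_patches):
        ps = int(rng.integers(config.noise_patch_size[0], config.noise_patch_size[1] + 1))
        r0 = int(rng.integers(0, max(1, h - ps)))
        c0 = int(rng.integers(0, max(1, w - ps)))
        px = image.pixels[r0:r0 + ps, c0:c0 + ps].astype(np.float64)
        px += rng.normal(0.0, config.noise_patch_sd, size=px.shape)
        image.pixels[r0:r0 + ps, c0:c0 + ps] = np.clip(np.rint(px), 0, 255).astype(np.uint8)
        image.noise_patches.append((r0, c0, r0 + ps, c0 + ps))

    for _ in range(config.n_cracks):
        render_crack(image, rng, config)

    # place spots with non-overlapping supports, away from borders
    spots: list[SpotModel] = []
    margin = config.min_roi_side
    # keep spots a noise-ROI-sized margin away from cracks and elevated-noise
    # patches so those regions stay available for their designed noise ROIs
    roi_margin = config.noise_roi_size[1] // 2 + 1
    if image.crack_mask.any():
        exclusion = ndimage.distance_transform_edt(~image.crack_mask) <= roi_margin
    else:
        exclusion = np.zeros(image.shape, dtype=bool)
    for pr0, pc0, pr1, pc1 in image.noise_patches:
        exclusion[max(0, pr0 - roi_margin):pr1 + roi_margin,
                  max(0, pc0 - roi_margin):pc1 + roi_margin] = True
    for _ in range(config.spots_per_image):
        for _try in range(config.max_placement_tries):
            sr = rng.uniform(*config.sigma_range)
            sc = rng.uniform(*config.sigma_range)
            amp = rng.uniform(*config.amplitude_range)
            tail = rng.uniform(*config.tail_range)
            reach = int(np.ceil(4 * max(sr * (1 + tail), sc))) + margin
            r0 = int(rng.integers(reach, h - reach))
            c0 = int(rng.integers(reach, w - reach))
            spot = SpotModel((r0, c0), amp, sr, sc, tail)
            prof, (lo_r, hi_r, lo_c, hi_c) = _spot_profile(spot, (h, w))
            support = prof >= 1.0
            zone = np.zeros((h, w), dtype=bool)
            zone[lo_r:hi_r, lo_c:hi_c] = ndimage.binary_dilation(support, iterations=3)
            if not (zone & (image.spot_support | exclusion)).any():
                image = render_spot(image, spot)
                spots.append(spot)
                break
        else:
            raise RuntimeError(
                f"could not place {config.spots_per_image} non-overlapping spots"
            )

    rois = [
        _spot_roi(image, spot, config, image_id, i) for i, spot in enumerate(spots)
    ]
    rois += sample_noise_rois(
        image, config.noise_per_image, config, rng,
        image_id=image_id, roi_id_start=len(spots),
    )
    return image, rois


def generate_dataset(
    config: GelSimConfig | None = None, seed: int = 0
) -> tuple[list[GelImage], list[ROISample]]:
    """Generate the full study design: images x (spot + noise) labelled ROIs.

    With the default configuration this yields 10 images and 1000 ROIs, 500
    per class. Fully determined by ``(config, seed)``.
    """
    config = config or GelSimConfig()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(config.n_images)
    images: list[GelImage] = []
    rois: list[ROISample] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        image, image_rois = generate_image(config, rng, image_id=i, seed=seed)
        images.append(image)
        rois.extend(image_rois)
    return images, rois
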