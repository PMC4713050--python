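"""Texture feature extraction over masked ROIs.

Six feature families, following the Mazda naming conventions:

* Histogram (first-order statistics of in-mask grey levels),
* Absolute gradient (moments of the gradient magnitude),
* Grey-level co-occurrence matrix, GLCM (Haralick second-order statistics
  at offsets ``S(dx,dy)`` for distances 1..5 in four directions),
* Run-length matrix, RLM (Galloway statistics in four directions),
* Autoregressive model (four-neighbour prediction of zero-mean intensity),
* Wavelet (orthonormal Haar subband energies at dyadic scales).

Pairwise and run statistics use only pixel pairs/segments fully inside the
mask; the AR and wavelet families operate on the bounding-box crop with mask
holes filled by the in-mask mean. Entropies use the natural logarithm with
``0*log 0 := 0``; skewness/kurtosis are population central-moment ratios
(kurtosis as excess) with degenerate zero-variance inputs mapped to 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = [
    "QuantizedROI",
    "GLCMOffset",
    "TextureConfig",
    "FeatureInventory",
    "default_inventory",
    "quantize",
    "histogram_features",
    "gradient_features",
    "glcm",
    "glcm_features",
    "rlm_features",
    "ar_features",
    "wavelet_features",
    "extract_all",
    "GLCM_FEATURES",
    "RLM_FEATURES",
    "GLCM_OFFSETS",
    "RLM_DIRECTIONS",
]

GLCM_FEATURES = (
    "AngScMom", "Contrast", "Correlat", "SumOfSqs", "InvDfMom",
    "SumAverg", "SumVarnc", "SumEntrp", "Entropy", "DifVarnc", "DifEntrp",
)
RLM_FEATURES = ("ShrtREmp", "LngREmph", "GLevNonU", "RLNonUni", "Fraction")
HIST_FEATURES = (
    "Mean", "Variance", "Skewness", "Kurtosis",
    "Perc.01%", "Perc.10%", "Perc.50%", "Perc.90%", "Perc.99%",
)
GRAD_FEATURES = ("GrMean", "GrVariance", "GrSkewness", "GrKurtosis", "GrNonZeros")
AR_FEATURES = ("Teta1", "Teta2", "Teta3", "Teta4", "Sigma")

#: (dr, dc) steps for the four canonical directions, keyed by Mazda suffix
RLM_DIRECTIONS = {"H": (0, 1), "V": (1, 0), "45": (-1, 1), "135": (1, 1)}


@dataclass(frozen=True)
class GLCMOffset:
    """Co-occurrence offset: distance ``d`` along direction ``theta`` degrees."""

    d: int
    theta: int

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("GLCM distance must be >= 1")
        if self.theta not in (0, 45, 90, 135):
            raise ValueError("theta must be one of 0, 45, 90, 135")

    @property
    def step(self) -> tuple[int, int]:
        """(drow, dcol) displacement of the second pixel of each pair."""
        return {
            0: (0, self.d),
            45: (-self.d, self.d),
            90: (-self.d, 0),
            135: (-self.d, -self.d),
        }[self.theta]

    @property
    def name(self) -> str:
        """Mazda-style ``S(dx,dy)`` tag (e.g. S(4,0), S(0,5), S(5,-5))."""
        return _glcm_offset_name(self)


#: default offsets: d in 1..5 x four directions, Figure-style S(d,0) ... S(d,-d)
GLCM_OFFSETS = tuple(
    GLCMOffset(d, theta) for d in range(1, 6) for theta in (0, 90, 45, 135)
)


def _glcm_offset_name(off: GLCMOffset) -> str:
    dr, dc = off.step
    # Mazda prints S(dx,dy) with dy >= 0 except the 135-degree family S(d,-d)
    mapping = {0: f"S({off.d},0)", 90: f"S(0,{off.d})",
               45: f"S({off.d},{off.d})", 135: f"S({off.d},-{off.d})"}
    return mapping[off.theta]


@dataclass
class QuantizedROI:
    """ROI grey levels mapped monotonically onto integers ``1..Ng``."""

    levels: np.ndarray
    mask: np.ndarray
    ng: int
    source_depth: int = 8


@dataclass
class TextureConfig:
    ng: int = 64
    normalization: str = "full-range"
    glcm_distances: tuple[int, ...] = (1, 2, 3, 4, 5)
    wavelet_scales: int = 4


def _as_arrays(roi) -> tuple[np.ndarray, np.ndarray]:
    """Accept a gelsim ROISample or a bare (pixels, mask-optional) array."""
    if hasattr(roi, "pixels"):
        pixels = np.asarray(roi.pixels)
        mask = np.asarray(roi.mask, dtype=bool)
    else:
        pixels = np.asarray(roi)
        mask = np.ones(pixels.shape, dtype=bool)
    if pixels.shape != mask.shape:
        raise ValueError("pixels and mask shapes differ")
    if not mask.any():
        raise ValueError("ROI mask is empty")
    return pixels.astype(np.float64), mask


# ------------------------------------------------------------- quantization


def quantize(roi, ng: int = 64, normalization: str = "full-range") -> QuantizedROI:
    """Map in-mask grey levels onto ``1..ng``.

    ``level = floor((g - lo) * ng / (hi - lo + 1)) + 1`` clipped to [1, ng],
    with the (lo, hi) window given by the normalization mode: ``full-range``
    uses (0, 255); ``three-sigma`` uses mean +/- 3 sd; ``percentile-1-99``
    the 1st and 99th in-mask percentiles. Degenerate windows fall back to
    full-range with a warning.
    """
    if ng < 2:
        raise ValueError("ng must be >= 2")
    pixels, mask = _as_arrays(roi)
    vals = pixels[mask]
    if normalization == "full-range":
        lo, hi = 0.0, 255.0
    elif normalization == "three-sigma":
        mu, sd = vals.mean(), vals.std()
        lo, hi = mu - 3 * sd, mu + 3 * sd
    elif normalization == "percentile-1-99":
        lo, hi = np.percentile(vals, [1, 99])
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    if hi <= lo:
        warnings.warn(
            "degenerate grey-level window; falling back to full-range",
            stacklevel=2,
        )
        lo, hi = 0.0, 255.0
    levels = np.floor((pixels - lo) * ng / (hi - lo + 1.0)).astype(np.int64) + 1
    levels = np.clip(levels, 1, ng)
    levels[~mask] = 0
    return QuantizedROI(levels=levels, mask=mask, ng=ng)


# ------------------------------------------------------------ moment helpers


def _moments(vals: np.ndarray) -> tuple[float, float, float, float]:
    """Population mean, variance, skewness and excess kurtosis (0 if sd=0)."""
    mu = float(vals.mean())
    var = float(vals.var())
    if var <= 0:
        return mu, 0.0, 0.0, 0.0
    z = (vals - mu) / np.sqrt(var)
    return mu, var, float((z ** 3).mean()), float((z ** 4).mean() - 3.0)


def _nearest_rank(vals_sorted: np.ndarray, q: float) -> float:
    n = len(vals_sorted)
    idx = max(1, int(np.ceil(q / 100.0 * n))) - 1
    return float(vals_sorted[idx])


# ---------------------------------------------------------------- histogram


def histogram_features(roi) -> dict[str, float]:
    pixels, mask = _as_arrays(roi)
    vals = pixels[mask]
    mu, var, skew, kurt = _moments(vals)
    s = np.sort(vals)
    return {
        "Mean": mu,
        "Variance": var,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Perc.01%": _nearest_rank(s, 1),
        "Perc.10%": _nearest_rank(s, 10),
        "Perc.50%": _nearest_rank(s, 50),
        "Perc.90%": _nearest_rank(s, 90),
        "Perc.99%": _nearest_rank(s, 99),
    }


# ----------------------------------------------------------------- gradient


def gradient_features(roi) -> dict[str, float]:
    """Moments of the absolute gradient magnitude over interior pixels.

    Central differences without scaling: dx = I(r,c+1) - I(r,c-1), dy
    likewise; interior = pixels whose four neighbours are in-mask.
    """
    pixels, mask = _as_arrays(roi)
    interior = (
        mask
        & np.roll(mask, 1, axis=0) & np.roll(mask, -1, axis=0)
        & np.roll(mask, 1, axis=1) & np.roll(mask, -1, axis=1)
    )
    # roll wraps around; edges of the crop cannot be interior
    interior[0, :] = interior[-1, :] = False
    interior[:, 0] = interior[:, -1] = False
    if not interior.any():
        raise ValueError("ROI too small: no interior pixels for the gradient")
    dx = np.roll(pixels, -1, axis=1) - np.roll(pixels, 1, axis=1)
    dy = np.roll(pixels, -1, axis=0) - np.roll(pixels, 1, axis=0)
    mag = np.sqrt(dx ** 2 + dy ** 2)[interior]
    mu, var, skew, kurt = _moments(mag)
    return {
        "GrMean": mu,
        "GrVariance": var,
        "GrSkewness": skew,
        "GrKurtosis": kurt,
        "GrNonZeros": float((mag > 0).mean()),
    }


# --------------------------------------------------------------------- GLCM


def glcm(q: QuantizedROI, off: GLCMOffset) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix ``p(i, j)``, i, j in 1..Ng.

    Counts every ordered pair with both endpoints in-mask, accumulated
    symmetrically, then normalized to sum 1. The returned matrix is 0-indexed
    (entry [0, 0] is level pair (1, 1)).
    """
    dr, dc = off.step
    lev, mask, ng = q.levels, q.mask, q.ng
    h, w = lev.shape
    r0a, r1a = max(0, -dr), min(h, h - dr)
    c0a, c1a = max(0, -dc), min(w, w - dc)
    if r0a >= r1a or c0a >= c1a:
        raise ValueError(f"no valid pixel pairs for offset {off}")
    a = lev[r0a:r1a, c0a:c1a]
    b = lev[r0a + dr:r1a + dr, c0a + dc:c1a + dc]
    valid = mask[r0a:r1a, c0a:c1a] & mask[r0a + dr:r1a + dr, c0a + dc:c1a + dc]
    if not valid.any():
        raise ValueError(f"no in-mask pixel pairs for offset {off}")
    i = a[valid] - 1
    j = b[valid] - 1
    counts = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng).astype(np.float64)
    counts += counts.T
    return counts / counts.sum()


def glcm_features(p: np.ndarray) -> dict[str, float]:
    """The 11 Haralick statistics of one normalized co-occurrence matrix."""
    ng = p.shape[0]
    idx = np.arange(1, ng + 1, dtype=np.float64)
    i = idx[:, None]
    j = idx[None, :]
    px = p.sum(axis=1)
    mu_x = float((idx * px).sum())
    var_x = float(((idx - mu_x) ** 2 * px).sum())
    # symmetric matrix: marginals coincide
    diff = i - j

    def _ent(v: np.ndarray) -> float:
        v = v[v > 0]
        return float(-(v * np.log(v)).sum())

    # p_{x+y}(k), k = 2..2Ng and p_{x-y}(k), k = 0..Ng-1
    ksum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (np.add.outer(np.arange(ng), np.arange(ng))).ravel(), p.ravel())
    kdiff = np.arange(0, ng, dtype=np.float64)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(np.subtract.outer(np.arange(ng), np.arange(ng))).ravel(), p.ravel())

    sum_avg = float((ksum * p_sum).sum())
    sum_var = float(((ksum - sum_avg) ** 2 * p_sum).sum())
    diff_avg = float((kdiff * p_diff).sum())
    if var_x > 0:
        correlat = float(((i * j * p).sum() - mu_x * mu_x) / var_x)
    else:
        correlat = 0.0
    return {
        "AngScMom": float((p ** 2).sum()),
        "Contrast": float((diff ** 2 * p).sum()),
        "Correlat": correlat,
        "SumOfSqs": float(((i - mu_x) ** 2 * p).sum()),
        "InvDfMom": float((p / (1.0 + diff ** 2)).sum()),
        "SumAverg": sum_avg,
        "SumVarnc": sum_var,
        "SumEntrp": _ent(p_sum),
        "Entropy": _ent(p.ravel()),
        "DifVarnc": float(((kdiff - diff_avg) ** 2 * p_diff).sum()),
        "DifEntrp": _ent(p_diff),
    }


# ---------------------------------------------------------------------- RLM


def _mask_lines(shape: tuple[int, int], step: tuple[int, int]):
    """Index arrays of every maximal pixel line in the given direction."""
    h, w = shape
    dr, dc = step
    if (dr, dc) == (0, 1):
        for r in range(h):
            yield np.full(w, r), np.arange(w)
    elif (dr, dc) == (1, 0):
        for c in range(w):
            yield np.arange(h), np.full(h, c)
    else:
        # diagonals: 45 deg = (-1, 1) -> anti-diagonals; 135 deg = (1, 1)
        for off in range(-h + 1, w):
            rr = np.arange(h)
            cc = rr + off if (dr, dc) == (1, 1) else off - rr + (h - 1)
            keep = (cc >= 0) & (cc < w)
            if keep.any():
                yield rr[keep], cc[keep]


def _run_lengths(levels_line: np.ndarray, mask_line: np.ndarray):
    """(level, length) of maximal constant runs within in-mask segments."""
    n = len(levels_line)
    start = 0
    for k in range(1, n + 1):
        boundary = (
            k == n
            or mask_line[k] != mask_line[k - 1]
            or levels_line[k] != levels_line[k - 1]
        )
        if boundary:
            if mask_line[start]:
                yield int(levels_line[start]), k - start
            start = k


def run_length_matrix(q: QuantizedROI, direction: str) -> np.ndarray:
    """Run-length matrix r[level-1, length-1] for one direction."""
    step = RLM_DIRECTIONS[direction]
    h, w = q.levels.shape
    maxlen = max(h, w)
    r = np.zeros((q.ng, maxlen), dtype=np.float64)
    for rr, cc in _mask_lines((h, w), step):
        for level, length in _run_lengths(q.levels[rr, cc], q.mask[rr, cc]):
            r[level - 1, length - 1] += 1
    return r


def rlm_features(q: QuantizedROI, direction: str) -> dict[str, float]:
    """Galloway run-length statistics for one direction (suffix H/V/45/135)."""
    r = run_length_matrix(q, direction)
    total = r.sum()
    if total == 0:
        raise ValueError("empty ROI: no runs")
    npix = int(q.mask.sum())
    lengths = np.arange(1, r.shape[1] + 1, dtype=np.float64)
    by_len = r.sum(axis=0)
    by_lev = r.sum(axis=1)
    return {
        f"ShrtREmp_{direction}": float((by_len / lengths ** 2).sum() / total),
        f"LngREmph_{direction}": float((by_len * lengths ** 2).sum() / total),
        f"GLevNonU_{direction}": float((by_lev ** 2).sum() / total),
        f"RLNonUni_{direction}": float((by_len ** 2).sum() / total),
        f"Fraction_{direction}": float(total / npix),
    }


# ----------------------------------------------------------------------- AR


def ar_features(roi) -> dict[str, float]:
    """First-order autoregressive image model.

    Zero-mean intensity ``s(r,c)`` is regressed on its W, N, NW and NE
    neighbours (least squares); ``Sigma`` is the population standard
    deviation of the residuals. Rank-deficient designs (e.g. a constant ROI)
    return all-zero parameters.
    """
    pixels, mask = _as_arrays(roi)
    s = pixels - pixels[mask].mean()
    ok = (
        mask
        & np.roll(mask, 1, axis=1)   # W
        & np.roll(mask, 1, axis=0)   # N
        & np.roll(np.roll(mask, 1, axis=0), 1, axis=1)   # NW
        & np.roll(np.roll(mask, 1, axis=0), -1, axis=1)  # NE
    )
    ok[0, :] = False
    ok[:, 0] = ok[:, -1] = False
    if ok.sum() < 5:
        raise ValueError("ROI too small for the autoregressive fit")
    y = s[ok]
    X = np.column_stack([
        np.roll(s, 1, axis=1)[ok],
        np.roll(s, 1, axis=0)[ok],
        np.roll(np.roll(s, 1, axis=0), 1, axis=1)[ok],
        np.roll(np.roll(s, 1, axis=0), -1, axis=1)[ok],
    ])
    if not np.any(X):
        return {"Teta1": 0.0, "Teta2": 0.0, "Teta3": 0.0, "Teta4": 0.0, "Sigma": 0.0}
    theta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 4:
        theta = np.zeros(4)
    resid = y - X @ theta
    return {
        "Teta1": float(theta[0]),
        "Teta2": float(theta[1]),
        "Teta3": float(theta[2]),
        "Teta4": float(theta[3]),
        "Sigma": float(resid.std()),
    }


# ------------------------------------------------------------------ wavelet


def wavelet_features(roi, scales: int = 4) -> dict[str, float]:
    """Orthonormal Haar subband energies of the bounding-box crop.

    Mask holes are filled with the in-mask mean; energy per subband is the
    mean squared coefficient. Scales whose input would fall below 2x2 are
    reported as NaN (excluded from modelling downstream).
    """
    pixels, mask = _as_arrays(roi)
    if pixels.shape[0] < 2 or pixels.shape[1] < 2:
        raise ValueError("bounding box below 2x2: wavelet undefined")
    filled = pixels.copy()
    filled[~mask] = pixels[mask].mean()
    out: dict[str, float] = {}
    current = filled
    for s in range(1, scales + 1):
        if current.shape[0] < 2 or current.shape[1] < 2:
            for band in ("LL", "LH", "HL", "HH"):
                out[f"WavEn{band}_s{s}"] = float("nan")
            continue
        ll, (lh, hl, hh) = pywt.dwt2(current, "haar", mode="periodization")
        for band, coef in (("LL", ll), ("LH", lh), ("HL", hl), ("HH", hh)):
            out[f"WavEn{band}_s{s}"] = float((coef ** 2).mean())
        current = ll
    return out


# --------------------------------------------------------------- inventory


@dataclass
class FeatureInventory:
    """Ordered list of (feature name, family) pairs to extract."""

    entries: list[tuple[str, str]] = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    @property
    def groups(self) -> dict[str, str]:
        return dict(self.entries)

    def group_features(self, group: str) -> list[str]:
        return [n for n, g in self.entries if g == group]

    def __len__(self) -> int:
        return len(self.entries)

    def __post_init__(self) -> None:
        names = self.names
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in inventory")


def default_inventory(config: TextureConfig | None = None) -> FeatureInventory:
    """The default 274-feature inventory.

    9 histogram + 5 gradient + 220 GLCM (11 statistics x 20 offsets) +
    20 run-length (5 statistics x 4 directions) + 5 autoregressive +
    15 wavelet (LL energies at scales 1-3; LH/HL/HH at scales 1-4).
    """
    config = config or TextureConfig()
    entries: list[tuple[str, str]] = []
    entries += [(n, "Histogram") for n in HIST_FEATURES]
    entries += [(n, "Gradient") for n in GRAD_FEATURES]
    for d in config.glcm_distances:
        for theta in (0, 90, 45, 135):
            tag = _glcm_offset_name(GLCMOffset(d, theta))
            entries += [(f"{tag}{f}", "GLCM") for f in GLCM_FEATURES]
    for direction in ("H", "V", "45", "135"):
        entries += [(f"{f}_{direction}", "RLM") for f in RLM_FEATURES]
    entries += [(n, "ARModel") for n in AR_FEATURES]
    for band in ("LL", "LH", "HL", "HH"):
        top = 3 if band == "LL" else config.wavelet_scales
        entries += [(f"WavEn{band}_s{s}", "Wavelet") for s in range(1, top + 1)]
    return FeatureInventory(entries)


def extract_all(roi, inventory: FeatureInventory | None = None,
                config: TextureConfig | None = None) -> dict[str, float]:
    """Extract every inventoried feature for one ROI, in inventory order."""
    inventory = inventory or default_inventory(config)
    config = config or TextureConfig()
    values: dict[str, float] = {}
    groups_needed = {g for _, g in inventory.entries}
    try:
        if "Histogram" in groups_needed:
            values.update(histogram_features(roi))
        if "Gradient" in groups_needed:
            values.update(gradient_features(roi))
        if "GLCM" in groups_needed or "RLM" in groups_needed:
            q = quantize(roi, ng=config.ng, normalization=config.normalization)
        if "GLCM" in groups_needed:
            for d in config.glcm_distances:
                for theta in (0, 90, 45, 135):
                    off = GLCMOffset(d, theta)
                    tag = _glcm_offset_name(off)
                    feats = glcm_features(glcm(q, off))
                    values.update({f"{tag}{k}": v for k, v in feats.items()})
        if "RLM" in groups_needed:
            for direction in RLM_DIRECTIONS:
                values.update(rlm_features(q, direction))
        if "ARModel" in groups_needed:
            values.update(ar_features(roi))
        if "Wavelet" in groups_needed:
            values.update(wavelet_features(roi, scales=config.wavelet_scales))
    except ValueError as exc:
        ident = getattr(roi, "roi_id", "?")
        raise ValueError(f"feature extraction failed for ROI {ident}: {exc}") from exc
    try:
        return {name: values[name] for name in inventory.names}
    except KeyError as exc:
        raise KeyError(f"inventory entry {exc} not produced by any family") from exc
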