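"""Nucleus morphometry from H&E tiles and inter-focus feature correlation.

The pathology arm works on square RGB tiles (default 2048 px at 0.5 um/px)
cut from the manually annotated cancer region of a whole-slide image.  Tiles
are color-standardized against one reference tile (Macenko stain
normalization), nuclei are segmented from the hematoxylin channel by
hierarchical two-then-three-class Otsu thresholding, ten morphometry
features are measured per nucleus, and each feature's distribution over all
nuclei of a focus is summarized as a 10-bin histogram plus five statistics
(mean, std, skewness, kurtosis, entropy).  Agreement between the two foci of
one patient is the Pearson correlation of their (cohort-standardized)
feature vectors: metastatic pairs, sharing one clone of origin, tend to look
alike; independent primaries do not.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps
from skimage import measure
from skimage.filters import threshold_multiotsu, threshold_otsu

log = logging.getLogger(__name__)

__all__ = [
    "Tile",
    "NUCLEUS_FEATURES",
    "DEFAULT_BIN_RANGES",
    "tile_image",
    "rgb_to_od",
    "od_to_rgb",
    "estimate_stain_matrix",
    "macenko_normalize",
    "segment_nuclei",
    "nucleus_features",
    "image_level_features",
    "image_feature_names",
    "histogram_feature_names",
    "focus_pair_correlation",
]

#: The ten per-nucleus morphometry features, in fixed order.
NUCLEUS_FEATURES = (
    "area",            # um^2
    "circularity",     # 4*pi*A/P^2
    "solidity",
    "rmean",           # channel means, 0-255
    "gmean",
    "bmean",
    "intensity_std",   # grayscale std inside the nucleus, 0-255 scale
    "dist_mean",       # centroid distance to the other nuclei in the tile, um
    "dist_max",
    "dist_min",
)

#: Fixed global histogram ranges per feature.  Fixed (not per-image) ranges
#: keep bins comparable across foci, which the correlation analysis needs.
DEFAULT_BIN_RANGES: dict[str, tuple[float, float]] = {
    "area": (0.0, 300.0),
    "circularity": (0.0, 1.25),
    "solidity": (0.0, 1.0),
    "rmean": (0.0, 255.0),
    "gmean": (0.0, 255.0),
    "bmean": (0.0, 255.0),
    "intensity_std": (0.0, 100.0),
    "dist_mean": (0.0, 300.0),
    "dist_max": (0.0, 500.0),
    "dist_min": (0.0, 200.0),
}

N_BINS = 10
_STATS = ("mean", "std", "skewness", "kurtosis", "entropy")

DEFAULT_TILE_SIDE = 2048
DEFAULT_MPP = 0.5
OD_BACKGROUND_THRESHOLD = 0.15


@dataclass(frozen=True)
class Tile:
    """A square RGB 8-bit tile with its physical pixel size."""

    pixels: np.ndarray  # (side, side, 3) uint8
    mpp: float = DEFAULT_MPP
    tile_id: str = ""

    def __post_init__(self):
        px = self.pixels
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] != px.shape[1]:
            raise ValueError(f"tile must be square RGB, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError("tile pixels must be 8-bit (uint8)")
        if self.mpp <= 0:
            raise ValueError("microns-per-pixel must be positive")

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


def tile_image(
    image: np.ndarray,
    mask: Optional[np.ndarray] = None,
    side: int = DEFAULT_TILE_SIDE,
    mpp: float = DEFAULT_MPP,
    min_mask_fraction: float = 0.5,
) -> list[Tile]:
    """Cut a non-overlapping grid of square tiles fully inside *image*.

    Partial edge tiles are discarded.  With a binary cancer-region *mask*,
    only tiles with at least ``min_mask_fraction`` of their pixels inside
    the mask are kept.
    """
    h, w = image.shape[:2]
    if mask is not None and mask.shape[:2] != (h, w):
        raise ValueError("mask shape must match image shape")
    if h < side or w < side:
        warnings.warn(f"image {h}x{w} smaller than one {side}-px tile; no tiles produced")
        return []
    tiles = []
    for r0 in range(0, h - side + 1, side):
        for c0 in range(0, w - side + 1, side):
            if mask is not None:
                frac = float(np.count_nonzero(mask[r0 : r0 + side, c0 : c0 + side])) / side**2
                if frac < min_mask_fraction:
                    continue
            tiles.append(
                Tile(
                    pixels=np.ascontiguousarray(image[r0 : r0 + side, c0 : c0 + side, :3]),
                    mpp=mpp,
                    tile_id=f"r{r0 // side}c{c0 // side}",
                )
            )
    return tiles


# ---------------------------------------------------------------------------
# Macenko stain normalization


def rgb_to_od(pixels: np.ndarray) -> np.ndarray:
    """Optical density transform OD = -log10((I + 1) / 256), per channel."""
    return -np.log10((pixels.astype(float) + 1.0) / 256.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    rgb = 256.0 * np.power(10.0, -od) - 1.0
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def _foreground(od_flat: np.ndarray, beta: float = OD_BACKGROUND_THRESHOLD) -> np.ndarray:
    """Stained-tissue pixels: all three OD channels at or above *beta*."""
    return (od_flat >= beta).all(axis=1)


def estimate_stain_matrix(od_pixels: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Macenko stain-vector estimate from foreground OD pixels (N x 3).

    The two stain directions are the ``alpha`` / ``100 - alpha`` percentile
    extremes of the pixel angles within the plane of the top-two singular
    vectors.  Returns a 3 x 2 matrix of unit column vectors with hematoxylin
    (the red-absorbing, blue-looking stain) first.
    """
    if od_pixels.shape[0] < 10:
        raise ValueError("too few foreground pixels to estimate stain vectors")
    _, _, vt = np.linalg.svd(od_pixels, full_matrices=False)
    basis = vt[:2].T  # 3 x 2 plane
    for j in range(2):  # orient the plane axes consistently
        if basis[:, j].sum() < 0:
            basis[:, j] *= -1
    proj = od_pixels @ basis
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [alpha, 100.0 - alpha])
    v1 = basis @ np.array([np.cos(lo), np.sin(lo)])
    v2 = basis @ np.array([np.cos(hi), np.sin(hi)])
    stains = []
    for v in (v1, v2):
        if v.sum() < 0:
            v = -v
        stains.append(v / np.linalg.norm(v))
    stains = np.array(stains).T  # 3 x 2
    # hematoxylin absorbs red most strongly -> larger first (red-OD) component
    if stains[0, 0] < stains[0, 1]:
        stains = stains[:, ::-1]
    return stains


def _stain_concentrations(od_flat: np.ndarray, stain_matrix: np.ndarray) -> np.ndarray:
    """Least-squares per-pixel stain concentrations (2 x N, clipped at 0)."""
    conc, *_ = np.linalg.lstsq(stain_matrix, od_flat.T, rcond=None)
    return np.clip(conc, 0.0, None)


def macenko_normalize(
    tile: Tile,
    reference: Tile,
    alpha: float = 1.0,
    beta: float = OD_BACKGROUND_THRESHOLD,
) -> Tile:
    """Map *tile*'s stain colors and concentration scale onto *reference*'s.

    Stain vectors are estimated per tile; concentrations are rescaled so
    their 99th percentiles match the reference's, then recombined with the
    reference stain matrix.  The OD residual outside the two-stain plane
    (noise/texture the stains cannot explain) is carried through unchanged,
    so normalizing a tile against itself is the identity.  Background
    pixels (below the OD threshold) are passed through unchanged.  A tile
    with no stained pixels is returned unchanged with a warning.
    """
    od = rgb_to_od(tile.pixels).reshape(-1, 3)
    fg = _foreground(od, beta)
    if not fg.any():
        warnings.warn(f"tile {tile.tile_id or '<unnamed>'}: no stained pixels; passthrough")
        return tile
    ref_od = rgb_to_od(reference.pixels).reshape(-1, 3)
    ref_fg = _foreground(ref_od, beta)
    if not ref_fg.any():
        raise ValueError("reference tile has no stained pixels")

    src_stains = estimate_stain_matrix(od[fg], alpha)
    ref_stains = estimate_stain_matrix(ref_od[ref_fg], alpha)
    src_conc = _stain_concentrations(od, src_stains)
    ref_conc = _stain_concentrations(ref_od[ref_fg], ref_stains)

    src_p99 = np.percentile(src_conc[:, fg], 99, axis=1)
    ref_p99 = np.percentile(ref_conc, 99, axis=1)
    scale = np.divide(ref_p99, src_p99, out=np.ones(2), where=src_p99 > 1e-12)
    residual = od - (src_stains @ src_conc).T
    out_od = (ref_stains @ (src_conc * scale[:, None])).T + residual

    out = od_to_rgb(out_od).reshape(tile.pixels.shape).copy()
    flat = out.reshape(-1, 3)
    flat[~fg] = tile.pixels.reshape(-1, 3)[~fg]
    return replace(tile, pixels=out)


# ---------------------------------------------------------------------------
# Nucleus segmentation


def hematoxylin_channel(tile: Tile, beta: float = OD_BACKGROUND_THRESHOLD) -> np.ndarray:
    """Per-pixel hematoxylin concentration via tile-level Macenko stain separation.

    Falls back to inverted luminance OD when stain estimation is degenerate
    (too few stained pixels or a collapsed color space).
    """
    od = rgb_to_od(tile.pixels).reshape(-1, 3)
    fg = _foreground(od, beta)
    try:
        stains = estimate_stain_matrix(od[fg])
        conc = _stain_concentrations(od, stains)
        h = conc[0]
    except (ValueError, np.linalg.LinAlgError):
        log.warning("tile %s: stain estimation degenerate; using luminance OD", tile.tile_id)
        h = od.mean(axis=1)
    return h.reshape(tile.pixels.shape[:2])


def segment_nuclei(
    tile: Tile,
    min_area_um2: float = 10.0,
    max_area_um2: float = 500.0,
) -> np.ndarray:
    """Label nuclei in a (normalized) tile; returns an integer mask with labels 1..K.

    The hematoxylin channel is thresholded hierarchically: a two-class Otsu
    split separates stained tissue from background, then a three-class Otsu
    split within the stained pixels yields two refined cut levels separating
    weakly stained cytoplasm from nuclei.  Each candidate level (coarse,
    refined-low, refined-high) is labelled and the level retaining the most
    components inside the size window wins, with the tighter mask preferred
    on ties — so the hierarchy neither shatters homogeneous nuclei nor
    swallows cytoplasm.  Components outside [min_area, max_area] um^2 are
    removed and the survivors relabelled 1..K.
    """
    zeros = np.zeros(tile.pixels.shape[:2], dtype=np.int32)
    # light smoothing suppresses pixel-noise speckle that would bridge nuclei
    h = ndimage.gaussian_filter(hematoxylin_channel(tile), sigma=1.0)
    finite = h[np.isfinite(h)]
    if finite.size == 0 or np.allclose(finite.max(), finite.min()):
        return zeros
    try:
        t1 = threshold_otsu(h)
    except ValueError:
        return zeros
    stained = h > t1
    if not stained.any():
        return zeros
    cuts = [t1]
    try:
        cuts.extend(threshold_multiotsu(h[stained], classes=3))
    except ValueError:  # too few distinct levels for a 3-class split
        pass

    px_area = tile.mpp**2

    def _label_filtered(mask: np.ndarray) -> tuple[np.ndarray, int]:
        labels = measure.label(ndimage.binary_fill_holes(mask), connectivity=2)
        out = np.zeros_like(labels, dtype=np.int32)
        kept = 0
        for rp in measure.regionprops(labels):
            if min_area_um2 <= rp.area * px_area <= max_area_um2:
                kept += 1
                out[labels == rp.label] = kept
        return out, kept

    best, best_key = zeros, (-1, 0)
    for cut in cuts:
        mask = h > cut
        if not mask.any():
            continue
        labelled, kept = _label_filtered(mask)
        key = (kept, -int(mask.sum()))  # most nuclei, then tightest mask
        if key > best_key:
            best, best_key = labelled, key
    return best


# ---------------------------------------------------------------------------
# Feature extraction


def nucleus_features(labels: np.ndarray, tile: Tile) -> pd.DataFrame:
    """Ten morphometry features per labelled nucleus.

    Distances are centroid-to-centroid within the tile, in microns; a tile
    with a single nucleus gets all three distance features set to 0 rather
    than being dropped.
    """
    if labels.shape != tile.pixels.shape[:2]:
        raise ValueError("labels and tile must be aligned")
    mpp = tile.mpp
    props = measure.regionprops(labels, intensity_image=tile.pixels)
    if not props:
        return pd.DataFrame(columns=["tile_id", "label", *NUCLEUS_FEATURES])
    centroids = np.array([rp.centroid for rp in props]) * mpp
    if len(props) > 1:
        diff = centroids[:, None, :] - centroids[None, :, :]
        dmat = np.sqrt((diff**2).sum(axis=2))
        np.fill_diagonal(dmat, np.nan)
    rows = []
    gray = tile.pixels.astype(float).mean(axis=2)
    for i, rp in enumerate(props):
        area_um2 = rp.area * mpp**2
        perim = rp.perimeter
        circ = 4.0 * np.pi * rp.area / perim**2 if perim > 0 else 0.0
        rmean, gmean, bmean = rp.intensity_mean
        region_gray = gray[tuple(rp.coords.T)]
        if len(props) > 1:
            d = dmat[i]
            dist_mean = float(np.nanmean(d))
            dist_max = float(np.nanmax(d))
            dist_min = float(np.nanmin(d))
        else:
            dist_mean = dist_max = dist_min = 0.0
        rows.append(
            {
                "tile_id": tile.tile_id,
                "label": rp.label,
                "area": area_um2,
                "circularity": float(circ),
                "solidity": float(rp.solidity),
                "rmean": float(rmean),
                "gmean": float(gmean),
                "bmean": float(bmean),
                "intensity_std": float(region_gray.std()),
                "dist_mean": dist_mean,
                "dist_max": dist_max,
                "dist_min": dist_min,
            }
        )
    return pd.DataFrame(rows)


def image_feature_names(features: Sequence[str] = NUCLEUS_FEATURES) -> list[str]:
    """The 150 image-level feature names, in fixed order."""
    names = []
    for feat in features:
        names.extend(f"{feat}_bin{k}" for k in range(1, N_BINS + 1))
        names.extend(f"{feat}_{stat}" for stat in _STATS)
    return names


def histogram_feature_names(features: Sequence[str] = NUCLEUS_FEATURES) -> list[str]:
    """The 100-feature histogram-bins-only subset."""
    return [f"{feat}_bin{k}" for feat in features for k in range(1, N_BINS + 1)]


def image_level_features(
    records: pd.DataFrame,
    bin_ranges: Mapping[str, tuple[float, float]] = DEFAULT_BIN_RANGES,
) -> pd.Series:
    """Summarize a focus's nucleus table into the 150-value image feature vector.

    Per nucleus feature: a 10-bin histogram over the fixed global range
    (values clipped into range, bins normalized to sum 1) plus mean,
    population std, Fisher skewness, excess kurtosis, and Shannon entropy
    (base 2) of the normalized histogram.  Zero-variance distributions get
    skewness and kurtosis 0 by convention so the vector stays finite.
    """
    if records.empty:
        raise ValueError("cannot summarize an empty nucleus table")
    out: dict[str, float] = {}
    for feat in NUCLEUS_FEATURES:
        values = records[feat].to_numpy(dtype=float)
        lo, hi = bin_ranges[feat]
        clipped = np.clip(values, lo, hi)
        hist, _ = np.histogram(clipped, bins=N_BINS, range=(lo, hi))
        h = hist / hist.sum()
        for k in range(N_BINS):
            out[f"{feat}_bin{k + 1}"] = float(h[k])
        out[f"{feat}_mean"] = float(values.mean())
        std = float(values.std(ddof=0))
        out[f"{feat}_std"] = std
        if std == 0.0:
            out[f"{feat}_skewness"] = 0.0
            out[f"{feat}_kurtosis"] = 0.0
        else:
            out[f"{feat}_skewness"] = float(sps.skew(values, bias=True))
            out[f"{feat}_kurtosis"] = float(sps.kurtosis(values, fisher=True, bias=True))
        nz = h[h > 0]
        out[f"{feat}_entropy"] = float(-(nz * np.log2(nz)).sum())
    return pd.Series(out, index=image_feature_names())


def focus_pair_correlation(
    va: pd.Series,
    vb: pd.Series,
    cohort_mean: Optional[pd.Series] = None,
    cohort_std: Optional[pd.Series] = None,
    method: str = "pearson",
) -> float:
    """Correlation between the image-feature vectors of a patient's two foci.

    With cohort statistics given, each feature is standardized
    ((v - mean) / std) first; features with zero cohort variance are
    dropped as uninformative.  Raises when either resulting vector has no
    variance (correlation undefined).
    """
    if not va.index.equals(vb.index):
        vb = vb.reindex(va.index)
    a = va.to_numpy(dtype=float)
    b = vb.to_numpy(dtype=float)
    if cohort_mean is not None and cohort_std is not None:
        mu = cohort_mean.reindex(va.index).to_numpy(dtype=float)
        sd = cohort_std.reindex(va.index).to_numpy(dtype=float)
        keep = sd > 0
        if not keep.any():
            raise ValueError("all features have zero cohort variance")
        a = (a[keep] - mu[keep]) / sd[keep]
        b = (b[keep] - mu[keep]) / sd[keep]
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for a zero-variance feature vector")
    if method == "pearson":
        return float(np.corrcoef(a, b)[0, 1])
    if method == "spearman":
        return float(sps.spearmanr(a, b).statistic)
    raise ValueError(f"unknown correlation method {method!r}")
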