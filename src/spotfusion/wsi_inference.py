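"""Zero-shot whole-slide-image workflow: tile, score, filter, predict.

Each non-overlapping tile is scored as nuclei_fraction * tanh(tissue_fraction);
tiles with less than 60% tissue are excluded, the top 20 surviving tiles are
resized to the encoder resolution and decoded, and the elementwise mean of
their predicted expression vectors is the slide-level prediction.

Tissue is detected by thresholding HSV saturation (near-white background has
low saturation); nuclei by thresholding the hematoxylin channel after color
deconvolution.  Both detectors are classical, transparent, and pluggable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from PIL import Image
from skimage.color import rgb2hed, rgb2hsv
from skimage.filters import threshold_otsu

__all__ = [
    "PatchScore",
    "tissue_nuclei_fractions",
    "score_patch",
    "tile_origins",
    "select_patches",
    "predict_wsi",
]

TISSUE_EXCLUSION_THRESHOLD = 0.6


@dataclass
class PatchScore:
    tile_origin: tuple  # (x, y) pixels
    T_t: float          # tissue fraction
    N_t: float          # nuclei fraction
    score: float
    excluded: bool


def tissue_nuclei_fractions(
    tile: np.ndarray,
    saturation_threshold: float | None = 0.08,
    hematoxylin_threshold: float | None = 0.07,
) -> tuple:
    """Return (tissue fraction, nuclei fraction) of an RGB tile.

    Pass ``None`` for either threshold to fall back to Otsu's method on the
    corresponding channel.
    """
    tile = np.asarray(tile)
    if tile.size == 0:
        raise ValueError("empty tile")
    rgb = tile.astype(float) / 255.0
    sat = rgb2hsv(rgb)[..., 1]
    if saturation_threshold is None:
        saturation_threshold = threshold_otsu(sat) if np.ptp(sat) > 0 else 0.5
    tissue = sat > saturation_threshold

    hema = rgb2hed(rgb)[..., 0]
    if hematoxylin_threshold is None:
        hematoxylin_threshold = threshold_otsu(hema) if np.ptp(hema) > 0 else 0.5
    nuclei = hema > hematoxylin_threshold

    return float(tissue.mean()), float(nuclei.mean())


def score_patch(T_t: float, N_t: float, tile_origin: tuple = (0, 0)) -> PatchScore:
    """score = N_t * tanh(T_t); tiles with T_t < 0.6 are excluded (the
    boundary itself is retained)."""
    if not (0.0 <= T_t <= 1.0 and 0.0 <= N_t <= 1.0):
        raise ValueError(f"fractions must lie in [0, 1], got T_t={T_t}, N_t={N_t}")
    return PatchScore(
        tile_origin=tuple(tile_origin),
        T_t=float(T_t),
        N_t=float(N_t),
        score=float(N_t * np.tanh(T_t)),
        excluded=T_t < TISSUE_EXCLUSION_THRESHOLD,
    )


def tile_origins(width: int, height: int, tile_size: int) -> list:
    """Raster-order origins of the non-overlapping tile grid."""
    return [(x, y)
            for y in range(0, height - tile_size + 1, tile_size)
            for x in range(0, width - tile_size + 1, tile_size)]


def select_patches(
    wsi: np.ndarray,
    tile_size: int = 512,
    n: int = 20,
    saturation_threshold: float | None = 0.08,
    hematoxylin_threshold: float | None = 0.07,
):
    """Grid-tile the slide, score every tile, drop excluded ones, return the
    top-n tiles by score (ties by raster order).

    Returns ``(tiles, scores)``: the selected tile images and the full list
    of :class:`PatchScore` for every grid tile.
    """
    wsi = np.asarray(wsi)
    height, width = wsi.shape[:2]
    if height < tile_size or width < tile_size:
        raise ValueError(f"slide {width}x{height} smaller than one {tile_size}px tile")
    scores = []
    for x, y in tile_origins(width, height, tile_size):
        T_t, N_t = tissue_nuclei_fractions(
            wsi[y:y + tile_size, x:x + tile_size],
            saturation_threshold, hematoxylin_threshold)
        scores.append(score_patch(T_t, N_t, tile_origin=(x, y)))
    survivors = [i for i, s in enumerate(scores) if not s.excluded]
    # stable: ties keep raster order
    survivors.sort(key=lambda i: -scores[i].score)
    chosen = survivors[:n]
    if len(chosen) < n:
        warnings.warn(
            f"only {len(chosen)} of the requested {n} tiles pass the "
            f"{TISSUE_EXCLUSION_THRESHOLD:.0%} tissue filter")
    tiles = [wsi[s.tile_origin[1]:s.tile_origin[1] + tile_size,
                 s.tile_origin[0]:s.tile_origin[0] + tile_size]
             for s in (scores[i] for i in chosen)]
    return tiles, scores


def predict_wsi(tiles, image_encoder, decoder) -> np.ndarray:
    """Resize tiles to the encoder resolution, encode, decode, and average
    the per-tile predictions into one expression vector."""
    tiles = list(tiles)
    if not tiles:
        raise ValueError("no tiles to predict from")
    resolution = image_encoder.config.input_resolution
    resized = np.stack([
        np.asarray(Image.fromarray(np.asarray(t)).resize((resolution, resolution), Image.BILINEAR))
        for t in tiles
    ])
    image_encoder.eval()
    V = image_encoder(resized).data
    preds = decoder.predict(V)
    return preds.mean(axis=0)
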