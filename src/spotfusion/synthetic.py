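"""Seeded synthetic data: paired patches and counts sharing a planted latent.

Each spot draws a latent vector z; the image patch is an analytic, linear
render of z (fixed per-slice spatial basis patterns) plus Gaussian pixel
noise, and the UMI counts are Poisson with rates depth * softmax(W z) for a
fixed loading matrix W.  Because both modalities are exact functions of the
same z (up to noise), cross-modal alignment and image-to-expression decoding
are learnable and their recovery is testable without any external download.

A companion generator paints a synthetic whole-slide image with known
per-tile tissue and nuclei fractions for exercising the patch-scoring
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spatial_dataset import SpotSlice

__all__ = ["SyntheticSpec", "generate_slice", "generate_wsi_fixture"]


@dataclass
class SyntheticSpec:
    grid_shape: tuple = (16, 16)      # rows x cols of the spot lattice
    n_genes: int = 200
    latent_dim: int = 4
    image_size: int = 40
    noise_sd: float = 0.02            # pixel noise, fraction of the 255 range
    count_depth: float = 5000.0       # expected UMI per spot
    spot_spacing: float = 50.0        # pixel distance between grid neighbors
    rng_seed: int = 0

    @property
    def n_spots(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def validate(self) -> None:
        if self.grid_shape[0] < 1 or self.grid_shape[1] < 1:
            raise ValueError(f"invalid grid shape {self.grid_shape}")
        if self.latent_dim > min(self.n_genes, 16):
            raise ValueError(f"latent_dim {self.latent_dim} exceeds min(n_genes, 16)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.count_depth <= 0 or self.image_size < 4:
            raise ValueError("count_depth must be positive and image_size >= 4")


def _latent_basis(rng: np.random.Generator, latent_dim: int, size: int) -> np.ndarray:
    """Smooth spatial basis patterns, one RGB pattern per latent component.

    Low-frequency sinusoids with random orientation/phase per channel: linear
    in z, spatially structured, and easily picked up by a small patch encoder.
    """
    yy, xx = np.mgrid[0:size, 0:size] / float(size)
    basis = np.empty((latent_dim, size, size, 3))
    for k in range(latent_dim):
        for c in range(3):
            fx, fy = rng.uniform(0.5, 2.0, size=2)
            phase = rng.uniform(0, 2 * np.pi)
            sign = rng.choice([-1.0, 1.0])
            basis[k, :, :, c] = sign * np.sin(2 * np.pi * (fx * xx + fy * yy) + phase)
    return basis


def generate_slice(spec: SyntheticSpec, slice_id: str = "synthetic"):
    """Generate one slice; returns (SpotSlice, latents z of shape (n, d))."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    rows, cols = spec.grid_shape
    n, d = spec.n_spots, spec.latent_dim

    z = rng.standard_normal((n, d))
    # expression: Poisson(depth * softmax(z W)) with fixed loadings W
    W = rng.standard_normal((d, spec.n_genes)) * 1.5
    logits = z @ W
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    counts = rng.poisson(spec.count_depth * probs).astype(np.int64)

    # images: linear render of z on fixed spatial basis patterns
    basis = _latent_basis(rng, d, spec.image_size)
    render = 127.0 + 45.0 * np.tensordot(z, basis, axes=(1, 0)) / np.sqrt(d)
    if spec.noise_sd > 0:
        render = render + rng.standard_normal(render.shape) * spec.noise_sd * 255.0
    patches = np.clip(np.round(render), 0, 255).astype(np.uint8)

    rr, cc = np.divmod(np.arange(n), cols)
    coords = np.stack([cc * spec.spot_spacing + spec.spot_spacing / 2,
                       rr * spec.spot_spacing + spec.spot_spacing / 2], axis=1)

    slc = SpotSlice(
        slice_id=slice_id,
        patches=patches,
        counts=counts,
        gene_names=[f"gene-{i:04d}" for i in range(spec.n_genes)],
        coords=coords,
    )
    return slc, z


# ---------------------------------------------------------------------------
# WSI fixture
# ---------------------------------------------------------------------------

def generate_wsi_fixture(
    width: int,
    height: int,
    n_tissue_regions: int,
    rng_seed: int,
    tile_size: int = 512,
    nuclei_density: float = 0.004,
):
    """Paint a synthetic H&E-like slide with known per-tile fractions.

    Background is near-white; tissue regions are saturated eosin-pink
    ellipses; nuclei are small dark hematoxylin-violet disks scattered inside
    tissue with a left-to-right density gradient (so tile scores vary).

    Returns ``(image, tiles)`` where ``tiles`` is a DataFrame with columns
    ``x0, y0, tissue_frac, nuclei_frac`` — exact mask-pixel fractions per
    non-overlapping ``tile_size`` tile.
    """
    if width < tile_size or height < tile_size:
        raise ValueError(f"slide {width}x{height} smaller than one {tile_size}px tile")
    rng = np.random.default_rng(rng_seed)
    image = np.full((height, width, 3), 244, dtype=np.uint8)
    tissue_mask = np.zeros((height, width), dtype=bool)
    nuclei_mask = np.zeros((height, width), dtype=bool)

    yy, xx = np.mgrid[0:height, 0:width]
    for _ in range(n_tissue_regions):
        cx = rng.uniform(0.1 * width, 0.9 * width)
        cy = rng.uniform(0.1 * height, 0.9 * height)
        ax = rng.uniform(0.2, 0.55) * width / 2
        ay = rng.uniform(0.2, 0.55) * height / 2
        region = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
        tissue_mask |= region

    image[tissue_mask] = (231, 161, 193)  # eosin-stained cytoplasm

    if tissue_mask.any():
        area = int(tissue_mask.sum())
        n_nuclei = int(area * nuclei_density)
        ys, xs = np.nonzero(tissue_mask)
        # density gradient: nuclei increasingly likely toward the right edge
        weight = 0.2 + 0.8 * xs / max(width - 1, 1)
        weight = weight / weight.sum()
        pick = rng.choice(len(xs), size=min(n_nuclei, len(xs)), replace=False, p=weight)
        radius = 3
        for idx in pick:
            cy, cx = ys[idx], xs[idx]
            y0, y1 = max(cy - radius, 0), min(cy + radius + 1, height)
            x0, x1 = max(cx - radius, 0), min(cx + radius + 1, width)
            sub = (xx[y0:y1, x0:x1] - cx) ** 2 + (yy[y0:y1, x0:x1] - cy) ** 2 <= radius ** 2
            nuclei_mask[y0:y1, x0:x1] |= sub
        nuclei_mask &= tissue_mask
        image[nuclei_mask] = (64, 44, 122)  # hematoxylin-stained nuclei

    records = []
    for y0 in range(0, height - tile_size + 1, tile_size):
        for x0 in range(0, width - tile_size + 1, tile_size):
            t = tissue_mask[y0:y0 + tile_size, x0:x0 + tile_size]
            nmask = nuclei_mask[y0:y0 + tile_size, x0:x0 + tile_size]
            records.append({
                "x0": x0,
                "y0": y0,
                "tissue_frac": float(t.mean()),
                "nuclei_frac": float(nmask.mean()),
            })
    return image, pd.DataFrame.from_records(records)
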