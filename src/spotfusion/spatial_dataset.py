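"""Spot-level spatial transcriptomics data model, I/O and preprocessing.

A *spot* couples a small H&E image patch with a UMI count vector and an
(x, y) coordinate.  This module holds the container types, readers and
writers for the on-disk slice layout, and the preprocessing chain used
throughout the package: CPM log-normalization, highly-variable-gene and
target-panel selection, patch cropping and photometric augmentation.

Coordinates are pixel-space patch centers, 0-based, ordered (x=column,
y=row).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix, issparse

__all__ = [
    "SpotSlice",
    "GenePanel",
    "NormalizedExpression",
    "load_slice",
    "read_slice_dir",
    "write_slice_dir",
    "center_crop",
    "normalize_expression",
    "select_hvg",
    "select_target_genes",
    "augment_patch",
    "resize_patches",
]


@dataclass
class SpotSlice:
    """One slice: paired patches, UMI counts, coordinates, gene names."""

    slice_id: str
    patches: np.ndarray  # (n, H, W, 3) uint8
    counts: np.ndarray   # (n, n_genes) non-negative integers
    gene_names: list
    coords: np.ndarray   # (n, 2) float, (x, y)

    def __post_init__(self):
        self.patches = np.asarray(self.patches)
        self.counts = np.asarray(self.counts)
        self.coords = np.asarray(self.coords, dtype=float)
        self.gene_names = list(self.gene_names)
        self.validate()

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    def validate(self) -> None:
        n = self.counts.shape[0]
        if self.patches.shape[0] != n or self.coords.shape[0] != n:
            raise ValueError(
                f"slice {self.slice_id!r}: inconsistent spot counts — "
                f"patches {self.patches.shape[0]}, counts {n}, coords {self.coords.shape[0]}"
            )
        if self.patches.ndim != 4 or self.patches.shape[-1] != 3:
            raise ValueError(f"patches must be (n, H, W, 3), got {self.patches.shape}")
        if self.coords.shape[1] != 2:
            raise ValueError(f"coords must be (n, 2), got {self.coords.shape}")
        if np.any(self.counts < 0) or not np.allclose(self.counts, np.round(self.counts)):
            raise ValueError("counts must be non-negative integers")
        if len(self.gene_names) != self.counts.shape[1]:
            raise ValueError(
                f"{len(self.gene_names)} gene names for {self.counts.shape[1]} count columns"
            )
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError("gene names must be unique")


@dataclass
class GenePanel:
    """An ordered gene list: 'hvg' (encoder input) or 'target' (decoder output)."""

    names: list
    kind: str  # "hvg" | "target"

    def __post_init__(self):
        self.names = list(self.names)
        if self.kind not in ("hvg", "target"):
            raise ValueError(f"panel kind must be 'hvg' or 'target', got {self.kind!r}")
        if len(set(self.names)) != len(self.names):
            raise ValueError("panel gene names must be unique")

    @property
    def size(self) -> int:
        return len(self.names)


@dataclass
class NormalizedExpression:
    matrix: np.ndarray
    panel: GenePanel

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != self.panel.size:
            raise ValueError(
                f"matrix has {self.matrix.shape[1]} columns for panel of size {self.panel.size}"
            )


# ---------------------------------------------------------------------------
# cropping and augmentation
# ---------------------------------------------------------------------------

def center_crop(image: np.ndarray, center: tuple, size: int) -> np.ndarray:
    """Crop a ``size``×``size`` window centered at ``center`` = (x, y).

    Windows that overhang the image border are zero-padded so every spot
    yields a patch of identical shape.
    """
    if size <= 0:
        raise ValueError(f"crop size must be positive, got {size}")
    image = np.asarray(image)
    h, w = image.shape[:2]
    x, y = center
    if not (0 <= x < w and 0 <= y < h):
        raise ValueError(f"center ({x}, {y}) outside image of size {w}x{h}")
    x0 = int(round(x)) - size // 2
    y0 = int(round(y)) - size // 2
    out = np.zeros((size, size) + image.shape[2:], dtype=image.dtype)
    sy0, sy1 = max(y0, 0), min(y0 + size, h)
    sx0, sx1 = max(x0, 0), min(x0 + size, w)
    out[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = image[sy0:sy1, sx0:sx1]
    return out


def augment_patch(
    patch: np.ndarray,
    rng_seed: int,
    scale_range: tuple = (0.9, 1.0),
    flip_prob: float = 0.5,
    brightness: float = 0.1,
    contrast: float = 0.1,
) -> np.ndarray:
    """Photometric/geometric training augmentation, fully seeded.

    Applies in order: random crop-and-resize (area scale drawn from
    ``scale_range``), horizontal then vertical flip each with probability
    ``flip_prob``, additive brightness jitter within ±``brightness`` (as a
    fraction of the 255 range) and multiplicative contrast jitter within
    ±``contrast`` about the patch mean.
    """
    patch = np.asarray(patch)
    if patch.size == 0:
        raise ValueError("empty patch")
    rng = np.random.default_rng(rng_seed)
    h, w = patch.shape[:2]
    out = patch

    scale = rng.uniform(*scale_range)
    if scale < 1.0:
        ch, cw = max(1, int(round(h * scale))), max(1, int(round(w * scale)))
        y0 = rng.integers(0, h - ch + 1)
        x0 = rng.integers(0, w - cw + 1)
        crop = out[y0:y0 + ch, x0:x0 + cw]
        out = np.asarray(Image.fromarray(crop).resize((w, h), Image.BILINEAR))

    if rng.random() < flip_prob:
        out = out[:, ::-1]
    if rng.random() < flip_prob:
        out = out[::-1, :]

    outf = out.astype(np.float64)
    if brightness > 0:
        outf = outf + rng.uniform(-brightness, brightness) * 255.0
    if contrast > 0:
        factor = 1.0 + rng.uniform(-contrast, contrast)
        outf = (outf - outf.mean()) * factor + outf.mean()
    return np.clip(np.round(outf), 0, 255).astype(np.uint8)


def resize_patches(patches: np.ndarray, resolution: int) -> np.ndarray:
    """Bilinear-resize a stack of patches to the encoder input resolution."""
    patches = np.asarray(patches)
    if patches.shape[1] == resolution and patches.shape[2] == resolution:
        return patches
    out = np.empty((patches.shape[0], resolution, resolution, patches.shape[3]), dtype=patches.dtype)
    for i, p in enumerate(patches):
        out[i] = np.asarray(Image.fromarray(p).resize((resolution, resolution), Image.BILINEAR))
    return out


# ---------------------------------------------------------------------------
# normalization and panel selection
# ---------------------------------------------------------------------------

def normalize_expression(counts: np.ndarray) -> np.ndarray:
    """Counts-per-million log normalization: ln(1 + 1e6 * c / spot total).

    The pseudo-count keeps zeros at exactly zero and makes the transform
    defined everywhere; within a spot the rank order of counts is preserved.
    """
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1)
    bad = np.flatnonzero(totals <= 0)
    if bad.size:
        raise ValueError(f"spots with zero total counts: {bad.tolist()}")
    return np.log1p(1e6 * counts / totals[:, None])


def _ranked_panel(scores: np.ndarray, gene_names: Sequence[str], k: int, kind: str) -> GenePanel:
    if k > len(gene_names):
        raise ValueError(f"k={k} exceeds the {len(gene_names)} available genes")
    order = sorted(range(len(gene_names)), key=lambda i: (-scores[i], gene_names[i]))
    return GenePanel([gene_names[i] for i in order[:k]], kind=kind)


def select_hvg(normalized: np.ndarray, gene_names: Sequence[str], k: int = 2000) -> GenePanel:
    """Top-k highly variable genes by dispersion (variance/mean) of the
    log-normalized values; ties broken by gene name. Constant and silent
    genes score zero and rank last."""
    normalized = np.asarray(normalized, dtype=float)
    mean = normalized.mean(axis=0)
    var = normalized.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    return _ranked_panel(dispersion, gene_names, k, "hvg")


def select_target_genes(normalized: np.ndarray, gene_names: Sequence[str], k: int = 300) -> GenePanel:
    """Top-k genes by mean log-normalized expression across all spots."""
    normalized = np.asarray(normalized, dtype=float)
    return _ranked_panel(normalized.mean(axis=0), gene_names, k, "target")


def subset_to_panel(normalized: np.ndarray, gene_names: Sequence[str], panel: GenePanel) -> NormalizedExpression:
    index = {g: i for i, g in enumerate(gene_names)}
    missing = [g for g in panel.names if g not in index]
    if missing:
        raise ValueError(f"panel genes absent from matrix: {missing[:5]}")
    cols = [index[g] for g in panel.names]
    return NormalizedExpression(np.asarray(normalized)[:, cols], panel)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_counts(counts_path: Path) -> np.ndarray:
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        m = mmread(counts_path)
        return np.asarray(m.todense() if issparse(m) else m)
    return pd.read_csv(counts_path, sep=None, engine="python", header=None).to_numpy()


def _read_column(path: Path) -> list:
    return pd.read_csv(path, sep="\t", header=None)[0].astype(str).tolist()


def _read_coords(path: Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", header=None)
    # accept either "x y" or "barcode x y"
    numeric = df.select_dtypes(include=[np.number])
    return numeric.to_numpy(dtype=float)[:, -2:]


def load_slice(
    counts_path,
    genes_path,
    coords_path,
    image_source,
    patch_size: int = 40,
    slice_id: str | None = None,
) -> SpotSlice:
    """Assemble a :class:`SpotSlice` from a counts matrix, gene list, spot
    coordinates and one full-slice image; patches are center-cropped at each
    coordinate."""
    counts = _read_counts(Path(counts_path))
    gene_names = _read_column(Path(genes_path))
    coords = _read_coords(Path(coords_path))
    if coords.shape[0] != counts.shape[0]:
        raise ValueError(
            f"{coords_path} has {coords.shape[0]} coordinate rows but "
            f"{counts_path} has {counts.shape[0]} count rows"
        )
    if len(gene_names) != counts.shape[1]:
        raise ValueError(
            f"{genes_path} lists {len(gene_names)} genes but {counts_path} "
            f"has {counts.shape[1]} columns"
        )
    image = np.asarray(Image.open(image_source).convert("RGB"))
    h, w = image.shape[:2]
    outside = [
        i for i, (x, y) in enumerate(coords)
        if not (0 <= x < w and 0 <= y < h)
    ]
    if outside:
        raise ValueError(f"coordinates outside {w}x{h} image bounds for spots {outside}")
    patches = np.stack([center_crop(image, (x, y), patch_size) for x, y in coords])
    return SpotSlice(
        slice_id=slice_id or Path(counts_path).stem,
        patches=patches,
        counts=counts.astype(np.int64),
        gene_names=gene_names,
        coords=coords,
    )


def write_slice_dir(slc: SpotSlice, out_dir) -> Path:
    """Serialize a slice to ``{counts.mtx, genes.tsv, barcodes.tsv,
    coords.tsv, patches/NNNN.png, manifest.json}``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mmwrite(out_dir / "counts.mtx", csr_matrix(slc.counts))
    pd.Series(slc.gene_names).to_csv(out_dir / "genes.tsv", sep="\t", header=False, index=False)
    barcodes = [f"spot-{i:04d}" for i in range(slc.n)]
    pd.Series(barcodes).to_csv(out_dir / "barcodes.tsv", sep="\t", header=False, index=False)
    pd.DataFrame({"barcode": barcodes, "x": slc.coords[:, 0], "y": slc.coords[:, 1]}).to_csv(
        out_dir / "coords.tsv", sep="\t", header=False, index=False
    )
    patch_dir = out_dir / "patches"
    patch_dir.mkdir(exist_ok=True)
    for i, patch in enumerate(slc.patches):
        Image.fromarray(patch).save(patch_dir / f"{i:04d}.png")
    manifest = {
        "slice_id": slc.slice_id,
        "n_spots": int(slc.n),
        "n_genes": len(slc.gene_names),
        "patch_size": [int(slc.patches.shape[1]), int(slc.patches.shape[2])],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir


def read_slice_dir(slice_dir) -> SpotSlice:
    """Load a slice from the directory layout written by write_slice_dir."""
    slice_dir = Path(slice_dir)
    manifest = json.loads((slice_dir / "manifest.json").read_text())
    counts = _read_counts(slice_dir / "counts.mtx")
    gene_names = _read_column(slice_dir / "genes.tsv")
    coords = _read_coords(slice_dir / "coords.tsv")
    n = manifest["n_spots"]
    if counts.shape[0] != n:
        raise ValueError(f"{slice_dir/'counts.mtx'} has {counts.shape[0]} rows, manifest says {n}")
    patches = np.stack([
        np.asarray(Image.open(slice_dir / "patches" / f"{i:04d}.png").convert("RGB"))
        for i in range(n)
    ])
    return SpotSlice(
        slice_id=manifest["slice_id"],
        patches=patches,
        counts=counts.astype(np.int64),
        gene_names=gene_names,
        coords=coords,
    )
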