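"""Attention heatmaps and latent-space export."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import PatchRecord
from .schema import CLASS_NAMES


class VisualizeError(ValueError):
    pass


def attention_raster(
    slide_shape: tuple[int, int],
    patch_records: list[PatchRecord],
    attention: np.ndarray,
    class_index: int,
) -> np.ndarray:
    """Paint per-patch attention into patch footprints, min-max normalized
    to [0, 1] per slide.  Background (no patch) stays NaN."""
    if attention.shape[1] != len(patch_records):
        raise VisualizeError(
            f"attention has {attention.shape[1]} columns but {len(patch_records)} patches"
        )
    weights = np.asarray(attention[class_index], dtype=float)
    lo, hi = weights.min(), weights.max()
    norm = np.zeros_like(weights) if hi - lo < 1e-12 else (weights - lo) / (hi - lo)
    canvas = np.full(slide_shape, np.nan)
    for rec, value in zip(patch_records, norm):
        canvas[rec.y : rec.y + rec.patch_size, rec.x : rec.x + rec.patch_size] = value
    return canvas


def render_heatmap(
    thumbnail: np.ndarray,
    patch_records: list[PatchRecord],
    attention: np.ndarray,
    class_index: int,
    alpha: float = 0.5,
) -> np.ndarray:
    """Alpha-blend the attention raster over a slide thumbnail.

    The thumbnail must be at the patch extraction scale (same coordinates as
    the patch records).  Background pixels are left untouched; normalization
    is monotone, so the weight ranking is conserved.
    """
    from matplotlib import colormaps

    canvas = attention_raster(thumbnail.shape[:2], patch_records, attention, class_index)
    rgb = thumbnail.astype(np.float64) / 255.0 if thumbnail.dtype == np.uint8 else thumbnail.copy()
    colored = colormaps["inferno"](np.nan_to_num(canvas))[..., :3]
    inside = ~np.isnan(canvas)
    rgb[inside] = (1 - alpha) * rgb[inside] + alpha * colored[inside]
    return rgb


def export_latent(
    embeddings: np.ndarray,
    patch_probs: np.ndarray,
    threshold: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Filter confident patches and project their embeddings to 2-D.

    Keeps only patches whose maximum class probability exceeds the threshold,
    tags each with its predicted class, and computes seeded t-SNE coordinates
    (exact method, deterministic given the seed).
    """
    from sklearn.manifold import TSNE

    embeddings = np.asarray(embeddings, dtype=float)
    patch_probs = np.asarray(patch_probs, dtype=float)
    if len(embeddings) != len(patch_probs):
        raise VisualizeError("embeddings and probabilities are misaligned")
    top = patch_probs.max(axis=1)
    keep = top > threshold
    frame = pd.DataFrame(
        {
            "predicted_class": [CLASS_NAMES[i] for i in patch_probs[keep].argmax(axis=1)],
            "confidence": top[keep],
        }
    )
    n = int(keep.sum())
    if n == 0:
        frame["x"] = pd.Series(dtype=float)
        frame["y"] = pd.Series(dtype=float)
        return frame
    if n < 3:
        coords = np.zeros((n, 2))
    else:
        tsne = TSNE(
            n_components=2,
            perplexity=min(30.0, (n - 1) / 3.0),
            random_state=seed,
            init="pca",
            method="exact" if n < 200 else "barnes_hut",
        )
        coords = tsne.fit_transform(embeddings[keep])
    frame["x"] = coords[:, 0]
    frame["y"] = coords[:, 1]
    return frame
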