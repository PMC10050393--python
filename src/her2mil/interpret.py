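"""Interpretability artefacts: attention and intensity heatmaps on the tile
grid, their discordance mask, and 2-D projection of tile embeddings.

The attention heatmap shows where the MIL classifier looked; the patchwise
mean-DAB heatmap shows where the stain is.  Cells where the two disagree —
high attention on weak staining or vice versa — are exactly the regions
where the model is using morphology rather than intensity, so the package
exposes that disagreement as a computable mask instead of leaving it to
visual inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import EmptyBagError, TileBag
from .stain import RUIFROK_HDAB, StainProfile, mean_tile_dab

#: sentinel for grid cells whose tile was discarded (distinct from low values)
MISSING = np.nan


@dataclass
class Heatmap:
    """Per-tile values on the R x C grid, min–max normalised to [0, 1].

    ``constant`` flags a degenerate input (zero range): all present cells are
    set to 0 rather than dividing by zero.  Missing (discarded) tiles hold
    NaN so they are never confused with genuinely low values.
    """

    values: np.ndarray
    constant: bool = False

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape

    def present_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)


def _normalise_to_grid(values: np.ndarray, coords, grid_shape) -> Heatmap:
    grid = np.full(grid_shape, MISSING)
    seen = set()
    for v, (r, c) in zip(values, coords):
        if (r, c) in seen:
            raise ValueError(f"duplicate grid cell {(r, c)}")
        if not (0 <= r < grid_shape[0] and 0 <= c < grid_shape[1]):
            raise ValueError(f"grid cell {(r, c)} outside grid {grid_shape}")
        seen.add((r, c))
        grid[r, c] = v
    lo = np.nanmin(grid)
    hi = np.nanmax(grid)
    if hi - lo < 1e-12:
        out = np.where(np.isnan(grid), MISSING, 0.0)
        return Heatmap(out, constant=True)
    return Heatmap((grid - lo) / (hi - lo), constant=False)


def attention_heatmap(weights, coords, grid_shape) -> Heatmap:
    """Place attention weights on the tile grid and min–max normalise.

    ``weights`` align with ``coords`` (grid_row, grid_col) pairs, i.e. the
    bag's stable tile order; placement keys on coordinates so any permuted
    bag yields the identical map.
    """
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(coords):
        raise ValueError("weights and coords length mismatch")
    return _normalise_to_grid(weights, coords, grid_shape)


def intensity_heatmap(bag: TileBag, profile: StainProfile = RUIFROK_HDAB) -> Heatmap:
    """Patchwise mean DAB concentration on the tile grid, normalised."""
    if len(bag) == 0:
        raise EmptyBagError(f"spot {bag.spot_id!r}: empty bag")
    means = [mean_tile_dab(t, profile) for t in bag.tiles]
    return _normalise_to_grid(np.array(means), bag.coords, bag.grid_shape)


def discordance_mask(attention: Heatmap, intensity: Heatmap,
                     delta: float = 0.5) -> np.ndarray:
    """True where |attention − intensity| > delta (both cells present)."""
    if attention.grid_shape != intensity.grid_shape:
        raise ValueError(
            f"grid mismatch {attention.grid_shape} vs {intensity.grid_shape}"
        )
    both = attention.present_mask() & intensity.present_mask()
    diff = np.abs(np.where(both, attention.values - intensity.values, 0.0))
    return (diff > delta) & both


def embed_2d(embeddings: np.ndarray, seed: int = 0,
             perplexity: float = 30.0) -> np.ndarray:
    """t-SNE projection of tile embeddings to 2-D (deterministic per seed).

    Perplexity is capped below the point count as t-SNE requires; this is
    plumbing around scikit-learn's implementation, not a re-derivation.
    """
    from sklearn.manifold import TSNE

    emb = np.asarray(embeddings, dtype=float)
    if emb.ndim != 2 or emb.shape[0] < 5:
        raise ValueError("need at least 5 embedding vectors")
    perp = min(perplexity, (emb.shape[0] - 1) / 3.0)
    tsne = TSNE(n_components=2, perplexity=perp, random_state=seed, init="pca")
    return tsne.fit_transform(emb)


def render_panel(attention: Heatmap, intensity: Heatmap, out_path=None,
                 spot_image=None):
    """Side-by-side attention vs mean-intensity panel (optionally with the
    spot image); returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_axes = 3 if spot_image is not None else 2
    fig, axes = plt.subplots(1, n_axes, figsize=(4 * n_axes, 4))
    col = 0
    if spot_image is not None:
        axes[col].imshow(spot_image.pixels)
        axes[col].set_title(f"spot {spot_image.spot_id}")
        axes[col].axis("off")
        col += 1
    for ax, hm, title in (
        (axes[col], attention, "attention"),
        (axes[col + 1], intensity, "mean DAB intensity"),
    ):
        im = ax.imshow(hm.values, vmin=0, vmax=1, cmap="inferno")
        ax.set_title(title + (" (constant)" if hm.constant else ""))
        ax.axis("off")
        fig.colorbar(im, ax=ax, fraction=0.046)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
    return fig
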