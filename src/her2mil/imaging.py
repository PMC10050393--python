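"""Spot-image I/O, tiling into bags, empty-tile filtering and downscaling.

A tissue-microarray (TMA) *spot* is a single square RGB image of one stained
tissue core.  For multiple-instance learning the spot is cut into a regular
grid of non-overlapping square tiles; tiles containing no tissue (essentially
white background) are discarded before bagging.  For the whole-image
classifier the spot is instead downscaled to a fixed side with area-averaging
resampling.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

#: default tile side in pixels for full-resolution spots
TILE_SIZE = 224

#: a tile is "empty" if fewer than this fraction of its pixels carry tissue
DEFAULT_TISSUE_FRACTION = 0.10
#: a pixel carries tissue if its summed-over-channels optical density exceeds this
DEFAULT_OD_THRESHOLD = 0.15


class DimensionError(ValueError):
    """Image dimensions incompatible with the requested operation."""


class EmptyBagError(ValueError):
    """A tile bag ended up with no tiles (all discarded or never created)."""


@dataclass
class SpotImage:
    """One TMA spot: an H x W x 3 array of 8-bit RGB intensities."""

    pixels: np.ndarray
    spot_id: str = ""
    pixel_size_hint: float | None = None  # microns per pixel, informational

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise DimensionError(
                f"spot {self.spot_id!r}: expected H x W x 3 RGB array, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise DimensionError(f"spot {self.spot_id!r}: degenerate image {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError(
                    f"spot {self.spot_id!r}: channel values outside [0, 255]"
                )
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class Tile:
    """A square patch cut from a spot, addressed by its 0-based grid cell."""

    pixels: np.ndarray
    grid_row: int
    grid_col: int
    spot_id: str = ""

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass
class TileBag:
    """The MIL unit: the ordered (row-major) tiles of one spot.

    Tile order is stable so attention weights can be mapped back onto the
    grid reproducibly.  ``grid_shape`` is the full candidate grid before any
    empty tiles were discarded.
    """

    tiles: list[Tile]
    spot_id: str = ""
    grid_shape: tuple[int, int] = (0, 0)
    label: object | None = None
    tile_size: int = TILE_SIZE
    discarded: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tiles)

    @property
    def coords(self) -> list[tuple[int, int]]:
        return [(t.grid_row, t.grid_col) for t in self.tiles]

    def pixel_stack(self) -> np.ndarray:
        """All tiles as one n x s x s x 3 uint8 array."""
        return np.stack([t.pixels for t in self.tiles])


def is_empty_tile(
    tile: Tile | np.ndarray,
    od_threshold: float = DEFAULT_OD_THRESHOLD,
    tissue_fraction: float = DEFAULT_TISSUE_FRACTION,
) -> bool:
    """Decide whether a tile contains (almost) no tissue.

    A pixel is "tissue" when its optical density summed over RGB channels
    exceeds ``od_threshold`` (the same transparency cut Macenko estimation
    uses); a tile is empty when fewer than ``tissue_fraction`` of its pixels
    are tissue.  All-black tiles are *kept* — they are scanner artefacts that
    should reach quality control, not vanish — but logged.
    """
    if not od_threshold > 0:
        raise ValueError("od_threshold must be positive")
    if not 0 < tissue_fraction < 1:
        raise ValueError("tissue_fraction must lie in (0, 1)")
    px = tile.pixels if isinstance(tile, Tile) else np.asarray(tile)
    od_sum = -np.log10(np.maximum(px.astype(np.float64), 1.0) / 255.0).sum(axis=2)
    frac = float(np.mean(od_sum > od_threshold))
    if frac > 0.99 and px.mean() < 5:
        logger.warning("near-black tile flagged as possible scanner artefact")
    return frac < tissue_fraction


def tile_image(
    image: SpotImage,
    tile_size: int = TILE_SIZE,
    discard_empty: bool = False,
    od_threshold: float = DEFAULT_OD_THRESHOLD,
    tissue_fraction: float = DEFAULT_TISSUE_FRACTION,
) -> TileBag:
    """Cut a spot into non-overlapping ``tile_size`` tiles, row-major.

    Remainder pixels at the right/bottom edges are dropped (never padded).
    With ``discard_empty`` the background-only tiles are removed from the bag
    but their grid cells are remembered in ``bag.discarded``.
    """
    if tile_size < 1:
        raise ValueError("tile_size must be positive")
    h, w = image.height, image.width
    if h < tile_size or w < tile_size:
        raise DimensionError(
            f"spot {image.spot_id!r}: image {h}x{w} smaller than tile size {tile_size}"
        )
    n_rows, n_cols = h // tile_size, w // tile_size
    tiles: list[Tile] = []
    discarded: list[tuple[int, int]] = []
    for r in range(n_rows):
        for c in range(n_cols):
            px = image.pixels[
                r * tile_size : (r + 1) * tile_size,
                c * tile_size : (c + 1) * tile_size,
            ]
            t = Tile(px, r, c, image.spot_id)
            if discard_empty and is_empty_tile(t, od_threshold, tissue_fraction):
                discarded.append((r, c))
            else:
                tiles.append(t)
    if not tiles:
        raise EmptyBagError(
            f"spot {image.spot_id!r}: all {n_rows * n_cols} tiles empty"
        )
    return TileBag(
        tiles=tiles,
        spot_id=image.spot_id,
        grid_shape=(n_rows, n_cols),
        tile_size=tile_size,
        discarded=discarded,
    )


def downscale(
    image: SpotImage, target_side: int = 1024, method: str = "area"
) -> tuple[SpotImage, float]:
    """Downscale a square spot to ``target_side`` and report the scale factor.

    Area-averaging resampling by default (``method="bilinear"`` as an
    alternative).  Returns ``(image, factor)`` where ``factor`` is the linear
    ratio of input to output side, e.g. 5468 -> 1024 gives 5.34.
    """
    if image.height != image.width:
        raise DimensionError(
            f"spot {image.spot_id!r}: downscale expects a square image, "
            f"got {image.height}x{image.width}"
        )
    if target_side < 1:
        raise ValueError("target_side must be positive")
    factor = image.height / target_side
    if image.height == target_side:
        return SpotImage(image.pixels.copy(), image.spot_id, image.pixel_size_hint), factor
    resample = {"area": Image.BOX, "bilinear": Image.BILINEAR}[method]
    out = Image.fromarray(image.pixels).resize((target_side, target_side), resample)
    hint = None
    if image.pixel_size_hint is not None:
        hint = image.pixel_size_hint * factor
    return SpotImage(np.asarray(out), image.spot_id, hint), factor


# ---------------------------------------------------------------------------
# I/O


def read_spot(path: str | os.PathLike, spot_id: str | None = None) -> SpotImage:
    """Read a JPEG/PNG/TIFF spot image as RGB."""
    with Image.open(path) as im:
        px = np.asarray(im.convert("RGB"))
    if spot_id is None:
        spot_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return SpotImage(px, spot_id)


def write_spot(image: SpotImage, path: str | os.PathLike) -> None:
    Image.fromarray(image.pixels).save(path)


def save_bag(bag: TileBag, out_dir: str | os.PathLike) -> None:
    """Persist a bag as tile PNGs plus a CSV manifest (spot_id, grid cell)."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for t in bag.tiles:
        name = f"{bag.spot_id}_r{t.grid_row:03d}_c{t.grid_col:03d}.png"
        Image.fromarray(t.pixels).save(os.path.join(out_dir, name))
        rows.append(
            {"spot_id": bag.spot_id, "grid_row": t.grid_row, "grid_col": t.grid_col,
             "file": name}
        )
    manifest = pd.DataFrame(rows)
    manifest.attrs["grid_shape"] = bag.grid_shape
    header = pd.DataFrame(
        [{"spot_id": bag.spot_id, "grid_rows": bag.grid_shape[0],
          "grid_cols": bag.grid_shape[1], "tile_size": bag.tile_size}]
    )
    header.to_csv(os.path.join(out_dir, "bag_info.csv"), index=False)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)


def load_bag(bag_dir: str | os.PathLike) -> TileBag:
    manifest = pd.read_csv(os.path.join(bag_dir, "manifest.csv"))
    info = pd.read_csv(os.path.join(bag_dir, "bag_info.csv")).iloc[0]
    tiles = []
    for _, row in manifest.iterrows():
        with Image.open(os.path.join(bag_dir, row["file"])) as im:
            px = np.asarray(im.convert("RGB"))
        tiles.append(Tile(px, int(row["grid_row"]), int(row["grid_col"]),
                          str(row["spot_id"])))
    if not tiles:
        raise EmptyBagError(f"bag directory {bag_dir!r} holds no tiles")
    return TileBag(
        tiles=tiles,
        spot_id=str(info["spot_id"]),
        grid_shape=(int(info["grid_rows"]), int(info["grid_cols"])),
        tile_size=int(info["tile_size"]),
    )
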