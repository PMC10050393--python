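"""H-DAB stain mathematics: optical density, colour deconvolution, Macenko
estimation and cross-cohort stain matching.

Stained tissue attenuates light according to Beer–Lambert: the optical
density ``OD = -log10(I / I0)`` of a pixel is (to first order) a linear
mixture of per-stain unit "colour" vectors weighted by stain concentrations.
Colour deconvolution inverts that 3x3 linear system to recover per-pixel
concentrations of hematoxylin (blue nuclear counterstain), DAB (brown HER2
chromogen) and a residual channel.  The Macenko procedure estimates the two
dominant stain vectors of an image from the principal plane of its OD cloud,
which lets one cohort's staining be re-expressed in another cohort's colours.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .imaging import SpotImage, Tile


class SingularProfileError(ValueError):
    """Stain matrix is singular or numerically rank deficient."""


class DegenerateImageError(ValueError):
    """Image lacks enough stained tissue for stain estimation."""


@dataclass
class ODImage:
    """Per-channel optical density of an RGB image (non-negative, finite)."""

    values: np.ndarray
    i0: float = 255.0


@dataclass
class StainProfile:
    """A 3x3 stain matrix (rows: hematoxylin, DAB, residual unit OD vectors)
    plus robust maximum concentrations of the two true stains."""

    stain_matrix: np.ndarray
    max_concentrations: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 1.0])
    )

    def __post_init__(self) -> None:
        m = np.asarray(self.stain_matrix, dtype=np.float64)
        if m.shape != (3, 3):
            raise ValueError(f"stain matrix must be 3x3, got {m.shape}")
        norms = np.linalg.norm(m, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError(f"stain matrix rows must be unit norm, norms={norms}")
        if abs(np.linalg.det(m)) < 1e-8:
            raise SingularProfileError("stain matrix is singular")
        self.stain_matrix = m
        self.max_concentrations = np.asarray(self.max_concentrations, dtype=np.float64)
        if self.max_concentrations.shape != (2,) or np.any(self.max_concentrations <= 0):
            raise ValueError("max_concentrations must be two positive reals")

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "stain_matrix": self.stain_matrix.tolist(),
                    "max_concentrations": self.max_concentrations.tolist(),
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "StainProfile":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.array(d["stain_matrix"]), np.array(d["max_concentrations"]))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _hdab_default() -> StainProfile:
    # Ruifrok–Johnston published H-DAB vectors (ImageJ "H DAB" preset).
    h = _unit(np.array([0.650, 0.704, 0.286]))
    dab = _unit(np.array([0.268, 0.570, 0.776]))
    res = _unit(np.cross(h, dab))
    return StainProfile(np.stack([h, dab, res]), np.array([1.0, 1.0]))


#: fixed fallback profile used when Macenko estimation fails or is disabled
RUIFROK_HDAB: StainProfile = _hdab_default()


def rgb_to_od(image: SpotImage | np.ndarray, i0: float = 255.0) -> ODImage:
    """Beer–Lambert transform, base-10 log; intensities clipped to >= 1."""
    if i0 <= 0:
        raise ValueError("i0 must be positive")
    px = image.pixels if isinstance(image, SpotImage) else np.asarray(image)
    od = -np.log10(np.maximum(px.astype(np.float64), 1.0) / i0)
    return ODImage(od, i0)


def od_to_rgb(od: ODImage | np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Invert the Beer–Lambert transform; output clipped to [0, 255] uint8."""
    if isinstance(od, ODImage):
        values, i0 = od.values, od.i0
    else:
        values = np.asarray(od)
    rgb = i0 * np.power(10.0, -np.maximum(values, 0.0))
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


@dataclass
class ConcentrationMap:
    """Per-pixel stain concentrations, channel order matching the profile rows."""

    values: np.ndarray
    profile: StainProfile


def deconvolve(od: ODImage | np.ndarray, profile: StainProfile) -> ConcentrationMap:
    """Solve ``c @ M = od`` per pixel for the concentration vector ``c``.

    Negative concentrations are retained — they are informative about model
    misfit; clip explicitly downstream if needed.  Falls back to least
    squares when the profile is ill-conditioned.
    """
    values = od.values if isinstance(od, ODImage) else np.asarray(od, dtype=np.float64)
    m = profile.stain_matrix
    flat = values.reshape(-1, 3)
    if np.linalg.cond(m) < 1e8:
        conc = np.linalg.solve(m.T, flat.T).T
    else:
        conc = np.linalg.lstsq(m.T, flat.T, rcond=None)[0].T
    return ConcentrationMap(conc.reshape(values.shape), profile)


def _convolve(values: np.ndarray, profile: StainProfile) -> np.ndarray:
    flat = values.reshape(-1, 3) @ profile.stain_matrix
    return flat.reshape(values.shape)


def convolve(conc: ConcentrationMap | np.ndarray, profile: StainProfile) -> np.ndarray:
    """Recompose optical density from concentrations: ``od = c @ M``."""
    values = conc.values if isinstance(conc, ConcentrationMap) else np.asarray(conc)
    return _convolve(values, profile)


def macenko_estimate(
    image: SpotImage | np.ndarray,
    alpha_percentile: float = 1.0,
    beta: float = 0.15,
    min_tissue_pixels: int = 100,
) -> StainProfile:
    """Estimate the two dominant stain vectors from the OD cloud.

    Transparent pixels (summed OD below ``beta``) are removed, the principal
    plane of the remaining OD vectors is found, and the extreme-angle
    (``alpha`` / ``100 - alpha`` percentile) directions in that plane are
    taken as the stain vectors.  The row whose blue-channel OD is *smaller*
    is labelled hematoxylin (a blue stain transmits blue light, so its blue
    absorbance is the lower one; DAB absorbs blue strongly).  The residual
    row is the unit cross product.  Robust (99th percentile) concentrations
    of the two stains are stored for Macenko-style normalisation.
    """
    od = rgb_to_od(image).values.reshape(-1, 3)
    tissue = od[od.sum(axis=1) > beta]
    if tissue.shape[0] < min_tissue_pixels:
        raise DegenerateImageError(
            f"only {tissue.shape[0]} tissue pixels above beta={beta}; "
            f"need >= {min_tissue_pixels}"
        )
    # principal plane of the OD cloud
    cov = np.cov(tissue, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-2] < 1e-6 * max(evals[-1], 1e-12) or evals[-1] <= 0:
        raise DegenerateImageError(
            "OD cloud is rank deficient (single stain?); "
            "fall back to a fixed profile such as RUIFROK_HDAB"
        )
    basis = evecs[:, -2:]  # 3x2, columns span the plane
    # orient the basis so projections are predominantly positive
    proj = tissue @ basis
    for j in range(2):
        if proj[:, j].sum() < 0:
            basis[:, j] = -basis[:, j]
            proj[:, j] = -proj[:, j]
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo = np.percentile(phi, alpha_percentile)
    hi = np.percentile(phi, 100.0 - alpha_percentile)
    v1 = basis @ np.array([np.cos(lo), np.sin(lo)])
    v2 = basis @ np.array([np.cos(hi), np.sin(hi)])
    # stain vectors are absorbances: flip to the non-negative orthant side
    if v1.sum() < 0:
        v1 = -v1
    if v2.sum() < 0:
        v2 = -v2
    v1, v2 = _unit(v1), _unit(v2)
    # 8-bit quantisation can leave a spurious second eigenvalue, so rank
    # deficiency is also diagnosed from the extreme vectors themselves
    if abs(float(v1 @ v2)) > np.cos(np.deg2rad(1.0)):
        raise DegenerateImageError(
            "extreme-angle stain vectors nearly collinear (single stain?); "
            "fall back to a fixed profile such as RUIFROK_HDAB"
        )
    # hematoxylin = smaller blue-channel OD
    hema, dab = (v1, v2) if v1[2] <= v2[2] else (v2, v1)
    res = _unit(np.cross(hema, dab))
    matrix = np.stack([hema, dab, res])
    conc = deconvolve(tissue.reshape(-1, 1, 3), StainProfile(matrix)).values.reshape(-1, 3)
    maxima = np.percentile(np.maximum(conc[:, :2], 0.0), 99, axis=0)
    maxima = np.maximum(maxima, 1e-6)
    return StainProfile(matrix, maxima)


def normalize_stains(
    image: SpotImage, source: StainProfile, target: StainProfile
) -> SpotImage:
    """Re-express a spot stained under ``source`` in ``target`` colours.

    Deconvolve with the source profile, rescale the hematoxylin and DAB
    concentrations by the ratio of robust maxima, reconvolve with the target
    stain matrix, and map back to RGB (clipped to [0, 255]).  White (OD 0)
    is a fixed point.
    """
    od = rgb_to_od(image)
    conc = deconvolve(od, source).values.copy()
    scale = target.max_concentrations / source.max_concentrations
    conc[..., 0] *= scale[0]
    conc[..., 1] *= scale[1]
    new_od = _convolve(conc, target)
    return SpotImage(od_to_rgb(new_od, od.i0), image.spot_id, image.pixel_size_hint)


def mean_tile_dab(tile: Tile | np.ndarray, profile: StainProfile) -> float:
    """Mean DAB concentration over all pixels of a tile."""
    px = tile.pixels if isinstance(tile, Tile) else np.asarray(tile)
    conc = deconvolve(rgb_to_od(px), profile)
    return float(conc.values[..., 1].mean())
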