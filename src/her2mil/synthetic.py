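"""Synthetic IHC spot generator: labelled cohorts with controllable
intensity-coded and morphology-coded signal.

Each spot is a circular tissue disc on a white background.  Cell nuclei are
rendered as hematoxylin-toned blobs; HER2 positivity is rendered as DAB
staining with two components that mirror how pathologists grade it:

* *intensity* — the peak DAB optical density and a diffuse "sheet" of
  confluent membranous staining in a hotspot region, both increasing with
  IHC score;
* *morphology* — membranous rings around nuclei whose rendered arc fraction
  ("membrane completeness") increases with score: complete thin rings in
  strongly positive tissue, short fragmented arcs in equivocal/negative
  tissue.

Two regimes control what carries the HER2-status signal in score-2 spots:

* ``intensity_coded`` — equivocal-positive spots are rendered with higher
  peak DAB than equivocal-negative ones, so a staining-intensity feature
  suffices to resolve status;
* ``morphology_only`` — both score-2 statuses draw the peak DAB from the
  *same* distribution and the per-cell DAB mass is equalised by
  construction (fragmented membranes are rendered darker and thicker so
  arc-length x thickness x density is constant); only the membranous
  pattern distinguishes the classes, so any model beating chance must use
  morphology.

The composite is rendered through Beer–Lambert with the fixed H-DAB stain
profile, plus per-channel Gaussian OD noise and mild vignetting so Macenko
stain estimation is exercised non-trivially.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .evaluation import SpotLabel, ish_call, score_to_status
from .imaging import SpotImage
from .stain import RUIFROK_HDAB, StainProfile, od_to_rgb

REGIMES = ("intensity_coded", "morphology_only")

#: per-score rendering presets: peak DAB OD, membrane completeness,
#: fraction of cells stained, diffuse (confluent-sheet) fraction of peak OD
SCORE_PRESETS: dict[int, dict[str, float]] = {
    0: dict(dab_peak_od=0.02, membrane_completeness=0.10,
            stained_fraction=0.05, diffuse_fraction=0.00),
    1: dict(dab_peak_od=0.35, membrane_completeness=0.35,
            stained_fraction=0.50, diffuse_fraction=0.35),
    2: dict(dab_peak_od=0.72, membrane_completeness=0.55,
            stained_fraction=0.80, diffuse_fraction=0.55),
    3: dict(dab_peak_od=1.15, membrane_completeness=0.95,
            stained_fraction=0.95, diffuse_fraction=0.85),
}

#: score-2 status-dependent overrides in the intensity-coded regime
INTENSITY_CODED_SCORE2 = {
    0: dict(dab_peak_od=0.55, membrane_completeness=0.45, diffuse_fraction=0.50),
    1: dict(dab_peak_od=0.90, membrane_completeness=0.80, diffuse_fraction=0.65),
}

#: score-2 status-dependent overrides in the morphology-only regime:
#: identical intensity parameters, different membranous pattern
MORPHOLOGY_ONLY_SCORE2 = {
    0: dict(dab_peak_od=0.72, membrane_completeness=0.30, diffuse_fraction=0.55),
    1: dict(dab_peak_od=0.72, membrane_completeness=0.90, diffuse_fraction=0.55),
}

#: reference completeness at which ring OD/thickness are the nominal values;
#: the mass-equalisation in morphology_only is relative to this
_COMPLETENESS_REF = 0.90

#: default cohort score mix follows the one fully printed distribution
#: (an external 653-sample cohort with 416/186/14/37 spots of scores 0-3)
EXTERNAL_COHORT_PROPORTIONS = (416 / 653, 186 / 653, 14 / 653, 37 / 653)


@dataclass
class SyntheticSpotSpec:
    """Parameters of one generated spot; fields left ``None`` are filled
    from the per-score presets for the chosen regime."""

    score: int
    status: int | None = None
    regime: str = "intensity_coded"
    side_px: int = 1344
    tile_size: int = 32
    cell_density: float = 3.0  # expected cells per (tile_size^2) of tissue
    membrane_completeness: float | None = None
    dab_peak_od: float | None = None
    stained_fraction: float | None = None
    diffuse_fraction: float | None = None
    noise_sd: float = 0.02
    vignette_od: float = 0.04
    intensity_jitter: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.score not in (0, 1, 2, 3):
            raise ValueError(f"invalid score {self.score!r}")
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        if self.side_px % self.tile_size != 0:
            raise ValueError(
                f"side_px {self.side_px} must be a multiple of tile_size "
                f"{self.tile_size}"
            )
        if self.status is None:
            if self.score == 2:
                raise ValueError("score-2 spots need an explicit status")
            self.status = score_to_status(self.score)
        if self.score != 2 and self.status != score_to_status(self.score):
            raise ValueError(
                f"status {self.status} inconsistent with score {self.score}"
            )
        preset = dict(SCORE_PRESETS[self.score])
        if self.score == 2:
            table = (INTENSITY_CODED_SCORE2 if self.regime == "intensity_coded"
                     else MORPHOLOGY_ONLY_SCORE2)
            preset.update(table[self.status])
        for key, value in preset.items():
            if getattr(self, key) is None:
                setattr(self, key, value)
        if not 0.0 <= self.membrane_completeness <= 1.0:
            raise ValueError("membrane_completeness must lie in [0, 1]")


def _stamp(field_arr: np.ndarray, cy: float, cx: float, patch: np.ndarray,
           py: int, px: int) -> None:
    """Add a small patch centred at (cy, cx) into a full-size field."""
    s = field_arr.shape[0]
    y0, x0 = int(round(cy)) - py // 2, int(round(cx)) - px // 2
    ys, xs = max(y0, 0), max(x0, 0)
    ye, xe = min(y0 + py, s), min(x0 + px, s)
    if ye <= ys or xe <= xs:
        return
    field_arr[ys:ye, xs:xe] += patch[ys - y0 : ye - y0, xs - x0 : xe - x0]


def generate_spot(spec: SyntheticSpotSpec,
                  rng: np.random.Generator | None = None,
                  profile: StainProfile = RUIFROK_HDAB
                  ) -> tuple[SpotImage, SpotLabel]:
    """Render one spot and its internally consistent ground-truth label."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    s = spec.side_px
    centre = s / 2.0
    radius = 0.45 * s * (1.0 + rng.uniform(-0.03, 0.03))
    yy, xx = np.mgrid[0:s, 0:s]
    rr = np.hypot(yy - centre, xx - centre)
    tissue = rr <= radius

    h_field = np.zeros((s, s))
    dab_field = np.zeros((s, s))

    # faint stromal counterstain with low-frequency texture inside the disc
    texture = gaussian_filter(rng.standard_normal((s, s)), sigma=s / 24.0)
    texture = texture / max(np.abs(texture).max(), 1e-9)
    h_field[tissue] += 0.10 + 0.04 * texture[tissue]

    # cell nuclei and membranes
    r_n = max(2.5, s / 64.0)
    n_cells = rng.poisson(spec.cell_density * np.pi * radius**2 / spec.tile_size**2)
    theta = rng.uniform(0, 2 * np.pi, n_cells)
    rad = radius * 0.97 * np.sqrt(rng.uniform(0, 1, n_cells))
    cys = centre + rad * np.sin(theta)
    cxs = centre + rad * np.cos(theta)
    stained = rng.uniform(size=n_cells) < spec.stained_fraction

    # mass equalisation: fragmented membranes are rendered thicker (same
    # peak OD) so the DAB mass per cell is independent of completeness —
    # keeping the OD identical also keeps 8-bit quantisation effects equal
    # across morphologies
    c = max(spec.membrane_completeness, 0.05)
    comp_factor = _COMPLETENESS_REF / c if c < _COMPLETENESS_REF else 1.0
    ring_od = spec.dab_peak_od
    thick = (r_n / 2.2) * comp_factor
    r_m = 1.6 * r_n

    pw = int(np.ceil(2 * (r_m + thick) + 3))
    pc = pw / 2.0
    pyy, pxx = np.mgrid[0:pw, 0:pw]
    pdist = np.hypot(pyy - pc, pxx - pc)
    pang = np.arctan2(pyy - pc, pxx - pc)  # [-pi, pi]
    nucleus_patch_base = np.exp(-(pdist**2) / (2 * (r_n / 1.6) ** 2))
    ring_band = np.exp(-((pdist - r_m) ** 2) / (2 * (thick / 1.5) ** 2))

    for i in range(n_cells):
        amp = 0.65 * (1.0 + 0.25 * rng.standard_normal())
        _stamp(h_field, cys[i], cxs[i], max(amp, 0.1) * nucleus_patch_base, pw, pw)
        if not stained[i] or spec.dab_peak_od <= 0:
            continue
        # draw the membranous arcs: total angular fraction = completeness,
        # split into several fragments when incomplete.  One arc per equal
        # sector (random offset within it) so arcs never overlap and the
        # rendered coverage is exactly the requested completeness.
        n_arcs = 1 if c >= 0.8 else int(rng.integers(2, 5))
        width = 2 * np.pi * c / n_arcs
        sector = 2 * np.pi / n_arcs
        rot = rng.uniform(0, 2 * np.pi)
        arc_mask = np.zeros((pw, pw), dtype=bool)
        for a in range(n_arcs):
            start = rot + a * sector + rng.uniform(0, sector - width)
            d = np.mod(pang - start, 2 * np.pi)
            arc_mask |= d <= width
        cell_od = ring_od * (1.0 + spec.intensity_jitter * rng.standard_normal())
        _stamp(dab_field, cys[i], cxs[i],
               max(cell_od, 0.0) * ring_band * arc_mask, pw, pw)

    # diffuse confluent staining in a hotspot region (strongly positive
    # tissue reads as a near-uniform brown sheet at tile scale)
    if spec.diffuse_fraction > 0 and spec.dab_peak_od > 0:
        hot_r = 1.2 * spec.tile_size
        ht = rng.uniform(0, 2 * np.pi)
        hd = rng.uniform(0, max(radius - hot_r, 1.0))
        hy, hx = centre + hd * np.sin(ht), centre + hd * np.cos(ht)
        hot = np.hypot(yy - hy, xx - hx) <= hot_r
        amp = spec.diffuse_fraction * spec.dab_peak_od * (
            1.0 + spec.intensity_jitter * rng.standard_normal()
        )
        # composite as a floor (not additive) so the rendered DAB OD stays
        # bounded by the nominal peak and the membrane-mass equalisation of
        # the morphology_only regime is unaffected
        mask = hot & tissue
        dab_field[mask] = np.maximum(dab_field[mask], max(amp, 0.0))

    dab_field[~tissue] = 0.0
    h_field[~tissue] = 0.0
    np.clip(dab_field, 0.0, 2.2, out=dab_field)

    # Beer–Lambert composition with the H-DAB profile
    od = (h_field[:, :, None] * profile.stain_matrix[0]
          + dab_field[:, :, None] * profile.stain_matrix[1])
    if spec.vignette_od > 0:
        od += spec.vignette_od * ((rr / (s / 2.0)) ** 2)[:, :, None] / np.sqrt(3.0)
    if spec.noise_sd > 0:
        od += spec.noise_sd * rng.standard_normal(od.shape)
    image = SpotImage(od_to_rgb(np.maximum(od, 0.0)),
                      spot_id=f"synthetic_{spec.score}{spec.status}_{spec.seed}")

    if spec.score == 2:
        her2, cen17 = generate_ish_counts(spec.status, rng)
        label = SpotLabel(image.spot_id, spec.score, spec.status,
                          her2_signals=her2, cen17_signals=cen17)
    else:
        label = SpotLabel(image.spot_id, spec.score)
    return image, label


def generate_ish_counts(status: int, rng: np.random.Generator
                        ) -> tuple[float, float]:
    """Draw HER2/CEN17 mean signal counts whose clinical reading reproduces
    the requested status by construction."""
    if status not in (0, 1):
        raise ValueError(f"status must be 0 or 1, got {status!r}")
    cen17 = float(rng.uniform(1.5, 3.0))
    if status == 1:
        if rng.random() < 0.5:
            her2 = float(rng.uniform(2.2, 8.0)) * cen17
        else:
            her2 = float(rng.uniform(6.5, 12.0))
    else:
        her2 = float(rng.uniform(0.8, 1.8)) * cen17  # < 6 since cen17 <= 3
    assert ish_call(her2, cen17) == status
    return round(her2, 2), round(cen17, 2)


@dataclass
class SyntheticCohort:
    """A generated cohort: spot images, labels, and the config snapshot."""

    images: list[SpotImage]
    labels: list[SpotLabel]
    config: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.images)

    def to_dir(self, out_dir: str | os.PathLike) -> None:
        """Write PNG spots, labels.csv (training-module schema) and the
        generator config snapshot."""
        import pandas as pd
        import yaml
        from .imaging import write_spot

        os.makedirs(out_dir, exist_ok=True)
        rows = []
        for img, lab in zip(self.images, self.labels):
            write_spot(img, os.path.join(out_dir, f"{lab.spot_id}.png"))
            rows.append({
                "spot_id": lab.spot_id,
                "ihc_score": lab.ihc_score,
                "her2_status": lab.her2_status,
                "her2_signals": lab.her2_signals,
                "cen17_signals": lab.cen17_signals,
            })
        pd.DataFrame(rows).to_csv(os.path.join(out_dir, "labels.csv"), index=False)
        with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
            yaml.safe_dump(self.config, fh)


def _apportion(n: int, proportions) -> list[int]:
    """Largest-remainder apportionment of n spots over the score classes."""
    p = np.asarray(proportions, dtype=float)
    if p.min() < 0 or not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("proportions must be non-negative and sum to 1")
    raw = n * p
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts)):
        if counts.sum() == n:
            break
        counts[i] += 1
    return counts.tolist()


def generate_cohort(
    n: int,
    class_proportions=EXTERNAL_COHORT_PROPORTIONS,
    regime: str = "intensity_coded",
    seed: int = 0,
    side_px: int = 1344,
    tile_size: int = 32,
    score2_positive_fraction: float = 0.5,
    **spec_overrides,
) -> SyntheticCohort:
    """Generate a labelled cohort, deterministic in ``seed``.

    Score counts follow largest-remainder apportionment of
    ``class_proportions`` (default mirrors the external-cohort distribution
    416/186/14/37 over scores 0-3); score-2 spots are split
    ``score2_positive_fraction`` positive and receive ISH counts consistent
    with their status.
    """
    if regime not in REGIMES:
        raise ValueError(f"regime must be one of {REGIMES}")
    n_requested = int(np.sum(np.asarray(class_proportions, dtype=float) > 0))
    if n < n_requested:
        raise ValueError(f"n={n} too small for {n_requested} requested classes")
    counts = _apportion(n, class_proportions)
    rng = np.random.default_rng(seed)
    images, labels = [], []
    uid = 0
    for score, count in zip((0, 1, 2, 3), counts):
        if score == 2:
            n_pos = int(round(score2_positive_fraction * count))
            statuses = [1] * n_pos + [0] * (count - n_pos)
        else:
            statuses = [score_to_status(score)] * count
        for status in statuses:
            spec = SyntheticSpotSpec(
                score=score, status=status, regime=regime, side_px=side_px,
                tile_size=tile_size, seed=int(rng.integers(2**31)),
                **spec_overrides,
            )
            img, lab = generate_spot(spec)
            lab.spot_id = f"spot_{uid:04d}_s{score}h{status}"
            img.spot_id = lab.spot_id
            uid += 1
            images.append(img)
            labels.append(lab)
    config = dict(
        n=n, class_proportions=list(map(float, class_proportions)),
        regime=regime, seed=seed, side_px=side_px, tile_size=tile_size,
        score2_positive_fraction=score2_positive_fraction,
        overrides={k: float(v) if isinstance(v, (int, float)) else v
                   for k, v in spec_overrides.items()},
    )
    return SyntheticCohort(images, labels, config)
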