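"""Synthetic planning-CT phantoms with vertebra-like bone and textured lesions.

Each phantom is a soft-tissue background holding a column of vertebra-like
bodies (trabecular interior + high-HU cortical shell, stacked elliptical
cylinders with disc gaps).  Lesions are spheroids placed inside the
trabecular bone with an HU offset and their own texture correlation length,
so both first-order and texture feature families carry class signal.
Tissue texture is correlated Gaussian noise: white noise smoothed with a
Gaussian filter at the tissue's correlation length and rescaled to the
tissue's HU standard deviation.

All randomness is driven by one seed; identical configs and seeds give
bit-identical volumes and points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .image import CTVolume, ImageGrid, PointClass, PointLabel

__all__ = ["PhantomConfig", "LesionTruth", "PhantomSample", "generate_phantom", "generate_cohort"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, tissue HU statistics and sampling plan of one phantom.

    Defaults use a 128 x 128 x 40 grid at (1, 1, 3) mm — a cropped analogue
    of a 512 x 512 planning CT with 3 mm slices — and standard CT tissue
    ranges: soft tissue 40 +/- 15 HU, trabecular bone 250 +/- 50 HU,
    cortical shell 1000 +/- 100 HU.  Lesions are lytic by default
    (-150 HU offset) with a longer texture correlation length than bone.
    """

    shape: tuple[int, int, int] = (128, 128, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    background_hu: float = 40.0
    background_sd: float = 15.0
    trabecular_hu: float = 250.0
    trabecular_sd: float = 50.0
    cortical_hu: float = 1000.0
    cortical_sd: float = 100.0
    lesion_offset_hu: float = -150.0
    lesion_offset_sd: float = 30.0
    lesion_diameter_range: tuple[float, float] = (8.0, 16.0)
    bone_corr_mm: float = 2.0
    lesion_corr_mm: float = 5.0
    vertebra_semiaxes_mm: tuple[float, float] = (22.0, 16.0)
    vertebra_height_mm: float = 28.0
    disc_gap_mm: float = 3.0
    cortical_thickness_mm: float = 2.0
    point_z_margin_mm: float = 25.0  # keeps default ROIs mostly unclipped
    n_lesions: int = 3
    n_healthy_points: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("background_sd", "trabecular_sd", "cortical_sd", "lesion_offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.lesion_diameter_range
        if not (0 < lo <= hi):
            raise ValueError("lesion_diameter_range must satisfy 0 < lo <= hi")
        if hi > 2 * min(self.vertebra_semiaxes_mm):
            raise ValueError("lesions larger than the vertebral body cannot be placed")


@dataclass(frozen=True)
class LesionTruth:
    center_mm: tuple[float, float, float]
    diameter_mm: float
    hu_offset: float


@dataclass
class PhantomSample:
    volume: CTVolume
    points: list[PointLabel]
    truth: list[LesionTruth]


def _correlated_noise(rng, shape, spacing, corr_mm: float) -> np.ndarray:
    """Unit-variance Gaussian noise with the given correlation length (mm)."""
    white = rng.standard_normal(shape)
    sigma = [max(corr_mm / s, 1e-6) for s in spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigma, mode="reflect")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _tissue_masks(cfg: PhantomConfig, grid: ImageGrid):
    """Boolean (trabecular, cortical) masks of the vertebral column."""
    xs, ys, zs = grid.voxel_centers()
    cx = xs.mean()
    cy = ys.mean()
    ax, ay = cfg.vertebra_semiaxes_mm
    t = cfg.cortical_thickness_mm

    dx = (xs - cx)[:, None]
    dy = (ys - cy)[None, :]
    outer = (dx / ax) ** 2 + (dy / ay) ** 2 <= 1.0
    inner = (dx / (ax - t)) ** 2 + (dy / (ay - t)) ** 2 <= 1.0

    period = cfg.vertebra_height_mm + cfg.disc_gap_mm
    in_body = (zs - zs[0]) % period < cfg.vertebra_height_mm

    outer3 = outer[:, :, None] & in_body[None, None, :]
    inner3 = inner[:, :, None] & in_body[None, None, :]
    return inner3, outer3 & ~inner3


def generate_phantom(config: PhantomConfig) -> PhantomSample:
    """Generate one phantom volume with its truth records and point labels.

    Lesion centers are rejection-sampled inside the trabecular compartment
    (pairwise separated by the mean of their diameters); healthy-bone points
    are sampled in trabecular bone farther than one lesion diameter from
    every lesion center.  Placement failures after bounded retries raise
    with the number placed.
    """
    rng = np.random.default_rng(config.seed)
    grid = ImageGrid(origin=(0.0, 0.0, 0.0), spacing=config.spacing, shape=config.shape)
    trabecular, cortical = _tissue_masks(config, grid)

    values = config.background_hu + config.background_sd * _correlated_noise(
        rng, config.shape, config.spacing, config.bone_corr_mm
    )
    bone_noise = _correlated_noise(rng, config.shape, config.spacing, config.bone_corr_mm)
    values[trabecular] = config.trabecular_hu + config.trabecular_sd * bone_noise[trabecular]
    values[cortical] = config.cortical_hu + config.cortical_sd * bone_noise[cortical]

    xs, ys, zs = grid.voxel_centers()
    X = xs[:, None, None]
    Y = ys[None, :, None]
    Z = zs[None, None, :]

    # lesion/point candidate voxels: trabecular, away from the z faces
    lo_d, hi_d = config.lesion_diameter_range
    candidates = np.argwhere(trabecular)
    cand_mm = grid.index_to_mm(candidates)
    zc_ok = (cand_mm[:, 2] >= zs[0] + config.point_z_margin_mm) & (
        cand_mm[:, 2] <= zs[-1] - config.point_z_margin_mm
    )
    candidates_mm = cand_mm[zc_ok]
    # distance (mm) from each trabecular voxel to the nearest non-trabecular
    # voxel: a sphere of radius r centered there fits iff edt >= r
    edt = ndimage.distance_transform_edt(trabecular, sampling=config.spacing)
    cand_edt = edt[tuple(candidates[zc_ok].T)]

    truth: list[LesionTruth] = []
    max_tries = 50 * max(config.n_lesions, 1)
    tries = 0
    lesion_noise = _correlated_noise(rng, config.shape, config.spacing, config.lesion_corr_mm)
    while len(truth) < config.n_lesions:
        if tries >= max_tries:
            raise RuntimeError(
                f"could only place {len(truth)} of {config.n_lesions} lesions "
                f"after {tries} attempts"
            )
        tries += 1
        diameter = float(rng.uniform(lo_d, hi_d))
        r = diameter / 2.0
        pool = candidates_mm[cand_edt >= r]
        if len(pool) == 0:
            continue
        center = pool[rng.integers(len(pool))]
        if any(
            np.linalg.norm(center - np.asarray(t.center_mm)) < (diameter + t.diameter_mm) / 2.0
            for t in truth
        ):
            continue
        offset = float(
            config.lesion_offset_hu + config.lesion_offset_sd * rng.standard_normal()
        )
        inside = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2 <= r**2
        values[inside] = (
            config.trabecular_hu
            + offset
            + config.trabecular_sd * lesion_noise[inside]
        )
        truth.append(LesionTruth(tuple(center), diameter, offset))

    points: list[PointLabel] = []
    pid = f"phantom-{config.seed}"
    for i, t in enumerate(truth):
        points.append(
            PointLabel(
                patient_id=pid,
                position=t.center_mm,
                label=PointClass.BM,
                annotator="synthetic-truth",
                point_id=f"{pid}-BM{i}",
            )
        )

    if config.n_healthy_points > 0:
        hb_positions = _sample_healthy_points(config, rng, candidates_mm, truth)
        for i, pos in enumerate(hb_positions):
            points.append(
                PointLabel(
                    patient_id=pid,
                    position=tuple(pos),
                    label=PointClass.HB,
                    annotator="synthetic-truth",
                    point_id=f"{pid}-HB{i}",
                )
            )

    volume = CTVolume(grid=grid, values=values, patient_id=pid)
    return PhantomSample(volume=volume, points=points, truth=truth)


def _sample_healthy_points(cfg, rng, candidates_mm, truth) -> list[np.ndarray]:
    out: list[np.ndarray] = []
    max_tries = 500 * cfg.n_healthy_points
    tries = 0
    while len(out) < cfg.n_healthy_points:
        if tries >= max_tries or len(candidates_mm) == 0:
            raise RuntimeError(
                f"could only place {len(out)} of {cfg.n_healthy_points} healthy points"
            )
        tries += 1
        pos = candidates_mm[rng.integers(len(candidates_mm))]
        # stay more than one lesion diameter from every lesion center
        if any(
            np.linalg.norm(pos - np.asarray(t.center_mm)) <= t.diameter_mm for t in truth
        ):
            continue
        if any(np.linalg.norm(pos - q) < 5.0 for q in out):
            continue  # avoid duplicate/near-duplicate picks
        out.append(pos)
    return out


@dataclass(frozen=True)
class CohortConfig:
    """Two-arm cohort: lesioned patients vs. lesion-free healthy-bone patients."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    lesions_per_patient: int = 3
    hb_points_per_patient: int = 4


def generate_cohort(
    config: PhantomConfig | CohortConfig,
    n_patients: int,
    bm_fraction: float = 0.5,
    master_seed: int | None = None,
) -> list[PhantomSample]:
    """Generate a cohort of independent phantoms with per-patient seeds.

    The first ``round(n_patients * bm_fraction)`` patients carry lesions
    (their labeled points are the lesion centers); the rest are lesion-free
    and carry healthy-bone points only.  Per-patient seeds derive
    deterministically from the master seed (default: the phantom config's).
    """
    if n_patients < 2:
        raise ValueError("n_patients must be >= 2")
    if not (0.0 < bm_fraction < 1.0):
        raise ValueError("bm_fraction must lie in (0, 1)")
    cohort = config if isinstance(config, CohortConfig) else CohortConfig(phantom=config)
    base = cohort.phantom
    if master_seed is None:
        master_seed = base.seed

    n_bm = int(round(n_patients * bm_fraction))
    seeds = np.random.SeedSequence(master_seed).generate_state(n_patients) % (2**31)

    samples = []
    for i in range(n_patients):
        is_bm = i < n_bm
        cfg = replace(
            base,
            seed=int(seeds[i]),
            n_lesions=cohort.lesions_per_patient if is_bm else 0,
            n_healthy_points=0 if is_bm else cohort.hb_points_per_patient,
        )
        sample = generate_phantom(cfg)
        role = "BM" if is_bm else "HB"
        pid = f"P{i:03d}-{role}"
        sample.volume.patient_id = pid
        sample.points = [
            replace(p, patient_id=pid, point_id=f"{pid}-{p.label.value}{k}")
            for k, p in enumerate(sample.points)
        ]
        samples.append(sample)
    logger.info("generated cohort: %d lesioned + %d healthy patients", n_bm, n_patients - n_bm)
    return samples
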