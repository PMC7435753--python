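"""Seeded synthetic chest phantoms with stage-wise ground truth.

Each phantom is a 2D grayscale slice emulating the geometry that makes
pulmonary nodule detection hard: a bright thorax ellipse containing two
dark lung fields (the parenchyma), bright circular nodules strictly
inside the parenchyma, bright non-nodule distractors both inside the
lungs (vessel cross-sections and short vessel segments) and outside them
(rib/sternum blobs), plus additive Gaussian noise.

Ground truth is produced for every cascade stage:

* ``parenchyma_mask`` — the two lung fields;
* ``candidate_mask`` — every small bright inside-lung structure
  (nodules *and* vessels), the over-inclusive target of stage two;
* ``nodule_mask`` — the union of the annotated nodule discs only.

The nesting ``nodule_mask ⊆ candidate_mask ⊆ parenchyma_mask`` holds
pixel-wise by construction.  Intensities are already normalised to
[0, 1]; Hounsfield-unit windowing for real CT lives in :mod:`.io`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "NoduleAnnotation",
    "PhantomParams",
    "PhantomSample",
    "generate_phantom",
    "generate_dataset",
    "rasterize_disc",
    "save_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class NoduleAnnotation:
    """One annotated nodule: center (row, col), diameter and contrast.

    ``contrast`` is the intensity offset of the drawn disc above the
    surrounding parenchyma, in [0, 1].
    """

    center_row: float
    center_col: float
    diameter: float
    contrast: float = 0.7

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("nodule diameter must be positive")


@dataclass(frozen=True)
class PhantomParams:
    """Generation parameters for one phantom population.

    Defaults describe a desk-scale 64x64 slice: one to three nodules of
    3-9 px diameter, a few vessel cross-sections/segments inside the
    lungs and one to three bright blobs outside them.  Diameters up to
    30 px are supported at larger ``image_size``.
    """

    image_size: int = 64
    nodule_count_range: tuple[int, int] = (1, 3)
    nodule_diameter_range: tuple[float, float] = (3.0, 9.0)
    vessel_count_range: tuple[int, int] = (2, 5)
    distractor_count_range: tuple[int, int] = (1, 3)
    noise_sigma: float = 0.03
    parenchyma_intensity: float = 0.15
    tissue_intensity: float = 0.65
    lesion_intensity: float = 0.85

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32 to fit two lung fields")
        for name in ("nodule_count_range", "vessel_count_range", "distractor_count_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name} must be a non-empty non-negative interval")
        lo, hi = self.nodule_diameter_range
        if lo <= 0 or lo > hi:
            raise ValueError("nodule_diameter_range must be a positive interval")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class PhantomSample:
    """One phantom slice with its stage-wise ground truth."""

    image: np.ndarray
    parenchyma_mask: np.ndarray
    candidate_mask: np.ndarray
    nodule_mask: np.ndarray
    nodules: list[NoduleAnnotation] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        shapes = {self.image.shape, self.parenchyma_mask.shape,
                  self.candidate_mask.shape, self.nodule_mask.shape}
        if len(shapes) != 1:
            raise ValueError("image and masks must share dimensions")
        if np.any(self.nodule_mask & ~self.candidate_mask):
            raise ValueError("nodule_mask must be contained in candidate_mask")
        if np.any(self.candidate_mask & ~self.parenchyma_mask):
            raise ValueError("candidate_mask must be contained in parenchyma_mask")


def rasterize_disc(shape: tuple[int, int], center_row: float, center_col: float,
                   diameter: float) -> np.ndarray:
    """Boolean mask of pixels whose centers lie within diameter/2 of the center."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center_row) ** 2 + (cc - center_col) ** 2 <= (diameter / 2.0) ** 2


def _ellipse(shape, cr, cc, ra, rb) -> np.ndarray:
    rr, col = np.ogrid[: shape[0], : shape[1]]
    return ((rr - cr) / ra) ** 2 + ((col - cc) / rb) ** 2 <= 1.0


def _sample_inside(rng: np.random.Generator, allowed: np.ndarray,
                   margin: float) -> tuple[float, float] | None:
    """Pick a point at least ``margin`` pixels inside the allowed region."""
    dist = ndimage.distance_transform_edt(allowed)
    ok = np.argwhere(dist > margin)
    if len(ok) == 0:
        return None
    r, c = ok[rng.integers(len(ok))]
    return float(r), float(c)


def generate_phantom(params: PhantomParams, seed: int) -> PhantomSample:
    """Generate one seeded phantom slice with ground truth for all stages.

    Deterministic for a fixed ``(params, seed)``.  Raises ``ValueError``
    when ``image_size`` cannot contain two lung fields plus margins.
    """
    if not isinstance(params, PhantomParams):
        raise TypeError("params must be a PhantomParams")
    rng = np.random.default_rng(seed)
    n = params.image_size
    shape = (n, n)

    # body: a bright thorax ellipse on a dark (air) background
    image = np.full(shape, 0.05, dtype=np.float64)
    thorax = _ellipse(shape, n / 2, n / 2, 0.46 * n, 0.44 * n)
    image[thorax] = params.tissue_intensity

    # two dark lung fields
    lung_l = _ellipse(shape, 0.52 * n, 0.32 * n, 0.30 * n, 0.16 * n)
    lung_r = _ellipse(shape, 0.52 * n, 0.68 * n, 0.30 * n, 0.16 * n)
    parenchyma = (lung_l | lung_r) & thorax
    if parenchyma.sum() < 0.05 * n * n:
        raise ValueError("image_size too small to contain two lung fields")
    image[parenchyma] = params.parenchyma_intensity

    nodule_mask = np.zeros(shape, dtype=bool)
    candidate_mask = np.zeros(shape, dtype=bool)
    annotations: list[NoduleAnnotation] = []

    # nodules: bright discs strictly inside the parenchyma
    n_nod = int(rng.integers(params.nodule_count_range[0],
                             params.nodule_count_range[1] + 1))
    occupied = np.zeros(shape, dtype=bool)
    for _ in range(n_nod):
        d = float(rng.uniform(*params.nodule_diameter_range))
        # keep the disc inside the lungs and clear of earlier lesions
        allowed = parenchyma & ~ndimage.binary_dilation(occupied, iterations=max(int(d) + 2, 1))
        center = _sample_inside(rng, allowed, d / 2.0 + 1.0)
        if center is None:
            continue
        disc = rasterize_disc(shape, center[0], center[1], d)
        contrast = params.lesion_intensity - params.parenchyma_intensity
        image[disc] = params.lesion_intensity
        nodule_mask |= disc
        occupied |= disc
        annotations.append(NoduleAnnotation(center[0], center[1], d, contrast))

    # vessels: small bright discs and short segments inside the lungs,
    # candidates but never nodules
    vessel_mask = np.zeros(shape, dtype=bool)
    n_ves = int(rng.integers(params.vessel_count_range[0],
                             params.vessel_count_range[1] + 1))
    for _ in range(n_ves):
        allowed = parenchyma & ~ndimage.binary_dilation(occupied, iterations=3)
        center = _sample_inside(rng, allowed, 2.0)
        if center is None:
            continue
        if rng.random() < 0.5:
            piece = rasterize_disc(shape, center[0], center[1], float(rng.uniform(1.5, 2.8)))
        else:  # short vessel segment: a thin line of 2 px-wide discs
            theta = rng.uniform(0, np.pi)
            length = rng.uniform(4, 8)
            piece = np.zeros(shape, dtype=bool)
            for t in np.linspace(-length / 2, length / 2, int(2 * length)):
                piece |= rasterize_disc(shape, center[0] + t * np.sin(theta),
                                        center[1] + t * np.cos(theta), 2.0)
        piece &= parenchyma & ~ndimage.binary_dilation(nodule_mask, iterations=2)
        image[piece] = 0.55  # vessels are dimmer than lesions
        vessel_mask |= piece
        occupied |= piece
    candidate_mask = nodule_mask | vessel_mask

    # distractor blobs outside the parenchyma (ribs / sternum), excluded
    # from every mask: the stage-1 gate must remove them
    n_dis = int(rng.integers(params.distractor_count_range[0],
                             params.distractor_count_range[1] + 1))
    outside = thorax & ~ndimage.binary_dilation(parenchyma, iterations=2)
    for _ in range(n_dis):
        center = _sample_inside(rng, outside, 2.5)
        if center is None:
            continue
        blob = rasterize_disc(shape, center[0], center[1], float(rng.uniform(3, 6)))
        blob &= outside
        image[blob] = min(params.lesion_intensity + 0.1, 1.0)

    if params.noise_sigma > 0:
        image = image + rng.normal(0.0, params.noise_sigma, size=shape)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)

    sample = PhantomSample(image=image, parenchyma_mask=parenchyma,
                           candidate_mask=candidate_mask, nodule_mask=nodule_mask,
                           nodules=annotations, seed=int(seed))
    sample.validate()
    return sample


def generate_dataset(n: int, params: PhantomParams, seed: int,
                     negative_fraction: float = 0.3) -> list[PhantomSample]:
    """Generate ``n`` phantoms with per-sample seeds derived from ``seed``.

    ``negative_fraction`` of the samples (rounded) are generated with zero
    nodules so the empty-ground-truth branch of the dice loss is
    exercised during training.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= negative_fraction <= 1.0:
        raise ValueError("negative_fraction must lie in [0, 1]")
    master = np.random.default_rng(seed)
    seeds = master.integers(0, 2**31 - 1, size=n)
    n_neg = int(round(n * negative_fraction))
    neg_idx = set(master.permutation(n)[:n_neg].tolist())
    neg_params = replace(params, nodule_count_range=(0, 0))
    samples = []
    for i in range(n):
        p = neg_params if i in neg_idx else params
        samples.append(generate_phantom(p, int(seeds[i])))
    return samples


# -- on-disk layout ---------------------------------------------------------

def _write_mask(path: Path, mask: np.ndarray) -> None:
    iio.imwrite(path, (mask.astype(np.uint8) * 255))


def save_dataset(samples: list[PhantomSample], out_dir: str | Path,
                 master_seed: int | None = None) -> None:
    """One directory per sample: 16-bit image.png, binary masks, annotations.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = []
    for i, s in enumerate(samples):
        d = out_dir / f"sample_{i:04d}"
        d.mkdir(exist_ok=True)
        iio.imwrite(d / "image.png", np.round(s.image * 65535).astype(np.uint16))
        _write_mask(d / "parenchyma.png", s.parenchyma_mask)
        _write_mask(d / "candidates.png", s.candidate_mask)
        _write_mask(d / "nodules.png", s.nodule_mask)
        pd.DataFrame(
            [(j, a.center_row, a.center_col, a.diameter)
             for j, a in enumerate(s.nodules)],
            columns=["id", "center_row", "center_col", "diameter"],
        ).to_csv(d / "annotations.csv", index=False)
        names.append(d.name)
    manifest = {"samples": names,
                "master_seed": master_seed,
                "sample_seeds": [s.seed for s in samples]}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_dataset(in_dir: str | Path) -> list[PhantomSample]:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    samples = []
    for name, seed in zip(manifest["samples"], manifest["sample_seeds"]):
        d = in_dir / name
        image = iio.imread(d / "image.png").astype(np.float32) / 65535.0
        masks = {m: iio.imread(d / f"{m}.png") > 127
                 for m in ("parenchyma", "candidates", "nodules")}
        ann = pd.read_csv(d / "annotations.csv")
        nodules = [NoduleAnnotation(r.center_row, r.center_col, r.diameter)
                   for r in ann.itertuples()]
        samples.append(PhantomSample(image=image,
                                     parenchyma_mask=masks["parenchyma"],
                                     candidate_mask=masks["candidates"],
                                     nodule_mask=masks["nodules"],
                                     nodules=nodules, seed=int(seed)))
    return samples
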