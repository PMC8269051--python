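"""Synthetic portal-venous liver CT phantoms.

Generates 2-D patches and small 3-D volumes that mimic the gross intensity
statistics of contrast-enhanced liver CT: roughly homogeneous hyperdense
parenchyma, round hypodense lesions, additive acquisition noise, everything
in Hounsfield units (HU). The phantoms carry exact lesion ground truth so
the rest of the pipeline (patch extraction, autoencoder training, latent
editing, classification) is testable without any external scan data.

The phantom is deliberately simple: lesions are soft-edged filled discs and
the parenchyma texture is smoothed Gaussian noise. It is a testbed, not an
anatomical simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomSpec",
    "generate_patch",
    "generate_dataset",
    "generate_volume",
    "save_dataset",
]

#: plausible CT attenuation range for a 12-bit scanner, HU
HU_RANGE = (-1024.0, 3071.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic liver-patch generator.

    All intensities are Hounsfield units. Defaults place both tissues well
    inside the display window [-110, 190] HU used downstream, with lesions
    clearly hypodense relative to the enhanced parenchyma.

    Parameters
    ----------
    patch_px : pixels per patch side.
    parenchyma_mean, parenchyma_sd : liver tissue intensity and the sd of
        its (spatially smoothed) texture.
    lesion_mean, lesion_sd : lesion intensity and texture sd; must be
        hypodense, i.e. ``lesion_mean < parenchyma_mean``.
    lesion_radius_range : (min, max) lesion radius in pixels; the disc must
        fit inside half the patch.
    noise_sd : sd of additive white acquisition noise.
    background_mean : intensity of non-liver voxels in volumes.
    liver_shape : ``"full"`` (whole patch/slice is liver), ``"ellipse"``
        (axis-aligned ellipse with semi-axes ``liver_axes`` as fractions of
        the slice extent) or ``"none"`` (no liver at all).
    liver_axes : ellipse semi-axes as (row, col) fractions of the extent.
    contrast_floor : minimum required parenchyma-lesion contrast in HU.
    texture_scale_px : correlation length of the tissue texture.
    soft_edge_px : Gaussian sigma used to feather the lesion rim.
    """

    patch_px: int = 96
    parenchyma_mean: float = 110.0
    parenchyma_sd: float = 10.0
    lesion_mean: float = 45.0
    lesion_sd: float = 10.0
    lesion_radius_range: tuple[float, float] = (8.0, 20.0)
    noise_sd: float = 8.0
    background_mean: float = -30.0
    liver_shape: str = "full"
    liver_axes: tuple[float, float] = (0.32, 0.38)
    contrast_floor: float = 40.0
    texture_scale_px: float = 6.0
    soft_edge_px: float = 1.0

    def __post_init__(self) -> None:
        values = [
            self.parenchyma_mean, self.parenchyma_sd, self.lesion_mean,
            self.lesion_sd, self.noise_sd, self.background_mean,
            self.contrast_floor,
        ]
        if not np.all(np.isfinite(values)):
            raise ValueError("all HU parameters must be finite")
        if self.patch_px < 2:
            raise ValueError(f"patch_px must be >= 2, got {self.patch_px}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.parenchyma_mean <= self.lesion_mean:
            raise ValueError(
                "lesions must be hypodense: parenchyma_mean "
                f"({self.parenchyma_mean}) must exceed lesion_mean "
                f"({self.lesion_mean})"
            )
        if self.parenchyma_mean - self.lesion_mean < self.contrast_floor:
            raise ValueError(
                f"parenchyma-lesion contrast "
                f"{self.parenchyma_mean - self.lesion_mean:g} HU is below the "
                f"contrast floor {self.contrast_floor:g} HU"
            )
        rmin, rmax = self.lesion_radius_range
        if not (0 < rmin <= rmax):
            raise ValueError(
                f"lesion_radius_range must satisfy 0 < min <= max, "
                f"got {self.lesion_radius_range}"
            )
        if rmax >= self.patch_px / 2:
            raise ValueError(
                f"max lesion radius {rmax} must be < patch_px/2 "
                f"= {self.patch_px / 2}"
            )
        if self.liver_shape not in ("full", "ellipse", "none"):
            raise ValueError(
                f"liver_shape must be 'full', 'ellipse' or 'none', "
                f"got {self.liver_shape!r}"
            )


def _rng(seed: int) -> np.random.Generator:
    # counter-based stream: one Philox instance per call, no global state
    return np.random.Generator(np.random.Philox(seed))


def _texture(rng: np.random.Generator, shape: tuple[int, ...],
             mean: float, sd: float, scale_px: float) -> np.ndarray:
    """Spatially correlated Gaussian texture with given pointwise moments."""
    white = rng.standard_normal(shape)
    if scale_px > 0:
        smooth = ndimage.gaussian_filter(white, scale_px, mode="wrap")
        s = smooth.std()
        if s > 0:
            smooth = smooth / s
    else:
        smooth = white
    return mean + sd * smooth


def _disc_mask(shape: tuple[int, int], center: tuple[float, float],
               radius: float, soft_px: float) -> tuple[np.ndarray, np.ndarray]:
    """Hard boolean disc plus a feathered [0, 1] blend weight."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dist2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    hard = dist2 <= radius**2
    if soft_px > 0:
        soft = ndimage.gaussian_filter(hard.astype(float), soft_px)
    else:
        soft = hard.astype(float)
    return hard, soft


def generate_patch(
    spec: PhantomSpec,
    with_lesion: bool,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Generate one phantom liver patch in HU.

    Returns ``(patch, lesion_mask, label)`` with ``patch`` of shape
    ``(patch_px, patch_px)`` float64, ``lesion_mask`` boolean and
    ``label = int(with_lesion)``. The lesion, when present, is a filled
    soft-edged disc with a uniformly drawn radius, placed uniformly over
    the positions where it fits fully inside the patch. Deterministic given
    ``(spec, with_lesion, seed)``.
    """
    rng = _rng(seed)
    n = spec.patch_px
    patch = _texture(rng, (n, n), spec.parenchyma_mean, spec.parenchyma_sd,
                     spec.texture_scale_px)
    mask = np.zeros((n, n), dtype=bool)
    if with_lesion:
        rmin, rmax = spec.lesion_radius_range
        radius = rng.uniform(rmin, rmax)
        lo, hi = radius, n - radius
        center = (rng.uniform(lo, hi), rng.uniform(lo, hi))
        mask, blend = _disc_mask((n, n), center, radius, spec.soft_edge_px)
        lesion = _texture(rng, (n, n), spec.lesion_mean, spec.lesion_sd,
                          spec.texture_scale_px)
        patch = patch * (1.0 - blend) + lesion * blend
    patch = patch + rng.normal(0.0, spec.noise_sd, (n, n))
    np.clip(patch, *HU_RANGE, out=patch)
    return patch, mask, int(with_lesion)


def generate_dataset(
    spec: PhantomSpec,
    n_normal: int,
    n_lesion: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate a shuffled labeled patch collection.

    Returns ``(patches, masks, labels)``: patches ``(n, p, p)`` in HU, masks
    ``(n, p, p)`` boolean, labels ``(n,)`` in {0, 1} with exactly
    ``n_normal`` zeros and ``n_lesion`` ones. Per-patch seeds are derived
    from ``seed``, and the final order is a seed-deterministic shuffle.
    """
    if n_normal < 0 or n_lesion < 0:
        raise ValueError("patch counts must be >= 0")
    total = n_normal + n_lesion
    if total == 0:
        warnings.warn("both class counts are zero: returning an empty "
                      "collection", stacklevel=2)
    rng = _rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=total)
    labels = np.array([0] * n_normal + [1] * n_lesion, dtype=int)
    n = spec.patch_px
    patches = np.empty((total, n, n))
    masks = np.empty((total, n, n), dtype=bool)
    for i, (lab, s) in enumerate(zip(labels, child_seeds)):
        patches[i], masks[i], _ = generate_patch(spec, bool(lab), int(s))
    order = rng.permutation(total)
    return patches[order], masks[order], labels[order]


def _liver_slice_mask(spec: PhantomSpec, rows: int, cols: int) -> np.ndarray:
    if spec.liver_shape == "none":
        return np.zeros((rows, cols), dtype=bool)
    if spec.liver_shape == "full":
        return np.ones((rows, cols), dtype=bool)
    a, b = spec.liver_axes[0] * rows, spec.liver_axes[1] * cols
    rr, cc = np.ogrid[:rows, :cols]
    return ((rr - (rows - 1) / 2) / a) ** 2 + ((cc - (cols - 1) / 2) / b) ** 2 <= 1.0


def generate_volume(
    spec: PhantomSpec,
    shape: tuple[int, int, int],
    seed: int,
    n_lesions: int = 3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate a small 3-D phantom volume with liver and lesion masks.

    ``shape`` is ``(slices, rows, cols)``. The liver region is the same
    per-slice mask on every slice (a cylinder for the ellipse shape);
    lesions are spheres placed fully inside the liver. Voxels outside the
    liver are drawn around ``background_mean``. Returns
    ``(volume_hu, liver_mask, lesion_mask)`` with
    ``lesion_mask & liver_mask == lesion_mask``.
    """
    nz, ny, nx = shape
    if min(shape) < 1:
        raise ValueError(f"shape must be positive, got {shape}")
    if ny < spec.patch_px or nx < spec.patch_px:
        warnings.warn(
            f"in-plane extent {(ny, nx)} is smaller than one patch "
            f"({spec.patch_px} px): extraction will yield zero patches",
            stacklevel=2,
        )
    rng = _rng(seed)
    slice_mask = _liver_slice_mask(spec, ny, nx)
    liver = np.broadcast_to(slice_mask, shape).copy()

    volume = _texture(rng, shape, spec.background_mean, spec.parenchyma_sd,
                      spec.texture_scale_px)
    paren = _texture(rng, shape, spec.parenchyma_mean, spec.parenchyma_sd,
                     spec.texture_scale_px)
    volume[liver] = paren[liver]

    lesions = np.zeros(shape, dtype=bool)
    if liver.any() and n_lesions > 0:
        rmin, rmax = spec.lesion_radius_range
        zz, yy, xx = np.indices(shape, sparse=True)
        interior = np.argwhere(liver)
        for _ in range(n_lesions):
            radius = rng.uniform(rmin, min(rmax, max(nz / 2 - 1, rmin)))
            # rejection-sample a center whose sphere stays inside the liver
            for _attempt in range(200):
                cz, cy, cx = interior[rng.integers(len(interior))]
                ball = ((zz - cz) ** 2 + (yy - cy) ** 2
                        + (xx - cx) ** 2) <= radius**2
                if ball.sum() > 0 and (ball & ~liver).sum() == 0:
                    lesions |= ball
                    break
        if lesions.any():
            les_tex = _texture(rng, shape, spec.lesion_mean, spec.lesion_sd,
                               spec.texture_scale_px)
            blend = ndimage.gaussian_filter(lesions.astype(float),
                                            spec.soft_edge_px)
            volume = volume * (1.0 - blend) + les_tex * blend
    volume = volume + rng.normal(0.0, spec.noise_sd, shape)
    np.clip(volume, *HU_RANGE, out=volume)
    return volume, liver, lesions


def save_dataset(path: str | Path, patches: np.ndarray, labels: np.ndarray,
                 seed: int) -> None:
    """Write a patch collection as a stacked NIfTI plus a CSV manifest."""
    import nibabel as nib
    import pandas as pd

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    # NIfTI wants spatial-last axes; stack patches along the 3rd axis
    img = nib.Nifti1Image(np.transpose(patches, (1, 2, 0)).astype(np.float32),
                          affine=np.eye(4))
    nib.save(img, path / "patches.nii.gz")
    pd.DataFrame({
        "index": np.arange(len(labels)),
        "label": labels,
        "seed": seed,
    }).to_csv(path / "manifest.csv", index=False)
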