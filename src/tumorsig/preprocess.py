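"""CT volume to model-ready patches.

Axial slices are cut into overlapping square windows on a fixed stride grid,
windows with too little liver are dropped, intensities are clipped to a
narrow soft-tissue window and affinely rescaled to [-1, 1]. No resampling
and no further intensity normalization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PatchExtractionConfig",
    "clip_and_scale",
    "inverse_scale",
    "extract_patches",
    "label_patch",
    "sample_balanced",
]


@dataclass(frozen=True)
class PatchExtractionConfig:
    """Sliding-window extraction parameters.

    ``patch_px``/``stride_px`` define the window grid (windows are top-left
    anchored at multiples of the stride, 0-based, and must fit fully inside
    the slice). ``hu_min``/``hu_max`` is the clip window mapped onto
    [-1, 1]. A window is kept iff at least ``min_liver_fraction`` of its
    pixels are liver; it is labeled as lesion iff it contains at least
    ``min_lesion_px`` lesion pixels.
    """

    patch_px: int = 96
    stride_px: int = 48
    hu_min: float = -110.0
    hu_max: float = 190.0
    min_liver_fraction: float = 0.25
    min_lesion_px: int = 10

    def __post_init__(self) -> None:
        if self.hu_min >= self.hu_max:
            raise ValueError(
                f"hu_min ({self.hu_min}) must be < hu_max ({self.hu_max})")
        if not (0 < self.stride_px <= self.patch_px):
            raise ValueError(
                f"need 0 < stride_px <= patch_px, got stride {self.stride_px}"
                f" and patch {self.patch_px}")
        if not (0 < self.min_liver_fraction <= 1):
            raise ValueError(
                f"min_liver_fraction must be in (0, 1], got "
                f"{self.min_liver_fraction}")
        if self.min_lesion_px < 1:
            raise ValueError(
                f"min_lesion_px must be >= 1, got {self.min_lesion_px}")


def clip_and_scale(patch: np.ndarray,
                   cfg: PatchExtractionConfig = PatchExtractionConfig(),
                   ) -> np.ndarray:
    """Clip HU values to ``[hu_min, hu_max]`` and rescale to [-1, 1].

    The map is ``v -> 2 * (clip(v) - hu_min) / (hu_max - hu_min) - 1``:
    monotone, affine on the clip window, idempotent-compatible (values
    already in [-1, 1] HU-space are simply windowed again).
    """
    patch = np.asarray(patch, dtype=float)
    if not np.all(np.isfinite(patch)):
        raise ValueError("patch contains non-finite values")
    clipped = np.clip(patch, cfg.hu_min, cfg.hu_max)
    return 2.0 * (clipped - cfg.hu_min) / (cfg.hu_max - cfg.hu_min) - 1.0


def inverse_scale(normalized: np.ndarray,
                  cfg: PatchExtractionConfig = PatchExtractionConfig(),
                  tol: float = 1e-6) -> np.ndarray:
    """Map [-1, 1] model values back to HU (exact inverse on the window)."""
    normalized = np.asarray(normalized, dtype=float)
    if normalized.min() < -1.0 - tol or normalized.max() > 1.0 + tol:
        raise ValueError(
            f"normalized values must lie in [-1, 1]; got range "
            f"[{normalized.min():g}, {normalized.max():g}]")
    clipped = np.clip(normalized, -1.0, 1.0)
    return (clipped + 1.0) / 2.0 * (cfg.hu_max - cfg.hu_min) + cfg.hu_min


def _anchors(extent: int, patch_px: int, stride_px: int) -> list[int]:
    # top-left anchors at stride multiples; windows must fit fully
    return list(range(0, extent - patch_px + 1, stride_px))


def extract_patches(
    volume: np.ndarray,
    liver_mask: np.ndarray,
    cfg: PatchExtractionConfig = PatchExtractionConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Slide a 2-D window over each axial slice and keep liver windows.

    ``volume`` and ``liver_mask`` are ``(slices, rows, cols)`` (a single
    2-D slice is also accepted). Returns ``(patches, coords)`` where
    ``patches`` is ``(n, patch_px, patch_px)`` normalized to [-1, 1] and
    ``coords`` is ``(n, 3)`` int rows of ``(slice, row, col)`` anchors.
    """
    volume = np.asarray(volume, dtype=float)
    liver_mask = np.asarray(liver_mask).astype(bool)
    if volume.shape != liver_mask.shape:
        raise ValueError(
            f"volume shape {volume.shape} != liver mask shape "
            f"{liver_mask.shape}")
    if volume.ndim == 2:
        volume = volume[None]
        liver_mask = liver_mask[None]
    if volume.ndim != 3:
        raise ValueError(f"expected 2-D or 3-D input, got {volume.ndim}-D")

    p = cfg.patch_px
    min_px = cfg.min_liver_fraction * p * p
    patches, coords = [], []
    for z in range(volume.shape[0]):
        for r in _anchors(volume.shape[1], p, cfg.stride_px):
            for c in _anchors(volume.shape[2], p, cfg.stride_px):
                liver_px = liver_mask[z, r:r + p, c:c + p].sum()
                if liver_px >= min_px:
                    patches.append(clip_and_scale(
                        volume[z, r:r + p, c:c + p], cfg))
                    coords.append((z, r, c))
    if not patches:
        return (np.empty((0, p, p)), np.empty((0, 3), dtype=int))
    return np.stack(patches), np.array(coords, dtype=int)


def label_patch(coords: tuple[int, int, int], lesion_mask: np.ndarray,
                cfg: PatchExtractionConfig = PatchExtractionConfig()) -> int:
    """Label one window: 1 iff it covers >= ``min_lesion_px`` lesion pixels."""
    lesion_mask = np.asarray(lesion_mask).astype(bool)
    if lesion_mask.ndim == 2:
        lesion_mask = lesion_mask[None]
    z, r, c = coords
    p = cfg.patch_px
    window = lesion_mask[z, r:r + p, c:c + p]
    return int(window.sum() >= cfg.min_lesion_px)


def sample_balanced(
    patches: np.ndarray,
    labels: np.ndarray,
    n_per_class: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a balanced subset: ``n_per_class`` of each label, no replacement.

    Deterministic under ``seed``. Raises if a class has too few members,
    naming the deficient class.
    """
    labels = np.asarray(labels)
    rng = np.random.Generator(np.random.Philox(seed))
    picked = []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < n_per_class:
            raise ValueError(
                f"class {cls} has only {len(idx)} patches, "
                f"cannot sample {n_per_class}")
        picked.append(rng.choice(idx, size=n_per_class, replace=False))
    sel = np.concatenate(picked)
    sel = sel[rng.permutation(len(sel))]
    return np.asarray(patches)[sel], labels[sel]
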