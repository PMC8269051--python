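"""Digital-signature editing in latent space.

A trained encoder maps a 96x96 patch onto a small spatial grid of channel
vectors ("digital signatures"); each cell summarizes the appearance of the
image region under its receptive field (cell ``(i, j)`` roughly the 32x32
block centered at ``((i + 1/2) * 32, (j + 1/2) * 32)`` under defaults).
Replacing a cell's vector with one taken from another patch — or linearly
interpolating between the two — and decoding yields a *synthetic* patch in
which a lesion has been inserted, removed, or gradually blended in at that
location.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import NetworkBundle, decode, encode

__all__ = [
    "CellEdit", "swap_signature", "interpolate_signature", "sample_prior",
    "synthesize_patch", "interpolation_sweep",
]


@dataclass(frozen=True)
class CellEdit:
    """One latent-grid edit: copy/blend ``source_cell`` into ``target_cell``.

    ``alpha`` is the interpolation weight: 0 keeps the target's vector,
    1 replaces it with the source's (a pure swap).
    """

    target_cell: tuple[int, int]
    source_cell: tuple[int, int]
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")


def _check_cells(edits: list[CellEdit], shape: tuple[int, ...]) -> None:
    sh, sw = shape[0], shape[1]
    for e in edits:
        for cell in (e.target_cell, e.source_cell):
            r, c = cell
            if not (0 <= r < sh and 0 <= c < sw):
                raise IndexError(
                    f"cell {cell} outside latent grid {sh}x{sw}")


def swap_signature(target: np.ndarray, source: np.ndarray,
                   edits: list[CellEdit] | CellEdit) -> np.ndarray:
    """Replace channel vectors of edited cells by the source's vectors.

    Unedited cells are bit-identical to ``target``; inputs are not
    modified. Per-edit alphas are ignored here (pure replacement) — use
    :func:`interpolate_signature` for partial blends.
    """
    return interpolate_signature(target, source, edits, force_alpha=1.0)


def interpolate_signature(a: np.ndarray, b: np.ndarray,
                          edits: list[CellEdit] | CellEdit,
                          force_alpha: float | None = None) -> np.ndarray:
    """Blend edited cells: ``(1 - alpha) * a_cell + alpha * b_cell``.

    Unedited cells keep ``a``'s vectors. Cells and alphas come from
    ``edits``; ``force_alpha`` overrides every edit's alpha (used by the
    pure swap).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"latent shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 3:
        raise ValueError(f"expected a (S, S, C) latent, got shape {a.shape}")
    if isinstance(edits, CellEdit):
        edits = [edits]
    _check_cells(edits, a.shape)
    out = a.copy()
    for e in edits:
        alpha = e.alpha if force_alpha is None else force_alpha
        tr, tc = e.target_cell
        sr, sc = e.source_cell
        out[tr, tc] = (1.0 - alpha) * a[tr, tc] + alpha * b[sr, sc]
    return out


def sample_prior(latent_shape: tuple[int, int, int],
                 seed: int) -> np.ndarray:
    """Draw a latent code of i.i.d. standard-normal entries (the prior)."""
    if any(s < 1 for s in latent_shape):
        raise ValueError(f"invalid latent shape {latent_shape}")
    rng = np.random.Generator(np.random.Philox(seed))
    return rng.standard_normal(latent_shape)


def _require_trained(bundle: NetworkBundle) -> None:
    if bundle is None:
        raise ValueError("a trained model bundle is required")
    if not bundle.trained:
        raise ValueError(
            "bundle is untrained; train_model (or load a checkpoint) first")


def synthesize_patch(target_patch: np.ndarray, source_patch: np.ndarray,
                     edits: list[CellEdit] | CellEdit,
                     bundle: NetworkBundle) -> np.ndarray:
    """Encode both patches, apply the edits, decode the result.

    With an empty edit list this is exactly ``reconstruct(target_patch)``.
    Output values stay in [-1, 1] (decoder tanh).
    """
    _require_trained(bundle)
    z_t = encode(target_patch, bundle)
    z_s = encode(source_patch, bundle)
    if isinstance(edits, CellEdit):
        edits = [edits]
    return decode(interpolate_signature(z_t, z_s, edits), bundle)


def interpolation_sweep(target_patch: np.ndarray, source_patch: np.ndarray,
                        cell: tuple[int, int], alphas,
                        bundle: NetworkBundle,
                        source_cell: tuple[int, int] | None = None,
                        ) -> np.ndarray:
    """One synthetic patch per alpha, blending a single cell.

    ``alphas`` must be sorted ascending in [0, 1]; alpha 0 reproduces the
    reconstruction of the target. Returns a stack ``(len(alphas), H, W)``.
    """
    _require_trained(bundle)
    alphas = list(alphas)
    if any(not (0.0 <= a <= 1.0) for a in alphas):
        raise ValueError(f"alphas must lie in [0, 1], got {alphas}")
    if alphas != sorted(alphas):
        raise ValueError(f"alphas must be sorted ascending, got {alphas}")
    src = cell if source_cell is None else source_cell
    z_t = encode(target_patch, bundle)
    z_s = encode(source_patch, bundle)
    frames = [
        decode(interpolate_signature(z_t, z_s, CellEdit(cell, src, a)),
               bundle)
        for a in alphas
    ]
    return np.stack(frames)
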