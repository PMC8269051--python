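"""End-to-end phantom experiments at CPU ("desk") scale.

The full-scale setup (hundreds of thousands of real CT patches, 400
epochs, a 3x3x128 latent) needs a GPU. These recipes run the identical
pipeline at a reduced scale chosen for a single CPU: 2,000 phantom
patches (1,000 per class), a narrow IAE (base width 8, 3x3x16 latent) and
a short Adam schedule. They are what the test suite and the worked
examples execute.
"""

from __future__ import annotations

import numpy as np

from . import latent_ops, phantom, preprocess, signatures
from .model import ModelConfig, NetworkBundle, reconstruct, train_model

__all__ = [
    "desk_scale_config", "train_phantom_iae", "central_lesion_patches",
    "signature_classification", "manipulation_rates", "interpolation_rates",
    "CENTER_CELL", "CENTER_REGION",
]

#: latent cell whose receptive field covers the patch center, and the
#: corresponding 32x32 image block under the default 96 -> 3 encoder
CENTER_CELL = (1, 1)
CENTER_REGION = (slice(32, 64), slice(32, 64))


def desk_scale_config(seed: int = 0, epochs: int = 12) -> ModelConfig:
    """Reduced-width IAE configuration for CPU-scale phantom runs.

    Keeps the full-scale loss structure (L1 weight 500, input-noise
    variance 0.1, halfway learning-rate drop) but shrinks widths and the
    latent channel count and shortens the schedule; the small network
    tolerates a 5x larger learning rate, which compensates for running
    ~30x fewer epochs than the full-scale schedule.
    """
    return ModelConfig(
        latent_shape=(3, 3, 16), base_width=8, disc_fc=64, reg_hidden=64,
        epochs=epochs, lr_initial=1e-3, lr_reduced=1e-4,
        lr_switch_epoch=max(epochs // 2, 1), batch_size=32, seed=seed,
    )


def train_phantom_iae(
    seed: int = 0,
    n_per_class: int = 1000,
    epochs: int = 12,
    spec: phantom.PhantomSpec | None = None,
):
    """Generate a balanced phantom dataset and train the desk-scale IAE.

    Returns ``(bundle, history, patches, labels)`` with ``patches``
    already normalized to [-1, 1].
    """
    spec = spec or phantom.PhantomSpec()
    hu, _, labels = phantom.generate_dataset(spec, n_per_class, n_per_class,
                                             seed=seed)
    patches = preprocess.clip_and_scale(hu)
    bundle, history = train_model(patches, desk_scale_config(seed, epochs))
    return bundle, history, patches, labels


def central_lesion_patches(
    spec: phantom.PhantomSpec, n: int, seed_start: int,
    center_box: tuple[int, int] = (40, 56),
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministically select lesion patches with central lesions.

    Generates patches at consecutive seeds and keeps those whose lesion
    centroid falls in ``center_box`` (so the lesion sits under the center
    latent cell's receptive field). Returns ``n`` (patch_hu, mask) pairs.
    """
    lo, hi = center_box
    out: list[tuple[np.ndarray, np.ndarray]] = []
    seed = seed_start
    while len(out) < n:
        p, m, _ = phantom.generate_patch(spec, True, seed)
        seed += 1
        rr, cc = np.nonzero(m)
        if len(rr) and lo <= rr.mean() <= hi and lo <= cc.mean() <= hi:
            out.append((p, m))
    return out


def signature_classification(
    bundle: NetworkBundle, patches: np.ndarray, labels: np.ndarray,
    classifier: str = "svm", k_folds: int = 10, seed: int = 0,
) -> signatures.ClassifierReport:
    """Cross-validated lesion-vs-normal classification of latent codes."""
    feats = signatures.latent_features(patches, bundle)
    return signatures.crossval_classify(feats, labels, classifier, k_folds,
                                        seed)


def _paired_patches(spec: phantom.PhantomSpec, n_pairs: int, seed: int):
    lesion = central_lesion_patches(spec, n_pairs, seed_start=seed * 100_000)
    normal = [phantom.generate_patch(spec, False, seed * 100_000 + 50_000 + i)[0]
              for i in range(n_pairs)]
    for (lp, _), np_hu in zip(lesion, normal):
        yield (preprocess.clip_and_scale(np_hu),
               preprocess.clip_and_scale(lp))


def manipulation_rates(
    bundle: NetworkBundle, n_pairs: int = 50, seed: int = 1,
    spec: phantom.PhantomSpec | None = None,
) -> tuple[float, float]:
    """Lesion insertion/removal success rates over phantom patch pairs.

    For each pair, a lesion signature is swapped into the center cell of a
    normal patch (insertion: the edited 32x32 center region must darken
    relative to the unedited reconstruction) and the normal signature into
    the lesion patch (removal: the region must brighten). Returns the two
    success fractions.
    """
    ins_ok = rem_ok = 0
    edit = latent_ops.CellEdit(CENTER_CELL, CENTER_CELL)
    for norm, les in _paired_patches(spec or phantom.PhantomSpec(), n_pairs,
                                     seed):
        rec_n = reconstruct(norm, bundle)
        rec_l = reconstruct(les, bundle)
        inserted = latent_ops.synthesize_patch(norm, les, edit, bundle)
        removed = latent_ops.synthesize_patch(les, norm, edit, bundle)
        ins_ok += inserted[CENTER_REGION].mean() < rec_n[CENTER_REGION].mean()
        rem_ok += removed[CENTER_REGION].mean() > rec_l[CENTER_REGION].mean()
    return ins_ok / n_pairs, rem_ok / n_pairs


def interpolation_rates(
    bundle: NetworkBundle, n_pairs: int = 50, seed: int = 2,
    alphas=(0.0, 0.25, 0.5, 0.75, 1.0), tolerance: float = 0.05,
    spec: phantom.PhantomSpec | None = None,
) -> float:
    """Fraction of pairs with a monotone center-region intensity sweep.

    Sweeping the center cell from a normal to a lesion signature should
    darken the center region monotonically in alpha; violations up to
    ``tolerance`` times the endpoint-to-endpoint intensity change are
    allowed.
    """
    mono = 0
    for norm, les in _paired_patches(spec or phantom.PhantomSpec(), n_pairs,
                                     seed):
        sweep = latent_ops.interpolation_sweep(norm, les, CENTER_CELL,
                                               alphas, bundle)
        means = [frame[CENTER_REGION].mean() for frame in sweep]
        span = abs(means[-1] - means[0])
        tol = tolerance * (span if span > 0 else 1.0)
        mono += all(means[i + 1] <= means[i] + tol
                    for i in range(len(means) - 1))
    return mono / n_pairs
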