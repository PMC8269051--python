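"""Implicit autoencoder (IAE) with a spatially structured latent code.

The model is a denoising autoencoder whose two soft constraints are both
enforced adversarially:

* a **data discriminator** (conv + fully connected) judges real patches
  against decoder outputs, pushing reconstructions toward the image
  manifold;
* a **latent regularizer** (three fully connected layers) judges encoder
  outputs against i.i.d. standard-normal samples, pulling the latent code
  toward N(0, 1).

Encoder and decoder are fully convolutional; a 96x96 patch maps to a
``3 x 3 x C`` latent grid whose cells are the "digital signatures" of the
corresponding image regions. The decoder loss adds a pixel-wise L1
reconstruction term with a large weight (default 500) so that the L1 term
dominates and reconstructions stay close to the input; the adversarial
terms sharpen them. Input noise and geometric augmentation are applied
during training only — at inference the model is deterministic.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import nn

__all__ = [
    "ModelConfig", "NetworkBundle", "build_bundle",
    "add_input_noise", "augment", "encode", "decode",
    "reconstruction_l1", "decoder_loss", "adversarial_losses",
    "train_model", "reconstruct", "save_checkpoint", "load_checkpoint",
    "VERDICT_CLAMP",
]

#: probabilities are clamped to [VERDICT_CLAMP, 1 - VERDICT_CLAMP] in logs
VERDICT_CLAMP = 1e-7


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training schedule of the IAE.

    Defaults follow the full-scale setup (3x3x128 latent, L1 weight 500,
    input-noise variance 0.1, 400 epochs of Adam at 2e-4 dropping to 2e-5
    after epoch 200). ``base_width``, ``latent_shape`` and ``epochs`` can
    be shrunk for CPU-scale experiments; ``kernel_size=2`` (with no
    padding) yields an encoder whose latent cells have exactly
    non-overlapping 32x32 receptive fields, useful for locality probes.
    """

    latent_shape: tuple[int, int, int] = (3, 3, 128)
    l1_weight: float = 500.0
    input_noise_variance: float = 0.1
    epochs: int = 400
    lr_initial: float = 2e-4
    lr_reduced: float = 2e-5
    lr_switch_epoch: int = 200
    batch_size: int = 32
    augment_rotations: bool = True
    augment_flips: bool = True
    seed: int = 0
    patch_px: int = 96
    base_width: int = 32
    kernel_size: int = 4
    disc_fc: int = 128
    reg_hidden: int = 128
    critic_lr_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.l1_weight < 0:
            raise ValueError(f"l1_weight must be >= 0, got {self.l1_weight}")
        if self.input_noise_variance < 0:
            raise ValueError("input_noise_variance must be >= 0")
        if self.lr_initial <= 0 or self.lr_reduced <= 0:
            raise ValueError("learning rates must be > 0")
        if self.lr_switch_epoch > self.epochs:
            raise ValueError(
                f"lr_switch_epoch ({self.lr_switch_epoch}) must be <= epochs "
                f"({self.epochs})")
        if self.critic_lr_scale <= 0:
            raise ValueError("critic_lr_scale must be > 0")
        if self.kernel_size not in (2, 4):
            raise ValueError("kernel_size must be 2 or 4")
        sh, sw, _ = self.latent_shape
        if sh != sw:
            raise ValueError("latent grid must be square")
        stages = self._stages
        if self.patch_px != sh * 2**stages or stages < 1:
            raise ValueError(
                f"patch_px ({self.patch_px}) must be latent side ({sh}) "
                f"times a power of 2")

    @property
    def _stages(self) -> int:
        ratio = self.patch_px / self.latent_shape[0]
        return max(int(round(np.log2(ratio))), 0)


@dataclass
class NetworkBundle:
    """The four networks plus their configuration and training state."""

    encoder: nn.Sequential
    decoder: nn.Sequential
    discriminator: nn.Sequential
    regularizer: nn.Sequential
    config: ModelConfig
    trained: bool = False

    def nets(self) -> list[nn.Sequential]:
        return [self.encoder, self.decoder, self.discriminator,
                self.regularizer]


def _conv_geometry(k: int) -> tuple[int, int]:
    # stride-2 halving: k=4 needs pad 1, k=2 pad 0
    return (2, 1 if k == 4 else 0)


def build_bundle(config: ModelConfig) -> NetworkBundle:
    """Initialize the four networks from ``config.seed`` (untrained)."""
    rng = np.random.Generator(np.random.Philox(config.seed))
    sh, _, c_lat = config.latent_shape
    k = config.kernel_size
    stride, pad = _conv_geometry(k)
    stages = config._stages
    w = config.base_width
    widths = [min(w * 2**i, 8 * w) for i in range(stages - 1)]

    enc: list[nn.Layer] = []
    cin = 1
    for i, cout in enumerate(widths):
        enc.append(nn.Conv2d(cin, cout, k, stride, pad, rng))
        if i > 0:
            enc.append(nn.InstanceNorm2d(cout))
        enc.append(nn.LeakyReLU())
        cin = cout
    enc.append(nn.Conv2d(cin, c_lat, k, stride, pad, rng))  # linear latent
    encoder = nn.Sequential(*enc)

    dec: list[nn.Layer] = []
    cin = c_lat
    for cout in reversed(widths):
        dec.append(nn.ConvTranspose2d(cin, cout, k, stride, pad, rng))
        dec.append(nn.InstanceNorm2d(cout))
        dec.append(nn.ReLU())
        cin = cout
    dec.append(nn.ConvTranspose2d(cin, 1, k, stride, pad, rng))
    dec.append(nn.Tanh())
    decoder = nn.Sequential(*dec)

    # discriminator: 4 stride-2 conv blocks then 2 fully connected layers
    disc: list[nn.Layer] = []
    cin = 1
    side = config.patch_px
    for i in range(min(4, stages)):
        cout = min(w * 2**i, 8 * w)
        disc.append(nn.Conv2d(cin, cout, k, stride, pad, rng))
        disc.append(nn.LeakyReLU())
        cin = cout
        side //= 2
    disc.append(nn.Flatten())
    disc.append(nn.Dense(cin * side * side, config.disc_fc, rng))
    disc.append(nn.LeakyReLU())
    disc.append(nn.Dense(config.disc_fc, 1, rng))
    disc.append(nn.Sigmoid())
    discriminator = nn.Sequential(*disc)

    # latent regularizer: exactly three fully connected layers
    d_lat = sh * sh * c_lat
    regularizer = nn.Sequential(
        nn.Flatten(),
        nn.Dense(d_lat, config.reg_hidden, rng), nn.LeakyReLU(),
        nn.Dense(config.reg_hidden, config.reg_hidden, rng), nn.LeakyReLU(),
        nn.Dense(config.reg_hidden, 1, rng), nn.Sigmoid(),
    )
    return NetworkBundle(encoder, decoder, discriminator, regularizer,
                         config)


# ------------------------------------------------------- data transforms

def add_input_noise(patch: np.ndarray, variance: float,
                    seed: int | np.random.Generator = 0) -> np.ndarray:
    """Add i.i.d. Gaussian noise with the given *variance* (not sd).

    Used only during training to make the autoencoder denoising; the noise
    standard deviation is ``sqrt(variance)``.
    """
    if variance < 0:
        raise ValueError(f"variance must be >= 0, got {variance}")
    patch = np.asarray(patch, dtype=float)
    if variance == 0:
        return patch.copy()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.Generator(np.random.Philox(seed)))
    return patch + rng.normal(0.0, np.sqrt(variance), patch.shape)


def augment(patch: np.ndarray,
            seed: int | np.random.Generator = 0,
            rotations: bool = True, flips: bool = True) -> np.ndarray:
    """Random 90-degree rotation plus independent up-down/left-right flips.

    The rotation is uniform over {0, 90, 180, 270} degrees and each flip
    is applied with probability 1/2, so the pixel multiset is preserved
    exactly. Requires a square patch.
    """
    patch = np.asarray(patch)
    if patch.shape[-1] != patch.shape[-2]:
        raise ValueError(f"augment requires square patches, got shape "
                         f"{patch.shape}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.Generator(np.random.Philox(seed)))
    out = patch
    if rotations:
        out = np.rot90(out, k=int(rng.integers(4)), axes=(-2, -1))
    if flips:
        if rng.random() < 0.5:
            out = np.flip(out, axis=-2)
        if rng.random() < 0.5:
            out = np.flip(out, axis=-1)
    return out.copy()


# ------------------------------------------------------------- inference

def _as_batch(patch: np.ndarray, side: int) -> tuple[np.ndarray, bool]:
    patch = np.asarray(patch, dtype=nn.DTYPE)
    single = patch.ndim == 2
    if single:
        patch = patch[None]
    if patch.ndim != 3 or patch.shape[1] != side or patch.shape[2] != side:
        raise ValueError(
            f"expected patches of shape ({side}, {side}), got "
            f"{patch.shape[-2:]}")
    return patch[:, None], single  # NCHW


def encode(patch: np.ndarray, bundle: NetworkBundle) -> np.ndarray:
    """Encode patch(es) to latent code(s) of shape ``(S, S, C)``.

    Deterministic: no input noise is applied at inference.
    """
    x, single = _as_batch(patch, bundle.config.patch_px)
    z = bundle.encoder.forward(x, train=False)  # (N, C, S, S)
    z = np.transpose(z, (0, 2, 3, 1))  # (N, S, S, C)
    return z[0] if single else z


def decode(latent: np.ndarray, bundle: NetworkBundle) -> np.ndarray:
    """Decode latent code(s) to patch(es) in [-1, 1]."""
    latent = np.asarray(latent, dtype=float)
    shape = bundle.config.latent_shape
    single = latent.ndim == 3
    if single:
        latent = latent[None]
    if latent.shape[1:] != shape:
        raise ValueError(
            f"expected latent shape {shape}, got {latent.shape[1:]}")
    z = np.transpose(latent, (0, 3, 1, 2)).astype(nn.DTYPE)
    x = bundle.decoder.forward(z, train=False)[:, 0]
    return x[0] if single else x


def reconstruct(patch: np.ndarray, bundle: NetworkBundle) -> np.ndarray:
    """Deterministic encode-decode round trip (no latent modification)."""
    return decode(encode(patch, bundle), bundle)


# ----------------------------------------------------------------- losses

def reconstruction_l1(x: np.ndarray, xhat: np.ndarray) -> float:
    """Mean absolute pixel-wise difference."""
    x = np.asarray(x, dtype=float)
    xhat = np.asarray(xhat, dtype=float)
    if x.shape != xhat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {xhat.shape}")
    return float(np.mean(np.abs(x - xhat)))


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(p, VERDICT_CLAMP, 1.0 - VERDICT_CLAMP)


def decoder_loss(x: np.ndarray, xhat: np.ndarray, verdicts: np.ndarray,
                 l1_weight: float) -> float:
    """Weighted L1 plus the non-saturating adversarial generator term.

    ``loss = l1_weight * mean|x - xhat| - mean(log D(xhat))`` where the
    ``verdicts`` are the discriminator's real-probabilities for the
    reconstructions, clamped away from {0, 1}.
    """
    if l1_weight < 0:
        raise ValueError(f"l1_weight must be >= 0, got {l1_weight}")
    verdicts = np.asarray(verdicts, dtype=float)
    if verdicts.min() < 0.0 or verdicts.max() > 1.0:
        raise ValueError(
            f"discriminator verdicts must lie in [0, 1]; got range "
            f"[{verdicts.min():g}, {verdicts.max():g}]")
    adv = -np.mean(np.log(_clamp(verdicts)))
    return float(l1_weight * reconstruction_l1(x, xhat) + adv)


def _binary_adv_loss(p_real: np.ndarray, p_fake: np.ndarray) -> float:
    """Two-term discriminator objective -E log p_real - E log(1 - p_fake)."""
    p_real = _clamp(np.asarray(p_real, dtype=float))
    p_fake = _clamp(np.asarray(p_fake, dtype=float))
    return float(-np.mean(np.log(p_real)) - np.mean(np.log(1.0 - p_fake)))


def adversarial_losses(
    real: np.ndarray,
    fake: np.ndarray,
    latent: np.ndarray,
    prior: np.ndarray,
    bundle: NetworkBundle,
) -> dict[str, float]:
    """Evaluate all adversarial objectives on the given batches.

    The data discriminator separates real patches from decoder outputs;
    the latent regularizer separates standard-normal samples (its "real"
    class) from encoder outputs. Generator-side terms are the
    non-saturating ``-E log D(fake)`` / ``-E log R(latent)``. Returns a
    dict with keys ``discriminator``, ``regularizer``, ``gen_decoder``,
    ``gen_encoder``.
    """
    if min(len(real), len(fake), len(latent), len(prior)) == 0:
        raise ValueError("batches must be nonempty")
    side = bundle.config.patch_px
    xr, _ = _as_batch(real, side)
    xf, _ = _as_batch(fake, side)
    p_real = bundle.discriminator.forward(xr, train=False).ravel()
    p_fake = bundle.discriminator.forward(xf, train=False).ravel()

    z = np.asarray(latent, dtype=float)
    if z.ndim == 3:
        z = z[None]
    zp = np.asarray(prior, dtype=float)
    if zp.ndim == 3:
        zp = zp[None]
    r_lat = bundle.regularizer.forward(
        np.transpose(z, (0, 3, 1, 2)), train=False).ravel()
    r_prior = bundle.regularizer.forward(
        np.transpose(zp, (0, 3, 1, 2)), train=False).ravel()

    return {
        "discriminator": _binary_adv_loss(p_real, p_fake),
        "regularizer": _binary_adv_loss(r_prior, r_lat),
        "gen_decoder": float(-np.mean(np.log(_clamp(p_fake)))),
        "gen_encoder": float(-np.mean(np.log(_clamp(r_lat)))),
    }


# --------------------------------------------------------------- training

def _augment_batch(batch: np.ndarray, cfg: ModelConfig,
                   rng: np.random.Generator) -> np.ndarray:
    if not (cfg.augment_rotations or cfg.augment_flips):
        return batch
    return np.stack([
        augment(p, rng, rotations=cfg.augment_rotations,
                flips=cfg.augment_flips)
        for p in batch
    ])


def train_model(dataset: np.ndarray, config: ModelConfig,
                verbose: bool = False) -> tuple[NetworkBundle, pd.DataFrame]:
    """Train the IAE on a stack of normalized patches.

    ``dataset`` is ``(n, patch_px, patch_px)`` with values in [-1, 1].
    Per batch, three updates run in order: data discriminator, latent
    regularizer, then one joint encoder+decoder step on
    ``l1_weight * L1 + adversarial terms``. Input noise and augmentation
    are applied only here, never at inference. Returns the trained bundle
    and a per-epoch history (mean batch losses and the learning rate).
    """
    dataset = np.asarray(dataset, dtype=nn.DTYPE)
    if dataset.ndim != 3 or len(dataset) == 0:
        raise ValueError("dataset must be a nonempty (n, H, W) patch stack")
    side = config.patch_px
    if dataset.shape[1:] != (side, side):
        raise ValueError(
            f"expected ({side}, {side}) patches, got {dataset.shape[1:]}")

    bundle = build_bundle(config)
    rng = np.random.Generator(np.random.Philox([config.seed, 0xA5]))
    enc, dec = bundle.encoder, bundle.decoder
    disc, reg = bundle.discriminator, bundle.regularizer
    opt_d = nn.Adam([disc], config.lr_initial)
    opt_r = nn.Adam([reg], config.lr_initial)
    opt_g = nn.Adam([enc, dec], config.lr_initial)

    sh, sw, c_lat = config.latent_shape
    lam = config.l1_weight
    n = len(dataset)
    bs = min(config.batch_size, n)
    records = []
    for epoch in range(1, config.epochs + 1):
        lr = (config.lr_initial if epoch <= config.lr_switch_epoch
              else config.lr_reduced)
        opt_g.lr = lr
        opt_d.lr = opt_r.lr = lr * config.critic_lr_scale
        order = rng.permutation(n)
        ep = {"recon_l1": [], "dec_adv": [], "disc_loss": [], "reg_loss": []}
        for start in range(0, n - bs + 1, bs):
            idx = order[start:start + bs]
            x = _augment_batch(dataset[idx], config, rng)[:, None]
            x_noisy = add_input_noise(
                x, config.input_noise_variance, rng).astype(nn.DTYPE)

            z = enc.forward(x_noisy)          # (B, C, S, S)
            xhat = dec.forward(z)

            # -- discriminator step (generator outputs held fixed)
            b = len(idx)
            p = disc.forward(np.concatenate([x, xhat])).ravel()
            p_real, p_fake = _clamp(p[:b]), _clamp(p[b:])
            d_loss = _binary_adv_loss(p_real, p_fake)
            dp = np.concatenate([-1.0 / p_real, 1.0 / (1.0 - p_fake)]) / b
            disc.backward(dp[:, None])
            opt_d.step()

            # -- regularizer step
            prior = rng.standard_normal(z.shape, dtype=nn.DTYPE)
            q = reg.forward(np.concatenate([prior, z])).ravel()
            q_real, q_fake = _clamp(q[:b]), _clamp(q[b:])
            r_loss = _binary_adv_loss(q_real, q_fake)
            dq = np.concatenate([-1.0 / q_real, 1.0 / (1.0 - q_fake)]) / b
            reg.backward(dq[:, None])
            opt_r.step()

            # -- joint encoder/decoder step against the updated critics
            p2 = _clamp(disc.forward(xhat).ravel())
            dec_adv = float(-np.mean(np.log(p2)))
            dxhat = disc.backward((-1.0 / p2)[:, None] / b)
            l1 = reconstruction_l1(x, xhat)
            dxhat += lam * np.sign(xhat - x) / x.size
            dz = dec.backward(dxhat)

            q2 = _clamp(reg.forward(z).ravel())
            dz += reg.backward((-1.0 / q2)[:, None] / b)
            enc.backward(dz)
            opt_g.step()

            if not np.isfinite([d_loss, r_loss, l1, dec_adv]).all():
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch "
                    f"{start // bs}: l1={l1}, dec_adv={dec_adv}, "
                    f"disc={d_loss}, reg={r_loss}")
            ep["recon_l1"].append(l1)
            ep["dec_adv"].append(dec_adv)
            ep["disc_loss"].append(d_loss)
            ep["reg_loss"].append(r_loss)

        records.append({
            "epoch": epoch,
            **{k: float(np.mean(v)) for k, v in ep.items()},
            "lr": lr,
        })
        if verbose:
            r = records[-1]
            print(f"epoch {epoch:3d}  l1={r['recon_l1']:.4f}  "
                  f"dec_adv={r['dec_adv']:.3f}  d={r['disc_loss']:.3f}  "
                  f"r={r['reg_loss']:.3f}  lr={lr:g}")

    bundle.trained = config.epochs > 0
    history = pd.DataFrame(
        records, columns=["epoch", "recon_l1", "dec_adv", "disc_loss",
                          "reg_loss", "lr"])
    return bundle, history


# ------------------------------------------------------------ checkpoints

def save_checkpoint(bundle: NetworkBundle, history: pd.DataFrame,
                    path) -> None:
    """Write parameters + config + history to a single ``.npz`` archive."""
    arrays = {}
    for prefix, net in zip(("enc", "dec", "disc", "reg"), bundle.nets()):
        for key, val in net.state_dict().items():
            arrays[f"{prefix}/{key}"] = val
    cfg = asdict(bundle.config)
    meta = json.dumps({"config": cfg, "trained": bundle.trained})
    arrays["__meta__"] = np.frombuffer(meta.encode(), dtype=np.uint8)
    arrays["__history__"] = np.frombuffer(
        history.to_json(orient="split").encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path) -> tuple[NetworkBundle, pd.DataFrame]:
    """Rebuild a bundle from :func:`save_checkpoint` output, bit-identical."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = meta["config"]
        for key in ("latent_shape",):
            cfg[key] = tuple(cfg[key])
        config = ModelConfig(**cfg)
        bundle = build_bundle(config)
        bundle.trained = meta["trained"]
        for prefix, net in zip(("enc", "dec", "disc", "reg"), bundle.nets()):
            state = {k[len(prefix) + 1:]: data[k] for k in data.files
                     if k.startswith(prefix + "/")}
            net.load_state_dict(state)
        history = pd.read_json(
            io.StringIO(bytes(data["__history__"]).decode()), orient="split")
    return bundle, history
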