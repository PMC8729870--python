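"""3D conditional GAN mapping low-count dynamic PET frames to
reference-frame-like images.

One mapping is trained per (non-reference) frame index on motion-free pairs
``(low-count frame i, reference frame)``.  The generator is a 3D U-net-like
encoder-decoder with skip connections; the discriminator is a PatchGAN with
two extra convolutional layers.  The generator minimises

    L(G, D) = E[log D(x, y)] + E[log(1 - D(x, G(x)))]  +  lambda * E|G(x) - y|

with D maximising the first part; dropout in the generator realises the
noise input z and is disabled at inference, making predictions
deterministic.  Outputs are appearance proxies to guide registration, not
quantitative images.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator

from . import nn

EPS = 1e-7


# --------------------------------------------------------------------------- #
# Losses
# --------------------------------------------------------------------------- #


def adversarial_loss(d_real: np.ndarray, d_fake: np.ndarray) -> float:
    """Conditional-GAN minimax value: mean log D(x,y) + log(1 - D(x,G(x))).

    Probabilities are clamped at 1e-7, so the value is always <= 0; the
    uninformative discriminator D = 0.5 gives 2 log 0.5, and the supremum 0 is
    approached only by a perfect discriminator.
    """
    d_real = np.asarray(d_real, dtype=float)
    d_fake = np.asarray(d_fake, dtype=float)
    if d_real.size == 0 or d_fake.size == 0:
        raise ValueError("empty batch")
    d_real = np.clip(d_real, EPS, 1.0 - EPS)
    d_fake = np.clip(d_fake, EPS, 1.0 - EPS)
    return float(np.mean(np.log(d_real)) + np.mean(np.log(1.0 - d_fake)))


def generator_objective(adv_term: float, l1_term: float, lambda_l1: float) -> float:
    """Full generator objective: adversarial term + lambda * L1 term."""
    if lambda_l1 <= 0:
        raise ValueError("lambda_l1 must be > 0")
    return float(adv_term) + lambda_l1 * float(l1_term)


# --------------------------------------------------------------------------- #
# Configuration
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class CGANConfig:
    """Desk-scale defaults: 32^3 patches, depth-3 generator, 16 base channels,
    <= 20 epochs.  A full-scale run (clinical 344x344x127 volumes, taking
    GPU-hours per mapping) uses the same code with larger values; it is
    supported, not defaulted."""

    patch_shape: tuple[int, int, int] = (32, 32, 32)
    depth: int = 3
    base_channels: int = 16
    disc_channels: int = 16
    lambda_l1: float = 1.0
    #: scale on the (non-saturating) adversarial gradient reaching the
    #: generator.  With per-element mean normalisation of both loss terms the
    #: nominal weighting lets the adversarial push swamp the L1 anchor at desk
    #: scale; 0.05 keeps the GAN term a refinement of the L1 reconstruction.
    lambda_adv: float = 0.05
    dropout_rate: float = 0.3
    learning_rate: float = 1e-3
    disc_learning_rate: float = 2e-4
    epochs: int = 12
    batch_size: int = 2
    patches_per_volume: int = 2
    augment: bool = True
    augment_factor: int = 1  # extra augmented copies per pair per epoch
    residual: bool = False  # generator predicts input + correction
    #: zero this many border voxels of every prediction: zero-padded
    #: convolutions hallucinate bright rims at the volume faces, and those
    #: rims are grid-locked, biasing any registration run on mapped images
    edge_crop: int = 3
    norm_percentiles: tuple[float, float] = (0.1, 99.9)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_l1 <= 0:
            raise ValueError("lambda_l1 must be > 0")
        for s in self.patch_shape:
            if s % 2**self.depth:
                raise ValueError(
                    f"patch shape {self.patch_shape} not divisible by 2^depth"
                )


def build_generator(config: CGANConfig, rng: np.random.Generator) -> nn.UNet3D:
    return nn.UNet3D(config.depth, config.base_channels, rng,
                     config.dropout_rate, residual=config.residual)


def build_discriminator(config: CGANConfig, rng: np.random.Generator) -> nn.PatchDiscriminator:
    return nn.PatchDiscriminator(config.disc_channels, rng)


# --------------------------------------------------------------------------- #
# Normalisation and augmentation
# --------------------------------------------------------------------------- #


def robust_bounds(volume: np.ndarray, percentiles=(0.1, 99.9)) -> tuple[float, float]:
    lo, hi = np.percentile(volume, percentiles)
    if hi <= lo:
        hi = lo + 1.0
    return float(lo), float(hi)


def normalize(volume: np.ndarray, lo: float, hi: float) -> np.ndarray:
    v = 2.0 * (volume - lo) / (hi - lo) - 1.0
    return np.clip(v, -1.0, 1.0).astype(nn.DTYPE)


def denormalize(volume: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (volume + 1.0) * 0.5 * (hi - lo) + lo


def augment_pair(
    low: np.ndarray,
    ref: np.ndarray,
    seed: int,
    rotation_deg: float = 5.0,
    translation_vox: float = 2.0,
    shear: float = 0.05,
    noise_sigma: float = 0.03,
    brightness: float = 0.1,
    contrast: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Real-time augmentation: one spatial transform (rotation, translation,
    shear) shared by both volumes so spatial correspondence is preserved, and
    intensity perturbations (Gaussian noise, brightness, contrast) drawn
    independently per volume.  Intensity ranges assume inputs normalised to
    [-1, 1]."""
    if low.shape != ref.shape:
        raise ValueError("paired volumes must share a shape")
    rng = np.random.default_rng(seed)

    angles = rng.uniform(-rotation_deg, rotation_deg, 3)
    shift = rng.uniform(-translation_vox, translation_vox, 3)
    sh = rng.uniform(-shear, shear, 3)
    from scipy.spatial.transform import Rotation

    r = Rotation.from_euler("ZYX", angles, degrees=True).as_matrix()
    shear_m = np.eye(3)
    shear_m[0, 1], shear_m[1, 2], shear_m[0, 2] = sh
    m = r @ shear_m
    centre = (np.array(low.shape) - 1.0) / 2.0
    offset = centre - m @ centre - shift

    def spatial(v):
        if rotation_deg == 0 and translation_vox == 0 and shear == 0:
            return v.copy()
        return ndimage.affine_transform(v, m, offset=offset, order=1, mode="constant")

    def intensity(v):
        gain = 1.0 + rng.uniform(-contrast, contrast)
        bias = rng.uniform(-brightness, brightness)
        noise = rng.normal(0.0, noise_sigma, v.shape) if noise_sigma > 0 else 0.0
        return (v * gain + bias + noise).astype(nn.DTYPE)

    return intensity(spatial(low)), intensity(spatial(ref))


# --------------------------------------------------------------------------- #
# Estimator
# --------------------------------------------------------------------------- #


class CGANFrameMapping(BaseEstimator):
    """Conditional-GAN mapping for one dynamic-frame index.

    scikit-learn style estimator: ``fit(X, y)`` trains the mapping on
    ``X`` = low-count volumes ``(n, D, H, W)`` and ``y`` = matching
    reference-frame volumes; ``predict(X)`` returns reference-like volumes.

    Parameters mirror :class:`CGANConfig`.  Fitted attributes carry a
    trailing underscore: ``generator_``, ``discriminator_``,
    ``loss_history_`` (per-step DataFrame), ``ref_lo_``/``ref_hi_``
    (denormalisation bounds), ``initial_l1_``/``final_l1_``.
    """

    def __init__(
        self,
        frame_index: int | None = None,
        patch_shape: tuple[int, int, int] = (32, 32, 32),
        depth: int = 3,
        base_channels: int = 16,
        disc_channels: int = 16,
        lambda_l1: float = 1.0,
        lambda_adv: float = 0.05,
        dropout_rate: float = 0.3,
        learning_rate: float = 1e-3,
        disc_learning_rate: float = 2e-4,
        epochs: int = 12,
        batch_size: int = 2,
        patches_per_volume: int = 2,
        augment: bool = True,
        augment_factor: int = 1,
        residual: bool = False,
        edge_crop: int = 3,
        norm_percentiles: tuple[float, float] = (0.1, 99.9),
        random_state: int = 0,
    ):
        self.frame_index = frame_index
        self.patch_shape = patch_shape
        self.depth = depth
        self.base_channels = base_channels
        self.disc_channels = disc_channels
        self.lambda_l1 = lambda_l1
        self.lambda_adv = lambda_adv
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.disc_learning_rate = disc_learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.patches_per_volume = patches_per_volume
        self.augment = augment
        self.augment_factor = augment_factor
        self.residual = residual
        self.edge_crop = edge_crop
        self.norm_percentiles = norm_percentiles
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------- #

    def _config(self) -> CGANConfig:
        return CGANConfig(
            patch_shape=tuple(self.patch_shape),
            depth=self.depth,
            base_channels=self.base_channels,
            disc_channels=self.disc_channels,
            lambda_l1=self.lambda_l1,
            lambda_adv=self.lambda_adv,
            dropout_rate=self.dropout_rate,
            learning_rate=self.learning_rate,
            disc_learning_rate=self.disc_learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            patches_per_volume=self.patches_per_volume,
            augment=self.augment,
            augment_factor=self.augment_factor,
            residual=self.residual,
            edge_crop=self.edge_crop,
            norm_percentiles=tuple(self.norm_percentiles),
            rng_seed=self.random_state,
        )

    @staticmethod
    def _validate_volumes(X, name: str) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4:
            raise ValueError(f"{name} must be (n_volumes, D, H, W)")
        if not np.all(np.isfinite(X)):
            raise ValueError(f"{name} contains non-finite values")
        return X

    def _sample_patch(self, rng, *volumes):
        shape = volumes[0].shape
        ps = self._config().patch_shape
        origin = [
            rng.integers(0, max(shape[a] - ps[a], 0) + 1) for a in range(3)
        ]
        sl = tuple(slice(o, o + p) for o, p in zip(origin, ps))
        return [v[sl] for v in volumes]

    # -- API --------------------------------------------------------------- #

    def fit(self, X, y):
        config = self._config()
        X = self._validate_volumes(X, "X")
        Y = self._validate_volumes(y, "y")
        if X.shape != Y.shape:
            raise ValueError("X and y must have identical shapes")
        n = X.shape[0]
        if n < 2:
            raise ValueError("need >= 2 training pairs")
        for a in range(3):
            if X.shape[1 + a] < config.patch_shape[a]:
                raise ValueError("patch shape does not fit in the training volumes")

        rng = np.random.default_rng(config.rng_seed)
        net_rng = np.random.default_rng(rng.integers(2**31))
        self.generator_ = build_generator(config, net_rng)
        self.discriminator_ = build_discriminator(config, net_rng)
        opt_g = nn.Adam(self.generator_.params(), lr=config.learning_rate)
        opt_d = nn.Adam(self.discriminator_.params(), lr=config.disc_learning_rate)

        # per-volume robust normalisation; reference bounds are averaged and
        # stored for denormalising predictions
        xs, ys, ref_bounds = [], [], []
        for i in range(n):
            lo, hi = robust_bounds(X[i], config.norm_percentiles)
            xs.append(normalize(X[i], lo, hi))
            lo, hi = robust_bounds(Y[i], config.norm_percentiles)
            ys.append(normalize(Y[i], lo, hi))
            ref_bounds.append((lo, hi))
        self.ref_lo_ = float(np.mean([b[0] for b in ref_bounds]))
        self.ref_hi_ = float(np.mean([b[1] for b in ref_bounds]))
        self.input_shape_ = X.shape[1:]

        self.initial_l1_ = self._l1_loss(xs, ys)

        history = []
        step = 0
        lam = config.lambda_l1
        for epoch in range(config.epochs):
            order = rng.permutation(n)
            samples = []
            for i in order:
                xi, yi = xs[i], ys[i]
                copies = [(xi, yi)]
                if config.augment:
                    for _ in range(config.augment_factor):
                        copies.append(
                            augment_pair(xi, yi, int(rng.integers(2**31)))
                        )
                for cx, cy in copies:
                    for _ in range(config.patches_per_volume):
                        px, py = self._sample_patch(rng, cx, cy)
                        samples.append((px, py))
            rng.shuffle(samples)
            for k in range(0, len(samples), config.batch_size):
                batch = samples[k : k + config.batch_size]
                if len(batch) < 1:
                    continue
                bx = np.stack([s[0] for s in batch])[:, None]
                by = np.stack([s[1] for s in batch])[:, None]
                d_loss, g_adv, g_l1 = self._train_step(
                    bx, by, opt_g, opt_d, lam, config.lambda_adv
                )
                history.append(
                    {"step": step, "epoch": epoch, "adv_loss": d_loss,
                     "g_adv": g_adv, "g_l1": g_l1,
                     "g_objective": generator_objective(g_adv, g_l1, lam)}
                )
                step += 1
        self.loss_history_ = pd.DataFrame(history)
        self.final_l1_ = self._l1_loss(xs, ys)
        return self

    def _train_step(self, bx, by, opt_g, opt_d, lam, lam_adv):
        g = self.generator_
        d = self.discriminator_
        m = bx.shape[0]

        # ---- discriminator: maximise Eq. 1 (minimise BCE on real/fake)
        fake = g.forward(bx, train=True)
        inp = np.concatenate(
            [np.concatenate([bx, by], axis=1), np.concatenate([bx, fake], axis=1)],
            axis=0,
        )
        logits = d.forward(inp, train=True)
        probs = nn.sigmoid(logits)
        target = np.zeros_like(probs)
        target[:m] = 1.0
        opt_d.zero_grad()
        d.backward(((probs - target) / probs.size).astype(nn.DTYPE))
        opt_d.step()
        eq1 = adversarial_loss(probs[:m], probs[m:])

        # ---- generator: non-saturating adversarial + lambda * L1
        fake = g.forward(bx, train=True)
        logits = d.forward(np.concatenate([bx, fake], axis=1), train=True)
        probs = nn.sigmoid(logits)
        # d(-log D)/dlogit = D - 1 ; route through D to the fake channel
        g_from_d = d.backward(
            (lam_adv * (probs - 1.0) / probs.size).astype(nn.DTYPE)
        )[:, 1:2]
        l1 = float(np.mean(np.abs(fake - by)))
        g_l1_grad = lam * np.sign(fake - by) / fake.size
        opt_g.zero_grad()
        g.backward((g_from_d + g_l1_grad).astype(nn.DTYPE))
        opt_g.step()
        g_adv = float(-np.mean(np.log(np.clip(probs, EPS, 1 - EPS))))
        return eq1, g_adv, l1

    def _l1_loss(self, xs, ys) -> float:
        """Mean absolute error over centred patches, dropout off."""
        config = self._config()
        vals = []
        for xi, yi in zip(xs, ys):
            sl = tuple(
                slice((s - p) // 2, (s - p) // 2 + p)
                for s, p in zip(xi.shape, config.patch_shape)
            )
            pred = self.generator_.forward(xi[sl][None, None], train=False)
            vals.append(float(np.mean(np.abs(pred[0, 0] - yi[sl]))))
        return float(np.mean(vals))

    def predict(self, X):
        if not hasattr(self, "generator_"):
            raise RuntimeError("mapping is not fitted")
        X = self._validate_volumes(X, "X")
        if tuple(X.shape[1:]) != tuple(self.input_shape_):
            raise ValueError(
                f"volume shape {X.shape[1:]} does not match training shape "
                f"{tuple(self.input_shape_)}"
            )
        out = np.empty_like(X)
        for i in range(X.shape[0]):
            lo, hi = robust_bounds(X[i], self._config().norm_percentiles)
            norm = normalize(X[i], lo, hi)
            mapped = tiled_inference(
                self.generator_, norm, self._config().patch_shape
            )
            vol = denormalize(mapped, self.ref_lo_, self.ref_hi_)
            w = int(self.edge_crop)
            if w > 0:  # pad-contaminated rim carries no anatomy
                for axis in range(3):
                    sl_lo = [slice(None)] * 3
                    sl_hi = [slice(None)] * 3
                    sl_lo[axis] = slice(0, w)
                    sl_hi[axis] = slice(vol.shape[axis] - w, None)
                    vol[tuple(sl_lo)] = 0.0
                    vol[tuple(sl_hi)] = 0.0
            out[i] = vol
        return out


def tiled_inference(
    generator: nn.UNet3D, volume: np.ndarray, patch_shape: Sequence[int]
) -> np.ndarray:
    """Run the generator over overlapping tiles and blend with a separable
    triangular window; equals single-pass inference when one patch covers the
    whole volume."""
    shape = volume.shape
    step = 2**generator.depth
    if all(s % step == 0 for s in shape):
        # fully convolutional: a single whole-volume pass avoids tile seams
        out = generator.forward(volume[None, None].astype(nn.DTYPE), train=False)
        return out[0, 0]
    ps = tuple(min(p, s) for p, s in zip(patch_shape, shape))
    # pad so every dimension fits at least one patch and is reachable by tiles
    pad = [max(p - s, 0) for p, s in zip(ps, shape)]
    vol = np.pad(volume, [(0, p) for p in pad]) if any(pad) else volume

    if tuple(vol.shape) == tuple(ps):
        out = generator.forward(vol[None, None].astype(nn.DTYPE), train=False)[0, 0]
        return out[: shape[0], : shape[1], : shape[2]]

    def window(n):
        w = 1.0 - np.abs(np.linspace(-1, 1, n))
        return np.maximum(w, 0.05)

    w3 = (
        window(ps[0])[:, None, None]
        * window(ps[1])[None, :, None]
        * window(ps[2])[None, None, :]
    ).astype(nn.DTYPE)

    acc = np.zeros(vol.shape, dtype=np.float64)
    wacc = np.zeros(vol.shape, dtype=np.float64)
    starts = []
    for a in range(3):
        stride = max(ps[a] // 2, 1)
        s = list(range(0, max(vol.shape[a] - ps[a], 0) + 1, stride))
        if s[-1] != vol.shape[a] - ps[a]:
            s.append(vol.shape[a] - ps[a])
        starts.append(sorted(set(s)))
    for i in starts[0]:
        for j in starts[1]:
            for k in starts[2]:
                sl = (slice(i, i + ps[0]), slice(j, j + ps[1]), slice(k, k + ps[2]))
                tile = generator.forward(
                    vol[sl][None, None].astype(nn.DTYPE), train=False
                )[0, 0]
                acc[sl] += tile * w3
                wacc[sl] += w3
    out = (acc / wacc).astype(nn.DTYPE)
    return out[: shape[0], : shape[1], : shape[2]]


# --------------------------------------------------------------------------- #
# Functional wrappers and serialisation
# --------------------------------------------------------------------------- #


def train_mapping(
    training_pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    config: CGANConfig,
    frame_index: int | None = None,
) -> CGANFrameMapping:
    """Train the mapping for one frame index from motion-free pairs."""
    if len(training_pairs) < 2:
        raise ValueError("need >= 2 training pairs")
    X = np.stack([p[0] for p in training_pairs])
    Y = np.stack([p[1] for p in training_pairs])
    model = CGANFrameMapping(frame_index=frame_index, **_config_to_kwargs(config))
    return model.fit(X, Y)


def apply_mapping(model: CGANFrameMapping, low_count_frame: np.ndarray) -> np.ndarray:
    """Produce the artificially generated high-count image for one frame."""
    return model.predict(np.asarray(low_count_frame)[None])[0]


def _config_to_kwargs(config: CGANConfig) -> dict:
    d = asdict(config)
    d["random_state"] = d.pop("rng_seed")
    return d


def save_mapping(model: CGANFrameMapping, path) -> None:
    """Single-file serialisation: config + normalisation + weights + losses."""
    meta = {
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in model.get_params().items()},
        "ref_lo": model.ref_lo_,
        "ref_hi": model.ref_hi_,
        "input_shape": list(model.input_shape_),
        "initial_l1": model.initial_l1_,
        "final_l1": model.final_l1_,
    }
    arrays = {f"g_{i}": w for i, w in enumerate(model.generator_.state())}
    arrays.update({f"d_{i}": w for i, w in enumerate(model.discriminator_.state())})
    buf = io.StringIO()
    model.loss_history_.to_csv(buf, index=False)
    np.savez(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        losses=np.frombuffer(buf.getvalue().encode(), dtype=np.uint8),
        **arrays,
    )


def load_mapping(path) -> CGANFrameMapping:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        params = meta["params"]
        for key in ("patch_shape", "norm_percentiles"):
            params[key] = tuple(params[key])
        model = CGANFrameMapping(**params)
        rng = np.random.default_rng(0)
        model.generator_ = build_generator(model._config(), rng)
        model.discriminator_ = build_discriminator(model._config(), rng)
        g_arrays = [data[f"g_{i}"] for i in range(len(model.generator_.state()))]
        d_arrays = [data[f"d_{i}"] for i in range(len(model.discriminator_.state()))]
        model.generator_.load_state(g_arrays)
        model.discriminator_.load_state(d_arrays)
        model.ref_lo_ = meta["ref_lo"]
        model.ref_hi_ = meta["ref_hi"]
        model.input_shape_ = tuple(meta["input_shape"])
        model.initial_l1_ = meta["initial_l1"]
        model.final_l1_ = meta["final_l1"]
        model.loss_history_ = pd.read_csv(io.StringIO(bytes(data["losses"]).decode()))
    return model
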