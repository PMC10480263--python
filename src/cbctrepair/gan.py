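"""Conditional adversarial image-translation model.

The generator is an encoder–decoder U-Net: eight stride-2 convolution stages
(batch-normalised from the second stage, leaky-ReLU activations) down to a
2x2 bottleneck at 512-px input, mirrored by eight transposed-convolution
stages whose activations are depth-concatenated with the matching encoder
activation; dropout regularises the four innermost decoder stages; a final
convolution maps back to one channel. At full scale the flattened listing of
this architecture is exactly 61 layers. A 70-px-receptive-field patch
discriminator judges (input, candidate) channel pairs, and the generator is
trained against the adversarial term plus a strongly weighted L1 term — the
canonical pix2pix recipe.

Patient-specific transfer learning retrains only the last
``n_trainable_param_layers`` weight-bearing generator layers (default 2: the
final decoder batch-norm and the terminal convolution); every other
parameter is frozen bit-exactly.

The model is exposed as a scikit-learn-style estimator
(:class:`Pix2PixGAN`), with thin module-level wrappers for building,
training, inference and transfer.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .nn import Adam, BatchNorm2d, Conv2d, ConvTranspose2d, Dropout, LeakyReLU, Tanh
from .phantom import HU_MAX, HU_MIN

_HALF_RANGE = (HU_MAX - HU_MIN) / 2.0  # 2047.5


def normalize_hu(img: np.ndarray) -> np.ndarray:
    """Affine map of the HU range [-1024, 3071] onto [-1, 1].

    Field-of-view-exterior pixels stored as 0 map through the same affine
    (to 0 - (-1024))/2047.5 - 1 = -0.4998...; the network sees them as a
    distinct flat level rather than as air.
    """
    return ((np.asarray(img, np.float32) - HU_MIN) / _HALF_RANGE - 1.0).astype(np.float32)


def denormalize_hu(x: np.ndarray) -> np.ndarray:
    """Inverse of :func:`normalize_hu`."""
    return ((np.asarray(x, np.float32) + 1.0) * _HALF_RANGE + HU_MIN).astype(np.float32)


@dataclass(frozen=True)
class GeneratorSpec:
    """Architecture description of the U-Net generator.

    ``encoder_depth`` stride-2 stages halve the resolution each; the
    bottleneck spatial size input_size / 2**encoder_depth must be a positive
    integer. The full-scale profile is (512, 64, depth 8); the desk-scale
    profile used throughout the tests is (64-128 px, 8-16 filters, depth
    chosen so the bottleneck is >= 1).
    """

    input_size: int = 512
    base_filters: int = 64
    encoder_depth: int = 8
    n_dropout_stages: int = 4
    leaky_slope: float = 0.2
    dropout_rate: float = 0.5
    final_activation: str = "tanh"  # or "linear"

    def __post_init__(self):
        bottleneck = self.input_size / 2**self.encoder_depth
        if bottleneck < 1 or bottleneck != int(bottleneck):
            raise ValueError(
                f"input_size {self.input_size} with {self.encoder_depth} down-samplings "
                f"gives a non-integral or empty bottleneck ({bottleneck})"
            )
        if self.final_activation not in ("tanh", "linear"):
            raise ValueError("final_activation must be 'tanh' or 'linear'")


class UNetGenerator:
    """Encoder-decoder generator with skip connections; explicit backprop."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        self.spec = spec
        d, f = spec.encoder_depth, spec.base_filters
        ch = [min(f * 2**i, 8 * f) for i in range(d)]
        self.ch = ch
        self.n_drop = min(spec.n_dropout_stages, d)
        drop_rng = np.random.default_rng(rng.integers(0, 2**31))

        self.enc_convs = [
            Conv2d(1 if i == 0 else ch[i - 1], ch[i], rng=rng) for i in range(d)
        ]
        self.enc_bns = [None] + [BatchNorm2d(ch[i], rng=rng) for i in range(1, d)]
        self.enc_acts = [LeakyReLU(spec.leaky_slope) for _ in range(d)]

        out_ch = [ch[d - 2 - j] if j <= d - 2 else f for j in range(d)]
        in_ch = [ch[d - 1]] + [out_ch[j - 1] + ch[d - 1 - j] for j in range(1, d)]
        self.dec_tconvs = [ConvTranspose2d(in_ch[j], out_ch[j], rng=rng) for j in range(d)]
        self.dec_bns = [BatchNorm2d(out_ch[j], rng=rng) for j in range(d)]
        self.dec_drops = [
            Dropout(spec.dropout_rate, rng=drop_rng) if j < self.n_drop else None
            for j in range(d)
        ]
        self.dec_acts = [LeakyReLU(spec.leaky_slope) for _ in range(d)]

        # terminal convolution: (f + 1 input channels after the full-resolution
        # concat with the input image) -> 1, stride 1, size-preserving
        self.final_conv = Conv2d(out_ch[-1] + 1, 1, k=3, stride=1, pad=1, rng=rng)
        self.final_act = Tanh() if spec.final_activation == "tanh" else None

    # -- introspection ------------------------------------------------------

    def layer_listing(self) -> list[str]:
        """Flattened layer-kind sequence (61 entries at depth 8)."""
        d = self.spec.encoder_depth
        kinds = ["Image Input Layer", "Convolution 2D Layer", "Leaky ReLU Layer"]
        for _ in range(1, d):
            kinds += ["Convolution 2D Layer", "Batch Normalization Layer", "Leaky ReLU Layer"]
        for j in range(d):
            kinds += ["Transposed Convolution 2D Layer", "Batch Normalization Layer"]
            if j < self.n_drop:
                kinds += ["Dropout Layer"]
            kinds += ["Leaky ReLU Layer", "Depth Concatenation Layer"]
        kinds += ["Convolution 2D Layer"]
        return kinds

    def parameterized_layers(self) -> list:
        layers = [self.enc_convs[0]]
        for i in range(1, self.spec.encoder_depth):
            layers += [self.enc_convs[i], self.enc_bns[i]]
        for j in range(self.spec.encoder_depth):
            layers += [self.dec_tconvs[j], self.dec_bns[j]]
        layers.append(self.final_conv)
        return layers

    def all_layers(self) -> list:
        return self.parameterized_layers()

    def checksums(self) -> list[str]:
        return [l.checksum() for l in self.parameterized_layers()]

    def set_freeze_mask(self, n_trainable: int | None) -> None:
        """Freeze all but the last ``n_trainable`` parameterized layers."""
        layers = self.parameterized_layers()
        if n_trainable is None:
            n_trainable = len(layers)
        if not 1 <= n_trainable <= len(layers):
            raise ValueError(
                f"n_trainable_param_layers must be in [1, {len(layers)}], got {n_trainable}"
            )
        for i, layer in enumerate(layers):
            layer.trainable = i >= len(layers) - n_trainable

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        d = self.spec.encoder_depth
        enc = []
        h = x
        for i in range(d):
            h = self.enc_convs[i].forward(h, training)
            if self.enc_bns[i] is not None:
                h = self.enc_bns[i].forward(h, training)
            h = self.enc_acts[i].forward(h, training)
            enc.append(h)
        self._enc_shapes = [e.shape for e in enc]
        self._x_shape = x.shape
        h = enc[-1]
        self._split = []
        for j in range(d):
            h = self.dec_tconvs[j].forward(h, training)
            h = self.dec_bns[j].forward(h, training)
            if self.dec_drops[j] is not None:
                h = self.dec_drops[j].forward(h, training)
            h = self.dec_acts[j].forward(h, training)
            skip = enc[d - 2 - j] if j < d - 1 else x
            self._split.append(h.shape[1])
            h = np.concatenate([h, skip], axis=1)
        h = self.final_conv.forward(h, training)
        if self.final_act is not None:
            h = self.final_act.forward(h, training)
        return h

    def backward(self, g: np.ndarray) -> np.ndarray:
        d = self.spec.encoder_depth
        if self.final_act is not None:
            g = self.final_act.backward(g)
        g = self.final_conv.backward(g)
        enc_grads = [np.zeros(s, dtype=np.float32) for s in self._enc_shapes]
        x_grad = np.zeros(self._x_shape, dtype=np.float32)
        for j in range(d - 1, -1, -1):
            nch = self._split[j]
            g, g_skip = g[:, :nch], g[:, nch:]
            if j < d - 1:
                enc_grads[d - 2 - j] += g_skip
            else:
                x_grad += g_skip
            g = self.dec_acts[j].backward(g)
            if self.dec_drops[j] is not None:
                g = self.dec_drops[j].backward(g)
            g = self.dec_bns[j].backward(g)
            g = self.dec_tconvs[j].backward(g)
        enc_grads[d - 1] += g
        g = enc_grads[d - 1]
        for i in range(d - 1, -1, -1):
            g = self.enc_acts[i].backward(g)
            if self.enc_bns[i] is not None:
                g = self.enc_bns[i].backward(g)
            g = self.enc_convs[i].backward(g)
            if i > 0:
                g = g + enc_grads[i - 1]
        return x_grad + g


class PatchDiscriminator:
    """70-px receptive-field conditional patch discriminator.

    Consumes the channel-concatenated (input, candidate) pair and emits a
    spatial grid of realness logits; each unit judges one local patch.
    """

    ARCH = [(4, 2), (4, 2), (4, 2), (4, 1), (4, 1)]  # (kernel, stride) per conv

    def __init__(self, base_filters: int, rng: np.random.Generator):
        f = base_filters
        chans = [2, f, 2 * f, 4 * f, 8 * f, 1]
        self.convs, self.bns, self.acts = [], [], []
        for i, (k, s) in enumerate(self.ARCH):
            self.convs.append(Conv2d(chans[i], chans[i + 1], k=k, stride=s, pad=1, rng=rng))
            self.bns.append(BatchNorm2d(chans[i + 1], rng=rng) if 0 < i < len(self.ARCH) - 1 else None)
            self.acts.append(LeakyReLU(0.2) if i < len(self.ARCH) - 1 else None)

    @classmethod
    def receptive_field(cls) -> int:
        rf, jump = 1, 1
        for k, s in cls.ARCH:
            rf += (k - 1) * jump
            jump *= s
        return rf

    def all_layers(self) -> list:
        out = []
        for c, b in zip(self.convs, self.bns):
            out.append(c)
            if b is not None:
                out.append(b)
        return out

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        h = x
        for conv, bn, act in zip(self.convs, self.bns, self.acts):
            h = conv.forward(h, training)
            if bn is not None:
                h = bn.forward(h, training)
            if act is not None:
                h = act.forward(h, training)
        return h

    def backward(self, g: np.ndarray) -> np.ndarray:
        for conv, bn, act in zip(reversed(self.convs), reversed(self.bns), reversed(self.acts)):
            if act is not None:
                g = act.backward(g)
            if bn is not None:
                g = bn.backward(g)
            g = conv.backward(g)
        return g


def _bce_with_logits(logits: np.ndarray, target: float, weight: float = 1.0):
    """Stable binary cross-entropy on logits; returns (loss, dloss/dlogits)."""
    loss = np.maximum(logits, 0) - logits * target + np.log1p(np.exp(-np.abs(logits)))
    sig = 1.0 / (1.0 + np.exp(-logits))
    grad = weight * (sig - target) / logits.size
    return weight * float(loss.mean()), grad.astype(np.float32)


class Pix2PixGAN(BaseEstimator):
    """Conditional-adversarial image translator (scikit-learn estimator API).

    ``fit(X, y)`` trains the generator to map input slices X to target
    slices y (both (n, H, W) arrays in HU); ``predict(X)`` returns
    HU-clamped translations. ``transfer(X, y, ...)`` returns a new
    patient-specific estimator with all but the last
    ``n_trainable_param_layers`` generator layers frozen.

    Parameters mirror the pix2pix defaults: Adam(lr 2e-4, beta1 0.5),
    adversarial + ``l1_weight`` x L1 loss, batch size 1.
    """

    def __init__(
        self,
        input_size: int = 128,
        base_filters: int = 16,
        encoder_depth: int | None = None,
        n_dropout_stages: int = 4,
        epochs: int = 200,
        learning_rate: float = 2e-4,
        beta1: float = 0.5,
        l1_weight: float = 100.0,
        batch_size: int = 1,
        seed: int = 0,
        final_activation: str = "tanh",
    ):
        self.input_size = input_size
        self.base_filters = base_filters
        self.encoder_depth = encoder_depth
        self.n_dropout_stages = n_dropout_stages
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.l1_weight = l1_weight
        self.batch_size = batch_size
        self.seed = seed
        self.final_activation = final_activation

    # -- construction -------------------------------------------------------

    def _spec(self) -> GeneratorSpec:
        depth = self.encoder_depth
        if depth is None:
            depth = min(8, int(np.log2(self.input_size)))
        return GeneratorSpec(
            input_size=self.input_size,
            base_filters=self.base_filters,
            encoder_depth=depth,
            n_dropout_stages=self.n_dropout_stages,
            final_activation=self.final_activation,
        )

    def _build(self):
        ss = np.random.SeedSequence(self.seed).spawn(3)
        self.generator_ = UNetGenerator(self._spec(), np.random.default_rng(ss[0]))
        self.discriminator_ = PatchDiscriminator(
            self.base_filters, np.random.default_rng(ss[1])
        )
        self._shuffle_rng = np.random.default_rng(ss[2])
        self.history_ = []

    # -- training -----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Pix2PixGAN":
        X, y = self._validate_pair(X, y)
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        self._build()
        self._train(X, y, self.epochs, self.learning_rate)
        return self

    def _validate_pair(self, X, y):
        X = np.asarray(X, np.float32)
        y = np.asarray(y, np.float32)
        if X.ndim != 3 or X.shape != y.shape:
            raise ValueError("X and y must both be (n_slices, H, W) with equal shapes")
        if X.shape[0] < 1:
            raise ValueError("need at least one training pair")
        if X.shape[1] != self.input_size or X.shape[2] != self.input_size:
            raise ValueError(
                f"slices are {X.shape[1:]}, estimator expects {self.input_size} px"
            )
        return X, y

    def _train(self, X, y, epochs, lr):
        Xn = normalize_hu(X)[:, None]
        Yn = normalize_hu(y)[:, None]
        g_layers = self.generator_.parameterized_layers()
        d_layers = self.discriminator_.all_layers()
        opt_g = Adam(g_layers, lr=lr, beta1=self.beta1)
        opt_d = Adam(d_layers, lr=lr, beta1=self.beta1)
        n = Xn.shape[0]
        for _ in range(epochs):
            order = self._shuffle_rng.permutation(n)
            ep = {"d_loss": 0.0, "g_adv": 0.0, "g_l1": 0.0}
            n_batches = 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = Xn[idx], Yn[idx]
                fake = self.generator_.forward(xb, training=True)

                # discriminator step on (input, target) vs (input, fake)
                opt_d.zero_grad()
                logits_r = self.discriminator_.forward(
                    np.concatenate([xb, yb], axis=1), True
                )
                lr_loss, g_r = _bce_with_logits(logits_r, 1.0, 0.5)
                self.discriminator_.backward(g_r)
                logits_f = self.discriminator_.forward(
                    np.concatenate([xb, fake], axis=1), True
                )
                lf_loss, g_f = _bce_with_logits(logits_f, 0.0, 0.5)
                self.discriminator_.backward(g_f)
                opt_d.step()

                # generator step: adversarial (non-saturating) + weighted L1
                opt_d.zero_grad()
                opt_g.zero_grad()
                logits_g = self.discriminator_.forward(
                    np.concatenate([xb, fake], axis=1), True
                )
                adv_loss, g_adv = _bce_with_logits(logits_g, 1.0)
                d_input_grad = self.discriminator_.backward(g_adv)
                g_fake = d_input_grad[:, 1:2]
                diff = fake - yb
                l1_loss = float(np.abs(diff).mean())
                g_l1 = (self.l1_weight * np.sign(diff) / diff.size).astype(np.float32)
                self.generator_.backward(g_fake + g_l1)
                opt_g.step()

                ep["d_loss"] += lr_loss + lf_loss
                ep["g_adv"] += adv_loss
                ep["g_l1"] += l1_loss
                n_batches += 1
            self.history_.append({k: v / n_batches for k, v in ep.items()})
        if not np.isfinite(self.history_[-1]["g_l1"]):
            raise FloatingPointError(
                f"training diverged: non-finite loss {self.history_[-1]}"
            )
        return self

    # -- inference ----------------------------------------------------------

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Translate slices: normalise, forward, denormalise, clamp to HU."""
        if not hasattr(self, "generator_"):
            raise RuntimeError("estimator is not fitted")
        X = np.asarray(X, np.float32)
        single = X.ndim == 2
        if single:
            X = X[None]
        out = np.empty_like(X)
        for i in range(X.shape[0]):
            y = self.generator_.forward(normalize_hu(X[i])[None, None], training=False)
            out[i] = np.clip(denormalize_hu(y[0, 0]), HU_MIN, HU_MAX)
        return out[0] if single else out

    # -- transfer learning --------------------------------------------------

    def transfer(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int = 500,
        learning_rate: float | None = None,
        n_trainable_param_layers: int = 2,
        seed: int = 0,
    ) -> "Pix2PixGAN":
        """Patient-specific adaptation: retrain only the final generator layers.

        Returns a new estimator; ``self`` (the base model) is untouched.
        With ``epochs=0`` the copy is returned with parameters bit-identical
        to the base.
        """
        if not hasattr(self, "generator_"):
            raise RuntimeError("base estimator is not fitted")
        new = copy.deepcopy(self)
        new.generator_.set_freeze_mask(n_trainable_param_layers)
        new._shuffle_rng = np.random.default_rng(np.random.SeedSequence(seed))
        new.history_ = []
        if epochs > 0:
            X, y = new._validate_pair(X, y)
            new._train(X, y, epochs, learning_rate or self.learning_rate)
        return new


# -- thin functional wrappers ----------------------------------------------

def build_generator(spec: GeneratorSpec, seed: int = 0) -> UNetGenerator:
    return UNetGenerator(spec, np.random.default_rng(seed))

def build_discriminator(base_filters: int = 64, seed: int = 0) -> PatchDiscriminator:
    return PatchDiscriminator(base_filters, np.random.default_rng(seed))

def train(pairs, config: dict) -> tuple[Pix2PixGAN, list[dict]]:
    """Train an estimator from a list of PairedSample-like objects."""
    X = np.stack([p.input_img for p in pairs])
    y = np.stack([p.target_img for p in pairs])
    est = Pix2PixGAN(input_size=X.shape[1], **config)
    est.fit(X, y)
    return est, est.history_

def infer(model: Pix2PixGAN, img: np.ndarray) -> np.ndarray:
    return model.predict(img)

def transfer_learn(base: Pix2PixGAN, pairs, config: dict | None = None) -> Pix2PixGAN:
    cfg = {"epochs": 500, "n_trainable_param_layers": 2, "seed": 0}
    cfg.update(config or {})
    X = np.stack([p.input_img for p in pairs])
    y = np.stack([p.target_img for p in pairs])
    return base.transfer(X, y, **cfg)
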