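"""GAN image-translation deblurring network.

A U-net generator translates a motion-blurred CT image into a clear one; a
convolutional discriminator scores images as real (clear) or generated.
The training objective combines a pixel-wise L2 reconstruction loss with an
adversarial loss, ``L = L_rec + lambda * L_adv`` with ``lambda = 0.01``.

Architecture (all kernels 5x5, leaky-rectifier activations, stride-2
down/upsampling):

* generator encoder: C64-C128-C256-C512-C512-C512; decoder:
  DC512-DC512-DC512-DC256-DC128-DC64 followed by a stride-1 C3 with tanh.
  Skip connections concatenate encoder level l with decoder level 6-l.
* discriminator: four convolution stages (64-128-256-512) and two
  fully-connected stages, sigmoid output probability.

The layers are implemented directly on numpy (im2col convolutions backed by
BLAS, manual reverse-mode gradients, Adam updates) in float32; everything is
deterministic given a seed.  This module targets smoke-scale training —
overfitting a handful of small pairs to validate the architecture and loss
wiring — not full-scale restoration.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .core_io import GrayImage

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "LossWeights",
    "Generator",
    "Discriminator",
    "reconstruction_loss",
    "adversarial_loss",
    "total_objective",
    "train",
    "apply",
    "save_generator",
    "load_generator",
]

DTYPE = np.float32
LEAKY_SLOPE = 0.2
PROB_EPS = 1e-7
INIT_STD = 0.02

ENCODER_WIDTHS = (64, 128, 256, 512, 512, 512)
DECODER_WIDTHS = (512, 512, 512, 256, 128, 64)
DISCRIMINATOR_CONV_WIDTHS = (64, 128, 256, 512)
DISCRIMINATOR_FC_WIDTH = 512
KERNEL_SIZE = 5
IMAGE_CHANNELS = 3  # grayscale replicated to honor the 3-channel output map
DOWNSAMPLE_FACTOR = 2 ** len(ENCODER_WIDTHS)


@dataclasses.dataclass(frozen=True)
class GeneratorSpec:
    """Declarative layer plan of the generator (used for conformance checks)."""

    encoder_widths: tuple = ENCODER_WIDTHS
    decoder_widths: tuple = DECODER_WIDTHS
    output_channels: int = IMAGE_CHANNELS
    kernel_size: int = KERNEL_SIZE
    hidden_activation: str = "leaky_relu"
    output_activation: str = "tanh"
    #: (encoder level, decoder level) concatenation pairs, levels 1-based.
    skip_pairs: tuple = ((5, 1), (4, 2), (3, 3), (2, 4), (1, 5))


@dataclasses.dataclass(frozen=True)
class DiscriminatorSpec:
    """Declarative layer plan of the discriminator."""

    conv_widths: tuple = DISCRIMINATOR_CONV_WIDTHS
    fc_widths: tuple = (DISCRIMINATOR_FC_WIDTH, 1)
    kernel_size: int = KERNEL_SIZE
    hidden_activation: str = "leaky_relu"
    output_activation: str = "sigmoid"


@dataclasses.dataclass
class LossWeights:
    """Weights of the composite objective: adversarial weight ``lam`` > 0."""

    lam: float = 0.01

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("adversarial weight must be > 0")


# ---------------------------------------------------------------------------
# Layers (im2col convolutions, manual gradients)
# ---------------------------------------------------------------------------

class _Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, tuple]:
    """(N, C, H, W) -> (N*Ho*Wo, C*k*k) patch matrix."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, k, k)
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), (n, c, h, w, ho, wo)


def _col2im(
    cols: np.ndarray, shape: tuple, k: int, stride: int, pad: int
) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back to (N, C, H, W)."""
    n, c, h, w, ho, wo = shape
    patches = cols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for ki in range(k):
        for kj in range(k):
            xp[:, :, ki : ki + ho * stride : stride, kj : kj + wo * stride : stride] += (
                patches[:, :, :, :, ki, kj]
            )
    return xp[:, :, pad : pad + h, pad : pad + w]


class _Conv:
    """5x5 convolution; stride 2 halves the spatial size (stride 1 keeps it)."""

    def __init__(self, rng, cin: int, cout: int, k: int, stride: int):
        self.k, self.stride, self.pad = k, stride, k // 2
        self.cin, self.cout = cin, cout
        self.weight = _Param(rng.normal(0.0, INIT_STD, (cout, cin * k * k)))
        self.bias = _Param(np.zeros(cout))
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, shape = _im2col(x, self.k, self.stride, self.pad)
        self._cache = (cols, shape)
        n, _, _, _, ho, wo = shape
        y = cols @ self.weight.value.T + self.bias.value
        return y.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, shape = self._cache
        n, _, _, _, ho, wo = shape
        dyc = dy.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.cout)
        self.weight.grad += dyc.T @ cols
        self.bias.grad += dyc.sum(axis=0)
        dcols = dyc @ self.weight.value
        return _col2im(dcols, shape, self.k, self.stride, self.pad)


class _ConvTranspose:
    """5x5 stride-2 transposed convolution; doubles the spatial size."""

    def __init__(self, rng, cin: int, cout: int, k: int):
        self.k, self.stride, self.pad = k, 2, k // 2
        self.cin, self.cout = cin, cout
        self.weight = _Param(rng.normal(0.0, INIT_STD, (cin, cout * k * k)))
        self.bias = _Param(np.zeros(cout))
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        ho, wo = h * 2, w * 2
        x_flat = x.transpose(0, 2, 3, 1).reshape(n * h * w, c)
        dcols = x_flat @ self.weight.value
        # Scatter through the adjoint of the matching stride-2 convolution.
        y = _col2im(dcols, (n, self.cout, ho, wo, h, w), self.k, self.stride, self.pad)
        self._cache = (x_flat, (n, c, h, w, ho, wo))
        return y + self.bias.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_flat, (n, c, h, w, ho, wo) = self._cache
        cols, _ = _im2col(dy, self.k, self.stride, self.pad)
        self.weight.grad += x_flat.T @ cols
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        dx_flat = cols @ self.weight.value.T
        return dx_flat.reshape(n, h, w, c).transpose(0, 3, 1, 2)


class _Dense:
    def __init__(self, rng, nin: int, nout: int):
        self.nin, self.nout = nin, nout
        self.weight = _Param(rng.normal(0.0, INIT_STD, (nout, nin)))
        self.bias = _Param(np.zeros(nout))
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        self.weight.grad += dy.T @ x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value


class _LeakyReLU:
    def __init__(self, slope: float = LEAKY_SLOPE):
        self.slope = slope
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy)


class _Tanh:
    def __init__(self):
        self._y = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * (1.0 - self._y * self._y)


def _adam_step(params, lr: float, beta1: float, beta2: float, t: int, eps=1e-8):
    for p in params:
        p.m = beta1 * p.m + (1 - beta1) * p.grad
        p.v = beta2 * p.v + (1 - beta2) * (p.grad * p.grad)
        m_hat = p.m / (1 - beta1**t)
        v_hat = p.v / (1 - beta2**t)
        p.value -= lr * m_hat / (np.sqrt(v_hat) + eps)
        p.grad[:] = 0


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

class Generator:
    """U-net encoder/decoder per :class:`GeneratorSpec`."""

    def __init__(self, seed: int = 0, spec: GeneratorSpec | None = None):
        self.spec = spec or GeneratorSpec()
        rng = np.random.default_rng(seed)
        k = self.spec.kernel_size
        self.enc = []
        cin = self.spec.output_channels
        for width in self.spec.encoder_widths:
            self.enc.append((_Conv(rng, cin, width, k, 2), _LeakyReLU()))
            cin = width
        # Decoder level m consumes concat(previous decoder output,
        # encoder level 6-m) for m >= 2; level 1 consumes the bottleneck.
        self.dec = []
        n_levels = len(self.spec.decoder_widths)
        prev = self.spec.encoder_widths[-1]
        for m, width in enumerate(self.spec.decoder_widths, start=1):
            cin_m = prev if m == 1 else prev + self.spec.encoder_widths[n_levels - m]
            self.dec.append((_ConvTranspose(rng, cin_m, width, k), _LeakyReLU()))
            prev = width
        self.final = _Conv(rng, prev, self.spec.output_channels, k, 1)
        self.out_act = _Tanh()
        self._skips = None

    def params(self):
        out = []
        for conv, _ in self.enc:
            out.extend(conv.params())
        for deconv, _ in self.dec:
            out.extend(deconv.params())
        out.extend(self.final.params())
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[2] % DOWNSAMPLE_FACTOR or x.shape[3] % DOWNSAMPLE_FACTOR:
            raise ValueError(
                f"spatial dims {x.shape[2:]} must be divisible by "
                f"{DOWNSAMPLE_FACTOR}; pad the input first"
            )
        skips = []
        h = x
        for conv, act in self.enc:
            h = act.forward(conv.forward(h))
            skips.append(h)
        self._skips = skips
        n_levels = len(self.dec)
        self._concat_splits = []
        for m, (deconv, act) in enumerate(self.dec, start=1):
            if m > 1:
                skip = skips[n_levels - m]
                self._concat_splits.append(h.shape[1])
                h = np.concatenate([h, skip], axis=1)
            h = act.forward(deconv.forward(h))
        return self.out_act.forward(self.final.forward(h))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.final.backward(self.out_act.backward(dy))
        n_levels = len(self.dec)
        dskips = [None] * n_levels
        splits = list(self._concat_splits)
        for m in range(n_levels, 0, -1):
            deconv, act = self.dec[m - 1]
            dh = deconv.backward(act.backward(dh))
            if m > 1:
                split = splits.pop()
                dh, dskip = dh[:, :split], dh[:, split:]
                dskips[n_levels - m] = dskip
        dx = None
        for level in range(n_levels - 1, -1, -1):
            conv, act = self.enc[level]
            if dskips[level] is not None:
                dh = dh + dskips[level]
            dh = conv.backward(act.backward(dh))
        dx = dh
        return dx

    def describe(self) -> dict:
        """Introspection of the built network for conformance checks."""
        return {
            "encoder_widths": tuple(conv.cout for conv, _ in self.enc),
            "decoder_widths": tuple(dc.cout for dc, _ in self.dec),
            "decoder_input_widths": tuple(dc.cin for dc, _ in self.dec),
            "output_channels": self.final.cout,
            "kernel_sizes": tuple(
                layer.k for layer in
                [conv for conv, _ in self.enc] + [dc for dc, _ in self.dec] + [self.final]
            ),
            "hidden_activation": "leaky_relu",
            "output_activation": "tanh",
            "skip_pairs": self.spec.skip_pairs,
        }


class Discriminator:
    """Four conv stages + two fully-connected stages, sigmoid probability."""

    def __init__(self, seed: int = 0, input_size: int = 64,
                 spec: DiscriminatorSpec | None = None):
        self.spec = spec or DiscriminatorSpec()
        rng = np.random.default_rng(seed)
        k = self.spec.kernel_size
        self.convs = []
        cin = IMAGE_CHANNELS
        size = input_size
        for width in self.spec.conv_widths:
            self.convs.append((_Conv(rng, cin, width, k, 2), _LeakyReLU()))
            cin = width
            size //= 2
        self.flat_dim = cin * size * size
        self.fc1 = _Dense(rng, self.flat_dim, self.spec.fc_widths[0])
        self.fc1_act = _LeakyReLU()
        self.fc2 = _Dense(rng, self.spec.fc_widths[0], self.spec.fc_widths[1])
        self._cache_shape = None

    def params(self):
        out = []
        for conv, _ in self.convs:
            out.extend(conv.params())
        out.extend(self.fc1.params())
        out.extend(self.fc2.params())
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = x
        for conv, act in self.convs:
            h = act.forward(conv.forward(h))
        self._cache_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        if h.shape[1] != self.flat_dim:
            raise ValueError(
                f"discriminator built for flat dim {self.flat_dim}, got {h.shape[1]}"
            )
        h = self.fc1_act.forward(self.fc1.forward(h))
        logits = self.fc2.forward(h)
        # Sigmoid output: probability the input is a real (clear) image.
        self._probs = 1.0 / (1.0 + np.exp(-logits))
        return self._probs

    def backward(self, dprob: np.ndarray) -> np.ndarray:
        dlogits = dprob * self._probs * (1.0 - self._probs)
        dh = self.fc1.backward(self.fc1_act.backward(self.fc2.backward(dlogits)))
        dh = dh.reshape(self._cache_shape)
        for conv, act in reversed(self.convs):
            dh = conv.backward(act.backward(dh))
        return dh

    def describe(self) -> dict:
        return {
            "conv_widths": tuple(conv.cout for conv, _ in self.convs),
            "fc_widths": (self.fc1.nout, self.fc2.nout),
            "kernel_sizes": tuple(conv.k for conv, _ in self.convs),
            "hidden_activation": "leaky_relu",
            "output_activation": "sigmoid",
        }


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def reconstruction_loss(generated: np.ndarray, clear: np.ndarray) -> float:
    """Pixel-wise squared L2 distance, averaged per element.

    The per-element mean (rather than the raw sum) keeps the loss magnitude
    independent of image resolution and batch size.
    """
    generated = np.asarray(generated)
    clear = np.asarray(clear)
    if generated.shape != clear.shape:
        raise ValueError(f"shape mismatch {generated.shape} vs {clear.shape}")
    diff = generated.astype(np.float64) - clear.astype(np.float64)
    return float(np.mean(diff * diff))


def adversarial_loss(d_real: np.ndarray, d_fake: np.ndarray) -> float:
    """Discriminator objective ``-E[log D(f)] - E[log(1 - D(f_hat))]``.

    Probabilities are clamped to ``[eps, 1-eps]`` so the logs are finite.
    """
    d_real = np.clip(np.asarray(d_real, dtype=np.float64), PROB_EPS, 1 - PROB_EPS)
    d_fake = np.clip(np.asarray(d_fake, dtype=np.float64), PROB_EPS, 1 - PROB_EPS)
    return float(-np.mean(np.log(d_real)) - np.mean(np.log(1.0 - d_fake)))


def total_objective(rec: float, adv: float, lam: float = 0.01) -> float:
    """Composite objective ``L = L_rec + lam * L_adv`` (lam > 0)."""
    if lam <= 0:
        raise ValueError("lam must be > 0")
    return float(rec) + float(lam) * float(adv)


# ---------------------------------------------------------------------------
# Training and inference
# ---------------------------------------------------------------------------

def _to_tensor(image: GrayImage) -> np.ndarray:
    """Map a grayscale image to a 3-channel float tensor in [-1, 1]."""
    x = image.pixels.astype(DTYPE) / (image.max_value / 2.0) - 1.0
    return np.repeat(x[None, None], IMAGE_CHANNELS, axis=1)


def _from_tensor(t: np.ndarray, bit_depth: int) -> GrayImage:
    """Collapse channels and rescale tanh output to the image bit range."""
    max_value = (1 << bit_depth) - 1
    x = t[0].mean(axis=0).astype(np.float64)
    pixels = np.clip((x + 1.0) * (max_value / 2.0), 0, max_value)
    return GrayImage(pixels, bit_depth=bit_depth)


def train(
    pairs: list[tuple[GrayImage, GrayImage]],
    iterations: int = 200,
    batch_size: int = 1,
    seed: int = 0,
    lr: float = 2e-4,
    beta1: float = 0.5,
    beta2: float = 0.999,
    weights: LossWeights | None = None,
) -> tuple[Generator, list[dict]]:
    """Alternating discriminator/generator training on (clear, blurred) pairs.

    Each iteration draws the next ``batch_size`` pairs cyclically, takes one
    discriminator step on real clear images vs. current generator outputs,
    then one generator step on ``L_rec + lam * (-E[log D(f_hat)])`` (the
    non-saturating generator form of the adversarial objective).  The loss
    history records every term per iteration.  Deterministic given ``seed``.
    """
    if not pairs:
        raise ValueError("need at least one training pair")
    weights = weights or LossWeights()
    h, w = pairs[0][0].pixels.shape
    if h % DOWNSAMPLE_FACTOR or w % DOWNSAMPLE_FACTOR:
        raise ValueError(
            f"training images are {h}x{w}; spatial dims must be divisible by "
            f"{DOWNSAMPLE_FACTOR} — pad or crop the pairs first"
        )
    gen = Generator(seed=seed)
    disc = Discriminator(seed=seed + 1, input_size=h)
    clear_t = [_to_tensor(c) for c, _ in pairs]
    blurred_t = [_to_tensor(b) for _, b in pairs]

    history = []
    order = 0
    for it in range(1, iterations + 1):
        sel = [(order + i) % len(pairs) for i in range(batch_size)]
        order = (order + batch_size) % len(pairs)
        clear = np.concatenate([clear_t[i] for i in sel], axis=0)
        blurred = np.concatenate([blurred_t[i] for i in sel], axis=0)

        # --- discriminator step (generator frozen) ---
        fake = gen.forward(blurred)
        both = np.concatenate([clear, fake], axis=0)
        probs = disc.forward(both)
        n = len(sel)
        d_real, d_fake = probs[:n], probs[n:]
        d_loss = adversarial_loss(d_real, d_fake)
        p = np.clip(probs, PROB_EPS, 1 - PROB_EPS)
        dprob = np.empty_like(probs)
        dprob[:n] = -1.0 / (n * p[:n])          # -E[log D(real)]
        dprob[n:] = 1.0 / (n * (1.0 - p[n:]))   # -E[log(1 - D(fake))]
        disc.backward(dprob.astype(DTYPE))
        _adam_step(disc.params(), lr, beta1, beta2, it)

        # --- generator step ---
        # The generator did not change during the discriminator step, so the
        # forward pass (and the layer caches it left behind) is still valid.
        rec = reconstruction_loss(fake, clear)
        probs_fake = disc.forward(fake)
        pf = np.clip(probs_fake, PROB_EPS, 1 - PROB_EPS)
        g_adv = float(-np.mean(np.log(pf)))
        dprob_fake = (-1.0 / (len(sel) * pf)).astype(DTYPE)
        dfake_adv = disc.backward(dprob_fake)
        for param in disc.params():
            param.grad[:] = 0  # discriminator is frozen in this step
        dfake_rec = (2.0 / fake.size) * (fake - clear)
        gen.backward((dfake_rec + weights.lam * dfake_adv).astype(DTYPE))
        _adam_step(gen.params(), lr, beta1, beta2, it)

        history.append(
            {
                "iteration": it,
                "d_loss": d_loss,
                "g_reconstruction": rec,
                "g_adversarial": g_adv,
                "g_total": total_objective(rec, g_adv, weights.lam),
            }
        )
    return gen, history


def apply(generator: Generator, blurred: GrayImage) -> GrayImage:
    """Run the generator on a blurred image, returning the restored image."""
    h, w = blurred.pixels.shape
    if h % DOWNSAMPLE_FACTOR or w % DOWNSAMPLE_FACTOR:
        raise ValueError(
            f"image is {h}x{w}; spatial dims must be divisible by "
            f"{DOWNSAMPLE_FACTOR} — pad or crop first"
        )
    out = generator.forward(_to_tensor(blurred))
    return _from_tensor(out, blurred.bit_depth)


def save_generator(generator: Generator, path) -> None:
    """Serialize generator parameters to an ``.npz`` checkpoint."""
    arrays = {f"p{i}": p.value for i, p in enumerate(generator.params())}
    np.savez(path, **arrays)


def load_generator(path, seed: int = 0) -> Generator:
    """Rebuild a generator from a checkpoint written by :func:`save_generator`."""
    gen = Generator(seed=seed)
    with np.load(path) as data:
        params = gen.params()
        if len(data.files) != len(params):
            raise ValueError(f"checkpoint {path} does not match the architecture")
        for i, p in enumerate(params):
            p.value = data[f"p{i}"].astype(DTYPE)
    return gen
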