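"""Learned precorrection: a U-Net style surrogate for the iterative solver.

The iterative optimizer takes seconds per image; a convolutional
encoder-decoder trained on (target, precorrected) pairs produced by that
optimizer amortises the cost to a single forward pass.  One network is
trained per (prescription, display) pair — the kernel fingerprint is stored
in the checkpoint and checked at prediction time.

The architecture follows the familiar U-Net pattern: a contracting path of
double 3x3 convolutions with 2x2 max pooling, an expanding path with
bilinear x2 upsampling and skip connections, ReLU activations, and a
sigmoid output head that enforces the displayable [0, 1] range.  The
default preset (depth 3, 16 base channels) is sized to train on a single
CPU in minutes; ``paper_preset()`` returns the full-size configuration
(channels expanding 3 -> 92 -> ... -> 1472, learning rate 1e-4) for GPU use.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import _nn
from ._nn import Adam, Parameter, Tensor
from .exceptions import OptimizationError, ValidationError
from .precorrect import OptimConfig, optimize_lms
from .retina import validate_rgb_image
from .wavefront import LMSKernel

__all__ = [
    "SurrogateConfig",
    "TrainingPair",
    "SurrogateModel",
    "build_dataset",
    "train_surrogate",
    "predict",
    "save_model",
    "load_model",
    "paper_preset",
]


@dataclass(frozen=True)
class SurrogateConfig:
    depth: int = 3
    base_channels: int = 16
    kernel_size: int = 3
    learning_rate: float = 2e-3
    epochs: int = 150
    batch_size: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ValidationError("depth must be >= 1")
        if self.base_channels < 4:
            raise ValidationError("base_channels must be >= 4")
        if self.kernel_size != 3:
            raise ValidationError("only 3x3 convolutions are supported")


def paper_preset() -> SurrogateConfig:
    """Full-size configuration: 4 contracting levels starting at 92 channels
    (92 * 2^4 = 1472 at the bottleneck) with learning rate 1e-4."""
    return SurrogateConfig(depth=4, base_channels=92, learning_rate=1e-4, epochs=800)


@dataclass(frozen=True)
class TrainingPair:
    """A (target, optimizer-precorrected) image pair with provenance."""

    input: np.ndarray
    label: np.ndarray
    kernel_fingerprint: str
    optim_config: OptimConfig

    def __post_init__(self):
        if self.input.shape != self.label.shape:
            raise ValidationError("input and label must share a shape")


class SurrogateModel:
    """Weights + config + the fingerprint of the kernel it was trained for."""

    def __init__(self, cfg: SurrogateConfig, kernel_fingerprint: str, rng: np.random.Generator | None = None):
        self.cfg = cfg
        self.kernel_fingerprint = kernel_fingerprint
        rng = rng or np.random.default_rng(cfg.seed)
        self.params: dict[str, Parameter] = {}
        ch = [3] + [cfg.base_channels * 2**i for i in range(cfg.depth + 1)]
        # contracting path: double conv at each level (last entry = bottleneck)
        for lvl in range(cfg.depth + 1):
            cin = ch[lvl]
            cout = ch[lvl + 1]
            self._conv(f"enc{lvl}a", cin, cout, rng)
            self._conv(f"enc{lvl}b", cout, cout, rng)
        # expanding path
        for lvl in range(cfg.depth - 1, -1, -1):
            cskip = ch[lvl + 1]
            cup = ch[lvl + 2]
            self._conv(f"dec{lvl}a", cup + cskip, cskip, rng)
            self._conv(f"dec{lvl}b", cskip, cskip, rng)
        # 1x1 residual head, zero-initialised: the untrained network is the
        # identity map, so training only has to learn the correction field
        self.params["head_w"] = Parameter(np.zeros((3, ch[1])))
        self.params["head_b"] = Parameter(np.zeros(3))

    def _conv(self, name: str, cin: int, cout: int, rng):
        std = np.sqrt(2.0 / (cin * 9))  # He initialisation
        self.params[f"{name}_w"] = Parameter(rng.normal(0.0, std, (cout, cin, 3, 3)))
        self.params[f"{name}_b"] = Parameter(np.zeros(cout))

    def _double(self, x: Tensor, name: str) -> Tensor:
        p = self.params
        x = _nn.relu(_nn.conv2d(x, p[f"{name}a_w"], p[f"{name}a_b"]))
        return _nn.relu(_nn.conv2d(x, p[f"{name}b_w"], p[f"{name}b_b"]))

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        inp = x
        skips = []
        for lvl in range(cfg.depth):
            x = self._double(x, f"enc{lvl}")
            skips.append(x)
            x = _nn.maxpool2(x)
        x = self._double(x, f"enc{cfg.depth}")  # bottleneck
        for lvl in range(cfg.depth - 1, -1, -1):
            x = _nn.upsample2(x)
            x = _nn.concat(x, skips[lvl])
            x = self._double(x, f"dec{lvl}")
        r = _nn.conv1x1(x, self.params["head_w"], self.params["head_b"])
        # residual prediction bounded to the displayable range
        return _nn.hardsigmoid(_nn.add(inp, r))

    def parameters(self) -> list[Parameter]:
        return [self.params[k] for k in sorted(self.params)]


def _to_nchw(images: list[np.ndarray]) -> np.ndarray:
    return np.stack([im.transpose(2, 0, 1) for im in images])


def _check_shape(shape: tuple[int, int], depth: int):
    f = 2**depth
    if shape[0] % f or shape[1] % f:
        raise ValidationError(
            f"image size {shape} must be divisible by 2^depth = {f}"
        )


def build_dataset(
    images: list[np.ndarray] | dict[str, np.ndarray],
    kernel: LMSKernel,
    optim_cfg: OptimConfig = OptimConfig(),
) -> list[TrainingPair]:
    """Generate teacher labels by running the iterative optimizer per image."""
    if isinstance(images, dict):
        images = list(images.values())
    fp = kernel.fingerprint()
    pairs = []
    for i, img in enumerate(images):
        img = validate_rgb_image(img)
        try:
            res = optimize_lms(img, kernel, optim_cfg)
        except OptimizationError as exc:
            raise OptimizationError(
                f"teacher optimization failed on image {i}: {exc}", exc.loss_trace
            ) from exc
        pairs.append(TrainingPair(img, res.precorrected, fp, optim_cfg))
    return pairs


def train_surrogate(
    pairs: list[TrainingPair],
    cfg: SurrogateConfig = SurrogateConfig(),
) -> tuple[SurrogateModel, np.ndarray]:
    """Train the surrogate by MSE regression on teacher outputs.

    Full batches up to ``cfg.batch_size`` pairs per step; returns the model
    and the per-epoch loss history (mean over batches).  Deterministic for a
    fixed seed.
    """
    if len(pairs) < 2:
        raise ValidationError("need at least 2 training pairs")
    fps = {p.kernel_fingerprint for p in pairs}
    if len(fps) != 1:
        raise ValidationError("all pairs must come from the same kernel")
    shape = pairs[0].input.shape[:2]
    for p in pairs:
        if p.input.shape[:2] != shape:
            raise ValidationError("all pairs must share one image size")
    _check_shape(shape, cfg.depth)

    model = SurrogateModel(cfg, fps.pop())
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    X = _to_nchw([p.input for p in pairs])
    Y = _to_nchw([p.label for p in pairs])
    n = len(pairs)
    history = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            x = Tensor(X[sel])
            loss = _nn.mse(model.forward(x), Y[sel])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            loss = None  # free the autograd graph before the next forward
        history.append(float(np.mean(losses)))
    return model, np.asarray(history)


def predict(model: SurrogateModel, image: np.ndarray, expected_fingerprint: str | None = None,
            force: bool = False) -> np.ndarray:
    """Predict a precorrected image; output in [0, 1], same shape as input."""
    image = validate_rgb_image(image)
    _check_shape(image.shape[:2], model.cfg.depth)
    if expected_fingerprint is not None and expected_fingerprint != model.kernel_fingerprint and not force:
        raise ValidationError(
            "kernel fingerprint mismatch: model was trained for "
            f"{model.kernel_fingerprint}, got {expected_fingerprint} (use force=True to override)"
        )
    x = Tensor(image.transpose(2, 0, 1)[None])
    y = model.forward(x)
    return y.data[0].transpose(1, 2, 0)


def save_model(model: SurrogateModel, path) -> None:
    """Single-file checkpoint: weights plus embedded config and fingerprint."""
    meta = json.dumps(
        {"cfg": asdict(model.cfg), "kernel_fingerprint": model.kernel_fingerprint}
    )
    arrays = {k: p.data for k, p in model.params.items()}
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_model(path) -> SurrogateModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = SurrogateConfig(**meta["cfg"])
        model = SurrogateModel(cfg, meta["kernel_fingerprint"])
        for k in model.params:
            model.params[k].data = data[k].copy()
    return model
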