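"""Dense autoencoders for deviation vectors: vanilla, deep, tied, orthogonal.

The family of architectures is deliberately narrow.  A *vanilla* AE (vAE)
maps the 3n-dimensional input straight to the code layer y and back; a *deep*
AE (dAE) inserts exactly two hidden layers per side,

    x = L0 -> L1 -> L2 -> y -> L2 -> L1 -> z,

with |L1| = 250 when |x| < 250 and |x| + 30 otherwise, and |L2| = 125.  Four
activation functions are considered in the encoder and the decoder
independently: identity, sigmoid, leaky ReLU (negative slope alpha, default
0.3), and parametric leaky ReLU (one learnable alpha per layer, initialized
at 0.3).  The activation is applied after every affine map, code layer and
output layer included.

Two regularizers:

* weight tying — decoder weight matrices are not free parameters but live
  transposed views of the mirrored encoder matrices, halving the weight
  count; biases are never tied;
* orthogonality — a soft penalty beta * sum ||W_enc . W_dec - I||_F^2 over
  mirrored layer pairs drives mirrored products toward the identity.  For
  rectangular pairs the product orientation yielding the smaller square is
  compared against the identity of that dimension.

Training is plain mini-batch Adam on the summed-squared-error reconstruction
loss, implemented here directly in NumPy with analytic gradients (a gradient
check against finite differences guards the backward pass in the test
suite).  Everything is deterministic under the seeds supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .errors import InvalidSpecError, ShapeError, TrainingFailureError
from .superpose import DeviationDataset

__all__ = [
    "ActivationKind",
    "AEArchitectureSpec",
    "TrainConfig",
    "TrainedModel",
    "hidden_layer_sizes",
    "build_model",
    "forward",
    "loss",
    "train",
    "reconstruction_mse",
    "orthogonality_residual",
    "count_free_weights",
    "count_free_parameters",
    "quadratic_weight_estimate",
]

ACTIVATION_KINDS = ("identity", "sigmoid", "leaky_relu", "parametric_leaky_relu")


@dataclass(frozen=True)
class ActivationKind:
    """An activation function: identity, sigmoid, or (parametric) leaky ReLU.

    ``alpha`` is the negative-slope coefficient; it is fixed for
    ``leaky_relu`` and the learnable initial value for
    ``parametric_leaky_relu``.
    """

    kind: str
    alpha: float = 0.3

    def __post_init__(self) -> None:
        if self.kind not in ACTIVATION_KINDS:
            raise InvalidSpecError(
                f"activation must be one of {ACTIVATION_KINDS}, got {self.kind!r}"
            )
        if self.alpha < 0:
            raise InvalidSpecError("alpha must be non-negative")

    @classmethod
    def coerce(cls, value) -> "ActivationKind":
        if isinstance(value, cls):
            return value
        return cls(kind=str(value))

    @property
    def learnable(self) -> bool:
        return self.kind == "parametric_leaky_relu"


def _act(kind: str, z: np.ndarray, alpha: float) -> np.ndarray:
    if kind == "identity":
        return z
    if kind == "sigmoid":
        return expit(z)
    return np.where(z >= 0, z, alpha * z)


def _act_dz(kind: str, z: np.ndarray, h: np.ndarray, alpha: float) -> np.ndarray:
    if kind == "identity":
        return np.ones_like(z)
    if kind == "sigmoid":
        return h * (1.0 - h)
    return np.where(z >= 0, 1.0, alpha)


def hidden_layer_sizes(input_dim: int) -> tuple[int, int]:
    """Deep-architecture hidden sizes: (250 or |x|+30, 125)."""
    if input_dim < 1:
        raise InvalidSpecError("input_dim must be positive")
    l1 = 250 if input_dim < 250 else input_dim + 30
    return l1, 125


def quadratic_weight_estimate(input_dim: int) -> int:
    """Back-of-envelope O(|x|^2) weight count for a shallow autoencoder.

    The exact free-weight count of an untied vanilla AE is 2*|x|*|y|; since
    the code size |y| is a small constant, the quadratic estimate |x|^2 is
    the usual order-of-magnitude accounting for how shallow-AE size scales
    with input dimensionality.
    """
    return int(input_dim) ** 2


@dataclass(frozen=True)
class AEArchitectureSpec:
    """One point in the architecture grid.

    ``family`` is 'vanilla' (no hidden layers) or 'deep' (two hidden layers
    per side); ``tie_weights`` and ``orthogonality`` are mutually exclusive
    regularizers.
    """

    family: str
    code_dim: int
    encoder_activation: ActivationKind
    decoder_activation: ActivationKind
    tie_weights: bool = False
    orthogonality: bool = False

    def __post_init__(self) -> None:
        if self.family not in ("vanilla", "deep"):
            raise InvalidSpecError(f"unknown family {self.family!r}")
        if self.code_dim < 1:
            raise InvalidSpecError("code_dim must be positive")
        object.__setattr__(
            self, "encoder_activation", ActivationKind.coerce(self.encoder_activation)
        )
        object.__setattr__(
            self, "decoder_activation", ActivationKind.coerce(self.decoder_activation)
        )
        if self.tie_weights and self.orthogonality:
            raise InvalidSpecError(
                "tie_weights and orthogonality are mutually exclusive"
            )

    def layer_dims(self, input_dim: int) -> list[int]:
        """Encoder layer widths, input through code."""
        if self.code_dim >= input_dim:
            raise InvalidSpecError(
                f"code_dim {self.code_dim} must be below input_dim {input_dim}"
            )
        if self.family == "vanilla":
            return [input_dim, self.code_dim]
        l1, l2 = hidden_layer_sizes(input_dim)
        return [input_dim, l1, l2, self.code_dim]

    def name(self) -> str:
        short = {"identity": "I", "sigmoid": "sig", "leaky_relu": "LR",
                 "parametric_leaky_relu": "PLR"}
        tag = "o" if self.orthogonality else ("t" if self.tie_weights else "")
        fam = "vAE" if self.family == "vanilla" else "dAE"
        return (
            f"{tag}{fam}_E{short[self.encoder_activation.kind]}"
            f"_D{short[self.decoder_activation.kind]}_y{self.code_dim}"
        )


@dataclass
class TrainConfig:
    """Training hyperparameters (Adam, fixed epoch budget, no early stop)."""

    epochs: int = 100
    batch_size: int = 256
    learning_rate: float = 0.008
    leaky_alpha: float = 0.3
    seed: int = 0
    orthogonality_beta: float = 1.0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size) < 1 or self.learning_rate <= 0:
            raise InvalidSpecError("epochs, batch_size, learning_rate must be positive")
        if self.leaky_alpha < 0 or self.orthogonality_beta <= 0:
            raise InvalidSpecError("leaky_alpha and orthogonality_beta must be positive")


@dataclass
class TrainedModel:
    """Parameters of one (possibly untrained) autoencoder.

    ``enc_W[i]`` has shape (in_i, out_i) and acts by ``h @ W + b``.  When
    weights are tied, ``dec_W`` is None and decoder matrices are transposed
    views of the mirrored encoder matrices at all times.  ``enc_alpha`` /
    ``dec_alpha`` hold one learnable negative slope per parametric layer
    (0-d arrays), None elsewhere.
    """

    architecture: AEArchitectureSpec
    input_dim: int
    enc_W: list[np.ndarray]
    enc_b: list[np.ndarray]
    dec_W: list[np.ndarray] | None
    dec_b: list[np.ndarray]
    enc_alpha: list[np.ndarray | None]
    dec_alpha: list[np.ndarray | None]
    seed: int = 0
    history: dict = field(default_factory=lambda: {"train": [], "validation": []})

    @property
    def n_encoder_layers(self) -> int:
        return len(self.enc_W)

    def decoder_weight(self, j: int) -> np.ndarray:
        """Decoder weight matrix j (a live transposed view when tied)."""
        if self.dec_W is not None:
            return self.dec_W[j]
        return self.enc_W[self.n_encoder_layers - 1 - j].T

    def _alpha_value(self, side: str, i: int) -> float:
        store = self.enc_alpha if side == "enc" else self.dec_alpha
        if store[i] is not None:
            return float(store[i])
        act = (
            self.architecture.encoder_activation
            if side == "enc"
            else self.architecture.decoder_activation
        )
        return act.alpha

    def encode(self, X: np.ndarray) -> np.ndarray:
        codes, _ = forward(self, X)
        return codes

    def parameters(self) -> list[tuple[str, np.ndarray]]:
        """Free parameters as (name, array) pairs; arrays are live references."""
        params = [(f"enc_W{i}", W) for i, W in enumerate(self.enc_W)]
        if self.dec_W is not None:
            params += [(f"dec_W{j}", W) for j, W in enumerate(self.dec_W)]
        params += [(f"enc_b{i}", b) for i, b in enumerate(self.enc_b)]
        params += [(f"dec_b{j}", b) for j, b in enumerate(self.dec_b)]
        params += [
            (f"enc_alpha{i}", a) for i, a in enumerate(self.enc_alpha) if a is not None
        ]
        params += [
            (f"dec_alpha{j}", a) for j, a in enumerate(self.dec_alpha) if a is not None
        ]
        return params


def count_free_weights(model: TrainedModel) -> int:
    """Number of free weight-matrix entries (biases and alphas excluded)."""
    n = sum(W.size for W in model.enc_W)
    if model.dec_W is not None:
        n += sum(W.size for W in model.dec_W)
    return n


def count_free_parameters(model: TrainedModel) -> int:
    """All free parameters: weights, biases, and learnable alphas."""
    return sum(arr.size for _, arr in model.parameters())


def build_model(spec: AEArchitectureSpec, input_dim: int, seed: int = 0) -> TrainedModel:
    """Initialize an autoencoder under ``seed`` (Glorot-uniform weights).

    Biases start at zero; learnable alphas at the activation's initial
    value.  Tied decoders carry no weight storage of their own.
    """
    dims = spec.layer_dims(input_dim)
    rng = np.random.default_rng(seed)

    def glorot(fan_in: int, fan_out: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    enc_W = [glorot(dims[i], dims[i + 1]) for i in range(len(dims) - 1)]
    enc_b = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
    rdims = dims[::-1]
    if spec.tie_weights:
        dec_W = None
    else:
        dec_W = [glorot(rdims[j], rdims[j + 1]) for j in range(len(rdims) - 1)]
    dec_b = [np.zeros(rdims[j + 1]) for j in range(len(rdims) - 1)]

    def alphas(act: ActivationKind, count: int) -> list:
        if act.learnable:
            return [np.array(act.alpha, dtype=float) for _ in range(count)]
        return [None] * count

    return TrainedModel(
        architecture=spec,
        input_dim=input_dim,
        enc_W=enc_W,
        enc_b=enc_b,
        dec_W=dec_W,
        dec_b=dec_b,
        enc_alpha=alphas(spec.encoder_activation, len(enc_W)),
        dec_alpha=alphas(spec.decoder_activation, len(dec_b)),
        seed=seed,
    )


def _forward_full(model: TrainedModel, X: np.ndarray):
    """Forward pass caching pre-activations and activations per layer."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.input_dim:
        raise ShapeError(
            f"batch dimension {X.shape[1]} does not match input_dim {model.input_dim}"
        )
    E = model.n_encoder_layers
    enc_kind = model.architecture.encoder_activation.kind
    dec_kind = model.architecture.decoder_activation.kind
    hs, zs = [X], []
    h = X
    for i in range(E):
        z = h @ model.enc_W[i] + model.enc_b[i]
        h = _act(enc_kind, z, model._alpha_value("enc", i))
        zs.append(z)
        hs.append(h)
    code = h
    for j in range(E):
        z = h @ model.decoder_weight(j) + model.dec_b[j]
        h = _act(dec_kind, z, model._alpha_value("dec", j))
        zs.append(z)
        hs.append(h)
    return X, zs, hs, code, h


def forward(model: TrainedModel, batch: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Codes and reconstructions for a batch of deviation rows."""
    _, _, _, code, recon = _forward_full(model, batch)
    return code, recon


def _ortho_pairs(model: TrainedModel):
    """(encoder index, decoder index) mirrored pairs for the penalty."""
    E = model.n_encoder_layers
    return [(i, E - 1 - i) for i in range(E)]


def orthogonality_residual(model: TrainedModel) -> float:
    """Sum over mirrored pairs of ||W_enc . W_dec - I||_F^2 (unweighted).

    For rectangular pairs, the product orientation giving the smaller square
    matrix is compared against the identity of that dimension.
    """
    total = 0.0
    for i, j in _ortho_pairs(model):
        We = model.enc_W[i]  # (in, out)
        Wd = model.decoder_weight(j)  # (out, in)
        fan_in, fan_out = We.shape
        if fan_out <= fan_in:
            R = Wd @ We - np.eye(fan_out)
        else:
            R = We @ Wd - np.eye(fan_in)
        total += float((R**2).sum())
    return total


def loss(model: TrainedModel, batch: np.ndarray, beta: float = 1.0) -> float:
    """Mean summed-squared reconstruction error, plus the soft penalty.

    The orthogonality term beta * sum ||W_enc . W_dec - I||_F^2 enters only
    when the architecture flags it.
    """
    _, recon = forward(model, batch)
    X = np.atleast_2d(np.asarray(batch, dtype=float))
    value = float(((recon - X) ** 2).sum(axis=1).mean())
    if model.architecture.orthogonality:
        value += beta * orthogonality_residual(model)
    return value


def _loss_and_grads(model: TrainedModel, X: np.ndarray, beta: float):
    """Analytic loss and gradients for every free parameter."""
    X, zs, hs, _, recon = _forward_full(model, X)
    B = X.shape[0]
    E = model.n_encoder_layers
    enc_kind = model.architecture.encoder_activation.kind
    dec_kind = model.architecture.decoder_activation.kind
    tied = model.dec_W is None

    value = float(((recon - X) ** 2).sum(axis=1).mean())
    grads = {name: np.zeros_like(arr) for name, arr in model.parameters()}

    dH = 2.0 * (recon - X) / B
    # decoder layers, last to first
    for j in range(E - 1, -1, -1):
        z, h_out, h_in = zs[E + j], hs[E + j + 1], hs[E + j]
        alpha = model._alpha_value("dec", j)
        dZ = dH * _act_dz(dec_kind, z, h_out, alpha)
        if model.dec_alpha[j] is not None:
            grads[f"dec_alpha{j}"] += (dH * np.where(z >= 0, 0.0, z)).sum()
        gW = h_in.T @ dZ
        if tied:
            grads[f"enc_W{E - 1 - j}"] += gW.T
        else:
            grads[f"dec_W{j}"] += gW
        grads[f"dec_b{j}"] += dZ.sum(axis=0)
        dH = dZ @ model.decoder_weight(j).T
    # encoder layers, last to first
    for i in range(E - 1, -1, -1):
        z, h_out, h_in = zs[i], hs[i + 1], hs[i]
        alpha = model._alpha_value("enc", i)
        dZ = dH * _act_dz(enc_kind, z, h_out, alpha)
        if model.enc_alpha[i] is not None:
            grads[f"enc_alpha{i}"] += (dH * np.where(z >= 0, 0.0, z)).sum()
        grads[f"enc_W{i}"] += h_in.T @ dZ
        grads[f"enc_b{i}"] += dZ.sum(axis=0)
        dH = dZ @ model.enc_W[i].T

    if model.architecture.orthogonality:
        for i, j in _ortho_pairs(model):
            We = model.enc_W[i]
            Wd = model.decoder_weight(j)
            fan_in, fan_out = We.shape
            if fan_out <= fan_in:
                R = Wd @ We - np.eye(fan_out)
                gWe = Wd.T @ R
                gWd = R @ We.T
            else:
                R = We @ Wd - np.eye(fan_in)
                gWe = R @ Wd.T
                gWd = We.T @ R
            value += beta * float((R**2).sum())
            grads[f"enc_W{i}"] += 2.0 * beta * gWe
            if not tied:
                grads[f"dec_W{j}"] += 2.0 * beta * gWd
            else:
                grads[f"enc_W{i}"] += 2.0 * beta * gWd.T
    return value, grads


class _Adam:
    """Standard Adam with conventional moment decays (0.9, 0.999)."""

    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {name: np.zeros_like(arr) for name, arr in params}
        self.v = {name: np.zeros_like(arr) for name, arr in params}
        self.t = 0

    def step(self, params, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for name, arr in params:
            g = grads[name]
            self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * g
            self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * g**2
            update = (self.m[name] / b1t) / (np.sqrt(self.v[name] / b2t) + self.eps)
            arr -= self.lr * update


def train(
    model: TrainedModel,
    data: DeviationDataset,
    config: TrainConfig | None = None,
    step_callback=None,
) -> TrainedModel:
    """Train with Adam on shuffled mini-batches for a fixed epoch budget.

    ``history`` records the full training- and validation-set loss at the
    end of every epoch (validation monitored in tandem, no early stopping).
    ``step_callback(model, step)``, if given, runs after every optimizer
    step.  Raises :class:`TrainingFailureError` on non-finite loss.
    """
    config = config or TrainConfig()
    if not data.split:
        raise InvalidSpecError("dataset must be split before training")
    X_train = data.rows("train")
    X_val = data.rows("validation")
    if X_train.shape[0] == 0 or X_val.shape[0] == 0:
        raise InvalidSpecError("train and validation splits must be nonempty")

    params = model.parameters()
    opt = _Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    beta = config.orthogonality_beta
    model.history = {"train": [], "validation": []}

    step = 0
    for epoch in range(config.epochs):
        perm = rng.permutation(X_train.shape[0])
        for start in range(0, X_train.shape[0], config.batch_size):
            batch = X_train[perm[start : start + config.batch_size]]
            value, grads = _loss_and_grads(model, batch, beta)
            if not np.isfinite(value):
                raise TrainingFailureError(
                    f"non-finite loss at epoch {epoch}", epoch=epoch
                )
            opt.step(params, grads)
            step += 1
            if step_callback is not None:
                step_callback(model, step)
        tr = loss(model, X_train, beta)
        va = loss(model, X_val, beta)
        if not (np.isfinite(tr) and np.isfinite(va)):
            raise TrainingFailureError(f"non-finite loss at epoch {epoch}", epoch=epoch)
        model.history["train"].append(tr)
        model.history["validation"].append(va)
    return model


def reconstruction_mse(model: TrainedModel, test: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean and per-structure summed squared reconstruction error (Å²)."""
    test = np.atleast_2d(np.asarray(test, dtype=float))
    if test.shape[0] == 0:
        raise InvalidSpecError("test set is empty")
    _, recon = forward(model, test)
    per_structure = ((recon - test) ** 2).sum(axis=1)
    return float(per_structure.mean()), per_structure


def save_model(model: TrainedModel, path) -> None:
    """Serialize architecture and parameters to one ``.npz`` archive."""
    spec = model.architecture
    meta = dict(
        family=spec.family,
        code_dim=spec.code_dim,
        enc_act=spec.encoder_activation.kind,
        enc_alpha0=spec.encoder_activation.alpha,
        dec_act=spec.decoder_activation.kind,
        dec_alpha0=spec.decoder_activation.alpha,
        tie_weights=int(spec.tie_weights),
        orthogonality=int(spec.orthogonality),
        input_dim=model.input_dim,
        seed=model.seed,
    )
    arrays = {name: arr for name, arr in model.parameters()}
    np.savez(path, _meta=np.array(list(meta.items()), dtype=object), **arrays)


def load_model(path) -> TrainedModel:
    with np.load(path, allow_pickle=True) as data:
        meta = dict(data["_meta"])
        spec = AEArchitectureSpec(
            family=str(meta["family"]),
            code_dim=int(meta["code_dim"]),
            encoder_activation=ActivationKind(
                str(meta["enc_act"]), float(meta["enc_alpha0"])
            ),
            decoder_activation=ActivationKind(
                str(meta["dec_act"]), float(meta["dec_alpha0"])
            ),
            tie_weights=bool(int(meta["tie_weights"])),
            orthogonality=bool(int(meta["orthogonality"])),
        )
        model = build_model(spec, int(meta["input_dim"]), seed=int(meta["seed"]))
        for name, arr in model.parameters():
            arr[...] = data[name]
    return model
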