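"""Loss, optimizer, training loop, recycling, and evaluation metrics.

The training objective is a convex combination of voxel MSE and the
negated Pearson correlation between predicted and true density maps,
weighted 0.9999 / 1e-4 — correlation contributes a small scale-free pull
while MSE dominates. Evaluation reports per-example Pearson correlations
and phase errors of the predictions' structure factors in resolution
shells, the standard way phasing quality is judged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .dataset import ExampleRecord
from .nn.autodiff import Tensor
from .nn.model import ModelConfig, ModelParameters, forward, init_parameters
from .xtal import VolumeGrid, phase_error, sf_from_density

__all__ = [
    "LossConfig", "TrainConfig", "EvaluationReport", "DivergenceError",
    "pearson", "loss", "train", "recycle_train", "evaluate", "Adam",
]


@dataclass(frozen=True)
class LossConfig:
    """Loss weights: total = w_mse * MSE + w_pc * (-PC)."""

    w_mse: float = 0.9999
    w_pc: float = 1e-4
    epsilon: float = 1e-8

    def __post_init__(self) -> None:
        if self.w_mse < 0 or self.w_pc < 0:
            raise ValueError("loss weights must be non-negative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 8
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    recycle: bool = False
    recycle_epochs: int = 20
    dtype: str = "float32"  # working precision of weights and activations

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.recycle_epochs < 1:
            raise ValueError("epochs, batch_size and recycle_epochs must be positive")


class DivergenceError(RuntimeError):
    """Training hit a non-finite loss; carries the last stable parameters."""

    def __init__(self, message: str, last_stable: dict[str, np.ndarray]):
        super().__init__(message)
        self.last_stable = last_stable


def _values(m) -> np.ndarray:
    return m.values if isinstance(m, VolumeGrid) else np.asarray(m, dtype=float)


def pearson(e, e_prime, epsilon: float = 1e-8) -> float:
    """Pearson correlation over all voxels, with a guard constant.

    PC = sum((e'-mean e')(e-mean e)) / (sqrt(sum (e'-mean e')^2 + eps)
         * sqrt(sum (e-mean e)^2 + eps)); the small epsilon inside each
    root keeps constant maps from dividing by zero.
    """
    a, b = _values(e).ravel(), _values(e_prime).ravel()
    if a.shape != b.shape:
        raise ValueError("pearson: shape mismatch")
    da, db = a - a.mean(), b - b.mean()
    return float((db @ da) / (np.sqrt(db @ db + epsilon) * np.sqrt(da @ da + epsilon)))


def _pearson_t(pred: Tensor, target: Tensor, epsilon: float) -> Tensor:
    n = float(pred.data.size)
    dp = pred - pred.sum() * (1.0 / n)
    dt = target - target.sum() * (1.0 / n)
    num = (dp * dt).sum()
    den = ((dp * dp).sum() + epsilon) ** 0.5 * ((dt * dt).sum() + epsilon) ** 0.5
    return num / den


def _loss_t(pred: Tensor, target: Tensor, cfg: LossConfig) -> Tensor:
    diff = pred - target
    mse = (diff * diff).mean()
    out = cfg.w_mse * mse
    if cfg.w_pc != 0:
        out = out + cfg.w_pc * (-_pearson_t(pred, target, cfg.epsilon))
    return out


def loss(pred, target, cfg: LossConfig = LossConfig()) -> float:
    """Scalar training loss between a prediction and its target map."""
    a, b = _values(pred), _values(target)
    if a.shape != b.shape:
        raise ValueError("loss: shape mismatch")
    mse = float(np.mean((a - b) ** 2))
    return cfg.w_mse * mse + cfg.w_pc * (-pearson(b, a, cfg.epsilon))


class Adam:
    """Adam optimizer over a ModelParameters dict."""

    def __init__(self, params: ModelParameters, lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.tensors.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.tensors.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.tensors.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SGD:
    def __init__(self, params: ModelParameters, lr: float = 1e-2):
        self.params = params
        self.lr = lr

    def step(self) -> None:
        for p in self.params.tensors.values():
            if p.grad is not None:
                p.data -= self.lr * p.grad


def _make_optimizer(name: str, params: ModelParameters, lr: float):
    if name.lower() == "adam":
        return Adam(params, lr)
    if name.lower() == "sgd":
        return SGD(params, lr)
    raise ValueError(f"unknown optimizer {name!r}")


def _stack_examples(examples: list[ExampleRecord],
                    extra_channel: dict[str, np.ndarray] | None = None):
    """Stack a same-dims bin into (P, U, E) arrays for the model."""
    p = np.stack([ex.patterson.values for ex in examples])[:, None]
    e = np.stack([ex.density.values for ex in examples])[:, None]
    js = {len(ex.partials) for ex in examples}
    if len(js) > 1:
        raise ValueError("examples in one bin must share the partial count J")
    j = js.pop()
    u = (np.stack([ex.partials.as_array() for ex in examples])
         if j > 0 else None)
    if extra_channel is not None:
        extra = np.stack([extra_channel[ex.id] for ex in examples])[:, None]
        p = np.concatenate([p, extra], axis=1)
    return p, u, e


def _iter_batches(bins: dict, rng: np.random.Generator, batch_size: int):
    """Round-robin over dims bins, shuffled within each bin."""
    queues = []
    for dims in sorted(bins.keys()):
        exs = bins[dims]
        order = rng.permutation(len(exs))
        batches = [
            [exs[i] for i in order[k:k + batch_size]]
            for k in range(0, len(exs), batch_size)
        ]
        queues.append(batches)
    i = 0
    while any(queues):
        q = queues[i % len(queues)]
        if q:
            yield q.pop(0)
        i += 1


def _group_by_dims(examples: list[ExampleRecord]) -> dict:
    bins: dict = {}
    for ex in examples:
        bins.setdefault(ex.dims, []).append(ex)
    return bins


def train(
    model_config: ModelConfig,
    examples: list[ExampleRecord],
    cfg: TrainConfig = TrainConfig(),
    loss_cfg: LossConfig = LossConfig(),
    base_predictions: dict[str, np.ndarray] | None = None,
) -> tuple[ModelParameters, list[dict]]:
    """Mini-batch training of a freshly initialized model.

    Batches are drawn within grid-size bins (round-robin across bins,
    shuffled within bins by the config seed). Returns the trained
    parameters and a per-epoch history of mean loss and mean training PC.
    Raises DivergenceError (with the last stable parameter arrays) if the
    loss goes non-finite.
    """
    if not examples:
        raise ValueError("training requires at least one example")
    if base_predictions is not None and model_config.in_channels != 2:
        raise ValueError("recycling input requires in_channels=2")
    dtype = np.dtype(cfg.dtype).type
    params = init_parameters(model_config, dtype=dtype)
    opt = _make_optimizer(cfg.optimizer, params, cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    bins = _group_by_dims(examples)
    history: list[dict] = []
    last_stable = params.state_arrays()
    for epoch in range(cfg.epochs):
        losses, pcs = [], []
        for batch in _iter_batches(bins, rng, cfg.batch_size):
            p, u, e = _stack_examples(batch, base_predictions)
            pred = forward(p.astype(dtype), None if u is None else u.astype(dtype),
                           params)
            target = Tensor(e.astype(dtype))
            l = _loss_t(pred, target, loss_cfg)
            if not np.isfinite(l.data):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}", last_stable)
            params.zero_grad()
            l.backward()
            opt.step()
            losses.append(l.item())
            for bi in range(pred.shape[0]):
                pcs.append(pearson(e[bi, 0], pred.data[bi, 0], loss_cfg.epsilon))
        last_stable = params.state_arrays()
        history.append({
            "epoch": epoch,
            "loss": float(np.mean(losses)),
            "mean_pc": float(np.mean(pcs)),
        })
    return params, history


def predict_examples(params: ModelParameters, examples: list[ExampleRecord],
                     base_predictions: dict[str, np.ndarray] | None = None
                     ) -> dict[str, np.ndarray]:
    """Model predictions keyed by example id (unbatched by dims bin)."""
    out: dict[str, np.ndarray] = {}
    for dims, exs in _group_by_dims(examples).items():
        p, u, _ = _stack_examples(exs, base_predictions)
        pred = forward(p, u, params).data[:, 0]
        for ex, arr in zip(exs, pred):
            out[ex.id] = arr
    return out


def recycle_train(
    base_predictions: dict[str, np.ndarray],
    model_config: ModelConfig,
    examples: list[ExampleRecord],
    cfg: TrainConfig,
    loss_cfg: LossConfig = LossConfig(),
) -> tuple[ModelParameters, list[dict]]:
    """Retrain a fresh model with a previous model's predictions as a
    second input channel alongside the Patterson map.

    ``base_predictions`` must contain one map per training example id;
    channel order is fixed as (patterson, prediction).
    """
    missing = [ex.id for ex in examples if ex.id not in base_predictions]
    if missing:
        raise ValueError(f"missing base predictions for examples: {missing[:5]}")
    recycle_config = ModelConfig.from_dict(
        {**model_config.to_dict(), "in_channels": 2})
    recycle_cfg = TrainConfig(
        epochs=cfg.recycle_epochs, batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate, optimizer=cfg.optimizer,
        seed=cfg.seed + 1)
    return train(recycle_config, examples, recycle_cfg, loss_cfg,
                 base_predictions=base_predictions)


@dataclass
class EvaluationReport:
    """Aggregate prediction quality over a set of examples."""

    example_ids: list[str]
    pc: list[float]
    mean_phase_error_deg: list[float]
    shell_d_max: list[float]
    shell_d_min: list[float]
    shell_mean_phase_error_deg: list[float]
    shell_frac_examples_below_60: list[float]
    n_shells: int

    @property
    def mean_pc(self) -> float:
        return float(np.mean(self.pc))

    @property
    def overall_mean_phase_error_deg(self) -> float:
        return float(np.mean(self.mean_phase_error_deg))

    def to_dict(self) -> dict:
        return {
            "mean_pc": self.mean_pc,
            "overall_mean_phase_error_deg": self.overall_mean_phase_error_deg,
            "per_example": {
                "id": self.example_ids,
                "pc": self.pc,
                "mean_phase_error_deg": self.mean_phase_error_deg,
            },
            "shells": {
                "d_max": self.shell_d_max,
                "d_min": self.shell_d_min,
                "mean_phase_error_deg": self.shell_mean_phase_error_deg,
                "frac_examples_below_60": self.shell_frac_examples_below_60,
            },
            "n_shells": self.n_shells,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def _crystal_view(arr: np.ndarray, ex: ExampleRecord) -> VolumeGrid:
    dims = tuple(ex.meta.get("crystal_dims", arr.shape))
    sub = arr[: dims[0], : dims[1], : dims[2]]
    return VolumeGrid(sub, ex.cell, ex.density.spacing, kind="density")


def evaluate(
    params_or_predictions,
    examples: list[ExampleRecord],
    n_shells: int = 10,
    epsilon: float = 1e-8,
    base_predictions: dict[str, np.ndarray] | None = None,
) -> EvaluationReport:
    """Per-example PC and phase error of predictions vs ground truth.

    Accepts trained ModelParameters (predictions are computed) or a
    precomputed ``{id: map}`` dict. Phase errors compare structure factors
    obtained by forward transform of both maps to the d_min the examples
    were built at; F(0,0,0) is excluded. Shell fractions report, per
    resolution shell, the fraction of examples whose shell-mean error is
    below 60 degrees.
    """
    if isinstance(params_or_predictions, ModelParameters):
        predictions = predict_examples(params_or_predictions, examples,
                                       base_predictions)
    else:
        predictions = params_or_predictions
    ids, pcs, mpes = [], [], []
    shell_means, shell_dmax, shell_dmin = [], [], []
    for ex in examples:
        pred = predictions[ex.id]
        truth = ex.density.values
        ids.append(ex.id)
        pcs.append(pearson(truth, pred, epsilon))
        d_min = float(ex.meta.get("d_min", 1.5))
        truth_refs = sf_from_density(_crystal_view(truth, ex), d_min)
        pred_refs = sf_from_density(_crystal_view(pred, ex), d_min)
        pe = phase_error(pred_refs, truth_refs, n_shells)
        mpes.append(pe.mean_deg)
        shell_means.append(pe.shell_mean_deg)
        shell_dmax.append(pe.shell_d_max)
        shell_dmin.append(pe.shell_d_min)
    shell_means = np.array(shell_means)  # (n_examples, n_shells)
    with np.errstate(invalid="ignore"):
        frac_below = np.nanmean((shell_means < 60.0).astype(float), axis=0)
        mean_shell = np.nanmean(shell_means, axis=0)
    return EvaluationReport(
        example_ids=ids,
        pc=[float(x) for x in pcs],
        mean_phase_error_deg=[float(x) for x in mpes],
        shell_d_max=[float(x) for x in np.nanmax(np.array(shell_dmax), axis=0)],
        shell_d_min=[float(x) for x in np.nanmin(np.array(shell_dmin), axis=0)],
        shell_mean_phase_error_deg=[float(x) for x in mean_shell],
        shell_frac_examples_below_60=[float(x) for x in frac_below],
        n_shells=n_shells,
    )
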