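"""Standardisation, data splitting, L1 training and per-gene evaluation.

Training minimises mean absolute error (robust to the heavy-tailed outliers
typical of expression data) by mini-batch Adam with early stopping on
validation MAE; the parameters achieving the best validation MAE are the
ones retained.  Evaluation is per target gene: the mean absolute error of
each gene over test samples, summarised by its mean and standard deviation
across genes, plus gene-wise win fractions between model pairs and
histogram tables for density plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .models import LinearRegressionModel, NCLayer, NeuralModel

__all__ = [
    "TrainConfig",
    "DataSplit",
    "EvalReport",
    "GenewiseComparison",
    "TrainHistory",
    "Standardizer",
    "standardize",
    "split_data",
    "train_model",
    "evaluate_mae",
    "compare_genewise",
    "density_data",
]


@dataclass
class TrainConfig:
    """Hyperparameters of the L1 training loop.

    loss is fixed to mean absolute error; ``optimizer`` is "adam"
    (default) or "momentum" SGD.
    """

    optimizer: str = "adam"
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    momentum: float = 0.9
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 20
    dropout: float = 0.0
    restore_best: bool = True  # keep best-validation weights (else final epoch)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.optimizer not in ("adam", "momentum"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class DataSplit:
    """Disjoint, exhaustive train/validation/test sample indices."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)

    def __post_init__(self) -> None:
        blocks = [np.asarray(b, dtype=int) for b in (self.train, self.val, self.test)]
        self.train, self.val, self.test = blocks
        n = sum(len(b) for b in blocks)
        union = np.concatenate(blocks)
        if len(np.unique(union)) != n or set(union.tolist()) != set(range(n)):
            raise ValueError("split blocks must disjointly cover 0..n-1")


def split_data(
    n_samples: int,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> DataSplit:
    """Uniformly random partition; rounded val/test sizes, remainder to train."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_val = int(round(n_samples * fractions[1]))
    n_test = int(round(n_samples * fractions[2]))
    n_train = n_samples - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"empty block at n={n_samples}, fractions={fractions}: "
            f"sizes ({n_train}, {n_val}, {n_test})"
        )
    perm = np.random.default_rng(seed).permutation(n_samples)
    return DataSplit(
        train=np.sort(perm[:n_train]),
        val=np.sort(perm[n_train : n_train + n_val]),
        test=np.sort(perm[n_train + n_val :]),
        fractions=tuple(fractions),
    )


@dataclass
class Standardizer:
    """Per-gene location/scale learned on the training block only.

    Uses the population standard deviation (ddof=0).  Zero-variance genes
    map to constant 0 with a warning; their scale is stored as 1.
    """

    mean: np.ndarray
    scale: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.scale

    def inverse_transform(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.scale + self.mean


def standardize(
    train: np.ndarray, *other: np.ndarray
) -> tuple[list[np.ndarray], Standardizer]:
    """Z-score each gene using training-block statistics.

    Returns ``([train_std, *other_std], standardizer)``; the extra blocks
    (validation, test) are transformed with the training parameters.
    """
    train = np.asarray(train, dtype=float)
    if train.size == 0:
        raise ValueError("empty training block")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance gene(s) mapped to constant 0",
            stacklevel=2,
        )
        sd = np.where(degenerate, 1.0, sd)
    std = Standardizer(mean=mean, scale=sd)
    return [std.transform(b) for b in (train, *other)], std


# ---------------------------------------------------------------------------
# optimizers

class _Adam:
    def __init__(self, cfg: TrainConfig) -> None:
        self.cfg = cfg
        self.m: dict[int, np.ndarray] = {}
        self.v: dict[int, np.ndarray] = {}
        self.t = 0

    def step(self, model: NeuralModel) -> None:
        c = self.cfg
        self.t += 1
        bc1 = 1.0 - c.beta1**self.t
        bc2 = 1.0 - c.beta2**self.t
        for idx, (_, _, value, grad, mask) in enumerate(model.parameters()):
            if idx not in self.m:
                self.m[idx] = np.zeros_like(value)
                self.v[idx] = np.zeros_like(value)
            self.m[idx] = c.beta1 * self.m[idx] + (1 - c.beta1) * grad
            self.v[idx] = c.beta2 * self.v[idx] + (1 - c.beta2) * grad * grad
            update = (
                c.learning_rate
                * (self.m[idx] / bc1)
                / (np.sqrt(self.v[idx] / bc2) + c.eps)
            )
            value -= update
            if mask is not None:
                value *= np.broadcast_to(mask, value.shape)


class _Momentum:
    def __init__(self, cfg: TrainConfig) -> None:
        self.cfg = cfg
        self.vel: dict[int, np.ndarray] = {}

    def step(self, model: NeuralModel) -> None:
        c = self.cfg
        for idx, (_, _, value, grad, mask) in enumerate(model.parameters()):
            if idx not in self.vel:
                self.vel[idx] = np.zeros_like(value)
            self.vel[idx] = c.momentum * self.vel[idx] - c.learning_rate * grad
            value += self.vel[idx]
            if mask is not None:
                value *= np.broadcast_to(mask, value.shape)


@dataclass
class TrainHistory:
    train_mae: list[float] = field(default_factory=list)
    val_mae: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_mae: float = np.inf


def _batch_mae(model: NeuralModel, x: np.ndarray, y: np.ndarray, chunk: int = 4096) -> float:
    total = 0.0
    for start in range(0, len(x), chunk):
        pred = model.predict(x[start : start + chunk])
        total += np.abs(pred - y[start : start + chunk]).sum()
    return total / y.size


def train_model(
    model: NeuralModel,
    x: np.ndarray,
    y: np.ndarray,
    split: DataSplit,
    config: TrainConfig,
) -> TrainHistory:
    """Train in place with mini-batch L1 loss; keep the best-validation weights.

    The NC layer's off-mask weights carry zero gradients and are re-masked
    after every optimizer step, so they remain exactly zero throughout.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_tr, y_tr = x[split.train], y[split.train]
    x_val, y_val = x[split.val], y[split.val]
    rng = np.random.default_rng(config.seed)
    opt = _Adam(config) if config.optimizer == "adam" else _Momentum(config)
    history = TrainHistory()
    best_state = model.get_state()
    bad_epochs = 0

    n_train = len(x_tr)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n_train)
        epoch_abs = 0.0
        for start in range(0, n_train, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            pred = model.forward(xb, train=True)
            resid = pred - yb
            loss = np.abs(resid).mean()
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite L1 loss at epoch {epoch}, "
                    f"learning_rate={config.learning_rate}"
                )
            epoch_abs += np.abs(resid).sum()
            model.zero_grad()
            model.backward(np.sign(resid) / resid.size)
            opt.step(model)
        history.train_mae.append(epoch_abs / (n_train * y.shape[1]))

        val_mae = _batch_mae(model, x_val, y_val)
        history.val_mae.append(val_mae)
        if val_mae < history.best_val_mae:
            history.best_val_mae = val_mae
            history.best_epoch = epoch
            best_state = model.get_state()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break

    if config.restore_best:
        model.set_state(best_state)
    return history


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class EvalReport:
    """Per-target-gene MAE over test samples with across-gene summaries."""

    model: str
    per_gene_mae: np.ndarray
    gene_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.per_gene_mae = np.asarray(self.per_gene_mae, dtype=float)
        if np.any(self.per_gene_mae < 0):
            raise ValueError("per-gene MAE must be non-negative")

    @property
    def overall(self) -> float:
        return float(self.per_gene_mae.mean())

    @property
    def spread(self) -> float:
        """Standard deviation of per-gene MAE across genes."""
        return float(self.per_gene_mae.std(ddof=0))

    def summary(self) -> str:
        return f"{self.model}: MAE {self.overall:.4f} ± {self.spread:.4f}"


def evaluate_mae(
    model,
    x_test: np.ndarray,
    y_test: np.ndarray,
    gene_ids: list[str] | None = None,
    tag: str | None = None,
) -> EvalReport:
    """Per-gene mean absolute error of ``model.predict`` on the test block."""
    x_test = np.asarray(x_test, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    if len(x_test) == 0:
        raise ValueError("empty test block")
    pred = model.predict(x_test)
    per_gene = np.abs(pred - y_test).mean(axis=0)
    return EvalReport(
        model=tag or getattr(model, "tag", "model"),
        per_gene_mae=per_gene,
        gene_ids=gene_ids,
    )


@dataclass
class GenewiseComparison:
    """Share of target genes on which model A strictly beats model B."""

    model_a: str
    model_b: str
    fraction_a_better: float
    mae_a: np.ndarray
    mae_b: np.ndarray


def compare_genewise(a: EvalReport, b: EvalReport) -> GenewiseComparison:
    """Fraction of genes with strictly lower MAE under A; ties count for neither."""
    if a.per_gene_mae.shape != b.per_gene_mae.shape:
        raise ValueError("reports cover different numbers of genes")
    if a.gene_ids is not None and b.gene_ids is not None and a.gene_ids != b.gene_ids:
        raise ValueError("reports cover different gene lists")
    wins = np.count_nonzero(a.per_gene_mae < b.per_gene_mae)
    return GenewiseComparison(
        model_a=a.model,
        model_b=b.model,
        fraction_a_better=wins / a.per_gene_mae.size,
        mae_a=a.per_gene_mae,
        mae_b=b.per_gene_mae,
    )


def density_data(
    reports: list[EvalReport], bins: int | np.ndarray = 30
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Histogram per-gene MAE on shared bin edges (plot-ready density table)."""
    if not reports:
        raise ValueError("need at least one report")
    all_mae = np.concatenate([r.per_gene_mae for r in reports])
    edges = np.histogram_bin_edges(all_mae, bins=bins)
    counts = {r.model: np.histogram(r.per_gene_mae, bins=edges)[0] for r in reports}
    return edges, counts
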