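"""Model layers and architectures for landmark-to-target expression inference.

The centrepiece is the neighbour-connection (NC) layer: a linear layer over
graph node features in which node ``i``'s output depends only on the nodes
in ``N(i) | {i}``, with a distinct trainable weight for every
(edge, input-feature, output-feature) triple.  Unlike a graph convolution,
the weights are untied across edges, so the layer can learn how much each
specific neighbour matters; unlike a dense layer, everything off the
connectivity mask is structurally zero and never trained.

Forward and backward passes are written directly in NumPy: each layer
caches its inputs on ``forward`` and returns the input gradient from
``backward`` while accumulating parameter gradients, in the style of a
minimal define-by-run tape.  This keeps the sparsity constraint exact: the
off-mask positions of the NC weight tensor carry zero values and zero
gradients at every step.

Architectures mirror the experimental setup of the expression-inference
task: given a nominal hidden budget of ``H`` units and ``L`` hidden layers,

* ``NCNN``  = NC layer with ``h1 = floor(H / d)`` features per node,
  flattened to ``d * h1 <= H`` units, then an MLP with ``L - 1`` hidden
  layers of width ``H`` (log-sigmoid) and a linear output;
* ``GCN``   = same layout with the NC layer replaced by a two-path graph
  convolution (normalised-neighbour path plus self path, weights shared
  across nodes);
* ``MLP``   = the order-blind fully connected baseline, ``L`` hidden
  layers of width ``H`` with tanh activations (optionally dropout);
* ``LR``    = per-target least-squares linear regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .graph import BinaryGeneGraph, ConnectivityMask, build_mask, degree_and_normalize

__all__ = [
    "Activation",
    "ACTIVATIONS",
    "NCLayer",
    "GCNLayer",
    "DenseLayer",
    "FlattenNodes",
    "NeuralModel",
    "LinearRegressionModel",
    "ParamCount",
    "allocate_hidden",
    "flatten",
    "nc_forward",
    "gcn_forward",
    "ncnn_predict",
    "build_ncnn",
    "build_gcn_model",
    "build_mlp",
    "count_parameters",
    "fit_linear_regression",
]


# ---------------------------------------------------------------------------
# activations

@dataclass(frozen=True)
class Activation:
    name: str
    f: Callable[[np.ndarray], np.ndarray]
    df: Callable[[np.ndarray, np.ndarray], np.ndarray]  # df(z, a) -> sigma'(z)


def _logsigmoid(z: np.ndarray) -> np.ndarray:
    # log sigma(z) = -softplus(-z), computed stably on both tails
    return -np.logaddexp(0.0, -z)


ACTIVATIONS: dict[str, Activation] = {
    "identity": Activation("identity", lambda z: z, lambda z, a: np.ones_like(z)),
    "tanh": Activation("tanh", np.tanh, lambda z, a: 1.0 - a * a),
    "logsigmoid": Activation(
        "logsigmoid",
        _logsigmoid,
        # d/dz log sigma(z) = 1 - sigma(z) = sigma(-z) = exp(log sigma(z) - z)...
        # use sigma(-z) directly for stability
        lambda z, a: 1.0 / (1.0 + np.exp(z)),
    ),
    "relu": Activation(
        "relu",
        lambda z: np.maximum(z, 0.0),
        lambda z, a: (z > 0).astype(z.dtype),
    ),
}


def get_activation(name: str) -> Activation:
    try:
        return ACTIVATIONS[name]
    except KeyError:
        raise ValueError(f"unknown activation {name!r}") from None


# ---------------------------------------------------------------------------
# sizing

def allocate_hidden(H: int, d: int) -> int:
    """Per-node feature count ``h1 = floor(H / d)`` matching a width-H MLP.

    After flattening, the NC layer output has length ``d * h1 <= H``, so the
    graph models and the dense baseline are compared at (approximately) the
    same hidden width.
    """
    h1 = H // d
    if h1 < 1:
        raise ValueError(f"H={H} < d={d}: per-node width floor(H/d) would be 0")
    return h1


def flatten(node_features: np.ndarray) -> np.ndarray:
    """Flatten (..., d, h) node features to (..., d*h) by feature blocks.

    Column-block order: all nodes' feature 1, then all nodes' feature 2, ...
    so ``[[a, b], [c, d]]`` becomes ``(a, c, b, d)``.
    """
    x = np.asarray(node_features)
    if x.ndim == 2:
        return x.T.reshape(-1)
    return np.swapaxes(x, -1, -2).reshape(*x.shape[:-2], -1)


def unflatten(vec: np.ndarray, d: int, h: int) -> np.ndarray:
    v = np.asarray(vec)
    return np.swapaxes(v.reshape(*v.shape[:-1], h, d), -1, -2)


# ---------------------------------------------------------------------------
# layers (forward caches input, backward returns dX and accumulates grads)

class Layer:
    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


class NCLayer(Layer):
    """Neighbour-connection layer with untied per-edge weights.

    ``weight[m, k, i, j]`` scales input feature ``k`` of node ``j`` into
    output feature ``m`` of node ``i`` and exists only where
    ``mask[i, j] = 1`` (neighbours and self); one bias per
    (node, output feature).  Stored dense with a hard mask: off-mask
    entries are exactly zero and receive exactly zero gradient.
    """

    def __init__(
        self,
        mask: ConnectivityMask,
        h_in: int,
        h_out: int,
        activation: str = "tanh",
        rng: np.random.Generator | None = None,
    ) -> None:
        self.mask = mask.mask.astype(float)  # (d, d)
        d = mask.n_nodes
        self.d, self.h_in, self.h_out = d, h_in, h_out
        self.activation = get_activation(activation)
        rng = rng or np.random.default_rng(0)
        # symmetric-uniform init scaled by each node's incoming fan-in
        fan_in = (self.mask.sum(axis=1) * h_in)  # (|N(i)|+1) * h_in per node i
        limit = np.sqrt(3.0 / fan_in)  # variance 1/fan_in
        w = rng.uniform(-1.0, 1.0, size=(h_out, h_in, d, d)) * limit[None, None, :, None]
        w *= self.mask[None, None, :, :]
        self.params = {"W": w, "b": np.zeros((d, h_out))}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._x: np.ndarray | None = None
        self._z: np.ndarray | None = None
        self._a: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        # x: (n, d, h_in) -> (n, d, h_out)
        if x.ndim != 3 or x.shape[1] != self.d or x.shape[2] != self.h_in:
            raise ValueError(
                f"NC layer expects (n, {self.d}, {self.h_in}), got {x.shape}"
            )
        z = np.einsum("mkij,njk->nim", self.params["W"], x, optimize=True)
        z += self.params["b"][None, :, :]
        self._x, self._z = x, z
        self._a = self.activation.f(z)
        return self._a

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dz = dy * self.activation.df(self._z, self._a)
        self.grads["W"] += (
            np.einsum("nim,njk->mkij", dz, self._x, optimize=True)
            * self.mask[None, None, :, :]
        )
        self.grads["b"] += dz.sum(axis=0)
        return np.einsum("mkij,nim->njk", self.params["W"], dz, optimize=True)

    def param_masks(self) -> dict[str, np.ndarray | None]:
        return {"W": self.mask[None, None, :, :], "b": None}


class GCNLayer(Layer):
    """Two-path graph convolution with weights shared across nodes.

    Output = sigma(P X W1 + X W2) where P is the symmetrically normalised
    self-loop adjacency; W1 carries the neighbourhood path, W2 the raw self
    path.  No bias by default (``use_bias`` adds one per output feature).
    """

    def __init__(
        self,
        graph: BinaryGeneGraph,
        h_in: int,
        h_out: int,
        activation: str = "tanh",
        use_bias: bool = False,
        rng: np.random.Generator | None = None,
    ) -> None:
        _, self.normalized = degree_and_normalize(graph)
        self.d, self.h_in, self.h_out = graph.n_nodes, h_in, h_out
        self.activation = get_activation(activation)
        self.use_bias = use_bias
        rng = rng or np.random.default_rng(0)
        limit = np.sqrt(3.0 / h_in)
        self.params = {
            "W1": rng.uniform(-limit, limit, size=(h_in, h_out)),
            "W2": rng.uniform(-limit, limit, size=(h_in, h_out)),
        }
        if use_bias:
            self.params["b"] = np.zeros(h_out)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 3 or x.shape[1] != self.d or x.shape[2] != self.h_in:
            raise ValueError(
                f"GCN layer expects (n, {self.d}, {self.h_in}), got {x.shape}"
            )
        px = np.einsum("ij,njk->nik", self.normalized, x, optimize=True)
        z = px @ self.params["W1"] + x @ self.params["W2"]
        if self.use_bias:
            z += self.params["b"]
        self._x, self._px, self._z = x, px, z
        self._a = self.activation.f(z)
        return self._a

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dz = dy * self.activation.df(self._z, self._a)
        self.grads["W1"] += np.einsum("nik,nim->km", self._px, dz, optimize=True)
        self.grads["W2"] += np.einsum("nik,nim->km", self._x, dz, optimize=True)
        if self.use_bias:
            self.grads["b"] += dz.sum(axis=(0, 1))
        dpx = dz @ self.params["W1"].T
        dx = np.einsum("ij,nik->njk", self.normalized, dpx, optimize=True)
        dx += dz @ self.params["W2"].T
        return dx

    def param_masks(self) -> dict[str, np.ndarray | None]:
        return {k: None for k in self.params}


class FlattenNodes(Layer):
    """(n, d, h) -> (n, d*h) in feature-block order; no parameters."""

    def __init__(self, d: int, h: int) -> None:
        self.d, self.h = d, h
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return flatten(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return unflatten(dy, self.d, self.h)

    def param_masks(self) -> dict[str, np.ndarray | None]:
        return {}


class DenseLayer(Layer):
    """Fully connected layer with optional inverted dropout on its output."""

    def __init__(
        self,
        n_in: int,
        n_out: int,
        activation: str = "identity",
        dropout: float = 0.0,
        rng: np.random.Generator | None = None,
    ) -> None:
        self.n_in, self.n_out = n_in, n_out
        self.activation = get_activation(activation)
        self.dropout = float(dropout)
        rng = rng or np.random.default_rng(0)
        limit = np.sqrt(3.0 / n_in)
        self.params = {
            "W": rng.uniform(-limit, limit, size=(n_in, n_out)),
            "b": np.zeros(n_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        z = x @ self.params["W"] + self.params["b"]
        self._x, self._z = x, z
        a = self.activation.f(z)
        self._a = a
        if train and self.dropout > 0.0:
            keep = 1.0 - self.dropout
            self._drop = (self._rng.random(a.shape) < keep) / keep
            a = a * self._drop
        else:
            self._drop = None
        return a

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._drop is not None:
            dy = dy * self._drop
        dz = dy * self.activation.df(self._z, self._a)
        self.grads["W"] += self._x.T @ dz
        self.grads["b"] += dz.sum(axis=0)
        return dz @ self.params["W"].T

    def param_masks(self) -> dict[str, np.ndarray | None]:
        return {"W": None, "b": None}


# ---------------------------------------------------------------------------
# models

class NeuralModel:
    """A sequence of layers trained jointly; input is (n_samples, d)."""

    def __init__(self, layers: list[Layer], tag: str, graph_input: bool) -> None:
        self.layers = layers
        self.tag = tag
        self.graph_input = graph_input  # expects (n, d) reshaped to (n, d, 1)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = x[:, :, None] if self.graph_input else x
        for layer in self.layers:
            out = layer.forward(out, train=train)
        return out

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(np.asarray(x, dtype=float), train=False)

    def parameters(self):
        """Yield (layer_idx, name, value, grad, mask_or_None) tuples."""
        for li, layer in enumerate(self.layers):
            masks = layer.param_masks()
            for name, value in layer.params.items():
                yield li, name, value, layer.grads[name], masks[name]

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def get_state(self) -> dict[str, np.ndarray]:
        return {
            f"layer{li}.{name}": value.copy()
            for li, name, value, _, _ in self.parameters()
        }

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for li, name, value, _, _ in self.parameters():
            value[...] = state[f"layer{li}.{name}"]


def nc_forward(
    x: np.ndarray, layer: NCLayer, mask: ConnectivityMask | None = None
) -> np.ndarray:
    """Apply one NC layer to (n, d, h_in) features (thin functional wrapper)."""
    if mask is not None and not np.array_equal(
        mask.mask.astype(float), layer.mask
    ):
        raise ValueError("mask does not match the layer's connectivity")
    return layer.forward(np.asarray(x, dtype=float))


def gcn_forward(x: np.ndarray, layer: GCNLayer) -> np.ndarray:
    """Apply one GCN layer to (n, d, h_in) features."""
    return layer.forward(np.asarray(x, dtype=float))


def build_ncnn(
    graph: BinaryGeneGraph,
    n_targets: int,
    H: int,
    L: int = 2,
    nc_activation: str = "tanh",
    mlp_activation: str = "logsigmoid",
    seed: int = 0,
) -> NeuralModel:
    """NC layer + flatten + (L-1) log-sigmoid hidden layers + linear output.

    ``L`` counts hidden layers including the NC layer itself, matching the
    layer budget of the dense baseline.
    """
    if L < 1:
        raise ValueError("need at least one hidden layer")
    d = graph.n_nodes
    h1 = allocate_hidden(H, d)
    rng = np.random.default_rng(seed)
    mask = build_mask(graph)
    layers: list[Layer] = [
        NCLayer(mask, 1, h1, activation=nc_activation, rng=rng),
        FlattenNodes(d, h1),
    ]
    width = d * h1
    for _ in range(L - 1):
        layers.append(DenseLayer(width, H, activation=mlp_activation, rng=rng))
        width = H
    layers.append(DenseLayer(width, n_targets, activation="identity", rng=rng))
    return NeuralModel(layers, tag="NCNN", graph_input=True)


def build_gcn_model(
    graph: BinaryGeneGraph,
    n_targets: int,
    H: int,
    L: int = 2,
    gcn_activation: str = "tanh",
    mlp_activation: str = "logsigmoid",
    seed: int = 0,
) -> NeuralModel:
    """GCN layer + flatten + (L-1) hidden layers + linear output (sizing as NCNN)."""
    if L < 1:
        raise ValueError("need at least one hidden layer")
    d = graph.n_nodes
    h1 = allocate_hidden(H, d)
    rng = np.random.default_rng(seed)
    layers: list[Layer] = [
        GCNLayer(graph, 1, h1, activation=gcn_activation, rng=rng),
        FlattenNodes(d, h1),
    ]
    width = d * h1
    for _ in range(L - 1):
        layers.append(DenseLayer(width, H, activation=mlp_activation, rng=rng))
        width = H
    layers.append(DenseLayer(width, n_targets, activation="identity", rng=rng))
    return NeuralModel(layers, tag="GCN", graph_input=True)


def build_mlp(
    d: int,
    n_targets: int,
    H: int,
    L: int = 2,
    activation: str = "tanh",
    dropout: float = 0.0,
    seed: int = 0,
) -> NeuralModel:
    """Order-blind dense baseline: L tanh hidden layers of width H."""
    if L < 1:
        raise ValueError("need at least one hidden layer")
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    width = d
    for _ in range(L):
        layers.append(
            DenseLayer(width, H, activation=activation, dropout=dropout, rng=rng)
        )
        width = H
    layers.append(DenseLayer(width, n_targets, activation="identity", rng=rng))
    return NeuralModel(layers, tag="MLP", graph_input=False)


def ncnn_predict(
    x_samples: np.ndarray, model: NeuralModel, mask: ConnectivityMask | None = None
) -> np.ndarray:
    """Predict target expression for (n_samples, d) landmark expression."""
    if mask is not None:
        nc = model.layers[0]
        if isinstance(nc, NCLayer) and not np.array_equal(
            mask.mask.astype(float), nc.mask
        ):
            raise ValueError("mask does not match the model's NC layer")
    return model.predict(x_samples)


# ---------------------------------------------------------------------------
# linear regression baseline

class LinearRegressionModel:
    """Per-target least-squares fit; minimum-norm solution if rank deficient."""

    tag = "LR"

    def __init__(self, coef: np.ndarray, intercept: np.ndarray) -> None:
        self.coef = coef          # (d, n_targets)
        self.intercept = intercept  # (n_targets,)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) @ self.coef + self.intercept


def fit_linear_regression(x: np.ndarray, y: np.ndarray) -> LinearRegressionModel:
    """Ordinary least squares with intercept, one fit per target gene."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("X and Y sample counts differ")
    x_mean = x.mean(axis=0)
    y_mean = y.mean(axis=0)
    coef, _, rank, _ = np.linalg.lstsq(x - x_mean, y - y_mean, rcond=None)
    if rank < x.shape[1]:
        import warnings

        warnings.warn(
            f"design matrix rank {rank} < {x.shape[1]}: minimum-norm solution",
            stacklevel=2,
        )
    intercept = y_mean - x_mean @ coef
    return LinearRegressionModel(coef, intercept)


# ---------------------------------------------------------------------------
# parameter accounting

@dataclass
class ParamCount:
    """Trainable-parameter tallies for one model configuration.

    ``first_layer_edge_params`` counts only the neighbour-path weights of
    the first layer (the convention of sparse-connection complexity
    analyses: ``sum_i |N(i)| * h1 = 2|E| * h1`` for the NC layer, excluding
    the self-connection weights).  ``total_trainable`` enumerates every
    trainable entry, including self weights, biases and the head.
    """

    model: str
    first_layer_edge_params: int
    total_trainable: int


def _enumerate_trainable(model: NeuralModel) -> int:
    total = 0
    for _, _, value, _, mask in model.parameters():
        if mask is None:
            total += value.size
        else:
            total += int(np.count_nonzero(np.broadcast_to(mask, value.shape)))
    return total


def count_parameters(
    model_kind: str,
    graph: BinaryGeneGraph | None,
    H: int,
    n_targets: int,
    L: int = 2,
    d: int | None = None,
) -> ParamCount:
    """Closed-form parameter tallies per model family.

    * ``"mlp"``  — first layer ``d * H`` dense weights;
    * ``"ncnn"`` — first-layer edge weights ``2|E| * floor(H/d)``
      (neighbour path only); the total additionally counts the self
      weights ``d * floor(H/d)``, the biases, and the MLP head;
    * ``"gcn"``  — first layer ``2 * floor(H/d)`` shared weights.

    The closed forms are checked against brute-force enumeration of the
    instantiated model's trainable entries in the test-suite.
    """
    kind = model_kind.lower()
    if kind in ("ncnn", "gcn") and graph is None:
        raise ValueError(f"{model_kind} needs a graph")
    if d is None:
        d = graph.n_nodes if graph is not None else None
    if d is None:
        raise ValueError("node count d required")

    if kind in ("mlp", "d-gex", "dgex"):
        first = d * H
        model = build_mlp(d, n_targets, H, L=L)
        return ParamCount("MLP", first, _enumerate_trainable(model))
    if kind == "ncnn":
        h1 = allocate_hidden(H, d)
        first = 2 * graph.n_edges * h1
        model = build_ncnn(graph, n_targets, H, L=L)
        return ParamCount("NCNN", first, _enumerate_trainable(model))
    if kind == "gcn":
        h1 = allocate_hidden(H, d)
        first = 2 * h1
        model = build_gcn_model(graph, n_targets, H, L=L)
        return ParamCount("GCN", first, _enumerate_trainable(model))
    if kind == "lr":
        first = d * n_targets
        return ParamCount("LR", first, d * n_targets + n_targets)
    raise ValueError(f"unknown model kind {model_kind!r}")
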