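"""File formats: expression tables (TSV / GCT v1.2), checkpoints, reports.

TSV expression tables are samples-as-rows with a leading ``sample_id``
column; GCT v1.2 follows its own ecosystem convention of genes as rows
(version line ``#1.2``, dimensions line, ``Name``/``Description`` columns)
and is transposed on load.  All writers and readers round-trip their own
output bitwise; missing values are rejected rather than imputed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .models import (
    DenseLayer,
    FlattenNodes,
    GCNLayer,
    NCLayer,
    NeuralModel,
)
from .graph import BinaryGeneGraph, ConnectivityMask, build_mask
from .training import EvalReport, GenewiseComparison

__all__ = [
    "ExpressionTable",
    "load_expression",
    "save_expression_tsv",
    "save_expression_gct",
    "save_checkpoint",
    "load_checkpoint",
    "save_eval_report",
    "load_eval_report",
    "save_comparison",
    "write_manifest",
]


@dataclass
class ExpressionTable:
    """Samples × genes expression with a landmark/target role per gene."""

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    landmark: list[str]
    target: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError("values shape does not match sample/gene counts")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if set(self.landmark) & set(self.target):
            raise ValueError("landmark and target gene sets overlap")
        if set(self.landmark) | set(self.target) != set(self.gene_ids):
            raise ValueError("landmark+target must cover all genes")
        if np.isnan(self.values).any():
            raise ValueError("missing values are not supported")

    @property
    def X(self) -> np.ndarray:
        idx = [self.gene_ids.index(g) for g in self.landmark]
        return self.values[:, idx]

    @property
    def Y(self) -> np.ndarray:
        idx = [self.gene_ids.index(g) for g in self.target]
        return self.values[:, idx]


def _reorder(df: pd.DataFrame, landmark: list[str], target: list[str]) -> ExpressionTable:
    for g in [*landmark, *target]:
        if g not in df.columns:
            raise KeyError(f"gene {g!r} absent from expression file")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate gene {dup!r} in expression file")
    ordered = [*landmark, *target]
    return ExpressionTable(
        sample_ids=[str(s) for s in df.index],
        gene_ids=ordered,
        values=df[ordered].to_numpy(dtype=float),
        landmark=list(landmark),
        target=list(target),
    )


def load_expression(
    path: str | Path,
    landmark: list[str],
    target: list[str],
    format: str = "tsv",
) -> ExpressionTable:
    """Load a TSV (samples as rows) or GCT v1.2 (genes as rows) matrix.

    Genes are reordered to (landmark in given order, target in given
    order); genes present in the file but in neither list are dropped.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    elif format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise ValueError(f"expected GCT version line '#1.2', got {version!r}")
            nrow, ncol = (int(t) for t in fh.readline().split()[:2])
            df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
        if df.shape[0] != nrow or df.shape[1] - 2 != ncol:
            raise ValueError("GCT dimensions line disagrees with the table")
        df = df.set_index("Name").drop(columns="Description").T
    else:
        raise ValueError(f"unknown format {format!r}")
    return _reorder(df, landmark, target)


def save_expression_tsv(table: ExpressionTable, path: str | Path) -> None:
    df = pd.DataFrame(
        table.values, index=pd.Index(table.sample_ids, name="sample_id"),
        columns=table.gene_ids,
    )
    df.to_csv(path, sep="\t", float_format="%.17g")


def save_expression_gct(table: ExpressionTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{len(table.gene_ids)}\t{len(table.sample_ids)}\n")
        fh.write("Name\tDescription\t" + "\t".join(table.sample_ids) + "\n")
        for gi, gene in enumerate(table.gene_ids):
            row = "\t".join(f"{v:.17g}" for v in table.values[:, gi])
            fh.write(f"{gene}\tna\t{row}\n")


def gene_roles(table: ExpressionTable) -> dict[str, str]:
    roles = {g: "landmark" for g in table.landmark}
    roles.update({g: "target" for g in table.target})
    return roles


# ---------------------------------------------------------------------------
# model checkpoints

def save_checkpoint(model: NeuralModel, path: str | Path, seed: int | None = None) -> None:
    """Self-describing archive: layer specs, masks, parameters, seed."""
    arrays: dict[str, np.ndarray] = {}
    specs = []
    for li, layer in enumerate(model.layers):
        if isinstance(layer, NCLayer):
            spec = {
                "kind": "nc", "h_in": layer.h_in, "h_out": layer.h_out,
                "activation": layer.activation.name,
            }
            arrays[f"layer{li}.mask"] = layer.mask
        elif isinstance(layer, GCNLayer):
            spec = {
                "kind": "gcn", "h_in": layer.h_in, "h_out": layer.h_out,
                "activation": layer.activation.name, "use_bias": layer.use_bias,
            }
            arrays[f"layer{li}.normalized"] = layer.normalized
        elif isinstance(layer, FlattenNodes):
            spec = {"kind": "flatten", "d": layer.d, "h": layer.h}
        elif isinstance(layer, DenseLayer):
            spec = {
                "kind": "dense", "n_in": layer.n_in, "n_out": layer.n_out,
                "activation": layer.activation.name, "dropout": layer.dropout,
            }
        else:
            raise TypeError(f"cannot serialize layer {type(layer).__name__}")
        specs.append(spec)
        for name, value in layer.params.items():
            arrays[f"layer{li}.{name}"] = value
    meta = {"tag": model.tag, "graph_input": model.graph_input,
            "layers": specs, "seed": seed}
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8
    )
    _write_npz_deterministic(path, arrays)


def _write_npz_deterministic(path: str | Path, arrays: dict[str, np.ndarray]) -> None:
    """npz writer with fixed zip timestamps so identical states give
    byte-identical files."""
    import io as _io
    import zipfile

    with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
        for name in sorted(arrays):
            buf = _io.BytesIO()
            np.lib.format.write_array(buf, np.asarray(arrays[name]))
            info = zipfile.ZipInfo(f"{name}.npy", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, buf.getvalue())


def load_checkpoint(path: str | Path) -> NeuralModel:
    with np.load(path) as npz:
        arrays = {k: npz[k] for k in npz.files}
    meta = json.loads(arrays.pop("__meta__").tobytes().decode())
    layers = []
    for li, spec in enumerate(meta["layers"]):
        kind = spec["kind"]
        if kind == "nc":
            mask = ConnectivityMask(arrays[f"layer{li}.mask"].astype(np.int8))
            layer = NCLayer(mask, spec["h_in"], spec["h_out"], spec["activation"])
        elif kind == "gcn":
            normalized = arrays[f"layer{li}.normalized"]
            layer = GCNLayer.__new__(GCNLayer)
            layer.normalized = normalized
            layer.d = normalized.shape[0]
            layer.h_in, layer.h_out = spec["h_in"], spec["h_out"]
            from .models import get_activation

            layer.activation = get_activation(spec["activation"])
            layer.use_bias = spec["use_bias"]
            layer.params = {}
            layer.grads = {}
        elif kind == "flatten":
            layer = FlattenNodes(spec["d"], spec["h"])
        elif kind == "dense":
            layer = DenseLayer(
                spec["n_in"], spec["n_out"], spec["activation"], spec["dropout"]
            )
        else:
            raise ValueError(f"unknown layer kind {kind!r}")
        for key, value in arrays.items():
            prefix = f"layer{li}."
            if key.startswith(prefix):
                name = key[len(prefix):]
                if name in ("mask", "normalized"):
                    continue
                layer.params[name] = value.copy()
                layer.grads[name] = np.zeros_like(value)
        layers.append(layer)
    model = NeuralModel(layers, tag=meta["tag"], graph_input=meta["graph_input"])
    return model


# ---------------------------------------------------------------------------
# reports and manifests

def save_eval_report(report: EvalReport, path: str | Path) -> None:
    """Tab-delimited per-gene table with a trailing summary comment line."""
    with open(path, "w") as fh:
        fh.write("gene_id\tper_gene_mae\n")
        ids = report.gene_ids or [f"T{i + 1:04d}" for i in range(report.per_gene_mae.size)]
        for g, v in zip(ids, report.per_gene_mae):
            fh.write(f"{g}\t{v:.17g}\n")
        fh.write(f"# model={report.model}\toverall={report.overall:.17g}\t"
                 f"spread={report.spread:.17g}\n")


def load_eval_report(path: str | Path) -> EvalReport:
    genes, maes, model = [], [], "model"
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("model="):
                        model = tok[len("model="):]
                continue
            g, v = line.rstrip("\n").split("\t")
            genes.append(g)
            maes.append(float(v))
    return EvalReport(model=model, per_gene_mae=np.array(maes), gene_ids=genes)


def save_comparison(comparison: GenewiseComparison, path: str | Path,
                    gene_ids: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"gene_id\tmae_{comparison.model_a}\tmae_{comparison.model_b}\n")
        ids = gene_ids or [f"T{i + 1:04d}" for i in range(comparison.mae_a.size)]
        for g, a, b in zip(ids, comparison.mae_a, comparison.mae_b):
            fh.write(f"{g}\t{a:.17g}\t{b:.17g}\n")
        fh.write(f"# fraction_{comparison.model_a}_better="
                 f"{comparison.fraction_a_better:.17g}\n")


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, config: dict, seed: int,
                   inputs: list[str | Path] = (), outputs: list[str | Path] = ()) -> None:
    """Run manifest: config echo, seed, input digests, output paths."""
    from . import __version__

    # file names only, so identical runs into different directories stay
    # byte-identical
    manifest = {
        "package": "ncgex",
        "version": __version__,
        "seed": seed,
        "config": config,
        "inputs": {Path(p).name: file_digest(p) for p in inputs},
        "outputs": sorted(Path(p).name for p in outputs),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
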