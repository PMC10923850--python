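"""End-to-end learner for tree-structured hybrid classifiers.

Fitting proceeds in three phases: (1) the label tensors are condensed from
the training data and a conflict graph is built and max-cut per first-layer
module, giving each module's Boolean lookup table; (2) every training sample
is pushed through the module functions and its output-module configuration
counted against its label; (3) the output module assigns each configuration
a risk ``counter1 / (counter0 + counter1)`` and a majority-vote label.

Max-cut partitions are complement-symmetric, so each module lookup is
canonicalised (vertex 1 maps to 0); the output module is learned *after* the
module functions and absorbs any per-module complementation, leaving
predictions unchanged.

Configurations never seen in training have an undefined risk ratio; they are
flagged out-of-support and receive the training prevalence as risk and the
training majority class as label — with binary features any such prediction
is an extrapolation, and the prevalence is the honest prior.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

from .conflict import build_conflict_graph
from .exceptions import SchemaError, ShapeError
from .labeling import build_label_tensors
from .maxcut import CutSolution, MaxCutConfig, solve_maxcut
from .topology import (
    BinaryDataset,
    TreeTopology,
    decimal_encode,
    encode_samples,
)

MODEL_SCHEMA_VERSION = 1


@dataclass
class FitConfig:
    """Training settings: solver dispatch and out-of-support policy."""

    seed: Optional[int] = None
    exact_cap: int = 20
    n_roundings: int = 1000
    local_search: bool = True

    def maxcut_config(self, module_seed: Optional[int]) -> MaxCutConfig:
        return MaxCutConfig(
            exact_cap=self.exact_cap,
            n_roundings=self.n_roundings,
            local_search=self.local_search,
            seed=module_seed,
        )


@dataclass
class ModuleFunction:
    """Boolean lookup table of one first-layer module: vertex (1-based
    decimal configuration) -> output bit."""

    lookup: np.ndarray
    cut_value: float = 0.0
    method: str = ""

    def __post_init__(self) -> None:
        self.lookup = np.asarray(self.lookup, dtype=np.int8)
        if not np.isin(self.lookup, (0, 1)).all():
            raise ValueError("module function values must be binary")

    def __call__(self, vertex: int) -> int:
        return int(self.lookup[vertex - 1])


def identify_module_function(cut: CutSolution, m: int) -> ModuleFunction:
    """Read a module's Boolean function off a max-cut bipartition.

    Canonicalised so vertex 1 maps to 0; the complementary labelling encodes
    the same partition and is absorbed by the output module.
    """
    assignment = np.asarray(cut.assignment, dtype=np.int8)
    if assignment[0] == 1:
        assignment = 1 - assignment
    return ModuleFunction(assignment, cut.cut_value, cut.method)


@dataclass
class OutputModule:
    """Majority-vote aggregator over the 2^M module-output configurations."""

    func: np.ndarray  # predicted label per configuration
    risk: np.ndarray  # empirical mortality risk per configuration
    counter0: np.ndarray
    counter1: np.ndarray
    default_risk: float
    default_label: int

    def __post_init__(self) -> None:
        self.func = np.asarray(self.func, dtype=np.int8)
        self.risk = np.asarray(self.risk, dtype=np.float64)
        self.counter0 = np.asarray(self.counter0, dtype=np.int64)
        self.counter1 = np.asarray(self.counter1, dtype=np.int64)

    @property
    def unseen(self) -> np.ndarray:
        """Boolean mask of configurations never observed in training."""
        return (self.counter0 + self.counter1) == 0


@dataclass
class HybridModel:
    """A fitted tree-structured hybrid classifier."""

    topology: TreeTopology
    module_functions: list[ModuleFunction]
    output: OutputModule
    metadata: dict = field(default_factory=dict)

    # ---- forward passes ---------------------------------------------------

    def module_outputs(self, X: np.ndarray) -> np.ndarray:
        """First-layer bits f_1..f_M for each row of ``X`` (S x M)."""
        X = np.atleast_2d(np.asarray(X))
        profiles = encode_samples(X, self.topology)
        return np.stack(
            [
                func.lookup[profiles[:, m] - 1]
                for m, func in enumerate(self.module_functions)
            ],
            axis=1,
        )

    def output_configurations(self, X: np.ndarray) -> np.ndarray:
        """1-based output-module configuration index for each row."""
        f = self.module_outputs(X).astype(np.int64)
        M = len(self.module_functions)
        weights = 1 << np.arange(M - 1, -1, -1)
        return 1 + f @ weights

    def predict(self, X: np.ndarray) -> pd.DataFrame:
        """Per-row risk, predicted label and out-of-support flag."""
        idx = self.output_configurations(X) - 1
        unseen = self.output.unseen[idx]
        risk = np.where(unseen, self.output.default_risk, self.output.risk[idx])
        label = np.where(unseen, self.output.default_label, self.output.func[idx])
        return pd.DataFrame(
            {
                "risk": risk,
                "label": label.astype(int),
                "out_of_support": unseen,
            }
        )

    def predict_risk(self, x: Sequence[int]) -> float:
        return float(self.predict(np.atleast_2d(x))["risk"].iloc[0])

    def predict_label(self, x: Sequence[int]) -> int:
        return int(self.predict(np.atleast_2d(x))["label"].iloc[0])


def fit(
    dataset: BinaryDataset,
    topology: TreeTopology,
    config: Optional[FitConfig] = None,
) -> HybridModel:
    """Learn all first-layer module functions and the output module.

    Deterministic given ``config.seed``; per-module solver seeds are derived
    from it so modules are independent of solve order.
    """
    config = config or FitConfig()
    dataset = dataset.aligned_to(topology)
    tensors = build_label_tensors(dataset, topology)

    classes = np.unique(dataset.y)
    if len(classes) < 2:
        warnings.warn(
            "training labels contain a single class; module conflict graphs "
            "are empty and the model degenerates to the constant classifier",
            stacklevel=2,
        )

    seed_seq = np.random.SeedSequence(config.seed)
    module_seeds = [int(s) % (2**31) for s in seed_seq.generate_state(topology.n_modules)]

    module_functions: list[ModuleFunction] = []
    unconstrained: list[list[int]] = []
    for m in range(1, topology.n_modules + 1):
        graph = build_conflict_graph(tensors, topology, m)
        cut = solve_maxcut(graph, config.maxcut_config(module_seeds[m - 1]))
        module_functions.append(identify_module_function(cut, m))
        isolated = np.flatnonzero(graph.weights.sum(axis=1) == 0) + 1
        unconstrained.append([int(v) for v in isolated])

    # ---- output module: count labels per reached configuration -----------
    M = topology.n_modules
    n_configs = 1 << M
    counter0 = np.zeros(n_configs, dtype=np.int64)
    counter1 = np.zeros(n_configs, dtype=np.int64)
    stub = HybridModel(topology, module_functions, _empty_output(n_configs))
    idx = stub.output_configurations(dataset.X) - 1
    np.add.at(counter0, idx[dataset.y == 0], 1)
    np.add.at(counter1, idx[dataset.y == 1], 1)

    seen = (counter0 + counter1) > 0
    risk = np.zeros(n_configs, dtype=np.float64)
    risk[seen] = counter1[seen] / (counter0[seen] + counter1[seen])

    prevalence = float(dataset.y.mean())
    default_label = int(prevalence > 0.5)
    # majority vote; ties (counter0 == counter1 > 0) resolve to 1,
    # conservative toward flagging risk (risk is exactly 0.5 there anyway)
    func = np.where(seen, (counter1 >= counter0).astype(np.int8), default_label)
    risk[~seen] = prevalence

    output = OutputModule(
        func=func,
        risk=risk,
        counter0=counter0,
        counter1=counter1,
        default_risk=prevalence,
        default_label=default_label,
    )
    metadata = {
        "n_samples": int(dataset.n_samples),
        "label_prevalence": prevalence,
        "seed": config.seed,
        "solver_methods": [f.method for f in module_functions],
        "cut_values": [float(f.cut_value) for f in module_functions],
        "unconstrained_vertices": unconstrained,
        "n_unseen_configurations": int((~seen).sum()),
        "single_class": bool(len(classes) < 2),
    }
    return HybridModel(topology, module_functions, output, metadata)


def _empty_output(n_configs: int) -> OutputModule:
    zero = np.zeros(n_configs)
    return OutputModule(zero, zero, zero, zero, 0.0, 0)


def predict_risk(model: HybridModel, x: Sequence[int]) -> float:
    """Mortality-risk probability for one sample."""
    return model.predict_risk(x)


def predict_label(model: HybridModel, x: Sequence[int]) -> int:
    """Predicted binary outcome for one sample."""
    return model.predict_label(x)


def evaluate(model: HybridModel, dataset: BinaryDataset) -> dict:
    """Accuracy, recall, precision, F1 and ROC AUC on a labelled dataset.

    Labels come from the output module's majority vote; ROC AUC ranks the
    risk scores (midrank handling of ties).  On a single-class dataset the
    AUC is undefined and reported as None with a warning.
    """
    dataset = dataset.aligned_to(model.topology)
    preds = model.predict(dataset.X)
    y_true = dataset.y.astype(int)
    y_pred = preds["label"].to_numpy()
    metrics = {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "recall": float(recall_score(y_true, y_pred, zero_division=0)),
        "precision": float(precision_score(y_true, y_pred, zero_division=0)),
        "f1": float(f1_score(y_true, y_pred, zero_division=0)),
    }
    if len(np.unique(y_true)) < 2:
        warnings.warn("single-class dataset: ROC AUC undefined", stacklevel=2)
        metrics["roc_auc"] = None
    else:
        metrics["roc_auc"] = float(roc_auc_score(y_true, preds["risk"]))
    return metrics


# ---- serialization ---------------------------------------------------------


def save_model(model: HybridModel, path: str | Path) -> None:
    """Write a fitted model as versioned JSON (bit-exact round-trip)."""
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "topology": model.topology.to_mapping(),
        "module_functions": [
            {
                "lookup": model.module_functions[m].lookup.tolist(),
                "cut_value": model.module_functions[m].cut_value,
                "method": model.module_functions[m].method,
            }
            for m in range(model.topology.n_modules)
        ],
        "output": {
            "func": model.output.func.tolist(),
            "risk": model.output.risk.tolist(),
            "counter0": model.output.counter0.tolist(),
            "counter1": model.output.counter1.tolist(),
            "default_risk": model.output.default_risk,
            "default_label": model.output.default_label,
        },
        "metadata": model.metadata,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_model(path: str | Path) -> HybridModel:
    """Load a model written by :func:`save_model`."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not a valid model file ({exc})") from exc
    if not isinstance(payload, dict) or "schema_version" not in payload:
        raise SchemaError(f"{path}: missing schema_version")
    if payload["schema_version"] != MODEL_SCHEMA_VERSION:
        raise SchemaError(
            f"{path}: unsupported schema version {payload['schema_version']!r} "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    try:
        topology = TreeTopology.from_mapping(payload["topology"])
        module_functions = [
            ModuleFunction(
                np.asarray(entry["lookup"]),
                float(entry["cut_value"]),
                str(entry["method"]),
            )
            for entry in payload["module_functions"]
        ]
        out = payload["output"]
        output = OutputModule(
            func=np.asarray(out["func"]),
            risk=np.asarray(out["risk"]),
            counter0=np.asarray(out["counter0"]),
            counter1=np.asarray(out["counter1"]),
            default_risk=float(out["default_risk"]),
            default_label=int(out["default_label"]),
        )
        metadata = payload.get("metadata", {})
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: malformed model payload ({exc})") from exc
    if len(module_functions) != topology.n_modules:
        raise SchemaError(f"{path}: module count mismatch")
    return HybridModel(topology, module_functions, output, metadata)
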