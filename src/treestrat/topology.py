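"""Core domain types: network topology, binary datasets, and the 1-based
binary-to-decimal configuration encoding.

A tree-structured hybrid classifier wires ``N`` binary features (e.g. ICD-code
presence indicators) into ``M`` independent first-layer modules; module ``m``
reads a contiguous block of ``n_m`` features and emits a single bit.  All
lookup tables downstream are indexed by the *decimal profile* of a sample: the
1-based integer encoding of each module's feature block.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import InvalidInputError, ShapeError

#: Above this many inputs per module the exhaustive structures (2^{n_m}
#: vertices per conflict graph) become the practical bottleneck.
MODULE_SIZE_WARN = 8


def decimal_encode(bits: Sequence[int]) -> int:
    """Encode an ordered binary tuple as a 1-based decimal index.

    The most significant bit comes first:
    ``Decimal(x_1 ... x_n) = 1 + sum_i 2^(n-i) * x_i``, mapping ``{0,1}^n``
    bijectively onto ``{1, ..., 2^n}``.

    >>> decimal_encode((0, 1, 0))
    3
    """
    if len(bits) == 0:
        raise InvalidInputError("cannot encode an empty bit tuple")
    value = 1
    n = len(bits)
    for i, b in enumerate(bits):
        if b not in (0, 1):
            raise InvalidInputError(
                f"non-binary element {b!r} at position {i} (expected 0 or 1)"
            )
        value += (1 << (n - 1 - i)) * int(b)
    return value


def decimal_decode(index: int, n: int) -> tuple[int, ...]:
    """Invert :func:`decimal_encode`: recover the length-``n`` bit tuple.

    >>> decimal_decode(3, 3)
    (0, 1, 0)
    """
    if n < 1:
        raise InvalidInputError(f"bit width must be >= 1, got {n}")
    if not (1 <= index <= (1 << n)):
        raise InvalidInputError(
            f"index {index} out of range [1, {1 << n}] for {n} bits"
        )
    offset = index - 1
    return tuple((offset >> (n - 1 - i)) & 1 for i in range(n))


@dataclass(frozen=True)
class TreeTopology:
    """Assignment of ``N`` named binary features to ``M`` named modules.

    The assignment is an ordered partition: module ``m`` owns the ``m``-th
    consecutive block of ``module_sizes[m]`` feature positions.  Features are
    identified by name, so CSV column order can never silently re-wire the
    network — loaders reorder columns to topology order.
    """

    module_names: tuple[str, ...]
    module_sizes: tuple[int, ...]
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.module_names) != len(self.module_sizes):
            raise InvalidInputError("module_names and module_sizes length mismatch")
        if len(self.module_names) == 0:
            raise InvalidInputError("topology needs at least one module")
        if len(set(self.module_names)) != len(self.module_names):
            raise InvalidInputError("module names must be unique")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise InvalidInputError("feature names must be unique")
        for name, size in zip(self.module_names, self.module_sizes):
            if size < 1:
                raise InvalidInputError(f"module {name!r} has size {size} < 1")
            if size > MODULE_SIZE_WARN:
                warnings.warn(
                    f"module {name!r} has {size} inputs; conflict graphs grow "
                    f"as 2^size and sizes above {MODULE_SIZE_WARN} are slow",
                    stacklevel=2,
                )
        if sum(self.module_sizes) != len(self.feature_names):
            raise InvalidInputError(
                f"sum of module sizes {sum(self.module_sizes)} != "
                f"number of features {len(self.feature_names)}"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def n_modules(self) -> int:
        return len(self.module_names)

    @property
    def blocks(self) -> tuple[slice, ...]:
        """Column slice of each module's feature block."""
        out = []
        start = 0
        for size in self.module_sizes:
            out.append(slice(start, start + size))
            start += size
        return tuple(out)

    def module_features(self, m: int) -> tuple[str, ...]:
        """Feature names owned by 1-based module ``m``."""
        self._check_module_index(m)
        return tuple(self.feature_names[self.blocks[m - 1]])

    def _check_module_index(self, m: int) -> None:
        if not (1 <= m <= self.n_modules):
            raise IndexError(f"module index {m} out of range [1, {self.n_modules}]")

    # ---- construction / serialization -------------------------------------

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Sequence[str]]) -> "TreeTopology":
        """Build from an ordered ``{module name: [feature names]}`` mapping."""
        names = tuple(mapping.keys())
        sizes = tuple(len(v) for v in mapping.values())
        feats = tuple(f for v in mapping.values() for f in v)
        return cls(names, sizes, feats)

    @classmethod
    def from_file(cls, path: str | Path) -> "TreeTopology":
        """Load a topology config: JSON or YAML map of module -> feature list."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            mapping = yaml.safe_load(text)
        else:
            mapping = json.loads(text)
        if not isinstance(mapping, dict):
            raise InvalidInputError(f"{path}: topology config must be a mapping")
        for name, feats in mapping.items():
            if not isinstance(feats, (list, tuple)) or not feats:
                raise InvalidInputError(
                    f"{path}: module {name!r} must map to a non-empty feature list"
                )
        return cls.from_mapping(mapping)

    def to_mapping(self) -> dict[str, list[str]]:
        return {
            name: list(self.module_features(m + 1))
            for m, name in enumerate(self.module_names)
        }

    @classmethod
    def from_sizes(
        cls, sizes: Sequence[int], prefix: str = "module"
    ) -> "TreeTopology":
        """Anonymous topology with auto-generated module/feature names."""
        names = tuple(f"{prefix}{m + 1}" for m in range(len(sizes)))
        feats = []
        for m, size in enumerate(sizes):
            feats.extend(f"f{m + 1}_{i + 1}" for i in range(size))
        return cls(names, tuple(sizes), tuple(feats))


@dataclass
class BinaryDataset:
    """An ``S x N`` binary feature matrix with a binary outcome vector."""

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ShapeError(f"X must be 2-D, got ndim={self.X.ndim}")
        if self.X.shape[0] < 1:
            raise InvalidInputError("dataset must contain at least one sample")
        if self.y.shape != (self.X.shape[0],):
            raise ShapeError(
                f"y has shape {self.y.shape}, expected ({self.X.shape[0]},)"
            )
        if self.X.shape[1] != len(self.feature_names):
            raise ShapeError(
                f"{self.X.shape[1]} columns but {len(self.feature_names)} names"
            )
        if not np.isin(self.X, (0, 1)).all():
            bad = np.argwhere(~np.isin(self.X, (0, 1)))[0]
            raise InvalidInputError(
                f"non-binary feature value at row {bad[0]}, "
                f"column {self.feature_names[bad[1]]!r}"
            )
        if not np.isin(self.y, (0, 1)).all():
            bad = int(np.argwhere(~np.isin(self.y, (0, 1)))[0][0])
            raise InvalidInputError(f"non-binary label at row {bad}")
        self.X = self.X.astype(np.int8)
        self.y = self.y.astype(np.int8)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def aligned_to(self, topology: TreeTopology) -> "BinaryDataset":
        """Reorder columns to topology feature order (by name)."""
        if set(self.feature_names) != set(topology.feature_names):
            missing = set(topology.feature_names) - set(self.feature_names)
            extra = set(self.feature_names) - set(topology.feature_names)
            raise ShapeError(
                f"feature names do not match topology "
                f"(missing: {sorted(missing)}, unexpected: {sorted(extra)})"
            )
        if self.feature_names == topology.feature_names:
            return self
        order = [self.feature_names.index(f) for f in topology.feature_names]
        return BinaryDataset(self.X[:, order], self.y, topology.feature_names)

    @classmethod
    def from_csv(
        cls, path: str | Path, label_col: str = "label"
    ) -> "BinaryDataset":
        """Read a delimited dataset: header row, literal 0/1 cells only.

        Cells are never truthy-coerced; anything other than a literal 0 or 1
        is rejected with the offending row and column named.
        """
        frame = pd.read_csv(path, dtype=str)
        if label_col not in frame.columns:
            raise InvalidInputError(
                f"{path}: label column {label_col!r} not found "
                f"(columns: {list(frame.columns)})"
            )
        features = [c for c in frame.columns if c != label_col]
        values = frame[features + [label_col]].to_numpy()
        bad = ~np.isin(values, ("0", "1"))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            col = (features + [label_col])[c]
            raise InvalidInputError(
                f"{path}: non-binary cell {values[r, c]!r} at data row {r}, "
                f"column {col!r} (cells must be literal 0 or 1)"
            )
        X = frame[features].to_numpy(dtype=np.int8)
        y = frame[label_col].to_numpy(dtype=np.int8)
        return cls(X, y, tuple(features))

    def to_csv(self, path: str | Path, label_col: str = "label") -> None:
        frame = pd.DataFrame(self.X, columns=list(self.feature_names))
        frame[label_col] = self.y
        frame.to_csv(path, index=False)


def encode_sample(x: Sequence[int], topology: TreeTopology) -> tuple[int, ...]:
    """Decimal profile of one sample: the per-module 1-based block encodings.

    >>> topo = TreeTopology.from_sizes([3, 2, 2])
    >>> encode_sample((0, 1, 0, 1, 0, 0, 1), topo)
    (3, 3, 2)
    """
    x = np.asarray(x)
    if x.shape != (topology.n_features,):
        raise ShapeError(
            f"sample has shape {x.shape}, topology expects ({topology.n_features},)"
        )
    return tuple(
        decimal_encode(tuple(int(b) for b in x[block]))
        for block in topology.blocks
    )


def encode_samples(X: np.ndarray, topology: TreeTopology) -> np.ndarray:
    """Vectorized :func:`encode_sample` over the rows of ``X`` (S x M output)."""
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != topology.n_features:
        raise ShapeError(
            f"X has shape {X.shape}, topology expects (*, {topology.n_features})"
        )
    if not np.isin(X, (0, 1)).all():
        raise InvalidInputError("X contains non-binary entries")
    cols = []
    for block, size in zip(topology.blocks, topology.module_sizes):
        weights = 1 << np.arange(size - 1, -1, -1)
        cols.append(1 + X[:, block].astype(np.int64) @ weights)
    return np.stack(cols, axis=1)


def decode_profile(
    profile: Sequence[int], topology: TreeTopology
) -> tuple[int, ...]:
    """Inverse of :func:`encode_sample`: rebuild the flat binary vector."""
    if len(profile) != topology.n_modules:
        raise ShapeError(
            f"profile has {len(profile)} entries, topology has "
            f"{topology.n_modules} modules"
        )
    bits: list[int] = []
    for value, size in zip(profile, topology.module_sizes):
        bits.extend(decimal_decode(int(value), size))
    return tuple(bits)
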