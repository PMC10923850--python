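"""Conflict graphs: the graph-theoretic core of module identification.

For first-layer module ``m``, the conflict graph has one vertex per decimal
input configuration ``{1, ..., 2^{n_m}}``.  The weight between vertices ``a``
and ``b`` counts training-sample pairs that agree on every *other* module's
inputs (the context) but carry different labels while reaching ``a`` and ``b``
on module ``m`` — such a pair forces the module's outputs at ``a`` and ``b``
to differ, and the max-cut of the graph recovers the output bipartition that
honours as many of these constraints as possible.

Two constructions are provided: the production tensor-based build (sums of
``T0[a,c]*T1[b,c] + T0[b,c]*T1[a,c]`` over contexts ``c``) and an independent
O(S^2) pairwise enumeration used to cross-validate it.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .labeling import LabelTensors
from .topology import BinaryDataset, TreeTopology, encode_samples


@dataclass
class ConflictGraph:
    """Symmetric nonnegative-integer weight matrix over a module's 2^{n_m}
    input configurations (vertex ``k`` is matrix index ``k-1``)."""

    module_index: int  # 1-based
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.int64)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n):
            raise ValueError("weight matrix must be square")
        if (self.weights < 0).any():
            raise ValueError("conflict weights are pair counts; must be >= 0")
        if not np.array_equal(self.weights, self.weights.T):
            raise ValueError("conflict weight matrix must be symmetric")
        if np.diagonal(self.weights).any():
            raise ValueError("conflict graph has no self-loops")

    @property
    def n_vertices(self) -> int:
        return self.weights.shape[0]

    @property
    def total_weight(self) -> int:
        """Number of conflicting sample pairs (each counted once)."""
        return int(self.weights.sum() // 2)

    def to_edge_list(self, path: str | Path) -> None:
        """Write nonzero edges as ``vertex_a\tvertex_b\tweight`` lines."""
        lines = []
        for a in range(self.n_vertices):
            for b in range(a + 1, self.n_vertices):
                w = int(self.weights[a, b])
                if w:
                    lines.append(f"{a + 1}\t{b + 1}\t{w}")
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def build_conflict_graph(
    tensors: LabelTensors, topology: TreeTopology, m: int
) -> ConflictGraph:
    """Tensor-based conflict-graph construction for 1-based module ``m``.

    For each context (the joint profile of all other modules) the label
    counts are grouped by module-m configuration; each unordered pair (a, b)
    contributes ``T0[a,c]*T1[b,c] + T0[b,c]*T1[a,c]`` conflicting pairs.
    Only contexts with nonzero counts are visited, so cost scales with the
    number of occupied profiles rather than 2^N.
    """
    topology._check_module_index(m)
    n_vertices = 1 << topology.module_sizes[m - 1]
    W = np.zeros((n_vertices, n_vertices), dtype=np.int64)

    # context -> {module-m vertex: [count0, count1]}
    by_context: dict[tuple, dict[int, list[int]]] = defaultdict(dict)
    for source, slot in ((tensors.t0, 0), (tensors.t1, 1)):
        for profile, count in source.items():
            context = profile[: m - 1] + profile[m:]
            cell = by_context[context].setdefault(profile[m - 1], [0, 0])
            cell[slot] += count

    for cells in by_context.values():
        vertices = sorted(cells)
        for i, a in enumerate(vertices):
            c0a, c1a = cells[a]
            for b in vertices[i + 1 :]:
                c0b, c1b = cells[b]
                w = c0a * c1b + c0b * c1a
                if w:
                    W[a - 1, b - 1] += w
                    W[b - 1, a - 1] += w
    return ConflictGraph(m, W)


def pairwise_conflict_oracle(
    dataset: BinaryDataset, topology: TreeTopology, m: int
) -> np.ndarray:
    """Independent O(S^2) construction of module ``m``'s weight matrix.

    Enumerates all S(S-1)/2 sample pairs; a pair contributes one unit of
    weight at (P[m], Q[m]) precisely when the two samples' decimal profiles
    differ in *exactly* module ``m`` and their labels differ.  Used as the
    cross-check oracle for :func:`build_conflict_graph`.
    """
    topology._check_module_index(m)
    dataset = dataset.aligned_to(topology)
    profiles = encode_samples(dataset.X, topology)
    y = dataset.y.astype(np.int64)
    n_vertices = 1 << topology.module_sizes[m - 1]
    W = np.zeros((n_vertices, n_vertices), dtype=np.int64)

    p_idx, q_idx = np.triu_indices(dataset.n_samples, k=1)
    diff = profiles[p_idx] != profiles[q_idx]  # pairs x M
    eligible = (diff.sum(axis=1) == 1) & (y[p_idx] != y[q_idx]) & diff[:, m - 1]
    a = profiles[p_idx[eligible], m - 1] - 1
    b = profiles[q_idx[eligible], m - 1] - 1
    np.add.at(W, (a, b), 1)
    np.add.at(W, (b, a), 1)
    return W
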