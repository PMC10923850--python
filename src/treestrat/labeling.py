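"""The label function: condensing a training set into per-configuration
label-count tensors.

For a topology with ``M`` modules, the tensors ``T0`` and ``T1`` are rank-``M``
count arrays indexed by decimal profiles; ``T0[c]`` / ``T1[c]`` hold the number
of label-0 / label-1 samples whose profile is ``c``.  Storage is sparse (a map
from profile tuple to count): the dense tensor has ``2^N`` cells but clinical
data occupy few of them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ShapeError
from .topology import BinaryDataset, TreeTopology, encode_samples


@dataclass
class LabelTensors:
    """Sparse rank-M count tensors T0 (label 0) and T1 (label 1)."""

    topology: TreeTopology
    t0: dict[tuple[int, ...], int]
    t1: dict[tuple[int, ...], int]
    n_samples: int

    def to_dense(self) -> tuple[np.ndarray, np.ndarray]:
        """Dense arrays of shape ``(2^{n_1}, ..., 2^{n_M})`` (tests/debug only)."""
        shape = tuple(1 << s for s in self.topology.module_sizes)
        dense0 = np.zeros(shape, dtype=np.int64)
        dense1 = np.zeros(shape, dtype=np.int64)
        for profile, count in self.t0.items():
            dense0[tuple(v - 1 for v in profile)] = count
        for profile, count in self.t1.items():
            dense1[tuple(v - 1 for v in profile)] = count
        return dense0, dense1

    def nonzero_frame(self) -> pd.DataFrame:
        """All profiles with a nonzero count, as a tidy debug table."""
        profiles = sorted(set(self.t0) | set(self.t1))
        rows = [
            {
                **{
                    name: profile[m]
                    for m, name in enumerate(self.topology.module_names)
                },
                "count0": self.t0.get(profile, 0),
                "count1": self.t1.get(profile, 0),
            }
            for profile in profiles
        ]
        return pd.DataFrame(rows)


def build_label_tensors(
    dataset: BinaryDataset, topology: TreeTopology
) -> LabelTensors:
    """Count, per decimal profile, the label-0 and label-1 training samples.

    Every sample is counted exactly once, so the entries of T0 plus those of
    T1 always sum to the number of samples.
    """
    dataset = dataset.aligned_to(topology)
    profiles = encode_samples(dataset.X, topology)
    t0: Counter = Counter()
    t1: Counter = Counter()
    for profile, label in zip(map(tuple, profiles.tolist()), dataset.y):
        if label == 0:
            t0[profile] += 1
        else:
            t1[profile] += 1
    return LabelTensors(topology, dict(t0), dict(t1), dataset.n_samples)
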