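"""Planted-model generator for testing every learning stage without
restricted hospital data.

A :class:`PlantedTruth` is a generator-side ground truth shaped like a
fitted model: a topology, one Boolean lookup per first-layer module, and an
output lookup over the 2^M module-output configurations.  Datasets are drawn
with configurable per-feature prevalences (emulating ICD-code case mix),
labels computed through the planted network and optionally flipped with a
noise rate, and multiple "hospital" cohorts can be generated with shifted
prevalences to mimic an external-validation design.

Planted functions are rejection-sampled to be *relevant*: for every module
there is a context in which flipping the module's output flips the network
output.  Without relevance a module's conflict graph is empty and its
function unidentifiable, which would make recovery tests vacuous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .exceptions import InvalidInputError
from .topology import BinaryDataset, TreeTopology, encode_samples


@dataclass
class PlantedTruth:
    """Ground-truth tree-structured network plus its input distribution."""

    topology: TreeTopology
    module_lookups: list[np.ndarray]  # one (2^{n_m},) binary array per module
    output_lookup: np.ndarray  # (2^M,) binary array
    prevalences: np.ndarray  # per-feature Bernoulli probability
    noise_rate: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.module_lookups = [
            np.asarray(lk, dtype=np.int8) for lk in self.module_lookups
        ]
        self.output_lookup = np.asarray(self.output_lookup, dtype=np.int8)
        self.prevalences = np.asarray(self.prevalences, dtype=np.float64)
        if not (0.0 <= self.noise_rate < 0.5):
            raise InvalidInputError(
                f"noise rate must be in [0, 0.5), got {self.noise_rate}"
            )
        if self.prevalences.shape != (self.topology.n_features,):
            raise InvalidInputError("one prevalence per feature required")
        if ((self.prevalences <= 0) | (self.prevalences >= 1)).any():
            raise InvalidInputError("prevalences must lie strictly in (0, 1)")

    # ---- forward pass -----------------------------------------------------

    def labels(self, X: np.ndarray) -> np.ndarray:
        """Noise-free planted labels for the rows of ``X``."""
        profiles = encode_samples(np.atleast_2d(X), self.topology)
        f = np.stack(
            [
                self.module_lookups[m][profiles[:, m] - 1]
                for m in range(self.topology.n_modules)
            ],
            axis=1,
        ).astype(np.int64)
        M = self.topology.n_modules
        weights = 1 << np.arange(M - 1, -1, -1)
        return self.output_lookup[f @ weights]

    def module_is_relevant(self, m: int) -> bool:
        """True iff some context exists where flipping f_m flips the output
        (requires the module lookup to be non-constant as well)."""
        lookup = self.module_lookups[m - 1]
        if lookup.min() == lookup.max():
            return False
        M = self.topology.n_modules
        out = self.output_lookup
        bit = 1 << (M - m)  # module m drives this bit of the 0-based config
        idx = np.arange(1 << M)
        return bool((out[idx] != out[idx ^ bit]).any())

    # ---- serialization (CLI `simulate` truth dump) ------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "topology": self.topology.to_mapping(),
            "module_lookups": [lk.tolist() for lk in self.module_lookups],
            "output_lookup": self.output_lookup.tolist(),
            "prevalences": self.prevalences.tolist(),
            "noise_rate": self.noise_rate,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            topology=TreeTopology.from_mapping(payload["topology"]),
            module_lookups=[np.asarray(lk) for lk in payload["module_lookups"]],
            output_lookup=np.asarray(payload["output_lookup"]),
            prevalences=np.asarray(payload["prevalences"]),
            noise_rate=float(payload["noise_rate"]),
            seed=payload["seed"],
        )


def random_planted_truth(
    topology: Union[TreeTopology, Sequence[int]],
    seed: Optional[int] = None,
    prevalences: Union[float, Sequence[float], None] = None,
    noise_rate: float = 0.0,
    max_tries: int = 10_000,
) -> PlantedTruth:
    """Draw a planted truth whose modules are all relevant.

    Module lookups and the output lookup are sampled uniformly and
    rejection-sampled until every module passes the relevance check.
    """
    if not isinstance(topology, TreeTopology):
        topology = TreeTopology.from_sizes(topology)
    rng = np.random.default_rng(seed)
    if prevalences is None:
        prevalences = 0.5
    prevalences = np.broadcast_to(
        np.asarray(prevalences, dtype=np.float64), (topology.n_features,)
    ).copy()

    for _ in range(max_tries):
        module_lookups = [
            rng.integers(0, 2, size=1 << size, dtype=np.int8)
            for size in topology.module_sizes
        ]
        output_lookup = rng.integers(
            0, 2, size=1 << topology.n_modules, dtype=np.int8
        )
        truth = PlantedTruth(
            topology, module_lookups, output_lookup,
            prevalences, noise_rate, seed,
        )
        if all(
            truth.module_is_relevant(m)
            for m in range(1, topology.n_modules + 1)
        ):
            return truth
    raise RuntimeError(
        f"no relevant planted truth found in {max_tries} draws"
    )  # pragma: no cover - probability vanishes for any sane topology


def make_simple_case(seed: Optional[int] = None) -> PlantedTruth:
    """The 7-input, 3-module reference network (module sizes [3, 2, 2])."""
    return random_planted_truth([3, 2, 2], seed=seed)


def all_inputs(topology: TreeTopology) -> np.ndarray:
    """All 2^N binary input rows in lexicographic order."""
    n = topology.n_features
    idx = np.arange(1 << n, dtype=np.int64)
    shifts = np.arange(n - 1, -1, -1)
    return ((idx[:, None] >> shifts[None, :]) & 1).astype(np.int8)


def sample_dataset(
    truth: PlantedTruth,
    s: Optional[int] = None,
    mode: str = "iid",
    seed: Optional[int] = None,
    replicate: int = 1,
) -> BinaryDataset:
    """Draw a labelled dataset from a planted truth.

    ``mode="exhaustive"`` emits every binary input ``replicate`` times
    (``s`` is ignored); ``mode="iid"`` draws ``s`` rows with the truth's
    per-feature Bernoulli prevalences.  Labels are the planted outputs, each
    flipped independently with probability ``truth.noise_rate``.  When
    ``seed`` is omitted it is derived from the truth's own seed, so the same
    truth always yields the same dataset.
    """
    if mode not in ("iid", "exhaustive"):
        raise InvalidInputError(f"unknown sampling mode {mode!r}")
    if seed is None:
        seed = None if truth.seed is None else (truth.seed * 2654435761) % 2**31
    rng = np.random.default_rng(seed)
    if mode == "exhaustive":
        X = np.tile(all_inputs(truth.topology), (replicate, 1))
    else:
        if s is None or s < 1:
            raise InvalidInputError("iid sampling needs a sample count s >= 1")
        X = (
            rng.random((s, truth.topology.n_features)) < truth.prevalences
        ).astype(np.int8)
    y = truth.labels(X).copy()
    if truth.noise_rate > 0:
        flips = rng.random(len(y)) < truth.noise_rate
        y = y ^ flips.astype(np.int8)
    return BinaryDataset(X, y, truth.topology.feature_names)


@dataclass
class CohortCollection:
    """Multiple cohorts from one planted truth, with shifted case mixes."""

    datasets: list[BinaryDataset]
    prevalences: list[np.ndarray]
    relatedness_to_base: list[tuple[float, tuple[float, float]]] = field(
        default_factory=list
    )


def make_shifted_cohorts(
    truth: PlantedTruth,
    n_cohorts: int,
    prevalence_shifts: Union[float, Sequence[float]],
    sizes: Union[int, Sequence[int]],
    seed: Optional[int] = None,
    compute_relatedness: bool = True,
) -> CohortCollection:
    """Emulate a multi-hospital design: cohorts share the planted truth but
    differ in feature prevalences.

    ``prevalence_shifts`` gives the additive shift of cohort ``i`` relative
    to the truth's base prevalences (scalar = same shift for all cohorts
    after the first; the first cohort is always unshifted, playing the role
    of the derivation hospital).  Each cohort is paired with the mean and
    95% CI of its cross-cohort Jaccard similarity to the first cohort.
    """
    if n_cohorts < 1:
        raise InvalidInputError("need at least one cohort")
    shifts = np.broadcast_to(
        np.asarray(prevalence_shifts, dtype=np.float64), (n_cohorts,)
    ).copy()
    shifts[0] = 0.0
    sizes_arr = np.broadcast_to(np.asarray(sizes, dtype=int), (n_cohorts,))
    seed_seq = np.random.SeedSequence(seed)
    cohort_seeds = [int(x) % (2**31) for x in seed_seq.generate_state(n_cohorts)]

    datasets: list[BinaryDataset] = []
    prevalences: list[np.ndarray] = []
    for i in range(n_cohorts):
        prev = truth.prevalences + shifts[i]
        if ((prev <= 0) | (prev >= 1)).any():
            raise InvalidInputError(
                f"cohort {i}: shifted prevalence outside (0, 1)"
            )
        shifted = PlantedTruth(
            truth.topology,
            truth.module_lookups,
            truth.output_lookup,
            prev,
            truth.noise_rate,
            truth.seed,
        )
        datasets.append(
            sample_dataset(
                shifted, s=int(sizes_arr[i]), mode="iid", seed=cohort_seeds[i]
            )
        )
        prevalences.append(prev)

    relatedness: list[tuple[float, tuple[float, float]]] = []
    if compute_relatedness:
        from .interpret import cohort_relatedness

        relatedness = [
            cohort_relatedness(datasets[0].X, d.X) for d in datasets
        ]
    return CohortCollection(datasets, prevalences, relatedness)
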