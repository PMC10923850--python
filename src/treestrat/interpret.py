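"""Module-level attribution and cross-cohort interpretation analyses.

Because the hybrid model aggregates only ``M`` first-layer module outputs,
the Shapley "players" are those module outputs rather than raw features; the
coalition space is ``2^M`` and is enumerated *exactly*, removing the sampling
variance of kernel-based approximations.  A coalition's value is the model's
risk output with in-coalition module outputs fixed to the explained sample's
and out-of-coalition outputs averaged over a background set of module-output
profiles (the training distribution by default, recorded in the fitted
model's counters).

Also provided: the subset-wise interpretation-consistency test (rank-based
omnibus across modules with step-down pairwise comparisons) and the Jaccard
case-mix relatedness between cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb, factorial
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import CapacityError, InvalidInputError, ShapeError
from .model import HybridModel

SHAPLEY_MODULE_CAP = 15


@dataclass
class ShapleyReport:
    """Per-sample, per-module exact Shapley attributions of the risk output."""

    values: np.ndarray  # n_samples x M
    base_value: float  # mean risk over the background set
    module_names: tuple[str, ...]
    background_size: float  # total background weight

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.module_names))

    def mean_abs(self) -> np.ndarray:
        """Per-module mean absolute attribution over all samples."""
        return np.abs(self.values).mean(axis=0)


def _background_profiles(
    model: HybridModel, background: Optional[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Module-output profiles (P x M) and weights of the background set.

    Default background is the training distribution of module-output
    configurations, recovered from the fitted output-module counters.
    """
    M = model.topology.n_modules
    if background is None:
        counts = model.output.counter0 + model.output.counter1
        configs = np.flatnonzero(counts > 0)
        if len(configs) == 0:
            raise InvalidInputError("model has no training counts to use as background")
        shifts = np.arange(M - 1, -1, -1)
        profiles = (configs[:, None] >> shifts[None, :]) & 1
        return profiles.astype(np.int8), counts[configs].astype(np.float64)
    background = np.atleast_2d(np.asarray(background))
    if background.shape[1] != model.topology.n_features:
        raise ShapeError(
            f"background has {background.shape[1]} columns, topology expects "
            f"{model.topology.n_features}"
        )
    profiles = model.module_outputs(background)
    return profiles.astype(np.int8), np.ones(len(profiles), dtype=np.float64)


def exact_shapley_modules(
    model: HybridModel,
    samples: np.ndarray,
    background: Optional[np.ndarray] = None,
) -> ShapleyReport:
    """Exact Shapley attribution of each sample's risk to the M modules.

    All ``2^M`` coalitions are enumerated with the standard Shapley weights
    ``|C|! (M-|C|-1)! / M!``; with M <= ~10 this is both exact and fast.
    """
    M = model.topology.n_modules
    if M > SHAPLEY_MODULE_CAP:
        raise CapacityError(
            f"{M} modules exceeds the exact-enumeration cap of "
            f"{SHAPLEY_MODULE_CAP}"
        )
    samples = np.atleast_2d(np.asarray(samples))
    bg_profiles, bg_weights = _background_profiles(model, background)
    total_weight = float(bg_weights.sum())

    risk_eff = np.where(
        model.output.unseen, model.output.default_risk, model.output.risk
    )
    out_weights = 1 << np.arange(M - 1, -1, -1)
    sample_profiles = model.module_outputs(samples)

    # Shapley weight for a coalition of size c not containing the player
    w_size = np.array(
        [factorial(c) * factorial(M - 1 - c) / factorial(M) for c in range(M)]
    )

    masks = [np.array(mask) for mask in np.ndindex(*([2] * M))]

    values = np.zeros((len(samples), M))
    base_value = float(
        bg_weights @ risk_eff[(bg_profiles.astype(np.int64) @ out_weights)]
        / total_weight
    )
    for s, f_s in enumerate(sample_profiles):
        v = np.empty(1 << M)
        for mask_bits in masks:
            mask_id = int(mask_bits @ out_weights)
            mixed = np.where(mask_bits[None, :] == 1, f_s[None, :], bg_profiles)
            idx = mixed.astype(np.int64) @ out_weights
            v[mask_id] = float(bg_weights @ risk_eff[idx] / total_weight)
        for m in range(M):
            bit = int(out_weights[m])
            phi = 0.0
            for mask_id in range(1 << M):
                if mask_id & bit:
                    continue
                size = bin(mask_id).count("1")
                phi += w_size[size] * (v[mask_id | bit] - v[mask_id])
            values[s, m] = phi
    return ShapleyReport(
        values, base_value, model.topology.module_names, total_weight
    )


def mean_abs_shap_by_subset(
    report_values: Union[ShapleyReport, np.ndarray],
    subsets: Sequence[Sequence[int]],
) -> np.ndarray:
    """Per-subset, per-module mean absolute attribution (k x M).

    ``subsets`` is a list of row-index collections partitioning (or
    sampling) the report's samples; each must be non-empty.
    """
    values = (
        report_values.values
        if isinstance(report_values, ShapleyReport)
        else np.asarray(report_values)
    )
    out = []
    for i, idx in enumerate(subsets):
        idx = np.asarray(idx, dtype=int)
        if idx.size == 0:
            raise InvalidInputError(f"subset {i} is empty")
        out.append(np.abs(values[idx]).mean(axis=0))
    return np.asarray(out)


@dataclass
class ConsistencyResult:
    """Outcome of the rank-based interpretation-consistency test."""

    omnibus_statistic: float
    omnibus_pvalue: float
    average_ranks: pd.Series  # rank 1 = most important, averaged over subsets
    pairwise: pd.DataFrame  # z, adjusted p, reject per module pair
    alpha: float


def consistency_test(
    subset_means: np.ndarray,
    alpha: float = 0.1,
    module_names: Optional[Sequence[str]] = None,
) -> ConsistencyResult:
    """Test whether per-module mean |attribution| distributions differ.

    ``subset_means`` is the k x M matrix of per-subset, per-module mean
    absolute attributions.  Within each subset the modules are ranked
    (rank 1 = largest); the omnibus comparison across modules uses the
    Friedman statistic, and each module pair gets a z statistic
    ``|R_i - R_j| / sqrt(M(M+1)/(6k))`` on the average ranks with Holm
    step-down adjustment of the two-sided normal p-values.
    """
    data = np.asarray(subset_means, dtype=np.float64)
    if data.ndim != 2:
        raise InvalidInputError("subset_means must be a k x M matrix")
    k, M = data.shape
    if k < 2:
        raise InvalidInputError("need at least 2 subsets")
    if M < 2:
        raise InvalidInputError("need at least 2 modules")
    if not (0 < alpha < 1):
        raise InvalidInputError(f"alpha must lie in (0, 1), got {alpha}")
    names = tuple(module_names) if module_names else tuple(
        f"module{m + 1}" for m in range(M)
    )
    if len(names) != M:
        raise InvalidInputError("one name per module required")

    # rank 1 = most important within each subset (midranks on ties)
    ranks = np.apply_along_axis(stats.rankdata, 1, -data)
    avg_ranks = ranks.mean(axis=0)

    stat, pvalue = stats.friedmanchisquare(*[data[:, m] for m in range(M)])

    se = np.sqrt(M * (M + 1) / (6.0 * k))
    pairs = list(combinations(range(M), 2))
    z = np.array([abs(avg_ranks[i] - avg_ranks[j]) / se for i, j in pairs])
    p_raw = 2.0 * stats.norm.sf(z)
    reject, p_adj, _, _ = multipletests(p_raw, alpha=alpha, method="holm")

    table = pd.DataFrame(
        {
            "module_a": [names[i] for i, _ in pairs],
            "module_b": [names[j] for _, j in pairs],
            "z": z,
            "p_adjusted": p_adj,
            "reject": reject,
        }
    ).sort_values("z", ascending=False, ignore_index=True)
    return ConsistencyResult(
        float(stat),
        float(pvalue),
        pd.Series(avg_ranks, index=list(names)).sort_values(),
        table,
        alpha,
    )


def jaccard_similarity(a: Sequence[int], b: Sequence[int]) -> float:
    """Jaccard similarity of two binary vectors' 1-supports.

    Two all-zero vectors are identical samples and score 1.0 (warned, since
    the ratio is formally 0/0).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ShapeError(f"shape mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        warnings.warn(
            "both vectors all-zero; Jaccard defined as 1.0 (identical)",
            stacklevel=2,
        )
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def cohort_relatedness(
    cohort_a, cohort_b
) -> tuple[float, tuple[float, float]]:
    """Mean and normal-approximation 95% CI of the pairwise Jaccard
    similarity between all sample pairs of two cohorts.

    Accepts binary matrices or objects exposing ``.X`` (datasets).
    """
    A = np.atleast_2d(np.asarray(getattr(cohort_a, "X", cohort_a), dtype=np.float64))
    B = np.atleast_2d(np.asarray(getattr(cohort_b, "X", cohort_b), dtype=np.float64))
    if A.size == 0 or B.size == 0:
        raise InvalidInputError("cohorts must be non-empty")
    if A.shape[1] != B.shape[1]:
        raise ShapeError(
            f"cohorts have incompatible widths {A.shape[1]} vs {B.shape[1]}"
        )
    inter = A @ B.T
    union = A.sum(axis=1)[:, None] + B.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = np.where(union > 0, inter / np.where(union > 0, union, 1), 1.0)
    flat = sims.ravel()
    mean = float(flat.mean())
    half = 1.96 * float(flat.std(ddof=1)) / np.sqrt(flat.size) if flat.size > 1 else 0.0
    return mean, (mean - half, mean + half)
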