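"""Per-probe two-cluster discretization of methylation values.

Each probe's values are split into a low and a high cluster by the exact
one-dimensional 2-means solution: among the n-1 splits of the sorted values,
the one minimizing total within-cluster sum of squares is the global optimum
(1-D k-means clusters are contiguous in sorted order). Samples in the
higher-mean cluster are coded 1, the rest 0; the decision threshold is the
midpoint between the largest low-cluster value and the smallest high-cluster
value. On a validation cohort the splits are recomputed from that cohort's
own values rather than carried over, which absorbs cross-platform and
cross-batch location shifts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import MethylationMatrix
from .exceptions import DegenerateProbeError, ValidationError

__all__ = [
    "ProbeSplit",
    "BinaryFeatureMatrix",
    "two_means_split",
    "binarize_matrix",
    "rebinarize_panel",
]


@dataclass(frozen=True)
class ProbeSplit:
    """Two-cluster split of one probe."""

    probe_id: str
    threshold: float
    low_mean: float
    high_mean: float


@dataclass
class BinaryFeatureMatrix:
    """Sample × probe 0/1 features with their per-probe split metadata."""

    values: pd.DataFrame  # samples x probes, int 0/1
    splits: dict[str, ProbeSplit]
    dropped_probes: list[str]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.columns)


def two_means_split(values: Sequence[float], probe_id: str = "") -> tuple[ProbeSplit, np.ndarray]:
    """Exact 1-D 2-means: optimal split of sorted values by within-cluster SS.

    Ties in within-cluster sum of squares are broken toward the larger low
    cluster. Returns the split and the 0/1 labels in input order.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValidationError("two_means_split needs a 1-D array of >= 2 values")
    if np.all(x == x[0]):
        raise DegenerateProbeError(
            f"probe {probe_id or '<unnamed>'} has identical values; no 2-cluster split"
        )
    order = np.argsort(x, kind="stable")
    s = x[order]
    n = len(s)
    csum = np.cumsum(s)
    csq = np.cumsum(s * s)
    k = np.arange(1, n)  # size of the low cluster
    low_ss = csq[k - 1] - csum[k - 1] ** 2 / k
    high_sum = csum[-1] - csum[k - 1]
    high_sq = csq[-1] - csq[k - 1]
    high_ss = high_sq - high_sum**2 / (n - k)
    wcss = low_ss + high_ss
    # argmin over reversed order -> largest k among ties (within float exactness)
    best = len(wcss) - 1 - int(np.argmin(wcss[::-1]))
    k_low = best + 1
    low_mean = float(csum[k_low - 1] / k_low)
    high_mean = float((csum[-1] - csum[k_low - 1]) / (n - k_low))
    threshold = float((s[k_low - 1] + s[k_low]) / 2.0)
    labels = (x > threshold).astype(int)
    split = ProbeSplit(probe_id=probe_id, threshold=threshold, low_mean=low_mean, high_mean=high_mean)
    return split, labels


def binarize_matrix(
    matrix: MethylationMatrix, probes: Sequence[str] | None = None
) -> BinaryFeatureMatrix:
    """Apply the exact two-means split probe-wise.

    Degenerate (constant) probes are excluded and listed in
    ``dropped_probes``; everything else is deterministic.
    """
    if probes is None:
        probes = matrix.probe_ids
    missing = [p for p in probes if p not in matrix.values.index]
    if missing:
        raise ValidationError(f"probes not present in matrix: {missing}")
    columns: dict[str, np.ndarray] = {}
    splits: dict[str, ProbeSplit] = {}
    dropped: list[str] = []
    for probe in probes:
        row = matrix.values.loc[probe].to_numpy()
        try:
            split, labels = two_means_split(row, probe_id=probe)
        except DegenerateProbeError:
            dropped.append(probe)
            continue
        columns[probe] = labels
        splits[probe] = split
    values = pd.DataFrame(columns, index=matrix.sample_ids, dtype=int)
    return BinaryFeatureMatrix(values=values, splits=splits, dropped_probes=dropped)


def rebinarize_panel(
    new_matrix: MethylationMatrix, panel_probes: Sequence[str]
) -> BinaryFeatureMatrix:
    """Recompute 2-means splits for panel probes on a new cohort's own values."""
    missing = [p for p in panel_probes if p not in new_matrix.values.index]
    if missing:
        raise ValidationError(
            f"panel probe(s) missing from the new cohort: {missing}"
        )
    return binarize_matrix(new_matrix, panel_probes)
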