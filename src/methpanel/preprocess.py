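"""Value-space transforms and cross-cohort batch adjustment.

Beta values (methylation proportions) live in [0, 1] and are
variance-unstable near the boundaries; M-values, their logit2 transform
``M = log2(beta / (1 - beta))``, are unbounded and the natural scale for
linear modelling. Batch effects are removed per probe by one-way-ANOVA-style
mean centering: every batch's mean is shifted onto the probe's grand mean,
which leaves the grand mean untouched and zeroes the between-batch sum of
squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import BETA, M, MethylationMatrix, SampleSheet
from .exceptions import ConfigurationError, StateError, ValidationError

DEFAULT_EPSILON = 1e-6


def beta_to_m(matrix: MethylationMatrix, epsilon: float = DEFAULT_EPSILON) -> MethylationMatrix:
    """Logit2-transform a beta-space matrix, clipping into [epsilon, 1 - epsilon]."""
    if not 0.0 < epsilon < 0.5:
        raise ConfigurationError(f"epsilon must be in (0, 0.5), got {epsilon}")
    if matrix.value_space != BETA:
        raise StateError("beta_to_m requires a beta-space matrix")
    clipped = matrix.values.clip(lower=epsilon, upper=1.0 - epsilon)
    m = np.log2(clipped / (1.0 - clipped))
    return MethylationMatrix(m, M)


def m_to_beta(matrix: MethylationMatrix) -> MethylationMatrix:
    """Inverse-logit2 an M-space matrix back to beta proportions."""
    if matrix.value_space != M:
        raise StateError("m_to_beta requires an M-space matrix")
    p = np.exp2(matrix.values)
    beta = p / (1.0 + p)
    return MethylationMatrix(beta, BETA)


@dataclass
class BatchAdjustmentReport:
    """Per-(probe, batch) means before/after adjustment plus grand means."""

    batch_means_before: pd.DataFrame  # probes x batches
    batch_means_after: pd.DataFrame
    grand_means: pd.Series


def batch_adjust(
    matrix: MethylationMatrix, sheet: SampleSheet
) -> tuple[MethylationMatrix, BatchAdjustmentReport]:
    """Mean-center every probe within batch, restoring the probe grand mean.

    For probe *g*, sample *i* in batch *b*:
    ``x'_gi = x_gi - mean_g(b) + grand_mean_g``.
    Idempotent, and exact on the grand mean.
    """
    batches = pd.Series(
        sheet.batches_for(matrix.sample_ids), index=matrix.values.columns
    )
    counts = batches.value_counts()
    if (counts < 1).any():
        raise ValidationError("every batch must contain at least one sample")

    values = matrix.values
    grand = values.mean(axis=1)
    before = values.T.groupby(batches).mean().T  # probes x batches
    centered = values.copy()
    for batch, cols in batches.groupby(batches).groups.items():
        cols = list(cols)
        centered[cols] = values[cols].sub(before[batch], axis=0).add(grand, axis=0)
    after = centered.T.groupby(batches).mean().T
    report = BatchAdjustmentReport(before, after, grand)
    return MethylationMatrix(centered, matrix.value_space), report
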