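"""Probe-wise differential methylation with empirical-Bayes moderated t-statistics.

For each probe *g* a two-group linear model on M-values gives the effect
``logFC_g`` (mean tumor minus mean normal), the pooled residual variance
``s2_g`` on ``d_g = n_tumor + n_normal - 2`` degrees of freedom, and the
design constant ``v_g = 1/n_tumor + 1/n_normal``. Residual variances are then
shrunk toward a prior: the scaled-inverse-chi-square hyperparameters
``(d0, s0^2)`` are estimated by the method of moments on ``log s2_g`` and the
posterior variance is the precision-weighted blend

    s2_tilde_g = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g).

The moderated statistic ``t_g = logFC_g / sqrt(s2_tilde_g * v_g)`` is referred
to a t distribution on ``d0 + d_g`` degrees of freedom, p-values are adjusted
by Benjamini-Hochberg, and probes passing ``|logFC| > 1`` and adjusted
``p < 0.05`` are called differentially methylated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .data_io import M, MethylationMatrix, SampleSheet
from .exceptions import DesignError, EstimationError, StateError, ValidationError

__all__ = [
    "ProbeFits",
    "ModerationEstimate",
    "fit_probe_models",
    "estimate_moderation",
    "moderated_tests",
    "bh_adjust",
    "call_dmps",
    "summarize_dmps",
    "DifferentialMethylation",
    "DifferentialMethylationResults",
]

_MAX_DF = 1e6  # t with a million df is numerically normal


@dataclass
class ProbeFits:
    """Vectorized per-probe two-group fits."""

    probe_ids: list[str]
    logfc: np.ndarray  # tumor mean - normal mean, M units
    s2: np.ndarray  # pooled residual variance
    df_residual: int  # d_g, shared across probes in a two-group design
    v: float  # 1/n_tumor + 1/n_normal


@dataclass
class ModerationEstimate:
    """Prior degrees of freedom and prior variance for variance shrinkage."""

    d0: float  # may be math.inf
    s0_2: float

    def posterior_variance(self, s2: np.ndarray, df_residual: float) -> np.ndarray:
        if math.isinf(self.d0):
            return np.full_like(np.asarray(s2, dtype=float), self.s0_2)
        return (self.d0 * self.s0_2 + df_residual * np.asarray(s2, dtype=float)) / (
            self.d0 + df_residual
        )


def fit_probe_models(matrix: MethylationMatrix, sheet: SampleSheet) -> ProbeFits:
    """Two-group least squares per probe on an M-space matrix."""
    if matrix.value_space != M:
        raise StateError("differential methylation runs on M-space values")
    groups = sheet.groups_for(matrix.sample_ids)
    tumor = groups == "tumor"
    normal = groups == "normal"
    n_t, n_n = int(tumor.sum()), int(normal.sum())
    if n_t == 0 or n_n == 0:
        raise DesignError("both tumor and normal groups must be non-empty")
    if n_t + n_n < 3:
        raise DesignError("need at least 3 samples in total")

    values = matrix.values.to_numpy()
    mean_t = values[:, tumor].mean(axis=1)
    mean_n = values[:, normal].mean(axis=1)
    ss_t = ((values[:, tumor] - mean_t[:, None]) ** 2).sum(axis=1)
    ss_n = ((values[:, normal] - mean_n[:, None]) ** 2).sum(axis=1)
    df = n_t + n_n - 2
    return ProbeFits(
        probe_ids=matrix.probe_ids,
        logfc=mean_t - mean_n,
        s2=(ss_t + ss_n) / df,
        df_residual=df,
        v=1.0 / n_t + 1.0 / n_n,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (trigamma is strictly decreasing)."""
    if y <= 0:
        return math.inf
    lo, hi = 1e-10, 1e10
    # expand if needed; trigamma(1e-10) ~ 1e20, trigamma(1e10) ~ 1e-10
    from scipy.optimize import brentq

    f = lambda x: float(special.polygamma(1, x)) - y
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-12, maxiter=200))


def estimate_moderation(fits: ProbeFits) -> ModerationEstimate:
    """Method-of-moments fit of (d0, s0^2) on the log residual variances.

    With z_g = log s2_g and d = residual df, e_g = z_g - digamma(d/2) +
    log(d/2) has mean log s0^2 - digamma(d0/2) + log(d0/2) and excess
    variance trigamma(d0/2) beyond the sampling term trigamma(d/2); solving
    the trigamma equation yields d0. A non-positive excess collapses to an
    infinite-prior (all variances equal s0^2) estimate.
    """
    s2 = np.asarray(fits.s2, dtype=float)
    d = float(fits.df_residual)
    if len(s2) < 2:
        raise EstimationError("need at least 2 probes to estimate moderation")
    if np.all(s2 <= 0):
        raise EstimationError(
            "all residual variances are zero; moderation is degenerate "
            "(jitter the input or fall back to ordinary t-statistics)"
        )
    # probes with s2 == 0 have log-variance -inf; exclude them from the moment
    # fit (they still get shrunk by the resulting prior)
    positive = s2 > 0
    z = np.log(s2[positive])
    m = len(z)
    if m < 2:
        raise EstimationError("need at least 2 probes with positive variance")
    e = z - special.digamma(d / 2.0) + math.log(d / 2.0)
    e_bar = float(np.mean(e))
    excess = float(np.mean((e - e_bar) ** 2) * m / (m - 1.0)) - float(
        special.polygamma(1, d / 2.0)
    )
    if excess <= 0:
        return ModerationEstimate(d0=math.inf, s0_2=float(np.exp(e_bar)))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_2 = float(np.exp(e_bar + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)))
    return ModerationEstimate(d0=d0, s0_2=s0_2)


def moderated_tests(
    fits: ProbeFits,
    moderation: ModerationEstimate,
    symbols: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Moderated t-statistics and two-sided p-values (unadjusted).

    Returns a frame with columns ``probe_id, symbol, logFC, t, p, direction``.
    """
    s2_post = moderation.posterior_variance(fits.s2, fits.df_residual)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fits.logfc / np.sqrt(s2_post * fits.v)
    t = np.where(fits.logfc == 0.0, 0.0, t)
    df_total = min(moderation.d0 + fits.df_residual, _MAX_DF)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.minimum(p, 1.0)
    table = pd.DataFrame(
        {
            "probe_id": fits.probe_ids,
            "symbol": [
                (symbols or {}).get(pid, "") for pid in fits.probe_ids
            ],
            "logFC": fits.logfc,
            "t": t,
            "p": p,
        }
    )
    table["direction"] = np.where(table["logFC"] > 0, "hyper", "hypo")
    return table


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.min(p) < 0.0 or np.max(p) > 1.0 or not np.isfinite(p).all()):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def _sort_dmp_table(table: pd.DataFrame) -> pd.DataFrame:
    """adj_p ascending, ties by |logFC| descending then probe id."""
    key = table.assign(_abs=table["logFC"].abs())
    key = key.sort_values(
        by=["adj_p", "_abs", "probe_id"], ascending=[True, False, True], kind="stable"
    )
    return key.drop(columns="_abs").reset_index(drop=True)


def call_dmps(
    table: pd.DataFrame,
    logfc_threshold: float = 1.0,
    adjp_threshold: float = 0.05,
) -> pd.DataFrame:
    """Keep probes with |logFC| above threshold and adjusted p below threshold."""
    if "adj_p" not in table.columns:
        raise ValidationError("call_dmps requires adjusted p-values (column 'adj_p')")
    kept = table[
        (table["logFC"].abs() > logfc_threshold) & (table["adj_p"] < adjp_threshold)
    ].copy()
    kept["direction"] = np.where(kept["logFC"] > 0, "hyper", "hypo")
    return _sort_dmp_table(kept)


def summarize_dmps(table: pd.DataFrame) -> dict:
    """Counts and extreme records of a DMP table."""
    summary: dict = {
        "n_total": int(len(table)),
        "n_hyper": int((table["logFC"] > 0).sum()) if len(table) else 0,
        "n_hypo": int((table["logFC"] <= 0).sum()) if len(table) else 0,
    }
    if len(table):
        imax = table["logFC"].idxmax()
        imin = table["logFC"].idxmin()
        itop = table["adj_p"].idxmin()
        for name, idx in (("max_logfc", imax), ("min_logfc", imin), ("top", itop)):
            row = table.loc[idx]
            summary[name] = {
                "probe_id": row["probe_id"],
                "symbol": row.get("symbol", ""),
                "logFC": float(row["logFC"]),
                "adj_p": float(row["adj_p"]),
            }
    else:
        summary["max_logfc"] = summary["min_logfc"] = summary["top"] = None
    return summary


class DifferentialMethylation:
    """Two-group moderated-t differential methylation model.

    Parameters
    ----------
    matrix
        M-space methylation matrix (use :func:`methpanel.preprocess.beta_to_m`
        first for beta data).
    sheet
        Sample sheet giving each sample's ``tumor``/``normal`` label.
    symbols
        Optional probe-id -> gene-symbol annotation for reporting.
    """

    def __init__(
        self,
        matrix: MethylationMatrix,
        sheet: SampleSheet,
        symbols: dict[str, str] | None = None,
    ):
        self.matrix = matrix
        self.sheet = sheet
        self.symbols = symbols

    def fit(self) -> "DifferentialMethylationResults":
        fits = fit_probe_models(self.matrix, self.sheet)
        moderation = estimate_moderation(fits)
        table = moderated_tests(fits, moderation, self.symbols)
        table["adj_p"] = bh_adjust(table["p"].to_numpy())
        return DifferentialMethylationResults(self, fits, moderation, _sort_dmp_table(table))


class DifferentialMethylationResults:
    """Fitted per-probe statistics plus the moderation hyperparameters."""

    def __init__(
        self,
        model: DifferentialMethylation,
        fits: ProbeFits,
        moderation: ModerationEstimate,
        table: pd.DataFrame,
    ):
        self.model = model
        self.fits = fits
        self.moderation = moderation
        #: full per-probe table sorted by adjusted p
        self.table = table

    def call_dmps(
        self, logfc_threshold: float = 1.0, adjp_threshold: float = 0.05
    ) -> pd.DataFrame:
        return call_dmps(self.table, logfc_threshold, adjp_threshold)

    def summary(self, logfc_threshold: float = 1.0, adjp_threshold: float = 0.05) -> str:
        dmps = self.call_dmps(logfc_threshold, adjp_threshold)
        s = summarize_dmps(dmps)
        lines = [
            "Differential methylation (moderated t, BH-adjusted)",
            "===================================================",
            f"probes tested          {len(self.table)}",
            f"samples                {self.model.matrix.shape[1]}"
            f" (df_residual={self.fits.df_residual})",
            f"prior df (d0)          "
            + ("inf" if math.isinf(self.moderation.d0) else f"{self.moderation.d0:.3f}"),
            f"prior variance (s0^2)  {self.moderation.s0_2:.6f}",
            f"DMPs (|logFC|>{logfc_threshold}, adj p<{adjp_threshold})"
            f"  {s['n_total']} ({s['n_hyper']} hyper / {s['n_hypo']} hypo)",
        ]
        if s["max_logfc"] is not None:
            lines.append(
                f"largest logFC          {s['max_logfc']['logFC']:+.3f}"
                f" at {s['max_logfc']['probe_id']}"
            )
            lines.append(
                f"top probe by adj p     {s['top']['probe_id']}"
                f" (adj p = {s['top']['adj_p']:.3g})"
            )
        return "\n".join(lines)
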