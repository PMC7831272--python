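"""Expression filtering, normalization and negative-binomial differential
testing.

The differential test is a self-contained NB Wald test designed for the
small-replicate two-group design typical of livestock epigenome studies
(here 3 control vs 3 case libraries). Counts are modelled as
NB(mean mu, variance mu + alpha*mu^2). Per-feature dispersion is estimated
by method of moments pooled within groups, floored, and moderated toward
the across-feature median — at n = 3 per group the raw moment estimate is
far too noisy to use directly. The Wald statistic is the log2 fold change
divided by a delta-method standard error, referred to a standard normal,
two-sided. P-values are adjusted by Benjamini–Hochberg step-up.

This is intentionally simpler than DESeq2 (no dispersion trend, no
Cox–Reid adjustment, no LFC shrinkage); the calibration and power
properties in the test suite document how it behaves.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "NBTestParams",
    "filter_low_expression",
    "fpkm",
    "size_factors",
    "bh_adjust",
    "nb_wald_test",
]

LN2 = math.log(2.0)


@dataclass
class CountMatrix:
    """Integer count table (features x samples) with group labels.

    ``groups`` maps each sample id to its group label (e.g. ``control`` /
    ``FLHS``); ``lengths`` optionally gives feature lengths in bp for
    FPKM computation.
    """

    counts: pd.DataFrame
    groups: dict[str, str]
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        labels = pd.Series({s: self.groups[s] for s in self.counts.columns})
        small = labels.value_counts()[labels.value_counts() < 2]
        if len(small):
            raise ValueError(f"groups with fewer than 2 samples: {list(small.index)}")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.counts.index)
            if (self.lengths <= 0).any():
                raise ValueError("feature lengths must be positive")

    def group_columns(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s in self.counts.columns:
            out.setdefault(self.groups[s], []).append(s)
        return out


@dataclass
class NBTestParams:
    """Tuning knobs of the NB Wald test.

    pseudocount: added to both group means inside the log2 ratio so that
        zero means stay finite (counts-scale units).
    dispersion_floor: lower clamp on the moment estimate of alpha.
    moderation_weight: weight pulled toward the across-feature median
        dispersion; 0 keeps the raw per-feature estimate.
    padj_threshold / lfc_threshold: significance rule for direction calls.
    use_adjusted_p: direction calls use BH-adjusted p (RNA rule) when
        True, raw p when False (the differential-peak rule).
    """

    pseudocount: float = 0.5
    dispersion_floor: float = 1e-8
    moderation_weight: float = 0.5
    padj_threshold: float = 0.05
    lfc_threshold: float = 1.0
    use_adjusted_p: bool = True

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if not 0 <= self.moderation_weight <= 1:
            raise ValueError("moderation_weight must be in [0, 1]")


def filter_low_expression(
    cm: CountMatrix, min_count: int = 2, sample_frac: float = 0.9
) -> CountMatrix:
    """Drop features that are below ``min_count`` in at least
    ``sample_frac`` of samples. Feature order is preserved; an empty
    matrix passes through unchanged."""
    if cm.counts.shape[1] == 0 or cm.counts.shape[0] == 0:
        return cm
    frac_low = (cm.counts < min_count).sum(axis=1) / cm.counts.shape[1]
    keep = frac_low < sample_frac
    lengths = cm.lengths[keep] if cm.lengths is not None else None
    return CountMatrix(cm.counts.loc[keep], cm.groups, lengths)


def fpkm(cm: CountMatrix) -> pd.DataFrame:
    """Fragments per kilobase of feature per million mapped fragments:
    ``count / (length/1e3 * libsize/1e6)`` with libsize = column sum."""
    if cm.lengths is None:
        raise ValueError("FPKM requires feature lengths")
    if (cm.lengths <= 0).any():
        raise ValueError("zero or negative feature length")
    libsize = cm.counts.sum(axis=0)
    if (libsize <= 0).any():
        bad = list(libsize.index[libsize <= 0])
        raise ValueError(f"zero library size for samples {bad}")
    kb = cm.lengths.values[:, None] / 1e3
    millions = libsize.values[None, :] / 1e6
    return cm.counts / (kb * millions)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors.

    For each feature positive in every sample, compute count / geometric
    mean across samples; the factor of a sample is the median of those
    ratios. If no feature is positive everywhere, fall back to library
    size over mean library size (logged).
    """
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        logger.warning(
            "size_factors: no feature positive in all samples; "
            "falling back to library-size normalization"
        )
        lib = counts.sum(axis=0).astype(float)
        return lib / lib.mean()
    sub = counts.loc[positive].astype(float)
    log_geo = np.log(sub).mean(axis=1)
    ratios = np.log(sub).sub(log_geo, axis=0)
    return np.exp(ratios.median(axis=0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved,
    monotone and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def _pooled_dispersion(
    norm: np.ndarray, group_slices: list[np.ndarray], floor: float
) -> np.ndarray:
    """Method-of-moments NB dispersion pooled within groups.

    Within-group variance (ddof=1) pooled across groups is compared with
    the overall mean: alpha = (s2 - m) / m^2, clamped at ``floor``.
    """
    n_total = sum(idx.size for idx in group_slices)
    n_groups = len(group_slices)
    ss = np.zeros(norm.shape[0])
    for idx in group_slices:
        sub = norm[:, idx]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    pooled_var = ss / max(n_total - n_groups, 1)
    m = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - m) / np.square(m)
    alpha[~np.isfinite(alpha)] = floor
    return np.maximum(alpha, floor)


def nb_wald_test(
    cm: CountMatrix,
    params: NBTestParams | None = None,
    group_order: tuple[str, str] | None = None,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Two-group NB Wald differential test.

    Parameters
    ----------
    cm : CountMatrix with exactly two groups.
    params : test parameters (defaults: pseudocount 0.5, moderation 0.5).
    group_order : (A, B); the reported log2FC is group B over group A.
        Defaults to sorted group labels, with ``control`` forced to be A
        when present.
    factors : per-sample size factors; computed by median-of-ratios when
        not supplied. Pass all-ones when the input is already normalized.

    Returns
    -------
    DataFrame indexed by feature with columns baseMean, log2FC, p, padj,
    direction (up/down/ns).
    """
    params = params or NBTestParams()
    groups = cm.group_columns()
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {sorted(groups)}")
    if group_order is None:
        labels = sorted(groups)
        if "control" in labels and labels[0] != "control":
            labels = ["control"] + [l for l in labels if l != "control"]
        group_order = (labels[0], labels[1])
    a_label, b_label = group_order

    if factors is None:
        factors = size_factors(cm.counts)
    factors = factors.reindex(cm.counts.columns)
    norm = cm.counts.values / factors.values[None, :]

    cols = list(cm.counts.columns)
    idx_a = np.array([cols.index(s) for s in groups[a_label]])
    idx_b = np.array([cols.index(s) for s in groups[b_label]])
    n_a, n_b = idx_a.size, idx_b.size

    m_a = norm[:, idx_a].mean(axis=1)
    m_b = norm[:, idx_b].mean(axis=1)
    pc = params.pseudocount
    log2fc = np.log2((m_b + pc) / (m_a + pc))

    alpha = _pooled_dispersion(norm, [idx_a, idx_b], params.dispersion_floor)
    med = np.median(alpha)
    w = params.moderation_weight
    alpha = (1 - w) * alpha + w * med

    # delta method: Var(log2(m_g + pc)) ~= Var(m_g) / ((m_g + pc)^2 ln(2)^2)
    var_ma = (m_a + alpha * m_a**2) / n_a
    var_mb = (m_b + alpha * m_b**2) / n_b
    se2 = (var_ma / (m_a + pc) ** 2 + var_mb / (m_b + pc) ** 2) / LN2**2
    se = np.sqrt(se2)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se
    p = 2 * stats.norm.sf(np.abs(z))

    dead = (m_a == 0) & (m_b == 0)
    log2fc[dead] = 0.0
    p[dead] = 1.0
    p[~np.isfinite(p)] = 1.0

    padj = bh_adjust(p)
    # RNA rule: adjusted P <= threshold; peak rule: raw P < threshold
    if params.use_adjusted_p:
        sig = padj <= params.padj_threshold
    else:
        sig = p < params.padj_threshold
    direction = np.where(
        sig & (log2fc >= params.lfc_threshold),
        "up",
        np.where(sig & (log2fc <= -params.lfc_threshold), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "baseMean": norm.mean(axis=1),
            "log2FC": log2fc,
            "p": p,
            "padj": padj,
            "direction": direction,
        },
        index=cm.counts.index,
    )
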