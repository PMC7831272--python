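"""ChIP-qPCR and RT-qPCR quantification arithmetic.

Percent input
    The input aliquot is only a fraction of the chromatin used for the
    ChIP, so its Ct is first adjusted by log2(1/fraction) cycles (a 1/16
    input is 4 cycles "ahead"). Then %Input = 100 * 2^-(Ct_ChIP -
    Ct_input,adjusted).

Fold enrichment (ChIP-qPCR)
    ddCt = dCt_negative - dCt_positive, oriented so that stronger
    enrichment at the positive locus gives fold = 2^ddCt > 1.

Relative expression (RT-qPCR, 2^-ddCt)
    ddCt = (Ct_target - Ct_reference)_sample - (Ct_target -
    Ct_reference)_calibrator; fold = 2^-ddCt, the expression of the
    target normalized to a housekeeping gene and relative to the
    calibrator condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "QpcrRecord",
    "percent_input",
    "fold_enrichment",
    "relative_expression",
    "summarize_replicates",
]


@dataclass
class QpcrRecord:
    """One locus/condition measurement: cycle-threshold values for the
    ChIP and input wells (ChIP-qPCR) or target and reference gene
    (RT-qPCR), plus the input dilution fraction."""

    locus: str
    condition: str
    ct_chip: float | None = None
    ct_input: float | None = None
    ct_target: float | None = None
    ct_reference: float | None = None
    input_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.input_fraction <= 1:
            raise ValueError("input_fraction must be in (0, 1]")
        for ct in (self.ct_chip, self.ct_input, self.ct_target, self.ct_reference):
            if ct is not None and ct <= 0:
                raise ValueError("Ct values must be positive")


def percent_input(ct_chip: float, ct_input: float, input_fraction: float) -> float:
    """Percent of input recovered by the ChIP, on a 0-100 scale."""
    if input_fraction <= 0:
        raise ValueError("input_fraction must be positive")
    adjusted_input = ct_input - math.log2(1.0 / input_fraction)
    dct = ct_chip - adjusted_input
    return 100.0 * 2.0 ** (-dct)


def fold_enrichment(dct_positive: float, dct_negative: float) -> float:
    """Fold enrichment of the positive locus over the negative locus:
    2^(dCt_negative - dCt_positive)."""
    ddct = dct_negative - dct_positive
    return 2.0**ddct


def relative_expression(
    ct_target: float,
    ct_reference: float,
    ct_target_cal: float,
    ct_reference_cal: float,
) -> float:
    """2^-ddCt relative expression of a target gene normalized to a
    reference gene, versus a calibrator sample."""
    ddct = (ct_target - ct_reference) - (ct_target_cal - ct_reference_cal)
    return 2.0 ** (-ddct)


def summarize_replicates(
    table: pd.DataFrame, value_col: str = "value"
) -> pd.DataFrame:
    """Mean +/- SD of a derived quantity across replicates, grouped by
    locus and condition. Expects columns locus, condition, replicate and
    ``value_col``."""
    g = table.groupby(["locus", "condition"])[value_col]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    return out
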