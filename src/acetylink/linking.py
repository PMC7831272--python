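"""Correlation-based assignment of differential peaks to target genes.

Every differential peak is paired with each gene whose TSS lies within a
1-Mb window of the peak summit on the same chromosome. For each pair the
Pearson correlation between the peak's normalized H3K27ac signal and the
gene's FPKM across the matched samples is tested against a two-sided
t reference (t = r*sqrt((n-2)/(1-r^2)) on n-2 df). A link is retained at
|r| > 0.8 and p < 0.01. With n = 6 samples the p < 0.01 clause is the
binding constraint: it corresponds to |r| >~ 0.917, stricter than the
r cutoff itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "PeakGeneLink",
    "candidate_pairs",
    "link_test",
    "select_links",
    "top_peak_genes",
    "distance_decay",
    "links_to_frame",
]


@dataclass
class PeakGeneLink:
    peak_id: str
    gene_id: str
    distance: int  # |summit - TSS| bp
    r: float
    p: float
    sign: str  # positive | negative
    peak_direction: str = "ns"  # hyper | hypo | ns


def candidate_pairs(
    diff_peaks: list,
    annotation: GenomeAnnotation,
    window: int = 1_000_000,
) -> list[tuple[str, str, int]]:
    """All (peak_id, gene_id, distance) with summit-TSS distance <= window
    on the same chromosome. ``diff_peaks`` is any iterable of objects with
    id/chrom/summit attributes."""
    tss_by_chrom = annotation.tss_by_chrom()
    pairs: list[tuple[str, str, int]] = []
    for peak in diff_peaks:
        entries = tss_by_chrom.get(peak.chrom, [])
        if not entries:
            continue
        positions = np.array([t for t, _ in entries])
        lo = np.searchsorted(positions, peak.summit - window, side="left")
        hi = np.searchsorted(positions, peak.summit + window, side="right")
        for tss, gid in entries[lo:hi]:
            pairs.append((peak.id, gid, abs(peak.summit - tss)))
    return pairs


def link_test(peak_signal, gene_abundance) -> tuple[float, float, str | None]:
    """Pearson r and two-sided p for one peak-gene pair.

    Returns (r, p, reason); ``reason`` is non-None when the test is
    undefined (constant vector), in which case r and p are NaN and the
    pair must be rejected.
    """
    x = np.asarray(peak_signal, dtype=float)
    y = np.asarray(gene_abundance, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 matched samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan"), "constant vector"
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), None


def select_links(
    pairs: list[tuple[str, str, int]],
    peak_signal: pd.DataFrame,
    gene_abundance: pd.DataFrame,
    r_min: float = 0.8,
    p_max: float = 0.01,
    peak_directions: pd.Series | None = None,
) -> list[PeakGeneLink]:
    """Test every candidate pair and keep links with |r| > r_min and
    p < p_max. Sample columns of the two matrices are matched by order of
    ``peak_signal.columns``. Output is sorted by (peak id, gene id)."""
    cols = list(peak_signal.columns)
    gene_abundance = gene_abundance.reindex(columns=cols)
    links: list[PeakGeneLink] = []
    for peak_id, gene_id, dist in pairs:
        if peak_id not in peak_signal.index or gene_id not in gene_abundance.index:
            continue
        r, p, reason = link_test(
            peak_signal.loc[peak_id].values, gene_abundance.loc[gene_id].values
        )
        if reason is not None:
            logger.debug("pair (%s, %s) rejected: %s", peak_id, gene_id, reason)
            continue
        if abs(r) > r_min and p < p_max:
            direction = "ns"
            if peak_directions is not None and peak_id in peak_directions.index:
                direction = str(peak_directions.loc[peak_id])
            links.append(
                PeakGeneLink(
                    peak_id,
                    gene_id,
                    dist,
                    r,
                    p,
                    "positive" if r > 0 else "negative",
                    direction,
                )
            )
    links.sort(key=lambda l: (l.peak_id, l.gene_id))
    return links


def top_peak_genes(
    links: list[PeakGeneLink], k: int = 100
) -> dict[str, list[PeakGeneLink]]:
    """Top-k genes associated with hyper- and hypo-acetylated peaks.

    Per direction, links are ordered by p ascending, then |r| descending,
    then gene id; genes are de-duplicated keeping each gene's best link;
    the list is truncated to k.
    """
    out: dict[str, list[PeakGeneLink]] = {}
    for direction in ("hyper", "hypo"):
        subset = [l for l in links if l.peak_direction == direction]
        subset.sort(key=lambda l: (l.p, -abs(l.r), l.gene_id))
        seen: set[str] = set()
        best: list[PeakGeneLink] = []
        for l in subset:
            if l.gene_id not in seen:
                seen.add(l.gene_id)
                best.append(l)
        if len(best) < k:
            logger.info(
                "top_peak_genes: only %d %s-associated genes available (k=%d)",
                len(best), direction, k,
            )
        out[direction] = best[:k]
    return out


def distance_decay(
    links: list[PeakGeneLink],
    bin_width: int = 100_000,
    max_dist: int = 1_000_000,
) -> pd.DataFrame:
    """Histogram of link distances in ``bin_width`` bins over
    [0, max_dist], split by correlation sign and peak direction. Bin
    totals sum to the number of links."""
    n_bins = int(np.ceil(max_dist / bin_width))
    edges = [i * bin_width for i in range(n_bins + 1)]
    rows = []
    for i in range(n_bins):
        row = {"bin_start": edges[i], "bin_end": edges[i + 1]}
        for sign in ("positive", "negative"):
            for direction in ("hyper", "hypo", "ns"):
                row[f"{direction}_{sign}"] = 0
        rows.append(row)
    df = pd.DataFrame(rows)
    for l in links:
        b = min(l.distance // bin_width, n_bins - 1)
        df.loc[b, f"{l.peak_direction}_{l.sign}"] += 1
    df["total"] = df.drop(columns=["bin_start", "bin_end"]).sum(axis=1)
    return df


def links_to_frame(links: list[PeakGeneLink]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "peak": l.peak_id,
                "gene": l.gene_id,
                "distance": l.distance,
                "r": l.r,
                "p": l.p,
                "sign": l.sign,
                "peak_direction": l.peak_direction,
            }
            for l in links
        ],
        columns=["peak", "gene", "distance", "r", "p", "sign", "peak_direction"],
    )
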