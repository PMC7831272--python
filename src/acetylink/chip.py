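"""Peak merging, signal quantification and differential acetylation.

Per-sample H3K27ac peak calls are merged across all libraries by
single-linkage clustering of summit positions: two peaks on the same
chromosome join when their summits are less than 1 kb apart, and clusters
chain transitively (a chain's genomic span may therefore exceed 1 kb).
The merged interval is the union of its constituents; the consensus summit
is the summit of the constituent with the highest caller signal, ties
resolved to the leftmost summit.

Raw coverage of a merged peak is the number of read intervals overlapping
it by at least one base (half-open semantics). ChIP and input coverage are
each normalized by total mapped reads (per million) and by peak length
(per kb), and the normalized input is subtracted from the normalized ChIP
to correct fragmentation bias; negative values are floored at zero.

Differential acetylation reuses the NB Wald machinery on the normalized
signal rounded to integers, with size factors fixed at 1 (the coverage is
already depth-normalized). Peaks are called hyper-/hypo-acetylated in the
case group at raw P < 0.05 and |log2FC| >= 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Peak
from .rnaseq import CountMatrix, NBTestParams, nb_wald_test

logger = logging.getLogger(__name__)

__all__ = [
    "MergedPeak",
    "SignalMatrix",
    "merge_peaks",
    "quantify",
    "normalize_subtract",
    "differential_acetylation",
    "read_bed_reads",
]


@dataclass
class MergedPeak:
    id: str
    chrom: str
    start: int
    end: int
    summit: int
    constituents: dict[str, list[str]] = field(default_factory=dict)  # sample -> peak ids

    @property
    def length(self) -> int:
        return self.end - self.start

    def as_peak(self) -> Peak:
        return Peak(self.id, self.chrom, self.start, self.end, self.summit)


@dataclass
class SignalMatrix:
    """Per-merged-peak raw counts and normalized input-subtracted signal.

    ``raw_chip`` / ``raw_input`` are peaks x samples count tables;
    ``chip_totals`` / ``input_totals`` the per-sample total mapped read
    counts; ``lengths`` the merged peak lengths in bp. ``normalized`` is
    filled by :func:`normalize_subtract`.
    """

    peaks: list[MergedPeak]
    raw_chip: pd.DataFrame
    raw_input: pd.DataFrame | None = None
    chip_totals: pd.Series | None = None
    input_totals: pd.Series | None = None
    normalized: pd.DataFrame | None = None

    @property
    def lengths(self) -> pd.Series:
        return pd.Series({p.id: p.length for p in self.peaks}).reindex(
            self.raw_chip.index
        )


def merge_peaks(
    peak_sets: dict[str, list[Peak]], summit_dist: int = 1000
) -> list[MergedPeak]:
    """Single-linkage merge of per-sample peaks by summit distance.

    Peaks on the same chromosome whose summits are strictly less than
    ``summit_dist`` apart are linked; linkage is transitive. Returns
    merged peaks sorted by (chrom, start), ids ``mp_00001`` etc.
    """
    pooled: list[Peak] = []
    for sample, peaks in peak_sets.items():
        by_pos = sorted(peaks, key=lambda p: (p.chrom, p.start))
        for a, b in zip(by_pos, by_pos[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                logger.info(
                    "sample %s: overlapping peaks %s and %s", sample, a.id, b.id
                )
                break
        for p in peaks:
            if p.sample == "":
                p.sample = sample
            pooled.append(p)

    by_chrom: dict[str, list[Peak]] = {}
    for p in pooled:
        by_chrom.setdefault(p.chrom, []).append(p)

    merged: list[MergedPeak] = []
    for chrom in sorted(by_chrom):
        peaks = sorted(by_chrom[chrom], key=lambda p: (p.summit, p.start))
        cluster: list[Peak] = []
        for p in peaks:
            # on a line, single-linkage clusters are runs of consecutive
            # summits with gaps < summit_dist
            if cluster and p.summit - cluster[-1].summit >= summit_dist:
                merged.append(_finish_cluster(cluster))
                cluster = []
            cluster.append(p)
        if cluster:
            merged.append(_finish_cluster(cluster))

    merged.sort(key=lambda m: (m.chrom, m.start, m.end))
    for i, m in enumerate(merged, start=1):
        m.id = f"mp_{i:05d}"
    return merged


def _finish_cluster(cluster: list[Peak]) -> MergedPeak:
    start = min(p.start for p in cluster)
    end = max(p.end for p in cluster)
    best = max(cluster, key=lambda p: (p.signal, -p.summit))
    constituents: dict[str, list[str]] = {}
    for p in cluster:
        constituents.setdefault(p.sample, []).append(p.id)
    return MergedPeak("", cluster[0].chrom, start, end, best.summit, constituents)


def read_bed_reads(path) -> dict[str, np.ndarray]:
    """Read intervals from BED (first three columns) grouped by chromosome
    as an (n, 2) int array."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], comment="#",
        names=["chrom", "start", "end"],
    )
    return {
        chrom: sub[["start", "end"]].to_numpy()
        for chrom, sub in df.groupby("chrom", sort=False)
    }


def _count_overlaps(
    reads_by_chrom: dict[str, np.ndarray], peaks: list[MergedPeak]
) -> np.ndarray:
    """Number of read intervals overlapping each peak by >= 1 bp."""
    sorted_bounds: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    known = {p.chrom for p in peaks}
    for chrom, arr in reads_by_chrom.items():
        if chrom not in known:
            logger.warning("reads on unknown chromosome %s skipped", chrom)
            continue
        sorted_bounds[chrom] = (np.sort(arr[:, 0]), np.sort(arr[:, 1]))
    counts = np.zeros(len(peaks), dtype=int)
    for i, p in enumerate(peaks):
        if p.chrom not in sorted_bounds:
            continue
        starts, ends = sorted_bounds[p.chrom]
        # overlap iff read.start < peak.end and read.end > peak.start
        n_left = np.searchsorted(starts, p.end, side="left")
        n_gone = np.searchsorted(ends, p.start, side="right")
        counts[i] = n_left - n_gone
    return counts


def quantify(
    reads_per_sample: dict[str, dict[str, np.ndarray]],
    merged_peaks: list[MergedPeak],
    input_reads_per_sample: dict[str, dict[str, np.ndarray]] | None = None,
    chip_totals: dict[str, int] | None = None,
    input_totals: dict[str, int] | None = None,
) -> SignalMatrix:
    """Raw coverage counts of merged peaks per sample.

    ``reads_per_sample`` maps sample id -> chromosome -> (n, 2) interval
    array. Totals default to the number of supplied read intervals per
    sample (i.e. all reads mapped).
    """
    ids = [p.id for p in merged_peaks]
    chip = pd.DataFrame(
        {s: _count_overlaps(r, merged_peaks) for s, r in reads_per_sample.items()},
        index=ids,
    )
    if chip_totals is None:
        chip_totals = {
            s: int(sum(len(a) for a in r.values()))
            for s, r in reads_per_sample.items()
        }
    raw_input = None
    if input_reads_per_sample is not None:
        raw_input = pd.DataFrame(
            {
                s: _count_overlaps(r, merged_peaks)
                for s, r in input_reads_per_sample.items()
            },
            index=ids,
        )
        if input_totals is None:
            input_totals = {
                s: int(sum(len(a) for a in r.values()))
                for s, r in input_reads_per_sample.items()
            }
    return SignalMatrix(
        peaks=merged_peaks,
        raw_chip=chip,
        raw_input=raw_input,
        chip_totals=pd.Series(chip_totals, dtype=float),
        input_totals=pd.Series(input_totals, dtype=float) if input_totals else None,
    )


def normalize_subtract(signal: SignalMatrix) -> SignalMatrix:
    """Depth- and length-normalize ChIP and input coverage, subtract the
    input, floor at zero.

    norm = raw / (total_reads/1e6 * length/1e3); signal = max(0,
    norm_chip - norm_input). Requires a matched input column and total for
    every ChIP sample.
    """
    if signal.raw_input is None or signal.input_totals is None:
        raise ValueError("normalize_subtract requires input coverage and totals")
    for s in signal.raw_chip.columns:
        if s not in signal.raw_input.columns:
            raise ValueError(f"missing input sample for '{s}'")
        if s not in signal.input_totals.index:
            raise ValueError(f"missing input total for '{s}'")
        if s not in signal.chip_totals.index:
            raise ValueError(f"missing ChIP total for '{s}'")
    if (signal.chip_totals <= 0).any() or (signal.input_totals <= 0).any():
        raise ValueError("total mapped read counts must be positive")

    kb = signal.lengths.values[:, None] / 1e3
    chip_pm = signal.chip_totals.reindex(signal.raw_chip.columns).values[None, :] / 1e6
    input_pm = signal.input_totals.reindex(signal.raw_chip.columns).values[None, :] / 1e6
    norm_chip = signal.raw_chip.values / (chip_pm * kb)
    norm_input = (
        signal.raw_input.reindex(columns=signal.raw_chip.columns).values
        / (input_pm * kb)
    )
    signal.normalized = pd.DataFrame(
        np.maximum(norm_chip - norm_input, 0.0),
        index=signal.raw_chip.index,
        columns=signal.raw_chip.columns,
    )
    return signal


def differential_acetylation(
    signal: SignalMatrix,
    groups: dict[str, str],
    params: NBTestParams | None = None,
    group_order: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """NB Wald test on the normalized input-subtracted signal.

    The signal is rounded to the nearest integer (the NB model needs
    count-like input) and size factors are fixed at 1 because depth
    normalization has already been applied. Direction labels follow the
    raw-p rule: ``up`` = hyper-acetylated in the case group (log2FC >= 1,
    p < 0.05), ``down`` = hypo-acetylated. The result table adds a
    ``label`` column with hyper/hypo/ns.
    """
    if signal.normalized is None:
        raise ValueError("run normalize_subtract before differential_acetylation")
    if params is None:
        params = NBTestParams(use_adjusted_p=False)
    counts = signal.normalized.round().astype(int)
    cm = CountMatrix(counts, groups)
    res = nb_wald_test(
        cm,
        params,
        group_order=group_order,
        factors=pd.Series(1.0, index=counts.columns),
    )
    res["label"] = res["direction"].map({"up": "hyper", "down": "hypo", "ns": "ns"})
    return res
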