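"""Peak merging, coverage quantification and input subtraction."""

import numpy as np
import pandas as pd
import pytest

from acetylink.chip import (
    SignalMatrix,
    differential_acetylation,
    merge_peaks,
    normalize_subtract,
    quantify,
)
from acetylink.genome import Peak


def peak(summit, sample="s1", width=200, signal=1.0, chrom="chr1", pid=None):
    start = max(0, summit - width // 2)
    return Peak(
        pid or f"{sample}_{chrom}_{summit}", chrom, start, summit + width // 2,
        summit, sample, signal,
    )


def merge_oracle(peaks, summit_dist=1000):
    """O(n^2) single-linkage by union-find over summit-distance edges."""
    parent = list(range(len(peaks)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(peaks)):
        for j in range(i + 1, len(peaks)):
            if (
                peaks[i].chrom == peaks[j].chrom
                and abs(peaks[i].summit - peaks[j].summit) < summit_dist
            ):
                parent[find(i)] = find(j)
    clusters = {}
    for i, p in enumerate(peaks):
        clusters.setdefault(find(i), []).append(p)
    return sorted(
        sorted((p.chrom, p.start, p.end, p.summit) for p in c)
        for c in clusters.values()
    )


def merged_as_clusters(merged, peak_lookup):
    out = []
    for m in merged:
        members = []
        for sample, pids in m.constituents.items():
            members.extend(peak_lookup[pid] for pid in pids)
        out.append(sorted((p.chrom, p.start, p.end, p.summit) for p in members))
    return sorted(out)


class TestMergePeaks:
    def test_close_summits_merge(self):
        merged = merge_peaks({"a": [peak(100)], "b": [peak(900, "b")]})
        assert len(merged) == 1

    def test_distant_summits_stay_separate(self):
        merged = merge_peaks({"a": [peak(100)], "b": [peak(1200, "b")]})
        assert len(merged) == 2

    def test_chaining_is_transitive(self):
        # 100-900 and 900-1800 both < 1000 apart: one cluster despite
        # 100 vs 1800 exceeding the threshold
        merged = merge_peaks(
            {"a": [peak(100), peak(1800)], "b": [peak(900, "b")]}
        )
        assert len(merged) == 1
        assert merged[0].start == min(0, 900 - 100)

    def test_exactly_threshold_does_not_merge(self):
        merged = merge_peaks({"a": [peak(100)], "b": [peak(1100, "b")]})
        assert len(merged) == 2

    def test_union_interval_and_best_signal_summit(self):
        merged = merge_peaks(
            {
                "a": [peak(500, "a", width=400, signal=2.0)],
                "b": [peak(700, "b", width=600, signal=9.0)],
            }
        )
        (m,) = merged
        assert (m.start, m.end) == (300, 1000)
        assert m.summit == 700  # highest-signal constituent wins

    def test_summit_tie_breaks_leftmost(self):
        merged = merge_peaks(
            {"a": [peak(500, "a", signal=3.0)], "b": [peak(700, "b", signal=3.0)]}
        )
        assert merged[0].summit == 500

    def test_chromosomes_never_mix(self):
        merged = merge_peaks(
            {"a": [peak(100, chrom="chr1"), peak(100, chrom="chr2")]}
        )
        assert len(merged) == 2

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for trial in range(200):
            n = int(rng.integers(1, 51))
            peaks = []
            for i in range(n):
                chrom = f"chr{rng.integers(1, 3)}"
                summit = int(rng.integers(100, 20_000))
                peaks.append(
                    peak(
                        summit,
                        sample=f"s{rng.integers(1, 4)}",
                        width=int(rng.integers(50, 400)) * 2,
                        signal=float(rng.random()),
                        chrom=chrom,
                        pid=f"t{trial}_p{i}",
                    )
                )
            lookup = {p.id: p for p in peaks}
            by_sample = {}
            for p in peaks:
                by_sample.setdefault(p.sample, []).append(p)
            merged = merge_peaks(by_sample)
            assert merged_as_clusters(merged, lookup) == merge_oracle(peaks)

    def test_idempotent_on_merged_set(self):
        rng = np.random.default_rng(7)
        peaks = [
            peak(int(s), pid=f"p{i}")
            for i, s in enumerate(np.cumsum(rng.integers(200, 3000, size=40)) + 500)
        ]
        merged = merge_peaks({"s1": peaks})
        again = merge_peaks({"m": [m.as_peak() for m in merged]})
        assert [(m.chrom, m.start, m.end, m.summit) for m in again] == [
            (m.chrom, m.start, m.end, m.summit) for m in merged
        ]


class TestQuantify:
    def mk_merged(self):
        return merge_peaks({"s": [peak(400, "s", width=200, pid="pk")]})

    def test_counts_overlapping_reads(self):
        merged = self.mk_merged()  # interval [300, 500)
        reads = {"s1": {"chr1": np.array([[250, 350], [400, 450], [490, 600]])}}
        sig = quantify(reads, merged)
        assert sig.raw_chip.iloc[0, 0] == 3

    def test_half_open_abutment_not_counted(self):
        merged = self.mk_merged()
        reads = {"s1": {"chr1": np.array([[200, 300], [500, 600]])}}
        assert quantify(reads, merged).raw_chip.iloc[0, 0] == 0

    def test_spanning_read_counted_once(self):
        merged = self.mk_merged()
        reads = {"s1": {"chr1": np.array([[100, 900]])}}
        assert quantify(reads, merged).raw_chip.iloc[0, 0] == 1

    def test_read_order_invariance_and_count_bound(self):
        merged = merge_peaks(
            {"s": [peak(400, "s", pid="a"), peak(5000, "s", pid="b")]}
        )
        rng = np.random.default_rng(1)
        starts = rng.integers(0, 6000, size=300)
        reads = np.column_stack([starts, starts + 100])
        a = quantify({"s1": {"chr1": reads}}, merged)
        b = quantify({"s1": {"chr1": reads[::-1]}}, merged)
        pd.testing.assert_frame_equal(a.raw_chip, b.raw_chip)
        assert a.raw_chip["s1"].sum() <= len(reads)

    def test_unknown_chromosome_skipped(self, caplog):
        merged = self.mk_merged()
        reads = {"s1": {"chrUn": np.array([[300, 500]])}}
        assert quantify(reads, merged).raw_chip.iloc[0, 0] == 0


class TestNormalizeSubtract:
    def mk_signal(self, chip, inp, chip_total=1e7, input_total=1e7, length=1000):
        merged = merge_peaks(
            {"s": [peak(length // 2, "s", width=length, pid="pk")]}
        )
        merged[0].start, merged[0].end = 0, length
        return SignalMatrix(
            peaks=merged,
            raw_chip=pd.DataFrame({"s1": [chip]}, index=[merged[0].id]),
            raw_input=pd.DataFrame({"s1": [inp]}, index=[merged[0].id]),
            chip_totals=pd.Series({"s1": chip_total}),
            input_totals=pd.Series({"s1": input_total}),
        )

    def test_worked_example(self):
        # 200 vs 100 reads, both libraries 1e7, 1 kb peak -> 20 - 10 = 10
        sig = normalize_subtract(self.mk_signal(200, 100))
        assert sig.normalized.iloc[0, 0] == pytest.approx(10.0)

    def test_excess_input_floored_at_zero(self):
        sig = normalize_subtract(self.mk_signal(50, 500))
        assert sig.normalized.iloc[0, 0] == 0.0

    def test_joint_rescaling_invariance(self):
        a = normalize_subtract(self.mk_signal(200, 100))
        b = normalize_subtract(
            self.mk_signal(400, 100, chip_total=2e7, input_total=1e7)
        )
        assert a.normalized.iloc[0, 0] == pytest.approx(b.normalized.iloc[0, 0])

    def test_missing_input_sample_named(self):
        sig = self.mk_signal(10, 5)
        sig.raw_input = sig.raw_input.rename(columns={"s1": "other"})
        with pytest.raises(ValueError, match="'s1'"):
            normalize_subtract(sig)


class TestDifferentialAcetylation:
    def test_identical_groups_yield_no_calls(self):
        merged = merge_peaks(
            {"s": [peak(400, "s", pid="a"), peak(5000, "s", pid="b")]}
        )
        samples = [f"c{i}" for i in range(3)] + [f"f{i}" for i in range(3)]
        groups = {s: ("control" if s.startswith("c") else "FLHS") for s in samples}
        vals = pd.DataFrame(
            {s: [30.0, 12.0] for s in samples}, index=[m.id for m in merged]
        )
        sig = SignalMatrix(
            peaks=merged,
            raw_chip=vals,
            raw_input=vals * 0,
            chip_totals=pd.Series(1e6, index=samples),
            input_totals=pd.Series(1e6, index=samples),
        )
        sig.normalized = vals
        res = differential_acetylation(sig, groups)
        assert (res["label"] == "ns").all()
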