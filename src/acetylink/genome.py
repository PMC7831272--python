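"""Genome annotation model and peak classification.

Coordinate conventions
----------------------
All coordinates are held internally as 0-based half-open intervals, the
native BED convention. GTF input is 1-based inclusive and is converted on
read; writing converts back. The transcription start site (TSS) of a gene
is the 5'-most base of its canonical transcript: the interval start on the
plus strand and the last covered base (``end - 1``) on the minus strand.

The canonical transcript of a gene is the one with the largest summed exon
length, ties broken by lexicographically smallest transcript id.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "Transcript",
    "Gene",
    "GenomeAnnotation",
    "Peak",
    "FeatureLabel",
    "AnnotationError",
    "parse_annotation",
    "write_gtf",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_chrom_sizes",
    "classify_proximal_distal",
    "classify_feature",
    "intron_ordinal",
    "peak_gene_distance",
]


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass
class Transcript:
    id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted by start

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def introns(self) -> list[tuple[int, int]]:
        """Intervals between consecutive exons, in genomic order."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def validate(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"transcript {self.id}: bad strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"transcript {self.id} has no exons")
        for s, e in self.exons:
            if not s < e:
                raise AnnotationError(f"transcript {self.id}: empty exon ({s},{e})")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise AnnotationError(
                    f"transcript {self.id}: overlapping/unordered exons "
                    f"({s1},{e1}) and ({s2},{e2})"
                )


@dataclass
class Gene:
    id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    def canonical_transcript(self) -> Transcript:
        return min(
            self.transcripts.values(),
            key=lambda t: (-t.exonic_length, t.id),
        )

    @property
    def tss(self) -> int:
        t = self.canonical_transcript()
        return t.start if self.strand == "+" else t.end - 1


@dataclass
class GenomeAnnotation:
    chrom_sizes: dict[str, int]
    genes: dict[str, Gene]

    def __post_init__(self) -> None:
        self._tss_cache: dict[str, list[tuple[int, str]]] | None = None

    @property
    def tss(self) -> dict[str, int]:
        """Gene id -> TSS position (canonical transcript, strand-aware)."""
        return {gid: g.tss for gid, g in self.genes.items()}

    def tss_by_chrom(self) -> dict[str, list[tuple[int, str]]]:
        """Sorted (tss, gene_id) per chromosome; cached."""
        if self._tss_cache is None:
            out: dict[str, list[tuple[int, str]]] = {}
            for gid, g in self.genes.items():
                out.setdefault(g.chrom, []).append((g.tss, gid))
            for lst in out.values():
                lst.sort()
            self._tss_cache = out
        return self._tss_cache

    def validate(self) -> None:
        for g in self.genes.values():
            size = self.chrom_sizes.get(g.chrom)
            if size is not None and g.end > size:
                raise AnnotationError(f"gene {g.id} extends past end of {g.chrom}")
            for t in g.transcripts.values():
                t.validate()
                if t.start < g.start or t.end > g.end:
                    raise AnnotationError(
                        f"transcript {t.id} outside gene {g.id} bounds"
                    )


@dataclass
class Peak:
    """A called peak: 0-based half-open interval with an absolute summit.

    The summit is the base position of maximum read coverage within the
    peak. ``signal`` carries the caller's enrichment value (narrowPeak
    column 7) and is used to pick consensus summits when peaks are merged.
    """

    id: str
    chrom: str
    start: int
    end: int
    summit: int
    sample: str = ""
    signal: float = 0.0

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"peak {self.id}: summit {self.summit} outside [{self.start},{self.end})"
            )


@dataclass(frozen=True)
class FeatureLabel:
    """Genomic feature class of a position: promoter-TSS, exon, intron
    (with 1-based ordinal counted from the TSS side) or intergenic."""

    kind: str  # promoter-TSS | exon | intron | intergenic
    intron_ordinal: int | None = None

    def __post_init__(self) -> None:
        if (self.kind == "intron") != (self.intron_ordinal is not None):
            raise ValueError("intron ordinal present iff kind == 'intron'")


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _gtf_attributes(field9: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field9))


def parse_annotation(
    gtf_path, chrom_sizes: dict[str, int] | None = None
) -> GenomeAnnotation:
    """Parse a GTF file (Ensembl dialect) into a :class:`GenomeAnnotation`.

    Requires gene/transcript/exon features carrying ``gene_id`` (and
    ``transcript_id`` for transcripts/exons). 1-based inclusive GTF
    coordinates are converted to 0-based half-open. Genes or transcripts
    that are never declared explicitly are inferred from their exons.

    Raises
    ------
    AnnotationError
        On a malformed line (message names the line number) or an exon
        lying outside its transcript's declared bounds.
    """
    genes: dict[str, Gene] = {}
    tx_meta: dict[str, tuple[str, str, str, int, int]] = {}
    tx_exons: dict[str, list[tuple[int, int]]] = {}
    declared_bounds: dict[str, tuple[int, int]] = {}

    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise AnnotationError(
                    f"{gtf_path}: malformed GTF line {lineno}: expected 9 fields"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = parts[:9]
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise AnnotationError(
                    f"{gtf_path}: malformed GTF line {lineno}: non-integer coordinate"
                ) from exc
            if start1 < 1 or end1 < start1:
                raise AnnotationError(
                    f"{gtf_path}: malformed GTF line {lineno}: bad interval {start1}-{end1}"
                )
            start, end = start1 - 1, end1  # to 0-based half-open
            attr = _gtf_attributes(attrs)
            gid = attr.get("gene_id")
            if gid is None:
                raise AnnotationError(
                    f"{gtf_path}: malformed GTF line {lineno}: missing gene_id"
                )
            if feature == "gene":
                genes[gid] = Gene(gid, chrom, strand, start, end)
            elif feature in ("transcript", "exon"):
                tid = attr.get("transcript_id")
                if tid is None:
                    raise AnnotationError(
                        f"{gtf_path}: malformed GTF line {lineno}: missing transcript_id"
                    )
                if feature == "transcript":
                    declared_bounds[tid] = (start, end)
                    tx_meta.setdefault(tid, (gid, chrom, strand, start, end))
                else:
                    tx_meta.setdefault(tid, (gid, chrom, strand, start, end))
                    tx_exons.setdefault(tid, []).append((start, end))
            # other feature types (CDS, UTR, ...) are ignored

    for tid, exons in tx_exons.items():
        gid, chrom, strand, _s, _e = tx_meta[tid]
        exons = sorted(exons)
        if tid in declared_bounds:
            lo, hi = declared_bounds[tid]
            for s, e in exons:
                if s < lo or e > hi:
                    raise AnnotationError(
                        f"exon ({s},{e}) outside transcript {tid} bounds ({lo},{hi})"
                    )
        t = Transcript(tid, gid, chrom, strand, exons)
        t.validate()
        if gid not in genes:
            genes[gid] = Gene(gid, chrom, strand, t.start, t.end)
        g = genes[gid]
        g.start = min(g.start, t.start)
        g.end = max(g.end, t.end)
        g.transcripts[tid] = t

    for gid, g in genes.items():
        if not g.transcripts:
            raise AnnotationError(f"gene {gid} has no transcripts/exons")

    if chrom_sizes is None:
        chrom_sizes = {}
        for g in genes.values():
            chrom_sizes[g.chrom] = max(chrom_sizes.get(g.chrom, 0), g.end)
    ann = GenomeAnnotation(chrom_sizes, genes)
    ann.validate()
    return ann


def write_gtf(annotation: GenomeAnnotation, path) -> None:
    """Write gene/transcript/exon records, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for gid in sorted(annotation.genes):
            g = annotation.genes[gid]
            fh.write(
                f"{g.chrom}\tacetylink\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f'gene_id "{gid}";\n'
            )
            for tid in sorted(g.transcripts):
                t = g.transcripts[tid]
                fh.write(
                    f"{g.chrom}\tacetylink\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                    f'{g.strand}\t.\tgene_id "{gid}"; transcript_id "{tid}";\n'
                )
                for s, e in t.exons:
                    fh.write(
                        f"{g.chrom}\tacetylink\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                        f'gene_id "{gid}"; transcript_id "{tid}";\n'
                    )


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                name, size = line.split()[:2]
                sizes[name] = int(size)
    return sizes


def read_narrowpeak(path, sample: str = "") -> list[Peak]:
    """Read BED6+4 narrowPeak (summit = start + column-10 offset).

    Plain BED6 (or files with offset -1) fall back to the interval
    midpoint as the summit.
    """
    peaks = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 and f[3] != "." else f"{path}:{i}"
            signal = float(f[6]) if len(f) > 6 else 0.0
            if len(f) > 9 and int(f[9]) >= 0:
                summit = start + int(f[9])
            else:
                summit = (start + end) // 2
            peaks.append(Peak(name, chrom, start, end, summit, sample, signal))
    return peaks


def write_narrowpeak(peaks, path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.id}\t0\t.\t{p.signal:g}\t-1\t-1\t"
                f"{p.summit - p.start}\n"
            )


def _boundary_distance(peak: Peak, tss: int) -> int:
    """Distance from the peak's covered bases to a TSS; 0 when inside."""
    if peak.start <= tss < peak.end:
        return 0
    return peak.start - tss if tss < peak.start else tss - (peak.end - 1)


def classify_proximal_distal(
    peak: Peak, annotation: GenomeAnnotation, threshold_bp: int = 1000
) -> str:
    """Classify a peak as ``proximal`` (within ``threshold_bp`` of, or
    overlapping, any TSS — boundary-to-TSS distance, inclusive) or
    ``distal``. Chromosomes with no annotated gene yield ``distal``."""
    tss_list = annotation.tss_by_chrom().get(peak.chrom, [])
    for tss, _gid in tss_list:
        if _boundary_distance(peak, tss) <= threshold_bp:
            return "proximal"
    return "distal"


def intron_ordinal(position: int, transcript: Transcript) -> int | None:
    """1-based intron index of ``position``, counted from the TSS side
    (first intron is the one nearest the TSS on either strand); ``None``
    when the position is not intronic. Single-exon transcripts have no
    introns."""
    introns = transcript.introns()
    for i, (s, e) in enumerate(introns):
        if s <= position < e:
            return i + 1 if transcript.strand == "+" else len(introns) - i
    return None


def classify_feature(
    peak: Peak, annotation: GenomeAnnotation, promoter_bp: int = 1000
) -> FeatureLabel:
    """Label a peak by its summit with priority
    promoter-TSS > exon > intron > intergenic.

    promoter-TSS means the summit lies within ``promoter_bp`` of any TSS.
    Exon/intron membership is judged against the canonical transcript of
    each gene whose span contains the summit.
    """
    pos = peak.summit
    for tss, _gid in annotation.tss_by_chrom().get(peak.chrom, []):
        if abs(pos - tss) <= promoter_bp:
            return FeatureLabel("promoter-TSS")
    best_intron: int | None = None
    for g in annotation.genes.values():
        if g.chrom != peak.chrom or not (g.start <= pos < g.end):
            continue
        t = g.canonical_transcript()
        if any(s <= pos < e for s, e in t.exons):
            return FeatureLabel("exon")
        ordinal = intron_ordinal(pos, t)
        if ordinal is not None and (best_intron is None or ordinal < best_intron):
            best_intron = ordinal
    if best_intron is not None:
        return FeatureLabel("intron", best_intron)
    return FeatureLabel("intergenic")


def peak_gene_distance(peak: Peak, gene: Gene) -> int:
    """|summit - TSS| in bp; the two must share a chromosome."""
    if peak.chrom != gene.chrom:
        raise ValueError(
            f"peak {peak.id} ({peak.chrom}) and gene {gene.id} ({gene.chrom}) "
            "are on different chromosomes: distance undefined"
        )
    return abs(peak.summit - gene.tss)
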