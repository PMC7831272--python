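"""Seeded generator of a toy genome with planted regulatory structure.

Emulates the study design this package targets: two groups (control vs
FLHS) of three biological replicates each, profiled with both H3K27ac
ChIP-seq (ChIP + input libraries) and RNA-seq on the same animals. The
generator plants:

* differential peaks and genes at |log2FC| = ``planted_log2fc`` in a
  known fraction of features, with NB(mu, mu + alpha*mu^2) counts and
  lognormal per-sample depth factors;
* peak-gene pairs within 1 Mb whose gene abundance is an affine function
  of the peak's normalized, input-subtracted signal plus Gaussian noise
  calibrated to a target Pearson correlation;
* a sequence motif embedded in a known fraction of differential peak
  sequences.

Everything is a pure function of :class:`SimConfig` (seed included):
independent named RNG streams per sub-generator mean that, e.g., adding
peaks does not perturb the RNA count draws.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chip import MergedPeak, SignalMatrix
from .enrichment import PWM
from .genome import GenomeAnnotation, Gene, Peak, Transcript

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SimTruth",
    "default_pwm",
    "simulate_annotation",
    "simulate_peaks",
    "simulate_counts",
    "build_signal_matrix",
    "simulate_links",
    "simulate_sequences",
    "simulate_gene_sets",
    "simulate_all",
]

_BASES = np.array(list("ACGT"))


def default_pwm() -> PWM:
    """A sharp 8-bp motif (97% consensus weight) used when no PWM is
    supplied; consensus ACGTCAAT."""
    consensus = "ACGTCAAT"
    mat = np.full((len(consensus), 4), 0.01)
    for i, b in enumerate(consensus):
        mat[i, "ACGT".index(b)] = 0.97
    return PWM("sim_motif", mat)


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    The defaults mirror the study conditions the generator emulates:
    3 replicates per group, NB counts with dispersion ``nb_dispersion``,
    planted effects of |log2FC| = 2 in 5% of features, planted links at
    r = 0.99, motifs planted in every differential peak. Genome size and
    feature numbers are desk-scale.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 20_000_000
    n_genes: int = 400
    n_peaks: int = 600
    n_samples_per_group: int = 3
    nb_dispersion: float = 0.05
    base_mean: float = 100.0
    chip_base_mean: float = 500.0
    planted_diff_fraction: float = 0.05
    planted_log2fc: float = 2.0
    planted_link_fraction: float = 0.5
    target_link_r: float = 0.99
    motif_rate: float = 1.0
    motif_score_threshold: float = 0.8
    pwm: PWM | None = None
    size_factor_sd: float = 0.1
    input_scale: float = 0.5
    total_depth: int = 20_000_000
    link_fpkm_mean: float = 200.0
    link_fpkm_cv: float = 0.3

    def __post_init__(self) -> None:
        for name in ("planted_diff_fraction", "planted_link_fraction", "motif_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.base_mean <= 0:
            raise ValueError("base_mean must be > 0")
        if self.n_samples_per_group < 2:
            raise ValueError("need at least 2 samples per group")

    @property
    def samples(self) -> list[str]:
        n = self.n_samples_per_group
        return [f"ctrl_{i + 1}" for i in range(n)] + [
            f"flhs_{i + 1}" for i in range(n)
        ]

    @property
    def groups(self) -> dict[str, str]:
        return {
            s: ("control" if s.startswith("ctrl") else "FLHS") for s in self.samples
        }

    def get_pwm(self) -> PWM:
        return self.pwm if self.pwm is not None else default_pwm()


@dataclass
class SimTruth:
    """Planted ground truth: ids exist in the generated data."""

    diff_peaks: dict[str, float] = field(default_factory=dict)   # id -> true log2FC
    diff_genes: dict[str, float] = field(default_factory=dict)
    links: list[tuple[str, str, float]] = field(default_factory=list)
    motif_peaks: set[str] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"kind": "diff_peak", "id": k, "partner": "", "value": v}
            for k, v in sorted(self.diff_peaks.items())
        ]
        rows += [
            {"kind": "diff_gene", "id": k, "partner": "", "value": v}
            for k, v in sorted(self.diff_genes.items())
        ]
        rows += [
            {"kind": "link", "id": p, "partner": g, "value": r}
            for p, g, r in sorted(self.links)
        ]
        rows += [
            {"kind": "motif_peak", "id": k, "partner": "", "value": 1.0}
            for k in sorted(self.motif_peaks)
        ]
        return pd.DataFrame(rows, columns=["kind", "id", "partner", "value"])


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Independent, stable stream per component name."""
    return np.random.default_rng([seed, zlib.crc32(stream.encode())])


def _nb(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB draws with Var = mu + alpha*mu^2 (Poisson when alpha == 0)."""
    mean = np.asarray(mean, dtype=float)
    if alpha == 0:
        return rng.poisson(mean)
    shape = 1.0 / alpha
    return rng.negative_binomial(shape, shape / (shape + mean))


# --------------------------------------------------------------------------
# annotation

def simulate_annotation(config: SimConfig) -> GenomeAnnotation:
    """Non-overlapping genes with 2-6 exons each on random strands.

    Genes are distributed round-robin over chromosomes and packed left to
    right with random gaps; infeasible packing raises with a suggestion
    to enlarge the chromosome.
    """
    rng = _rng(config.seed, "annotation")
    chrom_sizes = {
        f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)
    }
    genes: dict[str, Gene] = {}
    per_chrom = [[] for _ in range(config.n_chroms)]
    for i in range(config.n_genes):
        per_chrom[i % config.n_chroms].append(i)

    for c, gene_idxs in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        n = len(gene_idxs)
        if n == 0:
            continue
        structures = []
        for _ in gene_idxs:
            n_exons = int(rng.integers(2, 7))
            exon_lens = rng.integers(100, 501, size=n_exons)
            intron_lens = rng.integers(200, 2001, size=n_exons - 1)
            structures.append((exon_lens, intron_lens))
        total_span = sum(int(e.sum() + i.sum()) for e, i in structures)
        slack = config.chrom_length - total_span - 20_000
        if slack <= 2_000 * (n + 1):
            raise ValueError(
                f"cannot pack {config.n_genes} genes into "
                f"{config.n_chroms} x {config.chrom_length} bp; "
                "increase chrom_length or reduce n_genes"
            )
        # random gap fractions rescaled to the available slack: spreads
        # genes over the whole chromosome and can never overflow
        raw = rng.random(n)
        gaps = (2_000 + raw / raw.sum() * (slack - 2_000 * (n + 1))).astype(int)
        cursor = 0
        for k, i in enumerate(gene_idxs):
            exon_lens, intron_lens = structures[k]
            span = int(exon_lens.sum() + intron_lens.sum())
            start = cursor + int(gaps[k])
            exons = []
            pos = start
            n_exons = len(exon_lens)
            for j in range(n_exons):
                exons.append((pos, pos + int(exon_lens[j])))
                pos += int(exon_lens[j])
                if j < n_exons - 1:
                    pos += int(intron_lens[j])
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"gene_{i + 1:05d}"
            tid = f"{gid}_t1"
            tx = Transcript(tid, gid, chrom, strand, exons)
            genes[gid] = Gene(gid, chrom, strand, start, start + span, {tid: tx})
            cursor = start + span
    ann = GenomeAnnotation(chrom_sizes, genes)
    ann.validate()
    return ann


# --------------------------------------------------------------------------
# peaks

def simulate_peaks(
    config: SimConfig, annotation: GenomeAnnotation
) -> tuple[list[MergedPeak], dict[str, list[Peak]], SimTruth]:
    """Consensus peak locations plus jittered per-sample peak calls.

    Consensus summits are spaced >= 3 kb apart so that per-sample jitter
    (<= 150 bp) never merges distinct locations under the 1-kb summit
    criterion. A ``planted_diff_fraction`` of locations is marked
    differential, half hyper- and half hypo-acetylated at
    ``planted_log2fc``.
    """
    rng = _rng(config.seed, "peaks")
    truth = SimTruth()
    per_chrom = [[] for _ in range(config.n_chroms)]
    for i in range(config.n_peaks):
        per_chrom[i % config.n_chroms].append(i)

    consensus: list[MergedPeak] = []
    for c, idxs in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        n = len(idxs)
        if n == 0:
            continue
        widths = rng.integers(400, 1_501, size=n)
        slack = config.chrom_length - int(widths.sum()) - 4_000
        if slack <= 3_000 * (n + 1):
            raise ValueError(
                "chromosome too small for requested peak count; "
                "increase chrom_length or reduce n_peaks"
            )
        raw = rng.random(n)
        gaps = (3_000 + raw / raw.sum() * (slack - 3_000 * (n + 1))).astype(int)
        cursor = 0
        for k in range(n):
            width = int(widths[k])
            start = cursor + int(gaps[k])
            end = start + width
            summit = start + int(rng.integers(width // 4, 3 * width // 4 + 1))
            consensus.append(MergedPeak("", chrom, start, end, summit))
            cursor = end
    consensus.sort(key=lambda m: (m.chrom, m.start))
    for i, m in enumerate(consensus, start=1):
        m.id = f"peak_{i:05d}"

    n_diff = int(round(config.n_peaks * config.planted_diff_fraction))
    diff_idx = rng.choice(len(consensus), size=n_diff, replace=False)
    for j, idx in enumerate(sorted(diff_idx)):
        sign = 1.0 if j % 2 == 0 else -1.0
        truth.diff_peaks[consensus[idx].id] = sign * config.planted_log2fc

    peak_sets: dict[str, list[Peak]] = {}
    for sample in config.samples:
        peaks = []
        for m in consensus:
            ds = int(rng.integers(-100, 101))
            de = int(rng.integers(-100, 101))
            dsum = int(rng.integers(-100, 101))
            start = max(0, m.start + ds)
            end = max(start + 50, m.end + de)
            summit = min(max(m.summit + dsum, start), end - 1)
            signal = float(np.round(rng.uniform(1, 50), 3))
            peaks.append(
                Peak(f"{sample}_{m.id}", m.chrom, start, end, summit, sample, signal)
            )
        peak_sets[sample] = peaks
    return consensus, peak_sets, truth


# --------------------------------------------------------------------------
# counts

def simulate_counts(
    config: SimConfig,
    annotation: GenomeAnnotation,
    peaks: list[MergedPeak],
    truth: SimTruth,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.Series]:
    """NB count tables: RNA (genes x samples), ChIP and input (peaks x
    samples), plus the per-sample lognormal depth factors.

    Case-group means of planted features are scaled by
    2^(true log2FC); input counts share each peak's baseline mean
    (scaled by ``input_scale``) without any group effect.
    """
    rng = _rng(config.seed, "counts")
    samples = config.samples
    n = len(samples)
    is_case = np.array([1.0 if config.groups[s] == "FLHS" else 0.0 for s in samples])
    size_fac = np.exp(rng.normal(0.0, config.size_factor_sd, size=n))

    gene_ids = sorted(annotation.genes)
    q = np.exp(rng.normal(np.log(config.base_mean), 0.5, size=len(gene_ids)))
    n_diff_g = int(round(len(gene_ids) * config.planted_diff_fraction))
    diff_gidx = sorted(rng.choice(len(gene_ids), size=n_diff_g, replace=False))
    lfc_g = np.zeros(len(gene_ids))
    for j, idx in enumerate(diff_gidx):
        lfc_g[idx] = (1.0 if j % 2 == 0 else -1.0) * config.planted_log2fc
        truth.diff_genes[gene_ids[idx]] = lfc_g[idx]
    mu_rna = size_fac[None, :] * q[:, None] * 2.0 ** (lfc_g[:, None] * is_case[None, :])
    rna = pd.DataFrame(
        _nb(rng, mu_rna, config.nb_dispersion), index=gene_ids, columns=samples
    )

    peak_ids = [m.id for m in peaks]
    c = np.exp(rng.normal(np.log(config.chip_base_mean), 0.5, size=len(peak_ids)))
    lfc_p = np.array([truth.diff_peaks.get(pid, 0.0) for pid in peak_ids])
    mu_chip = size_fac[None, :] * c[:, None] * 2.0 ** (lfc_p[:, None] * is_case[None, :])
    chip = pd.DataFrame(
        _nb(rng, mu_chip, config.nb_dispersion), index=peak_ids, columns=samples
    )
    mu_input = size_fac[None, :] * (config.input_scale * c)[:, None] * np.ones((1, n))
    inputs = pd.DataFrame(
        _nb(rng, mu_input, config.nb_dispersion), index=peak_ids, columns=samples
    )
    factors = pd.Series(size_fac, index=samples, name="size_factor")
    return rna, chip, inputs, factors


def build_signal_matrix(
    config: SimConfig,
    peaks: list[MergedPeak],
    chip: pd.DataFrame,
    inputs: pd.DataFrame,
    factors: pd.Series,
) -> SignalMatrix:
    """Assemble a SignalMatrix from simulated count tables; total mapped
    read counts are the depth factors scaled to ``total_depth`` so that
    depth normalization removes the planted per-sample scaling."""
    totals = (factors * config.total_depth).round()
    return SignalMatrix(
        peaks=peaks,
        raw_chip=chip,
        raw_input=inputs,
        chip_totals=totals.astype(float),
        input_totals=totals.astype(float),
    )


# --------------------------------------------------------------------------
# links

def simulate_links(
    config: SimConfig,
    normalized_signal: pd.DataFrame,
    peaks: list[MergedPeak],
    annotation: GenomeAnnotation,
    rna: pd.DataFrame,
    truth: SimTruth,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Rewrite the expression of one gene per selected differential peak
    so that its abundance tracks the peak's normalized signal at the
    target Pearson correlation.

    For a planted pair, the standardized gene abundance is
    r * z(signal) + sqrt(1 - r^2) * eps with iid standard normal eps, an
    affine function of the peak signal plus Gaussian noise. Pairs are
    drawn from genes with TSS within ``window`` of the peak summit on the
    same chromosome; differential peaks with no candidate gene are
    skipped with a warning. Returns the adjusted RNA count table.
    """
    rng = _rng(config.seed, "links")
    r = config.target_link_r
    tss_by_chrom = annotation.tss_by_chrom()
    lengths = pd.Series(
        {g.id: g.canonical_transcript().exonic_length for g in annotation.genes.values()}
    )
    lib = rna.sum(axis=0).astype(float)
    rna = rna.copy()

    diff_ids = sorted(truth.diff_peaks)
    n_link = int(round(len(diff_ids) * config.planted_link_fraction))
    chosen = [diff_ids[i] for i in sorted(rng.choice(len(diff_ids), n_link, replace=False))] if n_link else []
    by_id = {m.id: m for m in peaks}
    used_genes = set(truth.diff_genes)

    for pid in chosen:
        m = by_id[pid]
        entries = tss_by_chrom.get(m.chrom, [])
        candidates = [
            gid
            for tss, gid in entries
            if abs(tss - m.summit) <= window and gid not in used_genes
        ]
        if not candidates:
            logger.warning("no candidate gene within %d bp of %s; skipped", window, pid)
            continue
        gid = candidates[int(rng.integers(len(candidates)))]
        used_genes.add(gid)

        x = normalized_signal.loc[pid].values.astype(float)
        if np.ptp(x) == 0:
            logger.warning("constant signal for %s; link skipped", pid)
            continue
        z = (x - x.mean()) / x.std()
        eps = rng.normal(size=x.size)
        eps = (eps - eps.mean()) / eps.std()
        y_z = r * z + np.sqrt(1 - r**2) * eps
        mu, cv = config.link_fpkm_mean, config.link_fpkm_cv
        fpkm_target = np.maximum(mu * (1.0 + cv * y_z), 0.1)
        counts = np.round(
            fpkm_target * (lengths[gid] / 1e3) * (lib.values / 1e6)
        ).astype(int)
        rna.loc[gid] = np.maximum(counts, 0)
        truth.links.append((pid, gid, r))
    return rna


# --------------------------------------------------------------------------
# sequences

def _sample_motif(rng: np.random.Generator, pwm: PWM, rel_threshold: float) -> str:
    """Draw a motif instance from the PWM conditioned on scoring at least
    rel_threshold * max (rejection sampling; consensus as last resort)."""
    lo = pwm.log_odds
    cutoff = rel_threshold * pwm.max_score
    for _ in range(100):
        idx = np.array(
            [rng.choice(4, p=pwm.matrix[i]) for i in range(len(pwm))]
        )
        if lo[np.arange(len(pwm)), idx].sum() >= cutoff:
            return "".join(_BASES[idx])
    return pwm.consensus


def simulate_sequences(
    config: SimConfig, peaks: list[MergedPeak], truth: SimTruth
) -> dict[str, str]:
    """Uniform-random sequence per merged peak; a motif instance is
    embedded at a random position in ``motif_rate`` of the differential
    peaks. Returns id -> sequence."""
    rng = _rng(config.seed, "sequences")
    pwm = config.get_pwm()
    min_len = min((m.length for m in peaks), default=0)
    if peaks and len(pwm) > min_len:
        raise ValueError(
            f"PWM length {len(pwm)} exceeds shortest peak ({min_len} bp)"
        )
    diff_ids = sorted(truth.diff_peaks)
    n_plant = int(round(len(diff_ids) * config.motif_rate))
    planted = (
        {diff_ids[i] for i in rng.choice(len(diff_ids), n_plant, replace=False)}
        if n_plant
        else set()
    )
    seqs: dict[str, str] = {}
    for m in peaks:
        seq = "".join(_BASES[rng.integers(0, 4, size=m.length)])
        if m.id in planted:
            instance = _sample_motif(rng, pwm, config.motif_score_threshold)
            pos = int(rng.integers(0, m.length - len(pwm) + 1))
            seq = seq[:pos] + instance + seq[pos + len(pwm):]
            truth.motif_peaks.add(m.id)
        seqs[m.id] = seq
    return seqs


def simulate_gene_sets(
    config: SimConfig,
    gene_ids: list[str],
    spiked_genes: list[str] | None = None,
    n_sets: int = 20,
    set_size: int = 25,
) -> dict[str, list[str]]:
    """Synthetic gene sets for over-representation analysis: random draws
    from the gene universe, plus one set spiked with the supplied genes
    (e.g. planted link targets) when given."""
    rng = _rng(config.seed, "gene_sets")
    gene_ids = sorted(gene_ids)
    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        k = min(set_size, len(gene_ids))
        members = sorted(rng.choice(gene_ids, size=k, replace=False))
        sets[f"random_set_{i + 1:02d}"] = list(members)
    if spiked_genes:
        spike = sorted(spiked_genes)[:set_size]
        pad = max(0, set_size - len(spike))
        rest = [g for g in gene_ids if g not in set(spike)]
        extra = sorted(rng.choice(rest, size=min(pad, len(rest)), replace=False))
        sets["spiked_set"] = sorted(set(spike) | set(extra))
    return sets


# --------------------------------------------------------------------------
# one-call driver

def simulate_all(config: SimConfig) -> dict:
    """Run every generator stage in order and return a bundle dict with
    keys annotation, consensus_peaks, peak_sets, rna, chip, input,
    factors, signal, truth, sequences, gene_sets."""
    from .chip import normalize_subtract

    ann = simulate_annotation(config)
    consensus, peak_sets, truth = simulate_peaks(config, ann)
    rna, chip_counts, input_counts, factors = simulate_counts(
        config, ann, consensus, truth
    )
    signal = build_signal_matrix(config, consensus, chip_counts, input_counts, factors)
    normalize_subtract(signal)
    rna = simulate_links(config, signal.normalized, consensus, ann, rna, truth)
    seqs = simulate_sequences(config, consensus, truth)
    linked = [g for _, g, _ in truth.links]
    gene_sets = simulate_gene_sets(config, list(ann.genes), spiked_genes=linked)
    return {
        "annotation": ann,
        "consensus_peaks": consensus,
        "peak_sets": peak_sets,
        "rna": rna,
        "chip": chip_counts,
        "input": input_counts,
        "factors": factors,
        "signal": signal,
        "truth": truth,
        "sequences": seqs,
        "gene_sets": gene_sets,
    }
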