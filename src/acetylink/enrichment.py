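"""PWM motif scanning/enrichment and gene-set over-representation.

Motif hits are called by log-odds scoring: each window scores
sum(log2(p_base / background)) on both strands, and a window is a hit when
its score reaches ``rel_threshold`` (default 0.8) times the maximum
achievable score of the matrix. Enrichment of a motif in a target sequence
set against a background set, and over-representation of a query gene list
in annotated gene sets, are both assessed with the one-sided upper-tail
hypergeometric test, with BH correction across gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from Bio import motifs as bio_motifs

from .rnaseq import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "PWM",
    "EnrichmentResult",
    "scan_pwm",
    "motif_enrichment",
    "geneset_enrichment",
    "read_pwms",
    "read_gmt",
    "write_gmt",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}
PROB_CLAMP = 1e-4


@dataclass
class PWM:
    """Position weight matrix: L x 4 base probabilities over A,C,G,T.

    Probabilities are clamped to >= 1e-4 (and renormalized) at
    construction so log-odds scores stay finite. ``background`` defaults
    to uniform 0.25.
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4")
        if self.matrix.shape[0] < 4:
            raise ValueError("PWM must be at least 4 positions long")
        rowsum = self.matrix.sum(axis=1)
        if np.any(np.abs(rowsum - 1) > 1e-6):
            raise ValueError("PWM rows must sum to 1")
        self.matrix = np.clip(self.matrix, PROB_CLAMP, None)
        self.matrix /= self.matrix.sum(axis=1, keepdims=True)
        self.background = np.asarray(self.background, dtype=float)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.matrix / self.background[None, :])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))

    @classmethod
    def from_counts(cls, name: str, counts: np.ndarray, pseudocount: float = 0.0):
        counts = np.asarray(counts, dtype=float) + pseudocount
        return cls(name, counts / counts.sum(axis=1, keepdims=True))


@dataclass
class EnrichmentResult:
    name: str
    overlap: int          # targets (sequences or genes) in the set / with motif
    target_size: int      # size of the query / target collection
    universe_size: int    # pooled sequences or gene universe
    set_size: int         # sequences with motif in universe / gene-set size
    p: float
    padj: float | None = None
    target_fraction: float | None = None


def read_pwms(path) -> list[PWM]:
    """Read JASPAR-style plain-text matrices (via Bio.motifs); count
    matrices are converted to probabilities with a +0.5 pseudocount."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([[m.counts[b][i] for b in _BASES] for i in range(m.length)])
        out.append(PWM.from_counts(m.name or m.matrix_id, counts, pseudocount=0.5))
    return out


def _encode(sequence: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else (N) -> -1."""
    seq = sequence.upper()
    codes = np.full(len(seq), -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return codes


def scan_pwm(
    sequence: str, pwm: PWM, rel_threshold: float = 0.8
) -> list[tuple[int, str, float]]:
    """Scan both strands for motif hits.

    Returns (position, strand, score) tuples, 0-based positions on the
    forward strand. Windows containing a non-ACGT base are skipped.
    Sequences shorter than the motif return an empty list.

    Raises
    ------
    ValueError
        For a zero-information matrix (max achievable score <= 0), which
        cannot define a relative threshold.
    """
    max_score = pwm.max_score
    if max_score <= 0:
        raise ValueError(
            f"PWM {pwm.name!r} is unscannable: zero-information matrix "
            "(max log-odds score <= 0)"
        )
    L = len(pwm)
    codes = _encode(sequence)
    n = codes.size - L + 1
    if n <= 0:
        return []
    lo = pwm.log_odds
    lo_rc = lo[::-1, [_COMPLEMENT[i] for i in range(4)]]
    threshold = rel_threshold * max_score
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (windows >= 0).all(axis=1)
    hits: list[tuple[int, str, float]] = []
    if valid.any():
        idx = np.where(valid)[0]
        w = windows[idx]
        pos_scores = lo[np.arange(L)[None, :], w].sum(axis=1)
        rc_scores = lo_rc[np.arange(L)[None, :], w].sum(axis=1)
        for j, i in enumerate(idx):
            if pos_scores[j] >= threshold:
                hits.append((int(i), "+", float(pos_scores[j])))
            if rc_scores[j] >= threshold:
                hits.append((int(i), "-", float(rc_scores[j])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def _has_hit(seq: str, pwm: PWM, rel_threshold: float) -> bool:
    return bool(scan_pwm(seq, pwm, rel_threshold))


def motif_enrichment(
    target_seqs: dict[str, str],
    background_seqs: dict[str, str],
    pwm: PWM,
    rel_threshold: float = 0.8,
) -> EnrichmentResult:
    """Hypergeometric enrichment of motif-bearing sequences in the target
    set against the pooled target+background collection.

    A sequence counts once regardless of hit multiplicity. p is the
    one-sided upper-tail probability of drawing at least the observed
    number of motif-bearing sequences when sampling |targets| sequences
    from the pool.
    """
    if not target_seqs:
        raise ValueError("empty target sequence set")
    if not background_seqs:
        raise ValueError("empty background sequence set")
    t_hits = sum(_has_hit(s, pwm, rel_threshold) for s in target_seqs.values())
    b_hits = sum(_has_hit(s, pwm, rel_threshold) for s in background_seqs.values())
    n_t, n_b = len(target_seqs), len(background_seqs)
    N, K, n, k = n_t + n_b, t_hits + b_hits, n_t, t_hits
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(
        name=pwm.name,
        overlap=k,
        target_size=n_t,
        universe_size=N,
        set_size=K,
        p=p,
        target_fraction=k / n_t,
    )


def geneset_enrichment(
    query_genes,
    universe_genes,
    gene_sets: dict[str, list[str]],
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of a query gene list in each
    gene set, BH-adjusted across sets and sorted by p.

    Query genes outside the universe are dropped with a log message; gene
    sets are intersected with the universe.
    """
    universe = set(universe_genes)
    if not universe:
        raise ValueError("empty gene universe")
    query = set(query_genes)
    stray = query - universe
    if stray:
        logger.warning(
            "geneset_enrichment: %d query genes outside the universe dropped",
            len(stray),
        )
        query &= universe
    N, n = len(universe), len(query)
    results = []
    for name, members in gene_sets.items():
        in_universe = set(members) & universe
        K = len(in_universe)
        k = len(in_universe & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(
            EnrichmentResult(
                name=name,
                overlap=k,
                target_size=n,
                universe_size=N,
                set_size=K,
                p=p,
                target_fraction=(k / n) if n else 0.0,
            )
        )
    padj = bh_adjust([r.p for r in results]) if results else []
    for r, q in zip(results, padj):
        r.padj = float(q)
    results.sort(key=lambda r: (r.p, r.name))
    return results


def read_gmt(path) -> dict[str, list[str]]:
    """Read GMT: one set per line — name, description, member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            fh.write("\t".join([name, description, *gene_sets[name]]) + "\n")
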