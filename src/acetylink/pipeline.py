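"""End-to-end orchestration: simulate or load inputs, run every analysis
stage in order, and write a reproducible TSV report bundle.

Stage order: expression filter -> differential expression -> peak merge ->
quantification -> normalization/input subtraction -> differential
acetylation -> peak classification -> peak-gene linking -> distance decay
-> top target genes -> motif and gene-set enrichment. All stage outputs
are plain TSV with stable column order; a manifest records the config
hash and library versions so reruns can be diffed byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chip import (
    MergedPeak,
    SignalMatrix,
    differential_acetylation,
    merge_peaks,
    normalize_subtract,
)
from .enrichment import geneset_enrichment, motif_enrichment, read_gmt
from .genome import (
    GenomeAnnotation,
    classify_feature,
    classify_proximal_distal,
    parse_annotation,
    read_narrowpeak,
    write_gtf,
    write_narrowpeak,
)
from .linking import (
    candidate_pairs,
    distance_decay,
    links_to_frame,
    select_links,
    top_peak_genes,
)
from .rnaseq import CountMatrix, NBTestParams, filter_low_expression, fpkm, nb_wald_test
from .simulate import SimConfig, simulate_all

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run", "load_config"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclass
class Thresholds:
    """Stage thresholds; defaults are the study's published rules."""

    merge_summit_dist: int = 1000     # bp between summits (strictly less merges)
    proximal_bp: int = 1000           # TSS distance for proximal peaks
    link_window: int = 1_000_000      # candidate pair window, bp
    link_r_min: float = 0.8
    link_p_max: float = 0.01
    de_padj: float = 0.05             # RNA rule: adjusted p
    peak_p: float = 0.05              # peak rule: raw p
    lfc: float = 1.0                  # |log2FC| for both stages
    top_k: int = 100
    min_count: int = 2
    sample_frac: float = 0.9
    motif_rel_threshold: float = 0.8

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class PipelineConfig:
    outdir: str = "acetylink_out"
    seed: int = 0
    simulate: SimConfig | None = None
    inputs: dict = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)
    thresholds: Thresholds = field(default_factory=Thresholds)

    def validate(self, samples: list[str]) -> None:
        missing = [s for s in samples if s not in self.groups]
        if missing:
            raise PipelineError(
                f"config validation: samples without group label: {missing}"
            )


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline config (documented schema in README)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    thresholds = Thresholds(**raw.get("thresholds", {}))
    sim = None
    if raw.get("mode", "simulate") == "simulate" or "simulate" in raw:
        sim_kwargs = dict(raw.get("simulate", {}))
        sim_kwargs.setdefault("seed", raw.get("seed", 0))
        sim = SimConfig(**sim_kwargs)
    cfg = PipelineConfig(
        outdir=raw.get("outdir", "acetylink_out"),
        seed=raw.get("seed", 0),
        simulate=sim,
        inputs=raw.get("inputs", {}),
        groups=raw.get("groups", {}),
        thresholds=thresholds,
    )
    return cfg


def _config_hash(config: PipelineConfig) -> str:
    # outdir is a location, not an analysis parameter: excluded so the
    # same analysis hashes identically wherever it is written
    payload = {
        "seed": config.seed,
        "simulate": asdict(config.simulate) if config.simulate else None,
        "inputs": config.inputs,
        "groups": config.groups,
        "thresholds": asdict(config.thresholds),
    }
    if payload["simulate"] and payload["simulate"].get("pwm") is not None:
        pwm = payload["simulate"]["pwm"]
        payload["simulate"]["pwm"] = {
            "name": pwm["name"],
            "matrix": np.asarray(pwm["matrix"]).tolist(),
        }
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)


def _match_counts_to_merged(
    merged: list[MergedPeak], consensus: list[MergedPeak], tables: list[pd.DataFrame]
) -> list[pd.DataFrame]:
    """Re-index consensus-peak count tables onto merged-peak ids by
    interval overlap (the simulated per-sample calls jitter around each
    consensus location, so the mapping is 1-1)."""
    by_chrom: dict[str, list[MergedPeak]] = {}
    for cpk in consensus:
        by_chrom.setdefault(cpk.chrom, []).append(cpk)
    mapping: dict[str, str] = {}
    for m in merged:
        best, best_ov = None, 0
        for cpk in by_chrom.get(m.chrom, []):
            ov = min(m.end, cpk.end) - max(m.start, cpk.start)
            if ov > best_ov:
                best, best_ov = cpk, ov
        if best is None:
            raise PipelineError(f"merged peak {m.id} matches no consensus location")
        mapping[m.id] = best.id
    out = []
    for t in tables:
        rows = t.loc[[mapping[m.id] for m in merged]].copy()
        rows.index = [m.id for m in merged]
        out.append(rows)
    return mapping, out


def run(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns a dict of in-memory results and
    writes the report bundle under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    results: dict = {}
    t0 = time.time()

    def stage(name):
        logger.info("[%7.2fs] stage: %s", time.time() - t0, name)

    # ---- inputs -----------------------------------------------------
    stage("inputs")
    try:
        if config.simulate is not None:
            sim = simulate_all(config.simulate)
            ann: GenomeAnnotation = sim["annotation"]
            peak_sets = sim["peak_sets"]
            rna_counts = sim["rna"]
            groups = config.groups or config.simulate.groups
            sequences = sim["sequences"]
            gene_sets = sim["gene_sets"]
            results["truth"] = sim["truth"]
            write_gtf(ann, outdir / "annotation.gtf")
            sim["truth"].to_frame().pipe(_write_tsv, outdir / "truth.tsv")
        else:
            inp = config.inputs
            ann = parse_annotation(inp["gtf"])
            peak_sets = {
                s: read_narrowpeak(p, sample=s) for s, p in inp["peaks"].items()
            }
            rna_counts = pd.read_csv(inp["rna_counts"], sep="\t", index_col=0)
            groups = config.groups
            sequences = None
            if inp.get("sequences"):
                from Bio import SeqIO

                sequences = {
                    rec.id: str(rec.seq)
                    for rec in SeqIO.parse(inp["sequences"], "fasta")
                }
            gene_sets = read_gmt(inp["gene_sets"]) if inp.get("gene_sets") else None
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'inputs' failed: {exc}") from exc

    samples = list(rna_counts.columns)
    cfg_for_validation = PipelineConfig(
        outdir=config.outdir, seed=config.seed, groups=groups,
        thresholds=config.thresholds,
    )
    cfg_for_validation.validate(samples)

    # ---- RNA differential expression --------------------------------
    stage("rnaseq")
    try:
        lengths = pd.Series(
            {g.id: g.canonical_transcript().exonic_length for g in ann.genes.values()}
        )
        cm = CountMatrix(rna_counts, groups, lengths)
        cm = filter_low_expression(cm, th.min_count, th.sample_frac)
        de_params = NBTestParams(
            padj_threshold=th.de_padj, lfc_threshold=th.lfc, use_adjusted_p=True
        )
        rna_res = nb_wald_test(cm, de_params)
        abundance = fpkm(cm)
        _write_tsv(rna_res, outdir / "rna_diff.tsv", index_label="feature")
        _write_tsv(abundance, outdir / "fpkm.tsv", index_label="feature")
    except Exception as exc:
        raise PipelineError(f"stage 'rnaseq' failed: {exc}") from exc

    # ---- ChIP merge + quantify + differential ------------------------
    stage("chip")
    try:
        merged = merge_peaks(peak_sets, th.merge_summit_dist)
        write_narrowpeak([m.as_peak() for m in merged], outdir / "merged_peaks.narrowPeak")
        if config.simulate is not None:
            mapping, (chip_t, input_t) = _match_counts_to_merged(
                merged, sim["consensus_peaks"], [sim["chip"], sim["input"]]
            )
            totals = (sim["factors"] * config.simulate.total_depth).round().astype(float)
            signal = SignalMatrix(
                peaks=merged,
                raw_chip=chip_t,
                raw_input=input_t,
                chip_totals=totals,
                input_totals=totals,
            )
            # sequences were generated under consensus ids; re-key to merged
            if sequences:
                sequences = {mid: sequences[cid] for mid, cid in mapping.items()}
            results["peak_id_map"] = mapping
        else:
            from .chip import quantify, read_bed_reads

            inp = config.inputs
            chip_reads = {s: read_bed_reads(p) for s, p in inp["chip_reads"].items()}
            input_reads = {s: read_bed_reads(p) for s, p in inp["input_reads"].items()}
            totals_df = (
                pd.read_csv(inp["totals"], sep="\t", index_col=0)
                if inp.get("totals")
                else None
            )
            signal = quantify(
                chip_reads,
                merged,
                input_reads,
                chip_totals=(
                    totals_df["chip_total"].to_dict() if totals_df is not None else None
                ),
                input_totals=(
                    totals_df["input_total"].to_dict() if totals_df is not None else None
                ),
            )
        normalize_subtract(signal)
        peak_params = NBTestParams(
            padj_threshold=th.peak_p, lfc_threshold=th.lfc, use_adjusted_p=False
        )
        peak_res = differential_acetylation(signal, groups, peak_params)
        _write_tsv(signal.raw_chip, outdir / "signal_raw_chip.tsv", index_label="peak")
        _write_tsv(signal.normalized, outdir / "signal_normalized.tsv", index_label="peak")
        _write_tsv(peak_res, outdir / "peak_diff.tsv", index_label="peak")
    except Exception as exc:
        raise PipelineError(f"stage 'chip' failed: {exc}") from exc

    # ---- peak classification ----------------------------------------
    stage("classify")
    try:
        rows = []
        for m in merged:
            p = m.as_peak()
            label = classify_feature(p, ann, th.proximal_bp)
            rows.append(
                {
                    "peak": m.id,
                    "proximal_distal": classify_proximal_distal(p, ann, th.proximal_bp),
                    "feature": label.kind,
                    "intron_ordinal": label.intron_ordinal or "",
                }
            )
        classes = pd.DataFrame(rows)
        _write_tsv(classes, outdir / "peak_classes.tsv")
    except Exception as exc:
        raise PipelineError(f"stage 'classify' failed: {exc}") from exc

    # ---- linking -----------------------------------------------------
    stage("linking")
    try:
        diff_mask = peak_res["label"] != "ns"
        diff_peaks = [m.as_peak() for m in merged if diff_mask.loc[m.id]]
        pairs = candidate_pairs(diff_peaks, ann, th.link_window)
        links = select_links(
            pairs,
            signal.normalized,
            abundance,
            th.link_r_min,
            th.link_p_max,
            peak_directions=peak_res["label"],
        )
        link_df = links_to_frame(links)
        decay = distance_decay(links, max_dist=th.link_window)
        tops = top_peak_genes(links, th.top_k)
        _write_tsv(link_df, outdir / "links.tsv")
        _write_tsv(decay, outdir / "distance_decay.tsv")
        for direction, lst in tops.items():
            _write_tsv(links_to_frame(lst), outdir / f"top_genes_{direction}.tsv")
    except Exception as exc:
        raise PipelineError(f"stage 'linking' failed: {exc}") from exc

    # ---- enrichment --------------------------------------------------
    stage("enrichment")
    motif_df = pd.DataFrame(
        columns=["motif", "p", "q", "targets_with_motif", "pct_targets"]
    )
    gs_df = pd.DataFrame(columns=["set", "overlap", "set_size", "p", "padj"])
    try:
        if sequences:
            target = {m.id: sequences[m.id] for m in merged if diff_mask.loc[m.id]}
            background = {
                m.id: sequences[m.id] for m in merged if not diff_mask.loc[m.id]
            }
            pwms = []
            if config.simulate is not None:
                pwms = [config.simulate.get_pwm()]
            elif config.inputs.get("pwms"):
                from .enrichment import read_pwms

                pwms = read_pwms(config.inputs["pwms"])
            recs = []
            for pwm in pwms:
                if target and background:
                    r = motif_enrichment(target, background, pwm, th.motif_rel_threshold)
                    recs.append(
                        {
                            "motif": r.name,
                            "p": r.p,
                            "q": r.p,  # single-motif runs: q == p
                            "targets_with_motif": r.overlap,
                            "pct_targets": 100.0 * (r.target_fraction or 0.0),
                        }
                    )
            if recs:
                from .rnaseq import bh_adjust

                motif_df = pd.DataFrame(recs)
                motif_df["q"] = bh_adjust(motif_df["p"].values)
        if gene_sets:
            query = sorted(
                {l.gene_id for lst in tops.values() for l in lst}
            )
            universe = sorted(cm.counts.index)
            gs = geneset_enrichment(query, universe, gene_sets)
            gs_df = pd.DataFrame(
                [
                    {
                        "set": r.name,
                        "overlap": r.overlap,
                        "set_size": r.set_size,
                        "p": r.p,
                        "padj": r.padj,
                    }
                    for r in gs
                ]
            )
        _write_tsv(motif_df, outdir / "motif_enrichment.tsv")
        _write_tsv(gs_df, outdir / "geneset_enrichment.tsv")
    except Exception as exc:
        raise PipelineError(f"stage 'enrichment' failed: {exc}") from exc

    # ---- summary + manifest ------------------------------------------
    stage("summary")
    summary = pd.DataFrame(
        [
            {"metric": "n_genes_tested", "value": int(len(rna_res))},
            {"metric": "n_deg", "value": int((rna_res["direction"] != "ns").sum())},
            {"metric": "n_deg_up", "value": int((rna_res["direction"] == "up").sum())},
            {"metric": "n_deg_down", "value": int((rna_res["direction"] == "down").sum())},
            {"metric": "n_merged_peaks", "value": int(len(merged))},
            {"metric": "n_diff_peaks", "value": int((peak_res["label"] != "ns").sum())},
            {"metric": "n_hyper", "value": int((peak_res["label"] == "hyper").sum())},
            {"metric": "n_hypo", "value": int((peak_res["label"] == "hypo").sum())},
            {"metric": "n_proximal", "value": int((classes["proximal_distal"] == "proximal").sum())},
            {"metric": "n_distal", "value": int((classes["proximal_distal"] == "distal").sum())},
            {"metric": "n_links", "value": int(len(link_df))},
            {"metric": "n_links_positive", "value": int((link_df["sign"] == "positive").sum())},
            {"metric": "n_links_negative", "value": int((link_df["sign"] == "negative").sum())},
            {
                "metric": "mean_link_distance_kb",
                "value": float(np.round(link_df["distance"].mean() / 1e3, 3))
                if len(link_df)
                else 0.0,
            },
            {
                "metric": "top_geneset",
                "value": gs_df.iloc[0]["set"] if len(gs_df) else "",
            },
        ]
    )
    _write_tsv(summary, outdir / "summary.tsv")

    manifest = {
        "acetylink_version": __version__,
        "config_sha256": _config_hash(config),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    results.update(
        annotation=ann,
        merged_peaks=merged,
        rna_diff=rna_res,
        fpkm=abundance,
        signal=signal,
        peak_diff=peak_res,
        peak_classes=classes,
        links=links,
        link_table=link_df,
        distance_decay=decay,
        top_genes=tops,
        motif_enrichment=motif_df,
        geneset_enrichment=gs_df,
        summary=summary,
    )
    return results
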