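"""Generate a synthetic two-group H3K27ac + RNA-seq study.

Builds a toy genome (2 chromosomes, 400 genes), 600 consensus peaks with
per-sample jittered calls for 3 control and 3 case libraries, NB count
tables for RNA, ChIP and input, planted differential features, planted
peak-gene links and motif-bearing peak sequences.
"""

from acetylink.simulate import SimConfig, simulate_all

cfg = SimConfig(seed=42)
bundle = simulate_all(cfg)
truth = bundle["truth"]

print(f"samples               : {', '.join(cfg.samples)}")
print(f"genes / peaks         : {len(bundle['annotation'].genes)} / "
      f"{len(bundle['consensus_peaks'])}")
print(f"planted diff genes    : {len(truth.diff_genes)} at |log2FC| = "
      f"{cfg.planted_log2fc}")
print(f"planted diff peaks    : {len(truth.diff_peaks)}")
print(f"planted peak-gene links: {len(truth.links)} at target r = "
      f"{cfg.target_link_r}")
print(f"motif-bearing peaks   : {len(truth.motif_peaks)}")
print()
print("RNA counts (first 3 genes):")
print(bundle["rna"].head(3).to_string())
# Counts are NB-distributed with variance mu + alpha*mu^2 (alpha = 0.05)
# and lognormal per-sample depth factors, mimicking replicate libraries.
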